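# Methods

## The particle model

The package models a phospholipid nanodisc: a patch of POPC bilayer
encircled by two copies of the membrane scaffold protein MSP1E3D1. The
scattering body has three homogeneous regions sharing one elliptical
cross-section:

- a hydrophobic slab of the acyl chains (height `h_tail`),
- two headgroup layers realized as the difference between the full
  bilayer slab (height `h_total`) and the tail slab,
- a protein belt: the difference of two coaxial elliptical cylinders of
  constant radial thickness `T` and height `H_belt`.

All body dimensions derive from a small parameter vector by volume
bookkeeping:

```
A_core = N·A_head/2                  core ellipse area (two leaflets)
a = √(A_core·ε/π),  b = √(A_core/(ε·π))
h_tail = 2(v_lipid − v_head)/A_head
h_head = v_head/A_head,  h_total = h_tail + 2·h_head
v_belt = π·H_belt·[(a+T)(b+T) − ab],  v_MSP = v_belt/2
d_max  = √[(2(a+T))² + h_total²]
```

with `N` the number-weighted mean lipids per disc, `A_head` the area per
lipid headgroup, `ε = a/b ≥ 1` the axis ratio, `v_lipid`/`v_head` the
POPC and headgroup partial specific volumes.

The scattering amplitude of each body is the elliptical-cylinder form
factor `Ψ(u,w) = [2J₁(u)/u]·[sin w/w]` with `u = qR(φ)sinα`,
`R(φ) = √(a²sin²φ + b²cos²φ)`, `w = q(H/2)cosα`. The absolute-scale
intensity is

```
I(q) = scale · n_d · ⟨⟨|Σᵢ Δρᵢ Vᵢ Ψᵢ|²⟩_orient⟩_N + background   [cm⁻¹]
```

Key assumptions: homogeneous region densities (no atomistic detail), no
inter-particle structure factor (dilute limit), polydispersity carried
entirely by a Gaussian distribution of the lipid count `N` (truncated at
N ≥ 2), and no instrument resolution smearing by default (an optional
Gaussian q-smearing hook exists for SANS).

## Contrasts

X-ray scattering length densities are electron counts times the Thomson
length over the region volume; neutron densities come from Sears
coherent lengths with labile hydrogens exchanged against solvent
deuterium (`n_exch · exchange_fraction · d2o_fraction` H→D). Defaults:

| quantity | default | why |
|---|---|---|
| POPC head C₁₀H₁₈NO₈P | 319 Å³ | standard PC headgroup volume; head+tail = 1280 Å³, the refined POPC volume |
| POPC tail C₃₂H₆₄ | `v_lipid` − 319 Å³ | floats with the fitted lipid volume |
| MSP belt | average amino-acid residue composition scaled to the belt volume | the MSP1E3D1(−) sequence is not bundled; generic protein densities (ρ_x ≈ 12.4·10⁻⁶ Å⁻²) are accurate to a few % |
| exchange fraction | 0.9 | common value for solvent-exposed protein |
| D2O fraction (SANS) | 1.0 | buffer exchanged into D2O; exposed as a parameter |

Because the average-residue composition scales linearly with volume, the
belt density is volume-independent; only the tail density varies during
fitting.

## Canonical parameter sets

Two bundled states: unmodified disc (N=188, A_head=70.3 Å², T=9.8 Å,
v_lipid=1280 Å³) and DOTA-conjugated disc (N=247, A_head=61.6 Å²,
T=8.9 Å, v_lipid=1280 Å³). The belt height is 24 Å (two stacked
amphipathic helices) — the value under which those quadruples are
mutually consistent with the refined per-MSP volumes (37900/36800 Å³)
through the belt-volume identity. The axis ratios are not separately
determinable from the quadruples; they are fixed once at ε = 1.354
(unmodified; reproduces 37900 Å³ essentially exactly and gives
d_max = 131.5 Å) and ε = 1.35 (DOTA; v_MSP within 1.2%, d_max = 138.6 Å).
Lipid-count polydispersity is not reported for these preparations;
σ_N is set to 8% of the mean, typical of reconstituted discs. The
default number density 1.3·10¹⁶ cm⁻³ corresponds to ≈4 mg/ml.

## Numerical choices

- **Orientation average**: Gauss–Legendre quadrature over the
  symmetry-reduced octant, with the substitution μ = cos α absorbing the
  solid-angle weight. Default order 64×64 (≲10⁻¹³ relative error vs a
  256×128 reference on the canonical geometry for q ≤ 0.45 Å⁻¹).
- **Polydispersity**: 10-node Gauss–Legendre over N ± 3σ_N weighted by
  the Gaussian density, geometry re-derived per node.
- **Joint refinement**: bounded trust-region-reflective least squares on
  σ-weighted residuals. The structural vector is (N, A_core, ε, T,
  v_lipid, σ_N) plus per-curve scale and background; A_head is reported
  as 2·A_core/N, which avoids the A_head↔N circularity while matching
  the convention of quoting an area per headgroup. v_head stays fixed
  (the head/tail split is not identifiable from two contrasts).
  ε ≥ 1 breaks the ε ↔ 1/ε degeneracy.
- **Multi-start strategy**: each start first minimizes log-intensity
  residuals (the linear χ² surface traps optimizers on misaligned
  form-factor fringes; the log surface does not), then σ-weighted χ².
  Starts are log-uniform ±20% perturbations of the initial vector and
  are consumed lazily: the search stops once a start reaches reduced
  χ² ≤ 2. The search runs at reduced cost (quadrature 24×12, 5
  polydispersity nodes — both verified ≪ the 1% noise level); the best
  solution is then polished at 48×24/10 nodes, whose Jacobian provides
  the covariance (scaled by reduced χ²). Parameters within 10⁻⁶ of a
  bound are flagged.
- **IFT**: sine (Moore) basis `p(r) = Σ cₖ sin(kπr/d_max)` — exact
  endpoint zeros, diagonal roughness penalty `Σ cₖ²(kπ/d)⁴·d/2`. The
  number of basis functions defaults to the Shannon number
  `⌈q_max·d_max/π⌉ + 4`. The regularization weight is the largest α
  whose χ² stays within 10% of the best over a fixed log grid — a
  discrepancy-principle variant chosen over L-curve curvature detection,
  which proved unstable on noise-free synthetic curves (the curvature
  maximum can lock onto the over-smoothed branch). Uncertainties on
  p(r) by linear propagation through the regularized normal equations.
- **Dmax scan**: smallest candidate whose reduced χ² is within 5% of
  the scan minimum *plus one SD of the reduced-χ² statistic, √(2/n)* —
  without the absolute term the rule is ill-posed when χ² sits at the
  numerical floor — and whose p(r) has no negative lobe exceeding 5% of
  max|p| in the outer quarter of r. If nothing qualifies, or the best
  χ² exceeds 5 (grid missing the true dimension), the argmin is
  returned flagged.
- **Segment merging**: the high-q SANS segment is scaled by log-space
  least squares over the overlap (intensities span decades); exact
  duplicate q values are inverse-variance averaged.
- **Biexponential clearance**: bounded least squares, six seeded starts,
  phases ordered k₁ > k₂ after fitting; flagged monophasic when the
  slow amplitude is indistinguishable from zero or the rates from each
  other (|k₁−k₂| < 5% k₁).

## The synthetic-data generator

Generators stand in for undeposited beamline, SEC and PET data:

- **Scattering curves**: `I_noisy = I·(1 + 0.01·Z) + 10⁻⁴·Z′` cm⁻¹ by
  default (1% multiplicative noise, small additive floor), with σ set to
  the true per-point SD. SAXS covers 0.01–0.45 Å⁻¹ (100 log points);
  SANS is generated as two detector-distance segments (0.005–0.05 and
  0.03–0.30 Å⁻¹) that are merged by the same code path real two-setting
  data go through.
- **SEC radio-chromatograms**: two Gaussians (intact at 6.4 ml,
  degradation product at 8.6 ml), areas split by the declared intact
  fraction, Poisson counting noise, flat background subtracted and
  normalized to total counts.
- **Biodistribution**: per-organ biexponential %ID/g kinetics with
  Gaussian per-animal noise (10%, n = 10). The default blood parameters
  (A=9.0, k₁=0.35 h⁻¹, B=3.5, k₂=0.02 h⁻¹) bracket a 9.6 → 1.3 %ID/g
  trajectory between 1 h and 48 h; the tumor curve plateaus near
  4 %ID/g and muscle near 0.3 %ID/g (tumor-to-muscle ≈ 13).

What the generators deliberately do not emulate: instrument resolution
smearing, inter-particle interference, radiation damage, detector dead
time, SEC peak tailing, partial-volume effects in PET. Passing the
recovery tests therefore demonstrates the estimator is unbiased and
well-calibrated *under the model's own assumptions with realistic noise*,
not that those assumptions hold for any particular beamline dataset.

## Validation design

Raw data for this kind of study are typically not deposited, so
correctness rests on three legs:

1. **Independent oracles.** The quadrature intensity is checked against
   a Debye pair-sum over a ≤5000-bead discretization of the same body —
   a route that never touches Bessel functions or an explicit
   orientation average. The beads are tensor-product Gauss nodes per
   region (sinc(q·d) is analytic in the squared distance, so the pair
   sum converges spectrally); agreement is ≲0.2% for q ≤ 0.25 Å⁻¹ on
   both probes, within a 2% assertion. The circular limit is checked
   against a separately coded circular-cylinder average, and the IFT
   against the closed-form sphere p(r).
2. **Parameter recovery.** Twenty seeded replicates per disc state:
   simulate a SAXS+SANS pair at 1% noise, perturb all structural
   parameters ±20%, refit, and require the refined belt thickness,
   headgroup area and lipid count to sit within 3 estimated SDs of the
   generating values in ≥18/20 replicates (this checks calibration of
   the reported uncertainties, not just bias; replicates that fail to
   reach reduced χ² < 10 count as failures).
3. **Internal consistency.** The derived-geometry chain reproduces the
   canonical per-MSP volumes and the ≈130 Å maximum dimension.

Problem sizes (20 replicates, 100+100-point curves, search orders above)
were chosen so the full validation runs in minutes on a single core
while leaving the statistical conclusions unchanged at larger settings.

## Known limitations

- The MSP is modelled by average amino-acid composition, not its
  sequence; supply a real `Component` for sequence-level contrasts.
- Polydispersity in N only; shape (ε) polydispersity is not modelled.
- The IFT reports p(r) in back-transform-consistent units (I in cm⁻¹);
  no normalization convention is imposed.
- The biexponential clearance model is descriptive, not a physiological
  compartment model; rate constants are validated purely by recovery on
  synthetic data.
- Fitting two samples (unmodified and DOTA) shares no parameters; each
  dataset is refined independently.
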