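"""Forward scattering model of an MSP-belted phospholipid nanodisc.

The particle is an elliptical lipid-bilayer disc (hydrophobic acyl-chain
slab sandwiched between two headgroup layers, all sharing one ellipse
cross-section) wrapped by an elliptical-annulus protein belt of constant
thickness. Each body contributes Δρ·V·Ψ(q, α, φ) to the scattering
amplitude, where Ψ is the normalized elliptical-cylinder amplitude

    Ψ(u, w) = [2 J₁(u)/u] · [sin(w)/w],
    u = q R(φ) sin α,  R(φ) = √(a² sin²φ + b² cos²φ),  w = q (H/2) cos α,

and the intensity is the orientation average of |F|² followed by a
number-weighted average over a Gaussian distribution of lipids per disc:

    I(q) = scale · n_d · ⟨⟨|F(q)|²⟩_orient⟩_N + background   [cm⁻¹].

The headgroup region is realized as the difference of two coaxial slabs
(full bilayer height minus tail slab) and the belt as the difference of
two coaxial elliptical cylinders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import j1

from .constants import ANGSTROM2_TO_CM2
from .contrast import ContrastSet

__all__ = ["DiscParameters", "DiscGeometry", "derive_geometry", "form_amplitude", "intensity"]


@dataclass(frozen=True)
class DiscParameters:
    """Fit parameter vector of the nanodisc model.

    Attributes
    ----------
    n_lipid : float
        Number-weighted mean POPC molecules per disc.
    area_per_headgroup : float
        A_head, Å²; the bilayer core area is n_lipid · A_head / 2
        (two leaflets).
    belt_thickness : float
        Radial thickness T of the protein belt, Å.
    belt_height : float
        Axial height of the belt, Å (two stacked amphipathic helices,
        default 24 Å, independent of the bilayer height).
    axis_ratio : float
        ε = a/b ≥ 1 of the elliptical cross-section.
    sigma_n : float
        Gaussian SD of the lipid-count distribution (0 = monodisperse).
    v_lipid, v_head : float
        POPC partial specific volume and headgroup volume, Å³; the tail
        volume is v_lipid − v_head.
    scale, background : float
        Per-curve intensity factor (dimensionless) and flat incoherent
        background (cm⁻¹).
    number_density : float
        Discs per cm³ of sample.
    """

    n_lipid: float
    area_per_headgroup: float
    belt_thickness: float
    axis_ratio: float = 1.0
    sigma_n: float = 0.0
    belt_height: float = 24.0
    v_lipid: float = 1280.0
    v_head: float = 319.0
    scale: float = 1.0
    background: float = 0.0
    number_density: float = 1.3e16

    def __post_init__(self) -> None:
        if self.n_lipid < 2:
            raise ValueError("n_lipid must be >= 2")
        if self.axis_ratio < 1:
            raise ValueError("axis_ratio must be >= 1 (ellipse degeneracy convention)")
        if self.sigma_n < 0:
            raise ValueError("sigma_n must be >= 0")
        for name in ("area_per_headgroup", "belt_thickness", "belt_height", "v_lipid", "v_head"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.v_head >= self.v_lipid:
            raise ValueError("v_head must be smaller than v_lipid")

    def replace(self, **kw) -> "DiscParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class DiscGeometry:
    """Derived body dimensions of one disc (monodisperse snapshot)."""

    a: float  # core ellipse semi-major axis, Å
    b: float  # core ellipse semi-minor axis, Å
    h_tail: float  # hydrophobic slab height, Å
    h_head: float  # one headgroup layer height, Å
    h_total: float  # full bilayer height, Å
    belt_thickness: float  # T, Å
    belt_height: float  # H_belt, Å
    v_belt: float  # belt volume, Å³
    v_msp: float  # per-protein volume = v_belt / 2 (two MSPs per disc), Å³
    d_max_geom: float  # maximum interatomic distance of the body, Å


def derive_geometry(params: DiscParameters) -> DiscGeometry:
    """Derive all body dimensions from the parameter vector.

    The core ellipse area is fixed by lipid count and headgroup area
    (A_core = N·A_head/2); the slab heights follow from volume
    conservation (h_tail = 2(v_lipid − v_head)/A_head, h_head =
    v_head/A_head), and the per-MSP volume is half the belt annulus
    volume since two scaffold proteins wrap each disc.
    """
    a_core = params.n_lipid * params.area_per_headgroup / 2.0
    eps = params.axis_ratio
    a = np.sqrt(a_core * eps / np.pi)
    b = np.sqrt(a_core / (eps * np.pi))
    h_tail = 2.0 * (params.v_lipid - params.v_head) / params.area_per_headgroup
    h_head = params.v_head / params.area_per_headgroup
    h_total = h_tail + 2.0 * h_head
    T = params.belt_thickness
    v_belt = np.pi * params.belt_height * ((a + T) * (b + T) - a * b)
    d_max = np.hypot(2.0 * (a + T), max(h_total, params.belt_height))
    return DiscGeometry(
        a=float(a),
        b=float(b),
        h_tail=float(h_tail),
        h_head=float(h_head),
        h_total=float(h_total),
        belt_thickness=float(T),
        belt_height=float(params.belt_height),
        v_belt=float(v_belt),
        v_msp=float(v_belt / 2.0),
        d_max_geom=float(d_max),
    )


def _psi_radial(u: np.ndarray) -> np.ndarray:
    """2 J₁(u)/u with the analytic u→0 limit (→1)."""
    out = np.ones_like(u)
    nz = u != 0
    out[nz] = 2.0 * j1(u[nz]) / u[nz]
    return out


def _sinc(w: np.ndarray) -> np.ndarray:
    """sin(w)/w with the w→0 limit; np.sinc uses the π convention."""
    return np.sinc(w / np.pi)


def form_amplitude(
    q: float | np.ndarray,
    alpha: float | np.ndarray,
    phi: float | np.ndarray,
    geometry: DiscGeometry,
    contrasts: ContrastSet,
) -> np.ndarray:
    """Scattering amplitude F(q, α, φ) of one disc orientation, Å.

    α is the angle between the disc normal and q, φ the azimuth of q in
    the disc plane; broadcasting over the three inputs follows numpy
    rules. At q = 0 this reduces to Σ Δρᵢ Vᵢ.
    """
    q, alpha, phi = np.broadcast_arrays(
        np.asarray(q, float), np.asarray(alpha, float), np.asarray(phi, float)
    )
    g = geometry
    sin_a, cos_a = np.sin(alpha), np.cos(alpha)
    r_core = np.sqrt(g.a**2 * np.sin(phi) ** 2 + g.b**2 * np.cos(phi) ** 2)
    ao, bo = g.a + g.belt_thickness, g.b + g.belt_thickness
    r_out = np.sqrt(ao**2 * np.sin(phi) ** 2 + bo**2 * np.cos(phi) ** 2)

    psi_core = _psi_radial(q * r_core * sin_a)
    psi_out = _psi_radial(q * r_out * sin_a)

    area_core = np.pi * g.a * g.b
    v_tail = area_core * g.h_tail
    v_tot = area_core * g.h_total
    v_out = np.pi * ao * bo * g.belt_height
    v_in = area_core * g.belt_height

    amp_tail = v_tail * psi_core * _sinc(q * (g.h_tail / 2.0) * cos_a)
    amp_tot = v_tot * psi_core * _sinc(q * (g.h_total / 2.0) * cos_a)
    sinc_belt = _sinc(q * (g.belt_height / 2.0) * cos_a)
    amp_belt = v_out * psi_out * sinc_belt - v_in * psi_core * sinc_belt

    c = contrasts
    return (
        c.delta_rho_tail * amp_tail
        + c.delta_rho_head * (amp_tot - amp_tail)
        + c.delta_rho_belt * amp_belt
    )


def _orientation_nodes(n_alpha: int, n_phi: int):
    """Quadrature nodes for the symmetry-reduced octant average.

    The α integral uses the substitution μ = cos α so the sin α weight is
    absorbed: ⟨f⟩ = (2/π) ∫₀^{π/2} dφ ∫₀¹ f dμ.
    """
    x_mu, w_mu = leggauss(n_alpha)
    mu = 0.5 * (x_mu + 1.0)
    w_mu = 0.5 * w_mu
    x_phi, w_phi = leggauss(n_phi)
    phi = 0.25 * np.pi * (x_phi + 1.0)
    w_phi = 0.25 * np.pi * w_phi * (2.0 / np.pi)
    return mu, w_mu, phi, w_phi


def _lipid_count_nodes(n_lipid: float, sigma_n: float, n_nodes: int):
    """Gauss–Legendre nodes/weights of the truncated lipid-count Gaussian."""
    if sigma_n == 0.0:
        return np.array([n_lipid]), np.array([1.0])
    lo = max(2.0, n_lipid - 3.0 * sigma_n)
    hi = n_lipid + 3.0 * sigma_n
    x, w = leggauss(n_nodes)
    n = 0.5 * (hi - lo) * (x + 1.0) + lo
    pdf = np.exp(-0.5 * ((n - n_lipid) / sigma_n) ** 2)
    weights = w * pdf
    return n, weights / weights.sum()


def _mean_sq_amplitude(
    q: np.ndarray,
    geometry: DiscGeometry,
    contrasts: ContrastSet,
    mu: np.ndarray,
    w_mu: np.ndarray,
    phi: np.ndarray,
    w_phi: np.ndarray,
) -> np.ndarray:
    """⟨|F|²⟩ over orientations for a single geometry, vectorized in q."""
    g = geometry
    sin_a = np.sqrt(1.0 - mu**2)
    r_core = np.sqrt(g.a**2 * np.sin(phi) ** 2 + g.b**2 * np.cos(phi) ** 2)
    ao, bo = g.a + g.belt_thickness, g.b + g.belt_thickness
    r_out = np.sqrt(ao**2 * np.sin(phi) ** 2 + bo**2 * np.cos(phi) ** 2)

    # radial factors depend on (q, α, φ); axial factors only on (q, α)
    qs = q[:, None, None] * sin_a[None, :, None]
    psi_core = _psi_radial(qs * r_core[None, None, :])
    psi_out = _psi_radial(qs * r_out[None, None, :])

    qm = q[:, None] * mu[None, :]
    sinc_tail = _sinc(qm * (g.h_tail / 2.0))
    sinc_tot = _sinc(qm * (g.h_total / 2.0))
    sinc_belt = _sinc(qm * (g.belt_height / 2.0))

    area_core = np.pi * g.a * g.b
    v_tail = area_core * g.h_tail
    v_tot = area_core * g.h_total
    v_out = np.pi * ao * bo * g.belt_height
    v_in = area_core * g.belt_height

    c = contrasts
    # coefficient of psi_core as a function of (q, α); psi_out enters once
    coef_core = (
        c.delta_rho_tail * v_tail * sinc_tail
        + c.delta_rho_head * (v_tot * sinc_tot - v_tail * sinc_tail)
        - c.delta_rho_belt * v_in * sinc_belt
    )
    coef_out = c.delta_rho_belt * v_out * sinc_belt
    F = coef_core[:, :, None] * psi_core + coef_out[:, :, None] * psi_out
    return np.einsum("qap,a,p->q", F * F, w_mu, w_phi)


def intensity(
    q_grid: Sequence[float] | np.ndarray,
    params: DiscParameters,
    contrasts: ContrastSet,
    n_alpha: int = 64,
    n_phi: int = 64,
    n_poly: int = 10,
) -> np.ndarray:
    """Absolute-scale model intensity I(q) in cm⁻¹.

    Orientation averaging uses Gauss–Legendre quadrature of order
    ``n_alpha`` × ``n_phi`` over the symmetry-reduced octant; the
    number-weighted polydispersity average uses ``n_poly`` Gaussian
    quadrature nodes over n_lipid ± 3σ (truncated at n ≥ 2), with the
    geometry re-derived at every node.
    """
    q = np.asarray(q_grid, dtype=float)
    if n_alpha < 8 or n_phi < 8:
        warnings.warn("orientation quadrature order < 8; accuracy loss likely", stacklevel=2)
    mu, w_mu, phi, w_phi = _orientation_nodes(n_alpha, n_phi)
    n_nodes, n_weights = _lipid_count_nodes(params.n_lipid, params.sigma_n, n_poly)
    mean_sq = np.zeros_like(q)
    for n_i, w_i in zip(n_nodes, n_weights):
        geom = derive_geometry(params.replace(n_lipid=float(n_i), sigma_n=0.0))
        mean_sq += w_i * _mean_sq_amplitude(q, geom, contrasts, mu, w_mu, phi, w_phi)
    return params.scale * params.number_density * ANGSTROM2_TO_CM2 * mean_sq + params.background


def smeared_intensity(
    q_grid: np.ndarray,
    params: DiscParameters,
    contrasts: ContrastSet,
    q_sigma: float | np.ndarray,
    n_smear: int = 7,
    **kw,
) -> np.ndarray:
    """Gaussian q-resolution smearing hook (optional, mainly for SANS).

    Convolves the model with a Gaussian of SD ``q_sigma`` (scalar or
    per-point) by Gauss–Hermite quadrature, clipping shifted q at zero.
    """
    from numpy.polynomial.hermite_e import hermegauss

    q = np.asarray(q_grid, dtype=float)
    sig = np.broadcast_to(np.asarray(q_sigma, float), q.shape)
    x, w = hermegauss(n_smear)
    w = w / w.sum()
    out = np.zeros_like(q)
    for xi, wi in zip(x, w):
        q_shift = np.clip(q + xi * sig, 1e-6, None)
        out += wi * intensity(q_shift, params, contrasts, **kw)
    return out
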