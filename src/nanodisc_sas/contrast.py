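"""Excess scattering length densities for the three nanodisc regions.

The disc model weights each body (lipid tails, lipid headgroups, protein
belt) by its excess scattering length density Δρ = ρ_region − ρ_solvent.
X-ray densities come from electron counts, neutron densities from coherent
scattering lengths with labile hydrogens partially exchanged against the
D2O fraction of the solvent — the mechanism that makes the SANS contrast
of the same particle so different from the SAXS one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ELEMENT_TABLE, FM_TO_ANGSTROM, R_ELECTRON, V_WATER

__all__ = [
    "Component",
    "ContrastSet",
    "scattering_length_density",
    "solvent_density",
    "disc_contrasts",
    "POPC_HEAD",
    "POPC_TAIL",
    "average_protein",
]


class UnknownElementError(KeyError):
    pass


@dataclass(frozen=True)
class Component:
    """A chemical building block of the disc.

    ``atomic_composition`` maps element symbols to (possibly fractional)
    counts; ``n_exchangeable_h`` counts labile hydrogens that trade with
    solvent deuterium.
    """

    name: str
    atomic_composition: dict[str, float]
    molecular_volume: float  # Å³
    n_exchangeable_h: float = 0.0

    def __post_init__(self) -> None:
        if self.molecular_volume <= 0:
            raise ValueError("molecular_volume must be positive")
        if not self.atomic_composition:
            raise ValueError("atomic_composition must be non-empty")
        if any(v < 0 for v in self.atomic_composition.values()):
            raise ValueError("element counts must be non-negative")
        unknown = set(self.atomic_composition) - set(ELEMENT_TABLE)
        if unknown:
            raise UnknownElementError(
                f"unknown element(s) {sorted(unknown)}; supported: {sorted(ELEMENT_TABLE)}"
            )

    def with_volume(self, volume: float) -> "Component":
        return Component(self.name, dict(self.atomic_composition), volume, self.n_exchangeable_h)


@dataclass(frozen=True)
class ContrastSet:
    """Per-region excess scattering length densities for one probe, Å⁻²."""

    probe: str
    delta_rho_tail: float
    delta_rho_head: float
    delta_rho_belt: float
    rho_solvent: float

    def scaled(self, factor: float) -> "ContrastSet":
        return ContrastSet(
            self.probe,
            factor * self.delta_rho_tail,
            factor * self.delta_rho_head,
            factor * self.delta_rho_belt,
            self.rho_solvent,
        )


# --- default component table -------------------------------------------------

#: POPC phosphocholine headgroup (glycerol backbone + phosphate + choline).
POPC_HEAD = Component("POPC head", {"C": 10, "H": 18, "N": 1, "O": 8, "P": 1}, 319.0)

#: POPC acyl chains (palmitoyl + oleoyl, ester oxygens counted in the head).
POPC_TAIL = Component("POPC tail", {"C": 32, "H": 64}, 961.0)

# Average amino-acid residue (abundance-weighted), ~110.1 Da, 133.5 Å³ at a
# specific volume of 0.73 cm³/g; ~1.57 labile H per residue (backbone NH +
# side-chain OH/NH/SH).
_AVG_RESIDUE = {"C": 4.86, "H": 7.58, "N": 1.36, "O": 1.48, "S": 0.042}
_AVG_RESIDUE_VOLUME = 133.5
_AVG_RESIDUE_EXCH_H = 1.57


def average_protein(volume: float, name: str = "MSP") -> Component:
    """Protein of average amino-acid composition scaled to a given volume.

    Used for the MSP belt when no sequence is supplied: the number of
    average residues is ``volume / 133.5 Å³`` so the component reproduces
    generic protein scattering densities at the refined belt volume.
    """
    n_res = volume / _AVG_RESIDUE_VOLUME
    comp = {el: cnt * n_res for el, cnt in _AVG_RESIDUE.items()}
    return Component(name, comp, volume, n_exchangeable_h=_AVG_RESIDUE_EXCH_H * n_res)


# --- densities ---------------------------------------------------------------

_B_H = ELEMENT_TABLE["H"][0]
_B_D = ELEMENT_TABLE["D"][0]
_B_O = ELEMENT_TABLE["O"][0]


def solvent_density(probe: str, d2o_fraction: float) -> float:
    """Scattering length density of an H2O/D2O mixture, Å⁻²."""
    if not 0.0 <= d2o_fraction <= 1.0:
        raise ValueError("d2o_fraction must lie in [0, 1]")
    if probe == "xray":
        return 10.0 * R_ELECTRON / V_WATER
    if probe == "neutron":
        b = (2.0 * ((1.0 - d2o_fraction) * _B_H + d2o_fraction * _B_D) + _B_O) * FM_TO_ANGSTROM
        return b / V_WATER
    raise ValueError(f"unknown probe {probe!r}")


def scattering_length_density(
    component: Component,
    probe: str,
    d2o_fraction: float = 0.0,
    exchange_fraction: float = 0.9,
) -> float:
    """Scattering length density of a component, Å⁻².

    X-ray: total electrons × r_e / volume. Neutron: sum of coherent
    lengths with ``n_exchangeable_h · exchange_fraction · d2o_fraction``
    hydrogens replaced by deuterium.
    """
    if not (0.0 <= d2o_fraction <= 1.0 and 0.0 <= exchange_fraction <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    if probe == "xray":
        electrons = sum(n * ELEMENT_TABLE[el][1] for el, n in component.atomic_composition.items())
        return electrons * R_ELECTRON / component.molecular_volume
    if probe == "neutron":
        b_fm = sum(n * ELEMENT_TABLE[el][0] for el, n in component.atomic_composition.items())
        n_swapped = component.n_exchangeable_h * exchange_fraction * d2o_fraction
        b_fm += n_swapped * (_B_D - _B_H)
        return b_fm * FM_TO_ANGSTROM / component.molecular_volume
    raise ValueError(f"unknown probe {probe!r}")


def disc_contrasts(
    tail: Component = POPC_TAIL,
    head: Component = POPC_HEAD,
    belt: Component | None = None,
    probe: str = "xray",
    d2o_fraction: float = 0.0,
    exchange_fraction: float = 0.9,
    belt_volume: float = 37900.0,
) -> ContrastSet:
    """Excess densities of the three disc regions against the solvent.

    ``belt`` defaults to an average-composition protein at ``belt_volume``.
    """
    if belt is None:
        belt = average_protein(belt_volume)
    rho_s = solvent_density(probe, d2o_fraction)
    rho = [
        scattering_length_density(c, probe, d2o_fraction, exchange_fraction)
        for c in (tail, head, belt)
    ]
    out = ContrastSet(probe, rho[0] - rho_s, rho[1] - rho_s, rho[2] - rho_s, rho_s)
    if not all(np.isfinite([out.delta_rho_tail, out.delta_rho_head, out.delta_rho_belt])):
        raise ValueError("non-finite contrast")
    return out
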