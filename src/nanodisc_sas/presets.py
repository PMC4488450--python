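"""Canonical nanodisc parameter sets.

Two reference states of the MSP1E3D1/POPC disc are bundled: the
unmodified disc and the DOTA-conjugated disc, at their refined belt
thickness, area per headgroup, lipid count and POPC volume. The axis
ratios (not independently determinable from those four quantities alone)
are fixed at the values for which the belt-volume identity

    v_MSP = π·H_belt·[(a+T)(b+T) − ab] / 2

reproduces the refined per-MSP volumes (37900 / 36800 Å³) with the
default belt height of 24 Å: ε = 1.354 and 1.35 respectively. The
lipid-count polydispersity (not refined) is set to 8% of the mean, a
typical width for reconstituted disc preparations.
"""

from __future__ import annotations

from .disc_model import DiscParameters

__all__ = ["UNMODIFIED_DISC", "DOTA_DISC"]

#: Unmodified MSP1E3D1/POPC nanodisc.
UNMODIFIED_DISC = DiscParameters(
    n_lipid=188.0,
    area_per_headgroup=70.3,
    belt_thickness=9.8,
    axis_ratio=1.354,
    sigma_n=15.0,
    belt_height=24.0,
    v_lipid=1280.0,
    v_head=319.0,
    scale=1.0,
    background=0.0,
    number_density=1.3e16,
)

#: DOTA-conjugated disc (belt slightly thinner, more lipids per disc).
DOTA_DISC = DiscParameters(
    n_lipid=247.0,
    area_per_headgroup=61.6,
    belt_thickness=8.9,
    axis_ratio=1.35,
    sigma_n=20.0,
    belt_height=24.0,
    v_lipid=1280.0,
    v_head=319.0,
    scale=1.0,
    background=0.0,
    number_density=1.3e16,
)
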