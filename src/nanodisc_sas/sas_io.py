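"""Reading, writing, merging and absolute-scaling of small-angle scattering curves.

Curves are three-column whitespace-delimited ASCII (q [Å⁻¹], I [cm⁻¹],
σ [cm⁻¹]) with ``#`` comment lines, the de-facto interchange format of
SAXS/SANS beamlines. Buffer subtraction is assumed to have been done
upstream; curves handled here are background-subtracted, absolute-scaled
I(q).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

logger = logging.getLogger(__name__)

Probe = Literal["xray", "neutron"]

NM_PER_ANGSTROM_INV = 0.1  # q[Å⁻¹] = 0.1 · q[nm⁻¹]


class SASParseError(ValueError):
    """Raised when a scattering file cannot be parsed."""


class SASValidationError(ValueError):
    """Raised when curve data violate the SASCurve invariants."""


@dataclass(frozen=True)
class SASCurve:
    """One probe's absolute-scaled scattering curve.

    Attributes
    ----------
    q : ndarray
        Momentum transfer, Å⁻¹; strictly increasing, all positive.
    intensity : ndarray
        Differential scattering cross-section dΣ/dΩ, cm⁻¹.
    sigma : ndarray
        One-standard-deviation uncertainty on the intensity, cm⁻¹; positive.
    probe : {"xray", "neutron"}
    solvent_d2o_fraction : float
        D2O volume fraction of the solvent, in [0, 1].
    label : str
        Free-text identifier.
    metadata : dict
        Provenance record (calibration factors, merge scale, ...).
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    probe: Probe
    solvent_d2o_fraction: float = 0.0
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        object.__setattr__(self, "sigma", s)
        if not (q.shape == i.shape == s.shape) or q.ndim != 1:
            raise SASValidationError("q, intensity, sigma must be equal-length 1-D arrays")
        if q.size and (np.any(q <= 0) or np.any(np.diff(q) <= 0)):
            raise SASValidationError("q must be strictly increasing and positive")
        if np.any(s <= 0):
            raise SASValidationError("sigma must be positive elementwise")
        if not (0.0 <= self.solvent_d2o_fraction <= 1.0):
            raise SASValidationError("solvent_d2o_fraction must lie in [0, 1]")
        if self.probe not in ("xray", "neutron"):
            raise SASValidationError(f"unknown probe {self.probe!r}")

    def __len__(self) -> int:
        return self.q.size


@dataclass(frozen=True)
class CurveSegmentPair:
    """Two detector-distance segments of one measurement, low-q and high-q."""

    low_q_segment: SASCurve
    high_q_segment: SASCurve
    overlap_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.low_q_segment.probe != self.high_q_segment.probe:
            raise SASValidationError("segments must share a probe")


def read_sas_curve(
    path: str | Path,
    probe: Probe,
    d2o_fraction: float = 0.0,
    label: str = "",
    q_in_inverse_nm: bool = False,
) -> SASCurve:
    """Read a 3-column ASCII scattering curve.

    Rows containing non-finite values are dropped (with a logged count);
    a row with a column count other than 3 is a parse error. Set
    ``q_in_inverse_nm`` for files recorded in nm⁻¹ — the unit is never
    guessed from the data.
    """
    path = Path(path)
    rows: list[list[float]] = []
    n_dropped = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 3:
                raise SASParseError(
                    f"{path}:{lineno}: expected 3 columns, found {len(parts)}"
                )
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise SASParseError(f"{path}:{lineno}: non-numeric field") from exc
            if not all(np.isfinite(vals)):
                n_dropped += 1
                continue
            rows.append(vals)
    if n_dropped:
        logger.info("read_sas_curve: dropped %d non-finite rows from %s", n_dropped, path)
    if len(rows) < 5:
        raise SASParseError(f"{path}: fewer than 5 usable data rows")
    arr = np.array(rows, dtype=float)
    q = arr[:, 0] * (NM_PER_ANGSTROM_INV if q_in_inverse_nm else 1.0)
    if np.any(np.diff(q) <= 0):
        raise SASValidationError(f"{path}: q column is not strictly increasing")
    meta = {"source": str(path), "n_dropped_rows": n_dropped}
    return SASCurve(q, arr[:, 1], arr[:, 2], probe, d2o_fraction, label or path.stem, meta)


def write_sas_curve(path: str | Path, curve: SASCurve, sidecar: bool = True) -> None:
    """Write a curve as 3-column ASCII plus a YAML provenance sidecar."""
    path = Path(path)
    header = (
        f"# q[1/A]  I[1/cm]  sigma[1/cm]\n# probe: {curve.probe}"
        f"  d2o_fraction: {curve.solvent_d2o_fraction}  label: {curve.label}\n"
    )
    data = np.column_stack([curve.q, curve.intensity, curve.sigma])
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.17e")  # full float64 precision: read/write round-trips exactly
    if sidecar:
        meta = {
            "probe": curve.probe,
            "solvent_d2o_fraction": float(curve.solvent_d2o_fraction),
            "label": curve.label,
            "metadata": _plain(curve.metadata),
        }
        Path(str(path) + ".yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialisation."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def merge_segments(
    pair: CurveSegmentPair,
    scale: float | None = None,
    min_overlap_points: int = 3,
) -> SASCurve:
    """Merge two detector-distance segments into one curve.

    The high-q segment is multiplied by a scale factor obtained by
    log-space least squares over the overlap region (intensities span
    decades, so the log metric weights the whole overlap evenly); pass
    ``scale`` to override. The merged curve is the q-sorted union, with
    exactly duplicated q averaged by inverse variance.
    """
    low, high = pair.low_q_segment, pair.high_q_segment
    if scale is None:
        lo, hi = high.q.min(), low.q.max()
        sel = (high.q >= lo) & (high.q <= hi) & (high.intensity > 0)
        if sel.sum() < min_overlap_points:
            raise SASValidationError(
                "segments share fewer than "
                f"{min_overlap_points} overlap points; pass an explicit scale factor"
            )
        log_low = np.interp(high.q[sel], low.q, np.log(np.clip(low.intensity, 1e-300, None)))
        scale = float(np.exp(np.mean(log_low - np.log(high.intensity[sel]))))

    q = np.concatenate([low.q, high.q])
    i = np.concatenate([low.intensity, scale * high.intensity])
    s = np.concatenate([low.sigma, scale * high.sigma])
    order = np.argsort(q, kind="stable")
    q, i, s = q[order], i[order], s[order]

    # inverse-variance average of exactly duplicated q
    uniq, inverse = np.unique(q, return_inverse=True)
    if uniq.size != q.size:
        w = 1.0 / s**2
        wsum = np.bincount(inverse, weights=w)
        i = np.bincount(inverse, weights=w * i) / wsum
        s = np.sqrt(1.0 / wsum)
        q = uniq
    meta = dict(low.metadata)
    meta.update({"merged_from": [low.label, high.label], "overlap_scale": float(scale)})
    return SASCurve(q, i, s, low.probe, low.solvent_d2o_fraction, low.label or high.label, meta)


def absolute_scale(curve: SASCurve, calibration_factor: float) -> SASCurve:
    """Rescale a curve to absolute units with a secondary-standard factor."""
    if calibration_factor <= 0:
        raise ValueError("calibration factor must be positive")
    meta = dict(curve.metadata)
    meta["calibration_factor"] = meta.get("calibration_factor", 1.0) * calibration_factor
    return replace(
        curve,
        intensity=curve.intensity * calibration_factor,
        sigma=curve.sigma * calibration_factor,
        metadata=meta,
    )
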