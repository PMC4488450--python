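"""Tracer arithmetic for PET/gamma-counting biodistribution readouts.

Decay correction, counter-efficiency conversion, percent injected dose
per gram, organ ratios, biphasic (biexponential) blood-clearance fitting,
and the SEC intact-fraction used for plasma-stability assays. Times are
hours post-injection throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import CU64_HALF_LIFE_H
from .synthdata import Chromatogram

__all__ = [
    "DecayContext",
    "BiodistTable",
    "decay_correct",
    "decay_apply",
    "counts_to_activity",
    "activity_to_counts",
    "percent_id_per_gram",
    "biexponential_fit",
    "BiexpFit",
    "intact_fraction",
    "organ_ratio",
]


@dataclass(frozen=True)
class DecayContext:
    """Radionuclide decay bookkeeping (default: ⁶⁴Cu, 12.7 h)."""

    half_life: float = CU64_HALF_LIFE_H  # hours
    reference_time: float = 0.0  # hours post-injection

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError("half_life must be positive")


@dataclass(frozen=True)
class BiodistTable:
    """Organ × time %ID/g records, wrapping a validated DataFrame."""

    data: pd.DataFrame  # columns: organ, time_h, pid_g, sd, n

    def __post_init__(self) -> None:
        required = {"organ", "time_h", "pid_g"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (self.data["pid_g"] < 0).any() or (self.data["time_h"] < 0).any():
            raise ValueError("pid_g and time_h must be non-negative")

    @classmethod
    def from_csv(cls, path) -> "BiodistTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def series(self, organ: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.data[self.data["organ"] == organ].sort_values("time_h")
        if sub.empty:
            raise KeyError(f"organ {organ!r} not in table")
        return sub["time_h"].to_numpy(), sub["pid_g"].to_numpy()


def decay_correct(activity, elapsed, ctx: DecayContext = DecayContext()):
    """Correct a measured activity back to the reference time.

    ``activity · 2^(elapsed / half_life)`` — at one half-life the
    correction exactly doubles the value.
    """
    activity = np.asarray(activity, float)
    if np.any(activity < 0):
        raise ValueError("activity must be non-negative")
    out = activity * 2.0 ** (np.asarray(elapsed, float) / ctx.half_life)
    return float(out) if out.ndim == 0 else out


def decay_apply(activity, elapsed, ctx: DecayContext = DecayContext()):
    """Physically decay an activity forward in time (inverse of decay_correct)."""
    activity = np.asarray(activity, float)
    out = activity * 2.0 ** (-np.asarray(elapsed, float) / ctx.half_life)
    return float(out) if out.ndim == 0 else out


def counts_to_activity(count_rate, efficiency: float):
    """Detector count rate (counts/s) → activity (Bq) at a given efficiency."""
    if not 0.0 < efficiency <= 1.0:
        raise ValueError("efficiency must lie in (0, 1]")
    out = np.asarray(count_rate, float) / efficiency
    return float(out) if out.ndim == 0 else out


def activity_to_counts(activity, efficiency: float):
    """Inverse of :func:`counts_to_activity`."""
    if not 0.0 < efficiency <= 1.0:
        raise ValueError("efficiency must lie in (0, 1]")
    out = np.asarray(activity, float) * efficiency
    return float(out) if out.ndim == 0 else out


def percent_id_per_gram(tissue_activity: float, tissue_mass: float, injected: float) -> float:
    """%ID/g from decay-corrected tissue activity, tissue mass, injected dose."""
    if tissue_mass <= 0 or injected <= 0:
        raise ValueError("tissue_mass and injected dose must be positive")
    if tissue_activity < 0:
        raise ValueError("tissue_activity must be non-negative")
    return 100.0 * (tissue_activity / injected) / tissue_mass


@dataclass(frozen=True)
class BiexpFit:
    """Biexponential clearance fit A·e^(−k1·t) + B·e^(−k2·t), k1 > k2 ≥ 0."""

    A: float
    k1: float
    B: float
    k2: float
    sd: dict  # parameter -> SD (NaN when the covariance is singular)
    chi2_reduced: float
    monophasic: bool  # slow phase indistinguishable from the fast one / from zero

    def __call__(self, t):
        t = np.asarray(t, float)
        return self.A * np.exp(-self.k1 * t) + self.B * np.exp(-self.k2 * t)

    @property
    def half_times(self) -> tuple[float, float]:
        """Fast and slow phase half-times, hours."""
        return (np.log(2) / self.k1 if self.k1 > 0 else np.inf,
                np.log(2) / self.k2 if self.k2 > 0 else np.inf)


def biexponential_fit(
    times,
    conc,
    sigma=None,
    seed: int = 0,
    n_starts: int = 6,
) -> BiexpFit:
    """Weighted multi-start least-squares fit of biphasic clearance.

    Phases are ordered (k1 > k2 ≥ 0) after fitting. The result is
    flagged monophasic when the slow amplitude is indistinguishable from
    zero or the two rates are indistinguishable from each other.
    """
    t = np.asarray(times, float)
    y = np.asarray(conc, float)
    if t.size < 5:
        raise ValueError("need at least 5 time points")
    s = np.ones_like(y) if sigma is None else np.asarray(sigma, float)

    def resid(x):
        A, k1, B, k2 = x
        return (A * np.exp(-k1 * t) + B * np.exp(-k2 * t) - y) / s

    y0 = max(y.max(), 1e-12)
    t_span = max(t.max() - t.min(), 1.0)
    rng = np.random.default_rng(seed)
    lo = [0.0, 0.0, 0.0, 0.0]
    hi = [10 * y0, 100.0 / t_span, 10 * y0, 100.0 / t_span]
    best = None
    for i in range(n_starts):
        if i == 0:
            x0 = [0.7 * y0, 2.0 / t_span, 0.3 * y0, 0.1 / t_span]
        else:
            x0 = [
                y0 * rng.uniform(0.2, 1.5),
                rng.uniform(0.5, 10.0) / t_span,
                y0 * rng.uniform(0.05, 1.0),
                rng.uniform(0.005, 0.5) / t_span,
            ]
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), x_scale=[y0, 1 / t_span] * 2)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("biexponential fit failed to converge from any start")

    A, k1, B, k2 = best.x
    if k2 > k1:  # enforce fast-phase-first ordering
        A, k1, B, k2 = B, k2, A, k1
    dof = max(t.size - 4, 1)
    chi2_red = float(2 * best.cost / dof)
    try:
        cov = np.linalg.pinv(best.jac.T @ best.jac) * chi2_red
        sds = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        sds = np.full(4, np.nan)
    sd = dict(zip(("A", "k1", "B", "k2"), map(float, sds)))
    amp_total = A + B
    monophasic = bool(
        amp_total <= 0
        or min(A, B) / amp_total < 1e-3
        or (k1 > 0 and abs(k1 - k2) / k1 < 0.05)
        or (np.isfinite(sd["B"]) and sd["B"] > 0 and B < 2.0 * sd["B"])
    )
    return BiexpFit(float(A), float(k1), float(B), float(k2), sd, chi2_red, monophasic)


def intact_fraction(chrom: Chromatogram, window: tuple[float, float]) -> float:
    """Fraction of radioactivity eluting inside the intact-particle window.

    A flat baseline (median of the first and last 5% of bins) is removed
    from both the window and the total before taking the ratio.
    """
    lo, hi = window
    v, c = chrom.elution_volume, chrom.counts
    if lo >= hi or lo < v[0] or hi > v[-1]:
        raise ValueError("window must be a non-empty interval inside the elution range")
    sel = (v >= lo) & (v <= hi)
    if not sel.any():
        raise ValueError("window contains no bins")
    n_edge = max(1, int(0.05 * v.size))
    baseline = float(np.median(np.concatenate([c[:n_edge], c[-n_edge:]])))
    numer = c[sel].sum() - baseline * sel.sum()
    denom = c.sum() - baseline * v.size
    if denom <= 0:
        return 0.0
    return float(np.clip(numer / denom, 0.0, 1.0))


def organ_ratio(table: BiodistTable, numerator: str, denominator: str, time: float) -> float:
    """Ratio of %ID/g values of two organs at one time point (e.g. tumor/muscle)."""
    df = table.data
    def pick(organ):
        sub = df[(df["organ"] == organ) & (np.isclose(df["time_h"], time))]
        if sub.empty:
            raise KeyError(f"no record for organ {organ!r} at t={time} h")
        return float(sub["pid_g"].iloc[0])

    num, den = pick(numerator), pick(denominator)
    if den == 0:
        raise ZeroDivisionError(f"{denominator} %ID/g is zero at t={time} h")
    return num / den
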