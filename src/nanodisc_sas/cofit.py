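"""Simultaneous SAXS+SANS refinement of shared disc parameters.

Organized as a model/results pair: :class:`NanodiscModel` holds the data
(one or more absolute-scaled curves) and the fitting configuration;
``fit()`` runs bounded multi-start least squares and returns a
:class:`NanodiscFitResults` carrying the refined parameters, their
covariance, per-curve scale/background, the derived geometry report and
a ``summary()`` table.

The structural parameter vector is (n_lipid, A_core, ε, T, v_lipid, σ_N):
the area per headgroup is reported as 2·A_core/n_lipid rather than fitted
directly, which keeps the parameterization identifiable while matching
the convention of quoting A_head. Contrasts are recomputed at every
evaluation because the tail scattering length density depends on the
floating lipid volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .contrast import (
    POPC_HEAD,
    POPC_TAIL,
    ContrastSet,
    average_protein,
    disc_contrasts,
)
from .disc_model import DiscGeometry, DiscParameters, derive_geometry, intensity
from .sas_io import SASCurve

__all__ = ["NanodiscModel", "NanodiscFitResults", "joint_fit", "derived_report"]

STRUCT_NAMES = ("n_lipid", "a_core", "axis_ratio", "belt_thickness", "v_lipid", "sigma_n")

#: wide default bounds covering physically sensible MSP1E3D1/POPC discs
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "n_lipid": (50.0, 600.0),
    "a_core": (1500.0, 30000.0),
    "axis_ratio": (1.0, 2.0),
    "belt_thickness": (2.0, 30.0),
    "v_lipid": (950.0, 1600.0),
    "sigma_n": (0.0, 80.0),
    "scale": (0.05, 20.0),
    "background": (-0.05, 0.5),
}


def _params_to_x(p: DiscParameters) -> np.ndarray:
    a_core = p.n_lipid * p.area_per_headgroup / 2.0
    return np.array([p.n_lipid, a_core, p.axis_ratio, p.belt_thickness, p.v_lipid, p.sigma_n])


def _x_to_params(x: np.ndarray, template: DiscParameters) -> DiscParameters:
    n_lipid, a_core, eps, T, v_lipid, sigma_n = x
    return template.replace(
        n_lipid=float(n_lipid),
        area_per_headgroup=float(2.0 * a_core / n_lipid),
        axis_ratio=float(eps),
        belt_thickness=float(T),
        v_lipid=float(v_lipid),
        sigma_n=float(sigma_n),
        scale=1.0,
        background=0.0,
    )


class NanodiscModel:
    """Joint forward model of one or more scattering curves.

    Parameters
    ----------
    curves : sequence of SASCurve
        The absolute-scaled data; each carries its probe and solvent
        D2O fraction, from which per-curve contrasts are derived.
    init : DiscParameters
        Structural starting point (per-curve scale/background start at
        1 and 0 regardless of the values stored on ``init``).
    bounds : dict, optional
        Per-parameter (lo, hi) overrides of the defaults. A collapsed
        interval (lo == hi) fixes that parameter.
    exchange_fraction : float
        Labile-hydrogen exchange fraction used for the belt contrast.
    quad, polish_quad : (n_alpha, n_phi)
        Orientation-quadrature orders for the multi-start search and for
        the final polish/covariance pass.
    n_poly, search_n_poly : int
        Lipid-count quadrature nodes for the polish and for the cheaper
        multi-start search stage.
    """

    def __init__(
        self,
        curves: list[SASCurve],
        init: DiscParameters,
        bounds: dict[str, tuple[float, float]] | None = None,
        exchange_fraction: float = 0.9,
        quad: tuple[int, int] = (24, 12),
        polish_quad: tuple[int, int] = (48, 24),
        n_poly: int = 10,
        search_n_poly: int = 5,
    ) -> None:
        if not curves:
            raise ValueError("at least one curve is required")
        self.curves = list(curves)
        self.init = init
        self.bounds = dict(DEFAULT_BOUNDS)
        if bounds:
            self.bounds.update(bounds)
        self.exchange_fraction = exchange_fraction
        self.quad = quad
        self.polish_quad = polish_quad
        self.n_poly = n_poly
        self.search_n_poly = search_n_poly

        x0_struct = _params_to_x(init)
        names = list(STRUCT_NAMES)
        x0 = list(x0_struct)
        lo = [self.bounds[n][0] for n in names]
        hi = [self.bounds[n][1] for n in names]
        for i, c in enumerate(self.curves):
            names += [f"scale_{i}", f"background_{i}"]
            x0 += [1.0, 0.0]
            lo += [self.bounds["scale"][0], self.bounds["background"][0]]
            hi += [self.bounds["scale"][1], self.bounds["background"][1]]
        self.param_names = names
        self._x0_full = np.asarray(x0, float)
        self._lo_full = np.asarray(lo, float)
        self._hi_full = np.asarray(hi, float)
        if np.any(self._x0_full < self._lo_full) or np.any(self._x0_full > self._hi_full):
            raise ValueError("bounds must contain the initial parameter vector")
        self._free = self._lo_full < self._hi_full  # collapsed bounds => fixed

    # -- model evaluation ----------------------------------------------------

    def _contrasts_for(self, curve: SASCurve, v_lipid: float) -> ContrastSet:
        tail = POPC_TAIL.with_volume(v_lipid - POPC_HEAD.molecular_volume)
        belt = average_protein(1000.0)  # density independent of volume scaling
        return disc_contrasts(
            tail,
            POPC_HEAD,
            belt,
            probe=curve.probe,
            d2o_fraction=curve.solvent_d2o_fraction,
            exchange_fraction=self.exchange_fraction,
        )

    def _predict_full(
        self, x_full: np.ndarray, quad: tuple[int, int], n_poly: int | None = None
    ) -> list[np.ndarray]:
        params = _x_to_params(x_full[:6], self.init)
        out = []
        for i, c in enumerate(self.curves):
            scale, bkg = x_full[6 + 2 * i], x_full[7 + 2 * i]
            contr = self._contrasts_for(c, params.v_lipid)
            model = intensity(
                c.q,
                params.replace(scale=float(scale), background=float(bkg)),
                contr,
                n_alpha=quad[0],
                n_phi=quad[1],
                n_poly=self.n_poly if n_poly is None else n_poly,
            )
            out.append(model)
        return out

    def predict(self, x_full: np.ndarray | None = None, fine: bool = True) -> list[np.ndarray]:
        """Model intensities on each curve's q grid."""
        x = self._x0_full if x_full is None else np.asarray(x_full, float)
        return self._predict_full(x, self.polish_quad if fine else self.quad)

    def _residuals(
        self, x_free: np.ndarray, quad: tuple[int, int], n_poly: int | None = None
    ) -> np.ndarray:
        x_full = self._x0_full.copy()
        x_full[self._free] = x_free
        models = self._predict_full(x_full, quad, n_poly)
        return np.concatenate(
            [(m - c.intensity) / c.sigma for m, c in zip(models, self.curves)]
        )

    def _log_residuals(
        self, x_free: np.ndarray, quad: tuple[int, int], n_poly: int | None = None
    ) -> np.ndarray:
        """Relative-error residuals in log intensity.

        Used as a pre-stage: the log-space landscape is far less prone to
        fringe-misalignment local minima than the linear χ² surface.
        """
        x_full = self._x0_full.copy()
        x_full[self._free] = x_free
        models = self._predict_full(x_full, quad, n_poly)
        out = []
        for m, c in zip(models, self.curves):
            rel = c.sigma / np.abs(c.intensity)
            out.append(
                (np.log(np.clip(m, 1e-14, None)) - np.log(np.clip(c.intensity, 1e-14, None)))
                / rel
            )
        return np.concatenate(out)

    # -- fitting -------------------------------------------------------------

    def _starts(self, n_starts: int, rng: np.random.Generator) -> list[np.ndarray]:
        """Initial vector plus seeded log-uniform perturbations within bounds."""
        x0 = self._x0_full[self._free]
        lo, hi = self._lo_full[self._free], self._hi_full[self._free]
        starts = [x0]
        for _ in range(max(0, n_starts - 1)):
            fac = np.exp(rng.uniform(np.log(0.8), np.log(1.2), size=x0.size))
            pert = np.where(np.abs(x0) > 1e-12, x0 * fac, x0 + rng.uniform(-0.1, 0.1, x0.size))
            starts.append(np.clip(pert, lo, hi))
        return starts

    def fit(
        self,
        n_starts: int = 8,
        seed: int = 0,
        xtol: float = 1e-8,
        ftol: float = 1e-8,
        max_nfev: int | None = None,
        stop_chi2: float | None = 2.0,
    ) -> "NanodiscFitResults":
        """Bounded multi-start least squares; the best start is polished
        at the fine quadrature order and its Jacobian gives the covariance.

        Starts are consumed lazily: once a start reaches a reduced χ² of
        ``stop_chi2`` or better the remaining starts are skipped (set
        ``stop_chi2=None`` to always run all of them).
        """
        rng = np.random.default_rng(seed)
        n_pts = sum(len(c) for c in self.curves)
        dof = max(n_pts - int(self._free.sum()), 1)
        lo, hi = self._lo_full[self._free], self._hi_full[self._free]
        x_scale = np.maximum(np.abs(self._x0_full[self._free]), 1e-3)
        attempts = []
        for x_start in self._starts(n_starts, rng):
            try:
                pre = least_squares(
                    self._log_residuals,
                    x_start,
                    bounds=(lo, hi),
                    args=(self.quad, self.search_n_poly),
                    x_scale=x_scale,
                    xtol=1e-6,
                    ftol=1e-6,
                    max_nfev=150,
                )
                sol = least_squares(
                    self._residuals,
                    pre.x,
                    bounds=(lo, hi),
                    args=(self.quad, self.search_n_poly),
                    x_scale=x_scale,
                    xtol=xtol,
                    ftol=ftol,
                    max_nfev=max_nfev,
                )
                attempts.append(sol)
                if stop_chi2 is not None and 2.0 * sol.cost / dof <= stop_chi2:
                    break
            except Exception as exc:  # pragma: no cover - diagnostic path
                attempts.append(exc)
        solutions = [a for a in attempts if not isinstance(a, Exception)]
        if not solutions:
            raise RuntimeError(f"all {n_starts} starts failed: {attempts}")
        best = min(solutions, key=lambda s: s.cost)
        # polish at fine quadrature from the best coarse optimum
        polished = least_squares(
            self._residuals,
            best.x,
            bounds=(lo, hi),
            args=(self.polish_quad,),
            x_scale=x_scale,
            xtol=xtol,
            ftol=ftol,
        )
        return self._build_results(polished, n_starts, seed)

    def _build_results(self, sol, n_starts: int, seed: int) -> "NanodiscFitResults":
        x_full = self._x0_full.copy()
        x_full[self._free] = sol.x
        n_pts = sum(len(c) for c in self.curves)
        n_free = int(self._free.sum())
        dof = max(n_pts - n_free, 1)
        chi2_red = float(2.0 * sol.cost / dof)

        # covariance of the free parameters from the Jacobian at the optimum
        J = sol.jac
        cov_free = None
        try:
            JTJ = J.T @ J
            cov_free = np.linalg.pinv(JTJ) * chi2_red
        except np.linalg.LinAlgError:
            cov_free = None
        cov_full = np.full((x_full.size, x_full.size), np.nan)
        if cov_free is not None:
            idx = np.flatnonzero(self._free)
            cov_full[np.ix_(idx, idx)] = cov_free

        lo, hi = self._lo_full, self._hi_full
        span = np.where(hi > lo, hi - lo, 1.0)
        pinned = [
            self.param_names[i]
            for i in np.flatnonzero(self._free)
            if min(x_full[i] - lo[i], hi[i] - x_full[i]) < 1e-6 * span[i]
        ]
        if pinned:
            warnings.warn(f"parameters pinned at a bound: {pinned}", stacklevel=3)

        params_hat = _x_to_params(x_full[:6], self.init)
        per_curve = [
            {
                "label": c.label or f"curve_{i}",
                "probe": c.probe,
                "scale": float(x_full[6 + 2 * i]),
                "background": float(x_full[7 + 2 * i]),
            }
            for i, c in enumerate(self.curves)
        ]
        models = self._predict_full(x_full, self.polish_quad)
        chi2_per_curve = []
        for m, c in zip(models, self.curves):
            r = (m - c.intensity) / c.sigma
            chi2_per_curve.append(float(r @ r / max(len(c) - n_free, 1)))
        return NanodiscFitResults(
            model=self,
            x_full=x_full,
            params_hat=params_hat,
            per_curve=per_curve,
            chi2_reduced_total=chi2_red,
            chi2_reduced_per_curve=chi2_per_curve,
            covariance=cov_full,
            derived=derive_geometry(params_hat),
            n_starts_used=n_starts,
            seed=seed,
            pinned_parameters=pinned,
        )


@dataclass
class NanodiscFitResults:
    """Refined parameters, uncertainties, and the derived-geometry report."""

    model: NanodiscModel
    x_full: np.ndarray
    params_hat: DiscParameters
    per_curve: list[dict]
    chi2_reduced_total: float
    chi2_reduced_per_curve: list[float]
    covariance: np.ndarray  # full-vector covariance (NaN on fixed entries)
    derived: DiscGeometry
    n_starts_used: int
    seed: int
    pinned_parameters: list[str] = field(default_factory=list)

    @property
    def param_names(self) -> list[str]:
        return self.model.param_names

    def _index(self, name: str) -> int:
        return self.param_names.index(name)

    def value(self, name: str) -> float:
        return float(self.x_full[self._index(name)])

    def bse(self, name: str) -> float:
        i = self._index(name)
        v = self.covariance[i, i]
        return float(np.sqrt(v)) if np.isfinite(v) and v >= 0 else np.nan

    # derived quantities -----------------------------------------------------

    @property
    def area_per_headgroup(self) -> float:
        return self.params_hat.area_per_headgroup

    def _derived_value(self, x_struct: np.ndarray, key: str) -> float:
        p = _x_to_params(x_struct, self.model.init)
        if key == "n_lipid":
            return p.n_lipid
        if key == "area_per_headgroup":
            return p.area_per_headgroup
        if key == "belt_thickness":
            return p.belt_thickness
        if key == "v_lipid":
            return p.v_lipid
        g = derive_geometry(p)
        return getattr(g, key)

    def derived_sd(self, key: str) -> float:
        """Delta-method SD of a derived quantity from the structural covariance."""
        cov = self.covariance[:6, :6]
        if not np.all(np.isfinite(np.diag(cov)[self.model._free[:6]])):
            return np.nan
        cov = np.nan_to_num(cov)  # fixed parameters contribute zero variance
        x = self.x_full[:6]
        grad = np.zeros(6)
        lo, hi = self.model._lo_full[:6], self.model._hi_full[:6]
        for i in range(6):
            h = 1e-5 * max(abs(x[i]), 1e-6)
            xp, xm = x.copy(), x.copy()
            xp[i] = min(x[i] + h, hi[i])
            xm[i] = max(x[i] - h, lo[i])
            if xp[i] == xm[i]:
                continue
            grad[i] = (self._derived_value(xp, key) - self._derived_value(xm, key)) / (
                xp[i] - xm[i]
            )
        var = grad @ cov @ grad
        return float(np.sqrt(var)) if var >= 0 else np.nan

    def derived_report(self) -> pd.DataFrame:
        """Named derived quantities with delta-method uncertainties."""
        keys = [
            ("n_lipid", "lipids"),
            ("area_per_headgroup", "A^2"),
            ("belt_thickness", "A"),
            ("v_lipid", "A^3"),
            ("v_msp", "A^3"),
            ("h_total", "A"),
            ("d_max_geom", "A"),
        ]
        rows = []
        for key, unit in keys:
            rows.append(
                {
                    "quantity": key,
                    "value": self._derived_value(self.x_full[:6], key),
                    "sd": self.derived_sd(key),
                    "unit": unit,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Nanodisc joint SAXS/SANS refinement",
            "=" * 51,
            f"curves: {len(self.model.curves)}   "
            f"chi2_red(total) = {self.chi2_reduced_total:.4g}   "
            f"starts = {self.n_starts_used}   seed = {self.seed}",
        ]
        for pc, chi2 in zip(self.per_curve, self.chi2_reduced_per_curve):
            lines.append(
                f"  {pc['label']:<20s} [{pc['probe']:>7s}] scale={pc['scale']:.4g} "
                f"bkg={pc['background']:.3g} chi2_red={chi2:.4g}"
            )
        lines.append("-" * 51)
        for name in self.param_names:
            i = self._index(name)
            if not self.model._free[i]:
                lines.append(f"  {name:<18s} {self.x_full[i]:>12.5g}   (fixed)")
            else:
                lines.append(f"  {name:<18s} {self.x_full[i]:>12.5g} ± {self.bse(name):.3g}")
        lines.append("-" * 51)
        rep = self.derived_report()
        for _, row in rep.iterrows():
            sd = f"± {row.sd:.3g}" if np.isfinite(row.sd) else "(sd n/a)"
            lines.append(f"  {row.quantity:<18s} {row.value:>12.5g} {sd}  [{row.unit}]")
        if self.pinned_parameters:
            lines.append(f"warning: pinned at bounds: {self.pinned_parameters}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data and model overlay, one panel, log-log."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        models = self.model.predict(self.x_full)
        for c, m, pc in zip(self.model.curves, models, self.per_curve):
            ax.errorbar(c.q, c.intensity, c.sigma, fmt=".", ms=3, alpha=0.5, label=pc["label"])
            ax.plot(c.q, m, "-", lw=1.5)
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel(r"q [$\mathrm{\AA}^{-1}$]")
        ax.set_ylabel(r"I(q) [cm$^{-1}$]")
        ax.legend()
        return ax

    def to_yaml(self, path) -> None:
        import yaml
        from pathlib import Path

        from .sas_io import _plain

        p = self.params_hat
        doc = {
            "params_hat": {
                "n_lipid": p.n_lipid,
                "area_per_headgroup": p.area_per_headgroup,
                "belt_thickness": p.belt_thickness,
                "axis_ratio": p.axis_ratio,
                "sigma_n": p.sigma_n,
                "belt_height": p.belt_height,
                "v_lipid": p.v_lipid,
                "v_head": p.v_head,
            },
            "per_curve": _plain(self.per_curve),
            "chi2_reduced_total": self.chi2_reduced_total,
            "chi2_reduced_per_curve": _plain(self.chi2_reduced_per_curve),
            "derived": _plain(self.derived.__dict__),
            "n_starts_used": self.n_starts_used,
            "seed": self.seed,
            "pinned_parameters": self.pinned_parameters,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def joint_fit(
    curves: list[SASCurve],
    init: DiscParameters,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 8,
    seed: int = 0,
    **model_kw,
) -> NanodiscFitResults:
    """Functional wrapper: build a :class:`NanodiscModel` and fit it."""
    return NanodiscModel(curves, init, bounds=bounds, **model_kw).fit(
        n_starts=n_starts, seed=seed
    )


def derived_report(result: NanodiscFitResults) -> pd.DataFrame:
    """Table of derived quantities with propagated uncertainties."""
    return result.derived_report()
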