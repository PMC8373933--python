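"""Scenario zero-out attribution and the soil NOx emission-control penalty.

Source contributions are estimated by differencing labeled emission
scenarios (on minus off).  The soil-anthropogenic interaction is the second
difference (BASE - NoAnthro) - (NoSoil - NoAnthroSoil); on any additive
ozone response it vanishes, while a saturating response makes it negative —
soil emissions then *suppress* the ozone benefit of anthropogenic controls.

Response curves — percent decrease of an exposure metric versus the
anthropogenic emission-reduction fraction r — are summarised by a
logarithmic fit Delta(%) = p ln(1 + q r), fitted with a statsmodels-style
model/results pair.  Inverting the fit gives the reduction required for a
target, and the "soil NOx penalty" is the extra required reduction when soil
emissions are present compared to when they are absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy.optimize import curve_fit

from . import metrics as mx
from .scenarios import ScenarioLabel
from .synthetic import OzoneScenarioSet


# ---------------------------------------------------------------------------
# scenario algebra
# ---------------------------------------------------------------------------

def enhancement(scenario_set: OzoneScenarioSet, on_label, off_label,
                var: str = "o3") -> xr.DataArray:
    """Elementwise contribution of a source: field(on) - field(off)."""
    on = scenario_set.field(on_label, var)
    off = scenario_set.field(off_label, var)
    out = on - off
    out.name = f"enhancement_{on_label}_minus_{off_label}"
    return out


def regional_mean(field: xr.DataArray, region_mask: Optional[np.ndarray] = None,
                  weights: Optional[np.ndarray] = None) -> Dict[str, float]:
    """Period- and region-averaged value with the spatial std of cell means.

    ``region_mask`` selects cells; ``weights`` (e.g. cell areas) weight the
    spatial mean.  Returns mean, spatial std, and cell count.
    """
    cell_means = field.mean("time").values
    mask = np.ones(cell_means.shape, dtype=bool) if region_mask is None \
        else np.asarray(region_mask, dtype=bool)
    w = np.ones(cell_means.shape) if weights is None else np.asarray(weights, dtype=float)
    sel = cell_means[mask]
    wsel = w[mask]
    mean = float(np.sum(sel * wsel) / np.sum(wsel))
    return {"mean": mean, "std": float(np.std(sel)), "n_cells": int(mask.sum())}


def interaction_effect(scenario_set: OzoneScenarioSet, var: str = "o3") -> xr.DataArray:
    """Soil-anthropogenic interaction: (BASE - NoAnthro) - (NoSoil - NoAnthroSoil).

    Algebraically identical to BASE - NoAnthro - NoSoil + NoAnthroSoil; zero
    for an additive response, negative for a saturating one.
    """
    a = enhancement(scenario_set, "BASE", "NoAnthro", var)
    b = enhancement(scenario_set, "NoSoil", "NoAnthroSoil", var)
    out = a - b
    out.name = "interaction"
    return out


def suppression_percent(with_soil_enh: float, without_soil_enh: float) -> float:
    """Percent by which soil emissions suppress the anthropogenic enhancement."""
    if without_soil_enh == 0:
        raise ZeroDivisionError("without-soil enhancement is zero")
    return 100.0 * (without_soil_enh - with_soil_enh) / without_soil_enh


# ---------------------------------------------------------------------------
# response curves
# ---------------------------------------------------------------------------

_METRIC_FUNCS = ("MDA8", "AOT40", "NDGT70")


@dataclass
class ResponseCurve:
    """Percent decrease of a regional ozone metric along a reduction ladder."""

    metric: str                 # MDA8 | AOT40 | NDGT70
    reductions: np.ndarray      # fractions r, ascending, r[0] = 0
    change_pct: np.ndarray      # 100 (M(0) - M(r)) / M(0); 0 at r = 0
    soil_mode: str = "on"
    controlled_species: str = "NOx-only"
    metric_values: Optional[np.ndarray] = None  # raw regional metric at each r

    def __post_init__(self):
        self.reductions = np.asarray(self.reductions, dtype=float)
        self.change_pct = np.asarray(self.change_pct, dtype=float)
        if np.any(np.diff(self.reductions) <= 0):
            raise ValueError("reductions must be strictly ascending")


def regional_metric(o3: xr.DataArray, metric: str,
                    region_mask: Optional[np.ndarray] = None,
                    weights: Optional[np.ndarray] = None) -> float:
    """Region-averaged exposure metric from an hourly ppb field."""
    if metric == "MDA8":
        cell = mx.mda8_grid(o3).mean("time").values
    elif metric == "AOT40":
        cell = mx.aot40_grid(o3).values
    elif metric == "NDGT70":
        cell = mx.ndgt70_grid(mx.mda8_grid(o3)).values.astype(float)
    else:
        raise ValueError(f"unknown metric {metric!r}; expected one of {_METRIC_FUNCS}")
    mask = np.ones(cell.shape, dtype=bool) if region_mask is None \
        else np.asarray(region_mask, dtype=bool)
    w = np.ones(cell.shape) if weights is None else np.asarray(weights, dtype=float)
    return float(np.sum(cell[mask] * w[mask]) / np.sum(w[mask]))


def build_response_curves(scenario_set: OzoneScenarioSet, metric: str,
                          soil_mode: str = "on",
                          controlled_species: str = "NOx-only",
                          reductions: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
                          region_mask: Optional[np.ndarray] = None,
                          weights: Optional[np.ndarray] = None) -> ResponseCurve:
    """Metric response to the anthropogenic reduction ladder, % change vs r=0."""
    labels = [ScenarioLabel(anthro_fraction=1.0 - r, soil_mode=soil_mode,
                            controlled_species=controlled_species)
              for r in reductions]
    missing = [str(l) for l in labels if str(l) not in scenario_set.labels]
    if missing:
        raise KeyError(f"scenario set is missing ladder labels: {missing}")
    values = np.array([
        regional_metric(scenario_set.field(str(l)), metric, region_mask, weights)
        for l in labels
    ])
    base = values[0]
    if base == 0:
        raise ZeroDivisionError("baseline metric is zero; percent change undefined")
    change = 100.0 * (base - values) / base
    change[0] = 0.0
    return ResponseCurve(metric=metric, reductions=np.asarray(reductions, float),
                         change_pct=change, soil_mode=soil_mode,
                         controlled_species=controlled_species, metric_values=values)


# ---------------------------------------------------------------------------
# logarithmic response fit (model / results pair)
# ---------------------------------------------------------------------------

def _log_form(r, p, q):
    return p * np.log1p(q * r)


def _log_inverse(target, p, q):
    return np.expm1(target / p) / q


def _satlog_form(r, p, q):
    return -p * np.log1p(-q * r)


def _satlog_inverse(target, p, q):
    return -np.expm1(-target / p) / q


#: Named logarithmic forms: (function, closed-form inverse, curve_fit bounds, p0).
#: "log" is concave in r (diminishing returns); "satlog" is convex
#: (accelerating returns, the shape a saturating ozone-emission surface
#: produces as emissions are cut and the chemistry turns NOx-limited).
#: Parameter boxes are finite so the near-linear ridge (p -> inf, q -> 0 with
#: p*q fixed) terminates at the boundary instead of stalling the optimizer.
FORMS = {
    "log": (_log_form, _log_inverse, ([1e-8, 1e-8], [1e4, 1e3]), (10.0, 5.0)),
    "satlog": (_satlog_form, _satlog_inverse,
               ([1e-8, 1e-8], [1e4, 1.0 - 1e-9]), (30.0, 0.5)),
}


@dataclass
class RequiredReduction:
    """Emission reduction required for a target metric decrease."""

    target_pct: float
    reduction_pct: float        # required r, percent, clipped to [0, 100]
    reachable: bool             # target attainable within r <= 1


class LogResponseModel:
    """Logarithmic response model for percent metric decrease versus reduction r.

    Two named forms are built in, both monotone, anchored through the origin
    and invertible in closed form:

    - ``"log"`` (default): Delta = p ln(1 + q r), concave;
      inverse r = (exp(target/p) - 1)/q.
    - ``"satlog"``: Delta = -p ln(1 - q r), 0 < q < 1, convex — the exact
      percent-change shape of a saturating (logarithmic-in-emission) ozone
      surface, where cuts become more effective as emissions fall;
      inverse r = (1 - exp(-target/p))/q.
    - ``"auto"``: fit both, keep the one with the smaller residual norm.

    A custom callable ``form(r, p, q)`` (optionally with ``inverse``) can be
    supplied instead.

    Parameters
    ----------
    reductions : array of reduction fractions r in [0, 1]
    change_pct : array of percent metric decreases, 0 at r = 0
    """

    def __init__(self, reductions, change_pct, form="log",
                 inverse: Optional[Callable] = None, bounds=None, p0=None):
        self.r = np.asarray(reductions, dtype=float)
        self.y = np.asarray(change_pct, dtype=float)
        if len(self.r) < 3:
            raise ValueError("need at least 3 points to fit the response form")
        self.form_name = form if isinstance(form, str) else getattr(form, "__name__", "custom")
        if isinstance(form, str):
            if form == "auto":
                self.form = None
                self.inverse = None
                self.bounds = None
                self.p0 = None
                return
            if form not in FORMS:
                raise ValueError(f"unknown form {form!r}; use {list(FORMS)} or 'auto'")
            self.form, self.inverse, self.bounds, self.p0 = FORMS[form]
        else:
            self.form = form
            self.inverse = inverse
            self.bounds = bounds or ([1e-12, 1e-12], [np.inf, np.inf])
            self.p0 = p0 or (10.0, 5.0)

    @classmethod
    def from_curve(cls, curve: ResponseCurve, **kw) -> "LogResponseModel":
        return cls(curve.reductions, curve.change_pct, **kw)

    def fit(self, p0=None, maxfev: int = 20000) -> "LogResponseFit":
        if self.form_name == "auto":
            fits = []
            for name in FORMS:
                try:
                    fits.append(LogResponseModel(self.r, self.y, form=name).fit(maxfev=maxfev))
                except RuntimeError:
                    continue
            if not fits:
                raise RuntimeError("no logarithmic form converged on this curve")
            return min(fits, key=lambda f: f.resid_norm)
        try:
            popt, pcov = curve_fit(
                self.form, self.r, self.y,
                p0=np.asarray(p0 if p0 is not None else self.p0, float),
                bounds=self.bounds, maxfev=maxfev,
            )
        except RuntimeError as e:
            raise RuntimeError(
                f"logarithmic response fit failed to converge: {e}; "
                f"r={self.r.tolist()}, y={self.y.tolist()}"
            ) from e
        resid = self.y - self.form(self.r, *popt)
        return LogResponseFit(model=self, params=popt, cov=pcov,
                              resid=resid)


@dataclass
class LogResponseFit:
    """Results of a :class:`LogResponseModel` fit."""

    model: LogResponseModel
    params: np.ndarray          # (p, q)
    cov: np.ndarray
    resid: np.ndarray

    @property
    def p(self) -> float:
        return float(self.params[0])

    @property
    def q(self) -> float:
        return float(self.params[1])

    @property
    def bse(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.cov))

    @property
    def resid_norm(self) -> float:
        return float(np.linalg.norm(self.resid))

    @property
    def near_linear(self) -> bool:
        """Flags the expansion degeneracy: q r << 1 makes p ln(1+qr) ~ pq r."""
        return bool(self.q * self.model.r.max() < 0.1)

    def predict(self, r) -> np.ndarray:
        return self.model.form(np.asarray(r, dtype=float), *self.params)

    def max_change(self) -> float:
        """Largest attainable metric decrease, at full reduction r = 1."""
        return float(self.predict(1.0))

    def required_reduction(self, target_pct: float) -> RequiredReduction:
        """Invert the fit: reduction needed for a target percent decrease.

        Unreachable targets (beyond the r = 1 response) return a flagged
        result clipped to 100% rather than extrapolating.
        """
        if target_pct <= 0:
            return RequiredReduction(target_pct, 0.0, True)
        if self.model.inverse is None:
            raise ValueError("this response form has no inverse; supply one")
        r = float(self.model.inverse(target_pct, *self.params))
        reachable = r <= 1.0
        return RequiredReduction(target_pct, 100.0 * min(max(r, 0.0), 1.0), reachable)

    def bootstrap_ci(self, n_boot: int = 200, seed: int = 0,
                     level: float = 0.99) -> np.ndarray:
        """Residual-resampling bootstrap percentile intervals for (p, q).

        Returns a (2, 2) array: rows are parameters, columns (lo, hi).
        """
        rng = np.random.default_rng(seed)
        fitted = self.predict(self.model.r)
        n = len(self.resid)
        # inflate residuals for the 2 fitted parameters so the resampled
        # noise level matches the data noise (classic df correction)
        resid = self.resid * np.sqrt(n / max(n - 2, 1))
        boots = []
        for _ in range(n_boot):
            y = fitted + rng.choice(resid, size=n, replace=True)
            try:
                popt, _ = curve_fit(self.model.form, self.model.r, y,
                                    p0=self.params, bounds=self.model.bounds,
                                    maxfev=20000)
                boots.append(popt)
            except RuntimeError:
                continue
        boots = np.array(boots)
        lo = (1.0 - level) / 2.0 * 100.0
        return np.stack([np.percentile(boots[:, i], [lo, 100.0 - lo])
                         for i in range(2)])

    def summary(self) -> str:
        desc = {"log": "Delta(%) = p ln(1 + q r)",
                "satlog": "Delta(%) = -p ln(1 - q r)"}.get(self.model.form_name,
                                                           self.model.form_name)
        lines = [
            f"Logarithmic response fit [{self.model.form_name}]: {desc}",
            "-" * 50,
            f"{'param':>6} {'estimate':>12} {'std err':>12}",
            f"{'p':>6} {self.p:>12.4f} {self.bse[0]:>12.4f}",
            f"{'q':>6} {self.q:>12.4f} {self.bse[1]:>12.4f}",
            "-" * 50,
            f"n points: {len(self.model.r)}   residual norm: {self.resid_norm:.4g}",
            f"max change at r=1: {self.max_change():.2f}%",
        ]
        if self.near_linear:
            lines.append("warning: q r << 1 — form is nearly linear, (p, q) "
                         "individually degenerate (only p*q identified)")
        return "\n".join(lines)


def fit_log_response(curve: ResponseCurve, form="auto", **kw) -> LogResponseFit:
    """Fit a logarithmic form to a response curve (best of the named forms)."""
    return LogResponseModel.from_curve(curve, form=form).fit(**kw)


def required_reduction(fit: LogResponseFit, target_pct: float) -> RequiredReduction:
    return fit.required_reduction(target_pct)


# ---------------------------------------------------------------------------
# penalty
# ---------------------------------------------------------------------------

@dataclass
class PenaltyResult:
    """Extra anthropogenic reduction required because soil emissions are present.

    ``penalty`` is in percentage points of emission reduction:
    required(with soil) - required(without soil).
    """

    target_pct: float
    required_with_soil: float       # %
    required_without_soil: float    # %
    penalty: float                  # percentage points; NaN if either unreachable
    with_reachable: bool
    without_reachable: bool
    diagnostics: dict = field(default_factory=dict)


def soil_penalty(fit_with_soil: LogResponseFit, fit_without_soil: LogResponseFit,
                 target_pct: float) -> PenaltyResult:
    """Penalty for one ozone-control target, from the two fitted curves."""
    rw = fit_with_soil.required_reduction(target_pct)
    ro = fit_without_soil.required_reduction(target_pct)
    ok = rw.reachable and ro.reachable
    return PenaltyResult(
        target_pct=target_pct,
        required_with_soil=rw.reduction_pct,
        required_without_soil=ro.reduction_pct,
        penalty=(rw.reduction_pct - ro.reduction_pct) if ok else float("nan"),
        with_reachable=rw.reachable,
        without_reachable=ro.reachable,
        diagnostics={
            "with_soil": {"p": fit_with_soil.p, "q": fit_with_soil.q,
                          "resid_norm": fit_with_soil.resid_norm},
            "without_soil": {"p": fit_without_soil.p, "q": fit_without_soil.q,
                             "resid_norm": fit_without_soil.resid_norm},
        },
    )


def penalty_table(fit_with_soil: LogResponseFit, fit_without_soil: LogResponseFit,
                  targets: Iterable[float]) -> pd.DataFrame:
    """Penalties for several targets as a tidy table."""
    rows = []
    for t in targets:
        pr = soil_penalty(fit_with_soil, fit_without_soil, t)
        rows.append({
            "target_pct": pr.target_pct,
            "required_with_soil_pct": pr.required_with_soil,
            "required_without_soil_pct": pr.required_without_soil,
            "penalty_pp": pr.penalty,
            "reachable": pr.with_reachable and pr.without_reachable,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# uncertainty envelope
# ---------------------------------------------------------------------------

@dataclass
class EnvelopeResult:
    """Central estimate with a min-max envelope over soil-emission scalings."""

    central: float
    low: float
    high: float
    per_scale: Dict[float, float]

    @property
    def interval(self):
        return (self.low, self.high)


def uncertainty_envelope(compute: Callable[[float], float],
                         scale_factors: Sequence[float] = (0.5, 2.0),
                         central_scale: float = 1.0) -> EnvelopeResult:
    """Repeat a soil-scale-dependent computation under each scaling.

    ``compute(scale)`` maps a soil-emission scale factor (e.g. 0.5, 1, 2 for
    a factor-of-2 uncertainty) to a scalar result; the envelope is the
    min-max over all evaluated scales including the central one.
    """
    per_scale = {central_scale: float(compute(central_scale))}
    for s in scale_factors:
        if s not in per_scale:
            per_scale[s] = float(compute(s))
    vals = list(per_scale.values())
    return EnvelopeResult(central=per_scale[central_scale],
                          low=min(vals), high=max(vals), per_scale=per_scale)
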