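"""Milk withdrawal-interval (WDI) estimators.

Three estimators are provided:

* **half-life method** — ten terminal half-lives (>99% depletion),
  :func:`wdi_halflife`;
* **FDA-style tolerance-limit method** — pooled log-linear regression of the
  post-last-dose residue depletion, with the WDI defined as the time at
  which the upper one-sided 99th-percentile / 95%-confidence tolerance
  limit on concentration falls to the operational tolerance (the assay LOD
  when no finite tolerance exists);
* **EMA-style MRL method** — the same construction with the 95th percentile
  and the maximum residue limit (15 ng/mL for meloxicam in milk).

The tolerance limit at time ``t`` is ``yhat(t) + K(t) * s`` on the log
scale, where ``s`` is the residual SD, ``d(t) = sqrt(1/n + (t - tbar)^2 /
Sxx)`` is the prediction leverage, and ``K = d * q`` with ``q`` the
``gamma``-quantile of the noncentral t distribution with ``n - 2`` degrees
of freedom and noncentrality ``z_p / d``.  Continuous WDIs are rounded up
to the next milking interval for practical use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    BELOW_LOD,
    LOD_FILLED,
    MILK,
    StudyDataset,
    ValidationError,
    depletion_usable_mask,
)

__all__ = [
    "ToleranceSettings",
    "FDA_SETTINGS",
    "EMA_SETTINGS",
    "DepletionModel",
    "DepletionResults",
    "WDIResult",
    "wdi_halflife",
    "round_to_milking",
    "tolerance_factor",
    "estimate_wdi",
]

LOG10 = "base10"
NATURAL = "natural"


@dataclass(frozen=True)
class ToleranceSettings:
    """Percentile/confidence/tolerance triple of a regulatory WDI method."""

    percentile_p: float = 0.99
    confidence_gamma: float = 0.95
    tolerance_conc: float = 4.0  # ng/mL
    log_base: str = LOG10

    def __post_init__(self) -> None:
        if not 0 < self.percentile_p < 1:
            raise ValidationError("percentile_p must be in (0, 1)")
        if not 0 < self.confidence_gamma < 1:
            raise ValidationError("confidence_gamma must be in (0, 1)")
        if self.tolerance_conc <= 0:
            raise ValidationError("tolerance_conc must be positive")
        if self.log_base not in (LOG10, NATURAL):
            raise ValidationError(f"unknown log base {self.log_base!r}")


#: 99th percentile at 95% confidence against the 4 ng/mL LOD proxy tolerance
FDA_SETTINGS = ToleranceSettings(0.99, 0.95, 4.0, LOG10)
#: 95th percentile at 95% confidence against the 15 ng/mL milk MRL
EMA_SETTINGS = ToleranceSettings(0.95, 0.95, 15.0, NATURAL)


def wdi_halflife(t_half: float, factor: float = 10.0) -> float:
    """WDI as ``factor`` terminal half-lives (default 10, >99% depletion)."""
    if t_half <= 0:
        raise ValidationError("t_half must be positive")
    return factor * t_half


def round_to_milking(wdi_h: float, interval: float = 12.0) -> float:
    """Smallest multiple of the milking interval at or above ``wdi_h``."""
    if wdi_h < 0:
        raise ValidationError("wdi_h must be >= 0")
    n = math.ceil(wdi_h / interval - 1e-9)
    return float(max(n, 0) * interval)


def tolerance_factor(n_obs: int, dof: int, p: float, gamma: float, d: float) -> float:
    """One-sided regression tolerance factor K.

    The upper bound ``yhat + K*s`` covers the ``p``-quantile of the
    response distribution at a point with leverage ``d`` with confidence
    ``gamma``; ``K = d * q`` with ``q`` the ``gamma``-quantile of the
    noncentral t distribution (``dof`` degrees of freedom, noncentrality
    ``z_p / d``).
    """
    if dof < 1:
        raise ValidationError("dof must be >= 1")
    if d <= 0:
        raise ValidationError("leverage d must be positive")
    if not (0 < p < 1 and 0 < gamma < 1):
        raise ValidationError("p and gamma must be in (0, 1)")
    z_p = stats.norm.ppf(p)
    q = stats.nct.ppf(gamma, dof, z_p / d)
    if not np.isfinite(q):
        raise ValidationError("noncentral-t quantile is not finite")
    return float(d * q)


def _terminal_milk_observations(
    dataset: StudyDataset,
    *,
    include_lod_fill: bool = True,
    include_measured_bloq: bool = False,
    pooling: str = "pooled",
) -> pd.DataFrame:
    """Terminal-phase usable milk observations on the post-last-dose clock.

    Each animal contributes its milkings from its observed post-last-dose
    milk peak onward; measured values below the LLOQ (and all below-LOD
    records) are excluded unless assigned or simulated.  With
    ``pooling='animal_mean'`` replicates are averaged per animal/time.
    """
    t_dose = dataset.regimen.last_dose_time
    milk = dataset.matrix_frame(MILK)
    milk = milk[milk["time_h"] >= t_dose]
    usable = milk[depletion_usable_mask(milk, include_measured_bloq)]
    if not include_lod_fill:
        usable = usable[usable["provenance"] != LOD_FILLED]
    rows = []
    for animal, adf in usable.groupby("animal_id"):
        means = adf.groupby("time_h")["conc"].mean()
        if means.empty:
            continue
        tmax = means.idxmax()
        terminal = adf[adf["time_h"] >= tmax]
        if pooling == "animal_mean":
            terminal = terminal.groupby("time_h", as_index=False)["conc"].mean()
            terminal["animal_id"] = animal
            terminal["replicate"] = "mean"
        for r in terminal.itertuples(index=False):
            rows.append(
                {
                    "animal_id": animal,
                    "time_post_dose_h": float(r.time_h) - t_dose,
                    "conc": float(r.conc),
                    "replicate": str(r.replicate),
                }
            )
    return pd.DataFrame(rows)


class DepletionModel:
    """Pooled log-linear residue-depletion regression model.

    Observations are (time after last dose, concentration) pairs across all
    animals and replicates, assumed homogeneous given time.  ``fit()``
    returns :class:`DepletionResults` carrying the OLS estimates, residual
    SD, diagnostics and the tolerance-limit WDI machinery.
    """

    def __init__(self, time_post_dose_h, conc, animal_ids=None, min_points_per_animal: int = 4):
        t = np.asarray(time_post_dose_h, dtype=float)
        c = np.asarray(conc, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValidationError("time and concentration must be 1-d and aligned")
        if t.size < 3:
            raise ValidationError("depletion regression needs >= 3 observations")
        if np.any(c <= 0):
            raise ValidationError("concentrations must be positive (censor upstream)")
        if np.ptp(t) == 0:
            raise ValidationError("all observation times identical")
        self.time = t
        self.conc = c
        self.animal_ids = None if animal_ids is None else np.asarray(animal_ids)
        self.min_points_per_animal = min_points_per_animal

    @classmethod
    def from_dataset(
        cls,
        dataset: StudyDataset,
        *,
        pooling: str = "pooled",
        include_lod_fill: bool = True,
        include_measured_bloq: bool = False,
        min_points_per_animal: int = 4,
    ) -> "DepletionModel":
        obs = _terminal_milk_observations(
            dataset,
            include_lod_fill=include_lod_fill,
            include_measured_bloq=include_measured_bloq,
            pooling=pooling,
        )
        if obs.empty:
            raise ValidationError("no usable terminal milk observations")
        return cls(
            obs["time_post_dose_h"],
            obs["conc"],
            animal_ids=obs["animal_id"],
            min_points_per_animal=min_points_per_animal,
        )

    # ------------------------------------------------------------------
    def eligibility(self) -> dict:
        """Regulatory minimum-data diagnostics (10 animals, triplicates,
        >= min_points_per_animal distinct terminal times per animal)."""
        info: dict = {"n_obs": int(self.time.size)}
        if self.animal_ids is not None:
            per_animal = {}
            for a in np.unique(self.animal_ids):
                per_animal[str(a)] = int(len(set(self.time[self.animal_ids == a])))
            short = [a for a, k in per_animal.items() if k < self.min_points_per_animal]
            info["n_animals"] = len(per_animal)
            info["terminal_points_per_animal"] = per_animal
            info["animals_below_minimum"] = short
        return info

    def fit(self, log_base: str = LOG10) -> "DepletionResults":
        ln = np.log(self.conc)
        y = ln / math.log(10) if log_base == LOG10 else ln
        t = self.time
        n = t.size
        slope, intercept = np.polyfit(t, y, 1)
        resid = y - (slope * t + intercept)
        dof = n - 2
        s = math.sqrt(float(resid @ resid) / dof)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
        warnings_list = []
        if slope >= 0:
            warnings_list.append("non-negative depletion slope; no finite WDI")
        elig = self.eligibility()
        if elig.get("animals_below_minimum"):
            warnings_list.append(
                "animals below the minimum terminal-point count: "
                + ", ".join(elig["animals_below_minimum"])
            )
        return DepletionResults(
            model=self,
            slope=float(slope),
            intercept=float(intercept),
            n_obs=n,
            t_mean=float(t.mean()),
            sxx=float(((t - t.mean()) ** 2).sum()),
            residual_sd=s,
            r2=r2,
            log_base=log_base,
            dof=dof,
            warnings=warnings_list,
        )


@dataclass
class DepletionResults:
    """Fitted depletion regression with tolerance-limit WDI estimation."""

    model: DepletionModel
    slope: float
    intercept: float
    n_obs: int
    t_mean: float
    sxx: float
    residual_sd: float
    r2: float
    log_base: str
    dof: int
    warnings: list = field(default_factory=list)

    # ------------------------------------------------------------- helpers
    def _log(self, conc: float) -> float:
        return math.log10(conc) if self.log_base == LOG10 else math.log(conc)

    def predict_log(self, t) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(t, dtype=float)

    def leverage(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.sqrt(1.0 / self.n_obs + (t - self.t_mean) ** 2 / self.sxx)

    def tolerance_bound_log(self, t, settings: ToleranceSettings) -> np.ndarray:
        """Upper one-sided tolerance limit on log-concentration at time t."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        d = self.leverage(t)
        k = np.array(
            [
                tolerance_factor(
                    self.n_obs, self.dof, settings.percentile_p,
                    settings.confidence_gamma, float(di),
                )
                for di in d
            ]
        )
        return self.predict_log(t) + k * self.residual_sd

    # ------------------------------------------------------------- WDI
    def withdrawal_interval(
        self,
        settings: ToleranceSettings,
        *,
        horizon_h: float | None = None,
        milking_interval: float = 12.0,
        method_label: str | None = None,
    ) -> "WDIResult":
        """Latest time at which the tolerance bound reaches the tolerance.

        The bound is scanned over ``[0, horizon]`` (default horizon: the
        deterministic crossing of the mean line plus ten mean-line
        half-lives, at least 10x the data span) and the last down-crossing
        refined by bisection to 0.01 h.  If the bound sits below tolerance
        everywhere the WDI is 0; if it never comes down within the horizon
        the result is flagged non-finite.
        """
        target = self._log(settings.tolerance_conc)
        if self.slope >= 0:
            return WDIResult(
                method=method_label or "tolerance_limit",
                settings=settings,
                wdi_h=None,
                wdi_rounded_h=None,
                finite=False,
                diagnostics=self._diag(),
            )
        if horizon_h is None:
            half_life = -self._log(2.0) / self.slope if self.log_base == NATURAL else (
                math.log10(2) / -self.slope
            )
            mean_cross = (target - self.intercept) / self.slope
            horizon_h = max(
                10.0 * float(np.ptp(self.model.time)),
                mean_cross + 10.0 * half_life,
                120.0,
            )

        grid = np.arange(0.0, horizon_h + 0.25, 0.25)
        bound = self.tolerance_bound_log(grid, settings)
        above = bound > target
        if not above.any():
            wdi = 0.0
        elif above[-1]:
            return WDIResult(
                method=method_label or "tolerance_limit",
                settings=settings,
                wdi_h=None,
                wdi_rounded_h=None,
                finite=False,
                diagnostics=self._diag(),
            )
        else:
            # last index still above the target, then bisect the crossing
            i = int(np.where(above)[0][-1])
            lo, hi = grid[i], grid[i + 1]
            f = lambda t: float(self.tolerance_bound_log(t, settings)[0] - target)
            while hi - lo > 0.01:
                mid = 0.5 * (lo + hi)
                if f(mid) > 0:
                    lo = mid
                else:
                    hi = mid
            wdi = 0.5 * (lo + hi)
        return WDIResult(
            method=method_label or "tolerance_limit",
            settings=settings,
            wdi_h=float(wdi),
            wdi_rounded_h=round_to_milking(wdi, milking_interval),
            finite=True,
            diagnostics=self._diag(),
        )

    def _diag(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "n_obs": self.n_obs,
            "t_mean": self.t_mean,
            "sxx": self.sxx,
            "residual_sd": self.residual_sd,
            "r2": self.r2,
            "log_base": self.log_base,
            "warnings": list(self.warnings),
        }

    # ------------------------------------------------------------- extras
    def regression_pretests(self) -> dict:
        """Optional diagnostics: lack-of-fit F-test and Levene variance
        homogeneity across time points (reported, never acted on)."""
        out: dict = {}
        t, c = self.model.time, self.model.conc
        y = np.log10(c) if self.log_base == LOG10 else np.log(c)
        groups = [y[t == u] for u in np.unique(t)]
        reps = [g for g in groups if g.size > 1]
        if len(reps) >= 2:
            # pure-error decomposition for lack of fit
            sse = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
            resid = y - (self.slope * t + self.intercept)
            ss_res = float(resid @ resid)
            df_pe = sum(g.size - 1 for g in groups)
            df_lof = len(groups) - 2
            if df_lof > 0 and df_pe > 0 and sse > 0:
                f = ((ss_res - sse) / df_lof) / (sse / df_pe)
                out["lack_of_fit_F"] = f
                out["lack_of_fit_p"] = float(stats.f.sf(f, df_lof, df_pe))
            try:
                stat, p = stats.levene(*reps)
                out["levene_p"] = float(p)
            except Exception:  # pragma: no cover - degenerate groups
                pass
        return out

    def summary(self) -> str:
        lines = [
            "Residue depletion regression (log%s concentration vs h post last dose)"
            % ("10" if self.log_base == LOG10 else "e"),
            f"  n_obs={self.n_obs}  slope={self.slope:.5f}/h  intercept={self.intercept:.4f}",
            f"  residual_sd={self.residual_sd:.4f}  R2={self.r2:.4f}  t_mean={self.t_mean:.2f} h",
        ]
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)


@dataclass
class WDIResult:
    """One withdrawal-interval estimate with its provenance."""

    method: str
    settings: ToleranceSettings | float | None
    wdi_h: float | None
    wdi_rounded_h: float | None
    finite: bool = True
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> str:
        if not self.finite or self.wdi_h is None:
            return f"{self.method}: no finite WDI within the search horizon"
        return (
            f"{self.method}: WDI = {self.wdi_h:.2f} h "
            f"(rounded to {self.wdi_rounded_h:.0f} h milking interval)"
        )


def estimate_wdi(
    dataset: StudyDataset,
    method: str = "fda",
    *,
    settings: ToleranceSettings | None = None,
    t_half: float | None = None,
    factor: float = 10.0,
    pooling: str = "pooled",
    milking_interval: float | None = None,
) -> WDIResult:
    """One-call WDI estimation from a study dataset.

    ``method`` is ``"fda"`` (99th percentile vs LOD tolerance), ``"ema"``
    (95th percentile vs MRL) or ``"halflife"`` (requires ``t_half``, e.g.
    the geometric-mean theoretical milk half-life from the NCA).
    """
    interval = milking_interval if milking_interval is not None else dataset.milking_interval
    if method == "halflife":
        if t_half is None:
            raise ValidationError("halflife method requires t_half")
        wdi = wdi_halflife(t_half, factor)
        return WDIResult(
            method="halflife10",
            settings=factor,
            wdi_h=wdi,
            wdi_rounded_h=round_to_milking(wdi, interval),
            diagnostics={"t_half": t_half, "factor": factor},
        )
    base = {"fda": FDA_SETTINGS, "ema": EMA_SETTINGS}.get(method)
    if base is None:
        raise ValidationError(f"unknown WDI method {method!r}")
    st = settings or base
    model = DepletionModel.from_dataset(dataset, pooling=pooling)
    res = model.fit(st.log_base)
    label = "fda_tolerance" if method == "fda" else "ema_mrl"
    return res.withdrawal_interval(
        st, milking_interval=interval, method_label=label
    )
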