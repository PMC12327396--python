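"""Non-compartmental analysis (NCA) of multi-dose concentration-time data.

Per animal, the engine estimates the standard parameter set from plasma
around the first and the last dose of a repeated regimen — Cmax/Tmax, the
terminal elimination rate ``lambda_z`` and half-life, linear-trapezoid AUCs
(over a dosing interval, and extrapolated to infinity), percentage of
extrapolated area, MRT, Vd/F, CL/F and the accumulation ratio Rac — plus the
observed and theoretical milk parameters (Cmax, Tmax, theoretical terminal
half-life, AUC from the last dose to infinity) and the milk-to-plasma AUC
ratio.  Results are geometric-mean/GSD summarised across animals.

The terminal phase is chosen WinNonlin-style: among the last-k point sets
(k >= 3, excluding the observed Cmax point), the fit maximising adjusted R^2
wins, ties going to the larger set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    BELOW_LOD,
    MILK,
    PLASMA,
    DosingRegimen,
    StudyDataset,
    ValidationError,
    geometric_summary,
)
from .simulate import NG_PER_MG

__all__ = [
    "TerminalPhaseFit",
    "NCAConfig",
    "NCA",
    "NCAResults",
    "NoFitError",
    "select_terminal_phase",
    "auc_linear_trapezoid",
    "aumc_linear_trapezoid",
    "auc_extrapolated",
    "derived_parameters",
    "milk_parameters",
]


class NoFitError(ValueError):
    """A terminal log-linear phase could not be estimated."""


@dataclass(frozen=True)
class TerminalPhaseFit:
    """OLS fit of ln(conc) on time over the terminal phase."""

    lambda_z: float  # 1/h, positive
    intercept: float  # ln(ng/mL) at t=0 of the fit clock
    points_used: tuple  # times entering the regression
    r2_adj: float
    span_h: float

    @property
    def t_half(self) -> float:
        return math.log(2) / self.lambda_z

    def predict(self, t) -> np.ndarray:
        return np.exp(self.intercept - self.lambda_z * np.asarray(t, dtype=float))


def _ols_loglinear(t: np.ndarray, c: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, adjusted R^2 of ln(c) ~ t."""
    y = np.log(c)
    n = t.size
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        r2 = 1.0 if ss_res < 1e-24 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return float(slope), float(intercept), float(r2_adj)


def select_terminal_phase(
    times,
    concs,
    *,
    min_points: int = 3,
    max_points: int | None = None,
    exclude_tmax: bool = True,
    label: str = "",
) -> TerminalPhaseFit:
    """Choose the terminal log-linear phase and fit lambda_z.

    Candidate point sets are the last ``k`` observations for
    ``k = min_points .. K`` where the window never reaches back to the
    observed Cmax point (when ``exclude_tmax``).  The candidate with the
    highest adjusted R^2 (ties -> more points) whose slope is negative is
    returned.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    keep = np.isfinite(c) & (c > 0)
    t, c = t[keep], c[keep]
    order = np.argsort(t, kind="stable")
    t, c = t[order], c[order]
    i_max = int(np.argmax(c))
    first_idx = i_max + 1 if exclude_tmax else i_max
    t_cand, c_cand = t[first_idx:], c[first_idx:]
    n = t_cand.size
    if n < min_points:
        raise NoFitError(
            f"terminal phase needs >= {min_points} post-peak points"
            + (f" ({label})" if label else "")
        )
    k_hi = n if max_points is None else min(n, max_points)
    best = None
    for k in range(min_points, k_hi + 1):
        tt, cc = t_cand[-k:], c_cand[-k:]
        if np.ptp(tt) == 0:
            continue
        slope, intercept, r2_adj = _ols_loglinear(tt, cc)
        if slope >= 0:
            continue
        if best is None or r2_adj >= best[0] - 1e-12:
            best = (r2_adj, k, slope, intercept, tuple(tt))
    if best is None:
        raise NoFitError(
            "no negative-slope terminal phase found" + (f" ({label})" if label else "")
        )
    r2_adj, k, slope, intercept, used = best
    return TerminalPhaseFit(
        lambda_z=-slope,
        intercept=intercept,
        points_used=used,
        r2_adj=r2_adj,
        span_h=used[-1] - used[0],
    )


def auc_linear_trapezoid(times, concs, t_start: float, t_end: float) -> float:
    """Linear-trapezoid AUC of the sampled curve over [t_start, t_end].

    Window ends falling between samples are handled by linear
    interpolation; the window must lie inside the sampled span.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t_end < t_start:
        raise ValidationError("t_end must be >= t_start")
    if t_start < t[0] - 1e-9 or t_end > t[-1] + 1e-9:
        raise ValidationError(
            f"window [{t_start}, {t_end}] outside data span [{t[0]}, {t[-1]}]"
        )
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    grid = np.unique(np.concatenate([t[(t > t_start) & (t < t_end)], [t_start, t_end]]))
    vals = np.interp(grid, t, c)
    return float(np.trapezoid(vals, grid))


def aumc_linear_trapezoid(times, concs, t_start: float, t_end: float, origin: float = 0.0) -> float:
    """First-moment AUC (integral of (t-origin)*C dt) by linear trapezoids."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    return auc_linear_trapezoid(t, (t - origin) * c, t_start, t_end)


def auc_extrapolated(
    times, concs, fit: TerminalPhaseFit, t_start: float
) -> tuple[float, float]:
    """AUC from t_start to infinity and the % of area beyond the last sample.

    AUC_inf = AUC(t_start -> t_last) + C_last / lambda_z;
    pct = 100 * tail / AUC_inf.
    """
    if fit.lambda_z <= 0:
        raise ValidationError("lambda_z must be positive for extrapolation")
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    observed = auc_linear_trapezoid(t, c, t_start, t[-1])
    tail = c[-1] / fit.lambda_z
    total = observed + tail
    pct = 100.0 * tail / total if total > 0 else 0.0
    return float(total), float(pct)


def derived_parameters(
    dose_per_kg: float,
    auc_inf_ng_h: float,
    fit: TerminalPhaseFit,
    aumc_inf_ng_h2: float | None = None,
) -> dict:
    """CL/F, Vd/F and MRT from dose, AUC-to-infinity and the terminal fit.

    Dose is mg/kg, AUC ng*h/mL, so CL/F comes out in mL/kg/h and Vd/F in
    mL/kg without further conversion.
    """
    if auc_inf_ng_h <= 0:
        raise ValidationError("AUC to infinity must be positive")
    cl_over_f = dose_per_kg * NG_PER_MG / auc_inf_ng_h
    vd_over_f = cl_over_f / fit.lambda_z
    out = {"cl_over_f": cl_over_f, "vd_over_f": vd_over_f}
    if aumc_inf_ng_h2 is not None:
        out["mrt"] = aumc_inf_ng_h2 / auc_inf_ng_h
    return out


def _quantifiable_series(df: pd.DataFrame, include_bloq_values: bool = True) -> pd.DataFrame:
    """Mean usable concentration per time; drops below-LOD records and
    truncates at the last usable time."""
    usable = df[df["censor"] != BELOW_LOD].dropna(subset=["conc"])
    if not include_bloq_values:
        usable = usable[usable["censor"] == "quantified"]
    series = usable.groupby("time_h", as_index=False)["conc"].mean()
    return series.sort_values("time_h").reset_index(drop=True)


def milk_parameters(
    milk_df: pd.DataFrame,
    last_dose_time: float,
    *,
    min_points: int = 3,
    max_points: int | None = None,
    label: str = "",
) -> dict:
    """Observed and theoretical milk parameters after the last dose.

    Cmax/Tmax are read off the replicate-mean post-last-dose series (Tmax
    reported on the post-last-dose clock); the theoretical terminal
    half-life and AUC(last dose -> infinity) come from the terminal
    log-linear fit and trapezoid extrapolation.
    """
    series = _quantifiable_series(milk_df)
    t_all = series["time_h"].to_numpy()
    c_all = series["conc"].to_numpy()
    post = t_all >= last_dose_time
    if not post.any():
        raise NoFitError(f"no quantifiable milk after the last dose ({label})")
    t = t_all[post]
    c = c_all[post]
    i_max = int(np.argmax(c))
    fit = select_terminal_phase(
        t, c, min_points=min_points, max_points=max_points, label=label
    )
    # the AUC window starts at the dosing time, interpolating across the
    # milking straddling it when one exists on each side
    t_start = max(last_dose_time, float(t_all[0]))
    auc_inf, pct = auc_extrapolated(t_all, c_all, fit, t_start=t_start)
    return {
        "cmax_ug_ml": c[i_max] / 1000.0,
        "tmax_post_dose_h": t[i_max] - last_dose_time,
        "t_half_theo_h": fit.t_half,
        "lambda_z": fit.lambda_z,
        "auc_last_to_inf_ug_h_ml": auc_inf / 1000.0,
        "pct_extrapolated": pct,
        "terminal_fit": fit,
    }


@dataclass(frozen=True)
class NCAConfig:
    min_terminal_points: int = 3
    exclude_tmax: bool = True
    include_bloq_values: bool = True  # between-LOD/LLOQ values usable
    #: manual lambda-z override: animal_id -> number of last points to fit
    terminal_points_override: dict = field(default_factory=dict)


class NCA:
    """Non-compartmental analysis model over a StudyDataset.

    ``NCA(dataset).fit()`` returns :class:`NCAResults` with per-animal
    plasma (first-dose and last-dose) and milk parameter tables.
    """

    def __init__(self, dataset: StudyDataset, config: NCAConfig | None = None):
        self.dataset = dataset
        self.config = config or NCAConfig()

    def fit(self) -> "NCAResults":
        ds = self.dataset
        cfg = self.config
        regimen = ds.regimen
        tau = regimen.interval_tau
        t_last_dose = regimen.last_dose_time
        plasma_rows, milk_rows, failures = [], [], []
        for animal in ds.animal_ids:
            adf = ds.frame[ds.frame["animal_id"] == animal]
            row = {"animal_id": animal}
            pdf = adf[adf["matrix"] == PLASMA]
            if not pdf.empty:
                try:
                    row.update(self._plasma_parameters(pdf, regimen, cfg, animal))
                except NoFitError as exc:
                    failures.append(f"plasma/{animal}: {exc}")
            mdf = adf[adf["matrix"] == MILK]
            milk = None
            if not mdf.empty:
                override = cfg.terminal_points_override.get(animal)
                try:
                    milk = milk_parameters(
                        mdf,
                        t_last_dose,
                        min_points=override or cfg.min_terminal_points,
                        max_points=override,
                        label=f"milk/{animal}",
                    )
                except NoFitError as exc:
                    failures.append(f"milk/{animal}: {exc}")
            if milk is not None:
                mrow = {"animal_id": animal}
                mrow.update({k: v for k, v in milk.items() if k != "terminal_fit"})
                if row.get("auc_tau_to_inf_ug_h_ml"):
                    mrow["milk_plasma_auc_ratio"] = (
                        milk["auc_last_to_inf_ug_h_ml"] / row["auc_tau_to_inf_ug_h_ml"]
                    )
                milk_rows.append(mrow)
            if len(row) > 1:
                plasma_rows.append(row)
        return NCAResults(
            plasma=pd.DataFrame(plasma_rows),
            milk=pd.DataFrame(milk_rows),
            failures=failures,
            dataset=ds,
        )

    def _plasma_parameters(
        self, pdf: pd.DataFrame, regimen: DosingRegimen, cfg: NCAConfig, animal: str
    ) -> dict:
        tau = regimen.interval_tau
        t0 = regimen.first_dose_time
        t_last_dose = regimen.last_dose_time
        series = _quantifiable_series(pdf, cfg.include_bloq_values)
        t = series["time_h"].to_numpy()
        c = series["conc"].to_numpy()
        out: dict = {}

        # ---- first-dose interval [t0, t0 + tau]
        first = (t >= t0) & (t <= t0 + tau + 1e-9)
        t1, c1 = t[first], c[first]
        if t1.size >= 3 and c1.max() > 0:
            if t1[0] > t0:
                # pre-dose concentration is zero (below LOD): anchor the AUC
                t1 = np.concatenate([[t0], t1])
                c1 = np.concatenate([[0.0], c1])
            i_max = int(np.argmax(c1))
            out["cmax_first_ug_ml"] = c1[i_max] / 1000.0
            out["tmax_first_h"] = t1[i_max] - t0
            out["auc_0_tau_ug_h_ml"] = auc_linear_trapezoid(t1, c1, t0, t1[-1]) / 1000.0
            try:
                fit1 = select_terminal_phase(
                    t1, c1, min_points=cfg.min_terminal_points,
                    exclude_tmax=cfg.exclude_tmax, label=f"plasma-first/{animal}",
                )
            except NoFitError:
                # short first-dose windows may leave < 3 points past the
                # peak; fall back to a fit that admits the Cmax point
                try:
                    fit1 = select_terminal_phase(
                        t1, c1, min_points=cfg.min_terminal_points,
                        exclude_tmax=False, label=f"plasma-first/{animal}",
                    )
                except NoFitError:
                    fit1 = None
            if fit1 is not None:
                out["t_half_first_h"] = fit1.t_half
                auc1_inf, pct1 = auc_extrapolated(t1, c1, fit1, t_start=t0)
                out["auc_0_inf_ug_h_ml"] = auc1_inf / 1000.0
                out["pct_extrapolated_first"] = pct1

        # ---- last-dose segment [t_last_dose, end]
        lastseg = t >= t_last_dose - 1e-9
        t2, c2 = t[lastseg], c[lastseg]
        if t2.size >= 3 and c2.max() > 0:
            within_tau = t2 <= t_last_dose + tau + 1e-9
            t2tau, c2tau = t2[within_tau], c2[within_tau]
            i_max = int(np.argmax(c2tau)) if t2tau.size else int(np.argmax(c2))
            out["cmax_last_ug_ml"] = c2tau[i_max] / 1000.0
            out["tmax_last_h"] = t2tau[i_max] - t_last_dose
            override = cfg.terminal_points_override.get(animal)
            fit2 = select_terminal_phase(
                t2, c2,
                min_points=override or cfg.min_terminal_points,
                max_points=override,
                exclude_tmax=cfg.exclude_tmax, label=f"plasma-last/{animal}",
            )
            out["lambda_z"] = fit2.lambda_z
            out["t_half_last_h"] = fit2.t_half
            if t2tau.size >= 2:
                out["auc_tau_ss_ug_h_ml"] = (
                    auc_linear_trapezoid(t2tau, c2tau, t_last_dose, t2tau[-1]) / 1000.0
                )
            auc2_inf, pct2 = auc_extrapolated(t2, c2, fit2, t_start=t_last_dose)
            out["auc_tau_to_inf_ug_h_ml"] = auc2_inf / 1000.0
            out["pct_extrapolated_last"] = pct2
            aumc_obs = aumc_linear_trapezoid(t2, c2, t_last_dose, t2[-1], origin=t_last_dose)
            tl_rel = t2[-1] - t_last_dose
            aumc_inf = aumc_obs + c2[-1] * tl_rel / fit2.lambda_z + c2[-1] / fit2.lambda_z**2
            derived = derived_parameters(
                regimen.dose_per_kg, auc2_inf, fit2, aumc_inf_ng_h2=aumc_inf
            )
            out["cl_over_f_ml_kg_h"] = derived["cl_over_f"]
            out["vd_over_f_ml_kg"] = derived["vd_over_f"]
            out["mrt_h"] = derived["mrt"]
            if out.get("auc_0_tau_ug_h_ml") and out.get("auc_tau_ss_ug_h_ml"):
                out["rac"] = out["auc_tau_ss_ug_h_ml"] / out["auc_0_tau_ug_h_ml"]
        return out


@dataclass
class NCAResults:
    """Per-animal NCA tables plus geometric summaries."""

    plasma: pd.DataFrame
    milk: pd.DataFrame
    failures: list = field(default_factory=list)
    dataset: StudyDataset | None = None

    def summary(self, which: str = "milk") -> pd.DataFrame:
        """Geometric mean / GSD / range per parameter across animals."""
        table = {"milk": self.milk, "plasma": self.plasma}[which]
        rows = []
        for col in table.columns:
            if col == "animal_id":
                continue
            vals = table[col].dropna()
            vals = vals[vals > 0]
            if vals.empty:
                continue
            s = geometric_summary(vals)
            rows.append(
                {
                    "parameter": col,
                    "geometric_mean": s.gm,
                    "gsd": s.gsd,
                    "min": s.min,
                    "max": s.max,
                    "n": s.n,
                }
            )
        return pd.DataFrame(rows)
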