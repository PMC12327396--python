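"""Monte Carlo data-augmentation scenarios for tolerance-limit WDI analysis.

Regulatory tolerance-limit methods expect ten animals with triplicate
assays and at least four terminal-phase time points per animal.  Real
extra-label studies often fall short; three published augmentation
strategies make such datasets eligible:

1. **LOD back-fill** — animals lacking a fourth usable terminal milk time
   point receive an assigned concentration equal to the assay LOD at a
   chosen milking;
2. **virtual animals** — additional in-silico animals drawn per time point
   from the mean and coefficient of variation of a set of base animals;
3. **simulated replicates** — triplicates reconstructed from a single
   replicate (A) using the pooled mean/CV structure of that replicate.

All three are pure functions of (dataset, options, seed) and mark every
added record's provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    BELOW_LOD,
    LOD_FILLED,
    MILK,
    SIMULATED,
    StudyDataset,
    ValidationError,
    apply_censoring,
    depletion_usable_mask,
)

__all__ = [
    "scenario1_lod_fill",
    "scenario2_virtual_animals",
    "scenario3_simulated_replicates",
    "terminal_time_points",
    "select_base_animals",
    "generate_matched_dataset",
]

LOGNORMAL = "lognormal_meancv"
TRUNCNORM = "normal_truncated"


def _usable_milk(dataset: StudyDataset) -> pd.DataFrame:
    milk = dataset.matrix_frame(MILK)
    return milk[depletion_usable_mask(milk)]


def terminal_time_points(dataset: StudyDataset, animal_id: str) -> list[float]:
    """Quantifiable milk time points in the animal's post-last-dose
    depletion phase, counted from the replicate-mean peak milking onward
    (the counting convention of the regulatory minimum-data check)."""
    t_dose = dataset.regimen.last_dose_time
    usable = _usable_milk(dataset)
    adf = usable[(usable["animal_id"] == animal_id) & (usable["time_h"] >= t_dose)]
    if adf.empty:
        return []
    means = adf.groupby("time_h")["conc"].mean()
    tmax = means.idxmax()
    return sorted(means.index[means.index >= tmax].tolist())


def select_base_animals(dataset: StudyDataset, n: int = 5) -> list[str]:
    """Base animals for virtual-animal simulation: the animals quantifiable
    at their 4th terminal milk time point, i.e. the slower-eliminating
    half of the cohort.

    When more than ``n`` qualify, the ``n`` with the highest concentration
    at that milking are kept (the strongest slow-eliminator bias, which is
    the configuration this design is meant to emulate).
    """
    milk = dataset.matrix_frame(MILK)
    usable = milk[depletion_usable_mask(milk)]
    cand: dict[str, float] = {}
    for animal in sorted(milk["animal_id"].unique()):
        tp = terminal_time_points(dataset, animal)
        if len(tp) < 4:
            continue
        at4 = usable[(usable["animal_id"] == animal) & (usable["time_h"] == tp[3])]
        cand[animal] = float(at4["conc"].mean())
    if len(cand) < 2:
        raise ValidationError("fewer than two animals qualify as base animals")
    return sorted(sorted(cand, key=cand.get, reverse=True)[:n])


def generate_matched_dataset(seed: int, n_eligible: int = 5, max_tries: int = 500):
    """Simulate study cohorts until the published eligibility split appears.

    The study this generator emulates had exactly 5 of 10 animals with at
    least four quantifiable terminal milk time points; scenario comparisons
    are only meaningful at that matched design.  Walks simulation seeds
    from ``seed`` upward and returns the first dataset realising the
    ``n_eligible``-of-n split.
    """
    from .simulate import PopulationPK, generate_dataset

    for i in range(max_tries):
        pop = PopulationPK(seed=seed + i)
        ds = generate_dataset(pop)
        n_ok = sum(
            len(terminal_time_points(ds, a)) >= 4 for a in ds.animal_ids
        )
        if n_ok == n_eligible:
            return ds
    raise ValidationError(
        f"no {n_eligible}-eligible cohort within {max_tries} seeds from {seed}"
    )


def _draw(mean: float, cv: float, size: int, rng: np.random.Generator, distribution: str) -> np.ndarray:
    """Positive draws with the requested mean and coefficient of variation."""
    if mean <= 0:
        raise ValidationError("draw mean must be positive")
    if cv < 0:
        raise ValidationError("draw CV must be >= 0")
    if cv == 0:
        return np.full(size, mean)
    if distribution == LOGNORMAL:
        sigma2 = math.log(1.0 + cv * cv)
        mu = math.log(mean) - sigma2 / 2.0
        return np.exp(mu + math.sqrt(sigma2) * rng.standard_normal(size))
    if distribution == TRUNCNORM:
        sd = cv * mean
        a = (0.0 - mean) / sd
        return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)
    raise ValidationError(f"unknown distribution {distribution!r}")


def scenario1_lod_fill(
    dataset: StudyDataset,
    *,
    min_terminal_points: int = 4,
    fill_time_h: float = 166.0,
) -> StudyDataset:
    """Back-fill short animals with an LOD-valued terminal milking.

    Any animal with fewer than ``min_terminal_points`` usable terminal milk
    time points gets one record per replicate at ``fill_time_h`` (study
    clock) with concentration equal to the LOD, provenance ``lod_filled``.
    Compliant animals are untouched.
    """
    lod = dataset.limits.lod
    milk = dataset.matrix_frame(MILK)
    if milk.empty:
        raise ValidationError("dataset has no milk records")
    new_rows = []
    frame = dataset.frame
    for animal in sorted(milk["animal_id"].unique()):
        terminal = terminal_time_points(dataset, animal)
        if len(terminal) >= min_terminal_points:
            continue
        if terminal and fill_time_h <= max(terminal):
            raise ValidationError(
                f"fill time {fill_time_h} h is not after {animal}'s last "
                f"quantifiable milking ({max(terminal)} h)"
            )
        # the assignment replaces whatever unquantifiable measurement the
        # animal has at the fill milking
        drop = (
            (frame["animal_id"] == animal)
            & (frame["matrix"] == MILK)
            & (frame["time_h"] == float(fill_time_h))
        )
        frame = frame[~drop]
        replicates = sorted(milk[milk["animal_id"] == animal]["replicate"].unique())
        conc, censor = apply_censoring(lod, dataset.limits)
        for rep in replicates:
            new_rows.append(
                {
                    "animal_id": animal,
                    "matrix": MILK,
                    "time_h": float(fill_time_h),
                    "replicate": rep,
                    "conc": conc,
                    "censor": censor,
                    "provenance": LOD_FILLED,
                }
            )
    if not new_rows:
        return dataset.with_frame(frame)
    frame = pd.concat([frame, pd.DataFrame(new_rows)], ignore_index=True)
    return dataset.with_frame(frame)


def scenario2_virtual_animals(
    dataset: StudyDataset,
    base_animals: list[str],
    *,
    n_virtual: int = 5,
    seed: int = 0,
    distribution: str = LOGNORMAL,
    per_replicate_draws: bool = False,
    keep_other_animals: bool = False,
) -> StudyDataset:
    """Expand a small cohort with virtual animals drawn from its time-point
    statistics.

    The output cohort is the base animals plus ``n_virtual`` virtual
    animals (animals outside the base set are dropped unless
    ``keep_other_animals``, mirroring the published design of expanding a
    five-animal dataset to ten).  Virtual concentrations are generated at
    every milk time point where at least two base animals have a
    quantifiable value; the animal-mean concentrations of that quantifiable
    subset give the mean and CV, and each virtual animal gets one draw per
    time point (copied across the triplicate labels unless
    ``per_replicate_draws``).  Because the quantifiable subset at late time
    points is the slower-eliminating tail of the base cohort, the virtual
    animals inherit its survivor bias — the conservatism this design is
    known for.  Virtual animals carry ids ``V1..Vn`` and provenance
    ``simulated``.
    """
    if n_virtual < 1:
        raise ValidationError("n_virtual must be >= 1")
    if len(set(base_animals)) < 2:
        raise ValidationError("scenario 2 needs >= 2 base animals (CV undefined)")
    usable = _usable_milk(dataset)
    base = usable[usable["animal_id"].isin(base_animals)]
    missing = sorted(set(base_animals) - set(base["animal_id"]))
    if missing:
        raise ValidationError(f"base animals without usable milk data: {missing}")
    rng = np.random.default_rng(seed)
    replicates = sorted(dataset.matrix_frame(MILK)["replicate"].unique()) or ["A", "B", "C"]
    # animal-mean concentration per base animal per time point
    animal_means = base.groupby(["time_h", "animal_id"])["conc"].mean().reset_index()
    new_rows = []
    virtual_ids = [f"V{i + 1}" for i in range(n_virtual)]
    existing = set(dataset.frame["animal_id"])
    clash = existing.intersection(virtual_ids)
    if clash:
        raise ValidationError(f"virtual ids already present: {sorted(clash)}")
    for t, tdf in animal_means.groupby("time_h"):
        vals = tdf["conc"].to_numpy()
        if vals.size < 2:
            continue  # CV undefined: point not used for virtual animals
        mean = float(vals.mean())
        cv = float(vals.std(ddof=1) / mean)
        for vid in virtual_ids:
            if per_replicate_draws:
                draws = _draw(mean, cv, len(replicates), rng, distribution)
            else:
                draws = np.repeat(_draw(mean, cv, 1, rng, distribution), len(replicates))
            for rep, val in zip(replicates, draws):
                conc, censor = apply_censoring(float(val), dataset.limits)
                new_rows.append(
                    {
                        "animal_id": vid,
                        "matrix": MILK,
                        "time_h": float(t),
                        "replicate": rep,
                        "conc": conc,
                        "censor": censor,
                        "provenance": SIMULATED,
                    }
                )
    base_frame = dataset.frame
    if not keep_other_animals:
        keep = base_frame["animal_id"].isin(base_animals)
        base_frame = base_frame[keep]
    frame = pd.concat([base_frame, pd.DataFrame(new_rows)], ignore_index=True)
    weights = dict(dataset.body_weights)
    if not keep_other_animals:
        weights = {a: w for a, w in weights.items() if a in set(base_animals)}
    if weights:
        ref = float(np.mean(list(weights.values())))
        weights.update({vid: ref for vid in virtual_ids})
    return StudyDataset(
        regimen=dataset.regimen,
        limits=dataset.limits,
        frame=frame,
        milking_interval=dataset.milking_interval,
        first_milking_time=dataset.first_milking_time,
        body_weights=weights,
    )


def pooled_replicate_a_cv(dataset: StudyDataset, base_replicate: str = "A") -> float:
    """Pooled CV of Replicate A: root-mean-square across-animal CV at each
    terminal milk time point, pooled over time points with >= 2 animals."""
    t_dose = dataset.regimen.last_dose_time
    usable = _usable_milk(dataset)
    rep_a = usable[(usable["replicate"] == base_replicate) & (usable["time_h"] >= t_dose)]
    cvs = []
    for t, tdf in rep_a.groupby("time_h"):
        # keep true terminal points: past each animal's peak
        vals = []
        for animal, adf in tdf.groupby("animal_id"):
            if t in terminal_time_points(dataset, animal):
                vals.append(float(adf["conc"].iloc[0]))
        if len(vals) >= 2:
            v = np.asarray(vals)
            cvs.append(float(v.std(ddof=1) / v.mean()))
    if not cvs:
        raise ValidationError("no terminal time point with >= 2 Replicate-A values")
    return float(np.sqrt(np.mean(np.square(cvs))))


def scenario3_simulated_replicates(
    dataset: StudyDataset,
    *,
    seed: int = 0,
    cv_source: str = "pooled_terminal",
    fixed_cv: float | None = None,
    base_replicate: str = "A",
    distribution: str = LOGNORMAL,
) -> StudyDataset:
    """Rebuild triplicates from a single-replicate milk dataset.

    Milk is restricted to ``base_replicate``; two simulated replicates
    (``simulated_repB``/``simulated_repC``) are drawn per animal/time with
    mean equal to the Replicate-A value and CV from ``cv_source``
    (``"pooled_terminal"`` — the pooled across-animal Replicate-A CV — or
    ``"fixed"`` with ``fixed_cv``).  Below-LOD Replicate-A points stay
    below LOD in the generated replicates.
    """
    milk = dataset.matrix_frame(MILK)
    rep_a = milk[milk["replicate"] == base_replicate]
    if rep_a.empty:
        raise ValidationError(f"no Replicate {base_replicate} milk records")
    base_frame = pd.concat(
        [dataset.frame[dataset.frame["matrix"] != MILK], rep_a], ignore_index=True
    )
    restricted = dataset.with_frame(base_frame)
    if cv_source == "fixed":
        if fixed_cv is None or fixed_cv < 0:
            raise ValidationError("cv_source='fixed' requires fixed_cv >= 0")
        cv = float(fixed_cv)
    elif cv_source == "pooled_terminal":
        cv = pooled_replicate_a_cv(restricted, base_replicate)
    else:
        raise ValidationError(f"unknown cv_source {cv_source!r}")

    rng = np.random.default_rng(seed)
    new_rows = []
    for r in rep_a.itertuples(index=False):
        for new_rep in ("simulated_repB", "simulated_repC"):
            if r.censor == BELOW_LOD or pd.isna(r.conc):
                conc, censor = None, BELOW_LOD
            else:
                val = float(_draw(float(r.conc), cv, 1, rng, distribution)[0])
                conc, censor = apply_censoring(val, dataset.limits)
            new_rows.append(
                {
                    "animal_id": r.animal_id,
                    "matrix": MILK,
                    "time_h": float(r.time_h),
                    "replicate": new_rep,
                    "conc": np.nan if conc is None else conc,
                    "censor": censor,
                    "provenance": SIMULATED,
                }
            )
    frame = pd.concat([base_frame, pd.DataFrame(new_rows)], ignore_index=True)
    return dataset.with_frame(frame)
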