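"""Non-compartmental engine: terminal fits, AUCs, derived parameters."""

import math

import numpy as np
import pandas as pd
import pytest

from milkwdi.data import DosingRegimen, ValidationError
from milkwdi.nca import (
    NCA,
    NoFitError,
    auc_extrapolated,
    auc_linear_trapezoid,
    aumc_linear_trapezoid,
    derived_parameters,
    milk_parameters,
    select_terminal_phase,
)
from milkwdi.simulate import (
    IndividualPK,
    PopulationPK,
    SamplingSchedule,
    generate_dataset,
    simulate_plasma_profile,
)

from conftest import make_dataset


class TestTerminalPhase:
    def test_exact_exponential_recovered(self):
        t = np.array([10.0, 20, 30, 40, 50])
        c = 100.0 * np.exp(-0.1 * t)
        fit = select_terminal_phase(t, c, exclude_tmax=False)
        assert fit.lambda_z == pytest.approx(0.1, abs=1e-9)
        assert fit.t_half == pytest.approx(math.log(2) / 0.1, rel=1e-9)

    def test_two_fold_drop_gives_seven_hour_half_life(self):
        fit = select_terminal_phase(
            [0.0, 7.0], [100.0, 50.0], min_points=2, exclude_tmax=False
        )
        assert fit.t_half == pytest.approx(7.0, rel=1e-12)

    def test_insufficient_points_raise_no_fit(self):
        with pytest.raises(NoFitError, match="G9"):
            select_terminal_phase([0, 1, 2], [1.0, 5.0, 4.0], label="G9")

    def test_cmax_point_excluded_from_candidates(self):
        t = np.array([0.0, 2, 4, 8, 16, 24])
        c = np.array([1.0, 100.0, 80.0, 40.0, 10.0, 2.5])
        fit = select_terminal_phase(t, c)
        assert 2.0 not in fit.points_used

    def test_half_life_invariant_to_concentration_scale(self):
        t = np.array([5.0, 10, 20, 30, 40, 55])
        c = 80.0 * np.exp(-0.09 * t) * np.exp(0.02 * np.sin(t))
        a = select_terminal_phase(t, c, exclude_tmax=False)
        b = select_terminal_phase(t, 137.0 * c, exclude_tmax=False)
        assert a.t_half == pytest.approx(b.t_half, rel=1e-12)
        assert a.points_used == b.points_used

    def test_noisy_profiles_recover_ke_within_five_percent(self):
        # 100 animals, 3% assay CV, no inter-animal variability
        pop = PopulationPK(
            n_animals=100,
            seed=5,
            analytical_cv=0.03,
            iiv_gsd={"ka": 1.0, "ke": 1.0, "v_over_f": 1.0, "mp_ratio": 1.0},
        )
        ds = generate_dataset(pop)
        lam = NCA(ds).fit().plasma["lambda_z"].dropna()
        rel_err = np.abs(lam - pop.ke_gm) / pop.ke_gm
        assert np.median(rel_err) < 0.05


class TestAUC:
    def test_rectangle(self):
        assert auc_linear_trapezoid([0, 24], [2.0, 2.0], 0, 24) == pytest.approx(48.0)

    def test_triangle(self):
        assert auc_linear_trapezoid([0, 1, 2], [0, 2.0, 0], 0, 2) == pytest.approx(2.0)

    def test_dense_exponential_matches_analytic_integral(self):
        t = np.arange(0, 10.0001, 0.01)
        c = np.exp(-t)
        auc = auc_linear_trapezoid(t, c, 0, 10)
        assert auc == pytest.approx(1 - math.exp(-10), abs=1e-4)

    def test_additivity_at_interior_points(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 50, 20))
        c = rng.uniform(0.1, 10, 20)
        total = auc_linear_trapezoid(t, c, t[0], t[-1])
        split = auc_linear_trapezoid(t, c, t[0], t[7]) + auc_linear_trapezoid(
            t, c, t[7], t[-1]
        )
        assert split == pytest.approx(total, rel=1e-12)

    def test_window_outside_span_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            auc_linear_trapezoid([0, 10], [1.0, 1.0], 0, 20)

    def test_extrapolation_matches_closed_form(self):
        # exact exponential sampled from t=0: tail fraction is e^{-lam*t_last}
        lam = 0.12
        t = np.arange(0, 58.25, 0.25)
        c = 50.0 * np.exp(-lam * t)
        fit = select_terminal_phase(t, c, exclude_tmax=False)
        auc_inf, pct = auc_extrapolated(t, c, fit, 0.0)
        assert pct == pytest.approx(100.0 * math.exp(-lam * t[-1]), rel=1e-3)
        assert auc_inf == pytest.approx(50.0 / lam, rel=1e-3)

    def test_zero_last_concentration_gives_zero_tail(self):
        t = np.array([0.0, 10, 20, 30])
        c = np.array([100.0, 50, 25, 0.0])
        fit = select_terminal_phase(t[:3], c[:3], exclude_tmax=False)
        _, pct = auc_extrapolated(t, c, fit, 0.0)
        assert pct == 0.0


class TestDerivedParameters:
    def test_bolus_mrt_is_inverse_ke(self):
        ke = 0.1
        t = np.arange(0, 100.0, 0.05)
        c = 1000.0 * np.exp(-ke * t)
        fit = select_terminal_phase(t, c, exclude_tmax=False)
        auc = auc_linear_trapezoid(t, c, 0, t[-1]) + c[-1] / ke
        aumc = (
            aumc_linear_trapezoid(t, c, 0, t[-1])
            + c[-1] * t[-1] / ke
            + c[-1] / ke**2
        )
        out = derived_parameters(1.0, auc, fit, aumc_inf_ng_h2=aumc)
        assert out["mrt"] == pytest.approx(1.0 / ke, rel=0.01)

    def test_clearance_consistency_on_noiseless_profile(self):
        # engine CL/F equals ke * V/F when the AUC is well resolved
        p = IndividualPK(ka=0.30, ke=math.log(2) / 7.2, v_over_f=365.0, mp_ratio=0.27)
        reg = DosingRegimen(n_doses=1)
        t = np.arange(0.0, 240.0, 0.25)
        c = simulate_plasma_profile(p, reg, t)
        fit = select_terminal_phase(t[1:], c[1:], exclude_tmax=False)
        auc_inf, _ = auc_extrapolated(t, c, fit, 0.0)
        out = derived_parameters(reg.dose_per_kg, auc_inf, fit)
        assert out["cl_over_f"] == pytest.approx(p.ke * p.v_over_f, rel=0.01)
        assert out["vd_over_f"] == pytest.approx(p.v_over_f, rel=0.01)

    def test_no_accumulation_when_profiles_identical(self, noiseless_dataset):
        # Rac = AUC(0-tau, last)/AUC(0-tau, first); a single-dose regimen
        # repeated with negligible carryover gives ~1; here we instead check
        # the multi-dose engine value against the superposition prediction
        res = NCA(noiseless_dataset).fit()
        rac = res.plasma["rac"].iloc[0]
        ke = math.log(2) / 7.2
        predicted = 1.0 / (1.0 - math.exp(-ke * 24.0))
        assert rac == pytest.approx(predicted, rel=0.15)
        assert rac >= 1.0

    def test_extrapolated_fraction_small_with_long_sampling(self, default_dataset):
        # sampling to 168 h post dose spans ~20 half-lives: the plasma
        # extrapolated tail is well under 1.5%
        pct = NCA(default_dataset).fit().plasma["pct_extrapolated_last"].dropna()
        gm = math.exp(np.log(pct).mean())
        assert gm < 1.5


class TestMilkParameters:
    def test_noiseless_milk_matches_generator(self, noiseless_dataset, noiseless_population):
        res = NCA(noiseless_dataset).fit()
        row = res.milk.iloc[0]
        assert row["tmax_post_dose_h"] == pytest.approx(10.0)
        # terminal half-life parallels the plasma elimination half-life
        assert row["t_half_theo_h"] == pytest.approx(
            math.log(2) / noiseless_population.ke_gm, rel=0.07
        )

    def test_milk_plasma_auc_ratio_recovers_partition(self, noiseless_dataset, noiseless_population):
        res = NCA(noiseless_dataset).fit()
        ratio = res.milk["milk_plasma_auc_ratio"].iloc[0]
        assert ratio == pytest.approx(noiseless_population.mp_ratio_gm, rel=0.10)

    def test_terminal_override_forces_point_count(self, default_dataset):
        from milkwdi.nca import NCAConfig

        animal = default_dataset.animal_ids[0]
        auto = NCA(default_dataset).fit()
        forced = NCA(
            default_dataset, NCAConfig(terminal_points_override={animal: 3})
        ).fit()
        a = auto.milk.set_index("animal_id")
        f = forced.milk.set_index("animal_id")
        # only the overridden animal may change; others are bit-identical
        others = [x for x in a.index if x != animal]
        pd.testing.assert_frame_equal(a.loc[others], f.loc[others])

    def test_all_censored_series_raises(self):
        rows = [
            ("G1", "milk", t, "A", None, "below_lod")
            for t in (130.0, 142.0, 154.0)
        ]
        ds = make_dataset(rows)
        with pytest.raises(NoFitError):
            milk_parameters(ds.matrix_frame("milk"), last_dose_time=120.0)

    def test_failures_reported_not_raised(self):
        rows = [("G1", "milk", t, "A", None, "below_lod") for t in (130.0, 142.0, 154.0)]
        res = NCA(make_dataset(rows)).fit()
        assert res.milk.empty
        assert any("G1" in f for f in res.failures)
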