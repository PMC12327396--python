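"""Data-augmentation scenarios: LOD fill, virtual animals, replicates."""

import numpy as np
import pandas as pd
import pytest

from milkwdi.data import LOD_FILLED, SIMULATED, ValidationError
from milkwdi.scenarios import (
    pooled_replicate_a_cv,
    scenario1_lod_fill,
    scenario2_virtual_animals,
    scenario3_simulated_replicates,
    select_base_animals,
    terminal_time_points,
)
from milkwdi.simulate import PopulationPK, generate_dataset

from conftest import make_dataset


def _depletion_rows(animal, concs, reps=("A", "B", "C"), t0=130.0):
    rows = []
    for i, c in enumerate(concs):
        t = t0 + 12.0 * i
        for rep in reps:
            if c is None:
                rows.append((animal, "milk", t, rep, None, "below_lod"))
            else:
                censor = "quantified" if c >= 15 else "between_lod_lloq"
                rows.append((animal, "milk", t, rep, c, censor))
    return rows


@pytest.fixture()
def split_dataset():
    """Ten animals; exactly five lack a fourth quantifiable terminal point."""
    rows = []
    long_profile = [540.0, 170.0, 55.0, 18.0, None]  # 4 quantifiable points
    short_profile = [480.0, 150.0, 48.0, None, None]  # only 3
    for i in range(1, 6):
        rows += _depletion_rows(f"L{i}", long_profile)
    for i in range(1, 6):
        rows += _depletion_rows(f"S{i}", short_profile)
    return make_dataset(rows)


class TestScenario1:
    def test_compliant_animals_untouched(self, split_dataset):
        out = scenario1_lod_fill(split_dataset, fill_time_h=166.0)
        for i in range(1, 6):
            a = f"L{i}"
            before = split_dataset.frame[split_dataset.frame.animal_id == a]
            after = out.frame[out.frame.animal_id == a]
            pd.testing.assert_frame_equal(
                before.reset_index(drop=True), after.reset_index(drop=True)
            )

    def test_exactly_the_short_animals_receive_fills(self, split_dataset):
        out = scenario1_lod_fill(split_dataset, fill_time_h=166.0)
        filled = out.frame[out.frame.provenance == LOD_FILLED]
        assert sorted(filled.animal_id.unique()) == [f"S{i}" for i in range(1, 6)]
        # one record per replicate, at the LOD, at the fill milking
        assert len(filled) == 5 * 3
        assert (filled.time_h == 166.0).all()
        assert (filled.conc == split_dataset.limits.lod).all()

    def test_fill_restores_four_terminal_points(self, split_dataset):
        out = scenario1_lod_fill(split_dataset, fill_time_h=166.0)
        for i in range(1, 6):
            assert len(terminal_time_points(out, f"S{i}")) == 4

    def test_fill_before_last_quantifiable_milking_rejected(self, split_dataset):
        with pytest.raises(ValidationError, match="not after"):
            scenario1_lod_fill(split_dataset, fill_time_h=142.0)

    def test_no_milk_data_rejected(self):
        ds = make_dataset([("G1", "plasma", 8.0, "A", 900.0, "quantified")])
        with pytest.raises(ValidationError, match="milk"):
            scenario1_lod_fill(ds)


class TestScenario2:
    def test_zero_cv_reproduces_mean_profile(self):
        rows = _depletion_rows("A1", [540.0, 170.0, 55.0, 18.0]) + _depletion_rows(
            "A2", [540.0, 170.0, 55.0, 18.0]
        )
        ds = make_dataset(rows)
        out = scenario2_virtual_animals(ds, ["A1", "A2"], n_virtual=2, seed=0)
        virt = out.frame[out.frame.provenance == SIMULATED]
        for t, expected in [(130.0, 540.0), (142.0, 170.0), (154.0, 55.0), (166.0, 18.0)]:
            vals = virt[virt.time_h == t].conc
            assert np.allclose(vals, expected)

    def test_seed_determinism(self, split_dataset):
        base = [f"L{i}" for i in range(1, 6)]
        a = scenario2_virtual_animals(split_dataset, base, seed=9)
        b = scenario2_virtual_animals(split_dataset, base, seed=9)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_cohort_is_base_plus_virtuals(self, split_dataset):
        base = [f"L{i}" for i in range(1, 6)]
        out = scenario2_virtual_animals(split_dataset, base, n_virtual=5, seed=1)
        assert sorted(out.animal_ids) == sorted(base + [f"V{i}" for i in range(1, 6)])
        virt = out.frame[out.frame.animal_id.str.startswith("V")]
        assert (virt.provenance == SIMULATED).all()

    def test_draw_copied_across_replicates_by_default(self, split_dataset):
        base = [f"L{i}" for i in range(1, 6)]
        out = scenario2_virtual_animals(split_dataset, base, seed=1)
        virt = out.frame[out.frame.provenance == SIMULATED]
        spread = virt.groupby(["animal_id", "time_h"])["conc"].std()
        assert spread.fillna(0).max() == 0

    def test_too_few_base_animals_rejected(self, split_dataset):
        with pytest.raises(ValidationError, match="base"):
            scenario2_virtual_animals(split_dataset, ["L1"], seed=0)

    def test_base_selection_prefers_slow_eliminators(self, split_dataset):
        assert select_base_animals(split_dataset) == [f"L{i}" for i in range(1, 6)]


class TestScenario3:
    def test_zero_cv_duplicates_replicate_a(self, split_dataset):
        out = scenario3_simulated_replicates(
            split_dataset, seed=0, cv_source="fixed", fixed_cv=0.0
        )
        milk = out.matrix_frame("milk")
        wide = milk.pivot_table(
            index=["animal_id", "time_h"], columns="replicate", values="conc"
        )
        assert np.allclose(wide["simulated_repB"], wide["A"], equal_nan=True)
        assert np.allclose(wide["simulated_repC"], wide["A"], equal_nan=True)

    def test_exactly_three_replicates_per_time_point(self, split_dataset):
        out = scenario3_simulated_replicates(split_dataset, seed=0)
        counts = out.matrix_frame("milk").groupby(["animal_id", "time_h"]).size()
        assert set(counts) == {3}

    def test_below_lod_points_stay_censored(self, split_dataset):
        out = scenario3_simulated_replicates(split_dataset, seed=0)
        milk = out.matrix_frame("milk")
        for (_, _), grp in milk.groupby(["animal_id", "time_h"]):
            flags = set(grp.censor)
            assert flags != {"below_lod"} or grp.conc.isna().all()

    def test_mean_preserved_at_replicate_a_value(self):
        # lognormal draws are mean-corrected: E[simulated replicate] = A
        rows = _depletion_rows("A1", [500.0], reps=("A",))
        ds = make_dataset(rows)
        sims = [
            scenario3_simulated_replicates(
                ds, seed=s, cv_source="fixed", fixed_cv=0.4
            )
            .frame.query("provenance == 'simulated'")
            .conc.mean()
            for s in range(300)
        ]
        assert np.mean(sims) == pytest.approx(500.0, rel=0.02)

    def test_missing_replicate_a_rejected(self):
        ds = make_dataset(_depletion_rows("A1", [500.0, 200.0], reps=("B",)))
        with pytest.raises(ValidationError, match="Replicate"):
            scenario3_simulated_replicates(ds, seed=0)

    def test_pooled_cv_reflects_between_animal_spread(self, split_dataset):
        cv = pooled_replicate_a_cv(split_dataset)
        # two profile shapes only: modest but non-zero spread
        assert 0.0 < cv < 1.0

    def test_seed_determinism(self, split_dataset):
        a = scenario3_simulated_replicates(split_dataset, seed=3)
        b = scenario3_simulated_replicates(split_dataset, seed=3)
        pd.testing.assert_frame_equal(a.frame, b.frame)


class TestScenarioIntegration:
    def test_augmented_outputs_are_valid_datasets(self, default_dataset):
        s1 = scenario1_lod_fill(default_dataset)
        base = select_base_animals(default_dataset)
        s2 = scenario2_virtual_animals(default_dataset, base, seed=1)
        s3 = scenario3_simulated_replicates(default_dataset, seed=1)
        for ds in (s1, s2, s3):
            ds.validate()
            added = ds.frame[ds.frame.provenance != "measured"]
            assert set(added.provenance) <= {LOD_FILLED, SIMULATED}
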