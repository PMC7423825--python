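"""Protocol orchestration, cohort statistics and table building."""

import itertools

import numpy as np
import pytest

from bivent.errors import InsufficientDataError, InvalidParameterError, TitrationFailure
from bivent.protocol import (
    TABLE1_ROWS,
    TABLE2_ROWS,
    TABLE3_ROWS,
    build_report,
    paired_compare,
    run_animal_protocol,
    summarize,
    titrate_min_ne,
)
from bivent.sim import attach_impella, simulate


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

class TestSummarize:
    def test_mean_sd(self):
        s = summarize([1, 2, 3, 4, 5])
        assert s.style == "mean_sd"
        assert s.center == pytest.approx(3.0)
        assert s.spread[0] == pytest.approx(1.5811, rel=1e-3)

    def test_outlier_switches_to_median(self):
        s = summarize([1, 2, 3, 4, 100])
        assert s.style == "median_q"
        assert s.center == 3.0
        assert s.spread == (2.0, 4.0)

    def test_requires_two_values(self):
        with pytest.raises(InsufficientDataError):
            summarize([1.0])

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(50, 5, 18)
        s = summarize(x, style="mean_sd")
        # independent re-implementation with plain loops
        mean = sum(x) / len(x)
        var = sum((v - mean) ** 2 for v in x) / (len(x) - 1)
        assert s.center == pytest.approx(mean, rel=1e-12)
        assert s.spread[0] == pytest.approx(var ** 0.5, rel=1e-12)
        s2 = summarize(x, style="median_q")
        xs = sorted(x)
        assert s2.center == pytest.approx(np.percentile(x, 50))


class TestPairedCompare:
    def test_identical_samples_degenerate(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        r = paired_compare(a, a)
        assert r.p_raw == 1.0 and r.test == "degenerate"

    def test_signed_rank_exact_matches_enumeration(self):
        """All-positive differences {1..6}: enumerate all 64 sign
        assignments of the rank sum to get the exact two-sided p."""
        a = np.zeros(6)
        b = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        ranks = np.arange(1, 7)
        total = int(ranks.sum())
        observed = total  # every difference positive: W+ = 21
        count = 0
        for signs in itertools.product([0, 1], repeat=6):
            w_plus = sum(r for r, s in zip(ranks, signs) if s)
            # two-sided: W+ at least as extreme in either tail
            if w_plus >= observed or w_plus <= total - observed:
                count += 1
        p_exact = count / 64.0  # = 2/64
        r = paired_compare(a, b, test="signed-rank")
        assert r.test == "signed-rank"
        assert r.p_raw == pytest.approx(p_exact)
        assert p_exact == pytest.approx(1.0 / 32.0)

    def test_bonferroni_cap(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 10)
        b = a + rng.normal(0, 1, 10)
        r = paired_compare(a, b, m=3)
        assert r.p_adjusted == min(1.0, 3 * r.p_raw)
        r2 = paired_compare(a, a + np.full(10, 1e-12), m=1000)
        assert r2.p_adjusted <= 1.0

    def test_requires_five_pairs(self):
        with pytest.raises(InsufficientDataError):
            paired_compare([1, 2, 3], [2, 3, 4])


# ---------------------------------------------------------------------------
# titration
# ---------------------------------------------------------------------------

class TestTitration:
    def test_zero_dose_when_pump_alone_suffices(self, shocked):
        m, _, traj = shocked
        mi = attach_impella(m)
        dose = titrate_min_ne(mi, map_threshold=20.0, y0=traj["y_final"])
        assert dose == 0.0

    def test_failure_reports_achieved_map(self, shocked):
        m, _, traj = shocked
        mi = attach_impella(m)
        with pytest.raises(TitrationFailure) as e:
            titrate_min_ne(mi, map_threshold=400.0, dose_grid=[0.0, 0.05],
                           y0=traj["y_final"])
        assert e.value.achieved_map is not None

    def test_grid_must_include_zero(self, shocked):
        with pytest.raises(InvalidParameterError):
            titrate_min_ne(attach_impella(shocked[0]), dose_grid=[0.05, 0.1])

    def test_map_monotone_in_dose(self, shocked):
        m, _, traj = shocked
        mi = attach_impella(m)
        y = traj["y_final"]
        maps = []
        for dose in (0.0, 0.05, 0.15):
            from bivent.sim import apply_norepinephrine

            ss = simulate(apply_norepinephrine(mi, dose), 10.0, settle=6.0, y0=y)
            maps.append(ss.meta["map"])
        assert maps[0] < maps[1] < maps[2]


# ---------------------------------------------------------------------------
# per-animal protocol and report
# ---------------------------------------------------------------------------

class TestAnimalProtocol:
    def test_stage_sequence_and_dose_monotone(self, animal_run):
        stages = [r.stage for r in animal_run.records]
        assert stages == ["baseline", "shock", "impella_min_ne", "impella_mod_ne"]
        doses = [r.ne_dose for r in animal_run.records]
        assert all(b >= a for a, b in zip(doses, doses[1:]))

    def test_shock_collapses_and_pump_restores_output(self, animal_run):
        base = animal_run.record("baseline")
        shock = animal_run.record("shock")
        imp = animal_run.record("impella_min_ne")
        assert shock.co <= 0.6 * base.co
        assert imp.co > shock.co * 1.3

    def test_edv_ratio_inverts_under_support(self, animal_run):
        assert animal_run.record("baseline").ratios["edv"] < 1.0
        assert animal_run.record("impella_min_ne").ratios["edv"] > 1.0

    def test_minimum_dose_positive_for_nominal_animal(self, animal_run):
        assert animal_run.min_dose > 0.0

    def test_same_seed_reproduces_records_exactly(self, nominal, animal_run):
        again = run_animal_protocol(nominal)
        assert [r.as_dict() for r in again.records] == \
               [r.as_dict() for r in animal_run.records]


class TestReport:
    @pytest.fixture(scope="class")
    def tiny_cohort(self, nominal, animal_run):
        """Five pseudo-animals from jittered copies of the nominal run.

        Exercises the table builder without five full protocol runs."""
        import copy

        rng = np.random.default_rng(0)
        runs = []
        for i in range(5):
            run = copy.deepcopy(animal_run)
            run.animal_index = i
            for rec in run.records:
                f = 1.0 + rng.normal(0, 0.03)
                rec.co *= f
                rec.map *= f
                rec.lv.sw *= f
                rec.rv.sw *= f
            runs.append(run)
        return runs

    def test_row_sets_match_published_tables(self, tiny_cohort):
        report = build_report(tiny_cohort)
        assert list(report["table1"].data.index) == [r[0] for r in TABLE1_ROWS]
        assert list(report["table2"].data.index) == [r[0] for r in TABLE2_ROWS]
        assert list(report["table3"].data.index) == [r[0] for r in TABLE3_ROWS]

    def test_n_reported_per_stage(self, tiny_cohort):
        report = build_report(tiny_cohort)
        assert report["table1"].n_per_stage["baseline"] == 5
        assert report["table4"].n_per_stage["impella_mod_ne"] == 5

    def test_ratio_rows_consistent_with_components(self, tiny_cohort):
        for run in tiny_cohort:
            for rec in run.records:
                assert rec.ratios["sw"] == pytest.approx(rec.rv.sw / rec.lv.sw)
                assert rec.ratios["edv"] == pytest.approx(rec.rv.edv / rec.lv.edv)

    def test_edv_ratio_chart_data(self, tiny_cohort):
        report = build_report(tiny_cohort)
        df = report["edv_ratio"]
        assert list(df.columns) == ["baseline", "shock", "impella_min_ne"]
        assert len(df) == 5

    def test_too_few_animals_rejected(self, tiny_cohort):
        with pytest.raises(InsufficientDataError):
            build_report(tiny_cohort[:3])
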