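"""Oocyte assay quantification: Pf estimation, t tests, inhibition and
uptake summaries, with closed-form and simulation oracles."""

import math

import numpy as np
import pytest
from scipy.special import betainc

from mipkit.assays import (
    SwellingTimecourse,
    UptakeMeasurement,
    compute_pf,
    group_compare,
    inhibition_analysis,
    read_swelling_csv,
    read_uptake_csv,
    uptake_summary,
)
from mipkit.simulate import OocyteGeometry, simulate_swelling, simulate_uptake

GEO = OocyteGeometry()


def make_tc(vols, times=None, osm_in=200.0, osm_out=20.0):
    times = times if times is not None else [2.0 * i for i in range(len(vols))]
    return SwellingTimecourse(
        "oo1", "construct", tuple(times), tuple(vols),
        osm_in=osm_in, osm_out=osm_out, diameter_cm=GEO.diameter_cm,
    )


class TestComputePf:
    def test_flat_timecourse_gives_zero(self):
        est = compute_pf(make_tc([1.0] * 11))
        assert est.pf == 0.0
        assert est.slope == 0.0

    def test_noiseless_forward_simulation_inverts_exactly(self):
        true_pf = 0.0173
        tc, truth = simulate_swelling(true_pf, noise_sd=0.0, seed=1)
        est = compute_pf(tc)
        assert abs(est.pf - true_pf) / true_pf < 1e-3
        assert est.fit_quality > 0.999999

    def test_zero_gradient_raises(self):
        with pytest.raises(ValueError, match="gradient"):
            compute_pf(make_tc([1.0, 1.01, 1.02], osm_in=200.0, osm_out=200.0))

    def test_fewer_than_three_points_raises(self):
        with pytest.raises(ValueError, match=">=3"):
            compute_pf(make_tc([1.0, 1.01]))

    def test_scale_consistency_in_gradient(self):
        # doubling the gradient doubles the slope but leaves Pf unchanged
        tc1, _ = simulate_swelling(0.02, osm_in=200, osm_out=110, noise_sd=0.0)
        tc2, _ = simulate_swelling(0.02, osm_in=200, osm_out=20, noise_sd=0.0)
        e1, e2 = compute_pf(tc1), compute_pf(tc2)
        assert e2.slope == pytest.approx(2 * e1.slope, rel=1e-9)
        assert e2.pf == pytest.approx(e1.pf, rel=1e-9)

    def test_explicit_geometry_overrides_sphere(self):
        tc, _ = simulate_swelling(0.01, noise_sd=0.0)
        import dataclasses

        explicit = dataclasses.replace(
            tc, diameter_cm=None, v0_cm3=GEO.v0, s_cm2=GEO.surface)
        assert compute_pf(explicit).pf == pytest.approx(compute_pf(tc).pf)

    def test_recovery_error_small_under_default_noise(self):
        errs = []
        for seed in range(100):
            true_pf = 0.02
            tc, _ = simulate_swelling(true_pf, noise_sd=0.005, seed=seed)
            errs.append(abs(compute_pf(tc).pf - true_pf) / true_pf)
        assert np.median(errs) < 0.15


class TestGroupCompare:
    def test_identical_groups_t_zero_not_significant(self):
        res = group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == pytest.approx(0.0)
        assert not res.significant

    def test_matches_closed_form_pooled_t(self):
        # hand-computed: means 2 and 3, pooled variance 1, t = -sqrt(3/2)
        res = group_compare([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        t_expected = -math.sqrt(1.5)
        assert res.t_statistic == pytest.approx(t_expected, rel=1e-12)
        df = 4
        p_expected = betainc(df / 2, 0.5, df / (df + t_expected ** 2))
        assert res.p_value == pytest.approx(p_expected, rel=1e-9)
        assert res.p_value == pytest.approx(0.2878641347, rel=1e-6)

    def test_zero_variance_equal_means_convention(self):
        res = group_compare([2.0, 2.0], [2.0, 2.0])
        assert (res.t_statistic, res.p_value) == (0.0, 1.0)

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            group_compare([1.0], [1.0, 2.0])

    def test_sem_and_fold_change_reported(self):
        res = group_compare([10.0, 12.0, 14.0], [1.0, 2.0, 3.0])
        assert res.fold_change == pytest.approx(6.0)
        assert res.sem_b == pytest.approx(1.0 / math.sqrt(3))

    def test_tenfold_pf_difference_detected_with_high_power(self):
        hits = 0
        n_sim = 200
        for seed in range(n_sim):
            rng = np.random.default_rng(seed)
            pf_ctrl, pf_expr = 0.0015, 0.015
            ctrl = [compute_pf(simulate_swelling(
                pf_ctrl, noise_sd=0.005, seed=int(rng.integers(2**31)))[0]).pf
                for _ in range(10)]
            expr = [compute_pf(simulate_swelling(
                pf_expr, noise_sd=0.005, seed=int(rng.integers(2**31)))[0]).pf
                for _ in range(10)]
            if group_compare(expr, ctrl).significant:
                hits += 1
        assert hits / n_sim >= 0.95

    def test_significance_calls_match_permutation_test(self):
        """Pooled-t significance agrees with a permutation oracle at alpha=0.01."""
        rng = np.random.default_rng(2024)
        agree = 0
        n_data = 200
        for _ in range(n_data):
            ratio = float(rng.choice([1.0, 1.6, 2.5]))
            a = rng.gamma(8.0, ratio * 20.0 / 8.0, 10)
            b = rng.gamma(8.0, 20.0 / 8.0, 10)
            res = group_compare(a, b)
            pooled = np.concatenate([a, b])
            obs = abs(a.mean() - b.mean())
            perm = np.array([
                abs(s[:10].mean() - s[10:].mean())
                for s in (rng.permutation(pooled) for _ in range(999))
            ])
            p_perm = (1 + (perm >= obs).sum()) / 1000
            if (res.p_value < 0.01) == (p_perm < 0.01):
                agree += 1
        assert agree / n_data >= 0.95


class TestInhibition:
    def test_no_change_is_zero_inhibition(self):
        rep = inhibition_analysis([1.0, 1.1, 0.9, 1.0], [1.0, 1.1, 0.9, 1.0])
        assert rep.percent_inhibition == pytest.approx(0.0, abs=1e-9)
        assert not rep.blocked

    def test_eighty_percent_block_with_recovery(self):
        rng = np.random.default_rng(0)
        base = 1.0 + rng.normal(0, 0.08, 8)
        treated = 0.2 + rng.normal(0, 0.02, 8)
        recovered = 0.95 + rng.normal(0, 0.08, 8)
        rep = inhibition_analysis(base, treated, recovered)
        assert rep.percent_inhibition == pytest.approx(80.0, abs=3.0)
        assert rep.blocked
        assert rep.reversible is True

    def test_missing_recovery_group_not_assessed(self):
        rep = inhibition_analysis([1.0, 1.1, 0.9], [0.2, 0.25, 0.22])
        assert rep.reversible is None

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            inhibition_analysis([0.0, 0.0], [0.1, 0.1])


class TestUptake:
    def test_counts_equal_baseline_gives_zero_means(self):
        ms = [UptakeMeasurement(f"o{i}", g, "urea", 50.0, 50.0)
              for i in range(4) for g in ("construct", "water")]
        summary = uptake_summary(ms, "water")
        assert (summary.table.corrected_mean == 0.0).all()
        assert not summary.comparisons[("construct", "urea")].significant

    def test_negative_corrected_floored_and_flagged(self):
        m = UptakeMeasurement("o1", "water", "urea", 10.0, 25.0)
        assert m.corrected == 0.0
        assert m.floored

    def test_missing_control_group_named_in_error(self):
        ms = [UptakeMeasurement("o1", "construct", "urea", 5.0, 1.0),
              UptakeMeasurement("o2", "construct", "urea", 6.0, 1.0)]
        with pytest.raises(ValueError, match="water"):
            uptake_summary(ms, "water")

    def test_fivefold_uptake_ratio_detected(self):
        ms, _ = simulate_uptake(5.0, seed=8)
        summary = uptake_summary(ms, "water")
        cmp_res = summary.comparisons[("construct", "glycerol")]
        assert cmp_res.significant
        assert cmp_res.fold_change > 2.0


class TestCsvIngest:
    def test_swelling_roundtrip_through_csv(self, tmp_path):
        import pandas as pd

        tc, _ = simulate_swelling(0.01, seed=4, oocyte_id="a1", group="g")
        rows = [{"oocyte_id": tc.oocyte_id, "group": tc.group, "time_s": t,
                 "rel_volume": v, "osm_in": tc.osm_in, "osm_out": tc.osm_out,
                 "diameter_cm": tc.diameter_cm}
                for t, v in zip(tc.times, tc.relative_volume)]
        p = tmp_path / "sw.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        (back,) = read_swelling_csv(p)
        assert back.times == tc.times
        assert compute_pf(back).pf == pytest.approx(compute_pf(tc).pf)

    def test_uptake_csv_parsed(self, tmp_path):
        p = tmp_path / "up.csv"
        p.write_text(
            "oocyte_id,group,solute,counts,baseline_counts\n"
            "o1,water,urea,120,30\n"
        )
        (m,) = read_uptake_csv(p)
        assert m.corrected == 90.0
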