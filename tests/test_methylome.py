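"""DMR-calling chain: parsing, filters, clustering, region statistics,
and the Student's t-test, each checked against an independent oracle.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from epiexpr.methylome import (
    CandidateRegion,
    DmrConfig,
    MethylationMatrix,
    call_dmrs,
    cluster_into_regions,
    conversion_rate,
    detect_differential_cpgs,
    evaluate_candidate_regions,
    filter_sites,
    methylation_fractions,
    read_cpg_calls,
    site_methylation,
    summarize_direction,
    test_region as region_ttest,
    weighted_region_methylation,
    write_cpg_calls,
)
from epiexpr.simulate import MethylSimConfig, simulate_methylome

from conftest import make_matrix


def student_t_p_oracle(x, y):
    """Pooled-variance two-sided t-test via the regularized incomplete
    beta function — an independent code path from scipy.stats.ttest_ind."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    df = nx + ny - 2
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / df
    t = (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    return float(special.betainc(df / 2.0, 0.5, df / (df + t * t)))


class TestIO:
    def test_union_semantics(self, tmp_path):
        (tmp_path / "a.cov").write_text(
            "chr1\t100\t100\t50.0\t5\t5\nchr1\t200\t200\t100.0\t8\t0\n"
            "chr1\t300\t300\t0.0\t0\t9\nchr2\t50\t50\t25.0\t1\t3\n")
        (tmp_path / "b.cov").write_text(
            "chr1\t100\t100\t10.0\t1\t9\nchr1\t200\t200\t50.0\t4\t4\n"
            "chr1\t300\t300\t75.0\t6\t2\nchr1\t400\t400\t50.0\t5\t5\n")
        m = read_cpg_calls({"a": tmp_path / "a.cov", "b": tmp_path / "b.cov"},
                           {"a": "control", "b": "treated"})
        assert m.n_sites == 5
        assert m.total.loc[("chr2", 50), "b"] == 0  # uncovered fill
        assert m.total.loc[("chr1", 400), "a"] == 0
        assert m.meth.loc[("chr1", 100), "a"] == 5

    def test_empty_file_gives_zero_coverage_sample(self, tmp_path):
        (tmp_path / "a.cov").write_text("chr1\t100\t100\t50.0\t5\t5\n")
        (tmp_path / "b.cov").write_text("")
        m = read_cpg_calls({"a": tmp_path / "a.cov", "b": tmp_path / "b.cov"},
                           {"a": "control", "b": "treated"})
        assert (m.total["b"] == 0).all()

    @pytest.mark.parametrize("line,err", [
        ("chr1\t100\t101\t50.0\t5\t5\n", "start != end"),
        ("chr1\t100\t100\t50.0\t5.5\t5\n", "non-integer"),
        ("chr1\t100\t100\t50.0\t5\t5\nchr1\t100\t100\t50.0\t5\t5\n",
         "duplicate"),
    ])
    def test_malformed_inputs_raise_with_location(self, tmp_path, line, err):
        (tmp_path / "a.cov").write_text(line)
        with pytest.raises(ValueError, match=err):
            read_cpg_calls({"a": tmp_path / "a.cov"}, {"a": "control"})

    def test_write_read_roundtrip(self, tmp_path, small_methylome):
        m, _ = small_methylome
        write_cpg_calls(m, tmp_path)
        m2 = read_cpg_calls({s: tmp_path / f"{s}.cov" for s in m.samples},
                            m.groups.to_dict())
        assert m.meth.equals(m2.meth) and m.total.equals(m2.total)


class TestFilters:
    def test_shallow_observation_masked_not_site_removed(self):
        m = make_matrix([[5, 4, 5], [3, 2, 4]], [[9, 20, 20], [15, 15, 15]],
                        ["t1", "t2", "c1"], ["treated", "treated", "control"])
        cfg = DmrConfig(min_samples_covered_per_group=1)
        out = filter_sites(m, cfg)
        assert out.total.loc[("chr1", 100), "t1"] == 0   # 9 reads < 10: masked
        assert out.total.loc[("chr1", 100), "t2"] == 20  # kept for other sample
        assert out.n_sites == 2

    def test_identity_when_nothing_filters(self):
        m = make_matrix([[5, 5], [3, 4]], [[20, 20], [15, 15]],
                        ["t1", "c1"], ["treated", "control"])
        cfg = DmrConfig(min_samples_covered_per_group=1)
        out = filter_sites(m, cfg, blacklist=[])
        assert out.meth.equals(m.meth) and out.total.equals(m.total)

    def test_blacklist_removes_whole_site(self):
        m = make_matrix([[5, 5], [3, 4]], [[20, 20], [15, 15]],
                        ["t1", "c1"], ["treated", "control"],
                        positions=[100, 200])
        cfg = DmrConfig(min_samples_covered_per_group=1)
        out = filter_sites(m, cfg, blacklist=[("chr1", 99, 100)])
        assert out.n_sites == 1
        assert out.meth.index[0] == ("chr1", 200)

    def test_group_coverage_pruning_matches_brute_force(self, small_methylome):
        m, _ = small_methylome
        cfg = DmrConfig()
        out = filter_sites(m, cfg)
        # independent per-site scan on the raw fixture
        covered = (m.total.values >= cfg.min_reads)
        tcols = [m.samples.index(s) for s in m.sample_ids("treated")]
        ccols = [m.samples.index(s) for s in m.sample_ids("control")]
        keep = ((covered[:, tcols].sum(axis=1) >= 3)
                & (covered[:, ccols].sum(axis=1) >= 3))
        assert out.n_sites == int(keep.sum())

    def test_masking_monotonicity(self, small_methylome):
        """Raising min_reads never increases the differential-CpG count."""
        m, _ = small_methylome
        n_prev = None
        for min_reads in (5, 10, 20, 30):
            cfg = DmrConfig(min_reads=min_reads)
            diff = detect_differential_cpgs(filter_sites(m, cfg), cfg)
            if n_prev is not None:
                assert len(diff) <= n_prev
            n_prev = len(diff)


class TestSiteStats:
    def test_conversion_rate_formula(self):
        assert conversion_rate([0, 0], [50, 50]) == 1.0
        assert conversion_rate([1], [100]) == pytest.approx(0.99)
        with pytest.raises(ValueError):
            conversion_rate([0], [0])

    def test_simulated_spike_in_rate(self, small_methylome):
        m, _ = small_methylome
        lam_meth, lam_total = m.lambda_counts
        rate = conversion_rate(lam_meth.values, lam_total.values)
        n = lam_total.values.sum()
        se = np.sqrt(0.005 * 0.995 / n)
        assert abs(rate - 0.995) < 5 * se

    def test_site_methylation(self):
        assert site_methylation(5, 10) == 0.5
        assert site_methylation(0, 12) == 0.0
        assert np.isnan(site_methylation(0, 0))

    def test_fractions_nan_where_uncovered(self):
        m = make_matrix([[5, 0]], [[10, 0]], ["t1", "c1"],
                        ["treated", "control"])
        frac = methylation_fractions(m)
        assert frac.iloc[0, 0] == 0.5
        assert np.isnan(frac.iloc[0, 1])


class TestDifferentialCpGs:
    def test_threshold_rule(self):
        m = make_matrix(
            [[11, 11, 8, 8], [5, 5, 5, 5]],
            [[20, 20, 20, 20]] * 2,
            ["t1", "t2", "c1", "c2"],
            ["treated", "treated", "control", "control"],
        )
        cfg = DmrConfig(min_samples_covered_per_group=2)
        diff = detect_differential_cpgs(m, cfg)
        assert len(diff) == 1
        assert diff["delta"].iloc[0] == pytest.approx(15.0)

    def test_identical_groups_emit_nothing(self):
        m = make_matrix([[10, 10, 10, 10]], [[20, 20, 20, 20]],
                        ["t1", "t2", "c1", "c2"],
                        ["treated", "treated", "control", "control"])
        cfg = DmrConfig(min_samples_covered_per_group=2)
        assert detect_differential_cpgs(m, cfg).empty

    def test_null_fixture_matches_brute_force_scan(self):
        cfg_sim = MethylSimConfig(n_cpgs=2_000, chrom_length=2_000_000,
                                  n_dmrs_planted=0, seed=13)
        m, _ = simulate_methylome(cfg_sim)
        cfg = DmrConfig()
        filt = filter_sites(m, cfg)
        diff = detect_differential_cpgs(filt, cfg)
        frac = methylation_fractions(filt)
        t = frac[filt.sample_ids("treated")].to_numpy()
        c = frac[filt.sample_ids("control")].to_numpy()
        expect = 0
        for i in range(len(frac)):
            ti, ci = t[i][~np.isnan(t[i])], c[i][~np.isnan(c[i])]
            if len(ti) >= 3 and len(ci) >= 3 and \
                    abs(ti.mean() - ci.mean()) * 100 >= 10.0:
                expect += 1
        assert len(diff) == expect


def brute_force_segmentation(positions, signs, max_gap, min_cpgs,
                             use_sign=True):
    """Exhaustive left-to-right segmentation oracle for small inputs."""
    chains, cur = [], [0]
    for i in range(1, len(positions)):
        brk = positions[i] - positions[i - 1] > max_gap
        if use_sign and signs[i] != signs[i - 1]:
            brk = True
        if brk:
            chains.append(cur)
            cur = [i]
        else:
            cur.append(i)
    chains.append(cur)
    return [[positions[i] for i in ch] for ch in chains if len(ch) >= min_cpgs]


class TestClustering:
    def _diff(self, positions, deltas, chrom="chr1"):
        return pd.DataFrame({
            "chrom": chrom, "pos": positions,
            "mean_treat": 50.0, "mean_control": 40.0, "delta": deltas,
            "n_treat_covered": 5, "n_control_covered": 5,
        })

    def test_three_cpgs_one_region(self):
        regions = cluster_into_regions(
            self._diff([100, 200, 300], [15, 15, 15]), DmrConfig())
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.n_cpgs) == (100, 300, 3)

    def test_two_cpgs_no_region(self):
        assert cluster_into_regions(
            self._diff([100, 200], [15, 15]), DmrConfig()) == []

    def test_sign_flip_splits_chain(self):
        regions = cluster_into_regions(
            self._diff([100, 150, 200, 250, 300, 350],
                       [15, 15, -15, -15, -15, -15]), DmrConfig())
        assert len(regions) == 1  # 2-member hyper chain dropped
        assert regions[0].member_pos == (200, 250, 300, 350)

    def test_matches_exhaustive_segmentation(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(1, 21))
            pos = np.sort(rng.choice(np.arange(100, 5000, 7), n, replace=False))
            deltas = rng.choice([-15.0, 15.0], n)
            got = cluster_into_regions(self._diff(list(pos), list(deltas)),
                                       DmrConfig())
            want = brute_force_segmentation(list(pos), list(np.sign(deltas)),
                                            250, 3)
            assert [list(r.member_pos) for r in got] == want

    def test_threshold_zero_waives_sign_constraint(self):
        cfg = DmrConfig(cpg_delta_threshold=0.0)
        regions = cluster_into_regions(
            self._diff([100, 200, 300], [1.0, -1.0, 1.0]), cfg)
        assert len(regions) == 1 and regions[0].n_cpgs == 3


class TestRegionStats:
    def test_weighted_methylation_is_count_sum_ratio(self):
        m = make_matrix([[5, 2], [10, 3], [0, 1]],
                        [[10, 12], [10, 15], [10, 11]],
                        ["t1", "c1"], ["treated", "control"])
        r = CandidateRegion("chr1", 100, 300, (100, 200, 300))
        wm = weighted_region_methylation(m, r)
        assert wm["t1"] == pytest.approx(15 / 30)
        assert wm["c1"] == pytest.approx(6 / 38)

    def test_single_cpg_region_equals_site_methylation(self):
        m = make_matrix([[7, 3]], [[10, 10]], ["t1", "c1"],
                        ["treated", "control"])
        r = CandidateRegion("chr1", 100, 100, (100,))
        assert weighted_region_methylation(m, r, "t1") == \
            site_methylation(7, 10)

    def test_pooling_adjacent_regions_is_coverage_weighted(self, small_methylome):
        """Conservation: merging two adjacent spans gives the
        coverage-weighted average of their statistics."""
        m, _ = small_methylome
        pos = m.meth.index.get_level_values("pos")
        a = CandidateRegion("chr1", int(pos[0]), int(pos[4]),
                            tuple(map(int, pos[:5])))
        b = CandidateRegion("chr1", int(pos[5]), int(pos[9]),
                            tuple(map(int, pos[5:10])))
        ab = CandidateRegion("chr1", a.start, b.end, a.member_pos + b.member_pos)
        s = m.samples[0]
        ta = m.total.iloc[:5][s].sum()
        tb = m.total.iloc[5:10][s].sum()
        wa = weighted_region_methylation(m, a, s)
        wb = weighted_region_methylation(m, b, s)
        wab = weighted_region_methylation(m, ab, s)
        assert wab == pytest.approx((wa * ta + wb * tb) / (ta + tb))

    def test_region_statistic_identity_on_fixture(self, small_methylome):
        """The region statistic equals Σmeth/Σtotal recomputed
        independently, for every tested region and sample."""
        m, _ = small_methylome
        cfg = DmrConfig()
        filt = filter_sites(m, cfg)
        diff = detect_differential_cpgs(filt, cfg)
        regions = cluster_into_regions(diff, cfg)
        chroms = filt.meth.index.get_level_values("chrom")
        pos = filt.meth.index.get_level_values("pos")
        for r in regions:
            wm = weighted_region_methylation(filt, r)
            sel = (chroms == r.chrom) & (pos >= r.start) & (pos <= r.end)
            met = filt.meth.loc[sel].sum()
            tot = filt.total.loc[sel].sum()
            for s in filt.samples:
                if tot[s] > 0:
                    assert wm[s] == pytest.approx(met[s] / tot[s], abs=0)
                else:
                    assert np.isnan(wm[s])


class TestRegionTest:
    def _matrix_from_values(self, treat_vals, control_vals, depth=100):
        samples = [f"t{i}" for i in range(len(treat_vals))] + \
                  [f"c{i}" for i in range(len(control_vals))]
        groups = ["treated"] * len(treat_vals) + ["control"] * len(control_vals)
        vals = list(treat_vals) + list(control_vals)
        meth = [[int(round(v * depth)) for v in vals]]
        total = [[depth] * len(vals)]
        return make_matrix(meth, total, samples, groups), samples

    def test_identical_groups_rejected(self):
        m, _ = self._matrix_from_values([0.5, 0.6], [0.5, 0.6])
        r = CandidateRegion("chr1", 100, 100, (100,))
        rec = region_ttest(m, r, ["t0", "t1"], ["c0", "c1"], DmrConfig())
        assert rec is not None and not rec["significant"]

    def test_strong_separation_is_hyper(self):
        m, _ = self._matrix_from_values([0.70, 0.72, 0.71, 0.69],
                                        [0.30, 0.31, 0.29, 0.32])
        r = CandidateRegion("chr1", 100, 100, (100,))
        rec = region_ttest(m, r, ["t0", "t1", "t2", "t3"],
                          ["c0", "c1", "c2", "c3"], DmrConfig())
        assert rec["significant"] and rec["direction"] == "hyper"
        x = [0.70, 0.72, 0.71, 0.69]
        y = [0.30, 0.31, 0.29, 0.32]
        assert rec["p_value"] == pytest.approx(student_t_p_oracle(x, y),
                                               abs=1e-9)

    def test_degenerate_zero_variance(self):
        m, _ = self._matrix_from_values([0.5, 0.5], [0.2, 0.2])
        r = CandidateRegion("chr1", 100, 100, (100,))
        rec = region_ttest(m, r, ["t0", "t1"], ["c0", "c1"], DmrConfig())
        assert rec["degenerate"] and rec["p_value"] == 0.0
        m2, _ = self._matrix_from_values([0.5, 0.5], [0.5, 0.5])
        rec2 = region_ttest(m2, r, ["t0", "t1"], ["c0", "c1"], DmrConfig())
        assert rec2["p_value"] == 1.0 and not rec2["degenerate"]

    def test_p_values_match_high_precision_oracle(self, small_methylome):
        """Tested-region p-values agree with an independent Student's-t
        computation to 1e-9 (and with sympy to 1e-12 on a spot check)."""
        m, _ = small_methylome
        tested = evaluate_candidate_regions(
            m, cfg=DmrConfig(cpg_delta_threshold=0.0))
        frac = methylation_fractions(filter_sites(m, DmrConfig()))
        tcols = m.sample_ids("treated")
        ccols = m.sample_ids("control")
        checked = 0
        for rec in tested.itertuples():
            if rec.degenerate:
                continue
            r = CandidateRegion(rec.chrom, rec.start, rec.end, ())
            wm = weighted_region_methylation(
                filter_sites(m, DmrConfig()), r)
            x = wm[tcols].dropna().to_numpy()
            y = wm[ccols].dropna().to_numpy()
            assert rec.p_value == pytest.approx(student_t_p_oracle(x, y),
                                                abs=1e-9)
            checked += 1
        assert checked >= 100

    def test_sympy_high_precision_spot_check(self):
        import sympy

        rng = np.random.default_rng(23)
        for _ in range(5):
            x = rng.normal(0.5, 0.1, 5)
            y = rng.normal(0.45, 0.1, 5)
            p_fast = student_t_p_oracle(x, y)
            nx, ny = len(x), len(y)
            df = nx + ny - 2
            sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / df
            t = abs((np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / nx + 1 / ny)))
            z = sympy.Rational(df) / (sympy.Float(t, 30) ** 2 + df)
            p_exact = sympy.betainc_regularized(
                sympy.Rational(df, 2), sympy.Rational(1, 2), 0, z)
            assert abs(p_fast - float(p_exact)) < 1e-12


class TestCallDmrs:
    def test_empty_matrix_gives_empty_list(self):
        m = make_matrix(np.empty((0, 6), int), np.empty((0, 6), int),
                        [f"s{i}" for i in range(6)],
                        ["treated"] * 3 + ["control"] * 3)
        assert call_dmrs(m).empty

    def test_too_few_samples_raises(self):
        m = make_matrix([[5, 5, 5]], [[20, 20, 20]],
                        ["t1", "t2", "c1"],
                        ["treated", "treated", "control"])
        with pytest.raises(ValueError, match="treated|control"):
            call_dmrs(m)

    def test_direction_consistency_and_sorting(self, small_methylome):
        m, _ = small_methylome
        dmrs = call_dmrs(m)
        assert len(dmrs) > 0
        assert ((dmrs["delta"] > 0) == (dmrs["direction"] == "hyper")).all()
        assert (dmrs["n_cpgs"] >= 3).all()
        assert dmrs.sort_values(["chrom", "start"]).equals(dmrs)

    def test_direction_mix_recovered(self):
        """A planted 70/30 hyper/hypo mix is recovered within ±10 pp."""
        cfg = MethylSimConfig(n_dmrs_planted=50, dmr_direction_mix=0.7,
                              seed=31)
        m, truth = simulate_methylome(cfg)
        dmrs = call_dmrs(m)
        frac_hyper, frac_hypo = summarize_direction(dmrs)
        assert frac_hyper + frac_hypo == pytest.approx(1.0)
        assert abs(frac_hyper - 0.7) < 0.1

    def test_summarize_direction_counts(self):
        df = pd.DataFrame({"direction": ["hyper"] * 3 + ["hypo"]})
        assert summarize_direction(df) == (0.75, 0.25)
        assert summarize_direction(pd.DataFrame({"direction": ["hyper"]})) == \
            (1.0, 0.0)
        fh, fl = summarize_direction(pd.DataFrame(columns=["direction"]))
        assert np.isnan(fh) and np.isnan(fl)
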