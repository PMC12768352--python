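"""ΔΔCt, band/fluorescence normalization, miRNA filter, test battery vs oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sirnakit as sk

# ---------------------------------------------------------------------------
# Independent reference implementations (hand-coded formulas; used only as
# oracles, never called by the package)
# ---------------------------------------------------------------------------


def oracle_anova_f(groups):
    """One-way ANOVA F from explicit sums of squares."""
    all_v = np.concatenate(groups)
    grand = all_v.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_v) - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = stats.f.sf(f, df_b, df_w)
    return f, p


def oracle_tukey(groups, names):
    """Tukey-Kramer pairwise p-values via the studentized range distribution."""
    k = len(groups)
    df_w = sum(len(g) for g in groups) - k
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_w
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(mse / 2 * (1 / len(groups[i]) + 1 / len(groups[j])))
            q = abs(groups[i].mean() - groups[j].mean()) / se
            out[(names[i], names[j])] = float(stats.studentized_range.sf(q, k, df_w))
    return out


def oracle_pooled_t(a, b):
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


def oracle_bh(pvals):
    """Benjamini-Hochberg step-up, coded from the definition."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def oracle_mannwhitney_exact(a, b):
    """Exact two-sided Mann-Whitney p by enumeration of all group splits."""
    from itertools import combinations

    pooled = np.concatenate([a, b])
    na = len(a)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    idx = range(len(pooled))
    us = []
    for comb in combinations(idx, na):
        u = ranks[list(comb)].sum() - na * (na + 1) / 2
        us.append(u)
    us = np.array(us)
    mu = na * len(b) / 2
    p = np.mean(np.abs(us - mu) >= np.abs(u_obs - mu) - 1e-12)
    return float(p)


# ---------------------------------------------------------------------------
# ΔΔCt
# ---------------------------------------------------------------------------


def _ct_table(rows):
    return pd.DataFrame(rows, columns=["sample", "group", "replicate", "gene", "ct"])


class TestDdct:
    def test_forced_arithmetic(self):
        """Treated ΔCt 5, control mean ΔCt 4 -> ΔΔCt 1, fold change 0.5."""
        rows = [
            ("c1", "ctrl", 1, "eGFP", 24.0), ("c1", "ctrl", 1, "HKG", 20.0),
            ("t1", "trt", 1, "eGFP", 25.0), ("t1", "trt", 1, "HKG", 20.0),
        ]
        res = sk.ddct(_ct_table(rows), "eGFP", "HKG", "ctrl")
        t1 = res["per_sample"].set_index("sample").loc["t1"]
        assert t1["ddct"] == pytest.approx(1.0)
        assert t1["fold_change"] == pytest.approx(0.5)

    def test_control_vs_itself_is_unity(self):
        rows = [
            ("c1", "ctrl", 1, "eGFP", 24.0), ("c1", "ctrl", 1, "HKG", 20.0),
            ("t1", "trt", 1, "eGFP", 24.0), ("t1", "trt", 1, "HKG", 20.0),
        ]
        res = sk.ddct(_ct_table(rows), "eGFP", "HKG", "ctrl")
        assert res["groups"]["trt"]["mean_fold_change"] == pytest.approx(1.0)
        assert res["groups"]["trt"]["percent_knockdown"] == pytest.approx(0.0)

    def test_shift_invariance(self):
        """Adding a constant to every Ct leaves fold changes unchanged."""
        rows = [
            ("c1", "ctrl", 1, "eGFP", 24.0), ("c1", "ctrl", 1, "HKG", 20.0),
            ("c2", "ctrl", 2, "eGFP", 24.4), ("c2", "ctrl", 2, "HKG", 20.1),
            ("t1", "trt", 1, "eGFP", 25.5), ("t1", "trt", 1, "HKG", 20.2),
        ]
        base = sk.ddct(_ct_table(rows), "eGFP", "HKG", "ctrl")
        shifted_rows = [(s, g, r, gene, ct + 3.7) for s, g, r, gene, ct in rows]
        shifted = sk.ddct(_ct_table(shifted_rows), "eGFP", "HKG", "ctrl")
        pd.testing.assert_series_equal(
            base["per_sample"]["fold_change"], shifted["per_sample"]["fold_change"]
        )

    def test_knockdown_percent(self):
        """Three treated replicates around fold 0.6 -> ~40% knockdown."""
        rows = [
            ("c1", "ctrl", 1, "eGFP", 24.0), ("c1", "ctrl", 1, "HKG", 20.0),
            ("c2", "ctrl", 2, "eGFP", 24.0), ("c2", "ctrl", 2, "HKG", 20.0),
            ("c3", "ctrl", 3, "eGFP", 24.0), ("c3", "ctrl", 3, "HKG", 20.0),
        ]
        for i, fc in enumerate((0.58, 0.60, 0.62), start=1):
            rows.append((f"t{i}", "trt", i, "eGFP", 24.0 - math.log2(fc)))
            rows.append((f"t{i}", "trt", i, "HKG", 20.0))
        res = sk.ddct(_ct_table(rows), "eGFP", "HKG", "ctrl")
        assert res["groups"]["trt"]["percent_knockdown"] == pytest.approx(40.0, abs=0.1)
        # one-tailed test, knockdown direction declared by the caller
        res1 = sk.ddct(_ct_table(rows), "eGFP", "HKG", "ctrl", tail="one", direction="less")
        assert res1["tests"][0].p_value < 0.01

    def test_missing_reference_gene_is_error(self):
        rows = [
            ("c1", "ctrl", 1, "eGFP", 24.0), ("c1", "ctrl", 1, "HKG", 20.0),
            ("t1", "trt", 1, "eGFP", 25.0),
        ]
        with pytest.raises(ValueError, match="HKG"):
            sk.ddct(_ct_table(rows), "eGFP", "HKG", "ctrl")

    def test_empty_control_group_is_error(self):
        rows = [("t1", "trt", 1, "eGFP", 25.0), ("t1", "trt", 1, "HKG", 20.0)]
        with pytest.raises(ValueError, match="control group"):
            sk.ddct(_ct_table(rows), "eGFP", "HKG", "ctrl")


# ---------------------------------------------------------------------------
# Bands
# ---------------------------------------------------------------------------


def _band_table(rows):
    return pd.DataFrame(rows, columns=["membrane", "sample", "group", "protein", "intensity"])


class TestBandNorm:
    def test_proportional_loading_cancels(self):
        rows = [
            ("m1", "l1", "ctrl", "AGO2", 2.0), ("m1", "l1", "ctrl", "GAPDH", 2.0),
            ("m1", "l2", "trt", "AGO2", 4.0), ("m1", "l2", "trt", "GAPDH", 4.0),
        ]
        res = sk.band_norm(_band_table(rows), "ctrl")
        assert res["AGO2"]["table"]["fold_change"].tolist() == pytest.approx([1.0, 1.0])

    def test_forced_arithmetic(self):
        rows = [
            ("m1", "l1", "ctrl", "AGO2", 4.0), ("m1", "l1", "ctrl", "GAPDH", 4.0),
            ("m1", "l2", "trt", "AGO2", 2.0), ("m1", "l2", "trt", "GAPDH", 4.0),
        ]
        res = sk.band_norm(_band_table(rows), "ctrl")
        tbl = res["AGO2"]["table"].set_index("sample")
        assert tbl.loc["l1", "ratio"] == pytest.approx(1.0)
        assert tbl.loc["l2", "ratio"] == pytest.approx(0.5)
        assert tbl.loc["l2", "fold_change"] == pytest.approx(0.5)

    def test_exposure_invariance(self):
        rows = [
            ("m1", "l1", "ctrl", "AGO2", 3.0), ("m1", "l1", "ctrl", "GAPDH", 5.0),
            ("m1", "l2", "trt", "AGO2", 7.0), ("m1", "l2", "trt", "GAPDH", 6.0),
        ]
        a = sk.band_norm(_band_table(rows), "ctrl")
        scaled = [(m, l, g, p, v * 11.0) for m, l, g, p, v in rows]
        b = sk.band_norm(_band_table(scaled), "ctrl")
        pd.testing.assert_frame_equal(a["AGO2"]["table"], b["AGO2"]["table"])

    def test_missing_gapdh_lane_is_error(self):
        rows = [
            ("m1", "l1", "ctrl", "AGO2", 3.0), ("m1", "l1", "ctrl", "GAPDH", 5.0),
            ("m1", "l2", "trt", "AGO2", 7.0),
        ]
        with pytest.raises(ValueError, match="GAPDH"):
            sk.band_norm(_band_table(rows), "ctrl")

    def test_all_zero_membrane_is_error(self):
        rows = [("m1", "l1", "ctrl", "AGO2", 0.0), ("m1", "l1", "ctrl", "GAPDH", 0.0)]
        with pytest.raises(ValueError, match="all-zero"):
            sk.band_norm(_band_table(rows), "ctrl")


# ---------------------------------------------------------------------------
# Fluorescence
# ---------------------------------------------------------------------------


class TestFluorSummary:
    @staticmethod
    def _table(groups, n_embryos=25, noise=None, background=2.0, rng=None):
        rows = []
        for grp, (mean, images) in groups.items():
            for img in range(images):
                for e in range(n_embryos):
                    val = mean if rng is None else rng.normal(mean, noise)
                    rows.append({
                        "image": f"{grp}_{img}", "group": grp, "embryo_id": e,
                        "mean_intensity": max(val, 0.0), "background_intensity": background,
                    })
        return pd.DataFrame(rows)

    def test_background_subtraction(self):
        df = self._table({"a": (10.0, 2), "b": (10.0, 2)})
        res = sk.fluor_summary(df)
        assert (res["replicates"]["replicate_mean"] == 8.0).all()
        assert res["tests"][0].p_value == pytest.approx(1.0)

    def test_negative_net_clamped_with_warning(self):
        df = self._table({"a": (1.0, 2), "b": (3.0, 2)}, background=2.0)
        with pytest.warns(UserWarning, match="clamped"):
            res = sk.fluor_summary(df)
        assert (res["replicates"]["replicate_mean"] >= 0).all()

    def test_detects_known_group_difference(self):
        """N(10,1) vs N(8,1), 30 embryos x 3 images: effect ~2, significant."""
        rng = np.random.default_rng(4)
        df = self._table({"hi": (10.0, 3), "lo": (8.0, 3)}, n_embryos=30, noise=1.0, rng=rng)
        res = sk.fluor_summary(df)
        t = res["tests"][0]
        assert t.p_value < 0.05
        assert t.details["effect"] == pytest.approx(2.0, abs=0.5)

    def test_embryo_count_warning(self):
        df = self._table({"a": (10.0, 2), "b": (9.0, 2)}, n_embryos=5)
        with pytest.warns(UserWarning, match="20-30"):
            sk.fluor_summary(df)


# ---------------------------------------------------------------------------
# miRNA totals
# ---------------------------------------------------------------------------


class TestMirnaTotals:
    def test_guide_filter_rule(self):
        df = pd.DataFrame(
            {"r1": [1, 2, 0], "r2": [1, 0, 0], "r3": [1, 0, 0]},
            index=["gA", "gB", "gC"],
        )
        res = sk.mirna_totals(df)
        assert list(res["guides"].index) == ["gB"]  # {1,1,1} removed; {2,0,0} kept
        assert res["totals"] == {"r1": 2.0, "r2": 0.0, "r3": 0.0}

    def test_normalized_variant(self):
        df = pd.DataFrame({"r1": [4], "r2": [8]}, index=["g"])
        res = sk.mirna_totals(df, spikein_factors={"r1": 2.0, "r2": 4.0})
        assert res["normalized_totals"] == {"r1": 2.0, "r2": 2.0}

    def test_empty_table(self):
        res = sk.mirna_totals(pd.DataFrame())
        assert res["totals"] == {}


# ---------------------------------------------------------------------------
# Test battery vs oracles
# ---------------------------------------------------------------------------


def _fixtures(n=20, seed=3):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        k = int(rng.integers(3, 5))
        sizes = rng.integers(3, 7, size=k)
        shift = rng.normal(0, 2, size=k)
        out.append({
            f"g{j}": rng.normal(shift[j], 1.0, size=sizes[j]) for j in range(k)
        })
    return out


class TestBattery:
    def test_three_identical_groups(self):
        groups = {"a": [1.0, 2, 3], "b": [1.0, 2, 3], "c": [1.0, 2, 3]}
        res = sk.test_battery(groups, "anova_tukey")
        assert res[0].statistic == pytest.approx(0.0)
        assert all(not r.details["reject"] for r in res[1:])

    def test_tukey_flags_only_shifted_group(self):
        groups = {"a": [1.0, 2, 3], "b": [1.0, 2, 3], "c": [10.0, 11, 12]}
        res = sk.test_battery(groups, "anova_tukey")
        flagged = {r.comparison for r in res[1:] if r.details["reject"]}
        assert flagged == {"a vs c", "b vs c"}
        # cross-check every pair against the studentized-range oracle
        arrs = [np.array(groups[n], float) for n in groups]
        expect = oracle_tukey(arrs, list(groups))
        for r in res[1:]:
            n1, n2 = r.comparison.split(" vs ")
            assert r.p_value == pytest.approx(expect[(n1, n2)], abs=1e-6)

    def test_two_group_f_equals_t_squared(self):
        a, b = [1.0, 2.5, 3.1, 4.0], [2.0, 3.5, 5.0]
        t_res = sk.test_battery({"a": a, "b": b}, "t_two_tailed")[0]
        f, _ = oracle_anova_f([np.array(a), np.array(b)])
        assert t_res.statistic ** 2 == pytest.approx(f)

    def test_one_tailed_requires_direction(self):
        with pytest.raises(ValueError, match="direction"):
            sk.test_battery({"a": [1.0, 2], "b": [3.0, 4]}, "t_one_tailed")

    def test_constant_data_rejected_for_parametric(self):
        with pytest.raises(ValueError, match="degenerate"):
            sk.test_battery({"a": [1.0, 1], "b": [1.0, 1]}, "t_two_tailed")
        # rank test proceeds
        res = sk.test_battery({"a": [1.0, 1], "b": [1.0, 1]}, "mann_whitney")
        assert res[0].p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("i,fixture", list(enumerate(_fixtures())))
    def test_parametric_results_match_oracles(self, i, fixture):
        """ANOVA F/p and Tukey-Kramer adjusted p agree with independently
        coded formulas within 1e-6 on seeded fixtures."""
        names = list(fixture)
        arrs = [fixture[n] for n in names]
        res = sk.test_battery(fixture, "anova_tukey")
        f, p = oracle_anova_f(arrs)
        assert res[0].statistic == pytest.approx(f, abs=1e-6)
        assert res[0].p_value == pytest.approx(p, abs=1e-6)
        expect = oracle_tukey(arrs, names)
        for r in res[1:]:
            n1, n2 = r.comparison.split(" vs ")
            assert r.p_value == pytest.approx(expect[(n1, n2)], abs=1e-6)
        # t-test oracle on the first two groups
        t_res = sk.test_battery({n: fixture[n] for n in names[:2]}, "t_two_tailed")[0]
        t, tp = oracle_pooled_t(arrs[0], arrs[1])
        assert t_res.statistic == pytest.approx(t, abs=1e-6)
        assert t_res.p_value == pytest.approx(tp, abs=1e-6)

    def test_wilcoxon_exact_matches_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            a = rng.normal(0, 1, size=4)
            b = rng.normal(0.5, 1, size=5)
            res = sk.test_battery({"a": a, "b": b, "c": rng.normal(size=4)},
                                  "kruskal_wilcoxon_fdr")
            pair = next(r for r in res[1:] if r.comparison == "a vs b")
            assert pair.p_value == pytest.approx(oracle_mannwhitney_exact(a, b), abs=1e-9)

    def test_bh_adjustment_matches_oracle_and_is_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=15)
        adj = sk.bh_adjust(p)
        assert np.allclose(adj, oracle_bh(p), atol=1e-12)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
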