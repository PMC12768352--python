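"""Quantitative companion computations and the statistical test battery.

* ΔΔCt fold changes from RT-qPCR Ct tables (fold = 2^-ΔΔCt with
  ΔCt = Ct_target - Ct_reference and ΔΔCt taken against the control-group
  mean ΔCt);
* western-band double normalization (per-membrane darkest-band scaling, then
  division by the GAPDH loading control);
* background-subtracted fluorescence summaries with per-replicate means;
* the miRNA guide-count filter (keep guides with >= 2 reads in at least one
  replicate) and per-replicate totals;
* a test battery: one-/two-tailed t, one-way ANOVA with Tukey HSD,
  Kruskal-Wallis with pairwise Wilcoxon rank-sum + Benjamini-Hochberg FDR,
  and Mann-Whitney — the tests used across the figures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    test: str
    comparison: str
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    details: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# ΔΔCt
# ---------------------------------------------------------------------------

def ddct(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    control_group: str,
    *,
    tail: str = "two",
    direction: str = "less",
) -> dict:
    """Comparative-Ct (2^-ΔΔCt) fold changes with a group test on ΔCt values.

    ``ct`` has columns sample, group, replicate, gene, ct.  Per sample,
    ΔCt = Ct(target) - Ct(reference); per treated sample,
    ΔΔCt = ΔCt - mean ΔCt(control group); fold change = 2^-ΔΔCt; percent
    knockdown = (1 - mean fold change) x 100 per group.  Group comparison is
    a t-test on ΔCt values against the control group; for ``tail='one'`` the
    caller must state ``direction`` ('less' = knockdown, i.e. treated fold
    change below control, meaning treated ΔCt greater).
    """
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    wide = ct.pivot_table(index=["sample", "group"], columns="gene", values="ct")
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns:
            raise ValueError(f"gene {gene!r} missing from the Ct table")
    if wide[reference_gene].isna().any():
        bad = wide[wide[reference_gene].isna()].index.get_level_values("sample").tolist()
        raise ValueError(f"reference gene {reference_gene!r} missing for sample(s) {bad}")
    if wide[target_gene].isna().any():
        bad = wide[wide[target_gene].isna()].index.get_level_values("sample").tolist()
        raise ValueError(f"target gene {target_gene!r} missing for sample(s) {bad}")
    df = wide.reset_index()
    df["delta_ct"] = df[target_gene] - df[reference_gene]
    ctrl = df.loc[df.group == control_group, "delta_ct"]
    if ctrl.empty:
        raise ValueError(f"control group {control_group!r} has no samples")
    base = ctrl.mean()
    df["ddct"] = df["delta_ct"] - base
    df["fold_change"] = 2.0 ** (-df["ddct"])

    summary = {}
    tests = []
    for grp, sub in df.groupby("group"):
        fc = sub["fold_change"]
        summary[grp] = {
            "mean_fold_change": float(fc.mean()),
            "sd_fold_change": float(fc.std(ddof=1)) if len(fc) > 1 else float("nan"),
            "percent_knockdown": float((1.0 - fc.mean()) * 100.0),
            "n": int(len(fc)),
        }
        if grp == control_group or len(sub) < 2 or len(ctrl) < 2:
            continue
        # knockdown ('less' on fold change) means treated ΔCt is *greater*
        alternative = "two-sided" if tail == "two" else (
            "greater" if direction == "less" else "less"
        )
        stat, p = stats.ttest_ind(sub["delta_ct"], ctrl, alternative=alternative)
        tests.append(TestResult(
            test=f"t_{tail}_tailed", comparison=f"{grp} vs {control_group}",
            statistic=float(stat), p_value=float(p),
        ))
    return {"per_sample": df, "groups": summary, "tests": tests, "control_group": control_group}


# ---------------------------------------------------------------------------
# Western-band normalization
# ---------------------------------------------------------------------------

def band_norm(
    bands: pd.DataFrame,
    control_group: str,
    *,
    loading_control: str = "GAPDH",
    test: str | None = None,
) -> dict:
    """Darkest-band and loading-control double normalization of band intensities.

    Per membrane every intensity is divided by that membrane's maximal
    (darkest) band; each protein's normalized value is then divided by the
    lane's normalized loading control; fold changes are taken against the
    control-group mean.  The group test is a two-tailed t-test, or
    Mann-Whitney for non-normal data (auto-chosen by Shapiro-Wilk at
    alpha = 0.05 when ``test`` is None; the choice is reported).
    """
    df = bands.copy()
    for membrane, sub in df.groupby("membrane"):
        if (sub["intensity"] == 0).all():
            raise ValueError(f"membrane {membrane!r} has all-zero intensities")
        lanes = set(sub["sample"])
        gapdh_lanes = set(sub.loc[sub.protein == loading_control, "sample"])
        if lanes - gapdh_lanes:
            raise ValueError(
                f"membrane {membrane!r}: no {loading_control} band for lane(s) {sorted(lanes - gapdh_lanes)}"
            )
        df.loc[sub.index, "darkest_norm"] = sub["intensity"] / sub["intensity"].max()
    gapdh = df[df.protein == loading_control].set_index(["membrane", "sample"])["darkest_norm"]
    out_rows = []
    for (membrane, sample), sub in df[df.protein != loading_control].groupby(["membrane", "sample"]):
        for _, row in sub.iterrows():
            out_rows.append({
                "membrane": membrane, "sample": sample, "group": row["group"],
                "protein": row["protein"],
                "ratio": row["darkest_norm"] / gapdh.loc[(membrane, sample)],
            })
    ratios = pd.DataFrame(out_rows)
    results = {}
    for protein, sub in ratios.groupby("protein"):
        ctrl = sub.loc[sub.group == control_group, "ratio"]
        if ctrl.empty:
            raise ValueError(f"no control-group lanes for protein {protein!r}")
        sub = sub.copy()
        sub["fold_change"] = sub["ratio"] / ctrl.mean()
        test_res = None
        treated = sub.loc[sub.group != control_group, "ratio"]
        if len(treated) >= 2 and len(ctrl) >= 2:
            chosen = test
            if chosen is None:
                normal = all(
                    stats.shapiro(v)[1] > 0.05 for v in (treated, ctrl) if len(v) >= 3
                )
                chosen = "t_two_tailed" if normal else "mann_whitney"
            if chosen == "t_two_tailed":
                stat, p = stats.ttest_ind(treated, ctrl)
            elif chosen == "mann_whitney":
                stat, p = stats.mannwhitneyu(treated, ctrl, alternative="two-sided")
            else:
                raise ValueError(f"unknown test {chosen!r}")
            test_res = TestResult(chosen, f"treated vs {control_group}", float(stat), float(p))
        results[protein] = {"table": sub, "test": test_res}
    return results


# ---------------------------------------------------------------------------
# Fluorescence summaries
# ---------------------------------------------------------------------------

def fluor_summary(fluor: pd.DataFrame, *, alpha: float = 0.05) -> dict:
    """Background-subtracted per-replicate mean intensities plus a group t-test.

    Per embryo: mean_intensity - background_intensity, clamped at 0 with a
    warning if the background exceeds the signal; per image/replicate: the
    mean over its embryos (20-30 expected; a warning is emitted outside that
    range); groups compared by a two-tailed t-test on replicate means.
    """
    df = fluor.copy()
    df["net"] = df["mean_intensity"] - df["background_intensity"]
    if (df["net"] < 0).any():
        n_neg = int((df["net"] < 0).sum())
        warnings.warn(f"{n_neg} embryo(s) with background above signal; clamped to 0")
        df["net"] = df["net"].clip(lower=0)
    sizes = df.groupby("image").size()
    odd = sizes[(sizes < 20) | (sizes > 30)]
    if len(odd):
        warnings.warn(f"image(s) outside the expected 20-30 embryos: {odd.to_dict()}")
    reps = df.groupby(["group", "image"], as_index=False)["net"].mean().rename(columns={"net": "replicate_mean"})
    groups = list(reps["group"].unique())
    result = {"replicates": reps, "tests": []}
    if len(groups) == 2:
        a = reps.loc[reps.group == groups[0], "replicate_mean"]
        b = reps.loc[reps.group == groups[1], "replicate_mean"]
        if len(a) >= 2 and len(b) >= 2:
            if np.allclose(a.std(ddof=1), 0) and np.allclose(b.std(ddof=1), 0) and np.isclose(a.mean(), b.mean()):
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.ttest_ind(a, b)
            result["tests"].append(TestResult(
                "t_two_tailed", f"{groups[0]} vs {groups[1]}", float(stat), float(p),
                details={"effect": float(a.mean() - b.mean())},
            ))
    return result


# ---------------------------------------------------------------------------
# miRNA totals
# ---------------------------------------------------------------------------

def mirna_totals(
    guide_counts: pd.DataFrame,
    *,
    min_reads: int = 2,
    spikein_factors: dict[str, float] | None = None,
) -> dict:
    """Guide filter and per-replicate miRNA totals.

    ``guide_counts``: rows = guides, columns = replicate/sample names, values
    = read counts.  A guide is retained iff its count reaches ``min_reads``
    in at least one replicate.  Totals per replicate are sums over retained
    guides; if ``spikein_factors`` maps replicate -> spike-in factor, a
    spike-in-normalized variant is also emitted.
    """
    if guide_counts.empty:
        empty = guide_counts.copy()
        return {"guides": empty, "totals": {}, "normalized_totals": {}}
    keep = guide_counts.max(axis=1) >= min_reads
    kept = guide_counts.loc[keep]
    totals = kept.sum(axis=0).to_dict()
    normalized = {}
    if spikein_factors is not None:
        missing = set(guide_counts.columns) - set(spikein_factors)
        if missing:
            raise ValueError(f"no spike-in factor for replicate(s) {sorted(missing)}")
        normalized = {k: totals[k] / spikein_factors[k] for k in totals}
    return {"guides": kept, "totals": {k: float(v) for k, v in totals.items()},
            "normalized_totals": normalized}


# ---------------------------------------------------------------------------
# Test battery
# ---------------------------------------------------------------------------

TESTS = ("t_one_tailed", "t_two_tailed", "anova_tukey", "kruskal_wilcoxon_fdr", "mann_whitney")


def _check_groups(groups: dict[str, np.ndarray], min_groups: int) -> None:
    if len(groups) < min_groups:
        raise ValueError(f"need >= {min_groups} groups, got {len(groups)}")
    for name, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")


def test_battery(
    groups: dict[str, "np.ndarray | list[float]"],
    test: str,
    *,
    direction: str | None = None,
    alpha: float = 0.05,
) -> list[TestResult]:
    """Run one of the study's statistical tests on values grouped by label.

    ``direction`` is mandatory for one-tailed tests ('greater'/'less',
    first-listed group relative to the second); it is never inferred from the
    data.  Parametric tests refuse all-constant data; rank tests proceed.
    ``kruskal_wilcoxon_fdr`` runs Kruskal-Wallis followed by all pairwise
    two-sided Wilcoxon rank-sum tests with Benjamini-Hochberg adjustment.
    """
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}; known: {TESTS}")
    g = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    names = list(g)

    if test in ("t_one_tailed", "t_two_tailed", "mann_whitney"):
        _check_groups(g, 2)
        if len(g) != 2:
            raise ValueError(f"{test} compares exactly two groups")
        a, b = g[names[0]], g[names[1]]
        comparison = f"{names[0]} vs {names[1]}"
        if test == "mann_whitney":
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            return [TestResult(test, comparison, float(stat), float(p))]
        if np.std(a) == 0 and np.std(b) == 0:
            raise ValueError("degenerate (constant) data in every group; t-test undefined")
        if test == "t_one_tailed":
            if direction not in ("greater", "less"):
                raise ValueError("one-tailed test requires direction='greater' or 'less'")
            stat, p = stats.ttest_ind(a, b, alternative=direction)
        else:
            stat, p = stats.ttest_ind(a, b)
        return [TestResult(test, comparison, float(stat), float(p))]

    _check_groups(g, 3)
    values = np.concatenate([g[n] for n in names])
    labels = np.concatenate([[n] * len(g[n]) for n in names])

    if test == "anova_tukey":
        if all(np.std(v) == 0 for v in g.values()):
            raise ValueError("degenerate (constant) data in every group; ANOVA undefined")
        f_stat, f_p = stats.f_oneway(*[g[n] for n in names])
        out = [TestResult("anova", "omnibus", float(f_stat), float(f_p))]
        tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
        pairs = [
            (tk.groupsunique[i], tk.groupsunique[j])
            for i in range(len(tk.groupsunique))
            for j in range(i + 1, len(tk.groupsunique))
        ]
        for (g1, g2), md, padj, rej in zip(pairs, tk.meandiffs, tk.pvalues, tk.reject):
            out.append(TestResult(
                "tukey_hsd", f"{g1} vs {g2}", float(md), float(padj),
                details={"reject": bool(rej)},
            ))
        return out

    # kruskal_wilcoxon_fdr
    k_stat, k_p = stats.kruskal(*[g[n] for n in names])
    out = [TestResult("kruskal_wallis", "omnibus", float(k_stat), float(k_p))]
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    raw = []
    for a, b in pairs:
        method = "exact" if (len(g[a]) <= 8 and len(g[b]) <= 8) else "asymptotic"
        stat, p = stats.mannwhitneyu(g[a], g[b], alternative="two-sided", method=method)
        raw.append((a, b, float(stat), float(p)))
    _, adj, _, _ = multipletests([r[3] for r in raw], method="fdr_bh")
    for (a, b, stat, p), pa in zip(raw, adj):
        out.append(TestResult("wilcoxon_rank_sum", f"{a} vs {b}", stat, p, p_adjusted=float(pa)))
    return out


def bh_adjust(pvalues: "list[float] | np.ndarray") -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]
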