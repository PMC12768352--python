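"""Screens for secondary-siRNA amplification and RISC-loading enrichment.

Four independent lines of evidence for (or against) amplification of the
silencing response beyond the primary Dicer products:

upstream
    after injecting a dsRNA covering only part of the target, do siRNAs map
    upstream of the injected interval?  Template-directed RdRp synthesis on
    the target mRNA would produce them; primary dicing cannot.
rpph
    does removing 5'-triphosphates (RppH treatment) before ligation reveal
    extra target-mapped reads relative to mock-treated aliquots of the same
    RNA?  RdRp products carry 5'ppp and are invisible to standard ligation.
size_shift
    do treated libraries shift toward the longer secondary-siRNA length
    (22 nt), measured as the 22-nt fraction difference plus Jensen-Shannon
    divergence (natural log; the divergence is bounded by ln 2)?
loading
    are target siRNAs loaded into AGO/RISC at least as efficiently as the
    endogenous miRNA population (RPM ratio in IP / TraPR libraries)?

Each screen returns a :class:`ScreenResult` with an effect size, a test
statistic with p-value, and a categorical verdict.  Any group with fewer
than two replicates yields 'underpowered'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .assign import AssignedLibrary, TargetHit
from .metrics import SizeDistribution, _by_sequence, normalize


@dataclass
class ScreenResult:
    screen: str
    effect: float
    statistic: float | None
    p_value: float | None
    verdict: str  # signal | no_signal | underpowered
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.verdict not in ("signal", "no_signal", "underpowered"):
            raise ValueError(f"invalid verdict {self.verdict!r}")
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value out of [0, 1]")


# ---------------------------------------------------------------------------
# Upstream-mapping screen
# ---------------------------------------------------------------------------

def upstream_fraction(hits: list[TargetHit], interval_start: int) -> float:
    """Fraction of target-mapped read mass lying entirely upstream of the interval.

    Ratio of counts, so any per-library spike-in factor cancels; reads are
    counted once per sequence with multi-locus reads split equally across
    loci (a locus counts as upstream iff the match lies within
    ``[0, interval_start)``).
    """
    up = tot = 0.0
    for seq, hs in _by_sequence(hits).items():
        w = hs[0].count / len(hs)
        for h in hs:
            tot += w
            if h.start + h.length <= interval_start:
                up += w
    return up / tot if tot else 0.0


def upstream_test(
    hits_per_replicate: list[list[TargetHit]],
    injected_interval: tuple[int, int],
    *,
    tau: float = 0.01,
    alpha: float = 0.05,
) -> ScreenResult:
    """Test for siRNAs mapping upstream of the injected dsRNA interval.

    Verdict 'signal' requires the mean upstream fraction to exceed ``tau``
    AND a one-sample one-sided t-test of the per-replicate fractions against
    ``tau`` to reject at ``alpha``.
    """
    istart, _ = injected_interval
    if istart <= 0:
        raise ValueError("injected interval starts at 0: no upstream region to test")
    fracs = [upstream_fraction(h, istart) for h in hits_per_replicate]
    mean = float(np.mean(fracs)) if fracs else 0.0
    details = {"fractions": fracs, "tau": tau, "n": len(fracs)}
    if len(fracs) < 2:
        return ScreenResult("upstream", mean, None, None, "underpowered", details)
    if np.allclose(np.std(fracs), 0.0):
        stat, p = float("inf") if mean > tau else 0.0, 0.0 if mean > tau else 1.0
    else:
        stat, p = stats.ttest_1samp(fracs, tau, alternative="greater")
    verdict = "signal" if (mean > tau and p < alpha) else "no_signal"
    return ScreenResult("upstream", mean, float(stat), float(p), verdict, details)


# ---------------------------------------------------------------------------
# RppH contrast
# ---------------------------------------------------------------------------

def rpph_contrast(
    counts: pd.DataFrame,
    *,
    treated_label: str = "rpph",
    mock_label: str = "standard",
    alpha: float = 0.05,
    paired: bool = False,
) -> ScreenResult:
    """Treated-vs-mock contrast of spike-in-normalized target counts.

    ``counts`` needs columns ``group`` (protocol/treatment label),
    ``replicate`` and ``value`` (spike-in-normalized target count); extra
    groups (e.g. a second genetic background) join the one-way ANOVA.
    Default analysis is a one-way ANOVA with Tukey HSD pairwise contrasts
    (Tukey-Kramer for unbalanced groups); ``paired=True`` switches to a
    paired t-test on replicate-matched treated/mock values.  Effect is the
    treated/mock ratio of group means.  Verdict 'signal' requires
    treated > mock with the treated-vs-mock contrast significant at
    ``alpha``.
    """
    required = {"group", "replicate", "value"}
    if not required <= set(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    groups = counts["group"].unique().tolist()
    if len(groups) < 2:
        raise ValueError("need at least two groups for the contrast")
    for g in (treated_label, mock_label):
        if g not in groups:
            raise ValueError(f"group {g!r} not present (have {groups})")
    sizes = counts.groupby("group").size()
    t_mean = counts.loc[counts.group == treated_label, "value"].mean()
    m_mean = counts.loc[counts.group == mock_label, "value"].mean()
    effect = float(t_mean / m_mean) if m_mean else float("inf")
    details: dict = {"group_means": counts.groupby("group")["value"].mean().to_dict(), "n": sizes.to_dict()}
    if (sizes < 2).any():
        return ScreenResult("rpph", effect, None, None, "underpowered", details)

    if paired:
        wide = counts.pivot_table(index="replicate", columns="group", values="value")
        stat, p = stats.ttest_rel(wide[treated_label], wide[mock_label])
        details["test"] = "paired t"
    else:
        arrays = [g["value"].to_numpy() for _, g in counts.groupby("group")]
        f_stat, f_p = stats.f_oneway(*arrays)
        details["anova_F"], details["anova_p"] = float(f_stat), float(f_p)
        tk = pairwise_tukeyhsd(counts["value"].to_numpy(), counts["group"].to_numpy(), alpha=alpha)
        pairs = [
            (tk.groupsunique[i], tk.groupsunique[j])
            for i in range(len(tk.groupsunique))
            for j in range(i + 1, len(tk.groupsunique))
        ]
        details["tukey"] = [
            {"group1": g1, "group2": g2, "meandiff": float(md), "p_adj": float(pv)}
            for (g1, g2), md, pv in zip(pairs, tk.meandiffs, tk.pvalues)
        ]
        p_contrast = next(
            pv for (g1, g2), pv in zip(pairs, tk.pvalues)
            if {g1, g2} == {treated_label, mock_label}
        )
        stat, p = float(f_stat), float(p_contrast)
        details["test"] = "one-way ANOVA + Tukey HSD"
    verdict = "signal" if (t_mean > m_mean and p < alpha) else "no_signal"
    return ScreenResult("rpph", effect, float(stat), float(p), verdict, details)


# ---------------------------------------------------------------------------
# Size-shift screen
# ---------------------------------------------------------------------------

def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence in nats (bounded by ln 2)."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)

    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log(a[mask] / b[mask])))

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def size_shift(
    treated: list[SizeDistribution],
    mock: list[SizeDistribution],
    *,
    shift_length: int = 22,
    tau_jsd: float = 0.01,
    alpha: float = 0.05,
) -> ScreenResult:
    """Shift of the read-length spectrum toward the secondary-siRNA length.

    Effect = treated - mock difference in the ``shift_length``-nt fraction;
    plus the Jensen-Shannon divergence between the pooled length spectra.
    Verdict 'signal' requires a positive fraction difference significant by
    a two-sample t-test at ``alpha`` AND pooled JSD > ``tau_jsd``.
    """
    if not treated or not mock:
        raise ValueError("both groups need at least one size distribution")
    if any(d.total() == 0 for d in treated + mock):
        return ScreenResult("size_shift", float("nan"), None, None, "underpowered",
                            {"reason": "zero-total size distribution"})

    def frac22(d: SizeDistribution) -> float:
        return d.fractions().get(shift_length, 0.0)

    t_fracs = [frac22(d) for d in treated]
    m_fracs = [frac22(d) for d in mock]
    effect = float(np.mean(t_fracs) - np.mean(m_fracs))

    lengths = sorted(treated[0].combined)
    pool_t = np.array([sum(d.combined[L] for d in treated) for L in lengths], float)
    pool_m = np.array([sum(d.combined[L] for d in mock) for L in lengths], float)
    jsd = js_divergence(pool_t, pool_m)
    details = {
        "frac_treated": t_fracs, "frac_mock": m_fracs, "jsd_nats": jsd,
        "shift_length": shift_length, "tau_jsd": tau_jsd,
    }
    if len(t_fracs) < 2 or len(m_fracs) < 2:
        return ScreenResult("size_shift", effect, None, None, "underpowered", details)
    if np.allclose(np.std(t_fracs), 0) and np.allclose(np.std(m_fracs), 0):
        stat, p = (float("inf"), 0.0) if effect > 0 else (0.0, 1.0)
    else:
        stat, p = stats.ttest_ind(t_fracs, m_fracs)
    verdict = "signal" if (effect > 0 and p < alpha and jsd > tau_jsd) else "no_signal"
    return ScreenResult("size_shift", effect, float(stat), float(p), verdict, details)


# ---------------------------------------------------------------------------
# Loading-efficiency screen (AGO-IP / TraPR libraries)
# ---------------------------------------------------------------------------

def loading_enrichment(
    libraries: list[AssignedLibrary],
    *,
    min_guide_reads: int = 2,
    denominator: str = "mapped_total",
    alpha: float = 0.05,
) -> ScreenResult:
    """Target-siRNA vs miRNA loading efficiency in RISC-enriched libraries.

    Per replicate: RPM of target-mapped reads and RPM of the miRNA
    compartment restricted to guides with >= ``min_guide_reads`` reads in at
    least one replicate.  Effect is the ratio of the group means; the test is
    a two-tailed paired t-test of per-replicate target vs miRNA RPM.
    """
    n = len(libraries)
    if n < 2:
        return ScreenResult("loading", float("nan"), None, None, "underpowered",
                            {"reason": "fewer than two replicates"})
    # guide filter: max count across replicates >= min_guide_reads
    guide_max: dict[str, int] = {}
    for lib in libraries:
        for r in lib.compartments.get("mirna", []):
            guide_max[r.sequence] = max(guide_max.get(r.sequence, 0), r.count)
    kept = {s for s, c in guide_max.items() if c >= min_guide_reads}

    target_rpm, mirna_rpm = [], []
    for lib in libraries:
        nc = normalize(lib, denominator)
        mirna_count = sum(
            r.count for r in lib.compartments.get("mirna", []) if r.sequence in kept
        )
        if mirna_count == 0:
            return ScreenResult("loading", float("nan"), None, None, "underpowered",
                                {"reason": "replicate with zero retained miRNA reads"})
        target_rpm.append(nc.rpm)
        mirna_rpm.append(mirna_count * 1e6 / nc.denominator)
    effect = float(np.mean(target_rpm) / np.mean(mirna_rpm))
    details = {"target_rpm": target_rpm, "mirna_rpm": mirna_rpm, "n": n,
               "guides_retained": len(kept)}
    diffs = np.array(target_rpm) - np.array(mirna_rpm)
    if np.allclose(diffs.std(), 0):
        stat, p = (float("inf"), 0.0) if diffs.mean() != 0 else (0.0, 1.0)
    else:
        stat, p = stats.ttest_rel(target_rpm, mirna_rpm)
    verdict = "signal" if (effect > 1 and p < alpha) else "no_signal"
    return ScreenResult("loading", effect, float(stat), float(p), verdict, details)
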