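"""Per-library siRNA characterization.

Spike-in and RPM normalization, read-size distributions, strand-resolved
per-base coverage, Dicer phasing registers (modulo 20 / 21) with a
chi-square periodicity statistic, and positional nucleotide composition.

Phasing conventions
-------------------
Registers are taken at the 5' end of each unique siRNA species, on each
strand's own 5'->3' axis: '+' reads use their leftmost target coordinate,
'-' reads use ``target_length - start - length`` (the 5' end measured along
the antisense strand), because Dicer steps along each strand from that
strand's 5' end.  A library is called *phased* only when the chi-square test
against register uniformity rejects at p < 1e-3 AND the fullest register
holds more than 2/m of the species.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .assign import AssignedLibrary, TargetHit

LENGTH_RANGE = range(18, 31)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizedCounts:
    raw: int
    spikein_factor: float
    spikein_normalized: float
    rpm: float
    denominator: int
    denominator_def: str


def normalize(assigned: AssignedLibrary, denominator: str = "mapped_total") -> NormalizedCounts:
    """Spike-in- and depth-normalized target read counts.

    ``spikein_factor`` is the mean of the four per-spike-in counts; spike-in
    normalization divides the raw target count by it, making counts
    comparable across libraries with a shared molar spike-in input.  RPM uses
    ``denominator`` = 'mapped_total' (genome + target reads; spike-ins and
    unassigned excluded) or 'filtered_total' (all length-filtered reads).
    """
    spike = assigned.spikein_counts()
    if len(spike) != 4:
        raise ValueError("expected four spike-ins")
    if any(v == 0 for v in spike.values()):
        missing = [k for k, v in spike.items() if v == 0]
        raise ValueError(f"spike-in(s) with zero reads: {missing}; cannot spike-normalize")
    factor = float(np.mean(list(spike.values())))
    raw = assigned.compartment_count("target")
    if denominator == "mapped_total":
        denom = assigned.compartment_count("genome") + raw
    elif denominator == "filtered_total":
        denom = assigned.totals["filtered_total"]
    else:
        raise ValueError(f"unknown RPM denominator {denominator!r}")
    if denom == 0:
        raise ValueError("RPM denominator is zero")
    return NormalizedCounts(
        raw=raw,
        spikein_factor=factor,
        spikein_normalized=raw / factor,
        rpm=raw * 1e6 / denom,
        denominator=denom,
        denominator_def=denominator,
    )


def summarize_replicates(values: list[float]) -> dict[str, float]:
    """Mean with both standard deviation and standard error across replicates."""
    arr = np.asarray(values, dtype=float)
    n = len(arr)
    sd = float(arr.std(ddof=1)) if n > 1 else float("nan")
    return {
        "mean": float(arr.mean()),
        "sd": sd,
        "sem": sd / math.sqrt(n) if n > 1 else float("nan"),
        "n": n,
    }


# ---------------------------------------------------------------------------
# Reads grouped by sequence (strand resolution, multi-locus weights)
# ---------------------------------------------------------------------------

def _by_sequence(hits: list[TargetHit]) -> dict[str, list[TargetHit]]:
    d: dict[str, list[TargetHit]] = defaultdict(list)
    for h in hits:
        d[h.sequence].append(h)
    return d


def _read_strand(hs: list[TargetHit]) -> str:
    strands = {h.strand for h in hs}
    return hs[0].strand if len(strands) == 1 else "ambiguous"


# ---------------------------------------------------------------------------
# Size distribution
# ---------------------------------------------------------------------------

#: a length counts as modal when its count is within this factor of the peak
MODE_PLATEAU = 0.9


@dataclass
class SizeDistribution:
    """Multiplicity-weighted read counts per length 18-30, per strand.

    ``modes`` lists every length whose count reaches ``MODE_PLATEAU`` of the
    peak count, so a 20/21-nt plateau is reported as two modal lengths even
    though sampling noise breaks exact ties.
    """

    sense: dict[int, int]
    antisense: dict[int, int]
    combined: dict[int, int]
    modes: list[int]

    def total(self) -> int:
        return sum(self.combined.values())

    def fractions(self) -> dict[int, float]:
        t = self.total()
        return {L: c / t for L, c in self.combined.items()} if t else {L: 0.0 for L in self.combined}


def size_distribution(hits: list[TargetHit]) -> SizeDistribution:
    """Length histogram of target-mapped reads (each read counted once)."""
    sense = {L: 0 for L in LENGTH_RANGE}
    anti = {L: 0 for L in LENGTH_RANGE}
    comb = {L: 0 for L in LENGTH_RANGE}
    for seq, hs in _by_sequence(hits).items():
        L, c = hs[0].length, hs[0].count
        comb[L] += c
        strand = _read_strand(hs)
        if strand == "+":
            sense[L] += c
        elif strand == "-":
            anti[L] += c
    if any(comb.values()):
        top = max(comb.values())
        modes = sorted(L for L, c in comb.items() if c >= MODE_PLATEAU * top)
    else:
        modes = []
    return SizeDistribution(sense, anti, comb, modes)


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageProfile:
    """Per-base depth over the target, full multiplicity, per strand.

    Multi-locus reads contribute count/loci at each locus; reads matching
    both strands are excluded from the strand-resolved arrays (flagged
    ambiguous by assignment).
    """

    sense: np.ndarray
    antisense: np.ndarray

    @property
    def total_mass(self) -> float:
        return float(self.sense.sum() + self.antisense.sum())


def coverage(hits: list[TargetHit], target_length: int) -> CoverageProfile:
    sense = np.zeros(target_length)
    anti = np.zeros(target_length)
    for seq, hs in _by_sequence(hits).items():
        if _read_strand(hs) == "ambiguous":
            continue
        w = hs[0].count / len(hs)
        for h in hs:
            if h.start < 0 or h.start + h.length > target_length:
                raise ValueError(f"hit out of target bounds: {h}")
            arr = sense if h.strand == "+" else anti
            arr[h.start : h.start + h.length] += w
    return CoverageProfile(sense, anti)


def five_prime_end_counts(hits: list[TargetHit], target_length: int) -> dict[str, np.ndarray]:
    """Per-position 5'-end read counts, per strand, on sense coordinates."""
    sense = np.zeros(target_length)
    anti = np.zeros(target_length)
    for seq, hs in _by_sequence(hits).items():
        if _read_strand(hs) == "ambiguous":
            continue
        w = hs[0].count / len(hs)
        for h in hs:
            if h.strand == "+":
                sense[h.start] += w
            else:
                anti[h.start + h.length - 1] += w
    return {"sense": sense, "antisense": anti}


# ---------------------------------------------------------------------------
# Phasing
# ---------------------------------------------------------------------------

@dataclass
class PhasingProfile:
    modulus: int
    fractions: dict[str, np.ndarray]  # keys sense / antisense / pooled
    n_reads: dict[str, int]
    max_register_fraction: float      # pooled
    chi_square: float | None
    p_value: float | None
    phased: bool | None
    undefined: bool = False


def five_prime_position(hit: TargetHit, target_length: int) -> int:
    """5' position of a hit on its own strand's 5'->3' axis."""
    if hit.strand == "+":
        return hit.start
    return target_length - hit.start - hit.length


def phasing(
    uhits: list[TargetHit],
    m: int,
    target_length: int,
    *,
    alpha: float = 1e-3,
) -> PhasingProfile:
    """Register analysis of unique siRNA 5' ends modulo ``m``.

    Input must come from ``unique_hits`` (distinct single-locus 20-22 nt
    species, weight 1 each).  Emits per-strand and pooled register fractions,
    the fullest pooled register, and a chi-square goodness-of-fit against
    register uniformity.  With no reads the statistic is undefined and
    flagged rather than raised.
    """
    if m < 2:
        raise ValueError("modulus must be >= 2")
    regs: dict[str, list[int]] = {"sense": [], "antisense": []}
    for h in uhits:
        key = "sense" if h.strand == "+" else "antisense"
        regs[key].append(five_prime_position(h, target_length) % m)
    pooled = regs["sense"] + regs["antisense"]
    fractions = {}
    n_reads = {}
    for key, rs in [("sense", regs["sense"]), ("antisense", regs["antisense"]), ("pooled", pooled)]:
        counts = np.bincount(rs, minlength=m).astype(float)
        n = int(counts.sum())
        n_reads[key] = n
        fractions[key] = counts / n if n else counts
    if not pooled:
        return PhasingProfile(m, fractions, n_reads, float("nan"), None, None, None, undefined=True)
    counts = np.bincount(pooled, minlength=m)
    chi2, p = stats.chisquare(counts)
    max_frac = float(fractions["pooled"].max())
    return PhasingProfile(
        modulus=m,
        fractions=fractions,
        n_reads=n_reads,
        max_register_fraction=max_frac,
        chi_square=float(chi2),
        p_value=float(p),
        phased=bool(p < alpha and max_frac > 2.0 / m),
    )


# ---------------------------------------------------------------------------
# Nucleotide composition
# ---------------------------------------------------------------------------

BASES = "ACGT"


@dataclass
class CompositionMatrix:
    """4 x L positional nucleotide frequencies for reads of one length.

    ``mode`` 'total' weighs reads by multiplicity; 'unique' weighs each
    distinct sequence once.  Columns sum to 1 when any read is present.
    """

    length: int
    mode: str
    matrix: np.ndarray  # shape (4, L), rows A/C/G/T
    n_reads: float
    empty: bool = False


def composition(hits: list[TargetHit], length: int, mode: str = "total") -> CompositionMatrix:
    if mode not in ("total", "unique"):
        raise ValueError(f"mode must be total or unique, got {mode!r}")
    counts = np.zeros((4, length))
    n = 0.0
    base_idx = {b: i for i, b in enumerate(BASES)}
    for seq, hs in _by_sequence(hits).items():
        if hs[0].length != length:
            continue
        w = hs[0].count if mode == "total" else 1
        n += w
        for j, b in enumerate(seq):
            counts[base_idx[b], j] += w
    if n == 0:
        return CompositionMatrix(length, mode, counts, 0.0, empty=True)
    return CompositionMatrix(length, mode, counts / n, n)
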