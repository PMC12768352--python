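"""Compartment assignment of collapsed reads.

Each length-filtered read is assigned to exactly one compartment following a
genome-subtractive precedence: spike-in, then mature miRNA, then genome
proxy, then target transgene, then unassigned.  A read is tested against a
compartment only if it matched nothing earlier, so reads present both in the
genome and on the target are counted for the genome, never the target —
target-mapped reads are those that the genome cannot explain.

Matching is exact (0 mismatches) on both strands for genome and target;
spike-ins and mature miRNAs are single-stranded references matched on the
forward strand only.  miRNA matching allows the read to lie within the
mature sequence extended by up to 2 unconstrained nt on the 3' side, a
stand-in for quantifier-style windows around annotated matures.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .io import CollapsedRead, ReferenceBundle, VALID_ALPHABET, revcomp

COMPARTMENTS = ("spikein", "mirna", "genome", "target")
DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 30


@dataclass(frozen=True)
class TargetHit:
    """A perfect match of a read on the target.

    ``start`` is the 0-based position of the match's leftmost base on the
    target's sense coordinates regardless of strand; ``strand`` '-' means the
    read equals the reverse complement of the target slice.
    """

    sequence: str
    strand: str
    start: int
    length: int
    count: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class AssignedLibrary:
    """Partition of a library's collapsed reads into compartments."""

    compartments: dict[str, list[CollapsedRead]]
    target_hits: list[TargetHit]
    ambiguous_strand: set[str]
    totals: dict[str, int]
    target_name: str = "target"
    target_length: int = 0

    def compartment_count(self, name: str) -> int:
        return sum(r.count for r in self.compartments.get(name, []))

    def spikein_counts(self) -> dict[str, int]:
        return dict(self._spikein_counts)

    _spikein_counts: dict[str, int] = field(default_factory=dict)


def length_filter(
    reads: list[CollapsedRead], min_len: int = DEFAULT_MIN_LEN, max_len: int = DEFAULT_MAX_LEN
) -> list[CollapsedRead]:
    """Keep reads with min_len <= length <= max_len; multiplicities untouched."""
    if not 1 <= min_len <= max_len:
        raise ValueError(f"invalid length bounds [{min_len}, {max_len}]")
    return [r for r in reads if min_len <= len(r.sequence) <= max_len]


def _find_all(needle: str, haystack: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def match_exact(read: str, reference: tuple[str, str], count: int = 1) -> list[TargetHit]:
    """All perfect occurrences of ``read`` on both strands of ``reference``.

    Returns hits ordered by ascending start with '+' before '-' at ties.
    """
    _, refseq = reference
    bad = set(read) - VALID_ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotide(s) {sorted(bad)} in read")
    if len(read) > len(refseq):
        return []
    L = len(read)
    hits = [TargetHit(read, "+", i, L, count) for i in _find_all(read, refseq)]
    rc = revcomp(read)
    minus = [TargetHit(read, "-", i, L, count) for i in _find_all(rc, refseq)]
    if read == rc:  # reverse-complement palindrome: one locus, flagged upstream
        minus = []
    return sorted(hits + minus, key=lambda h: (h.start, h.strand))


def _matches_forward(read: str, refseq: str) -> bool:
    return refseq.find(read) != -1


def _matches_mirna(read: str, mature: str, overhang: int = 2) -> bool:
    """Read lies within mature extended by <= ``overhang`` nt past its 3' end.

    The extension bases are unknown and therefore unconstrained: the read's
    prefix up to the mature 3' end must match exactly.
    """
    if mature.find(read) != -1:
        return True
    for dangle in range(1, overhang + 1):
        if len(read) <= dangle:
            continue
        core = read[:-dangle]
        # core must align flush with the mature 3' end
        if len(core) <= len(mature) and mature.endswith(core):
            return True
    return False


def assign(
    reads: list[CollapsedRead],
    refs: ReferenceBundle,
    *,
    precedence: tuple[str, ...] = COMPARTMENTS,
    mirna_overhang: int = 2,
) -> AssignedLibrary:
    """Partition length-filtered collapsed reads into compartments.

    Every read lands in exactly one of spikein / mirna / genome / target /
    unassigned; all target hits (possibly multiple loci) are recorded with
    strand and 0-based start.
    """
    if set(precedence) != set(COMPARTMENTS):
        raise ValueError(f"precedence must be a permutation of {COMPARTMENTS}")
    if not refs.target_sequence:
        raise ValueError("reference bundle has no target sequence")

    comp: dict[str, list[CollapsedRead]] = defaultdict(list)
    spike_counts: dict[str, int] = {name: 0 for name, _ in refs.spikeins}
    target_hits: list[TargetHit] = []
    ambiguous: set[str] = set()
    total_in = sum(r.count for r in reads)

    for r in reads:
        seq = r.sequence
        placed = False
        for comp_name in precedence:
            if comp_name == "spikein":
                hit_name = next(
                    (n for n, s in refs.spikeins if _matches_forward(seq, s)), None
                )
                if hit_name is not None:
                    comp["spikein"].append(r)
                    spike_counts[hit_name] += r.count
                    placed = True
            elif comp_name == "mirna":
                if any(_matches_mirna(seq, s, mirna_overhang) for _, s in refs.mirnas):
                    comp["mirna"].append(r)
                    placed = True
            elif comp_name == "genome":
                if any(
                    _matches_forward(seq, s) or _matches_forward(revcomp(seq), s)
                    for _, s in refs.genome_proxy
                ):
                    comp["genome"].append(r)
                    placed = True
            elif comp_name == "target":
                hits = match_exact(seq, refs.target, count=r.count)
                if hits:
                    comp["target"].append(r)
                    target_hits.extend(hits)
                    strands = {h.strand for h in hits}
                    if strands == {"+", "-"} or seq == revcomp(seq):
                        ambiguous.add(seq)
                    placed = True
            if placed:
                break
        if not placed:
            comp["unassigned"].append(r)

    totals = {name: sum(x.count for x in comp.get(name, [])) for name in (*COMPARTMENTS, "unassigned")}
    totals["filtered_total"] = total_in
    lib = AssignedLibrary(
        compartments=dict(comp),
        target_hits=target_hits,
        ambiguous_strand=ambiguous,
        totals=totals,
        target_name=refs.target_name,
        target_length=len(refs.target_sequence),
    )
    lib._spikein_counts = spike_counts
    return lib


def unique_hits(
    hits: list[TargetHit], min_len: int = 20, max_len: int = 22
) -> list[TargetHit]:
    """Unique, single-locus hits in the siRNA size range, multiplicity 1.

    Keeps one record per distinct sequence whose only perfect match on the
    target is a single locus, with length within [min_len, max_len]; the
    multiplicity is collapsed to 1, so downstream phasing weighs each distinct
    siRNA species equally.
    """
    by_seq: dict[str, list[TargetHit]] = defaultdict(list)
    for h in hits:
        by_seq[h.sequence].append(h)
    out = []
    for seq, hs in by_seq.items():
        if len(hs) != 1:
            continue
        h = hs[0]
        if min_len <= h.length <= max_len:
            out.append(TargetHit(h.sequence, h.strand, h.start, h.length, 1))
    return sorted(out, key=lambda h: (h.start, h.strand, h.sequence))
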