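"""Synthetic dicing simulator.

Generates replicate small-RNA libraries (FASTQ + per-read ground-truth TSV)
under a parametric model of dsRNA dicing:

* a long dsRNA trigger covering ``injected_interval`` of a target transcript
  is processed into 20-21 nt siRNA duplexes;
* per-position initiation weights (dicing hotspots) are drawn once per
  *biology seed* from a gamma distribution, and per-locus sense-strand
  preference from a beta distribution — so replicates sharing a biology seed
  share hotspot and strand structure, reproducing the recurring coverage
  pattern seen across biological replicates, while sequencing noise is
  replicate-specific;
* optionally, a fraction of target-derived molecules are *secondary* siRNAs:
  antisense species synthesised on the target mRNA template, mapping upstream
  of the injected interval, carrying a 5'-triphosphate (RdRp products);
* a mature-miRNA background, four spike-in oligos at fixed input abundance,
  and random degradation fragments drawn from decoy sequences complete the
  pool;
* a library protocol capture mask (standard / RppH-treated / PANDORA) filters
  the pool by 5' chemistry, then reads are drawn multinomially to the
  requested depth.

Two seeds keep biology and sampling orthogonal: ``biology_seed`` alone
determines the molecule species set and abundances; ``sampling_seed`` alone
determines the multinomial draw.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    DEFAULT_SPIKEIN_NAMES,
    ReferenceBundle,
    clean_sequence,
    revcomp,
    write_fastq,
)

# truth-table / species label vocabulary
ORIGIN_PRIMARY = "primary_siRNA"
ORIGIN_SECONDARY = "secondary_siRNA"
ORIGIN_MIRNA = "miRNA"
ORIGIN_SPIKEIN = "spikein"
ORIGIN_NOISE = "noise"

FP_MONO = "monophosphate"
FP_TRI = "triphosphate"
FP_MOD = "modified"

SENSE = "sense"
ANTISENSE = "antisense"

TRUTH_COLUMNS = ["read_id", "origin", "strand", "start", "length", "five_prime"]


def _default_length_distribution() -> dict[int, float]:
    # modal mass at 20-21 nt with shoulders, matching siRNA-sized products
    d = {
        18: 0.030, 19: 0.070, 20: 0.300, 21: 0.300, 22: 0.120, 23: 0.070,
        24: 0.040, 25: 0.030, 26: 0.015, 27: 0.010, 28: 0.008, 29: 0.004,
        30: 0.003,
    }
    assert abs(sum(d.values()) - 1.0) < 1e-12
    return d


def _default_secondary_lengths() -> dict[int, float]:
    # RdRp products in nematodes run ~1 nt longer than Dicer products
    return {21: 0.2, 22: 0.5, 23: 0.2, 24: 0.1}


@dataclass
class SimConfig:
    """Parameters of one simulated library condition.

    The defaults describe a full-length dsRNA injection against a 720-nt
    target with no secondary amplification; replicates sharing
    ``biology_seed`` share hotspot/strand structure.
    """

    target_sequence: str
    injected_interval: tuple[int, int] = (0, 720)
    length_distribution: Mapping[int, float] = field(default_factory=_default_length_distribution)
    hotspot_concentration: float = 0.3
    strand_bias_concentration: float = 0.5
    secondary_fraction: float = 0.0
    secondary_length_shift: Mapping[int, float] = field(default_factory=_default_secondary_lengths)
    secondary_upstream_only: bool = True
    ppp_fraction_secondary: float = 1.0
    mirna_background: Sequence[tuple[str, float]] = ()
    spikein_sequences: Sequence[str] = ()
    noise_decoys: Sequence[str] = ()
    # library composition (relative pool mass per compartment)
    target_fraction: float = 0.20
    spikein_fraction: float = 0.02
    noise_fraction: float = 0.05
    # processive (end-initiated, phased) dicing instead of internal initiation
    processive: bool = False
    processive_step: int = 21
    depth: int = 100_000
    biology_seed: int = 0
    sampling_seed: int = 0

    def __post_init__(self) -> None:
        self.target_sequence = clean_sequence(self.target_sequence, context="target")
        start, end = self.injected_interval
        n = len(self.target_sequence)
        if not (0 <= start < end <= n):
            raise ValueError(f"injected_interval {self.injected_interval} outside target [0, {n})")
        lengths = self.length_distribution
        if abs(sum(lengths.values()) - 1.0) > 1e-9:
            raise ValueError("length_distribution must sum to 1")
        if any(p < 0 for p in lengths.values()):
            raise ValueError("length probabilities must be >= 0")
        for name, v in [
            ("secondary_fraction", self.secondary_fraction),
            ("ppp_fraction_secondary", self.ppp_fraction_secondary),
            ("target_fraction", self.target_fraction),
            ("spikein_fraction", self.spikein_fraction),
            ("noise_fraction", self.noise_fraction),
        ]:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.target_fraction + self.spikein_fraction + self.noise_fraction > 1.0 + 1e-12:
            raise ValueError("compartment fractions exceed 1")
        if self.hotspot_concentration <= 0 or self.strand_bias_concentration <= 0:
            raise ValueError("concentration parameters must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if n < max(lengths):
            raise ValueError("target shorter than the longest read length")


@dataclass(frozen=True)
class PoolSpecies:
    """One molecule species in the pre-sequencing pool."""

    sequence: str
    origin: str
    abundance: float
    strand: str | None = None  # relative to the target; None off-target
    start: int | None = None   # 0-based leftmost base on target sense coords
    length: int | None = None
    five_prime: str = FP_MONO


@dataclass
class TruePool:
    """Molecule species with relative abundances and truth labels."""

    species: list[PoolSpecies]
    config: SimConfig

    @property
    def total_abundance(self) -> float:
        return float(sum(s.abundance for s in self.species))

    def subset(self, origin: str) -> list[PoolSpecies]:
        return [s for s in self.species if s.origin == origin]


@dataclass(frozen=True)
class LibraryProtocol:
    """Capture chemistry of a small-RNA library protocol.

    Ligation-dependent protocols only see 5'-monophosphate species; RppH
    treatment converts 5'-triphosphate to monophosphate first; PANDORA-style
    treatment additionally removes blocking modifications.
    """

    name: str
    captures_triphosphate: bool
    captures_modified: bool


STANDARD = LibraryProtocol("standard", captures_triphosphate=False, captures_modified=False)
RPPH = LibraryProtocol("rpph", captures_triphosphate=True, captures_modified=False)
PANDORA = LibraryProtocol("pandora", captures_triphosphate=True, captures_modified=True)
PROTOCOLS = {p.name: p for p in (STANDARD, RPPH, PANDORA)}


def get_protocol(name: str) -> LibraryProtocol:
    try:
        return PROTOCOLS[name]
    except KeyError:
        raise ValueError(f"unknown protocol {name!r}; known: {sorted(PROTOCOLS)}") from None


# ---------------------------------------------------------------------------
# Reference generation (synthetic stand-ins with guaranteed disjointness)
# ---------------------------------------------------------------------------

def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def make_references(
    seed: int = 0,
    *,
    target_length: int = 720,
    n_mirnas: int = 20,
    n_decoys: int = 2,
    decoy_length: int = 1000,
    guard_k: int = 15,
) -> ReferenceBundle:
    """Build a synthetic reference bundle for simulation studies.

    All sequences are synthetic: a random target standing in for a 720-nt
    transgene CDS, random mature miRNAs, four random spike-in oligos named
    after the wet-lab spike-in mix, and dinucleotide-decoy contigs used both
    as the genome proxy and as the source of degradation-noise fragments.
    Rejection sampling guarantees that no ``guard_k``-mer is shared between
    the target (either strand) and any other reference, so compartment
    assignment on simulated data is exactly decidable.
    """
    rng = np.random.default_rng(seed)
    target = random_sequence(rng, target_length)
    forbidden = _kmers(target, guard_k) | _kmers(revcomp(target), guard_k)

    def draw_disjoint(length: int) -> str:
        for _ in range(1000):
            s = random_sequence(rng, length)
            ks = _kmers(s, guard_k) | _kmers(revcomp(s), guard_k)
            if not (ks & forbidden):
                forbidden.update(ks)
                return s
        raise RuntimeError("could not draw a disjoint sequence")  # pragma: no cover

    mirnas = [(f"mir-{i + 1}", draw_disjoint(int(rng.integers(21, 23)))) for i in range(n_mirnas)]
    spikeins = [(name, draw_disjoint(22)) for name in DEFAULT_SPIKEIN_NAMES]
    decoys = [(f"decoy-{i + 1}", draw_disjoint(decoy_length)) for i in range(n_decoys)]
    return ReferenceBundle(
        target=("target", target), genome_proxy=decoys, mirnas=mirnas, spikeins=spikeins
    )


def config_from_references(refs: ReferenceBundle, **overrides) -> SimConfig:
    """Convenience: a SimConfig wired to a reference bundle.

    miRNA background abundances follow a geometric profile (a few dominant
    guides, a long tail), as in real small-RNA libraries.
    """
    n = len(refs.mirnas)
    weights = [0.8 ** i for i in range(n)]
    total = sum(weights)
    background = [(seq, w / total) for (name, seq), w in zip(refs.mirnas, weights)]
    return SimConfig(
        target_sequence=refs.target_sequence,
        mirna_background=background,
        spikein_sequences=[s for _, s in refs.spikeins],
        noise_decoys=[s for _, s in refs.genome_proxy],
        **overrides,
    )


# ---------------------------------------------------------------------------
# Pool simulation
# ---------------------------------------------------------------------------

def simulate_pool(config: SimConfig) -> TruePool:
    """Draw the molecule-species pool for one biological sample.

    Deterministic given ``config.biology_seed``; ``sampling_seed`` is unused
    here by contract.
    """
    rng = np.random.default_rng(config.biology_seed)
    target = config.target_sequence
    istart, iend = config.injected_interval
    species: list[PoolSpecies] = []

    # --- target-derived siRNAs -------------------------------------------
    primary_mass = config.target_fraction * (1.0 - config.secondary_fraction)
    secondary_mass = config.target_fraction * config.secondary_fraction

    if config.processive:
        step = config.processive_step
        starts = list(range(istart, iend - step + 1, step))
        lengths = {step: 1.0}
    else:
        starts = list(range(istart, iend))
        lengths = dict(config.length_distribution)

    # hotspot weight and sense-strand preference per initiation locus,
    # drawn once per biology seed (shared across replicates); an infinite
    # concentration degenerates to uniform weights / unbiased strands
    if np.isinf(config.hotspot_concentration):
        w = np.ones(len(starts))
    else:
        w = rng.gamma(config.hotspot_concentration, 1.0, size=len(starts))
    if np.isinf(config.strand_bias_concentration):
        s_prob = np.full(len(starts), 0.5)
    else:
        s_prob = rng.beta(
            config.strand_bias_concentration, config.strand_bias_concentration, size=len(starts)
        )

    raw: list[tuple[str, str, int, int, float]] = []  # seq, strand, start, length, weight
    for pos, wp, sp in zip(starts, w, s_prob):
        for L, qL in lengths.items():
            if qL <= 0 or pos + L > iend:
                continue
            sub = target[pos : pos + L]
            raw.append((sub, SENSE, pos, L, wp * sp * qL))
            raw.append((revcomp(sub), ANTISENSE, pos, L, wp * (1.0 - sp) * qL))
    if primary_mass > 0 and raw:
        tot = sum(r[-1] for r in raw)
        for seq, strand, pos, L, wt in raw:
            if wt <= 0:
                continue
            species.append(
                PoolSpecies(seq, ORIGIN_PRIMARY, primary_mass * wt / tot, strand, pos, L, FP_MONO)
            )

    # --- secondary siRNAs -------------------------------------------------
    if secondary_mass > 0:
        sec: list[tuple[str, int, int, float]] = []
        for L, qL in config.secondary_length_shift.items():
            if qL <= 0:
                continue
            if config.secondary_upstream_only:
                if istart == 0:
                    raise ValueError("secondary_upstream_only requires injected_interval start > 0")
                valid = range(0, max(istart - L + 1, 0))
            else:
                valid = range(0, len(target) - L + 1)
            for pos in valid:
                sec.append((revcomp(target[pos : pos + L]), pos, L, qL))
        tot = sum(s[-1] for s in sec)
        for seq, pos, L, wt in sec:
            mass = secondary_mass * wt / tot
            ppp = config.ppp_fraction_secondary
            if ppp > 0:
                species.append(
                    PoolSpecies(seq, ORIGIN_SECONDARY, mass * ppp, ANTISENSE, pos, L, FP_TRI)
                )
            if ppp < 1:
                species.append(
                    PoolSpecies(seq, ORIGIN_SECONDARY, mass * (1 - ppp), ANTISENSE, pos, L, FP_MONO)
                )

    # --- miRNA background --------------------------------------------------
    mirna_mass = max(
        1.0 - config.target_fraction - config.spikein_fraction - config.noise_fraction, 0.0
    )
    if config.mirna_background and mirna_mass > 0:
        tot = sum(a for _, a in config.mirna_background)
        for seq, ab in config.mirna_background:
            if ab <= 0:
                continue
            seq = clean_sequence(seq, context="miRNA background")
            species.append(
                PoolSpecies(seq, ORIGIN_MIRNA, mirna_mass * ab / tot, None, None, len(seq), FP_MONO)
            )

    # --- spike-ins: equimolar fixed input ----------------------------------
    if config.spikein_sequences and config.spikein_fraction > 0:
        each = config.spikein_fraction / len(config.spikein_sequences)
        for seq in config.spikein_sequences:
            seq = clean_sequence(seq, context="spike-in")
            species.append(PoolSpecies(seq, ORIGIN_SPIKEIN, each, None, None, len(seq), FP_MONO))

    # --- degradation noise from decoys -------------------------------------
    if config.noise_decoys and config.noise_fraction > 0:
        n_frag = 200
        decoys = [clean_sequence(d, context="decoy") for d in config.noise_decoys]
        each = config.noise_fraction / n_frag
        for _ in range(n_frag):
            d = decoys[int(rng.integers(len(decoys)))]
            L = int(rng.integers(15, 31))
            pos = int(rng.integers(0, len(d) - L + 1))
            frag = d[pos : pos + L]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            species.append(PoolSpecies(frag, ORIGIN_NOISE, each, None, None, L, FP_MONO))

    if not species:
        raise ValueError("configuration produced an empty pool")
    return TruePool(species, config)


def apply_protocol(pool: TruePool, protocol: LibraryProtocol | str) -> TruePool:
    """Filter the pool by the protocol's 5'-chemistry capture mask."""
    if isinstance(protocol, str):
        protocol = get_protocol(protocol)
    if not pool.species:
        raise ValueError("cannot apply a protocol to an empty pool")
    keep = []
    for sp in pool.species:
        if sp.five_prime == FP_TRI and not protocol.captures_triphosphate:
            continue
        if sp.five_prime == FP_MOD and not protocol.captures_modified:
            continue
        keep.append(sp)
    return TruePool(keep, pool.config)


# ---------------------------------------------------------------------------
# Sequencing
# ---------------------------------------------------------------------------

def sample_library(
    pool: TruePool,
    depth: int | None = None,
    sampling_seed: int | None = None,
    *,
    protocol_name: str = "standard",
    read_prefix: str = "read",
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Multinomial sequencing draw over the pool.

    Returns ``(reads, truth)`` where ``reads`` is ``[(read_id, sequence), ...]``
    of exactly ``depth`` entries and ``truth`` has one row per read with
    columns ``read_id, origin, strand, start, length, five_prime``.
    """
    depth = pool.config.depth if depth is None else depth
    if depth <= 0:
        raise ValueError("depth must be positive")
    seed = pool.config.sampling_seed if sampling_seed is None else sampling_seed
    if not pool.species:
        raise ValueError(
            f"pool is empty after protocol {protocol_name!r}: nothing to sequence"
        )
    ab = np.array([s.abundance for s in pool.species], dtype=float)
    total = ab.sum()
    if total <= 0:
        raise ValueError("pool has zero total abundance")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, ab / total)
    idx = np.repeat(np.arange(len(pool.species)), counts)
    reads: list[tuple[str, str]] = []
    rows = []
    for i, k in enumerate(idx):
        sp = pool.species[k]
        rid = f"{read_prefix}_{i:07d}"
        reads.append((rid, sp.sequence))
        rows.append(
            (rid, sp.origin, sp.strand if sp.strand else "",
             sp.start if sp.start is not None else "", sp.length, sp.five_prime)
        )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return reads, truth


def hits_from_truth(truth: pd.DataFrame, target_sequence: str) -> list:
    """Target hits reconstructed from a ground-truth table.

    Oracle-side counterpart of exact-match assignment for simulated data:
    target-derived rows are grouped by (strand, start, length) and turned
    into :class:`~sirnakit.assign.TargetHit` records.  Useful for
    operating-characteristic loops where re-running string matching per
    replicate adds nothing (assignment equals truth tallies exactly on
    simulated libraries).
    """
    from .assign import TargetHit

    t = truth[truth.origin.isin([ORIGIN_PRIMARY, ORIGIN_SECONDARY])]
    hits = []
    for (strand, start, length), sub in t.groupby(["strand", "start", "length"]):
        start, length = int(start), int(length)
        seq = target_sequence[start : start + length]
        if strand == ANTISENSE:
            seq = revcomp(seq)
        hits.append(
            TargetHit(seq, "+" if strand == SENSE else "-", start, length, int(len(sub)))
        )
    return sorted(hits, key=lambda h: (h.start, h.strand))


# ---------------------------------------------------------------------------
# Experiment designs
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """One experimental group: a condition plus the protocols applied to it.

    With more than one protocol, the *same* RNA pool per replicate is run
    through each protocol (paired treated/untreated libraries from one
    extraction, as in an RppH contrast).
    """

    name: str
    config: SimConfig
    protocols: Sequence[str] = ("standard",)


def mock_config(config: SimConfig, **overrides) -> SimConfig:
    """The mock-injection counterpart of a dsRNA condition.

    Mock libraries contain miRNA background, spike-ins and noise only: no
    target-derived siRNA mass at all.
    """
    return replace(config, target_fraction=0.0, secondary_fraction=0.0, **overrides)


def make_design(
    groups: Sequence[GroupSpec],
    n_replicates: int,
    out_dir: str | Path,
    *,
    sampling_seeds: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Simulate one library per (group, protocol, replicate) and write them.

    Replicates of a group share the group's ``biology_seed`` (shared hotspot
    and strand structure) and differ in sampling seed.  Writes FASTQ + truth
    TSV per library plus ``sample_sheet.tsv`` and a JSON echo of each group
    config; returns the sample sheet.
    """
    if not groups:
        raise ValueError("need at least one group")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if sampling_seeds is not None and len(sampling_seeds) != n_replicates:
        raise ValueError(
            f"got {len(sampling_seeds)} sampling seeds for {n_replicates} replicates"
        )
    rows = []
    for g in groups:
        pool0 = simulate_pool(g.config)
        cfg_echo = asdict(g.config)
        cfg_echo["length_distribution"] = {int(k): v for k, v in g.config.length_distribution.items()}
        cfg_echo["secondary_length_shift"] = {int(k): v for k, v in g.config.secondary_length_shift.items()}
        (out / f"config_{g.name}.json").write_text(json.dumps(cfg_echo, indent=2, default=list))
        for r in range(1, n_replicates + 1):
            seed = (
                sampling_seeds[r - 1]
                if sampling_seeds is not None
                else (g.config.sampling_seed + 1009 * r + zlib.crc32(g.name.encode()) % 7919)
                % (2**31)
            )
            for j, prot_name in enumerate(g.protocols):
                captured = apply_protocol(pool0, prot_name)
                sample = f"{g.name}_{prot_name}_rep{r}" if len(g.protocols) > 1 else f"{g.name}_rep{r}"
                reads, truth = sample_library(
                    captured,
                    sampling_seed=(seed + 104729 * j) % (2**31),
                    protocol_name=prot_name,
                    read_prefix=sample,
                )
                fq = out / f"{sample}.fastq"
                tt = out / f"{sample}.truth.tsv"
                write_fastq(fq, reads)
                truth.to_csv(tt, sep="\t", index=False)
                rows.append(
                    {
                        "sample": sample,
                        "group": g.name,
                        "replicate": r,
                        "protocol": prot_name,
                        "fastq": fq.name,
                        "truth": tt.name,
                    }
                )
    sheet = pd.DataFrame(rows)
    sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    return sheet
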