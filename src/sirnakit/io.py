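"""Reference/sequence I/O and read collapsing.

Reads and writes the plain-text formats the pipeline touches (FASTA, FASTQ,
TSV tables, bedGraph) and collapses raw reads into unique sequences with
multiplicities.  Sequences are normalised to uppercase DNA (U -> T); ambiguity
codes are rejected because every downstream step relies on exact matching.

Coordinates everywhere in the package are 0-based, half-open; strand is
reported as '+'/'-' with '-' meaning the read equals the reverse complement of
the reference slice.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_ALPHABET = frozenset("ACGT")

#: default spike-in names (synthetic oligos named after the miRNAs whose
#: sequences they mimic in the wet-lab mix)
DEFAULT_SPIKEIN_NAMES = ("lin-4-5p", "miR-125a-5p", "miR-148a-3p", "miR-659-5p")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def clean_sequence(seq: str, *, context: str = "") -> str:
    """Uppercase, coerce U->T and validate the alphabet.

    Raises ``ValueError`` for empty sequences or characters outside ACGTU.
    """
    s = seq.strip().upper().replace("U", "T")
    if not s:
        raise ValueError(f"empty sequence{' in ' + context if context else ''}")
    bad = set(s) - VALID_ALPHABET
    if bad:
        raise ValueError(
            f"invalid nucleotide(s) {sorted(bad)}{' in ' + context if context else ''}; "
            "only A/C/G/T/U are accepted"
        )
    return s


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def _sniff_format(path: str | Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line[0]
                break
        else:
            raise ValueError(f"{path}: empty file")
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError(f"{path}: cannot determine format from leading character {first!r}")


def read_sequences(path: str | Path, format: str | None = None) -> list[tuple[str, str]]:
    """Parse a FASTA or FASTQ file into ``[(name, sequence), ...]``.

    ``format`` is 'fasta', 'fastq' or None (sniffed from the first record
    character).  Sequences are cleaned via :func:`clean_sequence`; malformed or
    empty records raise ``ValueError`` naming the offending record.
    """
    fmt = format or _sniff_format(path)
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    # cross-check the file actually is the declared format
    sniffed = _sniff_format(path)
    if sniffed != fmt:
        raise ValueError(f"{path}: declared {fmt} but file starts like {sniffed}")
    out: list[tuple[str, str]] = []
    for i, rec in enumerate(SeqIO.parse(str(path), fmt)):
        try:
            seq = clean_sequence(str(rec.seq), context=f"record {i} ({rec.id})")
        except ValueError as e:
            raise ValueError(f"{path}: {e}") from None
        out.append((rec.id, seq))
    if not out:
        raise ValueError(f"{path}: no records parsed")
    return out


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(s), id=n, description="") for n, s in records]
    SeqIO.write(recs, str(path), "fasta-2line")


def write_fastq(path: str | Path, records: Iterable[tuple[str, str]], quality_char: str = "I") -> None:
    """Write 4-line FASTQ records with a constant quality string (Q40 default)."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


# ---------------------------------------------------------------------------
# Collapsed reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CollapsedRead:
    """A distinct small-RNA sequence with its multiplicity in a library."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


def collapse(reads: Iterable[str]) -> list[CollapsedRead]:
    """Collapse raw read sequences into unique sequences with counts.

    Output is sorted by descending count, then sequence, so it is deterministic.
    Empty input gives an empty list; total count is conserved.
    """
    tally = Counter(reads)
    return [
        CollapsedRead(seq, n)
        for seq, n in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def expand(collapsed: Iterable[CollapsedRead]) -> list[str]:
    """Inverse of :func:`collapse` up to ordering (multiset identity)."""
    out: list[str] = []
    for cr in collapsed:
        out.extend([cr.sequence] * cr.count)
    return out


# ---------------------------------------------------------------------------
# Reference bundle
# ---------------------------------------------------------------------------

@dataclass
class ReferenceBundle:
    """All references the assignment step needs.

    target
        the transgene the dsRNA is directed against (e.g. a 720-nt eGFP CDS)
    genome_proxy
        named sequences standing in for the host genome
    mirnas
        mature miRNA sequences (18-24 nt typical)
    spikeins
        exactly four synthetic oligos of known input amount
    """

    target: tuple[str, str]
    genome_proxy: list[tuple[str, str]] = field(default_factory=list)
    mirnas: list[tuple[str, str]] = field(default_factory=list)
    spikeins: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.target = (self.target[0], clean_sequence(self.target[1], context="target"))
        self.genome_proxy = [(n, clean_sequence(s, context=n)) for n, s in self.genome_proxy]
        self.mirnas = [(n, clean_sequence(s, context=n)) for n, s in self.mirnas]
        self.spikeins = [(n, clean_sequence(s, context=n)) for n, s in self.spikeins]
        if len(self.spikeins) != 4:
            raise ValueError(f"expected exactly 4 spike-ins, got {len(self.spikeins)}")
        names = [self.target[0]]
        names += [n for n, _ in self.genome_proxy + self.mirnas + self.spikeins]
        if len(names) != len(set(names)):
            raise ValueError("reference names must be unique across the bundle")

    @property
    def target_name(self) -> str:
        return self.target[0]

    @property
    def target_sequence(self) -> str:
        return self.target[1]


def load_reference_bundle(directory: str | Path) -> ReferenceBundle:
    """Load a bundle from a directory with target.fa, genome_proxy.fa, mirnas.fa, spikeins.fa."""
    d = Path(directory)
    target = read_sequences(d / "target.fa", "fasta")
    if len(target) != 1:
        raise ValueError("target.fa must contain exactly one sequence")
    return ReferenceBundle(
        target=target[0],
        genome_proxy=read_sequences(d / "genome_proxy.fa", "fasta"),
        mirnas=read_sequences(d / "mirnas.fa", "fasta"),
        spikeins=read_sequences(d / "spikeins.fa", "fasta"),
    )


def write_reference_bundle(refs: ReferenceBundle, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_fasta(d / "target.fa", [refs.target])
    write_fasta(d / "genome_proxy.fa", refs.genome_proxy)
    write_fasta(d / "mirnas.fa", refs.mirnas)
    write_fasta(d / "spikeins.fa", refs.spikeins)


# ---------------------------------------------------------------------------
# Tabular inputs (TSV)
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = ["sample", "group", "replicate"]
CT_COLUMNS = ["sample", "group", "replicate", "gene", "ct"]
BAND_COLUMNS = ["membrane", "sample", "group", "protein", "intensity"]
FLUOR_COLUMNS = ["image", "group", "embryo_id", "mean_intensity", "background_intensity"]


def _read_tsv(path: str | Path, required: Sequence[str], numeric: Sequence[str]) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    if p.stat().st_size == 0:
        raise ValueError(f"{p}: empty file")
    df = pd.read_csv(p, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{p}: missing required column(s) {missing}")
    if df.empty:
        raise ValueError(f"{p}: no data rows")
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            raise ValueError(
                f"{p}: non-numeric value in column {col!r} at row index {int(bad.idxmax())}"
            )
        if df[col].isna().any():
            raise ValueError(f"{p}: missing value in numeric column {col!r}")
        df[col] = vals
    return df


def load_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, SAMPLE_SHEET_COLUMNS, [])
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r} in sample sheet")
    return df


def load_ct_table(path: str | Path, sample_sheet: pd.DataFrame | None = None) -> pd.DataFrame:
    """Load a Ct table (columns sample, group, replicate, gene, ct)."""
    df = _read_tsv(path, CT_COLUMNS, ["ct"])
    dup = df.duplicated(subset=["sample", "gene"])
    if dup.any():
        pair = df.loc[dup, ["sample", "gene"]].iloc[0]
        raise ValueError(f"duplicate (sample, gene) row: ({pair['sample']}, {pair['gene']})")
    _check_against_sheet(df, sample_sheet, path)
    return df


def load_band_table(path: str | Path, sample_sheet: pd.DataFrame | None = None) -> pd.DataFrame:
    df = _read_tsv(path, BAND_COLUMNS, ["intensity"])
    if (df["intensity"] < 0).any():
        raise ValueError("band intensities must be >= 0")
    _check_against_sheet(df, sample_sheet, path)
    return df


def load_fluor_table(path: str | Path, sample_sheet: pd.DataFrame | None = None) -> pd.DataFrame:
    df = _read_tsv(path, FLUOR_COLUMNS, ["mean_intensity", "background_intensity"])
    if (df[["mean_intensity", "background_intensity"]] < 0).any().any():
        raise ValueError("fluorescence intensities must be >= 0")
    return df


def _check_against_sheet(df: pd.DataFrame, sheet: pd.DataFrame | None, path) -> None:
    if sheet is None:
        return
    unknown = set(df["sample"]) - set(sheet["sample"])
    if unknown:
        raise ValueError(f"{path}: sample(s) {sorted(unknown)} not in the sample sheet")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(path: str | Path, chrom: str, depth) -> None:
    """Write a per-base depth array as a run-length-merged bedGraph track."""
    lines = []
    start = 0
    prev = None
    for i, v in enumerate(depth):
        if prev is None:
            prev = v
            continue
        if v != prev:
            lines.append(f"{chrom}\t{start}\t{i}\t{prev:g}")
            start, prev = i, v
    if prev is not None:
        lines.append(f"{chrom}\t{start}\t{len(depth)}\t{prev:g}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def to_one_based_inclusive(start: int, length: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive for reports."""
    return start + 1, start + length
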