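"""Reading, writing, orienting and quality-filtering amplicon sequences.

Input is one FASTA record per haploid drone (a single mitotype per record, no
heteroplasmy handling) plus a sample manifest joining sequence ids to region,
subspecies and country labels. All coordinates in the package are 0-based,
half-open; after :func:`orient_record` every sequence is stored on the +
strand, i.e. with the E2 forward primer upstream of the reverse-complemented
H2 primer.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "SampleManifest",
    "PrimerPair",
    "FastaParseError",
    "EmptyDatasetError",
    "read_fasta",
    "write_fasta",
    "orient_record",
    "qc_filter",
    "reverse_complement",
]

#: Alphabet allowed in unaligned sequences; "-" is legal only inside alignments.
UNALIGNED_ALPHABET = frozenset("ACGTN")

#: E2 / H2, the primer pair amplifying the COI-COII intergenic region.
E2_PRIMER = "GGCAGAATAAGTGCATTG"
H2_PRIMER = "CAATATCATTGATGACC"


class FastaParseError(ValueError):
    """Raised when a FASTA file is syntactically invalid or contains illegal symbols."""


class EmptyDatasetError(ValueError):
    """Raised when an input file yields no sequence records."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair; defaults are the E2/H2 pair for the COI-COII region."""

    forward: str = E2_PRIMER
    reverse: str = H2_PRIMER
    name_forward: str = "E2"
    name_reverse: str = "H2"

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("both primers must be non-empty")


@dataclass(frozen=True)
class SequenceRecord:
    """One sample's amplicon sequence with metadata.

    ``flags`` accumulates processing warnings (e.g. ``orientation-failed``);
    ``primer_span`` holds 0-based half-open (forward, reverse) primer match
    coordinates once orientation has succeeded.
    """

    sample_id: str
    bases: str
    region: str | None = None
    subspecies: str | None = None
    source: str = "sampled"
    flags: tuple[str, ...] = ()
    primer_span: tuple[tuple[int, int], tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"record {self.sample_id!r} has empty sequence")
        bad = set(self.bases) - UNALIGNED_ALPHABET - {"-"}
        if bad:
            raise ValueError(
                f"record {self.sample_id!r} contains illegal symbols {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def oriented(self) -> bool:
        return self.primer_span is not None

    def with_flags(self, *flags: str) -> "SequenceRecord":
        return replace(self, flags=self.flags + flags)


@dataclass
class SampleManifest:
    """Sample metadata table with columns sample_id, region, subspecies, country."""

    table: pd.DataFrame

    COLUMNS = ("sample_id", "region", "subspecies", "country")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        dup = self.table["sample_id"].duplicated()
        if dup.any():
            dups = self.table.loc[dup, "sample_id"].tolist()
            raise ValueError(f"duplicate sample_id in manifest: {dups}")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def read_csv(cls, path: str | Path) -> "SampleManifest":
        return cls(pd.read_csv(path, dtype=str))

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def lookup(self, sample_id: str) -> dict | None:
        rows = self.table[self.table["sample_id"] == sample_id]
        if rows.empty:
            return None
        return rows.iloc[0].to_dict()

    def unresolved_ids(self, records: list[SequenceRecord]) -> list[str]:
        """Record ids that cannot be joined to the manifest."""
        known = set(self.table["sample_id"])
        return [r.sample_id for r in records if r.sample_id not in known]


def _find_illegal_line(path: str | Path) -> tuple[int, str] | None:
    """Locate the first sequence line holding a symbol outside the DNA alphabet."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            bad = set(line.upper().replace("U", "T")) - UNALIGNED_ALPHABET - {"-"}
            if bad:
                return lineno, sorted(bad)[0]
    return None


def read_fasta(path: str | Path, source: str = "sampled") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    The description line is parsed as ``sample_id`` followed by free text.
    Bases are upper-cased and U is mapped to T. Malformed entries raise
    :class:`FastaParseError` naming the offending line; an empty file raises
    :class:`EmptyDatasetError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    bad = _find_illegal_line(path)
    if bad is not None:
        raise FastaParseError(
            f"{path}: illegal symbol {bad[1]!r} on line {bad[0]}"
        )
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        bases = str(entry.seq).upper().replace("U", "T")
        if not entry.id:
            raise FastaParseError(f"{path}: record with empty id")
        if entry.id in seen:
            raise FastaParseError(f"{path}: duplicate sample_id {entry.id!r}")
        seen.add(entry.id)
        records.append(SequenceRecord(sample_id=entry.id, bases=bases, source=source))
    if not records:
        raise EmptyDatasetError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: list[SequenceRecord], path: str | Path, line_width: int = 60
) -> None:
    """Write records to FASTA, wrapping sequence lines at ``line_width`` columns."""
    if not records:
        raise ValueError("refusing to write an empty record list")
    seqrecords = [
        SeqRecord(Seq(r.bases), id=r.sample_id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(seqrecords)


def _primer_hits(seq: str, primer: str, max_mismatch: int) -> list[int]:
    """Start positions where ``primer`` matches with at most ``max_mismatch``
    substitutions (no indels)."""
    k = len(primer)
    hits = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        mism = sum(1 for a, b in zip(window, primer) if a != b)
        if mism <= max_mismatch:
            hits.append(i)
    return hits


def _primer_layout(
    seq: str, primers: PrimerPair, max_mismatch: int
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Span of the forward primer and of the reverse-complemented reverse
    primer on ``seq``, or None if the expected layout is absent."""
    fwd = _primer_hits(seq, primers.forward, max_mismatch)
    rev = _primer_hits(seq, reverse_complement(primers.reverse), max_mismatch)
    klen_f, klen_r = len(primers.forward), len(primers.reverse)
    for f in fwd:
        later = [r for r in rev if r >= f + klen_f]
        if later:
            r = later[-1]
            return (f, f + klen_f), (r, r + klen_r)
    return None


def orient_record(
    record: SequenceRecord, primers: PrimerPair | None = None, max_mismatch: int = 2
) -> SequenceRecord:
    """Return the record on the strand where the forward primer lies upstream
    of the reverse-complemented reverse primer.

    Sanger reads merged from both directions may arrive on either strand. If
    neither strand shows the primer layout the record is returned flagged
    ``orientation-failed`` (to be excluded downstream), never raised on.
    Idempotent: orienting an oriented record is a no-op.
    """
    primers = primers or PrimerPair()
    if record.oriented:
        return record
    layout = _primer_layout(record.bases, primers, max_mismatch)
    if layout is not None:
        return replace(record, primer_span=layout)
    rc = reverse_complement(record.bases)
    layout = _primer_layout(rc, primers, max_mismatch)
    if layout is not None:
        return replace(record, bases=rc, primer_span=layout)
    return record.with_flags("orientation-failed")


def qc_filter(
    records: list[SequenceRecord],
    min_length: int = 300,
    max_n_fraction: float = 0.02,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Drop short and N-rich sequences, mirroring the manual removal of
    bad-quality Sanger reads.

    Returns the retained records plus a report table with one row per removed
    record and the reason (``orientation-failed``, ``min_length`` or
    ``max_n_fraction``). The input is partitioned: every record is either
    retained or reported, never both or neither.
    """
    retained: list[SequenceRecord] = []
    rows = []
    for rec in records:
        if "orientation-failed" in rec.flags:
            rows.append((rec.sample_id, "orientation-failed", len(rec), _n_frac(rec)))
        elif len(rec) < min_length:
            rows.append((rec.sample_id, "min_length", len(rec), _n_frac(rec)))
        elif _n_frac(rec) > max_n_fraction:
            rows.append((rec.sample_id, "max_n_fraction", len(rec), _n_frac(rec)))
        else:
            retained.append(rec)
    report = pd.DataFrame(
        rows, columns=["sample_id", "reason", "length", "n_fraction"]
    )
    return retained, report


def _n_frac(rec: SequenceRecord) -> float:
    return rec.bases.count("N") / len(rec)
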