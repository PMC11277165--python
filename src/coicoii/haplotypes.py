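"""Haplotype collapse, catalog matching and lineage-series nomenclature.

Records of one structure class are aligned in a unit-anchored fashion (each
unit occurrence aligned to its library reference, insertion columns merged
across records), collapsed to haplotypes by exact identity of the aligned
rows, matched against a catalog of named haplotypes, and novel groups are
named under the lineage-series convention used in the honey bee COI-COII
literature: a lineage letter plus an integer series (A74), with lowercase
suffixes for 1-2 SNP satellites of an existing name (A74c) and a fresh
integer for anything further away.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd

from coicoii.sequence_io import SequenceRecord
from coicoii.structure import (
    StructureAnnotation,
    UnitLibrary,
    annotate,
    assign_lineage,
    default_unit_library,
    _make_aligner,
)

__all__ = [
    "UnitAnchoredAlignment",
    "HaplotypeGroup",
    "HaplotypeCatalog",
    "CatalogEntry",
    "HaplotypeAssignment",
    "align_within_class",
    "collapse_haplotypes",
    "match_catalog",
    "assign_names",
    "summarize_structures",
    "summarize_haplotypes",
    "parse_haplotype_name",
]

#: Grammar of haplotype names: lineage letter, integer series, optional
#: lowercase suffix (underscore-joined published aliases accepted), optional
#: prime mark preserved from published names.
NAME_GRAMMAR = re.compile(r"^([A-Z])(\d+)(?:_?([a-z]+))?([′'])?$")

_PAIR_ALIGNER = _make_aligner()
# Unit-anchored block alignment is strictly global on both sides.
_PAIR_ALIGNER.open_left_deletion_score = -4
_PAIR_ALIGNER.extend_left_deletion_score = -1
_PAIR_ALIGNER.open_right_deletion_score = -4
_PAIR_ALIGNER.extend_right_deletion_score = -1


def parse_haplotype_name(name: str) -> tuple[str, int, str, str]:
    """Split a name like ``A74c`` or ``C2_d`` or ``A77′`` into
    (lineage letter, series number, suffix, prime)."""
    m = NAME_GRAMMAR.match(name)
    if not m:
        raise ValueError(f"name {name!r} does not follow the nomenclature grammar")
    letter, number, suffix, prime = m.groups()
    return letter, int(number), suffix or "", prime or ""


@dataclass(frozen=True)
class UnitAnchoredAlignment:
    """A gapped alignment of one structure class.

    Columns are the library reference positions of each unit block in
    structure order, plus insertion columns merged across rows at the same
    reference offset (left-justified). ``column_provenance`` records, per
    column, the originating unit label and either the unit-internal offset or
    an insertion tag.
    """

    structure_class: str
    rows: dict[str, str]
    column_provenance: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("ragged alignment rows")

    @property
    def column_count(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def subset(self, ids: list[str]) -> "UnitAnchoredAlignment":
        return replace(self, rows={i: self.rows[i] for i in ids})


@dataclass(frozen=True)
class HaplotypeGroup:
    members: tuple[str, ...]
    representative: str  # aligned sequence
    low_confidence: bool = False  # True when the rows carry N calls

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    lineage: str
    structure: str
    sequence: str | None  # aligned; None for metadata-only published entries
    provenance: str = "published"
    accession: str | None = None

    def __post_init__(self) -> None:
        parse_haplotype_name(self.name)


@dataclass
class HaplotypeCatalog:
    """Named haplotypes supporting matching and name generation."""

    entries: list[CatalogEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("duplicate names in catalog")

    def add(self, entry: CatalogEntry) -> None:
        if any(e.name == entry.name for e in self.entries):
            raise ValueError(f"name collision: {entry.name}")
        self.entries.append(entry)

    def of_structure(self, structure: str) -> list[CatalogEntry]:
        return [e for e in self.entries if e.structure == structure]

    def max_series(self, lineage: str) -> int:
        numbers = [
            parse_haplotype_name(e.name)[1]
            for e in self.entries
            if parse_haplotype_name(e.name)[0] == lineage
        ]
        return max(numbers, default=0)

    def occupied_suffixes(self, lineage: str, number: int) -> set[str]:
        out = set()
        for e in self.entries:
            letter, num, suffix, _ = parse_haplotype_name(e.name)
            if letter == lineage and num == number and suffix:
                out.add(suffix)
        return out

    @classmethod
    def load_published(cls) -> "HaplotypeCatalog":
        """The packaged catalog of published haplotype names.

        Metadata only (name, lineage, structure, GenBank accession): the
        deposited sequences live behind accessions and are fetched only by
        the optional online validation, so the default build stays offline.
        """
        ref = resources.files("coicoii").joinpath("data/published_haplotypes.tsv")
        with resources.as_file(ref) as path:
            table = pd.read_csv(path, sep="\t", dtype=str)
        return cls(
            entries=[
                CatalogEntry(
                    name=r["name"],
                    lineage=r["lineage"],
                    structure=r["structure"],
                    sequence=None,
                    provenance="published",
                    accession=r["accession"],
                )
                for _, r in table.iterrows()
            ]
        )

    @classmethod
    def from_fasta(cls, path: str | Path) -> "HaplotypeCatalog":
        """Catalog FASTA whose record ids are ``name|lineage|structure``."""
        from coicoii.sequence_io import read_fasta

        entries = []
        for rec in read_fasta(path, source="reference"):
            try:
                name, lineage, structure = rec.sample_id.split("|")
            except ValueError as exc:
                raise ValueError(
                    f"catalog id {rec.sample_id!r} is not name|lineage|structure"
                ) from exc
            entries.append(
                CatalogEntry(
                    name=name, lineage=lineage, structure=structure, sequence=rec.bases
                )
            )
        return cls(entries=entries)

    def to_fasta(self, path: str | Path) -> None:
        from coicoii.sequence_io import SequenceRecord, write_fasta

        records = [
            SequenceRecord(
                sample_id=f"{e.name}|{e.lineage}|{e.structure}",
                bases=e.sequence,
                source="reference",
            )
            for e in self.entries
            if e.sequence
        ]
        write_fasta(records, path)


@dataclass(frozen=True)
class HaplotypeAssignment:
    sample_id: str
    haplotype_name: str
    novelty: str  # known | renamed_alias | novel
    distance_to_nearest_known: float  # SNP count; inf when no catalog entry
    indel_difference: bool
    low_confidence: bool = False


# ---------------------------------------------------------------------------
# Unit-anchored alignment


def _align_block(segment: str, ref: str) -> tuple[dict[int, str], dict[int, str]]:
    """Globally align a record segment to a unit reference.

    Returns (column base per reference offset — '-' for deletions,
    insertions keyed by the reference offset *before* which they occur).
    """
    aln = _PAIR_ALIGNER.align(segment, ref)[0]
    tgt, qry = str(aln[0]), str(aln[1])
    columns: dict[int, str] = {}
    insertions: dict[int, str] = {}
    ref_off = 0
    for t, q in zip(tgt, qry):
        if q == "-":
            insertions[ref_off] = insertions.get(ref_off, "") + t
        else:
            columns[ref_off] = t
            ref_off += 1
    return columns, insertions


def align_within_class(
    records: list[SequenceRecord],
    annotations: list[StructureAnnotation] | None = None,
    library: UnitLibrary | None = None,
) -> UnitAnchoredAlignment:
    """Align records sharing one structure class, anchored on unit blocks.

    Each unit occurrence is pairwise-aligned to its library reference
    (global, +1/-1 match/mismatch, -4 gap open, -1 extend); columns are the
    reference positions plus insertion columns merged across records at the
    same reference offset, left-justified. Unmatched bases between unit
    matches travel with the following block as insertions at its 5' edge, so
    each row's gap-free sequence equals the record's full sequence.
    """
    library = library or default_unit_library()
    if annotations is None:
        annotations = [annotate(r, library) for r in records]
    ann_by_id = {a.record_id: a for a in annotations}
    structures = {ann_by_id[r.sample_id].structure for r in records}
    if len(structures) != 1:
        raise ValueError(f"mixed structure classes in one alignment: {structures}")
    structure = structures.pop()
    label_seqs = {
        tuple(m.label for m in ann_by_id[r.sample_id].matches) for r in records
    }
    if len(label_seqs) != 1:
        raise ValueError(f"records disagree on block label sequence: {label_seqs}")
    labels = label_seqs.pop()

    # Per block: aligned data per record.
    n_blocks = len(labels)
    per_block: list[dict[str, tuple[dict[int, str], dict[int, str]]]] = [
        {} for _ in range(n_blocks)
    ]
    trailing: dict[str, str] = {}
    for rec in records:
        ann = ann_by_id[rec.sample_id]
        prev_end = 0
        for b, match in enumerate(ann.matches):
            # Unmatched bases since the previous block join this segment.
            segment = rec.bases[prev_end : match.end]
            per_block[b][rec.sample_id] = _align_block(segment, library[match.label])
            prev_end = match.end
        trailing[rec.sample_id] = rec.bases[prev_end:]

    rows = {rec.sample_id: [] for rec in records}
    provenance: list[tuple[str, str]] = []
    for b, label in enumerate(labels):
        ref = library[label]
        ins_width: dict[int, int] = {}
        for rec in records:
            for off, ins in per_block[b][rec.sample_id][1].items():
                ins_width[off] = max(ins_width.get(off, 0), len(ins))
        for off in range(len(ref) + 1):
            width = ins_width.get(off, 0)
            if width:
                for rec in records:
                    ins = per_block[b][rec.sample_id][1].get(off, "")
                    rows[rec.sample_id].append(ins.ljust(width, "-"))
                for k in range(width):
                    provenance.append((label, f"ins{off}.{k}"))
            if off < len(ref):
                for rec in records:
                    rows[rec.sample_id].append(
                        per_block[b][rec.sample_id][0].get(off, "-")
                    )
                provenance.append((label, str(off)))
    trail_width = max((len(t) for t in trailing.values()), default=0)
    if trail_width:
        for rec in records:
            rows[rec.sample_id].append(trailing[rec.sample_id].ljust(trail_width, "-"))
        for k in range(trail_width):
            provenance.append(("3PRIME", f"trail.{k}"))
    aligned_rows = {rid: "".join(parts) for rid, parts in rows.items()}
    for rec in records:
        if aligned_rows[rec.sample_id].replace("-", "") != rec.bases:
            raise AssertionError(
                f"alignment row for {rec.sample_id} does not reproduce its sequence"
            )
    return UnitAnchoredAlignment(
        structure_class=structure,
        rows=aligned_rows,
        column_provenance=tuple(provenance),
    )


# ---------------------------------------------------------------------------
# Collapse and matching


def collapse_haplotypes(alignment: UnitAnchoredAlignment) -> list[HaplotypeGroup]:
    """Group identical aligned rows into haplotypes.

    N is never treated as a wildcard: rows merge only when byte-identical, so
    an N can never hide a real difference; N-bearing groups are flagged
    low-confidence. Groups are sorted by descending size, then lexicographic
    representative.
    """
    if not alignment.rows:
        raise ValueError("empty alignment")
    by_seq: dict[str, list[str]] = {}
    for sample_id in sorted(alignment.rows):
        by_seq.setdefault(alignment.rows[sample_id], []).append(sample_id)
    groups = [
        HaplotypeGroup(
            members=tuple(members),
            representative=seq,
            low_confidence="N" in seq,
        )
        for seq, members in by_seq.items()
    ]
    groups.sort(key=lambda g: (-g.size, g.representative))
    return groups


def _aligned_distance(a: str, b: str) -> tuple[int, bool]:
    """(SNP count, any-indel-column flag) between two equal-length aligned
    rows. N mismatches everything, itself included."""
    if len(a) != len(b):
        raise ValueError("rows of unequal length")
    snps = 0
    indel = False
    for x, y in zip(a, b):
        if x == "-" and y == "-":
            continue
        if x == "-" or y == "-":
            indel = True
        elif x != y or x == "N":
            snps += 1
    return snps, indel


def sequence_distance(
    seq_a: str, seq_b: str, library: UnitLibrary | None = None
) -> tuple[int, bool] | None:
    """Unit-anchored distance between two unaligned sequences of the same
    structure class; None when their structures differ."""
    library = library or default_unit_library()
    rec_a = SequenceRecord(sample_id="__a__", bases=seq_a, source="reference")
    rec_b = SequenceRecord(sample_id="__b__", bases=seq_b, source="reference")
    ann_a, ann_b = annotate(rec_a, library), annotate(rec_b, library)
    if ann_a.structure != ann_b.structure or not ann_a.resolved:
        return None
    try:
        aln = align_within_class([rec_a, rec_b], [ann_a, ann_b], library)
    except ValueError:
        return None
    return _aligned_distance(aln.rows["__a__"], aln.rows["__b__"])


def match_catalog(
    representative: str,
    catalog: HaplotypeCatalog,
    structure: str,
    library: UnitLibrary | None = None,
) -> tuple[str | None, float, bool]:
    """Nearest catalog entry of the same structure class.

    The representative (aligned or unaligned) is re-anchored against each
    sequence-bearing entry; returns the exact-match name at distance 0, else
    the nearest same-lineage entry with its SNP distance and an indel flag.
    Entries without sequences cannot be matched and are skipped.
    """
    library = library or default_unit_library()
    rep = representative.replace("-", "")
    lineage = assign_lineage(structure)
    best: tuple[str, int, bool] | None = None
    for entry in catalog.of_structure(structure):
        if entry.sequence is None or entry.lineage != lineage:
            continue
        dist = sequence_distance(rep, entry.sequence.replace("-", ""), library)
        if dist is None:
            continue
        snps, indel = dist
        if snps == 0 and not indel:
            return entry.name, 0, False
        if best is None or (snps, indel, entry.name) < (best[1], best[2], best[0]):
            best = (entry.name, snps, indel)
    if best is None:
        return None, math.inf, False
    return best


# ---------------------------------------------------------------------------
# Nomenclature


def _next_suffix(occupied: set[str]) -> str:
    for code in range(ord("a"), ord("z") + 1):
        if chr(code) not in occupied:
            return chr(code)
    raise ValueError("suffix series exhausted beyond 'z'; catalog redesign needed")


def assign_names(
    groups: list[HaplotypeGroup],
    catalog: HaplotypeCatalog,
    structure: str,
    library: UnitLibrary | None = None,
    max_suffix_snps: int = 2,
) -> tuple[list[HaplotypeAssignment], HaplotypeCatalog]:
    """Name haplotype groups of one structure class against the catalog.

    In deterministic group order: an exact match keeps its name; a group
    within ``max_suffix_snps`` SNPs (no indel difference) of a same-lineage
    entry takes that entry's base name plus the next free lowercase suffix
    (mirroring the published renaming pattern Alg1 -> A74c); anything else
    opens the next integer in the lineage series. Newly named groups are
    appended to the catalog with provenance ``this_run``, so a re-run over
    the same data reports every group as known (idempotence).
    """
    library = library or default_unit_library()
    lineage = assign_lineage(structure)
    assignments: list[HaplotypeAssignment] = []
    for group in groups:
        name, snps, indel = match_catalog(group.representative, catalog, structure, library)
        if name is not None and snps == 0 and not indel:
            novelty = "known"
        elif name is not None and snps <= max_suffix_snps and not indel:
            letter, number, _, _ = parse_haplotype_name(name)
            suffix = _next_suffix(catalog.occupied_suffixes(letter, number))
            name = f"{letter}{number}{suffix}"
            novelty = "renamed_alias"
            catalog.add(
                CatalogEntry(
                    name=name,
                    lineage=lineage,
                    structure=structure,
                    sequence=group.representative,
                    provenance="this_run",
                )
            )
        else:
            name = f"{lineage}{catalog.max_series(lineage) + 1}"
            novelty = "novel"
            catalog.add(
                CatalogEntry(
                    name=name,
                    lineage=lineage,
                    structure=structure,
                    sequence=group.representative,
                    provenance="this_run",
                )
            )
        for sample_id in group.members:
            assignments.append(
                HaplotypeAssignment(
                    sample_id=sample_id,
                    haplotype_name=name,
                    novelty=novelty,
                    distance_to_nearest_known=snps,
                    indel_difference=indel,
                    low_confidence=group.low_confidence,
                )
            )
    return assignments, catalog


# ---------------------------------------------------------------------------
# Summaries


def summarize_structures(
    annotations: list[StructureAnnotation],
    manifest,
    group_col: str = "country",
) -> pd.DataFrame:
    """Per population group, count and percentage of each structure string.

    Percentages are reported at one decimal; per-group percentages sum to
    100 +/- rounding.
    """
    table = manifest.table if hasattr(manifest, "table") else manifest
    meta = table.set_index("sample_id")[group_col]
    rows = []
    for ann in annotations:
        if not ann.resolved:
            continue
        group = meta.get(ann.record_id, "unknown")
        rows.append({"group": group, "structure": ann.structure})
    if not rows:
        return pd.DataFrame(columns=["group", "structure", "count", "percent"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["group", "structure"], sort=True)
        .size()
        .reset_index(name="count")
    )
    totals = out.groupby("group")["count"].transform("sum")
    out["percent"] = (100 * out["count"] / totals).round(1)
    return out.sort_values(["group", "count"], ascending=[True, False]).reset_index(
        drop=True
    )


def summarize_haplotypes(
    assignments: list[HaplotypeAssignment],
    manifest,
    group_col: str = "country",
) -> pd.DataFrame:
    """Per population group: haplotype counts, percentages and the regions /
    subspecies carrying each haplotype, ordered by descending count."""
    table = manifest.table if hasattr(manifest, "table") else manifest
    meta = table.set_index("sample_id")
    rows = []
    for a in assignments:
        info = meta.loc[a.sample_id] if a.sample_id in meta.index else None
        rows.append(
            {
                "group": info[group_col] if info is not None else "unknown",
                "haplotype": a.haplotype_name,
                "novelty": a.novelty,
                "region": info["region"] if info is not None else "",
                "subspecies": info["subspecies"] if info is not None else "",
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["group", "haplotype", "count", "percent", "regions", "subspecies"]
        )
    agg = (
        df.groupby(["group", "haplotype"], sort=True)
        .agg(
            count=("haplotype", "size"),
            novelty=("novelty", "first"),
            regions=("region", lambda s: ";".join(sorted(set(s)))),
            subspecies=("subspecies", lambda s: ";".join(sorted(set(s)))),
        )
        .reset_index()
    )
    totals = agg.groupby("group")["count"].transform("sum")
    agg["percent"] = (100 * agg["count"] / totals).round(1)
    agg = agg.sort_values(
        ["group", "count", "haplotype"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return agg[["group", "haplotype", "count", "percent", "novelty", "regions", "subspecies"]]
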