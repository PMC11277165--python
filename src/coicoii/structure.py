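"""Structural decomposition of the COI-COII intergenic region.

The spacer between the COI gene (carrying the tRNA-leu gene) and COII varies
between honey bee lineages in the presence and identity of a 5' P element
(P, P0 or P1 variants) and the tandem copy number of a ~0.2 kb Q element.
This module tiles an oriented amplicon against a library of reference unit
sequences, derives the structure string (e.g. ``P0QQ``) and calls the
maternal lineage:

* structure starting with P0 or P1  -> African A lineage
* structure starting with plain P   -> West-European M lineage
* structure with no P element (Q..) -> East-European C lineage
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

from Bio import Align

from coicoii.sequence_io import SequenceRecord

__all__ = [
    "UnitLibrary",
    "UnitMatch",
    "StructureAnnotation",
    "StructureResolutionError",
    "load_unit_library",
    "default_unit_library",
    "tile_units",
    "structure_string",
    "assign_lineage",
    "annotate",
]

#: Labels whose matches contribute to the structure string.
STRUCTURE_LABELS = ("P0", "P1", "P", "Q")
#: All unit labels a library may define, flanking stubs included.
ALL_LABELS = ("TRNA_LEU", "P", "P0", "P1", "Q", "COX2_STUB")
#: Regular grammar of well-formed structure strings.
STRUCTURE_GRAMMAR = re.compile(r"^(P0|P1|P)?Q+$")

#: Tolerated unmatched stretch between consecutive unit matches (bp).
MAX_TOLERATED_GAP = 10
#: Extra window length beyond the reference when aligning a unit at the cursor.
_WINDOW_SLACK = 16
#: Identity margin below which the top two P-variant calls are flagged ambiguous.
P_AMBIGUITY_MARGIN = 0.02


class StructureResolutionError(ValueError):
    """Raised when no Q unit can be located anywhere in a sequence."""


@dataclass(frozen=True)
class UnitLibrary:
    """Reference sequences for the structural elements plus the acceptance
    identity threshold used during tiling."""

    units: dict[str, str]
    min_identity: float = 0.75

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        for label, seq in self.units.items():
            if label not in ALL_LABELS:
                raise ValueError(f"unknown unit label {label!r}")
            if not seq:
                raise ValueError(f"unit {label!r} has empty reference")

    def __getitem__(self, label: str) -> str:
        return self.units[label]


@dataclass(frozen=True)
class UnitMatch:
    """One unit occurrence on an amplicon (0-based, half-open coordinates)."""

    label: str
    start: int
    end: int
    identity: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty unit match")


@dataclass(frozen=True)
class StructureAnnotation:
    record_id: str
    matches: tuple[UnitMatch, ...]
    structure: str
    lineage: str
    warnings: tuple[str, ...] = ()

    @property
    def resolved(self) -> bool:
        return self.lineage != "UNRESOLVED"


def load_unit_library(path: str | Path, min_identity: float = 0.75) -> UnitLibrary:
    """Load a unit library from FASTA; record ids are the unit labels."""
    from coicoii.sequence_io import read_fasta

    records = read_fasta(path, source="reference")
    return UnitLibrary(
        units={r.sample_id: r.bases for r in records}, min_identity=min_identity
    )


@lru_cache(maxsize=1)
def default_unit_library() -> UnitLibrary:
    """The packaged unit library: synthetic exemplar sequences for testing
    and closed-loop simulation (see scripts/make_unit_library.py). Real-data
    analyses should load a user-supplied exemplar library instead."""
    ref = resources.files("coicoii").joinpath("data/unit_library.synthetic.fasta")
    with resources.as_file(ref) as path:
        return load_unit_library(path)


def _make_aligner() -> Align.PairwiseAligner:
    """Global aligner with free end gaps on the amplicon (target) side only."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    aligner.open_left_deletion_score = 0
    aligner.extend_left_deletion_score = 0
    aligner.open_right_deletion_score = 0
    aligner.extend_right_deletion_score = 0
    return aligner


_TILING_ALIGNER = _make_aligner()

_LOCAL_ALIGNER = Align.PairwiseAligner()
_LOCAL_ALIGNER.mode = "local"
_LOCAL_ALIGNER.match_score = 1
_LOCAL_ALIGNER.mismatch_score = -1
_LOCAL_ALIGNER.open_gap_score = -4
_LOCAL_ALIGNER.extend_gap_score = -1


def _align_unit(window: str, ref: str) -> tuple[float, int, int]:
    """Semi-globally align ``ref`` into ``window``; return (identity,
    target_start, target_end). Identity is matches / len(ref)."""
    aln = _TILING_ALIGNER.align(window, ref)[0]
    counts = aln.counts()
    identity = counts.identities / len(ref)
    blocks = aln.aligned[0]
    if len(blocks) == 0:
        return 0.0, 0, 0
    return identity, int(blocks[0][0]), int(blocks[-1][1])


def _candidates_at(
    seq: str, cursor: int, library: UnitLibrary
) -> list[tuple[float, str, int, int]]:
    """Score every library unit at the cursor: (identity, label, start, end)."""
    out = []
    for label, ref in library.units.items():
        window = seq[cursor : cursor + len(ref) + _WINDOW_SLACK]
        if len(window) < 0.5 * len(ref):
            continue
        identity, t0, t1 = _align_unit(window, ref)
        if t1 > t0:
            out.append((identity, label, cursor + t0, cursor + t1))
    return out


def _best_candidate(
    cands: list[tuple[float, str, int, int]], library: UnitLibrary
) -> tuple[float, str, int, int] | None:
    if not cands:
        return None
    # Highest identity; ties -> longer reference, then lexicographic label.
    return max(
        cands, key=lambda c: (c[0], len(library.units[c[1]]), _neg_lex(c[1]))
    )


def _neg_lex(label: str) -> tuple[int, ...]:
    """Key that makes lexicographically *smaller* labels win under max()."""
    return tuple(-ord(ch) for ch in label)


def _anchor_search(seq: str, library: UnitLibrary) -> int | None:
    """Earliest start of any unit matching locally at min_identity, for
    records whose 5' end is not itself a unit."""
    best: tuple[int, float] | None = None
    for label, ref in library.units.items():
        aln = _LOCAL_ALIGNER.align(seq, ref)
        if len(aln) == 0:
            continue
        top = aln[0]
        identity = top.counts().identities / len(ref)
        if identity < library.min_identity:
            continue
        start = int(top.aligned[0][0][0])
        if best is None or start < best[0]:
            best = (start, identity)
    return None if best is None else best[0]


def tile_units(seq: str, library: UnitLibrary | None = None) -> tuple[list[UnitMatch], list[str]]:
    """Greedy left-to-right tiling of a sequence into unit matches.

    At each cursor position every library unit is aligned semi-globally (free
    end gaps on the amplicon side); the highest-identity unit at or above
    ``min_identity`` is accepted and the cursor advances to its end. Unmatched
    gaps shorter than 10 bp between units are tolerated and logged; larger
    unmatched stretches before the first Q yield an annotation warning.

    Returns (matches, warnings). Raises :class:`StructureResolutionError`
    when no Q unit is found anywhere.
    """
    library = library or default_unit_library()
    warnings: list[str] = []
    matches: list[UnitMatch] = []
    min_unit = min(len(r) for r in library.units.values())
    cursor = 0
    anchored = False
    while cursor <= len(seq) - max(8, int(0.5 * min_unit)):
        cands = _candidates_at(seq, cursor, library)
        best = _best_candidate(cands, library)
        if best is None or best[0] < library.min_identity:
            if not matches and not anchored:
                anchored = True
                start = _anchor_search(seq, library)
                if start is None or start <= cursor:
                    break
                if start >= MAX_TOLERATED_GAP:
                    warnings.append(f"unmatched-5prime-stretch:{start}bp")
                cursor = start
                continue
            break
        identity, label, start, end = best
        gap = start - cursor
        if gap >= MAX_TOLERATED_GAP:
            before_first_q = not any(m.label == "Q" for m in matches)
            if before_first_q:
                warnings.append(f"unmatched-stretch-before-Q:{gap}bp@{cursor}")
            else:
                warnings.append(f"unmatched-stretch:{gap}bp@{cursor}")
        elif gap > 0:
            warnings.append(f"tolerated-gap:{gap}bp@{cursor}")
        if label in ("P", "P0", "P1"):
            pvar = sorted(
                (c[0] for c in cands if c[1] in ("P", "P0", "P1")), reverse=True
            )
            if len(pvar) >= 2 and pvar[0] - pvar[1] < P_AMBIGUITY_MARGIN:
                warnings.append(f"ambiguous-P:{pvar[0]:.3f}-vs-{pvar[1]:.3f}")
        matches.append(UnitMatch(label=label, start=start, end=end, identity=identity))
        cursor = end
        if label == "COX2_STUB":
            break
    trailing = len(seq) - cursor
    if matches and matches[-1].label != "COX2_STUB" and trailing >= MAX_TOLERATED_GAP:
        warnings.append(f"unmatched-3prime-stretch:{trailing}bp")
    if not any(m.label == "Q" for m in matches):
        raise StructureResolutionError("no Q unit found in sequence")
    return matches, warnings


def structure_string(matches: list[UnitMatch]) -> str:
    """Concatenate the structure-bearing unit labels in positional order."""
    if not matches:
        raise ValueError("empty match list")
    return "".join(m.label for m in matches if m.label in STRUCTURE_LABELS)


def assign_lineage(structure: str) -> str:
    """Call the evolutionary lineage from a structure string.

    P0 or P1 first element -> A (African); plain P -> M (West-European);
    leading Q (no P element) -> C (East-European); anything else UNRESOLVED.
    """
    if not structure:
        raise ValueError("empty structure string")
    if structure.startswith(("P0", "P1")):
        return "A"
    if structure.startswith("P"):
        return "M"
    if structure.startswith("Q"):
        return "C"
    return "UNRESOLVED"


def derive_unit_library(
    examples: dict[str, str], min_identity: float = 0.75
) -> UnitLibrary:
    """Bootstrap a unit library from example sequences with known structures.

    ``examples`` maps a structure string (e.g. ``"P0QQ"``) to one unaligned
    example amplicon of that structure. The Q exemplar is extracted as the
    block inserted between two examples differing by one trailing Q copy; the
    COII stub is the tail after the last Q; the tRNA-leu stub is the aligned
    common head of a P-bearing and a P0-bearing example up to their longest
    internal gap (the P0 deletion), and the P/P0 exemplars are the respective
    remainders. P1 is omitted unless a P1-bearing example is supplied the
    same way. Useful for real data, where unit sequences are conventions of
    the literature rather than printed references.
    """
    aligner = _make_aligner()
    aligner.open_left_deletion_score = -4
    aligner.extend_left_deletion_score = -1
    aligner.open_right_deletion_score = -4
    aligner.extend_right_deletion_score = -1

    def gap_blocks(gapped: str) -> list[tuple[int, int]]:
        blocks, start = [], None
        for i, c in enumerate(gapped):
            if c == "-" and start is None:
                start = i
            elif c != "-" and start is not None:
                blocks.append((start, i))
                start = None
        if start is not None:
            blocks.append((start, len(gapped)))
        return blocks

    def q_count(structure: str) -> int:
        return structure.count("Q")

    def p_part(structure: str) -> str:
        return structure.replace("Q", "")

    # Q exemplar: insertion between two structures differing by one Q.
    q_exemplar = None
    items = sorted(examples.items())
    for (s1, x1), (s2, x2) in [(a, b) for a in items for b in items if a != b]:
        if p_part(s1) == p_part(s2) and q_count(s2) == q_count(s1) + 1:
            aln = aligner.align(x2, x1)[0]
            blocks = gap_blocks(str(aln[1]))
            if not blocks:
                continue
            start, end = max(blocks, key=lambda b: b[1] - b[0])
            tgt = str(aln[0])
            q_exemplar = tgt[start:end].replace("-", "")
            break
    if q_exemplar is None or len(q_exemplar) < 30:
        raise ValueError("need two examples differing by exactly one Q copy")

    local = Align.PairwiseAligner()
    local.mode = "local"
    local.match_score = 1
    local.mismatch_score = -1
    local.open_gap_score = -4
    local.extend_gap_score = -1

    def split_on_q(seq: str) -> tuple[str, str]:
        """(head before first Q, tail after last Q) of an example."""
        starts, ends = [], []
        pos = 0
        probe = seq
        offset = 0
        while True:
            aln = local.align(probe, q_exemplar)
            if len(aln) == 0:
                break
            top = aln[0]
            identity = top.counts().identities / len(q_exemplar)
            if identity < min_identity:
                break
            t0, t1 = int(top.aligned[0][0][0]), int(top.aligned[0][-1][1])
            starts.append(offset + t0)
            ends.append(offset + t1)
            offset += t1
            probe = seq[offset:]
            if len(probe) < 0.5 * len(q_exemplar):
                break
        if not starts:
            raise ValueError("no Q occurrence found in example")
        return seq[: min(starts)], seq[max(ends) :]

    heads: dict[str, str] = {}
    tail = None
    for structure, seq in items:
        head, t = split_on_q(seq)
        heads[p_part(structure)] = head
        if tail is None or len(t) < len(tail):
            tail = t
    if not tail:
        raise ValueError("could not extract a COII stub tail")

    units: dict[str, str] = {"Q": q_exemplar, "COX2_STUB": tail}
    if heads.get(""):
        # A no-P (C-lineage) example: its head before the first Q is the stub.
        units["TRNA_LEU"] = heads[""]
        for v in ("P", "P0", "P1"):
            if v in heads:
                exemplar = heads[v][len(units["TRNA_LEU"]) :]
                if len(exemplar) >= 20:
                    units[v] = exemplar
        return UnitLibrary(units=units, min_identity=min_identity)
    variants = [v for v in ("P", "P0", "P1") if v in heads]
    if len(variants) >= 2:
        a, b = variants[0], variants[1]
        aln = aligner.align(heads[a], heads[b])[0]
        row_a, row_b = str(aln[0]), str(aln[1])
        internal = [blk for r in (row_a, row_b) for blk in gap_blocks(r)]
        if internal:
            boundary_col = min(max(internal, key=lambda x: x[1] - x[0]))
        else:
            diff = [i for i, (x, y) in enumerate(zip(row_a, row_b)) if x != y]
            boundary_col = diff[0] if diff else len(row_a) // 2
        # Keep some shared context upstream of the divergence inside the P
        # exemplars so short post-deletion tails stay alignable.
        boundary_col = max(0, boundary_col - 25)
        trna = row_a[:boundary_col].replace("-", "")
        units["TRNA_LEU"] = trna or heads[a][: len(heads[a]) // 2]
        for v in variants:
            exemplar = heads[v][len(units["TRNA_LEU"]) :] if heads[v].startswith(
                units["TRNA_LEU"]
            ) else None
            if exemplar is None:
                # Head diverges from the chosen stub; strip by alignment length.
                exemplar = heads[v][min(len(units["TRNA_LEU"]), len(heads[v]) - 20) :]
            if len(exemplar) < 20:
                raise ValueError(f"derived {v} exemplar too short to be reliable")
            units[v] = exemplar
    elif len(variants) == 1:
        raise ValueError(
            "need examples of at least two P variants to place the tRNA-leu boundary"
        )
    return UnitLibrary(units=units, min_identity=min_identity)


def annotate(
    record: SequenceRecord, library: UnitLibrary | None = None
) -> StructureAnnotation:
    """Tile a record, derive its structure string and call the lineage.

    Deterministic for fixed inputs. Tiling failures (no Q unit anywhere) are
    converted into an UNRESOLVED annotation rather than raised, so batch
    callers can exclude and report such records.
    """
    library = library or default_unit_library()
    try:
        matches, warnings = tile_units(record.bases, library)
    except StructureResolutionError as exc:
        return StructureAnnotation(
            record_id=record.sample_id,
            matches=(),
            structure="",
            lineage="UNRESOLVED",
            warnings=(str(exc),),
        )
    structure = structure_string(matches)
    if STRUCTURE_GRAMMAR.match(structure):
        lineage = assign_lineage(structure)
    else:
        lineage = "UNRESOLVED"
        warnings = warnings + [f"malformed-structure:{structure}"]
    return StructureAnnotation(
        record_id=record.sample_id,
        matches=tuple(matches),
        structure=structure,
        lineage=lineage,
        warnings=tuple(warnings),
    )
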