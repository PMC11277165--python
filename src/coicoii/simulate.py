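"""Synthetic populations of COI-COII amplicons with known truth.

The generator emits populations whose architecture (P-variant + Q copy
number), haplotype identity and mutation history are fully known, so every
pipeline stage can be tested closed-loop without downloads. Unit reference
sequences are random exemplars of declared lengths — the published literature
prints no unit sequences, so these are stand-ins for testing, clearly
separated from any user-supplied real library (the annotator accepts either).

Defaults: P ~ 67 bp; P0 is the strict 15-bp-deletion derivative of P; P1 is
derived from P by one single-base indel plus seeded substitutions, applied
until all pairwise P-variant identities drop to <= 0.9 so the variants stay
distinguishable at the annotator's margin; Q ~ 196 bp and unrelated to P.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from coicoii.sequence_io import (
    E2_PRIMER,
    H2_PRIMER,
    SampleManifest,
    SequenceRecord,
    reverse_complement,
)
from coicoii.structure import STRUCTURE_GRAMMAR, UnitLibrary

__all__ = [
    "GroupSpec",
    "PopulationSpec",
    "TruthTable",
    "make_unit_library",
    "compose_sequence",
    "mutate_sequence",
    "replay_mutations",
    "generate_population",
    "algeria_like_spec",
]

BASES = "ACGT"

#: Default unit lengths (bp). Approximations chosen for testing; the P/Q
#: length scale follows the field's description of the region (P element a few
#: tens of bp, Q about 0.2 kb).
DEFAULT_UNIT_LENGTHS = {"TRNA_LEU": 65, "P": 67, "Q": 196, "COX2_STUB": 60}

#: Maximum pairwise identity tolerated between P-variant references.
P_VARIANT_MAX_IDENTITY = 0.90

#: Seed of the packaged default unit library (see scripts/make_unit_library.py).
PACKAGED_LIBRARY_SEED = 20240720

_ID_ALIGNER = Align.PairwiseAligner()
_ID_ALIGNER.mode = "global"
_ID_ALIGNER.match_score = 1
_ID_ALIGNER.mismatch_score = -1
_ID_ALIGNER.open_gap_score = -4
_ID_ALIGNER.extend_gap_score = -1


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity, normalized by the longer sequence."""
    aln = _ID_ALIGNER.align(a, b)[0]
    return aln.counts().identities / max(len(a), len(b))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def make_unit_library(
    seed: int,
    unit_lengths: dict[str, int] | None = None,
    min_identity: float = 0.75,
) -> UnitLibrary:
    """Generate a deterministic unit library from a seed.

    The tRNA-leu stub starts with the E2 primer site and the COII stub ends
    with the reverse-complemented H2 site, so composed amplicons carry the
    primer layout the wet assay expects. P0 is P with one 15-bp block
    deleted; P1 is P with one single-base deletion plus substitutions until
    every pairwise P-variant identity is <= 0.9.
    """
    lengths = dict(DEFAULT_UNIT_LENGTHS)
    if unit_lengths:
        lengths.update(unit_lengths)
    if lengths["P"] < 30:
        raise ValueError("P too short to host a 15-bp deletion derivative")
    if lengths["TRNA_LEU"] < len(E2_PRIMER) + 4 or lengths["COX2_STUB"] < len(H2_PRIMER) + 4:
        raise ValueError("flanking stubs too short to carry primer sites")
    rng = np.random.default_rng(seed)
    trna = E2_PRIMER + _random_dna(rng, lengths["TRNA_LEU"] - len(E2_PRIMER))
    cox2 = _random_dna(rng, lengths["COX2_STUB"] - len(H2_PRIMER)) + reverse_complement(
        H2_PRIMER
    )
    p = _random_dna(rng, lengths["P"])
    del_start = int(rng.integers(5, lengths["P"] - 20))
    p0 = p[:del_start] + p[del_start + 15 :]
    # P1: single-base indel derivative, then substitutions to the identity bound.
    indel_pos = int(rng.integers(3, lengths["P"] - 3))
    p1 = p[:indel_pos] + p[indel_pos + 1 :]
    positions = rng.permutation(len(p1))
    i = 0
    while (
        pairwise_identity(p1, p) > P_VARIANT_MAX_IDENTITY
        or pairwise_identity(p1, p0) > P_VARIANT_MAX_IDENTITY
    ):
        if i >= len(positions):
            raise ValueError("units too short to distinguish P variants")
        pos = int(positions[i])
        old = p1[pos]
        new = rng.choice([b for b in BASES if b != old])
        p1 = p1[:pos] + new + p1[pos + 1 :]
        i += 1
    q = _random_dna(rng, lengths["Q"])
    library = UnitLibrary(
        units={"TRNA_LEU": trna, "P": p, "P0": p0, "P1": p1, "Q": q, "COX2_STUB": cox2},
        min_identity=min_identity,
    )
    for x, y in (("P", "P0"), ("P", "P1"), ("P0", "P1")):
        if pairwise_identity(library[x], library[y]) > P_VARIANT_MAX_IDENTITY:
            raise ValueError(f"P variants {x}/{y} not distinguishable")
    return library


def parse_architecture(architecture: str) -> list[str]:
    """Split an architecture string into unit tokens (P0/P1/P/Q)."""
    if not STRUCTURE_GRAMMAR.match(architecture):
        raise ValueError(f"malformed architecture {architecture!r}")
    tokens: list[str] = []
    s = architecture
    while s:
        if s.startswith(("P0", "P1")):
            tokens.append(s[:2])
            s = s[2:]
        else:
            tokens.append(s[0])
            s = s[1:]
    return tokens


def compose_sequence(
    architecture: str, library: UnitLibrary, with_flanks: bool = True
) -> str:
    """Concatenate flanking stubs and the named units into an amplicon.

    Closure property: annotating the output recovers exactly the input
    architecture (at zero noise).
    """
    tokens = parse_architecture(architecture)
    parts = []
    if with_flanks:
        parts.append(library["TRNA_LEU"])
    parts.extend(library[t] for t in tokens)
    if with_flanks:
        parts.append(library["COX2_STUB"])
    return "".join(parts)


def _protected_intervals(seq: str) -> list[tuple[int, int]]:
    """Exact primer-site occurrences, protected from indels."""
    spans = []
    for probe in (E2_PRIMER, reverse_complement(H2_PRIMER)):
        start = seq.find(probe)
        while start != -1:
            spans.append((start, start + len(probe)))
            start = seq.find(probe, start + 1)
    return spans


def _in_protected(pos: int, length: int, spans: list[tuple[int, int]]) -> bool:
    return any(pos < e and pos + length > s for s, e in spans)


def mutate_sequence(
    seq: str,
    substitution_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> tuple[str, list[tuple]]:
    """Apply i.i.d. substitutions and at most one short indel.

    Substitutions hit each base independently at ``substitution_rate`` and
    change it to a uniformly chosen different base. With probability
    ``indel_rate`` one 1-3 bp insertion or deletion is placed outside primer
    sites. The returned log replays exactly: apply substitutions (original
    coordinates) then the indel.
    """
    if not 0 <= substitution_rate <= 1 or not 0 <= indel_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    log: list[tuple] = []
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < substitution_rate)[0]
    for pos in hits:
        pos = int(pos)
        old = chars[pos]
        new = str(rng.choice([b for b in BASES if b != old]))
        chars[pos] = new
        log.append(("sub", pos, old, new))
    mutated = "".join(chars)
    if rng.random() < indel_rate:
        protected = _protected_intervals(seq)
        length = int(rng.integers(1, 4))
        is_insertion = bool(rng.random() < 0.5)
        for _ in range(100):
            pos = int(rng.integers(0, len(mutated) + 1 if is_insertion else len(mutated) - length + 1))
            if not _in_protected(pos, 1 if is_insertion else length, protected):
                break
        else:  # pragma: no cover - tiny sequences only
            return mutated, log
        if is_insertion:
            ins = _random_dna(rng, length)
            mutated = mutated[:pos] + ins + mutated[pos:]
            log.append(("ins", pos, "", ins))
        else:
            removed = mutated[pos : pos + length]
            mutated = mutated[:pos] + mutated[pos + length :]
            log.append(("del", pos, removed, ""))
    return mutated, log


def replay_mutations(founder: str, log: list[tuple]) -> str:
    """Re-apply a mutation log to a founder sequence; exact reproduction."""
    chars = list(founder)
    for kind, pos, old, new in log:
        if kind == "sub":
            if chars[pos] != old:
                raise ValueError(f"replay mismatch at {pos}: {chars[pos]} != {old}")
            chars[pos] = new
    seq = "".join(chars)
    for kind, pos, old, new in log:
        if kind == "ins":
            seq = seq[:pos] + new + seq[pos:]
        elif kind == "del":
            if seq[pos : pos + len(old)] != old:
                raise ValueError("replay deletion mismatch")
            seq = seq[:pos] + seq[pos + len(old) :]
    return seq


@dataclass(frozen=True)
class GroupSpec:
    """One population group: a structure class with a haplotype composition."""

    label: str
    n_records: int
    architecture: str
    n_haplotypes: int
    haplotype_weights: tuple[float, ...] | None = None
    subspecies: str = "intermissa"
    country: str | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        if self.n_records < 1 or self.n_haplotypes < 1:
            raise ValueError("n_records and n_haplotypes must be positive")
        parse_architecture(self.architecture)
        if self.haplotype_weights is not None:
            if len(self.haplotype_weights) != self.n_haplotypes:
                raise ValueError("one weight per haplotype required")
            if abs(sum(self.haplotype_weights) - 1.0) > 1e-9:
                raise ValueError("haplotype weights must sum to 1")
            if any(w < 0 for w in self.haplotype_weights):
                raise ValueError("negative haplotype weight")


@dataclass(frozen=True)
class PopulationSpec:
    groups: tuple[GroupSpec, ...]
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        if not 0 <= self.substitution_rate <= 1 or not 0 <= self.indel_rate <= 1:
            raise ValueError("rates must lie in [0, 1]")


@dataclass
class TruthTable:
    """Ground truth for a generated population.

    ``table`` has one row per record; ``founders`` maps (group index,
    haplotype index) to the founder sequence; ``logs`` maps sample_id to its
    mutation log. Replaying a log on the founder reproduces the record.
    """

    table: pd.DataFrame
    founders: dict[tuple[int, int], str]
    logs: dict[str, list[tuple]]


def _quota_counts(weights: np.ndarray, n: int) -> list[int]:
    """Largest-remainder allocation of n records to weights; deterministic.

    Every positive-weight class receives at least one record whenever the
    class count does not exceed n, so a planted haplotype cannot silently
    vanish from the realized sample.
    """
    raw = weights * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in range(remainder):
        counts[order[i % len(order)]] += 1
    if len(weights) <= n:
        while (counts == 0).any():
            zero = int(np.argmin(counts))
            rich = int(np.argmax(counts))
            counts[zero] += 1
            counts[rich] -= 1
    return counts.tolist()


def generate_population(
    spec: PopulationSpec, library: UnitLibrary | None = None
) -> tuple[list[SequenceRecord], TruthTable, SampleManifest]:
    """Generate a population of amplicon records with full ground truth.

    Founders within a group differ by planted substitutions at disjoint
    positions (pairwise distance >= 3, so downstream 1-2-SNP suffix naming
    cannot merge them); record counts per haplotype follow the group weights
    by largest-remainder quota; noise is applied per record. One seeded
    random stream drives the whole call, consumed in group order, so output
    is byte-identical per seed.
    """
    from coicoii.structure import default_unit_library

    library = library or default_unit_library()
    rng = np.random.default_rng(spec.seed)
    records: list[SequenceRecord] = []
    truth_rows = []
    manifest_rows = []
    founders: dict[tuple[int, int], str] = {}
    logs: dict[str, list[tuple]] = {}
    for g_idx, group in enumerate(spec.groups):
        base = compose_sequence(group.architecture, library, with_flanks=True)
        protected = _protected_intervals(base)
        pool = [
            p
            for p in rng.permutation(len(base)).tolist()
            if not _in_protected(p, 1, protected)
        ]
        if 3 * (group.n_haplotypes - 1) > len(pool):
            raise ValueError("sequence too short to plant distinct founders")
        for h in range(group.n_haplotypes):
            if h == 0:
                founders[(g_idx, h)] = base
                continue
            chars = list(base)
            for pos in pool[3 * (h - 1) : 3 * h]:
                old = chars[pos]
                chars[pos] = str(rng.choice([b for b in BASES if b != old]))
            founders[(g_idx, h)] = "".join(chars)
        weights = (
            np.asarray(group.haplotype_weights)
            if group.haplotype_weights is not None
            else np.full(group.n_haplotypes, 1.0 / group.n_haplotypes)
        )
        counts = _quota_counts(weights, group.n_records)
        hap_indices = [h for h, c in enumerate(counts) for _ in range(c)]
        hap_indices = [hap_indices[i] for i in rng.permutation(len(hap_indices))]
        for r_idx, h in enumerate(hap_indices):
            sample_id = f"{group.label}_g{g_idx}_{r_idx:04d}"
            founder = founders[(g_idx, h)]
            seq, log = mutate_sequence(
                founder, spec.substitution_rate, spec.indel_rate, rng
            )
            records.append(
                SequenceRecord(
                    sample_id=sample_id,
                    bases=seq,
                    region=group.region or group.label,
                    subspecies=group.subspecies,
                    source="synthetic",
                )
            )
            logs[sample_id] = log
            indel_delta = sum(
                len(new) - len(old) for kind, _, old, new in log if kind != "sub"
            )
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "group_index": g_idx,
                    "group_label": group.label,
                    "architecture": group.architecture,
                    "haplotype_index": h,
                    "mutations": json.dumps(log),
                    "primer_fwd_start": 0,
                    "primer_fwd_end": len(E2_PRIMER),
                    "primer_rev_start": len(seq) - len(H2_PRIMER),
                    "primer_rev_end": len(seq),
                }
            )
            manifest_rows.append(
                {
                    "sample_id": sample_id,
                    "region": group.region or group.label,
                    "subspecies": group.subspecies,
                    "country": group.country or group.label,
                }
            )
    truth = TruthTable(
        table=pd.DataFrame(truth_rows), founders=founders, logs=logs
    )
    manifest = SampleManifest(pd.DataFrame(manifest_rows))
    return records, truth, manifest


def algeria_like_spec(
    seed: int = 0, substitution_rate: float = 0.0, indel_rate: float = 0.0
) -> PopulationSpec:
    """A 68-record population shaped like the Algerian study sample.

    Structure split 24 P0Q / 42 P0QQ / 2 P0QQQ (35.3 / 61.8 / 2.9 %) with 24
    planted haplotypes in total; the most common haplotype covers 16 of 68
    records (23.5 %).
    """

    def weights(counts: list[int]) -> tuple[float, ...]:
        total = sum(counts)
        return tuple(c / total for c in counts)

    return PopulationSpec(
        groups=(
            GroupSpec(
                label="Algeria",
                n_records=24,
                architecture="P0Q",
                n_haplotypes=8,
                haplotype_weights=weights([7, 5, 4, 4, 1, 1, 1, 1]),
                country="Algeria",
                region="Algeria-P0Q",
            ),
            GroupSpec(
                label="Algeria",
                n_records=42,
                architecture="P0QQ",
                n_haplotypes=14,
                haplotype_weights=weights([16, 5, 4, 3, 2, 2, 2, 2, 1, 1, 1, 1, 1, 1]),
                country="Algeria",
                region="Algeria-P0QQ",
            ),
            GroupSpec(
                label="Algeria",
                n_records=2,
                architecture="P0QQQ",
                n_haplotypes=2,
                country="Algeria",
                region="Algeria-P0QQQ",
            ),
        ),
        substitution_rate=substitution_rate,
        indel_rate=indel_rate,
        seed=seed,
    )
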