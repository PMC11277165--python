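"""In-silico DraI PCR-RFLP: amplicon location and restriction digestion.

The DraI test types honey bee mitotypes by digesting the E2/H2 PCR product
with DraI (recognition TTTAAA, blunt cut after the third base). This module
reproduces the digestion computationally on a linear amplicon: every
occurrence of the recognition string on the top strand is found by a step-1
sliding window (TTTAAA is its own reverse complement, so a top-strand scan is
complete), cut coordinates deduplicated, and fragments reported 5'->3'.
"""

from __future__ import annotations

from dataclasses import dataclass

from coicoii.sequence_io import PrimerPair, SequenceRecord, reverse_complement

__all__ = [
    "RestrictionEnzymeSpec",
    "RestrictionProfile",
    "InvertedPrimerError",
    "DRA_I",
    "find_amplicon",
    "digest",
    "drai_profile",
]


class InvertedPrimerError(ValueError):
    """Raised when the primers are found in inverted order on a sequence."""


@dataclass(frozen=True)
class RestrictionEnzymeSpec:
    """A restriction enzyme: recognition string and top-strand cut offset."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError("empty recognition sequence")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset outside recognition site")


DRA_I = RestrictionEnzymeSpec(name="DraI", recognition="TTTAAA", cut_offset=3)


@dataclass(frozen=True)
class RestrictionProfile:
    record_id: str
    amplicon_span: tuple[int, int]
    site_positions: tuple[int, ...]
    fragment_lengths: tuple[int, ...]
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        length = self.amplicon_span[1] - self.amplicon_span[0]
        if sum(self.fragment_lengths) != length:
            raise AssertionError("fragment lengths do not sum to amplicon length")
        if len(self.fragment_lengths) != len(self.site_positions) + 1:
            raise AssertionError("fragment/cut count mismatch")
        if any(f <= 0 for f in self.fragment_lengths):
            raise AssertionError("empty fragment")

    @property
    def gel_view(self) -> tuple[int, ...]:
        """Fragment lengths sorted descending, mimicking gel band order."""
        return tuple(sorted(self.fragment_lengths, reverse=True))


def find_amplicon(
    seq: str, primers: PrimerPair | None = None, max_mismatch: int = 2
) -> tuple[int, int, tuple[str, ...]]:
    """Locate the E2..H2' amplicon span on an oriented sequence.

    Returns ``(start, end, warnings)`` — the half-open span from the start of
    the forward-primer match to the end of the reverse-complemented
    reverse-primer match. A bare amplicon without primer sites yields the full
    span with a ``primers-not-found`` warning; primers in inverted order raise
    :class:`InvertedPrimerError`.
    """
    from coicoii.sequence_io import _primer_hits

    primers = primers or PrimerPair()
    fwd = _primer_hits(seq, primers.forward, max_mismatch)
    rev = _primer_hits(seq, reverse_complement(primers.reverse), max_mismatch)
    if not fwd and not rev:
        return 0, len(seq), ("primers-not-found, full-length assumed",)
    if fwd and not rev:
        return fwd[0], len(seq), ("reverse-primer-not-found",)
    if rev and not fwd:
        return 0, rev[-1] + len(primers.reverse), ("forward-primer-not-found",)
    start = fwd[0]
    rend_candidates = [r for r in rev if r >= start + len(primers.forward)]
    if not rend_candidates:
        raise InvertedPrimerError(
            "forward primer found downstream of the reverse primer site"
        )
    end = rend_candidates[-1] + len(primers.reverse)
    return start, end, ()


def digest(
    seq: str, enzyme: RestrictionEnzymeSpec = DRA_I, record_id: str = ""
) -> RestrictionProfile:
    """Digest a linear amplicon, returning cut positions and fragment lengths.

    All recognition-site occurrences count, overlapping ones included; cuts at
    identical coordinates are deduplicated. N never matches the recognition
    site. Zero sites is valid (single full-length fragment).
    """
    site = enzyme.recognition
    k = len(site)
    cuts = sorted(
        {
            i + enzyme.cut_offset
            for i in range(len(seq) - k + 1)
            if seq[i : i + k] == site
        }
    )
    # A cut at coordinate 0 or len(seq) produces no new fragment boundary.
    cuts = [c for c in cuts if 0 < c < len(seq)]
    bounds = [0] + cuts + [len(seq)]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return RestrictionProfile(
        record_id=record_id,
        amplicon_span=(0, len(seq)),
        site_positions=tuple(cuts),
        fragment_lengths=fragments,
    )


def drai_profile(
    record: SequenceRecord,
    primers: PrimerPair | None = None,
    enzyme: RestrictionEnzymeSpec = DRA_I,
    max_mismatch: int = 2,
) -> RestrictionProfile:
    """Locate the amplicon in a record and digest it. Deterministic."""
    start, end, warnings = find_amplicon(record.bases, primers, max_mismatch)
    profile = digest(record.bases[start:end], enzyme, record_id=record.sample_id)
    return RestrictionProfile(
        record_id=record.sample_id,
        amplicon_span=(start, end),
        site_positions=profile.site_positions,
        fragment_lengths=profile.fragment_lengths,
        warnings=warnings,
    )
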