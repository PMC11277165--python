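"""Unit-anchored alignment, haplotype collapse, catalog matching, nomenclature."""

import math

import pandas as pd
import pytest

from coicoii.haplotypes import (
    CatalogEntry,
    HaplotypeCatalog,
    align_within_class,
    assign_names,
    collapse_haplotypes,
    match_catalog,
    parse_haplotype_name,
    summarize_haplotypes,
    summarize_structures,
    UnitAnchoredAlignment,
)
from coicoii.sequence_io import SequenceRecord
from coicoii.structure import annotate
from coicoii.simulate import (
    GroupSpec,
    PopulationSpec,
    compose_sequence,
    generate_population,
)


def _records(library, arch, seqs):
    recs = [
        SequenceRecord(sample_id=f"s{i}", bases=s, source="synthetic")
        for i, s in enumerate(seqs)
    ]
    anns = [annotate(r, library) for r in recs]
    assert all(a.structure == arch for a in anns)
    return recs, anns


def _substitute(seq: str, pos: int, base: str) -> str:
    assert seq[pos] != base
    return seq[:pos] + base + seq[pos + 1 :]


class TestAlignment:
    def test_identical_records_align_without_gaps(self, library):
        seq = compose_sequence("P0Q", library)
        recs, anns = _records(library, "P0Q", [seq] * 3)
        aln = align_within_class(recs, anns, library)
        assert all(row == recs[0].bases for row in aln.rows.values())
        assert "-" not in next(iter(aln.rows.values()))

    def test_rows_reproduce_their_sequences(self, library):
        seq = compose_sequence("P0QQ", library)
        variant = _substitute(seq, 200, "A" if seq[200] != "A" else "C")
        recs, anns = _records(library, "P0QQ", [seq, variant])
        aln = align_within_class(recs, anns, library)
        for rec in recs:
            assert aln.rows[rec.sample_id].replace("-", "") == rec.bases

    def test_two_bp_deletion_shows_one_gap_block(self, library):
        seq = compose_sequence("P0Q", library)
        # delete 2 bp inside the Q unit
        pos = len(seq) - 120
        deleted = seq[:pos] + seq[pos + 2 :]
        recs, anns = _records(library, "P0Q", [seq, deleted])
        aln = align_within_class(recs, anns, library)
        gapped = aln.rows["s1"]
        assert gapped.count("-") == 2
        assert "--" in gapped and "---" not in gapped

    def test_mixed_structure_classes_rejected(self, library):
        a = SequenceRecord(sample_id="a", bases=compose_sequence("P0Q", library))
        b = SequenceRecord(sample_id="b", bases=compose_sequence("P0QQ", library))
        with pytest.raises(ValueError, match="mixed structure"):
            align_within_class([a, b], None, library)


class TestCollapse:
    def test_identical_rows_form_one_group(self, library):
        seq = compose_sequence("PQ", library)
        recs, anns = _records(library, "PQ", [seq] * 5)
        groups = collapse_haplotypes(align_within_class(recs, anns, library))
        assert len(groups) == 1 and groups[0].size == 5

    def test_single_snp_separates_groups(self, library):
        seq = compose_sequence("PQ", library)
        variant = _substitute(seq, 150, "A" if seq[150] != "A" else "C")
        recs, anns = _records(library, "PQ", [seq, variant])
        groups = collapse_haplotypes(align_within_class(recs, anns, library))
        assert len(groups) == 2

    @pytest.mark.parametrize("seed, k, n", [(1, 1, 10), (2, 7, 60), (3, 24, 68), (4, 30, 200)])
    def test_group_count_equals_planted_haplotype_count(self, library, seed, k, n):
        spec = PopulationSpec(
            groups=(
                GroupSpec(label="g", n_records=n, architecture="P0QQ", n_haplotypes=k),
            ),
            seed=seed,
        )
        records, truth, _ = generate_population(spec, library)
        anns = [annotate(r, library) for r in records]
        groups = collapse_haplotypes(align_within_class(records, anns, library))
        n_planted = len({truth.founders[key] for key in truth.founders})
        assert len(groups) == n_planted == k
        assert sum(g.size for g in groups) == n

    def test_n_bearing_rows_flagged_and_never_merged_unless_identical(self):
        aln = UnitAnchoredAlignment(
            structure_class="Q",
            rows={"a": "ACGT", "b": "ACNT", "c": "ACNT", "d": "ACGT"},
            column_provenance=(("Q", "0"), ("Q", "1"), ("Q", "2"), ("Q", "3")),
        )
        groups = collapse_haplotypes(aln)
        assert len(groups) == 2
        n_group = next(g for g in groups if "N" in g.representative)
        assert n_group.low_confidence
        assert set(n_group.members) == {"b", "c"}


class TestCatalogMatching:
    def _catalog(self, library, base_seq):
        return HaplotypeCatalog(
            entries=[
                CatalogEntry(
                    name="A74", lineage="A", structure="P0QQ", sequence=base_seq
                )
            ]
        )

    def test_exact_match_returns_name_and_zero_distance(self, library):
        seq = compose_sequence("P0QQ", library)
        cat = self._catalog(library, seq)
        assert match_catalog(seq, cat, "P0QQ", library) == ("A74", 0, False)

    def test_one_snp_variant_reports_distance_one(self, library):
        seq = compose_sequence("P0QQ", library)
        cat = self._catalog(library, seq)
        variant = _substitute(seq, 300, "A" if seq[300] != "A" else "C")
        name, dist, indel = match_catalog(variant, cat, "P0QQ", library)
        assert (name, dist, indel) == ("A74", 1, False)

    def test_empty_catalog_class_returns_none_and_inf(self, library):
        seq = compose_sequence("P0QQ", library)
        name, dist, indel = match_catalog(seq, HaplotypeCatalog(), "P0QQ", library)
        assert name is None and math.isinf(dist) and indel is False


class TestNomenclature:
    @pytest.mark.parametrize(
        "name, parsed",
        [
            ("A74", ("A", 74, "", "")),
            ("A74c", ("A", 74, "c", "")),
            ("C2_d", ("C", 2, "d", "")),
            ("A77′", ("A", 77, "", "′")),
            ("M4r", ("M", 4, "r", "")),
            ("A1x", ("A", 1, "x", "")),
        ],
    )
    def test_name_grammar_parses_published_forms(self, name, parsed):
        assert parse_haplotype_name(name) == parsed

    @pytest.mark.parametrize("bad", ["74A", "A", "a74", "A74C", "A74-1"])
    def test_malformed_names_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_haplotype_name(bad)

    def _groups_and_catalog(self, library, snps_away, occupied_suffixes=("a", "b")):
        from coicoii.haplotypes import HaplotypeGroup

        base = compose_sequence("P0QQ", library)
        entries = [CatalogEntry(name="A74", lineage="A", structure="P0QQ", sequence=base)]
        suffix_seed = 30
        for i, suf in enumerate(occupied_suffixes):
            s = _substitute(base, suffix_seed + i, "A" if base[suffix_seed + i] != "A" else "C")
            entries.append(
                CatalogEntry(name=f"A74{suf}", lineage="A", structure="P0QQ", sequence=s)
            )
        entries.append(
            CatalogEntry(
                name="A76",
                lineage="A",
                structure="P0QQ",
                sequence=_substitute(base, 400, "A" if base[400] != "A" else "C"),
            )
        )
        rep = base
        for k in range(snps_away):
            pos = 200 + 7 * k
            rep = _substitute(rep, pos, "A" if rep[pos] != "A" else "C")
        group = HaplotypeGroup(members=("x1",), representative=rep)
        return [group], HaplotypeCatalog(entries=entries)

    def test_exact_match_keeps_existing_name(self, library):
        groups, cat = self._groups_and_catalog(library, snps_away=0)
        assignments, _ = assign_names(groups, cat, "P0QQ", library)
        assert assignments[0].haplotype_name == "A74"
        assert assignments[0].novelty == "known"

    def test_one_snp_variant_gets_next_free_suffix(self, library):
        """The published renaming pattern: a 1-2 SNP satellite of A74 with
        suffixes a and b occupied becomes A74c."""
        groups, cat = self._groups_and_catalog(library, snps_away=1)
        assignments, cat = assign_names(groups, cat, "P0QQ", library)
        assert assignments[0].haplotype_name == "A74c"
        assert assignments[0].novelty == "renamed_alias"

    def test_distant_variant_opens_next_series_number(self, library):
        groups, cat = self._groups_and_catalog(library, snps_away=5)
        assignments, _ = assign_names(groups, cat, "P0QQ", library)
        assert assignments[0].haplotype_name == "A77"
        assert assignments[0].novelty == "novel"

    def test_naming_is_idempotent_on_rerun(self, library):
        spec = PopulationSpec(
            groups=(
                GroupSpec(label="g", n_records=30, architecture="P0QQ", n_haplotypes=6),
            ),
            seed=9,
        )
        records, _, _ = generate_population(spec, library)
        anns = [annotate(r, library) for r in records]
        aln = align_within_class(records, anns, library)
        groups = collapse_haplotypes(aln)
        cat = HaplotypeCatalog()
        first, cat = assign_names(groups, cat, "P0QQ", library)
        second, _ = assign_names(groups, cat, "P0QQ", library)
        assert [a.haplotype_name for a in second] == [a.haplotype_name for a in first]
        assert all(a.novelty == "known" for a in second)

    def test_emitted_names_follow_grammar_without_collisions(self, library):
        spec = PopulationSpec(
            groups=(
                GroupSpec(label="g", n_records=40, architecture="PQ", n_haplotypes=8),
            ),
            seed=11,
        )
        records, _, _ = generate_population(spec, library)
        anns = [annotate(r, library) for r in records]
        groups = collapse_haplotypes(align_within_class(records, anns, library))
        assignments, cat = assign_names(groups, HaplotypeCatalog(), "PQ", library)
        names = {a.haplotype_name for a in assignments}
        for name in names:
            letter, _, _, prime = parse_haplotype_name(name)
            assert letter == "M" and prime == ""
        new_entries = [e for e in cat.entries if e.provenance == "this_run"]
        assert len(new_entries) == len(groups)
        # every record named exactly once
        assert len(assignments) == 40


class TestPublishedCatalog:
    def test_packaged_catalog_names_and_series(self):
        cat = HaplotypeCatalog.load_published()
        assert len(cat.entries) == 17
        assert cat.max_series("A") == 77
        assert cat.occupied_suffixes("A", 74) == {"a", "b"}
        structures = [e.structure for e in cat.entries]
        assert structures.count("P0QQ") == 13
        assert structures.count("P0Q") == 2
        assert structures.count("P0QQQ") == 1
        assert structures.count("PQQ") == 1


class TestSummaries:
    def _manifest(self, ids, region="r1", subspecies="intermissa", country="Algeria"):
        import pandas as pd
        from coicoii.sequence_io import SampleManifest

        return SampleManifest(
            pd.DataFrame(
                {
                    "sample_id": ids,
                    "region": region,
                    "subspecies": subspecies,
                    "country": country,
                }
            )
        )

    def test_structure_percentages_on_68_record_composition(self, library):
        from coicoii.structure import StructureAnnotation

        anns = []
        for structure, count in (("P0Q", 24), ("P0QQ", 42), ("P0QQQ", 2)):
            for i in range(count):
                anns.append(
                    StructureAnnotation(
                        record_id=f"{structure}_{i}",
                        matches=(),
                        structure=structure,
                        lineage="A",
                    )
                )
        manifest = self._manifest([a.record_id for a in anns])
        table = summarize_structures(anns, manifest)
        pct = dict(zip(table["structure"], table["percent"]))
        assert pct == {"P0Q": 35.3, "P0QQ": 61.8, "P0QQQ": 2.9}
        assert abs(table["percent"].sum() - 100) <= 0.2

    def test_single_structure_group_is_100_percent(self, library):
        from coicoii.structure import StructureAnnotation

        anns = [
            StructureAnnotation(record_id=f"s{i}", matches=(), structure="Q", lineage="C")
            for i in range(5)
        ]
        table = summarize_structures(anns, self._manifest([a.record_id for a in anns]))
        assert table["percent"].tolist() == [100.0]

    def test_haplotype_summary_lists_both_subspecies(self):
        from coicoii.haplotypes import HaplotypeAssignment
        from coicoii.sequence_io import SampleManifest

        assignments = [
            HaplotypeAssignment("s1", "A74", "known", 0, False),
            HaplotypeAssignment("s2", "A74", "known", 0, False),
        ]
        manifest = SampleManifest(
            pd.DataFrame(
                {
                    "sample_id": ["s1", "s2"],
                    "region": ["north", "south"],
                    "subspecies": ["intermissa", "sahariensis"],
                    "country": ["Algeria", "Algeria"],
                }
            )
        )
        table = summarize_haplotypes(assignments, manifest)
        assert table.loc[0, "subspecies"] == "intermissa;sahariensis"
        assert table.loc[0, "percent"] == 100.0

    def test_all_distinct_haplotypes_split_percentages_evenly(self):
        from coicoii.haplotypes import HaplotypeAssignment

        assignments = [
            HaplotypeAssignment(f"s{i}", f"A{i + 1}", "novel", math.inf, False)
            for i in range(4)
        ]
        manifest = self._manifest([f"s{i}" for i in range(4)])
        table = summarize_haplotypes(assignments, manifest)
        assert table["percent"].tolist() == [25.0] * 4
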