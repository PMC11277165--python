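"""End-to-end orchestration: orient -> QC -> annotate -> RFLP ->
align/collapse/name -> recode/network -> summaries.

Every threshold lives in the config and the resolved config is embedded in
the run report, so the curation decisions that a manual analysis makes
silently (quality cuts, identity thresholds, naming margins) are auditable
in every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from coicoii.sequence_io import (
    PrimerPair,
    SampleManifest,
    orient_record,
    qc_filter,
    read_fasta,
)
from coicoii.structure import (
    StructureAnnotation,
    UnitLibrary,
    annotate,
    default_unit_library,
    load_unit_library,
)
from coicoii.rflp import DRA_I, RestrictionEnzymeSpec, drai_profile
from coicoii.haplotypes import (
    HaplotypeCatalog,
    align_within_class,
    assign_names,
    collapse_haplotypes,
    summarize_haplotypes,
    summarize_structures,
)
from coicoii.network import build_networks, export_network, recode_alignment

__all__ = ["PipelineConfig", "RunReport", "run"]

logger = logging.getLogger("coicoii")


@dataclass
class PipelineConfig:
    input_fasta: str
    manifest: str | None = None
    unit_library: str | None = None
    catalog: str | None = None
    outdir: str = "coicoii_out"
    min_length: int = 300
    max_n_fraction: float = 0.02
    primer_forward: str = PrimerPair().forward
    primer_reverse: str = PrimerPair().reverse
    primer_max_mismatch: int = 2
    enzyme_name: str = DRA_I.name
    enzyme_recognition: str = DRA_I.recognition
    enzyme_cut_offset: int = DRA_I.cut_offset
    max_suffix_snps: int = 2
    epsilon: int = 0
    group_col: str = "country"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def primers(self) -> PrimerPair:
        return PrimerPair(forward=self.primer_forward, reverse=self.primer_reverse)

    def enzyme(self) -> RestrictionEnzymeSpec:
        return RestrictionEnzymeSpec(
            name=self.enzyme_name,
            recognition=self.enzyme_recognition,
            cut_offset=self.enzyme_cut_offset,
        )

    def resolve_library(self) -> UnitLibrary:
        if self.unit_library:
            return load_unit_library(self.unit_library)
        return default_unit_library()

    def resolve_catalog(self) -> HaplotypeCatalog:
        if self.catalog:
            return HaplotypeCatalog.from_fasta(self.catalog)
        return HaplotypeCatalog.load_published()

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage accounting of a pipeline run.

    Counts are monotonically non-increasing through the filtering stages
    (read >= oriented >= qc_passed >= structure_resolved = haplotyped).
    """

    counts: dict[str, int]
    warnings: list[str]
    tables: dict[str, str]
    config: dict
    config_hash: str

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "counts": self.counts,
                    "warnings": self.warnings,
                    "tables": self.tables,
                    "config": self.config,
                    "config_hash": self.config_hash,
                },
                fh,
                indent=2,
                default=str,
            )


def run(config: PipelineConfig) -> RunReport:
    """Execute the full pipeline; deterministic for fixed config and inputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    library = config.resolve_library()
    catalog = config.resolve_catalog()
    primers = config.primers()
    enzyme = config.enzyme()
    warnings: list[str] = []
    tables: dict[str, str] = {}

    records = read_fasta(config.input_fasta)
    n_read = len(records)
    if config.manifest:
        manifest = SampleManifest.read_csv(config.manifest)
        missing = manifest.unresolved_ids(records)
        if missing:
            warnings.append(f"records missing from manifest: {missing}")
    else:
        manifest = SampleManifest(
            pd.DataFrame(
                {
                    "sample_id": [r.sample_id for r in records],
                    "region": "unknown",
                    "subspecies": "unknown",
                    "country": "unknown",
                }
            )
        )

    oriented = []
    for rec in records:
        out = orient_record(rec, primers, config.primer_max_mismatch)
        if "orientation-failed" in out.flags:
            warnings.append(f"orientation failed: {rec.sample_id}")
        oriented.append(out)
    n_oriented = sum(1 for r in oriented if r.oriented)

    retained, qc_report = qc_filter(
        oriented, config.min_length, config.max_n_fraction
    )
    qc_path = outdir / "qc_report.csv"
    qc_report.to_csv(qc_path, index=False)
    tables["qc_report"] = str(qc_path)

    annotations = [annotate(r, library) for r in retained]
    resolved = [a for a in annotations if a.resolved]
    for a in annotations:
        if not a.resolved:
            warnings.append(f"structure unresolved: {a.record_id}")
        for w in a.warnings:
            if w.startswith("ambiguous-P"):
                warnings.append(f"{a.record_id}: {w}")
    ann_path = outdir / "annotations.csv"
    pd.DataFrame(
        {
            "sample_id": [a.record_id for a in annotations],
            "structure": [a.structure for a in annotations],
            "lineage": [a.lineage for a in annotations],
            "warnings": [";".join(a.warnings) for a in annotations],
        }
    ).to_csv(ann_path, index=False)
    tables["annotations"] = str(ann_path)
    iv_rows = [
        {
            "sample_id": a.record_id,
            "start": m.start,
            "end": m.end,
            "label": m.label,
            "identity": round(m.identity, 4),
        }
        for a in annotations
        for m in a.matches
    ]
    iv_path = outdir / "unit_intervals.csv"
    pd.DataFrame(iv_rows).to_csv(iv_path, index=False)
    tables["unit_intervals"] = str(iv_path)

    profiles = [
        drai_profile(r, primers, enzyme, config.primer_max_mismatch)
        for r in retained
    ]
    rflp_path = outdir / "rflp_profiles.csv"
    pd.DataFrame(
        {
            "sample_id": [p.record_id for p in profiles],
            "n_sites": [len(p.site_positions) for p in profiles],
            "fragment_lengths": [
                "/".join(map(str, p.fragment_lengths)) for p in profiles
            ],
        }
    ).to_csv(rflp_path, index=False)
    tables["rflp_profiles"] = str(rflp_path)

    resolved_ids = {a.record_id for a in resolved}
    by_structure: dict[str, list] = {}
    ann_by_id = {a.record_id: a for a in resolved}
    for rec in retained:
        if rec.sample_id in resolved_ids:
            by_structure.setdefault(ann_by_id[rec.sample_id].structure, []).append(rec)

    all_assignments = []
    alignments = {}
    frequencies: dict[str, dict[str, int]] = {}
    populations: dict[str, dict[str, str]] = {}
    meta = manifest.table.set_index("sample_id")
    for structure in sorted(by_structure):
        recs = by_structure[structure]
        aln = align_within_class(
            recs, [ann_by_id[r.sample_id] for r in recs], library
        )
        groups = collapse_haplotypes(aln)
        for g in groups:
            if g.low_confidence:
                warnings.append(
                    f"low-confidence haplotype group (N-bearing): {g.members}"
                )
        assignments, catalog = assign_names(
            groups, catalog, structure, library, config.max_suffix_snps
        )
        all_assignments.extend(assignments)
        name_of = {a.sample_id: a.haplotype_name for a in assignments}
        hap_rows: dict[str, str] = {}
        freq: dict[str, int] = {}
        pops: dict[str, set] = {}
        for g in groups:
            name = name_of[g.members[0]]
            hap_rows[name] = g.representative
            freq[name] = g.size
            pops[name] = {
                str(meta.loc[m, config.group_col]) if m in meta.index else "unknown"
                for m in g.members
            }
        alignments[structure] = type(aln)(
            structure_class=structure,
            rows=hap_rows,
            column_provenance=aln.column_provenance,
        )
        frequencies[structure] = freq
        populations[structure] = {k: ";".join(sorted(v)) for k, v in pops.items()}

    assign_path = outdir / "assignments.csv"
    pd.DataFrame([asdict(a) for a in all_assignments]).to_csv(
        assign_path, index=False
    )
    tables["assignments"] = str(assign_path)

    struct_summary = summarize_structures(resolved, manifest, config.group_col)
    ss_path = outdir / "structure_summary.csv"
    struct_summary.to_csv(ss_path, index=False)
    tables["structure_summary"] = str(ss_path)
    hap_summary = summarize_haplotypes(all_assignments, manifest, config.group_col)
    hs_path = outdir / "haplotype_summary.csv"
    hap_summary.to_csv(hs_path, index=False)
    tables["haplotype_summary"] = str(hs_path)

    networks_dir = outdir / "networks"
    networks_dir.mkdir(exist_ok=True)
    networks = build_networks(
        alignments, config.epsilon, frequencies, populations
    )
    for cls, net in networks.items():
        export_network(net, networks_dir / f"{cls}.graphml", "graphml")
        export_network(net, networks_dir / f"{cls}.nex", "nexus")
        tables[f"network_{cls}"] = str(networks_dir / f"{cls}.graphml")

    report = RunReport(
        counts={
            "read": n_read,
            "oriented": n_oriented,
            "qc_passed": len(retained),
            "structure_resolved": len(resolved),
            "haplotyped": len(all_assignments),
            "haplotypes": len({a.haplotype_name for a in all_assignments}),
        },
        warnings=warnings,
        tables=tables,
        config=asdict(config),
        config_hash=config.config_hash(),
    )
    report.to_json(outdir / "report.json")
    return report
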