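"""Pipeline orchestration and cohort summaries.

``run_pipeline`` composes the full typing chain per strain — locus
detection, split-locus joining, role inference, positional disambiguation,
rhamnan/PSP partitioning, genotype assignment (minting novel labels in
input order), eps pathway classing, mobility scanning and structure-feature
prediction — and aggregates a strain table plus cohort statistics.
``summarize_fixture`` computes the same statistics directly from the
packaged in-study strain table, bypassing the sequence stages.

All cluster lengths use the end - start convention; a split locus reports
the sum of its fragment lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import pandas as pd
import yaml

from .context_scanner import ContextParams, SplitParams, detect_split_locus, scan_context
from .genome_io import Genome, StrainRecord
from .genotyper import (GenotypeDB, assign_cwps_genotype, assign_eps_genotype,
                        default_cwps_db)
from .glycan import predict_structure_features
from .locus_finder import FinderParams, find_locus, qc_locus
from .role_inference import RefProtein, assign_roles
from .similarity import AlignParams

logger = logging.getLogger("pellicle")


@dataclass
class PipelineConfig:
    align: AlignParams = field(default_factory=lambda: AlignParams(prescreen_min_shared=0.05))
    finder: FinderParams = field(default_factory=FinderParams)
    context: ContextParams = field(default_factory=ContextParams)
    split: SplitParams = field(default_factory=SplitParams)
    role_sim_threshold: float = 40.0
    cwps_sim_threshold: float = 30.0   # criterion iii: < 30% amino-acid similarity
    eps_match_threshold: float = 80.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        if "align" in raw:
            cfg.align = AlignParams(**raw["align"])
        if "finder" in raw:
            cfg.finder = FinderParams(**raw["finder"])
        if "context" in raw:
            cfg.context = ContextParams(**raw["context"])
        if "split" in raw:
            cfg.split = SplitParams(**raw["split"])
        for key in ("role_sim_threshold", "cwps_sim_threshold", "eps_match_threshold"):
            if key in raw:
                setattr(cfg, key, float(raw[key]))
        return cfg

    def to_yaml(self, path) -> None:
        raw = {
            "align": asdict(self.align),
            "finder": {k: v for k, v in asdict(self.finder).items() if k != "align"},
            "context": asdict(self.context),
            "split": asdict(self.split),
            "role_sim_threshold": self.role_sim_threshold,
            "cwps_sim_threshold": self.cwps_sim_threshold,
            "eps_match_threshold": self.eps_match_threshold,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class CohortSummary:
    n_strains: int
    n_with_cwps: int
    n_with_eps: int
    distinct_cwps_labels: list[str]
    distinct_eps_labels: list[str]
    per_species_label_sets: dict[str, set[str]]
    shared_labels: list[str]
    exclusive_labels: dict[str, list[str]]
    cwps_length_min: Optional[int]
    cwps_length_max: Optional[int]
    rows: list[dict]

    @property
    def n_distinct_cwps(self) -> int:
        return len(self.distinct_cwps_labels)

    @property
    def n_distinct_eps(self) -> int:
        return len(self.distinct_eps_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def label_count(self, species: str, label: str) -> int:
        return sum(1 for r in self.rows
                   if r["species"] == species and r["cwps_label"] == label)


def _aggregate(rows: list[dict]) -> CohortSummary:
    cw_labels = sorted({r["cwps_label"] for r in rows if r["cwps_label"]})
    eps_labels = sorted({r["eps_label"] for r in rows if r["eps_label"]})
    per_species: dict[str, set[str]] = {}
    for r in rows:
        if r["cwps_label"]:
            per_species.setdefault(r["species"], set()).add(r["cwps_label"])
    shared = sorted(
        l for l in cw_labels
        if sum(1 for s in per_species.values() if l in s) >= 2
    )
    exclusive = {
        sp: sorted(l for l in labels
                   if sum(1 for s in per_species.values() if l in s) == 1)
        for sp, labels in per_species.items()
    }
    lengths = [r["cwps_length"] for r in rows if r["cwps_length"]]
    return CohortSummary(
        n_strains=len(rows),
        n_with_cwps=sum(1 for r in rows if r["cwps_label"]),
        n_with_eps=sum(1 for r in rows if r["eps_label"]),
        distinct_cwps_labels=cw_labels,
        distinct_eps_labels=eps_labels,
        per_species_label_sets=per_species,
        shared_labels=shared,
        exclusive_labels=exclusive,
        cwps_length_min=min(lengths) if lengths else None,
        cwps_length_max=max(lengths) if lengths else None,
        rows=rows,
    )


def type_genome(genome: Genome, config: PipelineConfig, refdb: list[RefProtein],
                cwps_db: GenotypeDB, eps_db: GenotypeDB) -> dict:
    """Run every typing stage on one genome; returns a strain-table row."""
    row = {
        "species": genome.species, "strain": genome.id,
        "cwps_label": None, "cwps_novel": None, "cwps_fragments": [],
        "cwps_length": None, "cwps_genes": None, "cwps_organization": None,
        "cwps_split": False, "cwps_qc_ok": None,
        "eps_label": None, "eps_novel": None, "eps_length": None,
        "eps_pathway": None, "island_flag": None, "island_span": None,
        "ice_without_orit": None, "replicon": None,
        "precursors": None, "modifications": None,
        "error": None,
    }
    ref_cwps = {f"{p.role}|{p.name}": p.sequence for p in refdb
                if p.kind in ("cwps", "any")}
    ref_eps = {f"{p.role}|{p.name}": p.sequence for p in refdb
               if p.kind in ("eps", "any")}
    cw_regions = find_locus(genome, "cwps", config.finder, refdb=ref_cwps)
    cw_regions = detect_split_locus(cw_regions, genome, config.split)
    if cw_regions:
        locus = max(cw_regions, key=lambda r: r.gene_count)
        typed = assign_roles(locus, refdb, params=config.align,
                             role_sim_threshold=config.role_sim_threshold)
        call = assign_cwps_genotype(typed, cwps_db,
                                    sim_threshold=config.cwps_sim_threshold,
                                    params=config.align)
        qc = qc_locus(locus)
        mob = scan_context(genome, locus, config.context)
        feats = predict_structure_features(typed)
        row.update(
            cwps_label=call.label, cwps_novel=call.is_novel,
            cwps_fragments=[(s, e) for _, s, e in locus.fragments],
            cwps_length=locus.total_length, cwps_genes=locus.gene_count,
            cwps_organization=typed.organization, cwps_split=locus.split,
            cwps_qc_ok=qc.length_in_expected_range and qc.gene_count_in_expected_range,
            replicon=mob.replicon,
            precursors=sorted(feats.precursors),
            modifications=sorted(feats.modifications),
        )
    eps_regions = find_locus(genome, "eps", config.finder, refdb=ref_eps)
    eps_regions = detect_split_locus(eps_regions, genome, config.split)
    if eps_regions:
        locus = max(eps_regions, key=lambda r: r.gene_count)
        typed = assign_roles(locus, refdb, params=config.align,
                             role_sim_threshold=config.role_sim_threshold)
        call = assign_eps_genotype(typed, eps_db,
                                   match_threshold=config.eps_match_threshold,
                                   params=config.align)
        mob = scan_context(genome, locus, config.context)
        row.update(
            eps_label=call.label, eps_novel=call.is_novel,
            eps_length=locus.total_length, eps_pathway=typed.pathway_class,
            island_flag=mob.island_flag, island_span=mob.island_span_estimate,
            ice_without_orit=mob.ice_without_orit,
        )
    return row


def run_pipeline(genomes: list[Genome], config: PipelineConfig | None = None,
                 refdb: list[RefProtein] | None = None,
                 cwps_db: GenotypeDB | None = None,
                 eps_db: GenotypeDB | None = None) -> CohortSummary:
    """Type a cohort of genomes.  Deterministic given inputs and config.

    Per-strain failures are logged and reported as undetermined rows; they
    never abort the cohort.
    """
    if not genomes:
        raise ValueError("no genomes supplied")
    config = config or PipelineConfig()
    if refdb is None:
        from .synthetic_data import build_refdb
        refdb = build_refdb()
    cwps_db = cwps_db if cwps_db is not None else default_cwps_db()
    eps_db = eps_db if eps_db is not None else GenotypeDB(next_label_rule="roman")
    rows = []
    for genome in genomes:
        try:
            rows.append(type_genome(genome, config, refdb, cwps_db, eps_db))
        except Exception as exc:  # pragma: no cover - defensive path
            logger.exception("strain %s failed", genome.id)
            rows.append({
                "species": genome.species, "strain": genome.id,
                "cwps_label": None, "cwps_novel": None, "cwps_fragments": [],
                "cwps_length": None, "cwps_genes": None,
                "cwps_organization": None, "cwps_split": False,
                "cwps_qc_ok": None, "eps_label": None, "eps_novel": None,
                "eps_length": None, "eps_pathway": None, "island_flag": None,
                "island_span": None, "ice_without_orit": None,
                "replicon": None, "precursors": None, "modifications": None,
                "error": str(exc),
            })
    return _aggregate(rows)


def summarize_fixture(records: list[StrainRecord]) -> CohortSummary:
    """Cohort summary from the packaged strain table (printed labels and
    coordinates only; no sequence stages)."""
    rows = []
    for rec in records:
        rows.append({
            "species": rec.species, "strain": rec.strain,
            "cwps_label": rec.cwps_genotype, "cwps_novel": None,
            "cwps_fragments": rec.cwps_fragments,
            "cwps_length": rec.cwps_length,
            "cwps_genes": None, "cwps_organization": None,
            "cwps_split": len(rec.cwps_fragments) > 1, "cwps_qc_ok": None,
            "eps_label": rec.eps_genotype, "eps_novel": None,
            "eps_length": rec.eps_length, "eps_pathway": None,
            "island_flag": None, "island_span": None,
            "ice_without_orit": None, "replicon": None,
            "precursors": None, "modifications": None, "error": None,
        })
    return _aggregate(rows)
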