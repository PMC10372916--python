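"""End-to-end orchestration: map -> quantify -> normalize -> classify -> filter.

Single-process, in-memory design: the data are desk-scale (<= ~1e5
evidence rows), so there is no streaming or parallelism. Every count
logged at INFO also appears in the summary/qc output objects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from succinylome.candidates import (
    CandidateTable,
    FilterSpec,
    compartment_distribution,
    filter_candidates,
    rank_candidates,
)
from succinylome.differential import DiffCall, SummaryReport, call_items, summarize
from succinylome.io_formats import AnnotationSet, EvidenceRow, Proteome, write_results
from succinylome.normalize import QCReport, SiteQuantNorm, normalize_sites, qc_report, run_offsets
from succinylome.quant import ProteinQuant, SiteQuantRaw, protein_ratios, site_ratios
from succinylome.sitemap import KsuSiteKey, PeptideIndex, collect_sites

logger = logging.getLogger(__name__)

DEFAULT_COMPARTMENT_ORDER = (
    "mitochondrion",
    "cytoplasm",
    "extracellular exosome",
    "extracellular matrix",
    "nucleus",
    "plasma membrane",
)


@dataclass(frozen=True)
class PipelineConfig:
    threshold_log2: float = 1.0
    centering: bool = True
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    compartment_order: tuple[str, ...] = DEFAULT_COMPARTMENT_ORDER

    def __post_init__(self) -> None:
        if self.threshold_log2 <= 0:
            raise ValueError(f"threshold_log2 must be > 0, got {self.threshold_log2}")


@dataclass
class PipelineResult:
    proteins: list[ProteinQuant]
    sites_raw: list[SiteQuantRaw]
    sites_norm: list[SiteQuantNorm]
    protein_calls: list[DiffCall]
    site_calls: list[DiffCall]
    summary: SummaryReport
    qc: QCReport
    candidates: CandidateTable
    compartments_all_ksu: dict[str, float | None]
    compartments_up_ksu: dict[str, float | None]
    protein_offsets: dict[int, float]

    def protein_table(self) -> pd.DataFrame:
        rows = []
        for p in sorted(self.proteins, key=lambda p: p.protein_id):
            rows.append(
                {
                    "protein_id": p.protein_id,
                    "ratio_rep1": p.ratio_by_rep.get(1),
                    "ratio_rep2": p.ratio_by_rep.get(2),
                    "n_pep_rep1": p.n_peptides_by_rep.get(1, 0),
                    "n_pep_rep2": p.n_peptides_by_rep.get(2, 0),
                }
            )
        return pd.DataFrame(
            rows, columns=["protein_id", "ratio_rep1", "ratio_rep2", "n_pep_rep1", "n_pep_rep2"]
        )

    def site_table(self) -> pd.DataFrame:
        call_by_site = {c.item_id: c.call for c in self.site_calls}
        raw_by_site = {s.site: s for s in self.sites_raw}
        rows = []
        for sn in sorted(self.sites_norm, key=lambda s: s.site):
            raw = raw_by_site[sn.site]
            rows.append(
                {
                    "protein_id": sn.site.protein_id,
                    "position": sn.site.position,
                    "ratio_rep1": raw.ratio_by_rep.get(1),
                    "ratio_rep2": raw.ratio_by_rep.get(2),
                    "norm_log2_rep1": sn.norm_log2_by_rep.get(1),
                    "norm_log2_rep2": sn.norm_log2_by_rep.get(2),
                    "merged_log2": sn.merged_log2,
                    "n_reps": sn.n_reps,
                    "flags": sn.flag,
                    "call": call_by_site.get(sn.site, "not_quantified"),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "protein_id", "position", "ratio_rep1", "ratio_rep2",
                "norm_log2_rep1", "norm_log2_rep2", "merged_log2", "n_reps", "flags", "call",
            ],
        )


def run_pipeline(
    proteome: Proteome,
    evidence: Sequence[EvidenceRow],
    annotations: AnnotationSet,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run the full analysis on validated evidence rows.

    ``evidence`` mixes proteome and enriched rows from both replicates;
    rows route themselves by their ``experiment`` field.
    """
    index = PeptideIndex(proteome)

    proteome_rows = [r for r in evidence if r.experiment == "proteome"]
    enriched_rows = [r for r in evidence if r.experiment == "enriched"]

    proteins = protein_ratios(proteome_rows, proteome, index)
    logger.info("quantified %d proteins", len(proteins))

    site_coll = collect_sites([r for r in enriched_rows if r.is_modified], proteome, index)
    logger.info(
        "identified %d Ksu sites on %d proteins (unique rows %d, ambiguous %d, unmapped %d)",
        site_coll.n_sites_identified, site_coll.n_proteins_identified,
        site_coll.n_unique, site_coll.n_ambiguous, site_coll.n_unmapped,
    )
    sites_raw = site_ratios(site_coll)
    qc = qc_report(proteins, sites_raw)

    offsets = run_offsets(proteins) if config.centering else {}
    if offsets:
        # centering shifts raw log2 ratios; normalized site values are
        # invariant since site and protein shift alike within a replicate
        for p in proteins:
            for rep in list(p.ratio_by_rep):
                p.ratio_by_rep[rep] = p.ratio_by_rep[rep] / 2.0 ** offsets[rep]
        for s in sites_raw:
            for rep in list(s.ratio_by_rep):
                if rep in offsets:
                    s.ratio_by_rep[rep] = s.ratio_by_rep[rep] / 2.0 ** offsets[rep]

    sites_norm = normalize_sites(sites_raw, proteins)

    protein_log2 = {
        p.protein_id: sum(math.log2(v) for v in p.ratio_by_rep.values()) / len(p.ratio_by_rep)
        for p in proteins
        if p.ratio_by_rep
    }
    protein_calls = call_items(protein_log2, config.threshold_log2)
    site_log2 = {s.site: s.merged_log2 for s in sites_norm if s.merged_log2 is not None}
    site_calls = call_items(site_log2, config.threshold_log2)

    site_protein_index = {s.site: s.site.protein_id for s in sites_norm}
    summary = summarize(
        protein_calls,
        site_calls,
        site_protein_index,
        n_protein_quantified=len(proteins),
        n_site_identified=site_coll.n_sites_identified,
        n_site_quantified=sum(1 for s in sites_raw if s.quantified),
        n_ksu_protein_quantified=len({s.site.protein_id for s in sites_raw if s.quantified}),
    )
    logger.info(
        "quantified %d proteins, %d (%s%%) DEPs; %d/%d sites differential",
        summary.n_protein_quantified, summary.n_dep, summary.pct_dep,
        summary.n_site_diff, summary.n_site_quantified,
    )

    all_ksu_proteins = {s.site.protein_id for s in sites_raw}
    up_ksu_proteins = {c.item_id.protein_id for c in site_calls if c.call == "up"}
    comp_all = compartment_distribution(all_ksu_proteins, annotations, config.compartment_order)
    comp_up = compartment_distribution(up_ksu_proteins, annotations, config.compartment_order)

    cand = filter_candidates(site_calls, annotations, config.filter_spec)
    logger.info(
        "candidates: %d sites on %d proteins (stages: %s)",
        cand.n_sites, cand.n_proteins, cand.stage_counts,
    )

    return PipelineResult(
        proteins=proteins,
        sites_raw=sites_raw,
        sites_norm=sites_norm,
        protein_calls=protein_calls,
        site_calls=site_calls,
        summary=summary,
        qc=qc,
        candidates=cand,
        compartments_all_ksu=comp_all,
        compartments_up_ksu=comp_up,
        protein_offsets=offsets,
    )


def write_pipeline_outputs(result: PipelineResult, out_dir) -> list:
    """Write proteins.tsv, sites.tsv, candidates.tsv, summary.json, qc.json."""
    summary = result.summary.to_dict()
    summary["stage_counts"] = result.candidates.stage_counts
    summary["compartments_all_ksu"] = result.compartments_all_ksu
    summary["compartments_up_ksu"] = result.compartments_up_ksu
    tables = {
        "proteins": result.protein_table(),
        "sites": result.site_table(),
        "candidates": rank_candidates(result.candidates),
        "summary": summary,
        "qc": result.qc.to_dict(),
    }
    return write_results(tables, out_dir)
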