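"""Subcellular-localization filtering of up-regulated succinylation sites.

The candidate-substrate cascade keeps up-regulated Ksu sites on proteins
that are extracellular (exosome/matrix) or cytoplasmic by GO cellular
component annotation while excluding anything annotated to the
mitochondrion (matrix / inner membrane included). Term matching is
exact-string on normalized (lower-case, trimmed) labels: the annotation
table is expected to carry already-mapped compartment labels, and GO DAG
expansion is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from succinylome.differential import DiffCall
from succinylome.io_formats import AnnotationSet, normalize_term
from succinylome.normalize import round1
from succinylome.sitemap import KsuSiteKey

DEFAULT_EXTRACELLULAR = frozenset({"extracellular exosome", "extracellular matrix"})
DEFAULT_CYTOPLASM = frozenset({"cytoplasm"})
DEFAULT_EXCLUDE = frozenset({"mitochondrion", "mitochondrial matrix", "mitochondrial inner membrane"})


@dataclass(frozen=True)
class FilterSpec:
    """Term sets driving the two-stage localization filter.

    ``extracellular_terms`` and ``cytoplasm_terms`` define the two
    inclusion stages; ``exclude_terms`` vetoes a protein outright.
    ``include_terms`` (the union of the two stages) must not intersect
    ``exclude_terms``.
    """

    extracellular_terms: frozenset[str] = DEFAULT_EXTRACELLULAR
    cytoplasm_terms: frozenset[str] = DEFAULT_CYTOPLASM
    exclude_terms: frozenset[str] = DEFAULT_EXCLUDE

    def __post_init__(self) -> None:
        object.__setattr__(self, "extracellular_terms", frozenset(map(normalize_term, self.extracellular_terms)))
        object.__setattr__(self, "cytoplasm_terms", frozenset(map(normalize_term, self.cytoplasm_terms)))
        object.__setattr__(self, "exclude_terms", frozenset(map(normalize_term, self.exclude_terms)))
        if self.include_terms & self.exclude_terms:
            raise ValueError(
                f"include/exclude overlap: {sorted(self.include_terms & self.exclude_terms)}"
            )

    @property
    def include_terms(self) -> frozenset[str]:
        return self.extracellular_terms | self.cytoplasm_terms


@dataclass
class CandidateTable:
    """Final candidate-substrate sites (call=up, localization-filtered)."""

    rows: pd.DataFrame  # protein_id, position, merged_log2, matched_terms
    n_sites: int
    n_proteins: int
    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)


def compartment_distribution(
    proteins: set[str] | Sequence[str],
    annotations: AnnotationSet,
    compartments: Sequence[str],
) -> dict[str, float | None]:
    """Percent of proteins per compartment, single-assignment.

    Each protein is assigned to the *first* compartment in the ordered
    list whose term it carries (pie-chart style mutually exclusive
    bins); proteins matching none are pooled under "other". Percents are
    rounded to one decimal and sum to 100 up to rounding. An empty
    protein set yields all-None percents.
    """
    if not compartments:
        raise ValueError("compartments must be non-empty")
    comp_norm = [normalize_term(c) for c in compartments]
    proteins = set(proteins)
    labels = comp_norm + ["other"]
    if not proteins:
        return {c: None for c in labels}
    counts = dict.fromkeys(labels, 0)
    for pid in proteins:
        terms = annotations.get(pid)
        for c in comp_norm:
            if c in terms:
                counts[c] += 1
                break
        else:
            counts["other"] += 1
    n = len(proteins)
    return {c: round1(100.0 * k / n) for c, k in counts.items()}


def filter_candidates(
    site_calls: Sequence[DiffCall],
    annotations: AnnotationSet,
    spec: FilterSpec = FilterSpec(),
    merged_log2_by_site: Mapping[KsuSiteKey, float] | None = None,
) -> CandidateTable:
    """Apply the two-stage localization cascade to up-regulated sites.

    Stage 1 (extracellular): up-sites on proteins carrying an
    extracellular term and no exclude term. Stage 2 (cytoplasmic):
    up-sites on proteins carrying a cytoplasm term. Final: the union of
    the stages restricted to proteins with no exclude-term annotation —
    mitochondrial annotation vetoes a protein even when it is also
    cytoplasmic. Per-stage site/protein counts are reported.
    """
    up_sites = [c.item_id for c in site_calls if c.call == "up"]
    fc = {c.item_id: c.log2fc for c in site_calls}
    if merged_log2_by_site:
        fc.update(merged_log2_by_site)

    def _has(pid: str, terms: frozenset[str]) -> bool:
        return bool(annotations.get(pid) & terms)

    stage1 = [s for s in up_sites if _has(s.protein_id, spec.extracellular_terms) and not _has(s.protein_id, spec.exclude_terms)]
    stage2 = [s for s in up_sites if _has(s.protein_id, spec.cytoplasm_terms)]
    final = sorted(
        {s for s in stage1} | {s for s in stage2 if not _has(s.protein_id, spec.exclude_terms)}
    )

    rows = []
    for s in final:
        matched = sorted(annotations.get(s.protein_id) & spec.include_terms)
        rows.append(
            {
                "protein_id": s.protein_id,
                "position": s.position,
                "merged_log2": fc.get(s),
                "matched_terms": ";".join(matched),
            }
        )
    df = pd.DataFrame(rows, columns=["protein_id", "position", "merged_log2", "matched_terms"])
    stage_counts = {
        "extracellular": {"sites": len(stage1), "proteins": len({s.protein_id for s in stage1})},
        "cytoplasm": {"sites": len(stage2), "proteins": len({s.protein_id for s in stage2})},
        "final": {"sites": len(final), "proteins": len({s.protein_id for s in final})},
    }
    return CandidateTable(
        rows=df,
        n_sites=len(final),
        n_proteins=len({s.protein_id for s in final}),
        stage_counts=stage_counts,
    )


def rank_candidates(table: CandidateTable) -> pd.DataFrame:
    """Order candidate proteins for manual triage.

    Sort key: number of up-sites descending, then max merged log2
    descending, then protein id ascending — deterministic, so the same
    table always ranks the same way. Returns the site-level table with
    proteins in rank order and a ``rank`` column.
    """
    df = table.rows
    if df.empty:
        out = df.copy()
        out["rank"] = pd.Series(dtype=int)
        return out
    stats = (
        df.groupby("protein_id")
        .agg(n_up_sites=("position", "size"), max_log2=("merged_log2", "max"))
        .reset_index()
    )
    stats = stats.sort_values(
        by=["n_up_sites", "max_log2", "protein_id"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    stats["rank"] = stats.index + 1
    out = df.merge(stats[["protein_id", "rank", "n_up_sites"]], on="protein_id")
    return out.sort_values(by=["rank", "position"], kind="mergesort").reset_index(drop=True)
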