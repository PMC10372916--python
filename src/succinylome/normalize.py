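"""Protein-level normalization of site ratios, run centering, replicate
merging, and replicate QC (Pearson correlation and overlap).

The key quantity downstream is the *protein-normalized* site log2 ratio,
log2(site H/L) - log2(protein H/L), which isolates the change in
modification stoichiometry from the change in protein abundance.

Run centering subtracts the per-replicate median of protein log2 ratios
(from the whole-proteome run) from every log2 ratio of that replicate,
removing global labeling/mixing bias. It is deliberately isolated in
one operation so a pipeline config can disable it; normalized site
values are invariant to it (the shift cancels in the subtraction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from succinylome.quant import REPLICATES, ProteinQuant, SiteQuantRaw
from succinylome.sitemap import KsuSiteKey


def round1(x: float) -> float:
    """Round to one decimal, half away from zero."""
    return math.copysign(math.floor(abs(x) * 10 + 0.5), x) / 10


def center_run(log2_values: Sequence[float]) -> list[float]:
    """Subtract the median from a vector of log2 ratios.

    The caller passes the replicate's proteome-run protein log2 ratios to
    determine the offset; here the same median is applied to the vector
    itself (the simple, self-centering form used when proteins and sites
    share a run: use :func:`run_offsets` to apply one run's protein
    median to its sites).
    """
    if len(log2_values) == 0:
        raise ValueError("cannot center an empty run")
    med = float(np.median(log2_values))
    return [v - med for v in log2_values]


def run_offsets(proteins: Sequence[ProteinQuant]) -> dict[int, float]:
    """Per-replicate centering offset = median protein log2 ratio."""
    offsets: dict[int, float] = {}
    for rep in REPLICATES:
        vals = [math.log2(p.ratio_by_rep[rep]) for p in proteins if rep in p.ratio_by_rep]
        if vals:
            offsets[rep] = float(np.median(vals))
    return offsets


@dataclass
class SiteQuantNorm:
    site: KsuSiteKey
    norm_log2_by_rep: dict[int, float] = field(default_factory=dict)
    merged_log2: float | None = None
    n_reps: int = 0
    flag: str = ""  # "" | "unnormalized"

    @property
    def quantified(self) -> bool:
        return self.merged_log2 is not None


def normalize_sites(
    sites: Sequence[SiteQuantRaw],
    proteins: Sequence[ProteinQuant],
) -> list[SiteQuantNorm]:
    """Normalize site ratios to the host protein's ratio, per replicate,
    then merge replicates by arithmetic mean of the available values.

    A site whose protein lacks a ratio in a replicate gets no normalized
    value there. A quantified site with no normalized value in either
    replicate is reported with its raw log2 ratio and flagged
    ``unnormalized`` rather than dropped, matching the "either
    replicate" quantification convention that maximizes coverage.
    """
    protein_by_id = {p.protein_id: p for p in proteins}
    out: list[SiteQuantNorm] = []
    for sq in sites:
        norm = SiteQuantNorm(site=sq.site)
        prot = protein_by_id.get(sq.site.protein_id)
        for rep, ratio in sq.ratio_by_rep.items():
            if prot is not None and rep in prot.ratio_by_rep:
                norm.norm_log2_by_rep[rep] = math.log2(ratio) - math.log2(prot.ratio_by_rep[rep])
        if norm.norm_log2_by_rep:
            vals = list(norm.norm_log2_by_rep.values())
            norm.merged_log2 = sum(vals) / len(vals)
            norm.n_reps = len(vals)
        elif sq.ratio_by_rep:
            vals = [math.log2(r) for r in sq.ratio_by_rep.values()]
            norm.merged_log2 = sum(vals) / len(vals)
            norm.n_reps = len(vals)
            norm.flag = "unnormalized"
        out.append(norm)
    return out


@dataclass
class QCReport:
    pearson_protein: float | None
    pearson_site: float | None
    protein_overlap: tuple[int, int, float | None]  # (intersection, union, percent)
    site_overlap: tuple[int, int, float | None]

    def to_dict(self) -> dict:
        return {
            "pearson_protein": self.pearson_protein,
            "pearson_site": self.pearson_site,
            "protein_overlap": {
                "intersection": self.protein_overlap[0],
                "union": self.protein_overlap[1],
                "percent": self.protein_overlap[2],
            },
            "site_overlap": {
                "intersection": self.site_overlap[0],
                "union": self.site_overlap[1],
                "percent": self.site_overlap[2],
            },
        }


def pearson(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Pearson r; None (undefined) for fewer than two pairs or zero variance.

    Undefined correlations are reported as None, never 0 — zero is a
    meaningful correlation value.
    """
    if len(x) < 2 or len(x) != len(y):
        return None
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if xa.std() == 0 or ya.std() == 0:
        return None
    return float(np.corrcoef(xa, ya)[0, 1])


def overlap_percent(intersection: int, union: int) -> float | None:
    """Replicate overlap as a percentage, one decimal (half away from zero)."""
    if union == 0:
        return None
    return round1(100.0 * intersection / union)


def qc_report(
    proteins: Sequence[ProteinQuant],
    sites_raw: Sequence[SiteQuantRaw],
) -> QCReport:
    """Replicate reproducibility QC on *raw* H/L ratios.

    Pearson correlations are computed on log2 raw ratios over items
    quantified in both replicates. Overlap percent is
    100 * |both replicates| / |either replicate| for Ksu proteins
    (identified in both vs either) and Ksu sites. The overlap statistic
    is symmetric under relabeling replicate 1 <-> 2.
    """
    p1, p2 = [], []
    for p in proteins:
        if 1 in p.ratio_by_rep and 2 in p.ratio_by_rep:
            p1.append(math.log2(p.ratio_by_rep[1]))
            p2.append(math.log2(p.ratio_by_rep[2]))
    s1, s2 = [], []
    for s in sites_raw:
        if 1 in s.ratio_by_rep and 2 in s.ratio_by_rep:
            s1.append(math.log2(s.ratio_by_rep[1]))
            s2.append(math.log2(s.ratio_by_rep[2]))

    site_sets = {rep: {s.site for s in sites_raw if rep in s.identified_in} for rep in REPLICATES}
    prot_sets = {rep: {s.protein_id for s in site_sets[rep]} for rep in REPLICATES}

    def _overlap(sets: dict[int, set]) -> tuple[int, int, float | None]:
        inter = len(sets[1] & sets[2])
        union = len(sets[1] | sets[2])
        return (inter, union, overlap_percent(inter, union))

    return QCReport(
        pearson_protein=pearson(p1, p2),
        pearson_site=pearson(s1, s2),
        protein_overlap=_overlap(prot_sets),
        site_overlap=_overlap(site_sets),
    )
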