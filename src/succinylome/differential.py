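"""Fold-change classification of proteins and succinylation sites.

The classification rule is strict two-fold change on merged log2 ratios:
call = up when log2fc > threshold, down when log2fc < -threshold, else
unchanged. A ratio of exactly 2 ("two times" on the nose) is therefore
unchanged — the rule is "more than two times". No p-values or FDR are
computed; the design uses fold-change thresholds only.

Percentages are rounded to one decimal, half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import pandas as pd

from succinylome.normalize import SiteQuantNorm, round1
from succinylome.sitemap import KsuSiteKey

CALLS = ("up", "down", "unchanged")


@dataclass(frozen=True)
class DiffCall:
    item_id: Hashable  # protein_id or KsuSiteKey
    log2fc: float
    call: str
    threshold_log2: float = 1.0


def classify(log2fc: float, threshold_log2: float = 1.0) -> str:
    """Strict-threshold piecewise classification of one log2 fold change."""
    if threshold_log2 <= 0:
        raise ValueError(f"threshold_log2 must be > 0, got {threshold_log2}")
    if log2fc > threshold_log2:
        return "up"
    if log2fc < -threshold_log2:
        return "down"
    return "unchanged"


def call_items(
    log2fc_by_id: Mapping[Hashable, float | None], threshold_log2: float = 1.0
) -> list[DiffCall]:
    """Classify every item with a merged log2fc; items with a missing
    value are excluded (they stay quantified-only in the counts)."""
    return [
        DiffCall(item, fc, classify(fc, threshold_log2), threshold_log2)
        for item, fc in log2fc_by_id.items()
        if fc is not None
    ]


@dataclass
class SummaryReport:
    """Headline counts and fractions of the differential analysis.

    Percent denominators: DEP percents are over quantified proteins;
    the differential-site percent is over quantified sites; the
    differential-Ksu-protein percent counts proteins with >=1
    differential site over Ksu-quantified proteins.
    """

    n_protein_quantified: int
    n_dep: int
    n_dep_up: int
    n_dep_down: int
    pct_dep: float | None
    pct_up: float | None
    pct_down: float | None
    n_site_identified: int
    n_site_quantified: int
    n_site_diff: int
    n_site_diff_up: int
    pct_site_diff_of_quantified: float | None
    n_ksu_protein_quantified: int
    n_ksu_protein_diff: int
    pct_ksu_protein_diff: float | None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _pct(num: int, denom: int) -> float | None:
    return None if denom == 0 else round1(100.0 * num / denom)


def summarize(
    protein_calls: Sequence[DiffCall],
    site_calls: Sequence[DiffCall],
    site_protein_index: Mapping[KsuSiteKey, str],
    *,
    n_protein_quantified: int | None = None,
    n_site_identified: int | None = None,
    n_site_quantified: int | None = None,
    n_ksu_protein_quantified: int | None = None,
) -> SummaryReport:
    """Build the summary report from classified proteins and sites.

    The ``n_*`` keyword overrides let the caller supply denominators that
    include quantified-but-unclassifiable items (e.g. identified sites
    without a ratio); they default to what the call lists imply.
    """
    n_pq = n_protein_quantified if n_protein_quantified is not None else len(protein_calls)
    n_dep_up = sum(1 for c in protein_calls if c.call == "up")
    n_dep_down = sum(1 for c in protein_calls if c.call == "down")
    n_dep = n_dep_up + n_dep_down

    n_sq = n_site_quantified if n_site_quantified is not None else len(site_calls)
    n_si = n_site_identified if n_site_identified is not None else n_sq
    n_site_diff = sum(1 for c in site_calls if c.call != "unchanged")
    n_site_diff_up = sum(1 for c in site_calls if c.call == "up")

    ksu_prot_quant = {site_protein_index[c.item_id] for c in site_calls if c.item_id in site_protein_index}
    ksu_prot_diff = {
        site_protein_index[c.item_id]
        for c in site_calls
        if c.call != "unchanged" and c.item_id in site_protein_index
    }
    n_kpq = (
        n_ksu_protein_quantified if n_ksu_protein_quantified is not None else len(ksu_prot_quant)
    )

    return SummaryReport(
        n_protein_quantified=n_pq,
        n_dep=n_dep,
        n_dep_up=n_dep_up,
        n_dep_down=n_dep_down,
        pct_dep=_pct(n_dep, n_pq),
        pct_up=_pct(n_dep_up, n_pq),
        pct_down=_pct(n_dep_down, n_pq),
        n_site_identified=n_si,
        n_site_quantified=n_sq,
        n_site_diff=n_site_diff,
        n_site_diff_up=n_site_diff_up,
        pct_site_diff_of_quantified=_pct(n_site_diff_up, n_sq),
        n_ksu_protein_quantified=n_kpq,
        n_ksu_protein_diff=len(ksu_prot_diff),
        pct_ksu_protein_diff=_pct(len(ksu_prot_diff), n_kpq),
    )


def per_protein_site_table(
    protein_id: str,
    site_norms: Sequence[SiteQuantNorm],
    site_calls: Sequence[DiffCall],
    known_mods: Mapping[int, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """All identified sites of one protein, with call and co-modification
    flags — the per-protein report used to triage individual substrates
    (e.g. a 7-site table with 4 sites marked up).

    ``known_mods`` maps residue positions to co-occurring modification
    labels such as "ac" (acetylation) or "ub" (ubiquitylation). Unknown
    proteins yield an empty table.
    """
    known_mods = known_mods or {}
    call_by_site = {c.item_id: c for c in site_calls}
    rows = []
    for sn in sorted((s for s in site_norms if s.site.protein_id == protein_id), key=lambda s: s.site.position):
        call = call_by_site.get(sn.site)
        rows.append(
            {
                "protein_id": protein_id,
                "position": sn.site.position,
                "site": f"K{sn.site.position}",
                "merged_log2": sn.merged_log2,
                "call": call.call if call else "not_quantified",
                "known_mods": ";".join(known_mods.get(sn.site.position, [])),
            }
        )
    return pd.DataFrame(
        rows, columns=["protein_id", "position", "site", "merged_log2", "call", "known_mods"]
    )
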