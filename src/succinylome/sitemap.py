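"""Map succinylated peptides onto protein residue coordinates.

A peptide is placed by exact substring search against every protein in
the database. Only peptides matching exactly one protein at exactly one
offset yield site coordinates; shared or repeated peptides are flagged
ambiguous and contribute no sites (conservative: no razor-protein
logic). I and L are distinct residues — sequences come from a defined
FASTA, not from de novo calls.

Coordinates are 1-based: a peptide starting at 0-based protein offset
``o`` with a modification at 1-based peptide offset ``m`` marks residue
``o + m`` of the protein.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Sequence

from succinylome.io_formats import EvidenceRow, Proteome


@dataclass(frozen=True, order=True)
class KsuSiteKey:
    """A succinylation site: protein + 1-based lysine position."""

    protein_id: str
    position: int

    def __str__(self) -> str:
        return f"{self.protein_id}-K{self.position}"


@dataclass(frozen=True)
class MappingResult:
    row: EvidenceRow
    sites: tuple[KsuSiteKey, ...]
    status: str  # unique | ambiguous | unmapped


class PeptideIndex:
    """Occurrence index over a proteome.

    Concatenates all sequences with a sentinel and locates peptides with
    ``str.find`` (C speed), translating global hit offsets back to
    (protein_id, 0-based offset) via bisect. Equivalent to scanning each
    protein independently, which the tests verify against a brute-force
    oracle.
    """

    def __init__(self, proteome: Proteome) -> None:
        self.proteome = proteome
        self._ids: list[str] = []
        self._starts: list[int] = []
        parts: list[str] = []
        pos = 0
        for pid, seq in proteome.records.items():
            self._ids.append(pid)
            self._starts.append(pos)
            parts.append(seq)
            pos += len(seq) + 1  # +1 for sentinel
        self._blob = "|".join(parts)
        self._lengths = [len(proteome.records[pid]) for pid in self._ids]
        self._cache: dict[str, list[tuple[str, int]]] = {}
        self._cache_limit = 3

    def occurrences(self, peptide: str, limit: int = 3) -> list[tuple[str, int]]:
        """All (protein_id, 0-based offset) occurrences, up to ``limit``.

        Results for the common small limits are memoized: evidence
        tables repeat the same peptide many times.
        """
        if limit <= self._cache_limit:
            cached = self._cache.get(peptide)
            if cached is None:
                cached = self._scan(peptide, self._cache_limit)
                self._cache[peptide] = cached
            return cached[:limit]
        return self._scan(peptide, limit)

    def _scan(self, peptide: str, limit: int) -> list[tuple[str, int]]:
        hits: list[tuple[str, int]] = []
        start = 0
        while len(hits) < limit:
            g = self._blob.find(peptide, start)
            if g == -1:
                break
            i = bisect.bisect_right(self._starts, g) - 1
            local = g - self._starts[i]
            # sentinel '|' cannot occur inside a peptide, so a hit never spans records
            if local + len(peptide) <= self._lengths[i]:
                hits.append((self._ids[i], local))
            start = g + 1
        return hits


def map_peptide(
    row: EvidenceRow, proteome: Proteome, index: PeptideIndex | None = None
) -> MappingResult:
    """Place one evidence row; unique placements yield site keys.

    Status is ``unique`` (exactly one protein, one offset), ``ambiguous``
    (two or more placements, across or within proteins) or ``unmapped``.
    """
    if index is None:
        index = PeptideIndex(proteome)
    hits = index.occurrences(row.peptide, limit=2)
    if not hits:
        return MappingResult(row, (), "unmapped")
    if len(hits) > 1:
        return MappingResult(row, (), "ambiguous")
    pid, off = hits[0]
    sites = tuple(KsuSiteKey(pid, off + m) for m, _kind in row.mods)
    for s in sites:
        assert proteome[s.protein_id][s.position - 1] == "K", s
    return MappingResult(row, sites, "unique")


@dataclass
class SiteCollection:
    """Uniquely mapped evidence grouped by site, with mapping tallies."""

    by_site: dict[KsuSiteKey, list[EvidenceRow]]
    protein_of_row: dict[int, str]  # id(row) -> protein for uniquely mapped rows
    n_unique: int
    n_ambiguous: int
    n_unmapped: int

    @property
    def n_sites_identified(self) -> int:
        return len(self.by_site)

    @property
    def n_proteins_identified(self) -> int:
        return len({s.protein_id for s in self.by_site})


def collect_sites(
    rows: Iterable[EvidenceRow],
    proteome: Proteome,
    index: PeptideIndex | None = None,
) -> SiteCollection:
    """Group uniquely mapped modified rows by site.

    A peptide carrying k succinyl mods contributes evidence to k sites.
    Mapping is per-row and order-independent, so the result does not
    depend on evidence order.
    """
    if index is None:
        index = PeptideIndex(proteome)
    by_site: dict[KsuSiteKey, list[EvidenceRow]] = {}
    protein_of_row: dict[int, str] = {}
    n_unique = n_ambiguous = n_unmapped = 0
    for row in rows:
        res = map_peptide(row, proteome, index)
        if res.status == "unique":
            n_unique += 1
            protein_of_row[id(row)] = res.sites[0].protein_id if res.sites else ""
            for site in res.sites:
                by_site.setdefault(site, []).append(row)
        elif res.status == "ambiguous":
            n_ambiguous += 1
        else:
            n_unmapped += 1
    return SiteCollection(by_site, protein_of_row, n_unique, n_ambiguous, n_unmapped)


def map_unmodified_rows(
    rows: Sequence[EvidenceRow], proteome: Proteome, index: PeptideIndex | None = None
) -> dict[str, list[EvidenceRow]]:
    """Group uniquely mapped *unmodified* rows by protein (for protein quant)."""
    if index is None:
        index = PeptideIndex(proteome)
    by_protein: dict[str, list[EvidenceRow]] = {}
    for row in rows:
        if row.is_modified:
            continue
        hits = index.occurrences(row.peptide, limit=2)
        if len(hits) == 1:
            by_protein.setdefault(hits[0][0], []).append(row)
    return by_protein
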