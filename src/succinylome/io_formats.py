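"""Readers and writers for every file the pipeline touches.

File conventions
----------------
* FASTA: one record per protein, identifier = first whitespace token.
* Evidence TSV columns: ``peptide``, ``mods`` (semicolon list of
  ``K<offset>(su)``, offsets 1-based within the peptide, empty allowed),
  ``intensity_L``, ``intensity_H`` (non-negative or empty = missing),
  ``replicate`` (1|2), ``experiment`` (proteome|enriched).
* Annotation TSV columns: ``protein_id``, ``gocc_term`` — one pair per row.

Missing intensities are encoded as the empty field. A literal 0 is also
treated as missing: an MS intensity of zero is non-detection, and keeping
it would produce zero or infinite ratios downstream.

All residue coordinates in files are 1-based and closed, matching the
field's site naming convention (e.g. "K118").
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

EVIDENCE_COLUMNS = ["peptide", "mods", "intensity_L", "intensity_H", "replicate", "experiment"]

_MOD_TOKEN = re.compile(r"^K(\d+)\(su\)$")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class Proteome:
    """Protein sequence database: id -> uppercase amino-acid sequence."""

    records: Mapping[str, str]

    def __post_init__(self) -> None:
        for pid, seq in self.records.items():
            if not seq:
                raise FormatError(f"empty sequence for protein {pid!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, protein_id: str) -> str:
        return self.records[protein_id]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.records


@dataclass(frozen=True)
class EvidenceRow:
    """One quantified peptide observation from one replicate of one run.

    ``mods`` holds ``(offset, kind)`` pairs with 1-based offsets into
    ``peptide``; the only modification kind handled is ``"su"``
    (succinylation) and the modified residue must be lysine.
    """

    peptide: str
    mods: tuple[tuple[int, str], ...]
    intensity_L: float | None
    intensity_H: float | None
    replicate: int
    experiment: str

    def __post_init__(self) -> None:
        if not self.peptide:
            raise FormatError("empty peptide sequence")
        for off, kind in self.mods:
            if not 1 <= off <= len(self.peptide):
                raise FormatError(
                    f"mod offset {off} outside peptide of length {len(self.peptide)}"
                )
            if self.peptide[off - 1] != "K":
                raise FormatError(f"mod offset {off} is not on K in {self.peptide!r}")
            if kind != "su":
                raise FormatError(f"unknown modification kind {kind!r}")
        for label, val in (("intensity_L", self.intensity_L), ("intensity_H", self.intensity_H)):
            if val is not None and val < 0:
                raise FormatError(f"{label} is negative: {val}")
        if self.replicate not in (1, 2):
            raise FormatError(f"replicate must be 1 or 2, got {self.replicate}")
        if self.experiment not in ("proteome", "enriched"):
            raise FormatError(f"experiment must be proteome|enriched, got {self.experiment!r}")

    @property
    def is_modified(self) -> bool:
        return bool(self.mods)


@dataclass
class AnnotationSet:
    """Protein -> set of GO cellular-component term strings.

    Lookups for unannotated proteins return the empty set. Terms are
    normalized to lower-case, trimmed strings at load time.
    """

    terms: dict[str, frozenset[str]] = field(default_factory=dict)

    def get(self, protein_id: str) -> frozenset[str]:
        return self.terms.get(protein_id, frozenset())

    def __len__(self) -> int:
        return len(self.terms)


def normalize_term(term: str) -> str:
    return " ".join(term.strip().lower().split())


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> Proteome:
    """Parse a protein FASTA into a :class:`Proteome`.

    Rejects duplicate identifiers, empty sequences and residues outside
    the 20-letter alphabet plus X.
    """
    path = Path(path)
    records: dict[str, str] = {}
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FormatError(f"{path}: line 1: not FASTA content ({exc})") from exc
    for rec in parsed:
        pid = rec.id
        seq = str(rec.seq).upper()
        if pid in records:
            raise FormatError(f"{path}: duplicate protein id {pid!r}")
        if not seq:
            raise FormatError(f"{path}: empty sequence for {pid!r}")
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise FormatError(f"{path}: invalid residues {sorted(bad)} in {pid!r}")
        records[pid] = seq
    if not records:
        # SeqIO silently yields nothing for non-FASTA content
        with open(path) as fh:
            first = fh.readline()
        if not first.startswith(">"):
            raise FormatError(f"{path}: line 1: not FASTA content")
        raise FormatError(f"{path}: no records parsed")
    return Proteome(records)


def write_fasta(proteome: Proteome, path: str | Path, width: int = 60) -> None:
    """Write a proteome deterministically (insertion order, fixed wrap)."""
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in proteome.records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Evidence tables


def parse_mods(mods_str: str) -> tuple[tuple[int, str], ...]:
    """Parse a ``K8(su);K12(su)`` style string into (offset, kind) pairs."""
    if not mods_str or not mods_str.strip():
        return ()
    out = []
    for token in mods_str.strip().split(";"):
        m = _MOD_TOKEN.match(token.strip())
        if m is None:
            raise FormatError(f"malformed mods token {token!r}")
        out.append((int(m.group(1)), "su"))
    return tuple(out)


def format_mods(mods: Iterable[tuple[int, str]]) -> str:
    return ";".join(f"K{off}({kind})" for off, kind in mods)


def _parse_intensity(raw: object) -> float | None:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    s = str(raw).strip()
    if not s:
        return None
    val = float(s)
    if val < 0:
        raise FormatError(f"negative intensity {val}")
    return val if val > 0 else None  # 0 == non-detection


def read_evidence(path: str | Path) -> list[EvidenceRow]:
    """Read an evidence TSV, validating every row.

    Rows whose modification offset does not land on a lysine are excluded
    with a warning (the exclusion count is logged), mirroring how search
    engines occasionally emit off-residue localizations. Structural
    problems (missing columns, malformed mods) raise :class:`FormatError`
    with the offending row number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")

    rows: list[EvidenceRow] = []
    n_excluded = 0
    for i, rec in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            mods = parse_mods(rec.mods)
            peptide = rec.peptide.strip()
            # off-K mods are data errors worth tolerating; everything else is fatal
            off_k = [off for off, _ in mods if not (1 <= off <= len(peptide)) or peptide[off - 1] != "K"]
            if off_k:
                n_excluded += 1
                logger.warning("%s: row %d: mod offset(s) %s not on K; row excluded", path, i, off_k)
                continue
            rows.append(
                EvidenceRow(
                    peptide=peptide,
                    mods=mods,
                    intensity_L=_parse_intensity(rec.intensity_L),
                    intensity_H=_parse_intensity(rec.intensity_H),
                    replicate=int(rec.replicate),
                    experiment=rec.experiment.strip(),
                )
            )
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path}: row {i}: {exc}") from exc
    if n_excluded:
        logger.warning("%s: excluded %d rows with off-K modification offsets", path, n_excluded)
    read_evidence.last_excluded = n_excluded  # type: ignore[attr-defined]
    return rows


read_evidence.last_excluded = 0  # type: ignore[attr-defined]


def write_evidence(rows: Iterable[EvidenceRow], path: str | Path) -> None:
    """Write evidence rows as TSV; float intensities use repr so that
    read(write(x)) round-trips to the exact same binary values."""
    with open(path, "w") as fh:
        fh.write("\t".join(EVIDENCE_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.peptide,
                        format_mods(r.mods),
                        "" if r.intensity_L is None else repr(r.intensity_L),
                        "" if r.intensity_H is None else repr(r.intensity_H),
                        str(r.replicate),
                        r.experiment,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Annotations


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read a protein_id / gocc_term TSV into an :class:`AnnotationSet`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("protein_id", "gocc_term"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    acc: dict[str, set[str]] = {}
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        term = normalize_term(rec.gocc_term)
        if not term:
            raise FormatError(f"{path}: row {i}: empty gocc_term")
        acc.setdefault(rec.protein_id.strip(), set()).add(term)
    return AnnotationSet({pid: frozenset(ts) for pid, ts in acc.items()})


def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tgocc_term\n")
        for pid in sorted(ann.terms):
            for term in sorted(ann.terms[pid]):
                fh.write(f"{pid}\t{term}\n")


# ---------------------------------------------------------------------------
# Result tables


def write_results(tables: Mapping[str, object], out_dir: str | Path) -> list[Path]:
    """Write result tables/objects into ``out_dir`` deterministically.

    DataFrames are written as TSV (``<name>.tsv``); everything else is
    JSON-serialized with sorted keys (``<name>.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in sorted(tables):
        obj = tables[name]
        if isinstance(obj, pd.DataFrame):
            p = out_dir / f"{name}.tsv"
            obj.to_csv(p, sep="\t", index=False)
        else:
            p = out_dir / f"{name}.json"
            with open(p, "w") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True)
                fh.write("\n")
        written.append(p)
    return written
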