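"""Synthetic SILAC succinylome study generator.

Emulates the two-cell-line / two-biological-replicate SILAC design that
the analysis assumes: a whole-proteome run and a Ksu-IP-enriched run,
each in two replicates, over a shared protein database. Heavy (H)
corresponds to the aggressive cell line, light (L) to the parental one;
the ratio convention is H/L throughout.

What is modeled
---------------
* Protein sequences with UniProt-average amino-acid composition.
* In-silico tryptic digestion (cleave after K/R, not before P),
  peptide length 7-25. Succinylation blocks trypsin at the modified
  lysine, so each enriched peptide carries its Ksu internally as one
  forced missed cleavage — the chemistry real enrichment data shows.
* True protein log2(H/L) ratios with a configured fraction of
  differential proteins, and true protein-normalized site log2 ratios
  with a configured fraction of up-regulated sites. Site ratios are
  sampled independently of the host protein's ratio: the protein-
  normalized change in modification stoichiometry is the signal of
  interest, not abundance.
* Multiplicative log-normal intensity noise per channel, a
  between-replicate shift of true log2 ratios, and missing channels.
* A compartment-labeled proteome (GO cellular-component terms with
  sampling weights).

Post-identification evidence only: no spectra, m/z, retention times,
decoys or isotope impurities are simulated.

Defaults approximate the scale of a two-cell-line prostate-cancer
succinylome screen: ~3000 quantified proteins, ~450 Ksu sites, 6.5%
differential proteins (about one in five of them up), 35.5% of sites
up-regulated with down-regulation rare.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from succinylome.io_formats import (
    AnnotationSet,
    EvidenceRow,
    Proteome,
    write_annotations,
    write_evidence,
    write_fasta,
)
from succinylome.sitemap import KsuSiteKey, PeptideIndex

# UniProt-average amino-acid frequencies (percent)
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_FREQ = np.array(
    [8.25, 1.37, 5.45, 6.75, 3.86, 7.07, 2.27, 5.96, 5.84, 9.66,
     2.42, 4.06, 4.70, 3.93, 5.53, 6.56, 5.34, 6.87, 1.08, 2.92]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

PEPTIDE_LEN_RANGE = (7, 25)

# direction splits within the differential classes, fixed study-like
# constants: roughly one DEP in five is up-regulated, and down-regulated
# sites are rare (order one in several hundred quantified sites).
DEP_UP_SHARE = 36 / 194
SITE_DOWN_RATE = 1 / 406

# magnitude ranges (log2) for differential vs null items
_DIFF_MAG = (1.3, 2.8)
_NULL_SIGMA = 0.3
_NULL_CLIP = 0.8

DEFAULT_COMPARTMENTS = (
    ("cytoplasm", 0.34),
    ("mitochondrion", 0.22),
    ("nucleus", 0.16),
    ("extracellular exosome", 0.12),
    ("plasma membrane", 0.08),
    ("extracellular matrix", 0.03),
    ("mitochondrial matrix", 0.03),
    ("mitochondrial inner membrane", 0.02),
)


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design knobs for the synthetic generator.

    noise_sigma and replicate_sigma are in log2 units; base_intensity in
    arbitrary MS intensity units.
    """

    n_proteins: int = 2958
    protein_length_range: tuple[int, int] = (50, 600)
    frac_dep: float = 0.065
    frac_site_up: float = 0.355
    sites_per_protein: float = 0.22
    peptides_per_protein: float = 5.0
    evidence_per_peptide: float = 2.0
    noise_sigma: float = 0.2
    replicate_sigma: float = 0.1
    base_intensity: float = 1.0e6
    compartments: tuple[tuple[str, float], ...] = DEFAULT_COMPARTMENTS
    missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError(f"n_proteins must be >= 1, got {self.n_proteins}")
        lo, hi = self.protein_length_range
        if lo < 10 or hi < lo:
            raise ConfigError(f"protein_length_range invalid: {self.protein_length_range}")
        for name in ("frac_dep", "frac_site_up", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        for name in ("noise_sigma", "replicate_sigma", "sites_per_protein",
                     "peptides_per_protein", "evidence_per_peptide"):
            v = getattr(self, name)
            if v < 0:
                raise ConfigError(f"{name} must be >= 0, got {v}")
        if self.base_intensity <= 0:
            raise ConfigError(f"base_intensity must be > 0, got {self.base_intensity}")
        if not self.compartments:
            raise ConfigError("compartments must be non-empty")
        if any(w < 0 for _, w in self.compartments) or sum(w for _, w in self.compartments) <= 0:
            raise ConfigError("compartments weights must be non-negative with positive sum")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the dataset for recovery tests."""

    protein_log2: dict[str, float] = field(default_factory=dict)
    site_log2: dict[KsuSiteKey, float] = field(default_factory=dict)
    dep_flags: dict[str, str] = field(default_factory=dict)
    site_flags: dict[KsuSiteKey, str] = field(default_factory=dict)
    compartment: dict[str, frozenset[str]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "protein_log2": {p: v for p, v in sorted(self.protein_log2.items())},
            "site_log2": {f"{s.protein_id}:{s.position}": v for s, v in sorted(self.site_log2.items())},
            "dep_flags": {p: v for p, v in sorted(self.dep_flags.items())},
            "site_flags": {f"{s.protein_id}:{s.position}": v for s, v in sorted(self.site_flags.items())},
            "compartment": {p: sorted(ts) for p, ts in sorted(self.compartment.items())},
        }


@dataclass
class Dataset:
    """In-memory synthetic study plus the file names used on disk."""

    proteome: Proteome
    annotations: AnnotationSet
    evidence: dict[tuple[str, int], list[EvidenceRow]]  # (experiment, replicate) -> rows
    truth: SyntheticTruth
    config: GeneratorConfig

    def all_evidence(self) -> list[EvidenceRow]:
        out: list[EvidenceRow] = []
        for key in sorted(self.evidence):
            out.extend(self.evidence[key])
        return out


def tryptic_digest(seq: str, blocked: frozenset[int] = frozenset()) -> list[tuple[int, str]]:
    """In-silico trypsin digestion: cleave after K/R unless the next
    residue is P or the K/R position (0-based) is blocked (succinylated
    lysine resists trypsin). Returns (0-based start, peptide) fragments
    covering the sequence with no length filter.
    """
    frags: list[tuple[int, str]] = []
    start = 0
    for i, aa in enumerate(seq):
        if aa in "KR" and i + 1 < len(seq) and seq[i + 1] != "P" and i not in blocked:
            frags.append((start, seq[start : i + 1]))
            start = i + 1
    if start < len(seq):
        frags.append((start, seq[start:]))
    return frags


def _truth_counts(flags: dict) -> dict[str, int]:
    return {
        "up": sum(1 for v in flags.values() if v == "up"),
        "down": sum(1 for v in flags.values() if v == "down"),
        "unchanged": sum(1 for v in flags.values() if v == "unchanged"),
    }


def truth_summary(truth: SyntheticTruth) -> dict:
    """Exhaustive counts over the truth table; the counts partition it."""
    return {
        "n_proteins": len(truth.protein_log2),
        "n_sites": len(truth.site_log2),
        "protein_flags": _truth_counts(truth.dep_flags),
        "site_flags": _truth_counts(truth.site_flags),
    }


def _sample_protein_truth(rng: np.random.Generator, cfg: GeneratorConfig, n: int):
    is_dep = rng.random(n) < cfg.frac_dep
    is_up = rng.random(n) < DEP_UP_SHARE
    mag = rng.uniform(*_DIFF_MAG, size=n)
    null = np.clip(rng.normal(0.0, _NULL_SIGMA, size=n), -_NULL_CLIP, _NULL_CLIP)
    log2 = np.where(is_dep, np.where(is_up, mag, -mag), null)
    flags = np.where(is_dep, np.where(is_up, "up", "down"), "unchanged")
    return log2, flags


def _sample_site_truth(rng: np.random.Generator, cfg: GeneratorConfig) -> tuple[float, str]:
    u = rng.random()
    if u < cfg.frac_site_up:
        return float(rng.uniform(*_DIFF_MAG)), "up"
    if u < cfg.frac_site_up + SITE_DOWN_RATE:
        return float(-rng.uniform(*_DIFF_MAG)), "down"
    return float(np.clip(rng.normal(0.0, _NULL_SIGMA), -_NULL_CLIP, _NULL_CLIP)), "unchanged"


def _intensity_pair(
    rng: np.random.Generator, cfg: GeneratorConfig, true_log2: float
) -> tuple[float | None, float | None]:
    # the fold change splits symmetrically between the two channels
    nl = rng.normal(0.0, cfg.noise_sigma) if cfg.noise_sigma > 0 else 0.0
    nh = rng.normal(0.0, cfg.noise_sigma) if cfg.noise_sigma > 0 else 0.0
    lo = cfg.base_intensity * 2.0 ** (-true_log2 / 2 + nl)
    hi = cfg.base_intensity * 2.0 ** (true_log2 / 2 + nh)
    miss_l = cfg.missing_rate > 0 and rng.random() < cfg.missing_rate
    miss_h = cfg.missing_rate > 0 and rng.random() < cfg.missing_rate
    return (None if miss_l else lo, None if miss_h else hi)


def generate_dataset(config: GeneratorConfig, out_dir: str | Path | None = None) -> Dataset:
    """Generate one complete synthetic study.

    Returns the in-memory dataset; when ``out_dir`` is given, also
    writes proteome.fasta, annotations.tsv, the four evidence tables
    (evidence_{proteome,enriched}_rep{1,2}.tsv) and truth.json. The same
    config and seed always produce byte-identical files.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    ids = [f"P{i:05d}" for i in range(1, n + 1)]

    # --- sequences ---------------------------------------------------
    lo, hi = cfg.protein_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    aa = np.array(list(_AA))
    seqs = {
        pid: "".join(rng.choice(aa, size=int(L), p=_AA_FREQ)) for pid, L in zip(ids, lengths)
    }
    proteome = Proteome(seqs)
    index = PeptideIndex(proteome)

    # --- compartments ------------------------------------------------
    labels = [c for c, _ in cfg.compartments]
    weights = np.array([w for _, w in cfg.compartments], float)
    weights /= weights.sum()
    compartment: dict[str, frozenset[str]] = {}
    for pid in ids:
        terms = {labels[int(rng.choice(len(labels), p=weights))]}
        if rng.random() < 0.2:  # some proteins annotate to two compartments
            terms.add(labels[int(rng.choice(len(labels), p=weights))])
        compartment[pid] = frozenset(terms)
    annotations = AnnotationSet(dict(compartment))

    # --- protein truth -----------------------------------------------
    p_log2, p_flags = _sample_protein_truth(rng, cfg, n)
    truth = SyntheticTruth(
        protein_log2={pid: float(v) for pid, v in zip(ids, p_log2)},
        dep_flags={pid: str(f) for pid, f in zip(ids, p_flags)},
        compartment=compartment,
    )

    # --- peptide pools and sites -------------------------------------
    # proteome-run pool: unique tryptic peptides of usable length
    pmin, pmax = PEPTIDE_LEN_RANGE
    proteome_pool: dict[str, list[str]] = {}
    for pid in ids:
        pool = [
            pep
            for _, pep in tryptic_digest(seqs[pid])
            if pmin <= len(pep) <= pmax and len(index.occurrences(pep, limit=2)) == 1
        ]
        proteome_pool[pid] = pool

    # sites: Poisson count per protein, placed on lysines whose
    # succinylation-blocked peptide is usable and unique; sites sharing
    # one enriched peptide share one truth value (the peptide is the
    # quantified unit)
    site_peptides: dict[str, list[tuple[int, str, tuple[int, ...]]]] = {}
    for pid in ids:
        if not proteome_pool[pid]:
            continue  # protein invisible to the proteome run: carries no sites
        seq = seqs[pid]
        k_pos = [i for i, c in enumerate(seq) if c == "K" and i + 1 < len(seq)]
        n_sites = int(rng.poisson(cfg.sites_per_protein))
        if n_sites == 0 or not k_pos:
            continue
        chosen = sorted(
            int(k_pos[j]) for j in rng.choice(len(k_pos), size=min(n_sites, len(k_pos)), replace=False)
        )
        frags = tryptic_digest(seq, blocked=frozenset(chosen))
        kept: list[tuple[int, str, tuple[int, ...]]] = []
        for start, pep in frags:
            in_pep = [p for p in chosen if start <= p < start + len(pep)]
            if not in_pep:
                continue
            if not (pmin <= len(pep) <= pmax):
                continue
            if len(index.occurrences(pep, limit=2)) != 1:
                continue
            # positions as 1-based protein coordinates
            kept.append((start, pep, tuple(p + 1 for p in in_pep)))
        if kept:
            site_peptides[pid] = kept
            for start, pep, positions in kept:
                s_log2, s_flag = _sample_site_truth(rng, cfg)
                for pos in positions:
                    key = KsuSiteKey(pid, pos)
                    assert seq[pos - 1] == "K"
                    truth.site_log2[key] = s_log2
                    truth.site_flags[key] = s_flag

    # --- evidence emission -------------------------------------------
    evidence: dict[tuple[str, int], list[EvidenceRow]] = {
        ("proteome", 1): [], ("proteome", 2): [], ("enriched", 1): [], ("enriched", 2): [],
    }
    for rep in (1, 2):
        for pid in ids:
            pool = proteome_pool[pid]
            if not pool:
                continue
            dp = rng.normal(0.0, cfg.replicate_sigma) if cfg.replicate_sigma > 0 else 0.0
            t_prot = truth.protein_log2[pid] + dp
            n_pep = max(1, int(rng.poisson(cfg.peptides_per_protein)))
            n_pep = min(n_pep, len(pool))
            picked = [pool[j] for j in sorted(rng.choice(len(pool), size=n_pep, replace=False))]
            for pep in picked:
                for _ in range(max(1, int(rng.poisson(cfg.evidence_per_peptide)))):
                    L, H = _intensity_pair(rng, cfg, t_prot)
                    evidence[("proteome", rep)].append(
                        EvidenceRow(pep, (), L, H, rep, "proteome")
                    )
            for start, pep, positions in site_peptides.get(pid, []):
                ds = rng.normal(0.0, cfg.replicate_sigma) if cfg.replicate_sigma > 0 else 0.0
                t_site = t_prot + truth.site_log2[KsuSiteKey(pid, positions[0])] + ds
                mods = tuple((pos - start, "su") for pos in positions)
                for _ in range(max(1, int(rng.poisson(cfg.evidence_per_peptide)))):
                    L, H = _intensity_pair(rng, cfg, t_site)
                    evidence[("enriched", rep)].append(
                        EvidenceRow(pep, mods, L, H, rep, "enriched")
                    )

    ds = Dataset(proteome, annotations, evidence, truth, cfg)
    if out_dir is not None:
        write_dataset(ds, out_dir)
    return ds


def dataset_filenames() -> dict[str, str]:
    return {
        "fasta": "proteome.fasta",
        "annotations": "annotations.tsv",
        "truth": "truth.json",
        **{
            f"evidence_{exp}_rep{rep}": f"evidence_{exp}_rep{rep}.tsv"
            for exp in ("proteome", "enriched")
            for rep in (1, 2)
        },
    }


def write_dataset(ds: Dataset, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = dataset_filenames()
    written = []
    write_fasta(ds.proteome, out_dir / names["fasta"])
    written.append(out_dir / names["fasta"])
    write_annotations(ds.annotations, out_dir / names["annotations"])
    written.append(out_dir / names["annotations"])
    for (exp, rep), rows in sorted(ds.evidence.items()):
        p = out_dir / names[f"evidence_{exp}_rep{rep}"]
        write_evidence(rows, p)
        written.append(p)
    with open(out_dir / names["truth"], "w") as fh:
        json.dump(ds.truth.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(out_dir / names["truth"])
    return written


def load_truth(path: str | Path) -> SyntheticTruth:
    with open(path) as fh:
        raw = json.load(fh)

    def _key(s: str) -> KsuSiteKey:
        pid, pos = s.rsplit(":", 1)
        return KsuSiteKey(pid, int(pos))

    return SyntheticTruth(
        protein_log2=dict(raw["protein_log2"]),
        site_log2={_key(k): v for k, v in raw["site_log2"].items()},
        dep_flags=dict(raw["dep_flags"]),
        site_flags={_key(k): v for k, v in raw["site_flags"].items()},
        compartment={p: frozenset(ts) for p, ts in raw["compartment"].items()},
    )


def config_to_dict(cfg: GeneratorConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["protein_length_range"] = list(cfg.protein_length_range)
    d["compartments"] = [[c, w] for c, w in cfg.compartments]
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    if "protein_length_range" in d:
        d["protein_length_range"] = tuple(d["protein_length_range"])
    if "compartments" in d:
        d["compartments"] = tuple((c, float(w)) for c, w in d["compartments"])
    return GeneratorConfig(**d)
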