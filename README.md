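# succinylome

Quantitative analysis of lysine succinylation (Ksu) from SILAC
proteomics: from peptide-level heavy/light evidence to
protein-normalized succinylation-site ratios, differential calls at a
two-fold threshold, and localization-filtered candidate substrates.

## The problem

In a SILAC experiment two cell populations are labeled with light
(K0R0) or heavy (K8R10) amino acids, mixed, digested with trypsin and
measured by LC-MS/MS; the H/L intensity ratio of each peptide measures
relative abundance between the conditions. To study succinylation, a
second aliquot of the digest is enriched with an anti-succinyl-lysine
antibody so that modified peptides become observable. The quantity of
biological interest for a site is not its raw H/L ratio — which mixes
abundance change with modification change — but the **protein-normalized
site ratio**

```
log2 FC(site) = log2( site H/L ) − log2( protein H/L )
```

which isolates the change in modification stoichiometry. Sites whose
normalized ratio exceeds two-fold (strictly, |log2 FC| > 1) are called
differential, and up-regulated sites on extracellular or cytoplasmic —
but not mitochondrial — proteins are retained as candidate substrates
of a cytosolic desuccinylase such as SIRT5.

This package implements that pipeline for generic evidence tables, plus
a synthetic-data generator with known ground truth so every stage is
testable without any raw mass-spectrometry download.

## What it does

| module | role |
| --- | --- |
| `synthetic_data` | generate a full synthetic study (FASTA, annotations, 4 evidence tables, truth) with tryptic digestion and succinylation-blocked cleavage |
| `io_formats` | strict readers/writers for FASTA, evidence TSV, annotation TSV, result tables |
| `sitemap` | exact-substring placement of peptides, Ksu-site coordinates (1-based, e.g. K118) |
| `quant` | median H/L ratios per replicate at protein and site level |
| `normalize` | protein-level normalization, run centering, replicate merging, Pearson/overlap QC |
| `differential` | strict 2-fold classification (up/down/unchanged) and summary fractions |
| `candidates` | GOCC compartment distributions and the extracellular/cytoplasm-minus-mitochondrion filter cascade |
| `cli` | `succinylome generate | run | report` |

## Worked example

```bash
python analysis/01_simulate.py --seed 1     # synthetic study -> results/dataset/
python analysis/02_run_pipeline.py          # full analysis   -> results/run/
python analysis/03_differential.py
python analysis/04_candidates.py
python analysis/05_recovery_benchmarks.py --seed 1
```

With seed 1 this prints (abridged):

```
2958 proteins (38 up, 145 down), 406 Ksu sites (139 up), 62369 evidence rows
quantified 2952 proteins; identified 406 Ksu sites, quantified 404
replicate Pearson r: proteins 0.93, Ksu sites 0.95
proteins: 2952 quantified, 184 (6.2%) DEPs (39 up / 145 down)
Ksu sites: 406 identified, 404 quantified, 142 differential of which 138 up (34.2% of quantified sites)
zero-noise: max |site error| = 6.66e-16 log2 units, call agreement 1.000 over 148 sites
noisy: site RMSE 0.150 log2, up-recall 1.000, false-up rate 0.0000 over 217 sites
```

Reading: of ~3000 quantified proteins only ~6% change at the protein
level, while ~35% of quantified Ksu sites increase — the modification
changes far more than the proteome, which is exactly the contrast the
design is meant to expose. The benchmark lines show the pipeline
returns ground truth exactly when noise is zero, and keeps essentially
perfect up-site recall at a realistic noise level (log-normal channel
noise of 0.2 log2 units).

The same pipeline runs from the shell on any conforming inputs:

```bash
succinylome generate --out data/ --seed 7
succinylome run --fasta data/proteome.fasta \
    --evidence data/evidence_proteome_rep1.tsv --evidence data/evidence_proteome_rep2.tsv \
    --evidence data/evidence_enriched_rep1.tsv --evidence data/evidence_enriched_rep2.tsv \
    --annotations data/annotations.tsv --out out/
succinylome report --out out/
```

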