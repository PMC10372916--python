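# Methods

## Quantification model

Each evidence row is one quantified observation of a peptide in one
replicate of one experiment (whole-proteome or Ksu-IP-enriched), with
light and heavy channel intensities. The pipeline computes, per
replicate:

* **evidence ratio** r = I_H / I_L, defined only when both channels are
  present and positive. An intensity of 0 is treated as missing — MS
  non-detection, not a measured zero — which avoids zero/infinite
  ratios.
* **protein ratio** = median evidence ratio of the protein's uniquely
  mapped, unmodified peptides from the whole-proteome run. The median
  (not the mean) is used because SILAC evidence ratios are roughly
  log-normal with occasional outliers; this is standard practice.
  Enriched-run intensities are never used as protein denominators (IP
  biases them), and succinylated peptides seen in the proteome run are
  excluded from protein quantification for the same consistency reason.
* **site ratio** = median evidence ratio over enriched rows covering
  the site. A peptide with k succinyl mods contributes to k sites; when
  several sites share one peptide they share one measured ratio, because
  the peptide — not the residue — is the quantified unit.
* **normalized site value** = log2(site ratio) − log2(protein ratio),
  per replicate; replicates are merged by the arithmetic mean of the
  available values ("either replicate" quantification, which maximizes
  coverage and naturally reproduces identified > quantified attrition).
  A quantified site with no protein denominator in any replicate is
  retained with its raw log2 value and flagged `unnormalized` rather
  than silently dropped.

**Run centering.** Optionally (default on), the per-replicate median of
protein log2 ratios is subtracted from all log2 ratios of that
replicate, removing global labeling/mixing bias. It is isolated in one
operation and configurable because normalized site values are invariant
to it (the shift cancels in the site − protein subtraction); only raw
protein log2 values are affected. Recovery benchmarks that compare
protein estimates against simulation truth therefore run with centering
off.

**Classification.** call = up if log2FC > t, down if log2FC < −t, else
unchanged, with t = 1 (two-fold) by default and strict inequalities: a
ratio of exactly 2 is *not* "more than two times" and stays unchanged.
No p-values or FDR are computed — the design thresholds fold change
only, which is the appropriate choice for n = 2 biological replicates.
Percentages are rounded to one decimal, half away from zero; note that
194/2958 = 6.557% rounds to 6.6 under this convention but truncates to
6.5, so consumers comparing against truncated reports should allow
±0.1 percentage point.

**Site mapping.** Peptides are placed by exact substring search against
the full protein database (an occurrence index over the concatenated
proteome; verified in tests against a brute-force per-protein scan).
Only peptides with exactly one placement yield sites; shared peptides
are dropped rather than resolved by razor-protein logic, a conservative
choice that cannot mis-assign a site. I and L are distinct. Coordinates
are 1-based: a peptide starting at 0-based protein offset o with a mod
at 1-based peptide offset m marks residue o + m (the immunogen-peptide
worked example places its succinyl-K at residue 118).

**QC.** Replicate reproducibility is reported as Pearson correlation of
log2 raw H/L ratios over items quantified in both replicates (raw, not
normalized, ratios — the conventional labeling-ratio QC), and as
overlap percent 100·|both|/|either| for Ksu proteins and Ksu sites.
Undefined correlations (fewer than two common items, zero variance) are
reported as null, never 0, since 0 is a meaningful value.

## Candidate filter

Up-regulated sites pass a two-stage GO cellular-component cascade:
stage 1 keeps sites on proteins annotated with an extracellular term
(default: extracellular exosome, extracellular matrix) and no exclude
term; stage 2 keeps sites on cytoplasm-annotated proteins; the final
table is the union of the stages restricted to proteins without any
exclude term (default: mitochondrion, mitochondrial matrix,
mitochondrial inner membrane). Exclusion dominates: a protein annotated
both cytoplasm and mitochondrion is vetoed. The filter spec holds the
three term sets separately (rather than one flat include set) because
the two inclusion stages are reported separately; the union is still
checked for disjointness against the exclude set. Term matching is
exact string on normalized (lower-case, trimmed) labels: the annotation
table is expected to carry already-mapped compartment labels, and GO
DAG expansion is deliberately out of scope.

Compartment distributions assign each protein to the first matching
compartment of an ordered list (mutually exclusive pie-style bins,
order configurable); unmatched proteins pool into "other".

Candidate proteins are ranked by (number of up-sites desc, max merged
log2 desc, id asc) — a deterministic ordering for manual triage.

## Synthetic-data generator

The generator emulates a two-cell-line, two-biological-replicate SILAC
succinylome screen: heavy = the aggressive line, ratio convention H/L.

* **Sequences**: random proteins with UniProt-average amino-acid
  composition, lengths uniform in 50–600 residues.
* **Digestion**: in-silico trypsin (cleave after K/R, not before P),
  peptides of length 7–25. Succinylation blocks trypsin at the modified
  lysine, so enriched peptides are generated from a digest with
  cleavage suppressed at succinylated positions — each Ksu site sits
  internally in its peptide with one forced missed cleavage, as in real
  enrichment data. No other missed-cleavage modeling.
* **Truth**: protein log2 ratios are differential with probability
  `frac_dep` (magnitude uniform in 1.3–2.8 log2, about one in five up,
  the rest down) and otherwise null (normal, sd 0.3, clipped at ±0.8).
  Site (protein-normalized) log2 ratios are sampled independently of
  the host protein — the normalized stoichiometry change is the signal
  of interest — up with probability `frac_site_up`, down rarely
  (~1/400), otherwise null as above.
* **Intensities**: I_L = B·2^(−t/2+ε), I_H = B·2^(+t/2+ε′) with t the
  replicate-level true log2 ratio (truth plus a per-replicate shift of
  sd `replicate_sigma`), B = `base_intensity`, and ε, ε′ independent
  normal with sd `noise_sigma` (log2 units) — multiplicative log-normal
  channel noise. Each channel is independently missing with probability
  `missing_rate`.
* **Compartments**: each protein draws one (sometimes two) GOCC labels
  from a weighted list spanning cytoplasm, mitochondrion (plus matrix /
  inner membrane), nucleus, extracellular exosome/matrix and plasma
  membrane.

Defaults are the study-scale conditions: 2958 proteins, `frac_dep`
0.065, `frac_site_up` 0.355, noise sd 0.2, replicate shift sd 0.1,
missing rate 0.1 (reproducing roughly the observed
identified-vs-quantified site attrition), mean 5 peptides/protein and 2
evidence rows/peptide. `sites_per_protein` (Poisson mean 0.22 across
all proteins) is set so that roughly 450 sites survive the
peptide-length and uniqueness filters. Same config + seed gives
byte-identical output files (floats serialized with `repr` so values
round-trip exactly).

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: spectrum-level effects (m/z,
retention time, identification FDR, isotope impurity), peptide-level
detectability bias, correlated site clustering within proteins (sites
are Poisson across all proteins rather than concentrated on a small
Ksu subpopulation), replicate-level *detection* dropout (missingness is
per channel, so replicate overlap in synthetic data is near 100%,
unlike real enrichment runs), and any correlation between compartment
and regulation. Results on real evidence tables depend on upstream
search quality, which is entirely out of scope here.

## Numerical and design choices

* Evidence, protein and site aggregation is order-independent (median)
  and tested as such; candidate ranking breaks ties lexicographically.
* Benchmark problem sizes — 200 proteins for the zero-noise limit, 300
  proteins with mean 4 evidence rows per peptide for the noisy
  benchmark, full 2958-protein scale for the default study — are the
  package's standard configurations for these checks and run in well
  under a minute each.
* Undefined percentages (zero denominators) are null, not 0.
* The filter cascade's union rule (extracellular ∪ cytoplasmic, minus
  exclude-annotated proteins) is one consistent reading of staged
  localization selection; it is isolated behind `FilterSpec` so
  alternative set algebras are directly testable.
* Replicate-overlap arithmetic on externally reported counts
  occasionally exposes inconsistent totals (e.g. a site total printed
  two ways); the QC operation exposes raw intersection/union counts so
  any such discrepancy can be audited rather than hidden.

## Known limitations

* No localization-probability scoring of the modified residue; the
  pipeline trusts upstream site assignments (off-lysine assignments are
  rejected at parse time with a counted warning).
* No shared-peptide (razor) assignment; shared peptides are discarded.
* Fold-change-only differential calling — no variance model, by design.
* MaxQuant-style evidence dialects are not parsed directly; inputs must
  follow the documented TSV schema (a thin column-mapping step upstream
  of `read_evidence` suffices).
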