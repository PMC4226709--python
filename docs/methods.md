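# Methods

This document specifies the statistical conventions of each pipeline stage,
the synthetic-data model, and the reasoning behind the non-obvious design
decisions. Everything here is implemented in `src/lncomat/` and exercised by
the property-based test suite.

## 1. Input formats and conventions

- **Expression matrix** (`formats.read_expression`): TSV, features × samples,
  log2-scale intensities, finite values only. An optional reserved `biotype`
  column labels each feature `mRNA` or `lncRNA` (default `mRNA`). The sample
  sheet (TSV) has columns `sample`, `patient`, `tissue` (`N`/`T`), `size`
  (`S`/`L`/`NA`); the size class `NA` marks normal tissue and is read as the
  literal string, never as missing data.
- **Annotation**: GTF (1-based closed intervals on disk) or BED12 (0-based
  half-open, exon structure from block sizes/starts, biotype carried in a
  13th-column `biotype=` tag). Internally all coordinates are 0-based
  half-open. Parsers validate strand, interval non-emptiness, and exon
  ordering, and fail loudly on malformed input.
- **Gene sets**: GMT (`name<TAB>description<TAB>member...`), members
  de-duplicated preserving order.

## 2. Quantile normalization

Standard rank-mean quantile normalization: sort each column, average across
columns at each rank to form the reference distribution, then assign each
value the reference value of its within-column rank. Ties receive the mean of
the reference values of their tied ranks (the "average rank" rule), so the
procedure is exactly idempotent and post-normalization column value multisets
are identical to within floating-point error.

## 3. Paired differential expression

Contrasts are defined per tumor size class against each patient's matched
normal sample: for feature *g* and size class *c*, the per-patient difference
is `d_i = tumor_i − normal_i` on the log2 scale, so

- `log2FC = mean(d)`, and
- the paired t statistic is `t = mean(d) / (sd(d)/√n)` with `df = n − 1`,
  two-sided p from the t distribution.

A feature is called dysregulated when **|log2FC| ≥ log2(threshold)**
(inclusive; default threshold = 2, i.e. two-fold) **and p < α** (strict;
default α = 0.05). Raw p-values are the default, matching common microarray
practice at small n; `adjust="bh"` applies Benjamini–Hochberg per contrast.
Degenerate features (zero variance of differences) are flagged: all-zero
differences get `t = 0, p = 1`; constant non-zero differences get a signed
infinite t and the smallest positive double as p.

Downstream summaries:

- **Venn partition** of the S and L calls into `S_only_up/down`,
  `L_only_up/down`, `both_up/down`, `discordant` (opposite directions — kept
  separate rather than silently merged), and `uncalled`.
- **Signature sets**: set 1 (mRNA) / set 3 (lncRNA) = called in L only;
  set 2 (mRNA) / set 4 (lncRNA) = called in L with the same direction in S
  and |log2FC_L| − |log2FC_S| ≥ 1 ("more dramatic in large tumors"). Sets 1
  and 2 are not mutually exclusive.

## 4. Genomic-context classification of lncRNAs

Each lncRNA receives exactly one of six subtypes by a priority cascade
(first match wins), evaluated against every annotated coding gene on the same
chromosome:

1. **exon sense-overlapping** — overlaps an exon, same strand;
2. **intron sense-overlapping** — contained in an intron, same strand;
3. **natural antisense** — overlaps an exon, opposite strand;
4. **intronic antisense** — contained in an intron, opposite strand;
5. **bidirectional** — no overlap, divergent head-to-head orientation with a
   TSS-to-TSS gap ≤ 1000 bp (TSS = interval start on `+`, interval end on
   `-`; divergent means the `-` partner lies upstream of the `+` partner);
6. **intergenic** — none of the above.

When several genes satisfy the winning rule, the partner is the gene with the
largest overlap, then the smallest TSS gap, then the lexicographically
smallest id — fully deterministic. **Cis pairs** (lncRNA, partner mRNA) are
formed for every subtype except intergenic (no partner) and exon
sense-overlapping (same-strand exonic overlap is more likely a transcript
isoform or annotation artifact than cis regulation, and on single-channel
arrays its correlation is confounded by probe cross-hybridization).

The implementation uses an interval tree per chromosome (neighborhood widened
by the bidirectional window); the test suite proves exact agreement with a
brute-force all-pairs reimplementation of the rules above on hundreds of
random adversarial genomes.

## 5. Co-expression matrix, trichotomization, relevance

Pearson correlations are computed between every dysregulated mRNA (rows) and
dysregulated lncRNA (columns) across all samples (optionally tumor samples
only); at least 3 samples are required, and zero-variance features yield an
explicit NaN ("undefined") rather than a silent 0. The matrix is
**trichotomized** with a strict cutoff: `+1` if r > 0.8, `−1` if r < −0.8,
else `0`. The **relevance score** of an mRNA against a designated lncRNA set
is the sum of |r| over the cutoff-passing cells of those columns; mRNAs are
ranked by score with deterministic id-based tie-breaking. Selection is by
top-k or by minimum score.

## 6. Enrichment

Over-representation of a query list in each gene set uses the upper-tail
hypergeometric probability `P(X ≥ k)` for `X ~ Hypergeom(N, K, n)` (universe
size N, set size within the universe K, query size n, overlap k), computed in
log space via `scipy.stats.hypergeom.sf(k−1, N, K, n)`. Sets are intersected
with the universe first; sets with no member in the universe are excluded and
reported. BH q-values are computed over **all tested sets** before any
min-overlap display filter, so hiding rows never changes q-values.

## 7. Cross-dataset comparison

Datasets are compared only on exactly matching gene ids (case/whitespace
canonicalization, no symbol aliasing): (a) the sample × sample Euclidean
distance matrix rescaled by its maximum entry (zero diagonal, max exactly 1),
and (b) the Pearson correlation of per-gene log2 fold changes over the common
gene set.

## 8. Synthetic data generator

### Study design

The default design is **triplet**: each of 5 patients contributes a normal
(`N`), a small-tumor (`S`) and a large-tumor (`L`) sample (15 samples). This
is the minimal design in which both contrasts are paired within patients,
which the paired t-test requires; a **disjoint** design (separate small- and
large-tumor patient groups, each with their own matched normal) is available
for sensitivity analyses.

### Toy genome

Genes occupy fixed, well-separated slots (20 kb slot, 3 kb gene with two
600 bp terminal exons) on a configurable number of chromosomes. Each lncRNA
(400 bp) draws an intended subtype from `subtype_mix` and is placed in a
geometry that realizes that subtype and **no accidental second
relationship**: overlap subtypes sit inside/over a unique host gene,
bidirectional lncRNAs sit divergently 300 bp from a host TSS, intergenic
lncRNAs sit ≥ 6 kb from any gene. Requests that do not fit raise
`CapacityError` rather than silently degrading the geometry. Problem sizes
(default 300 mRNAs, 120 lncRNAs) are chosen so the full pipeline and its
validation run in seconds on one CPU while keeping every subtype represented
with double-digit counts.

### Expression model

Per feature *g* and sample *s*:

```
x_gs = baseline_g + patient_gp(s) + delta_g(size(s))·1[tumor]
       + Σ_f gamma_gf · factor_fs + eps_gs
```

- `baseline_g ~ U(6, 12)` (log2 intensity scale);
- `patient_gp ~ N(0, patient_sd²)`, shared across one patient's samples
  (induces within-patient correlation, the reason pairing helps);
- `delta_g`: planted mean shift for DE features — direction drawn with the
  biotype's bias (mRNAs mostly down, lncRNAs mostly up), magnitude
  `Gamma(shape=6, scale=effect/6)` so the mean effect is `effect_small` /
  `effect_large` with realistic spread; large-tumor effects are drawn larger
  on average (`effect_large > effect_small`), producing the size-dependent
  increase in dysregulated features;
- `factor_fs ~ N(0, 1)` i.i.d. per sample: one shared latent factor per
  planted cis pair and one for the optional co-expression module;
- `eps_gs ~ N(0, noise_sd²)`.

**Loading calibration.** For two features sharing one factor with loadings
±γ on top of independent variance σ² = patient_sd² + noise_sd², the
population correlation is `±γ²/(γ²+σ²)`. Solving `γ² = σ²·ρ/(1−ρ)` makes the
planted pair correlation exactly the signed target ρ. The sign of each cis
pair is drawn from a per-subtype probability-of-positive profile (default:
intron sense-overlapping overwhelmingly positive, intronic antisense mostly
negative), so the pipeline's cis correlation profile has a recoverable
qualitative signature.

**Module planting.** The optional module (e.g. 30 mRNAs + 10 lncRNAs) shares
a single latent factor with loading solved for `module_rho`; module members
carry **no planted mean shift**, because stacking group-mean structure on top
of the factor would change the population correlation away from the declared
ρ. The factor is honest sample-level biological variation: it also inflates
the paired-difference variance of loaded features, making their DE calls
harder — by design, not by accident.

**Gene sets.** `n_genesets` random mRNA sets of `geneset_size`; the first set
has `enriched_fraction` of its members swapped for planted down-regulated
large-tumor mRNAs, giving a known enrichment target.

**Determinism.** All randomness forks from one seed into named substreams
(`SeedSequence([seed, crc32(name)])`), so output is byte-identical across
runs and enabling one planted feature class never perturbs the draws of
another. Every planted quantity is recorded in a `TruthManifest`
(JSON-serializable, round-trip tested).

## 9. Numerical and engineering choices

- Degenerate statistics are explicit: NaN sentinels for undefined
  correlations, flags for zero-variance t-tests, contract errors (exit code
  4 in the CLI) for empty inputs — never silent zeros.
- Sorting is everywhere stable (mergesort) with deterministic id tie-breaks,
  so all outputs are reproducible byte for byte.
- Parsers for GTF/BED12 are small and hand-rolled: the pipeline needs only
  transcript intervals, strand, biotype and exon blocks, and a ~100-line
  validating parser is easier to audit than a general-purpose genomics
  dependency whose schema assumptions (attribute vocabularies, hierarchy
  reconstruction) exceed this scope.
- Standard statistics come from established libraries (scipy for t/hypergeom
  distributions and linkage, statsmodels for BH); only the conventions
  specific to this pipeline (tie rules, threshold semantics, scoring) are
  implemented directly, and each is pinned by an oracle test.
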