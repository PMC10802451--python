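# Methods

## Scope and model

mutmotif analyzes forward-mutation experiments in haploid microbes: a
mutagen-treated culture is plated on selective medium (canavanine for
the yeast CAN1 reporter), resistant isolates are whole-genome
sequenced, and the analysis asks (i) whether the mutagen raised the
mutation frequency, and (ii) whether the induced mutations carry a
sequence-context signature — here, by default, C→A substitutions at
gCn (mutated base capitalized, n = any base, both strands considered).

The pipeline consumes already-called variants (VCF or TSV), a reference
FASTA, and colony-count tables; alignment and variant calling are out
of scope.

## Variant filtering

Calls are filtered in a fixed order so each removal has exactly one
attributed cause:

1. **non-SNV** — indels/MNVs are set aside; the downstream statistics
   are defined on single-base substitutions;
2. **VAF < 0.90** — a clonal haploid mutation is expected near 100%
   variant allele frequency; the threshold is inclusive (0.90 kept),
   reading "a filter of 90%" as a retention bound;
3. **parent subtraction** — exact (contig, pos, ref, alt) matches to the
   untreated parent culture are pre-existing;
4. **recurrence** — a key seen in ≥ 2 distinct isolates pre-existed in
   the shared culture and is removed from every carrier. Matching is on
   the full key, not position, since two different substitutions at one
   site are independent events. Recurrence is assessed within the
   cohort passed to the operation.

The cascade is idempotent and conserves calls (input = kept + the four
removal buckets, per sample).

## Spectrum

Substitutions are folded onto the pyrimidine strand (G→T ≡ C→A),
giving six classes; per-isolate counts and the cohort arithmetic mean
per isolate are reported, plus an optional 96-channel table keyed by
the reference trinucleotide (pyrimidine-centered; contexts truncated by
contig ends are N-padded and excluded from the 96-channel table).

## Motif enrichment

For motif gCn→A in one sample:

* `m_class` — C→A mutations (both strands);
* `m_motif` — the subset whose strand-aware reference context matches
  the motif (C with 5′ g, or G with 3′ c);
* `x_motif`, `x_class` — double-stranded motif-occurrence and
  class-base counts summed over one ±20 bp window per class mutation,
  **with the mutated position replaced by N** (N matches nothing,
  including "n"); overlapping windows count with multiplicity.

Fold-enrichment `E = (m_motif/m_class) / (x_motif/x_class)`;
significance from a one-sided Fisher's exact test on
`[[m_motif, m_class−m_motif], [x_motif, x_class−x_motif]]`
(alternative: motif over-represented among mutations), computed as the
upper hypergeometric tail; attributable mutation load
`m_motif·(E−1)/E`, floored at 0.

### Why the mutated base is masked

Each window is centered on a mutation, so an unmasked window always
contains that mutation's own context. The denominator then grows with
the numerator and the estimate saturates: for window length L the
largest reportable enrichment is `max_q qL/(q²L+1)` (q = per-base
probability of the motif's context class), about 3.2–3.6 for L = 41
regardless of genome composition. Masking the mutated position keeps
the opportunity set a property of the neighborhood rather than of the
mutation and removes the ceiling. The cost is a small upward bias
(order 1/(L·density), ~5% for gCn in a 38% GC genome) when mutations
fall uniformly, because masking also hides motif occurrences that
overlap the mutated base; the Fisher test absorbs this at realistic
sample sizes, and the synthetic-data calibration (below) accounts for
it exactly.

### Degenerate inputs

`m_class = 0` yields an explicitly flagged undefined result (E, p, load
are NA, not 0 or 1 — absence of class mutations is not evidence).
`x_motif = 0` with `m_motif > 0` flags E as infinite; p is still
computed from the table. Degenerate Fisher tables (any zero margin)
return p = 1.

### Modes and options

Per-sample analysis is the default; pooled mode concatenates a group's
calls into one result for group-level summaries. Optional
Benjamini–Hochberg adjustment across samples (off by default). The
opportunity denominator can alternatively be computed genome-wide
(`context_source="genome"`); windows-only is the default so numerator
and denominator describe the same neighborhoods. Any motif expressible
as one uppercase mutated base plus lowercase IUPAC context (e.g. tCw)
is supported; purine-centered input patterns are folded onto the
pyrimidine strand at construction.

## Plate-assay statistics

* mutation frequency = Can^R per ml / viable per ml;
* viability % = 100 × treated viable titer / untreated viable titer,
  not clamped at 100 (the formula is a plain ratio);
* medians with distribution-free order-statistic CIs: the interval
  (x₍k₎, x₍n−k+1₎) with k the largest integer such that
  2·BinomCDF(k−1; n, ½) ≤ 0.05, conservative coverage ≥ 95% for any
  continuous distribution; for n < 6 no such interval exists and
  (min, max) is returned flagged;
* fold-change = ratio of group medians (medians are what the assay
  figures plot); median-of-paired-ratios is available as an option;
* one-sided Mann-Whitney U (alternative: treated stochastically
  greater). Exact p by full enumeration of the permutation distribution
  of U over all C(n₁+n₂, n₁) group assignments, with midranks for ties,
  whenever that count is ≤ 10⁶ (covers the ≤ ~12-culture groups typical
  of plating assays); otherwise the normal approximation with
  tie-corrected variance and a 0.5 continuity correction. The two
  branches agree to within ~0.008 at 8 vs 8.

## Synthetic data

The generator emulates the experiment end to end, deterministically
under a seed:

* **Genome** — i.i.d. bases with P(G)=P(C)=gc/2; default 38% GC
  (yeast-like). No replication timing, chromatin, or compositional
  heterogeneity: passing tests demonstrate statistical correctness of
  the estimators, not robustness to genomic covariates.
* **Cohorts** — per isolate, a Poisson number of class mutations
  (default mean 200) is placed over the genome's C/G sites by weighted
  sampling without replacement; motif sites carry weight w > 1 chosen
  by calibration (below). Genuine calls get VAF in [0.93, 1.0].
  Planted confounders occupy sites disjoint from genuine calls (and
  genuine sites are unique across isolates by default) so
  filter-accuracy tests are exact: `n_shared` keys duplicated into two
  isolates, `n_parent` keys copied into the parent call set and one
  isolate, `n_low_vaf` sub-threshold artifacts per isolate (VAF
  0.10–0.85). A truth record categorizes every emitted call.
* **Calibration** — the planted weight is derived from the genome
  itself: mean masked-window (motif, class) opportunity counts are
  measured for a subsample of motif-centered and non-motif-centered
  class sites, the motif fraction r among mutations that makes the
  *expected estimate* equal E\* is the root of a quadratic in r, and
  w = r(1−f)/(f(1−r)) with f the genomic motif-site fraction. This
  makes E\* the analytically known expectation of the statistic rather
  than a nominal rate parameter. Because the motif fraction among
  mutations cannot exceed 1, enrichments beyond what the windowed
  statistic can express on the given genome raise an error instead of
  silently truncating.
* **Assays** — per culture, viable titer is log-normal around a nominal
  2×10⁷/ml (scaled by a planted viability), log-sd `dispersion`
  (default 0.3); the Can^R colony count is Poisson with mean
  frequency × viable cells plated, converted back to per-ml titers.
  Culture-to-culture variability is log-normal rather than
  Luria–Delbrück: the pipeline analyzes frequencies, not rates, and
  jackpot modeling is out of scope; heavy tails can be approximated by
  raising the dispersion.

## Problem sizes used in the checks

Parameter recovery uses a 500 kb genome, 100 isolates, 200 class
mutations each at E\* ∈ {1, 2, 5}; filter accuracy a 100 kb genome with
36 isolates; strand symmetry 100 fixtures of 400 bp; assay recovery
1000 regenerations of 6-culture groups; the Fisher and Mann-Whitney
oracles enumerate all tables with margins ≤ 30 and all group sizes
≤ 7 respectively. The acceptance script simulates four 36-isolate
cohorts on a 300 kb genome and 12-culture assays, matching the scale of
the motivating experimental design.

## Known limitations

* The enrichment estimator's masking bias (~+5% at null for dense
  motifs) is documented above; for sparse motifs (e.g. tCw) it is
  negligible.
* The i.i.d. genome model understates opportunity-count variance
  relative to real genomes with compositional structure.
* Mutation frequencies are treated as exchangeable across cultures;
  no Luria–Delbrück rate estimation is provided.
* The VCF reader expects a VAF in FORMAT/FREQ (percent string),
  FORMAT/AF, or INFO/AF; other encodings need the TSV dialect or a
  configured default VAF.
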