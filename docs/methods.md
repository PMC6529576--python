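# Methods

This note describes the models and procedures implemented in `exomeburden`,
their assumptions, the parameters that matter, and the design choices made
where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## 1. The synthetic cohort generator

`exomeburden.simulate` emulates the data structure of a small matched
tumor–normal exome study of an aggressive kidney cancer: a handful of
patients, each contributing one tumor and one normal call set, a binary
vital-status label, somatic SNVs whose trinucleotide spectra follow a
mixture of mutational-signature profiles, germline variation partly shared
across patients, and the artifact classes typical of amplicon semiconductor
sequencing (homopolymer indels, caller quality flags, low-read-support
calls).

### Genome model

`build_toy_exome(n_genes, mean_cds_length, seed)` places `n_genes`
non-overlapping genes on one chromosome of uniform random sequence. CDS
lengths are Poisson around the requested mean in codons (floored at 10
codons, always a multiple of 3); strands are random; genes never touch the
chromosome edges so every coding position has defined 5′/3′ neighbours for
trinucleotide lookup. Genes are pure CDS — no introns or UTRs — because the
downstream computations need only the coding/noncoding distinction and the
synonymous/missense/nonsense triple. Coordinates are stored 0-based
half-open internally and 1-based inclusive in all emitted files (VCF
convention), with explicit converters.

### Cohort configuration (defaults and why)

| parameter | default | rationale |
| --- | --- | --- |
| `n_patients` | 10 | the cohort size of the emulated study design |
| `somatic_rate` | 900 /tumor | puts the cohort somatic load at ~9×10³, the order observed in low-mutation-rate kidney tumors at exome scale; per-patient counts are not otherwise constrained |
| `germline_rate` | 200 /patient | ~2 variants/kb on the ~100 kb toy genome — a density that gives the panel-of-normals stage real work at toy scale |
| `shared_germline_fraction` | 0.5 | half of germline draws come from a cohort-wide pool, so cross-patient germline recurrence (the reason the panel uses *all* normals) actually occurs |
| `mortality_fraction` | 0.4 | 4 of 10 patients deceased, as in the emulated design |
| `exonic_fraction` | 0.54 | somatic exonic placement probability; matches the exonic proportion typical of somatic call sets in this assay class |
| `read_support_mean` | 30 | shifted Poisson 1 + Pois(mean−1), ~30× support |
| `low_support_fraction` | 0.05 | 5% of calls get 1–2 supporting reads, exercising the <3-read filter |
| `artifact_flag_rate` | 0.02 | per-flag per-call probability; ~10% of calls end up carrying ≥1 of the 5 quality flags |
| `homopolymer_indel_rate` | 50 /sample | artifactual indels anchored in runs of ≥4 identical bases, truth-labeled `artifact`; all are removed by the SNV restriction, reproducing the indel wipe-out this filter chain causes |
| `joint_flag_rate` | 0.01 | probability a variant re-acquires a flag in the joint genotyping pass |

Vital status uses a deterministic largest-remainder assignment (patient *i*
is deceased iff ⌊(i+1)f⌋ > ⌊i·f⌋), so any prefix of *n* patients carries
⌊n·f⌋ deceased and adding a patient never relabels an earlier one. All
other randomness is drawn from one stream per patient, derived from the
master seed by fixed offsets; the germline pool and the site partition have
their own streams. Consequently adding a patient leaves earlier patients'
files byte-identical (tested).

### Site partition

A fixed 30% of genome positions is reserved for germline variation and the
remaining 70% for somatic variation. This guarantees a somatic allele can
never coincide with a germline allele of another patient, which makes
panel-of-normals subtraction *exact* at toy scale and lets the test suite
assert zero germline leakage and 100% retention of clean somatic calls.
Real data offer no such guarantee — in a real cohort, somatic alleles that
coincide with germline polymorphisms are lost to the panel — so passing
these tests demonstrates correctness of the filter logic, not the
sensitivity achievable on real data.

### Somatic spectra and burden effects

Each somatic SNV first draws a 96-category from the patient's
exposure-weighted signature mixture, then a genome site whose (pyrimidine-
normalized) reference trinucleotide matches, in the exonic or intergenic
zone per `exonic_fraction`. For deceased patients, exonic sites inside
planted burden genes are up-weighted by the configured multiplier, so a 20×
gene receives ~20× the per-base somatic rate of other genes *within the
fixed per-tumor total*. Because site choice ignores coding consequence,
planted burden effects do not perturb the synonymous/nonsynonymous balance
— the simulated cohorts are neutral by construction, which the dN/dS stage
should (and does) report.

Known departures from real data: no read-level simulation, no base-quality
model, fixed flag probabilities independent of sequence context (except
homopolymer indels), no copy-number or structural variation, and
within-patient somatic sites are drawn without replacement (no multi-hit
sites in one tumor).

## 2. Somatic variant refinement

Stage order is fixed: per-sample flag filter → merge/genotype/re-filter →
panel-of-normals germline subtraction → read-support filter (≥3) → SNV
restriction, then recurrent-variant exclusion for the selection analysis.

The merge step unions all variant keys that survived the per-sample flag
filter in at least one sample and genotypes each key in every sample. When
the pre-filter calls are supplied, genotypes are looked up there — this
models re-genotyping from the reads, and is what keeps a germline variant
visible in its normal tissue when only the normal's call happened to be
flagged (without it, such variants leak into the somatic set; the test
suite pins this behavior). Samples with no call at all get an imputed
hom-ref entry with zero read support; no likelihood recomputation is
attempted because no read data exist. Variants carrying a joint-pass flag
are removed from all samples.

Variant identity is the exact `(chrom, pos, ref, alt)` tuple with no
left-alignment or normalization — sufficient for the simulator, a
documented limitation for real VCFs.

Recurrent exclusion removes allele keys present in more than `max_tumors`
(default 1) patients' somatic sets before dN/dS, since recurrent "somatic"
alleles in a small cohort are overwhelmingly residual germline leakage that
would inflate selection estimates.

## 3. Consequence annotation

Strand-aware codon lookup under the standard nuclear genetic code (NCBI
table 1, via Biopython). Stop-gain is `nonsense`; stop-loss is binned as
`missense` (rare at toy scale; a dedicated category would be constantly
empty). The element vocabulary is `exonic`/`intergenic` only. The test
suite checks the full 90-SNV enumeration of a 30-bp gene against an
independently hand-coded codon table, and strand symmetry against the
reverse-complement construction.

## 4. Burden test, ranking, inflation

Per gene: 2×2 table (variants in gene vs. elsewhere) × (deceased vs.
alive), pooled over patients (cohort-summed allele occurrences; a
presence/absence mode is not provided because at ~10 patients it cannot
produce small p-values, making count pooling the only reading consistent
with the analysis design). Two-sided Fisher exact p uses minimum-likelihood
summation with R's 1e-7 relative tolerance on point-probability ties; this
convention reproduces two-decimal clinical-table p-values (0.05, 1.00) that
the doubling convention does not. The hypergeometric pmf is computed from
log-gamma directly for speed at enumeration scale; the suite cross-checks
against `scipy.stats.fisher_exact` and an exact integer-arithmetic
enumeration oracle.

Ranking is by ascending p with ties broken by descending in-gene count,
then gene id. No multiple-testing adjustment is applied: the list feeds
enrichment and the analysis is explicitly exploratory.

λ is the median of the p-values mapped to upper-tail 1-df χ² quantiles,
divided by the χ²₁ median (≈0.4549364) — the closed-form-testable median
method, no regression variant. Two behaviors are worth knowing. First,
with planted effects λ rises far above 1; that is signal, not
miscalibration. Second, exact-test p-values are discrete and conservative,
so λ sits *below* 1 when per-gene counts are small; at the default cohort
scale (~90 variants per gene) the 20-seed average λ on null cohorts is
within [0.8, 1.25] (tested), but on much sparser count tables the median
method will under-shoot — a property of exact tests, not an implementation
artifact.

QQ coordinates pair −log₁₀ of the k/(n+1) uniform order statistics with
−log₁₀ of the sorted observed p.

The external validation mode applies the identical 2×2 construction and
test to a user-supplied per-gene count table (deceased/alive counts plus
group totals), flagging genes at nominal 0.05.

## 5. dN/dS with trinucleotide-context correction

Opportunities: every coding position contributes its 3 possible single-base
changes, each classified (synonymous/missense/nonsense) by codon table and
binned by the 96 pyrimidine-normalized context classes; conservation
(Σ opportunities = 3 × coding bases) is asserted and tested.

Rates: per-class synonymous rate = observed synonymous count / synonymous
opportunities. Classes with fewer than `min_obs` (default 5) observed
synonymous mutations share a pooled rate within their 6-type substitution
group. Pooling all 96 classes down to 6 types whenever any class is sparse
would erase exactly the context structure (e.g. CpG C>T enrichment) the
correction exists for, so the pooling is hierarchical and deterministic;
the number of pooled classes is recorded in the estimate.

Point estimates: ω_mis = N_mis/E[N_mis] and ω_trunc = N_non/E[N_non] with
E[·] = Σ_c rate_c × opportunities_c. The combined exome-wide ω, its
neutrality test and 95% CI come from a joint Poisson profile likelihood —
synonymous counts S_g ~ Pois(μ_g O^syn_g), nonsynonymous N_g ~
Pois(ω μ_g O^non_g), with the nuisance rates μ_g profiled out analytically.
Treating the synonymous-derived expectation as fixed (a plain one-sample
Poisson test) ignores the 1/S variance component and visibly over-rejects
under neutrality; the profile form is calibrated (≤10% rejections at α=0.05
over 20 neutral seeds, tested). Per-gene estimates reuse the exome-wide
rates as fixed against gene-local opportunities (each gene is a small
fraction of the exome, so rate uncertainty is second-order there); genes
with zero observed substitutions are reported as undefined, never 0/0.

This is deliberately not a covariate model: no gene-level negative-binomial
dispersion, no expression/replication-timing covariates. It supports the
two conclusions such an analysis draws at this scale — an exome-wide ratio
with a neutrality test, and per-gene screening.

Sampling note for the neutral benchmark: a single n=2,000 uniform draw
gives the exome-wide ratio a standard deviation of ≈0.05 (the 1/S and 1/N
Poisson terms), so the acceptance check and `scripts/acceptance.py`
evaluate the mean of three replicate draws; the estimand is unchanged.

## 6. Mutational signatures

Spectra: SNVs are binned by (pyrimidine substitution type, 5′ base, 3′
base), reverse-complementing purine-reference records; row order is
lexicographic by (substitution, 5′, 3′) and written in every catalog and
spectrum file header column.

Fitting: exposures of a fixed catalog maximize the multinomial likelihood
over the simplex via EM (update e_k ∝ e_k Σ_i x_i S_ik / (Se)_i), which is
monotone in likelihood and derivative-free; convergence at max-change
<1e-8 or 10⁴ iterations; weights below 1e-6 are snapped to zero.
Uncertainty: percentile intervals over ≥1,000 multinomial resamples of the
spectrum, refit from a warm start.

Select-and-refit: stage 1 fits the full catalog; a signature is selected
iff its bootstrap lower bound is strictly positive *and* its point weight
is ≥ `threshold` (default 0.05); stage 2 refits the selected subset. The
"significant activity" rule is an interpretation (the procedure it mirrors
is Bayesian and does not define one); it is exposed as configuration. If
nothing is selected the single best-weight signature is kept, with a
warning. Per-tumor spectra of a few hundred SNVs select noisily, so the
pipeline's cohort-level active set comes from the pooled spectrum; the
per-tumor fits are still written.

The shipped 30-column catalog (`data/signature_catalog_synthetic.tsv`) is
synthetic — Dirichlet(0.3) columns from a fixed seed, generated by
`synthetic_catalog()` — because reference signature catalogs cannot be
redistributed. Its sparsity is comparable to real signature profiles,
which is what makes mixtures identifiable in the tests.

Exposure–covariate association uses Spearman rank correlation with an
exact permutation p for n ≤ 10 (full enumeration of rank pairings in
memory-bounded batches; ties handled by average ranks) and the large-sample
approximation above that.

## 7. Gene-set enrichment and subsampling sensitivity

Enrichment p for a set is the hypergeometric upper tail P(overlap ≥
observed) with |query| draws from the universe; Benjamini–Hochberg
adjustment across the library (via statsmodels). The universe defaults to
the union of library sets; supplying the set of all genes with ≥1 somatic
variant is the recommended setting for real analyses. Identifiers are
uppercased; duplicates within a set are collapsed.

Sensitivity: `n_subsamples` random query subsets, sizes uniform on a
configured integer range (clamped to the query size; the size distribution
is a choice — nothing in the emulated protocol specifies it), each
re-enriched; the report gives per-set significant proportions overall and
stratified by subsample size. Defaults (71,000 subsets, sizes 30–100)
mirror the emulated protocol's scale; tests and the demo use small values.

## 8. Pipeline

`run_pipeline` executes the enabled stages in dependency order from a YAML
config, validates the config (including stage-dependency closure) before
touching anything, funnels all randomness through named seeds, embeds a
config hash in the run report, and is byte-deterministic given identical
config. The run report contains only derived quantities (no timestamps) so
report hashes are comparable across runs.

## Problem sizes used in the tests

The suite runs cohort-scale checks at the defaults (100-gene × ~900 bp
exome, 10 patients, 900 somatic SNVs/tumor) for burden calibration and
power (20 seeds each), n=2,000 draws for dN/dS behavior, and n=10,000 SNVs
for signature recovery; unit-level oracles use exhaustive enumeration
(margins ≤ 30 for the exact test, universes ≤ 20 for enrichment, all 90
SNVs of a 30-bp gene for annotation). These sizes were chosen so each
statistical property is tested at the scale where its guarantee is stated.

## Known limitations

- No allele normalization; real caller VCFs need left-alignment upstream.
- Toy gene models lack introns/UTRs; element vocabulary is binary.
- The dN/dS estimator is not a substitute for covariate-based selection
  models when gene-level dispersion matters.
- The λ median method under-shoots on sparse discrete p ensembles (see §4).
- Signature selection is purely statistical; no biological-coherence
  judgment is attempted.
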