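# Methods

`panelqc` implements a panel-based correlation method for defining the
identity of a cultured cell population — the motivating case is a
synovium-derived mesenchymal stem cell (MSC) product that has no single
specific surface marker — together with the preprocessing it depends on and
a synthetic-data generator that makes the whole pipeline testable without
any expression download.

## The identity statistic

Two samples are compared by the coefficient of determination

    R² = corr(x, y)²

where `x`, `y` are the samples' log2-TPM vectors restricted to a curated
panel of lineage-associated genes, and `corr` is the Pearson correlation.
The comparison anchor for a population is its **reference profile**: the
per-gene *median* log2-TPM across its lots.

The estimator choice is deliberate and configurable. "Coefficient of
determination" can also mean 1 − SSE/SST about the identity line `y = x`;
that variant penalises systematic offsets (a globally shifted but perfectly
proportional sample scores < 1). `r_squared(..., mode="identity_line")`
provides it; the default is squared Pearson, which is symmetric, invariant
to positive affine transforms of either argument, and invariant to the
logarithm base used upstream (a property test asserts this). A negative
Pearson slope is flagged with a warning because squaring hides the sign.

Genes imputed as absent (see below) are *included* in the correlation:
absence of expression is treated as information, not as missingness.

## Preprocessing

**Read trimming.** Per base, Phred score q maps to error probability
p = 10^(−q/10). With limit ℓ = 0.05, the differences d_i = ℓ − p_i are
accumulated with the running sum clamped at zero
(s_i = max(0, s_{i−1} + d_i)). The retained interval is 0-based half-open
[start, end): `start` is the first index with s_i > 0, `end` is the index
of the *first occurrence* of the maximal s plus one (first-occurrence is
the tie-break; the rule itself does not fix one). A read whose sum never
becomes positive is discarded. One tempting invariant is false and
deliberately not asserted: lowering a single base's quality can *lengthen*
the kept interval, because erasing an early peak can hand the argmax to a
later peak that survives a clamp-to-zero reset unchanged. The monotone
quantity is the maximal clamped sum (the kept segment's quality mass),
which never increases under degradation.

**Normalization.** RPKM_gs = counts_gs / (length_g/10³) / (libsize_s/10⁶);
TPM rescales each sample's RPKM column to sum to 10⁶ (asserted to relative
tolerance 10⁻⁶ whenever a matrix claims the TPM unit). FASTQ quality
encoding is fixed to Phred+33; there is no Phred+64 autodetection.
Alignment and read counting are out of scope — counts are an input.

**Log transform.** log2 is applied after replacing zeros by half the
smallest positive TPM *in the whole matrix*. Half-the-minimum is one
reproducible choice of "below the minimum measured value"; it guarantees
every imputed value sits strictly below every observed one, so undetected
genes pull the correlation rather than vanishing from it. The imputation
value is recorded in `attrs["log_impute_value"]`. A per-sample minimum was
considered and rejected: it would give the same biological absence
different numeric codes in different samples. Base 2 is the transcriptomics
convention; R² is invariant to the choice.

## Thresholds and classification

From the R² values of other-tissue MSC populations against the target
reference (each population entering as its median profile), the same-type
lower bound is

    lower = mean + k · SD,   k = 1 by default,

with the *sample* SD (n−1 denominator): on the reference worked example
(0.821, 0.786, 0.821) this yields 0.809 + 0.020 = 0.829, whereas the
population SD would give 0.826. Statistics are reported at 3 decimals and
the bound is the sum of the *rounded* mean and SD — the unrounded sum,
0.8295…, would round to 0.830 and disagree with how the printed statistics
compose. The non-MSC upper bound is the maximum observed non-MSC R²,
*ceiling*-rounded to 3 decimals: plain rounding could place the bound below
the observed maximum and push the defining sample out of its own class.

Classification is a monotone step function with inclusive boundaries:
R² ≥ lower → `target_msc`; R² ≤ upper → `non_msc_like`; otherwise
`other_msc_zone`. The middle zone is not a failure label — it is
other-tissue MSC territory. Whether mean + 1 SD is a general rule or a
one-off product specification is open; the multiplier is therefore a
parameter. `monitor_passages` applies the same decision per culture passage
and reports the first passage at which the label degrades plus a
least-squares R² slope.

## Detection power

Discrimination of population *c* from the target is

    %CV(c) = |(R²_self − R²_c) / R²_self| × 100,

where R²_self is a target lot's agreement with its own population median.
Detection power of the curated panel against a comparator gene set (an
equal-size random draw, or all genes) is the ratio CV_panel / CV_comparator,
always computed from unrounded R². Reports round R² to 3 decimals, CV to
integer percent and power to 2 decimals (half-up); internal math is never
rounded, which is precisely what reproduces the published power values from
their printed R² inputs. Random comparator panels are drawn uniformly
without replacement from the *sorted* gene universe under a fixed seed, so
the draw is independent of input file order.

## Clustering

Samples are clustered on panel-restricted log2-TPM with correlation
distance d = 1 − Pearson r and average linkage. The distance deliberately
uses r, not R²: anticorrelated samples must be maximally distant (d = 2),
which squaring would conflate with perfect agreement. Average-linkage
heights are monotone (no inversions), and the dendrogram exports to Newick
with ultrametric branch lengths (node height = merge distance / 2; labels
containing whitespace, underscores or Newick syntax are quoted). The
original analysis tool's distance/linkage settings are unpublished, so
cluster topology is a qualitative target: the asserted analogue is that
every multi-lot type's samples are mutual nearest neighbors.

## Synthetic data generator

The generator states a world matching the data structure the method was
built for: 1 target MSC type (4 lots), 3 other-tissue MSC types (3 lots
each) and 5 non-MSC singleton types — 18 samples over 2,000 genes with a
200-gene panel, desk-scale by design.

Per gene, baseline log2 expression is N(4, 2²). Each type adds an effect
with SD 1.6 on panel genes and 0.4 elsewhere — the panel-concentrated
divergence that gives a curated panel its advantage. A type with
relatedness w to the target draws its effect as

    e_type = w · e_target + sqrt(1 − w²) · e_indep,

i.e. w is the *correlation* between type effects while the divergence
variance stays constant. The additive-shrinkage alternative
(baseline + w·e_target + (1−w)·e_indep) was rejected: it shrinks a type's
total divergence along with its similarity, which pins related types'
R² against the target near the same-type band and cannot produce three
separated R² regimes. Relatedness is stored per type (its similarity to
the target); defaults: other-tissue MSCs 0.78/0.75/0.72, fibroblast-like
0.50 down to lymphocyte-like 0.10, ordered as the biology suggests.

Lots add N(0, 0.2²) per gene; expected read counts follow from relative
abundance × gene length at a 2×10⁶ library; counts are Poisson
(gamma-overdispersion available, off by default). Dropout zeros are applied
at an overall rate of 5% *weighted toward low-abundance genes*
(weight ∝ exp(−expected/τ), τ = 5 counts): uniform dropout was rejected
because, combined with the below-minimum imputation rule, it injects
several log2 units of uncorrelated noise into 5% of all genes and collapses
same-type R² to ~0.3 — no real bulk library zeroes out high-abundance
genes at random. All randomness derives from a single integer seed.

`calibrated_config` returns this packaged configuration; its calibration
bands (realized median panel R²: same-type in [0.90, 0.99], other-MSC in
[0.75, 0.87], non-MSC ≤ 0.73) are met at these defaults over 20 seeds
(measured 0.956 / 0.783 / max 0.673).

**What a green simulation test does and does not establish.** It
establishes that the statistics, thresholds and benchmarking behave
correctly on data whose generative structure matches the method's
assumptions (panel-concentrated divergence, a relatedness ordering, log-
normal expression). It does not establish the published absolute R² values
(those require the original expression data), real amplicon primer bias,
batch effects, or biologically structured covariance between gene modules.

## Numerical choices and degenerate inputs

- R² requires ≥ 3 shared genes and non-constant vectors; variance underflow
  raises the same degenerate-input error as exact constancy.
- TPM conversion refuses all-zero samples by name; RPKM refuses missing or
  non-positive gene lengths by gene.
- Panel/matrix gene resolution: exact gene_id first, then case-insensitive
  symbol; zero overlap is an error rather than an empty result.
- Duplicate panel rows are merged (categories unioned, exclusion flags
  OR-ed, first occurrence fixes order); a gene flagged for two exclusion
  reasons is removed once, with a warning.
- Linkage ties follow scipy's deterministic lowest-index ordering.

## Known limitations

- No alignment/quantification from reads: the bridge between the trimming
  utility and the counts matrix is external by design.
- The classifier has exactly three labels; populations that sit below even
  the fibroblast range (e.g. iPSC-derived MSCs in the motivating data) are
  reported as non-MSC-like, with no dedicated "artificial MSC" category.
- Power comparisons assume the comparator gene set is scored on the same
  samples and reference construction as the panel.
- The generator's gene-gene covariance is diagonal given type; co-regulated
  modules, batch structure and primer efficiency are not modeled.
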