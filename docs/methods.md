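# Methods

## Amplicon model and pipeline

Each Ty family contributes two amplicon types: an **LTR amplicon** spanning
the whole LTR (default 330 b, so it covers both solo and element-attached
LTRs) and an **internal amplicon**, a window of the element's internal
region used purely as a full-element counter. A mate pair tiles its
template end-to-end: R1 is the template's first `read_length` bases, R2 the
reverse complement of its last `read_length` bases, so an LTR pair overlaps
by `2*read_length − ltr_length` (70 b at the defaults read_length=200,
ltr_length=330) and an internal pair by `overlap_length` exactly.

**Merging** scans all overlaps of at least `min_overlap` (10) bases between
R1 and reverse-complemented R2, discards overlaps with mismatch density
above 0.25, and keeps the one maximizing matches − mismatches (ties to the
longer overlap). At mismatching positions the higher-quality base wins,
ties going to R1. These defaults follow common read-joiner conventions;
the merged length invariant `len(R1)+len(R2)−overlap` is tested.

**Family/element assignment** aligns each distinct merged sequence globally
(match +1, mismatch −1, gap −2) against every panel reference and takes the
best identity, computed over aligned columns excluding terminal gaps so
that length-ragged merges are compared over their shared span. Reads below
0.80 identity to every reference are left unassigned; reads with more than
10% ambiguous bases are dropped before alignment. Full global alignment
was chosen over seeded local search because amplicons are short and
determinism matters more than speed; assignments are cached per distinct
sequence, so deeply sequenced low-diversity samples cost one alignment pass
per variant.

**Dereplication** collapses identical LTR sequences within a family into
variants with summed counts and counts internal-region reads as TY
(full-element) counts. **OTU clustering** agglomerates variants under
single, complete or average linkage (default average), merging while the
smallest inter-cluster linkage distance is ≤ the cutoff (default 0.03) and
breaking ties toward the lowest variant index; the implementation is a
direct O(n³) agglomeration, deterministic by construction, and is
cross-checked in the tests against scipy's hierarchical clustering and an
independently written exhaustive oracle. OTU count is non-increasing in the
cutoff (tested).

## Diversity and group comparison

Shannon entropy is natural-log (the convention of the diversity software
ecosystem this follows; evenness H/ln S is base-free anyway). Chao1 uses
the bias-corrected form S_obs + n1(n1−1)/(2(n2+1)) to avoid the
division-by-zero of the classic n1²/(2 n2) estimator; the classic form is
available behind a flag. Evenness is reported as missing when only one
category is observed. Diversity defaults to OTU-aggregated abundances with
variant-level as an option, since which of the two the original workflow
used is not stated — both are exposed.

Two-condition comparisons use a gated procedure mirroring standard
commercial-statistics practice: Shapiro–Wilk per group and Levene's test
(mean-centered by default, switchable to median) each gate at α = 0.05; if
all three pass, a one-tailed Welch t-test is used, otherwise a one-tailed
Mann–Whitney U. The caller supplies the direction; the gate logic (e.g. a
non-normal richness metric routing to Mann–Whitney) is tested behaviorally.

## Activity statistics

Ta1's family set is taken from the reference sample, and a missing family
or zero denominator raises an error naming the family rather than silently
shrinking the mean — a mean over a changed family set is not comparable
across samples. TY in Ta2 is interpreted as the total full-element count
summed over families (it is written unsubscripted in the source
formulation), and SI as the Shannon index of the pooled all-family LTR
abundance vector. Ta1 is invariant to uniform scaling of one sample's
counts (depth cancels within the sample); in Ta2 the depth term enters
through the TY totals, which cancel only between sample and reference, so
the tested invariance is joint scaling of both.

## Synthetic data

Reference sequences are uniform-random over {A,C,G,T}; LTR references are
regenerated until all inter-family identities are < 0.70, making family
assignment at the 0.80 identity floor unambiguous (real Ty sequence
content, PCR bias and chimeras are deliberately not modelled). LTR variants
are per-base substitution mutants (default rate 0.02) of the family
reference; variant abundances default to a symmetric Dirichlet draw and are
fully overridable, which the diversity-gradient analyses use. Qualities are
constant Q30; the merger's quality-consensus path is exercised with
explicitly constructed mismatching pairs instead. Sequencing errors are
per-base substitutions at a configurable rate; with the rate at zero the
pipeline must (and does) reproduce the generator's ground truth exactly,
which is the pipeline's strongest correctness guarantee — but it also means
passing the round-trip says nothing about indel errors, quality-dependent
error profiles or chimera formation in real data.

Phenotype tables draw TULA ~ U(60, 80) % and Ta2 ~ U(0.6, 1.2) — ranges
chosen so the noiseless linear predictor −2.39·TULA + 69.98·Ta2 + 152.43
stays within [0, 100] % survival — and add Gaussian noise with default
SD 9.19, matching the published fit's standard error of estimate. Simulated
survival is intentionally not clipped to [0, 100]: clipping would bias the
coefficient-recovery properties the generator exists to support.

Gene-set generation partitions the universe by inclusion–exclusion into the
planted overlap cells (the M∩T-outside-H cell is left empty), then wires a
directed network in which every T-CORE gene receives at least one edge from
a transposon node, plus decoy edges (regulator → transposons, ordinary
gene → gene) that cannot change the level-1 out-neighborhood. The core-set
module applied to these outputs recovers the planted counts exactly.

## Regression report

The survival model is OLS with intercept via statsmodels. Derived
quantities use the standard identities (df = n − k − 1): partial_j =
t_j/√(t_j²+df), part_j = t_j·√((1−R²)/df), adj R² = 1−(1−R²)(n−1)/df,
F = (R²/k)/((1−R²)/df), tolerance_j = 1 − R² of x_j on the other
predictors, VIF = 1/tolerance, beta_j = B_j·sd(x_j)/sd(y). The t-formula
partials are verified against the residual-regression definition to 1e-10
on random instances. Importance weights are squared partials; the reported
ratio is w_first/w_second. The sample size behind the published report is
never printed; n = 8 is inferred as the unique integer satisfying the
adjusted-R² identity at R² = 0.815 and adj R² = 0.741 (and confirmed by
F = 11.014), and is recorded as an inference, not a given. Coefficient
p-values are two-tailed, consistent with the printed 0.005/0.043 at df = 5.
Display rounding is 2 dp for correlations/tolerance/VIF and 3 dp for F;
full precision is kept internally.

For the gene-set route, the overlap percentages use |H-CORE| as the shared
denominator; the published ratio is denominator-invariant, which is the
quantity the tests pin down. Pairwise stress-assay comparisons use the
rank-sum (independent-samples Wilcoxon) test and a hand-implemented Dunn
z-test on pooled mean ranks with tie correction, each family BH-adjusted.

## Problem sizes and numerical choices

Simulated samples default to 1000 read pairs — enough for every family to
receive internal reads (so Ta1 is defined) while keeping the full
merge→align→cluster pipeline fast; analysis drivers and the acceptance
script use this size, and the Monte-Carlo recovery studies use 500
replicates at n = 8. Randomized property sweeps run ≥ 1000 count tables.
All generators accept explicit seeds or numpy Generators; identical seeds
give byte-identical outputs. Degenerate inputs (all-zero abundance weights,
single observed category, zero TY counts, singular designs, identical
groups in the omnibus test) raise typed errors or return defined boundary
values as documented per function.

## Known limitations

Absolute diversity values and the original study's Table of p-values cannot
be reproduced: they depend on the deposited raw reads and on clustering
parameters (cutoff, linkage) the original workflow does not state. The
original primer sequences and amplicon lengths are likewise unpublished, so
the panel geometry here is a stated placeholder. M-CORE inference and
enrichment analyses are inputs/out of scope, not reimplemented.
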