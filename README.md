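# tyquant

Quantifying yeast Ty retrotransposon activity from LTR amplicon sequencing,
and weighing a regulator's direct transcriptional contribution to thermal
tolerance against its transposon-mediated one.

## The problem

*Saccharomyces cerevisiae* carries five LTR-retrotransposon families
(Ty1–Ty5). Recombination between an element's two long terminal repeats
excises the internal sequence and leaves a solo LTR behind, so the ratio of
LTR copies to full elements — and the sequence diversity of the LTR pool —
records transposition/excision turnover. Amplicon sequencing of family-
specific internal and LTR regions yields per-sample count tables from which
two activity statistics are computed relative to a designated reference
sample (e.g. wild type grown at 30 °C):

- **Ta1** = mean over families *n* of (LTR_n/TY_n) / (LTR_ref,n/TY_ref,n) —
  copy-number sensitive, blind to sequence diversity;
- **Ta2** = (SI/TY) / (SI_ref/TY_ref), where SI is the Shannon index (nats)
  of the sample's pooled LTR variant abundances and TY its total
  full-element count — sensitive to diversity change per element.

Downstream, heat-shock survival is modelled as an ordinary least-squares fit

    Survival45 = b1·TULA + b2·Ta2 + b0

where TULA is the membrane's total unsaturated lipid acid content (%,
a proxy for direct transcriptional regulation of lipid desaturation) and Ta2
proxies transposon-mediated regulation. Squared partial correlations of the
two predictors serve as importance weights; their ratio weighs the direct
route against the transposon route. A complementary gene-set view
intersects the heat-response core DEG set (H-CORE) with the
mutation-network gene set (M-CORE) and with the first out-going network
neighbors of the regulator-affected transposons (T-CORE): the overlap
percentages |H∩M|/|H| and |H∩T|/|H| give the same kind of weight ratio.

Because the study's raw reads and per-strain tables are not packaged here, a
first-class synthetic-data module (`tyquant.synthgen`) generates every input
with known ground truth — reference panels, paired reads, phenotype tables
drawn from the survival equation, and gene sets with planted overlaps — so
the whole pipeline is testable offline.

## Worked example

```python
import numpy as np
from tyquant import synthgen, pipeline, activity
from tyquant.diversity import shannon

cfg = synthgen.SimulationConfig(seed=20260, n_reads_per_sample=1000,
                                sequencing_error_rate=0.0)
panel = synthgen.make_panel(cfg)
rng = np.random.default_rng(cfg.seed)
variants = synthgen.make_variants(panel, cfg, rng)
even   = {f: [1.0]*4 for f in panel.families}          # reference, 30 C
skewed = {f: [8.0, 1.0, 0.5, 0.5] for f in panel.families}  # stressed pool
ref_pairs, _ = synthgen.simulate_sample(panel, cfg, even,  sample_id="ref",
                                        variants=variants, rng=rng)
q_pairs, _   = synthgen.simulate_sample(panel, cfg, skewed, sample_id="q",
                                        variants=variants, rng=rng)
ref = pipeline.profile_sample(ref_pairs, panel, sample_id="ref", otu_level=False)
q   = pipeline.profile_sample(q_pairs,   panel, sample_id="q",   otu_level=False)
res = activity.activity_result(q.counts, ref.counts,
                               shannon(q.counts.pooled_variant_counts()),
                               shannon(ref.counts.pooled_variant_counts()))
print(res.ta1, res.ta2)
```

Running the equivalent driver scripts (`python analysis/01_simulate.py` …
`05_survival_weights.py`) prints, among other lines:

```
ref_30C: 1000/1000 reads assigned, Shannon=2.9785 Chao1=20.0 evenness=0.9942 (truth recovered: True)
stress_37C: 1000/1000 reads assigned, Shannon=2.3096 Chao1=20.0 evenness=0.7710 (truth recovered: True)
stress vs reference: Ta1=1.0898, Ta2=0.8087
reference vs itself: Ta1=1.0000, Ta2=1.0000
|H|=10000, |H&M|=913 (9.13%), |H&T|=698 (6.98%)
direct : transposon-mediated weight ratio = 1.31
from printed inputs: F=11.014, adjR2=0.741, partials=(-0.90, 0.77), weights=(0.810, 0.593), ratio=1.37
```

Every read of the error-free simulation is merged, assigned and counted
back exactly (Shannon matches the generator's closed-form truth to machine
precision); the skewed stressed pool drops evenness and pulls Ta2 below 1
while Ta1 barely moves — the two statistics dissociate copy-number change
from diversity change. The gene-set overlap ratio (1.31) and the
squared-partial weight ratio (1.37) are the two independent estimates of
how much stronger the direct route is than the transposon route.

The package also provides the supporting procedures used around these
results: gated two-group comparisons of diversity metrics (Shapiro–Wilk and
Levene gates choosing a one-tailed Welch t-test or Mann–Whitney U),
Kruskal–Wallis / pairwise Wilcoxon / Dunn stress-assay tests with
Benjamini–Hochberg adjustment, 2^−ΔΔCt qRT-PCR fold changes, and R²-based
expression-correlation flags.

A thin CLI mirrors the library: `tyquant simulate | amplicon | activity |
coresets | weigh | stress` (see `tyquant --help`).

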