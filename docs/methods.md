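# Methods

## Experimental design being modelled

The pipeline analyses a common-reference two-colour microarray design: seven
*Medicago truncatula* nodule samples (wild-type nodules at 4, 10 and 14 dpi;
16-dpi nodules treated two days with ammonium nitrate, "NN"; and 10-dpi
nodules induced by the *exoA*, *bacA* and *fixJ* rhizobial mutants), each
hybridised against the same pool of nitrogen-starved non-inoculated control
roots, with four replicates per condition. Each observation is therefore
already a log2(sample/control) ratio, and every condition is a single
contrast against zero. A companion qRT-PCR design covers eight root
conditions (purified Nod-factor treatment; wild-type inoculation at 1 and
3 dpi; the *nfp*, *hcl-1*, *lin*, *exoA* and *efd-1* symbiotic mutants) plus
control roots, with three biological repetitions and an ubiquitin reference
gene.

## Differential expression

- **Normalisation** is per-sample median centring (`normalize`). It assumes
  most genes are unchanged, which holds for real arrays (~20% of probes DE)
  but *not* for the synthetic datasets, which are DE-dominated by
  construction; recovery pipelines therefore call on the simulated ratios
  directly (`nodclass call --no-normalize`).
- **Testing**: one-sample two-sided *t* on the replicate log2 ratios
  (3 degrees of freedom at n = 4). A two-sample test would be wrong here:
  the reference is built into each ratio. Zero replicate variance with a
  nonzero mean is deterministic evidence of change under the model, so it
  receives the limit p = 0 and a `degenerate` flag (visible in output);
  zero variance at mean 0 receives p = 1. Probes with fewer than two
  non-missing replicates are flagged `untestable` and forced to `none`.
- **Multiple testing**: Benjamini–Hochberg step-up, applied within each
  condition (each condition is one contrast). A pooled mode across all
  conditions exists behind `AnalysisConfig.pooled_adjust` for sensitivity
  analyses; per-condition is the default.
- **Calls**: up iff linear ratio = 2^(mean log2) ≥ `ratio_threshold` (1.5)
  and adjusted p ≤ `alpha` (0.05); down symmetrically at 1/1.5. Both bounds
  inclusive. The 1.5 threshold is deliberately permissive: biologically
  validated nodulation genes show array ratios below 2 (e.g. ~1.79 at
  4 dpi), so a 2-fold cut-off would lose them.

## Nodule expression classes

Calls are refined to four levels per condition. Among a probe's up calls,
let R_max be the largest mean linear ratio; a condition is **maximal
induction** if its ratio ≥ `weak_fraction` × R_max (default 0.5, a free
parameter exposed in config — the published class definitions distinguish
"weak" from "maximal" induction only graphically) and **weak induction**
otherwise. The condition of strongest expression ("argmax") is the largest
ratio, ties broken by the fixed order WT4, WT10, WT14, NN, exoA, bacA, fixJ.

Classification is a first-match-wins precedence list (see
`classify_probe`): repressed (no up, some down); unclear (mixed signs, down
anywhere except NN); exo2 (up only in exoA); exo1 (argmax exoA, other ups);
zone1-2 / N4 (argmax WT4, without / with exoA expression); all / all*
(up in WT4 plus ≥ `most_samples_k` = 3 of {WT10, WT14, bacA, fixJ}, NN never
considered, with / without exoA); NN (argmax NN); diff1 / diff2 (not up at
4 dpi, up in older nodules and fixJ, with / without bacA); bacA; fixJ;
fix+ (up confined to WT10/WT14, NN not up — NN *down* is expected for
genes switched off by nitrate, so only up-calls at NN exclude fix+);
fix+\_NN (mature-nodule and NN expression, mutants silent); wt-nodules
(up only in wild-type-induced samples); unclear otherwise. The published
descriptions do not state how overlapping patterns were disambiguated; this
order puts the most exclusive patterns first and is exercised exhaustively —
all 3^7 call vectors receive exactly one label, cross-checked against an
independent re-implementation of the rule table.

The per-class level templates (one representative vector per class, also
shipped as `data/class_templates.yaml`) are the single source of truth for
both the classifier tests and the synthetic-data generator, so the two
cannot drift apart. WT10 and WT14 are planted identically in every template,
reflecting that nitrogen-fixing 10- and 14-dpi nodules show the closest
profiles — which is why condition clustering merges them first.

## Clustering and co-expression

Distance is 1 − Pearson r on per-condition mean log2 profiles (replicate
averaging first, matching how sample-profile dendrograms are drawn);
zero-variance profiles are excluded with a warning. Average linkage is the
unweighted (UPGMA-style) update, implemented directly so that tie-breaking
is deterministic (smallest cluster indices in creation order); it is
validated against `scipy.cluster.hierarchy.linkage(method="average")` on
tie-free random instances. Newick branch lengths are parent-minus-child
merge heights. Co-expression queries return all probes with r ≥ threshold
(default 0.8) sorted by descending r, excluding the reference itself.

## Cross-platform concordance

"Qualitatively similar" between two platforms is formalised as: call sign
(up/none/down) agrees in at least `min_agree` of the shared conditions,
default all-but-one. This is one defensible reading of an undefined verbal
criterion; it is fully configurable, symmetric in its arguments, and
monotone in `min_agree`. Probes without a cross-platform id mapping are
excluded from the denominator. The published 84% figure itself requires the
external Affymetrix atlas and is out of scope; the metric is what ships.

## Root qRT-PCR patterns

Relative expression is 2^−ΔΔCt with amplification efficiency fixed at 100%
(no efficiencies are available for the modelled assays). Per-replicate
ΔΔCt uses the replicate's own (target − reference) ΔCt minus the mean
control-root ΔCt; significance reuses the same t/BH machinery as the array
pipeline (three replicates, BH across genes within each condition), since no
explicit qPCR call rule is published and symmetry keeps one code path.

Symbols: `0` not significant or fold inside (1/1.5, 1.5); `-` significant
repression; among significant inductions, `++` if the condition attains the
gene's maximum fold and that maximum is ≥ `high_factor` (2.0) × the largest
fold among the *other* wild-type situations (NF, WT 1 dpi, WT 3 dpi; floor
1.0 — so a flat profile yields `+` everywhere); `+-` if the fold is
< `weak_vs_wt` (0.5) × the weakest significant wild-type inoculation fold
(the reference for "weaker than in the WT situations" is the *minimum* of
the up-called WT 1/3 dpi folds — the only reading consistent with a
3-fold mutant induction counting as `+` alongside WT folds of 3 and 8);
`+` otherwise. Grading a mutant induction with no significant wild-type
inoculation fold raises a domain error. `high_factor` and `weak_vs_wt` are
config values because the symbols are defined only verbally.

Pattern matching tests a symbol vector against the eight printed archetype
rows, with composite slots ("+/++", "+/+-") as allowed-sets exactly as
printed; among multiple matches the most specific template (smallest total
allowed-set size) wins. On the planted alphabet the eight templates are
mutually exclusive (tested exhaustively).

## Synthetic data: what it emulates, what it does not

The generator plants each probe's true per-condition mean from its class
template: maximal induction at `max_log2_effect` = 3.0 (8-fold), weak
induction at `weak_log2_effect` = 0.8 (≈1.74-fold — above the 1.5 call
threshold but below half the maximal ratio, so the weak/max split is
exercised), repression at −3.0, and adds i.i.d. Gaussian noise on the log2
scale (log-normal on the linear scale, the standard two-colour error
model). `noise_sd` defaults to 0.15; no replicate variance estimates are
published, so this is a free parameter chosen to give a replicate SEM of
0.075 log2 units at n = 4 — tight but realistic for averaged two-colour
ratios. Root genes are planted from concrete fold profiles that realise
each pattern's symbol row (e.g. A3: WT 4- and 10-fold, mutants 1.7-fold for
`+-`); reference-gene Ct is constant at 20, target control Ct at 25.

Not emulated: dye bias, spatial artefacts, cross-hybridisation, probe-level
intensity dependence of variance, or correlated replicates. Passing recovery
tests therefore demonstrates correctness of the calling/classification
logic under the declared error model, not robustness to array artefacts.

## Problem sizes and numerical choices

The default verification runs use ~1,000 probes (59–62 per class) for
noise-free recovery and 20 seeds × 850 probes (50 per class plus 50
non-differential) for noisy recovery — large enough for stable per-class
rates while keeping the whole suite under a minute apart from the noisy
sweep. Mean per-class recovery at noise 0.15 is ≈99.8% (minimum class
≈98.5%); the residual errors are single weak calls dropping below threshold
and moving a probe to an adjacent class (e.g. diff1 → diff2 when the bacA
call is missed). Writers emit rows in sorted probe order with fixed
condition order and `%.6g` floats, so repeated writes are byte-identical;
table round-trips are exact to that precision. BH handles missing p-values
by propagating NaN without counting them toward m.

## Known limitations

- The precedence order of the class rules is a reconstruction; a different
  defensible order would shuffle a small number of boundary probes between
  adjacent classes (all counts here are over synthetic data).
- `weak_fraction` = 0.5 on the linear scale is a modelling choice, not a
  published constant.
- The concordance metric and the qPCR symbol thresholds formalise verbal
  definitions; both are exposed in `AnalysisConfig` rather than hard-coded.
- Probe identifiers are opaque strings; no id-space translation is
  attempted.
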