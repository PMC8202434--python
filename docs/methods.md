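# Methods

`grnwaves` reconstructs dynamic transcriptional regulatory networks from a
two-arm (control vs cytokine-treated) bulk RNA-seq time course, an shRNA
knockdown panel, and a ChIP-seq-derived TF→target prior. This note records
the models, the numerical choices, and what the synthetic benchmarks do and
do not establish.

## Consensus differential expression

Counts are modeled per gene as negative binomial with mean μ and variance
μ + αμ² (α the dispersion). Normalization is median-of-ratios: genes with
no zero anywhere form the reference; a sample's size factor is the median
of its counts over the genes' geometric means. Log size factors enter the
GLM as offsets.

Dispersion is a gene-wise method-of-moments estimate pooled over design
cells (one cell per condition × time × perturbation): with cell mean m and
variance s², α̂ solves Σ w (s² − m) = α Σ w m² over cells, w = n−1, floored
at 1e−8. There is deliberately no empirical-Bayes shrinkage: the package's
contribution is the consensus rule, and a closed-form estimator keeps every
stage independently testable. The cost is a known small-sample effect:
plugging a noisy per-gene α̂ into a high-df test is mildly anti-conservative
(the interaction test's null rejection at p<0.05 is ≈0.10 instead of 0.05 at
n = 3 with ten time points; it is exact when α is known). The consensus
call, which requires agreement across tests, absorbs this: the edge-free
null consensus fraction is ≪ 0.05 under both rules.

Three tests run per gene on a shared batched IRLS engine (log link, fixed
α, max 100 iterations, relative deviance tolerance 1e−8; all genes share
the design matrix so each IRLS step is one batched p×p solve across the
matrix). Non-converged or all-zero genes are flagged and reported p = 1,
never raised:

- **Wald** — z = β̂/SE on the treated coefficient of ~condition + time
  (categorical time), SE from the expected information.
- **LRT** — deviance of ~time minus ~condition + time against χ²(1).
  Deviance differences avoid gamma-function cancellation entirely, so the
  statistic is stable even at the dispersion floor (Poisson limit).
- **time-course** — LRT of the condition:time interaction (~condition +
  time + condition:time vs ~condition + time), χ² with (#times − 1) df;
  this is the test that detects treatment-specific temporal shapes, e.g. a
  pulse confined to two of ten time points whose time-averaged main effect
  is too small for the other two tests. Categorical (not spline) time is
  used as the reference choice.

P-values are Benjamini–Hochberg adjusted per test. A gene is consensus-DE
when ≥2 tests pass FDR < 0.05 (`agree_by_two`) or ≥1 (`any`); the rule and
threshold are run-level configuration, matching the two analysis arms the
method was designed for. Direction follows the sign of the Wald log2 fold
change; disagreement in sign among calling tests yields "mixed", an exact
zero yields "none" and is excluded from signed node annotation.

## Transcriptional waves

Replicates are averaged per treated time point and the Pearson correlation
between time-point profiles is computed across all measured genes
(DEG-only is available; the gene universe used by the original analysis is
not stated). Waves are found by exhaustive search over all contiguous
segmentations of the post-baseline time points into k blocks (k = 3 by
default), maximizing mean within-block minus mean between-block
correlation — an explicit, oracle-checkable objective standing in for the
visual block structure such matrices show. Ties break toward the earliest
boundaries, making the output deterministic; the search equals a
brute-force enumeration by construction and is tested against an
independent implementation on thousands of random instances.

Kinetic classes: a consensus-DE gene qualifies in a wave when |log2FC| ≥ 1
(configurable) at some time point inside the wave and the gene is
significant in the wave-restricted consensus DE. Early-and-late-but-not-
intermediate qualification is "bimodal"; otherwise the gene takes the
qualifying wave with the largest |log2FC|; no qualification leaves it
"unclassified". Bimodal genes enter both the early and late wave gene sets
(GMT output).

## Knockdown panel

Knockdown efficiency is 1 − (TF expression under its shRNA)/(expression
under scramble), on size-factor-normalized means plus pseudocount 1,
clipped to [0,1]; perturbations below the 0.6 gate are excluded from edge
inference. The effect of a perturbation on a gene of interest is
log10(perturbed/control) − log10(scramble perturbed/control), the double
ratio that cancels treatment-wide trends.

Perturbation DE contrasts a TF's treated knockdown samples against treated
scramble with the Wald machinery; size factors and dispersions come from
the *full* panel (all perturbations and arms — ~44 cells) rather than the
six samples in the contrast, which is what keeps the per-contrast FDR
calibrated at n = 3. Significant responders become validated edges with
the inverted sign (up upon knockdown ⇒ repression); self-edges are
excluded.

**Minimum detectable effect.** At n = 3 per group, α = 0.1 and 90%
knockdown, the standard error of the log-mean contrast is ≈√(2(α+1/μ)/3) ≈
0.38 log2 units for well-expressed genes; with a BH-effective threshold of
|z| ≈ 3.4 in a panel-sized test family, ~90% power requires an effect of
≈2.0 log2 units, while an effect of 1.5 sits near 55% power. The package
therefore treats 2.0 as the panel's minimum detectable effect: recovery
benchmarks report the fraction of ground-truth edges at or above it (and,
separately, over all edges ≥1.5, which is power-limited by design, not by
implementation).

The TF × GOI effect-score matrix is summarized by column-centered SVD;
regulator modules split by the sign of the PC1 score, with the
largest-|PC1| TF anchoring module_1 to remove the SVD's global sign
ambiguity.

## Networks, ranking, hierarchy, bridging

Per wave, the network holds the wave's DE TFs plus DE genes reachable from
them by a prior edge; edges are those prior relations (sign "unknown"
unless the prior carries one). Validated edges overlay with provenance
"validated"/"both"; sign conflicts resolve toward validation and are
flagged. Edges between two DE TFs are kept.

TF dominance combines two axes, each min-max normalized over the wave's
TFs (a degenerate spread maps to 0.5): the −log10 one-sided hypergeometric
tail P(X ≥ k) for DE enrichment among the TF's prior targets (urn: N =
prior∩measured universe, K = DE genes, n = TF's targets, k = DE targets;
raw p-values compress dominance, hence the log transform), and closeness
centrality on the undirected projection with component scaling,
((m−1)/Σd)·((m−1)/(N−1)), which handles the disconnected subgraphs wave
networks produce (harmonic centrality is a config alternative; the exact
centrality and normalization of the original are unnamed, so both choices
are documented interpretations). The rank score is their mean; ties break
by smaller enrichment p, then gene id, so the order is total and
deterministic.

The TF-only backbone is condensed by strongly connected components and
layered by longest-path depth from the sources: pure sources (only
outgoing regulation) sit at layer 0, pure sinks at the bottom, cycle
members share a layer. Longest-path (not shortest-path) depth is what
makes both boundary rules hold simultaneously and is deterministic.

A TF differentially expressed in two or more waves is bridging; the
combined graph links each TF to a meta-node per wave in which it has DE
targets, weighted by target count.

## Signatures and module scores

Membership scores count the datasets containing a gene. Perturbation
candidates are TFs DE in both lineages with ISG membership ≥ 1 ("more than
1" in the source narrative is read as ≥1, since all of its chosen TFs are
described as ISGs; the stricter ≥2 is one flag away) and either TIL
support or external-signature membership.

Module scores follow the binned matched-control scheme (defaults n_bins =
24, n_control = 100, seeded): genes bin by average expression into
equal-occupancy bins; each set gene draws up to n_control controls without
replacement from its bin excluding set genes; a sample's score is
mean(set) − mean(pooled controls). A constant matrix scores exactly 0 and
the score is invariant to adding a constant. Because controls are matched
on the *overall* average, a shift applied to a large fraction of samples
is split between set and control pools; the shift itself is identified as
the shifted-vs-unshifted score contrast, which is what the benchmarks
assert.

## Synthetic data

The generator emulates the study design: ten-point 0–96 h grid, two arms,
three replicates, NB counts (α = 0.1, a typical bulk RNA-seq value),
log-uniform library factors in (0.7, 1.4), log-uniform baselines in
(20, 2000). Treated TF activity is a unit-peak Gaussian in log-time
(sd 0.5) centred at the geometric mean of its wave window (early 1–2 h,
intermediate 4–16 h, late 48–96 h); TFs gain amplitude × activity on the
log2 scale (amplitude 3 by default) and each target gains
sign·effect·activity summed over incoming edges. The knockdown panel is an
endpoint steady state: all non-flat TFs fully active under treatment, the
perturbed TF's own mean multiplied by 1 − efficiency (0.9 by default,
comfortably past the 0.6 gate) and its regulatory input scaled by the same
factor.

The bundled fixture plants 8 TFs per wave (one hub with 60 targets, the
rest 12), 4 flat TFs, and 1200 targets (~1230 genes), with effects uniform
in (1.5, 2.5) and 20% repressors; the 21 highest-out-degree TFs form the
knockdown panel. Its analysis grid is {0,1,2,4,8,16,48,72,96}: the 24 h
point of the full default grid falls between the intermediate and late
windows and belongs to neither wave, so the fixture samples the eight
post-baseline points that segment cleanly — matching the eight time points
the wave analysis is defined over.

What passing these benchmarks does **not** show: the generator has no
batch structure, no composition shifts beyond the planted effects, no
gene–gene dispersion trend, no secondary (indirect) regulation, and no
single-cell dropout; real-data performance on those axes is untested.

## Problem sizes and reproducibility

Default benchmark sizes (chosen so the whole battery runs in well under a
minute each): 2000-gene null and planted-effect simulations; the ~1230-gene
fixture for end-to-end runs; 300–1000 random instances for the
segmentation/hierarchy/ranking oracles; exhaustive urns to N = 30 for the
hypergeometric check. One global seed fans out to per-stage seeds by
hashing the stage name, so stages rerun independently yet reproducibly;
every artifact is plain text written in sorted order, and a rerun at the
same seed is byte-identical (the manifest records the config hash, which
excludes the output path).
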