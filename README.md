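# grnwaves

Dynamic transcriptional-regulatory-network analysis of cytokine-response
time courses.

When primary cells are stimulated with a cytokine such as a type I
interferon, the transcriptional response unfolds in discrete temporal
**waves** — blocks of time points whose genome-wide expression profiles are
mutually highly correlated. `grnwaves` turns a two-arm (control vs
treated) bulk RNA-seq time course, an shRNA knockdown panel, and a
ChIP-seq-derived TF→target prior into wave-specific regulatory networks
with ranked, hierarchically layered transcription factors. It is aimed at
computational biologists dissecting dynamic gene regulation — e.g. how
interferon shapes T-cell co-inhibitory receptor expression — and ships a
synthetic-data generator with full ground truth so every stage is testable
without any download.

The pipeline:

1. **Consensus differential expression** — per gene, three NB-GLM tests
   (Wald on the condition coefficient; likelihood-ratio test of the
   condition term; a time-course LRT of the condition × time interaction),
   each BH-adjusted; a gene is DE when ≥2 tests pass FDR < 0.05
   (`agree_by_two`) or ≥1 (`any`).
2. **Waves** — Pearson correlation between treated time-point profiles,
   then exhaustive segmentation into contiguous blocks maximizing
   (mean within-block r) − (mean between-block r); each DE gene gets a
   kinetic class (early / intermediate / late / bimodal).
3. **Perturbation** — knockdown efficiency 1 − kd/scramble gated at 60%;
   effect scores log₁₀(kd fold change) − log₁₀(scramble fold change);
   knockdown-vs-scramble DE yields sign-inverted **validated edges**
   (up upon knockdown ⇒ repression); PCA over the effect matrix splits
   regulators into two modules by PC1.
4. **Networks** — per wave, DE TFs and their DE prior targets become
   nodes/edges; validated edges overlay the prior. TFs are ranked by the
   mean of min-max-normalized −log₁₀ hypergeometric enrichment
   P(X ≥ k) and closeness centrality; the TF backbone is layered into a
   hierarchy (SCC condensation, longest-path depth: sources on top); TFs
   DE in ≥2 waves are **bridging** TFs.
5. **Signatures** — membership scores, perturbation-candidate selection,
   and binned matched-control module scores for wave gene sets.

## Worked example

Run the full pipeline on the bundled synthetic fixture (≈1230 genes, two
arms × 9 time points × 3 replicates, a 21-TF knockdown panel, and a
ground-truth network with one hub TF per wave):

```sh
grnwaves run-all --config examples/synthetic.yaml --outdir run --seed 11
```

or equivalently from Python:

```python
from grnwaves.pipeline import PipelineConfig, run_pipeline
manifest = run_pipeline(PipelineConfig(outdir="run", seed=11, synthetic={}))
print(manifest["summary"])
```

The run takes ~10 s and prints (abridged):

```
wave_windows:         early [1, 2]   intermediate [4, 8, 16]   late [48, 72, 96]
n_de_genes:           279
kinetic_class_counts: early 61, intermediate 76, late 115, bimodal 11, unclassified 16
n_validated_edges:    382
top_tf_per_wave:      early TF_EARLY_00, intermediate TF_INTERMEDIATE_00, late TF_LATE_00
n_bridging_tfs:       1
```

Reading this: the segmentation recovered exactly the three planted wave
windows; 279 genes passed the three-way consensus at FDR 0.05; the
knockdown panel validated 382 signed edges; and in each wave the planted
hub regulator (the TF with by far the most targets) ranks first. The
per-wave ranking table (`run/tf_ranking_intermediate.tsv`) shows why:

```
tf                   hg_p    centrality  hg_norm  cent_norm  rank_score  rank
TF_INTERMEDIATE_00   0.0000  0.3299      1.0000   1.0000     1.0000      1
TF_INTERMEDIATE_07   0.0001  0.2238      0.0486   0.5845     0.3165      2
```

The hub dominates both ranking axes: the most enriched target set and the
highest closeness centrality.

Artifacts are plain text (TSV/CSV/GMT/JSON/GraphML/SIF) and byte-identical
across reruns at a fixed seed; `run/manifest.json` lists all of them with
the config hash and per-stage seeds.

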