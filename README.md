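# mlsom — multi-layer SOM transcriptome portrayal for drug repositioning

`mlsom` asks a concrete translational question: *if a drug demonstrably
reverses the transcriptional signature of one disease, which other diseases
carry the same signature and could be treated with it?* It answers it by
jointly clustering several case/control expression studies — a drug-action
dataset (treated vs baseline/placebo), the drug's approved target disease
(disease vs healthy), and candidate repositioning diseases — into one
self-organizing map and comparing how co-regulated gene modules respond
across the studies. The approach suits biologics (antibodies, recombinant
proteins) in particular, where structure-based repositioning is not an
option.

## The method

1. **Preprocessing.** Each study ("layer") is a gene × sample log2
   expression matrix (RMA-like). Layers are quantile-normalized
   independently, every gene is centered over *all* samples of *all* layers
   (Δe scale), and each layer is rescaled by one scalar so its mean per-gene
   SD equals the across-layer median — no single layer dominates training.
2. **Joint SOM.** Genes are objects, their Δe profiles across all samples
   are features. Batch Kohonen training on a K×K grid (production default
   45×45) yields "metagenes" — prototype profiles of microclusters of
   co-expressed genes. Because training is joint, every unit holds the same
   genes in every layer, so per-sample grid images ("portraits") are
   directly comparable across layers.
3. **Spots.** Units exceeding the 95th percentile of a group portrait's
   values are overexpressed; the union over all group portraits is segmented
   into connected components ("spots" A, B, C, …) — the units of
   differential analysis.
4. **Differential spot calling.** Per layer and contrast, each spot gets a
   presence/absence vote (|target − reference| mean spot expression beyond
   ±1 SD of the spot's metagene expression in that layer) and a t-test vote
   (Welch p < 0.05 **and** linear fold change 2^Δ > 1.5), combined
   conservatively (both must agree).
5. **Verdict.** A drug is a repositioning *candidate* for a disease iff at
   least one spot is regulated antagonistically — up in the disease contrast
   and down under the drug, or vice versa. Disease spots the drug leaves
   untouched are reported too: they flag pathology the drug would not
   address.

Supporting analyses: Fisher exact (hypergeometric tail) spot annotation
against GMT gene sets with Benjamini–Hochberg FDR per spot; sample-wise
gene-set Z scores (GSZ, standardized set mean √n·(x̄_set − x̄)/s); and
Pathway Signal Flow (PSF), which propagates linear fold changes from
pathway inputs to sinks, multiplying through activating edges and dividing
through inhibiting ones.

## Worked example

The package ships a generator for synthetic multi-layer studies with
planted co-regulated modules (`mlsom.simulate`). The canonical scenario
plants one 100-gene module **up** in two disease layers, leaves a third
disease untouched, and lets the drug layer reverse it:

```python
from mlsom import PipelineConfig, analyze, repositioning_scenario

dataset, truth = repositioning_scenario(seed=1)   # 2,000 genes, 4 layers
result = analyze(dataset, PipelineConfig(grid_size=20, random_seed=1))
for v in result.verdicts:
    print(v.disease_layer, v.verdict, v.antagonistic_spots)
```

prints

```
dis1 candidate [('R', 'up', 'down')]
dis2 candidate [('R', 'up', 'down')]
dis3 not_supported []
```

Spot R is the planted module (109 genes, 100 of them planted): upregulated
in both diseases, downregulated by the drug — an antagonistic "drug target"
spot, hence *candidate* — while the null disease shows no dysregulated spot
and comes out *not_supported*. `examples/` contains four narrative scripts
covering training/portraits, spot calling and verdicts, enrichment + GSZ,
and PSF.

## Command line

The same workflow is scriptable from the shell; subcommands exchange
plain-text intermediates and compose to the same artifacts as one `run`:

```bash
mlsom simulate --outdir study --seed 1
mlsom run --config study/config.yaml --outdir out --grid 20 --seed 1
# or stage by stage: normalize → train → spots → call → enrich → psf
```

Outputs: the joint matrix, model (prototypes/assignment/training log),
spot tables and profiles, the spot-perturbation table and heatmap, verdict
JSON/text, enrichment and GSZ tables, PSF node/sink signals, portrait PNGs,
and a run manifest with input checksums, seed, and per-stage timings.

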