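# stromasig

Stability-resampled differential expression and signature discovery for
stromal-cell expression compendia.

## The problem

Mesenchymal stromal cells (MSCs) isolated from bone marrow (BM), adipose
tissue (AD) or placenta (PL) are defined operationally — plastic adherence,
a handful of CD surface markers, trilineage differentiation — and bulk
expression compendia assembled from many public series are the natural way
to ask what these cells share transcriptionally and what distinguishes
them from fibroblasts and from hematopoietic stem/progenitor cells
(HSPCs). Two obstacles make naive analysis fragile:

* **heterogeneous recruitment** — samples come from many labs, platforms
  and batches, so any single differential-expression (DE) fit depends
  heavily on which samples happened to be included;
* **multi-step derivations** — a "lineage signature" is not one contrast
  but the intersection of several contrasts plus external evidence, so
  instability compounds.

`stromasig` implements a resampling protocol that turns contrast
instability from a nuisance into a measurement, together with every
supporting step: platform merging, frozen-reference normalization,
moderated DE, set-algebraic signature derivation, marker-panel enrichment,
PCA/clustering structure analysis, thresholded coexpression networks, and
growth-rate comparison. A first-class synthetic-data module generates
compendia with planted ground truth so that every claim the pipeline makes
is testable.

## The statistics at the core

For a two-group contrast with per-gene pooled variance *s²<sub>g</sub>* on
*d<sub>g</sub>* degrees of freedom, gene variances are modelled as draws
from a scaled inverse-χ² prior with hyperparameters (*d₀*, *s₀²*),
estimated by method of moments on log *s²*. The moderated statistic

&nbsp;&nbsp;&nbsp;&nbsp;*s̃²<sub>g</sub>* = (*d₀s₀²* + *d<sub>g</sub>s²<sub>g</sub>*) / (*d₀* + *d<sub>g</sub>*),
&nbsp;&nbsp;&nbsp;&nbsp;*t<sub>g</sub>* = logFC*<sub>g</sub>* / √(*s̃²<sub>g</sub>* (1/n<sub>A</sub> + 1/n<sub>B</sub>))

is referred to a t distribution on *d₀* + *d<sub>g</sub>* df, with
Benjamini–Hochberg FDR control (a gene is DE when fdr < 0.05; no
fold-change cutoff).

The **stability protocol** resamples each contrast: per iteration draw 7
columns per group with replacement, rerun the full moderated pipeline, and
call DE genes. The *stable* set is the running intersection of
per-iteration calls (direction-consistent by construction); iteration
stops when both stable-set sizes have been flat for a patience window
("plateau", default 20 iterations after at least 50) or at a hard cap
(200). Stable genes are ranked by FDR in every iteration and summarised by
their median rank. Contrasts over internally heterogeneous groups never
plateau — their stable set keeps eroding — which is exactly the diagnostic
the protocol is designed to expose.

Downstream, tissue-specific signatures are intersections of a class's
up-lists against every other stromal class; the conservative lineage core
intersects the tissue-vs-HSPC up-lists with a meta-analysis up-list and an
external expression footprint. Marker panels (CD antigens, cytokines) are
scored with the upper-tail hypergeometric test, coexpression networks keep
gene pairs with Pearson *r* ≥ 0.95, and population doubling times
PDT = T<sub>Expan</sub>·log 2 / log(Q₂/Q₁) are compared with the exact
Wilcoxon rank-sum test.

## Worked example

Run the full pipeline on the default synthetic compendium (2,000 genes; 60
samples in five classes — BM-MSC, AD-MSC, PL-MSC, FIB, HSPC — across three
batches; planted lineage and tissue signatures at logFC 1.5):

```bash
stromasig run --seed 0 --outdir demo
```

The run writes `expression.tsv`, `normalized.tsv`, per-contrast stability
tables, `core_signature.tsv`, `enrichment.tsv`, network files and PCA/
distance tables, plus a `manifest.yaml` with per-stage input/output hashes
(rerunning with an unchanged config skips every stage). Inspect the
signature flow:

```bash
$ python - <<'EOF'
import yaml
print(yaml.safe_load(open("demo/core_signature.yaml")))
EOF
{'inputs': {'AD-MSC_vs_HSPC': 174, 'BM-MSC_vs_HSPC': 180,
            'PL-MSC_vs_HSPC': 181, 'footprint': 180, 'meta_up': 140},
 'n_core': 140,
 'stages': [['after BM-MSC_vs_HSPC', 180], ['after AD-MSC_vs_HSPC', 142],
            ['after PL-MSC_vs_HSPC', 140], ['after meta_up', 140],
            ['after footprint', 140]]}
```

Reading: each tissue-MSC class had ~175–180 stably up-regulated genes
against the out-of-lineage HSPC group; intersecting the three lists, then
the pooled-mesenchymal meta list, then the external footprint leaves a
140-gene core. Of the 150 planted lineage genes, 140 are recovered
(93% recall) with zero false inclusions — the genes lost are those whose
simulated variance sits in the heavy tail of the inverse-χ² prior, which
is precisely the fragility the stability filter is built to remove.

Single operations are exposed as subcommands (`simulate`, `merge`,
`normalize`, `de`, `stability`, `signature`, `network`, `pca`, `growth`)
and as a plain Python API:

```python
import stromasig as ss
mat, ann, truth = ss.simulate_dataset(ss.SimulationConfig(seed=0))
contrast = ss.contrast_from_annotation(ann, "BM-MSC", "HSPC")
result = ss.resample_contrast(mat, ann, contrast, ss.ResamplingConfig(seed=0))
print(len(result.stable_up), result.plateaued)
```

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
generator and its limits, numerical choices and known limitations.
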