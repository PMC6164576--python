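# conexnet

Consensus miRNA co-expression modules and miRNA–mRNA–trait integration.

`conexnet` is for transcriptomics researchers who have a miRNA count matrix
measured under several conditions (for example dietary treatments of the
same animals), matched mRNA expression, phenotypes, and a table of
sequence-predicted miRNA targets, and who want to answer: *which groups of
miRNAs are co-expressed in every condition, which phenotypes do those
groups track, and which specific miRNA–mRNA pairs plausibly mediate the
relationship?*

## The method

Per condition, pairwise Pearson correlation is mapped to a **signed
similarity** s = (1 + r)/2, raised to a soft-thresholding power (β = 9) to
give a weighted adjacency a = s^β, and converted to a **topological overlap
measure**

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),

where l_ij sums shared-neighbour adjacency and k_i is connectivity. The
element-wise minimum of the per-condition TOMs (after quantile calibration)
is the **consensus** network; average-linkage clustering on 1 − TOM plus a
dynamic branch cut (minimum module size 20, deepSplit 2, mergeCutHeight
0.25) yields consensus modules, refined by eigengene-connectivity (k.ME)
reassignment. Each module is summarised by its **eigengene** (first
principal component of standardised member expression); members with
k.ME > 0.6 are its representatives and the maximum-k.ME member is the hub.
Modules with an eigengene–trait correlation |r| > 0.5 at p < 0.05 are
carried into integration: predicted targets above the 95th context++
percentile and present in the mRNA data are tested for negative
miRNA–mRNA correlation at Benjamini–Hochberg FDR < 0.05, and a
**miRNA–mRNA–trait triple** is reported when both members of a co-expressed
pair also correlate with the same trait at FDR < 0.05. Gene lists can be
tested for over-representation against GMT gene sets with a hypergeometric
test. Details and design rationale: [docs/methods.md](docs/methods.md).

The package also ships a synthetic-data generator that plants known modules
(shared-latent-factor model), eigengene-linked traits and negatively
regulated targets at the scale of the motivating study (321 miRNAs,
3 conditions × 12 samples, modules of 70/34/86), so that every stage is
testable without any data download, plus transcriptions of the study's
printed summary tables as packaged fixtures.

## Worked example

```python
from conexnet.synthetic import generate_dataset, recovery_ari
from conexnet.report import run_pipeline_data

ds = generate_dataset(seed=42)          # planted modules of 70/34/86
rep, art = run_pipeline_data(
    ds.mirna_counts, ds.condition_map, ds.phenotypes, ds.targets, ds.mrna_expr
)
print("module sizes:", rep.module_sizes)
print("selected modules:", rep.selected_modules)
print("triples:", rep.n_triples, "per trait:", rep.triples_per_trait)
print("ARI vs planted truth: %.3f" % recovery_ari(art["assignment"].labels, ds.truth))
```

prints

```
module sizes: {'turquoise': 86, 'blue': 70, 'brown': 36}
selected modules: ['blue', 'brown', 'turquoise']
triples: 41 per trait: {'trait_01': 14, 'trait_02': 12, 'trait_03': 15}
ARI vs planted truth: 0.985
```

The detected sizes track the planted 86/70/34 (labels are size-ranked
colours; `brown` here carries 2 extra borderline features), all three
modules are flagged against their planted trait, and 41 miRNA–mRNA–trait
triples survive the negative-correlation and FDR filters — each row a
(module, miRNA, gene, trait) record with the three correlations and FDRs.
The adjusted Rand index of 0.985 says the detected membership is
essentially the planted truth.

The same pipeline is available from the shell:

```
conexnet simulate  --seed 42 --out sim/
conexnet preprocess --counts sim/mirna_counts.tsv --conditions sim/conditions.tsv --out pre/
conexnet network   --expr-dir pre/ --out net/
conexnet traits    --expr-dir pre/ --modules net/modules.tsv --phenotypes sim/phenotypes.tsv --out tr/
conexnet integrate --expr-dir pre/ --mrna sim/mrna_expr.tsv --targets sim/targets.tsv \
                   --members tr/kme_selected.tsv --phenotypes sim/phenotypes.tsv --out integ/
conexnet verify-fixtures
```

`conexnet run --config cfg.toml` executes everything in one step, and
`conexnet enrich` tests a gene list against GMT sets.

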