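# rpos — robust proportional overlapping score gene selection

`rpos` is a filter-based feature-selection tool for binary-class
expression matrices (microarray or any numeric gene × sample table with
two-class labels). It ranks genes by how little their expression
distributions overlap between the two classes, using outlier-resistant
interval estimates, and assembles a final gene set from a greedy
set-cover pass plus a round-robin ranked list. It is aimed at the
n ≪ p regime where a classifier must be trained on a handful of genes
chosen from thousands.

## The method

For each gene *j* and class *c* a **core interval** is built from the
class's expression values:

    R_{j,c} = [ Q1_{j,c} − 0.9·MAD_{j,c},  Q3_{j,c} + 0.9·MAD_{j,c} ]

with Q1/Q3 the quartiles and MAD the raw median absolute deviation.
The MAD has a 50% breakdown point (versus 25% for the interquartile
range), so the intervals barely move even when a third of a class's
values are wild outliers. An IQR-dispersion variant is included as a
baseline for controlled comparisons.

From the two class intervals the method derives the overlap region
R^v_j (their intersection), the total core interval R_j (their span),
the non-outlier samples N_j (values inside their own class interval),
and the split of N_j into overlapped samples O_j (inside R^v_j) and
unambiguous samples O′_j. Each gene scores

    RPOS_j = 4 · (|R^v_j| / |R_j|) · (|O_j| / |N_j|) · φ_{j,0} · φ_{j,1}

where φ_{j,c} = |O_{j,c}|/|O_j| is class *c*'s share of the overlapped
samples; the factor 4 normalises the score into [0, 1]. **Smaller is
better**: a gene whose classes do not overlap scores 0.

Selection then runs in two stages: (1) a greedy set-cover over the
**gene masks** (the indicator of O′_j per gene) picks genes that
together classify the most training samples unambiguously; (2) the
remaining genes are split by their **relative dominant class** (the
class each gene separates better), sorted by ascending RPOS, and
interleaved round-robin. The final set of r genes takes the greedy
picks first, topped up from the ranked list.

## Worked example

```python
from rpos import (SelectionConfig, SyntheticSpec, generate_dataset,
                  select_genes, score_all_genes)

spec = SyntheticSpec(p=500, n_informative=10, n_per_class=(30, 30),
                     effect_size=2.5, seed=7)
ds = generate_dataset(spec)
cfg = SelectionConfig(n_genes=10)
result = select_genes(ds.data, cfg)
scores = {s.gene_id: s for s in score_all_genes(ds.data, cfg)[0]}
truth = {ds.data.gene_ids[j] for j in ds.informative_genes}
for rank, g in enumerate(result.final, 1):
    s = scores[g]
    print(f"{rank:>2}  {g}  rpos={s.rpos:.4f}  rdc={s.rdc}  "
          f"{result.provenance[g]:<10}  planted={g in truth}")
```

prints

```
 1  g222  rpos=0.0000  rdc=1  min_subset  planted=True
 2  g095  rpos=0.0000  rdc=1  min_subset  planted=True
 3  g086  rpos=0.0000  rdc=0  ranked      planted=True
 4  g042  rpos=0.0000  rdc=1  ranked      planted=True
 5  g121  rpos=0.0000  rdc=0  ranked      planted=True
 6  g289  rpos=0.0000  rdc=1  ranked      planted=True
 7  g342  rpos=0.0012  rdc=0  ranked      planted=True
 8  g194  rpos=0.0135  rdc=1  ranked      planted=True
 9  g160  rpos=0.0062  rdc=0  ranked      planted=True
10  g192  rpos=0.0198  rdc=1  ranked      planted=True
```

All ten selected genes are the ten planted informative ones: the two
greedy picks cover the training samples unambiguously, and the ranked
remainder is dominated by the other planted genes, whose scores sit at
or near 0 while noise genes score far higher. The `rdc` column shows
which class each gene separates better.

The same pipeline is available from the shell:

```bash
rpos synthesize --p 500 --n-informative 10 --seed 7 --output demo.csv
rpos select --input demo.csv --label-column class --n-genes 10 --output selected.tsv
rpos evaluate --input demo.csv --label-column class --runs 20 \
     --gene-counts 5,10 --classifier knn --seed 1 --output eval.json
```

`select` writes a TSV report (rank, gene_id, rpos, rdc, source);
`evaluate` runs the repeated random-split protocol — select genes on
the training part only, fit a classifier (random forest, k-NN, or SVM)
on the selected genes, and report error rate, Brier score and
sensitivity on the test part — as a JSON report.

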