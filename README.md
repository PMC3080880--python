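# anchorlign

Alignment and phylogenetic placement of hypervariable fungal ITS
sequences, built around two ideas: **iterative alignment/tree
co-estimation** and the **anchored alignment** of the ITS region.

The nuclear ribosomal internal transcribed spacer (ITS = ITS1 + 5.8S +
ITS2) is the standard fungal barcode, but across genera its spacers are so
divergent (whole-ITS similarity typically below 70%) that automated
multiple alignment — and with it, tree-based placement of unidentified
environmental sequences — becomes unreliable. The conserved ~160 nt 5.8S
gene embedded between the spacers is a particular hazard: alignment can
lock onto it and drag the variable spacers out of register.

`anchorlign` implements four strategies and compares them on data with
known truth:

| strategy | what it does |
|---|---|
| `baseline_whole` | one-pass progressive alignment + distance tree |
| `coest_whole` | iterated: guide tree → progressive alignment → tree re-estimation → Jukes–Cantor likelihood score, best pair kept |
| `coest_anchored` | 5.8S replaced by a constant 16-character anchor, then co-estimation on ITS1 + anchor + ITS2 |
| `coest_58s_reincluded` | the anchored strategy's best alignment with the true 5.8S spliced back, then tree + bootstrap support |

Environmental (unlabeled) sequences are placed by walking each query leaf
toward the root of the support-annotated tree: the first clade with
support > 0.94 whose references carry a single group label assigns that
label.

Because real multi-accession datasets are not redistributable, the package
ships a first-class simulator: Yule trees, Jukes–Cantor substitutions with
per-region rate multipliers (fast ITS1/ITS2 flanking a slow 5.8S),
Poisson/geometric indels, clade-defined group labels, masked queries, and
database-style artifacts (reverse-complemented, truncated, and fragment
records). It emits the true tree, the true alignment and region
annotations, so every pipeline stage is tested against ground truth.
See `docs/methods.md` for the model, parameter defaults, and numerical
conventions.

## Worked example

```python
from anchorlign import SimConfig, PipelineConfig, simulate_and_run

result = simulate_and_run(
    SimConfig(n_taxa=16, n_queries=4, seed=11),
    PipelineConfig(runs=2, iterations=5, bootstrap_replicates=100, seed=11),
)
cols = ["strategy", "ncol", "informative_percent", "supported_fraction",
        "rf_normalized", "n_assigned", "assignment_accuracy"]
print(result.comparison[cols].to_string(index=False))
```

prints

```
            strategy  ncol  informative_percent  supported_fraction  rf_normalized  n_assigned  assignment_accuracy
      baseline_whole   742                   40            0.818182       0.090909           3                  1.0
         coest_whole   776                   35            0.818182       0.181818           3                  1.0
      coest_anchored   637                   36            0.818182       0.272727           3                  1.0
coest_58s_reincluded   781                   34            0.818182       0.272727           3                  1.0
```

Reading the table: `ncol` is the alignment width the strategy produced;
`informative_percent` the share of parsimony-informative columns;
`supported_fraction` the share of internal edges with bootstrap support
above 0.94; `rf_normalized` the Robinson–Foulds distance to the true tree
(0 = topology fully recovered, 1 = no shared bipartitions); and the last
two columns show that 3 of the 4 masked environmental queries were placed
in a supported clade and every placement recovered the query's true group.
(One query record was excluded by the length/ITS2 filters — its record was
simulated as a database artifact.)

The same pipeline runs from the shell:

```bash
anchorlign simulate --out data/ --seed 11
anchorlign run-all --fasta data/records.fasta --regions data/regions.tsv \
    --groups groups.tsv --seed 11 --out out/
# or both steps at once:
anchorlign simulate-and-run --seed 11 --out out/
```

Individual stages are exposed as `anchorlign prep / anchor / align /
support / evaluate / assign`.

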