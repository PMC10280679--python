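# stressid

Stress-source identification for athlete cohorts: a two-phase
(dividing/agglomerating) hierarchical clustering algorithm, a Gaussian
radial-basis-function (RBF) anxiety classifier trained end-to-end by batch
gradient descent, weighted stress scoring, and a synthetic cohort
generator with embedded reference tables.

A cohort is a CSV with one row per athlete and twelve factor columns on a
`[0, 10]` scale, in three blocks: `A1–A4` (physical condition), `B1–B4`
(competition state), `C1–C4` (cognitive state).

## Library overview

| Module | Contents |
| --- | --- |
| `stressid.data_model` | `Dataset`, `Partition`, `AnxietyClass`, `RiskLevel`, CSV I/O, score validation |
| `stressid.hier_clustering` | histogram-valley split selection, `dividing_phase`, `agglomerating_phase`, `cluster` |
| `stressid.rbf` | `RBFNetwork`, analytic gradients, `train`, risk/class prediction, JSON persistence |
| `stressid.scoring` | weighted Q score, truncated column summaries, correlation-dendrogram factor grouping |
| `stressid.synthetic` | block-structured Gaussian cohort generator, embedded 10-athlete reference tables |
| `stressid.cli` | `stressid` command-line entry point |

```python
from stressid import GeneratorConfig, generate_cohort, cluster, train

cohort, labels = generate_cohort(GeneratorConfig(seed=1))
partition, tree = cluster(cohort)          # recovers the three classes
result = train(cohort.values, labels)      # RBF classifier, converged
```

## Command line

All commands are deterministic given their inputs and `--seed`; every
output gets a `.meta.json` sidecar with the configuration hash.

```sh
stressid simulate --n 500 --seed 1 --out-cohort cohort.csv --out-labels labels.csv
stressid cluster  --in-csv cohort.csv --out-partition partition.csv --out-tree tree.json
stressid train    --in-csv cohort.csv --labels-csv labels.csv \
                  --out-model model.json --out-trace trace.csv
stressid predict  --model model.json --in-csv cohort.csv --out-csv predictions.csv
stressid evaluate --model model.json --in-csv cohort.csv --labels-csv labels.csv \
                  --out-metrics metrics.json
stressid score    --in-csv cohort.csv --out-scores q.csv --out-summary summary.csv
```

Any flag can also be supplied through `--config file.yaml`.

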