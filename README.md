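# ontoeval

An evaluation framework for ontology-based gene-function prediction.
It implements the full assessment stack used to judge CAFA-style
submissions — gene-centric precision/recall with ancestor up-propagation
summarized by average precision, term-centric AUROC with mid-rank tie
handling, and an information-content "informativeness" criterion judged
against a prevalence null — together with the reference baselines
(prevalence, root-only, IEA carry-forward, per-species incidence), a
naive normalized-rank aggregator, and a synthetic benchmark generator
that produces complete worlds (ontology, annotation corpus,
waiting-period gold-standard update, simulated predictor families) with
known ground truth.

## Layout

| module | contents |
| --- | --- |
| `ontoeval.ontology` | OBO parsing, is_a DAG with per-namespace roots, reflexive ancestor closure, annotation/score up-propagation, information content, Resnik/Lin similarity |
| `ontoeval.annotations` | GAF 2.x reader/writer, evidence-code filtering, CAFA-style 3-column prediction I/O with (0,1] score and 1000-term cap validation, waiting-period target selection |
| `ontoeval.metrics` | per-gene PR curves and average precision, term AUROC, evaluable-term selection (10–100 members), informativeness threshold/score/rate, multifunctionality diagnostics |
| `ontoeval.baselines` | prevalence, root-only, IEA carry-forward and species-incidence predictors; average-normalized-rank aggregation along either axis |
| `ontoeval.synthetic` | seeded benchmark worlds: layered random DAGs, heavy-tailed corpora with species skew, confirmation-biased gold updates, noisy-oracle / homology-copy / prevalence-mimic / binary-oracle predictor families |
| `ontoeval.report` | end-to-end evaluation pipeline and TSV report writers |
| `ontoeval.cli` | `ontoeval` command (`simulate`, `baseline`, `aggregate`, `evaluate`) |

## CLI

Generate a benchmark world, derive baselines, and evaluate:

```sh
ontoeval simulate --seed 11 --n-terms 300 --n-genes 2000 --n-targets 200 \
    --predictor noisy_oracle:0.2 --predictor prevalence_mimic:0 \
    --out-dir world/

ontoeval baseline world/ontology.obo world/corpus_before.gaf prevalence \
    --out prevalence.tsv

ontoeval aggregate world/ontology.obo world/pred_*.tsv --out aggregate.tsv

cat world/corpus_before.gaf world/gold_update.gaf > after.gaf
ontoeval evaluate world/ontology.obo world/corpus_before.gaf after.gaf \
    world/pred_*.tsv --out-dir report/
```

`evaluate` writes `per_gene.tsv` (average precision, best semantic
similarity, informativeness flag per gene and algorithm), `per_term.tsv`
(AUROC per evaluable term) and `summary.tsv` (per-algorithm means and
the null threshold), plus the run configuration as JSON.

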