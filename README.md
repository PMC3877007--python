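# chemopanel

Drug-sensitivity panel analysis as a reusable, tested pipeline:

- **`dose_response`** — control normalization of plate signals (T/C, fraction
  affected) and 4-parameter logistic IC50 estimation with absolute-IC50
  censoring (`>X`) and mean aggregation over independent experiments.
- **`median_effect`** — median-effect line fitting (slope m, median-effect
  dose Dm, plot linearity r), dose/effect conversions, and combination-index
  scoring of constant-ratio drug pairs (exclusive and nonexclusive forms,
  synergism / additive / antagonism classification).
- **`profile_clustering`** — Ward agglomeration of compounds by their
  log10 IC50 fingerprint across the cell-line panel, with censoring policies
  and Newick export.
- **`expression_association`** — a per-gene Pearson correlation screen of
  natural-scale expression against compound potency, two-sided t-based
  p-values, an expression floor filter (signal > 500), a raw p < 0.0005 hit
  cutoff, and Bonferroni / Benjamini–Hochberg context thresholds.
- **`go_frequency`** — GO Biological Process term-frequency ranking (top 30)
  for association hit lists.
- **`pk_context`** — ng/ml ↔ µM conversion and Cmax-vs-IC50 exposure
  coverage, with a packaged clinical-exposure reference table.
- **`synth`** — synthetic generators with known ground truth (plates,
  constant-ratio combination experiments with a tunable interaction factor,
  clustered potency panels, expression matrices with planted correlations,
  annotation tables), used by the test suite and the demo pipeline.
- **`interface`** — TSV/CSV readers and writers (censored `>X` entries
  round-trip), YAML configuration, and the end-to-end orchestration.

## CLI

```sh
chemopanel run-all --seed 1 --out out/            # full synthetic demo
chemopanel simulate --seed 1 --out demo/          # same, writes all inputs/outputs
chemopanel fit --plates plates.csv --out potency.tsv
chemopanel synergy --plates plates.csv --drug-a A --drug-b B --mixture A+B \
    --ratio 0.5,0.5 --out ci.tsv
chemopanel cluster --potency potency.tsv --out-dir out/
chemopanel associate --expression expr.tsv --potency potency.tsv \
    --compound CPD1 --out assoc.tsv
chemopanel goterms --assoc assoc.tsv --annotation ann.tsv --out go.tsv
chemopanel pkconvert --ng-per-ml 1000 --mw 500
```

`run-all` accepts a YAML config (`--config`); every knob and stage toggle is
a field of `chemopanel.interface.PipelineConfig`. All randomness derives
from the single config seed, and outputs are byte-reproducible.

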