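# decluster

Differential-evolution clustering with a diversity-driven **double-mutation**
strategy, together with classical baselines (K-Means, K-Means++, standard
DE-K-Means) and a benchmark harness for repeated-run protocols on UCI-style
tabular data.

The optimizer encodes `k` cluster centers as a flat vector of `k*d` genes and
minimizes the **unsquared within-class distance** (WCD): the sum over all
objects of the Euclidean distance to the nearest center. Each generation it
measures population diversity as `lambda = sigma / ||mu||` (mean
individual-to-centroid distance over centroid magnitude) and picks the
mutation strategy accordingly:

* `lambda >= threshold` (population still spread) → **DE/best/1**, exploiting
  the incumbent optimum for fast convergence;
* `lambda < threshold` (population collapsed) → **DE/rand/1**, re-injecting
  exploration to escape local optima.

Binomial crossover and strict greedy selection complete the loop; runs stop
at a generation cap or after 400 consecutive generations with a bit-identical
best fitness. Individuals are initialized as k distinct randomly selected
data rows (the classical random-center convention; uniform-in-bounds
initialization is available via `DEConfig.init="uniform"`), which is what
makes every benchmark run land on the same optimum.

## Layout

| module | contents |
| --- | --- |
| `decluster.metrics` | distances, nearest-center assignment, WCD objective (scalar + vectorized batch) |
| `decluster.engine` | generic DE machinery: population, rand/1, best/1, current-to-best/1, crossover, selection, diversity indicator |
| `decluster.clustering` | center encoding, the double-mutation algorithm, the DE-K-Means baseline, run profiles |
| `decluster.kmeans` | Lloyd's K-Means and K-Means++ (D²) seeding |
| `decluster.datasets` | CSV / UCI `.data` readers, bundled Iris/Wine/Zoo, Gaussian-mixture and prescription-matrix generators |
| `decluster.benchmark` | repeated-run protocol, table-shaped summaries, JSON/text reports |
| `decluster.cli` | `decluster run …` command |

The bundled Iris keeps the two historically erroneous rows exactly as
distributed by the UCI repository (scikit-learn ≥ 0.23 silently corrects them
to Fisher's values, which shifts every benchmark statistic).

## CLI

```bash
decluster run --data builtin:iris --k 3 \
    --algo improved --algo de_kmeans --algo kmeans --algo kmeans_pp \
    --runs 40 --profile uci --seed 0 --out results/iris
```

`--data` also accepts a CSV/`.data` path or a synthetic spec such as
`synthetic:gaussian_mixture:k=3,n=300,d=2`. `--profile uci` uses F=0.6,
CR=0.5, NP=10·k·d, λ-threshold 0.005, stagnation 400, cap 1500;
`--profile tcm` switches to threshold 0.001 and cap 2500. Any profile field
can be overridden with `--config overrides.yaml`. Outputs: a fixed-column
text table, a full-precision JSON report, and per-run convergence CSVs.

## Reference values

With the bundled data and the `uci` profile, 40-run statistics reproduce:
Iris improved min = max = mean = 96.6555; Iris K-Means min = 97.3259; Iris
DE-K-Means min = 96.6555; Wine improved min = 16292.1846; Zoo improved min
≈ 98.8 (the Zoo runs never converge within the 1500-generation cap, so the
minimum keeps improving with initialization quality; see the benchmark
tables for the classical reference values).
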