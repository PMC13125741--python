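# fscore

Exact and large-sample statistical inference for F-beta classification
scores: confidence intervals, hypothesis tests, and power / sample-size
calculations for a single classifier and for the difference between two
independent classifiers evaluated on a shared test set.

## Model

A classifier observed on a test set with `N` instances, `S` actual
positives, `d` true positives and `b` false positives has estimated score

```
f_beta = (1 + beta^2) d / (b + d + beta^2 S)          (F1 when beta = 1)
```

`d ~ Binomial(S, ps)` and `b ~ Binomial(N-S, p_alpha)` are treated as
independent, and `p_alpha` is calibrated so the expected estimated score
equals the target score implied by a (sensitivity `ps`, precision `pp`)
pair.  Everything downstream works with the exact discrete distribution
of `f_beta` (or of the difference of two such scores):

- **`ci_one` / `ci_two`** — equal-tail intervals on the exact support,
  with add-0.5 smoothed plug-in rates.
- **`test_one_point`** — minimum-tail exact test of H0: score =
  F_beta(ps0, pp0).
- **`test_one_benchmark`** — supremum of the point-null p-value over the
  iso-score curve of a benchmark value (no (ps0, pp0) required).
- **`test_two_pooled` / `test_two_sup`** — tests for equality of two
  classifiers' scores via the pooled-rate null, or the conservative
  supremum over all common score values.
- **`power_one` / `power_two`, `sample_size_one` / `sample_size_two`** —
  exact analytic power, and minimal-N design search with `S = N * pI`.
- **`normal_approx`** — delta-method normal surrogates used automatically
  when the exact support exceeds a mass-point threshold (default 20 000).
- **`sim_bench`** — seeded confusion-table generator plus Monte-Carlo
  harness for coverage, type-I error and empirical power grids.

## Command line

Every subcommand emits a JSON result (inputs, method used, version) to
stdout; `--mode {auto,exact,normal}` selects the computation path.

```bash
fscore ci-one   --N 15841 --S 38 --tp 38 --fp 9 --level 0.95
fscore ci-two   --N 15841 --S 38 --tp1 38 --fp1 9 --tp2 30 --fp2 854
fscore test-one --N 50 --S 20 --tp 16 --fp 10 --ps0 0.8 --pp0 0.5
fscore test-one --N 50 --S 20 --tp 16 --fp 10 --fbeta0 0.615   # benchmark null
fscore test-two --N 15841 --S 38 --tp1 38 --fp1 9 --tp2 30 --fp2 854
fscore power-one --N 150 --S 60 --ps0 0.8 --pp0 0.5 --ps1 0.9 --pp1 0.6
fscore power-two --N 250 --S 100 --ps1 0.8 --pp1 0.5 --ps2 0.9 --pp2 0.6
fscore size-one  --ps0 0.8 --pp0 0.5 --ps1 0.9 --pp1 0.6 --pI 0.4 --target-power 0.9
fscore simulate  --scenario coverage-single --reps 1000 --seed 0 --tsv grid.tsv
```

Exit codes: 0 success, 2 validation error, 3 infeasible design (no
false-positive rate can reach the requested score — increase `S` or
adjust the rates).

## Library example

```python
from fscore import ConfusionTable, PairedObservation, PerfParams, ci_one, power_two

ci = ci_one(ConfusionTable(N=15841, S=38, d=38, b=9), level=0.95)
print(ci.lower, ci.upper)          # 0.817, 0.950

res = power_two(PerfParams(ps=0.789, pp=0.034), PerfParams(ps=1.0, pp=0.809),
                N=1584, S=4, alpha=0.001)
print(res.power)                   # 0.98
```

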