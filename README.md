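# lakeq

Reinforcement-learning model selection with residual compensation for
multivariate water-quality forecasting.

Hourly records of lake-eutrophication indicators (permanganate index, COD,
BOD₅, TOC, NH₃-N, chroma, conductivity, TDS, turbidity, NO₃-N, chlorophyll-a,
fluoride) switch character abruptly — smooth diurnal stretches, storm-driven
level shifts, noisy bloom periods — and no single forecasting model is best
everywhere. `lakeq` treats the choice of forecaster as a sequential decision
problem: a tabular triple-Q agent picks, at every hour, which base model to
trust, and a second identical learning pass over the first pass's error
series predicts the forecast error, which is added back into the final
prediction ("dual" compensation).

## The method

**Exploration schedule.** The probability of exploiting the learned table
grows with the episode index *u* along an arctangent curve,
ε(*u*) = (2/π)·arctan(*s*(*u* − *u*₀)) (defaults *s* = 0.2, *u*₀ = 0.1):
early episodes explore widely, later ones are almost purely greedy.

**Multi-indicator reward.** A forecast ŷ of the s-vector y earns
*R* = (1/s) Σᵢ −|yᵢ − ŷᵢ| on z-scored channels — zero only for a perfect
forecast, negative otherwise.

**Triple-Q update.** Three tables Q₁, Q₂, Q₃ are all moved toward their own
bootstrapped targets from the shared combined table Q\*:

    Qᵢ(S,A) ← Q*(S,A) + α [R + γ·maxₐ Qᵢ(S′,a) − Q*(S,A)],  i = 1,2,3

and the touched cell of Q\* is rebuilt from the cellwise mean and minimum,

    λ = |Q_ave − Q_min| / (c + |Q_ave − Q_min|),
    Q* = λ·Q_ave + (1 − λ)·Q_min,

a pessimism-weighted combination that counteracts the max-operator's
optimism. States and actions both index the registered model set (the state
at *t*+1 is the model chosen at *t*). Defaults: α = 0.1, γ = 0.9, c = 1.

**Dual stages.** Stage 1 learns model selection on the indicator series; a
deterministic greedy pass produces the preliminary predictions and the error
series (truth − preliminary); stage 2 re-initializes everything and learns
to forecast the next error; at prediction time the corrected error is added
to the preliminary forecast.

**Preprocessing.** Recursive average filtering (trailing uniform window,
ramp-in partial sums at the start) denoises each channel; correlation PCA
reports eigenvalues, variance-interpretation rates, SPSS-convention
loadings, communalities and the cumulative ≥ 85 % retention rule, with KMO
and Bartlett sphericity as suitability diagnostics.

## Worked example

```python
from lakeq import (
    RegimeSpec, RunConfig, SmootherConfig, SyntheticSpec,
    evaluate_one_step, fit_pca, generate, generate_regime_benchmark,
    mae, recursive_average_filter, run_dd,
)

series = generate(SyntheticSpec(seed=1))          # 1008 h x 12 indicators
smoothed = recursive_average_filter(series, SmootherConfig(5))
report = fit_pca(smoothed, retention_threshold=85.0)
print(f"KMO {report.kmo:.3f}; Bartlett chi2 {report.bartlett_chi2:.1f} "
      f"on {report.bartlett_df} df")
print(f"retained {report.n_components} components "
      f"({report.cumulative_rates[report.n_components-1]:.1f}% of variance)")

bench, labels = generate_regime_benchmark(RegimeSpec(seed=0))
dd = run_dd(bench, RunConfig(seed=0))             # both learning stages
res = evaluate_one_step(dd, bench, 900, 990)      # held-out 90 hours
print(f"test MAE  final (DD-3Q): {mae(res['truth'], res['final']):.4f}")
print(f"test MAE  preliminary  : {mae(res['truth'], res['preliminary']):.4f}")
```

prints

```
KMO 0.869; Bartlett chi2 26011.7 on 66 df
retained 3 components (93.7% of variance)
test MAE  final (DD-3Q): 0.9757
test MAE  preliminary  : 0.9864
```

The KMO of 0.87 says the synthetic indicators share enough correlation for
PCA to be meaningful; three components carry 94 % of the variance. On the
regime-switching benchmark the compensated (dual-stage) forecast improves on
the preliminary single-stage forecast. `res["choices"]` logs the model each
stage picked at every hour.

The same chain is available from the shell:

```bash
lakeq simulate --out data.csv --seed 1
lakeq preprocess --input data.csv --window 5 --retention 85 --output-dir prep/
lakeq train --input prep/smoothed.csv --out model/
lakeq predict --model model/ --history prep/smoothed.csv --horizon 90 --out forecast.csv
lakeq evaluate --truth truth.csv --pred forecast.csv
```

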