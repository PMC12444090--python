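# stabcurve

**Adaptive-sampling learning curves for dataset-size planning.**

How much data does a model need before its accuracy — and the run-to-run
spread of that accuracy — is good enough?  `stabcurve` answers this for
any fit/predict model (and, in a model-free mode, for plain test
statistics) by treating the available dataset as a pool from which smaller
datasets are repeatedly subsampled, stabilizing the resulting accuracy
distributions, fitting power-law learning curves and extrapolating them.

The distinguishing piece is the *adaptive repetition loop*: at each sample
size, `m ≥ 2` parallel accuracy distributions are grown in blocks of `k0`
repetitions until their mean, median and 25th/75th percentiles agree
pairwise within a user tolerance.  The repetition count is thus chosen
automatically per sample size — enough to make conclusions independent of
the sampling run, no more than needed.  Each characteristic is then fit
against sample size with

    f(d) = α·d^β + γ

whose asymptote γ is the *limit accuracy* (the accuracy approached with
unbounded data); inverting f gives the dataset size required for a target
accuracy or uncertainty.  A shuffled-target baseline locates the minimum
size where real learning starts, and a percentile-crossing check flags
where the fitted curves stop being trustworthy.

Intended users: anyone costing out data collection or annotation — ML
practitioners planning labeling budgets, life scientists sizing
measurement campaigns, statisticians stabilizing effect-size estimates for
power analyses.

## Worked example

A synthetic pool `y = x + ε` with unit signal and unit noise has a known
limit test R² of `1/(1+1) = 0.5` — so we can check the tool against the
truth:

```python
import numpy as np
import stabcurve as sc

spec = sc.SyntheticSpec(n_samples=2000, weight_vector=(1.0,), noise_sd=1.0, seed=11)
pool = sc.generate_pool(spec)

config = sc.StudyConfig(
    size_ladder_S=tuple(np.linspace(10, 100, 10)),  # % of the pool
    m_instances=2, k0_base_reps=100, tolerance=0.005,
    max_reps_cap=1_000_000, master_seed=11,
)
results = sc.run_study(pool, sc.OLSAdapter(), config)
for r in results:
    print(f"n={r.n_percent:5.1f}%  d_n={r.d_n:4d}  k_n={r.final_k_n:5d}  "
          f"test mean R2={r.summaries[(1, 'te')].mean:.4f}")

points = sc.build_curve_points(results, "te", "mean", instance_j=1)
fit = sc.fit_power_law(points, split="te", characteristic="mean")
print(f"limit accuracy gamma = {fit.gamma:.4f}")
print(f"test rows needed for R2=0.48: {sc.required_sample_size(fit, 0.48):.0f}")
```

Output:

```
n= 10.0%  d_n= 200  k_n= 1400  test mean R2=0.4717
n= 20.0%  d_n= 400  k_n=  900  test mean R2=0.4842
n= 30.0%  d_n= 600  k_n=  400  test mean R2=0.4918
n= 40.0%  d_n= 800  k_n=  300  test mean R2=0.4882
n= 50.0%  d_n=1000  k_n=  300  test mean R2=0.4913
n= 60.0%  d_n=1200  k_n= 1200  test mean R2=0.4934
n= 70.0%  d_n=1400  k_n=  300  test mean R2=0.4953
n= 80.0%  d_n=1600  k_n=  200  test mean R2=0.4957
n= 90.0%  d_n=1800  k_n=  200  test mean R2=0.4962
n=100.0%  d_n=2000  k_n=  900  test mean R2=0.4943
```

and `limit accuracy gamma = 0.4989`, `test rows needed for R2=0.48: 89` —
the fitted asymptote lands on the analytic 0.5 to within about 0.001, and
the adaptive loop spent 1400 repetitions where the distributions were
noisy but only 200–400 where they were already stable.

Notice the values: the *observed* test R² at the full pool is 0.4943, but
the *extrapolated* limit is 0.499 — the curve separates "what the data
shows now" from "what more data would buy".

## Command line

```bash
stabcurve fit      --config examples/synthetic.yaml --out run1      # adaptive study
stabcurve curves   --config study.yaml --target-accuracy 0.48       # fits + extrapolation
stabcurve curves   --config study.yaml --holdout-points 7           # fit 7 points, test the rest
stabcurve baseline --config study.yaml                              # minimum learning size n0
stabcurve stat     --config study.yaml --statistic mean             # model-free statistic mode
stabcurve fixed    --config study.yaml --reps 50                    # non-adaptive comparator
```

Each run writes a tidy `accuracies.csv` (one row per repetition) and a
`manifest.json` that echoes the full configuration and master seed — a run
is bit-reproducible from its manifest.

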