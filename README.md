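# cppopt

Continuous, autoregulation-oriented optimal cerebral perfusion pressure
(CPPopt) targeting from 10-s averaged arterial blood pressure (ABP) and
intracranial pressure (ICP) trends.

The package implements the multi-window weighted CPPopt algorithm in two
variants sharing one code path:

* **new** (default): 5-min *median* CPP pre-filter, 3 % minimum bin count,
  an R²_full ≥ 0.2 criterion, and weight = R²_full for accepted parabolic
  fits;
* **previous**: 5-min *mean* pre-filter, 2 % minimum bin count, no R²
  criterion, and weight = exp(−window hours) · exp(−fit RMSE).

Every minute, PRx (the moving 5-min Pearson correlation of 10-s ABP and
ICP) is plotted against pre-filtered CPP over 36 trailing windows
(2 h 10 min … 8 h by 10 min), binned into 5-mmHg bins over 40–120 mmHg,
fitted with a quadratic on the Fisher-transformed PRx scale, judged
against an acceptance-criteria stack (data coverage, parabolic shape,
minimum Y span 0.2, Y region [−0.3, 0.6], R²_full), combined by weighted
average, and smoothed with an exponentially weighted average
(α = 0.1, 2-h buffer). No value is emitted until 4 h of valid input has
accumulated (50 % of the maximal 8-h buffer).

Also included:

* `cppopt.simulate` — virtual patients whose windowed ABP–ICP correlation
  is a programmable U-shaped function of CPP (known ground-truth optimum),
  and Fourier phase-randomized surrogates for false-positive testing;
* `cppopt.metrics` — stability index, yield, CPP−CPPopt deviation, jump
  counting, plausibility;
* `cppopt.evaluation` — cohort runner, Mann–Whitney p-values, rank AUC.

## CLI

```sh
# generate a 10-h virtual patient and compute its CPPopt trend
cppopt simulate --spec patient.yaml --out rec.csv
cppopt compute --input rec.csv --variant new --out trend.csv

# phase-randomized surrogate of a recording
cppopt surrogate --input rec.csv --seed 7 --out rec_noise.csv

# trend quality report / cohort comparison
cppopt metrics --trend trend.csv --out report.json
cppopt cohort --specs specs.yaml --outcome-seed 1 --out cohort.json
```

Recording CSVs have columns `datetime` (ISO-8601), `abp[mmHg]`,
`icp[mmHg]`; empty cells are missing samples. Trend CSVs add `cpp`,
`prx`, `prx_ft`, `cppopt_raw`, `cppopt`, `n_windows`,
`rejection_summary`. Configuration YAML keys mirror the
`CppoptConfig` field names (e.g. `n_bins`, `min_bin_count_frac`,
`weighting`); unknown keys are rejected.

## Python API

```python
from cppopt import CppoptConfig, VirtualPatientSpec, compute_cppopt, simulate_patient

abp, icp = simulate_patient(VirtualPatientSpec(duration=36000, true_opt=75, seed=1))
trend = compute_cppopt(abp, icp, CppoptConfig())
trend.smoothed        # minute-by-minute CPPopt (SampledSeries)
```

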