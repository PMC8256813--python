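# weibullcv

Interval estimation for the **difference between the coefficients of
variation of two independent Weibull distributions**, with a Monte-Carlo
engine for evaluating coverage probability and expected length.

The Weibull distribution, with density

```
f(x; a, k) = (k/a) (x/a)^(k-1) exp[-(x/a)^k],   x > 0,
```

is the standard model for wind-speed measurements (and for lifetimes and
other positive skewed data).  Its coefficient of variation depends only on
the shape parameter,

```
λ(k) = sqrt( Γ(1 + 2/k) / Γ(1 + 1/k)² − 1 ),
```

so comparing the *relative* dispersion of two sites or populations —
for instance to decide which area has the steadier wind resource for a
turbine installation — reduces to interval estimation of

```
δ = λ(k_X) − λ(k_Y)
```

from two independent samples.  `weibullcv` implements six interval
constructions for δ:

| tag        | construction |
|------------|--------------|
| `GCI`      | generalized confidence interval from generalized pivotal quantities of the shapes |
| `PB`       | percentile bootstrap |
| `BS`       | bootstrap with standard errors (normal interval around the MLE plug-in δ̂) |
| `MOVER_HR` | MOVER recombination of per-group Hendricks–Robey CV intervals |
| `MCMC`     | Bayesian equal-tailed credible interval (Gibbs + random-walk Metropolis) |
| `HPD`      | Bayesian highest-posterior-density interval from the same chains |

plus maximum-likelihood fitting (Newton–Raphson with the Menon closed-form
start), AIC/BIC screening of Weibull vs exponential/gamma/log-normal fits,
a synthetic-data generator, and a simulation engine that reproduces
coverage/expected-length tables over a 96-cell scenario grid.

## Worked example

Generate a small synthetic two-site dataset and analyze it:

```
$ weibullcv fixture --nx 12 --ax 1.8 --kx 1.5 --ny 11 --ay 4.6 --ky 9.1 --seed 7 --out winds
$ weibullcv analyze --x winds.csv --long --value-col value --group-col group --seed 1
# weibullcv 0.1.0  seed=1  alpha=0.05  q=2500 B=500 T=20000 burn_in=1000 prior=0.1,0.1,0.1,0.1
# inputs: winds.csv:9414d1889bf3
groups: X (n=12), Y (m=11)
scale_x=1.8275 shape_x=1.5824 cv_x=0.6464
scale_y=4.7879 shape_y=8.6918 cv_y=0.1373
delta_hat=0.5091
  method  lower  upper  length
     GCI 0.3114 1.0739  0.7625
      PB 0.2456 0.6979  0.4523
      BS 0.2657 0.7526  0.4869
MOVER_HR 0.2115 0.8068  0.5953
    MCMC 0.2492 0.9560  0.7068
     HPD 0.1981 0.8742  0.6760
```

Site X (shape 1.58) has CV 0.65, site Y (shape 8.69) has CV 0.14: X's wind
speeds are far more variable relative to their mean.  Every 95% interval
for δ = λ_X − λ_Y lies above zero, so the difference in relative dispersion
is significant at that level.  The same workflow is available in Python via
`weibullcv.read_samples` / `weibullcv.analyze_two_samples`.

Coverage studies run from the same CLI:

```
$ weibullcv simulate --reduced --seed 0 --out results.csv     # 96-cell grid, desk scale
```

or per-cell in Python:

```python
from weibullcv import Scenario, run_scenario
(r,) = run_scenario(Scenario(n=10, m=10, k_x=1, k_y=1, methods=("MOVER_HR",), M=5000, seed=0))
print(r.coverage, r.expected_length)   # 0.965 1.3456
```

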