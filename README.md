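# sempower

Monte Carlo power analysis for selecting among **non-nested structural
equation models**.

When competing theories about a psychological construct translate into
factor models that are not nested — say, a unitary "g-factor of memory"
versus a bi-partite episodic/semantic split versus a tri-partite
pattern-separation / pattern-completion / generalization architecture —
the classical likelihood-ratio χ² test is unavailable, and the sample size
needed to tell the models apart cannot be read off a rule of thumb.
`sempower` answers the planning question by brute force: simulate data
from the hypothesized population model, fit every candidate by maximum
likelihood, apply a model-selection rule, and count how often the
generating model wins.

It is aimed at researchers planning latent-variable studies (the built-in
case study is a 13-task memory battery for developmental samples), but the
machinery — model dialect, ML estimator, fit indices, selection rule,
simulation engine — is generic confirmatory factor analysis.

## The model and the decision rule

Each candidate is a confirmatory factor model for p = 13 standardized task
scores,

    Σ(θ) = Λ Φ Λ' + Θ,

with loadings Λ, factor correlations Φ and diagonal residual variances Θ.
Population models fix every loading at `a`, residuals at `1 − a²`, and all
factor correlations at `r`; two tasks in the tri-partite model load on two
factors at once with the rescaled value `b = a / √(2 + 2r)`, so every
indicator keeps unit variance. Candidate models are fitted by minimizing
the normal-theory discrepancy

    F_ML = ln|Σ(θ)| − ln|S| + tr(S Σ(θ)⁻¹) − p,

giving T = n·F_ML, CFI, RMSEA and BIC = −2ℓ + q·ln n per model. One
replication is scored by the two-stage rule: keep candidates with
**CFI > .95 and RMSEA < .06**, then select the **lowest BIC** among them;
if any candidate fails to converge, or none passes, no model is selected
and the replication counts as a recovery failure. "Power" is the
proportion of replications selecting the generating model; "type-I error"
is the proportion selecting the focal complex model when a simpler one
generated the data.

## Worked example

Estimate the power to recover the tri-partite model at loadings 0.7 and
factor correlations 0.3 for two candidate sample sizes:

```python
import sempower as sp
from sempower import mc_engine

design = mc_engine.build_design([0.7], [0.3], [50, 125], 3, replications=200)
summary = mc_engine.summarize(mc_engine.run(design, master_seed=7))
print(summary[["a", "r", "n", "power_correct", "power_mc_se", "n_nonconvergence"]])
```

```
  a   r   n  power_correct  power_mc_se  n_nonconvergence
0.7 0.3  50           0.51     0.035348                 0
0.7 0.3 125           0.97     0.012062                 0
```

At n = 50 the correct model wins only about half the time; at n = 125 the
design is adequately powered (97% ± 1.2% here; 1000-replication runs pin
this cell at ≥ 95%). Loadings themselves can be planned from published
reliabilities:

```python
>>> sp.loading_from_reliability(0.7, 4)   # Cronbach's alpha 0.7 from 4 items
0.6070...
```

The same engine runs from the shell:

```sh
sempower run -c config.yaml          # writes results.csv, summary.csv, manifest.yaml
sempower plot out/summary.csv -o fig/power_curves
sempower convert-reliability --alpha 0.7 --k 4
sempower validate-model model3.txt
```

where `config.yaml` lists the generating model, the `a`/`r`/`n` grids, the
replication count and the master seed. Results are bit-reproducible for
any degree of parallelism: each replication draws from a stream keyed on
(master seed, condition index, replication index).

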