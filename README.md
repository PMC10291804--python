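# bifcat

Bifactor graded-response calibration and multidimensional computerized
adaptive testing (MCAT) simulation for ordinal patient-reported outcome
instruments.

Long multidimensional health-related quality-of-life questionnaires burden
patients and clinicians. If the item pool is calibrated under an item
response theory model, an adaptive test can pick, respondent by respondent,
only the items that are informative at the current trait estimate and stop
once a precision target is met — often halving the instrument's length
without losing measurement quality on the main score. `bifcat` provides the
complete simulation pipeline for studying this trade-off on instruments
with a *bifactor* structure (every item loads on a broad general factor and
at most one domain-specific group factor, all factors mutually
uncorrelated), such as the 54-item multiple-sclerosis quality-of-life
inventory whose 44-item calibrated pool motivates the default settings.

## The model and the adaptive loop

Responses follow the bifactor graded response model. For an item with
ordered categories `x ∈ {0, …, K−1}`, general slope `a_g`, group slope
`a_s` on group factor `s`, and strictly decreasing intercepts
`d_1 > … > d_{K−1}`:

    P*_k(θ) = logistic(a_g θ_0 + a_s θ_s + d_k),    P_k = P*_k − P*_{k+1}

with `P*_0 = 1`, `P*_K = 0`. Calibration is marginal maximum likelihood by
Bock–Aitkin EM; the bifactor structure reduces all integrals to
two-dimensional quadrature regardless of the number of group factors, and
missing responses simply drop out of the likelihood (full information).
Local dependence is screened with Yen's Q3 (residual correlations above
0.20 flag a pair; the member with the smaller integrated information
function is removed).

The adaptive engine scores by the multidimensional maximum a posteriori
(MAP) estimator under an MVN(0, I) prior, and selects items by the
determinant rule: administer the candidate maximizing
`det(J + I_i(θ̂))`, where `J` is the current posterior information matrix
and `I_i` the item's Fisher information. Stopping follows a 2×2×2
factorial of rules — SE threshold on the general factor (0.32 or 0.40,
i.e. reliability `1 − SE²` of 0.90 or 0.84), SE threshold 0.50 on every
group factor, and a minimal change of 0.01 in `θ̂` from one item to the
next — plus a no-rule "full" benchmark. Performance is summarized by
administered-item counts, item reduction, SE at termination, Pearson
correlation of `θ̂` with the simulated truth, and
`RMSD = sqrt(Σ_j (θ̂_j − θ_j)² / N)`.

## Worked example

```python
import bifcat as bc

bank = bc.generate_item_bank(bc.BankSpec(seed=3))      # 44 items, 10 groups
thetas = bc.generate_thetas(200, bank.D, seed=11)      # MVN(0, I_11) truths
responses = bc.simulate_responses(thetas, bank, seed=12)
results = bc.run_design(bc.factorial_design(), bank, thetas, responses)
summary = bc.summarize_design(results, thetas, bank)
print(summary[["simulation", "median_items", "item_reduction_pct",
               "mean_se_general", "correlation_general", "rmsd_general"]]
      .round(3).to_string(index=False))
```

prints

```
simulation  median_items  item_reduction_pct  mean_se_general  correlation_general  rmsd_general
      full          44.0               0.000            0.167                0.982         0.184
      sim1          44.0               0.000            0.167                0.982         0.184
      sim2          35.0              25.693            0.199                0.974         0.220
      sim3          15.0              65.273            0.301                0.946         0.318
      sim4          15.0              65.568            0.303                0.945         0.320
      sim5          44.0               0.000            0.167                0.982         0.184
      sim6          35.0              25.693            0.199                0.974         0.220
      sim7          11.0              74.034            0.363                0.927         0.365
      sim8          11.0              74.091            0.364                0.927         0.365
```

Rows `sim1`/`sim5` administer the whole bank: the 0.50 group-SE rule binds
because ten small group factors must all reach that precision, so the rows
differing only in the general-factor threshold coincide (likewise
`sim2`/`sim6`). Relaxing the general threshold from 0.32 (`sim3`) to 0.40
(`sim7`) shortens the median test from 15 to 11 items at the cost of a
higher RMSD (0.318 → 0.365) and a lower correlation with the true general
trait. The `examples/` directory walks through each capability
(bank/response generation, calibration and Q3 screening, a step-by-step
adaptive trace, the factorial design); a thin CLI (`bifcat make-bank`,
`make-data`, `calibrate`, `screen`, `simulate`, `evaluate`, `run-study`) wraps
the same pipeline for shell use.

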