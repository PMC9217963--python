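# symnet

Network analysis of binary lifetime symptom data with polygenic and
environmental risk factors: regularized Ising network estimation, bridge-node
identification, bootstrap stability diagnostics, and the accompanying
sensitivity analyses — plus a synthetic-cohort generator so every stage runs
end-to-end without access-controlled participant data.

## The problem

Depression and psychosis frequently co-occur. The network approach to
psychopathology treats this comorbidity as arising from interactions between
individual symptoms rather than between disorder-level sum scores: a
**bridge symptom** is one that connects the symptom clusters of two
disorders and can spread activation between them. This package implements
the full analysis pipeline used to find such bridges in large
questionnaire cohorts (binary lifetime symptom items, plus risk factors
such as cumulative trauma, neighborhood deprivation, air pollution,
greenspace and polygenic risk scores), for example in UK Biobank-style
mental-health questionnaire data, where the raw data are access-controlled.

## The model

Binary items x ∈ {0,1}^p are modelled as a pairwise Markov random field
(Ising model)

    P(x) ∝ exp( Σᵢ τᵢ xᵢ + Σ_{i<j} ω_ij xᵢ xⱼ )

whose couplings ω_ij are conditional log-odds-ratios: an edge is an
association that survives conditioning on all other nodes, read like a
partial correlation. Estimation is **eLasso**: each node is regressed on
all others by ℓ1-penalized logistic regression; the penalty minimizing the
extended Bayesian Information Criterion

    EBIC = −2ℓ + k·ln n + 2γ·k·ln(p−1),   γ = 0.25 by default

is selected per node, and the two directed coefficients of each pair are
symmetrized (AND rule, mean aggregation). For mixed binary/continuous data
a pairwise **mixed graphical model** replaces the per-node family
(logistic/Gaussian) as appropriate.

Downstream indices: strength, closeness, betweenness, expected influence,
and one-/two-step **bridge expected influence** over predefined symptom
communities; the top 25% of nodes by two-step bridge EI are the bridges.
Stability is assessed with case-dropping bootstrapped centrality
(CS-coefficient; ≥ 0.5 is conventionally stable) and bootstrapped edge-weight
confidence intervals with a 70% retention rule.

## Worked example

```python
import symnet as sn

# synthetic 20k-participant cohort: 14 binary symptom/impairment items with
# realistic endorsement rates, skip logic, and planted bridge couplings
cohort = sn.ukb_like_cohort(n=20_000, seed=7)

res = sn.IsingModel(cohort.step1_items).fit()
print(res.summary())

cent = res.centrality(communities=cohort.step1_items.communities)
bridges = sn.select_bridges(cent["bei2"], fraction=0.25)
print("bridge nodes:", ", ".join(bridges.selected))
```

prints

```
Ising network (eLasso, EBIC selection)
==========================================
nodes:            14
observations:     20000
gamma:            0.25
rule:             AND
possible edges:   91
nonzero edges:    43 (47%)
mean |weight|:    1.06
bridge nodes: Dei, Psi, Con, Wor
```

Of the 91 possible edges among the 14 nodes, 43 survive EBIC selection under
the AND rule, with mean absolute conditional log-odds-ratio 1.06. The four
nodes with the highest two-step bridge expected influence — depression
impairment (`Dei`), psychosis impairment (`Psi`), conspiracy beliefs (`Con`)
and feelings of worthlessness (`Wor`) — are exactly the cohort generator's
planted bridge nodes.

The same analysis runs from the shell:

```bash
symnet simulate --n 20000 --seed 7 --out cohort
symnet estimate --in cohort.cohort.tsv --meta cohort.meta.tsv --out net
symnet metrics --net net.json --meta cohort.meta.tsv --out centrality.tsv
symnet stability --in cohort.cohort.tsv --meta cohort.meta.tsv --b 1000 \
    --seed 7 --out stability.json
```

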