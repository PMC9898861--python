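# symptomnet

Network psychometrics for two-wave binary symptom panels, built around
the 9-item Problem Gambling Severity Index (PGSI) but usable with any
p ≥ 2 binary symptom screen.

Symptom-network analysis treats a disorder as a system of interacting
symptoms rather than manifestations of a single latent cause. For rare,
dichotomized symptoms (community gambling samples endorse individual
PGSI items at only ~2–8%), the appropriate cross-sectional model is the
Ising model — a pairwise Markov random field on {0,1}^p,

    P(x) ∝ exp( Σᵢ τᵢ xᵢ + Σ_{i<j} W_ij xᵢ xⱼ ),

whose couplings W are estimated by node-wise L1-penalized logistic
regression with extended-BIC model selection (γ = 0.25) and AND-rule
edge assembly. Longitudinal spread between waves is modelled as a
cross-lagged panel network (CLPN): per wave-2 symptom, an L1 logistic
regression on all wave-1 symptoms, with the penalty chosen by tenfold
cross-validated deviance and the one-standard-error rule. Around these
two estimators the package provides:

- PGSI scoring, risk classification (0 / 1–2 / 3–7 / 8+), dichotomization,
  prevalence tables, Cronbach's α, paired t and McNemar tests;
- strength / closeness / betweenness centrality (undirected) and
  in-/out-strength (directed), raw and standardized;
- congruence of two networks (edge-presence φ, Spearman ρ) and
  permutation invariance tests on the maximum edge difference (M) and
  global-strength difference (S);
- bootstrap edge CIs, edge/centrality difference tests, and the
  case-dropping correlation-stability (CS) coefficient;
- a synthetic two-wave generator with known ground-truth networks, so
  every estimator is validated by parameter recovery.

See `docs/methods.md` for the full model and design documentation.

## Worked example

Generate a panel from the `strong_recovery` scenario (a 9-node chain
graph with couplings of 2, 30% marginal endorsement, n = 2000, plus
strong cross-lagged effects from symptoms 2 and 6) and re-estimate it:

```python
import numpy as np
import symptomnet as sn

ising, clpn, n = sn.default_scenario("strong_recovery")
panel = sn.generate_two_wave(ising, clpn, n, seed=7)

net = sn.estimate_ising(panel.wave(0))          # EBIC-LASSO, AND rule
print(net.nonzero_edges(), "of", net.n_possible_edges(),
      "edges, mean weight", round(net.mean_nonzero_weight(), 2))
# -> 8 of 36 edges, mean weight 1.81

tab = sn.centrality_table(net.weights, [str(i + 1) for i in range(9)])
print(tab[["node", "strength", "strength_z"]].round(2))
```

The estimator recovers exactly the 8 chain edges (no false positives at
this n), with weights shrunk toward zero by the L1 penalty (mean 1.81
vs. the generating 2.0). The chain ends (nodes 1 and 9) have one
neighbour instead of two, and the strength column shows it: ~1.7 for
the ends versus ~3.4–3.8 (z ≈ −1.8 vs. +0.3…+0.7) for interior nodes.

```python
dnet = sn.estimate_clpn(panel, seed=3)          # 10-fold CV, 1SE rule
print(dnet.nonzero_edges(), "of 81 directed edges, mean",
      round(dnet.mean_nonzero_weight(), 2))
# -> 9 of 81 directed edges, mean 1.41
instr, outstr = sn.directed_strength(dnet.matrix)
print("top out-strength:", (np.argsort(outstr)[-2:] + 1).tolist())
# -> top out-strength: [2, 6]
```

The cross-lagged estimator keeps 9 of 81 possible directed edges, and
the two generating "driver" symptoms — 2 (tolerance) and 6 (health
problems) — rank highest on out-strength, i.e. they are the wave-1
symptoms that most strongly predict wave-2 symptoms.

The same workflow runs from the shell:

```bash
symptomnet simulate --scenario paper_like --seed 7 --out panel.csv
symptomnet run --config cfg.json        # full pipeline, see AnalysisConfig
symptomnet report --bundle symptomnet_out/
```

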