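# fcdyn — dynamic directed functional connectivity for intracranial time series

`fcdyn` implements an end-to-end analysis of task-related **directed
functional connectivity (FC)** in multichannel electrophysiology (SEEG-like)
recordings, for researchers studying how cortical networks reconfigure
across cognitive tasks. Because clinical intracranial recordings generally
cannot be shared, the package ships a synthetic session generator with
known ground-truth networks, so every stage of the analysis is exercised —
and quantitatively validated — against exact directed coupling structure.

## What it computes

**Ensemble connectivity estimation.** On each signal window (channels ×
samples), four measures are computed in a common source-row → target-column
orientation:

- **BCorrU** — absolute Pearson correlation `|r(x_i, x_j)|` (undirected);
- **BCorrD** — directional lagged correlation: `c⁺(i,j) = max_{1≤τ≤L} |r(x_i(t−τ), x_j(t))|`,
  kept only when it beats the reverse direction (winner-take-all);
- **COH1** — coherence from the MVAR cross-spectral density
  `S(f) = H(f) Σ_w H(f)*`, `C_ij = |S_ij| / √(S_ii S_jj)`, with
  `H(f) = Ā(f)⁻¹` the model transfer function;
- **PDC** — partial directed coherence
  `π_{i←j}(f) = |Ā_ij(f)| / √(Σ_k |Ā_kj(f)|²)`, the column-normalized
  Fourier coefficient matrix of a fitted MVAR model
  `x(t) = Σ_k A_k x(t−k) + w(t)`.

The four matrices are **fused** by weighted logistic memberships
`FC(i,j) = Σ_m α_m σ(k_m (M_m(i,j) − θ_m))`, whose parameters are tuned by a
genetic algorithm maximizing edge-detection AUC on simulated networks.

**FC dynamics.** Fused FC is computed in sliding windows (5 s, 50% overlap);
the FCD matrix holds the Pearson correlation between the vectorized FC
patterns of every window pair, making task-specific connectivity states
visible as blocks.

**Task states.** Window FC patterns are clustered (spectral, BIRCH),
embedded with t-SNE, and classified (random forest, RBF-SVM) under
stratified, time-separated 5-fold cross-validation. Evaluation uses
formula-defined metrics implemented from first principles: normalized
mutual information `MI = 2I(Y,T)/(H(Y)+H(T))`, pair-counting Fowlkes–Mallows
`FM = TP/√((TP+FP)(TP+FN))`, Rand index `RI = (TP+TN)/(all pairs)`, adjusted
Rand, balanced accuracy, per-class precision, Hamming loss and MAE.

**Region profiles and contrasts.** Channel FC maps to brain regions by the
maximum link weight per directed region pair; each region × task is profiled
by seven centralities (in/out-degree, closeness-in/out, betweenness,
Katz-in/out, all in [0, 1]). Between tasks, links are classified by the
1-D Wasserstein distance between their weight distributions, and per-region
degree is contrasted by one-sided Mann–Whitney U tests with a
median-threshold highlight rule (α = 0.001, medians 0.5 / 0.8).

## Worked example

The numbered drivers under `analysis/` run the full study on a simulated
10-channel, three-task session (3 × 60 s at 1000 Hz, distinct ground-truth
networks of density 0.2 per task):

```bash
python analysis/01_simulate_session.py   # writes results/session/
python analysis/02_tune_fusion.py        # GA-tunes the fusion parameters
python analysis/03_sliding_dynamics.py   # windowed FC + FCD matrix
python analysis/04_task_states.py        # clustering, t-SNE, classification
python analysis/05_network_profiles.py   # region graphs + 7-metric profiles
python analysis/06_task_contrasts.py     # Wasserstein links + degree contrasts
```

With the default seed this prints, among other things:

```
held-out fused AUC:         1.000
  single PDC     AUC:      1.000
  single BCorrD  AUC:      0.882
FCD similarity within tasks 0.970, between tasks -0.003 (gap 0.973)
spectral  MI=1.000 FM=1.000 AR=1.000 acc=1.000 BAS=1.000
rfc       acc=1.000 BAS=1.000 hamming=0.000 mae=0.000
label-permutation control acc=0.246 (chance = 1/3 = 0.333)
```

Reading: the GA-tuned fusion recovers the true directed edges on held-out
networks as well as the best single measure (AUC 1.0); the FCD matrix is
nearly block-diagonal in task (within-task similarity 0.97 vs ≈0 between
tasks); both clustering algorithms and both classifiers recover the task
structure perfectly on this synthetic session, while the label-permutation
control stays at chance — confirming that the decoding signal comes from
the task-specific networks, not from leakage.

A `fcdyn` CLI exposes the same stages (`fcdyn simulate`, `tune`,
`dynamics`, `cluster`, `classify`, `profiles`, `compare`, `run`).

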