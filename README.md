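# dynfc — dynamic functional-network analysis with planted ground truth

`dynfc` implements a complete time-varying functional-connectivity analysis
of multivariate node time series (the kind extracted from parcellated
resting-state fMRI): exponentially weighted sliding-window correlation,
signed-modularity community detection per window, temporal co-occurrence
(module-allegiance) matrices, three node-level dynamics metrics, two
null-model controls, and cross-validated canonical-correlation prediction
of behavior — together with a synthetic-data generator that plants known
community structure, known flexible nodes, twin retest sessions, and a
known brain–behavior coupling, so every stage of the analysis can be
validated against ground truth.

It is aimed at researchers who study dynamic brain-network organization
(e.g., the salience network's transient coupling to other systems) and
want a tested, reproducible reference implementation of this analysis
chain, and at methodologists who want calibrated planted-structure
benchmarks for time-varying community analysis.

## The analysis

**Windowed connectivity.** For each subject, node signals (TR `dt`, first
20 frames discarded, high-pass filtered at 0.008 Hz) are windowed (40 s
window, advancing one step at a time) with exponentially decaying weights

    w_t = w_0 e^{(t-T)/θ},  t = 1..T,   w_0 = (1 - e^{-1/θ}) / (1 - e^{-T/θ}),

θ = T/3, and all node pairs get the weighted Pearson correlation

    r_w = Σ_t w_t (x_t - x̄)(y_t - ȳ) / √( Σ_t w_t (x_t - x̄)² · Σ_t w_t (y_t - ȳ)² ),

Fisher z-transformed.

**Communities and co-occurrence.** Each windowed matrix — complete,
unthresholded, signed, weighted — is partitioned by a Louvain-style
optimization of the asymmetric signed quality

    Q* = (1/v⁺) Σ_ij (w⁺_ij - e⁺_ij) δ(c_i, c_j) - (1/(v⁺+v⁻)) Σ_ij (w⁻_ij - e⁻_ij) δ(c_i, c_j),

best of 100 seeded initializations per matrix. The per-window partitions
give each subject's temporal co-occurrence matrix `C_ij` = fraction of
windows in which nodes i and j share a community.

**Node metrics.** Relative to the reference partition (communities of the
group-averaged static matrix; node i's native community `u_i`):

* temporal flexibility `f_i = Σ_{j∉u_i} C_ij / Σ_{j≠i} C_ij`,
* spatiotemporal diversity `h_i = -(1/log m) Σ_u p_i(u) log p_i(u)` with
  `p_i(u) = s_i(u)/s_i`,
* within-community centrality `z_i = (s_i(u_i) - s̄(u_i)) / σ_s(u_i)`,

plus static node strength and participation coefficient for comparison.

**Controls.** Phase-randomized surrogates (per-node amplitude spectra
preserved exactly, cross-correlations destroyed) must abolish all planted
node differences; and the variance explained by the first principal
component of `C` is compared against random graphs with matched weight,
degree, and strength distributions (empirical p).

**Brain–behavior.** The mean flexibility of the high-flexibility node set
predicts a 3-score behavioral battery through 4-fold cross-validated CCA;
the pooled held-out Spearman ρ is tested by permuting the brain measure
across subjects and repeating the whole cross-validated analysis.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
planted cohort (40 nodes: three 12-node stable communities plus a 4-node
flexible coalition labeled "SN" in the atlas; 20 subjects, 2 sessions):

```bash
python analysis/02_static_structure.py
# reference partition: 4 communities, Q* = 0.4312
# adjusted Rand index vs planted static labels: 1.000

python analysis/04_node_metrics.py
# per-network mean flexibility: SN 0.805, net0 0.118, net2 0.118, net1 0.117
# SN vs other networks: max Holm-corrected p = 1.14e-05
# high-flexibility cluster: ['n036', 'n037', 'n038', 'n039']

python analysis/05_null_models.py
# observed  flexibility: flexible 0.805 vs stable 0.118, Wilcoxon p < 1e-5
# surrogate flexibility: flexible 0.764 vs stable 0.754, Wilcoxon p = 0.84
# PC1 variance fraction 0.500 (null 0.103 ± 0.009), p = 0.000999

python analysis/06_behavior_cca.py
# held-out Spearman rho = 0.374, permutation p = 0.0075 (2000 permutations)

python analysis/07_session_retest.py
# mean co-occurrence similarity across sessions: r = 0.999, p = 2e-21
# high-flex cluster overlap: 100% in both directions
```

Read: the static analysis recovers the planted communities exactly; the
planted flexible coalition tops the flexibility ranking, forms the
high-flexibility cluster, and is the most flexible "network"; the effect
vanishes on phase-randomized data while the co-occurrence matrix remains
far more structured than matched random graphs; the planted behavioral
coupling (r = 0.45) is detected by the permutation test; and the whole
pattern replicates across twin sessions. Tables land in `results/`.

## Layout

```
src/dynfc/        simulate, io, connectivity, community, metrics, nulls,
                  behavior, pipeline
analysis/         numbered study drivers (01_simulate ... 07_session_retest)
tests/            pytest suite, including end-to-end acceptance properties
scripts/          acceptance.py
docs/methods.md   model, parameters, numerical choices, limitations
```
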