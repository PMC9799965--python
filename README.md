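# chrononet

Graph-theoretic analysis of diurnal variation in resting-state functional
connectomes.

Resting-state fMRI connectivity is not static over the day: comparing a
morning and an evening scanning session of the same subjects — and
morning-type ("lark") versus evening-type ("owl") chronotypes — reveals
topological shifts in the whole-brain functional network.  `chrononet`
implements the full analysis pipeline for such a two-session,
two-chronotype design, from region-of-interest (ROI) time series to
permutation statistics, together with a synthetic cohort generator so the
entire pipeline runs end-to-end with no access to scanner data.

The pipeline, for each subject and session:

1. **Connectome construction** — Pearson correlation of the T×N ROI time
   series (N = 200 cortical regions in 7 functional systems by default),
   Fisher *r*-to-*z* (z = atanh r), then proportional thresholding at
   densities 0.05–0.50 (step 0.05) on |z| and binarization, so every
   subject's graph has the same edge count at each density.
2. **Graph metrics** — nodal degree k_i, path length L_i, clustering C_i,
   efficiency E_i, betweenness BC_i, participation P_i = 1 − Σ_m
   (k_i(m)/k_i)²; global L, C, E, Newman assortativity r, Laplacian
   synchronizability S = λ₂/λ_max, small-worldness
   σ = (C/C_rand)/(L/L_rand) against seeded degree-preserving rewirings,
   and modularity Q; plus AUC of every metric-versus-density curve.
3. **Mesoscale** — multilayer modularity over subjects-as-layers,
   Q = (1/2μ) Σ_ijsr [(A_ijs − γ k_is k_js/2m_s)δ_sr + ωδ_ij] δ(σ_is, σ_jr),
   maximized by a Louvain-style optimizer with iterated-local-search
   refinement; module allegiance P_ij (fraction of layers co-assigning
   regions i, j); recruitment R_iS and integration I_iS of each region to
   its own/other systems, regionally and at the 7×7 system level.
4. **Hubs** — degree-above-mean regions of the group-average network at
   density 0.05, split into provincial (P < 0.3) and connector (P ≥ 0.3).
5. **Statistics** — permutation mixed-design ANOVA (time-of-day within
   subjects × chronotype between subjects, sign-flip / label-shuffle
   nulls), one-way and identity-line permutation tests, covariate-adjusted
   permutation correlations with questionnaire scores,
   Benjamini–Hochberg FDR, and a "significant in more than half of the
   densities" consolidation rule.

## Worked example

The numbered scripts under `analysis/` run the whole study on a scaled
synthetic cohort (12 subjects per chronotype, 56 regions, T=325,
TR=1.8 s) with an injected evening integration increase (+0.15 on
between-system correlations) and an ET somatomotor effect:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_build_networks.py
python analysis/03_graph_metrics.py
python analysis/04_mesoscale.py
python analysis/05_hubs.py
python analysis/06_group_stats.py
```

`02` prints the session contrast the generator planted — mean
between-system Fisher-z 0.094 (morning) vs 0.241 (evening) with
within-system z ≈ 0.35 in both — and `04` shows how the multilayer
partition turns that into mesoscale coefficients:

```
morning  Q=0.4134 (6 communities); mean recruitment 1.000, mean integration 0.026
evening  Q=0.2263 (1 communities); mean recruitment 1.000, mean integration 1.000
evening - morning regional integration: mean +0.974 (positive in 100% of regions)
```

i.e. in the evening the systems dissolve into one community (high
integration) while in the morning they stay segregated.  `06` then runs
the permutation statistics; on this cohort the time-of-day effect is
significant for small-worldness, modularity and assortativity across most
densities, the one-way test on integration coefficients gives
p ≈ 0.0005 (evening > morning, FDR-significant), and the cohort
demographics table reproduces the expected null group differences.
Tables land under `results/run/`.

All outputs are plain CSV/TSV/JSON; every random choice descends from one
seed, so reruns are byte-identical.

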