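# neuroemergence

Tools for asking how much the dynamics of a brain *as a whole* exceed the sum
of its parts — and how that capacity depends on the structural connectome.
The package links four quantitative views of whole-brain organisation, built
for resting-state fMRI of severely brain-injured patients (disorders of
consciousness: minimally conscious state, MCS, and unresponsive wakefulness
syndrome, UWS) versus healthy controls, but applicable to any parcellated
timeseries + connectome data:

1. **Causal emergence capacity** (Integrated Information Decomposition).
   For each pair of regional BOLD signals, the time-delayed mutual
   information I(X_{t−τ}; X_t) is decomposed into redundant, unique and
   synergistic atoms; the synergy of the past about the future upper-bounds
   the unique predictive power any macroscopic feature could have, and
   splits into *downward causation* (macro → micro) and *causal decoupling*
   (macro → macro).  Redundancy functions: common change in surprisal (CCS)
   and minimum mutual information (MMI); estimators: discrete plug-in on
   mean-binarised signals and closed-form Gaussian.
2. **Spatiotemporal hierarchy of intrinsic-driven ignition.**  Spontaneous
   events (narrowband z > 1 crossings) recruit co-eventful regions within a
   4-TR window; the across-region standard deviation of mean recruitment
   breadth measures how hierarchically organised the dynamics are.
3. **Network controllability** of the structural connectome under linear
   dynamics x(t+1) = A x(t) + B_K u_K(t): average controllability
   trace(W_K) via the discrete Lyapunov equation, and modal controllability
   φ_i = Σ_j (1 − λ_j²) v_ij², plus strict-majority consensus connectomes.
4. **Dynamic mean-field whole-brain model** (coupled excitatory–inhibitory
   populations per region, feedback inhibition control, Balloon–Windkessel
   BOLD) with global coupling G selected by a stability criterion or by
   fitting functional connectivity dynamics (sliding-window FC similarity,
   Kolmogorov–Smirnov distance).

Because the patient data this design targets are restricted, the package
ships a synthetic-cohort generator with a planted, monotone group lesion
(weight attenuation, edge dropout, hub-backbone weakening, weight disorder)
and a packaged demographic table of the 22 patients, so the entire analysis
chain is testable end-to-end without any download.

## Worked example

```python
from neuroemergence.pipeline import (
    PipelineConfig, run_subject_measures, run_group_analysis, report_to_text)
from neuroemergence.synthetic_data import SyntheticCohortSpec, generate_var_cohort

spec = SyntheticCohortSpec(seed=7)          # 18 control / 11 MCS / 10 UWS
cohort = generate_var_cohort(spec)          # connectomes, timeseries, labels
table = run_subject_measures(cohort, PipelineConfig(seed=7))
report = run_group_analysis(table, PipelineConfig(seed=7))
print(report_to_text(report))
```

prints (excerpt):

```
capacity: F(2, 36) = 27.573, p = 5.471e-08
    MCS vs control: t = -5.588, adj. p = 0.0003, d = -2.139
    UWS vs control: t = -5.256, adj. p = 0.0003, d = -2.073
hierarchy: F(2, 36) = 30.335, p = 1.897e-08
    UWS vs control: t = -6.530, adj. p = 0.0003, d = -2.576
modal_controllability: F(2, 36) = 76.495, p = 1.09e-13
    UWS vs control: t = -10.352, adj. p = 0.00015, d = -4.083
cross-measure Spearman correlations:
    capacity ~ hierarchy: rho = 0.646, p = 9.024e-06
    capacity ~ modal_controllability: rho = 0.702, p = 6.285e-07
    hierarchy ~ modal_controllability: rho = 0.598, p = 5.734e-05
```

Reading this: each row is one measure's omnibus ANOVA over the three groups
followed by FDR-corrected permutation post-hocs (10,000 permutations).  The
planted lesion is recovered — emergence capacity, ignition hierarchy and
modal controllability are all significantly lower in the UWS analogue than
in controls, and the three measures correlate positively across subjects,
the same qualitative pattern the analysis chain is designed to detect in
patient data.

A command-line interface wraps the same pipeline:

```bash
neuroemergence simulate-data --out cohort/ --seed 7
neuroemergence measures cohort/ --out measures.tsv
neuroemergence group-stats measures.tsv --out report/
neuroemergence all --out study/ --seed 7       # everything in one run
```

Timeseries and connectomes are plain delimited matrices with small YAML
sidecars (region labels, TR, group), so simulated and empirical data flow
through identical code paths.

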