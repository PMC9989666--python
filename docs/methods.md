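# Methods

This note documents the models and procedures implemented in
`neuroemergence`, the choices made where the design was genuinely open, and
what the synthetic-data experiments do and do not demonstrate.

## Causal emergence from information decomposition

The microscale is a pair of regional BOLD signals evolving jointly,
X_t = (X¹_t, X²_t).  The time-delayed mutual information (TDMI)
I(X_{t−τ}; X_t) is decomposed into sixteen atoms indexed by a (past, future)
pair drawn from {redundant, unique-1, unique-2, synergistic}.  A system can
host causally emergent macroscopic features exactly to the extent that its
past carries *synergistic* information about its future, so the package
reports:

* **emergence capacity** — the synergy of the forward partial information
  decomposition (PID) whose sources are the two past states and whose target
  is the composite future state;
* **downward causation** — the synergy-in-past atoms landing on redundant or
  unique future components (macro → micro);
* **causal decoupling** — the synergy → synergy atom (macro → macro);
* **normalized capacity** — capacity / TDMI, the *fraction* of temporal
  information carried synergistically.

Two redundancy functions are implemented.  *Minimum mutual information*
(MMI): redundancy = min over sources of the source–target MI.  *Common change
in surprisal* (CCS): per joint state, the local co-information counts as
redundancy only when all local terms and the co-information share one strict
sign; a state with any local term exactly zero contributes nothing.  The
canonical XOR and COPY distributions separate the two functions and are fixed
in the test suite to machine precision.

The full 16-atom lattice is solved with MMI double-redundancy — the bottom
atom is the minimum of the four cross MIs I(X^i_{t−τ}; X^j_t) — by Möbius
inversion of the cumulative informations on the product lattice.  This is
equivalent to the usual linear system relating the atoms to the Shannon MIs
between all past/future variable subsets, and the implementation asserts the
two defining invariants on random distributions: the atoms sum to the TDMI,
and marginalising the future index reproduces the forward MMI PID.  One
consequence worth stating explicitly, because it is counter-intuitive: for
two *independent* copy chains MMI assigns one bit of forward redundancy (the
same artifact as its COPY-gate behaviour), so the copy-chain lattice contains
non-zero off-diagonal atoms, some negative.  The test suite freezes the
hand-derived table rather than the naive all-diagonal one.

Because CCS provides no agreed 16-atom solution, the CCS path computes the
aggregate capacity directly from the forward PID (exactly as one computes it
with standard PID tools) and splits it into downward causation and decoupling
in the proportions given by the MMI lattice.  The split is therefore
MMI-flavoured for both methods; the capacity itself is method-pure.

**Estimators.**  The discrete plug-in estimator binarises each (optionally
HRF-deconvolved) series at its own mean — strictly above the mean maps to 1,
ties to 0 (ties have measure zero for continuous data) — and counts the 16
joint states at lag τ (default 1 TR; τ = 4 TRs is exposed).  The Gaussian
estimator computes every MI in closed form from the lagged sample covariance
(½·log₂ det ratios), with a 1e−9 ridge on near-singular covariances, and
uses MMI redundancy (CCS is undefined for it).  The two estimators are
positively rank-correlated across random VAR pairs (Spearman ρ > 0.5,
asserted in tests).  Global capacity is the mean over all unordered region
pairs; self-pairs are excluded as degenerate, and constant-signal regions
are skipped with a logged count.

**HRF deconvolution** is a Wiener filter against the canonical double-gamma
response (peak 6 s, undershoot 16 s, peak/undershoot ratio 6) sampled at TR,
with a noise floor of 1e−3 of the peak spectral power.  It is exposed as a
pipeline toggle and off by default for synthetic data, which is not
haemodynamically convolved; the round-trip (convolve, deconvolve, correlate
> 0.9) is tested.

## Intrinsic-driven ignition and spatiotemporal hierarchy

Signals are band-pass filtered to 0.04–0.07 Hz (2nd-order zero-phase
Butterworth; the filter order is a package choice), z-scored per region, and
events detected as upward crossings of z = 1 (no event possible at the first
sample).  For each driver event at (i, t) the participating set is every
region with at least one event in the window [t, t+3] (window = 4 TRs,
anchored at the driver event, the driver's own timepoint included).  The
co-event matrix links every participating pair, so its largest connected
component is simply the participating-set cardinality; the clique
equivalence is asserted against networkx in tests.  Each region's ignition
breadths are averaged over its events, and the spatiotemporal hierarchy is
the sample (n−1) standard deviation of those means across regions.  Regions
without events are excluded from the standard deviation by default (a toggle
includes them as zero).  Simultaneous events in two regions open two driver
windows.

## Network controllability

The network model is x(t+1) = A x(t) + B_K u_K(t) with A the structural
matrix divided by (largest singular value + 1), which enforces Schur
stability.  Average controllability of node i is the trace of the
single-node controllability Gramian; since
trace(W_i) = Σ_τ ‖A^τ e_i‖², one discrete Lyapunov solve
M = AᵀMA + I yields all nodes as diag(M), and the equivalence with the
truncated per-node Gramian sum is asserted to 1e−10.  Modal controllability
is φ_i = Σ_j (1 − λ_j²) v_ij² from the symmetric eigendecomposition
(eigenvalues sorted descending; degenerate subspaces are handled implicitly
because the sum over a degenerate subspace is rotation-invariant).
Whole-brain values are unweighted means over regions.

A useful identity: the global modal controllability equals 1 − mean λ² of
the normalised matrix.  Uniform attenuation of all weights *shrinks* the
normalised eigenvalues and therefore *raises* global modal controllability —
patient-like reductions in modal controllability cannot come from uniform
weight loss, only from spectral reorganisation.  This identity drove the
design of the synthetic lesion model (below).

The consensus connectome keeps an edge only when strictly more than half of
the subjects have it, valued as the mean over the subjects that do.

## Dynamic mean-field model

Each region holds one excitatory (NMDA) and one inhibitory (GABA) population
of the standard reduced mean-field form: sigmoidal rate transfer
r(I) = (aI − b)/(1 − exp(−d(aI − b))), gating relaxation with τ_E = 100 ms,
τ_I = 10 ms, γ = 0.641, J_NMDA = 0.15 nA, w⁺ = 1.4, I₀ = 0.382 nA
(W_E = 1.0, W_I = 0.7), a_E = 310 nC⁻¹, b_E = 125 Hz, d_E = 0.16 s,
a_I = 615, b_I = 177, d_I = 0.087, noise σ = 0.01 nA — the literature
constants for this model family, collected in one dataclass so deviations
are auditable.  Integration is Euler–Maruyama at dt = 0.1 ms.  The input
connectome is scaled by its maximum entry, and inter-regional coupling is
G · J_NMDA · (W S_E).

**Feedback inhibition control (FIC)** tunes per-region inhibitory weights J
so the time-averaged excitatory current sits at b_E/a_E − 0.026 nA (≈ 3 Hz).
The update is a damped Newton step using the exact sensitivity
dI_E/dJ_i = −⟨S_I,i⟩, with a per-region gain that is halved whenever the
error changes sign (the plain Newton iteration oscillates between under- and
over-inhibited states near criticality).  Currents are measured over the
last half of a 6 s probe; convergence is |ΔI| < 0.01 nA everywhere, checked
against the 2.6–4 Hz firing band in tests.

**BOLD observation** uses the four-state Balloon–Windkessel haemodynamic
model (κ = 0.65 s⁻¹, γ = 0.41 s⁻¹, τ = 0.98 s, α = 0.32, ρ = 0.34,
V₀ = 0.04, k₁ = 7ρ, k₂ = 2, k₃ = 2ρ − 0.2) driven by the excitatory gating
variable, advanced at 1 ms inside the integration loop and sampled at TR.
Simulated BOLD is band-pass filtered like empirical data (0.008–0.09 Hz, or
0.04–0.07 Hz inside the ignition stage).

**Choosing G.**  The stability criterion sweeps an ascending grid (default
0.1 to 2.5 in steps of 0.1, early-stopped at the first unstable value) and
returns the largest value strictly below the first unstable one.  "Unstable"
means any region's mean excitatory rate over the last half of a 60 s probe
exceeds 10 Hz, the integration produces non-finite state, or FIC itself can
no longer hold the target band — the last clause makes the selection robust
near criticality, where rate-based probes are noisy.  The FCD alternative
simulates n runs per grid value and minimises the mean two-sample
Kolmogorov–Smirnov statistic between pooled empirical and simulated
distributions of sliding-window FC similarity (window 30 TRs, step 3 TRs;
FCD values pooled per group by default, per-subject means exposed as an
option).

## Synthetic cohorts

The generator replaces restricted patient data and defines the study
conditions: three groups (18 control / 11 MCS / 10 UWS analogues), TR = 2 s,
300 timepoints, 60 regions by default.

**Connectomes.**  Edges are Bernoulli(density = 0.3) on the upper triangle;
weights are log-normal with a streamline-count magnitude (scale 500),
multiplied by a rank-one hub backbone (s_i s_j)^h where s is a *fixed*
population hub profile (log-normal quantiles, σ = 0.5) with small
per-subject jitter — the same regions are hubs in every subject, as in real
cohorts.  The group lesion has four monotone-in-severity ingredients:
weight attenuation (1.0 / 0.7 / 0.4), edge dropout (0 / 0.1 / 0.2), hub
exponent h (1.0 / 0.5 / 0.0) and weight disorder σ_w (0.5 / 0.75 / 1.0).
Attenuation and dropout are the obvious surrogates for streamline loss; hub
weakening and increased disorder are what actually lower modal
controllability (they flatten the spectrum — see the identity above) and are
biologically motivated by the known vulnerability of hub connections to
severe injury.

**Timeseries.**  A first-order linear stochastic process
x(t+Δ) = W x(t) + ε with iid Gaussian innovations, W proportional to the
connectome and rescaled so its spectral radius equals
coupling_scale × group attenuation (capped at 0.95; coupling_scale = 0.95).
Scaling by the group attenuation directly — rather than through the weights,
which the singular-value normalisation would cancel — is what plants the
effective-coupling ordering control > MCS > UWS.  The process is simulated
at a sub-TR step (Δ = TR/4) and decimated to TR: at TR resolution the
0.04–0.07 Hz ignition band lies too far from a VAR(1) passband for coupling
to be visible in-band, whereas at Δ = 0.5 s the in-band coupling gain is
roughly 27× the noise floor and the planted hierarchy ordering is
recoverable.  The stationary covariance of the fine-step process still obeys
the discrete Lyapunov equation, preserving closed-form oracles.

**What passing tests show — and what they do not.**  The synthetic cohort
demonstrates parameter recovery: the pipeline's measures detect a planted,
monotone group effect of realistic magnitude through the exact analysis
chain used for real data.  It does not emulate haemodynamic convolution,
scanner noise spectra, motion artefacts, aetiology heterogeneity, or
empirical connectome topology beyond hubs + heavy-tailed weights; effect
sizes on real data will be smaller and the generator's linear dynamics
cannot validate the nonlinear model-fitting loop beyond self-consistency.

## Model-based replication experiment

Per group (control and UWS analogue), a consensus connectome is built from
10 synthetic subjects at 20 regions.  Because a strict-majority consensus of
Bernoulli(p) graphs is nearly empty for small p, the replication cohort uses
per-subject density 0.6, where the consensus retains a meaningful edge set
in both groups.  G is then selected per group by fitting the group's own
empirical (synthetic-cohort) functional connectivity dynamics — grid 0.4 to
3.2 in steps of 0.4, one 4-minute simulation per grid value, FCD pooled per
group — and 10 simulations of 5 model-minutes each are scored with the same
emergence and hierarchy measures as empirical data and compared with
permutation t-tests under FDR correction.

The FCD fit, rather than the stability criterion, is used for this
experiment deliberately.  At 20 regions the stability-selected comparison is
dominated by how far each model's selected G happens to land below its own
critical point: both models then operate in closely matched near-critical
regimes, the residual structural contrast is small (|d| < 1), and its sign
varies with the consensus draw.  Fitting G to each group's dynamics instead
propagates the planted coupling difference into the models (fitted G is
lower for the lesioned group, as expected for weakly coupled dynamics) and
yields a robust, large-effect ordering of simulated emergence capacity and
hierarchy.  Both selection modes are implemented; stability remains the
default of the generic pipeline entry point.

Problem sizes (20 regions, 10 simulations, 5-minute runs, 3 empirical runs
and 2 simulations per grid value in the self-fit recovery experiment) are
desk-scale choices that keep the full suite runnable on a laptop CPU while
preserving every qualitative contrast of the full-scale design.

## Numerical and degenerate-input choices

* Logarithms are base 2 throughout; all information is in bits.
* Plug-in pmfs must sum to 1 within 1e−12; PID consistency is enforced to
  1e−9.
* Constant series: binarisation raises a dedicated error; pairwise loops
  skip the pair with a warning; event detection treats filter round-off on
  constant regions as no events.
* The all-zero connectome normalises to itself (with a warning) and yields
  average controllability 1 and modal controllability 1 for every node.
* Permutation p-values use the add-one estimator (b+1)/(m+1), never zero.
* ANCOVA drops constant covariates, reports the partial F for the group
  factor, and raises on genuinely collinear designs naming a removable
  column; a saturated fit (outcome fully explained by covariates) reports
  F = 0 rather than 0/0 noise.
* All randomness flows through explicit integer seeds; cohort generation,
  DMF simulation and permutation tests are bit-reproducible for a fixed
  seed.

## Self-fit recovery of G

The coupling-fit machinery is validated by a recovery experiment: BOLD is
generated from the model at a known G on a 20-node synthetic connectome
(six runs of six model-minutes), and `fit_g_to_fcd` re-estimates G on a
0.2-step grid from three simulations per grid value.  Recovery is typically
exact.  Its known failure mode is not the KS fit but feedback-inhibition
tuning variability near criticality: re-tuning J at the true G from a
different probe realisation can settle on a slightly different inhibitory
balance whose FCD distribution differs measurably, occasionally displacing
the KS minimum by one or two grid steps.  Deeply subcritical operating
points are identifiable but with a shallower KS landscape.

## Known limitations

* Emergence is pairwise only; no ≥3-region decomposition.
* CCS atoms beyond the aggregate capacity are not defined here.
* The 16-atom lattice is MMI-only, with the known MMI redundancy artifacts.
* The DMF stability point on small dense synthetic connectomes sits at much
  lower G (≈0.3–0.6) than on large empirical connectomes; G values are not
  comparable across connectome scales.
* The demographics table ships 22 patient rows; analyses that require both
  modalities filter to the 21 rows with a usable diffusion scan rather than
  hard-coding either count.
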