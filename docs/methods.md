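# Methods

`netvb` implements a network-level virtual-brain analysis pipeline: it
simulates resting-state dynamics of a brain sub-network (e.g., the default
mode network) on its structural connectome with a reduced Wong–Wang
excitatory/inhibitory neural-mass model, transforms the neural activity
into BOLD with the Balloon–Windkessel model, fits the four global
parameters of the model to static and dynamic functional connectivity, and
runs the cohort statistics that relate fitted parameters to cognition and
cluster subjects into fingerprints.

## Neural-mass model

Each node carries an excitatory (NMDA) and an inhibitory (GABA) population
described by synaptic gating variables `S_E, S_I ∈ [0, 1]`.  Input currents
(nA) at node *i* are

    I_E^i = W_E·I_0 + w₊·J_NMDA·S_E^i + G·J_NMDA·Σ_j C_ij·S_E^j − J_i·S_I^i
    I_I^i = W_I·I_0 + J_NMDA·S_E^i − S_I^i + λ·G·J_NMDA·Σ_j C_ij·S_E^j

with `C` the (max-one-normalized) structural connectome.  Firing rates come
from the sigmoidal transfer function `H(x) = (a·x − b)/(1 − exp(−d(a·x − b)))`
(evaluated by a Taylor expansion within |d·(a·x−b)| < 1e−5 of its removable
singularity, where it equals `1/d`), and the gating obeys

    dS_E = (−S_E/τ_E + (1 − S_E)·γ·r_E) dt + σ dW
    dS_I = (−S_I/τ_I + r_I) dt + σ dW

integrated by Euler–Maruyama (default dt = 1 ms) with independent Gaussian
increments per node and population, drawn from one seeded generator in
node-major order (E before I) so runs are bitwise reproducible.  States are
clipped to [0, 1] after every step (clip events counted).  Defaults: a_E =
310, b_E = 125, d_E = 0.16, a_I = 615, b_I = 177, d_I = 0.087, τ_E = 0.1 s,
τ_I = 0.01 s, γ = 0.641, I₀ = 0.382 nA, W_E = 1, W_I = 0.7, σ = 0.01 nA,
λ = 0 (no long-range drive onto the inhibitory pool).  All constants live
in one overridable record.  The four fitted parameters are the global
coupling `G`, excitatory coupling `J_NMDA`, recurrent excitation `w₊`, and
inhibitory coupling `J_i`.

The model is bistable over much of the (G, J_i) plane: a high-firing
saturated branch (S_E ≈ 0.9) and a low-firing branch (S_E ≈ 0.02).  The
fitting studies operate on the low branch near the transition, where
noise-driven fluctuations are largest and the functional observables are
most sensitive to the parameters; deep inside either branch the observables
become nearly parameter-independent.

The first 10 s of every simulation are discarded as transient; multi-start
model inversion draws the initial gating uniformly from [0, 0.2] per seed,
otherwise the default start is S_E = S_I = 0.001.

## Hemodynamics

Per node, the Balloon–Windkessel states (vasodilatory signal s, inflow f,
venous volume v, deoxyhemoglobin q) follow

    ds/dt = z − κ·s − γ_f·(f − 1),   df/dt = s,
    τ_h·dv/dt = f − v^{1/α},
    τ_h·dq/dt = f·(1 − (1−ρ)^{1/f})/ρ − v^{1/α−1}·q,

driven by `z = S_E`, with readout `y = V0·(k1(1−q) + k2(1−q/v) + k3(1−v))`
and the classical coefficients k1 = 7ρ, k2 = 2, k3 = 2ρ − 0.2 (κ = 0.65/s,
γ_f = 0.41/s, τ_h = 0.98 s, α = 0.32, ρ = 0.34, V0 = 0.02).  Euler
integration at the neural step; a tenfold-finer-step consistency test is
included.

Two initializations are provided.  `init="rest"` (the contract default)
starts at s = 0, f = v = q = 1, which makes zero drive an exact fixed point
with y ≡ 0.  `init="steady"` starts each node at the algebraic steady state
of its initial drive value.  The fitting chain uses `init="steady"`: the
neural drive has a non-zero baseline, and starting from rest superimposes a
large shared onset ramp (an order of magnitude above the intrinsic BOLD
fluctuations) on all nodes, which dominates every correlation observable
and masks the parameter dependence that the inversion needs.

Simulated BOLD is resampled to scanner TR by bin-averaging (closer to
scanner integration than decimation); 480 s at TR 2.4 s gives the 200
volumes of the reference acquisition.

## Observables and cost

* **Static FC** — pairwise Pearson correlation over the full series, Fisher
  z-transform capped at |z| = 18, entries with z < 0.1206 set to zero
  (signed threshold, i.e., negative correlations removed; an absolute-value
  option exists), zero diagonal.
* **FCD** — sliding-window FC (window 40 s, step one TR), each window's FC
  vectorized over its upper triangle, windows correlated against each other
  into a symmetric window-by-window matrix with unit diagonal.  The window
  length in volumes is `round(40 / TR)` = 17 at TR 2.4 (the `40s-nominal`
  preset); a `paper-count` preset of 23 volumes is also shipped, which
  yields 178 windows from a 200-volume series.  The two presets exist
  because the nominal 40 s window and the reported window count of the
  reference acquisition are mutually inconsistent; no intent is guessed.
* **Fit metrics** — PCC: Pearson correlation between the upper triangles of
  experimental and simulated (thresholded) static FC.  KS: two-sample
  Kolmogorov–Smirnov statistic between the distributions of FCD
  upper-triangle entries.  Cost: `(1 − PCC) + KS`, in [0, 3], lower is
  better.  A simulation whose FC is entirely sub-threshold carries no
  static pattern and is scored PCC = 0.

## Model inversion

The cost is minimized by exhaustive grid search (optionally refined), the
transparent realization of iterative parameter adjustment.  Each grid point
is evaluated with several RNG seeds — a seed fixes both the noise stream
and the multi-start initial state — and scored by the mean cost across
seeds; ties are broken by lower (G, J_i, J_NMDA, w₊) in that order.  The
full evaluation trace is retained.  Reliability is reported as the
per-parameter range and standard deviation of per-seed argmins, flagged
unstable when the range exceeds one grid step.

**Identifiability.**  On small networks the cost surface has a pronounced
ridge along compensating (G, J_i) directions that hold the E/I balance
fixed; both observables are much more sensitive to the distance from the
branch transition than to the position along it.  The parameter-recovery
study therefore (i) places the ground truth near the transition, where the
observables are most informative, (ii) uses a modular connectome (two
communities bridged by weak edges), so that the level of cross-module
integration — and hence the FC pattern, not just its overall level — is
informative about G, and (iii) spaces the J_i grid so that
balance-compensating cells fall between grid points.  The concrete
connectome and truth cell were chosen by a small identifiability pilot
(truth-versus-neighbor cost margins on held-out target seeds) before the
replicate study was run.  Recovery is assessed as the fraction of
replicate datasets whose argmin is exactly the generating cell.

## Cohort statistics

* **Network contrasts** — per subject, parameter value in one network minus
  the mean over the other five; pooled linear residualization on age and
  sex (a simplified form of a covariate-adjusted GLM); per clinical group,
  mean with a bias-corrected accelerated (BCa) bootstrap CI at fixed seed.
* **Backward regression** — OLS of each cognitive domain score on the
  network parameters; the predictor with the largest p-value is removed
  (one per step, ties broken by name) while that p ≥ 0.05; the final R² is
  the explained-variance fraction.  No correction across domain models is
  applied.  Note the procedure's intrinsic ceiling: each pure-noise
  predictor survives with probability ≈ α, so with five noise predictors
  the exact true model is recovered in only ≈ (1−α)⁵ ≈ 77% of replicates
  even at infinite signal-to-noise.
* **Feature selection** — LASSO (cross-validated penalty) of the ordinally
  encoded diagnostic class (HC = 0, AD = 1, FTD = 2) on standardized
  features; survivors with |Pearson correlation| to the class < 0.1
  dropped; then the highest-VIF feature is removed iteratively until three
  remain.  Selection is invariant to affine rescaling of any feature.
* **Clustering** — cluster count by the Tibshirani gap statistic
  (uniform-bounding-box reference, B = 50, one-standard-error rule), then
  K-means (k-means++, 10 restarts, fixed seed) labels each subject;
  per-cluster MMSE and therapy summaries are attached.

## Synthetic data

The generators provide every input with known ground truth:

* **Connectomes** — symmetric zero-diagonal log-normal weights (μ = 0,
  σ = 1 before normalization, mimicking heavy-tailed streamline counts) at
  a requested edge density, rejected until connected, max-one normalized.
* **Surrogate experimental BOLD** — the forward chain at known parameters
  plus independent Gaussian observation noise; the ground truth travels in
  a sidecar.
* **Cohorts** — per subject and network, parameters are a base value
  (G = 1.5, J_NMDA = 0.15, w₊ = 1.4, J_i = 1.0) plus a group offset
  (default ±25% of base, following the reported direction-of-change
  patterns per group and network: e.g., in AD, G raised in DMN and lowered
  in LN, J_i raised in AN and lowered in LN) plus Gaussian subject noise
  (SD = 10% of base).  Domain scores (0–4) are linear in one standardized
  designated feature per domain with noise calibrated so the population
  explained variance equals a configured target (default R² = 0.30, the
  midpoint of the 0.20–0.45 band the regressions are expected to land in).
  MMSE is 29 minus six times the standardized pathological offset burden
  plus unit noise, clipped to [0, 30].  Parameters are independent across
  networks — a documented simplification; real cohorts have inter-network
  covariance, so passing tests demonstrate machinery correctness, not
  realism of the joint distribution.

## Problem sizes and numerical choices

Validation studies use 6-node connectomes, 480-s series at TR 2.4 s
(200 volumes), dt = 1 ms, 3 seeds per grid point, and 10 replicate
datasets; cohort studies use 40–200 subjects.  These sizes were chosen so
the full validation suite runs on a single desktop core.  Root-finding
oracles (scipy `hybr`) verify fixed points independently of the time
integrators; degenerate inputs (all-zero connectomes, constant series,
sub-threshold FC, single-seed stability requests) raise or are scored by
the documented conventions rather than silently proceeding.

## Known limitations

* Exhaustive grid search scales multiplicatively in grid sizes; no
  gradient-based or Bayesian inversion.
* No conduction delays or regional parameter heterogeneity; parameters are
  global per network, as in the fitted model family.
* The (G, J_i) ridge limits joint identifiability on small homogeneous
  networks; fits on richer connectomes are better conditioned.
* The cohort generator's independence and linearity assumptions are
  idealizations; its role is to validate the statistical machinery.
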