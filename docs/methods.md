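# Methods

## Measurement model

Each record represents one leaf measured in three consecutive phases:
ambient PAR (`amb`), 10 s at 2000 µmol photons m⁻² s⁻¹ (`high`), and
10 s of darkness with weak far-red background (`rec`). Per phase the
instrument reports a chlorophyll fluorescence triplet (Fs, Fm′, Fo′) and
two ~300 ms DIRK traces: the 520 nm electrochromic shift (ECS, a linear
probe of thylakoid pmf) and the 810 nm absorbance change (P700 redox
state).

Estimators:

| quantity | formula | units / notes |
|---|---|---|
| Φ_II | (Fm′ − Fs)/Fm′ | fraction |
| LEF | Φ_II · PAR · c | µmol e⁻ m⁻² s⁻¹; c = 0.42 by default (0.84 leaf absorptivity × 0.5 PSII excitation partition), configurable |
| NPQt | 4.88/(Fm′/Fo′ − 1) − 1 | dimensionless; 4.88 is the unquenched Fm/Fo′ − 1 reference of the total-NPQ method |
| qL | ((Fm′−Fs)/(Fm′−Fo′))·(Fo′/Fs) | fraction of oxidized Q_A |
| ECSt, g_H⁺ | single-exponential DIRK fit, amplitude and rate | amplitude normalized by SPAD; rate in s⁻¹ |
| P700⁺ | 810 nm DIRK amplitude | raw ΔA units; only ECSt is SPAD-normalized, matching the convention that the normalization corrects leaf-optics effects on the pmf probe |

The DIRK model is a single exponential with offset. Initial guesses come
from trace endpoints and a log-linear slope; the rate is bounded
positive and the amplitude non-negative; optimization is
Levenberg–Marquardt-style nonlinear least squares (scipy `curve_fit`,
tolerances 1e-13 so noiseless traces recover to machine precision). Fits
with R² below a configurable floor (default 0.5) are marked failed but
keep diagnostics so QC can cite a reason. Fo′ comes from each phase's own
measurement; the far-red phase supplies the recovery values.

Missing-value policy: undefined estimates (NPQt at Fm′ ≤ Fo′, ECSt after
a failed fit, non-positive SPAD) propagate as NaN with a reason string;
nothing is imputed and out-of-range values are returned rather than
clipped, so QC sees them.

## Synthetic survey generator

The generator emulates the statistical structure a field survey of this
design produces, with full ground truth:

- **Environment.** Sampling hour is uniform over the daylight window;
  PAR_amb follows a half-sine diurnal envelope (peak 1800
  µmol m⁻² s⁻¹) scaled by cos(leaf angle) and a uniform canopy-shading
  factor. T_leaf is built from the standardized √PAR score so that the
  population correlation r(√PAR_amb, T_leaf) equals a configurable
  target (default 0.6); its SD (default 3.5 °C) is the weather noise.
- **Regimes.** A multinomial logit in standardized (T_leaf, √PAR_amb)
  assigns each leaf a limitation regime. Defaults make the rapid-NPQ
  regime (model2) monotonically more likely at high temperature/PAR and
  photosynthetic control (model3) at low values, with small
  covariate-free shares of PSI-acceptor limitation (model1) and an
  intermediate class drawn 50/50 from the model2/model3 response
  distributions (the realized branch is recorded separately).
- **Responses.** ECSt_amb saturates in PAR; the high-light step adds a
  large pmf increment except under model1 (suppressed, 0.02–0.08 ΔA vs
  0.4–1.2). qL and P700⁺ light potentials carry the regime's sign
  pattern with magnitudes ≥ 0.05–0.08, well clear of noise at the
  default settings. The rapid NPQ change is slope × ΔECSt/SPAD with
  slope 35.1 (model2) or 1.6 (model3), the package's default extreme
  qE sensitivities, plus leaf-level scatter (SD 0.05).
- **Consistency.** A fluorescence triplet determines only two free
  ratios, so of (Φ_II, NPQt, qL) only two are independent:
  qL = Φ_II/(1−Φ_II) · (NPQt+1)/4.88. The generator plants qL and NPQt
  and derives Φ_II, making all planted values mutually consistent; with
  zero noise the pipeline recovers every planted parameter exactly.
- **Noise.** Multiplicative Gaussian on each fluorescence yield
  (relative SD 0.005), additive Gaussian on every trace point (SD
  0.005). Defaults keep derived-parameter errors one to two orders of
  magnitude below the planted regime contrasts.
- **Pathologies.** A configurable fraction of leaves is corrupted for QC
  testing, cycling through: assignment to a known-defective device id,
  flattened ECS traces (fit-quality failure), and Fs > Fm′ (negative
  Φ_II). Each planted pathology triggers at least one exclude flag and
  clean leaves trigger none at default noise, so flag accounting is
  exact.

What the simulator does **not** emulate: biophysical thylakoid ion/ODE
dynamics, stomatal or CO₂ effects, diurnal acclimation trends,
instrument gain drift, or spatial/temporal autocorrelation between
leaves. Passing tests therefore demonstrate correctness of the
estimators and the statistical machinery under the assumed data model,
not robustness to every field artifact.

## QC

Rules are declarative (YAML-overridable) and never mutate values:
Φ_II ∈ [0,1], qL ∈ [0,1], NPQt ∈ [−0.1, 15], ECSt ≥ 0,
g_H⁺ ∈ (0, 500] s⁻¹, DIRK R² ≥ 0.5 (both ECS and P700 fits),
Fm′ > Fs per phase, plus a device blacklist. Flags carry
(leaf_id, rule_id, reason, severity) and are set-deduplicated, so counts
are order-independent. `exclude` mode drops flagged rows from the
analysis view only; the stored table always retains all rows.

## Mixture clustering

Features are (response, √PAR_amb, T_leaf); √PAR partially linearizes
light-response curves and spreads the low-light range. Features are
z-scored by default (means/SDs stored for back-transforming reported
cluster means). EM runs over K ∈ [1, 12] (default 1–6) × six covariance
families; each candidate gets `n_init` (default 4) k-means++-seeded
starts; convergence is relative log-likelihood change < 1e-8 or 500
sweeps. Numerical choices:

- covariance ridge 1e-6 on the diagonal every M-step;
- a component collapsing below d+1 effective members, or with a
  covariance eigenvalue at the ridge floor (< 100× ridge), has an
  unbounded likelihood and no MLE — that EM run is rejected, exactly as
  a singular candidate is dropped. This is what keeps BIC honest on
  small samples: without it, spiked single-point components win;
- BIC = −2·logL + p·log n with p = (K−1) + K·d + family covariance
  parameters; ties resolve to smaller K, then the simpler family;
- EM monotonicity is checked on every iteration (1e-10 relative slack)
  and a violation raises;
- MAP assignment breaks responsibility ties toward the lowest index;
  components are relabeled by ascending mean √PAR (original units) so
  cluster numbering is reproducible.

Cluster transfer keeps baseline labels fixed and recomputes per-cluster
summaries and within-cluster OLS on another response, separating "where
the clusters are" from "how each responds". Subsample robustness refits
on random fractions and scores agreement with the full-data clustering
(restricted to the subsample) by adjusted Rand index; fraction 1.0
reuses the master seed so the identity case is exact.

## Mechanism calls

Point labels are a pure function of the signs of (qL_high−amb,
P⁺_high−amb) with a dead-zone margin (default 0; the regions are drawn
without a stated tolerance, so the margin is exposed as a parameter
rather than fixed). Cluster-level labels are majority votes; reports
include per-region fractions, T_leaf/√PAR medians and IQRs, and
per-cluster NPQ-vs-ECSt slopes (OLS with intercept — the no-intercept
variant was considered and rejected because a nonzero NPQ response at
zero net pmf change would otherwise bias the sensitivity estimate).

Classification accuracy against simulator truth is scored on the
*realized* regime: intermediate-regime leaves draw one of the two pure
response branches by construction, and the sign plane has no region that
could identify "intermediate" from a single observation, so the nominal
label would bound accuracy by the intermediate fraction regardless of
classifier quality.

## Problem sizes

Test-suite and acceptance-script runs use 40–1000 simulated leaves,
200-replicate noise ensembles, 100-seed model-selection sweeps and
10-replicate subsample panels — sizes at which every Monte-Carlo
criterion is stable across seeds while a full run stays in the
few-minute range on one core.

## Known limitations

- The DIRK model is a single exponential; multiphasic ECS relaxation
  (e.g. counterion-movement phases) will bias g_H⁺ slightly low on real
  traces.
- Pass-through mode (exports carrying device-computed parameters only)
  trusts the instrument's fits; QC range rules still apply but R² rules
  cannot.
- The logit regime model is phenomenological: it reproduces the observed
  covariate association of mechanisms, not a biophysical temperature
  dependence.
- BIC selection with the degeneracy guard is conservative on very small
  clusters (< d+1 points); genuinely tiny subpopulations will be merged
  into neighbours.
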