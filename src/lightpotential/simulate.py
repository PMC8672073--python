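"""Synthetic leaf-response generator with planted ground truth.

The generator emulates the structure of a field light-potential survey:
each synthetic leaf carries correlated diurnal environment covariates
(PAR_amb, T_leaf), a mechanistic response regime, planted photosynthetic
parameters for the three protocol phases (ambient / 10 s at
2000 µmol m⁻² s⁻¹ / 10 s far-red dark), and rendered raw optical
signals — fluorescence yield triplets and ~300 ms exponential DIRK
traces — that invert the estimators in :mod:`lightpotential.derive`, so
that with zero noise the pipeline recovers the planted values exactly.

Response regimes mirror the three mechanistic models of light-fluctuation
limitation:

* ``model1`` — PSI acceptor-side limitation: Q_A and P700 both net
  reduced by the high-light step (qL and P⁺ light potentials negative),
  pmf buildup suppressed.
* ``model2`` — rapid NPQ (qE): Q_A and P700 both net oxidized; NPQ
  responds steeply to the pmf increase (slope ``slope_model2``).
* ``model3`` — photosynthetic control (PCON) without qE: Q_A net
  reduced but P700 net oxidized; NPQ barely responds
  (slope ``slope_model3``).
* ``intermediate`` — a 50/50 mixture of model2- and model3-like draws;
  the realized branch is recorded as ``regime_realized``.

Regime membership follows a multinomial logit in (T_leaf, √PAR_amb) so
that model2 prevails at high leaf temperature and PAR and model3 at low
values.

Planted (Φ_II, NPQt, qL) are mutually consistent: a fluorescence triplet
(Fs, Fm', Fo') determines only two free ratios, linked by
qL = Φ_II/(1−Φ_II) · (NPQt+1)/4.88, so the generator plants qL and NPQt
and derives Φ_II from them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .derive import NPQT_CONSTANT

logger = logging.getLogger(__name__)

REGIMES = ("model1", "model2", "model3", "intermediate")

#: default multinomial-logit coefficients (intercept, T_leaf, sqrt PAR)
#: on standardized covariates; model2 monotone increasing in both,
#: model3 decreasing, the rest covariate-free.
DEFAULT_REGIME_COEFFS = {
    "model1": (-3.0, 0.0, 0.0),
    "model2": (0.0, 1.5, 1.5),
    "model3": (0.0, -1.5, -1.5),
    "intermediate": (-1.2, 0.0, 0.0),
}


@dataclass
class SimConfig:
    """Study-condition parameters of the generator.

    Durations follow the field protocol: 10 s at 2000 µmol m⁻² s⁻¹
    followed by a 10 s far-red dark period, with ~300 ms DIRK dark
    intervals sampled at ``dirk_rate_hz``.
    """

    n_leaves: int = 500
    seed: int = 0
    par_high: float = 2000.0
    t_high_s: float = 10.0
    t_dark_s: float = 10.0
    dirk_len_s: float = 0.3
    dirk_rate_hz: float = 1000.0
    noise_sd_fluor: float = 0.005   # relative SD on each fluorescence yield
    noise_sd_ecs: float = 0.005     # absolute SD per DIRK trace point
    # environment
    envelope: str = "half-sine"     # or "flat"
    par_peak: float = 1800.0        # envelope peak, µmol m⁻² s⁻¹
    daylight: tuple[float, float] = (5.5, 19.0)   # hours
    corr_par_tleaf: float = 0.6     # target Pearson r(√PAR_amb, T_leaf)
    t_leaf_mean: float = 26.0       # °C
    t_leaf_sd: float = 3.5          # weather-noise SD, °C
    # regimes & responses
    regime_logit_coeffs: dict = field(
        default_factory=lambda: dict(DEFAULT_REGIME_COEFFS)
    )
    slope_model2: float = 35.1      # NPQ per unit normalized ECSt
    slope_model3: float = 1.6
    npq_scatter_sd: float = 0.05    # leaf-level scatter around the NPQ response
    # QC pathologies
    defect_frac: float = 0.0
    device_ids: tuple[str, ...] = ("MSQ-01", "MSQ-02", "MSQ-03", "MSQ-99")
    defective_device: str = "MSQ-99"

    def validate(self) -> None:
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        for name in ("t_high_s", "t_dark_s", "dirk_len_s", "dirk_rate_hz", "par_high"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd_fluor < 0 or self.noise_sd_ecs < 0:
            raise ValueError("noise SDs must be non-negative")
        if not -1 < self.corr_par_tleaf < 1:
            raise ValueError("corr_par_tleaf must be in (-1, 1)")
        if not 0 <= self.defect_frac <= 1:
            raise ValueError("defect_frac must be in [0, 1]")
        if self.envelope not in ("half-sine", "flat"):
            raise ValueError(f"unknown envelope {self.envelope!r}")
        if set(self.regime_logit_coeffs) != set(REGIMES):
            raise ValueError(f"regime_logit_coeffs must have keys {REGIMES}")


@dataclass
class GroundTruth:
    """Planted parameters for one leaf (simulator-side twins of the
    derived quantities)."""

    leaf_id: str
    regime: str
    regime_realized: str
    defect: str              # "", "device", "flat_ecs", "bad_fluor"
    spad: float
    gh_plus: float
    phi2: dict               # phase -> value
    npqt: dict
    ql: dict
    ecs_amp: dict            # raw ΔA amplitude, pre-SPAD normalization
    ecst: dict               # normalized, ΔA per SPAD unit
    p700_ox: dict
    p700_rate: float

    def validate(self) -> None:
        for phase in ("amb", "high", "rec"):
            if not 0 <= self.phi2[phase] < 1:
                raise ValueError(f"phi2[{phase}] out of [0, 1)")
            if self.npqt[phase] < 0:
                raise ValueError(f"npqt[{phase}] negative")
            if not 0 <= self.ql[phase] <= 1:
                raise ValueError(f"ql[{phase}] out of [0, 1]")
            if self.ecs_amp[phase] <= 0 or self.p700_ox[phase] <= 0:
                raise ValueError("planted amplitudes must be positive")
        if self.gh_plus <= 0:
            raise ValueError("gh_plus must be positive")


@dataclass
class RawMeasurement:
    """One leaf's raw three-phase signals plus environment metadata."""

    leaf_id: str
    device_id: str
    timestamp: float         # hour of day
    par_amb: float
    par_high: float
    t_leaf: float
    t_ambient: float
    leaf_angle: float
    lat: float
    lon: float
    spad: float
    fluor: dict              # phase -> (fs, fm_prime, fo_prime)
    ecs_traces: dict         # phase -> (t, y) arrays
    p700_traces: dict

    def to_mapping(self) -> dict:
        """Flatten to the key convention consumed by the derive module."""
        out = {
            "leaf_id": self.leaf_id,
            "device_id": self.device_id,
            "timestamp": self.timestamp,
            "par_amb": self.par_amb,
            "par_high": self.par_high,
            "t_leaf": self.t_leaf,
            "t_ambient": self.t_ambient,
            "leaf_angle": self.leaf_angle,
            "lat": self.lat,
            "lon": self.lon,
            "spad": self.spad,
        }
        for phase in ("amb", "high", "rec"):
            fs, fm, fo = self.fluor[phase]
            out[f"fs_{phase}"] = fs
            out[f"fm_prime_{phase}"] = fm
            out[f"fo_prime_{phase}"] = fo
            out[f"ecs_t_{phase}"], out[f"ecs_y_{phase}"] = self.ecs_traces[phase]
            out[f"p700_t_{phase}"], out[f"p700_y_{phase}"] = self.p700_traces[phase]
        return out


def _standardize_covariates(par_amb, t_leaf, cfg: SimConfig):
    z_t = (np.asarray(t_leaf, dtype=float) - cfg.t_leaf_mean) / max(cfg.t_leaf_sd, 1e-9)
    z_p = (np.sqrt(np.asarray(par_amb, dtype=float)) - 20.0) / 10.0
    return z_t, z_p


def sample_environment(cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw correlated diurnal environment covariates for each leaf.

    PAR_amb follows a half-sine daylight envelope scaled by the cosine of
    the leaf-angle offset and a canopy shading factor; T_leaf is built
    from the standardized √PAR_amb score so that the population Pearson
    correlation r(√PAR_amb, T_leaf) equals ``corr_par_tleaf``.
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    n = cfg.n_leaves
    sunrise, sunset = cfg.daylight
    hour = rng.uniform(sunrise + 0.1, sunset - 0.4, n)
    if cfg.envelope == "half-sine":
        envelope = cfg.par_peak * np.sin(np.pi * (hour - sunrise) / (sunset - sunrise))
    else:
        envelope = np.full(n, cfg.par_peak)
    leaf_angle = rng.uniform(0.0, 60.0, n)
    shade = rng.uniform(0.05, 1.0, n)          # canopy position attenuation
    par_amb = np.clip(envelope * np.cos(np.radians(leaf_angle)) * shade, 1.0, None)

    sqrt_par = np.sqrt(par_amb)
    z = (sqrt_par - sqrt_par.mean()) / max(sqrt_par.std(), 1e-12)
    rho = cfg.corr_par_tleaf
    eps = rng.standard_normal(n)
    t_leaf = cfg.t_leaf_mean + cfg.t_leaf_sd * (rho * z + math.sqrt(1 - rho**2) * eps)
    t_ambient = t_leaf - rng.uniform(0.0, 2.0, n)

    device_id = rng.choice(np.asarray(cfg.device_ids, dtype=object), n)
    lat = 42.6734 + rng.normal(0, 1e-4, n)
    lon = -84.4870 + rng.normal(0, 1e-4, n)
    return pd.DataFrame(
        {
            "timestamp": hour,
            "par_amb": par_amb,
            "t_leaf": t_leaf,
            "t_ambient": t_ambient,
            "leaf_angle": leaf_angle,
            "device_id": device_id,
            "lat": lat,
            "lon": lon,
        }
    )


def regime_probabilities(par_amb, t_leaf, cfg: SimConfig) -> pd.DataFrame:
    """Multinomial-logit regime probabilities at given covariates."""
    z_t, z_p = _standardize_covariates(par_amb, t_leaf, cfg)
    logits = np.stack(
        [
            np.broadcast_to(
                cfg.regime_logit_coeffs[r][0]
                + cfg.regime_logit_coeffs[r][1] * z_t
                + cfg.regime_logit_coeffs[r][2] * z_p,
                np.broadcast(z_t, z_p).shape,
            )
            for r in REGIMES
        ],
        axis=-1,
    )
    logits = logits - logits.max(axis=-1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=-1, keepdims=True)
    return pd.DataFrame(np.atleast_2d(p), columns=list(REGIMES))


def assign_regime(par_amb, t_leaf, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Categorical regime draw from the logit model."""
    if not (np.all(np.isfinite(par_amb)) and np.all(np.isfinite(t_leaf))):
        raise ValueError("covariates must be finite")
    probs = regime_probabilities(par_amb, t_leaf, cfg).to_numpy()
    u = rng.random(probs.shape[0])
    idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return np.asarray(REGIMES, dtype=object)[idx]


def _phi2_from(ql_value: float, npqt_value: float) -> float:
    # invert qL = phi2/(1-phi2) * (NPQt+1)/4.88
    x = NPQT_CONSTANT * ql_value / (npqt_value + 1.0)
    return x / (1.0 + x)


def _plant_truth(leaf_id: str, env: Mapping, regime: str, cfg: SimConfig,
                 rng: np.random.Generator) -> GroundTruth:
    """Draw mutually consistent planted parameters for one leaf."""
    par = float(env["par_amb"])
    spad = float(np.clip(rng.normal(40.0, 6.0), 15.0, 70.0))
    gh = float(rng.uniform(20.0, 80.0))
    p700_rate = float(rng.uniform(15.0, 60.0))

    branch = regime
    if regime == "intermediate":
        branch = "model2" if rng.random() < 0.5 else "model3"

    # pmf: ambient ECS amplitude saturating in PAR; the high-light step
    # adds a large pmf increment except under model1 (electron backup
    # suppresses proton flux).
    amp_amb = max(0.2 + 1.0 * par / (par + 300.0) + rng.normal(0, 0.08), 0.05)
    if regime == "model1":
        d_amp = rng.uniform(0.02, 0.08)
    else:
        d_amp = rng.uniform(0.4, 1.2)
    amp_high = amp_amb + d_amp
    amp_rec = float(rng.uniform(0.08, 0.18))
    ecs_amp = {"amb": amp_amb, "high": amp_high, "rec": amp_rec}

    # P700 oxidation: near-linear in PAR at ambient; net oxidation under
    # model2/model3, net reduction under model1.
    p_amb = max(0.12 + 0.45 * par / 2000.0 + rng.normal(0, 0.02), 0.06)
    if branch == "model1":
        p_high = max(p_amb - rng.uniform(0.06, 0.2), 0.05)
        if p_amb - p_high < 0.02:   # keep the net-reduction sign resolvable
            p_amb = p_high + 0.02
    else:
        p_high = p_amb + rng.uniform(0.06, 0.25)
    p_rec = float(rng.uniform(0.06, 0.12))
    p700 = {"amb": p_amb, "high": p_high, "rec": p_rec}

    # Q_A redox state
    ql_amb = float(np.clip(0.35 + 0.4 * par / (par + 400.0) + rng.normal(0, 0.04),
                           0.25, 0.8))
    if branch == "model2":
        ql_high = min(ql_amb + rng.uniform(0.08, 0.25), 0.97)
    else:  # model1 / model3: net reduction of Q_A
        ql_high = max(ql_amb - rng.uniform(0.08, 0.25), 0.03)
    ql_rec = float(rng.uniform(0.85, 0.95))
    ql_vals = {"amb": ql_amb, "high": ql_high, "rec": ql_rec}

    # NPQ: ambient level rises with PAR; the rapid response to the pmf
    # step follows the regime's qE sensitivity (NPQ per unit ECSt/SPAD).
    npq_amb = max(0.2 + 2.0 * par / (par + 500.0) + rng.normal(0, 0.1), 0.01)
    slope = cfg.slope_model2 if branch == "model2" else cfg.slope_model3
    d_npq = slope * d_amp / spad + rng.normal(0, cfg.npq_scatter_sd)
    npq_high = max(npq_amb + d_npq, npq_amb * 0.5)
    npq_rec = 0.35 * npq_amb
    npq = {"amb": npq_amb, "high": npq_high, "rec": npq_rec}

    phi2_vals = {ph: _phi2_from(ql_vals[ph], npq[ph]) for ph in ("amb", "high", "rec")}

    truth = GroundTruth(
        leaf_id=leaf_id,
        regime=regime,
        regime_realized=branch,
        defect="",
        spad=spad,
        gh_plus=gh,
        phi2=phi2_vals,
        npqt=npq,
        ql=ql_vals,
        ecs_amp=ecs_amp,
        ecst={ph: ecs_amp[ph] / spad for ph in ecs_amp},
        p700_ox=p700,
        p700_rate=p700_rate,
    )
    truth.validate()
    return truth


def _triplet_from(phi2_value: float, npqt_value: float, gain: float) -> tuple[float, float, float]:
    """Invert the fluorescence estimators: planted (phi2, NPQt) -> (Fs, Fm', Fo')."""
    if not 0 <= phi2_value < 1:
        raise ValueError(f"phi2 {phi2_value} outside [0, 1)")
    if npqt_value < 0:
        raise ValueError(f"npqt {npqt_value} negative")
    fm = gain
    fs = fm * (1.0 - phi2_value)
    r = (npqt_value + 1.0) / (npqt_value + 1.0 + NPQT_CONSTANT)   # Fo'/Fm'
    fo = fm * r
    return fs, fm, fo


def render_measurement(truth: GroundTruth, env: Mapping, cfg: SimConfig,
                       rng: np.random.Generator) -> RawMeasurement:
    """Render one leaf's raw signals from its planted parameters.

    Fluorescence triplets are the algebraic inversion of the phi2/NPQt/qL
    estimators at a random instrument gain, with multiplicative Gaussian
    noise per yield; DIRK traces are offset + amplitude·exp(−rate·t) with
    additive Gaussian noise.  Planted phi2 below 0.01 is clamped to 0.01
    (logged) so Fs stays strictly below Fm' under noise.  Infeasible
    planted values raise with the leaf id.
    """
    t = np.arange(0.0, cfg.dirk_len_s, 1.0 / cfg.dirk_rate_hz)
    fluor: dict = {}
    ecs_traces: dict = {}
    p700_traces: dict = {}
    for phase in ("amb", "high", "rec"):
        gain = rng.uniform(800.0, 2000.0)
        p2 = truth.phi2[phase]
        if p2 < 0.01:
            logger.warning(
                "leaf %s phase %s: planted phi2=%.4g clamped to 0.01",
                truth.leaf_id, phase, p2,
            )
            p2 = 0.01   # keeps Fm' > Fs under multiplicative noise
        try:
            fs, fm, fo = _triplet_from(p2, truth.npqt[phase], gain)
        except ValueError as exc:
            raise ValueError(f"leaf {truth.leaf_id}, phase {phase}: {exc}") from exc
        if cfg.noise_sd_fluor > 0:
            for _ in range(20):
                f = np.array([fs, fm, fo]) * (
                    1.0 + rng.normal(0, cfg.noise_sd_fluor, 3)
                )
                if f[1] > f[0] > 0 and f[1] > f[2] > 0:
                    fs, fm, fo = f
                    break
        fluor[phase] = (float(fs), float(fm), float(fo))

        offset = rng.uniform(0.0, 0.1)
        y = offset + truth.ecs_amp[phase] * np.exp(-truth.gh_plus * t)
        y = y + rng.normal(0, cfg.noise_sd_ecs, len(t)) if cfg.noise_sd_ecs > 0 else y
        ecs_traces[phase] = (t.copy(), y)

        offset_p = rng.uniform(0.0, 0.1)
        yp = offset_p + truth.p700_ox[phase] * np.exp(-truth.p700_rate * t)
        yp = yp + rng.normal(0, cfg.noise_sd_ecs, len(t)) if cfg.noise_sd_ecs > 0 else yp
        p700_traces[phase] = (t.copy(), yp)

    return RawMeasurement(
        leaf_id=truth.leaf_id,
        device_id=str(env["device_id"]),
        timestamp=float(env["timestamp"]),
        par_amb=float(env["par_amb"]),
        par_high=cfg.par_high,
        t_leaf=float(env["t_leaf"]),
        t_ambient=float(env["t_ambient"]),
        leaf_angle=float(env["leaf_angle"]),
        lat=float(env["lat"]),
        lon=float(env["lon"]),
        spad=truth.spad,
        fluor=fluor,
        ecs_traces=ecs_traces,
        p700_traces=p700_traces,
    )


def _apply_defect(meas: RawMeasurement, truth: GroundTruth, kind: str,
                  cfg: SimConfig, rng: np.random.Generator) -> None:
    """Corrupt a rendered measurement in place to plant a QC pathology."""
    truth.defect = kind
    if kind == "device":
        meas.device_id = cfg.defective_device
    elif kind == "flat_ecs":
        for phase in ("amb", "high", "rec"):
            t, y = meas.ecs_traces[phase]
            flat = np.full_like(y, y.mean())
            noise = rng.normal(0, max(cfg.noise_sd_ecs, 1e-4), len(y))
            meas.ecs_traces[phase] = (t, flat + noise)
    elif kind == "bad_fluor":
        fs, fm, fo = meas.fluor["high"]
        meas.fluor["high"] = (fm * 1.15, fm, fo)   # Fs > Fm' -> phi2 < 0
    else:
        raise ValueError(f"unknown defect kind {kind!r}")


def simulate_dataset(cfg: SimConfig) -> tuple[list[RawMeasurement], list[GroundTruth]]:
    """Generate a full ground-truthed dataset.

    A fraction ``defect_frac`` of leaves is rendered pathological for QC
    testing, cycling through defect kinds (defective device, flat ECS
    traces, inverted fluorescence).  Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    env = sample_environment(cfg, rng)
    # keep clean leaves off the blacklisted device
    clean_ids = [d for d in cfg.device_ids if d != cfg.defective_device]
    mask = env["device_id"] == cfg.defective_device
    if mask.any():
        env.loc[mask, "device_id"] = rng.choice(np.asarray(clean_ids, dtype=object),
                                                int(mask.sum()))
    regimes = assign_regime(env["par_amb"].to_numpy(), env["t_leaf"].to_numpy(), cfg, rng)

    n_defect = int(round(cfg.defect_frac * cfg.n_leaves))
    defect_idx = rng.choice(cfg.n_leaves, size=n_defect, replace=False) if n_defect else []
    defect_kinds = {int(i): ("device", "flat_ecs", "bad_fluor")[j % 3]
                    for j, i in enumerate(defect_idx)}

    measurements: list[RawMeasurement] = []
    truths: list[GroundTruth] = []
    for i in range(cfg.n_leaves):
        leaf_id = f"leaf-{i:05d}"
        row = env.iloc[i]
        truth = _plant_truth(leaf_id, row, regimes[i], cfg, rng)
        meas = render_measurement(truth, row, cfg, rng)
        if i in defect_kinds:
            _apply_defect(meas, truth, defect_kinds[i], cfg, rng)
        measurements.append(meas)
        truths.append(truth)
    return measurements, truths


def truth_frame(truths: list[GroundTruth]) -> pd.DataFrame:
    """Ground truth as a flat table (phase dicts expanded into columns)."""
    rows = []
    for tr in truths:
        row = {
            "leaf_id": tr.leaf_id,
            "regime": tr.regime,
            "regime_realized": tr.regime_realized,
            "defect": tr.defect,
            "spad": tr.spad,
            "gh_plus": tr.gh_plus,
            "p700_rate": tr.p700_rate,
        }
        for param in ("phi2", "npqt", "ql", "ecs_amp", "ecst", "p700_ox"):
            for phase, val in getattr(tr, param).items():
                row[f"{param}_{phase}"] = val
        rows.append(row)
    return pd.DataFrame(rows)
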