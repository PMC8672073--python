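"""Estimation of photosynthetic parameters from raw optical signals.

Each field measurement consists of three phases — ambient PAR (``amb``),
10 s at full-sunlight-equivalent PAR (``high``), and 10 s of far-red
darkness (``rec``) — and in each phase the instrument records a
chlorophyll-fluorescence yield triplet (Fs, Fm', Fo') and two
dark-interval relaxation kinetics (DIRK) traces: the ~520 nm
electrochromic shift (ECS) and the ~810 nm P700 absorbance change.

From these we estimate, per phase:

* ``phi2``     — PSII quantum efficiency, (Fm' − Fs)/Fm'
* ``lef``      — linear electron flow, phi2 × PAR × c (c ≈ 0.42, the
                 product of leaf absorptivity ~0.84 and the ~0.5 PSII
                 excitation partition)
* ``npqt``     — "total NPQ" without a dark-adapted reference,
                 4.88/(Fm'/Fo' − 1) − 1
* ``ql``       — fraction of Q_A in the oxidized (open) state,
                 ((Fm'−Fs)/(Fm'−Fo')) · (Fo'/Fs)
* ``ecst``     — ECS DIRK amplitude normalized by SPAD chlorophyll,
                 a relative proton-motive-force (pmf) measure
* ``gh_plus``  — ATP-synthase proton conductivity, the ECS decay rate
                 constant (s⁻¹)
* ``p700_ox``  — P700⁺ pool, the 810 nm DIRK amplitude (raw ΔA units)

"Light potential" parameters are the phase differences, e.g.
``npqt_high_amb = npqt_high − npqt_amb``: the capacity of the leaf to
respond to a sudden step to full sunlight.

Out-of-range raw values (e.g. Fs > Fm') are *returned*, not raised: the
QC stage flags them so that no data are silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

NPQT_CONSTANT = 4.88          # unquenched Fm/Fo' − 1 reference ratio
DEFAULT_LEF_COEFF = 0.42      # 0.84 absorptivity × 0.5 PSII partition

PHASES = ("amb", "high", "rec")
#: parameters for which phase differences ("light potentials") are formed
DIFF_PARAMS = ("phi2", "lef", "npqt", "ql", "ecst", "gh_plus", "p700_ox")
DIFF_PAIRS = (("high", "amb"), ("amb", "rec"), ("high", "rec"))


@dataclass
class DeriveConfig:
    """Constants of the estimators.

    lef_coeff : absorptivity × PSII partition factor in the LEF estimate.
    npqt_const : reference constant of the total-NPQ estimator.
    r2_floor : minimum DIRK-fit R² below which a fit is marked failed
        (the amplitude/rate are still reported as diagnostics).
    """

    lef_coeff: float = DEFAULT_LEF_COEFF
    npqt_const: float = NPQT_CONSTANT
    r2_floor: float = 0.5


def phi2(fs: float, fm_prime: float) -> float:
    """PSII quantum efficiency (Fm' − Fs)/Fm'.

    Fs > Fm' yields a negative value, which is kept so QC can flag it.
    """
    fs = np.asarray(fs, dtype=float)
    fm = np.asarray(fm_prime, dtype=float)
    if np.any(fm <= 0):
        raise ValueError("fm_prime must be positive")
    out = (fm - fs) / fm
    return out.item() if out.ndim == 0 else out


def lef(phi2_value: float, par: float, coeff: float = DEFAULT_LEF_COEFF) -> float:
    """Linear electron flow, µmol electrons m⁻² s⁻¹ = phi2 × PAR × coeff."""
    if not 0 < coeff <= 1:
        raise ValueError("coeff must be in (0, 1]")
    par = np.asarray(par, dtype=float)
    if np.any(par < 0):
        raise ValueError("par must be non-negative")
    out = np.asarray(phi2_value, dtype=float) * par * coeff
    return out.item() if out.ndim == 0 else out


def npqt(fm_prime: float, fo_prime: float, const: float = NPQT_CONSTANT) -> float:
    """Total NPQ from the Fm'/Fo' ratio: const/(Fm'/Fo' − 1) − 1.

    Undefined (Fm' ≤ Fo') returns NaN — a flagged missing value, never a
    spuriously finite number near the Fm' → Fo' pole.
    """
    fm = np.asarray(fm_prime, dtype=float)
    fo = np.asarray(fo_prime, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = fm / fo
        out = np.where((fo > 0) & (fm > fo), const / (ratio - 1.0) - 1.0, np.nan)
    return out.item() if out.ndim == 0 else out


def ql(fs: float, fm_prime: float, fo_prime: float) -> float:
    """Fraction of oxidized Q_A: ((Fm'−Fs)/(Fm'−Fo')) · (Fo'/Fs)."""
    fs = np.asarray(fs, dtype=float)
    fm = np.asarray(fm_prime, dtype=float)
    fo = np.asarray(fo_prime, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            (fs > 0) & (fo > 0) & (fm > fo),
            (fm - fs) / (fm - fo) * (fo / fs),
            np.nan,
        )
    return out.item() if out.ndim == 0 else out


def normalize_ecst(amplitude: float, spad: float) -> float:
    """ECS amplitude per unit SPAD chlorophyll (relative pmf).

    Normalization removes leaf-thickness / chloroplast-number differences.
    Non-positive SPAD gives NaN (flagged missing).
    """
    amplitude = np.asarray(amplitude, dtype=float)
    spad = np.asarray(spad, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(spad > 0, amplitude / spad, np.nan)
    return out.item() if out.ndim == 0 else out


@dataclass
class DirkFit:
    """Result of a single-exponential DIRK fit y(t) = offset + A·exp(−k·t)."""

    amplitude: float
    rate: float
    offset: float
    r2: float
    resid_sd: float
    success: bool
    message: str = ""


def _dirk_model(t, offset, amplitude, rate):
    return offset + amplitude * np.exp(-rate * t)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    # endpoint heuristic: tail mean approximates the offset, the first
    # point minus the offset approximates the amplitude; rate from a
    # log-linear regression on the positive part of the residual decay.
    n_tail = max(3, len(y) // 10)
    offset0 = float(np.mean(y[-n_tail:]))
    amp0 = max(float(y[0] - offset0), 1e-12)
    resid = y - offset0
    mask = resid > amp0 * 1e-3
    if mask.sum() >= 3:
        slope = np.polyfit(t[mask], np.log(resid[mask]), 1)[0]
        rate0 = max(-slope, 1e-3)
    else:
        rate0 = 3.0 / max(t[-1], 1e-9)
    return offset0, amp0, rate0


def fit_dirk(
    t: Sequence[float],
    y: Sequence[float],
    kind: str = "ecs",
    r2_floor: float = 0.5,
) -> DirkFit:
    """Fit a DIRK trace to a single-exponential decay with offset.

    Returns the decay amplitude (ECSt in raw ΔA, or the P700⁺ proxy),
    the rate constant (g_H+ for ECS, s⁻¹; bounded positive) and the
    baseline offset.  A fit with R² below ``r2_floor`` (flat or
    pathological traces) is marked unsuccessful but keeps its partial
    diagnostics so QC can report a reason.
    """
    if kind not in ("ecs", "p700"):
        raise ValueError(f"unknown trace kind {kind!r}")
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.ndim != 1 or t.shape != y.shape or len(t) < 4:
        raise ValueError("trace must be 1-D with at least 4 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("trace time must be strictly increasing")

    offset0, amp0, rate0 = _initial_guess(t, y)
    try:
        popt, _ = curve_fit(
            _dirk_model,
            t,
            y,
            p0=(offset0, amp0, rate0),
            bounds=([-np.inf, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
            xtol=1e-13,
            ftol=1e-13,
            maxfev=10000,
        )
    except RuntimeError as exc:  # non-convergence
        return DirkFit(np.nan, np.nan, offset0, 0.0, np.nan, False, f"no convergence: {exc}")

    offset, amplitude, rate = popt
    resid = y - _dirk_model(t, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    resid_sd = float(np.sqrt(ss_res / max(len(y) - 3, 1)))
    ok = r2 >= r2_floor
    msg = "" if ok else f"low-information fit (R²={r2:.3f} < {r2_floor})"
    return DirkFit(float(amplitude), float(rate), float(offset), r2, resid_sd, ok, msg)


@dataclass
class PhotoParams:
    """Derived parameters for one protocol phase."""

    phi2: float
    lef: float
    npqt: float
    ql: float
    ecst: float
    gh_plus: float
    p700_ox: float
    ecs_r2: float = np.nan
    p700_r2: float = np.nan
    notes: list[str] = field(default_factory=list)


@dataclass
class LeafRecord:
    """One leaf's derived parameters across phases plus light potentials."""

    leaf_id: str
    metadata: dict
    amb: PhotoParams
    high: PhotoParams
    rec: PhotoParams
    diffs: dict = field(default_factory=dict)
    sqrt_par: float = np.nan


def _derive_phase(
    raw: Mapping, phase: str, par: float, spad: float, cfg: DeriveConfig
) -> PhotoParams:
    fs = raw[f"fs_{phase}"]
    fm = raw[f"fm_prime_{phase}"]
    fo = raw[f"fo_prime_{phase}"]
    notes: list[str] = []
    p2 = phi2(fs, fm)
    if p2 < 0:
        notes.append(f"fs > fm_prime in phase {phase}")
    nq = npqt(fm, fo, cfg.npqt_const)
    if math.isnan(nq):
        notes.append(f"npqt undefined (fm_prime <= fo_prime) in phase {phase}")
    q = ql(fs, fm, fo)

    ecs = fit_dirk(raw[f"ecs_t_{phase}"], raw[f"ecs_y_{phase}"], "ecs", cfg.r2_floor)
    p7 = fit_dirk(raw[f"p700_t_{phase}"], raw[f"p700_y_{phase}"], "p700", cfg.r2_floor)
    if not ecs.success:
        notes.append(f"ecs fit failed in phase {phase}: {ecs.message}")
    if not p7.success:
        notes.append(f"p700 fit failed in phase {phase}: {p7.message}")

    ecst = normalize_ecst(ecs.amplitude, spad) if ecs.success else np.nan
    gh = ecs.rate if ecs.success else np.nan
    p700_amp = p7.amplitude if p7.success else np.nan

    return PhotoParams(
        phi2=p2,
        lef=lef(p2, par, cfg.lef_coeff),
        npqt=nq,
        ql=q,
        ecst=ecst,
        gh_plus=gh,
        p700_ox=p700_amp,
        ecs_r2=ecs.r2,
        p700_r2=p7.r2,
        notes=notes,
    )


#: PAR experienced in each phase: ambient in amb, the high step in high,
#: darkness (far red only) in rec.
def _phase_par(phase: str, par_amb: float, par_high: float) -> float:
    return {"amb": par_amb, "high": par_high, "rec": 0.0}[phase]


def assemble_record(raw: Mapping, cfg: DeriveConfig | None = None) -> LeafRecord:
    """Derive all phase parameters and light potentials for one leaf.

    ``raw`` is a mapping with the RawMeasurement fields (see
    :mod:`lightpotential.simulate`): metadata, per-phase fluorescence
    triplets and per-phase DIRK traces (``ecs_t_amb``/``ecs_y_amb`` ...).
    Failed sub-fits propagate as NaN with a reason in the phase notes;
    a missing phase is a record-level error.
    """
    cfg = cfg or DeriveConfig()
    for phase in PHASES:
        for key in (f"fs_{phase}", f"fm_prime_{phase}", f"fo_prime_{phase}"):
            if key not in raw:
                raise KeyError(f"missing phase data: {key}")
    par_amb = float(raw["par_amb"])
    par_high = float(raw.get("par_high", 2000.0))
    spad = float(raw["spad"])

    phases = {
        phase: _derive_phase(raw, phase, _phase_par(phase, par_amb, par_high), spad, cfg)
        for phase in PHASES
    }

    diffs: dict[str, float] = {}
    for param in DIFF_PARAMS:
        for a, b in DIFF_PAIRS:
            diffs[f"{param}_{a}_{b}"] = getattr(phases[a], param) - getattr(phases[b], param)

    meta_keys = (
        "device_id",
        "timestamp",
        "par_amb",
        "t_leaf",
        "t_ambient",
        "leaf_angle",
        "lat",
        "lon",
        "spad",
    )
    metadata = {k: raw[k] for k in meta_keys if k in raw}
    return LeafRecord(
        leaf_id=str(raw["leaf_id"]),
        metadata=metadata,
        amb=phases["amb"],
        high=phases["high"],
        rec=phases["rec"],
        diffs=diffs,
        sqrt_par=math.sqrt(par_amb),
    )


def record_to_row(rec: LeafRecord) -> dict:
    """Flatten a LeafRecord into one table row (stable column dictionary)."""
    row: dict = {"leaf_id": rec.leaf_id, **rec.metadata, "sqrt_par": rec.sqrt_par}
    for phase in PHASES:
        p: PhotoParams = getattr(rec, phase)
        for param in DIFF_PARAMS:
            row[f"{param}_{phase}"] = getattr(p, param)
        row[f"ecs_r2_{phase}"] = p.ecs_r2
        row[f"p700_r2_{phase}"] = p.p700_r2
    row.update(rec.diffs)
    row["notes"] = "; ".join(n for phase in PHASES for n in getattr(rec, phase).notes)
    return row


def derive_table(
    raws: Sequence[Mapping], cfg: DeriveConfig | None = None
) -> pd.DataFrame:
    """Run :func:`assemble_record` over a dataset; one row per leaf.

    Raw fluorescence yields are carried along (``fs_amb`` ...) so QC rules
    that reason about the unreduced signals can be applied to the table.
    """
    rows = []
    for raw in raws:
        if hasattr(raw, "to_mapping"):
            raw = raw.to_mapping()
        row = record_to_row(assemble_record(raw, cfg))
        for phase in PHASES:
            for key in (f"fs_{phase}", f"fm_prime_{phase}", f"fo_prime_{phase}"):
                row[key] = raw[key]
        rows.append(row)
    return pd.DataFrame(rows)
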