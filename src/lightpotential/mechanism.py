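"""Mechanistic classification of light-fluctuation limitations.

Three mechanistic models predict distinct sign patterns in the light
potentials of the Q_A redox state (qL_high−amb) and of P700 oxidation
(P⁺_high−amb) when a leaf is stepped to full-sunlight PAR:

* Model 1 — PSI acceptor-side limitation: electrons back up through the
  chain, so both Q_A and P700 go net *reduced*
  (qL_high−amb < 0, P⁺_high−amb < 0).
* Model 2 — rapid NPQ (qE): excitation delivery to PSII drops, so both
  pools go net *oxidized* (qL_high−amb > 0, P⁺_high−amb > 0).
* Model 3 — photosynthetic control (PCON) without qE: plastoquinol
  oxidation at cytochrome b6f slows, so Q_A goes net *reduced* while
  P700 goes net *oxidized* (qL_high−amb < 0, P⁺_high−amb > 0).

The fourth quadrant (Q_A oxidized, P700 reduced) is predicted by none of
the models; points there, or inside the dead-zone margin around zero,
are unclassified.

The qE-vs-PCON balance is quantified per cluster as the OLS slope of
rapid NPQ change (NPQ_high−amb) on rapid pmf change (ECSt_high−amb):
steep slopes indicate NPQ responding readily to lumen acidification,
shallow slopes indicate pmf building with little qE response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MODEL1 = "model1_psi_acceptor"
MODEL2 = "model2_npq"
MODEL3 = "model3_pcon"
UNCLASSIFIED = "intermediate_unclassified"
LABELS = (MODEL1, MODEL2, MODEL3, UNCLASSIFIED)

#: map simulator regime names onto classifier labels
REGIME_TO_LABEL = {
    "model1": MODEL1,
    "model2": MODEL2,
    "model3": MODEL3,
    "intermediate": UNCLASSIFIED,
}


def classify_point(ql_diff: float, p700_diff: float, margin: float = 0.0) -> str:
    """Sign-region label for one observation.

    ``margin`` is a dead zone around zero: a diff with magnitude at or
    below it counts as sign-indeterminate, sending the point to
    unclassified.  Missing inputs are unclassified.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if not (np.isfinite(ql_diff) and np.isfinite(p700_diff)):
        return UNCLASSIFIED
    if p700_diff < -margin and ql_diff < -margin:
        return MODEL1
    if p700_diff > margin and ql_diff > margin:
        return MODEL2
    if p700_diff > margin and ql_diff < -margin:
        return MODEL3
    return UNCLASSIFIED


def classify_points(
    table: pd.DataFrame,
    ql_col: str = "ql_high_amb",
    p700_col: str = "p700_ox_high_amb",
    margin: float = 0.0,
) -> pd.Series:
    """Vectorized :func:`classify_point` over a derived table."""
    ql_d = table[ql_col].to_numpy(dtype=float)
    p_d = table[p700_col].to_numpy(dtype=float)
    labels = np.full(len(table), UNCLASSIFIED, dtype=object)
    finite = np.isfinite(ql_d) & np.isfinite(p_d)
    labels[finite & (p_d < -margin) & (ql_d < -margin)] = MODEL1
    labels[finite & (p_d > margin) & (ql_d > margin)] = MODEL2
    labels[finite & (p_d > margin) & (ql_d < -margin)] = MODEL3
    return pd.Series(labels, index=table.index, name="mechanism_label")


def ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, standard error and intercept of y on x (with intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    vx = np.var(x)
    if n < 3 or vx == 0:
        return np.nan, np.nan, np.nan
    slope = float(np.cov(x, y, bias=True)[0, 1] / vx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - intercept - slope * x
    se = float(np.sqrt(resid @ resid / (n - 2) / (n * vx)))
    return slope, se, intercept


def cluster_slopes(
    table: pd.DataFrame,
    assignments: np.ndarray,
    y_col: str = "npqt_high_amb",
    x_col: str = "ecst_high_amb",
    row_index: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-cluster OLS slope of rapid NPQ on rapid pmf change.

    Clusters with fewer than 3 usable rows or zero variance in the pmf
    change are reported inestimable (NaN slope with a note).
    """
    sub = table.loc[row_index] if row_index is not None else table
    sub = sub.reset_index(drop=True)
    assignments = np.asarray(assignments)
    out = []
    for c in np.unique(assignments):
        rows = sub[assignments == c].dropna(subset=[y_col, x_col])
        n = len(rows)
        slope, se, intercept = ols_slope(rows[x_col].to_numpy(), rows[y_col].to_numpy())
        note = ""
        if n < 3:
            note = "inestimable: fewer than 3 rows"
        elif not np.isfinite(slope):
            note = "inestimable: zero variance in pmf change"
        out.append({"cluster": int(c), "slope": slope, "se": se,
                    "intercept": intercept, "n": n, "note": note})
    return pd.DataFrame(out)


@dataclass
class MechanismReport:
    """Cluster-level view of the sign-region classification."""

    point_labels: pd.Series
    cluster_table: pd.DataFrame
    slopes: pd.DataFrame
    margin: float


def mechanism_report(
    table: pd.DataFrame,
    assignments: np.ndarray,
    margin: float = 0.0,
    ql_col: str = "ql_high_amb",
    p700_col: str = "p700_ox_high_amb",
    row_index: np.ndarray | None = None,
) -> MechanismReport:
    """Per-cluster majority labels, model-region fractions, covariate
    distribution summaries (median, IQR of T_leaf and √PAR_amb) and
    NPQ-vs-pmf slopes."""
    sub = table.loc[row_index] if row_index is not None else table
    sub = sub.reset_index(drop=True)
    assignments = np.asarray(assignments)
    labels = classify_points(sub, ql_col, p700_col, margin)

    rows = []
    for c in np.unique(assignments):
        in_c = assignments == c
        lab_c = labels[in_c]
        n = int(in_c.sum())
        fractions = {f"frac_{lab}": float((lab_c == lab).mean()) for lab in LABELS}
        majority = lab_c.value_counts().idxmax() if n else UNCLASSIFIED
        row = {"cluster": int(c), "n": n, "majority_label": majority, **fractions}
        for col, name in (("t_leaf", "t_leaf"), ("sqrt_par", "sqrt_par")):
            if col in sub.columns:
                vals = sub.loc[in_c, col].dropna()
                row[f"{name}_median"] = float(vals.median()) if len(vals) else np.nan
                row[f"{name}_iqr"] = (
                    float(vals.quantile(0.75) - vals.quantile(0.25)) if len(vals) else np.nan
                )
        rows.append(row)
    cluster_table = pd.DataFrame(rows)
    slopes = cluster_slopes(sub, assignments)
    cluster_table = cluster_table.merge(
        slopes[["cluster", "slope", "se"]], on="cluster", how="left"
    )
    return MechanismReport(labels, cluster_table, slopes, margin)
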