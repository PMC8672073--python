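"""Gaussian mixture clustering of responses against environment covariates.

Photosynthetic responses in the field depend jointly on ambient PAR and
leaf temperature, and those covariates are themselves correlated through
weather and time of day.  Unsupervised GMM clustering of
(response, √PAR_amb, T_leaf) feature triplets separates regions of
distinct interaction without hand-chosen covariate slices; within-cluster
ordinary least squares then quantifies which covariate drives the
response inside each region.

The mixture is fitted by expectation–maximization over a lattice of six
covariance parametrizations — {spherical, diagonal, full} × {equal
across components, varying} — and the number of components K and the
family are selected jointly by the Bayesian information criterion
BIC = −2·loglik + p·log(n) (minimized).  Tied ("equal") families
constrain the volume/shape/orientation of the component covariances,
trading flexibility for parameter economy exactly as in model-based
clustering practice.

A fitted baseline clustering for one response can be *transferred* to
another response measured on the same leaves: rows keep their baseline
cluster labels while per-cluster summaries and covariate dependencies are
recomputed, exposing how the interaction pattern changes between, e.g.,
ambient and high-light NPQ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.cluster import kmeans_plusplus
from sklearn.metrics import adjusted_rand_score

#: covariance families ordered by increasing complexity (tie-break order)
FAMILIES = (
    "spherical-equal",
    "spherical-varying",
    "diagonal-equal",
    "diagonal-varying",
    "full-equal",
    "full-varying",
)

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class FeatureSpec:
    """Columns entering the mixture: one response plus the covariates."""

    response: str
    covariates: tuple[str, ...] = ("sqrt_par", "t_leaf")
    standardize: bool = True

    @property
    def columns(self) -> list[str]:
        return [self.response, *self.covariates]


@dataclass
class GmmFit:
    """A selected mixture with its full model-selection table."""

    k: int
    family: str
    weights: np.ndarray
    means: np.ndarray               # (k, d), standardized space
    covariances: np.ndarray         # (k, d, d), standardized space
    responsibilities: np.ndarray    # (n, k)
    assignments: np.ndarray         # (n,), MAP labels
    loglik: float
    loglik_trace: np.ndarray
    bic: float
    bic_table: pd.DataFrame
    n_init: int
    seed: int
    feature_names: list[str]
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    row_index: np.ndarray           # original table index of the used rows
    n_dropped: int = 0

    @property
    def means_original(self) -> np.ndarray:
        """Cluster means back-transformed to original feature units."""
        return self.means * self.scale_sd + self.scale_mean

    def to_json(self) -> str:
        payload = {
            "k": int(self.k),
            "family": self.family,
            "weights": self.weights.tolist(),
            "means": self.means_original.tolist(),
            "covariances": self.covariances.tolist(),
            "loglik": self.loglik,
            "bic": self.bic,
            "bic_table": self.bic_table.to_dict(orient="records"),
            "n_init": int(self.n_init),
            "seed": int(self.seed),
            "feature_names": self.feature_names,
            "standardized": True,
            "scale_mean": self.scale_mean.tolist(),
            "scale_sd": self.scale_sd.tolist(),
        }
        return json.dumps(payload, indent=2)


def n_cov_params(family: str, k: int, d: int) -> int:
    shape, tying = family.split("-")
    per = {"spherical": 1, "diagonal": d, "full": d * (d + 1) // 2}[shape]
    return per if tying == "equal" else k * per


def n_params(family: str, k: int, d: int) -> int:
    return (k - 1) + k * d + n_cov_params(family, k, d)


def _log_gauss(X: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Component log densities, (n, k), via batched Cholesky."""
    d = X.shape[1]
    chol = np.linalg.cholesky(covs)                      # (k, d, d)
    logdet = 2.0 * np.log(np.diagonal(chol, axis1=1, axis2=2)).sum(axis=1)
    diff = X[None, :, :] - means[:, None, :]             # (k, n, d)
    # batched triangular solve: z = chol^{-1} diff^T per component
    z = np.linalg.solve(chol, np.swapaxes(diff, 1, 2))   # (k, d, n)
    maha = np.einsum("kdn,kdn->kn", z, z)
    return (-0.5 * (d * LOG2PI + logdet[:, None] + maha)).T


def _logsumexp_rows(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=1)
    return m + np.log(np.exp(a - m[:, None]).sum(axis=1))


def _m_step(X: np.ndarray, resp: np.ndarray, family: str, reg: float):
    n, d = X.shape
    k = resp.shape[1]
    nk = resp.sum(axis=0) + 1e-300
    weights = nk / n
    means = (resp.T @ X) / nk[:, None]
    shape, tying = family.split("-")

    diff = X[None, :, :] - means[:, None, :]             # (k, n, d)
    scat = np.einsum("nk,knd,kne->kde", resp, diff, diff)
    if tying == "equal":
        pooled = scat.sum(axis=0) / n
        covs = np.repeat(pooled[None], k, axis=0)
    else:
        covs = scat / nk[:, None, None]

    if shape == "diagonal":
        eye = np.eye(d, dtype=bool)
        covs = np.where(eye[None], covs, 0.0)
    elif shape == "spherical":
        var = np.trace(covs, axis1=1, axis2=2) / d
        covs = var[:, None, None] * np.eye(d)[None]
    covs = covs + reg * np.eye(d)[None]
    return weights, means, covs


def _em_once(X: np.ndarray, k: int, family: str, rng_seed: int,
             tol: float, max_iter: int, reg: float):
    n, d = X.shape
    if k == 1:
        resp = np.ones((n, 1))
    else:
        centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=rng_seed)
        dist = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
        hard = dist.argmin(axis=1)
        resp = np.zeros((n, k))
        resp[np.arange(n), hard] = 1.0
        # guard against an empty initial component
        for j in range(k):
            if resp[:, j].sum() < 1:
                resp[dist[:, j].argmin()] = 0.0
                resp[dist[:, j].argmin(), j] = 1.0

    def _check_degenerate(weights, covs):
        # a component collapsing onto fewer points than dimensions+1, or
        # with covariance shrinking to the ridge floor, has an unbounded
        # likelihood: the candidate run has no MLE and must be rejected.
        if k > 1 and np.any(weights * n < d + 1):
            raise RuntimeError("degenerate component (too few members)")
        eigmin = np.linalg.eigvalsh(covs)[:, 0].min()
        if eigmin < 100.0 * reg:
            raise RuntimeError("degenerate component (collapsed covariance)")

    weights, means, covs = _m_step(X, resp, family, reg)
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        _check_degenerate(weights, covs)
        log_comp = _log_gauss(X, means, covs) + np.log(weights + 1e-300)
        norm = _logsumexp_rows(log_comp)
        loglik = float(norm.sum())
        trace.append(loglik)
        if loglik + 1e-10 * max(abs(loglik), 1.0) < prev:
            raise RuntimeError("EM log-likelihood decreased")
        if abs(loglik - prev) < tol * max(abs(loglik), 1.0):
            break
        prev = loglik
        resp = np.exp(log_comp - norm[:, None])
        weights, means, covs = _m_step(X, resp, family, reg)
    _check_degenerate(weights, covs)
    log_comp = _log_gauss(X, means, covs) + np.log(weights + 1e-300)
    norm = _logsumexp_rows(log_comp)
    resp = np.exp(log_comp - norm[:, None])
    return weights, means, covs, resp, float(norm.sum()), np.asarray(trace)


def fit_gmm(
    table: pd.DataFrame,
    spec: FeatureSpec,
    k_range: Iterable[int] = range(1, 7),
    families: Sequence[str] = FAMILIES,
    n_init: int = 4,
    seed: int = 0,
    reg: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 500,
    order_by: str | None = "sqrt_par",
) -> GmmFit:
    """Fit mixtures over (K, family) and select by BIC.

    Rows with missing values in any feature column are excluded and
    counted in ``n_dropped``.  Each candidate gets ``n_init``
    k-means++-seeded EM starts; EM iterates to relative log-likelihood
    change < ``tol`` or ``max_iter`` sweeps.  Singular candidates (after
    ridge regularization ``reg``) are dropped with a warning row in the
    BIC table.  Ties in BIC resolve to smaller K, then the simpler
    family.  Selected components are relabeled by ascending cluster mean
    of ``order_by`` (original units; falls back to the first feature).

    Fully deterministic given (table, spec, seed).
    """
    k_range = sorted(set(int(k) for k in k_range))
    if min(k_range) < 1 or max(k_range) > 12:
        raise ValueError("k_range must lie within [1, 12]")
    unknown = [f for f in families if f not in FAMILIES]
    if unknown:
        raise ValueError(f"unknown covariance families: {unknown}")
    missing = [c for c in spec.columns if c not in table.columns]
    if missing:
        raise KeyError(f"feature columns not in table: {missing}")

    feats = table[spec.columns].astype(float)
    mask = feats.notna().all(axis=1)
    X = feats[mask].to_numpy()
    row_index = np.asarray(table.index[mask])
    n, d = X.shape
    if n < 10:
        raise ValueError(f"need >= 10 usable rows, got {n}")

    if spec.standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        mu, sd = np.zeros(d), np.ones(d)
    Z = (X - mu) / sd

    master = np.random.default_rng(seed)
    rows = []
    candidates = {}
    for k in k_range:
        for family in families:
            init_seeds = master.integers(0, 2**31 - 1, size=n_init)
            best = None
            for s in init_seeds:
                try:
                    res = _em_once(Z, k, family, int(s), tol, max_iter, reg)
                except (np.linalg.LinAlgError, RuntimeError):
                    continue
                if best is None or res[4] > best[4]:
                    best = res
            p = n_params(family, k, d)
            if best is None:
                rows.append({"k": k, "family": family, "loglik": np.nan,
                             "n_params": p, "bic": np.nan, "ok": False})
                continue
            bic = -2.0 * best[4] + p * np.log(n)
            rows.append({"k": k, "family": family, "loglik": best[4],
                         "n_params": p, "bic": bic, "ok": True})
            candidates[(k, family)] = best
    bic_table = pd.DataFrame(rows)
    ok = bic_table[bic_table["ok"]]
    if ok.empty:
        raise RuntimeError("every (K, family) candidate failed")
    order = ok.assign(
        _fam_rank=ok["family"].map(FAMILIES.index)
    ).sort_values(["bic", "k", "_fam_rank"], kind="mergesort")
    sel = order.iloc[0]
    k_sel, fam_sel = int(sel["k"]), str(sel["family"])
    weights, means, covs, resp, loglik, trace = candidates[(k_sel, fam_sel)]

    # canonical component order: ascending mean of the ordering feature
    if order_by in spec.columns:
        oi = spec.columns.index(order_by)
    else:
        oi = 0
    means_orig = means * sd + mu
    perm = np.argsort(means_orig[:, oi], kind="stable")
    weights, means, covs, resp = weights[perm], means[perm], covs[perm], resp[:, perm]
    assignments = resp.argmax(axis=1)

    return GmmFit(
        k=k_sel, family=fam_sel, weights=weights, means=means, covariances=covs,
        responsibilities=resp, assignments=assignments, loglik=loglik,
        loglik_trace=trace, bic=float(sel["bic"]), bic_table=bic_table,
        n_init=n_init, seed=seed, feature_names=spec.columns,
        scale_mean=mu, scale_sd=sd, row_index=row_index,
        n_dropped=int((~mask).sum()),
    )


def within_cluster_dependence(
    table: pd.DataFrame,
    assignments: np.ndarray,
    response: str,
    covariates: Sequence[str] = ("sqrt_par", "t_leaf"),
    alpha: float = 0.05,
    min_rows: int = 5,
    row_index: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-cluster OLS of the response on the covariates.

    Returns a tidy coefficient table (cluster, term, coef, se, t, p,
    significant, n, note).  Clusters below ``min_rows`` are reported as
    untestable; rank-deficient designs mark coefficients inestimable;
    a zero-variance response is fitted trivially (all coefficients 0)
    and noted.
    """
    sub = table.loc[row_index] if row_index is not None else table
    sub = sub.reset_index(drop=True)
    out = []
    for c in np.unique(assignments):
        rows = sub[np.asarray(assignments) == c]
        rows = rows.dropna(subset=[response, *covariates])
        n = len(rows)
        if n < min_rows:
            out.append({"cluster": int(c), "term": None, "coef": np.nan,
                        "se": np.nan, "t": np.nan, "p": np.nan,
                        "significant": False, "n": n, "note": "untestable: too few rows"})
            continue
        y = rows[response].to_numpy()
        Xd = sm.add_constant(rows[list(covariates)].to_numpy())
        note = ""
        if np.var(y) == 0:
            for term in ("const", *covariates):
                out.append({"cluster": int(c), "term": term, "coef": 0.0 if term != "const" else float(y[0]),
                            "se": 0.0, "t": np.nan, "p": np.nan, "significant": False,
                            "n": n, "note": "zero-variance response"})
            continue
        rank = np.linalg.matrix_rank(Xd)
        if rank < Xd.shape[1]:
            for term in ("const", *covariates):
                out.append({"cluster": int(c), "term": term, "coef": np.nan,
                            "se": np.nan, "t": np.nan, "p": np.nan, "significant": False,
                            "n": n, "note": "inestimable: rank-deficient design"})
            continue
        fit = sm.OLS(y, Xd).fit()
        for term, b, se, tval, pval in zip(("const", *covariates), fit.params,
                                           fit.bse, fit.tvalues, fit.pvalues):
            out.append({"cluster": int(c), "term": term, "coef": float(b),
                        "se": float(se), "t": float(tval), "p": float(pval),
                        "significant": bool(pval < alpha), "n": n, "note": note})
    return pd.DataFrame(out)


def fit_linear_effects(
    table: pd.DataFrame,
    response: str,
    covariates: Sequence[str] = ("sqrt_par", "t_leaf"),
):
    """Global OLS of response on the covariates and their interaction."""
    rows = table.dropna(subset=[response, *covariates])
    if len(rows) < 10:
        raise ValueError(f"need >= 10 rows, got {len(rows)}")
    a, b = covariates
    X = pd.DataFrame(
        {a: rows[a], b: rows[b], f"{a}:{b}": rows[a] * rows[b]}
    )
    return sm.OLS(rows[response].to_numpy(), sm.add_constant(X)).fit()


@dataclass
class TransferResult:
    """Baseline cluster labels re-examined on another response."""

    response: str
    summaries: pd.DataFrame      # per-cluster mean/sd/n of the new response
    dependence: pd.DataFrame     # within-cluster OLS on the new response


def transfer_assignments(
    baseline: GmmFit,
    table: pd.DataFrame,
    other_response: str,
    covariates: Sequence[str] = ("sqrt_par", "t_leaf"),
    alpha: float = 0.05,
) -> TransferResult:
    """Apply the baseline clustering configuration to another response.

    Rows keep their baseline labels; only the summaries and covariate
    dependencies are recomputed.  Rows must be the same table (row
    identity via the fit's stored index).
    """
    if other_response not in table.columns:
        raise KeyError(f"column {other_response!r} not in table")
    if not np.all(np.isin(baseline.row_index, table.index)):
        raise ValueError("table rows do not match the baseline fit")
    sub = table.loc[baseline.row_index]
    summaries = (
        pd.DataFrame({
            "cluster": baseline.assignments,
            other_response: sub[other_response].to_numpy(),
        })
        .groupby("cluster")[other_response]
        .agg(["mean", "std", "count"])
        .rename(columns={"count": "n"})
        .reset_index()
    )
    dep = within_cluster_dependence(
        table, baseline.assignments, other_response, covariates,
        alpha=alpha, row_index=baseline.row_index,
    )
    return TransferResult(other_response, summaries, dep)


def subsample_robustness(
    table: pd.DataFrame,
    spec: FeatureSpec,
    fractions: Sequence[float] = (0.25, 0.5, 0.75, 1.0),
    n_reps: int = 10,
    seed: int = 0,
    min_rows: int = 10,
    **fit_kwargs,
) -> pd.DataFrame:
    """Stability of the clustering under random subsampling.

    For each fraction and replicate the GMM is refitted on the subsample
    and compared — by adjusted Rand index — with the full-data clustering
    restricted to the same rows.  Fraction 1.0 reuses the master seed, so
    it reproduces the full fit exactly (ARI 1, same K).
    """
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    full = fit_gmm(table, spec, seed=seed, **fit_kwargs)
    full_labels = pd.Series(full.assignments, index=full.row_index)
    rng = np.random.default_rng(seed)
    out = []
    for frac in fractions:
        for rep in range(n_reps):
            rep_seed = seed if frac == 1.0 else int(rng.integers(0, 2**31 - 1))
            n_take = int(round(frac * len(table)))
            idx = np.sort(
                np.random.default_rng(rep_seed).choice(
                    np.asarray(table.index), size=n_take, replace=False)
            ) if frac < 1.0 else np.asarray(table.index)
            sub = table.loc[idx]
            usable = sub[spec.columns].notna().all(axis=1).sum()
            if usable < min_rows:
                out.append({"fraction": frac, "rep": rep, "n": int(usable),
                            "selected_k": np.nan, "ari": np.nan,
                            "note": "skipped: subsample below minimum rows"})
                continue
            refit = fit_gmm(sub, spec, seed=rep_seed, **fit_kwargs)
            ref_labels = full_labels.loc[refit.row_index]
            ari = adjusted_rand_score(ref_labels.to_numpy(), refit.assignments)
            out.append({"fraction": frac, "rep": rep, "n": len(sub),
                        "selected_k": refit.k, "ari": float(ari), "note": ""})
    return pd.DataFrame(out)
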