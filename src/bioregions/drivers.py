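"""Multinomial driver models, information-theoretic ranking, and PERMANOVA.

Sub-region membership (a categorical response with K levels) is modelled
by multinomial logistic regression on environmental predictor sets, with
selected Moran's Eigenvector Maps appended as spatial covariates.
Candidates are ranked by AICc and Akaike weights; the explained deviance
of the best model is partitioned into unique environmental, unique
spatial, and shared components.  A distance-based two-way PERMANOVA
compares classification schemes on the raw Simpson matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .betadiv import DissimilarityMatrix
from .data import SiteRegistry
from .spatial import Correlogram, correlogram

logger = logging.getLogger(__name__)

__all__ = ["MultinomialFit", "ModelTable", "DeviancePartition",
           "fit_multinomial", "null_deviance", "aicc", "waicc",
           "build_candidates", "explained_deviance", "partition_deviance",
           "permanova_2way", "residual_diagnostics"]


@dataclass
class MultinomialFit:
    """A fitted multinomial logistic model.

    Coefficients are (K-1) x (p+1) against the reference class (the
    largest class); predictors are standardized internally and the
    coefficients refer to the standardized scale.
    """

    classes: np.ndarray
    reference: object
    coef: np.ndarray
    log_lik: float
    n: int
    p_effective: int
    predictor_names: list[str]
    probabilities: np.ndarray        # n x K, columns ordered as `classes`
    y_index: np.ndarray              # observed class index per observation
    converged: bool = True

    @property
    def deviance(self) -> float:
        return -2.0 * self.log_lik


@dataclass
class DeviancePartition:
    total_explained: float
    unique_env: float
    unique_spatial: float
    shared: float

    @property
    def unexplained(self) -> float:
        return 1.0 - self.total_explained

    def shares_of_explained(self) -> tuple[float, float]:
        """(unique env, unique spatial) as fractions of explained deviance."""
        t = self.total_explained
        if t == 0:
            return np.nan, np.nan
        return self.unique_env / t, self.unique_spatial / t


@dataclass
class ModelTable:
    """Ranked candidate models with AICc statistics."""

    table: pd.DataFrame
    fits: dict = field(default_factory=dict)

    def best(self) -> str:
        return str(self.table.iloc[0]["model"])


def _design(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize columns and prepend an intercept."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (x - mu) / sd
    return np.column_stack([np.ones(len(x)), z]), mu, sd


def fit_multinomial(labels, design: pd.DataFrame | np.ndarray,
                    ridge: float = 1e-8, max_iter: int = 500,
                    tol: float = 1e-10) -> MultinomialFit:
    """Maximum-likelihood multinomial logistic regression.

    A tiny ridge penalty keeps the optimum finite on separable data; the
    reported log-likelihood is the unpenalized value at the estimate.
    Deterministic (zero initialization, L-BFGS with analytic gradient).
    """
    if isinstance(design, pd.DataFrame):
        names = [str(c) for c in design.columns]
        x = design.to_numpy(dtype=float)
    else:
        x = np.asarray(design, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = [f"x{j}" for j in range(x.shape[1])]
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    k = classes.size
    if k < 2:
        raise ValueError("need at least two classes")
    if np.any(counts < 2):
        raise ValueError("every class needs at least two observations")
    ref = classes[int(counts.argmax())]
    others = [c for c in classes if c != ref]
    order = [ref] + others                      # column 0 = reference
    col_of = {c: i for i, c in enumerate(order)}
    yi = np.array([col_of[v] for v in y])
    xd, _, _ = _design(x) if x.shape[1] else (np.ones((len(y), 1)), None, None)
    n, p1 = xd.shape
    km1 = k - 1

    y_onehot = np.zeros((n, k))
    y_onehot[np.arange(n), yi] = 1.0

    def nll_grad(theta):
        b = theta.reshape(km1, p1)
        eta = np.column_stack([np.zeros(n), xd @ b.T])    # reference eta = 0
        eta -= eta.max(axis=1, keepdims=True)
        expo = np.exp(eta)
        prob = expo / expo.sum(axis=1, keepdims=True)
        ll = np.sum(np.log(prob[np.arange(n), yi] + 1e-300))
        nll = -ll + ridge * np.sum(b**2)
        grad = (prob - y_onehot)[:, 1:].T @ xd + 2.0 * ridge * b
        return nll, grad.ravel()

    theta0 = np.zeros(km1 * p1)
    res = minimize(nll_grad, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9})
    b = res.x.reshape(km1, p1)
    eta = np.column_stack([np.zeros(n), xd @ b.T])
    eta -= eta.max(axis=1, keepdims=True)
    expo = np.exp(eta)
    prob = expo / expo.sum(axis=1, keepdims=True)
    log_lik = float(np.sum(np.log(prob[np.arange(n), yi] + 1e-300)))
    # re-order probability columns to sorted class order
    prob_sorted = np.column_stack([prob[:, col_of[c]] for c in classes])
    yi_sorted = np.searchsorted(classes, y)
    return MultinomialFit(classes=classes, reference=ref, coef=b,
                          log_lik=log_lik, n=n, p_effective=km1 * p1,
                          predictor_names=names, probabilities=prob_sorted,
                          y_index=yi_sorted, converged=bool(res.success))


def null_deviance(labels) -> float:
    """Deviance of the intercept-only model: -2 Σ_g n_g ln(n_g/N)."""
    _, counts = np.unique(np.asarray(labels), return_counts=True)
    n = counts.sum()
    return float(-2.0 * np.sum(counts * np.log(counts / n)))


def aicc(fit_or_loglik, k: int | None = None, n: int | None = None) -> float:
    """Small-sample Akaike information criterion.

    AICc = -2ℓ + 2k + 2k(k+1)/(n-k-1), with k the number of free
    parameters ((K-1)(p+1) for a multinomial fit).
    """
    if isinstance(fit_or_loglik, MultinomialFit):
        ll, k, n = fit_or_loglik.log_lik, fit_or_loglik.p_effective, fit_or_loglik.n
    else:
        ll = float(fit_or_loglik)
        if k is None or n is None:
            raise ValueError("k and n required with a bare log-likelihood")
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined: n <= k + 1")
    return -2.0 * ll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def waicc(aicc_values) -> np.ndarray:
    """Akaike weights: w_m = exp(-Δ_m/2) / Σ exp(-Δ/2)."""
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


DEFAULT_SETS = {
    "soil": ["sand", "cec"],
    "topography": ["elevation", "elevation_cv"],
    "current_climate": ["AI"],
    "historical_climate": ["HAI", "hydric_change", "thermal_change"],
    "footprint": ["footprint"],
}
CURRENT_SETS = ["current_climate"]
HISTORICAL_SETS = ["historical_climate"]


def build_candidates(predictor_sets: dict[str, list[str]] | None = None,
                     current: list[str] | None = None,
                     historical: list[str] | None = None
                     ) -> dict[str, list[str]]:
    """Enumerate candidate predictor designs.

    Candidates: every single predictor, every named set, every
    current × historical set combination, and the full model.
    Duplicate designs (a single-variable set equals its lone predictor)
    collapse to one entry.  Spatial MEM columns are appended at fit
    time, not here.
    """
    sets = predictor_sets or DEFAULT_SETS
    if any(len(v) == 0 for v in sets.values()):
        raise ValueError("empty predictor set")
    current = current if current is not None else CURRENT_SETS
    historical = historical if historical is not None else HISTORICAL_SETS
    out: dict[str, list[str]] = {}
    seen: set[frozenset] = set()

    def add(name, cols):
        key = frozenset(cols)
        if key not in seen:
            seen.add(key)
            out[name] = list(cols)

    singles = sorted({v for vs in sets.values() for v in vs})
    for v in singles:
        add(v, [v])
    for name in sorted(sets):
        add(name, sets[name])
    for c in current:
        for h in historical:
            add(f"{c}+{h}", sets[c] + sets[h])
    add("full", [v for name in sets for v in sets[name]])
    return out


def rank_candidates(labels, predictor_table: pd.DataFrame,
                    candidates: dict[str, list[str]],
                    mem_vectors: np.ndarray | None = None,
                    ridge: float = 1e-8) -> ModelTable:
    """Fit every candidate (plus MEMs) and rank by AICc."""
    d_null = null_deviance(labels)
    mem_df = None
    if mem_vectors is not None and mem_vectors.size:
        mem_df = pd.DataFrame(
            mem_vectors, index=predictor_table.index,
            columns=[f"MEM{i+1}" for i in range(mem_vectors.shape[1])])
    rows = []
    fits = {}
    for name, cols in candidates.items():
        design = predictor_table[cols]
        if mem_df is not None:
            design = pd.concat([design, mem_df], axis=1)
        fit = fit_multinomial(labels, design, ridge=ridge)
        if fit.n - fit.p_effective - 1 <= 0:
            # AICc undefined at this sample size; candidate cannot compete
            logger.warning("dropping candidate '%s': %d parameters for "
                           "%d observations", name, fit.p_effective, fit.n)
            continue
        ed = (d_null - fit.deviance) / d_null
        rows.append({"model": name, "predictors": "+".join(cols),
                     "logLik": fit.log_lik, "k": fit.p_effective,
                     "AICc": aicc(fit), "explained_deviance": ed})
        fits[name] = fit
    if not rows:
        raise ValueError("no candidate supports AICc at this sample size")
    df = pd.DataFrame(rows)
    df["dAICc"] = df["AICc"] - df["AICc"].min()
    df["wAICc"] = waicc(df["AICc"].to_numpy())
    df = df.sort_values("AICc", kind="stable").reset_index(drop=True)
    return ModelTable(df, fits)


def explained_deviance(fit: MultinomialFit, d_null: float | None = None
                       ) -> float:
    """(D_null - D_model) / D_null."""
    if d_null is None:
        d_null = null_deviance(fit.classes[fit.y_index])
    if d_null == 0:
        raise ValueError("null deviance is zero")
    return (d_null - fit.deviance) / d_null


def partition_deviance(labels, env_design: pd.DataFrame,
                       mem_design: pd.DataFrame | np.ndarray,
                       ridge: float = 1e-8) -> DeviancePartition:
    """Partition explained deviance into unique and shared components.

    total = ED(env+mem); unique_env = total - ED(mem);
    unique_mem = total - ED(env); shared = ED(env) + ED(mem) - total.
    The three components sum to the total by construction.
    """
    if isinstance(mem_design, np.ndarray):
        mem_design = pd.DataFrame(
            mem_design, index=env_design.index,
            columns=[f"MEM{i+1}" for i in range(mem_design.shape[1])])
    d_null = null_deviance(labels)
    both = pd.concat([env_design, mem_design], axis=1)
    ed_both = explained_deviance(fit_multinomial(labels, both, ridge=ridge), d_null)
    ed_env = explained_deviance(fit_multinomial(labels, env_design, ridge=ridge), d_null)
    ed_mem = explained_deviance(fit_multinomial(labels, mem_design, ridge=ridge), d_null)
    return DeviancePartition(
        total_explained=ed_both,
        unique_env=ed_both - ed_mem,
        unique_spatial=ed_both - ed_env,
        shared=ed_env + ed_mem - ed_both,
    )


def _dummy(f: np.ndarray) -> np.ndarray:
    """Full-rank treatment-coded dummy matrix (no intercept column)."""
    levels = np.unique(f)
    return np.column_stack([(f == lv).astype(float) for lv in levels[1:]])


def _hat(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q @ q.T


def permanova_2way(d: DissimilarityMatrix, factor_a, factor_b,
                   n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Two-way PERMANOVA with sequential (Type-I) sums of squares.

    The Gower-centered inner-product matrix of the dissimilarities is
    partitioned by hat-matrix projections of the treatment-coded designs
    for A, B (after A), and the interaction (after both); pseudo-F uses
    the residual mean square and p-values come from free permutation of
    the rows/columns of the dissimilarity matrix.
    """
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    n = d.n
    if fa.size != n or fb.size != n:
        raise ValueError("factor length must match the matrix")
    if np.unique(fa).size < 2 or np.unique(fb).size < 2:
        raise ValueError("factors need at least two levels")
    g = _gower(d.d)
    ones = np.ones((n, 1))
    xa = np.column_stack([ones, _dummy(fa)])
    xab = np.column_stack([xa, _dummy(fb)])
    inter = _interaction(fa, fb)
    xfull = np.column_stack([xab, inter])
    h1, h2, hf = _hat(xa), _hat(xab), _hat(xfull)
    df_a = np.unique(fa).size - 1
    df_b = np.unique(fb).size - 1
    rank_full = np.linalg.matrix_rank(xfull)
    df_ab = rank_full - 1 - df_a - df_b
    df_res = n - rank_full
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom (factors confounded)")

    h0 = np.full((n, n), 1.0 / n)

    def stats(am):
        # Each hat matrix contains the intercept, so tr(H G) on the
        # Gower-centered G reduces to tr((H - H0) A) with A = -D²/2;
        # tr(A) = 0 because the diagonal of D is zero.
        t0 = np.sum(h0 * am)
        t1 = np.sum(h1 * am)
        t2 = np.sum(h2 * am)
        tf = np.sum(hf * am)
        ss_a = t1 - t0
        ss_b = t2 - t1
        ss_ab = tf - t2
        ss_res = np.trace(am) - tf
        ss_tot = np.trace(am) - t0
        return ss_a, ss_b, ss_ab, ss_res, ss_tot

    ss_a, ss_b, ss_ab, ss_res, ss_tot = stats(g)
    ms_res = ss_res / df_res
    f_a = (ss_a / df_a) / ms_res
    f_b = (ss_b / df_b) / ms_res
    f_ab = (ss_ab / df_ab) / ms_res if df_ab > 0 else np.nan

    rng = np.random.default_rng(seed)
    count = np.zeros(3)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        pa, pb, pab, pres, _ = stats(gp)
        pms = pres / df_res
        count[0] += (pa / df_a) / pms >= f_a - 1e-12
        count[1] += (pb / df_b) / pms >= f_b - 1e-12
        if df_ab > 0:
            count[2] += (pab / df_ab) / pms >= f_ab - 1e-12
    p = (count + 1) / (n_perm + 1)
    rows = [
        {"term": "A", "df": df_a, "SS": ss_a, "pseudo_F": f_a,
         "R2": ss_a / ss_tot, "p": p[0]},
        {"term": "B", "df": df_b, "SS": ss_b, "pseudo_F": f_b,
         "R2": ss_b / ss_tot, "p": p[1]},
        {"term": "AxB", "df": df_ab, "SS": ss_ab, "pseudo_F": f_ab,
         "R2": ss_ab / ss_tot, "p": p[2] if df_ab > 0 else np.nan},
        {"term": "Residual", "df": df_res, "SS": ss_res, "pseudo_F": np.nan,
         "R2": ss_res / ss_tot, "p": np.nan},
        {"term": "Total", "df": n - 1, "SS": ss_tot, "pseudo_F": np.nan,
         "R2": 1.0, "p": np.nan},
    ]
    return pd.DataFrame(rows)


def _gower(dm: np.ndarray) -> np.ndarray:
    """-D²/2; Gower centering happens inside the projection arithmetic."""
    return -0.5 * dm**2


def _interaction(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    da, db = _dummy(fa), _dummy(fb)
    cols = [da[:, i] * db[:, j] for i in range(da.shape[1])
            for j in range(db.shape[1])]
    return np.column_stack(cols) if cols else np.zeros((fa.size, 0))


def residual_diagnostics(fit: MultinomialFit, registry: SiteRegistry,
                         n_classes: int = 14, n_perm: int = 199,
                         seed: int = 0) -> Correlogram:
    """Correlogram of per-site residuals 1 - P(observed class)."""
    resid = 1.0 - fit.probabilities[np.arange(fit.n), fit.y_index]
    if np.ptp(resid) == 0:
        raise ValueError("residuals are constant")
    return correlogram(resid, registry, n_classes=n_classes, n_perm=n_perm,
                       seed=seed)
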