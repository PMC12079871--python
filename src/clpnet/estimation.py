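"""Cross-lagged panel network estimation via node-wise penalized regression.

The directed network over two waves is estimated one target node at a time:
each wave-2 node is regressed on *all* wave-1 nodes plus baseline covariates
with an L1 (LASSO) penalty, the penalty chosen by K-fold cross-validation.
Entry ``(i, j)`` of the assembled weight matrix is the coefficient of node
``i`` at wave 1 predicting node ``j`` at wave 2; the diagonal carries the
autoregressive paths, the off-diagonal the cross-lagged edges.

Coefficients are reported on the standardized-predictor scale (unit-variance
columns), which makes edge weights comparable across predictors.  The
penalized solves are delegated to scikit-learn's coordinate-descent path
(objective ``(1/2n)||y - Xb - b0||^2 + lambda * ||b||_1``); the surrounding
grid construction, fold bookkeeping, covariate handling, and matrix assembly
live here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import lasso_path

from .config import AnalysisConfig
from .panel_io import PanelDataset

__all__ = [
    "NodeFit",
    "CLPNResult",
    "Edge",
    "EdgeList",
    "fit_node_lasso",
    "estimate_clpn",
    "threshold_edges",
    "summarize_edges",
]


@dataclass
class NodeFit:
    """One target node's penalized regression on all wave-1 predictors."""

    target_id: str
    coefficients: dict[str, float]            # T1 node id -> weight
    covariate_coefficients: dict[str, float]  # covariate name -> weight
    intercept: float
    selected_penalty: float
    penalty_grid: np.ndarray
    cv_mean_error: np.ndarray                 # mean MSE per grid value
    r_squared_full: float

    def coefficient_vector(self, node_ids: list[str]) -> np.ndarray:
        return np.array([self.coefficients[i] for i in node_ids])


@dataclass
class CLPNResult:
    """Assembled directed T1 -> T2 coefficient matrix plus per-target fits.

    ``weights[i, j]`` is node i (T1) predicting node j (T2); the diagonal is
    autoregressive.  ``autoregressive_mean`` / ``crosslagged_mean`` are the
    signed means of the diagonal / all off-diagonal cells (the scale contrast
    conventionally reported for such networks).
    """

    weights: np.ndarray
    node_ids: list[str]
    node_constructs: list[str]
    fits: list[NodeFit]
    threshold: float = 0.0

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def autoregressive_mean(self) -> float:
        return float(np.mean(np.diag(self.weights)))

    @property
    def crosslagged_mean(self) -> float:
        off = ~np.eye(self.n_nodes, dtype=bool)
        return float(np.mean(self.weights[off]))

    def crosslagged_weights(self) -> np.ndarray:
        """Flat vector of off-diagonal cells in row-major order."""
        off = ~np.eye(self.n_nodes, dtype=bool)
        return self.weights[off]

    def to_json(self) -> str:
        return json.dumps({
            "node_ids": self.node_ids,
            "node_constructs": self.node_constructs,
            "weights": self.weights.tolist(),
            "threshold": self.threshold,
            "autoregressive_mean": self.autoregressive_mean,
            "crosslagged_mean": self.crosslagged_mean,
            "selected_penalties": {f.target_id: f.selected_penalty
                                   for f in self.fits},
        }, sort_keys=True)


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    weight: float
    is_autoregressive: bool


@dataclass
class EdgeList:
    """Edges sorted by |weight| descending; ties broken lexicographically."""

    edges: list[Edge]
    threshold: float = 0.0
    autoregressive: list[Edge] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.edges)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale columns to unit variance; zero-variance cols flagged."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Xs = np.zeros_like(X)
    Xs[:, keep] = (X[:, keep] - mu[keep]) / sd[keep]
    return Xs, keep


def _penalty_grid(Xs: np.ndarray, y: np.ndarray, penalize: np.ndarray,
                  size: int, decades: float = 4.0) -> np.ndarray:
    """Log-spaced grid from the data's lambda_max down ``decades`` orders.

    lambda_max is the smallest penalty at which every *penalized* coefficient
    is zero: ``max_k |x_k' (y - ybar)| / n`` over penalized columns.
    """
    n = len(y)
    resid = y - y.mean()
    grads = np.abs(Xs.T @ resid) / n
    lam_max = float(np.max(grads[penalize])) if penalize.any() else 1.0
    if lam_max <= 0:
        lam_max = 1e-3
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, size)


def _lasso_coefs(Xs: np.ndarray, y: np.ndarray, alphas: np.ndarray,
                 tol: float = 1e-4) -> np.ndarray:
    """Coefficient paths (p, n_alphas) for pre-standardized X.

    CV path fits use the solver's default tolerance; final fits are solved
    to high precision (tight ``tol``).
    """
    Xf = np.asfortranarray(Xs, dtype=np.float64)
    yc = np.ascontiguousarray(y - y.mean(), dtype=np.float64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign convergence chatter at tiny lambda
        # data is pre-centered/validated here, so skip sklearn's per-alpha checks
        _, coefs, _ = lasso_path(Xf, yc, alphas=alphas, tol=tol,
                                 max_iter=100_000, check_input=False)
    return coefs


def fit_node_lasso(y: np.ndarray, X: np.ndarray, folds: int,
                   penalty_grid: np.ndarray | None = None,
                   penalize_mask: np.ndarray | None = None,
                   seed: int = 0,
                   grid_size: int = 100,
                   lambda_rule: str = "min_cv_error",
                   fixed_penalty: float | None = None,
                   predictor_names: list[str] | None = None,
                   n_node_predictors: int | None = None,
                   target_id: str = "",
                   fold_order: np.ndarray | None = None) -> NodeFit:
    """Cross-validated LASSO regression of one target on wave-1 predictors.

    Predictors are standardized to unit variance internally and coefficients
    reported on that scale.  Fold assignment shuffles subjects once with the
    given seed and splits them into contiguous folds; the penalty minimizing
    fold-mean squared prediction error is selected (or the one-SE rule when
    configured).  Columns with ``penalize_mask`` False are left unpenalized,
    handled exactly by residualizing the target and penalized columns on the
    unpenalized block before the penalized solve.

    Passing ``fixed_penalty`` skips cross-validation and solves at that
    penalty directly (used by tests and diagnostic refits).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y disagree on sample size")
    if fixed_penalty is None and folds > n:
        raise ValueError(f"cv folds ({folds}) exceed sample size ({n})")
    if penalize_mask is None:
        penalize_mask = np.ones(p, dtype=bool)
    penalize_mask = np.asarray(penalize_mask, dtype=bool)
    names = predictor_names or [f"x{k}" for k in range(p)]
    n_nodes = n_node_predictors if n_node_predictors is not None else p

    Xs, keep = _standardize(X)
    if not keep.all():
        warnings.warn(
            f"dropping zero-variance predictors: "
            f"{[names[k] for k in np.flatnonzero(~keep)]}", RuntimeWarning)
    active_pen = penalize_mask & keep
    free = ~penalize_mask & keep  # unpenalized, nonconstant

    # Exact partial penalization: project out the unpenalized block first.
    if free.any():
        Z = np.column_stack([np.ones(n), Xs[:, free]])
        Q, _ = np.linalg.qr(Z)
        proj = lambda M: M - Q @ (Q.T @ M)  # noqa: E731
        y_work = proj(y)
        X_work = proj(Xs[:, active_pen])
    else:
        y_work = y - y.mean()
        X_work = Xs[:, active_pen]

    if penalty_grid is None:
        if X_work.size:
            penalty_grid = _penalty_grid(
                X_work, y_work, np.ones(X_work.shape[1], bool), grid_size)
        else:
            penalty_grid = np.array([1.0])
    penalty_grid = np.asarray(penalty_grid, dtype=float)

    if fixed_penalty is not None:
        selected = float(fixed_penalty)
        cv_mean = np.full(len(penalty_grid), np.nan)
    else:
        rng = np.random.default_rng(seed)
        # Shuffle a canonical subject ordering (not raw row positions) so
        # fold membership — hence the whole fit — is row-exchangeable.
        canon = np.arange(n) if fold_order is None \
            else np.asarray(fold_order, dtype=int)
        order = canon[rng.permutation(n)]
        fold_ids = np.empty(n, dtype=int)
        for f, chunk in enumerate(np.array_split(order, folds)):
            fold_ids[chunk] = f
        cv_err = np.zeros((folds, len(penalty_grid)))
        for f in range(folds):
            val = fold_ids == f
            tr = ~val
            mu = X_work[tr].mean(axis=0) if X_work.size else 0.0
            coefs = _lasso_coefs(X_work[tr] - mu, y_work[tr], penalty_grid)
            pred = (X_work[val] - mu) @ coefs + y_work[tr].mean()
            cv_err[f] = np.mean((y_work[val, None] - pred) ** 2, axis=0)
        cv_mean = cv_err.mean(axis=0)
        i_min = int(np.argmin(cv_mean))
        if lambda_rule == "one_se":
            se = cv_err.std(axis=0, ddof=1)[i_min] / np.sqrt(folds)
            ok = np.flatnonzero(cv_mean <= cv_mean[i_min] + se)
            i_sel = int(ok[0])  # grid is descending: first = largest penalty
        else:
            i_sel = i_min
        selected = float(penalty_grid[i_sel])

    if X_work.size:
        beta_pen = _lasso_coefs(X_work, y_work, np.array([selected]),
                                tol=1e-10)[:, 0]
    else:
        beta_pen = np.empty(0)

    beta = np.zeros(p)
    beta[np.flatnonzero(active_pen)] = beta_pen
    if free.any():
        # Recover the unpenalized block by OLS on the partialled residual.
        resid = y - Xs[:, active_pen] @ beta_pen
        Z = np.column_stack([np.ones(n), Xs[:, free]])
        gamma, *_ = np.linalg.lstsq(Z, resid, rcond=None)
        intercept = float(gamma[0])
        beta[np.flatnonzero(free)] = gamma[1:]
    else:
        intercept = float(y.mean())

    yhat = intercept + Xs @ beta
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)

    return NodeFit(
        target_id=target_id,
        coefficients={names[k]: float(beta[k]) for k in range(n_nodes)},
        covariate_coefficients={names[k]: float(beta[k])
                                for k in range(n_nodes, p)},
        intercept=intercept,
        selected_penalty=selected,
        penalty_grid=penalty_grid,
        cv_mean_error=cv_mean,
        r_squared_full=min(1.0, r2),
    )


def estimate_clpn(dataset: PanelDataset, config: AnalysisConfig
                  ) -> CLPNResult:
    """Estimate the full directed network: one CV-LASSO fit per wave-2 node.

    Expects a dataset whose waves have already been nonparanormal-transformed
    (``dataset.transformed``); covariates enter every regression and are
    penalized like node predictors unless ``config.penalize_covariates`` is
    off.  Deterministic given ``config.seed``: fold shuffles use the seed
    offset by the target index.
    """
    if not dataset.transformed:
        warnings.warn(
            "estimating on untransformed responses; apply "
            "transform_dataset() first for the standard pipeline",
            RuntimeWarning)
    p = dataset.n_nodes
    q = dataset.covariates.shape[1]
    X = np.column_stack([dataset.wave1, dataset.covariates]) if q \
        else dataset.wave1
    names = dataset.node_ids + list(dataset.covariate_names)
    mask = np.ones(p + q, dtype=bool)
    if not config.penalize_covariates:
        mask[p:] = False

    # canonical subject order keyed to ids: fold membership is then invariant
    # to joint row permutations of the dataset
    canon = np.argsort(np.asarray([str(s) for s in dataset.subject_ids]),
                       kind="stable")

    fits: list[NodeFit] = []
    weights = np.zeros((p, p))
    for j, node in enumerate(dataset.nodes):
        try:
            fit = fit_node_lasso(
                dataset.wave2[:, j], X, folds=config.cv_folds,
                penalize_mask=mask, seed=config.seed + j,
                grid_size=config.lambda_grid_size,
                lambda_rule=config.lambda_rule,
                predictor_names=names, n_node_predictors=p,
                target_id=node.id, fold_order=canon)
        except Exception as exc:  # annotate with the failing target
            raise RuntimeError(f"node fit failed for target {node.id}") from exc
        fits.append(fit)
        weights[:, j] = fit.coefficient_vector(dataset.node_ids)

    return CLPNResult(
        weights=weights,
        node_ids=dataset.node_ids,
        node_constructs=[nd.construct for nd in dataset.nodes],
        fits=fits,
    )


def compute_threshold(result: CLPNResult, rule: str,
                      fixed_value: float | None = None) -> float:
    off = result.crosslagged_weights()
    if rule == "fixed":
        if fixed_value is None:
            raise ValueError("fixed threshold rule requires a value")
        return float(fixed_value)
    nz = off[off != 0.0]
    if nz.size == 0:
        warnings.warn("no nonzero cross-lagged edges; threshold 0",
                      RuntimeWarning)
        return 0.0
    if rule == "mean_abs_nonzero_crosslagged":
        return float(np.mean(np.abs(nz)))
    if rule == "mean_signed_crosslagged":
        return float(np.mean(nz))
    raise ValueError(f"unknown threshold rule {rule!r}")


def threshold_edges(result: CLPNResult,
                    rule: str = "mean_abs_nonzero_crosslagged",
                    fixed_value: float | None = None) -> EdgeList:
    """Retain cross-lagged edges with |weight| >= threshold.

    The default threshold is the mean absolute nonzero cross-lagged weight;
    autoregressive paths never enter the threshold computation and are
    carried in a separate list.  Retention uses the weak inequality
    (an edge exactly at the threshold is kept).
    """
    thr = compute_threshold(result, rule, fixed_value)
    result.threshold = thr
    ids = result.node_ids
    edges: list[Edge] = []
    autos: list[Edge] = []
    for i in range(result.n_nodes):
        for j in range(result.n_nodes):
            w = float(result.weights[i, j])
            if i == j:
                if w != 0.0:
                    autos.append(Edge(ids[i], ids[j], w, True))
                continue
            if w != 0.0 and abs(w) >= thr:
                edges.append(Edge(ids[i], ids[j], w, False))
    key = lambda e: (-abs(e.weight), e.source, e.target)  # noqa: E731
    edges.sort(key=key)
    autos.sort(key=key)
    return EdgeList(edges=edges, threshold=thr, autoregressive=autos)


def summarize_edges(edges: EdgeList, top_k: int = 10) -> dict:
    """Counts, positive share (integer percent), and the top-k edge ranking."""
    n = len(edges.edges)
    n_pos = sum(1 for e in edges.edges if e.weight > 0)
    n_neg = sum(1 for e in edges.edges if e.weight < 0)
    pct_pos = int(round(100.0 * n_pos / n)) if n else 0
    return {
        "n_edges": n,
        "n_positive": n_pos,
        "n_negative": n_neg,
        "percent_positive": pct_pos,
        "top_edges": edges.edges[:top_k],
    }
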