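"""Prediction centrality for directed two-wave networks.

In-prediction quantifies how much of a node's wave-2 variance is accounted
for by *other* nodes' wave-1 values; out-prediction how much of other nodes'
wave-2 variance a node accounts for.  Both come in two scopes: cross-lagged
(all other nodes) and cross-construct (only nodes of the other construct).
Each quantity is operationalized as a difference of R-squared between nested
unpenalized least-squares models refit on the LASSO-selected support:

* the baseline model ``M0`` for target j contains the covariates and j's own
  autoregressive term (always, even if the penalized fit zeroed it — the
  autoregressive path must be partialled out of every cross-lagged quantity);
* ``crosslagged_in(j)  = R2(M0 + same-construct + other-construct) - R2(M0)``;
* ``crossconstruct_in(j) = R2(full_j) - R2(M0 + same-construct)``;
* ``crosslagged_out(i) = sum over targets j != i that retained i of
  [R2(full_j) - R2(full_j without i)]``, and ``crossconstruct_out`` the same
  sum restricted to targets in the other construct.

All quantities are nested-model R-squared differences, hence nonnegative
(clamped at tiny negative rounding error), and cross-construct values can
never exceed their cross-lagged counterparts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import CLPNResult
from .panel_io import PanelDataset

__all__ = ["CentralityTable", "compute_centrality", "centrality_report"]

INDEX_NAMES = ("crosslagged_out", "crosslagged_in",
               "crossconstruct_out", "crossconstruct_in")


@dataclass
class CentralityTable:
    """Per-node prediction-centrality indices (proportions of variance)."""

    node_ids: list[str]
    crosslagged_out: np.ndarray
    crosslagged_in: np.ndarray
    crossconstruct_out: np.ndarray
    crossconstruct_in: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node": self.node_ids,
            "crosslagged_out": self.crosslagged_out,
            "crosslagged_in": self.crosslagged_in,
            "crossconstruct_out": self.crossconstruct_out,
            "crossconstruct_in": self.crossconstruct_in,
        })

    def values(self, index_name: str) -> np.ndarray:
        if index_name not in INDEX_NAMES:
            raise KeyError(f"unknown centrality index {index_name!r}")
        return getattr(self, index_name)


def _r_squared(y: np.ndarray, X_cols: list[np.ndarray]) -> float:
    """R^2 of OLS with intercept; collinear columns handled by lstsq."""
    n = len(y)
    Z = np.column_stack([np.ones(n)] + X_cols) if X_cols else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0
    return 1.0 - float(np.sum(resid ** 2)) / ss_tot


def _clamp(x: float) -> float:
    if x < -1e-12:
        warnings.warn(f"nested delta-R^2 below rounding tolerance: {x:g}",
                      RuntimeWarning)
    return max(0.0, x)


def compute_centrality(dataset: PanelDataset, result: CLPNResult
                       ) -> CentralityTable:
    """In-/out-prediction at cross-lagged and cross-construct scope.

    ``result`` must have been estimated on ``dataset``; the selected support
    (nonzero off-diagonal weights) determines which predictors enter the
    unpenalized refits.  A node retained by no target has out-prediction
    exactly 0.
    """
    ids = result.node_ids
    if ids != dataset.node_ids:
        raise ValueError("result and dataset disagree on node order")
    p = len(ids)
    constructs = result.node_constructs
    W1 = dataset.wave1
    W2 = dataset.wave2
    cov_cols = [dataset.covariates[:, k]
                for k in range(dataset.covariates.shape[1])]

    cl_in = np.zeros(p)
    cc_in = np.zeros(p)
    cl_out = np.zeros(p)
    cc_out = np.zeros(p)

    for j in range(p):
        y = W2[:, j]
        support = [i for i in range(p)
                   if i != j and result.weights[i, j] != 0.0]
        same = [i for i in support if constructs[i] == constructs[j]]
        other = [i for i in support if constructs[i] != constructs[j]]

        base_cols = cov_cols + [W1[:, j]]  # autoregressive term always in M0
        r2_base = _r_squared(y, base_cols)
        r2_same = _r_squared(y, base_cols + [W1[:, i] for i in same])
        full_cols = base_cols + [W1[:, i] for i in same + other]
        r2_full = _r_squared(y, full_cols)

        cl_in[j] = _clamp(r2_full - r2_base)
        cc_in[j] = _clamp(r2_full - r2_same)

        # out-prediction contributions: leave-one-predictor-out from full_j
        for i in support:
            rest = [k for k in same + other if k != i]
            r2_wo = _r_squared(y, base_cols + [W1[:, k] for k in rest])
            contrib = _clamp(r2_full - r2_wo)
            cl_out[i] += contrib
            if constructs[i] != constructs[j]:
                cc_out[i] += contrib

    return CentralityTable(list(ids), cl_out, cl_in, cc_out, cc_in)


def centrality_report(table: CentralityTable) -> dict:
    """Ranked listings per index; ties broken by node id.

    Flags ``no_predictive_structure`` when every index is identically zero.
    """
    report: dict = {"rankings": {}, "top": {}}
    all_zero = True
    for name in INDEX_NAMES:
        vals = table.values(name)
        if np.any(vals != 0.0):
            all_zero = False
        order = sorted(range(len(vals)),
                       key=lambda k: (-vals[k], table.node_ids[k]))
        report["rankings"][name] = [
            (table.node_ids[k], float(vals[k])) for k in order]
        report["top"][name] = table.node_ids[order[0]]
    report["no_predictive_structure"] = all_zero
    return report
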