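"""Bootstrap accuracy and case-dropping stability for estimated networks.

Two resampling schemes, both fully driven by one root seed:

* **Nonparametric bootstrap** — subjects resampled with replacement, the
  whole estimation pipeline re-run per resample; yields percentile CIs per
  edge and pairwise difference tests for edges and centralities.
* **Case-dropping bootstrap** — increasing proportions of subjects dropped
  (without replacement), statistics recomputed on each subsample and
  correlated with the full-sample values; summarized by the correlation
  stability (CS) coefficient: the largest tested drop proportion at which at
  least ``cs_confidence`` of subsamples still correlate >= ``cs_correlation``
  with the full-sample statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import INDEX_NAMES, compute_centrality
from .config import AnalysisConfig
from .estimation import CLPNResult, estimate_clpn
from .panel_io import PanelDataset
from .preprocess import transform_dataset

__all__ = [
    "BootstrapResult",
    "StabilityResult",
    "bootstrap_edges",
    "edge_difference_test",
    "centrality_difference_test",
    "case_drop_stability",
]


@dataclass
class BootstrapResult:
    """Edge-weight (and optionally centrality) bootstrap distributions."""

    node_ids: list[str]
    n_boot: int
    seed: int
    estimates: np.ndarray        # full-sample p x p weights
    samples: np.ndarray          # (n_boot, p, p) resampled weights
    centrality_samples: dict[str, np.ndarray] = field(default_factory=dict)
    centrality_estimates: dict[str, np.ndarray] = field(default_factory=dict)
    n_redrawn: int = 0
    alpha: float = 0.05

    def _edge_index(self, edge: tuple[str, str]) -> tuple[int, int]:
        try:
            return self.node_ids.index(edge[0]), self.node_ids.index(edge[1])
        except ValueError:
            raise KeyError(f"edge {edge} not tracked in bootstrap") from None

    def edge_ci(self, edge: tuple[str, str]) -> tuple[float, float]:
        i, j = self._edge_index(edge)
        lo, hi = np.quantile(self.samples[:, i, j],
                             [self.alpha / 2, 1 - self.alpha / 2])
        return float(lo), float(hi)

    def edge_mean(self, edge: tuple[str, str]) -> float:
        i, j = self._edge_index(edge)
        return float(self.samples[:, i, j].mean())

    def summary_frame(self) -> pd.DataFrame:
        recs = []
        p = len(self.node_ids)
        for i in range(p):
            for j in range(p):
                lo, hi = self.edge_ci((self.node_ids[i], self.node_ids[j]))
                recs.append({
                    "source": self.node_ids[i], "target": self.node_ids[j],
                    "estimate": float(self.estimates[i, j]),
                    "boot_mean": float(self.samples[:, i, j].mean()),
                    "ci_low": lo, "ci_high": hi,
                    "is_autoregressive": i == j,
                })
        return pd.DataFrame(recs)


@dataclass
class StabilityResult:
    """Case-drop correlation curves plus CS coefficients.

    ``correlations[statistic]`` maps each tested drop proportion to the
    vector of subsample-vs-full-sample Pearson correlations; ``cs`` maps each
    statistic to its CS coefficient (0.0 when no tested proportion meets the
    criterion).
    """

    drop_proportions: tuple
    correlations: dict[str, dict[float, np.ndarray]]
    cs: dict[str, float]
    cs_correlation: float
    cs_confidence: float
    skipped: list[float] = field(default_factory=list)

    def curve_frame(self) -> pd.DataFrame:
        recs = []
        for stat, curves in self.correlations.items():
            for prop, corrs in curves.items():
                qs = np.quantile(corrs, [0.025, 0.5, 0.975])
                recs.append({
                    "statistic": stat, "drop_proportion": prop,
                    "mean_correlation": float(np.mean(corrs)),
                    "q025": float(qs[0]), "median": float(qs[1]),
                    "q975": float(qs[2]),
                })
        return pd.DataFrame(recs)


def _has_constant_node_column(ds: PanelDataset) -> bool:
    return bool((np.ptp(ds.wave1, axis=0) == 0).any()
                or (np.ptp(ds.wave2, axis=0) == 0).any())


def bootstrap_edges(dataset: PanelDataset, config: AnalysisConfig,
                    collect_centrality: bool = True,
                    full_result: CLPNResult | None = None) -> BootstrapResult:
    """Nonparametric bootstrap of the full estimation per subject resample.

    A degenerate resample (a node column going constant, which breaks the
    rank transform) is redrawn and counted.  When given a raw (ordinal)
    dataset the nonparanormal transform is re-applied inside every resample,
    so the CIs reflect the whole pipeline; an already-transformed dataset is
    resampled as-is.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = dataset.n_subjects
    p = dataset.n_nodes
    raw = not dataset.transformed
    full_ds = transform_dataset(dataset) if raw else dataset
    if full_result is None:
        full_result = estimate_clpn(full_ds, config)
    samples = np.zeros((config.n_boot, p, p))
    cent_samples = {name: np.zeros((config.n_boot, p))
                    for name in INDEX_NAMES} if collect_centrality else {}
    n_redrawn = 0
    for b in range(config.n_boot):
        for _attempt in range(100):
            idx = rng.integers(0, n, size=n)
            sub = dataset.subset(idx)
            if not _has_constant_node_column(sub):
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw a non-degenerate resample")
        if raw:
            sub = transform_dataset(sub)
        res = estimate_clpn(sub, config)
        samples[b] = res.weights
        if collect_centrality:
            tab = compute_centrality(sub, res)
            for name in INDEX_NAMES:
                cent_samples[name][b] = tab.values(name)
    cent_est = {}
    if collect_centrality:
        full_tab = compute_centrality(full_ds, full_result)
        cent_est = {name: full_tab.values(name) for name in INDEX_NAMES}
    if n_redrawn:
        warnings.warn(f"redrew {n_redrawn} degenerate bootstrap resamples",
                      RuntimeWarning)
    return BootstrapResult(
        node_ids=list(dataset.node_ids), n_boot=config.n_boot,
        seed=config.seed, estimates=full_result.weights.copy(),
        samples=samples, centrality_samples=cent_samples,
        centrality_estimates=cent_est, n_redrawn=n_redrawn)


def _ci_excludes_zero(draws: np.ndarray, alpha: float) -> bool:
    lo, hi = np.quantile(draws, [alpha / 2, 1 - alpha / 2])
    return bool(lo > 0.0 or hi < 0.0)


def edge_difference_test(boot: BootstrapResult, edge_a: tuple[str, str],
                         edge_b: tuple[str, str]) -> bool:
    """True when the bootstrap CI of (w_a - w_b) excludes zero."""
    ia, ja = boot._edge_index(edge_a)
    ib, jb = boot._edge_index(edge_b)
    diff = boot.samples[:, ia, ja] - boot.samples[:, ib, jb]
    if edge_a == edge_b:
        return False
    return _ci_excludes_zero(diff, boot.alpha)


def centrality_difference_test(boot: BootstrapResult, node_a: str,
                               node_b: str, index_name: str) -> bool:
    """Percentile-CI-of-difference test for one centrality index."""
    if index_name not in INDEX_NAMES:
        raise KeyError(f"unknown centrality index {index_name!r}")
    if not boot.centrality_samples:
        raise ValueError("bootstrap was run without centrality collection")
    try:
        ka = boot.node_ids.index(node_a)
        kb = boot.node_ids.index(node_b)
    except ValueError as exc:
        raise KeyError(str(exc)) from None
    if node_a == node_b:
        return False
    draws = boot.centrality_samples[index_name]
    return _ci_excludes_zero(draws[:, ka] - draws[:, kb], boot.alpha)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def case_drop_stability(dataset: PanelDataset, config: AnalysisConfig,
                        statistic_set: tuple[str, ...] = ("edge", "in", "out"),
                        n_boot: int | None = None) -> StabilityResult:
    """Case-dropping bootstrap and CS coefficients.

    For each drop proportion ``prop`` draws ``n_boot`` subsamples of
    ``ceil((1 - prop) * n)`` subjects without replacement, re-estimates the
    network (and centralities), and records the Pearson correlation of each
    statistic vector with its full-sample counterpart.  Statistics: ``edge``
    (all p*p weights), ``in`` / ``out`` (cross-lagged in-/out-prediction).
    Proportions leaving fewer subjects than CV folds (or < 10) are skipped
    with a warning.
    """
    if n_boot is None:
        n_boot = config.n_drop_boot
    need_cent = "in" in statistic_set or "out" in statistic_set
    rng = np.random.default_rng(config.seed)
    n = dataset.n_subjects
    raw = not dataset.transformed
    full_ds = transform_dataset(dataset) if raw else dataset
    full = estimate_clpn(full_ds, config)
    full_vecs: dict[str, np.ndarray] = {}
    if "edge" in statistic_set:
        full_vecs["edge"] = full.weights.ravel()
    if need_cent:
        tab = compute_centrality(full_ds, full)
        if "in" in statistic_set:
            full_vecs["in"] = tab.crosslagged_in
        if "out" in statistic_set:
            full_vecs["out"] = tab.crosslagged_out

    correlations: dict[str, dict[float, np.ndarray]] = \
        {s: {} for s in full_vecs}
    skipped: list[float] = []
    for prop in config.drop_proportions:
        m = int(np.ceil((1.0 - prop) * n))
        if m < max(config.cv_folds, 10):
            warnings.warn(f"drop proportion {prop} leaves {m} subjects; "
                          "skipped", RuntimeWarning)
            skipped.append(prop)
            continue
        corrs = {s: np.zeros(n_boot) for s in full_vecs}
        for b in range(n_boot):
            idx = rng.choice(n, size=m, replace=False)
            sub = dataset.subset(idx)
            if _has_constant_node_column(sub):
                for s in full_vecs:
                    corrs[s][b] = np.nan
                continue
            if raw:
                sub = transform_dataset(sub)
            res = estimate_clpn(sub, config)
            if "edge" in full_vecs:
                corrs["edge"][b] = _safe_corr(res.weights.ravel(),
                                              full_vecs["edge"])
            if need_cent:
                stab = compute_centrality(sub, res)
                if "in" in full_vecs:
                    corrs["in"][b] = _safe_corr(stab.crosslagged_in,
                                                full_vecs["in"])
                if "out" in full_vecs:
                    corrs["out"][b] = _safe_corr(stab.crosslagged_out,
                                                 full_vecs["out"])
        for s in full_vecs:
            correlations[s][float(prop)] = corrs[s][~np.isnan(corrs[s])]

    cs: dict[str, float] = {}
    for s, curves in correlations.items():
        best = 0.0
        for prop in sorted(curves):
            vals = curves[prop]
            if vals.size == 0:
                continue
            frac = float(np.mean(vals >= config.cs_correlation))
            if frac >= config.cs_confidence:
                best = max(best, prop)
        cs[s] = best
    return StabilityResult(
        drop_proportions=tuple(float(p) for p in config.drop_proportions
                               if p not in skipped),
        correlations=correlations, cs=cs,
        cs_correlation=config.cs_correlation,
        cs_confidence=config.cs_confidence, skipped=skipped)
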