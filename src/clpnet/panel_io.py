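"""Two-wave panel data model, CSV ingestion, and validation.

A panel dataset holds per-subject item responses for the same nodes at two
measurement waves plus baseline covariates.  Nodes belong to exactly one of
two constructs (e.g. generalized-anxiety symptoms ``GA`` and
intolerance-of-uncertainty elements ``IU``); each node declares its own
ordinal response range, so the same machinery serves instruments stored on
0-based or 1-based codings.

The CSV layout is one row per subject with columns ``subject_id``,
``<node_id>_t1`` and ``<node_id>_t2`` for every node, plus covariate columns
by name.  Missing values are a hard error: the analyses this package
implements assume complete panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NodeInfo",
    "PanelDataset",
    "PanelValidationError",
    "default_nodes",
    "load_panel",
    "write_panel",
]


class PanelValidationError(ValueError):
    """A panel file or in-memory dataset violates the panel contract."""


@dataclass(frozen=True)
class NodeInfo:
    """Metadata for one network node (questionnaire item).

    Parameters
    ----------
    id : str
        Short unique label, e.g. ``"GA1"`` or ``"IU10"``.
    construct : str
        Construct membership tag; a dataset uses exactly two constructs.
    description : str
        Free-text item content.
    response_min, response_max : int
        Inclusive bounds of the stored ordinal response scale.
    """

    id: str
    construct: str
    description: str = ""
    response_min: int = 1
    response_max: int = 5

    def __post_init__(self) -> None:
        if self.response_min >= self.response_max:
            raise PanelValidationError(
                f"node {self.id!r}: response_min ({self.response_min}) must be "
                f"< response_max ({self.response_max})"
            )

    @property
    def n_categories(self) -> int:
        return self.response_max - self.response_min + 1


# The 19-node geometry of the two instruments this package was written
# around: the 7-item generalized anxiety screener (GAD-7) and the 12-item
# short-form intolerance-of-uncertainty scale for children (IUSC-12).
_GA_ITEMS = [
    ("GA1", "Nervousness"),
    ("GA2", "Uncontrollable worry"),
    ("GA3", "Excessive worry"),
    ("GA4", "Trouble relaxing"),
    ("GA5", "Restlessness"),
    ("GA6", "Irritability"),
    ("GA7", "Feeling afraid"),
]
_IU_ITEMS = [
    ("IU1", "Upset by surprise events"),
    ("IU2", "Frustration at missing information"),
    ("IU3", "'Should think ahead' belief"),
    ("IU4", "Catastrophizing belief"),
    ("IU5", "Obsessive thoughts about the future"),
    ("IU6", "Aversive attitude to surprise"),
    ("IU7", "'Should prepare everything' belief"),
    ("IU8", "Uncertainty blocks enjoying life"),
    ("IU9", "Paralysed by not knowing"),
    ("IU10", "Cannot work well when unsure"),
    ("IU11", "Smallest doubt stops actions"),
    ("IU12", "Must escape uncertain situations"),
]


def default_nodes(ga_range: tuple[int, int] = (1, 4),
                  iu_range: tuple[int, int] = (1, 5)) -> list[NodeInfo]:
    """Node metadata for the default GA + IU instrument pair.

    The GA items default to 1-based four-category storage (the coding the
    descriptive tables this package mirrors were produced under); pass
    ``ga_range=(0, 3)`` for the instrument's native scoring.  Sum-score
    helpers convert between the two via the node count, so clinical-cutoff
    logic is unaffected by the stored coding.
    """
    ga = [NodeInfo(i, "GA", d, *ga_range) for i, d in _GA_ITEMS]
    iu = [NodeInfo(i, "IU", d, *iu_range) for i, d in _IU_ITEMS]
    return ga + iu


@dataclass
class PanelDataset:
    """Complete two-wave panel: responses at T1/T2 plus covariates.

    Invariants (enforced by :meth:`validate`): matching row counts, unique
    subject ids, no missing values, every response within its node's declared
    range.  ``wave1``/``wave2`` share the column order of ``nodes``.
    """

    subject_ids: list
    wave1: np.ndarray
    wave2: np.ndarray
    nodes: list[NodeInfo]
    covariates: np.ndarray = field(default=None)  # type: ignore[assignment]
    covariate_names: list[str] = field(default_factory=list)
    transformed: bool = False

    def __post_init__(self) -> None:
        self.wave1 = np.asarray(self.wave1, dtype=float)
        self.wave2 = np.asarray(self.wave2, dtype=float)
        if self.covariates is None:
            self.covariates = np.empty((len(self.subject_ids), 0))
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim == 1:
            self.covariates = self.covariates[:, None]

    # -- basic geometry -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def node_ids(self) -> list[str]:
        return [nd.id for nd in self.nodes]

    def construct_of(self, node_id: str) -> str:
        return self.nodes[self.node_ids.index(node_id)].construct

    def nodes_of_construct(self, construct: str) -> list[str]:
        return [nd.id for nd in self.nodes if nd.construct == construct]

    @property
    def constructs(self) -> list[str]:
        seen: list[str] = []
        for nd in self.nodes:
            if nd.construct not in seen:
                seen.append(nd.construct)
        return seen

    # -- validation -----------------------------------------------------
    def validate(self) -> "PanelDataset":
        n = self.n_subjects
        p = self.n_nodes
        if len(set(map(str, self.subject_ids))) != n:
            dupes = pd.Series(list(map(str, self.subject_ids)))
            dup = dupes[dupes.duplicated()].iloc[0]
            raise PanelValidationError(f"duplicated subject id {dup!r}")
        for name, mat in (("wave1", self.wave1), ("wave2", self.wave2)):
            if mat.shape != (n, p):
                raise PanelValidationError(
                    f"{name} has shape {mat.shape}, expected {(n, p)}")
        if self.covariates.shape[0] != n:
            raise PanelValidationError(
                f"covariates have {self.covariates.shape[0]} rows, expected {n}")
        if self.covariates.shape[1] != len(self.covariate_names):
            raise PanelValidationError(
                "covariate_names length does not match covariate columns")
        ids = [nd.id for nd in self.nodes]
        if len(set(ids)) != p:
            raise PanelValidationError("node ids are not unique")
        if len(self.constructs) > 2:
            raise PanelValidationError(
                f"more than two constructs present: {self.constructs}")
        for name, mat in (("wave1", self.wave1), ("wave2", self.wave2),
                          ("covariates", self.covariates)):
            if mat.size and not np.all(np.isfinite(mat)):
                i, j = np.argwhere(~np.isfinite(mat))[0]
                raise PanelValidationError(
                    f"missing/non-finite value in {name} at subject "
                    f"{self.subject_ids[i]!r}, column {j}")
        if not self.transformed:
            for j, nd in enumerate(self.nodes):
                for name, mat in (("t1", self.wave1), ("t2", self.wave2)):
                    col = mat[:, j]
                    bad = (col < nd.response_min) | (col > nd.response_max)
                    if bad.any():
                        i = int(np.argmax(bad))
                        raise PanelValidationError(
                            f"out-of-range value {col[i]:g} for node {nd.id} "
                            f"({name}) at subject {self.subject_ids[i]!r}: "
                            f"allowed [{nd.response_min}, {nd.response_max}]")
        return self

    # -- derived quantities ----------------------------------------------
    def sum_score(self, construct: str, wave: int = 1,
                  zero_based: bool = False) -> np.ndarray:
        """Per-subject construct sum score at the given wave.

        With ``zero_based=True`` the score is re-expressed on a 0-started
        item scale by subtracting ``response_min`` per item, which is how
        published clinical cutoffs (e.g. GAD-7 >= 10) are defined.
        """
        idx = [j for j, nd in enumerate(self.nodes) if nd.construct == construct]
        if not idx:
            raise KeyError(f"no nodes in construct {construct!r}")
        mat = self.wave1 if wave == 1 else self.wave2
        total = mat[:, idx].sum(axis=1)
        if zero_based:
            total = total - sum(self.nodes[j].response_min for j in idx)
        return total

    def subset(self, row_mask: np.ndarray) -> "PanelDataset":
        """Row-subset copy (used by subgrouping and resampling)."""
        idx = np.asarray(row_mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            subject_ids=[self.subject_ids[i] for i in idx],
            wave1=self.wave1[idx],
            wave2=self.wave2[idx],
            covariates=self.covariates[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame in the documented CSV layout."""
        data: dict[str, object] = {"subject_id": self.subject_ids}
        for w, mat in ((1, self.wave1), (2, self.wave2)):
            for j, nd in enumerate(self.nodes):
                data[f"{nd.id}_t{w}"] = mat[:, j]
        for k, name in enumerate(self.covariate_names):
            data[name] = self.covariates[:, k]
        return pd.DataFrame(data)


def load_panel(path, node_spec: Sequence[NodeInfo],
               covariate_names: Sequence[str] = ()) -> PanelDataset:
    """Read and validate a wide-format two-wave panel CSV.

    Raises :class:`PanelValidationError` naming the missing column,
    out-of-range cell, or duplicated subject id on the first violation.
    """
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise PanelValidationError("missing column 'subject_id'")
    required = [f"{nd.id}_t{w}" for w in (1, 2) for nd in node_spec]
    required += list(covariate_names)
    for col in required:
        if col not in df.columns:
            raise PanelValidationError(f"missing column {col!r}")
    wave1 = df[[f"{nd.id}_t1" for nd in node_spec]].to_numpy(dtype=float)
    wave2 = df[[f"{nd.id}_t2" for nd in node_spec]].to_numpy(dtype=float)
    cov = df[list(covariate_names)].to_numpy(dtype=float) if covariate_names \
        else np.empty((len(df), 0))
    ds = PanelDataset(
        subject_ids=df["subject_id"].tolist(),
        wave1=wave1,
        wave2=wave2,
        nodes=list(node_spec),
        covariates=cov,
        covariate_names=list(covariate_names),
    )
    return ds.validate()


def write_panel(dataset: PanelDataset, path) -> None:
    """Write a dataset in the CSV layout :func:`load_panel` reads."""
    dataset.to_frame().to_csv(path, index=False)
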