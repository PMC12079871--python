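"""Shared fixtures: toy panels, small synthetic specs, fast configs."""

import numpy as np
import pytest

from clpnet.config import AnalysisConfig
from clpnet.panel_io import NodeInfo, PanelDataset
from clpnet.simulate import SyntheticSpec


def small_nodes(n_ga: int = 2, n_iu: int = 2,
                ga_range=(1, 4), iu_range=(1, 5)) -> list[NodeInfo]:
    ga = [NodeInfo(f"GA{i+1}", "GA", response_min=ga_range[0],
                   response_max=ga_range[1]) for i in range(n_ga)]
    iu = [NodeInfo(f"IU{i+1}", "IU", response_min=iu_range[0],
                   response_max=iu_range[1]) for i in range(n_iu)]
    return ga + iu


@pytest.fixture
def toy_nodes():
    return small_nodes(2, 2)


@pytest.fixture
def toy_csv(tmp_path, toy_nodes):
    """3-subject wide-format panel CSV with 2 GA + 2 IU nodes + 1 covariate."""
    lines = ["subject_id,GA1_t1,GA2_t1,IU1_t1,IU2_t1,"
             "GA1_t2,GA2_t2,IU1_t2,IU2_t2,age",
             "s1,1,2,3,4,2,1,4,3,15",
             "s2,3,4,5,1,1,2,3,4,16",
             "s3,2,2,2,2,3,3,3,3,14"]
    path = tmp_path / "panel.csv"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def fast_config():
    """Desk-scale config: fewer folds / smaller grid / tiny bootstraps."""
    return AnalysisConfig(cv_folds=5, lambda_grid_size=30, n_boot=20,
                          n_drop_boot=10, drop_proportions=(0.1, 0.3),
                          seed=0)


def strong_spec(n_subjects: int, p_per_construct: int = 3,
                weights=(0.2, 0.5), seed: int = 0) -> SyntheticSpec:
    """Small two-construct spec with a few strong cross-lagged paths."""
    nodes = small_nodes(p_per_construct, p_per_construct)
    p = len(nodes)
    rng = np.random.default_rng(seed)
    B = np.eye(p) * 0.3
    # one strong path per node, alternating across constructs
    for i in range(p):
        j = (i + p_per_construct) % p
        B[i, j] = rng.uniform(*weights)
    return SyntheticSpec(n_subjects=n_subjects, nodes=nodes, true_b=B,
                         seed=seed)


@pytest.fixture
def toy_dataset(toy_nodes):
    rng = np.random.default_rng(42)
    n = 60
    w1 = np.column_stack([rng.integers(nd.response_min, nd.response_max + 1,
                                       size=n) for nd in toy_nodes])
    w2 = np.column_stack([rng.integers(nd.response_min, nd.response_max + 1,
                                       size=n) for nd in toy_nodes])
    return PanelDataset(subject_ids=list(range(n)), wave1=w1, wave2=w2,
                        nodes=toy_nodes,
                        covariates=rng.standard_normal((n, 1)),
                        covariate_names=["nle"]).validate()
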