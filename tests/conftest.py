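import json

import numpy as np
import pandas as pd
import pytest

from oorkit.io import LabelHierarchy, ProbabilityMatrix


@pytest.fixture
def two_lineage_hierarchy() -> LabelHierarchy:
    return LabelHierarchy.from_mapping(
        {
            "CD4-T": {"tissue": "immune", "cell_class": "T"},
            "CD8-T": {"tissue": "immune", "cell_class": "T"},
            "basal": {"tissue": "breast", "cell_class": "epithelial"},
            "luminal": {"tissue": "breast", "cell_class": "epithelial"},
        }
    )


@pytest.fixture
def small_matrix() -> ProbabilityMatrix:
    return ProbabilityMatrix(
        cell_ids=["a", "b"],
        label_ids=["x", "y", "z"],
        values=np.array([[0.9, 0.05, 0.05], [0.2, 0.3, 0.5]]),
    )


@pytest.fixture
def prob_csv(tmp_path):
    path = tmp_path / "probs.csv"
    path.write_text(
        "cell_id,x,y,z\n"
        "a,0.9,0.05,0.05\n"
        "b,0.2,0.3,0.5\n"
    )
    return path


@pytest.fixture
def meta_csv(tmp_path):
    path = tmp_path / "meta.csv"
    path.write_text(
        "cell_id,condition,cluster\n"
        "b,control,c0\n"
        "a,case,c0\n"
    )
    return path


@pytest.fixture
def hierarchy_json(tmp_path):
    path = tmp_path / "hierarchy.json"
    path.write_text(
        json.dumps(
            {
                "x": {"tissue": "immune", "cell_class": "T"},
                "y": {"tissue": "immune", "cell_class": "T"},
                "z": {"tissue": "breast", "cell_class": "epithelial"},
            }
        )
    )
    return path


def random_dirichlet_rows(n: int, k: int, seed: int = 0, alpha: float = 0.7) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.full(k, alpha), size=n)
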