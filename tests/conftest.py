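import numpy as np
import pandas as pd
import pytest

from dmakit.io import ExpressionDataset, GroupAssignment


def make_dataset(values, probe_ids=None, sample_ids=None, detection=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    probe_ids = probe_ids or [f"P{i+1}" for i in range(n)]
    sample_ids = sample_ids or [f"S{j+1}" for j in range(m)]
    det = None
    if detection is not None:
        det = pd.DataFrame(np.asarray(detection, dtype=float),
                           index=probe_ids, columns=sample_ids)
    return ExpressionDataset(
        pd.DataFrame(values, index=probe_ids, columns=sample_ids), det)


@pytest.fixture
def two_group_6() -> tuple[ExpressionDataset, GroupAssignment]:
    """3 probes x 6 samples, ctrl/trt split, hand-checkable values."""
    data = make_dataset(
        [[10, 12, 14, 20, 24, 28],
         [100, 110, 90, 95, 105, 100],
         [50, 55, 45, 200, 210, 190]],
        sample_ids=["c1", "c2", "c3", "t1", "t2", "t3"])
    groups = GroupAssignment(
        {"c1": "ctrl", "c2": "ctrl", "c3": "ctrl",
         "t1": "trt", "t2": "trt", "t3": "trt"},
        ["ctrl", "trt"])
    return data, groups


TOY_OBO = """format-version: 1.2

[Term]
id: T:0001
name: root
namespace: toy

[Term]
id: T:0002
name: child A
namespace: toy
is_a: T:0001

[Term]
id: T:0003
name: child B
namespace: toy
is_a: T:0001

[Term]
id: T:0004
name: grandchild
namespace: toy
is_a: T:0002

[Term]
id: T:0005
name: gone
namespace: toy
is_a: T:0001
is_obsolete: true
"""


@pytest.fixture
def toy_obo(tmp_path):
    p = tmp_path / "toy.obo"
    p.write_text(TOY_OBO)
    return p
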