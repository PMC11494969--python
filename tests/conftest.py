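import numpy as np
import pandas as pd
import pytest

from dynomics.network import Edge, EntityRef, NodeRef, TwoSliceNetwork
from dynomics.preprocess import OmicsDataset


def entity(name: str, omic_type: str) -> EntityRef:
    return EntityRef(name, omic_type)


def make_edge(src: EntityRef, dst: EntityRef, lag: int = 1, weight: float = 0.5, score: float = 1.0) -> Edge:
    """Edge between slice-appropriate nodes: lag 1 -> 0->1, lag 0 -> 1->1."""
    src_slice = 1 - lag
    return Edge(NodeRef(src, src_slice), NodeRef(dst, 1), weight, score)


def build_network(label: str, edges) -> TwoSliceNetwork:
    """edges: iterable of (srcEntity, dstEntity, lag, score) or Edge."""
    net = TwoSliceNetwork(label)
    for item in edges:
        net.add_edge(item if isinstance(item, Edge) else make_edge(item[0], item[1], item[2], score=item[3]))
    return net


def long_frame(records) -> pd.DataFrame:
    """records: (subject, time, entity, omic_type, value[, has_compound_id])."""
    rows = []
    for rec in records:
        subject, time, ent, omic, value = rec[:5]
        has_id = rec[5] if len(rec) > 5 else True
        rows.append(
            dict(subject=subject, time=time, entity=ent, omic_type=omic, value=value, has_compound_id=has_id)
        )
    return pd.DataFrame(rows)


def make_dataset(records) -> OmicsDataset:
    return OmicsDataset(long_frame(records))


@pytest.fixture
def taxa():
    return [entity(f"T{i}", "taxon") for i in range(4)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
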