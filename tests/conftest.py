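import numpy as np
import pytest

from funcmap.model import Classification, ClassNode, ProteinRecord
from funcmap.simulate import random_protein


def build_classification(name, paths, leaf_seqs, records):
    """Construct a Classification from path tuples and plain dicts.

    ``paths``: iterable of node-id tuples from root to leaf.
    ``leaf_seqs``: leaf id -> set of seq ids.
    ``records``: seq id -> residues (or ProteinRecord).
    """
    nodes: dict[str, ClassNode] = {}
    for path in paths:
        parent = None
        for nid in path:
            if nid not in nodes:
                nodes[nid] = ClassNode(nid, nid, parent)
                if parent is not None:
                    nodes[parent].children.append(nid)
            parent = nid
    recs = {
        sid: r if isinstance(r, ProteinRecord) else ProteinRecord(sid, r, source_db=name)
        for sid, r in records.items()
    }
    return Classification(name, nodes, {k: set(v) for k, v in leaf_seqs.items()}, recs)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_tree():
    """root with two internal nodes A, B; three sequence-bearing leaves."""
    seqs = {
        "s1": random_protein(80, np.random.default_rng(1)),
        "s2": random_protein(90, np.random.default_rng(2)),
        "s3": random_protein(100, np.random.default_rng(3)),
    }
    return build_classification(
        "toy",
        [("root", "A", "x"), ("root", "A", "y"), ("root", "B", "z")],
        {"x": {"s1"}, "y": {"s2"}, "z": {"s3"}},
        seqs,
    )
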