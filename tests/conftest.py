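"""Shared fixtures: small synthetic corpora and simple reference trees.

All fixtures are generated programmatically with fixed seeds; nothing is
loaded from disk.
"""

import numpy as np
import pytest

import hemopoint as hp
from hemopoint.geometry import VesselSegment, VesselTree


@pytest.fixture(scope="session")
def base_tree():
    return hp.make_base_tree(0, 1)


def single_segment_tree(radius=0.0015, length=0.03, stenosis=None, inlet_velocity_for_flow=None):
    """A one-tube 'LAD-like' tree from inlet to outlet along +x."""
    stens = (stenosis,) if stenosis else ()
    seg = VesselSegment(
        id="tube", start_node="in", end_node="out", length=length,
        radius=radius, role="lad_proximal", stenoses=stens,
    )
    return VesselTree(
        nodes={"in": np.zeros(3), "out": np.array([length, 0.0, 0.0])},
        segments=[seg],
        inlet_node="in",
        outlet_nodes=["out"],
    )


@pytest.fixture
def tube_tree():
    return single_segment_tree()


@pytest.fixture(scope="session")
def tiny_velocity_corpus():
    cfg = hp.CorpusConfig(
        n_base_train=3, n_base_test=2, expansions_per_base=2,
        field_kind="velocity", op_state="preoperative",
        n_query=512, surface_density=0.02,
    )
    return hp.build_corpus(cfg, master_seed=7)


@pytest.fixture(scope="session")
def tiny_pressure_corpus():
    cfg = hp.CorpusConfig(
        n_base_train=3, n_base_test=2, expansions_per_base=2,
        field_kind="pressure", op_state="preoperative",
        n_query=512, surface_density=0.02,
    )
    return hp.build_corpus(cfg, master_seed=7)


@pytest.fixture(scope="session")
def tiny_trained(tiny_velocity_corpus):
    """A briefly trained surrogate for contract tests (not accuracy)."""
    model = hp.HemodynamicPointNet(
        tiny_velocity_corpus, hp.NetworkConfig(epochs=3, seed=11)
    )
    return model.fit()
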