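"""Vessel-tree construction, expansion, grafting and point sampling."""

import networkx as nx
import numpy as np
import pytest

import hemopoint as hp
from hemopoint.exceptions import ConfigurationError, GeometryError, PreconditionError
from hemopoint.geometry import (
    GeometryRanges,
    Stenosis,
    interior_points,
    surface_points,
    tree_from_yaml,
    tree_to_yaml,
)
from conftest import single_segment_tree


@pytest.mark.parametrize("template_id", [0, 1, 2])
def test_templates_are_valid_preoperative_trees(template_id):
    t = hp.make_base_tree(template_id, seed := 1)
    assert len(t.segments) >= 5
    assert t.op_state == "preoperative"
    assert not t.segments_by_role("graft")
    # LAD is split into exactly proximal + distal
    assert len(t.segments_by_role("lad_proximal")) == 1
    assert len(t.segments_by_role("lad_distal")) == 1
    g = nx.MultiGraph()
    g.add_edges_from((s.start_node, s.end_node) for s in t.segments)
    assert nx.is_connected(g)


def test_base_tree_deterministic():
    a = hp.make_base_tree(0, 42)
    b = hp.make_base_tree(0, 42)
    for k in a.nodes:
        assert np.array_equal(a.nodes[k], b.nodes[k])
    assert [s.stenoses for s in a.segments] == [s.stenoses for s in b.segments]


def test_unknown_template_rejected():
    with pytest.raises(ConfigurationError):
        hp.make_base_tree(99, 1)


def test_stenosis_validation():
    with pytest.raises(GeometryError):
        Stenosis(rate=1.0, center=0.5, extent=0.01)
    with pytest.raises(GeometryError):
        Stenosis(rate=0.5, center=0.0, extent=0.01)


class TestExpansion:
    def test_count_and_determinism(self, base_tree):
        v1 = hp.expand_model(base_tree, GeometryRanges(), 9, seed=3)
        v2 = hp.expand_model(base_tree, GeometryRanges(), 9, seed=3)
        assert len(v1) == 9
        for a, b in zip(v1, v2):
            assert a.params == b.params
            for k in a.nodes:
                assert np.array_equal(a.nodes[k], b.nodes[k])

    def test_sampled_rates_stay_in_range(self, base_tree):
        variants = hp.expand_model(base_tree, GeometryRanges(), 400, seed=5)
        rates = [
            st.rate for t in variants for s in t.segments for st in s.stenoses
        ]
        assert len(rates) >= 400
        assert min(rates) >= 0.60
        assert max(rates) <= 0.90

    def test_collapsed_ranges_give_identical_variants(self, base_tree):
        r = GeometryRanges(
            stenosis_rate=(0.7, 0.7), n_stenoses=(1, 1),
            bifurcation_angle_deg=(50.0, 50.0), n_side_branches=(2, 2),
            ascending_aorta_diameter_mm=(25.0, 25.0),
            descending_aorta_diameter_mm=(17.0, 17.0),
            arch_angle_deg=(100.0, 100.0), stenosis_center_frac=(0.5, 0.5),
        )
        variants = hp.expand_model(base_tree, r, 5, seed=9)
        ref = variants[0]
        for v in variants[1:]:
            assert v.params == ref.params
            for k in ref.nodes:
                assert np.array_equal(v.nodes[k], ref.nodes[k])

    def test_degenerate_range_rejected(self):
        with pytest.raises(ConfigurationError):
            GeometryRanges(stenosis_rate=(0.9, 0.6))


class TestGraft:
    def test_graft_topology(self, base_tree):
        post = hp.add_graft(base_tree, seed=5)
        grafts = post.segments_by_role("graft")
        assert post.op_state == "postoperative"
        assert len(grafts) == 1
        assert grafts[0].radius == pytest.approx(0.001)
        g = nx.MultiGraph()
        g.add_edges_from(
            (s.start_node, s.end_node) for s in post.segments
        )
        assert g.number_of_edges() - g.number_of_nodes() + 1 == 1
        # removing the graft restores a tree
        g2 = nx.MultiGraph()
        g2.add_edges_from(
            (s.start_node, s.end_node) for s in post.segments if s.role != "graft"
        )
        assert nx.is_connected(g2)
        assert g2.number_of_edges() == g2.number_of_nodes() - 1

    def test_graft_lands_distal_to_worst_stenosis(self, base_tree):
        post = hp.add_graft(base_tree, seed=5)
        graft = post.segments_by_role("graft")[0]
        dist = post.segments_by_role("lad_distal")[0]
        assert graft.end_node == dist.start_node

    def test_double_graft_rejected(self, base_tree):
        post = hp.add_graft(base_tree, seed=5)
        with pytest.raises(PreconditionError):
            hp.add_graft(post, seed=6)

    def test_graft_requires_stenosed_lad(self, base_tree):
        r = GeometryRanges(n_stenoses=(0, 0))
        (no_sten,) = hp.expand_model(base_tree, r, 1, seed=1)
        with pytest.raises(PreconditionError):
            hp.add_graft(no_sten, seed=1)


class TestSurfaceSampling:
    def test_points_lie_on_radius_profile(self):
        tree = single_segment_tree(
            stenosis=Stenosis(rate=0.8, center=0.5, extent=0.008)
        )
        seg = tree.segments[0]
        cloud = surface_points(tree, points_per_mm2=2.0, seed=1)
        p = cloud.coordinates
        x = p[:, 0]  # tube runs along +x from the origin
        perp = np.linalg.norm(p[:, 1:], axis=1)
        assert np.max(np.abs(perp - seg.radius_at(x))) < 1e-9

    def test_density_doubling_doubles_count(self, base_tree):
        n1 = len(surface_points(base_tree, 0.02, seed=2))
        n2 = len(surface_points(base_tree, 0.04, seed=2))
        assert 1.8 <= n2 / n1 <= 2.2

    def test_deterministic(self, base_tree):
        a = surface_points(base_tree, 0.02, seed=3).coordinates
        b = surface_points(base_tree, 0.02, seed=3).coordinates
        assert np.array_equal(a, b)

    def test_positive_density_required(self, base_tree):
        with pytest.raises(ConfigurationError):
            surface_points(base_tree, 0.0, seed=1)


class TestInteriorSampling:
    def test_count_and_strict_interior(self, base_tree):
        pts = interior_points(base_tree, 4096, seed=4)
        assert len(pts) == 4096
        assert np.all(pts.radial_frac < 1.0)

    def test_radial_distribution_uniform_over_disk(self, base_tree):
        from scipy.stats import kstest

        pts = interior_points(base_tree, 10_000, seed=6)
        # uniform-over-disk: rho^2 ~ U(0,1)
        stat = kstest(pts.radial_frac**2, "uniform")
        assert stat.pvalue > 0.01

    def test_tuple_iteration_matches_arrays(self, base_tree):
        pts = interior_points(base_tree, 16, seed=1)
        coord, seg_id, af, rf = next(iter(pts))
        assert coord.shape == (3,)
        assert seg_id in {s.id for s in base_tree.segments}
        assert 0.0 <= af <= 1.0 and 0.0 <= rf < 1.0


def test_yaml_round_trip(tmp_path, base_tree):
    post = hp.add_graft(base_tree, seed=2)
    f = tmp_path / "tree.yaml"
    tree_to_yaml(post, f)
    back = tree_from_yaml(f)
    assert back.op_state == "postoperative"
    assert {s.id for s in back.segments} == {s.id for s in post.segments}
    for a, b in zip(post.segments, back.segments):
        assert a.stenoses == b.stenoses
        assert a.length == pytest.approx(b.length, rel=0, abs=0)
    for k in post.nodes:
        assert np.array_equal(post.nodes[k], back.nodes[k])


def test_stl_export(tmp_path, base_tree):
    import trimesh

    f = tmp_path / "tree.stl"
    hp.geometry.export_stl(base_tree, f, circumferential=12, axial_step_mm=4.0)
    mesh = trimesh.load(f)
    assert len(mesh.vertices) > 100
    assert len(mesh.faces) > 100
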