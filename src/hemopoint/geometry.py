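"""Idealized stenosed coronary–aortic vessel trees and their point clouds.

The package works on parametric tube networks: an aorta-like trunk (ascending
limb, arch carrying 0–3 superior branches, descending limb) plus the three
main coronary branches (LAD split into a proximal and a distal segment by the
stenosis site, LCX, RA) and, postoperatively, a single 2 mm bypass graft
routed around the highest-grade LAD stenosis.  Every cross-section is
circular; stenoses are smooth cosine-shaped constrictions of the radius
profile.  Three built-in templates provide distinct base topologies, and
:func:`expand_model` draws geometric parameters uniformly from clinically
motivated ranges (stenosis rate 60–90 %, 1–2 stenoses, bifurcation angle
30–90°, 0–3 side branches, ascending aorta 20–30 mm, descending 15–20 mm,
arch angulation 80–140°) to multiply each base model into variants.

Units are SI throughout (meters); millimetres appear only in configuration
fields explicitly suffixed ``_mm``.  Coordinates are right-handed Cartesian
with the origin at the inlet centroid and +z pointing cranially.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import yaml

from ._seeds import child_rng
from .exceptions import (
    ConfigurationError,
    GeometryError,
    PreconditionError,
    StructuralError,
)

__all__ = [
    "Stenosis",
    "VesselSegment",
    "VesselTree",
    "GeometryRanges",
    "ROLE_TO_REGION",
    "REGIONS",
    "make_base_tree",
    "expand_model",
    "add_graft",
    "surface_points",
    "interior_points",
    "SurfacePointCloud",
    "InteriorPoints",
    "export_stl",
    "tree_to_yaml",
    "tree_from_yaml",
]

ROLES = ("aorta", "lad_proximal", "lad_distal", "lcx", "ra", "side_branch", "graft")

#: Anatomical region label used in error reports, per segment role.
ROLE_TO_REGION = {
    "aorta": "aorta_and_branches",
    "side_branch": "aorta_and_branches",
    "lad_proximal": "lad_proximal",
    "lad_distal": "lad_distal",
    "lcx": "lcx",
    "ra": "ra",
    "graft": "graft",
}

REGIONS = ("lad_proximal", "lad_distal", "lcx", "ra", "graft", "aorta_and_branches")


@dataclass(frozen=True)
class Stenosis:
    """Smooth axisymmetric constriction of a segment's radius profile.

    rate
        Diameter-reduction fraction in [0, 1): throat radius = R(1 − rate).
    center
        Position of the throat as a fraction of segment length, in (0, 1).
    extent
        Axial length of the constriction window in meters.
    """

    rate: float
    center: float
    extent: float

    def __post_init__(self):
        if not 0.0 <= self.rate < 1.0:
            raise GeometryError(f"stenosis rate {self.rate} outside [0, 1)")
        if not 0.0 < self.center < 1.0:
            raise GeometryError(f"stenosis center {self.center} outside (0, 1)")
        if self.extent <= 0:
            raise GeometryError("stenosis extent must be positive")


@dataclass(frozen=True)
class VesselSegment:
    """One tube of the network with an optional bowed (arc) centerline.

    The centerline is the straight chord from ``start_node`` to ``end_node``
    unless ``bow`` is set, in which case the chord is displaced by
    ``sin(pi*u) * bow`` (used for the bypass graft so its lumen does not
    coincide with the native LAD).  ``length`` is the arc length of the
    centerline and is what hydraulic resistance integrates over.
    """

    id: str
    start_node: str
    end_node: str
    length: float
    radius: float
    role: str
    stenoses: tuple[Stenosis, ...] = ()
    bow: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.radius <= 0:
            raise GeometryError(f"segment {self.id}: radius must be positive")
        if self.length <= 0:
            raise GeometryError(f"segment {self.id}: length must be positive")
        if self.role not in ROLES:
            raise GeometryError(f"segment {self.id}: unknown role {self.role!r}")
        for st in self.stenoses:
            if st.extent >= self.length:
                raise GeometryError(
                    f"segment {self.id}: stenosis extent {st.extent} >= length"
                )
            if self.radius * (1.0 - st.rate) <= 0:
                raise GeometryError(f"segment {self.id}: non-positive throat radius")
        if self.bow is not None and self.stenoses:
            raise GeometryError("stenoses on bowed segments are not supported")

    # -- radius profile -----------------------------------------------------

    def radius_at(self, x):
        """Lumen radius at axial position(s) ``x`` (meters along centerline).

        Cosine-bump profile per stenosis; overlapping bumps take the tightest
        constriction.  Outside every window the radius is the nominal one.
        """
        x = np.asarray(x, dtype=float)
        r = np.full(x.shape, self.radius)
        for st in self.stenoses:
            xc = st.center * self.length
            dx = x - xc
            inside = np.abs(dx) <= st.extent / 2.0
            bump = (self.radius * st.rate / 2.0) * (
                1.0 + np.cos(2.0 * np.pi * dx / st.extent)
            )
            r = np.where(inside, np.minimum(r, self.radius - bump), r)
        return r

    def stenosis_windows(self) -> list[tuple[float, float]]:
        """Merged, clipped axial intervals in which the radius departs from
        nominal; empty for unstenosed segments."""
        ivals = []
        for st in self.stenoses:
            xc = st.center * self.length
            a = max(0.0, xc - st.extent / 2.0)
            b = min(self.length, xc + st.extent / 2.0)
            if b > a:
                ivals.append((a, b))
        ivals.sort()
        merged: list[tuple[float, float]] = []
        for a, b in ivals:
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        return merged


@dataclass
class VesselTree:
    """A connected tube network with one inlet and ≥1 zero-pressure outlets.

    Preoperative trees are acyclic; postoperative trees contain exactly one
    graft segment which closes exactly one cycle.
    """

    nodes: dict[str, np.ndarray]
    segments: list[VesselSegment]
    inlet_node: str
    outlet_nodes: list[str]
    op_state: str = "preoperative"
    template_id: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = {k: np.asarray(v, dtype=float) for k, v in self.nodes.items()}
        self.validate()

    # -- lookups ------------------------------------------------------------

    def segment(self, seg_id: str) -> VesselSegment:
        for s in self.segments:
            if s.id == seg_id:
                return s
        raise KeyError(seg_id)

    def segments_by_role(self, role: str) -> list[VesselSegment]:
        return [s for s in self.segments if s.role == role]

    def chord(self, seg: VesselSegment) -> float:
        return float(
            np.linalg.norm(self.nodes[seg.end_node] - self.nodes[seg.start_node])
        )

    # -- centerline geometry ------------------------------------------------

    def point_at(self, seg: VesselSegment, u):
        """Centerline point(s) at chord fraction(s) ``u`` in [0, 1]."""
        u = np.asarray(u, dtype=float)
        a = self.nodes[seg.start_node]
        b = self.nodes[seg.end_node]
        p = a[None, :] + np.multiply.outer(u.ravel(), b - a)
        if seg.bow is not None:
            p = p + np.multiply.outer(np.sin(np.pi * u.ravel()), np.asarray(seg.bow))
        return p.reshape(u.shape + (3,))

    def tangent_at(self, seg: VesselSegment, u):
        """Unit tangent(s) at chord fraction(s) ``u``."""
        u = np.asarray(u, dtype=float)
        a = self.nodes[seg.start_node]
        b = self.nodes[seg.end_node]
        t = np.broadcast_to(b - a, u.shape + (3,)).copy()
        if seg.bow is not None:
            t = t + np.multiply.outer(
                np.pi * np.cos(np.pi * u), np.asarray(seg.bow)
            )
        return t / np.linalg.norm(t, axis=-1, keepdims=True)

    def frame_at(self, seg: VesselSegment, u):
        """(tangent, normal1, normal2) orthonormal frame(s) at ``u``."""
        t = self.tangent_at(seg, u)
        helper = np.array([0.0, 0.0, 1.0])
        n1 = np.cross(t, helper)
        bad = np.linalg.norm(n1, axis=-1) < 1e-8
        if np.any(bad):
            n1 = np.where(bad[..., None], np.cross(t, [0.0, 1.0, 0.0]), n1)
        n1 = n1 / np.linalg.norm(n1, axis=-1, keepdims=True)
        n2 = np.cross(t, n1)
        return t, n1, n2

    def axial_position(self, seg: VesselSegment, u):
        """Arc length from segment start at chord fraction(s) ``u``.

        Straight segments: ``u * length``.  Bowed segments use a dense
        arc-length table (the graft carries no stenoses, so only the total
        matters hydraulically; the table keeps sampling consistent).
        """
        u = np.asarray(u, dtype=float)
        if seg.bow is None:
            return u * seg.length
        ug, sg = self._arc_table(seg)
        return np.interp(u, ug, sg)

    def _arc_table(self, seg: VesselSegment, n: int = 2049):
        ug = np.linspace(0.0, 1.0, n)
        p = self.point_at(seg, ug)
        ds = np.linalg.norm(np.diff(p, axis=0), axis=1)
        sg = np.concatenate([[0.0], np.cumsum(ds)])
        return ug, sg

    def arc_length(self, seg: VesselSegment) -> float:
        if seg.bow is None:
            return seg.length
        return float(self._arc_table(seg)[1][-1])

    # -- structural invariants ----------------------------------------------

    def _multigraph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes)
        for s in self.segments:
            g.add_edge(s.start_node, s.end_node, key=s.id)
        return g

    def validate(self) -> None:
        if self.op_state not in ("preoperative", "postoperative"):
            raise StructuralError(f"unknown op_state {self.op_state!r}")
        if self.inlet_node in self.outlet_nodes:
            raise StructuralError("inlet node coincides with an outlet")
        for s in self.segments:
            for n in (s.start_node, s.end_node):
                if n not in self.nodes:
                    raise StructuralError(f"segment {s.id} references unknown node {n}")
        g = self._multigraph()
        if g.number_of_nodes() and not nx.is_connected(g):
            raise StructuralError("vessel graph is disconnected")
        n_cycles = g.number_of_edges() - g.number_of_nodes() + 1
        grafts = self.segments_by_role("graft")
        if self.op_state == "preoperative":
            if grafts:
                raise StructuralError("preoperative tree contains a graft")
            if n_cycles != 0:
                raise StructuralError("preoperative tree must be acyclic")
        else:
            if len(grafts) != 1:
                raise StructuralError("postoperative tree needs exactly one graft")
            if n_cycles != 1:
                raise StructuralError("postoperative tree must contain exactly one cycle")


@dataclass(frozen=True)
class GeometryRanges:
    """Uniform sampling ranges for the model-expansion procedure.

    Intervals are closed ``(low, high)`` tuples; integer intervals are
    inclusive on both ends.  Defaults follow the morphology ranges the corpus
    is designed to emulate; the stenosis center interval and extent are the
    package's own parameterization of "random positions on the LAD".
    """

    stenosis_rate: tuple[float, float] = (0.60, 0.90)
    n_stenoses: tuple[int, int] = (1, 2)
    bifurcation_angle_deg: tuple[float, float] = (30.0, 90.0)
    n_side_branches: tuple[int, int] = (0, 3)
    ascending_aorta_diameter_mm: tuple[float, float] = (20.0, 30.0)
    descending_aorta_diameter_mm: tuple[float, float] = (15.0, 20.0)
    arch_angle_deg: tuple[float, float] = (80.0, 140.0)
    stenosis_center_frac: tuple[float, float] = (0.25, 0.75)
    graft_diameter_mm: float = 2.0
    stenosis_extent_mm: float = 8.0

    def __post_init__(self):
        for name in (
            "stenosis_rate",
            "n_stenoses",
            "bifurcation_angle_deg",
            "n_side_branches",
            "ascending_aorta_diameter_mm",
            "descending_aorta_diameter_mm",
            "arch_angle_deg",
            "stenosis_center_frac",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"degenerate range {name}: {lo} > {hi}")
        if self.graft_diameter_mm <= 0 or self.stenosis_extent_mm <= 0:
            raise ConfigurationError("diameters/extents must be positive")


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

# Side-branch and coronary dimensions are not constrained by the emulated
# morphology ranges; the values below are the package's invented defaults
# (documented in docs/methods.md) chosen at adult human scale.
_TEMPLATES = {
    0: dict(
        L_asc1=0.040, L_asc2=0.030, L_arch=0.060, L_desc=0.090,
        L_lad_prox=0.030, L_lad_dist=0.040, L_lcx=0.035, L_ra=0.040,
        L_side=0.030, r_lad=0.0015, r_lcx=0.0014, r_ra=0.0015, r_side=0.004,
        n_side_branches=1, n_stenoses=1,
    ),
    1: dict(
        L_asc1=0.045, L_asc2=0.025, L_arch=0.070, L_desc=0.080,
        L_lad_prox=0.035, L_lad_dist=0.045, L_lcx=0.030, L_ra=0.045,
        L_side=0.028, r_lad=0.0016, r_lcx=0.0013, r_ra=0.0014, r_side=0.0045,
        n_side_branches=2, n_stenoses=2,
    ),
    2: dict(
        L_asc1=0.035, L_asc2=0.035, L_arch=0.055, L_desc=0.100,
        L_lad_prox=0.028, L_lad_dist=0.050, L_lcx=0.038, L_ra=0.038,
        L_side=0.032, r_lad=0.0014, r_lcx=0.0015, r_ra=0.0016, r_side=0.0035,
        n_side_branches=3, n_stenoses=1,
    ),
}

_DEFAULT_PARAMS = dict(
    ascending_aorta_diameter_mm=25.0,
    descending_aorta_diameter_mm=17.5,
    arch_angle_deg=110.0,
    bifurcation_angle_deg=60.0,
    stenosis_extent_mm=8.0,
    length_scale=1.0,
)


def _rotate_y(v, angle_rad):
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    x, y, z = v
    return np.array([c * x + s * z, y, -s * x + c * z])


def _rotate_about(v, axis, angle_rad):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


def _build_tree(template_id: int, params: dict, op_state: str = "preoperative") -> VesselTree:
    """Deterministically construct a tree from a full parameter dict."""
    if template_id not in _TEMPLATES:
        raise ConfigurationError(f"unknown template id {template_id}")
    t = _TEMPLATES[template_id]
    ls = params["length_scale"]
    r_asc = params["ascending_aorta_diameter_mm"] / 2000.0
    r_desc = params["descending_aorta_diameter_mm"] / 2000.0
    r_arch = 0.5 * (r_asc + r_desc)
    arch_turn = np.deg2rad(params["arch_angle_deg"])
    n_side = int(params["n_side_branches"])
    extent = params["stenosis_extent_mm"] / 1000.0

    nodes: dict[str, np.ndarray] = {}
    segs: list[VesselSegment] = []
    outlets: list[str] = []

    nodes["inlet"] = np.zeros(3)
    nodes["ostium"] = np.array([0.0, 0.0, t["L_asc1"] * ls])
    nodes["arch0"] = nodes["ostium"] + np.array([0.0, 0.0, t["L_asc2"] * ls])
    segs.append(VesselSegment("asc1", "inlet", "ostium", t["L_asc1"] * ls, r_asc, "aorta"))
    segs.append(VesselSegment("asc2", "ostium", "arch0", t["L_asc2"] * ls, r_asc, "aorta"))

    # arch: (n_side + 1) straight sub-segments turning arch_turn in total
    n_sub = n_side + 1
    sub_len = t["L_arch"] * ls / n_sub
    prev = "arch0"
    for k in range(n_sub):
        theta = arch_turn * (k + 0.5) / n_sub
        d = _rotate_y(np.array([0.0, 0.0, 1.0]), theta)
        nxt = f"arch{k + 1}"
        nodes[nxt] = nodes[prev] + d * sub_len
        segs.append(VesselSegment(f"arch_s{k}", prev, nxt, sub_len, r_arch, "aorta"))
        if k < n_side:
            bid = f"side{k}"
            nodes[f"{bid}_out"] = nodes[nxt] + np.array([0.0, 0.0, t["L_side"] * ls])
            segs.append(
                VesselSegment(bid, nxt, f"{bid}_out", t["L_side"] * ls, t["r_side"], "side_branch")
            )
            outlets.append(f"{bid}_out")
        prev = nxt

    d_desc = _rotate_y(np.array([0.0, 0.0, 1.0]), arch_turn)
    nodes["desc_out"] = nodes[prev] + d_desc * t["L_desc"] * ls
    segs.append(VesselSegment("desc", prev, "desc_out", t["L_desc"] * ls, r_desc, "aorta"))
    outlets.append("desc_out")

    # coronaries branch from the ostium node on the ascending aorta
    d_lad = np.array([-0.35, 0.55, -0.76])
    d_lad = d_lad / np.linalg.norm(d_lad)
    bif_axis = np.cross(d_lad, [0.0, 0.0, 1.0])
    d_lcx = _rotate_about(d_lad, bif_axis, np.deg2rad(params["bifurcation_angle_deg"]))
    d_ra = np.array([0.55, -0.45, -0.70])
    d_ra = d_ra / np.linalg.norm(d_ra)

    stens = tuple(
        Stenosis(rate=float(r), center=float(c), extent=extent)
        for r, c in params["stenoses"]
    )
    L_lp = t["L_lad_prox"] * ls
    nodes["lad_split"] = nodes["ostium"] + d_lad * L_lp
    nodes["lad_out"] = nodes["lad_split"] + d_lad * t["L_lad_dist"] * ls
    segs.append(
        VesselSegment("lad_prox", "ostium", "lad_split", L_lp, t["r_lad"], "lad_proximal", stens)
    )
    segs.append(
        VesselSegment("lad_dist", "lad_split", "lad_out", t["L_lad_dist"] * ls, t["r_lad"], "lad_distal")
    )
    outlets.append("lad_out")

    nodes["lcx_out"] = nodes["ostium"] + d_lcx * t["L_lcx"] * ls
    segs.append(VesselSegment("lcx", "ostium", "lcx_out", t["L_lcx"] * ls, t["r_lcx"], "lcx"))
    outlets.append("lcx_out")

    nodes["ra_out"] = nodes["ostium"] + d_ra * t["L_ra"] * ls
    segs.append(VesselSegment("ra", "ostium", "ra_out", t["L_ra"] * ls, t["r_ra"], "ra"))
    outlets.append("ra_out")

    return VesselTree(
        nodes=nodes,
        segments=segs,
        inlet_node="inlet",
        outlet_nodes=outlets,
        op_state=op_state,
        template_id=template_id,
        params=dict(params),
    )


def make_base_tree(template_id: int, scale_seed: int) -> VesselTree:
    """Build one of the built-in preoperative base topologies.

    ``scale_seed`` deterministically jitters the overall length scale (±5 %)
    and the base stenosis placement, standing in for per-patient variability
    among the original anatomies that a corpus is expanded from.
    """
    if template_id not in _TEMPLATES:
        raise ConfigurationError(f"unknown template id {template_id}")
    t = _TEMPLATES[template_id]
    rng = child_rng(scale_seed, "base", template_id)
    params = dict(_DEFAULT_PARAMS)
    params["length_scale"] = float(rng.uniform(0.95, 1.05))
    params["n_side_branches"] = t["n_side_branches"]
    centers = np.sort(rng.uniform(0.3, 0.7, size=t["n_stenoses"]))
    params["stenoses"] = [(0.75, float(c)) for c in centers]
    return _build_tree(template_id, params)


def expand_model(
    base: VesselTree, ranges: GeometryRanges, count: int, seed: int
) -> list[VesselTree]:
    """Draw ``count`` geometric variants of ``base`` uniformly from ``ranges``.

    Every applicable parameter (stenosis count/rates/centers, bifurcation
    angle, side-branch count, aortic diameters, arch angulation) is redrawn
    independently per variant; template topology and length scale are kept.
    Deterministic for fixed ``(base, ranges, count, seed)``.
    """
    if count < 1:
        raise ConfigurationError("count must be >= 1")
    variants = []
    for i in range(count):
        rng = child_rng(seed, "expand", i)
        p = dict(base.params)
        # fixed draw order so collapsed ranges give identical variants
        n_st = int(rng.integers(ranges.n_stenoses[0], ranges.n_stenoses[1] + 1))
        rates = rng.uniform(*ranges.stenosis_rate, size=max(n_st, 1))
        centers = np.sort(rng.uniform(*ranges.stenosis_center_frac, size=max(n_st, 1)))
        p["stenoses"] = [(float(r), float(c)) for r, c in zip(rates[:n_st], centers[:n_st])]
        p["bifurcation_angle_deg"] = float(rng.uniform(*ranges.bifurcation_angle_deg))
        p["n_side_branches"] = int(
            rng.integers(ranges.n_side_branches[0], ranges.n_side_branches[1] + 1)
        )
        p["ascending_aorta_diameter_mm"] = float(
            rng.uniform(*ranges.ascending_aorta_diameter_mm)
        )
        p["descending_aorta_diameter_mm"] = float(
            rng.uniform(*ranges.descending_aorta_diameter_mm)
        )
        p["arch_angle_deg"] = float(rng.uniform(*ranges.arch_angle_deg))
        p["stenosis_extent_mm"] = ranges.stenosis_extent_mm
        variants.append(_build_tree(base.template_id, p, op_state=base.op_state))
    return variants


def add_graft(tree: VesselTree, seed: int, graft_diameter_mm: float = 2.0) -> VesselTree:
    """Return a postoperative copy with one bypass graft around the worst
    LAD stenosis.

    The graft (default diameter 2 mm, i.e. radius 1 mm) runs from the
    coronary ostium on the ascending trunk to the node immediately distal to
    the highest-grade stenosis (the proximal end of the distal LAD segment),
    along a laterally bowed centerline so its lumen is disjoint from the
    native LAD.  Original segments are unchanged.
    """
    if tree.op_state != "preoperative":
        raise PreconditionError("tree is already postoperative")
    lad_segs = [
        s for s in tree.segments
        if s.role in ("lad_proximal", "lad_distal") and s.stenoses
    ]
    if not lad_segs:
        raise PreconditionError("no stenosed LAD segment to bypass")
    worst = max(lad_segs, key=lambda s: max(st.rate for st in s.stenoses))
    rng = child_rng(seed, "graft")
    a = tree.nodes[worst.start_node]
    b = tree.nodes[worst.end_node]
    chord = b - a
    side = np.cross(chord, [0.0, 0.0, 1.0])
    if np.linalg.norm(side) < 1e-12:
        side = np.cross(chord, [0.0, 1.0, 0.0])
    side = side / np.linalg.norm(side)
    bow = tuple(side * float(rng.uniform(0.008, 0.012)))

    graft = VesselSegment(
        id="graft",
        start_node=worst.start_node,
        end_node=worst.end_node,
        length=1.0,  # placeholder, replaced by arc length below
        radius=graft_diameter_mm / 2000.0,
        role="graft",
        bow=bow,
    )
    # arc length of the bowed chord
    tmp = dataclasses.replace(graft, length=float(np.linalg.norm(chord)))
    probe = VesselTree.__new__(VesselTree)
    probe.nodes = dict(tree.nodes)
    arc = probe._arc_table(tmp)[1][-1]
    graft = dataclasses.replace(graft, length=float(arc))

    return VesselTree(
        nodes=dict(tree.nodes),
        segments=list(tree.segments) + [graft],
        inlet_node=tree.inlet_node,
        outlet_nodes=list(tree.outlet_nodes),
        op_state="postoperative",
        template_id=tree.template_id,
        params=dict(tree.params),
    )


# ---------------------------------------------------------------------------
# Point sampling
# ---------------------------------------------------------------------------


@dataclass
class SurfacePointCloud:
    """Wall ("model") point cloud: coordinates only, M × 3, meters."""

    coordinates: np.ndarray

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise GeometryError("surface coordinates must be M x 3")
        if len(self.coordinates) < 1 or not np.all(np.isfinite(self.coordinates)):
            raise GeometryError("surface coordinates must be finite and non-empty")

    def __len__(self):
        return len(self.coordinates)


@dataclass
class InteriorPoints:
    """Interior samples with the lumen parameterization the oracle evaluates.

    ``segment_ids[i]``, ``axial_frac[i]`` (chord fraction in [0,1]) and
    ``radial_frac[i]`` (< 1) locate point i inside its tube without any
    nearest-neighbor search; ``theta`` is the azimuth used to reconstruct
    coordinates.
    """

    coordinates: np.ndarray
    segment_ids: np.ndarray
    axial_frac: np.ndarray
    radial_frac: np.ndarray
    theta: np.ndarray

    def __len__(self):
        return len(self.coordinates)

    def __iter__(self):
        for i in range(len(self)):
            yield (
                self.coordinates[i],
                str(self.segment_ids[i]),
                float(self.axial_frac[i]),
                float(self.radial_frac[i]),
            )


def _segment_wall_area(tree: VesselTree, seg: VesselSegment, n: int = 1001) -> float:
    """Lateral wall area ∫ 2π r(x) dx (m²)."""
    x = np.linspace(0.0, seg.length, n)
    return float(np.trapezoid(2.0 * np.pi * seg.radius_at(x), x))


def _segment_volume(tree: VesselTree, seg: VesselSegment, n: int = 1001) -> float:
    """Lumen volume ∫ π r(x)² dx (m³)."""
    x = np.linspace(0.0, seg.length, n)
    return float(np.trapezoid(np.pi * seg.radius_at(x) ** 2, x))


def surface_points(tree: VesselTree, points_per_mm2: float, seed: int) -> SurfacePointCloud:
    """Sample the tubular wall uniformly at ``points_per_mm2`` (points/mm²).

    Per segment the point count is ``round(density × wall area)`` (≥ 1), so
    doubling the density doubles the count up to rounding.  Each point sits
    exactly on the stenosed radius profile: its distance to the centerline
    point at the same axial station equals the local radius by construction.
    """
    if points_per_mm2 <= 0:
        raise ConfigurationError("surface density must be positive")
    rng = child_rng(seed, "surface")
    pts = []
    for seg in tree.segments:
        area_mm2 = _segment_wall_area(tree, seg) * 1e6
        n = max(1, int(round(points_per_mm2 * area_mm2)))
        u = rng.uniform(0.0, 1.0, size=n)
        th = rng.uniform(0.0, 2.0 * np.pi, size=n)
        x = tree.axial_position(seg, u)
        r = seg.radius_at(x)
        c = tree.point_at(seg, u)
        _, n1, n2 = tree.frame_at(seg, u)
        pts.append(c + r[:, None] * (np.cos(th)[:, None] * n1 + np.sin(th)[:, None] * n2))
    return SurfacePointCloud(np.concatenate(pts, axis=0))


def interior_points(tree: VesselTree, n_points: int, seed: int) -> InteriorPoints:
    """Sample ``n_points`` strictly inside the lumen, uniformly in volume.

    Segments are chosen with probability proportional to lumen volume; within
    a segment the axial station is uniform and the radial fraction follows
    the uniform-over-disk law (ρ = √u).
    """
    if n_points < 1:
        raise ConfigurationError("n_points must be >= 1")
    rng = child_rng(seed, "interior")
    vols = np.array([_segment_volume(tree, s) for s in tree.segments])
    probs = vols / vols.sum()
    seg_idx = rng.choice(len(tree.segments), size=n_points, p=probs)
    u = rng.uniform(0.0, 1.0, size=n_points)
    rho = np.sqrt(rng.uniform(0.0, 1.0, size=n_points))
    rho = np.minimum(rho, 1.0 - 1e-12)
    th = rng.uniform(0.0, 2.0 * np.pi, size=n_points)

    coords = np.empty((n_points, 3))
    seg_ids = np.empty(n_points, dtype=object)
    for k, seg in enumerate(tree.segments):
        m = seg_idx == k
        if not np.any(m):
            continue
        x = tree.axial_position(seg, u[m])
        r = seg.radius_at(x)
        c = tree.point_at(seg, u[m])
        _, n1, n2 = tree.frame_at(seg, u[m])
        off = (rho[m] * r)[:, None] * (
            np.cos(th[m])[:, None] * n1 + np.sin(th[m])[:, None] * n2
        )
        coords[m] = c + off
        seg_ids[m] = seg.id
    return InteriorPoints(
        coordinates=coords,
        segment_ids=np.array([str(s) for s in seg_ids]),
        axial_frac=u,
        radial_frac=rho,
        theta=th,
    )


# ---------------------------------------------------------------------------
# Serialization / export
# ---------------------------------------------------------------------------


def tree_to_yaml(tree: VesselTree, path) -> None:
    """Write the full tree description as a nested key-value document."""
    doc = {
        "op_state": tree.op_state,
        "template_id": tree.template_id,
        "inlet_node": tree.inlet_node,
        "outlet_nodes": list(tree.outlet_nodes),
        "nodes": {k: [float(x) for x in v] for k, v in tree.nodes.items()},
        "segments": [
            {
                "id": s.id,
                "start_node": s.start_node,
                "end_node": s.end_node,
                "length": float(s.length),
                "radius": float(s.radius),
                "role": s.role,
                "bow": None if s.bow is None else [float(x) for x in s.bow],
                "stenoses": [
                    {"rate": st.rate, "center": st.center, "extent": st.extent}
                    for st in s.stenoses
                ],
            }
            for s in tree.segments
        ],
        "params": _jsonable(tree.params),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def tree_from_yaml(path) -> VesselTree:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    segs = [
        VesselSegment(
            id=d["id"],
            start_node=d["start_node"],
            end_node=d["end_node"],
            length=d["length"],
            radius=d["radius"],
            role=d["role"],
            bow=None if d.get("bow") is None else tuple(d["bow"]),
            stenoses=tuple(
                Stenosis(rate=s["rate"], center=s["center"], extent=s["extent"])
                for s in d.get("stenoses", [])
            ),
        )
        for d in doc["segments"]
    ]
    return VesselTree(
        nodes={k: np.array(v) for k, v in doc["nodes"].items()},
        segments=segs,
        inlet_node=doc["inlet_node"],
        outlet_nodes=list(doc["outlet_nodes"]),
        op_state=doc["op_state"],
        template_id=doc.get("template_id", 0),
        params=doc.get("params", {}),
    )


def export_stl(tree: VesselTree, path, circumferential: int = 24, axial_step_mm: float = 1.0):
    """Triangulate every tube wall and write an STL file (via trimesh)."""
    import trimesh

    verts, faces = [], []
    for seg in tree.segments:
        n_ax = max(2, int(np.ceil(seg.length * 1000.0 / axial_step_mm)) + 1)
        u = np.linspace(0.0, 1.0, n_ax)
        x = tree.axial_position(seg, u)
        r = seg.radius_at(x)
        c = tree.point_at(seg, u)
        _, n1, n2 = tree.frame_at(seg, u)
        th = np.linspace(0.0, 2 * np.pi, circumferential, endpoint=False)
        base = len(verts)
        ring = (
            c[:, None, :]
            + r[:, None, None] * (np.cos(th)[None, :, None] * n1[:, None, :]
                                  + np.sin(th)[None, :, None] * n2[:, None, :])
        )
        verts.extend(ring.reshape(-1, 3))
        for i in range(n_ax - 1):
            for j in range(circumferential):
                a0 = base + i * circumferential + j
                a1 = base + i * circumferential + (j + 1) % circumferential
                b0 = a0 + circumferential
                b1 = a1 + circumferential
                faces.append([a0, b0, a1])
                faces.append([a1, b0, b1])
    mesh = trimesh.Trimesh(vertices=np.array(verts), faces=np.array(faces), process=False)
    mesh.export(path)
    return mesh
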