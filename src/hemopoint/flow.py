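"""Reduced-order steady-flow oracle: Poiseuille hydraulic network.

Each segment is a hydraulic resistor R_h = ∫ 8μ/(π r(x)⁴) dx along its
centerline; Kirchhoff balance at the nodes with a fixed volumetric inflow at
the inlet (inlet velocity × inlet cross-section) and zero pressure at every
outlet yields nodal pressures and signed segment flows.  Inside a segment the
velocity closes to a parabolic (Poiseuille) profile u(ρ) = 2·ū·(1 − ρ²) along
the local tangent and the pressure drops with the cumulative resistance
integral, so velocity and pressure are available analytically at any interior
point without interpolation.

The model is linear (creeping flow): inertial and expansion losses across
stenoses are neglected, and there is no secondary or vortical motion.  This
keeps the solve exact and its conservation invariants assertable; it is a
deliberate fidelity limit relative to full 3-D CFD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import GeometryError, OutOfLumenError, StructuralError
from .geometry import (
    VesselSegment,
    VesselTree,
    surface_points,
    interior_points,
    ROLE_TO_REGION,
)

__all__ = [
    "FluidProperties",
    "BoundaryConditions",
    "NetworkSolution",
    "segment_resistance",
    "solve_network",
    "velocity_at",
    "pressure_at",
    "velocities_at",
    "pressures_at",
    "make_sample",
]

_CONSERVATION_RTOL = 1e-10


@dataclass(frozen=True)
class FluidProperties:
    """Blood treated as an incompressible Newtonian fluid."""

    density: float = 1050.0  # kg/m^3
    viscosity: float = 0.0035  # Pa*s

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise GeometryError("fluid properties must be positive")


@dataclass(frozen=True)
class BoundaryConditions:
    """Steady peak-systolic inflow; all outlets at zero gauge pressure."""

    inlet_velocity: float = 1.125  # m/s
    outlet_pressure: float = 0.0  # Pa, fixed

    def __post_init__(self):
        if self.inlet_velocity <= 0:
            raise GeometryError("inlet velocity must be positive")
        if self.outlet_pressure != 0.0:
            raise GeometryError("outlet pressure is fixed at 0 Pa (gauge)")


@dataclass
class NetworkSolution:
    """Signed segment flows (start→end positive) and nodal pressures."""

    segment_flows: dict[str, float]
    node_pressures: dict[str, float]
    inlet_flow: float
    resistances: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Resistance
# ---------------------------------------------------------------------------

_QUAD_POINTS = 1001  # per stenosis window (odd, composite Simpson)


def _simpson(y: np.ndarray, x: np.ndarray) -> float:
    from scipy.integrate import simpson

    return float(simpson(y, x=x))


def segment_resistance(seg: VesselSegment, fluid: FluidProperties) -> float:
    """Hydraulic resistance ∫ 8μ/(π r(x)⁴) dx in Pa·s/m³.

    Uniform stretches use the closed form 8μL/(πR⁴); each stenosis window is
    integrated by fixed 1001-point composite Simpson on the cosine profile.
    """
    if np.any(seg.radius_at(np.linspace(0, seg.length, 257)) <= 0):
        raise GeometryError(f"segment {seg.id}: non-positive lumen radius")
    mu = fluid.viscosity
    k = 8.0 * mu / np.pi
    windows = seg.stenosis_windows()
    uniform_len = seg.length - sum(b - a for a, b in windows)
    total = k * uniform_len / seg.radius**4
    for a, b in windows:
        x = np.linspace(a, b, _QUAD_POINTS)
        total += _simpson(k / seg.radius_at(x) ** 4, x)
    return total


def _cumulative_resistance(seg: VesselSegment, fluid: FluidProperties, xs: np.ndarray) -> np.ndarray:
    """∫₀ˣ 8μ/(π r)⁴ for each x in ``xs`` (meters along the centerline).

    Exact on uniform stretches; within stenosis windows a dense cumulative
    grid consistent with :func:`segment_resistance` is interpolated.
    """
    from scipy.integrate import cumulative_simpson

    mu = fluid.viscosity
    k = 8.0 * mu / np.pi
    xs = np.asarray(xs, dtype=float)
    out = np.zeros(xs.shape)
    pos = 0.0
    acc = 0.0
    g_uniform = k / seg.radius**4
    for a, b in seg.stenosis_windows():
        # uniform stretch [pos, a]
        m = xs > pos
        out[m & (xs <= a)] = acc + g_uniform * (xs[m & (xs <= a)] - pos)
        acc += g_uniform * (a - pos)
        # window [a, b]
        xg = np.linspace(a, b, _QUAD_POINTS)
        cg = cumulative_simpson(k / seg.radius_at(xg) ** 4, x=xg, initial=0.0)
        inwin = (xs > a) & (xs <= b)
        out[inwin] = acc + np.interp(xs[inwin], xg, cg)
        acc += float(cg[-1])
        pos = b
    m = xs > pos
    out[m] = acc + g_uniform * (xs[m] - pos)
    out[xs <= 0] = 0.0
    return out


# ---------------------------------------------------------------------------
# Network solve
# ---------------------------------------------------------------------------


def solve_network(
    tree: VesselTree,
    bc: BoundaryConditions = BoundaryConditions(),
    fluid: FluidProperties = FluidProperties(),
) -> NetworkSolution:
    """Solve the Kirchhoff nodal-pressure system for the whole tree.

    The inlet carries Q_in = v_in × π R_inlet²; all outlet nodes are held at
    exactly 0 Pa.  Raises if the system is singular or if nodal mass balance
    exceeds 1e−10 of the inlet flow (it never should).
    """
    inlet_segs = [s for s in tree.segments if tree.inlet_node in (s.start_node, s.end_node)]
    if not inlet_segs:
        raise StructuralError("inlet node has no attached segment")
    r_inlet = inlet_segs[0].radius
    q_in = bc.inlet_velocity * np.pi * r_inlet**2

    node_ids = list(tree.nodes)
    idx = {n: i for i, n in enumerate(node_ids)}
    n = len(node_ids)
    G = np.zeros((n, n))
    b = np.zeros(n)
    resistances = {}
    for seg in tree.segments:
        rh = segment_resistance(seg, fluid)
        resistances[seg.id] = rh
        g = 1.0 / rh
        i, j = idx[seg.start_node], idx[seg.end_node]
        G[i, i] += g
        G[j, j] += g
        G[i, j] -= g
        G[j, i] -= g
    b[idx[tree.inlet_node]] = q_in
    # Dirichlet rows for outlets
    for o in tree.outlet_nodes:
        i = idx[o]
        G[i, :] = 0.0
        G[i, i] = 1.0
        b[i] = 0.0
    try:
        p = np.linalg.solve(G, b)
    except np.linalg.LinAlgError as e:
        raise StructuralError(f"singular hydraulic system: {e}") from e
    if not np.all(np.isfinite(p)):
        raise StructuralError("non-finite nodal pressures")

    flows = {
        seg.id: (p[idx[seg.start_node]] - p[idx[seg.end_node]]) / resistances[seg.id]
        for seg in tree.segments
    }
    sol = NetworkSolution(
        segment_flows=flows,
        node_pressures={nid: (0.0 if nid in tree.outlet_nodes else float(p[idx[nid]])) for nid in node_ids},
        inlet_flow=float(q_in),
        resistances=resistances,
    )
    _check_conservation(tree, sol)
    return sol


def _check_conservation(tree: VesselTree, sol: NetworkSolution) -> None:
    imbalance = {n: 0.0 for n in tree.nodes}
    for seg in tree.segments:
        q = sol.segment_flows[seg.id]
        imbalance[seg.start_node] -= q
        imbalance[seg.end_node] += q
    imbalance[tree.inlet_node] += sol.inlet_flow
    worst = max(
        abs(v) for n, v in imbalance.items() if n not in tree.outlet_nodes
    )
    if worst > _CONSERVATION_RTOL * abs(sol.inlet_flow):
        raise StructuralError(
            f"mass conservation violated: {worst / sol.inlet_flow:.3e} relative"
        )


# ---------------------------------------------------------------------------
# Point evaluation
# ---------------------------------------------------------------------------


def _mean_velocity(seg: VesselSegment, sol: NetworkSolution, x: np.ndarray) -> np.ndarray:
    q = sol.segment_flows[seg.id]
    return q / (np.pi * seg.radius_at(x) ** 2)


def velocities_at(
    tree: VesselTree,
    sol: NetworkSolution,
    segment_ids: np.ndarray,
    axial_frac: np.ndarray,
    radial_frac: np.ndarray,
) -> np.ndarray:
    """Vectorized Poiseuille velocity vectors (N × 3, m/s)."""
    segment_ids = np.asarray(segment_ids)
    axial_frac = np.asarray(axial_frac, dtype=float)
    radial_frac = np.asarray(radial_frac, dtype=float)
    if np.any(radial_frac >= 1.0) or np.any(radial_frac < 0.0):
        raise OutOfLumenError("radial fraction outside [0, 1)")
    out = np.empty((len(segment_ids), 3))
    for seg in tree.segments:
        m = segment_ids == seg.id
        if not np.any(m):
            continue
        u = axial_frac[m]
        x = tree.axial_position(seg, u)
        ubar = _mean_velocity(seg, sol, x)
        mag = 2.0 * ubar * (1.0 - radial_frac[m] ** 2)
        t = tree.tangent_at(seg, u)
        out[m] = mag[:, None] * t
    return out


def velocity_at(tree: VesselTree, sol: NetworkSolution, point) -> np.ndarray:
    """Velocity 3-vector at one (segment_id, axial_fraction, radial_fraction)."""
    seg_id, af, rf = point
    return velocities_at(tree, sol, np.array([seg_id]), np.array([af]), np.array([rf]))[0]


def pressures_at(
    tree: VesselTree,
    sol: NetworkSolution,
    segment_ids: np.ndarray,
    axial_frac: np.ndarray,
    radial_frac: np.ndarray | None = None,
    fluid: FluidProperties = FluidProperties(),
) -> np.ndarray:
    """Vectorized pressures (Pa): upstream node pressure minus the partial
    resistance integral times the segment flow.  Radially uniform."""
    segment_ids = np.asarray(segment_ids)
    axial_frac = np.asarray(axial_frac, dtype=float)
    if radial_frac is not None and np.any(np.asarray(radial_frac) >= 1.0):
        raise OutOfLumenError("radial fraction outside [0, 1)")
    out = np.empty(len(segment_ids))
    for seg in tree.segments:
        m = segment_ids == seg.id
        if not np.any(m):
            continue
        x = tree.axial_position(seg, axial_frac[m])
        p0 = sol.node_pressures[seg.start_node]
        out[m] = p0 - sol.segment_flows[seg.id] * _cumulative_resistance(seg, fluid, x)
    return out


def pressure_at(tree, sol, point, fluid: FluidProperties = FluidProperties()) -> float:
    seg_id, af, rf = point
    return float(
        pressures_at(tree, sol, np.array([seg_id]), np.array([af]), np.array([rf]), fluid)[0]
    )


# ---------------------------------------------------------------------------
# Sample assembly
# ---------------------------------------------------------------------------


def make_sample(
    tree: VesselTree,
    bc: BoundaryConditions,
    fluid: FluidProperties,
    n_query: int,
    surface_density: float,
    field_kind: str,
    seed: int,
    model_id: str = "model",
    base_model_id: str = "base",
):
    """Solve the tree and bundle surface + query clouds into one sample.

    ``field_kind`` is ``velocity`` (3-vector targets, m/s) or ``pressure``
    (scalar replicated into three identical components, Pa).
    """
    from .data import HemodynamicSample, QueryPointCloud, pressure_to_components

    if field_kind not in ("velocity", "pressure"):
        raise GeometryError(f"unknown field kind {field_kind!r}")
    sol = solve_network(tree, bc, fluid)
    surf = surface_points(tree, surface_density, seed)
    interior = interior_points(tree, n_query, seed)
    if field_kind == "velocity":
        targets = velocities_at(
            tree, sol, interior.segment_ids, interior.axial_frac, interior.radial_frac
        )
    else:
        p = pressures_at(
            tree, sol, interior.segment_ids, interior.axial_frac, interior.radial_frac, fluid
        )
        targets = pressure_to_components(p)
    role_of = {s.id: s.role for s in tree.segments}
    region = np.array([ROLE_TO_REGION[role_of[sid]] for sid in interior.segment_ids])
    query = QueryPointCloud(
        coordinates=interior.coordinates, targets=targets, region=region
    )
    return HemodynamicSample(
        surface=surf,
        query=query,
        op_state=tree.op_state,
        field_kind=field_kind,
        model_id=model_id,
        base_model_id=base_model_id,
        tree=tree,
        solution=sol,
        interior=interior,
    )
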