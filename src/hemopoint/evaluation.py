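"""Error metrics, regional reports, clinical indices and error attribution.

Two error functions quantify the disagreement between a predicted and a
reference field over a selected set of points, both reported as percentages:

* NMAE — mean absolute error normalized by the range of reference-field
  magnitudes over the selected region:
  ``(1/N) Σ‖P_i − P̂_i‖ / (max‖P‖ − min‖P‖) × 100``.
* MRE — mean per-point relative error: ``(1/N) Σ ‖P_i − P̂_i‖/‖P_i‖ × 100``.

``‖·‖`` is the per-point Euclidean norm (absolute value for scalar fields);
both metrics are therefore invariant to rigid rotations of the field and MRE
is scale invariant.  Reports aggregate per-region, per-model values as
mean ± population standard deviation across models.

Clinical indices: FFR (mean pressure in a thin cross-sectional slab 3 cm
downstream of the worst LAD stenosis over mean pressure at the LAD entry,
both offset by a fixed aortic reference pressure because the oracle works in
gauge pressure with zero-pressure outlets) and graft inlet flow (mean axial
velocity over the graft inlet slab × π d²/4).  Method agreement uses Pearson
correlation and Bland–Altman limits.  A k-NN least-squares velocity-gradient
estimator provides vorticity magnitudes for vortex-region masking and
high-error overlap analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy import stats as sps

from ._seeds import child_rng, child_seed
from .exceptions import EvaluationError, PreconditionError, UserInputError
from .geometry import REGIONS, VesselTree
from .flow import NetworkSolution, velocities_at

__all__ = [
    "nmae",
    "mre",
    "pointwise_relative_error",
    "ErrorReport",
    "regional_report",
    "ClinicalIndices",
    "compute_ffr",
    "compute_ffr_from_points",
    "graft_flow",
    "AgreementStats",
    "agreement",
    "VortexField",
    "vorticity_field",
    "OverlapStats",
    "high_error_overlap",
    "SweepResult",
    "training_size_sweep",
]

#: MRE exclusion floor: points whose reference magnitude is below this
#: fraction of the region maximum are excluded (and counted).
MRE_FLOOR_FRACTION = 1e-9

#: Default additive reference pressure for FFR (100 mmHg in Pa): the oracle
#: and its boundary conditions are gauge (zero-pressure outlets), so a
#: documented aortic reference must be added to both slab means for the
#: ratio to behave like a clinical FFR.  Applied identically to reference
#: and predicted fields.
FFR_REFERENCE_PRESSURE = 13332.0


def _magnitudes(arr) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.ndim == 1:
        return np.abs(a)
    if a.ndim == 2:
        return np.linalg.norm(a, axis=1)
    raise UserInputError("fields must be (N,) or (N, k) arrays")


def _check_shapes(truth, pred):
    t = np.asarray(truth, dtype=float)
    p = np.asarray(pred, dtype=float)
    if t.shape != p.shape:
        raise UserInputError(f"shape mismatch: {t.shape} vs {p.shape}")
    if t.shape[0] < 1:
        raise UserInputError("empty selection")
    return t, p


def nmae(truth, pred) -> float:
    """Range-normalized mean absolute error, percent."""
    t, p = _check_shapes(truth, pred)
    mags = _magnitudes(t)
    rng_ = mags.max() - mags.min()
    if rng_ <= 0:
        raise EvaluationError("NMAE undefined: constant reference magnitude")
    return float(_magnitudes(t - p).mean() / rng_ * 100.0)


def mre(truth, pred, return_excluded: bool = False):
    """Mean relative error, percent, over points above the exclusion floor."""
    t, p = _check_shapes(truth, pred)
    mags = _magnitudes(t)
    keep = mags >= MRE_FLOOR_FRACTION * mags.max()
    n_excluded = int((~keep).sum())
    if not np.any(keep):
        raise EvaluationError("MRE undefined: all points below magnitude floor")
    val = float((_magnitudes(t - p)[keep] / mags[keep]).mean() * 100.0)
    if return_excluded:
        return val, n_excluded
    return val


def pointwise_relative_error(truth, pred) -> np.ndarray:
    """Per-point relative error in percent (NaN below the exclusion floor)."""
    t, p = _check_shapes(truth, pred)
    mags = _magnitudes(t)
    out = np.full(len(t), np.nan)
    keep = mags >= MRE_FLOOR_FRACTION * mags.max()
    out[keep] = _magnitudes(t - p)[keep] / mags[keep] * 100.0
    return out


# ---------------------------------------------------------------------------
# Regional report
# ---------------------------------------------------------------------------


@dataclass
class ErrorReport:
    """Per-region NMAE/MRE, mean ± population std across models."""

    regions: list[str]
    nmae_mean: dict[str, float]
    nmae_std: dict[str, float]
    mre_mean: dict[str, float]
    mre_std: dict[str, float]
    n_models: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        """Tables-style layout: rows = metric, columns = regions."""
        rows = {}
        rows["NMAE"] = {
            r: f"{self.nmae_mean[r]:.2f} ± {self.nmae_std[r]:.2f}" for r in self.regions
        }
        rows["MRE"] = {
            r: f"{self.mre_mean[r]:.2f} ± {self.mre_std[r]:.2f}" for r in self.regions
        }
        return pd.DataFrame(rows).T[self.regions]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "region": self.regions,
                "nmae_mean": [self.nmae_mean[r] for r in self.regions],
                "nmae_std": [self.nmae_std[r] for r in self.regions],
                "mre_mean": [self.mre_mean[r] for r in self.regions],
                "mre_std": [self.mre_std[r] for r in self.regions],
                "n_models": [self.n_models[r] for r in self.regions],
            }
        )
        df.to_csv(path, index=False)


def regional_report(samples, predictions) -> ErrorReport:
    """Aggregate per-region errors over ≥1 models.

    For each model, each region's NMAE uses the region-local magnitude range
    of the reference field; values are then averaged across models with the
    population standard deviation as spread.  Regions absent from a model
    (e.g. graft preoperatively) are skipped for that model; a region absent
    everywhere is dropped from the report.
    """
    if len(samples) != len(predictions):
        raise UserInputError("one prediction array per sample required")
    per_region: dict[str, list[tuple[float, float]]] = {r: [] for r in REGIONS}
    for s, pred in zip(samples, predictions):
        pred = np.asarray(pred, dtype=float)
        for region in REGIONS:
            m = s.query.region == region
            if not np.any(m):
                if region != "graft" or s.op_state == "postoperative":
                    warnings.warn(
                        f"model {s.model_id}: region {region!r} has no points; skipped"
                    )
                continue
            try:
                v_nmae = nmae(s.query.targets[m], pred[m])
                v_mre = mre(s.query.targets[m], pred[m])
            except EvaluationError as e:
                warnings.warn(f"model {s.model_id}, region {region!r}: {e}")
                continue
            per_region[region].append((v_nmae, v_mre))
    regions = [r for r in REGIONS if per_region[r]]
    rep = ErrorReport(regions=regions, nmae_mean={}, nmae_std={}, mre_mean={},
                      mre_std={}, n_models={})
    for r in regions:
        arr = np.array(per_region[r])
        rep.nmae_mean[r] = float(arr[:, 0].mean())
        rep.nmae_std[r] = float(arr[:, 0].std(ddof=0))
        rep.mre_mean[r] = float(arr[:, 1].mean())
        rep.mre_std[r] = float(arr[:, 1].std(ddof=0))
        rep.n_models[r] = len(arr)
    return rep


# ---------------------------------------------------------------------------
# Clinical indices
# ---------------------------------------------------------------------------


@dataclass
class ClinicalIndices:
    ffr: float | None = None
    graft_flow: float | None = None
    reference_pressure: float = FFR_REFERENCE_PRESSURE


def _project_axial(tree: VesselTree, seg, coords: np.ndarray) -> np.ndarray:
    """Arc-length position of each coordinate along a straight segment."""
    a = tree.nodes[seg.start_node]
    b = tree.nodes[seg.end_node]
    axis = (b - a) / np.linalg.norm(b - a)
    return (coords - a) @ axis


def _lad_path(tree: VesselTree):
    prox = tree.segments_by_role("lad_proximal")
    dist = tree.segments_by_role("lad_distal")
    if not prox or not any(s.stenoses for s in prox + dist):
        raise PreconditionError("tree has no stenosed LAD")
    return prox[0], (dist[0] if dist else None)


def _slab_mean(values, positions, center, half, min_points, max_widen=8):
    """Mean of ``values`` whose position lies within ±half of center; the
    half-width doubles (up to ×max_widen) until ≥ min_points points fall in."""
    widen = 1
    while True:
        m = np.abs(positions - center) <= half * widen
        if m.sum() >= min_points or widen >= max_widen:
            break
        widen *= 2
    if m.sum() == 0:
        raise EvaluationError("empty cross-sectional slab even after widening")
    if m.sum() < min_points:
        warnings.warn(f"slab kept only {int(m.sum())} points after max widening")
    return float(np.mean(values[m]))


def _ffr_slab_geometry(tree: VesselTree, distal_offset: float):
    """Locate the LAD entry slab and the distal slab for FFR.

    Returns (prox_segment, local entry position, target segment, target
    region name, local distal position); the distal position is clamped (with
    a warning) when the offset overshoots the distal LAD.
    """
    prox, dist = _lad_path(tree)
    stenosed = max(
        (s for s in (prox, dist) if s is not None and s.stenoses),
        key=lambda s: max(st.rate for st in s.stenoses),
    )
    worst = max(stenosed.stenoses, key=lambda st: st.rate)
    if stenosed.id == prox.id:
        path = [(prox, "lad_proximal", 0.0)]
        if dist is not None:
            path.append((dist, "lad_distal", prox.length))
        center_arc = worst.center * prox.length
    else:
        path = [(dist, "lad_distal", 0.0)]
        center_arc = worst.center * dist.length

    target = center_arc + distal_offset
    seg_target, region_target, arc0 = path[0]
    for seg, rname, a0 in path:
        if a0 <= target <= a0 + seg.length:
            seg_target, region_target, arc0 = seg, rname, a0
    local = target - arc0
    if local > seg_target.length:
        local = 0.8 * seg_target.length
        warnings.warn(
            "distal FFR offset beyond the LAD; clamped to 80% of the distal segment"
        )
    return prox, seg_target, region_target, local


def _sample_slab(tree, seg, center, half, n, rng):
    """Uniform lumen samples in the axial window [center-half, center+half]."""
    x = rng.uniform(max(0.0, center - half), min(seg.length, center + half), size=n)
    u = x / seg.length
    rho = np.minimum(np.sqrt(rng.uniform(0.0, 1.0, size=n)), 1.0 - 1e-12)
    th = rng.uniform(0.0, 2 * np.pi, size=n)
    c = tree.point_at(seg, u)
    _, n1, n2 = tree.frame_at(seg, u)
    r = seg.radius_at(x)
    coords = c + (rho * r)[:, None] * (
        np.cos(th)[:, None] * n1 + np.sin(th)[:, None] * n2
    )
    return coords, u, rho


def compute_ffr(
    tree: VesselTree,
    pressure_source,
    distal_offset: float = 0.03,
    reference_pressure: float = FFR_REFERENCE_PRESSURE,
    slab_frac: float = 0.02,
    n_slab_points: int = 2000,
    seed: int = 0,
) -> float:
    """FFR from a pressure field accessor.

    Ratio of the mean pressure over a thin cross-sectional slab
    ``distal_offset`` meters downstream of the worst LAD stenosis to the mean
    pressure over the LAD entry slab, both offset by ``reference_pressure``
    (the oracle works in gauge pressure with zero-pressure outlets, so the
    raw ratio is not a clinical FFR; the documented additive reference makes
    it one and keeps it in (0, 1]).

    ``pressure_source`` is either a :class:`~hemopoint.flow.NetworkSolution`
    or a callable mapping coordinates (N×3) to scalar pressures (N,), e.g. a
    trained network's prediction (mean of the three replicated components).
    Slab points are sampled by this function, so the computation is identical
    for oracle and predicted fields.
    """
    from .flow import NetworkSolution, pressures_at

    prox, seg_d, _region_d, local = _ffr_slab_geometry(tree, distal_offset)
    rng = child_rng(seed, "ffrslab")
    half_e = slab_frac * prox.length / 2.0
    half_d = slab_frac * seg_d.length / 2.0
    means = []
    for seg, center, half in ((prox, half_e, half_e), (seg_d, local, half_d)):
        coords, u, _rho = _sample_slab(tree, seg, center, half, n_slab_points, rng)
        if isinstance(pressure_source, NetworkSolution):
            p = pressures_at(
                tree, pressure_source, np.full(len(u), seg.id, dtype=object), u
            )
        else:
            p = np.asarray(pressure_source(coords), dtype=float).reshape(-1)
        means.append(float(p.mean()))
    p_entry, p_dist = means
    return float((p_dist + reference_pressure) / (p_entry + reference_pressure))


def compute_ffr_from_points(
    tree: VesselTree,
    coords: np.ndarray,
    region: np.ndarray,
    pressures: np.ndarray,
    distal_offset: float = 0.03,
    reference_pressure: float = FFR_REFERENCE_PRESSURE,
    slab_frac: float = 0.02,
    min_points: int = 30,
) -> float:
    """FFR from a fixed interior point cloud (e.g. reloaded CSV predictions).

    Same slab geometry as :func:`compute_ffr`, but the slab means are taken
    over the given points; slabs too thin to catch ``min_points`` points are
    widened (×2 up to ×8) before giving up.
    """
    coords = np.asarray(coords, dtype=float)
    pressures = np.asarray(pressures, dtype=float)
    prox, seg_d, region_d, local = _ffr_slab_geometry(tree, distal_offset)

    m_entry = region == "lad_proximal"
    if not np.any(m_entry):
        raise EvaluationError("no points in the LAD entry region")
    pos_entry = _project_axial(tree, prox, coords[m_entry])
    half = slab_frac * prox.length / 2.0
    p_entry = _slab_mean(pressures[m_entry], pos_entry, half, half, min_points)

    m_d = region == region_d
    if not np.any(m_d):
        raise EvaluationError(f"no points in region {region_d!r} for distal slab")
    pos_d = _project_axial(tree, seg_d, coords[m_d])
    half_d = slab_frac * seg_d.length / 2.0
    p_dist = _slab_mean(pressures[m_d], pos_d, local, half_d, min_points)

    return float((p_dist + reference_pressure) / (p_entry + reference_pressure))


def graft_flow(
    tree: VesselTree,
    velocity_source,
    n_slab_points: int = 20000,
    seed: int = 0,
    slab_frac: float = 0.05,
) -> float:
    """Graft inlet flow (m³/s): mean axial velocity over the inlet slab × πd²/4.

    ``velocity_source`` is either a :class:`NetworkSolution` (velocities come
    from the oracle profile) or a callable mapping coordinates (N×3) to
    velocity vectors (N×3), e.g. a trained network's predictor.  The slab is
    sampled uniformly over the lumen cross-section near the graft inlet.
    """
    grafts = tree.segments_by_role("graft")
    if not grafts:
        raise PreconditionError("tree has no graft segment")
    seg = grafts[0]
    rng = child_rng(seed, "graftslab")
    u = rng.uniform(0.0, slab_frac, size=n_slab_points)
    rho = np.sqrt(rng.uniform(0.0, 1.0, size=n_slab_points))
    rho = np.minimum(rho, 1.0 - 1e-12)
    th = rng.uniform(0.0, 2 * np.pi, size=n_slab_points)
    if isinstance(velocity_source, NetworkSolution):
        v = velocities_at(
            tree, velocity_source, np.full(n_slab_points, seg.id, dtype=object), u, rho
        )
    else:
        c = tree.point_at(seg, u)
        _, n1, n2 = tree.frame_at(seg, u)
        x = tree.axial_position(seg, u)
        r = seg.radius_at(x)
        coords = c + (rho * r)[:, None] * (
            np.cos(th)[:, None] * n1 + np.sin(th)[:, None] * n2
        )
        v = np.asarray(velocity_source(coords), dtype=float)
    t = tree.tangent_at(seg, u)
    axial = np.einsum("ij,ij->i", v, t)
    return float(axial.mean() * np.pi * seg.radius**2)


# ---------------------------------------------------------------------------
# Method agreement
# ---------------------------------------------------------------------------


@dataclass
class AgreementStats:
    pearson_r: float
    p_value: float
    mean_difference: float
    loa_low: float
    loa_high: float
    n: int
    n_within_limits: int


def agreement(values_a, values_b) -> AgreementStats:
    """Pearson correlation plus Bland–Altman limits of agreement.

    Differences are ``a − b``; limits are mean ± 1.96 × population SD.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise UserInputError("agreement needs two equal-length 1-D arrays")
    n = len(a)
    if n < 3:
        raise UserInputError("agreement needs n >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise EvaluationError("Pearson r undefined: zero variance input")
    r, p = sps.pearsonr(a, b)
    d = a - b
    mean_d = float(d.mean())
    sd = float(d.std(ddof=0))
    lo, hi = mean_d - 1.96 * sd, mean_d + 1.96 * sd
    within = int(np.sum((d >= lo) & (d <= hi)))
    return AgreementStats(
        pearson_r=float(r),
        p_value=float(p),
        mean_difference=mean_d,
        loa_low=float(lo),
        loa_high=float(hi),
        n=n,
        n_within_limits=within,
    )


def bland_altman_plot(stats_or_pair, path):
    """Save a Bland–Altman plot (means vs differences with limit lines)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a, b = stats_or_pair
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    st = agreement(a, b)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2, a - b, s=12, alpha=0.7)
    for y, style in ((st.mean_difference, "-"), (st.loa_low, "--"), (st.loa_high, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (a − b)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return st


# ---------------------------------------------------------------------------
# Vorticity / error attribution
# ---------------------------------------------------------------------------


@dataclass
class VortexField:
    magnitude: np.ndarray  # |curl u| per point, 1/s
    mask: np.ndarray  # magnitude > threshold (False where flagged)
    flagged: np.ndarray  # degenerate neighborhoods, excluded from mask
    threshold: float


def vorticity_field(
    coordinates: np.ndarray,
    velocities: np.ndarray,
    k_neighbors: int = 20,
    threshold: float | None = None,
) -> VortexField:
    """Per-point vorticity magnitude via weighted least-squares gradients.

    For each point the velocity-gradient tensor is fitted over its k nearest
    neighbors with Gaussian distance weights; vorticity is the curl of that
    fit.  Rank-deficient neighborhoods (e.g. coplanar points) are flagged and
    excluded from the vortex mask.  Default threshold: 90th percentile of the
    unflagged magnitudes.
    """
    coords = np.asarray(coordinates, dtype=float)
    vel = np.asarray(velocities, dtype=float)
    n = len(coords)
    if not (n > k_neighbors >= 10):
        raise UserInputError("need N > k_neighbors >= 10")
    tree = cKDTree(coords)
    dist, idx = tree.query(coords, k=k_neighbors + 1)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    dx = coords[idx] - coords[:, None, :]  # (n, k, 3)
    dv = vel[idx] - vel[:, None, :]
    h = np.maximum(dist.mean(axis=1, keepdims=True), 1e-300)
    w = np.exp(-((dist / h) ** 2))  # (n, k)
    wdx = w[:, :, None] * dx
    M = np.einsum("nka,nkb->nab", wdx, dx)
    rhs = np.einsum("nka,nkb->nab", wdx, dv)
    eig = np.linalg.eigvalsh(M)
    flagged = (eig[:, 0] <= 1e-10 * np.maximum(eig[:, -1], 1e-300)) | ~np.isfinite(
        eig
    ).all(axis=1)
    M_safe = np.where(flagged[:, None, None], np.eye(3)[None], M)
    G = np.linalg.solve(M_safe, rhs)  # G[n, a, b] ≈ ∂u_b/∂x_a
    curl = np.stack(
        [
            G[:, 1, 2] - G[:, 2, 1],
            G[:, 2, 0] - G[:, 0, 2],
            G[:, 0, 1] - G[:, 1, 0],
        ],
        axis=1,
    )
    mag = np.linalg.norm(curl, axis=1)
    mag[flagged] = 0.0
    if threshold is None:
        ok = mag[~flagged]
        threshold = float(np.percentile(ok, 90)) if len(ok) else 0.0
    mask = (mag > threshold) & ~flagged
    return VortexField(magnitude=mag, mask=mask, flagged=flagged, threshold=float(threshold))


@dataclass
class OverlapStats:
    n_high_error: int
    n_vortex: int
    vortex_fraction: float
    overlap: float  # fraction of high-error points inside the vortex mask (NaN if none)
    per_region: dict = field(default_factory=dict)


def high_error_overlap(
    point_mre_percent: np.ndarray,
    vortex_mask: np.ndarray,
    error_threshold: float = 10.0,
    region: np.ndarray | None = None,
) -> OverlapStats:
    """How much of the high-error point set falls inside the vortex mask."""
    err = np.asarray(point_mre_percent, dtype=float)
    mask = np.asarray(vortex_mask, dtype=bool)
    if err.shape != mask.shape:
        raise UserInputError("error and mask arrays must align")
    high = err > error_threshold
    n_high = int(high.sum())
    overlap = float(mask[high].mean()) if n_high else float("nan")
    per_region = {}
    if region is not None:
        region = np.asarray(region)
        for r in np.unique(region):
            m = region == r
            nh = int((high & m).sum())
            per_region[str(r)] = {
                "n_high_error": nh,
                "overlap": float(mask[high & m].mean()) if nh else float("nan"),
            }
    return OverlapStats(
        n_high_error=n_high,
        n_vortex=int(mask.sum()),
        vortex_fraction=float(mask.mean()),
        overlap=overlap,
        per_region=per_region,
    )


# ---------------------------------------------------------------------------
# Training-set-size sweep
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    fractions: list[float]
    mre_values: list[float]
    spearman_rho: float
    spearman_p: float

    def to_csv(self, path):
        pd.DataFrame({"fraction": self.fractions, "mre": self.mre_values}).to_csv(
            path, index=False
        )


def region_mre(samples, predictions, region: str) -> float:
    """Mean over models of the region-local MRE."""
    vals = []
    for s, pred in zip(samples, predictions):
        m = s.query.region == region
        if np.any(m):
            vals.append(mre(s.query.targets[m], np.asarray(pred)[m]))
    if not vals:
        raise EvaluationError(f"region {region!r} absent from every model")
    return float(np.mean(vals))


def sweep_fraction_seed(seed: int, k: int) -> int:
    """Derived network seed used for the k-th fraction of a sweep."""
    return int(child_seed(seed, "fit", k).generate_state(1)[0] % (2**31))


def training_size_sweep(
    corpus,
    config,
    fractions=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    region: str = "aorta_and_branches",
    seed: int = 0,
) -> SweepResult:
    """Fix the test set, train fresh networks on growing nested subsets of
    the training models, and track the region MRE (learning curve).

    Subsets are nested (a random order is drawn once, then prefixes taken)
    and keep the corpus ordering, so fraction 1.0 reproduces a standard
    training run with the same derived seed exactly.
    """
    import dataclasses

    from .network import PointNetRegressor, train_network

    n = len(corpus.train)
    order = child_rng(seed, "subset").permutation(n)
    used_fracs, mres = [], []
    for k, f in enumerate(fractions):
        n_sub = int(np.ceil(f * n))
        if n_sub < 1:
            warnings.warn(f"fraction {f} yields no training models; skipped")
            continue
        sub = [corpus.train[i] for i in sorted(order[:n_sub])]
        cfg = dataclasses.replace(config, seed=sweep_fraction_seed(seed, k))
        model = PointNetRegressor(cfg)

        class _Sub:
            train = sub

        train_network(model, _Sub, cfg)
        preds = [
            model.predict(s.surface.coordinates, s.query.coordinates)
            for s in corpus.test
        ]
        used_fracs.append(float(f))
        mres.append(region_mre(corpus.test, preds, region))
    if len(used_fracs) >= 2:
        rho, p = sps.spearmanr(used_fracs, mres)
    else:
        rho, p = float("nan"), float("nan")
    return SweepResult(
        fractions=used_fracs,
        mre_values=mres,
        spearman_rho=float(rho),
        spearman_p=float(p),
    )
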