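"""Corpus assembly, train/test splitting and CSV persistence.

A corpus is a set of :class:`HemodynamicSample` objects, one per vessel
model: the wall ("model") point cloud, the interior ("query") point cloud
with 3-component targets and anatomical region labels, and metadata.  Four
independent corpora exist per study (preoperative/postoperative × velocity/
pressure) and are trained separately.

The canonical interchange format is plain CSV (comma-separated, header row,
UTF-8, '.' decimal): ``x,y,z`` for surface clouds and
``x,y,z,tx,ty,tz,region`` for query clouds, written with 17 significant
digits so round-trips are lossless to 1e−12 relative.  Coordinates and
targets are deliberately NOT normalized.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seeds import child_seed
from .exceptions import ConfigurationError, FormatError, UserInputError
from .geometry import (
    GeometryRanges,
    InteriorPoints,
    SurfacePointCloud,
    VesselTree,
    add_graft,
    expand_model,
    make_base_tree,
)
from .flow import BoundaryConditions, FluidProperties, make_sample

__all__ = [
    "QueryPointCloud",
    "HemodynamicSample",
    "CorpusSplit",
    "CorpusConfig",
    "build_corpus",
    "write_sample",
    "read_sample",
    "write_corpus",
    "read_corpus",
    "pressure_to_components",
]

_FLOAT_FMT = "%.17g"
_SURFACE_COLS = ["x", "y", "z"]
_QUERY_COLS = ["x", "y", "z", "tx", "ty", "tz", "region"]


@dataclass
class QueryPointCloud:
    """Interior points with 3-component hemodynamic targets.

    For pressure fields every target row holds three identical components
    (the scalar replicated), mirroring the velocity layout so one network
    architecture serves both field kinds.
    """

    coordinates: np.ndarray
    targets: np.ndarray
    region: np.ndarray

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        self.region = np.asarray(self.region)
        n = len(self.coordinates)
        if n < 1 or self.coordinates.shape != (n, 3):
            raise UserInputError("query coordinates must be N x 3, N >= 1")
        if self.targets.shape != (n, 3):
            raise UserInputError("query targets must be N x 3")
        if self.region.shape != (n,):
            raise UserInputError("region labels must be length N")
        if not (np.all(np.isfinite(self.coordinates)) and np.all(np.isfinite(self.targets))):
            raise UserInputError("query cloud contains non-finite values")

    def __len__(self):
        return len(self.coordinates)


@dataclass
class HemodynamicSample:
    """One model's paired clouds plus metadata.

    ``tree``, ``solution`` and ``interior`` are in-memory conveniences (kept
    when the sample was generated by the oracle, absent after CSV reload);
    persistence carries only clouds + metadata.
    """

    surface: SurfacePointCloud
    query: QueryPointCloud
    op_state: str
    field_kind: str
    model_id: str
    base_model_id: str
    tree: VesselTree | None = None
    solution: object | None = None
    interior: InteriorPoints | None = None

    def __post_init__(self):
        if self.field_kind == "pressure":
            t = self.query.targets
            if not np.allclose(t[:, 0], t[:, 1]) or not np.allclose(t[:, 0], t[:, 2]):
                raise UserInputError(
                    "pressure sample targets must replicate the scalar in 3 components"
                )

    @property
    def scalar_targets(self) -> np.ndarray:
        """Scalar view of the targets (mean of the three components)."""
        return self.query.targets.mean(axis=1)


@dataclass
class CorpusSplit:
    """Train/test corpora with structural split hygiene.

    No ``base_model_id`` may appear on both sides: variants expanded from one
    base anatomy always live in the same split.
    """

    train: list[HemodynamicSample]
    test: list[HemodynamicSample]

    def __post_init__(self):
        shared = {s.base_model_id for s in self.train} & {
            s.base_model_id for s in self.test
        }
        if shared:
            raise UserInputError(
                f"base models shared between train and test: {sorted(shared)}"
            )


def pressure_to_components(pressures) -> np.ndarray:
    """Replicate N scalar pressures into an N × 3 array of equal components."""
    p = np.asarray(pressures, dtype=float)
    if p.ndim != 1:
        p = p.reshape(-1)
    if not np.all(np.isfinite(p)):
        raise UserInputError("non-finite pressure values")
    return np.repeat(p[:, None], 3, axis=1)


# ---------------------------------------------------------------------------
# Corpus construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorpusConfig:
    """Generation settings for one corpus (single op_state × field_kind)."""

    n_base_train: int = 10
    n_base_test: int = 2
    expansions_per_base: int = 10
    op_state: str = "preoperative"
    field_kind: str = "velocity"
    n_query: int = 2048
    surface_density: float = 0.03  # points per mm^2 (~512 pts on a base model)
    ranges: GeometryRanges = field(default_factory=GeometryRanges)
    bc: BoundaryConditions = field(default_factory=BoundaryConditions)
    fluid: FluidProperties = field(default_factory=FluidProperties)

    def __post_init__(self):
        if min(self.n_base_train, self.n_base_test, self.expansions_per_base) < 1:
            raise ConfigurationError("corpus counts must be >= 1")
        if self.op_state not in ("preoperative", "postoperative"):
            raise ConfigurationError(f"unknown op_state {self.op_state!r}")
        if self.field_kind not in ("velocity", "pressure"):
            raise ConfigurationError(f"unknown field_kind {self.field_kind!r}")


def build_corpus(config: CorpusConfig, master_seed: int) -> CorpusSplit:
    """Generate, expand and solve the full corpus from one master seed.

    Base trees cycle through the built-in templates; each base is expanded
    into ``expansions_per_base`` variants which all inherit its split
    membership, so the split invariant holds by construction.  Fully
    reproducible: every random draw derives from ``master_seed`` through the
    documented seed-splitting rule.
    """
    n_total = config.n_base_train + config.n_base_test

    def make_for_base(i: int) -> list[HemodynamicSample]:
        base_id = f"base{i:04d}"
        base_seed = int(child_seed(master_seed, "base", i).generate_state(1)[0] % (2**31))
        base = make_base_tree(i % 3, base_seed)
        exp_seed = int(child_seed(master_seed, "expand", i).generate_state(1)[0] % (2**31))
        variants = expand_model(base, config.ranges, config.expansions_per_base, exp_seed)
        samples = []
        for j, tree in enumerate(variants):
            if config.op_state == "postoperative":
                graft_seed = int(
                    child_seed(master_seed, "graft", i, j).generate_state(1)[0] % (2**31)
                )
                tree = add_graft(tree, graft_seed, config.ranges.graft_diameter_mm)
            s_seed = int(
                child_seed(master_seed, "sample", i, j).generate_state(1)[0] % (2**31)
            )
            samples.append(
                make_sample(
                    tree,
                    config.bc,
                    config.fluid,
                    config.n_query,
                    config.surface_density,
                    config.field_kind,
                    s_seed,
                    model_id=f"{base_id}_v{j:02d}",
                    base_model_id=base_id,
                )
            )
        return samples

    train: list[HemodynamicSample] = []
    test: list[HemodynamicSample] = []
    for i in range(n_total):
        samples = make_for_base(i)
        (train if i < config.n_base_train else test).extend(samples)
    return CorpusSplit(train=train, test=test)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def _read_table(path: Path, expected_cols: list[str], kind: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as e:
        raise FormatError(f"{path}: unreadable CSV ({e})") from e
    if list(df.columns) != expected_cols:
        raise FormatError(
            f"{path}: {kind} cloud must have exactly columns {expected_cols}, "
            f"found {list(df.columns)}",
            line=1,
        )
    numeric = [c for c in expected_cols if c != "region"]
    out = {}
    for c in numeric:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.index[vals.isna() & df[c].notna()]
        if len(bad) or vals.isna().any():
            row = int((vals.isna()).idxmax())
            raise FormatError(f"{path}: non-numeric value in column {c!r}", line=row + 2)
        out[c] = vals.to_numpy()
    if "region" in expected_cols:
        out["region"] = df["region"].to_numpy()
    return pd.DataFrame(out)


def write_sample(path, sample: HemodynamicSample) -> None:
    """Write one sample as a directory: surface.csv, query.csv, meta.yaml."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(sample.surface.coordinates, columns=_SURFACE_COLS).to_csv(
        d / "surface.csv", index=False, float_format=_FLOAT_FMT
    )
    q = pd.DataFrame(sample.query.coordinates, columns=["x", "y", "z"])
    q[["tx", "ty", "tz"]] = sample.query.targets
    q["region"] = sample.query.region
    q.to_csv(d / "query.csv", index=False, float_format=_FLOAT_FMT)
    meta = {
        "op_state": sample.op_state,
        "field_kind": sample.field_kind,
        "model_id": sample.model_id,
        "base_model_id": sample.base_model_id,
    }
    with open(d / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
    if sample.tree is not None:
        from .geometry import tree_to_yaml

        tree_to_yaml(sample.tree, d / "tree.yaml")


def read_sample(path) -> HemodynamicSample:
    """Read a sample directory written by :func:`write_sample`."""
    d = Path(path)
    if not d.is_dir():
        raise FormatError(f"sample directory not found: {d}")
    surf_df = _read_table(d / "surface.csv", _SURFACE_COLS, "surface")
    q_df = _read_table(d / "query.csv", _QUERY_COLS, "query")
    with open(d / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    tree = None
    if (d / "tree.yaml").exists():
        from .geometry import tree_from_yaml

        tree = tree_from_yaml(d / "tree.yaml")
    return HemodynamicSample(
        surface=SurfacePointCloud(surf_df[["x", "y", "z"]].to_numpy()),
        query=QueryPointCloud(
            coordinates=q_df[["x", "y", "z"]].to_numpy(),
            targets=q_df[["tx", "ty", "tz"]].to_numpy(),
            region=q_df["region"].to_numpy(),
        ),
        op_state=meta["op_state"],
        field_kind=meta["field_kind"],
        model_id=meta["model_id"],
        base_model_id=meta["base_model_id"],
        tree=tree,
    )


def config_hash(config: CorpusConfig, master_seed: int) -> str:
    blob = json.dumps(
        {
            "config": {
                k: (dataclass_dict(v) if hasattr(v, "__dataclass_fields__") else v)
                for k, v in dataclass_dict(config).items()
            },
            "master_seed": master_seed,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def dataclass_dict(obj):
    import dataclasses

    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}


def write_corpus(split: CorpusSplit, path, config: CorpusConfig | None = None,
                 master_seed: int | None = None) -> None:
    """Write every sample plus a manifest naming paths, split and settings."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {"train": [], "test": [], "format_version": 1}
    if config is not None and master_seed is not None:
        manifest["config_hash"] = config_hash(config, master_seed)
        manifest["master_seed"] = master_seed
    for split_name in ("train", "test"):
        for s in getattr(split, split_name):
            rel = f"{split_name}/{s.model_id}"
            write_sample(d / rel, s)
            manifest[split_name].append(
                {"path": rel, "model_id": s.model_id, "base_model_id": s.base_model_id}
            )
    with open(d / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_corpus(path) -> CorpusSplit:
    d = Path(path)
    mf = d / "manifest.yaml"
    if not mf.exists():
        raise FormatError(f"no manifest.yaml under {d}")
    with open(mf) as fh:
        manifest = yaml.safe_load(fh)
    train = [read_sample(d / e["path"]) for e in manifest.get("train", [])]
    test = [read_sample(d / e["path"]) for e in manifest.get("test", [])]
    return CorpusSplit(train=train, test=test)  # split hygiene re-checked here


def write_ply(cloud_coords: np.ndarray, path) -> None:
    """ASCII vertex-only PLY export for viewers."""
    coords = np.asarray(cloud_coords, dtype=float)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(coords)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\nend_header\n")
        for row in coords:
            fh.write(f"{row[0]:.9g} {row[1]:.9g} {row[2]:.9g}\n")
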