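"""Synthetic phantoms and cohorts with known ground truth.

Two generators make every pipeline stage testable without imaging data:

* :func:`make_phantom` builds a tractogram of straight or arced streamline
  bundles between cuboid nodes on a voxel grid, with uniform in-corridor
  seeding and optional single-streamline spurious connections, returning
  the ground-truth edge membership;
* :func:`make_cohort` draws per-subject connectomes for three groups
  (control / PD without memory impairment / PD with memory impairment)
  from one log-normal base network, with configurable global strength
  multipliers, an extra focal reduction on a designated node set, and
  cognitive composites tied to network strength and education through a
  Gaussian copula so that target rank correlations hold in expectation.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .connectome import Connectome, _traversed_voxels
from .parcellation import NodeRegion, dk82_labels, focal_27_node_ids
from .tractogram import Streamline, Tractogram, VoxelGrid

__all__ = [
    "Bundle",
    "PhantomSpec",
    "Phantom",
    "CohortSpec",
    "make_phantom",
    "make_cohort",
    "make_pvalue_mixture",
]


# ---------------------------------------------------------------------------
# phantom tractograms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Bundle:
    """A streamline bundle between two phantom nodes."""

    node_i: int
    node_j: int
    count: int = 50
    geometry: str = "straight"  # "straight" | "arc"
    arc_offset_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("bundle count must be >= 0")
        if self.geometry not in {"straight", "arc"}:
            raise ValueError(f"unknown bundle geometry {self.geometry!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and seeding of a synthetic tractography phantom.

    Nodes are cubes of ``node_extent`` voxels per side laid out along the
    x axis with center spacing ``node_spacing_mm`` (a multiple of the
    voxel edge), so a default chain bundle has arc length exactly equal to
    the spacing.  ``p_voxel`` seed points per voxel echoes uniform
    per-voxel seeding paradigms (125 seeds per voxel is typical for
    whole-brain tracking; the default here is a desk-scale 25).
    ``spurious_rate`` adds, per unconnected node pair, a single-streamline
    arced false-positive connection with that probability.
    """

    n_nodes: int = 10
    node_extent: int = 2
    node_spacing_mm: float = 20.0
    voxel_edge_mm: float = 2.0
    bundles: tuple[Bundle, ...] | None = None
    p_voxel: int = 25
    spurious_rate: float = 0.0
    spurious_count: int = 1
    spurious_arc_offset_mm: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("a phantom needs at least two nodes")
        if self.p_voxel < 1:
            raise ValueError("p_voxel must be >= 1")
        if not 0 <= self.spurious_rate <= 1:
            raise ValueError("spurious_rate must lie in [0, 1]")
        spacing_vox = self.node_spacing_mm / self.voxel_edge_mm
        if abs(spacing_vox - round(spacing_vox)) > 1e-9:
            raise ValueError("node spacing must be a multiple of the voxel edge")
        if round(spacing_vox) < self.node_extent:
            raise ValueError("node cuboids overlap: spacing smaller than node extent")

    def resolved_bundles(self) -> tuple[Bundle, ...]:
        if self.bundles is not None:
            return self.bundles
        return tuple(Bundle(k, k + 1) for k in range(self.n_nodes - 1))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "bundles" in raw and raw["bundles"] is not None:
            raw["bundles"] = tuple(Bundle(**b) for b in raw["bundles"])
        return cls(**raw)


@dataclass
class Phantom:
    """A generated phantom with its ground truth."""

    tractogram: Tractogram
    parcellation: list[NodeRegion]
    bundle_members: dict[tuple[int, int], list[int]]
    spurious_pairs: list[tuple[int, int]]


def _phantom_geometry(spec: PhantomSpec):
    e = spec.voxel_edge_mm
    ext = spec.node_extent
    spacing_vox = round(spec.node_spacing_mm / e)
    margin = 2
    max_offset = max(
        [b.arc_offset_mm for b in spec.resolved_bundles() if b.geometry == "arc"]
        + [spec.spurious_arc_offset_mm if spec.spurious_rate > 0 else 0.0]
        + [0.0]
    )
    off_vox = int(math.ceil(max_offset / e)) + 2
    nx = 2 * margin + (spec.n_nodes - 1) * spacing_vox + ext
    ny = margin + ext + off_vox
    nz = 2 * margin + ext
    grid = VoxelGrid((nx, ny, nz), (e, e, e))
    side = ext * e
    area = 6.0 * side * side
    nodes = []
    for m in range(spec.n_nodes):
        x0 = margin + m * spacing_vox
        voxels = frozenset(
            (x0 + dx, margin + dy, margin + dz)
            for dx in range(ext)
            for dy in range(ext)
            for dz in range(ext)
        )
        nodes.append(
            NodeRegion(
                node_id=m,
                label=f"node{m:02d}",
                hemisphere="none",
                surface_area_mm2=area,
                voxel_members=voxels,
            )
        )
    centers = {
        m: np.array(
            [
                (margin + m * spacing_vox + ext / 2.0) * e,
                (margin + ext / 2.0) * e,
                (margin + ext / 2.0) * e,
            ]
        )
        for m in range(spec.n_nodes)
    }
    return grid, nodes, centers


def _polyline(ci: np.ndarray, cj: np.ndarray, geometry: str, offset_mm: float) -> np.ndarray:
    if geometry == "straight":
        return np.vstack([ci, cj])
    # quadratic Bezier arcing in +y; midpoint offset equals offset_mm
    ctrl = 0.5 * (ci + cj) + np.array([0.0, 2.0 * offset_mm, 0.0])
    t = np.linspace(0.0, 1.0, 33)[:, None]
    return (1 - t) ** 2 * ci + 2 * t * (1 - t) * ctrl + t**2 * cj


def _seed_point_in_voxel(points: np.ndarray, grid: VoxelGrid, voxel) -> np.ndarray:
    """First densely-resampled point of the polyline inside ``voxel``."""
    step = min(grid.voxel_edges) / 8.0
    seg = np.diff(points, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    for k in range(len(seg)):
        n = max(int(np.ceil(seg_len[k] / step)), 1)
        for frac in np.arange(n + 1) / n:
            pt = points[k] + frac * seg[k]
            if grid.voxel_of(pt) == tuple(voxel):
                return pt
    raise RuntimeError(f"polyline does not visit voxel {voxel}")  # pragma: no cover


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Generate a phantom tractogram, its parcellation and ground truth."""
    grid, nodes, centers = _phantom_geometry(spec)
    node_voxels = set().union(*(n.voxel_members for n in nodes))
    rng_bundle, rng_spur = (
        np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(2)
    )
    streamlines: list[Streamline] = []
    bundle_members: dict[tuple[int, int], list[int]] = {}

    def emit(i: int, j: int, count: int, geometry: str, offset: float, rng) -> list[int]:
        path = _polyline(centers[i], centers[j], geometry, offset)
        corridor = sorted(_traversed_voxels(path, grid) - node_voxels)
        if not corridor:
            raise ValueError(f"bundle {i}-{j} has no corridor voxels")
        refs = []
        for _ in range(count):
            voxel = corridor[int(rng.integers(len(corridor)))]
            seed_idx = int(rng.integers(1, spec.p_voxel + 1))
            streamlines.append(Streamline(path.copy(), voxel, seed_idx))
            refs.append(len(streamlines) - 1)
        return refs

    bundle_pairs = set()
    for b in spec.resolved_bundles():
        pair = (min(b.node_i, b.node_j), max(b.node_i, b.node_j))
        bundle_pairs.add(pair)
        refs = emit(pair[0], pair[1], b.count, b.geometry, b.arc_offset_mm, rng_bundle)
        bundle_members.setdefault(pair, []).extend(refs)

    spurious_pairs: list[tuple[int, int]] = []
    if spec.spurious_rate > 0:
        for i in range(spec.n_nodes):
            for j in range(i + 1, spec.n_nodes):
                if (i, j) in bundle_pairs:
                    continue
                if rng_spur.random() < spec.spurious_rate:
                    emit(i, j, spec.spurious_count, "arc", spec.spurious_arc_offset_mm, rng_spur)
                    spurious_pairs.append((i, j))

    tract = Tractogram(grid, streamlines, spec.p_voxel)
    return Phantom(tract, nodes, bundle_members, spurious_pairs)


# ---------------------------------------------------------------------------
# grouped cohorts
# ---------------------------------------------------------------------------

def _default_group_sizes() -> dict[str, int]:
    return {"control": 40, "pd_well": 31, "pd_mi": 9}


def _default_multipliers() -> dict[str, float]:
    # 1 - 0.0499 and 1 - 0.1323: the injected global strength reductions
    return {"control": 1.0, "pd_well": 0.9501, "pd_mi": 0.8677}


def _default_strength_corr() -> dict[tuple[str, str], float]:
    return {
        ("control", "working_memory"): 0.22,
        ("control", "processing_speed"): 0.02,
        ("control", "memory"): 0.23,
        ("pd_well", "working_memory"): -0.52,
        ("pd_well", "processing_speed"): 0.17,
        ("pd_well", "memory"): -0.18,
        ("pd_well", "updrs_iii"): 0.01,
        ("pd_mi", "working_memory"): -0.30,
        ("pd_mi", "processing_speed"): -0.53,
        ("pd_mi", "memory"): 0.12,
        ("pd_mi", "updrs_iii"): 0.68,
    }


def _default_education_corr() -> dict[str, float]:
    return {
        "working_memory": 0.30,
        "processing_speed": 0.30,
        "memory": 0.30,
        "updrs_iii": 0.0,
    }


def _default_demographics() -> dict[str, dict[str, tuple[float, float]]]:
    return {
        "control": {"education": (16.75, 2.35), "age": (68.18, 4.64)},
        "pd_well": {"education": (16.8, 2.91), "age": (67.3, 5.02), "updrs_iii": (18.2, 11.6)},
        "pd_mi": {"education": (14.3, 2.74), "age": (69.4, 6.77), "updrs_iii": (15.7, 7.25)},
    }


def _default_composites() -> dict[str, dict[str, tuple[float, float]]]:
    return {
        "control": {"working_memory": (1.15, 0.55), "processing_speed": (0.16, 0.47), "memory": (0.0, 1.0)},
        "pd_well": {"working_memory": (0.89, 0.77), "processing_speed": (-0.42, 0.56), "memory": (-0.32, 0.70)},
        "pd_mi": {"working_memory": (0.27, 0.57), "processing_speed": (-0.68, 0.76), "memory": (-1.76, 0.20)},
    }


@dataclass
class CohortSpec:
    """Statistical structure of a synthetic three-group cohort.

    One base network (fixed support at the target density, log-normal
    weights) is shared by all subjects; each subject's connectome is the
    base scaled by a group strength multiplier, a per-subject log-normal
    factor and per-edge log-normal noise (both mean-one).  Groups in
    ``focal_groups`` additionally shrink edges incident to the
    ``focal_nodes`` set by ``focal_multiplier``; the matrix is then
    rescaled so the expected global mean strength still equals the group
    multiplier times the base value, keeping the injected global contrast
    exact while the focal nodes carry the largest local differences.
    """

    group_sizes: dict[str, int] = field(default_factory=_default_group_sizes)
    n_nodes: int = 82
    density: float = 0.40
    weight_log_mu: float = math.log(1e-3)
    weight_log_sigma: float = 1.0
    strength_multipliers: dict[str, float] = field(default_factory=_default_multipliers)
    focal_nodes: tuple[int, ...] | None = None
    focal_multiplier: float = 0.85
    focal_groups: tuple[str, ...] = ("pd_mi",)
    subject_sigma: float = 0.10
    edge_sigma: float = 0.20
    strength_corr: dict[tuple[str, str], float] = field(default_factory=_default_strength_corr)
    education_corr: dict[str, float] = field(default_factory=_default_education_corr)
    demographics: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_default_demographics
    )
    composites: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_default_composites
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.density < 1:
            raise ValueError("density must lie in (0, 1)")
        sizes = list(self.group_sizes.values())
        if any(s < 2 for s in sizes) or min(sizes) < 5:
            raise ValueError("all groups need >= 2 subjects and the smallest >= 5")
        for g, m in self.strength_multipliers.items():
            if not 0 < m <= 1:
                raise ValueError(f"strength multiplier for {g!r} must lie in (0, 1]")
        if not 0 < self.focal_multiplier <= 1:
            raise ValueError("focal multiplier must lie in (0, 1]")
        for key, rho in self.strength_corr.items():
            if not -1 < rho < 1:
                raise ValueError(f"correlation target {key} outside (-1, 1)")
        for key, rho in self.education_corr.items():
            if not -1 < rho < 1:
                raise ValueError(f"education correlation target {key} outside (-1, 1)")

    def resolved_focal_nodes(self) -> tuple[int, ...]:
        if self.focal_nodes is not None:
            return tuple(self.focal_nodes)
        if self.n_nodes == 82:
            return tuple(focal_27_node_ids())
        return ()

    def node_labels(self) -> list[str]:
        if self.n_nodes == 82:
            return [
                ("left " if r["hemisphere"] == "left" else "right ") + r["label"]
                for r in dk82_labels()
            ]
        return [f"node{k:03d}" for k in range(self.n_nodes)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "strength_corr" in raw:
            raw["strength_corr"] = {
                (k.split("/")[0], k.split("/")[1]): v for k, v in raw["strength_corr"].items()
            }
        for key in ("focal_nodes", "focal_groups"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _normal_scores(values: np.ndarray) -> np.ndarray:
    n = len(values)
    ranks = stats.rankdata(values)
    return stats.norm.ppf((ranks - 0.375) / (n + 0.25))


def _copula_coeff(rho_s: float) -> float:
    """Latent Pearson coefficient hitting a Spearman target in expectation."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def make_cohort(spec: CohortSpec) -> tuple[dict[str, Connectome], pd.DataFrame]:
    """Generate per-subject connectomes and the matching cohort table.

    Returns a mapping subject_id -> Connectome and a table with columns
    subject_id, group, age, education, updrs_iii (NaN for controls),
    working_memory, processing_speed, memory.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_base, rng_subj, rng_cog = (np.random.default_rng(s) for s in ss.spawn(3))
    n = spec.n_nodes
    labels = spec.node_labels()
    iu = np.triu_indices(n, k=1)
    n_pairs = len(iu[0])
    n_edges = int(round(spec.density * n_pairs))
    chosen = rng_base.choice(n_pairs, size=n_edges, replace=False)
    base_vals = np.zeros(n_pairs)
    base_vals[chosen] = rng_base.lognormal(spec.weight_log_mu, spec.weight_log_sigma, n_edges)
    base = np.zeros((n, n))
    base[iu] = base_vals
    base += base.T

    focal = np.array(spec.resolved_focal_nodes(), dtype=int)
    shaped: dict[str, np.ndarray] = {}
    for group in spec.group_sizes:
        M = base.copy()
        if group in spec.focal_groups and focal.size and spec.focal_multiplier < 1:
            mask = np.zeros(n, dtype=bool)
            mask[focal] = True
            incident = mask[:, None] | mask[None, :]
            M = np.where(incident, M * spec.focal_multiplier, M)
            M *= base.sum() / M.sum()  # keep the expected global mean strength
        shaped[group] = M * spec.strength_multipliers.get(group, 1.0)

    connectomes: dict[str, Connectome] = {}
    records: list[dict] = []
    mean_strengths: dict[str, list[float]] = {g: [] for g in spec.group_sizes}
    subject_ids: dict[str, list[str]] = {g: [] for g in spec.group_sizes}
    for group, size in spec.group_sizes.items():
        for k in range(size):
            sid = f"{group}_{k:03d}"
            subj_factor = math.exp(
                rng_subj.normal(0.0, spec.subject_sigma) - spec.subject_sigma**2 / 2.0
            )
            noise_u = np.exp(
                rng_subj.normal(0.0, spec.edge_sigma, n_pairs) - spec.edge_sigma**2 / 2.0
            )
            vals = shaped[group][iu] * subj_factor * noise_u
            W = np.zeros((n, n))
            W[iu] = vals
            W += W.T
            c = Connectome(labels, W)
            connectomes[sid] = c
            mean_strengths[group].append(float(W.sum(axis=1).mean()))
            subject_ids[group].append(sid)

    demo = spec.demographics
    comps = spec.composites
    for group, size in spec.group_sizes.items():
        g_demo = demo.get(group, {})
        edu_mu, edu_sd = g_demo.get("education", (16.0, 2.5))
        age_mu, age_sd = g_demo.get("age", (68.0, 5.0))
        education = rng_cog.normal(edu_mu, edu_sd, size)
        age = rng_cog.normal(age_mu, age_sd, size)
        z_strength = _normal_scores(np.array(mean_strengths[group]))
        z_edu = _normal_scores(education)
        measures: dict[str, np.ndarray] = {}
        measure_params = dict(comps.get(group, {}))
        if "updrs_iii" in g_demo:
            measure_params["updrs_iii"] = g_demo["updrs_iii"]
        for measure, (mu, sd) in measure_params.items():
            a = _copula_coeff(spec.strength_corr.get((group, measure), 0.0))
            b = _copula_coeff(spec.education_corr.get(measure, 0.0))
            resid = 1.0 - a * a - b * b
            if resid < 0:
                raise ValueError(
                    f"correlation targets for {group}/{measure} are jointly infeasible"
                )
            eps = rng_cog.normal(0.0, 1.0, size)
            latent = a * z_strength + b * z_edu + math.sqrt(resid) * eps
            measures[measure] = mu + sd * latent
        for k, sid in enumerate(subject_ids[group]):
            records.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "age": float(age[k]),
                    "education": float(education[k]),
                    "updrs_iii": float(measures["updrs_iii"][k])
                    if "updrs_iii" in measures
                    else float("nan"),
                    "working_memory": float(measures.get("working_memory", np.zeros(size))[k]),
                    "processing_speed": float(
                        measures.get("processing_speed", np.zeros(size))[k]
                    ),
                    "memory": float(measures.get("memory", np.zeros(size))[k]),
                }
            )
    return connectomes, pd.DataFrame(records)


def make_pvalue_mixture(
    n: int, pi0: float, effect: float, seed: int = 0
) -> np.ndarray:
    """n*pi0 uniform nulls plus n*(1-pi0) one-sided alternative p-values
    (survival probabilities of N(effect, 1) test statistics), shuffled."""
    if not 0 <= pi0 <= 1:
        raise ValueError("pi0 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n0 = int(round(n * pi0))
    nulls = rng.uniform(size=n0)
    alts = stats.norm.sf(rng.normal(effect, 1.0, n - n0))
    p = np.concatenate([nulls, alts])
    rng.shuffle(p)
    return p
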