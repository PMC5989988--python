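"""Node parcellations: gray-matter regions with voxel membership.

A parcellation is a list of :class:`NodeRegion`. The package ships the
82-region cortical + subcortical labelling (34 Desikan-Killiany cortical
regions and 7 subcortical structures per hemisphere) used for whole-brain
connectomes, together with the default 27-node focal set used by the
synthetic cohort generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "NodeRegion",
    "load_parcellation",
    "save_parcellation",
    "validate_parcellation",
    "dk82_labels",
    "focal_27_node_ids",
]

_HEMISPHERES = {"left", "right", "none"}


@dataclass(frozen=True)
class NodeRegion:
    """A parcellation node: label, hemisphere, surface area and voxels.

    ``surface_area_mm2`` is the node's surface area A_i entering the edge
    weight; ``voxel_members`` is the set of grid indices the region covers.
    """

    node_id: int
    label: str
    hemisphere: str
    surface_area_mm2: float
    voxel_members: frozenset[tuple[int, int, int]]

    def __post_init__(self) -> None:
        if self.hemisphere not in _HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {_HEMISPHERES}, got {self.hemisphere!r}")
        if not self.surface_area_mm2 > 0:
            raise ValueError(f"surface area must be positive, got {self.surface_area_mm2}")
        if not self.voxel_members:
            raise ValueError(f"node {self.label!r} has no member voxels")
        object.__setattr__(
            self, "voxel_members", frozenset(tuple(int(i) for i in v) for v in self.voxel_members)
        )

    @property
    def name(self) -> str:
        prefix = {"left": "left ", "right": "right ", "none": ""}[self.hemisphere]
        return prefix + self.label


def validate_parcellation(parcellation: Iterable[NodeRegion], grid=None) -> list[NodeRegion]:
    """Check id uniqueness, pairwise-disjoint voxel sets and grid bounds."""
    nodes = list(parcellation)
    ids = [n.node_id for n in nodes]
    if len(set(ids)) != len(ids):
        raise ValueError("node ids are not unique")
    seen: dict[tuple[int, int, int], int] = {}
    for n in nodes:
        for v in n.voxel_members:
            if v in seen:
                raise ValueError(
                    f"voxel {v} belongs to both node {seen[v]} and node {n.node_id}"
                )
            seen[v] = n.node_id
            if grid is not None and not grid.contains(v):
                raise ValueError(f"voxel {v} of node {n.node_id} outside grid {grid.shape}")
    return nodes


def save_parcellation(path: str | Path, parcellation: Iterable[NodeRegion]) -> None:
    payload = [
        {
            "id": n.node_id,
            "label": n.label,
            "hemisphere": n.hemisphere,
            "surface_area_mm2": n.surface_area_mm2,
            "voxels": sorted(list(v) for v in n.voxel_members),
        }
        for n in parcellation
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_parcellation(path: str | Path) -> list[NodeRegion]:
    payload = json.loads(Path(path).read_text())
    nodes = [
        NodeRegion(
            node_id=int(rec["id"]),
            label=str(rec["label"]),
            hemisphere=str(rec.get("hemisphere", "none")),
            surface_area_mm2=float(rec["surface_area_mm2"]),
            voxel_members=frozenset(tuple(int(i) for i in v) for v in rec["voxels"]),
        )
        for rec in payload
    ]
    return validate_parcellation(nodes)


def _labels_payload() -> dict:
    with resources.files("tractonet.data").joinpath("dk82_labels.json").open() as fh:
        return json.load(fh)


def dk82_labels() -> list[dict]:
    """The shipped 82-node labelling: id, label, hemisphere, type."""
    return _labels_payload()["nodes"]


def focal_27_node_ids() -> list[int]:
    """Node ids of the default 27-node focal set (bilateral putamen, caudal
    middle frontal, inferior parietal, postcentral, posterior cingulate,
    precentral, precuneus and rostral middle frontal, plus left pallidum,
    entorhinal, isthmus cingulate, middle temporal, pars opercularis,
    bankssts, supramarginal and superior temporal, and right lateral
    occipital, rostral anterior cingulate and superior parietal)."""
    return list(_labels_payload()["focal_27"])
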