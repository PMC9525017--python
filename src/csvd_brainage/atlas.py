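"""Composite brain atlas specification.

The analysis parcellates grey matter into named regions spanning three
compartments — cerebral cortex, subcortical grey matter and cerebellum —
with cortical parcels carrying one of the seven canonical large-scale
functional network labels (visual, somatomotor, dorsal attention, ventral
attention/salience, limbic, default mode, executive control).  The default
composition is 400 cortical + 14 subcortical + 28 cerebellar regions
(442 total).  The atlas defines how voxel-level grey-matter-volume (GMV)
feature columns group into regions, which in turn defines one regional
brain-age model per region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

SEVEN_NETWORKS: tuple[str, ...] = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "default_mode",
    "executive_control",
)

COMPARTMENTS: tuple[str, ...] = ("cortical", "subcortical", "cerebellar")


@dataclass(frozen=True)
class Region:
    """One atlas parcel.

    ``network`` is one of the seven canonical functional networks for
    cortical parcels, and the compartment name for subcortical and
    cerebellar parcels.
    """

    region_id: str
    name: str
    compartment: str
    network: str

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"Region {self.region_id!r}: compartment must be one of "
                f"{COMPARTMENTS}, got {self.compartment!r}"
            )


@dataclass
class AtlasSpec:
    """A named set of regions plus the voxel-feature count for each.

    Parameters
    ----------
    regions:
        Ordered parcels; ``region_id`` values must be unique.
    voxels_per_region:
        Number of voxel-level GMV feature columns per region (>= 1 each).
    """

    regions: list[Region]
    voxels_per_region: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate region_ids: {dupes}")
        if not self.regions:
            raise ValueError("atlas must contain at least one region")
        missing = [i for i in ids if i not in self.voxels_per_region]
        if missing:
            raise ValueError(f"voxels_per_region missing entries for: {missing}")
        bad = {i: v for i, v in self.voxels_per_region.items() if int(v) < 1}
        if bad:
            raise ValueError(f"every region needs >= 1 voxel feature, got {bad}")

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def compartment_of(self, region_id: str) -> str:
        return self._by_id[region_id].compartment

    def network_of(self, region_id: str) -> str:
        return self._by_id[region_id].network

    @property
    def _by_id(self) -> dict[str, Region]:
        return {r.region_id: r for r in self.regions}

    def compartment_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in COMPARTMENTS}
        for r in self.regions:
            counts[r.compartment] += 1
        return counts

    def voxel_columns(self, region_id: str) -> list[str]:
        """Feature-table column names for one region's voxel features."""
        if region_id not in self.voxels_per_region:
            raise KeyError(f"unknown region_id {region_id!r}")
        n = self.voxels_per_region[region_id]
        return [f"{region_id}__v{j:03d}" for j in range(n)]

    def all_voxel_columns(self) -> list[str]:
        cols: list[str] = []
        for r in self.regions:
            cols.extend(self.voxel_columns(r.region_id))
        return cols

    # ------------------------------------------------------------------ io
    def to_json(self, path: str | Path) -> None:
        payload = {
            "regions": [
                {
                    "region_id": r.region_id,
                    "name": r.name,
                    "compartment": r.compartment,
                    "network": r.network,
                    "n_voxels": self.voxels_per_region[r.region_id],
                }
                for r in self.regions
            ]
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "AtlasSpec":
        payload = json.loads(Path(path).read_text())
        regions = [
            Region(d["region_id"], d["name"], d["compartment"], d["network"])
            for d in payload["regions"]
        ]
        voxels = {d["region_id"]: int(d["n_voxels"]) for d in payload["regions"]}
        return cls(regions=regions, voxels_per_region=voxels)


def make_atlas(
    n_cortical: int = 400,
    n_subcortical: int = 14,
    n_cerebellar: int = 28,
    voxels_per_region: int = 10,
) -> AtlasSpec:
    """Build a composite atlas with the given compartment sizes.

    Cortical parcels cycle through the seven canonical networks;
    subcortical and cerebellar parcels carry their compartment as the
    network label.  Defaults give the 442-region composition
    (400 cortical, 14 subcortical, 28 cerebellar).
    """
    if min(n_cortical, n_subcortical, n_cerebellar) < 0:
        raise ValueError("compartment counts must be non-negative")
    if n_cortical + n_subcortical + n_cerebellar == 0:
        raise ValueError("atlas must contain at least one region")
    if voxels_per_region < 1:
        raise ValueError("voxels_per_region must be >= 1")
    regions: list[Region] = []
    for i in range(n_cortical):
        net = SEVEN_NETWORKS[i % len(SEVEN_NETWORKS)]
        rid = f"ctx{i + 1:03d}"
        regions.append(Region(rid, f"cortical_{net}_{i + 1}", "cortical", net))
    for i in range(n_subcortical):
        rid = f"sub{i + 1:03d}"
        regions.append(Region(rid, f"subcortical_{i + 1}", "subcortical", "subcortical"))
    for i in range(n_cerebellar):
        rid = f"cbl{i + 1:03d}"
        regions.append(Region(rid, f"cerebellar_{i + 1}", "cerebellar", "cerebellar"))
    voxels = {r.region_id: voxels_per_region for r in regions}
    return AtlasSpec(regions=regions, voxels_per_region=voxels)
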