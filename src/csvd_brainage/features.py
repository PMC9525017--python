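"""Grey-matter-volume feature container.

A :class:`FeatureSet` holds the voxel-level GMV feature matrix for a cohort
(one row per subject, columns grouped into atlas regions) and derives the
region-mean view used by the global brain-age model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import AtlasSpec


@dataclass
class FeatureSet:
    """Voxel-level GMV features keyed to subjects and atlas regions.

    ``voxels`` is indexed by subject_id with one column per voxel feature,
    named ``<region_id>__v<j>`` as given by ``atlas.voxel_columns``.
    """

    voxels: pd.DataFrame
    atlas: AtlasSpec

    def __post_init__(self) -> None:
        expected = self.atlas.all_voxel_columns()
        missing = [c for c in expected if c not in self.voxels.columns]
        extra = [c for c in self.voxels.columns if c not in set(expected)]
        if missing or extra:
            raise ValueError(
                f"feature columns do not match atlas; missing={missing[:5]}"
                f"{'...' if len(missing) > 5 else ''}, extra={extra[:5]}"
                f"{'...' if len(extra) > 5 else ''}"
            )
        # canonical column order
        self.voxels = self.voxels[expected]

    @property
    def subject_ids(self) -> np.ndarray:
        return self.voxels.index.to_numpy()

    @property
    def n_subjects(self) -> int:
        return len(self.voxels)

    def region_block(self, region_id: str) -> pd.DataFrame:
        """The voxel-feature columns of one region."""
        return self.voxels[self.atlas.voxel_columns(region_id)]

    def region_mean(self) -> pd.DataFrame:
        """Region-mean GMV: one column per region (global-model features)."""
        cols = {}
        for rid in self.atlas.region_ids:
            cols[rid] = self.voxels[self.atlas.voxel_columns(rid)].mean(axis=1)
        return pd.DataFrame(cols, index=self.voxels.index)
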