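"""Marker-based cerebral small vessel disease (CSVD) classification.

CSVD is defined on three MRI markers: white matter hyperintensity (WMH)
lesion load, lacunes and cerebral microbleeds (CMBs).  WMH volume is
normalised by total intracranial volume (TIV); a subject is classified as
CSVD when their WMH/TIV ratio is at or above the cohort's 50th percentile
AND they carry at least one lacune or at least one CMB.  The percentile is
empirical over the full analysed cohort, so the threshold is a property of
the cohort, not a fixed constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: empirical quantile convention used for the WMH-ratio split
QUANTILE_METHOD = "median_unbiased"

_ML_PER_UNIT = {"ml": 1.0, "l": 1000.0}


@dataclass(frozen=True)
class MarkerRecord:
    """CSVD marker measurements for one subject."""

    subject_id: str
    wmh_volume: float
    tiv: float
    lacune_count: int
    cmb_count: int
    wmh_unit: str = "ml"
    tiv_unit: str = "ml"

    def __post_init__(self) -> None:
        if self.wmh_volume < 0:
            raise ValueError(f"{self.subject_id}: wmh_volume must be >= 0")
        if self.tiv <= 0:
            raise ValueError(f"{self.subject_id}: tiv must be > 0")
        for nm, v in (("lacune_count", self.lacune_count), ("cmb_count", self.cmb_count)):
            if int(v) != v or v < 0:
                raise ValueError(f"{self.subject_id}: {nm} must be an integer >= 0")


def wmh_ratio(wmh_volume, tiv, wmh_unit: str = "ml", tiv_unit: str = "ml"):
    """Unitless WMH lesion load: WMH volume divided by TIV.

    Accepts scalars or arrays.  Volumes may be given in millilitres
    (``"ml"``) or litres (``"l"``); they are reconciled before division.
    """
    for unit in (wmh_unit, tiv_unit):
        if unit not in _ML_PER_UNIT:
            raise ValueError(f"unknown volume unit {unit!r}; use 'ml' or 'l'")
    wmh_ml = np.asarray(wmh_volume, dtype=float) * _ML_PER_UNIT[wmh_unit]
    tiv_ml = np.asarray(tiv, dtype=float) * _ML_PER_UNIT[tiv_unit]
    if np.any(tiv_ml <= 0):
        raise ValueError("tiv must be strictly positive")
    out = wmh_ml / tiv_ml
    return float(out) if out.ndim == 0 else out


@dataclass
class CsvdClassification:
    """Per-subject CSVD flags plus the threshold and rule provenance."""

    flags: pd.Series  # bool, indexed by subject_id
    threshold: float  # WMH/TIV ratio cut-off actually used
    percentile: float
    table: pd.DataFrame  # subject_id, wmh_ratio, lacune_count, cmb_count, csvd
    provenance: dict = field(default_factory=dict)

    @property
    def n_csvd(self) -> int:
        return int(self.flags.sum())

    def subgroup_counts(self) -> dict[str, int]:
        """Within the CSVD group: lacune-positive, CMB-positive, both.

        Satisfies the inclusion–exclusion identity
        ``n_lacune + n_cmb - n_both == n_csvd`` because every CSVD subject
        has at least one of the two lesion types by construction of the rule.
        """
        g = self.table[self.table["csvd"]]
        lac = g["lacune_count"] >= 1
        cmb = g["cmb_count"] >= 1
        return {
            "n_csvd": int(len(g)),
            "n_lacune": int(lac.sum()),
            "n_cmb": int(cmb.sum()),
            "n_both": int((lac & cmb).sum()),
        }


def _markers_frame(markers) -> pd.DataFrame:
    if isinstance(markers, pd.DataFrame):
        required = {"subject_id", "lacune_count", "cmb_count"}
        missing = sorted(required - set(markers.columns))
        if missing:
            raise ValueError(f"marker table missing columns: {missing}")
        df = markers.copy()
        if "wmh_ratio" not in df.columns:
            if not {"wmh_volume_ml", "tiv_l"} <= set(df.columns):
                raise ValueError(
                    "marker table needs either a wmh_ratio column or "
                    "wmh_volume_ml + tiv_l columns"
                )
            df["wmh_ratio"] = wmh_ratio(
                df["wmh_volume_ml"].to_numpy(), df["tiv_l"].to_numpy(),
                wmh_unit="ml", tiv_unit="l",
            )
        return df[["subject_id", "wmh_ratio", "lacune_count", "cmb_count"]]
    rows = []
    for rec in markers:
        rows.append(
            {
                "subject_id": rec.subject_id,
                "wmh_ratio": wmh_ratio(rec.wmh_volume, rec.tiv, rec.wmh_unit, rec.tiv_unit),
                "lacune_count": rec.lacune_count,
                "cmb_count": rec.cmb_count,
            }
        )
    return pd.DataFrame(rows)


def classify_csvd(markers, percentile: float = 50.0) -> CsvdClassification:
    """Apply the CSVD rule: high WMH load AND (lacunes OR CMBs).

    Parameters
    ----------
    markers:
        Either a list of :class:`MarkerRecord` or a DataFrame with columns
        ``subject_id``, ``lacune_count``, ``cmb_count`` and either
        ``wmh_ratio`` or (``wmh_volume_ml``, ``tiv_l``).
    percentile:
        WMH-ratio cut point (default the 50th, i.e. the cohort median).

    The empirical percentile uses the median-unbiased quantile convention
    and the "at or above" comparison; both are recorded in the provenance
    block.  Classification is invariant to subject order and to any common
    rescaling of the ratios.
    """
    if not 0 < percentile < 100:
        raise ValueError(f"percentile must be in (0, 100), got {percentile}")
    df = _markers_frame(markers)
    if len(df) < 2:
        raise ValueError(f"need at least 2 subjects to classify, got {len(df)}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_ids in marker table")
    ratios = df["wmh_ratio"].to_numpy(dtype=float)
    threshold = float(np.quantile(ratios, percentile / 100.0, method=QUANTILE_METHOD))
    lesion = (df["lacune_count"].to_numpy() >= 1) | (df["cmb_count"].to_numpy() >= 1)
    flags = (ratios >= threshold) & lesion
    table = df.assign(csvd=flags)
    out = CsvdClassification(
        flags=pd.Series(flags, index=df["subject_id"].to_numpy(), name="csvd"),
        threshold=threshold,
        percentile=percentile,
        table=table,
        provenance={
            "rule": "wmh_ratio >= empirical percentile AND (lacune_count >= 1 OR cmb_count >= 1)",
            "percentile": percentile,
            "quantile_method": QUANTILE_METHOD,
            "threshold": threshold,
            "n_subjects": int(len(df)),
            "rule_version": "1",
        },
    )
    # audit: every flagged subject satisfies both conjuncts
    g = table[table["csvd"]]
    assert bool(((g["wmh_ratio"] >= threshold)).all())
    assert bool(((g["lacune_count"] >= 1) | (g["cmb_count"] >= 1)).all())
    return out
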