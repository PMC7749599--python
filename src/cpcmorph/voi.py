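"""VOI averaging of fitted transition elements and direct-ratio baselines."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cpcmorph.cpc import CpcVolume, ELEMENT_NAMES
from cpcmorph.phantom import ProbabilityMapSet

logger = logging.getLogger(__name__)

#: Direct longitudinal comparator features: per-voxel follow-up/baseline
#: probability ratios, averaged within each region.
RATIO_FEATURES = ("gm_ratio", "wm_ratio", "csf_ratio")
_RATIO_CHANNEL = {"gm_ratio": 0, "wm_ratio": 1, "csf_ratio": 2}

LONG_COLUMNS = ["subject_id", "group", "region", "element", "value", "n_voxels"]


@dataclass
class LabelVolume:
    """Integer region labels on the analysis grid; label 0 is unlabeled."""

    labels: np.ndarray
    name_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer-valued")
        if 0 in self.name_map:
            raise ValueError("label 0 is reserved for unlabeled background")

    def region_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]

    def region_name(self, label: int) -> str:
        return self.name_map.get(label, f"region_{label}")


@dataclass
class VoiFeatureTable:
    """Long-format (subject, region, element) feature table with group labels."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(LONG_COLUMNS) - set(self.rows.columns)
        if missing:
            raise ValueError(f"feature table missing columns: {sorted(missing)}")

    @property
    def groups(self) -> pd.Series:
        return self.rows.groupby("subject_id", sort=False)["group"].first()

    def feature_names(self) -> list[str]:
        return sorted(
            (self.rows["region"] + "|" + self.rows["element"]).unique().tolist()
        )

    def to_wide(self) -> pd.DataFrame:
        """Subjects x "region|element" matrix with a leading ``group`` column."""
        df = self.rows.copy()
        df["feature"] = df["region"] + "|" + df["element"]
        wide = df.pivot_table(
            index="subject_id", columns="feature", values="value", aggfunc="first"
        )
        wide.insert(0, "group", self.groups.reindex(wide.index))
        return wide.sort_index()

    @staticmethod
    def concat(tables: list["VoiFeatureTable"]) -> "VoiFeatureTable":
        return VoiFeatureTable(pd.concat([t.rows for t in tables], ignore_index=True))


def average_in_voi(
    cpc: CpcVolume,
    labels: LabelVolume,
    subject_id: str = "subject",
    group: str = "",
) -> VoiFeatureTable:
    """Mean of each fitted element over the valid voxels of each region.

    Regions with no valid voxels produce a missing value (NaN) with a
    voxel count of 0.
    """
    if cpc.grid_shape != labels.labels.shape:
        raise ValueError(
            f"grid mismatch: cpc {cpc.grid_shape} vs labels {labels.labels.shape}"
        )
    records = []
    for region_id in labels.region_ids():
        sel = (labels.labels == region_id) & cpc.validity_mask
        n = int(sel.sum())
        region = labels.region_name(region_id)
        if n == 0:
            logger.warning("region %s has no valid voxels", region)
        for k, element in enumerate(ELEMENT_NAMES):
            value = float(cpc.channels[k][sel].mean()) if n else np.nan
            records.append((subject_id, group, region, element, value, n))
    return VoiFeatureTable(pd.DataFrame(records, columns=LONG_COLUMNS))


def direct_ratio_features(
    maps_t: ProbabilityMapSet,
    maps_tt: ProbabilityMapSet,
    labels: LabelVolume,
    prob_threshold: float = 0.2,
    subject_id: str = "subject",
    group: str = "",
    method: str = "mean_of_ratios",
) -> VoiFeatureTable:
    """Per-region mean follow-up/baseline probability ratio for GM, WM, CSF.

    Voxels whose baseline probability is below ``prob_threshold`` are
    excluded from the ratio (guards against division blow-up, mirroring
    the exclusion used in the matrix fit).  ``method`` selects
    ``mean_of_ratios`` (default) or ``ratio_of_means``.
    """
    if maps_t.grid_shape != maps_tt.grid_shape or maps_t.grid_shape != labels.labels.shape:
        raise ValueError("maps and labels must share one grid")
    if method not in ("mean_of_ratios", "ratio_of_means"):
        raise ValueError(f"unknown method {method!r}")
    valid = maps_t.voxel_validity & maps_tt.voxel_validity
    records = []
    for region_id in labels.region_ids():
        region_sel = (labels.labels == region_id) & valid
        region = labels.region_name(region_id)
        for feature in RATIO_FEATURES:
            ch = _RATIO_CHANNEL[feature]
            base = maps_t.data[ch]
            follow = maps_tt.data[ch]
            sel = region_sel & (base >= prob_threshold)
            n = int(sel.sum())
            if n == 0:
                logger.warning("region %s: no voxels above threshold for %s", region, feature)
                value = np.nan
            elif method == "mean_of_ratios":
                value = float(np.mean(follow[sel] / base[sel]))
            else:
                value = float(follow[sel].mean() / base[sel].mean())
            records.append((subject_id, group, region, feature, value, n))
    return VoiFeatureTable(pd.DataFrame(records, columns=LONG_COLUMNS))


def subject_features(
    cpc: CpcVolume,
    maps_t: ProbabilityMapSet,
    maps_tt: ProbabilityMapSet,
    labels: LabelVolume,
    subject_id: str,
    group: str,
    prob_threshold: float = 0.2,
    ratio_method: str = "mean_of_ratios",
) -> VoiFeatureTable:
    """All features for one subject: 16 element means + 3 ratio features per region."""
    elems = average_in_voi(cpc, labels, subject_id=subject_id, group=group)
    ratios = direct_ratio_features(
        maps_t,
        maps_tt,
        labels,
        prob_threshold=prob_threshold,
        subject_id=subject_id,
        group=group,
        method=ratio_method,
    )
    return VoiFeatureTable.concat([elems, ratios])
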