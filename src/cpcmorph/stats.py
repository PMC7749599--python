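"""Nonparametric ROC/AUC group discrimination of VOI features."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from cpcmorph.voi import VoiFeatureTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RocResult:
    region: str
    element: str
    group_pair: tuple[str, str]  # (negative class, positive class)
    auc: float
    orientation: int  # +1 if raw AUC >= 0.5, else -1 (1 - AUC reported)
    n_neg: int
    n_pos: int


def auc_mann_whitney(scores_neg: np.ndarray, scores_pos: np.ndarray) -> float:
    """Rank-based AUC: P(random positive score > random negative score).

    Ties count 0.5.  Equals the Mann-Whitney U statistic divided by
    ``n_pos * n_neg``.
    """
    neg = np.asarray(scores_neg, dtype=np.float64)
    pos = np.asarray(scores_pos, dtype=np.float64)
    if neg.size == 0 or pos.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.isfinite(neg).all() and np.isfinite(pos).all()):
        raise ValueError("scores must be finite")
    ranks = rankdata(np.concatenate([neg, pos]))
    rank_sum_pos = ranks[neg.size :].sum()
    u = rank_sum_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def rank_regions(
    features: VoiFeatureTable, group_pair: tuple[str, str]
) -> list[RocResult]:
    """One oriented AUC per (region, element), sorted descending.

    ``group_pair`` is (negative class, positive class).  AUCs below 0.5
    are reported as 1 - AUC with orientation -1, so the ranking reflects
    discrimination magnitude regardless of effect direction.  Ties break
    lexicographically by (region, element).  Columns missing for every
    subject of either group are skipped.
    """
    neg_name, pos_name = group_pair
    groups = features.groups
    for name in group_pair:
        if (groups == name).sum() < 2:
            raise ValueError(f"need >= 2 subjects in group {name!r}")
    rows = features.rows
    results: list[RocResult] = []
    for (region, element), sub in rows.groupby(["region", "element"], sort=True):
        sub = sub.dropna(subset=["value"])
        neg = sub.loc[sub["group"] == neg_name, "value"].to_numpy()
        pos = sub.loc[sub["group"] == pos_name, "value"].to_numpy()
        if neg.size == 0 or pos.size == 0:
            logger.warning("skipping all-missing feature %s|%s", region, element)
            continue
        raw = auc_mann_whitney(neg, pos)
        orientation = 1 if raw >= 0.5 else -1
        auc = raw if orientation == 1 else 1.0 - raw
        results.append(
            RocResult(region, element, (neg_name, pos_name), auc, orientation,
                      int(neg.size), int(pos.size))
        )
    results.sort(key=lambda r: (-r.auc, r.region, r.element))
    return results


def roc_table(results: list[RocResult]) -> pd.DataFrame:
    """Ranked results as a table: rank, element, region, AUC, sizes, orientation."""
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(results) + 1),
            "element": [r.element for r in results],
            "region": [r.region for r in results],
            "auc": [r.auc for r in results],
            "orientation": [r.orientation for r in results],
            "n_neg": [r.n_neg for r in results],
            "n_pos": [r.n_pos for r in results],
        }
    )
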