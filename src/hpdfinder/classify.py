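"""Random-forest robustness harness.

Class-shifted fuzzy sites make artifactual features class predictive, so a
classifier trained on an unfiltered feature table can anchor on artifacts
("hijacking").  This module reproduces the diagnostic: train an ensemble of
independently seeded random forests, rank features by mean impurity-decrease
importance across the ensemble, and count how many of the top-k features are
HPD-tainted under each removal strategy, alongside per-class out-of-bag
error rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .consistency import ConsistentRegion, FeatureTable, _mz_in_regions

logger = logging.getLogger(__name__)

__all__ = ["ImportanceReport", "TaintReport", "rf_importance_ensemble", "hpd_taint_report"]


@dataclass(frozen=True)
class ImportanceReport:
    """Ensemble feature ranking and per-class out-of-bag error.

    ``ranking`` has columns ``feature_id``, ``mz``, ``mean_importance`` and
    is sorted by mean importance descending, ties broken by m/z ascending.
    ``class_errors`` maps class label to the OOB error averaged over forests.
    """

    ranking: pd.DataFrame
    class_errors: dict[str, float]
    n_forests: int
    n_trees: int
    seed: int


@dataclass(frozen=True)
class TaintReport:
    k: int
    n_tainted: int
    tainted_ids: tuple[str, ...]


def rf_importance_ensemble(
    table: FeatureTable,
    n_forests: int = 20,
    n_trees: int = 1000,
    seed: int = 0,
) -> ImportanceReport:
    """Train ``n_forests`` random forests (forest *i* seeded ``seed + i``,
    default hyperparameters apart from the tree count) and aggregate.

    Missing feature values count as zero intensity.  Per-class error is
    estimated out-of-bag; the handful of samples without OOB votes in a
    forest (possible at very small tree counts) are excluded from that
    forest's error.
    """
    labels = sorted(set(table.classes))
    if len(labels) != 2:
        raise ValueError(f"need exactly two classes, got {labels}")
    if table.n_features < 2:
        raise ValueError("need at least 2 features")
    counts = table.classes.value_counts()
    if counts.min() < 4:
        raise ValueError(f"need >= 4 samples per class, got {counts.to_dict()}")

    sample_ids = list(table.values.columns)
    X = table.values[sample_ids].T.fillna(0.0).to_numpy()
    y = table.classes.loc[sample_ids].to_numpy()

    imp = np.zeros(table.n_features)
    err_sums = {lab: 0.0 for lab in labels}
    err_n = {lab: 0 for lab in labels}
    for i in range(n_forests):
        rf = RandomForestClassifier(
            n_estimators=n_trees, oob_score=True, random_state=seed + i, n_jobs=1
        )
        rf.fit(X, y)
        imp += rf.feature_importances_
        dec = rf.oob_decision_function_
        voted = np.nan_to_num(dec, nan=0.0).sum(axis=1) > 0
        pred = rf.classes_[np.nan_to_num(dec, nan=0.0).argmax(axis=1)]
        for lab in labels:
            m = (y == lab) & voted
            if m.any():
                err_sums[lab] += float((pred[m] != lab).mean())
                err_n[lab] += 1
    imp /= n_forests

    ranking = pd.DataFrame(
        {
            "feature_id": table.values.index,
            "mz": table.feature_mz.to_numpy(dtype=float),
            "mean_importance": imp,
        }
    ).sort_values(
        by=["mean_importance", "mz"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    class_errors = {
        lab: (err_sums[lab] / err_n[lab] if err_n[lab] else float("nan"))
        for lab in labels
    }
    return ImportanceReport(
        ranking=ranking,
        class_errors=class_errors,
        n_forests=n_forests,
        n_trees=n_trees,
        seed=seed,
    )


def hpd_taint_report(
    report: ImportanceReport, regions: Sequence[ConsistentRegion], k: int = 30
) -> TaintReport:
    """Count HPD-tainted features among the top-k of the importance ranking."""
    n = len(report.ranking)
    if k > n:
        logger.warning("top-k = %d exceeds the %d ranked features; using all", k, n)
        k = n
    top = report.ranking.iloc[:k]
    hit = _mz_in_regions(top["mz"].to_numpy(dtype=float), regions)
    return TaintReport(
        k=k,
        n_tainted=int(hit.sum()),
        tainted_ids=tuple(top.loc[hit, "feature_id"]),
    )
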