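"""Oral feeding-readiness modeling from per-session NNS features.

Sessions are labeled from the unit's feeding log (same subject, same day):
any oral (PO) feed -> 1 "ready"; exclusively tube feeds (NG/OG) -> 0 "not
ready"; no record that day -> 2 "unknown".  Discriminative features are
selected by per-feature rank tests with Benjamini-Yekutieli false-discovery
control (valid under arbitrary dependence), features are min-max scaled per
column, sessions are clustered by Ward's minimum-variance criterion, and
the two-cluster partition is scored against the known labels by accuracy,
false-positive ratio, and a chi-squared test of independence.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .assess_io import FeedMode, FeedingRecord

LABEL_NOT_READY = 0
LABEL_READY = 1
LABEL_UNKNOWN = 2

#: The two rate features that are exact linear functions of their counts
#: over a fixed-length window, dropped before clustering (9/11 kept).
DEPENDENT_FEATURES = ("nns_cycles_per_min", "bursts_per_min")


@dataclass
class ReadinessDataset:
    feature_matrix: np.ndarray        # sessions x features
    labels: np.ndarray                # 0 / 1 / 2 per session
    session_ids: list[str]
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.feature_matrix = np.asarray(self.feature_matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.feature_matrix.shape[0] != self.labels.size:
            raise ValueError("feature matrix rows must match label count")
        if np.isnan(self.feature_matrix).any():
            raise ValueError("feature matrix contains missing values; "
                             "impute or drop rows before assembly")


@dataclass
class ClusterOutcome:
    assignments: np.ndarray
    linkage_record: np.ndarray
    chi2: float
    p_value: float
    accuracy: float
    false_positive_ratio: float
    contingency: np.ndarray           # 2 clusters x 2 known labels [0, 1]


def assign_labels(sessions: list[tuple[str, date]],
                  feeding_records: list[FeedingRecord]) -> np.ndarray:
    """Label each (subject_id, date) session from the feeding log.

    Same-subject same-day feeds are aggregated: any PO (or mixed-with-oral)
    feed -> ready (1); only tube feeds -> not ready (0); no record -> 2.
    """
    by_key: dict[tuple[str, date], list[FeedMode]] = {}
    for rec in feeding_records:
        by_key.setdefault((rec.subject_id, rec.date), []).append(rec.feed_mode)

    labels = np.empty(len(sessions), dtype=int)
    for i, (subject, day) in enumerate(sessions):
        modes = by_key.get((subject, day))
        if not modes:
            labels[i] = LABEL_UNKNOWN
        elif any(m in (FeedMode.PO, FeedMode.MIXED) for m in modes):
            labels[i] = LABEL_READY
        else:
            labels[i] = LABEL_NOT_READY
    return labels


def select_features(dataset: ReadinessDataset, alpha: float = 0.05
                    ) -> tuple[list[str], np.ndarray]:
    """Keep features that separate ready from not-ready sessions.

    Per feature, a two-sided Mann-Whitney U test compares label-0 vs
    label-1 sessions (unknowns excluded); the Benjamini-Yekutieli step-up at
    level ``alpha`` controls the false-discovery rate under arbitrary
    dependence.  Returns (kept feature names, all p-values).
    """
    known = dataset.labels != LABEL_UNKNOWN
    y = dataset.labels[known]
    X = dataset.feature_matrix[known]
    n0, n1 = int(np.sum(y == 0)), int(np.sum(y == 1))
    if n0 < 2 or n1 < 2:
        raise ValueError(
            f"need >= 2 sessions per known class, got {n0} not-ready / {n1} ready"
        )
    pvals = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        a, b = X[y == 0, j], X[y == 1, j]
        if np.ptp(X[:, j]) == 0:
            pvals[j] = 1.0  # constant feature carries no signal
        else:
            pvals[j] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    keep = benjamini_yekutieli(pvals, alpha)
    kept = [name for name, k in zip(dataset.feature_names, keep) if k]
    return kept, pvals


def benjamini_yekutieli(pvals: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Boolean keep-mask from the BY step-up procedure."""
    reject, _, _, _ = multipletests(np.asarray(pvals, dtype=float),
                                    alpha=alpha, method="fdr_by")
    return reject


def scale_features(matrix: np.ndarray, mode: str = "minmax-columns") -> np.ndarray:
    """Column-wise min-max scaling to [0, 1]; constant columns map to 0."""
    if mode != "minmax-columns":
        raise ValueError(f"unknown scaling mode {mode!r}")
    X = np.asarray(matrix, dtype=float)
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    out = np.zeros_like(X)
    nz = span > 0
    out[:, nz] = (X[:, nz] - lo[nz]) / span[nz]
    return out


def cluster_ward(matrix: np.ndarray, k: int = 2
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative Ward clustering on Euclidean distances, cut to ``k``.

    Returns (0-based assignments, linkage record) — the merge history is
    kept for dendrogram/heat-map export.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < k:
        raise ValueError(f"cannot cut {X.shape[0]} rows into {k} clusters")
    Z = linkage(X, method="ward")
    assignments = fcluster(Z, t=k, criterion="maxclust") - 1
    return assignments, Z


def evaluate_clusters(assignments: np.ndarray, labels: np.ndarray,
                      linkage_record: np.ndarray | None = None) -> ClusterOutcome:
    """Score a two-cluster partition against known 0/1 labels.

    Unknown-label sessions are excluded.  The cluster -> label mapping is
    the better of the two possibilities; accuracy = correct / known;
    false-positive ratio = FP / (FP + TN) with "ready" as the positive
    class; chi-squared (1 df, no continuity correction) on the 2x2
    contingency table.  A degenerate single-cluster assignment yields the
    majority-class accuracy and chi2 = 0.
    """
    assignments = np.asarray(assignments, dtype=int)
    labels = np.asarray(labels, dtype=int)
    known = labels != LABEL_UNKNOWN
    a = assignments[known]
    y = labels[known]
    if not (np.any(y == 0) and np.any(y == 1)):
        raise ValueError("need at least one known session of each class")

    # contingency: rows clusters {0,1}, cols labels {0,1}
    cont = np.zeros((2, 2))
    for ci in (0, 1):
        for li in (0, 1):
            cont[ci, li] = np.sum((a == ci) & (y == li))

    # best of the two cluster->label mappings
    correct_id = cont[0, 0] + cont[1, 1]      # cluster i -> label i
    correct_sw = cont[0, 1] + cont[1, 0]      # cluster i -> label 1-i
    n_known = y.size
    if correct_id >= correct_sw:
        pred = a
    else:
        pred = 1 - a
    accuracy = float(np.sum(pred == y)) / n_known

    fp = float(np.sum((pred == 1) & (y == 0)))
    tn = float(np.sum((pred == 0) & (y == 0)))
    fpr = fp / (fp + tn) if (fp + tn) > 0 else 0.0

    chi2, p = chi2_2x2(cont)
    return ClusterOutcome(
        assignments=assignments,
        linkage_record=(linkage_record if linkage_record is not None
                        else np.zeros((0, 4))),
        chi2=chi2,
        p_value=p,
        accuracy=accuracy,
        false_positive_ratio=fpr,
        contingency=cont,
    )


def chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) on a 2x2 table.

    Degenerate tables (an empty margin) return (0, 1): a single-cluster or
    single-class split carries no association evidence.
    """
    t = np.asarray(table, dtype=float)
    n = t.sum()
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if n == 0 or np.any(rows == 0) or np.any(cols == 0):
        return 0.0, 1.0
    expected = np.outer(rows, cols) / n
    chi2 = float(((t - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass
class ReadinessReport:
    outcome: ClusterOutcome
    kept_features: list[str]
    p_values: dict[str, float]
    scaled_matrix: np.ndarray
    feature_names_used: list[str]
    row_order: np.ndarray             # dendrogram leaf order for heat maps


def run_readiness_analysis(dataset: ReadinessDataset, alpha: float = 0.05,
                           k: int = 2,
                           drop_dependent: bool = True) -> ReadinessReport:
    """Full readiness pipeline on an assembled dataset.

    Drops the two linearly dependent rate features, selects features by
    rank test + BY control (falling back to all candidates when none
    survive), min-max scales, Ward-clusters all sessions (unknowns
    included), and scores the partition against the known labels.
    """
    names = list(dataset.feature_names)
    X = dataset.feature_matrix
    if drop_dependent:
        keep_idx = [i for i, nm in enumerate(names) if nm not in DEPENDENT_FEATURES]
        names = [names[i] for i in keep_idx]
        X = X[:, keep_idx]
    working = ReadinessDataset(X, dataset.labels, dataset.session_ids, names)

    if np.all(dataset.labels == LABEL_UNKNOWN):
        raise ValueError("all session labels are unknown; nothing to model")

    kept, pvals = select_features(working, alpha=alpha)
    used = kept if kept else names  # no survivor -> cluster on all candidates
    idx = [names.index(nm) for nm in used]
    scaled = scale_features(X[:, idx])
    assignments, Z = cluster_ward(scaled, k=k)
    outcome = evaluate_clusters(assignments, dataset.labels, linkage_record=Z)

    from scipy.cluster.hierarchy import leaves_list

    return ReadinessReport(
        outcome=outcome,
        kept_features=kept,
        p_values=dict(zip(names, pvals)),
        scaled_matrix=scaled,
        feature_names_used=used,
        row_order=leaves_list(Z),
    )


def dataset_from_features(features: pd.DataFrame,
                          feeding_records: list[FeedingRecord]) -> ReadinessDataset:
    """Assemble a dataset from a combined per-session feature table.

    ``features`` needs ``session_id``, ``subject_id``, ``date`` columns plus
    numeric feature columns; rows with missing feature values are dropped
    (recorded via the returned session list).
    """
    meta_cols = {"session_id", "subject_id", "date", "window_start_s",
                 "window_end_s", "pma_days"}
    feat_cols = [c for c in features.columns if c not in meta_cols]
    clean = features.dropna(subset=feat_cols)
    sessions = [(str(r.subject_id), _as_date(r.date)) for r in clean.itertuples()]
    labels = assign_labels(sessions, feeding_records)
    return ReadinessDataset(
        feature_matrix=clean[feat_cols].to_numpy(float),
        labels=labels,
        session_ids=[str(s) for s in clean["session_id"]],
        feature_names=feat_cols,
    )


def _as_date(value) -> date:
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value)[:10])
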