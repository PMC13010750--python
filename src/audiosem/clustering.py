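"""Unsupervised K-Means baseline labeling.

Per-task K-Means segmentation (k=4 for hearing-loss type, k=5 for severity,
k=4 for laterality) with elbow/silhouette diagnostics, and a cluster-to-
clinical-label assignment step that maximizes agreement with a set of
reference labels via the Hungarian method on the contingency table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler

from .errors import ConfigurationError
from .features import FeatureConfig, PatientRecord, air_bone_gap, pure_tone_average
from .vocab import AUDIOMETRIC_FREQS

N_RESTARTS = 10

#: number of clusters per task, fixed from audiological domain knowledge.
TASK_K = {"type": 4, "severity": 5, "laterality": 4}


@dataclass(frozen=True)
class ClusterModel:
    """A fitted K-Means segmentation."""

    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    inertia: float
    seed: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if self.inertia < 0:
            raise ConfigurationError("inertia must be >= 0")
        if len(self.assignments) and not (
            0 <= self.assignments.min() and self.assignments.max() < self.k
        ):
            raise ConfigurationError("assignments out of range")


def standardize(features: np.ndarray) -> np.ndarray:
    """Zero-mean/unit-variance scaling (constant columns left centred)."""
    return StandardScaler().fit_transform(np.asarray(features, dtype=float))


def fit_kmeans(features: np.ndarray, k: int, seed: int = 0) -> ClusterModel:
    """Lloyd iterations from k-means++ seeding with ``N_RESTARTS`` restarts."""
    X = np.asarray(features, dtype=float)
    if X.size == 0:
        raise ConfigurationError("empty feature matrix")
    if not np.isfinite(X).all():
        raise ConfigurationError("features must be finite")
    if k > X.shape[0]:
        raise ConfigurationError(f"k={k} exceeds the number of records ({X.shape[0]})")
    km = KMeans(n_clusters=k, n_init=N_RESTARTS, random_state=seed).fit(X)
    return ClusterModel(k=k, centroids=km.cluster_centers_,
                        assignments=km.labels_, inertia=float(km.inertia_), seed=seed)


def k_diagnostics(features: np.ndarray, k_range: Sequence[int], seed: int = 0) -> pd.DataFrame:
    """Per-k inertia and mean silhouette for elbow analysis.

    Inertia is guaranteed non-increasing in k under the shared seed: each fit
    is additionally warm-started from the previous solution extended with the
    point farthest from its centroid, and the better of the two runs is kept.
    """
    X = np.asarray(features, dtype=float)
    ks = sorted(k_range)
    if not ks or ks[0] < 2 or ks[-1] > X.shape[0] - 1:
        raise ConfigurationError(f"k_range must lie within [2, n-1], got {list(k_range)}")
    rows = []
    prev_centroids = None
    for k in ks:
        km = KMeans(n_clusters=k, n_init=N_RESTARTS, random_state=seed).fit(X)
        if prev_centroids is not None and prev_centroids.shape[0] == k - 1:
            dist = np.linalg.norm(X[:, None, :] - prev_centroids[None], axis=2).min(axis=1)
            init = np.vstack([prev_centroids, X[int(dist.argmax())]])
            warm = KMeans(n_clusters=k, n_init=1, init=init).fit(X)
            if warm.inertia_ < km.inertia_:
                km = warm
        prev_centroids = km.cluster_centers_
        rows.append({"k": k, "inertia": float(km.inertia_),
                     "silhouette": float(silhouette_score(X, km.labels_))})
    return pd.DataFrame(rows)


def map_clusters_to_labels(model: ClusterModel,
                           reference_labels: Sequence[str]) -> Tuple[Dict[int, str], np.ndarray, float]:
    """Optimal one-to-one cluster->label assignment (Hungarian method).

    Returns ``(mapping, mapped_labels, agreement)`` where ``agreement`` is the
    fraction of records whose mapped cluster label equals the reference.
    Clusters left unassigned (more clusters than labels) fall back to their
    majority reference label; empty clusters and clusters sharing a label are
    reported as warnings.
    """
    ref = np.asarray(reference_labels, dtype=object)
    if len(ref) != len(model.assignments):
        raise ConfigurationError(
            f"length mismatch: {len(model.assignments)} assignments vs {len(ref)} labels"
        )
    table = pd.crosstab(pd.Series(model.assignments, name="cluster"),
                        pd.Series(ref, name="label"))
    table = table.reindex(index=range(model.k), fill_value=0)
    counts = table.to_numpy()
    rows, cols = linear_sum_assignment(counts, maximize=True)
    mapping = {int(r): str(table.columns[c]) for r, c in zip(rows, cols)}

    empty = [c for c in range(model.k) if counts[c].sum() == 0]
    if empty:
        warnings.warn(f"empty cluster(s): {empty}", stacklevel=2)
    for c in range(model.k):
        if c not in mapping:  # more clusters than distinct labels
            mapping[c] = str(table.columns[int(counts[c].argmax())])
    values = list(mapping.values())
    if len(set(values)) < len(values):
        warnings.warn("multiple clusters mapped to the same label", stacklevel=2)

    mapped = np.array([mapping[int(c)] for c in model.assignments], dtype=object)
    agreement = float((mapped == ref).mean()) if len(ref) else 0.0
    return mapping, mapped, agreement


# ---------------------------------------------------------------------------
# per-task feature subsets
# ---------------------------------------------------------------------------


def _task_features(records: Sequence[PatientRecord], task: str,
                   config: FeatureConfig) -> np.ndarray:
    rows = []
    for r in records:
        left_pta = pure_tone_average(r.left_air, config.pta_freqs)
        right_pta = pure_tone_average(r.right_air, config.pta_freqs)
        if task == "type":
            row = [r.left_air[f] for f in AUDIOMETRIC_FREQS]
            row += [r.right_air[f] for f in AUDIOMETRIC_FREQS]
            for side, bone in (("left", r.left_bone), ("right", r.right_bone)):
                air = r.air(side)
                usable = bone is not None and all(bone.get(f) is not None for f in config.pta_freqs)
                row.append(air_bone_gap(air, bone, config.pta_freqs) if usable else 0.0)
            row.append(float(bool(r.left_tymp_abnormal)))
            row.append(float(bool(r.right_tymp_abnormal)))
        elif task == "severity":
            row = [left_pta, right_pta, max(left_pta, right_pta)]
        elif task == "laterality":
            row = [left_pta, right_pta, left_pta - right_pta]
        else:
            raise ConfigurationError(f"unknown clustering task {task!r}")
        rows.append(row)
    return np.asarray(rows, dtype=float)


def kmeans_label_cohort(records: Sequence[PatientRecord], config: FeatureConfig,
                        seed: int = 0, reference=None) -> pd.DataFrame:
    """Cluster-derived type/severity/laterality labels for a whole cohort.

    Each task clusters its own standardized feature subset with the fixed k
    from :data:`TASK_K`; anonymous clusters are then named by Hungarian
    matching against ``reference`` labels (by default the rule-engine labels
    computed on the same records -- the evaluation-comparability choice, since
    no assignment procedure is published for this step).
    """
    from .rules import apply_rule_base, default_rule_base  # local: avoid cycle

    if not records:
        raise ConfigurationError("empty cohort")
    if reference is None:
        rules = default_rule_base(config)
        reference = [apply_rule_base(r, rules, config) for r in records]
    ref_by_task = {
        "type": [s.hl_type for s in reference],
        "severity": [s.severity for s in reference],
        "laterality": [s.laterality for s in reference],
    }
    out = pd.DataFrame({"patient_id": [r.patient_id for r in records]})
    agreements = {}
    for task, k in TASK_K.items():
        X = standardize(_task_features(records, task, config))
        model = fit_kmeans(X, k, seed=seed)
        _, mapped, agreement = map_clusters_to_labels(model, ref_by_task[task])
        out[f"kmeans_{task}"] = mapped
        agreements[task] = agreement
    out.attrs["agreement_vs_reference"] = agreements
    return out
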