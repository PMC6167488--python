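"""Terminal-chain conformer analysis.

The substrate's aliphatic tail interconverts between rotamers; here the two
relevant ones differ in the torsion that places the chain-truncation carbon
(anti vs gauche about the last backbone bond). The module computes signed
dihedrals, classifies frames into conformer 1 / conformer 2 / other by
configurable torsion bins, and clusters frames in a circular-safe
(sine/cosine embedded) torsion space with k-means to pick representative
medoid frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from omega_access.errors import ConfigurationError, ContractError, DegenerateGeometryError


@dataclass(frozen=True)
class DihedralFeature:
    frame_index: int
    torsions: tuple[float, ...]  # degrees, each in (-180, 180]


@dataclass(frozen=True)
class ConformerLabel:
    frame_index: int
    label: str  # "1", "2" or "other"


#: default torsion bins: anti -> conformer 1, (positive) gauche -> conformer 2
DEFAULT_BINS: dict[str, list[tuple[float, float]]] = {
    "1": [(120.0, 180.0), (-180.0, -120.0)],
    "2": [(0.0, 120.0)],
}


def torsion(p1, p2, p3, p4) -> float:
    """Signed dihedral p1-p2-p3-p4 in (-180, 180] (standard atan2 form).

    The sign flips under mirror imaging. Raises on a collinear triple,
    where the dihedral is undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 == 0 or np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("torsion: collinear atoms, dihedral undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / nb2)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:  # normalize the closed end of the interval
        ang += 360.0
    return float(ang)


def _validate_bins(bins: dict[str, list[tuple[float, float]]]) -> None:
    intervals = [iv for ivs in bins.values() for iv in ivs]
    for lo, hi in intervals:
        if not (-180.0 <= lo < hi <= 180.0):
            raise ConfigurationError(f"torsion bin ({lo}, {hi}] out of range")
    for i, (lo1, hi1) in enumerate(intervals):
        for lo2, hi2 in intervals[i + 1 :]:
            if max(lo1, lo2) < min(hi1, hi2):
                raise ConfigurationError(
                    f"torsion bins ({lo1}, {hi1}] and ({lo2}, {hi2}] overlap"
                )


def classify_conformer(
    features: DihedralFeature,
    bins: dict[str, list[tuple[float, float]]] | None = None,
    torsion_index: int = 0,
) -> ConformerLabel:
    """Label a frame by which half-open bin (lo, hi] holds its branch torsion."""
    bins = bins if bins is not None else DEFAULT_BINS
    _validate_bins(bins)
    t = features.torsions[torsion_index]
    for label, intervals in bins.items():
        if any(lo < t <= hi for lo, hi in intervals):
            return ConformerLabel(frame_index=features.frame_index, label=label)
    return ConformerLabel(frame_index=features.frame_index, label="other")


@dataclass
class ClusterResult:
    assignments: np.ndarray  # cluster id per feature
    medoid_frames: list[int]  # frame_index of the frame nearest each centroid
    inertia: float = field(default=0.0)


def kmeans_frames(
    features: list[DihedralFeature], k: int, seed: int = 0
) -> ClusterResult:
    """k-means over sine/cosine-embedded torsions; medoids as representatives.

    The (sin, cos) embedding makes the metric circular-safe: -179 and +179
    degrees are close. The representative of each cluster is the real frame
    nearest its centroid, so downstream stages always receive an actual
    snapshot.
    """
    n = len(features)
    if k < 1 or k > n:
        raise ContractError(f"kmeans_frames: need 1 <= k <= {n}, got {k}")
    t = np.radians([f.torsions for f in features])
    X = np.concatenate([np.sin(t), np.cos(t)], axis=1)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assignments = km.fit_predict(X)
    medoids: list[int] = []
    for c in range(k):
        members = np.flatnonzero(assignments == c)
        d2 = np.sum((X[members] - km.cluster_centers_[c]) ** 2, axis=1)
        medoids.append(features[int(members[np.argmin(d2)])].frame_index)
    return ClusterResult(
        assignments=assignments, medoid_frames=medoids, inertia=float(km.inertia_)
    )


def conformer_census(
    labels: list[ConformerLabel],
    satisfied_frames: set[int] | None = None,
) -> dict[str, float]:
    """Fraction of frames per conformer label.

    With ``satisfied_frames`` given, only criteria-satisfying frames are
    counted (the census mode matching the accessibility analysis); otherwise
    all frames count.
    """
    pool = [
        l for l in labels
        if satisfied_frames is None or l.frame_index in satisfied_frames
    ]
    if not pool:
        return {}
    out: dict[str, float] = {}
    for l in pool:
        out[l.label] = out.get(l.label, 0.0) + 1.0
    return {k: v / len(pool) for k, v in sorted(out.items())}
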