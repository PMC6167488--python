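"""Geometric kernels for the accessibility indices.

The two indices measured per frame are the distance d from a candidate
hydrogen to the oxo oxygen of Compound I and the angle theta at the oxo
vertex between that hydrogen and the heme iron (H-O-Fe). theta is defined
with the oxo atom at the vertex; the choice is stated here because the
index is often drawn rather than written as a formula.

Also provided: per-frame record extraction over all configured sites,
closest-hydrogen reduction with a documented tie-break, and pro-R/pro-S
assignment of prochiral methylene hydrogens via a signed-volume rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from omega_access.errors import ContractError, DegenerateGeometryError
from omega_access.structures_io import (
    Frame,
    ReactiveCenter,
    Selector,
    SiteDefinition,
    site_sort_key,
)

logger = logging.getLogger(__name__)

#: |det| of the three priority bond vectors (A^3) below which a center is
#: treated as planar and prochirality assignment refuses to guess.
PLANARITY_THRESHOLD = 1e-6


@dataclass(frozen=True, slots=True)
class GeometricRecord:
    """One (frame, site, hydrogen) measurement: d in Angstrom, theta in degrees."""

    frame_index: int
    site_label: str
    hydrogen: Selector
    d: float
    theta: float

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError(f"d must be positive, got {self.d}")
        if not 0.0 <= self.theta <= 180.0:
            raise ValueError(f"theta must lie in [0, 180], got {self.theta}")


def distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two points (Angstrom)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("distance: inputs must be finite")
    return float(np.linalg.norm(a - b))


def angle(h: np.ndarray, oxo: np.ndarray, fe: np.ndarray) -> float:
    """Angle at the oxo vertex between rays oxo->h and oxo->fe, in degrees.

    Uses the numerically stable atan2 form, exact at 0 and 180 degrees.
    """
    h = np.asarray(h, dtype=float)
    oxo = np.asarray(oxo, dtype=float)
    fe = np.asarray(fe, dtype=float)
    u = h - oxo
    v = fe - oxo
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError(
            "angle: zero-length ray (hydrogen or iron coincides with the oxo atom)"
        )
    cross = np.linalg.norm(np.cross(u, v))
    dot = float(np.dot(u, v))
    return float(np.degrees(np.arctan2(cross, dot)))


def frame_records(
    frame: Frame, center: ReactiveCenter, sites: list[SiteDefinition]
) -> list[GeometricRecord]:
    """Measure (d, theta) for every hydrogen of every site in one frame.

    Emits one record per (site, attached hydrogen); multi-hydrogen sites are
    reduced to their closest hydrogen only downstream, so the full set stays
    available for audit.
    """
    oxo = frame.position(center.oxo)
    fe = frame.position(center.iron)
    records: list[GeometricRecord] = []
    for site in sites:
        for hsel in site.hydrogens:
            hpos = frame.position(hsel)
            records.append(
                GeometricRecord(
                    frame_index=frame.index,
                    site_label=site.label,
                    hydrogen=hsel,
                    d=distance(hpos, oxo),
                    theta=angle(hpos, oxo, fe),
                )
            )
    return records


def closest_hydrogen(records: list[GeometricRecord]) -> GeometricRecord:
    """The record with minimal d among all hydrogens of one frame.

    Exact ties are broken by the documented site ordering (terminal site
    first), then by hydrogen atom name, and are reported on the module
    logger.
    """
    if not records:
        raise ContractError("closest_hydrogen: empty record list")
    frames = {r.frame_index for r in records}
    if len(frames) != 1:
        raise ContractError(
            f"closest_hydrogen: records span multiple frames {sorted(frames)}"
        )
    best = min(records, key=lambda r: (r.d, site_sort_key(r.site_label), r.hydrogen[1]))
    ties = [r for r in records if r.d == best.d and r is not best]
    if ties:
        logger.warning(
            "frame %d: %d-way distance tie at d=%.4f A resolved to site %s (%s)",
            best.frame_index, len(ties) + 1, best.d, best.site_label, best.hydrogen[1],
        )
    return best


def assign_prochirality(
    carbon: np.ndarray,
    h1: np.ndarray,
    h2: np.ndarray,
    toward_omega: np.ndarray,
    toward_chain: np.ndarray,
) -> dict[str, str]:
    """Label the two hydrogens of a prochiral methylene as pro-R / pro-S.

    Substituent priority is fixed as toward_omega > toward_chain > H. A
    hydrogen is pro-R when promoting it above both heavy substituents gives a
    clockwise (R-like) priority arrangement, i.e. when the determinant of the
    priority-ordered bond vectors (v_H, v_omega, v_chain) is negative; this
    is equivalent to the usual isotope-promotion rule because a cyclic row
    permutation preserves the determinant sign. Mirror-imaging all input
    coordinates therefore swaps the labels.
    """
    carbon = np.asarray(carbon, dtype=float)
    v_o = np.asarray(toward_omega, dtype=float) - carbon
    v_c = np.asarray(toward_chain, dtype=float) - carbon
    v1 = np.asarray(h1, dtype=float) - carbon
    v2 = np.asarray(h2, dtype=float) - carbon
    det1 = float(np.linalg.det(np.array([v1, v_o, v_c])))
    det2 = float(np.linalg.det(np.array([v2, v_o, v_c])))
    if abs(det1) < PLANARITY_THRESHOLD or abs(det2) < PLANARITY_THRESHOLD:
        raise DegenerateGeometryError(
            "assign_prochirality: near-planar center "
            f"(|det| = {min(abs(det1), abs(det2)):.2e} A^3)"
        )
    if det1 * det2 > 0:
        raise DegenerateGeometryError(
            "assign_prochirality: both hydrogens fall on the same side of the "
            "substituent plane; not a tetrahedral center"
        )
    lab1 = "pro-R" if det1 < 0 else "pro-S"
    lab2 = "pro-R" if det2 < 0 else "pro-S"
    return {"h1": lab1, "h2": lab2}
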