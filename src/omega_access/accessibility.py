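"""Criteria-based frame classification and per-site accessibility statistics.

A frame "presents" a site to the iron-oxo when (a) that site's hydrogen is
the closest of all candidate hydrogens to the oxo atom, (b) the hydrogen-oxo
distance d does not exceed d_max, and (c) the H-O-Fe angle theta lies inside
the near-attack window. All bounds are inclusive. Per-site frequencies are
reported two ways: among criteria-satisfying frames (the headline
accessibility profile) and as closest-site attribution over all frames with
no windows (the distance-only variant).

Frames from an MD trajectory are autocorrelated, so uncertainty comes from a
moving-block bootstrap rather than a binomial formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from omega_access.errors import ContractError
from omega_access.geometry import GeometricRecord, closest_hydrogen
from omega_access.structures_io import site_sort_key


@dataclass(frozen=True)
class CriteriaSpec:
    """Near-attack criteria. Defaults: d <= 2.8 A and 125 <= theta <= 150 deg."""

    d_max: float = 2.8
    theta_min: float = 125.0
    theta_max: float = 150.0
    require_global_closest: bool = True

    def __post_init__(self) -> None:
        if not self.d_max > 0:
            raise ValueError("d_max must be positive")
        if not 0.0 <= self.theta_min < self.theta_max <= 180.0:
            raise ValueError("need 0 <= theta_min < theta_max <= 180")

    def window_ok(self, d: float, theta: float) -> bool:
        return d <= self.d_max and self.theta_min <= theta <= self.theta_max


@dataclass(frozen=True)
class FrameOutcome:
    frame_index: int
    satisfied: bool
    site_label: str | None
    d: float
    theta: float
    #: sites whose own closest hydrogen passes the windows (used by the
    #: relaxed require_global_closest=False mode; superset of site_label)
    passing_sites: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.satisfied and self.site_label is None:
            raise ValueError("a satisfied outcome must name its site")


@dataclass
class AccessibilityProfile:
    n_frames: int
    satisfying_fraction: float
    site_frequencies: dict[str, float]
    distance_only_frequencies: dict[str, float]
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: alternate normalization of satisfied-site counts over ALL frames
    all_frames_frequencies: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ci"] = {k: list(v) for k, v in self.ci.items()}
        return d


def classify_frame(
    records: list[GeometricRecord], spec: CriteriaSpec | None = None
) -> FrameOutcome:
    """Apply the criteria to one frame's records.

    With the default closest-hydrogen rule at most one site can satisfy per
    frame: the windows are tested on the globally closest hydrogen only.
    With ``require_global_closest=False`` each site is judged on its own
    closest hydrogen; the frame is satisfied if any site passes and is
    attributed to the passing site with the smallest d.
    """
    spec = spec or CriteriaSpec()
    if not records:
        raise ContractError("classify_frame: no records")
    best = closest_hydrogen(records)
    if spec.require_global_closest:
        ok = spec.window_ok(best.d, best.theta)
        return FrameOutcome(
            frame_index=best.frame_index,
            satisfied=ok,
            site_label=best.site_label if ok else None,
            d=best.d,
            theta=best.theta,
            passing_sites=(best.site_label,) if ok else (),
        )
    per_site: dict[str, GeometricRecord] = {}
    for r in records:
        cur = per_site.get(r.site_label)
        if cur is None or (r.d, r.hydrogen[1]) < (cur.d, cur.hydrogen[1]):
            per_site[r.site_label] = r
    passing = sorted(
        (r for r in per_site.values() if spec.window_ok(r.d, r.theta)),
        key=lambda r: (r.d, site_sort_key(r.site_label)),
    )
    if passing:
        top = passing[0]
        return FrameOutcome(
            frame_index=top.frame_index,
            satisfied=True,
            site_label=top.site_label,
            d=top.d,
            theta=top.theta,
            passing_sites=tuple(r.site_label for r in passing),
        )
    return FrameOutcome(
        frame_index=best.frame_index,
        satisfied=False,
        site_label=None,
        d=best.d,
        theta=best.theta,
    )


def _check_unique_frames(outcomes: list[FrameOutcome]) -> None:
    seen = [o.frame_index for o in outcomes]
    if len(set(seen)) != len(seen):
        raise ContractError("profile: duplicate frame indices in outcomes")


def profile(
    outcomes: list[FrameOutcome],
    records_by_frame: list[list[GeometricRecord]],
) -> AccessibilityProfile:
    """Aggregate frame outcomes into per-site frequencies.

    ``site_frequencies`` are proportions among the criteria-satisfying
    frames (they sum to 1 when any frame satisfies);
    ``distance_only_frequencies`` attribute every frame to the site of its
    globally closest hydrogen, windows ignored, and always sum to 1.
    """
    if not outcomes:
        raise ContractError("profile: no outcomes")
    _check_unique_frames(outcomes)
    n = len(outcomes)
    satisfied = [o for o in outcomes if o.satisfied]
    site_freq: dict[str, float] = {}
    for o in satisfied:
        site_freq[o.site_label] = site_freq.get(o.site_label, 0.0) + 1.0
    if satisfied:
        site_freq = {k: v / len(satisfied) for k, v in site_freq.items()}
    all_freq = {k: v * len(satisfied) / n for k, v in site_freq.items()}

    dist_only: dict[str, float] = {}
    for recs in records_by_frame:
        lab = closest_hydrogen(recs).site_label
        dist_only[lab] = dist_only.get(lab, 0.0) + 1.0
    total = sum(dist_only.values())
    if total:
        dist_only = {k: v / total for k, v in dist_only.items()}

    order = lambda d: dict(sorted(d.items(), key=lambda kv: site_sort_key(kv[0])))
    return AccessibilityProfile(
        n_frames=n,
        satisfying_fraction=len(satisfied) / n,
        site_frequencies=order(site_freq),
        distance_only_frequencies=order(dist_only),
        all_frames_frequencies=order(all_freq),
    )


def bootstrap_ci(
    outcomes: list[FrameOutcome],
    n_boot: int = 1000,
    block: int = 50,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Moving-block bootstrap CIs (2.5/97.5 percentiles) for the profile.

    Resamples contiguous blocks of frame outcomes to respect trajectory
    autocorrelation (default block of 50 frames, about 100 ps at a 2-ps
    saving interval). Returns per-site intervals for the frequency among
    satisfying frames plus the interval for the satisfying fraction itself
    under the key ``"satisfying_fraction"``.
    """
    if n_boot < 100:
        raise ContractError("bootstrap_ci: n_boot must be >= 100")
    n = len(outcomes)
    if block < 1 or block > n:
        raise ContractError(f"bootstrap_ci: block must lie in [1, {n}]")
    rng = np.random.default_rng(seed)
    sats = np.array([o.satisfied for o in outcomes], dtype=bool)
    labels = np.array(
        [o.site_label if o.satisfied else "" for o in outcomes], dtype=object
    )
    sites = sorted({l for l in labels if l}, key=site_sort_key)
    n_blocks = int(np.ceil(n / block))
    starts_max = n - block + 1

    frac = np.empty(n_boot)
    freqs = {s: np.full(n_boot, np.nan) for s in sites}
    for b in range(n_boot):
        starts = rng.integers(0, starts_max, size=n_blocks)
        idx = (starts[:, None] + np.arange(block)[None, :]).ravel()[:n]
        s = sats[idx]
        frac[b] = s.mean()
        ns = s.sum()
        if ns:
            lab = labels[idx][s]
            for site in sites:
                freqs[site][b] = np.count_nonzero(lab == site) / ns
    ci: dict[str, tuple[float, float]] = {}
    for site in sites:
        vals = freqs[site][~np.isnan(freqs[site])]
        lo, hi = np.percentile(vals, [2.5, 97.5])
        ci[site] = (float(lo), float(hi))
    lo, hi = np.percentile(frac, [2.5, 97.5])
    ci["satisfying_fraction"] = (float(lo), float(hi))
    return ci


@dataclass
class ConsensusReport:
    pooled: AccessibilityProfile
    per_run_top_site: list[str | None]
    dispersion: dict[str, float]
    divergent_runs: list[int]


def compare_runs(profiles: list[AccessibilityProfile]) -> ConsensusReport:
    """Pool several independent runs and flag disagreement on the top site.

    Pooling is frame-weighted; dispersion is the across-run standard
    deviation of each site frequency. Runs whose top satisfying site differs
    from the pooled top site are flagged by index.
    """
    if len(profiles) < 2:
        raise ContractError("compare_runs: need at least 2 profiles")
    site_sets = [set(p.distance_only_frequencies) for p in profiles]
    if any(s != site_sets[0] for s in site_sets[1:]):
        raise ContractError("compare_runs: profiles cover different site sets")

    total = sum(p.n_frames for p in profiles)
    sat_counts = {p_i: p.satisfying_fraction * p.n_frames for p_i, p in enumerate(profiles)}
    total_sat = sum(sat_counts.values())
    sites = sorted(
        {s for p in profiles for s in p.site_frequencies}, key=site_sort_key
    )
    pooled_site = {}
    for s in sites:
        cnt = sum(
            p.site_frequencies.get(s, 0.0) * sat_counts[i]
            for i, p in enumerate(profiles)
        )
        pooled_site[s] = cnt / total_sat if total_sat else 0.0
    pooled_dist: dict[str, float] = {}
    for s in site_sets[0]:
        pooled_dist[s] = (
            sum(p.distance_only_frequencies.get(s, 0.0) * p.n_frames for p in profiles)
            / total
        )
    order = lambda d: dict(sorted(d.items(), key=lambda kv: site_sort_key(kv[0])))
    pooled = AccessibilityProfile(
        n_frames=total,
        satisfying_fraction=total_sat / total,
        site_frequencies=order(pooled_site),
        distance_only_frequencies=order(pooled_dist),
    )
    dispersion = {
        s: float(np.std([p.site_frequencies.get(s, 0.0) for p in profiles]))
        for s in sites
    }
    tops = [
        max(p.site_frequencies, key=p.site_frequencies.get)
        if p.site_frequencies
        else None
        for p in profiles
    ]
    pooled_top = max(pooled_site, key=pooled_site.get) if pooled_site else None
    divergent = [i for i, t in enumerate(tops) if t is not None and t != pooled_top]
    return ConsensusReport(
        pooled=pooled,
        per_run_top_site=tops,
        dispersion=dispersion,
        divergent_runs=divergent,
    )


def analyze_trajectory(trajectory, center, sites, spec: CriteriaSpec | None = None):
    """Convenience end-to-end: records per frame, outcomes, and the profile.

    Returns (records_by_frame, outcomes, profile).
    """
    from omega_access.geometry import frame_records

    spec = spec or CriteriaSpec()
    records_by_frame = [frame_records(fr, center, sites) for fr in trajectory]
    outcomes = [classify_frame(recs, spec) for recs in records_by_frame]
    return records_by_frame, outcomes, profile(outcomes, records_by_frame)
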