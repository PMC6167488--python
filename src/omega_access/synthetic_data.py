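"""Ground-truth trajectory generators.

MD trajectories behind published accessibility analyses are rarely
deposited, so the test strategy here is parameter recovery on synthetic
data: every frame is drawn from a generative model with known per-site
occupancy probabilities p, a known near-attack window pass probability q,
and known conformer fractions, and the analysis pipeline must recover
those numbers.

Two output levels share one frame sampler:

* :func:`sample_records` emits geometric records directly (fast, exact);
* :func:`emit_pdb_trajectory` builds an actual multi-model PDB of a minimal
  Compound I fragment (Fe at the origin, oxo on +z at 1.62 A, four pyrrole
  nitrogens, an axial thiolate S) plus an isohexane-like six-carbon tail
  with explicit hydrogens, placing the presented site's hydrogen so that
  the sampled (d, theta) pair is realized exactly; the rest of the tail is
  built from ideal bond geometry (C-C 1.53 A, C-H 1.09 A, tetrahedral
  angles) with coordinate jitter and always points away from the oxo atom,
  so the presented hydrogen is the globally closest one by construction.

The Fe-oxo distance and ideal bond parameters are generator conveniences,
not claims about any particular system.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from omega_access.errors import ContractError
from omega_access.geometry import GeometricRecord, assign_prochirality
from omega_access.structures_io import (
    AtomRecord,
    Frame,
    Trajectory,
    write_multimodel_pdb,
)

FE_OXO_DISTANCE = 1.62  # A, generator convention
CC_BOND = 1.53
CH_BOND = 1.09
TET_ANGLE = 109.471


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic trajectory.

    ``site_probs`` is the per-frame probability that a given site is the one
    presented to the iron-oxo (its hydrogen is the closest); ``pass_prob``
    is the probability that the presented hydrogen's (d, theta) pair falls
    inside the default near-attack windows. The presented pair is drawn from
    a truncated normal for d (A) and a von Mises for theta (degrees),
    conditioned inside or outside the windows by the pass draw; truncation
    is resample-based so the conditional distributions stay exact.
    """

    n_frames: int
    site_probs: dict[str, float]
    pass_prob: float = 0.30
    d_mean: float = 2.6
    d_sd: float = 0.3
    theta_mean: float = 137.5
    theta_sd: float = 10.0
    d_max: float = 2.8
    theta_min: float = 125.0
    theta_max: float = 150.0
    background_offset: float = 1.5
    conformer_probs: dict[int, float] = field(default_factory=lambda: {1: 0.85, 2: 0.15})
    ar1_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ContractError("n_frames must be >= 1")
        tot = sum(self.site_probs.values())
        if not math.isclose(tot, 1.0, abs_tol=1e-9) or any(
            p < 0 for p in self.site_probs.values()
        ):
            raise ContractError(f"site_probs must be non-negative and sum to 1, got {tot}")
        if not 0.0 <= self.pass_prob <= 1.0:
            raise ContractError("pass_prob must lie in [0, 1]")
        ctot = sum(self.conformer_probs.values())
        if not math.isclose(ctot, 1.0, abs_tol=1e-9):
            raise ContractError("conformer_probs must sum to 1")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ContractError("ar1_rho must lie in [0, 1)")

    def truth(self) -> dict:
        return {
            "site_probs": dict(self.site_probs),
            "pass_prob": self.pass_prob,
            "conformer_probs": {str(k): v for k, v in self.conformer_probs.items()},
            "seed": self.seed,
        }


def vk1_like_spec(n_frames: int = 20_000, seed: int = 0, **overrides) -> GeneratorSpec:
    """The omega-dominant regime: p = (0.92, 0.05, 0.02, 0.01) over
    (omega, omega-1, omega-2R, omega-2S), nothing at omega-3, q = 0.30."""
    kwargs = dict(
        n_frames=n_frames,
        site_probs={
            "omega": 0.92,
            "omega-1": 0.05,
            "omega-2R": 0.02,
            "omega-2S": 0.01,
            "omega-3R": 0.0,
            "omega-3S": 0.0,
        },
        pass_prob=0.30,
        seed=seed,
    )
    kwargs.update(overrides)
    return GeneratorSpec(**kwargs)


# ---------------------------------------------------------------------------
# Fragment topology (names match the packaged vk1_sites.yaml)
# ---------------------------------------------------------------------------

HEME_ATOMS = (  # (name, element, x, y, z) — residue 1, "CPI"
    ("FE", "FE", 0.0, 0.0, 0.0),
    ("O1", "O", 0.0, 0.0, FE_OXO_DISTANCE),
    ("NA", "N", 2.0, 0.0, 0.0),
    ("NB", "N", 0.0, 2.0, 0.0),
    ("NC", "N", -2.0, 0.0, 0.0),
    ("ND", "N", 0.0, -2.0, 0.0),
    ("S1", "S", 0.0, 0.0, -2.3),
)

SITE_HYDROGENS = {
    "omega": ("H11", "H12", "H13"),
    "omega-1": ("H21",),
}
TAIL_RESID = 2
TAIL_RESNAME = "VKF"
#: build order of the tail atoms (carbons then hydrogens)
TAIL_ATOMS = (
    "C1", "C2", "C3", "C4", "C5", "CB",
    "H11", "H12", "H13", "H21", "HB1", "HB2", "HB3",
    "H31", "H32", "H41", "H42", "H51", "H52", "H53",
)
SITE_CARBON = {"omega": "C1", "omega-1": "C2", "omega-2": "C3", "omega-3": "C4"}
#: hydrogens belonging to candidate sites; only these compete under the
#: closest-hydrogen rule (cap and branch methyl hydrogens are spectators)
SITE_H_NAMES = ("H11", "H12", "H13", "H21", "H31", "H32", "H41", "H42")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _nerf(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d with |cd| = bond, angle(b,c,d) and torsion(a,b,c,d)."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-math.cos(ang), math.sin(ang) * math.cos(tor), math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_tail_template(branch_torsion: float = 180.0) -> dict[str, np.ndarray]:
    """Ideal-geometry isohexane-like tail; ``branch_torsion`` is the
    C2-C3-C4-C5 dihedral placing the truncation carbon (anti ~ conformer 1,
    gauche ~ conformer 2)."""
    pos: dict[str, np.ndarray] = {}
    pos["C1"] = np.zeros(3)
    pos["C2"] = np.array([CC_BOND, 0.0, 0.0])
    a = math.radians(180.0 - TET_ANGLE)
    pos["C3"] = pos["C2"] + CC_BOND * np.array([math.cos(a), math.sin(a), 0.0])
    pos["C4"] = _nerf(pos["C1"], pos["C2"], pos["C3"], CC_BOND, TET_ANGLE, 180.0)
    pos["C5"] = _nerf(pos["C2"], pos["C3"], pos["C4"], CC_BOND, TET_ANGLE, branch_torsion)
    pos["CB"] = _nerf(pos["C4"], pos["C3"], pos["C2"], CC_BOND, TET_ANGLE, 60.0)
    pos["H21"] = _nerf(pos["C4"], pos["C3"], pos["C2"], CH_BOND, TET_ANGLE, -60.0)
    for name, t in (("H11", 60.0), ("H12", 180.0), ("H13", -60.0)):
        pos[name] = _nerf(pos["C3"], pos["C2"], pos["C1"], CH_BOND, TET_ANGLE, t)
    for name, t in (("HB1", 60.0), ("HB2", 180.0), ("HB3", -60.0)):
        pos[name] = _nerf(pos["C1"], pos["C2"], pos["CB"], CH_BOND, TET_ANGLE, t)
    for name, t in (("H31", 60.0), ("H32", -60.0)):
        pos[name] = _nerf(pos["C1"], pos["C2"], pos["C3"], CH_BOND, TET_ANGLE, t)
    for name, dt in (("H41", -120.0), ("H42", 120.0)):
        tt = branch_torsion + dt
        tt = (tt + 180.0) % 360.0 - 180.0
        pos[name] = _nerf(pos["C2"], pos["C3"], pos["C4"], CH_BOND, TET_ANGLE, tt)
    for name, t in (("H51", 60.0), ("H52", 180.0), ("H53", -60.0)):
        pos[name] = _nerf(pos["C3"], pos["C4"], pos["C5"], CH_BOND, TET_ANGLE, t)
    return pos


def fragment_prochirality() -> dict[str, dict[str, str]]:
    """pro-R/pro-S labels of the template's methylene hydrogens.

    Fixed by the template's handedness; rigid placement preserves them, so
    they hold for every emitted frame.
    """
    pos = build_tail_template()
    out: dict[str, dict[str, str]] = {}
    for parent, (carbon, h1, h2, n_omega, n_chain) in {
        "omega-2": ("C3", "H31", "H32", "C2", "C4"),
        "omega-3": ("C4", "H41", "H42", "C3", "C5"),
    }.items():
        labels = assign_prochirality(
            pos[carbon], pos[h1], pos[h2], pos[n_omega], pos[n_chain]
        )
        out[parent] = {h1: labels["h1"], h2: labels["h2"]}
    return out


def _hydrogen_for_site(site: str, rng: np.random.Generator,
                       prochirality: dict[str, dict[str, str]]) -> str:
    if site in SITE_HYDROGENS:
        return str(rng.choice(SITE_HYDROGENS[site]))
    parent, rs = site[:-1], site[-1]
    want = "pro-R" if rs == "R" else "pro-S"
    for h, lab in prochirality[parent].items():
        if lab == want:
            return h
    raise ContractError(f"no hydrogen with label {want} at {parent}")


# ---------------------------------------------------------------------------
# Frame-level sampling shared by both output modes
# ---------------------------------------------------------------------------

def _sample_d_theta(spec: GeneratorSpec, rng: np.random.Generator,
                    inside: bool) -> tuple[float, float]:
    kappa = 1.0 / math.radians(spec.theta_sd) ** 2
    mu = math.radians(spec.theta_mean)
    for _ in range(10_000):
        d = rng.normal(spec.d_mean, spec.d_sd)
        if d <= 0.5:  # keep H off the oxo atom
            continue
        theta = math.degrees(rng.vonmises(mu, kappa))
        if not 0.0 < theta < 180.0:
            continue
        ok = d <= spec.d_max and spec.theta_min <= theta <= spec.theta_max
        if ok == inside:
            return float(d), float(theta)
    raise ContractError(
        "could not sample (d, theta) on the requested side of the windows; "
        "check the distribution parameters against the windows"
    )


def sample_frame_plans(spec: GeneratorSpec, rng: np.random.Generator | None = None):
    """Yield one plan per frame: presented site and hydrogen, (d, theta),
    window-pass flag, conformer and branch torsion."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    prochirality = fragment_prochirality()
    sites = list(spec.site_probs)
    probs = np.array([spec.site_probs[s] for s in sites])
    conformers = sorted(spec.conformer_probs)
    cprobs = np.array([spec.conformer_probs[c] for c in conformers])
    prev_site: str | None = None
    for i in range(spec.n_frames):
        if prev_site is not None and spec.ar1_rho > 0 and rng.random() < spec.ar1_rho:
            site = prev_site
        else:
            site = sites[int(rng.choice(len(sites), p=probs))]
        prev_site = site
        passed = bool(rng.random() < spec.pass_prob)
        d, theta = _sample_d_theta(spec, rng, inside=passed)
        conformer = int(conformers[int(rng.choice(len(conformers), p=cprobs))])
        torsion_center = 180.0 if conformer == 1 else 60.0
        branch_torsion = float(np.clip(rng.normal(torsion_center, 8.0),
                                       torsion_center - 30, torsion_center + 30))
        if branch_torsion > 180.0:
            branch_torsion -= 360.0
        yield {
            "frame": i,
            "site": site,
            "hydrogen": _hydrogen_for_site(site, rng, prochirality),
            "d": d,
            "theta": theta,
            "passed": passed,
            "conformer": conformer,
            "branch_torsion": branch_torsion,
        }


def sample_records(spec: GeneratorSpec):
    """Record-level generation: (records_by_frame, plans, truth).

    The presented site's chosen hydrogen carries the sampled (d, theta);
    every other hydrogen is pushed out by ``background_offset`` plus noise,
    so the presented hydrogen is the closest by construction.
    """
    rng = np.random.default_rng(spec.seed)
    prochirality = fragment_prochirality()
    site_layout: list[tuple[str, tuple[str, ...]]] = [
        ("omega", SITE_HYDROGENS["omega"]),
        ("omega-1", SITE_HYDROGENS["omega-1"]),
    ]
    for parent in ("omega-2", "omega-3"):
        for h, lab in prochirality[parent].items():
            site_layout.append((parent + ("R" if lab == "pro-R" else "S"), (h,)))

    records_by_frame: list[list[GeometricRecord]] = []
    plans: list[dict] = []
    for plan in sample_frame_plans(spec, rng):
        plans.append(plan)
        recs: list[GeometricRecord] = []
        for site, hnames in site_layout:
            for h in hnames:
                if site == plan["site"] and h == plan["hydrogen"]:
                    d, theta = plan["d"], plan["theta"]
                else:
                    d = plan["d"] + spec.background_offset + abs(rng.normal(0.0, 0.3))
                    theta = float(rng.uniform(30.0, 170.0))
                recs.append(
                    GeometricRecord(
                        frame_index=plan["frame"],
                        site_label=site,
                        hydrogen=(TAIL_RESID, h),
                        d=d,
                        theta=theta,
                    )
                )
        records_by_frame.append(recs)
    return records_by_frame, plans, spec.truth()


# ---------------------------------------------------------------------------
# Coordinate-level generation
# ---------------------------------------------------------------------------

def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a onto unit vector b (Rodrigues)."""
    c = float(np.dot(a, b))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        axis = np.cross(a, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(axis) < 1e-9:
            axis = np.cross(a, np.array([0.0, 1.0, 0.0]))
        axis = _unit(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    v = np.cross(a, b)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K / (1.0 + c)


def _axis_rotation(axis: np.ndarray, psi: float) -> np.ndarray:
    axis = _unit(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(psi) * K + (1 - math.cos(psi)) * (K @ K)


def build_frames(spec: GeneratorSpec, mirror: bool = False) -> tuple[Trajectory, list[dict]]:
    """Construct coordinate frames realizing each frame plan exactly.

    Returns the trajectory and the per-frame plans (the generation truth).
    With ``mirror=True`` every coordinate's x is negated after construction,
    which swaps all pro-R/pro-S relationships while leaving every distance
    and angle unchanged.
    """
    rng = np.random.default_rng(spec.seed)
    oxo = np.array([0.0, 0.0, FE_OXO_DISTANCE])
    # O -> Fe points along -z
    frames: list[Frame] = []
    plans: list[dict] = []
    for plan in sample_frame_plans(spec, rng):
        plans.append(plan)
        template = build_tail_template(plan["branch_torsion"])
        jitter = {n: rng.normal(0.0, 0.01, size=3) for n in template}
        template = {n: p + jitter[n] for n, p in template.items()}
        h_name = plan["hydrogen"]
        c_name = SITE_CARBON[plan["site"].rstrip("RS") if plan["site"][-1] in "RS"
                             else plan["site"]]
        d, theta_deg = plan["d"], plan["theta"]
        theta = math.radians(theta_deg)
        placed = None
        for _attempt in range(200):
            phi = rng.uniform(0.0, 2.0 * math.pi)
            u = np.array(
                [math.sin(theta) * math.cos(phi),
                 math.sin(theta) * math.sin(phi),
                 -math.cos(theta)]
            )  # angle(u, O->Fe) = theta since O->Fe is -z
            target_h = oxo + d * u
            w = _unit(template[c_name] - template[h_name])
            R = _axis_rotation(u, rng.uniform(0.0, 2.0 * math.pi)) @ _rotation_between(w, u)
            pos = {
                n: R @ (p - template[h_name]) + target_h for n, p in template.items()
            }
            d_others = [
                np.linalg.norm(pos[n] - oxo)
                for n in SITE_H_NAMES
                if n != h_name
            ]
            if min(d_others) > d + 0.05 and all(
                np.linalg.norm(pos[n]) > 1.2 for n in pos  # keep off the iron
            ):
                placed = pos
                break
        if placed is None:
            raise ContractError(
                f"frame {plan['frame']}: could not place the tail without a "
                "closer competing hydrogen"
            )
        atoms: list[AtomRecord] = []
        serial = 1
        for name, element, x, y, z in HEME_ATOMS:
            atoms.append(AtomRecord(serial, name, element, "CPI", 1,
                                    np.array([x, y, z])))
            serial += 1
        for name in TAIL_ATOMS:
            atoms.append(
                AtomRecord(serial, name, "H" if name.startswith("H") else "C",
                           TAIL_RESNAME, TAIL_RESID, placed[name])
            )
            serial += 1
        if mirror:
            for a in atoms:
                a.position = a.position * np.array([-1.0, 1.0, 1.0])
        frames.append(Frame(index=plan["frame"], atoms=atoms))
    return Trajectory(frames=frames), plans


def emit_pdb_trajectory(
    spec: GeneratorSpec,
    path: str | Path,
    truth_path: str | Path | None = None,
    mirror: bool = False,
) -> dict:
    """Write a synthetic multi-model PDB (and optional truth JSON); returns truth."""
    trajectory, plans = build_frames(spec, mirror=mirror)
    write_multimodel_pdb(trajectory, path)
    truth = spec.truth()
    truth["mirror"] = mirror
    if truth_path is not None:
        with Path(truth_path).open("w") as fh:
            json.dump(truth, fh, indent=2)
    return truth
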