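"""Structure data model and I/O.

Atoms, frames and trajectories with a constant-topology contract, a
multi-model PDB reader/writer (the reference trajectory path), optional
binary-trajectory reading through MDAnalysis, TSV persistence for geometric
records, and resolution of YAML site definitions against a trajectory.

Unit policy (enforced at every I/O boundary): coordinates in Angstrom,
angles in degrees, energies in kJ/mol. Frames are 0-indexed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from omega_access.errors import (
    ConfigurationError,
    ContractError,
    ParseError,
    TopologyError,
)

# Canonical ASCII site vocabulary. Greek forms are accepted on input and
# normalized; the order below is the tie-break order used when two hydrogens
# are exactly equidistant from the oxo atom (terminal site wins).
SITE_ORDER: tuple[str, ...] = (
    "omega",
    "omega_prime",
    "omega_dblprime",
    "omega-1",
    "omega-2",
    "omega-2R",
    "omega-2S",
    "omega-3",
    "omega-3R",
    "omega-3S",
)

_SITE_ALIASES: dict[str, str] = {
    "ω": "omega",
    "ω′": "omega_prime",
    "ω'": "omega_prime",
    "ω″": "omega_dblprime",
    "ω''": "omega_dblprime",
    "w": "omega",
}
for _suffix in ("-1", "-2", "-2R", "-2S", "-3", "-3R", "-3S"):
    _SITE_ALIASES["ω" + _suffix] = "omega" + _suffix
    _SITE_ALIASES["w" + _suffix] = "omega" + _suffix


def normalize_site_label(label: str) -> str:
    """Map a site label (Greek or ASCII spelling) to its canonical form."""
    label = label.strip()
    return _SITE_ALIASES.get(label, label)


def site_sort_key(label: str) -> tuple[int, str]:
    """Sort key implementing the documented site ordering (unknown labels last)."""
    try:
        return (SITE_ORDER.index(label), label)
    except ValueError:
        return (len(SITE_ORDER), label)


# An atom selector is a (residue_id, atom_name) pair; serial numbers are
# never used for selection because MD tools renumber them freely.
Selector = tuple[int, str]


@dataclass(slots=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not self.element:
            raise ValueError("element symbol must be non-empty")
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")


@dataclass(slots=True)
class Frame:
    """One snapshot: an ordered atom list with an optional time stamp (ps)."""

    index: int
    atoms: list[AtomRecord]
    time: float | None = None
    _index_map: dict[Selector, int] = field(default=None, repr=False)  # type: ignore[assignment]
    _coords: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def topology_signature(self) -> tuple[tuple[str, str, int], ...]:
        return tuple((a.name, a.element, a.residue_id) for a in self.atoms)

    @property
    def coords(self) -> np.ndarray:
        if self._coords is None:
            self._coords = np.array([a.position for a in self.atoms])
        return self._coords

    def atom_index(self, selector: Selector) -> int:
        if self._index_map is None:
            self._index_map = {
                (a.residue_id, a.name): i for i, a in enumerate(self.atoms)
            }
        try:
            return self._index_map[(selector[0], selector[1])]
        except KeyError:
            raise TopologyError(
                f"selector (residue {selector[0]}, atom {selector[1]!r}) does not "
                f"resolve in frame {self.index}"
            ) from None

    def position(self, selector: Selector) -> np.ndarray:
        return self.atoms[self.atom_index(selector)].position


@dataclass
class Trajectory:
    """Ordered frames sharing one topology (same atom names/elements/order)."""

    frames: list[Frame]
    topology_hash: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise ContractError("a trajectory needs at least one frame")
        ref = self.frames[0].topology_signature()
        for fr in self.frames[1:]:
            if fr.topology_signature() != ref:
                raise TopologyError(
                    f"frame {fr.index} does not share the topology of frame "
                    f"{self.frames[0].index} (atom count/names/order differ)"
                )
        if not self.topology_hash:
            h = hashlib.sha1()
            for name, element, resid in ref:
                h.update(f"{name}:{element}:{resid};".encode())
            self.topology_hash = h.hexdigest()

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


@dataclass(frozen=True)
class ReactiveCenter:
    """Selectors for the heme iron and its oxo oxygen (Compound I)."""

    iron: Selector
    oxo: Selector


@dataclass
class SiteDefinition:
    """A candidate hydrogen-abstraction site on the substrate.

    ``neighbor_carbons`` orders the two heavy substituents of a prochiral
    carbon as (toward the omega end, toward the rest of the chain); this
    ordering fixes the substituent priorities used for pro-R/pro-S labels.
    """

    label: str
    carbon: Selector
    hydrogens: list[Selector]
    prochiral: bool = False
    neighbor_carbons: tuple[Selector, Selector] | None = None
    parent_label: str | None = None

    def __post_init__(self) -> None:
        self.label = normalize_site_label(self.label)
        if self.label == "omega" and len(self.hydrogens) != 3:
            raise ConfigurationError(
                f"omega site must carry exactly 3 hydrogens, got {len(self.hydrogens)}"
            )
        if self.label != "omega" and len(self.hydrogens) > 2:
            raise ConfigurationError(
                f"internal site {self.label!r} may carry at most 2 hydrogens"
            )


# ---------------------------------------------------------------------------
# Multi-model PDB
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, line_number: int, serial_fallback: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = serial_fallback
    name = line[12:16].strip()
    residue_name = line[17:20].strip()
    try:
        residue_id = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise ParseError(f"malformed ATOM/HETATM record: {exc}", line_number)
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back on the leading letter of the atom name, PDB v2 style
        element = name.lstrip("0123456789")[:1]
    if not name or not element:
        raise ParseError("ATOM/HETATM record lacks an atom name/element", line_number)
    return AtomRecord(serial, name, element, residue_name, residue_id, np.array([x, y, z]))


def read_multimodel_pdb(path: str | Path) -> Trajectory:
    """Read a (possibly multi-MODEL) PDB file as a trajectory.

    One frame per MODEL/ENDMDL block; a file without MODEL records yields a
    single-frame trajectory. Atom order is preserved. A topology mismatch
    between models raises :class:`TopologyError` naming the offending frame.
    """
    path = Path(path)
    frames: list[Frame] = []
    current: list[AtomRecord] | None = None
    in_model = False
    saw_model = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                in_model = True
                current = []
            elif rec == "ENDMDL":
                if current is None:
                    raise ParseError("ENDMDL without a matching MODEL", lineno)
                frames.append(Frame(index=len(frames), atoms=current))
                current = None
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                atom = _parse_atom_line(line, lineno, serial_fallback=0)
                if in_model:
                    current.append(atom)  # type: ignore[union-attr]
                else:
                    if saw_model:
                        # stray atoms between models are a format violation
                        raise ParseError("ATOM record outside MODEL block", lineno)
                    if current is None:
                        current = []
                    current.append(atom)
    if current and not saw_model:
        frames.append(Frame(index=0, atoms=current))
    if not frames:
        raise ParseError(f"no coordinates found in {path}")
    return Trajectory(frames=frames)


def write_multimodel_pdb(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (HETATM records, 3-dp coordinates)."""
    path = Path(path)
    with path.open("w") as fh:
        for fr in trajectory.frames:
            fh.write(f"MODEL     {fr.index + 1:4d}\n")
            for a in fr.atoms:
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                x, y, z = a.position
                fh.write(
                    f"HETATM{a.serial:5d} {name:<4s}{a.residue_name:>4s}  "
                    f"{a.residue_id:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"  1.00  0.00          {a.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_trajectory(
    path: str | Path, topology: str | Path | None = None
) -> Trajectory:
    """Read a trajectory in PDB or a binary format (XTC/TRR/DCD).

    PDB files go through :func:`read_multimodel_pdb`. Binary formats need a
    PDB ``topology`` and are converted through MDAnalysis (coordinates come
    back in Angstrom) behind the same :class:`Trajectory` contract.
    """
    path = Path(path)
    if path.suffix.lower() in (".pdb", ".ent") or topology is None:
        return read_multimodel_pdb(path)
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ConfigurationError(
            "reading binary trajectories requires the 'trajectories' extra (MDAnalysis)"
        ) from exc
    u = mda.Universe(str(topology), str(path))
    frames: list[Frame] = []
    for i, ts in enumerate(u.trajectory):
        atoms = [
            AtomRecord(
                serial=int(a.id),
                name=str(a.name),
                element=str(getattr(a, "element", "") or a.name[:1]),
                residue_name=str(a.resname),
                residue_id=int(a.resid),
                position=np.array(a.position, dtype=float),
            )
            for a in u.atoms
        ]
        frames.append(Frame(index=i, atoms=atoms, time=float(ts.time)))
    return Trajectory(frames=frames)


# ---------------------------------------------------------------------------
# Geometric-record TSV
# ---------------------------------------------------------------------------

RECORD_COLUMNS = ("frame", "site", "hydrogen_residue_id", "hydrogen_name",
                  "d_angstrom", "theta_degrees")


def write_records_tsv(records: Iterable, path: str | Path) -> None:
    """Persist geometric records as TSV, ordered by (frame, site, hydrogen name)."""
    rows = [
        {
            "frame": r.frame_index,
            "site": r.site_label,
            "hydrogen_residue_id": r.hydrogen[0],
            "hydrogen_name": r.hydrogen[1],
            "d_angstrom": r.d,
            "theta_degrees": r.theta,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
    if len(df):
        df["_site_order"] = [site_sort_key(s)[0] for s in df["site"]]
        df = df.sort_values(
            ["frame", "_site_order", "site", "hydrogen_name"], kind="stable"
        ).drop(columns="_site_order")
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_records_tsv(path: str | Path) -> list:
    """Read back records written by :func:`write_records_tsv`."""
    from omega_access.geometry import GeometricRecord

    df = pd.read_csv(path, sep="\t")
    return [
        GeometricRecord(
            frame_index=int(row.frame),
            site_label=str(row.site),
            hydrogen=(int(row.hydrogen_residue_id), str(row.hydrogen_name)),
            d=float(row.d_angstrom),
            theta=float(row.theta_degrees),
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Site configuration
# ---------------------------------------------------------------------------

def _as_selector(obj, context: str) -> Selector:
    if (
        not isinstance(obj, (list, tuple))
        or len(obj) != 2
        or not isinstance(obj[1], str)
    ):
        raise ConfigurationError(
            f"{context}: selector must be a [residue_id, atom_name] pair, got {obj!r}"
        )
    return (int(obj[0]), str(obj[1]))


def load_site_config(path: str | Path) -> dict:
    """Load a YAML site-definition document (see the packaged vk1_sites.yaml)."""
    with Path(path).open() as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "sites" not in doc or "reactive_center" not in doc:
        raise ConfigurationError(
            "site config must define 'reactive_center' and 'sites'"
        )
    return dict(doc)


def load_packaged_site_config() -> dict:
    """The site-definition document for the packaged synthetic VK1 fragment."""
    from importlib import resources

    text = (resources.files("omega_access.data") / "vk1_sites.yaml").read_text()
    doc = yaml.safe_load(text)
    return dict(doc)


def resolve_reactive_center(config: Mapping, trajectory: Trajectory) -> ReactiveCenter:
    rc = config["reactive_center"]
    iron = _as_selector(rc["iron"], "reactive_center.iron")
    oxo = _as_selector(rc["oxo"], "reactive_center.oxo")
    frame0 = trajectory.frames[0]
    for sel, elem in ((iron, "FE"), (oxo, "O")):
        try:
            atom = frame0.atoms[frame0.atom_index(sel)]
        except TopologyError as exc:
            raise ConfigurationError(str(exc)) from exc
        if atom.element.upper() != elem and not (elem == "FE" and atom.element.upper() == "FE"):
            raise ConfigurationError(
                f"reactive-center atom {sel} has element {atom.element!r}, expected {elem}"
            )
    return ReactiveCenter(iron=iron, oxo=oxo)


def resolve_sites(config: Mapping, trajectory: Trajectory) -> list[SiteDefinition]:
    """Resolve YAML site entries against frame 0 and split prochiral sites.

    Prochiral sites (exactly two hydrogens, ``prochiral: true``) are split
    into R/S-labelled single-hydrogen definitions using the pro-R/pro-S
    assignment on frame 0; the assignment is held fixed afterwards because
    the topology is constant.
    """
    from omega_access.geometry import assign_prochirality

    frame0 = trajectory.frames[0]
    resolved: list[SiteDefinition] = []
    for entry in config["sites"]:
        label = normalize_site_label(str(entry["label"]))
        carbon = _as_selector(entry["carbon"], f"site {label}: carbon")
        hydrogens = [
            _as_selector(h, f"site {label}: hydrogen") for h in entry["hydrogens"]
        ]
        prochiral = bool(entry.get("prochiral", False))
        neighbors = entry.get("neighbor_carbons")
        for sel in [carbon, *hydrogens]:
            try:
                frame0.atom_index(sel)
            except TopologyError as exc:
                raise ConfigurationError(str(exc)) from exc
        site = SiteDefinition(
            label=label,
            carbon=carbon,
            hydrogens=hydrogens,
            prochiral=prochiral,
            neighbor_carbons=(
                tuple(_as_selector(n, f"site {label}: neighbor") for n in neighbors)
                if neighbors
                else None
            ),
        )
        if not prochiral:
            resolved.append(site)
            continue
        if len(hydrogens) != 2 or site.neighbor_carbons is None:
            raise ConfigurationError(
                f"prochiral site {label!r} needs exactly 2 hydrogens and "
                "neighbor_carbons [toward_omega, toward_chain]"
            )
        toward_omega, toward_chain = site.neighbor_carbons
        labels = assign_prochirality(
            frame0.position(carbon),
            frame0.position(hydrogens[0]),
            frame0.position(hydrogens[1]),
            frame0.position(toward_omega),
            frame0.position(toward_chain),
        )
        for h, key in zip(hydrogens, ("h1", "h2")):
            suffix = "R" if labels[key] == "pro-R" else "S"
            resolved.append(
                SiteDefinition(
                    label=f"{label}{suffix}",
                    carbon=carbon,
                    hydrogens=[h],
                    prochiral=True,
                    neighbor_carbons=site.neighbor_carbons,
                    parent_label=label,
                )
            )
    resolved.sort(key=lambda s: site_sort_key(s.label))
    return resolved
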