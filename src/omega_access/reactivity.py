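"""Intrinsic hydrogen-abstraction reactivity and accessibility-vs-reactivity ranking.

The packaged reference table carries DFT activation energies (kJ/mol) for
hydrogen abstraction by a truncated Compound I model at each candidate site
of the vitamin K1 tail, for the two terminal-chain conformers. The three
terminal methyl hydrogens appear as separate entries (omega, omega_prime,
omega_dblprime) in conformer 1 only. These numbers are reference data —
recomputing them is electronic-structure work outside this package's scope.

The central comparison: the terminal (omega) site has the HIGHEST intrinsic
barrier — C-H bonds are strongest there — yet it dominates the trajectory
accessibility profile, so a ranking that follows accessibility first
reproduces the experimentally observed regioselectivity while a pure
reactivity ranking does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from omega_access.accessibility import AccessibilityProfile
from omega_access.errors import ContractError
from omega_access.structures_io import normalize_site_label, site_sort_key

OMEGA_FAMILY = ("omega", "omega_prime", "omega_dblprime")


@dataclass
class ReactivityTable:
    """Activation energies (kJ/mol) keyed by (site_label, conformer)."""

    entries: dict[tuple[str, int], float]
    provenance: str = ""

    def __post_init__(self) -> None:
        import math

        for (site, conf), e in self.entries.items():
            if not (math.isfinite(e) and e > 0):
                raise ValueError(f"non-positive/non-finite energy for ({site}, {conf})")

    def lookup(self, site: str, conformer: int) -> float | None:
        """Energy for (site, conformer), or None where the table has no entry."""
        return self.entries.get((normalize_site_label(site), conformer))

    def sites(self) -> list[str]:
        return sorted({s for s, _ in self.entries}, key=site_sort_key)

    def min_barrier(self, site: str) -> float:
        """Minimum barrier for a site across conformers (family-collapsed for omega)."""
        site = normalize_site_label(site)
        family = OMEGA_FAMILY if site == "omega" else (site,)
        vals = [e for (s, _), e in self.entries.items() if s in family]
        if not vals:
            raise ContractError(f"no table entries for site {site!r}")
        return min(vals)


@dataclass
class SomRanking:
    """An ordered list of candidate sites of metabolism with per-site notes."""

    order: list[str]
    basis: str  # accessibility | reactivity | combined
    notes: dict[str, str] = field(default_factory=dict)


def load_table(path: str | Path) -> ReactivityTable:
    """Load a user-supplied TSV (columns site, conformer, activation_energy_kj_mol)."""
    df = pd.read_csv(path, sep="\t")
    entries = {
        (normalize_site_label(str(r.site)), int(r.conformer)): float(
            r.activation_energy_kj_mol
        )
        for r in df.itertuples()
    }
    return ReactivityTable(entries=entries, provenance=str(path))


def load_table1() -> ReactivityTable:
    """The packaged vitamin K1 activation-energy reference table (14 entries)."""
    ref = resources.files("omega_access.data") / "activation_energies_vk1.tsv"
    with resources.as_file(ref) as p:
        table = load_table(p)
    table.provenance = "packaged DFT activation energies for the truncated VK1 tail"
    return table


def omega_excess_range(table: ReactivityTable) -> tuple[float, float]:
    """(min, max) over all pairwise (omega-family energy − non-omega energy).

    Quantifies how much harder the terminal hydrogens are to abstract than
    any internal site, across both conformers.
    """
    omega_vals = [e for (s, _), e in table.entries.items() if s in OMEGA_FAMILY]
    other_vals = [e for (s, _), e in table.entries.items() if s not in OMEGA_FAMILY]
    if not omega_vals or not other_vals:
        raise ContractError("omega_excess_range: need omega-family and non-omega entries")
    diffs = [o - x for o in omega_vals for x in other_vals]
    return (min(diffs), max(diffs))


def conformer_shift(table: ReactivityTable) -> dict[str, float]:
    """Per-site conformer-1 minus conformer-2 barrier; sites missing either are omitted."""
    out = {}
    for site in table.sites():
        e1 = table.lookup(site, 1)
        e2 = table.lookup(site, 2)
        if e1 is not None and e2 is not None:
            out[site] = e1 - e2
    return dict(sorted(out.items(), key=lambda kv: site_sort_key(kv[0])))


def _collapse_to_table_sites(
    freqs: dict[str, float], table: ReactivityTable
) -> dict[str, float]:
    table_sites = set(table.sites())
    out: dict[str, float] = {}
    for site, f in freqs.items():
        s = normalize_site_label(site)
        if s in OMEGA_FAMILY:
            s = "omega"
        if s not in table_sites and s != "omega":
            raise ContractError(f"profile site {site!r} has no reactivity entry")
        out[s] = out.get(s, 0.0) + f
    return out


def rank_sites(
    profile: AccessibilityProfile,
    table: ReactivityTable,
    basis: str = "combined",
) -> SomRanking:
    """Rank candidate sites of metabolism.

    - ``accessibility``: descending frequency among criteria-satisfying
      frames (table ignored; sites absent from the profile rank last).
    - ``reactivity``: ascending minimum barrier per site, omega collapsed to
      its most reactive hydrogen.
    - ``combined``: accessibility order with reactivity only breaking exact
      frequency ties; per-site notes flag rank conflicts between the two
      orderings.
    """
    if basis not in ("accessibility", "reactivity", "combined"):
        raise ContractError(f"unknown ranking basis {basis!r}")
    freqs = _collapse_to_table_sites(profile.site_frequencies, table)
    ranked_sites = sorted(
        {("omega" if s in OMEGA_FAMILY else s) for s in table.sites()},
        key=site_sort_key,
    )
    barrier = {s: table.min_barrier(s) for s in ranked_sites}
    freq = {s: freqs.get(s, 0.0) for s in ranked_sites}

    if basis == "accessibility":
        order = sorted(ranked_sites, key=lambda s: (-freq[s], site_sort_key(s)))
    elif basis == "reactivity":
        order = sorted(ranked_sites, key=lambda s: (barrier[s], site_sort_key(s)))
    else:
        order = sorted(ranked_sites, key=lambda s: (-freq[s], barrier[s], site_sort_key(s)))

    notes: dict[str, str] = {}
    acc_order = sorted(ranked_sites, key=lambda s: (-freq[s], site_sort_key(s)))
    rea_order = sorted(ranked_sites, key=lambda s: (barrier[s], site_sort_key(s)))
    for s in ranked_sites:
        ra, rr = acc_order.index(s), rea_order.index(s)
        if ra != rr:
            notes[s] = (
                f"accessibility rank {ra + 1} vs reactivity rank {rr + 1} "
                f"(freq {freq[s]:.3f}, min barrier {barrier[s]:.2f} kJ/mol)"
            )
    return SomRanking(order=order, basis=basis, notes=notes)
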