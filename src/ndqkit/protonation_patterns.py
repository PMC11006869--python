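"""Protonation-pattern enumeration and energy-based model selection.

The Schiff-base counterion complex of the Subgroup-2 sodium pump consists of
three titratable carboxylic residues (E64, D105, D242).  Each residue is
either deprotonated or protonated with the proton in one of four starting
orientations, and patterns with up to two protonated residues are
considered; with three residues and four orientations this gives
1 + 3*4 + 3*4^2 = 61 patterns (1 zero-, 12 single-, 48 double-protonation).

Quantum-chemical energies for each pattern are computed elsewhere; this
module consumes the resulting table and applies the selection rule: keep the
patterns whose vertical excitation energy falls within the method's error
window of the experimental value, then choose the one with the lowest
ground-state energy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ProtonationPattern",
    "PatternEnergyRecord",
    "ModelSelection",
    "DEFAULT_RESIDUES",
    "enumerate_patterns",
    "count_by_level",
    "select_consistent_model",
    "ev_from_nm",
    "nm_from_ev",
    "patterns_to_frame",
]

DEFAULT_RESIDUES = ("E64", "D105", "D242")

# hc in eV*nm, for converting an absorption maximum to an excitation energy
HC_EV_NM = 1239.842

DEPROTONATED = 0


@dataclass(frozen=True)
class ProtonationPattern:
    """Per-residue protonation state: 0 = deprotonated, 1..k = orientation."""

    residues: tuple[str, ...]
    states: tuple[int, ...]

    def __post_init__(self):
        if len(self.residues) != len(self.states):
            raise ValueError("residues/states length mismatch")
        if any(s < 0 for s in self.states):
            raise ValueError("states must be >= 0")

    @property
    def n_protons(self) -> int:
        return sum(1 for s in self.states if s != DEPROTONATED)

    @property
    def label(self) -> str:
        return "|".join(
            f"{r}:{'d' if s == DEPROTONATED else f'p{s}'}"
            for r, s in zip(self.residues, self.states)
        )


@dataclass(frozen=True)
class PatternEnergyRecord:
    pattern_id: str
    ground_state_energy: float
    energy_unit: str          # e.g. 'hartree' or 'kJ/mol'
    vertical_excitation_eV: float


@dataclass
class ModelSelection:
    consistent: bool
    chosen: list[str]                  # lowest-ground-energy ids (all ties)
    shortlist: list[PatternEnergyRecord]  # in-window records, energy-ranked


def enumerate_patterns(
    residues: tuple[str, ...] = DEFAULT_RESIDUES,
    n_orientations: int = 4,
    max_protonated: int = 2,
) -> list[ProtonationPattern]:
    """All protonation patterns up to ``max_protonated`` protonated residues.

    Canonical deterministic order: by proton count, then lexicographically by
    the state tuple.  Total count is sum_k C(n, k) * n_orientations^k.
    """
    n = len(residues)
    if n_orientations < 1 or max_protonated < 0:
        raise ValueError("parameters must be non-negative (orientations >= 1)")
    if max_protonated > n:
        raise ValueError("max_protonated exceeds number of residues")
    patterns = []
    for k in range(max_protonated + 1):
        level = []
        for which in itertools.combinations(range(n), k):
            for orients in itertools.product(range(1, n_orientations + 1), repeat=k):
                states = [DEPROTONATED] * n
                for idx, o in zip(which, orients):
                    states[idx] = o
                level.append(ProtonationPattern(residues=tuple(residues), states=tuple(states)))
        level.sort(key=lambda p: p.states)
        patterns.extend(level)
    return patterns


def count_by_level(patterns: list[ProtonationPattern]) -> dict[int, int]:
    """Pattern counts keyed by number of protonated residues."""
    counts: dict[int, int] = {}
    for p in patterns:
        counts[p.n_protons] = counts.get(p.n_protons, 0) + 1
    return counts


def select_consistent_model(
    table: list[PatternEnergyRecord],
    experimental_excitation_eV: float,
    tolerance_eV: float = 0.3,
    required_proton_count: int | None = None,
    proton_counts: dict[str, int] | None = None,
) -> ModelSelection:
    """Excitation-window shortlist, then lowest ground-state energy.

    The shortlist contains records with |E_exc - E_experimental| <=
    tolerance_eV (optionally restricted to a given proton count, which
    requires ``proton_counts`` mapping record ids to counts), ranked by
    ground-state energy.  The chosen list holds every record tied at the
    minimum.  An empty shortlist yields ``consistent=False`` rather than an
    exception.  Mixed energy units are rejected.
    """
    if not table:
        raise ValueError("empty energy table")
    units = {r.energy_unit for r in table}
    if len(units) > 1:
        raise ValueError(f"mixed energy units {sorted(units)}")
    shortlist = [
        r
        for r in table
        if abs(r.vertical_excitation_eV - experimental_excitation_eV) <= tolerance_eV
    ]
    if required_proton_count is not None:
        if proton_counts is None:
            raise ValueError("proton_counts required to filter by proton count")
        shortlist = [
            r for r in shortlist if proton_counts.get(r.pattern_id) == required_proton_count
        ]
    if not shortlist:
        return ModelSelection(consistent=False, chosen=[], shortlist=[])
    shortlist = sorted(shortlist, key=lambda r: (r.ground_state_energy, r.pattern_id))
    best = shortlist[0].ground_state_energy
    chosen = [r.pattern_id for r in shortlist if r.ground_state_energy == best]
    return ModelSelection(consistent=True, chosen=chosen, shortlist=shortlist)


def ev_from_nm(wavelength_nm: float) -> float:
    """Photon energy (eV) of a wavelength (nm): E = 1239.842 / λ."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return HC_EV_NM / wavelength_nm


def nm_from_ev(energy_eV: float) -> float:
    if energy_eV <= 0:
        raise ValueError("energy must be positive")
    return HC_EV_NM / energy_eV


def patterns_to_frame(patterns: list[ProtonationPattern]) -> pd.DataFrame:
    """Tabular view: one row per pattern with per-residue state columns."""
    rows = []
    for i, p in enumerate(patterns):
        row = {"pattern_id": f"m{i + 1}", "label": p.label, "n_protons": p.n_protons}
        for r, s in zip(p.residues, p.states):
            row[r] = "deprotonated" if s == DEPROTONATED else f"protonated@{s}"
        rows.append(row)
    return pd.DataFrame(rows)
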