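"""Coordinate-level metrics: contact distances, Kabsch RMSD, residue counts.

The quantities of interest are simple but must be computed reproducibly from
deposited coordinates: the shortest carboxyl-oxygen contact between the
counterion residues (the low-barrier-hydrogen-bond signature, ~2.1 Å between
E64 and D105), Schiff-base distances, Cα RMSD between models determined at
different pH or by different techniques, and the span of modeled residues.

PDB/mmCIF parsing is delegated to gemmi; a flat :class:`StructureModel`
(list of atoms with one coordinate set after alt-loc resolution) is the
in-memory container the metrics operate on.  The Kabsch superposition is
implemented here (SVD with determinant correction); tests cross-check it
against an independent quaternion-method oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import gemmi

__all__ = [
    "Atom",
    "StructureModel",
    "SuperpositionResult",
    "read_structure",
    "write_pdb",
    "select_atoms",
    "min_distance",
    "kabsch_superpose",
    "kabsch_rmsd",
    "modeled_residue_range",
    "schiff_base_nitrogen",
]

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class Atom:
    chain: str
    res_number: int
    res_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    alt_loc: str = ""

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class StructureModel:
    """Flat atom list with one coordinate per atom site."""

    atoms: list[Atom]
    source_format: str = "unknown"

    def __post_init__(self):
        seen = set()
        for a in self.atoms:
            key = (a.chain, a.res_number, a.atom_name, a.alt_loc)
            if key in seen:
                raise ValueError(f"duplicate atom {key}")
            seen.add(key)
            if not np.all(np.isfinite(a.xyz)):
                raise ValueError(f"non-finite coordinates for {key}")

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms])

    def chains(self) -> list[str]:
        out = []
        for a in self.atoms:
            if a.chain not in out:
                out.append(a.chain)
        return out


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms_used: int
    selection: str = ""


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one alt-loc per atom site: highest occupancy, ties prefer 'A'."""
    groups: dict[tuple, list[Atom]] = {}
    order = []
    for a in atoms:
        key = (a.chain, a.res_number, a.res_name, a.atom_name)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(a)
    out = []
    for key in order:
        cands = groups[key]
        best = sorted(
            cands, key=lambda a: (-a.occupancy, a.alt_loc != "A", a.alt_loc)
        )[0]
        out.append(
            Atom(
                chain=best.chain,
                res_number=best.res_number,
                res_name=best.res_name,
                atom_name=best.atom_name,
                element=best.element,
                x=best.x, y=best.y, z=best.z,
                occupancy=best.occupancy,
                alt_loc="",
            )
        )
    return out


def read_structure(source: str | Path, fmt: str | None = None) -> StructureModel:
    """Load ATOM/HETATM records from a PDB or mmCIF file (or literal text).

    ``fmt`` ('pdb' or 'mmcif') is required when ``source`` is a text block;
    for paths it is inferred from the suffix.  Alternate locations are
    resolved to the highest-occupancy conformer (ties prefer 'A').
    """
    text = None
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(path)
        if fmt is None:
            fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
        text = path.read_text()
    else:
        text = str(source)
        if fmt is None:
            raise ValueError("fmt required when reading from a text block")

    if not text.strip():
        raise ValueError("empty structure input")

    if fmt == "pdb":
        st = gemmi.read_pdb_string(text)
    elif fmt == "mmcif":
        doc = gemmi.cif.read_string(text)
        st = gemmi.make_structure_from_block(doc.sole_block())
    else:
        raise ValueError(f"unknown format {fmt!r}")

    atoms = []
    if len(st) == 0:
        raise ValueError("no models in structure")
    model = st[0]
    for chain in model:
        for res in chain:
            for at in res:
                atoms.append(
                    Atom(
                        chain=chain.name,
                        res_number=res.seqid.num,
                        res_name=res.name,
                        atom_name=at.name,
                        element=at.element.name.upper(),
                        x=at.pos.x, y=at.pos.y, z=at.pos.z,
                        occupancy=at.occ,
                        alt_loc=at.altloc.strip() if at.altloc else "",
                    )
                )
    if not atoms:
        raise ValueError("no atoms parsed")
    return StructureModel(atoms=_resolve_altlocs(atoms), source_format=fmt)


def write_pdb(model: StructureModel, path: str | Path | None = None) -> str:
    """Write the toy PDB dialect (fixed-column ATOM records + END)."""
    lines = []
    for i, a in enumerate(model.atoms, start=1):
        name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
        lines.append(
            f"ATOM  {i:5d} {name}{'':1s}{a.res_name:<3s} {a.chain:1s}"
            f"{a.res_number:4d}    {a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
            f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
        )
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def _parse_residue_spec(spec: str) -> tuple[str | None, int]:
    """'E64' / 'GLU64' / '64' -> (residue name or None, number)."""
    spec = spec.strip()
    i = 0
    while i < len(spec) and not spec[i].isdigit():
        i += 1
    name, num = spec[:i], spec[i:]
    if not num:
        raise ValueError(f"residue spec {spec!r} has no number")
    number = int(num)
    if not name:
        return None, number
    name = name.upper()
    if len(name) == 1:
        name = THREE_LETTER.get(name, name)
    return name, number


def select_atoms(model: StructureModel, selection: str) -> list[Atom]:
    """Select atoms by a 'chain/residue/atoms' pattern.

    Examples: ``A/E64/OE1,OE2`` (carboxyl oxygens of Glu 64 in chain A),
    ``A/105/*`` (all atoms of residue 105), ``*/*/CA`` (all Cα atoms).
    """
    parts = selection.split("/")
    if len(parts) != 3:
        raise ValueError(f"selection {selection!r} must be chain/residue/atoms")
    chain_pat, res_pat, atom_pat = (p.strip() for p in parts)
    res_name = res_num = None
    if res_pat != "*":
        res_name, res_num = _parse_residue_spec(res_pat)
    atom_names = None if atom_pat == "*" else {a.strip().upper() for a in atom_pat.split(",")}
    out = []
    for a in model.atoms:
        if chain_pat != "*" and a.chain != chain_pat:
            continue
        if res_num is not None and a.res_number != res_num:
            continue
        if res_name is not None and a.res_name.upper() != res_name:
            continue
        if atom_names is not None and a.atom_name.upper() not in atom_names:
            continue
        out.append(a)
    if not out:
        raise ValueError(f"selection {selection!r} matched no atoms")
    return out


def min_distance(
    model: StructureModel, selection_a: str, selection_b: str
) -> tuple[float, tuple[Atom, Atom]]:
    """Minimum Euclidean distance (Å) over the cross-product of two selections."""
    atoms_a = select_atoms(model, selection_a)
    atoms_b = select_atoms(model, selection_b)
    pa = np.array([a.xyz for a in atoms_a])
    pb = np.array([b.xyz for b in atoms_b])
    d2 = np.sum((pa[:, None, :] - pb[None, :, :]) ** 2, axis=-1)
    i, j = np.unravel_index(np.argmin(d2), d2.shape)
    return float(np.sqrt(d2[i, j])), (atoms_a[i], atoms_b[j])


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Optimal proper rigid superposition of paired point sets (P onto Q).

    Kabsch algorithm: SVD of the covariance of the centered sets with a
    determinant correction so the rotation is proper (det = +1).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("need two matched (n>=3, 3) coordinate arrays")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return SuperpositionResult(
        rotation=R, translation=t, rmsd=rmsd, n_atoms_used=P.shape[0]
    )


def kabsch_rmsd(
    model_a: StructureModel,
    model_b: StructureModel,
    selection: str = "*/*/CA",
    include_waters: bool = False,
) -> SuperpositionResult:
    """RMSD between two models after optimal superposition.

    Atoms are paired by (chain, residue number, atom name) within the
    selection (Cα by default).  Waters are excluded unless requested.
    """
    def keyed(model):
        out = {}
        for a in select_atoms(model, selection):
            if not include_waters and a.res_name in WATER_NAMES:
                continue
            out[(a.chain, a.res_number, a.atom_name)] = a
        return out

    ka, kb = keyed(model_a), keyed(model_b)
    common = sorted(set(ka) & set(kb))
    if len(common) < 3:
        raise ValueError("fewer than 3 common atoms under the pairing rule")
    P = np.array([ka[k].xyz for k in common])
    Q = np.array([kb[k].xyz for k in common])
    result = kabsch_superpose(P, Q)
    result.selection = selection
    return result


def modeled_residue_range(model: StructureModel, chain: str) -> tuple[int, int, int]:
    """(first, last, count) of residue numbers with at least one atom."""
    nums = sorted({a.res_number for a in model.atoms if a.chain == chain})
    if not nums:
        raise ValueError(f"unknown chain {chain!r}")
    return nums[0], nums[-1], len(nums)


def schiff_base_nitrogen(
    model: StructureModel, max_bond: float = 2.0
) -> Atom | None:
    """The NZ atom of the retinal-linked lysine (NZ–C15 of RET < max_bond Å)."""
    nz = [a for a in model.atoms if a.res_name == "LYS" and a.atom_name == "NZ"]
    c15 = [a for a in model.atoms if a.res_name == "RET" and a.atom_name == "C15"]
    for n in nz:
        for c in c15:
            if np.linalg.norm(n.xyz - c.xyz) < max_bond:
                return n
    return None
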