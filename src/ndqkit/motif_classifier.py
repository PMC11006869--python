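"""Reference-anchored motif classification of NDQ-rhodopsin sequence sets.

Sodium-pumping rhodopsins are recognized by the residues they carry at
functionally diagnostic positions of a reference protein (KR2): the motif
spelled by the residues aligned to KR2 R109, N112, D116, Q123, D251 and K216
reads RNDQDK in true NDQ pumps, and the residue aligned to KR2 L74 splits the
clade into Subgroup 1 (Leu/Ile) and Subgroup 2 (Glu, the extra Schiff-base
counterion).  This module maps reference residue numbers to alignment
columns, extracts per-sequence motifs, applies the motif/length/duplicate
filters, reduces the set at 90% identity with a greedy CD-HIT-style scheme,
assigns subgroups, and writes a neighbor-joining tree as plumbing for
downstream phylogenetics.

Conventions: reference residue numbers are 1-based; alignment columns are
0-based internally and 1-based in user-facing output.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO, Align
import skbio

__all__ = [
    "SequenceRecord",
    "ReferenceAnchoredAlignment",
    "MotifSpec",
    "ClassificationResult",
    "IdentityClustering",
    "KR2_ANCHOR_POSITIONS",
    "KR2_MOTIF",
    "SUBGROUP_POSITION",
    "build_reference_map",
    "extract_motif",
    "apply_filters",
    "pairwise_identity",
    "cluster_by_identity",
    "classify_subgroup",
    "nj_tree",
    "classify_alignment",
    "read_alignment_fasta",
    "write_fasta",
]

GAP = "-"
ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX" + GAP)

# KR2-numbered anchor positions in the order that spells the canonical motif.
# Note the last two anchors are listed 251 then 216, not in ascending order:
# the motif string order follows the listing order, which spells RNDQDK.
KR2_ANCHOR_POSITIONS = (109, 112, 116, 123, 251, 216)
KR2_MOTIF = "RNDQDK"
SUBGROUP_POSITION = 74

SUBGROUP_RULES = {"E": "Subgroup2", "L": "Subgroup1", "I": "Subgroup1"}


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    residues: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("empty sequence id")
        bad = set(self.residues.upper()) - ALPHABET
        if bad:
            raise ValueError(f"invalid residue letters {sorted(bad)} in {self.id}")

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass
class ReferenceAnchoredAlignment:
    """An MSA with one row designated as the numbering reference."""

    records: list[SequenceRecord]
    reference_id: str
    reference_numbering_offset: int = 1

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids")
        if self.reference_id not in ids:
            raise ValueError(f"reference {self.reference_id!r} not in alignment")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def reference(self) -> SequenceRecord:
        return next(r for r in self.records if r.id == self.reference_id)

    def record(self, record_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(f"unknown record id {record_id!r}")


@dataclass(frozen=True)
class MotifSpec:
    """Ordered (reference position, allowed letters) anchors.

    The motif string is spelled in the order the anchors are listed, which
    need not be ascending in reference numbering.
    """

    anchors: tuple[tuple[int, frozenset[str]], ...]

    def __post_init__(self):
        positions = [p for p, _ in self.anchors]
        if len(set(positions)) != len(positions):
            raise ValueError("anchor positions must be unique")
        if any(not letters for _, letters in self.anchors):
            raise ValueError("empty allowed-letter set")

    @classmethod
    def from_motif_string(cls, positions, motif: str) -> "MotifSpec":
        if len(positions) != len(motif):
            raise ValueError("positions/motif length mismatch")
        return cls(tuple((int(p), frozenset(m.upper())) for p, m in zip(positions, motif)))

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.anchors)

    def matches(self, motif: str) -> bool:
        # 'X' and gaps never satisfy an anchor
        return len(motif) == len(self.anchors) and all(
            m in letters and m not in (GAP, "X")
            for m, (_, letters) in zip(motif, self.anchors)
        )


def default_motif_spec() -> MotifSpec:
    return MotifSpec.from_motif_string(KR2_ANCHOR_POSITIONS, KR2_MOTIF)


@dataclass
class ClassificationResult:
    id: str
    motif: str
    passed_filters: dict[str, bool]
    subgroup: str
    subgroup_residue: str


@dataclass
class IdentityClustering:
    representatives: list[str]
    membership: dict[str, str]
    threshold: float


def build_reference_map(
    aln: ReferenceAnchoredAlignment, positions
) -> dict[int, int]:
    """Map 1-based reference residue numbers to 0-based alignment columns.

    Column c maps to position p iff the reference row has its p-th non-gap
    character (counting from the numbering offset) in column c.
    """
    ref = aln.reference.residues
    offset = aln.reference_numbering_offset
    wanted = set(int(p) for p in positions)
    n_res = len(ref) - ref.count(GAP)
    for p in wanted:
        idx = p - offset + 1  # ordinal of the residue within the ungapped reference
        if idx < 1 or idx > n_res:
            raise ValueError(f"position {p} beyond reference length {n_res}")
    mapping = {}
    count = 0
    for col, ch in enumerate(ref):
        if ch != GAP:
            count += 1
            pos = count + offset - 1
            if pos in wanted:
                mapping[pos] = col
    return mapping


def extract_motif(
    aln: ReferenceAnchoredAlignment, spec: MotifSpec, record_id: str
) -> str:
    """Read a record's letters at the mapped anchor columns, in anchor order."""
    mapping = build_reference_map(aln, spec.positions)
    row = aln.record(record_id).residues
    return "".join(row[mapping[p]].upper() for p in spec.positions)


def apply_filters(
    aln: ReferenceAnchoredAlignment,
    spec: MotifSpec,
    min_length: int = 250,
    include_reference: bool = True,
) -> list[ClassificationResult]:
    """Motif, length and duplicate filters over the aligned records.

    A record is kept iff its motif letters satisfy every anchor, its ungapped
    length is strictly greater than ``min_length``, and its ungapped sequence
    string (case-insensitive) has not been seen earlier in input order.
    """
    mapping = build_reference_map(aln, spec.positions)
    seen: set[str] = set()
    results = []
    for rec in aln.records:
        if rec.id == aln.reference_id and not include_reference:
            continue
        motif = "".join(rec.residues[mapping[p]].upper() for p in spec.positions)
        ungapped = rec.ungapped.upper()
        flags = {
            "motif": spec.matches(motif),
            "length": len(ungapped) > min_length,
            "unique": ungapped not in seen,
        }
        seen.add(ungapped)
        results.append(
            ClassificationResult(
                id=rec.id,
                motif=motif,
                passed_filters=flags,
                subgroup="unassigned",
                subgroup_residue="",
            )
        )
    return results


_aligner = None


def _global_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 2.0
        a.mismatch_score = -1.0
        a.open_gap_score = -5.0
        a.extend_gap_score = -0.5
        _aligner = a
    return _aligner


def pairwise_identity(a: str, b: str, aligned: bool = False) -> float:
    """Fraction of identical residues between two sequences.

    ``aligned=True``: both strings are alignment rows of equal length;
    identity = identical non-gap matched columns / columns where at least
    the shorter (fewer non-gap residues) sequence has a residue.
    ``aligned=False``: a global alignment is built first and identity is
    matches / min(ungapped lengths), the CD-HIT convention.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    a, b = a.upper(), b.upper()
    if aligned:
        if len(a) != len(b):
            raise ValueError("aligned mode requires equal-length rows")
        na = sum(c != GAP for c in a)
        nb = sum(c != GAP for c in b)
        shorter = a if na <= nb else b
        denom = sum(c != GAP for c in shorter)
        if denom == 0:
            raise ValueError("all-gap sequence")
        matches = sum(x == y != GAP for x, y in zip(a, b))
        return matches / denom
    ua, ub = a.replace(GAP, ""), b.replace(GAP, "")
    if not ua or not ub:
        raise ValueError("empty sequence after degapping")
    aln = _global_aligner().align(ua, ub)[0]
    sa, sb = aln[0], aln[1]
    matches = sum(x == y != "-" for x, y in zip(sa, sb))
    return matches / min(len(ua), len(ub))


def cluster_by_identity(
    records: list[SequenceRecord], threshold: float = 0.90, aligned: bool = False
) -> IdentityClustering:
    """Greedy CD-HIT-style reduction of a sequence set.

    Records are sorted by ungapped length descending (ties by id); the first
    seeds a cluster and each subsequent record joins the first representative
    to which its identity is >= threshold, otherwise it seeds a new cluster.
    """
    if not records:
        raise ValueError("no records to cluster")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r.ungapped), r.id))
    reps: list[SequenceRecord] = []
    membership: dict[str, str] = {}
    for rec in ordered:
        home = None
        for rep in reps:
            if pairwise_identity(rec.residues, rep.residues, aligned=aligned) >= threshold:
                home = rep
                break
        if home is None:
            reps.append(rec)
            membership[rec.id] = rec.id
        else:
            membership[rec.id] = home.id
    return IdentityClustering(
        representatives=[r.id for r in reps], membership=membership, threshold=threshold
    )


def classify_subgroup(letter_at_74: str) -> str:
    """'E' -> Subgroup2, 'L'/'I' -> Subgroup1, anything else unassigned."""
    return SUBGROUP_RULES.get(letter_at_74.upper(), "unassigned")


def nj_tree(distance_matrix: np.ndarray, ids: list[str]) -> str:
    """Neighbor-joining Newick string from a distance matrix (via scikit-bio)."""
    dm = np.asarray(distance_matrix, dtype=float)
    if dm.shape[0] != dm.shape[1] or dm.shape[0] < 3:
        raise ValueError("need a square matrix with n >= 3")
    if not np.allclose(dm, dm.T):
        raise ValueError("distance matrix must be symmetric")
    tree = skbio.tree.nj(skbio.DistanceMatrix(dm, ids))
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def classify_alignment(
    aln: ReferenceAnchoredAlignment,
    spec: MotifSpec | None = None,
    subgroup_position: int = SUBGROUP_POSITION,
    min_length: int = 250,
    identity_threshold: float = 0.90,
    include_reference: bool = True,
) -> tuple[pd.DataFrame, IdentityClustering]:
    """End-to-end pipeline: motifs, filters, subgroups, identity reduction.

    Returns a per-record report (id, motif, filter flags, subgroup letter and
    label, representative id) and the clustering of the records that passed
    all filters.
    """
    if spec is None:
        spec = default_motif_spec()
    results = apply_filters(aln, spec, min_length=min_length, include_reference=include_reference)
    sub_col = build_reference_map(aln, [subgroup_position])[subgroup_position]
    rows = []
    kept_records = []
    for res in results:
        rec = aln.record(res.id)
        letter = rec.residues[sub_col].upper()
        res.subgroup_residue = letter
        res.subgroup = classify_subgroup(letter)
        passed = all(res.passed_filters.values())
        if passed:
            kept_records.append(rec)
        rows.append(
            {
                "id": res.id,
                "motif": res.motif,
                "motif_ok": res.passed_filters["motif"],
                "length_ok": res.passed_filters["length"],
                "unique_ok": res.passed_filters["unique"],
                "passed": passed,
                "subgroup_residue": letter,
                "subgroup": res.subgroup,
            }
        )
    clustering = (
        cluster_by_identity(kept_records, threshold=identity_threshold)
        if kept_records
        else IdentityClustering([], {}, identity_threshold)
    )
    report = pd.DataFrame(rows)
    report["representative"] = report["id"].map(clustering.membership).fillna("")
    return report, clustering


# ---------------------------------------------------------------------------
# FASTA I/O (Biopython-backed)


def read_alignment_fasta(path, reference_id: str, offset: int = 1) -> ReferenceAnchoredAlignment:
    records = [
        SequenceRecord(id=r.id, residues=str(r.seq).upper())
        for r in SeqIO.parse(str(path), "fasta")
    ]
    return ReferenceAnchoredAlignment(
        records=records, reference_id=reference_id, reference_numbering_offset=offset
    )


def write_fasta(records: list[tuple[str, str]] | list[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            rid, seq = (rec.id, rec.residues) if isinstance(rec, SequenceRecord) else rec
            fh.write(f">{rid}\n{seq}\n")
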