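"""Reading and writing the coordinate formats of a docking campaign.

PDBQT is the AutoDock family's coordinate format: PDB-style ATOM/HETATM
records extended with a partial charge and an AutoDock atom-type code in the
trailing columns, plus a torsion tree (ROOT/BRANCH/TORSDOF) for ligands.
Docked ligand files hold one pose per MODEL/ENDMDL block.

This module parses receptors and multi-pose ligand files into typed in-memory
atoms, derives the interaction classes (hydrophobic / H-bond acceptor /
H-bond donor heavy atom) that the empirical scoring terms need, and reads the
term breakdown printed by a docking engine's score-only log as an alternate
feature source.  Writers are provided to emit the same dialect, mainly so
synthetic fixtures can round-trip through the parser.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "TypedAtom",
    "Receptor",
    "LigandPoseSet",
    "PdbqtError",
    "PdbqtParseError",
    "UnknownAtomTypeError",
    "InconsistentPosesError",
    "ScoreLogError",
    "KNOWN_ATOM_TYPES",
    "HYDROPHOBIC_TYPES",
    "ACCEPTOR_TYPES",
    "DONOR_HEAVY_CANDIDATES",
    "HYDROGEN_TYPES",
    "DEFAULT_LOG_LABELS",
    "assign_interaction_classes",
    "scoreable_atoms",
    "parse_pdbqt_receptor",
    "parse_pdbqt_ligand",
    "parse_engine_score_log",
    "write_pdbqt_receptor",
    "write_pdbqt_ligand",
    "write_engine_score_log",
]

# ---------------------------------------------------------------------------
# Atom typing vocabulary
# ---------------------------------------------------------------------------

#: Aliphatic carbon "C" and aromatic carbon "A" are distinct codes; halogens
#: count as hydrophobic.  "NA"/"OA" are the H-bond-accepting nitrogen/oxygen
#: variants; "HD" is a polar (donor) hydrogen, "H" a non-polar one.
HYDROPHOBIC_TYPES = frozenset({"C", "A", "F", "Cl", "Br", "I"})
ACCEPTOR_TYPES = frozenset({"NA", "OA"})
DONOR_HEAVY_CANDIDATES = frozenset({"N", "NA", "O", "OA"})
HYDROGEN_TYPES = frozenset({"H", "HD"})

KNOWN_ATOM_TYPES = frozenset(
    HYDROPHOBIC_TYPES
    | ACCEPTOR_TYPES
    | DONOR_HEAVY_CANDIDATES
    | HYDROGEN_TYPES
    | {"S", "SA", "P"}
)

#: Covalent N-H / O-H bonds are shorter than 1.05 Å, so when no bond table is
#: available a polar hydrogen within this distance marks its heavy neighbour
#: as a donor.
POLAR_H_BOND_DISTANCE = 1.1


class PdbqtError(ValueError):
    """Base class for PDBQT/engine-log errors raised by this module."""


class PdbqtParseError(PdbqtError):
    """A malformed record; the message names the offending line number."""


class UnknownAtomTypeError(PdbqtError):
    """An atom-type code outside the closed vocabulary."""

    def __init__(self, code: str, line_number: int | None = None):
        self.code = code
        where = f" (line {line_number})" if line_number is not None else ""
        super().__init__(
            f"unknown atom-type code {code!r}{where}; known codes: "
            + ", ".join(sorted(KNOWN_ATOM_TYPES))
        )


class InconsistentPosesError(PdbqtError):
    """MODEL blocks of one ligand file disagree on atom count or ordering."""


class ScoreLogError(PdbqtError):
    """A score-only engine log is missing one or more labelled values."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TypedAtom:
    """One atom with coordinates, engine atom type and interaction classes."""

    serial: int
    name: str
    element_type: str
    x: float
    y: float
    z: float
    partial_charge: float = 0.0
    is_hydrophobic: bool = False
    is_acceptor: bool = False
    is_donor_heavy: bool = False

    @property
    def coords(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass(frozen=True)
class Receptor:
    """A receptor structure: heavy atoms plus polar hydrogens.

    ``reference_point`` is an optional coordinate (e.g. a catalytic-residue
    side chain) used to sanity-check whether docked poses sit in the active
    site.
    """

    structure_id: str
    atoms: tuple[TypedAtom, ...]
    reference_point: tuple[float, float, float] | None = None

    def __post_init__(self):
        if not self.atoms:
            raise PdbqtError(f"receptor {self.structure_id!r}: no atoms")


@dataclass(frozen=True)
class LigandPoseSet:
    """Docked poses of one ligand; all poses share atom count and order."""

    ligand_id: str
    poses: tuple[tuple[TypedAtom, ...], ...]
    n_rotatable: int = 0

    def __post_init__(self):
        if not self.poses or any(len(p) == 0 for p in self.poses):
            raise PdbqtError(f"ligand {self.ligand_id!r}: empty pose set")
        ref_types = [a.element_type for a in self.poses[0]]
        for i, pose in enumerate(self.poses[1:], start=2):
            if [a.element_type for a in pose] != ref_types:
                raise InconsistentPosesError(
                    f"ligand {self.ligand_id!r}: pose {i} atom count/ordering "
                    f"differs from pose 1 ({len(pose)} vs {len(ref_types)} atoms)"
                )
        if self.n_rotatable < 0:
            raise PdbqtError("n_rotatable must be non-negative")


# ---------------------------------------------------------------------------
# Interaction-class assignment
# ---------------------------------------------------------------------------


def assign_interaction_classes(
    atoms: Sequence[TypedAtom],
    bonds: Mapping[int, Iterable[int]] | None = None,
) -> list[TypedAtom]:
    """Set hydrophobic / acceptor / donor-heavy flags from atom types.

    Hydrophobic: C, A and the halogens.  Acceptor: NA, OA.  A nitrogen or
    oxygen is a donor heavy atom when it carries a polar hydrogen (type HD):
    bonded per ``bonds`` (serial -> neighbour serials) when given, otherwise
    any HD within :data:`POLAR_H_BOND_DISTANCE`.  Pure classification — the
    atom list itself (including hydrogens) is returned re-flagged; use
    :func:`scoreable_atoms` to drop hydrogens for scoring.
    """
    for a in atoms:
        if a.element_type not in KNOWN_ATOM_TYPES:
            raise UnknownAtomTypeError(a.element_type)

    polar_h = [a for a in atoms if a.element_type == "HD"]
    by_serial = {a.serial: a for a in atoms}

    def has_polar_h(atom: TypedAtom) -> bool:
        if bonds is not None:
            return any(
                by_serial.get(n) is not None
                and by_serial[n].element_type == "HD"
                for n in bonds.get(atom.serial, ())
            )
        return any(
            math.dist(atom.coords, h.coords) <= POLAR_H_BOND_DISTANCE
            for h in polar_h
        )

    out = []
    for a in atoms:
        donor = a.element_type in DONOR_HEAVY_CANDIDATES and has_polar_h(a)
        out.append(
            replace(
                a,
                is_hydrophobic=a.element_type in HYDROPHOBIC_TYPES,
                is_acceptor=a.element_type in ACCEPTOR_TYPES,
                is_donor_heavy=donor,
            )
        )
    return out


def scoreable_atoms(atoms: Sequence[TypedAtom]) -> list[TypedAtom]:
    """Heavy atoms only: hydrogens are implicit in the united-atom terms."""
    return [a for a in atoms if a.element_type not in HYDROGEN_TYPES]


# ---------------------------------------------------------------------------
# PDBQT parsing
# ---------------------------------------------------------------------------


def _parse_atom_line(line: str, lineno: int) -> TypedAtom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PdbqtParseError(
            f"line {lineno}: malformed ATOM/HETATM record ({exc})"
        ) from None
    tail = line[54:].split()
    if not tail:
        raise PdbqtParseError(f"line {lineno}: missing atom-type field")
    element_type = tail[-1]
    if element_type not in KNOWN_ATOM_TYPES:
        raise UnknownAtomTypeError(element_type, lineno)
    charge = 0.0
    if len(tail) >= 2:
        try:
            charge = float(tail[-2])
        except ValueError:
            charge = 0.0
    return TypedAtom(
        serial=serial, name=name, element_type=element_type,
        x=x, y=y, z=z, partial_charge=charge,
    )


def parse_pdbqt_receptor(
    text: str,
    structure_id: str = "receptor",
    reference_point: tuple[float, float, float] | None = None,
) -> Receptor:
    """Parse a receptor PDBQT; assigns interaction classes.

    Waters and hetero ligands are expected to have been removed upstream
    during structure preparation.
    """
    atoms = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            atoms.append(_parse_atom_line(line, lineno))
    if not atoms:
        raise PdbqtParseError("no atoms: text contains no ATOM/HETATM records")
    return Receptor(
        structure_id=structure_id,
        atoms=tuple(assign_interaction_classes(atoms)),
        reference_point=reference_point,
    )


def parse_pdbqt_ligand(text: str, ligand_id: str = "ligand") -> LigandPoseSet:
    """Parse a (possibly multi-MODEL) ligand PDBQT into a pose set.

    One pose per MODEL block, or a single pose when no MODEL records exist.
    ``n_rotatable`` comes from the first TORSDOF record, falling back to the
    number of BRANCH records in one pose, else 0.
    """
    poses: list[list[TypedAtom]] = []
    current: list[TypedAtom] = []
    in_model = False
    saw_model = False
    torsdof: int | None = None
    branch_counts: list[int] = []
    branches = 0

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line.split(None, 1)[0] if line.strip() else ""
        if rec == "MODEL":
            saw_model = True
            in_model = True
            current = []
            branches = 0
        elif rec == "ENDMDL":
            in_model = False
            poses.append(current)
            branch_counts.append(branches)
            current = []
        elif rec in ("ATOM", "HETATM"):
            current.append(_parse_atom_line(line, lineno))
        elif rec == "BRANCH":
            branches += 1
        elif rec == "TORSDOF" and torsdof is None:
            try:
                torsdof = int(line.split()[1])
            except (IndexError, ValueError):
                raise PdbqtParseError(
                    f"line {lineno}: malformed TORSDOF record"
                ) from None

    if not saw_model:
        poses = [current]
        branch_counts = [branches]
    elif current:
        # trailing atoms after the last ENDMDL (tolerate unclosed MODEL)
        poses.append(current)
        branch_counts.append(branches)

    poses = [p for p in poses if p]
    if not poses:
        raise PdbqtParseError("no atoms: text contains no ATOM/HETATM records")

    counts = {len(p) for p in poses}
    if len(counts) > 1:
        raise InconsistentPosesError(
            f"ligand {ligand_id!r}: MODEL blocks have inconsistent atom "
            f"counts {sorted(counts)}"
        )

    n_rot = torsdof if torsdof is not None else (branch_counts[0] if branch_counts else 0)
    return LigandPoseSet(
        ligand_id=ligand_id,
        poses=tuple(tuple(assign_interaction_classes(p)) for p in poses),
        n_rotatable=n_rot,
    )


# ---------------------------------------------------------------------------
# PDBQT writing (fixture generation; minimal MODEL/ROOT dialect)
# ---------------------------------------------------------------------------


def _format_atom_line(a: TypedAtom, resname: str = "LIG") -> str:
    name = a.name if a.name else a.element_type
    return (
        f"ATOM  {a.serial:5d} {name:<4}{resname:<3} A   1    "
        f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}  1.00  0.00    "
        f"{a.partial_charge:6.3f} {a.element_type}"
    )


def write_pdbqt_receptor(receptor: Receptor) -> str:
    lines = [_format_atom_line(a, resname="REC") for a in receptor.atoms]
    lines.append("TER")
    return "\n".join(lines) + "\n"


def write_pdbqt_ligand(pose_set: LigandPoseSet) -> str:
    """Emit a multi-MODEL ligand PDBQT that re-parses to the same pose set."""
    lines: list[str] = []
    for i, pose in enumerate(pose_set.poses, start=1):
        lines.append(f"MODEL {i}")
        lines.append("ROOT")
        lines.extend(_format_atom_line(a) for a in pose)
        lines.append("ENDROOT")
        lines.append(f"TORSDOF {pose_set.n_rotatable}")
        lines.append("ENDMDL")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Engine score-only logs
# ---------------------------------------------------------------------------

#: Labels printed by the engine release the defaults reproduce; override via
#: config when a different release words its log differently.
DEFAULT_LOG_LABELS: dict[str, str] = {
    "gauss1": "gauss 1",
    "gauss2": "gauss 2",
    "repulsion": "repulsion",
    "hydrophobic": "hydrophobic",
    "hbond": "Hydrogen",
    "score": "Affinity",
}


def parse_engine_score_log(text: str, labels: Mapping[str, str] | None = None):
    """Parse a score-only engine log into a :class:`~dockscreen.scoring.TermVector`.

    The five interaction terms come from their labelled lines; the composite
    score comes from the affinity line (the rotatable-bond penalty is not
    printed per-term by score-only mode but is folded into the affinity).
    """
    from .scoring import TermVector  # local import to avoid a cycle

    labels = dict(DEFAULT_LOG_LABELS, **(labels or {}))
    values: dict[str, float] = {}
    missing: list[str] = []
    for key, label in labels.items():
        m = re.search(
            rf"^\s*{re.escape(label)}\s*:?\s*([-+]?[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)",
            text,
            flags=re.MULTILINE,
        )
        if m is None:
            missing.append(f"{key} (label {label!r})")
        else:
            values[key] = float(m.group(1))
    if missing:
        raise ScoreLogError(
            "score-only log is missing: " + "; ".join(missing)
        )
    return TermVector(**values)


def write_engine_score_log(terms, labels: Mapping[str, str] | None = None) -> str:
    """Emit a score-only log in the engine's dialect (fixture round-trips)."""
    labels = dict(DEFAULT_LOG_LABELS, **(labels or {}))
    lines = [
        f"{labels['score']}: {terms.score:.5f} (kcal/mol)",
        "Intermolecular contributions to the terms, before weighting:",
    ]
    for key in ("gauss1", "gauss2", "repulsion", "hydrophobic", "hbond"):
        lines.append(f"    {labels[key]:<12}: {getattr(terms, key):.5f}")
    return "\n".join(lines) + "\n"
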