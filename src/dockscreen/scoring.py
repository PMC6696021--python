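"""Empirical pairwise interaction terms and the composite docking score.

The scoring function is the Vina-family empirical potential: five pairwise
terms, each a function of the inter-atomic *surface distance*
``d = r - R_i - R_j`` (centre distance minus both van der Waals radii):

* ``gauss1``      — exp(-(d/0.5)^2), a tight contact Gaussian
* ``gauss2``      — exp(-((d-3)/2)^2), a broad Gaussian centred at 3 Å
* ``repulsion``   — d^2 for d < 0, else 0 (steric clash penalty)
* ``hydrophobic`` — ramp 1→0 over d in [0.5, 1.5], only between two
  hydrophobic atoms
* ``hbond``       — ramp 1→0 over d in [-0.7, 0], only between a donor heavy
  atom and an acceptor

Terms are summed over all intermolecular heavy-atom pairs within an 8 Å
centre-distance cutoff.  The composite score is the weighted term sum divided
by ``1 + w_rot * N_rot``, penalising ligand flexibility.  These per-pose term
vectors — not just the composite — are the feature set for the downstream
classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .pdbqt_io import Receptor, TypedAtom, scoreable_atoms

__all__ = [
    "TermVector",
    "WeightSet",
    "DEFAULT_WEIGHTS",
    "DEFAULT_VDW_RADII",
    "FEATURE_COLUMNS",
    "surface_distance",
    "pair_terms",
    "intermolecular_terms",
    "vina_score",
    "score_ligand_poses",
    "pose_rmsd",
    "centroid_reference_distance",
    "ScoringError",
]

#: Canonical feature-column order used in every table, CSV header and model.
FEATURE_COLUMNS = ("gauss1", "gauss2", "repulsion", "hydrophobic", "hbond", "score")


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class TermVector:
    """The six-feature record for one ligand pose against one structure."""

    gauss1: float
    gauss2: float
    repulsion: float
    hydrophobic: float
    hbond: float
    score: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in FEATURE_COLUMNS], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "TermVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (6,):
            raise ScoringError(f"expected 6 components, got shape {arr.shape}")
        return cls(**dict(zip(FEATURE_COLUMNS, arr.tolist())))


@dataclass(frozen=True)
class WeightSet:
    """Term weights (kcal/mol per unit term), rotatable-bond penalty, cutoff.

    Defaults are the published weights of the scoring function the docking
    engine implements, so an engine score-only run and this module agree.
    """

    w_gauss1: float = -0.035579
    w_gauss2: float = -0.005156
    w_repulsion: float = 0.840245
    w_hydrophobic: float = -0.035069
    w_hbond: float = -0.587439
    w_rot: float = 0.05846
    cutoff: float = 8.0

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ScoringError("cutoff must be positive")

    @property
    def term_weights(self) -> np.ndarray:
        return np.array(
            [self.w_gauss1, self.w_gauss2, self.w_repulsion,
             self.w_hydrophobic, self.w_hbond]
        )


DEFAULT_WEIGHTS = WeightSet()

#: van der Waals radii (Å) per engine atom type; scoring an atom whose type
#: has no entry is an error rather than a silent default.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.9, "A": 1.9,
    "N": 1.8, "NA": 1.8,
    "O": 1.7, "OA": 1.7,
    "S": 2.0, "SA": 2.0,
    "P": 2.1,
    "F": 1.5, "Cl": 1.8, "Br": 2.0, "I": 2.2,
}


def surface_distance(r: float, R_i: float, R_j: float) -> float:
    """Surface distance d = r − R_i − R_j; negative when atoms overlap."""
    return r - R_i - R_j


def pair_terms(d: float, i: TypedAtom, j: TypedAtom) -> tuple[float, float, float, float, float]:
    """The five per-pair term contributions at surface distance ``d``.

    Hydrophobic requires both atoms hydrophobic; the H-bond term requires a
    donor-heavy/acceptor pair (either direction).  Both ramps are linear
    between their plateaus.
    """
    gauss1 = float(np.exp(-((d / 0.5) ** 2)))
    gauss2 = float(np.exp(-(((d - 3.0) / 2.0) ** 2)))
    repulsion = d * d if d < 0 else 0.0
    hydrophobic = 0.0
    if i.is_hydrophobic and j.is_hydrophobic:
        hydrophobic = float(np.clip((1.5 - d) / 1.0, 0.0, 1.0))
    hbond = 0.0
    if (i.is_donor_heavy and j.is_acceptor) or (i.is_acceptor and j.is_donor_heavy):
        hbond = float(np.clip((0.0 - d) / 0.7, 0.0, 1.0))
    return gauss1, gauss2, repulsion, hydrophobic, hbond


def _atom_arrays(atoms: Sequence[TypedAtom], radii: Mapping[str, float]):
    xyz = np.array([a.coords for a in atoms], dtype=float)
    try:
        rad = np.array([radii[a.element_type] for a in atoms], dtype=float)
    except KeyError as exc:
        raise ScoringError(
            f"no van der Waals radius configured for atom type {exc.args[0]!r}"
        ) from None
    hyd = np.array([a.is_hydrophobic for a in atoms], dtype=bool)
    don = np.array([a.is_donor_heavy for a in atoms], dtype=bool)
    acc = np.array([a.is_acceptor for a in atoms], dtype=bool)
    return xyz, rad, hyd, don, acc


def intermolecular_terms(
    pose: Sequence[TypedAtom],
    receptor: Receptor,
    weights: WeightSet = DEFAULT_WEIGHTS,
    radii: Mapping[str, float] | None = None,
    n_rotatable: int = 0,
) -> TermVector:
    """Sum the five terms over all ligand×receptor heavy-atom pairs.

    Pairs beyond ``weights.cutoff`` centre distance contribute nothing.  The
    ``score`` field is the composite :func:`vina_score` of the summed terms.
    Intramolecular ligand contributions are not included: the feature of
    interest is the part that varies across receptor structures.
    """
    radii = DEFAULT_VDW_RADII if radii is None else radii
    lig = scoreable_atoms(pose)
    rec = scoreable_atoms(receptor.atoms)
    if not lig:
        raise ScoringError("empty ligand pose (no heavy atoms)")
    if not rec:
        raise ScoringError(f"receptor {receptor.structure_id!r} has no heavy atoms")

    lx, lr, lh, ld, la = _atom_arrays(lig, radii)
    rx, rr, rh, rd, ra = _atom_arrays(rec, radii)

    r = cdist(lx, rx)                       # centre distances, L×R
    within = r <= weights.cutoff
    d = r - lr[:, None] - rr[None, :]       # surface distances

    gauss1 = np.exp(-((d / 0.5) ** 2))
    gauss2 = np.exp(-(((d - 3.0) / 2.0) ** 2))
    repulsion = np.where(d < 0, d * d, 0.0)
    hyd_pair = lh[:, None] & rh[None, :]
    hydrophobic = np.where(hyd_pair, np.clip((1.5 - d), 0.0, 1.0), 0.0)
    hb_pair = (ld[:, None] & ra[None, :]) | (la[:, None] & rd[None, :])
    hbond = np.where(hb_pair, np.clip(-d / 0.7, 0.0, 1.0), 0.0)

    sums = np.array([
        float((t * within).sum())
        for t in (gauss1, gauss2, repulsion, hydrophobic, hbond)
    ])
    score = vina_score(sums, n_rotatable, weights)
    return TermVector(*sums, score=score)


def vina_score(
    interaction_terms: Sequence[float] | TermVector,
    n_rotatable: int,
    weights: WeightSet = DEFAULT_WEIGHTS,
) -> float:
    """Composite score: weighted term sum over ``1 + w_rot * N_rot``.

    The denominator is the conformational-entropy penalty for rotatable
    bonds; with no rotatable bonds the score is the plain weighted sum.
    """
    if n_rotatable < 0:
        raise ScoringError("n_rotatable must be non-negative")
    if isinstance(interaction_terms, TermVector):
        t = interaction_terms.as_array()[:5]
    else:
        t = np.asarray(interaction_terms, dtype=float)
        if t.shape != (5,):
            raise ScoringError(f"expected 5 interaction terms, got {t.shape}")
    return float(weights.term_weights @ t / (1.0 + weights.w_rot * n_rotatable))


def score_ligand_poses(
    receptor: Receptor,
    pose_set,
    weights: WeightSet = DEFAULT_WEIGHTS,
    radii: Mapping[str, float] | None = None,
) -> list[TermVector]:
    """One TermVector per pose of a ligand against one receptor structure."""
    return [
        intermolecular_terms(pose, receptor, weights, radii,
                             n_rotatable=pose_set.n_rotatable)
        for pose in pose_set.poses
    ]


def pose_rmsd(a: Sequence[TypedAtom], b: Sequence[TypedAtom]) -> float:
    """Heavy-atom RMSD between two poses in the shared receptor frame.

    No superposition is applied (redocking convention) and no symmetry
    correction is attempted; atoms are compared by position in the list.
    """
    ha, hb = scoreable_atoms(a), scoreable_atoms(b)
    if len(ha) != len(hb):
        raise ScoringError(
            f"atom-count mismatch: {len(ha)} vs {len(hb)} heavy atoms"
        )
    if not ha:
        raise ScoringError("empty pose")
    xa = np.array([at.coords for at in ha])
    xb = np.array([at.coords for at in hb])
    return float(np.sqrt(((xa - xb) ** 2).sum(axis=1).mean()))


def centroid_reference_distance(
    pose: Sequence[TypedAtom],
    reference_point: Sequence[float] | None,
    threshold: float = 10.0,
) -> tuple[float, bool]:
    """Distance from the pose's heavy-atom centroid to a reference point.

    Used as a pose sanity check: a pose whose centroid is farther than
    ``threshold`` (default 10 Å) from the catalytic reference is flagged as
    sitting outside the active site.  Returns ``(distance, in_site)``.
    """
    if reference_point is None:
        raise ScoringError("receptor has no reference_point")
    heavy = scoreable_atoms(pose)
    if not heavy:
        raise ScoringError("empty pose")
    centroid = np.array([a.coords for a in heavy]).mean(axis=0)
    dist = float(np.linalg.norm(centroid - np.asarray(reference_point, dtype=float)))
    return dist, dist <= threshold
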