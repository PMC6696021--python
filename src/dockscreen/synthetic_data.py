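"""Synthetic inputs for every pipeline stage — no downloads required.

Two generator families:

* **Toy complexes** — random receptor pockets (atoms uniform in a docking
  box) and ligand pose sets (jittered copies of a compact base conformation
  near the box centre), with controllable atom-type palettes so individual
  interaction terms can be switched on or off.  Written as valid PDBQT.

* **Planted-activity datasets** — per-ligand standardized latent features
  whose linear combination (plus Gaussian noise) determines log-activity:
  ``log10(Ki/µM) = 1 − u``, ``u = w·z + intercept + ε``.  The calibration
  puts the 10 µM threshold at ``u = 0`` so that threshold splits the classes
  near 50/50 (mirroring a near-balanced Ki dataset), while 1 µM and 100 µM
  remain meaningful.  Per-structure tables add structure-specific feature
  perturbations and per-pose jitter on top, so pose/structure averaging has
  something to average away.

Everything is a pure function of its seed and spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .ensemble_features import build_pose_table, pose_table_to_matrix
from .pdbqt_io import (
    LigandPoseSet,
    Receptor,
    TypedAtom,
    assign_interaction_classes,
    write_pdbqt_ligand,
    write_pdbqt_receptor,
)
from .scoring import DEFAULT_WEIGHTS, FEATURE_COLUMNS, score_ligand_poses

__all__ = [
    "ToyComplexSpec",
    "PlantedActivityModel",
    "SyntheticDataError",
    "make_toy_complex",
    "make_activity_dataset",
    "make_campaign_fixture",
    "DEFAULT_TRUE_WEIGHTS",
    "TERM_MEANS",
    "TERM_SCALES",
]


class SyntheticDataError(ValueError):
    pass


#: Plausible raw magnitudes per feature column (gauss1, gauss2, repulsion,
#: hydrophobic, hbond, score) so synthetic tables look like real term sums.
TERM_MEANS = np.array([45.0, 650.0, 1.8, 18.0, 2.2, -7.0])
TERM_SCALES = np.array([9.0, 130.0, 0.45, 4.5, 0.55, 1.1])

#: Planted weights on the standardized features: favourable-contact terms
#: push toward activity, repulsion and a less-negative composite score push
#: away.  All six are nonzero so sign-recovery is well-posed.
DEFAULT_TRUE_WEIGHTS = np.array([0.8, 0.3, -0.6, 0.7, 0.9, -1.2])


@dataclass(frozen=True)
class ToyComplexSpec:
    """Geometry and composition of one random receptor/ligand complex."""

    n_receptor_atoms: int = 60
    n_ligand_atoms: int = 12
    n_poses: int = 3
    box: tuple[float, float, float] = (26.0, 28.0, 32.0)
    #: heavy-atom sampling palette (type -> weight); polar hydrogens are
    #: attached separately to N/O-type atoms
    type_palette: dict = field(default_factory=lambda: {
        "C": 0.45, "A": 0.15, "OA": 0.15, "N": 0.10, "NA": 0.05, "S": 0.05,
        "Cl": 0.05,
    })
    polar_h_fraction: float = 0.5   # chance an N/O heavy atom carries an HD
    pose_jitter: float = 0.4        # Å, per-atom positional noise per pose
    seed: int = 0

    def __post_init__(self):
        if self.n_receptor_atoms <= 0 or self.n_ligand_atoms <= 0:
            raise SyntheticDataError("atom counts must be positive")
        if self.n_poses <= 0:
            raise SyntheticDataError("need at least one pose")


def _sample_atoms(rng: np.random.Generator, n: int, centers: np.ndarray,
                  palette: dict, polar_h_fraction: float,
                  serial_start: int = 1) -> list[TypedAtom]:
    types = list(palette)
    weights = np.array([palette[t] for t in types], dtype=float)
    weights /= weights.sum()
    chosen = rng.choice(types, size=n, p=weights)
    atoms: list[TypedAtom] = []
    serial = serial_start
    for i in range(n):
        x, y, z = centers[i]
        t = str(chosen[i])
        atoms.append(TypedAtom(serial=serial, name=t, element_type=t,
                               x=float(x), y=float(y), z=float(z),
                               partial_charge=float(np.round(rng.normal(0, 0.2), 3))))
        serial += 1
        # attach a polar hydrogen to some N/O heavy atoms so donors exist
        if t in ("N", "NA", "OA") and rng.random() < polar_h_fraction:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            hx, hy, hz = centers[i] + 0.96 * direction
            atoms.append(TypedAtom(serial=serial, name="HD", element_type="HD",
                                   x=float(hx), y=float(hy), z=float(hz),
                                   partial_charge=0.2))
            serial += 1
    return assign_interaction_classes(atoms)


def make_toy_complex(spec: ToyComplexSpec,
                     ligand_id: str = "lig",
                     structure_id: str = "toy") -> tuple[Receptor, LigandPoseSet]:
    """One random receptor and a matching multi-pose ligand.

    Receptor heavy atoms are uniform in the box (centred at the origin);
    ligand poses are per-atom jittered copies of a compact base conformation
    near the box centre.  The receptor's reference point is its centroid, so
    centroid-distance pose checks work out of the box.
    """
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    rec_xyz = (rng.random((spec.n_receptor_atoms, 3)) - 0.5) * box
    rec_atoms = _sample_atoms(rng, spec.n_receptor_atoms, rec_xyz,
                              spec.type_palette, spec.polar_h_fraction)
    centroid = np.array([[a.x, a.y, a.z] for a in rec_atoms]).mean(axis=0)
    receptor = Receptor(structure_id=structure_id, atoms=tuple(rec_atoms),
                        reference_point=tuple(np.round(centroid, 3)))

    base_xyz = rng.normal(scale=1.6, size=(spec.n_ligand_atoms, 3))
    # pick ligand types once; every pose reuses them in the same order
    lig_template = _sample_atoms(rng, spec.n_ligand_atoms, base_xyz,
                                 spec.type_palette, spec.polar_h_fraction)
    poses = []
    for _ in range(spec.n_poses):
        shift = rng.normal(scale=0.8, size=3)
        pose = []
        for a in lig_template:
            dx, dy, dz = rng.normal(scale=spec.pose_jitter, size=3)
            pose.append(TypedAtom(
                serial=a.serial, name=a.name, element_type=a.element_type,
                x=round(a.x + shift[0] + dx, 3),
                y=round(a.y + shift[1] + dy, 3),
                z=round(a.z + shift[2] + dz, 3),
                partial_charge=a.partial_charge,
            ))
        poses.append(tuple(assign_interaction_classes(pose)))
    n_rot = int(rng.integers(0, 9))
    return receptor, LigandPoseSet(ligand_id=ligand_id, poses=tuple(poses),
                                   n_rotatable=n_rot)


# ---------------------------------------------------------------------------
# Planted-activity datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedActivityModel:
    """Ground-truth linear activity model on standardized features."""

    true_weights: tuple = tuple(DEFAULT_TRUE_WEIGHTS.tolist())
    intercept: float = 0.0
    noise_sd: float = 0.5
    n_structures: int = 10
    n_poses: int = 3
    structure_sd: float = 0.3
    pose_sd: float = 0.15
    seed: int = 1

    def __post_init__(self):
        if self.noise_sd < 0:
            raise SyntheticDataError("noise_sd must be non-negative")
        if len(self.true_weights) != len(FEATURE_COLUMNS):
            raise SyntheticDataError("true_weights must have 6 components")


def make_activity_dataset(model: PlantedActivityModel, n_ligands: int = 300
                          ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a complete planted-signal activity campaign.

    Returns ``(pose_table, activity_table, truth)``:

    * pose_table — tidy per-(ligand, structure, pose) feature rows on raw
      term scales;
    * activity_table — ``ligand_id, ki_uM`` with
      ``log10(Ki) = 1 − u``, ``u = w·z + intercept + ε``;
    * truth — the latent standardized ensemble features ``z``, latents ``u``,
      weights, and the noiseless raw ensemble feature table.
    """
    if n_ligands < 20:
        raise SyntheticDataError("n_ligands must be at least 20")
    rng = np.random.default_rng(model.seed)
    w = np.asarray(model.true_weights, dtype=float)
    p = len(FEATURE_COLUMNS)

    ligand_ids = [f"lig_{i:04d}" for i in range(n_ligands)]
    z = rng.standard_normal((n_ligands, p))
    eps = rng.normal(scale=model.noise_sd, size=n_ligands) if model.noise_sd > 0 \
        else np.zeros(n_ligands)
    u = z @ w + model.intercept + eps
    log_ki = 1.0 - u                       # u = 0 <-> Ki = 10 µM
    ki = np.clip(10.0 ** log_ki, 1e-4, 1e6)

    rows = []
    for s in range(model.n_structures):
        z_struct = z + rng.normal(scale=model.structure_sd, size=z.shape)
        for pose in range(model.n_poses):
            z_pose = z_struct + rng.normal(scale=model.pose_sd, size=z.shape)
            raw = TERM_MEANS + TERM_SCALES * z_pose
            for i, lig in enumerate(ligand_ids):
                rows.append({"ligand_id": lig,
                             "structure_id": f"struct_{s:02d}",
                             "pose": pose + 1,
                             **dict(zip(FEATURE_COLUMNS, raw[i]))})
    pose_df = pd.DataFrame(rows)
    activity_df = pd.DataFrame({"ligand_id": ligand_ids,
                                "ki_uM": np.round(ki, 6)})
    truth = {
        "z": z, "u": u, "weights": w, "intercept": model.intercept,
        "ensemble_features_raw": pd.DataFrame(
            TERM_MEANS + TERM_SCALES * z, index=ligand_ids,
            columns=list(FEATURE_COLUMNS)),
        "labels_10uM": (ki < 10.0).astype(int),
    }
    return pose_df, activity_df, truth


# ---------------------------------------------------------------------------
# Full campaign fixture on disk
# ---------------------------------------------------------------------------


def _make_ligand_template(rng: np.random.Generator, spec: ToyComplexSpec):
    base_xyz = rng.normal(scale=1.6, size=(spec.n_ligand_atoms, 3))
    return _sample_atoms(rng, spec.n_ligand_atoms, base_xyz,
                         spec.type_palette, spec.polar_h_fraction)


def make_campaign_fixture(out_dir: str | Path, seed: int = 0,
                          n_structures: int = 10, n_ligands: int = 50,
                          n_poses: int = 3,
                          complex_spec: ToyComplexSpec | None = None) -> dict:
    """Write a complete miniature screening campaign to ``out_dir``.

    Layout: ``receptors/<structure>.pdbqt``, ``poses/<structure>/<ligand>.pdbqt``
    (multi-MODEL), ``activities.csv`` and ``config.yaml``.  Activities are
    planted: the written poses are scored, the ensemble features
    standardized, and Ki derived from the planted linear model, so the
    end-to-end pipeline has real signal to recover.

    Refuses to write into an existing non-empty directory.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        raise SyntheticDataError(f"target directory {out} exists and is not empty")
    (out / "receptors").mkdir(parents=True, exist_ok=True)
    (out / "poses").mkdir(exist_ok=True)

    spec = complex_spec or ToyComplexSpec()
    rng = np.random.default_rng(seed)

    structures: list[tuple[str, Receptor]] = []
    for s in range(n_structures):
        sid = f"struct_{s:02d}"
        receptor, _ = make_toy_complex(
            ToyComplexSpec(**{**spec.__dict__, "seed": int(rng.integers(2**31))}),
            structure_id=sid)
        (out / "receptors" / f"{sid}.pdbqt").write_text(
            write_pdbqt_receptor(receptor))
        structures.append((sid, receptor))

    ligand_templates = []
    for i in range(n_ligands):
        lid = f"lig_{i:03d}"
        template = _make_ligand_template(rng, spec)
        n_rot = int(rng.integers(0, 9))
        ligand_templates.append((lid, template, n_rot))

    records = []
    for sid, receptor in structures:
        pose_dir = out / "poses" / sid
        pose_dir.mkdir()
        center = np.asarray(receptor.reference_point)
        for lid, template, n_rot in ligand_templates:
            poses = []
            for _ in range(n_poses):
                shift = center + rng.normal(scale=1.5, size=3)
                pose = []
                for a in template:
                    d = rng.normal(scale=spec.pose_jitter, size=3)
                    pose.append(TypedAtom(
                        serial=a.serial, name=a.name,
                        element_type=a.element_type,
                        x=round(a.x + shift[0] + d[0], 3),
                        y=round(a.y + shift[1] + d[1], 3),
                        z=round(a.z + shift[2] + d[2], 3),
                        partial_charge=a.partial_charge))
                poses.append(tuple(assign_interaction_classes(pose)))
            pose_set = LigandPoseSet(ligand_id=lid, poses=tuple(poses),
                                     n_rotatable=n_rot)
            (pose_dir / f"{lid}.pdbqt").write_text(write_pdbqt_ligand(pose_set))
            for p_idx, tv in enumerate(score_ligand_poses(receptor, pose_set), 1):
                records.append((lid, sid, p_idx, tv))

    pose_df = build_pose_table(records)
    matrix = pose_table_to_matrix(pose_df, keep_per_structure=False)
    feats = matrix.features
    std = feats.std(axis=0)
    std[std == 0] = 1.0
    z = (feats - feats.mean(axis=0)) / std
    u = z @ DEFAULT_TRUE_WEIGHTS + rng.normal(scale=0.4, size=len(matrix.ligand_ids))
    ki = np.clip(10.0 ** (1.0 - u), 1e-4, 1e6)
    activity_df = pd.DataFrame({"ligand_id": matrix.ligand_ids,
                                "ki_uM": np.round(ki, 6)})
    activity_df.to_csv(out / "activities.csv", index=False)

    config = {
        "weights": {k: getattr(DEFAULT_WEIGHTS, k)
                    for k in ("w_gauss1", "w_gauss2", "w_repulsion",
                              "w_hydrophobic", "w_hbond", "w_rot", "cutoff")},
        "n_structures": n_structures, "n_ligands": n_ligands,
        "n_poses": n_poses, "seed": seed,
    }
    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))

    return {
        "root": out,
        "receptors": [out / "receptors" / f"{sid}.pdbqt" for sid, _ in structures],
        "activities": out / "activities.csv",
        "config": out / "config.yaml",
        "n_pose_rows": len(records),
    }
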