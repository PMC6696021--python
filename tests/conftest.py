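"""Shared fixtures: toy complexes, planted-activity datasets, a campaign."""

from __future__ import annotations

import numpy as np
import pytest

import dockscreen as ds


@pytest.fixture(scope="session")
def toy_complex():
    return ds.make_toy_complex(ds.ToyComplexSpec(seed=7))


@pytest.fixture(scope="session")
def planted_dataset():
    """Default planted-signal campaign: 300 ligands, 10 structures, 3 poses."""
    pose_df, activity_df, truth = ds.make_activity_dataset(
        ds.PlantedActivityModel(seed=1), n_ligands=300)
    matrix = ds.pose_table_to_matrix(pose_df)
    ki = dict(zip(activity_df["ligand_id"], activity_df["ki_uM"]))
    labels = np.array([ki[l] < 10.0 for l in matrix.ligand_ids], dtype=int)
    return {"pose_df": pose_df, "activity_df": activity_df, "truth": truth,
            "matrix": matrix, "ki": ki, "labels": labels}


@pytest.fixture(scope="session")
def planted_split(planted_dataset):
    tr, te = ds.split_dataset(
        list(range(len(planted_dataset["labels"]))), ds.SplitSpec(seed=1))
    return np.asarray(tr), np.asarray(te)


@pytest.fixture(scope="session")
def campaign_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("campaign") / "fixture"
    ds.make_campaign_fixture(out, seed=5)
    return out


def random_typed_atom(rng, serial, element_type=None, scale=5.0):
    """A random atom with interaction classes derived from its type."""
    types = ["C", "A", "N", "NA", "OA", "S", "Cl"]
    t = element_type or str(rng.choice(types))
    x, y, z = rng.normal(scale=scale, size=3)
    atom = ds.TypedAtom(serial=serial, name=t, element_type=t,
                        x=float(x), y=float(y), z=float(z))
    return ds.assign_interaction_classes([atom])[0]
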