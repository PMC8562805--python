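import numpy as np
import pytest

from ddgscan.fixtures import FixtureRecipe, make_toy_complex, write_fixture_battery
from ddgscan.structures import read_structure


@pytest.fixture(scope="session")
def recipe():
    return FixtureRecipe(seed=0)


@pytest.fixture(scope="session")
def query(recipe):
    return make_toy_complex(recipe)


@pytest.fixture(scope="session")
def subunits(recipe):
    return recipe.subunits()


@pytest.fixture(scope="session")
def battery_dir(tmp_path_factory):
    """Standard fixture battery written once per session."""
    directory = tmp_path_factory.mktemp("battery")
    write_fixture_battery(directory, seed=0)
    return directory


@pytest.fixture(scope="session")
def battery_manifest(battery_dir):
    import json

    with open(battery_dir / "manifest.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def query_from_file(battery_dir):
    return read_structure(battery_dir / "query.pdb")


def quaternion_superpose_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Independent minimum-RMSD oracle via Horn's quaternion eigenvalue
    method: the optimal rotation's quality is the largest eigenvalue of the
    4x4 key matrix built from the correlation of the centered point sets,
    and min RMSD^2 = (|P|^2 + |Q|^2 - 2*lambda_max) / n.  Quaternions
    parameterise proper rotations only, so reflections are excluded, as in
    the implementation under test — but by a disjoint algorithm.
    """
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)
    M = P.T @ Q
    sxx, sxy, sxz = M[0]
    syx, syy, syz = M[1]
    szx, szy, szz = M[2]
    K = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    n = P.shape[0]
    msd = max((np.sum(P**2) + np.sum(Q**2) - 2.0 * lam) / n, 0.0)
    return float(np.sqrt(msd))
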