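"""Kabsch superposition, chain assignment, and the filter cascade."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import quaternion_superpose_rmsd
from ddgscan.fixtures import (
    FixtureRecipe,
    Perturbation,
    derive_homolog,
    make_toy_complex,
)
from ddgscan.matcher import (
    RigidTransform,
    filter_homolog,
    kabsch_superpose,
    match_chains,
    superpose_complex,
)
from ddgscan.seqsearch import align_pair, sequence_identity
from ddgscan.structures import SubunitDefinition


class TestKabsch:
    def test_identical_sets_give_zero_and_identity(self):
        P = np.random.default_rng(0).normal(0, 5, (10, 3))
        tr, rmsd = kabsch_superpose(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(tr.translation, 0, atol=1e-9)

    def test_rigid_motion_recovered_exactly(self):
        rng = np.random.default_rng(1)
        P = rng.normal(0, 5, (25, 3))
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(0, 20, 3)
        _, rmsd = kabsch_superpose(P, P @ R.T + t)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_quaternion_oracle_on_random_instances(self):
        """100 seeded random point sets, n = 3..50, vs Horn's method."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(3, 51))
            P = rng.normal(0, 10, (n, 3))
            Q = P @ Rotation.random(rng=rng).as_matrix().T
            Q = Q + rng.normal(0, 1.0, (n, 3)) + rng.normal(0, 5, 3)
            _, rmsd = kabsch_superpose(P, Q)
            assert rmsd == pytest.approx(quaternion_superpose_rmsd(P, Q), abs=1e-6)

    def test_rmsd_invariant_to_rigid_pretransform(self):
        rng = np.random.default_rng(3)
        P = rng.normal(0, 5, (15, 3))
        Q = P + rng.normal(0, 0.8, (15, 3))
        _, rmsd0 = kabsch_superpose(P, Q)
        for _ in range(5):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.normal(0, 30, 3)
            _, rmsd1 = kabsch_superpose(P @ R.T + t, Q)
            assert rmsd1 == pytest.approx(rmsd0, abs=1e-6)

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[i, 0.0, 0.0] for i in range(5)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)

    def test_rotation_is_proper_even_for_planar_sets(self):
        rng = np.random.default_rng(4)
        P = rng.normal(0, 5, (12, 3))
        P[:, 2] = 0.0  # planar: reflection would cheat if allowed
        Q = -P  # point inversion, an improper transform
        tr, _ = kabsch_superpose(P, Q)
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_improper_rotation_matrix_rejected(self):
        with pytest.raises(ValueError, match="proper"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestMatchChains:
    def test_exact_copy_trivial_assignment(self, query, subunits):
        corr = match_chains(query, subunits, query)
        assert corr.pairs["A"][0] == "A"
        assert corr.pairs["B"][0] == "B"
        assert all(v == 1.0 for v in corr.identities.values())
        assert corr.unmatched_subject_chains == []

    def test_missing_required_chain_is_rejection(self, query, subunits):
        dropped, _ = derive_homolog(
            query, Perturbation(drop_chains=("B",)), seed=1, structure_id="d"
        )
        assert match_chains(query, subunits, dropped) is None

    def test_homodimer_assignment_matches_brute_force(self):
        """Equal-sequence chains: optimal assignment exists and agrees with
        explicit enumeration of both pairings on total identity."""
        base = make_toy_complex(FixtureRecipe(seed=5, structure_id="homo"))
        # make B's sequence equal to A's -> homodimer
        import dataclasses

        from ddgscan.fixtures import _ONE_TO_THREE
        from ddgscan.structures import Chain, ComplexStructure

        seq = base.chains[0].sequence
        b_res = [
            dataclasses.replace(r, resname=_ONE_TO_THREE[aa])
            for r, aa in zip(base.chains[1].residues, seq)
        ]
        homo = ComplexStructure(
            "homo", [base.chains[0], Chain("B", b_res)]
        )
        subunits = SubunitDefinition(["A"], ["B"])
        corr = match_chains(homo, subunits, homo)
        # brute force: both assignments have equal total identity
        ident = {}
        for uc, sc in itertools.product("AB", repeat=2):
            ident[(uc, sc)] = sequence_identity(
                align_pair(homo.chain(uc).sequence, homo.chain(sc).sequence)
            )
        assert ident[("A", "A")] + ident[("B", "B")] == pytest.approx(
            ident[("A", "B")] + ident[("B", "A")]
        )
        # tie resolved by pooled RMSD: the un-swapped assignment superposes
        # exactly, the swapped one cannot
        assert corr.pairs["A"][0] == "A" and corr.pairs["B"][0] == "B"

    def test_extraneous_chain_listed_unmatched(self, query, subunits):
        extra = make_toy_complex(
            FixtureRecipe(seed=0, n_chains_subunit2=2, structure_id="big")
        )
        corr = match_chains(query, subunits, extra)
        assert corr is not None
        assert corr.unmatched_subject_chains == ["C"]


class TestSuperposeComplex:
    def test_rotated_copy_with_extra_chain_moves_consistently(self, query, subunits):
        rng = np.random.default_rng(11)
        big = make_toy_complex(
            FixtureRecipe(seed=0, n_chains_subunit2=2, structure_id="big")
        )
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(0, 10, 3)
        from ddgscan.structures import transform_structure

        moved = transform_structure(big, R, t)
        corr = match_chains(query, subunits, moved)
        fitted, rmsd = superpose_complex(query, subunits, moved, corr)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        # extraneous chain C carried back to its original frame
        orig_c = np.array(
            [a.position for r in big.chain("C").residues for a in r.atoms]
        )
        fit_c = np.array(
            [a.position for r in fitted.chain("C").residues for a in r.atoms]
        )
        assert np.allclose(orig_c, fit_c, atol=1e-6)

    def test_displaced_subunit_exceeds_gate(self, query, subunits):
        displaced, _ = derive_homolog(
            query,
            Perturbation(displace_subunit2=20.0),
            seed=2,
            subunits=subunits,
            structure_id="disp",
        )
        corr = match_chains(query, subunits, displaced)
        _, rmsd = superpose_complex(query, subunits, displaced, corr)
        assert rmsd > 6.0
        # the best-fit RMSD of a half displaced by d is ~d/2
        assert rmsd == pytest.approx(10.0, rel=0.15)

    def test_noise_gives_rmsd_near_noise_magnitude(self, query, subunits):
        noisy, _ = derive_homolog(
            query,
            Perturbation(noise_sigma=0.5),
            seed=3,
            subunits=subunits,
            structure_id="noisy",
        )
        corr = match_chains(query, subunits, noisy)
        _, rmsd = superpose_complex(query, subunits, noisy, corr)
        # expected ~ sigma * sqrt(3) per-atom displacement
        assert 0.4 < rmsd < 1.5
        assert rmsd < 6.0


class TestFilterCascade:
    def test_self_acceptance(self, query, subunits):
        d = filter_homolog(query, subunits, query)
        assert d.accepted
        assert d.stage_reached == "accepted"
        assert d.rmsd == pytest.approx(0.0, abs=1e-9)
        assert all(v == 1.0 for v in d.per_chain_identity.values())

    def test_mutated_chain_rejected_at_identity(self, query, subunits):
        variant, meta = derive_homolog(
            query,
            Perturbation(mutation_fraction=0.15),
            seed=4,
            subunits=subunits,
            structure_id="m15",
        )
        d = filter_homolog(query, subunits, variant)
        assert d.stage_reached == "identity_check"
        assert not d.accepted
        assert min(d.per_chain_identity.values()) < 0.90

    def test_displaced_subunit_rejected_at_rmsd(self, query, subunits):
        variant, _ = derive_homolog(
            query,
            Perturbation(displace_subunit2=20.0),
            seed=5,
            subunits=subunits,
            structure_id="d20",
        )
        d = filter_homolog(query, subunits, variant)
        assert d.stage_reached == "rmsd_check"
        assert not d.accepted

    def test_accepted_set_monotone_in_rmsd_cutoff(self, query, subunits):
        variants = []
        for i, pert in enumerate(
            [
                Perturbation(),
                Perturbation(noise_sigma=0.5),
                Perturbation(displace_subunit2=14.0),
                Perturbation(displace_subunit2=20.0),
                Perturbation(displace_subunit2=30.0),
            ]
        ):
            v, _ = derive_homolog(
                query, pert, seed=100 + i, subunits=subunits, structure_id=f"v{i}"
            )
            variants.append(v)
        accepted_at = {}
        for cutoff in (2.0, 6.0, 8.0, 20.0):
            accepted_at[cutoff] = {
                v.structure_id
                for v in variants
                if filter_homolog(query, subunits, v, rmsd_cutoff=cutoff).accepted
            }
        cuts = sorted(accepted_at)
        for lo, hi in zip(cuts, cuts[1:]):
            assert accepted_at[lo] <= accepted_at[hi]

    def test_accepted_decision_satisfies_its_own_invariant(self, query, subunits):
        v, _ = derive_homolog(
            query,
            Perturbation(rigid=True, noise_sigma=0.2),
            seed=6,
            subunits=subunits,
            structure_id="ok",
        )
        d = filter_homolog(query, subunits, v)
        assert d.accepted
        assert all(i >= 0.90 for i in d.per_chain_identity.values())
        assert d.rmsd is not None and d.rmsd <= 6.0
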