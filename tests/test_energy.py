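import math

import numpy as np
import pytest

from triplexlens.energy import (
    interaction_energy_series,
    level_cross_energy,
    level_hbond_energy,
    level_profile,
    level_stack_energy,
    pair_energy,
)
from triplexlens.errors import ExclusionError, SingularityError, ValidationError
from triplexlens.synthtraj import PlantedPair, build_ideal_triplex, synthesize_trajectory
from triplexlens.topology import Atom, ForceFieldParams, Topology, default_params
from triplexlens.trajio import Trajectory
from triplexlens.triplexcode import SequenceRecord, align_windows

COULOMB_F = 1389.35458


def make_atom(charge=0.0, sigma=3.0, epsilon=0.5, index=0):
    return Atom(
        index=index, name="B", element="O", chain_id="A", res_name="U",
        level=1, charge=charge, sigma=sigma, epsilon=epsilon,
        roles=frozenset({"acceptor"}),
    )


def brute_force_pair_sum(coords, topology, params, idx_a, idx_b):
    """Independent double-loop oracle over an atom-pair block."""
    total = 0.0
    for i in idx_a:
        for j in idx_b:
            r = float(np.linalg.norm(coords[i] - coords[j]))
            lj, cb = pair_energy(topology.atoms[i], topology.atoms[j], r, params)
            total += lj + cb
    return total


def residue_idx(topology, chain, level):
    return list(topology.residue_atoms(chain, level))


@pytest.fixture(scope="module")
def four_level_system():
    rna = SequenceRecord("r", "UCGU", "rna")  # one mismatch at level 3
    dna = SequenceRecord("d", "AGGA", "dna")
    aln = align_windows(rna, 1, dna, 1, 4)
    params = default_params()
    topology, reference = build_ideal_triplex(aln, params=params)
    traj, _ = synthesize_trajectory(
        topology, reference, 5, 0.5, 0.15,
        [PlantedPair(1, "B", 1, 0.8), PlantedPair(2, "B", 2, 0.8, n_bonds=2)],
        seed=31,
    )
    return topology, traj, params


class TestPairEnergy:
    def test_lj_zero_crossing(self):
        a = make_atom(charge=0.0, sigma=3.0)
        b = make_atom(charge=0.0, sigma=3.0, index=1)
        lj, cb = pair_energy(a, b, 3.0, default_params())
        assert lj == pytest.approx(0.0, abs=1e-12)
        assert cb == 0.0

    def test_lj_minimum_is_minus_epsilon(self):
        eps = 0.7
        a = make_atom(sigma=3.2, epsilon=eps)
        b = make_atom(sigma=3.2, epsilon=eps, index=1)
        r = 2.0 ** (1.0 / 6.0) * 3.2
        lj, _ = pair_energy(a, b, r, default_params())
        assert lj == pytest.approx(-eps, rel=1e-12)

    def test_coulomb_constant(self):
        a = make_atom(charge=1.0, epsilon=0.0)
        b = make_atom(charge=1.0, epsilon=0.0, index=1)
        _, cb = pair_energy(a, b, 10.0, default_params())
        assert cb == pytest.approx(138.935458, rel=1e-12)

    def test_beyond_cutoff_zero(self):
        a = make_atom(charge=1.0)
        b = make_atom(charge=1.0, index=1)
        assert pair_energy(a, b, 10.01, default_params(cutoff=10.0)) == (0.0, 0.0)

    def test_zero_distance_singularity(self):
        a, b = make_atom(), make_atom(index=1)
        with pytest.raises(SingularityError):
            pair_energy(a, b, 0.0, default_params())

    def test_symmetry(self):
        a = make_atom(charge=0.3, sigma=3.1, epsilon=0.4)
        b = make_atom(charge=-0.6, sigma=3.6, epsilon=0.9, index=1)
        p = default_params()
        assert pair_energy(a, b, 4.2, p) == pair_energy(b, a, 4.2, p)

    def test_coulomb_linearity_in_charge(self):
        p = default_params()
        b = make_atom(charge=-0.5, index=1)
        _, cb1 = pair_energy(make_atom(charge=0.2), b, 5.0, p)
        _, cb2 = pair_energy(make_atom(charge=0.4), b, 5.0, p)
        assert cb2 == pytest.approx(2.0 * cb1, rel=1e-12)


class TestInteractionSeries:
    def test_zeros_when_everything_far(self):
        params = default_params(cutoff=10.0)
        rna = SequenceRecord("r", "UUUU", "rna")
        dna = SequenceRecord("d", "AAAA", "dna")
        topology, reference = build_ideal_triplex(
            align_windows(rna, 1, dna, 1, 4), params=params
        )
        coords = reference[None].copy()
        rna_idx = topology.select(selection="rna")
        coords[0, rna_idx] += 500.0  # push RNA out of cutoff range
        traj = Trajectory(coords=coords, times=np.array([0.0]))
        series = interaction_energy_series(traj, topology, params)
        assert series["e_lj"][0] == 0.0
        assert series["e_cb"][0] == 0.0

    def test_matches_brute_force(self, four_level_system):
        topology, traj, params = four_level_system
        series = interaction_energy_series(traj, topology, params)
        idx_rna = topology.select(selection="rna")
        idx_dna = topology.select(selection="duplex")
        for f in range(traj.n_frames):
            oracle = brute_force_pair_sum(
                traj.coords[f], topology, params, idx_rna, idx_dna
            )
            assert series["e_total"][f] == pytest.approx(oracle, rel=1e-9)

    def test_total_is_lj_plus_cb(self, four_level_system):
        topology, traj, params = four_level_system
        series = interaction_energy_series(traj, topology, params)
        assert np.allclose(
            series["e_total"], series["e_lj"] + series["e_cb"], rtol=1e-12
        )

    def test_clip_all_levels_is_identity(self, four_level_system):
        topology, traj, params = four_level_system
        full = interaction_energy_series(traj, topology, params)
        clipped = interaction_energy_series(
            traj, topology, params, clip_levels=[1, 2, 3, 4]
        )
        assert np.allclose(full["e_total"], clipped["e_total"])

    def test_clip_subset_reduces_pairs(self, four_level_system):
        topology, traj, params = four_level_system
        clipped = interaction_energy_series(
            traj, topology, params, clip_levels=[2, 3]
        )
        idx_rna = topology.select(selection="rna", levels=[2, 3])
        idx_dna = topology.select(selection="duplex", levels=[2, 3])
        oracle = brute_force_pair_sum(
            traj.coords[0], topology, params, idx_rna, idx_dna
        )
        assert clipped["e_total"][0] == pytest.approx(oracle, rel=1e-9)

    def test_cutoff_monotone_pair_set(self, four_level_system):
        # energies with cutoffs r1<r2 differ only by pairs with r in (r1,r2]
        topology, traj, params = four_level_system
        p_small = default_params(cutoff=6.0)
        p_large = default_params(cutoff=12.0)
        small = interaction_energy_series(traj, topology, p_small)
        large = interaction_energy_series(traj, topology, p_large)
        idx_rna = topology.select(selection="rna")
        idx_dna = topology.select(selection="duplex")
        for f in range(2):
            diff = 0.0
            for i in idx_rna:
                for j in idx_dna:
                    r = float(np.linalg.norm(traj.coords[f, i] - traj.coords[f, j]))
                    if 6.0 < r <= 12.0:
                        lj, cb = pair_energy(
                            topology.atoms[i], topology.atoms[j], r, p_large
                        )
                        diff += lj + cb
            assert large["e_total"][f] - small["e_total"][f] == pytest.approx(
                diff, rel=1e-9, abs=1e-9
            )


class TestLevelEnergies:
    def test_hbond_matches_brute_force(self, four_level_system):
        topology, traj, params = four_level_system
        for f in range(traj.n_frames):
            coords = traj.coords[f]
            for i in (2, 3):
                oracle = sum(
                    brute_force_pair_sum(
                        coords, topology, params,
                        residue_idx(topology, x, i), residue_idx(topology, y, i),
                    )
                    for x, y in (("A", "B"), ("B", "C"), ("A", "C"))
                )
                got = level_hbond_energy(coords, topology, params, i)
                assert got == pytest.approx(oracle, rel=1e-9)

    def test_cross_matches_brute_force(self, four_level_system):
        topology, traj, params = four_level_system
        coords = traj.coords[0]
        for i in (2, 3):
            oracle = sum(
                brute_force_pair_sum(
                    coords, topology, params,
                    residue_idx(topology, "B", i),
                    residue_idx(topology, other, j),
                )
                for other in ("A", "C")
                for j in (i - 1, i + 1)
            )
            assert level_cross_energy(coords, topology, params, i) == (
                pytest.approx(oracle, rel=1e-9)
            )

    def test_stack_matches_brute_force(self, four_level_system):
        topology, traj, params = four_level_system
        coords = traj.coords[0]
        oracle = sum(
            brute_force_pair_sum(
                coords, topology, params,
                residue_idx(topology, chain, 2), residue_idx(topology, chain, 3),
            )
            for chain in ("A", "B", "C")
        )
        assert level_stack_energy(coords, topology, params, 2) == (
            pytest.approx(oracle, rel=1e-9)
        )

    def test_terminal_levels_excluded(self, four_level_system):
        topology, traj, params = four_level_system
        coords = traj.coords[0]
        for fn in (level_hbond_energy, level_cross_energy):
            with pytest.raises(ExclusionError):
                fn(coords, topology, params, 1)
            with pytest.raises(ExclusionError):
                fn(coords, topology, params, 4)
        with pytest.raises(ExclusionError):
            level_stack_energy(coords, topology, params, 3)  # step hits terminal
        with pytest.raises(ValidationError, match="last level"):
            level_stack_energy(coords, topology, params, 4)

    def test_charge_scaling_linearity(self, four_level_system):
        # doubling chain-A charges doubles A-involving Coulomb terms and
        # leaves the B–C term unchanged
        topology, traj, params = four_level_system
        coords = traj.coords[0]
        i = 2

        def cb_pair(topo, x, y):
            total = 0.0
            for ia in residue_idx(topo, x, i):
                for ja in residue_idx(topo, y, i):
                    r = float(np.linalg.norm(coords[ia] - coords[ja]))
                    if r <= params.cutoff:
                        total += (
                            params.coulomb_f
                            * topo.atoms[ia].charge
                            * topo.atoms[ja].charge
                            / r
                        )
            return total

        doubled_atoms = [
            a if a.chain_id != "A" else Atom(
                index=a.index, name=a.name, element=a.element,
                chain_id=a.chain_id, res_name=a.res_name, level=a.level,
                charge=2.0 * a.charge, sigma=a.sigma, epsilon=a.epsilon,
                roles=a.roles, parent=a.parent,
            )
            for a in topology.atoms
        ]
        doubled = Topology(doubled_atoms, chains=topology.chains)
        assert cb_pair(doubled, "A", "B") == pytest.approx(
            2.0 * cb_pair(topology, "A", "B"), rel=1e-12
        )
        assert cb_pair(doubled, "B", "C") == pytest.approx(
            cb_pair(topology, "B", "C"), rel=1e-12
        )


class TestLevelProfile:
    def test_levels_covered(self, stable_bundle):
        profile = level_profile(
            stable_bundle.trajectory, stable_bundle.topology,
            stable_bundle.params, all_frames=True,
        )
        assert list(profile["level"]) == list(range(2, 15))

    def test_decomposition_consistency(self, stable_bundle):
        profile = level_profile(
            stable_bundle.trajectory, stable_bundle.topology,
            stable_bundle.params, all_frames=True,
        )
        assert np.allclose(
            profile["e_total"],
            profile["e_hb"] + profile["e_cross"] + profile["e_stack"],
            rtol=1e-9,
        )

    def test_constant_trajectory_equals_single_frame(self, static_trajectory,
                                                     params):
        topology, traj, _ = static_trajectory
        profile = level_profile(traj, topology, params, all_frames=True)
        coords = traj.coords[0]
        for _, row in profile.iterrows():
            i = int(row["level"])
            assert row["e_hb"] == pytest.approx(
                level_hbond_energy(coords, topology, params, i), rel=1e-12
            )

    def test_conservation_oracle(self, four_level_system):
        # profile totals equal the brute-force sum over all included
        # residue-pair interactions
        topology, traj, params = four_level_system
        profile = level_profile(traj, topology, params, all_frames=True)
        total = profile["e_total"].sum()

        oracle = 0.0
        for f in range(traj.n_frames):
            coords = traj.coords[f]
            for i in (2, 3):
                oracle += level_hbond_energy(coords, topology, params, i)
                oracle += level_cross_energy(coords, topology, params, i)
            oracle += level_stack_energy(coords, topology, params, 2)
        oracle /= traj.n_frames
        assert total == pytest.approx(oracle, rel=1e-9)

    def test_too_few_levels(self, params):
        from triplexlens.topology import template_atoms

        atoms = []
        idx = 0
        for chain, res in (("A", "U"), ("B", "A"), ("C", "T")):
            for level in (1, 2):
                atoms.extend(template_atoms(chain, res, level, params, idx))
                idx += 5
        topology = Topology(atoms)
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(1, topology.n_atoms, 3)) * 20.0
        traj = Trajectory(coords=coords, times=np.array([0.0]))
        with pytest.raises(ValidationError, match="3 levels"):
            level_profile(traj, topology, params, all_frames=True)


class TestOrdering:
    def test_more_bonds_more_negative_energy(self):
        from triplexlens.scenarios import generate_scenario

        strong = generate_scenario("stable_A", seed=2, n_frames=60)
        weak = generate_scenario("unstable_A", seed=2, n_frames=60)
        e_strong = interaction_energy_series(
            strong.trajectory, strong.topology, strong.params
        )["e_total"].mean()
        e_weak = interaction_energy_series(
            weak.trajectory, weak.topology, weak.params
        )["e_total"].mean()
        assert e_strong < e_weak
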