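"""Duplex pairing, the nonbonded energy kernel, regional averages,
box-concentration arithmetic."""

import dataclasses

import numpy as np
import pytest

from agomg import (
    COULOMB_CONSTANT,
    DEFAULT_GUIDE,
    DEFAULT_TARGET,
    EnergyOptions,
    PairEnergyMatrix,
    RegionPartition,
    SimulationBox,
    SyntheticSystemSpec,
    build_duplex,
    duplex_energy_profile,
    generate_complex,
    generate_trajectory,
    ion_concentration_mM,
    ions_for_concentration,
    pair_interaction_energy,
    regional_average_energy,
    toy_param_table,
)
from agomg.structure_io import AtomRecord, ComplexTopology, NonbondedParamTable, Role

import pandas as pd


class TestBuildDuplex:
    def test_printed_sequences_form_15_wc_pairs(self):
        duplex = build_duplex(DEFAULT_GUIDE, DEFAULT_TARGET, strict_wc=True)
        assert duplex.length == 15
        from agomg.energetics import WC_COMPLEMENT
        for _, g, t in duplex.pairs:
            assert WC_COMPLEMENT[t] == g

    def test_two_mer_antiparallel_pairing(self):
        duplex = build_duplex("AC", "GU", strict_wc=True)
        # pair 1: target G with guide position 2 (C); pair 2: target U with A
        assert duplex.pairs == ((1, "C", "G"), (2, "A", "U"))

    def test_mismatch_reported_by_pair_index(self):
        target = DEFAULT_TARGET[:2] + "A" + DEFAULT_TARGET[3:]  # G->A at pos 3
        with pytest.raises(ValueError, match="pair index 3"):
            build_duplex(DEFAULT_GUIDE, target, strict_wc=True)
        # non-strict mode accepts the same duplex
        assert build_duplex(DEFAULT_GUIDE, target, strict_wc=False).length == 15

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            build_duplex("ACGU", "ACG")

    def test_non_rna_alphabet_rejected(self):
        with pytest.raises(ValueError, match="non-RNA"):
            build_duplex("ACGX", "ACGU")


def _two_atom_system(q1, q2, r, eps=0.0, rmin_half=1.0):
    """One-atom guide vs one-atom target nucleotide at distance r."""
    atoms = [
        AtomRecord(1, "N1", "N", 1, "A", "G", Role.GUIDE_RNA),
        AtomRecord(2, "N3", "N", 1, "U", "T", Role.TARGET_RNA),
    ]
    topo = ComplexTopology(atoms)
    frame = np.array([[0.0, 0, 0], [r, 0, 0]])
    params = NonbondedParamTable(pd.DataFrame(
        [("A", "N1", q1, eps, rmin_half), ("U", "N3", q2, eps, rmin_half)],
        columns=NonbondedParamTable.COLUMNS))
    duplex = build_duplex("A", "U", strict_wc=True)
    return topo, frame, params, duplex


class TestPairInteractionEnergy:
    def test_coulomb_closed_form(self):
        # k_e * (+1)(-1) / 3.320636 = -100.0 kcal/mol
        topo, frame, params, duplex = _two_atom_system(1.0, -1.0,
                                                       COULOMB_CONSTANT / 100)
        e = pair_interaction_energy(frame, topo, duplex, 1, params)
        assert e == pytest.approx(-100.0, abs=1e-9)

    def test_lj_minimum_at_rmin(self):
        topo, frame, params, duplex = _two_atom_system(
            0.0, 0.0, r=2.0, eps=0.25, rmin_half=1.0)  # r == R_ij == 2
        e = pair_interaction_energy(frame, topo, duplex, 1, params)
        assert e == pytest.approx(-0.25, abs=1e-12)  # -sqrt(eps_i eps_j)

    def test_relative_dielectric_scales_coulomb(self):
        topo, frame, params, duplex = _two_atom_system(1.0, -1.0, 3.0)
        e1 = pair_interaction_energy(frame, topo, duplex, 1, params)
        e4 = pair_interaction_energy(
            frame, topo, duplex, 1, params,
            EnergyOptions(relative_dielectric=4.0))
        assert e4 == pytest.approx(e1 / 4.0)

    def test_matches_explicit_double_loop_oracle(self, default_spec, params):
        topo, frame = generate_complex(default_spec)
        duplex = build_duplex(default_spec.guide, default_spec.target)
        for k in (1, 8, 15):
            e = pair_interaction_energy(frame, topo, duplex, k, params)
            # brute-force oracle: explicit python loop over atom pairs
            from agomg.energetics import RNA_BACKBONE_ATOMS
            L = duplex.length

            def atom_set(chain, rid):
                return [i for i, a in enumerate(topo.atoms)
                        if a.chain_id == chain and a.residue_id == rid
                        and a.atom_name not in RNA_BACKBONE_ATOMS]

            g_atoms = atom_set("G", L - k + 1)
            t_atoms = atom_set("T", k)
            expected = 0.0
            for i in g_atoms:
                for j in t_atoms:
                    ai, aj = topo.atoms[i], topo.atoms[j]
                    qi, ei, ri = params.lookup(ai.residue_name, ai.atom_name)
                    qj, ej, rj = params.lookup(aj.residue_name, aj.atom_name)
                    r = float(np.linalg.norm(frame[i] - frame[j]))
                    expected += COULOMB_CONSTANT * qi * qj / r
                    rat6 = ((ri + rj) / r) ** 6
                    expected += np.sqrt(ei * ej) * (rat6 ** 2 - 2 * rat6)
            assert e == pytest.approx(expected, abs=1e-10)

    def test_energy_symmetric_in_atom_sets(self):
        from agomg.energetics import _nonbonded_sum
        rng = np.random.default_rng(0)
        ca, cb = rng.normal(size=(3, 3)), rng.normal(size=(4, 3)) + 5
        qa, qb = rng.normal(size=3), rng.normal(size=4)
        ea, eb = rng.uniform(0, 1, 3), rng.uniform(0, 1, 4)
        ra, rb = rng.uniform(1, 2, 3), rng.uniform(1, 2, 4)
        opts = EnergyOptions()
        assert _nonbonded_sum(ca, cb, qa, qb, ea, eb, ra, rb, opts) == (
            _nonbonded_sum(cb, ca, qb, qa, eb, ea, rb, ra, opts))

    def test_charge_scaling_is_quadratic_with_lj_zeroed(self):
        topo, frame, params, duplex = _two_atom_system(0.3, -0.2, 4.0)
        e1 = pair_interaction_energy(frame, topo, duplex, 1, params)
        topo, frame, params3, duplex = _two_atom_system(0.9, -0.6, 4.0)
        e3 = pair_interaction_energy(frame, topo, duplex, 1, params3)
        assert e3 == pytest.approx(9.0 * e1, rel=1e-12)

    def test_rigid_transform_leaves_energies_unchanged(self, default_spec,
                                                       params):
        from conftest import random_rotation
        topo, frame = generate_complex(default_spec)
        duplex = build_duplex(default_spec.guide, default_spec.target)
        rng = np.random.default_rng(1)
        moved = frame @ random_rotation(rng).T + rng.normal(size=3) * 20
        for k in (2, 9):
            e0 = pair_interaction_energy(frame, topo, duplex, k, params)
            e1 = pair_interaction_energy(moved, topo, duplex, k, params)
            assert e1 == pytest.approx(e0, abs=1e-9)

    def test_gc_pairs_bind_stronger_than_au_on_ladder(self, default_spec,
                                                      params):
        topo, frame = generate_complex(default_spec)
        duplex = build_duplex(default_spec.guide, default_spec.target)
        energies = {
            (t, g): pair_interaction_energy(frame, topo, duplex, k, params)
            for k, g, t in duplex.pairs
        }
        gc = [e for (t, g), e in energies.items() if {t, g} == {"G", "C"}]
        au = [e for (t, g), e in energies.items() if {t, g} == {"A", "U"}]
        assert max(gc) < min(au)  # 3 polar contacts beat 2

    def test_missing_parameter_is_an_error(self):
        topo, frame, params, duplex = _two_atom_system(1.0, -1.0, 3.0)
        bad = NonbondedParamTable(params.frame[params.frame.atom_name != "N3"])
        from agomg import ParameterLookupError
        with pytest.raises(ParameterLookupError, match="N3"):
            pair_interaction_energy(frame, topo, duplex, 1, bad)

    def test_coincident_atoms_error(self):
        topo, frame, params, duplex = _two_atom_system(1.0, -1.0, 3.0)
        with pytest.raises(ValueError, match="zero"):
            pair_interaction_energy(np.zeros((2, 3)), topo, duplex, 1, params)


class TestDuplexEnergyProfile:
    @pytest.fixture()
    def two_pair_spec(self):
        return SyntheticSystemSpec(
            group="low", n_residues=8, missing_residue_ids=(), guide="AC",
            target="GU", n_extra_ions=0, n_frames=2, seed=3)

    def test_identical_frames_identical_rows(self, two_pair_spec, params):
        topo, frame = generate_complex(two_pair_spec)
        from agomg import Trajectory
        traj = Trajectory(topo, np.array([0.0, 1.0]),
                          np.stack([frame, frame]))
        duplex = build_duplex("AC", "GU")
        matrix = duplex_energy_profile(traj, duplex, params, window_ps=None)
        np.testing.assert_allclose(matrix.energies[0], matrix.energies[1])

    def test_separated_pairs_have_negligible_energy(self, two_pair_spec,
                                                    params):
        topo, frame = generate_complex(two_pair_spec)
        far = frame.copy()
        guide_atoms = np.flatnonzero(topo.roles == "guide_rna")
        far[guide_atoms] += np.array([100.0, 0, 0])
        from agomg import Trajectory
        traj = Trajectory(topo, np.array([0.0, 1.0]), np.stack([frame, far]))
        duplex = build_duplex("AC", "GU")
        matrix = duplex_energy_profile(traj, duplex, params, window_ps=None)
        assert np.all(np.abs(matrix.energies[1]) < 0.01)
        assert np.all(matrix.energies[0] < -1.0)  # bound frame is attractive

    def test_default_window_yields_601_samples(self, two_pair_spec, params):
        spec = dataclasses.replace(two_pair_spec, n_frames=2001,
                                   frame_interval_ps=5.0)
        traj, _ = generate_trajectory(spec, 0)
        duplex = build_duplex("AC", "GU")
        matrix = duplex_energy_profile(traj, duplex, params)  # 7-10 ns, 5 ps
        assert matrix.energies.shape[0] == 601
        assert matrix.times_ps[0] == 7000.0 and matrix.times_ps[-1] == 10000.0

    def test_empty_window_rejected(self, two_pair_spec, params):
        topo, frame = generate_complex(two_pair_spec)
        from agomg import Trajectory
        traj = Trajectory(topo, np.array([0.0, 1.0]), np.stack([frame, frame]))
        with pytest.raises(ValueError, match="empty"):
            duplex_energy_profile(traj, build_duplex("AC", "GU"), params,
                                  window_ps=(50.0, 60.0))


class TestRegionalAverages:
    def test_uniform_energies_average_to_themselves(self):
        matrix = PairEnergyMatrix(np.array([0.0]), -np.ones((1, 15)))
        out = regional_average_energy(matrix)
        for col in ("Region1", "Region2", "Region3", "whole"):
            assert out[col].iloc[0] == pytest.approx(-1.0)

    def test_index_valued_energies_follow_hand_arithmetic(self):
        matrix = PairEnergyMatrix(np.array([0.0]),
                                  np.arange(1.0, 16.0)[None, :])
        out = regional_average_energy(matrix)
        assert out["Region1"].iloc[0] == pytest.approx(2.5)
        assert out["Region2"].iloc[0] == pytest.approx(8.0)
        assert out["Region3"].iloc[0] == pytest.approx(13.5)
        assert out["whole"].iloc[0] == pytest.approx(8.0)

    def test_within_region_permutation_invariance(self):
        rng = np.random.default_rng(4)
        row = rng.normal(size=15)
        permuted = row.copy()
        permuted[4:11] = rng.permutation(row[4:11])  # shuffle Region2 only
        m1 = PairEnergyMatrix(np.array([0.0]), row[None, :])
        m2 = PairEnergyMatrix(np.array([0.0]), permuted[None, :])
        out1, out2 = regional_average_energy(m1), regional_average_energy(m2)
        assert out1["Region2"].iloc[0] == pytest.approx(out2["Region2"].iloc[0])

    def test_partition_must_cover_matrix(self):
        matrix = PairEnergyMatrix(np.array([0.0]), np.zeros((1, 10)))
        with pytest.raises(ValueError, match="partition"):
            regional_average_energy(matrix, RegionPartition())

    def test_noncontiguous_partition_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            RegionPartition((("A", 1, 4), ("B", 6, 15)))


class TestIonConcentration:
    def test_ten_ions_in_152A_box_is_5mM(self):
        box = SimulationBox((152.0,) * 3)
        conc = ion_concentration_mM(10, box)
        assert conc == pytest.approx(4.73, abs=0.005)
        assert round(conc) == 5

    def test_zero_ions_zero_concentration(self):
        assert ion_concentration_mM(0, SimulationBox((152.0,) * 3)) == 0.0

    def test_inverse_round_trips(self):
        box = SimulationBox((152.0,) * 3)
        assert ions_for_concentration(4.73, box) == 10
        for n in (1, 5, 10, 20):
            assert ions_for_concentration(
                ion_concentration_mM(n, box), box) == n
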