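"""Arg guanidinium orientation classification against scripted truth."""

import numpy as np
import pytest

from adsorbkit import arginine, synthetic
from adsorbkit.arginine import CONTACT_PARALLEL, CONTACT_PERPENDICULAR, NO_CONTACT
from adsorbkit.io_formats import AnalysisConfig, Topology, Trajectory


def _arg_system(tilt_deg, dz=0.2):
    """Single Arg: guanidinium quartet at a given plane tilt, plus CA/CB."""
    off = synthetic._guanidinium_offsets(tilt_deg)
    names = ["CA", "CB", "CZ", "NE", "NH1", "NH2"]
    coords = np.zeros((1, 6, 3))
    coords[0, 0] = [0, 0, dz + 0.35]
    coords[0, 1] = [0, 0.05, dz + 0.25]
    coords[0, 2:] = off + [0, 0, dz]
    topo = Topology(names, ["ARG"] * 6, [1] * 6, ["A"] * 6)
    return topo, Trajectory(times=[0.0], coords=coords)


class TestClassifier:
    def test_coplanar_contact_is_parallel(self, surface):
        topo, traj = _arg_system(tilt_deg=0.0, dz=0.2)
        group = arginine.find_guanidinium_groups(topo)[0]
        assert arginine.classify_arg_state(traj.coords[0], group, surface) \
            == CONTACT_PARALLEL

    def test_upright_contact_is_perpendicular(self, surface):
        topo, traj = _arg_system(tilt_deg=90.0, dz=0.2)
        group = arginine.find_guanidinium_groups(topo)[0]
        assert arginine.classify_arg_state(traj.coords[0], group, surface) \
            == CONTACT_PERPENDICULAR

    def test_far_is_no_contact_regardless_of_angles(self, surface):
        topo, traj = _arg_system(tilt_deg=90.0, dz=0.40)
        group = arginine.find_guanidinium_groups(topo)[0]
        assert arginine.classify_arg_state(traj.coords[0], group, surface) == NO_CONTACT

    def test_missing_core_atom_names_residue(self, surface):
        topo = Topology(["CA", "CZ", "NE", "NH1"], ["ARG"] * 4, [6] * 4, ["A"] * 4)
        with pytest.raises(ValueError, match="ARG6"):
            arginine.find_guanidinium_groups(topo)


class TestStateMap:
    def test_matches_ledger_everywhere(self, small_sheet, surface):
        topo, traj, ledger = small_sheet
        smap = arginine.orientation_state_map(traj, topo, surface)
        assert smap.states.shape == ledger.arg_tilt.shape
        assert (smap.states == ledger.arg_states(30.0)).mean() == 1.0

    def test_exactly_one_state_per_frame_arg(self, small_sheet, surface):
        topo, traj, _ = small_sheet
        smap = arginine.orientation_state_map(traj, topo, surface)
        assert np.isin(smap.states, [0, 1, 2]).all()

    def test_row_order_follows_topology(self, small_sheet, surface):
        topo, traj, ledger = small_sheet
        smap = arginine.orientation_state_map(traj, topo, surface)
        groups = arginine.find_guanidinium_groups(topo)
        assert smap.arg_labels == [g.arg_label for g in groups]
        assert len(smap.arg_labels) == len(ledger.arg_keys)

    def test_scripted_switch_time_recovered(self, surface):
        # one Arg scripted upright for 2 ns, flat afterwards
        script = synthetic.AdsorptionScript(
            t_end=4.0, frame_interval=0.1,
            phases=[synthetic.Phase(0.0, 4.0, "plateau", 0.0)],
            per_residue_attach={(0, 2): 0.0},
            per_arg_orientation={(0, 2): [(0.0, 90.0), (2.0, 0.0)]})
        topo, traj, _ = synthetic.make_beta_sheet_system(n_chains=1, script=script,
                                                         seed=0)
        smap = arginine.orientation_state_map(traj, topo, surface)
        col = smap.states[:, smap.arg_labels.index("A:ARG2")]
        switch = smap.times[np.nonzero(col == CONTACT_PARALLEL)[0][0]]
        assert switch == pytest.approx(2.0, abs=0.1)
        assert (col[smap.times < 2.0] == CONTACT_PERPENDICULAR).all()


class TestFirstContactStats:
    def test_scripted_fraction_recovered_exactly(self, small_sheet, surface):
        topo, traj, ledger = small_sheet
        smap = arginine.orientation_state_map(traj, topo, surface)
        stats = arginine.first_contact_orientation_stats(smap)
        truth = ledger.arg_states(30.0)
        n_perp = n_con = 0
        for g in range(truth.shape[1]):
            hits = np.nonzero(truth[:, g] != NO_CONTACT)[0]
            if hits.size:
                n_con += 1
                n_perp += truth[hits[0], g] == CONTACT_PERPENDICULAR
        assert stats["n_contacting"] == n_con
        assert stats["fraction_perpendicular"] == pytest.approx(n_perp / n_con)

    def test_single_parallel_first_gives_zero(self, surface):
        script = synthetic.AdsorptionScript(
            t_end=2.0, frame_interval=0.1,
            phases=[synthetic.Phase(0.0, 2.0, "plateau", 0.0)],
            per_residue_attach={(0, 2): 1.0},
            per_arg_orientation={(0, 2): [(0.0, 0.0)]})
        topo, traj, _ = synthetic.make_beta_sheet_system(n_chains=1, script=script,
                                                         seed=0)
        smap = arginine.orientation_state_map(traj, topo, surface)
        assert arginine.first_contact_orientation_stats(smap)[
            "fraction_perpendicular"] == 0.0

    def test_no_contacts_yields_absent_fraction(self, surface):
        script = synthetic.AdsorptionScript(
            t_end=1.0, frame_interval=0.1,
            phases=[synthetic.Phase(0.0, 1.0, "approach", 0.0)])
        topo, traj, _ = synthetic.make_beta_sheet_system(n_chains=1, script=script,
                                                         seed=0)
        smap = arginine.orientation_state_map(traj, topo, surface)
        assert arginine.first_contact_orientation_stats(smap)[
            "fraction_perpendicular"] is None

    def test_fraction_non_increasing_with_wider_threshold(self, surface):
        # borderline tilts: 45 deg classifies perpendicular at the 30-deg
        # threshold but parallel at 45 deg (max bond elevation 37.8 deg)
        script = synthetic.AdsorptionScript(
            t_end=2.0, frame_interval=0.1,
            phases=[synthetic.Phase(0.0, 2.0, "plateau", 0.0)],
            per_residue_attach={(0, 2): 0.5, (0, 4): 0.5},
            per_arg_orientation={(0, 2): [(0.0, 45.0)], (0, 4): [(0.0, 90.0)]})
        topo, traj, _ = synthetic.make_beta_sheet_system(n_chains=1, script=script,
                                                         seed=0)
        fracs = []
        for thr in (30.0, 45.0):
            cfg = AnalysisConfig(angle_threshold=thr)
            smap = arginine.orientation_state_map(traj, topo, surface, cfg)
            fracs.append(arginine.first_contact_orientation_stats(smap)[
                "fraction_perpendicular"])
        assert fracs[0] == 1.0
        assert fracs[1] == 0.5
        assert fracs[1] <= fracs[0]


def test_run_length_encoding_dwells(surface):
    script = synthetic.AdsorptionScript(
        t_end=4.0, frame_interval=0.5,
        phases=[synthetic.Phase(0.0, 4.0, "plateau", 0.0)],
        per_residue_attach={(0, 2): 0.0},
        per_arg_orientation={(0, 2): [(0.0, 90.0), (2.0, 0.0)]})
    topo, traj, _ = synthetic.make_beta_sheet_system(n_chains=1, script=script, seed=0)
    smap = arginine.orientation_state_map(traj, topo, surface)
    runs = arginine.run_length_encode(smap)
    perp = runs[(runs.arg_label == "A:ARG2") & (runs.state == "contact_perpendicular")]
    assert len(perp) == 1
    assert perp.dwell_ns.iloc[0] == pytest.approx(2.0)
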