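"""Contact kinetics against the generator's ground-truth ledger."""

import numpy as np
import pandas as pd
import pytest

from adsorbkit import contacts, synthetic
from adsorbkit.datasets import fn_gold_first_contact_times
from adsorbkit.io_formats import SurfaceModel, Trajectory


class TestAtomicContactCount:
    def test_all_far_zero(self, surface):
        traj = Trajectory(times=[0.0, 1.0], coords=np.full((2, 5, 3), 1.0))
        cs = contacts.atomic_contact_count(traj, surface)
        assert np.array_equal(cs.atomic_contacts, [0, 0])

    def test_known_subset_counted(self, surface):
        coords = np.full((1, 10, 3), 2.0)
        coords[0, :5, 2] = 0.2
        traj = Trajectory(times=[0.0], coords=coords)
        assert contacts.atomic_contact_count(traj, surface).atomic_contacts[0] == 5

    def test_boundary_is_strict(self, surface):
        coords = np.zeros((1, 1, 3))
        coords[0, 0, 2] = 0.35
        traj = Trajectory(times=[0.0], coords=coords)
        assert contacts.atomic_contact_count(traj, surface, cutoff=0.35
                                             ).atomic_contacts[0] == 0

    def test_matches_generator_ledger(self, small_sheet, surface):
        topo, traj, ledger = small_sheet
        cs = contacts.atomic_contact_count(traj, surface)
        assert np.array_equal(cs.atomic_contacts, ledger.atomic_contact_count)

    def test_empty_subset_rejected(self, small_sheet, surface):
        _, traj, _ = small_sheet
        with pytest.raises(ValueError):
            contacts.atomic_contact_count(traj, surface, atom_subset=np.array([], int))

    def test_subset_counts_sum_over_residues(self, small_sheet, surface):
        topo, traj, _ = small_sheet
        total = contacts.atomic_contact_count(traj, surface).atomic_contacts
        parts = sum(contacts.atomic_contact_count(traj, surface, atom_subset=idx
                                                  ).atomic_contacts
                    for idx in topo.residue_atom_indices())
        assert np.array_equal(total, parts)


class TestResidueMinDzMap:
    def test_normalization_pinned_and_ratio(self, surface):
        coords = np.zeros((3, 2, 3))
        coords[:, 0, 2] = 0.1          # pinned at the global minimum
        coords[:, 1, 2] = 1.0          # 10x farther
        from adsorbkit.io_formats import Topology
        topo = Topology(["CA", "CA"], ["ALA", "GLY"], [1, 2], ["A", "A"])
        traj = Trajectory(times=[0, 1, 2], coords=coords)
        res = contacts.residue_min_dz_map(traj, topo, surface)
        assert np.allclose(res["normalized"][:, 0], 1.0)
        assert np.allclose(res["normalized"][:, 1], 0.1)
        assert res["dz_ref"] == pytest.approx(0.1)

    def test_monotone_approach_gives_monotone_map(self, surface):
        from adsorbkit.io_formats import Topology
        z = np.linspace(2.0, 0.2, 50)
        coords = np.zeros((50, 1, 3))
        coords[:, 0, 2] = z
        topo = Topology(["CA"], ["ALA"], [1], ["A"])
        traj = Trajectory(times=np.arange(50.0), coords=coords)
        v = contacts.residue_min_dz_map(traj, topo, surface)["normalized"][:, 0]
        assert np.all(np.diff(v) >= -1e-12)


class TestFirstContact:
    def test_ledger_recovery_within_one_frame(self, small_sheet, surface):
        topo, traj, ledger = small_sheet
        dt = traj.times[1] - traj.times[0]
        tab = contacts.first_contact_times(traj, topo, surface).set_index("residue_label")
        for lab, t_true in ledger.first_contact.items():
            got = tab.loc[lab, "t_first_ns"]
            if t_true is None:
                assert np.isnan(got)
            else:
                assert abs(got - t_true) <= dt + 1e-12

    def test_initial_contact_reports_time_zero(self, surface):
        from adsorbkit.io_formats import Topology
        coords = np.zeros((3, 1, 3))
        coords[:, 0, 2] = 0.1
        topo = Topology(["CH3"], ["ACE"], [1], ["A"])
        traj = Trajectory(times=[0.0, 1.0, 2.0], coords=coords)
        tab = contacts.first_contact_times(traj, topo, surface)
        assert tab.t_first_ns.iloc[0] == 0.0

    def test_cutoff_monotonicity(self, small_sheet, surface):
        # a larger cutoff can only be met earlier (or equally late)
        topo, traj, _ = small_sheet
        t_small = contacts.first_contact_times(traj, topo, surface, cutoff=0.2
                                               )["t_first_ns"].to_numpy()
        t_large = contacts.first_contact_times(traj, topo, surface, cutoff=0.4
                                               )["t_first_ns"].to_numpy()
        both = ~np.isnan(t_small)
        assert np.all(np.isnan(t_small) | ~np.isnan(t_large))
        assert np.all(t_small[both] >= t_large[both] - 1e-12)


class TestAggregation:
    def test_reference_dataset_reproduces_published_averages(self):
        tables = fn_gold_first_contact_times(long_format=True)
        res = contacts.aggregate_first_contact_by_type(tables)
        expected = {"ACE": 12.86, "ALA": 30.62, "ARG": 0.31, "ASN": 21.59,
                    "ASP": 13.07, "GLN": 24.96, "GLU": 25.76, "GLY": 3.35,
                    "HIS": 22.90, "ILE": 24.47, "LEU": 15.39, "LYS": 4.88,
                    "NAC": 18.63, "PHE": 50.12, "PRO": 10.07, "SER": 6.86,
                    "THR": 7.80, "TYR": 11.78, "VAL": 34.68}
        for rtype, avg in expected.items():
            assert res["mean"][rtype] == pytest.approx(avg, abs=0.005 + 1e-9), rtype

    def test_absent_cells_excluded_from_mean(self):
        tab = pd.DataFrame({"residue_label": ["LYS1", "LYS1"],
                            "residue_type": ["LYS", "LYS"],
                            "sim_id": ["a", "b"],
                            "t_first_ns": [7.15, np.nan]})
        res = contacts.aggregate_first_contact_by_type([tab])
        assert res["mean"]["LYS"] == pytest.approx(7.15)

    def test_cell_is_min_over_residues_of_type(self):
        tab = pd.DataFrame({"residue_label": ["ARG1", "ARG5"],
                            "residue_type": ["ARG", "ARG"],
                            "sim_id": ["a", "a"],
                            "t_first_ns": [3.0, 1.0]})
        res = contacts.aggregate_first_contact_by_type([tab])
        assert res["matrix"].loc["ARG", "a"] == pytest.approx(1.0)
        mean_cell = contacts.aggregate_first_contact_by_type([tab], cell_statistic="mean")
        assert mean_cell["matrix"].loc["ARG", "a"] == pytest.approx(2.0)

    def test_column_minimum_flagged(self):
        tables = fn_gold_first_contact_times(long_format=True)
        res = contacts.aggregate_first_contact_by_type(tables)
        assert bool(res["is_column_min"].loc["ARG", "60deg"])
        assert res["is_column_min"]["60deg"].sum() == 1


class TestPhaseDetection:
    def test_constant_series_single_plateau(self):
        seg = contacts.detect_adsorption_phases(np.full(400, 42.0),
                                                np.arange(400) * 0.025)
        assert seg.boundaries == []
        assert seg.labels == ["plateau"]

    def test_noise_free_piecewise_linear_exact(self):
        times, clean, led = synthetic.scripted_contact_series(noise_sigma=0.0)
        seg = contacts.detect_adsorption_phases(clean, times)
        dt = times[1] - times[0]
        assert len(seg.boundaries) == len(led.phase_boundaries)
        for got, true in zip(seg.boundaries, led.phase_boundaries):
            assert abs(got - true) <= dt + 1e-12
        assert seg.labels == led.phase_labels

    def test_injected_jump_recovered_on_noisy_series(self):
        times, noisy, led = synthetic.scripted_contact_series(seed=2)
        seg = contacts.detect_adsorption_phases(noisy, times)
        jumps = [b for b, lab in zip(seg.boundaries, seg.labels[1:])
                 if lab == "cooperative_jump"]
        assert any(57.0 <= b <= 59.0 for b in jumps)

    def test_two_jumps_recovered_in_order(self):
        plan = [(0, 3, "approach", 0, 0), (3, 23, "gradual_increase", 0, 250),
                (23, 40, "plateau", 250, 255), (40, 42, "cooperative_jump", 255, 400),
                (42, 58, "plateau", 400, 405), (58, 60, "cooperative_jump", 405, 560),
                (60, 100, "gradual_increase", 560, 800)]
        times, y, _ = synthetic.scripted_contact_series(plan=plan, seed=4)
        seg = contacts.detect_adsorption_phases(y, times)
        jump_starts = [seg.boundaries[i - 1] for i, lab in enumerate(seg.labels)
                       if lab == "cooperative_jump"]
        assert len(jump_starts) == 2
        assert 39.0 <= jump_starts[0] <= 41.0
        assert 57.0 <= jump_starts[1] <= 59.0
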