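import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chaptraj import contact_kinetics as ck
from chaptraj.contact_kinetics import (
    BindingKinetics,
    ContactSet,
    DistanceSeries,
    EventRecord,
    binding_kinetics,
    contact_probability,
    count_contacts,
    detect_events,
    end_to_end_metrics,
    hydrophilic_fraction,
    min_distance_series,
)
from chaptraj.errors import (
    ConfigurationError,
    DegenerateInputError,
    SelectionError,
    ThresholdError,
)
from chaptraj.md_io import SelectionSpec, Trajectory

from conftest import (
    brute_count_contacts,
    brute_first_binding_time,
    brute_min_distance,
    brute_min_image_distance,
    make_random_system,
    make_random_trajectory,
)


def _series(values, dt=1.0):
    values = np.asarray(values, dtype=float)
    return DistanceSeries(
        times_ps=np.arange(len(values), dtype=float) * dt, values_nm=values
    )


class TestMinDistanceSeries:
    def test_two_atoms(self, rng):
        system = make_random_system(2, rng)
        coords = np.array([[[0.0, 0, 0], [0, 0, 0.3]]])
        traj = Trajectory(
            system=system, times_ps=np.array([0.0]), coords=coords
        )
        s = min_distance_series(traj, np.array([0]), np.array([1]))
        assert s.values_nm[0] == pytest.approx(0.3)

    def test_matches_brute_force(self, rng):
        traj = make_random_trajectory(100, 20, rng)
        sel_a = np.arange(50)
        sel_b = np.arange(50, 100)
        s = min_distance_series(traj, sel_a, sel_b)
        for f in range(traj.n_frames):
            expected = brute_min_distance(
                traj.coords[f, sel_a], traj.coords[f, sel_b]
            )
            assert s.values_nm[f] == pytest.approx(expected, abs=1e-12)

    def test_pbc_minimum_image(self, rng):
        system = make_random_system(10, rng, box_nm=0.9)
        coords = np.empty((1, 10, 3))
        coords[0, :5] = rng.uniform(0, 0.9, (5, 3))
        coords[0, 5:] = coords[0, :5] + np.array([1.0, 0.0, 0.0])  # half box over
        boxes = np.array([[2.0, 2.0, 2.0, 90.0, 90.0, 90.0]])
        traj = Trajectory(
            system=system, times_ps=np.array([0.0]), coords=coords, boxes=boxes
        )
        naive = min_distance_series(traj, np.arange(5), np.arange(5, 10))
        wrapped = min_distance_series(
            traj, np.arange(5), np.arange(5, 10), use_pbc=True
        )
        assert wrapped.values_nm[0] <= naive.values_nm[0] + 1e-12
        expected = brute_min_image_distance(
            coords[0, :5], coords[0, 5:], [2.0, 2.0, 2.0]
        )
        assert wrapped.values_nm[0] == pytest.approx(expected, abs=1e-12)

    def test_overlapping_selections_rejected(self, rng):
        traj = make_random_trajectory(10, 2, rng)
        with pytest.raises(SelectionError):
            min_distance_series(traj, np.arange(5), np.arange(4, 10))

    def test_pbc_without_box_rejected(self, rng):
        traj = make_random_trajectory(10, 2, rng)
        with pytest.raises(ConfigurationError):
            min_distance_series(traj, np.arange(5), np.arange(5, 10), use_pbc=True)


class TestDetectEvents:
    def test_manual_trace(self):
        events = detect_events(_series([1.2, 0.35, 0.5, 1.1, 0.3]))
        assert [(e.kind, e.frame_index) for e in events] == [
            ("attachment", 1),
            ("detachment", 3),
            ("attachment", 4),
        ]

    def test_never_binds(self):
        assert detect_events(_series([1.2, 1.5, 1.1])) == []

    def test_hysteresis_band_does_not_attach(self):
        assert detect_events(_series([1.5, 0.5, 0.45, 1.5])) == []

    def test_band_does_not_detach(self):
        events = detect_events(_series([1.5, 0.3, 0.8, 0.95, 0.3]))
        assert len(events) == 1 and events[0].kind == "attachment"

    def test_threshold_ties_do_not_switch(self):
        assert detect_events(_series([1.5, 0.4, 0.4])) == []
        events = detect_events(_series([1.5, 0.3, 1.0, 1.0]))
        assert len(events) == 1

    def test_bad_thresholds(self):
        with pytest.raises(ThresholdError):
            detect_events(_series([1.0]), attach_nm=1.0, detach_nm=0.4)

    def test_retimestamping_invariance(self, rng):
        values = rng.uniform(0.1, 1.6, 200)
        e1 = detect_events(_series(values, dt=1.0))
        s2 = DistanceSeries(
            times_ps=np.cumsum(rng.uniform(0.5, 3.0, 200)), values_nm=values
        )
        e2 = detect_events(s2)
        assert [e.frame_index for e in e1] == [e.frame_index for e in e2]
        assert [e.kind for e in e1] == [e.kind for e in e2]

    @given(
        values=st.lists(
            st.floats(min_value=0.0, max_value=2.0, allow_nan=False),
            min_size=1,
            max_size=300,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_hysteresis_counting_property(self, values):
        events = detect_events(_series(values))
        n_att = sum(1 for e in events if e.kind == "attachment")
        n_det = sum(1 for e in events if e.kind == "detachment")
        assert n_det <= n_att <= n_det + 1
        kinds = [e.kind for e in events]
        assert kinds == (["attachment", "detachment"] * len(kinds))[: len(kinds)]


class TestBindingKinetics:
    def _events(self, spec):
        """spec: list of (kind_char, time_ns)."""
        return [
            EventRecord(
                "attachment" if k == "a" else "detachment", t * 1000.0, i
            )
            for i, (k, t) in enumerate(spec)
        ]

    def test_definition_example(self):
        events = self._events([("a", 10), ("d", 20), ("a", 50)])
        kin = binding_kinetics([events])
        assert kin.tau_ns == pytest.approx(50.0)
        assert kin.n_events == 1

    def test_single_attachment(self):
        kin = binding_kinetics([self._events([("a", 2.75)])])
        assert kin.tau_ns == pytest.approx(2.75)
        assert kin.n_events == 0

    def test_ends_unbound_excluded(self):
        kin = binding_kinetics(
            [self._events([("a", 1), ("d", 2)]), self._events([("a", 5)])]
        )
        assert kin.n_unbound == 1
        assert kin.tau_ns == pytest.approx(5.0)
        assert kin.n_events == 1

    def test_no_stable_binding_is_none_not_zero(self):
        kin = binding_kinetics([self._events([("a", 1), ("d", 2)])])
        assert kin.tau_ns is None
        assert kin.n_events == 1

    def test_non_alternating_rejected(self):
        with pytest.raises(ValueError):
            binding_kinetics([self._events([("d", 1)])])
        with pytest.raises(ValueError):
            binding_kinetics([self._events([("a", 1), ("a", 2)])])

    def test_against_brute_force_scan_enumerated(self, rng):
        # >= 20 enumerated alternating event lists, vs brute-force scan
        cases = 0
        for n_events in range(0, 9):
            for _ in range(4):
                times = np.sort(rng.uniform(0, 300, n_events))
                kinds = ["a", "d"] * ((n_events + 1) // 2)
                events = self._events(list(zip(kinds[:n_events], times)))
                kin = binding_kinetics([events])
                expected = brute_first_binding_time(events)
                if expected is None:
                    assert kin.tau_ns is None
                else:
                    assert kin.tau_ns == pytest.approx(expected / 1000.0)
                cases += 1
        assert cases >= 20


class TestContactProbability:
    def _one_residue_traj(self, distances):
        """Two single-atom molecules; residue 1 probes residue 2."""
        system = make_random_system(2, np.random.default_rng(0), with_h=False)
        object.__setattr__(system, "residue_indices", np.array([1, 2]))
        coords = np.zeros((len(distances), 2, 3))
        for f, d in enumerate(distances):
            coords[f, 1, 0] = d
        return Trajectory(
            system=system,
            times_ps=np.arange(len(distances), dtype=float),
            coords=coords,
        )

    def test_half_of_frames(self):
        traj = self._one_residue_traj([0.3, 0.5, 0.35, 1.2])
        probs = contact_probability(
            traj,
            probe=SelectionSpec(name="p", residues=(1,), atom_filter="heavy"),
            target=SelectionSpec(name="t", residues=(2,), atom_filter="heavy"),
        )
        assert probs[1] == pytest.approx(0.5)

    def test_always_bound(self):
        traj = self._one_residue_traj([0.1, 0.2, 0.3])
        probs = contact_probability(
            traj,
            probe=SelectionSpec(name="p", residues=(1,), atom_filter="heavy"),
            target=SelectionSpec(name="t", residues=(2,), atom_filter="heavy"),
        )
        assert probs[1] == 1.0

    def test_equals_histogram_integration(self, rng):
        distances = rng.uniform(0.05, 1.5, 400)
        traj = self._one_residue_traj(distances)
        probs = contact_probability(
            traj,
            probe=SelectionSpec(name="p", residues=(1,), atom_filter="heavy"),
            target=SelectionSpec(name="t", residues=(2,), atom_filter="heavy"),
        )
        # integrate a fine normalized histogram below the cutoff; the edge
        # grid places 0.4 exactly on a bin boundary so the comparison is exact
        edges = np.concatenate(
            [np.linspace(0.0, 0.4, 2001), np.linspace(0.4, 2.0, 8001)[1:]]
        )
        hist, _ = np.histogram(distances, bins=edges, density=True)
        widths = np.diff(edges)
        below = (hist[:2000] * widths[:2000]).sum()
        assert probs[1] == pytest.approx(below, abs=1e-12)

    def test_monotone_in_cutoff(self, rng):
        traj = make_random_trajectory(30, 10, rng)
        probe = SelectionSpec(name="p", residues=(1,), atom_filter="heavy")
        target = SelectionSpec(name="t", residues=(3,), atom_filter="heavy")
        prev = 0.0
        for cutoff in (0.2, 0.4, 0.8, 1.6, 3.2):
            probs = contact_probability(traj, probe, target, cutoff_nm=cutoff)
            val = probs[1]
            assert 0.0 <= val <= 1.0
            assert val >= prev
            prev = val


class TestCountContacts:
    def test_two_atoms_in_contact(self):
        coords = np.array([[0.0, 0, 0], [0, 0, 0.3]])
        n, cs = count_contacts(coords, np.array([0]), np.array([1]))
        assert n == 1 and len(cs) == 1

    def test_no_contacts(self):
        coords = np.array([[0.0, 0, 0], [0, 0, 5.0]])
        n, _ = count_contacts(coords, np.array([0]), np.array([1]))
        assert n == 0

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            coords = rng.uniform(0, 1.0, (40, 3))
            sel_a = np.arange(20)
            sel_b = np.arange(20, 40)
            n, cs = count_contacts(coords, sel_a, sel_b, cutoff_nm=0.4)
            expected = brute_count_contacts(coords[sel_a], coords[sel_b], 0.4)
            assert n == expected == len(cs)

    def test_pairs_cross_selections(self, rng):
        coords = rng.uniform(0, 0.5, (10, 3))
        _, cs = count_contacts(coords, np.arange(5), np.arange(5, 10), 0.4)
        for a, b in cs.pairs:
            assert a < 5 <= b


class TestHydrophilicFraction:
    def _system(self, elements):
        n = len(elements)
        return make_random_system(n, np.random.default_rng(1), with_h=False).__class__(
            atom_ids=np.arange(1, n + 1),
            atom_names=tuple(elements),
            elements=tuple(elements),
            residue_indices=np.ones(n, dtype=int),
            residue_names=tuple("UNK" for _ in range(n)),
            chain_ids=tuple("A" for _ in range(n)),
            coords=np.zeros((n, 3)),
        )

    def test_mixed_contacts(self):
        system = self._system(["N", "O", "C", "C", "O", "N"])
        cs = ContactSet(
            pairs=((0, 1), (2, 3), (1, 4), (2, 5)), cutoff_nm=0.4
        )
        # (N,O) yes, (C,C) no, (O,O) yes, (C,N) no -> 0.5
        result = hydrophilic_fraction([cs], system)
        assert result.pooled == pytest.approx(0.5)

    def test_all_carbon(self):
        system = self._system(["C", "C", "C"])
        cs = ContactSet(pairs=((0, 1), (1, 2)), cutoff_nm=0.4)
        assert hydrophilic_fraction([cs], system).pooled == 0.0

    def test_zero_contacts_undefined(self):
        system = self._system(["C", "C"])
        with pytest.raises(DegenerateInputError):
            hydrophilic_fraction([ContactSet(pairs=(), cutoff_nm=0.4)], system)

    def test_window_variant(self):
        system = self._system(["N", "O", "C", "C"])
        hydro = ContactSet(pairs=((0, 1),), cutoff_nm=0.4)
        apolar = ContactSet(pairs=((2, 3),), cutoff_nm=0.4)
        full = hydrophilic_fraction([hydro, apolar], system)
        early = hydrophilic_fraction([hydro, apolar], system, frame_window=(0, 1))
        assert full.pooled == pytest.approx(0.5)
        assert early.pooled == pytest.approx(1.0)

    def test_matches_brute_force_classification(self, rng):
        system = make_random_system(30, rng, with_h=False)
        n, cs = count_contacts(
            system.coords, np.arange(15), np.arange(15, 30), cutoff_nm=1.0
        )
        if n == 0:
            pytest.skip("no contacts in random draw")
        result = hydrophilic_fraction([cs], system)
        expected = sum(
            1
            for a, b in cs.pairs
            if system.elements[a] in "NO" and system.elements[b] in "NO"
        ) / len(cs.pairs)
        assert result.pooled == pytest.approx(expected)


class TestEndToEndMetrics:
    def _chain_traj(self, positions_per_res):
        """One heavy atom per residue at the given positions."""
        n = len(positions_per_res)
        system = make_random_system(n, np.random.default_rng(2), with_h=False)
        object.__setattr__(system, "residue_indices", np.arange(1, n + 1))
        object.__setattr__(system, "elements", tuple("C" for _ in range(n)))
        coords = np.asarray(positions_per_res, dtype=float)[None]
        return Trajectory(
            system=system, times_ps=np.array([0.0]), coords=coords
        )

    def test_extended_chain_zero_contacts(self):
        pos = [[i * 0.5, 0, 0] for i in range(12)]
        traj = self._chain_traj(pos)
        m = end_to_end_metrics(
            traj, SelectionSpec(name="chain", residue_range=(1, 12))
        )
        assert m.contact_counts[0] == 0
        assert m.com_distance_nm[0] > 1.0

    def test_hairpin_termini_in_contact(self):
        pos = [[i * 0.3, 0, 0] for i in range(5)]
        pos += [[(4 - i) * 0.3, 0.25, 0] for i in range(5)]
        traj = self._chain_traj(pos)
        m = end_to_end_metrics(
            traj, SelectionSpec(name="chain", residue_range=(1, 10)), n_end=5
        )
        assert m.contact_counts[0] >= 1
        assert m.com_distance_nm[0] < 1.0

    def test_chain_too_short(self):
        traj = self._chain_traj([[i * 0.5, 0, 0] for i in range(6)])
        with pytest.raises(SelectionError):
            end_to_end_metrics(
                traj, SelectionSpec(name="chain", residue_range=(1, 6)), n_end=5
            )

    def test_matches_brute_force(self, rng):
        pos = rng.uniform(0, 1.5, (14, 3))
        traj = self._chain_traj(pos)
        m = end_to_end_metrics(
            traj, SelectionSpec(name="chain", residue_range=(1, 14)), n_end=5
        )
        expected = brute_count_contacts(pos[:5], pos[-5:], 0.4)
        assert m.contact_counts[0] == expected
        com_head = pos[:5].mean(axis=0)   # equal masses: plain mean
        com_tail = pos[-5:].mean(axis=0)
        assert m.com_distance_nm[0] == pytest.approx(
            np.linalg.norm(com_head - com_tail), abs=1e-12
        )


class TestSyntheticGroundTruth:
    def test_noise_free_traces_detected_exactly(self):
        from chaptraj.synthetic_data import TwoStateSpec, gen_binding_trace

        for seed in range(10):
            trace = gen_binding_trace(
                TwoStateSpec(seed=seed, duration_ns=50.0)
            )
            detected = detect_events(trace.series)
            assert [(e.kind, e.frame_index) for e in detected] == [
                (e.kind, e.frame_index) for e in trace.true_events
            ]
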