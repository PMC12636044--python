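import numpy as np
import pytest

from memhairpin import binding, synth
from memhairpin.binding import (ContactConfig, ContactSeries, KineticsConfig,
                                bca_bootstrap, classify_states,
                                count_contacts, count_contacts_bruteforce,
                                first_binding_cdf, residue_occupancy)


def _two_atom_frame(separation):
    coords = np.array([[2.0, 2.0, 1.0], [2.0, 2.0, 1.0 - separation]])
    box = np.array([5.0, 5.0, 5.0])
    return coords, box


def _series(counts, dt=1.0, **kw):
    counts = np.asarray(counts)
    return ContactSeries(times=np.arange(len(counts)) * dt, pair_count=counts,
                         residue_contact=np.zeros((len(counts), 1), dtype=bool),
                         residues=np.array([1]), **kw)


class TestCountContacts:
    @pytest.mark.parametrize("sep,expected", [(0.35, 1), (0.40, 1), (0.45, 0)])
    def test_cutoff_boundary(self, sep, expected):
        """0.4 nm is a closed cutoff: at it, the pair still counts."""
        coords, box = _two_atom_frame(sep)
        n, res, dmin = count_contacts(coords, box, np.array([0]), np.array([1]),
                                      residue_of=np.array([7]),
                                      residues=np.array([7]))
        assert n == expected
        assert res[0] == (expected == 1)
        assert dmin == pytest.approx(sep, abs=1e-12)

    def test_empty_selection_raises(self):
        coords, box = _two_atom_frame(0.3)
        with pytest.raises(ValueError, match="empty"):
            count_contacts(coords, box, np.array([], dtype=int), np.array([1]),
                           residue_of=np.array([]), residues=np.array([1]))

    def test_missing_box_with_pbc_raises(self):
        coords, _ = _two_atom_frame(0.3)
        with pytest.raises(ValueError, match="box"):
            count_contacts(coords, None, np.array([0]), np.array([1]),
                           residue_of=np.array([1]), residues=np.array([1]))

    def test_periodic_image_counts(self):
        # atoms across the x boundary are neighbours under minimum image
        coords = np.array([[0.1, 2.0, 2.0], [4.9, 2.0, 2.0]])
        box = np.array([5.0, 5.0, 5.0])
        n, _, _ = count_contacts(coords, box, np.array([0]), np.array([1]),
                                 residue_of=np.array([1]),
                                 residues=np.array([1]))
        assert n == 1

    def test_tree_equals_bruteforce_on_random_configs(self):
        """Cell/tree neighbour search exactly reproduces the O(N·M) loop."""
        rng = np.random.default_rng(0)
        box = np.array([5.0, 5.0, 5.0])
        for _ in range(100):
            n_p, n_m = 200, 400
            coords = np.vstack([rng.uniform(0, 5, (n_p, 3)),
                                rng.uniform(0, 5, (n_m, 3))])
            pi = np.arange(n_p)
            mi = np.arange(n_p, n_p + n_m)
            fast, _, _ = count_contacts(coords, box, pi, mi,
                                        residue_of=np.zeros(n_p, dtype=int),
                                        residues=np.array([0]))
            slow = count_contacts_bruteforce(coords, box, pi, mi)
            assert fast == slow


class TestContactSeries:
    def test_far_peptide_all_zero(self, hairpin, membrane_pg100):
        traj = synth.simulate_binding_trajectory(
            hairpin, membrane_pg100,
            synth.BindingSimSpec(well_depth=0.0, start_height=2.0, n_frames=5,
                                 seed=0))
        s = binding.contact_series(traj)
        assert np.all(s.pair_count == 0)
        assert not s.residue_contact.any()
        assert np.all(s.min_distance > 0.4)

    def test_counts_match_bruteforce_frame_by_frame(self, hairpin,
                                                    membrane_pg100):
        traj = synth.simulate_binding_trajectory(
            hairpin, membrane_pg100,
            synth.BindingSimSpec(well_depth=5.0, start_height=0.3, n_frames=20,
                                 seed=4))
        s = binding.contact_series(traj)
        pi = np.array([a.index for a in traj.atoms
                       if a.group == "protein" and a.is_heavy])
        mi = np.array([a.index for a in traj.atoms
                       if a.group == "membrane" and a.is_heavy])
        for i, frame in enumerate(traj.frames):
            assert s.pair_count[i] == count_contacts_bruteforce(
                frame.coordinates, frame.box, pi, mi)

    def test_residue_flag_implies_pair(self, hairpin, membrane_pg100):
        traj = synth.simulate_binding_trajectory(
            hairpin, membrane_pg100,
            synth.BindingSimSpec(well_depth=5.0, start_height=0.3, n_frames=30,
                                 seed=8))
        s = binding.contact_series(traj)
        flagged = s.residue_contact.any(axis=1)
        assert np.all(s.pair_count[flagged] >= 1)


class TestClassifyStates:
    def test_constructed_bind_then_unbind(self):
        """≥5 contacts for 5 frames at dt=1 ns binds at the run start; the
        trailing 2-frame low run (2 ns ≥ 0.5 ns) unbinds at its start."""
        ss = classify_states(_series([0, 0, 6, 6, 6, 6, 6, 2, 2]))
        assert ss.first_binding_time == pytest.approx(2.0)
        assert list(ss.labels) == ["unbound"] * 2 + ["bound"] * 5 + ["unbound"] * 2
        assert ss.events == [("unbound", 0.0, 2.0), ("bound", 2.0, 7.0),
                             ("unbound", 7.0, 9.0)]

    def test_immediate_binding(self):
        ss = classify_states(_series([7, 8, 9, 6, 5, 6]))
        assert ss.first_binding_time == 0.0
        assert all(l == "bound" for l in ss.labels)

    def test_subthreshold_dwell_is_not_binding(self):
        ss = classify_states(_series([0, 6, 6, 6, 6, 0, 0, 0]))
        assert ss.first_binding_time is None
        assert all(l == "unbound" for l in ss.labels)

    def test_short_low_run_does_not_unbind(self):
        # dt = 0.2 ns: a 2-frame dip (0.4 ns < 0.5 ns) stays bound
        counts = [6] * 30 + [1, 1] + [6] * 10
        ss = classify_states(_series(counts, dt=0.2))
        assert all(l == "bound" for l in ss.labels)

    def test_time_shift_invariance(self):
        counts = [0, 0, 6, 6, 6, 6, 6, 2, 2]
        a = classify_states(_series(counts))
        s = _series(counts)
        s.times = s.times + 100.0
        b = classify_states(s)
        assert list(a.labels) == list(b.labels)
        assert b.first_binding_time == a.first_binding_time + 100.0

    def test_prepended_unbound_frames_shift_binding(self):
        base = [6] * 6
        a = classify_states(_series(base))
        b = classify_states(_series([0, 0, 0] + base))
        assert b.first_binding_time == a.first_binding_time + 3.0

    def test_latent_state_recovery_easy_regime(self):
        """Labels recover the generator's latent states on ≥95% of frames
        when the state means are well separated and dwells ≫ thresholds."""
        for seed in range(20):
            spec = synth.ContactSeriesSimSpec(
                k_on=0.005, k_off=0.002, mu_bound=20.0, mu_unbound=0.5,
                dt=0.5, n_frames=2000, seed=seed)
            times, counts, latent = synth.generate_contact_series(spec)
            s = ContactSeries(times=times, pair_count=counts,
                              residue_contact=np.zeros((2000, 1), dtype=bool),
                              residues=np.array([1]))
            labels = classify_states(s).labels
            agreement = np.mean((labels == "bound").astype(int) == latent)
            assert agreement >= 0.95


class TestFirstBindingCdf:
    def _ss(self, t):
        return binding.StateSeries(times=np.arange(1), labels=np.array(["bound"]),
                                   first_binding_time=t, events=[])

    def test_two_events_of_twenty(self):
        series = [self._ss(3.0), self._ss(10.0)] + [self._ss(None)] * 18
        times, counts = first_binding_cdf(series, n_replicas=20)
        np.testing.assert_array_equal(times, [3.0, 10.0])
        np.testing.assert_array_equal(counts, [1, 2])

    def test_all_replicas_bind_reaches_n(self):
        series = [self._ss(float(i)) for i in range(20)]
        _, counts = first_binding_cdf(series, n_replicas=20)
        assert counts[-1] == 20
        assert np.all(np.diff(counts) > 0)

    def test_no_events_empty(self):
        times, counts = first_binding_cdf([self._ss(None)] * 5, n_replicas=5)
        assert times.size == 0 and counts.size == 0


class TestResidueOccupancy:
    def _series_from_matrix(self, mat, replica_id=0):
        mat = np.asarray(mat, dtype=bool)
        return ContactSeries(times=np.arange(mat.shape[0], dtype=float),
                             pair_count=mat.sum(axis=1),
                             residue_contact=mat,
                             residues=np.arange(mat.shape[1]) + 1,
                             replica_id=replica_id)

    def test_single_replica_quarter(self):
        s = self._series_from_matrix([[1], [0], [0], [0]])
        prof = residue_occupancy([s], n_resamples=50)
        assert prof.p_contact[0] == pytest.approx(0.25)

    def test_always_bound_degenerate_ci(self):
        reps = [self._series_from_matrix(np.ones((10, 2)), i) for i in range(5)]
        prof = residue_occupancy(reps, n_resamples=100)
        np.testing.assert_allclose(prof.p_contact, 1.0)
        np.testing.assert_allclose(prof.ci_low, 1.0)
        np.testing.assert_allclose(prof.ci_high, 1.0)

    def test_binomial_sampling_oracle(self):
        """Mean occupancy over 20 replicas of Bernoulli(0.3) frames sits
        within 3 standard errors of 0.3."""
        rng = np.random.default_rng(5)
        p, n_frames, n_rep = 0.3, 200, 20
        reps = [self._series_from_matrix(rng.random((n_frames, 1)) < p, i)
                for i in range(n_rep)]
        prof = residue_occupancy(reps, n_resamples=200, seed=1)
        se = np.sqrt(p * (1 - p) / (n_frames * n_rep))
        assert abs(prof.p_contact[0] - p) < 3 * se
        assert prof.ci_low[0] <= prof.p_contact[0] <= prof.ci_high[0]

    def test_pooled_equals_mean_for_equal_lengths(self):
        rng = np.random.default_rng(2)
        reps = [self._series_from_matrix(rng.random((50, 3)) < 0.4, i)
                for i in range(4)]
        a = residue_occupancy(reps, n_resamples=50, seed=0)
        b = residue_occupancy(reps, n_resamples=50, seed=0, pooled=True)
        np.testing.assert_allclose(a.p_contact, b.p_contact)


class TestBcaBootstrap:
    def test_degenerate_zero_width(self):
        assert bca_bootstrap(np.full(8, 3.5)) == (3.5, 3.5)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            bca_bootstrap(np.array([1.0]))

    def test_symmetric_data_close_to_percentile(self):
        """For symmetric data the bias and acceleration are ≈0, so BCa
        barely differs from the plain percentile interval."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        x = np.concatenate([x, -x])  # exactly symmetric about 0
        lo, hi = bca_bootstrap(x, n_resamples=2000, seed=4)
        boot = np.array([np.mean(rng.choice(x, x.size)) for _ in range(2000)])
        plo, phi = np.percentile(boot, [2.5, 97.5])
        width = phi - plo
        assert abs(lo - plo) < 0.25 * width
        assert abs(hi - phi) < 0.25 * width

    def test_coverage_of_normal_mean(self):
        """Monte-Carlo coverage at n=20 over 500 repetitions stays near the
        nominal 0.95 level."""
        rng = np.random.default_rng(0)
        hits = 0
        for rep in range(500):
            x = rng.normal(size=20)
            lo, hi = bca_bootstrap(x, n_resamples=1000, level=0.95, seed=rep)
            hits += lo <= 0.0 <= hi
        assert 0.91 <= hits / 500 <= 0.985
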