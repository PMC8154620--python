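"""Tests for the synthetic generators: MC sampler, hidden chains, emissions, series."""

import numpy as np
import pytest

from cgtkit.constants import R_GAS_KJ
from cgtkit.descriptors import radius_of_gyration
from cgtkit.msm import count_transitions, stationary_distribution
from cgtkit.synthetic import (
    BeadChainParams,
    emit_conformations,
    generate_equilibrium_series,
    generate_hidden_state_trajectory,
    generate_rate_series,
    make_cgt_study,
    metropolis_transition_matrix,
    sample_harmonic_bond_1d,
    simulate_bead_chain,
)


class TestBeadChainSampler:
    def test_same_seed_identical_trajectories(self):
        p = BeadChainParams()
        t1 = simulate_bead_chain(8, 300.0, 5000, p, seed=11)
        t2 = simulate_bead_chain(8, 300.0, 5000, p, seed=11)
        np.testing.assert_array_equal(t1.coordinates, t2.coordinates)

    def test_attraction_collapses_the_chain(self):
        base = dict(n_beads=12, temperature=300.0, n_steps=200_000, seed=5,
                    warmup_steps=50_000)
        open_p = BeadChainParams(bend_k=0.0, attract_eps0=0.0)
        closed_p = BeadChainParams(bend_k=0.0, attract_eps0=5.0)
        t_open = simulate_bead_chain(params=open_p, **base)
        t_closed = simulate_bead_chain(params=closed_p, **base)
        rg_open = radius_of_gyration(t_open.coordinates).mean()
        rg_closed = radius_of_gyration(t_closed.coordinates).mean()
        assert rg_open > rg_closed

    def test_bond_lengths_stay_physical(self):
        p = BeadChainParams()
        t = simulate_bead_chain(10, 300.0, 100_000, p, seed=2, warmup_steps=10_000)
        t.validate_bonds(p.bond_b0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_bead_chain(3, 300.0, 100)
        with pytest.raises(ValueError):
            simulate_bead_chain(8, -5.0, 100)
        with pytest.raises(ValueError):
            simulate_bead_chain(8, 300.0, 100, BeadChainParams(attract_slope=-1))

    def test_equipartition_of_harmonic_bond(self):
        """1D harmonic test mode: Var(x) -> R T / k (closed form)."""
        k, T = 1000.0, 300.0
        x = sample_harmonic_bond_1d(k, T, n_steps=1_000_000, seed=3)
        x = x[100_000:]  # discard warm-up
        expected = R_GAS_KJ * T / k
        # standard error of the variance with correlated samples: estimate
        # the integrated autocorrelation crudely via block averaging
        blocks = x.reshape(90, -1).var(axis=1, ddof=1)
        se = blocks.std(ddof=1) / np.sqrt(len(blocks))
        assert abs(x.var(ddof=1) - expected) < 3 * se

    def test_boltzmann_weights_on_three_bead_toy(self):
        """Detailed balance check: the sampled bend-angle distribution of a
        3-bead chain matches exhaustive Boltzmann integration over the
        internal coordinates (r1, r2, theta) on a dense grid."""
        p = BeadChainParams(bond_k=2000.0, bend_k=3.0, attract_eps0=1.0,
                            attract_cutoff=0.6, step_size=0.08)
        T = 300.0
        beta = 1.0 / (R_GAS_KJ * T)

        # oracle: E[cos theta] under the Boltzmann density with the
        # Cartesian-measure Jacobian r1^2 r2^2 sin(theta)
        r = np.linspace(0.15, 0.35, 81)
        th = np.linspace(1e-3, np.pi - 1e-3, 181)
        R1, R2, TH = np.meshgrid(r, r, th, indexing="ij")
        # bend angle theta here is between bond vectors; distance 0-2:
        d02 = np.sqrt(R1**2 + R2**2 - 2 * R1 * R2 * np.cos(np.pi - TH))
        E = (
            0.5 * p.bond_k * ((R1 - p.bond_b0) ** 2 + (R2 - p.bond_b0) ** 2)
            + 0.5 * p.bend_k * TH**2
        )
        att = np.where(
            d02 < p.attract_cutoff,
            -p.eps_eff(T) * (1 - (d02 / p.attract_cutoff) ** 2) ** 2,
            0.0,
        )
        E = E + att
        w = R1**2 * R2**2 * np.sin(TH) * np.exp(-beta * (E - E.min()))
        expected = float((w * np.cos(TH)).sum() / w.sum())

        traj = simulate_bead_chain(
            4, T, 2_000_000, p, seed=17, warmup_steps=100_000, save_every=20
        )
        # use the first three beads' bend angle; bead 4 decouples the
        # n_beads >= 4 constraint from the 3-bead geometry under test
        c = traj.coordinates
        b1 = c[:, 1] - c[:, 0]
        b2 = c[:, 2] - c[:, 1]
        ct = np.einsum("fd,fd->f", b1, b2) / (
            np.linalg.norm(b1, axis=1) * np.linalg.norm(b2, axis=1)
        )
        samples = ct  # cos(theta)
        blocks = samples.reshape(100, -1).mean(axis=1)
        se = blocks.std(ddof=1) / np.sqrt(len(blocks))
        assert abs(samples.mean() - expected) < 3 * se + 0.01


class TestHiddenChain:
    def test_occupancy_matches_stationary_distribution(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        seq = generate_hidden_state_trajectory(T, 1_000_000, seed=1)
        occ = (seq == 0).mean()
        # stationary = (p10, p01)/(p01+p10) = (2/3, 1/3)
        n_switch = (np.diff(seq) != 0).sum()
        se = np.sqrt(2.0 / n_switch) * (2 / 3) * (1 / 3) * 2  # conservative
        assert abs(occ - 2 / 3) < 3 * se + 0.003

    def test_identity_matrix_freezes_the_chain(self):
        seq = generate_hidden_state_trajectory(
            np.eye(3), 1000, initial_distribution=[0, 0, 1], seed=0
        )
        assert (seq == 2).all()

    def test_fixed_seed_reproducible(self):
        T = np.array([[0.5, 0.5], [0.5, 0.5]])
        s1 = generate_hidden_state_trajectory(T, 10_000, seed=9)
        s2 = generate_hidden_state_trajectory(T, 10_000, seed=9)
        np.testing.assert_array_equal(s1, s2)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            generate_hidden_state_trajectory(np.array([[0.9, 0.2], [0.2, 0.8]]), 10)

    def test_lag1_frequencies_converge_to_generator(self):
        T = np.array([[0.85, 0.1, 0.05], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]])
        seq = generate_hidden_state_trajectory(T, 500_000, seed=4)
        C = count_transitions([seq], 1, 3).astype(float)
        emp = C / C.sum(axis=1, keepdims=True)
        assert np.abs(emp - T).max() < 0.01


class TestEmissions:
    def test_zero_noise_reproduces_templates(self, templates):
        seq = np.array([0, 3, 1, 2, 2])
        traj = emit_conformations(seq, templates, noise_sd=0.0)
        np.testing.assert_array_equal(traj.coordinates, templates[seq])

    def test_bimodal_rg_with_two_templates(self, templates):
        two = templates[[0, 3]]  # extended vs compact
        seq = np.array([0] * 500 + [1] * 500)
        traj = emit_conformations(seq, two, noise_sd=0.02, seed=1)
        rg = radius_of_gyration(traj.coordinates)
        rg0 = radius_of_gyration(two[0])
        rg1 = radius_of_gyration(two[1])
        assert abs(rg[:500].mean() - rg0) < 0.05
        assert abs(rg[500:].mean() - rg1) < 0.05
        # well separated modes
        assert rg[:500].min() > rg[500:].max()

    def test_missing_template_rejected(self, templates):
        with pytest.raises(ValueError):
            emit_conformations(np.array([0, 7]), templates, 0.0)

    def test_fixed_seed_reproducible(self, templates):
        seq = np.array([0, 1, 2, 3])
        t1 = emit_conformations(seq, templates, 0.05, seed=2)
        t2 = emit_conformations(seq, templates, 0.05, seed=2)
        np.testing.assert_array_equal(t1.coordinates, t2.coordinates)


class TestClosedFormSeries:
    def test_K_is_one_at_transition_temperature(self):
        tab = generate_equilibrium_series(
            100.0, 351.86, np.array([284.20]), noise_sd=0.0
        )
        assert tab["K_eq"][0] == pytest.approx(1.0, rel=1e-3)

    def test_noiseless_lnK_exactly_linear_in_invT(self):
        tab = generate_equilibrium_series(80.0, 250.0, np.linspace(260, 310, 11))
        x = 1 / tab["temperature"]
        y = np.log(tab["K_eq"])
        r = np.corrcoef(x, y)[0, 1] ** 2
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_doubling_dS_halves_T_star(self):
        from cgtkit.thermo import vant_hoff_fit

        temps = np.linspace(100, 400, 7)
        f1 = vant_hoff_fit(
            temps, generate_equilibrium_series(100.0, 300.0, temps)["K_eq"]
        )
        f2 = vant_hoff_fit(
            temps, generate_equilibrium_series(100.0, 600.0, temps)["K_eq"]
        )
        assert f2.T_star == pytest.approx(f1.T_star / 2, rel=1e-9)

    def test_rate_series_zero_barrier(self):
        tab = generate_rate_series(0.5, 0.0, np.array([250.0, 300.0]))
        np.testing.assert_allclose(tab["rate"], 0.5 * tab["temperature"])


class TestMetropolisMatrix:
    def test_stationary_distribution_is_exact(self, rng):
        pi = rng.dirichlet(np.ones(4))
        q = np.full((4, 4), 0.15)
        np.fill_diagonal(q, 0.0)
        M = metropolis_transition_matrix(pi, q)
        np.testing.assert_allclose(stationary_distribution(M), pi, atol=1e-10)
        # detailed balance
        np.testing.assert_allclose(pi[:, None] * M, (pi[:, None] * M).T, atol=1e-12)

    def test_asymmetric_proposal_rejected(self):
        q = np.zeros((2, 2))
        q[0, 1] = 0.5
        with pytest.raises(ValueError):
            metropolis_transition_matrix(np.array([0.5, 0.5]), q)


class TestStudyConstruction:
    def test_ground_truth_follows_vant_hoff_law(self):
        study = make_cgt_study(n_frames=10, n_replicas=1, seed=0)
        gt = study.ground_truth
        from cgtkit.thermo import vant_hoff_fit

        temps = study.temperatures
        K = np.array([gt.extras["K_eq_true"][T] for T in temps])
        fit = vant_hoff_fit(temps, K)
        assert fit.dH == pytest.approx(100.0, rel=1e-9)
        assert fit.dS == pytest.approx(351.86, rel=1e-9)

    def test_templates_rg_rank_matches_names(self, templates):
        rg = radius_of_gyration(templates)
        # order [C0, C1, G1, G0]: coil Rg descending, globule G1 > G0
        assert rg[0] > rg[1] > rg[2] > rg[3]

    def test_same_seed_bitwise_identical_study(self):
        s1 = make_cgt_study(n_frames=500, n_replicas=2, seed=3)
        s2 = make_cgt_study(n_frames=500, n_replicas=2, seed=3)
        for t1, t2 in zip(s1.trajectories, s2.trajectories):
            np.testing.assert_array_equal(t1.coordinates, t2.coordinates)

    def test_stationary_odds_equal_K(self):
        study = make_cgt_study(n_frames=10, n_replicas=1, seed=0)
        gt = study.ground_truth
        for T, M in gt.hidden_transition_matrix.items():
            pi = stationary_distribution(M)
            K = pi[2:].sum() / pi[:2].sum()
            assert K == pytest.approx(gt.extras["K_eq_true"][T], rel=1e-8)
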