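"""Event-sequence model core: trajectories, likelihoods, optimization,
MCMC.  Brute-force enumeration over all (subtype, stage) pairs and over all
valid event orders serves as the independent oracle on small grids."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.stats import kendalltau

import mssustain as ms
from mssustain.sustain import (
    is_valid_sequence,
    random_valid_sequence,
    McmcSamples,
)

# ---------------------------------------------------------------- oracles


def oracle_expected_value(grid, feature, stage, sequence):
    """Independent piecewise-linear trajectory: plain np.interp through the
    control points described in the model definition."""
    T = len(grid.thresholds)
    positions = [list(sequence).index(feature * T + r) + 1 for r in range(T)]
    xp, fp = [0.0], [0.0]
    for p, z in zip(positions, grid.thresholds):
        xp.append(float(p))
        fp.append(float(z))
    if positions[-1] < grid.n_events:
        xp.append(float(grid.n_events))
        fp.append(grid.z_max)
    return float(np.interp(stage, xp, fp))


def oracle_total_loglik(Z, model):
    """Direct enumeration of sum_n log sum_c f_c/(E+1) sum_k prod_i N(...)."""
    grid = model.grid
    E = grid.n_events
    total = 0.0
    sigma = np.broadcast_to(np.asarray(model.sigma, float),
                            (grid.n_features,))
    for n in range(Z.shape[0]):
        acc = 0.0
        for c in range(model.n_subtypes):
            for k in range(E + 1):
                lik = 1.0
                for i in range(grid.n_features):
                    g = oracle_expected_value(grid, i, k, model.sequences[c])
                    lik *= stats.norm.pdf(Z[n, i], loc=g, scale=sigma[i])
                acc += model.fractions[c] * lik / (E + 1)
        total += np.log(acc)
    return total


def all_valid_sequences(grid):
    """Every permutation of the event grid respecting threshold order."""
    return [np.asarray(p) for p in itertools.permutations(range(grid.n_events))
            if is_valid_sequence(grid, np.asarray(p))]


# ----------------------------------------------------------------- grids


def test_event_grid_sizes():
    """13 features x z in {1,2,3} give the canonical 39-event grid; the
    product rule holds for degenerate and scaled-down grids."""
    assert ms.build_event_grid([f"f{i}" for i in range(13)]).n_events == 39
    assert ms.build_event_grid(["a"], thresholds=(1.0,), z_max=1.0).n_events == 1
    assert ms.build_event_grid([f"f{i}" for i in range(8)]).n_events == 24


def test_event_grid_validation():
    with pytest.raises(ValueError, match="duplicate"):
        ms.build_event_grid(["a", "a"])
    with pytest.raises(ValueError, match="increasing"):
        ms.build_event_grid(["a"], thresholds=(2.0, 1.0))
    with pytest.raises(ValueError, match="z_max"):
        ms.build_event_grid(["a"], thresholds=(1.0, 2.0, 3.0), z_max=2.0)


# ------------------------------------------------------------ trajectories


def test_expected_value_control_points_and_interpolation():
    """Stage 0 is always 0; threshold events pin their z-levels; between
    the last event and stage E the curve climbs linearly to z_max."""
    grid = ms.build_event_grid([f"f{i}" for i in range(13)])
    seq = np.arange(39)  # feature 0's events sit at positions 1, 2, 3
    assert ms.expected_value(grid, 5, 0, seq) == 0.0
    assert ms.expected_value(grid, 0, 2, seq) == pytest.approx(2.0)
    # hand interpolation: 3 + (21-3) * (5-3) / (39-3) = 4.0
    assert ms.expected_value(grid, 0, 21, seq) == pytest.approx(4.0)
    with pytest.raises(ValueError, match="stage"):
        ms.expected_value(grid, 0, 40, seq)


def test_expected_value_matches_oracle_everywhere():
    rng = np.random.default_rng(0)
    grid = ms.build_event_grid(["a", "b", "c"], thresholds=(1.0, 2.0))
    for _ in range(20):
        seq = random_valid_sequence(grid, rng)
        for i in range(3):
            for k in range(grid.n_events + 1):
                assert ms.expected_value(grid, i, k, seq) == pytest.approx(
                    oracle_expected_value(grid, i, k, seq))


def test_expected_value_monotone_in_stage():
    rng = np.random.default_rng(1)
    grid = ms.build_event_grid([f"f{i}" for i in range(5)])
    for _ in range(25):
        seq = random_valid_sequence(grid, rng)
        G = ms.expected_values(grid, seq)
        assert (np.diff(G, axis=1) >= -1e-12).all()


def test_terminal_control_point_dropped_when_last_event_at_E():
    grid = ms.build_event_grid(["a"], thresholds=(1.0,), z_max=5.0)
    # single event at position E=1: trajectory ends at z=1, not z_max
    assert ms.expected_value(grid, 0, 1, [0]) == pytest.approx(1.0)


# ------------------------------------------------------------- likelihoods


def test_stage_likelihoods_standard_normal_values():
    """One feature, threshold {1}, z_max 1, observation 0:
    L(0) = phi(0) = 0.39894, L(1) = phi(-1) = 0.24197."""
    grid = ms.build_event_grid(["a"], thresholds=(1.0,), z_max=1.0)
    L = ms.stage_likelihoods(np.array([0.0]), [0], grid, sigma=1.0)
    assert L[0] == pytest.approx(0.3989422804, abs=1e-7)
    assert L[1] == pytest.approx(0.2419707245, abs=1e-7)


def test_stage_likelihood_peaks_at_generating_stage():
    grid = ms.build_event_grid(["a", "b"], thresholds=(1.0, 2.0, 3.0))
    seq = np.array([0, 3, 1, 4, 2, 5])
    G = ms.expected_values(grid, seq)
    for k_star in (0, 2, 4, 6):
        L = ms.stage_likelihoods(G[:, k_star], seq, grid, sigma=0.05)
        assert int(np.argmax(L)) == k_star


def test_total_loglik_matches_enumeration_oracle():
    """Mixture log-likelihood equals the brute-force double enumeration."""
    rng = np.random.default_rng(4)
    grid = ms.build_event_grid(["a", "b"], thresholds=(1.0, 2.0))
    seqs = np.array([[0, 1, 2, 3], [2, 0, 3, 1]])
    model = ms.SubtypeModel(grid, seqs, np.array([0.6, 0.4]), sigma=0.8)
    Z = rng.normal(1.0, 1.5, size=(7, 2))
    assert ms.total_loglik(Z, model) == pytest.approx(
        oracle_total_loglik(Z, model), abs=1e-8)


def test_total_loglik_additive_and_label_invariant():
    rng = np.random.default_rng(5)
    grid = ms.build_event_grid(["a", "b", "c"])
    seqs = np.array([random_valid_sequence(grid, rng) for _ in range(2)])
    model = ms.SubtypeModel(grid, seqs, np.array([0.3, 0.7]))
    Z = rng.standard_normal((11, 3))
    ll = ms.total_loglik(Z, model)
    assert np.isfinite(ll)
    assert ms.total_loglik(np.vstack([Z, Z]), model) == pytest.approx(2 * ll)
    swapped = ms.SubtypeModel(grid, seqs[::-1].copy(),
                              np.array([0.7, 0.3]))
    assert ms.total_loglik(Z, swapped) == pytest.approx(ll)


# ------------------------------------------------------------ optimization


def test_optimizer_matches_exhaustive_search_small_grid():
    """On a 4-event grid the greedy multi-start optimizer attains the
    global maximum found by scoring all 24 valid orders."""
    rng = np.random.default_rng(6)
    grid = ms.build_event_grid(["a", "b", "c", "d"], thresholds=(1.0,),
                               z_max=3.0)
    true_seq = np.array([2, 0, 3, 1])
    G = ms.expected_values(grid, true_seq)
    ks = rng.integers(0, 5, size=40)
    Z = G[:, ks].T + rng.normal(0, 0.3, size=(40, 4))
    model1 = lambda s: ms.SubtypeModel(grid, np.asarray(s)[None, :],
                                       np.array([1.0]))
    scores = {tuple(s): ms.total_loglik(Z, model1(s))
              for s in all_valid_sequences(grid)}
    best_exhaustive = max(scores, key=scores.get)
    found = ms.optimize_sequence(Z, grid, starts=5, rng=1)
    assert tuple(found) == best_exhaustive


def test_optimizer_respects_threshold_order():
    rng = np.random.default_rng(7)
    grid = ms.build_event_grid([f"f{i}" for i in range(6)])
    Z = rng.standard_normal((60, 6)) * 2
    seq = ms.optimize_sequence(Z, grid, starts=2, rng=2)
    assert is_valid_sequence(grid, seq)


def test_planted_sequence_recovered_noiselessly():
    """A single-subtype cohort with near-zero measurement noise yields the
    planted order exactly (Kendall tau = 1)."""
    rng = np.random.default_rng(8)
    grid = ms.build_event_grid([f"f{i}" for i in range(6)])
    true_seq = random_valid_sequence(grid, rng)
    G = ms.expected_values(grid, true_seq)
    ks = rng.integers(0, grid.n_events + 1, size=400)
    Z = G[:, ks].T + rng.normal(0, 0.05, size=(400, 6))
    found = ms.optimize_sequence(Z, grid, starts=5, sigma=0.05, rng=3)
    pos_t = np.argsort(true_seq)
    pos_f = np.argsort(found)
    assert kendalltau(pos_t, pos_f).statistic == pytest.approx(1.0)


def test_fit_sustain_c1_reduces_to_optimize_sequence(g1_zscores, g1_grid,
                                                     fit_opts):
    sub = g1_zscores.head(300)
    model = ms.fit_sustain(sub, g1_grid, 1, fit_opts)
    direct = ms.optimize_sequence(
        sub, g1_grid, starts=fit_opts.starts, sigma=fit_opts.sigma,
        rng=np.random.default_rng(fit_opts.seed),
        max_sweeps=fit_opts.max_sweeps)
    assert model.n_subtypes == 1
    assert model.fractions[0] == pytest.approx(1.0)
    assert np.array_equal(model.sequences[0], direct)


def test_em_loglik_monotone_and_fractions_normalized(g1_zscores, g1_grid,
                                                     fit_opts):
    from mssustain.sustain import _em

    rng = np.random.default_rng(12)
    Z = g1_zscores[list(g1_grid.features)].to_numpy()[:600]
    seqs = np.array([random_valid_sequence(g1_grid, rng) for _ in range(2)])
    _, _, trace = _em(Z, g1_grid, seqs, np.array([0.5, 0.5]), fit_opts, rng)
    diffs = np.diff(trace)
    assert (diffs >= -1e-6).all()


# ------------------------------------------------------------------- MCMC


def _tiny_model_and_data(seed=13, n=25):
    rng = np.random.default_rng(seed)
    grid = ms.build_event_grid(["a", "b", "c", "d"], thresholds=(1.0,),
                               z_max=3.0)
    true_seq = np.array([1, 3, 0, 2])
    G = ms.expected_values(grid, true_seq)
    ks = rng.integers(0, 5, size=n)
    Z = G[:, ks].T + rng.normal(0, 0.6, size=(n, 4))
    model = ms.SubtypeModel(grid, true_seq[None, :], np.array([1.0]))
    return grid, model, Z


def test_mcmc_deterministic_given_seed():
    _, model, Z = _tiny_model_and_data()
    s1 = ms.mcmc_sample(Z, model, iterations=500, seed=42)
    s2 = ms.mcmc_sample(Z, model, iterations=500, seed=42)
    assert np.array_equal(s1.sequences, s2.sequences)
    assert np.allclose(s1.loglik_trace, s2.loglik_trace)
    assert s1.n_samples == (500 - 50 + 9) // 10  # (iters - burn) / thinning


def test_mcmc_posterior_matches_enumeration():
    """Sampled sequence frequencies agree with the exhaustive posterior
    over all 24 valid orders (uniform prior, single subtype)."""
    grid, model, Z = _tiny_model_and_data()
    post = {}
    for s in all_valid_sequences(grid):
        m = ms.SubtypeModel(grid, np.asarray(s)[None, :], np.array([1.0]))
        post[tuple(s)] = ms.total_loglik(Z, m)
    lse = np.logaddexp.reduce(list(post.values()))
    post = {k: np.exp(v - lse) for k, v in post.items()}

    samples = ms.mcmc_sample(Z, model, iterations=60_000, seed=7,
                             burn_in=0.1, thinning=5)
    seqs, counts = np.unique(samples.sequences[:, 0, :], axis=0,
                             return_counts=True)
    freq = {tuple(s): c / counts.sum() for s, c in zip(seqs, counts)}
    # Monte-Carlo error bound: thinned draws remain autocorrelated, so use
    # a conservative effective sample size of n_samples / 10
    n_eff = samples.n_samples / 10
    for key, p in post.items():
        se = np.sqrt(p * (1 - p) / n_eff)
        assert abs(freq.get(key, 0.0) - p) <= max(3 * se, 0.02)


def test_mcmc_invalid_arguments():
    _, model, Z = _tiny_model_and_data()
    with pytest.raises(ValueError):
        ms.mcmc_sample(Z, model, iterations=0)
    with pytest.raises(ValueError):
        ms.mcmc_sample(Z, model, iterations=100, burn_in=1.5)


def test_positional_distribution_degenerate_and_normalized():
    grid = ms.build_event_grid(["a", "b"], thresholds=(1.0, 2.0))
    seq = np.array([0, 2, 1, 3])
    samples = McmcSamples(
        grid=grid, sequences=np.tile(seq, (50, 1, 1)),
        fractions=np.ones((50, 1)), loglik_trace=np.zeros(50),
        iterations=50, burn_in=0.0, thinning=1)
    P = ms.positional_distribution(samples, 0)
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
    expected = np.zeros((4, 4))
    expected[seq, np.arange(4)] = 1.0
    assert np.array_equal(P, expected)


def test_mcmc_near_uniform_posterior_on_pure_noise():
    """With almost no data signal the chain wanders: every event's
    positional distribution has near-maximal entropy."""
    rng = np.random.default_rng(20)
    grid = ms.build_event_grid(["a", "b", "c", "d"], thresholds=(1.0,),
                               z_max=3.0)
    Z = rng.normal(0.5, 0.1, size=(3, 4))  # 3 visits, huge emission noise
    model = ms.SubtypeModel(grid, np.arange(4)[None, :], np.array([1.0]),
                            sigma=50.0)
    samples = ms.mcmc_sample(Z, model, iterations=40_000, seed=3, thinning=5)
    for e in range(4):
        p = ms.positional_distribution(samples, 0)[e]
        entropy = -(p[p > 0] * np.log(p[p > 0])).sum()
        assert entropy > 0.9 * np.log(4)


# ------------------------------------------------------------- assignment


def test_assign_posteriors_normalized_and_c1_trivial(g1_zscores, g1_grid):
    seq = np.arange(g1_grid.n_events)
    m1 = ms.SubtypeModel(g1_grid, seq[None, :], np.array([1.0]))
    asg = ms.assign(g1_zscores.head(40), m1)
    assert np.allclose(asg.table["prob_subtype_0"], 1.0)
    assert np.allclose(asg.stage_posteriors.sum(axis=1), 1.0, atol=1e-9)
    assert asg.table["modal_stage"].between(0, g1_grid.n_events).all()


def test_assign_confident_on_exact_trajectory(g1):
    """A visit lying exactly on one subtype's trajectory at a mid stage is
    assigned to that subtype with near certainty."""
    config, _, _ = g1
    truth = ms.planted_model(config)
    truth.sigma = np.full(truth.grid.n_features, 0.3)
    G = ms.expected_values(truth.grid, truth.sequences[1])
    z = G[:, 20]  # subtype 1 at stage 20
    asg = ms.assign(z[None, :], truth)
    assert asg.table["modal_subtype"].iloc[0] == 1
    assert asg.table["prob_subtype_1"].iloc[0] > 0.99
    assert asg.table["modal_stage"].iloc[0] == 20
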