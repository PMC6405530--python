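import numpy as np
import pandas as pd
import pytest
from conftest import toy_metadata

from invadepop import (
    SimConfig,
    align_runs,
    assign_individuals,
    assign_populations,
    average_runs,
    evanno_deltaK,
    gibbs_admixture,
    simulate_dataset,
)
from invadepop.admixture import (
    RunSummary,
    alignment_cost,
    exhaustive_alignment_cost,
)


def _summary(Q, low=None, high=None, K=None, rep=0, lnpd=0.0):
    Q = np.asarray(Q, dtype=float)
    K = K or Q.shape[1]
    return RunSummary(
        K=K,
        replicate=rep,
        mean_lnPD=lnpd,
        Q_mean=Q,
        Q_low=np.asarray(low if low is not None else Q - 0.05),
        Q_high=np.asarray(high if high is not None else Q + 0.05),
        individual_ids=[f"i{k}" for k in range(Q.shape[0])],
        ci_level=0.90,
    )


@pytest.fixture(scope="module")
def two_deme_run():
    cfg = SimConfig(
        n_native_demes=2,
        n_invasive_pops=0,
        pop_size=(30, 30),
        n_loci_full=60,
        F_native=0.25,
        ibd_strength=0.0,
        clonal_rate_native=0.0,
        missing_rate=0.02,
        n_common_garden=0,
        seed=21,
    )
    gm, meta, _ = simulate_dataset(cfg)
    run = gibbs_admixture(gm, K=2, burn_in=600, iters=1500, thin=3, seed=5)
    return gm, meta, run


def test_k1_is_degenerate():
    cfg = SimConfig(
        n_native_demes=1, n_invasive_pops=0, pop_size=(8, 8), n_loci_full=20,
        clonal_rate_native=0.0, missing_rate=0.0, n_common_garden=0, seed=1,
    )
    gm, _, _ = simulate_dataset(cfg)
    run = gibbs_admixture(gm, K=1, burn_in=50, iters=100, thin=2, seed=0)
    np.testing.assert_allclose(run.Q_mean, 1.0)
    np.testing.assert_allclose(run.Q_low, 1.0)
    np.testing.assert_allclose(run.Q_high, 1.0)
    assert np.isfinite(run.mean_lnPD)


def test_invalid_K_rejected(two_deme_run):
    gm, _, _ = two_deme_run
    with pytest.raises(ValueError, match="K"):
        gibbs_admixture(gm, K=0, burn_in=1, iters=2)


def test_two_demes_recovered(two_deme_run):
    """Well-separated demes: individuals strongly sorted at K=2."""
    gm, meta, run = two_deme_run
    assert run.Q_mean.max(axis=1).mean() >= 0.9
    assert np.allclose(run.Q_mean.sum(axis=1), 1.0, atol=1e-9)
    assert ((run.Q_low <= run.Q_mean + 1e-12) & (run.Q_mean <= run.Q_high + 1e-12)).all()
    # the two demes land in different clusters
    pops = np.array([i.split("_")[0] for i in gm.individual_ids])
    q0 = run.Q_mean[:, 0]
    means = [q0[pops == p].mean() for p in np.unique(pops)]
    assert abs(means[0] - means[1]) > 0.8


def test_fixed_seed_bit_identical(two_deme_run):
    gm, _, run = two_deme_run
    rerun = gibbs_admixture(gm, K=2, burn_in=600, iters=1500, thin=3, seed=5)
    np.testing.assert_array_equal(run.Q_mean, rerun.Q_mean)
    np.testing.assert_array_equal(rerun.loglik_trace, run.loglik_trace)


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

def _runs_from_table(table):
    return [
        _summary(np.ones((2, 1)), K=K, rep=r, lnpd=v)
        for K, vals in table.items()
        for r, v in enumerate(vals)
    ]


def test_deltaK_peaks_at_constructed_kink():
    # L(K): -1000, -500, -480, -470 (+- 1 across replicates); kink at K=2
    table = {
        1: [-1001, -999],
        2: [-501, -499],
        3: [-481, -479],
        4: [-471, -469],
    }
    sel = evanno_deltaK(_runs_from_table(table))
    assert sel.chosen_K == 2
    sd = np.std([-501, -499], ddof=1)
    expected = abs(-480 - 2 * (-500) + (-1000)) / sd
    row = sel.table.set_index("K").loc[2]
    assert row["deltaK"] == pytest.approx(expected)


def test_deltaK_flat_for_linear_evidence():
    table = {K: [-1000 + 100 * K + e for e in (-1, 1)] for K in range(1, 6)}
    sel = evanno_deltaK(_runs_from_table(table))
    inner = sel.table["deltaK"].to_numpy()[1:-1]
    assert np.nanmax(inner) == pytest.approx(0.0, abs=1e-9)


def test_deltaK_undefined_when_sd_zero():
    table = {1: [-10, -10], 2: [-5, -5], 3: [-4, -4]}
    sel = evanno_deltaK(_runs_from_table(table))
    assert np.isnan(sel.table.set_index("K").loc[2, "deltaK"])


def test_deltaK_requires_consecutive_K():
    table = {1: [-10, -9], 3: [-5, -4], 4: [-3, -2]}
    with pytest.raises(ValueError, match="consecutive"):
        evanno_deltaK(_runs_from_table(table))


# ---------------------------------------------------------------------------
# Run alignment
# ---------------------------------------------------------------------------

def test_alignment_recovers_column_swap():
    rng = np.random.default_rng(0)
    Q = rng.dirichlet(np.ones(3), size=10)
    ref = _summary(Q)
    swapped = _summary(Q[:, [2, 0, 1]], rep=1)
    aligned = align_runs([ref, swapped])
    np.testing.assert_allclose(aligned[1].Q_mean, Q, atol=1e-12)
    avg = average_runs(aligned)
    np.testing.assert_allclose(avg.Q_mean, Q, atol=1e-12)


def test_alignment_of_many_permuted_copies():
    rng = np.random.default_rng(1)
    Q = rng.dirichlet(np.ones(4), size=12)
    runs = [_summary(Q)]
    for r in range(1, 10):
        perm = rng.permutation(4)
        runs.append(_summary(Q[:, perm], rep=r))
    avg = average_runs(align_runs(runs))
    np.testing.assert_allclose(avg.Q_mean, Q, atol=1e-12)


@pytest.mark.parametrize("K", [2, 3, 4])
def test_alignment_cost_matches_exhaustive_search(K):
    rng = np.random.default_rng(K)
    for _ in range(5):
        a = _summary(rng.dirichlet(np.ones(K), size=8))
        b = _summary(rng.dirichlet(np.ones(K), size=8), rep=1)
        assert alignment_cost(b, a) == pytest.approx(
            exhaustive_alignment_cost(b, a), abs=1e-12
        )


# ---------------------------------------------------------------------------
# Assignment rules
# ---------------------------------------------------------------------------

def test_disjoint_intervals_assign_top_cluster():
    s = _summary(
        [[0.75, 0.25]], low=[[0.6, 0.1]], high=[[0.9, 0.4]]
    )
    assert assign_individuals(s)["call"].tolist() == ["cluster_1"]


def test_overlapping_intervals_are_admixed():
    s = _summary([[0.55, 0.45]], low=[[0.4, 0.3]], high=[[0.7, 0.6]])
    assert assign_individuals(s)["call"].tolist() == ["admixed"]


def test_argmax_tie_is_admixed():
    s = _summary([[0.5, 0.5]], low=[[0.45, 0.05]], high=[[0.55, 0.15]])
    assert assign_individuals(s)["call"].tolist() == ["admixed"]


@pytest.mark.parametrize("seed", range(5))
def test_k3_calls_match_interval_overlap_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 20
    Q = rng.dirichlet(np.ones(3), size=n)
    w = rng.uniform(0.01, 0.2, size=(n, 3))
    s = _summary(Q, low=np.clip(Q - w, 0, 1), high=np.clip(Q + w, 0, 1))
    calls = assign_individuals(s)["call"].tolist()
    for i in range(n):
        top = int(np.argmax(Q[i]))
        disjoint = all(
            s.Q_low[i, top] > s.Q_high[i, k] or s.Q_high[i, top] < s.Q_low[i, k]
            for k in range(3)
            if k != top
        )
        expected = f"cluster_{top + 1}" if disjoint else "admixed"
        assert calls[i] == expected


def test_population_call_rules():
    calls = pd.DataFrame(
        {
            "individual_id": [f"a{k}" for k in range(10)]
            + [f"b{k}" for k in range(10)]
            + [f"c{k}" for k in range(10)],
            "call": (
                ["cluster_1"] * 3 + ["cluster_2"] * 2 + ["admixed"] * 5
                + ["cluster_1"] * 2 + ["cluster_2"] * 2 + ["admixed"] * 6
                + ["admixed"] * 10
            ),
        }
    )
    meta = pd.DataFrame(
        {
            "individual_id": calls["individual_id"],
            "population": ["A"] * 10 + ["B"] * 10 + ["C"] * 10,
        }
    )
    out = assign_populations(calls, meta).set_index("population")
    assert out.loc["A", "call"] == "cluster_1"  # plurality of assigned
    assert out.loc["B", "call"] == "admixed"  # tie
    assert out.loc["C", "call"] == "admixed"  # everyone admixed
    assert out.loc["A", "prop_admixed"] == pytest.approx(0.5)
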