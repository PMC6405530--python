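import numpy as np
import pytest
from conftest import random_genotype_matrix, toy_metadata

from invadepop import (
    GenotypeMatrix,
    SimConfig,
    allelic_richness,
    ascertained_panel,
    compare_allelic_richness,
    maf_profile,
    pop_diversity,
    simulate_dataset,
    total_alleles,
    wc_fst,
)
from invadepop.diversity import _rarefied_ar
from oracles import exhaustive_rarefied_ar, tally_ho_hs, wc_theta_loops


def _matrix(calls, prefix="i"):
    calls = np.asarray(calls, dtype=np.int8)
    return GenotypeMatrix(
        [f"{prefix}{k}" for k in range(calls.shape[0])],
        [f"L{j}" for j in range(calls.shape[1])],
        calls,
    )


# ---------------------------------------------------------------------------
# Ho / Hs / F_IS
# ---------------------------------------------------------------------------

def test_all_heterozygotes_closed_form():
    """n=10 all-het locus: Ho=1, Hs=(10/9)(1-0.5-0.05)=0.5, F_IS=-1."""
    gm = _matrix(np.ones((10, 1)))
    meta = toy_metadata(gm, ["p"] * 10)
    (div,) = pop_diversity(gm, meta, n_boot=50, seed=0)
    assert div.Ho == pytest.approx(1.0)
    assert div.Hs == pytest.approx(0.5)
    assert div.FIS_mean == pytest.approx(-1.0)


def test_monomorphic_locus_contributes_zero():
    calls = np.column_stack([np.zeros(6), [0, 0, 1, 1, 2, 2]])
    gm = _matrix(calls)
    meta = toy_metadata(gm, ["p"] * 6)
    (div,) = pop_diversity(gm, meta, n_boot=50, seed=0)
    ho1, hs1 = tally_ho_hs([0, 0, 1, 1, 2, 2])
    assert div.Ho == pytest.approx(ho1 / 2)  # monomorphic locus averaged in as 0
    assert div.Hs == pytest.approx(hs1 / 2)


@pytest.mark.parametrize("seed", range(6))
def test_ho_hs_match_tally_oracle(seed):
    rng = np.random.default_rng(seed)
    gm = random_genotype_matrix(rng, n_ind=9, n_loci=7, missing_rate=0.1)
    meta = toy_metadata(gm, ["p"] * 9)
    (div,) = pop_diversity(gm, meta, n_boot=10, seed=0)
    hos, hss = [], []
    for j in range(gm.n_loci):
        col = gm.calls[:, j].tolist()
        if sum(1 for g in col if g != -1) < 2:
            continue
        ho, hs = tally_ho_hs(col)
        hos.append(ho)
        hss.append(hs)
    assert div.Ho == pytest.approx(np.mean(hos), abs=1e-12)
    assert div.Hs == pytest.approx(np.mean(hss), abs=1e-12)
    assert div.FIS_mean == pytest.approx(1 - np.mean(hos) / np.mean(hss), abs=1e-12)


def test_fis_bootstrap_is_seeded():
    rng = np.random.default_rng(1)
    gm = random_genotype_matrix(rng, n_ind=10, n_loci=12)
    meta = toy_metadata(gm, ["p"] * 10)
    a = pop_diversity(gm, meta, n_boot=200, seed=7)[0]
    b = pop_diversity(gm, meta, n_boot=200, seed=7)[0]
    assert a.FIS_CI95 == b.FIS_CI95


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def test_fixed_opposite_populations_give_theta_one():
    calls = np.vstack([np.zeros((5, 4)), np.full((5, 4), 2)])
    gm = _matrix(calls)
    meta = toy_metadata(gm, ["a"] * 5 + ["b"] * 5)
    res = wc_fst(gm, meta, n_boot=20, seed=0)
    assert res.FST == pytest.approx(1.0)


def test_identical_populations_give_theta_near_zero():
    rng = np.random.default_rng(2)
    block = rng.integers(0, 3, size=(8, 10)).astype(np.int8)
    gm = _matrix(np.vstack([block, block]))
    meta = toy_metadata(gm, ["a"] * 8 + ["b"] * 8)
    res = wc_fst(gm, meta, n_boot=20, seed=0)
    assert res.FST <= 0.01


@pytest.mark.parametrize("seed", range(6))
def test_theta_matches_loop_oracle(seed):
    rng = np.random.default_rng(seed)
    gm = random_genotype_matrix(rng, n_ind=18, n_loci=9, missing_rate=0.1)
    pops = [f"p{k % 3}" for k in range(18)]
    meta = toy_metadata(gm, pops)
    res = wc_fst(gm, meta, n_boot=10, seed=0)
    assert res.FST == pytest.approx(wc_theta_loops(gm.calls, pops), abs=1e-10)


def test_theta_invariant_to_population_label_order():
    rng = np.random.default_rng(9)
    gm = random_genotype_matrix(rng, n_ind=18, n_loci=8)
    pops = [f"p{k % 3}" for k in range(18)]
    relabel = {"p0": "z", "p1": "a", "p2": "m"}
    res1 = wc_fst(gm, toy_metadata(gm, pops), n_boot=10, seed=0)
    res2 = wc_fst(gm, toy_metadata(gm, [relabel[p] for p in pops]), n_boot=10, seed=0)
    assert res1.FST == pytest.approx(res2.FST, abs=1e-14)


def test_single_population_errors():
    gm = _matrix(np.zeros((4, 3)))
    meta = toy_metadata(gm, ["p"] * 4)
    with pytest.raises(ValueError, match="two populations"):
        wc_fst(gm, meta, n_boot=5)


def test_pairwise_matrix_is_symmetric_zero_diagonal():
    rng = np.random.default_rng(4)
    gm = random_genotype_matrix(rng, n_ind=18, n_loci=8)
    meta = toy_metadata(gm, [f"p{k % 3}" for k in range(18)])
    res = wc_fst(gm, meta, n_boot=10, seed=0, pairwise=True)
    m = res.pairwise_FST.to_numpy()
    np.testing.assert_allclose(m, m.T)
    np.testing.assert_allclose(np.diag(m), 0.0)


# ---------------------------------------------------------------------------
# Allelic richness
# ---------------------------------------------------------------------------

def test_monomorphic_locus_has_richness_one():
    ar = _rarefied_ar(np.array([10.0]), np.array([0.0]), g=4)
    assert ar[0] == pytest.approx(1.0)


@pytest.mark.parametrize("alt,total,g", [(3, 10, 4), (1, 8, 3), (5, 10, 2), (2, 6, 4)])
def test_rarefaction_matches_exhaustive_enumeration(alt, total, g):
    copies = [1] * alt + [0] * (total - alt)
    expected = exhaustive_rarefied_ar(copies, g)
    got = _rarefied_ar(np.array([float(total)]), np.array([float(alt)]), g)[0]
    assert got == pytest.approx(expected, abs=1e-12)


def test_richness_monotone_in_subsample_size():
    vals = [
        _rarefied_ar(np.array([20.0]), np.array([4.0]), g)[0] for g in range(2, 20)
    ]
    assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


def test_group_richness_uses_common_depth():
    rng = np.random.default_rng(0)
    gm = random_genotype_matrix(rng, n_ind=20, n_loci=10, missing_rate=0.05)
    meta = toy_metadata(
        gm,
        ["a"] * 8 + ["b"] * 12,
        range_of={"a": "native", "b": "invasive"},
    )
    out = allelic_richness(gm, meta)
    gs = {v.rarefaction_g for v in out.values()}
    assert len(gs) == 1
    for v in out.values():
        ok = v.AR_per_locus[~np.isnan(v.AR_per_locus)]
        assert ((ok >= 1 - 1e-12) & (ok <= 2 + 1e-12)).all()


# ---------------------------------------------------------------------------
# Total number of alleles
# ---------------------------------------------------------------------------

def test_tna_counts_observed_alleles():
    both = np.array([[0, 1], [2, 1], [1, 0]], dtype=np.int8)
    gm = _matrix(both)
    meta = toy_metadata(gm, ["p"] * 3, range_of={"p": "native"})
    res = total_alleles(gm, meta, "native", n_boot=20, seed=0)
    assert res.TNA == 4  # both alleles seen at both loci

    solo = _matrix(np.zeros((1, 5)))
    meta1 = toy_metadata(solo, ["p"], range_of={"p": "native"})
    res1 = total_alleles(solo, meta1, "native", n_boot=20, seed=0)
    assert res1.TNA == 5


def test_tna_bootstrap_can_only_lose_alleles():
    rng = np.random.default_rng(8)
    gm = random_genotype_matrix(rng, n_ind=15, n_loci=20)
    meta = toy_metadata(gm, ["p"] * 15, range_of={"p": "native"})
    res = total_alleles(gm, meta, "native", n_boot=300, seed=3)
    assert res.TNA_boot.mean() <= res.TNA + 1e-9
    assert (res.TNA_boot <= 2 * gm.n_loci).all()


# ---------------------------------------------------------------------------
# MAF profile
# ---------------------------------------------------------------------------

def test_maf_binning_conventions():
    # locus A: p=0.9 -> MAF 0.1 in [0.10, 0.15); locus B fixed -> [0, 0.05)
    calls = np.column_stack([[2, 2, 2, 2, 1], [0, 0, 0, 0, 0]])
    gm = _matrix(calls)
    meta = toy_metadata(gm, ["p"] * 5, range_of={"p": "native"})
    prof = maf_profile(gm, meta, "native")
    assert prof["maf"][0] == pytest.approx(0.1)
    assert prof["counts"][2] == 1  # [0.10, 0.15)
    assert prof["counts"][0] == 1  # fixed locus
    assert (prof["maf"] <= 0.5 + 1e-12).all()


def test_ascertained_panel_shifts_maf_mode_upward(small_sim):
    """High-MAF discovery ascertainment empties the low-frequency bins."""
    gm, meta, truth = small_sim
    full = maf_profile(gm, meta, "native")
    panel = maf_profile(ascertained_panel(gm, truth), meta, "native")
    assert panel["modal_bin"][0] > full["modal_bin"][0] or (
        panel["maf"].mean() > full["maf"].mean()
    )
    low_full = (full["maf"] < 0.1).mean()
    low_panel = (panel["maf"] < 0.1).mean()
    assert low_panel < low_full
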