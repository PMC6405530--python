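import numpy as np
import pandas as pd
import pytest
from conftest import random_genotype_matrix, toy_metadata
from oracles import cosine_law_km, exhaustive_mantel_p, literal_chord_distance

from invadepop import (
    chord_distance_matrix,
    geo_distance_matrix,
    mantel_test,
    rousset_ibd,
)
from invadepop.io import GenotypeMatrix


def _meta_at(coords):
    rows = []
    for k, (pop, (lat, lon)) in enumerate(coords.items()):
        rows.append(
            {
                "individual_id": f"{pop}_1",
                "population": pop,
                "range_label": "native",
                "longitude": lon,
                "latitude": lat,
                "source_type": "natural",
            }
        )
    return pd.DataFrame(rows)


def test_geo_distances_closed_forms():
    meta = _meta_at({"a": (0.0, 0.0), "b": (0.0, 180.0), "c": (0.0, 0.0)})
    km = geo_distance_matrix(meta)
    assert km.loc["a", "c"] == pytest.approx(0.0, abs=1e-9)
    assert km.loc["a", "b"] == pytest.approx(np.pi * 6371, rel=1e-9)
    assert (km.to_numpy() >= 0).all()
    np.testing.assert_allclose(km.to_numpy(), km.to_numpy().T)


@pytest.mark.parametrize("seed", range(5))
def test_geo_distances_match_law_of_cosines(seed):
    rng = np.random.default_rng(seed)
    coords = {
        f"p{k}": (rng.uniform(-60, 60), rng.uniform(-170, 170)) for k in range(5)
    }
    km = geo_distance_matrix(_meta_at(coords))
    pops = list(coords)
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            expect = cosine_law_km(*coords[a], *coords[b])
            assert km.loc[a, b] == pytest.approx(expect, rel=5e-3, abs=0.5)


def test_rousset_regression_recovers_exact_line():
    pops = [f"p{k}" for k in range(6)]
    rng = np.random.default_rng(0)
    d = np.zeros((6, 6))
    for i in range(6):
        for j in range(i + 1, 6):
            d[i, j] = d[j, i] = rng.uniform(10, 5000)
    km = pd.DataFrame(d, index=pops, columns=pops)
    # y = 0.01 * ln(d) exactly -> F = y/(1+y)
    y = 0.01 * np.log(d + np.eye(6))
    f = y / (1 + y)
    np.fill_diagonal(f, 0)
    fst = pd.DataFrame(f, index=pops, columns=pops)
    r, p, slope, intercept = rousset_ibd(fst, km)
    assert r == pytest.approx(1.0, abs=1e-9)
    assert slope == pytest.approx(0.01, abs=1e-9)
    assert p < 1e-10


def test_rousset_constant_response_is_undefined():
    pops = ["a", "b", "c", "d"]
    km = pd.DataFrame(
        np.array([[0, 1, 2, 3], [1, 0, 4, 5], [2, 4, 0, 6], [3, 5, 6, 0]], float) * 100,
        index=pops,
        columns=pops,
    )
    fst = pd.DataFrame(0.1 * (1 - np.eye(4)), index=pops, columns=pops)
    r, p, slope, _ = rousset_ibd(fst, km)
    assert r == 0.0 and np.isnan(p)


def test_chord_distance_closed_forms():
    calls = np.vstack([np.zeros((4, 5)), np.full((4, 5), 2)]).astype(np.int8)
    gm = GenotypeMatrix(
        [f"i{k}" for k in range(8)], [f"L{j}" for j in range(5)], calls
    )
    meta = toy_metadata(gm, ["a"] * 4 + ["b"] * 4)
    d = chord_distance_matrix(gm, meta)
    assert d.loc["a", "b"] == pytest.approx((2 / np.pi) * np.sqrt(2), rel=1e-12)

    same = GenotypeMatrix(
        [f"j{k}" for k in range(8)],
        [f"L{j}" for j in range(5)],
        np.vstack([calls[:4], calls[:4]]),
    )
    meta2 = toy_metadata(same, ["a"] * 4 + ["b"] * 4)
    assert chord_distance_matrix(same, meta2).loc["a", "b"] == pytest.approx(0.0)


@pytest.mark.parametrize("seed", range(4))
def test_chord_distance_matches_literal_oracle(seed):
    rng = np.random.default_rng(seed)
    gm = random_genotype_matrix(rng, n_ind=16, n_loci=12, missing_rate=0.0)
    pops = ["a"] * 8 + ["b"] * 8
    meta = toy_metadata(gm, pops)
    d = chord_distance_matrix(gm, meta)
    pa = gm.calls[:8].sum(axis=0) / 16
    pb = gm.calls[8:].sum(axis=0) / 16
    assert d.loc["a", "b"] == pytest.approx(literal_chord_distance(pa, pb), abs=1e-12)


def _sym(rng, n, scale=1.0):
    m = rng.uniform(0, scale, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return m


def test_mantel_identity_hits_floor():
    rng = np.random.default_rng(3)
    pops = [f"p{k}" for k in range(8)]
    a = pd.DataFrame(_sym(rng, 8), index=pops, columns=pops)
    r, p = mantel_test(a, a, n_perm=999, seed=0)
    assert r == pytest.approx(1.0)
    assert p <= 5 / 1000
    assert p >= 1 / 1000


def test_mantel_matches_exhaustive_enumeration():
    rng = np.random.default_rng(11)
    pops = ["a", "b", "c", "d"]
    A = _sym(rng, 4)
    B = _sym(rng, 4)
    a = pd.DataFrame(A, index=pops, columns=pops)
    b = pd.DataFrame(B, index=pops, columns=pops)
    r, p = mantel_test(a, b, n_perm=4999, seed=1)
    exact = exhaustive_mantel_p(A, B)
    assert p == pytest.approx(exact, abs=0.03)


def test_mantel_needs_four_populations():
    pops = ["a", "b", "c"]
    m = pd.DataFrame(np.zeros((3, 3)), index=pops, columns=pops)
    with pytest.raises(ValueError, match="4 populations"):
        mantel_test(m, m)


def test_mantel_seeded_reproducibility():
    rng = np.random.default_rng(7)
    pops = [f"p{k}" for k in range(6)]
    a = pd.DataFrame(_sym(rng, 6), index=pops, columns=pops)
    b = pd.DataFrame(_sym(rng, 6), index=pops, columns=pops)
    assert mantel_test(a, b, n_perm=499, seed=9) == mantel_test(
        a, b, n_perm=499, seed=9
    )


def test_mantel_agrees_with_skbio():
    """Cross-check r (exact) and p (stochastic) against scikit-bio."""
    skbio_distance = pytest.importorskip("skbio.stats.distance")
    rng = np.random.default_rng(13)
    pops = [f"p{k}" for k in range(7)]
    A = _sym(rng, 7)
    B = A + _sym(rng, 7, scale=0.3)
    np.fill_diagonal(B, 0)
    a = pd.DataFrame(A, index=pops, columns=pops)
    b = pd.DataFrame(B, index=pops, columns=pops)
    r, p = mantel_test(a, b, n_perm=1999, seed=3)
    sk_r, sk_p, _ = skbio_distance.mantel(
        skbio_distance.DistanceMatrix(A, pops),
        skbio_distance.DistanceMatrix(B, pops),
        permutations=1999,
        alternative="greater",
    )
    assert r == pytest.approx(sk_r, abs=1e-12)
    assert p == pytest.approx(sk_p, abs=0.05)


def test_mantel_null_p_values_roughly_uniform():
    """Independent matrices: permutation p is approximately uniform."""
    from scipy import stats

    ps = []
    for seed in range(60):
        rng = np.random.default_rng(1000 + seed)
        pops = [f"p{k}" for k in range(6)]
        a = pd.DataFrame(_sym(rng, 6), index=pops, columns=pops)
        b = pd.DataFrame(_sym(rng, 6), index=pops, columns=pops)
        _, p = mantel_test(a, b, n_perm=199, seed=seed)
        ps.append(p)
    assert stats.kstest(ps, "uniform").pvalue > 0.01
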