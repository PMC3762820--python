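"""Great-circle distances, Moran's I, Mantel tests and correlograms."""

import numpy as np
import pandas as pd
import pytest

from forestchange import spatial
from forestchange.change import sorensen_matrix
from forestchange.datamodel import DataError
from forestchange.geo import EARTH_RADIUS_KM, haversine_km
from forestchange.spatial import (DistanceMatrix, default_class_edges,
                                  env_distance, env_mantel_table,
                                  geo_distances, mantel, mantel_correlogram,
                                  morans_correlogram)


def towns_frame(lats, lons, ids=None):
    ids = ids or [f"T{i}" for i in range(len(lats))]
    return pd.DataFrame({"town_id": ids, "centroid_lat": lats,
                         "centroid_lon": lons})


def brute_morans_i(z, w):
    n = len(z)
    num = sum(w[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return (n / w.sum()) * num / sum(z_i ** 2 for z_i in z)


def test_geo_distances_basics():
    d = geo_distances(towns_frame([42.0, 42.0, 43.0], [-72.0, -72.0, -72.0]))
    assert d.values[0, 1] == 0.0
    # one degree of latitude ≈ 111.2 km
    assert d.values[0, 2] == pytest.approx(111.2, abs=0.1)


def test_geo_distances_match_law_of_cosines():
    """Triangle of towns vs. an independent spherical-law-of-cosines oracle."""
    lats = np.array([41.3, 44.7, 46.1])
    lons = np.array([-73.9, -70.2, -68.5])
    d = geo_distances(towns_frame(lats, lons)).values
    for i in range(3):
        for j in range(3):
            if i == j:
                continue
            p1, p2 = np.radians([lats[i], lons[i]]), np.radians([lats[j], lons[j]])
            cosang = (np.sin(p1[0]) * np.sin(p2[0])
                      + np.cos(p1[0]) * np.cos(p2[0]) * np.cos(p1[1] - p2[1]))
            oracle = EARTH_RADIUS_KM * np.arccos(np.clip(cosang, -1, 1))
            assert d[i, j] == pytest.approx(oracle, rel=1e-3)


def test_morans_i_matches_double_loop(rng):
    """Vectorized Moran's I equals the brute-force double loop to 1e-12."""
    n = 25
    lat = np.repeat(np.arange(5), 5) * 0.1 + 42.0
    lon = np.tile(np.arange(5), 5) * 0.1 - 72.0
    geo = geo_distances(towns_frame(lat, lon))
    values = lat * 3.0 + rng.normal(0, 0.05, n)
    edges = default_class_edges(geo, 12.0, max_fraction=1.0)
    res = morans_correlogram(values, geo, edges=edges, n_perm=49, seed=0)
    z = values - values.mean()
    for c, row in res.table.iterrows():
        w = ((geo.values >= row["lower_km"]) & (geo.values < row["upper_km"])).astype(float)
        np.fill_diagonal(w, 0.0)
        if w.sum() == 0:
            assert np.isnan(row["statistic"])
        else:
            assert row["statistic"] == pytest.approx(brute_morans_i(z, w), abs=1e-12)


def test_morans_hand_computed_four_towns():
    """One class covering all pairs: I from the textbook formula by hand."""
    geo = DistanceMatrix(list("ABCD"), np.array([
        [0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1], [1, 1, 1, 0]], dtype=float))
    values = np.array([1.0, 2.0, 3.0, 6.0])
    res = morans_correlogram(values, geo, edges=np.array([0.5, 1.5]),
                             n_perm=49, seed=0)
    z = values - values.mean()
    w = np.ones((4, 4)) - np.eye(4)
    expected = (4 / 12) * (z @ w @ z) / (z @ z)
    assert res.table["statistic"].iloc[0] == pytest.approx(expected, abs=1e-12)


def test_morans_gradient_significant_at_short_range(rng):
    lat = np.repeat(np.arange(6), 6) * 0.1 + 42.0
    lon = np.tile(np.arange(6), 6) * 0.1 - 72.0
    geo = geo_distances(towns_frame(lat, lon))
    values = lat * 10 + rng.normal(0, 0.1, 36)
    res = morans_correlogram(values, geo, class_width_km=12.0,
                             n_perm=199, seed=1)
    first = res.table.iloc[0]
    assert first["statistic"] > 0
    assert first["p"] < 0.05


def test_morans_null_mean_near_expectation(rng):
    """Permutation-null mean of I ≈ −1/(n−1)."""
    n = 30
    lat = rng.uniform(41, 43, n)
    lon = rng.uniform(-73, -71, n)
    geo = geo_distances(towns_frame(lat, lon))
    edges = np.array([0.0, 500.0])     # one class, all pairs
    stats = []
    for s in range(200):
        vals = rng.normal(size=n)
        res = morans_correlogram(vals, geo, edges=edges, n_perm=9, seed=s)
        stats.append(res.table["statistic"].iloc[0])
    assert np.mean(stats) == pytest.approx(-1 / (n - 1), abs=0.02)


def test_morans_constant_values_error():
    geo = geo_distances(towns_frame([42.0, 42.1, 42.2], [-72.0, -72.0, -72.0]))
    with pytest.raises(DataError):
        morans_correlogram(np.ones(3), geo, n_perm=9)


def test_mantel_identity_and_shift(rng):
    n = 10
    pts = rng.random((n, 2))
    dm = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    ids = [f"T{i}" for i in range(n)]
    a = DistanceMatrix(ids, dm)
    assert mantel(a, a, n_perm=99, seed=0).r == pytest.approx(1.0)
    shifted = dm + 0.7
    np.fill_diagonal(shifted, 0.0)
    b = DistanceMatrix(ids, shifted)
    assert mantel(a, b, n_perm=99, seed=0).r == pytest.approx(1.0)


def test_mantel_matches_brute_force(rng):
    """r equals the hand-computed Pearson correlation of the triangles."""
    n = 15
    def rand_dm():
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        return m
    ids = [f"T{i}" for i in range(n)]
    a, b = DistanceMatrix(ids, rand_dm()), DistanceMatrix(ids, rand_dm())
    iu = np.triu_indices(n, 1)
    expected = np.corrcoef(a.values[iu], b.values[iu])[0, 1]
    assert mantel(a, b, n_perm=99, seed=0).r == pytest.approx(expected, abs=1e-12)


def test_mantel_joint_relabel_invariance(rng):
    n = 12
    pts = rng.random((n, 2))
    dm1 = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    v = rng.random(n)
    dm2 = np.abs(v[:, None] - v[None, :])
    ids = [f"T{i}" for i in range(n)]
    r1 = mantel(DistanceMatrix(ids, dm1), DistanceMatrix(ids, dm2),
                n_perm=49, seed=0).r
    perm = rng.permutation(n)
    ids_p = [ids[i] for i in perm]
    r2 = mantel(DistanceMatrix(ids_p, dm1[np.ix_(perm, perm)]),
                DistanceMatrix(ids_p, dm2[np.ix_(perm, perm)]),
                n_perm=49, seed=0).r
    assert r1 == pytest.approx(r2, abs=1e-12)


def test_mantel_correlogram_gradient_pattern(rng):
    """Gradient-structured composition: positive r at the shortest lag,
    negative at the longest."""
    n = 40
    lat = np.linspace(41, 45, n)
    lon = np.full(n, -72.0)
    towns = towns_frame(lat, lon)
    geo = geo_distances(towns)
    # two-taxon composition sliding along the gradient
    p = np.linspace(0.05, 0.95, n)
    comp = np.column_stack([p, 1 - p]) + rng.normal(0, 0.01, (n, 2))
    comp = np.clip(comp, 1e-6, None)
    comp /= comp.sum(1, keepdims=True)
    dm = DistanceMatrix(towns["town_id"].tolist(), sorensen_matrix(comp))
    res = mantel_correlogram(dm, geo, class_width_km=60.0, n_perm=199, seed=2)
    t = res.table.dropna(subset=["statistic"])
    assert t["statistic"].iloc[0] > 0 and bool(t["significant"].iloc[0])
    assert t["statistic"].iloc[-1] < 0


def test_mantel_correlogram_single_class_degenerate():
    towns = towns_frame([42.0, 42.1, 42.2, 42.3], [-72.0] * 4)
    geo = geo_distances(towns)
    comp = np.array([[0.7, 0.3], [0.6, 0.4], [0.4, 0.6], [0.2, 0.8]])
    dm = DistanceMatrix(towns["town_id"].tolist(), sorensen_matrix(comp))
    res = mantel_correlogram(dm, geo, edges=np.array([0.0, 1e6]),
                             n_perm=49, seed=0)
    assert np.isnan(res.table["statistic"].iloc[0])
    assert not res.table["significant"].iloc[0]


def test_correlogram_pair_counts_conserved(rng):
    n = 20
    towns = towns_frame(rng.uniform(41, 44, n), rng.uniform(-74, -71, n))
    geo = geo_distances(towns)
    vals = rng.normal(size=n)
    coarse = morans_correlogram(vals, geo, class_width_km=60.0, n_perm=9,
                                seed=0, max_fraction=1.0)
    fine = morans_correlogram(vals, geo, class_width_km=30.0, n_perm=9,
                              seed=0, max_fraction=1.0)
    for _, row in coarse.table.iterrows():
        sub = fine.table[(fine.table["lower_km"] >= row["lower_km"] - 1e-9)
                         & (fine.table["upper_km"] <= row["upper_km"] + 1e-9)]
        if len(sub):
            assert sub["n_pairs"].sum() == row["n_pairs"]


def test_env_mantel_gdd_beats_random_covariate(small_landscape):
    """Composition generated from GDD niches correlates with GDD distance
    more than with an unrelated covariate."""
    towns = small_landscape.towns.copy()
    comp = small_landscape.truth_pre.to_numpy()
    ids = towns["town_id"].tolist()
    dm = DistanceMatrix(ids, sorensen_matrix(comp))
    table = env_mantel_table(dm, dm, towns,
                             covariates=("gdd", "soil_clay_pct"),
                             n_perm=99, seed=0)
    r_gdd = table[(table["covariate"] == "gdd")
                  & (table["era"] == "precolonial")]["r_m"].iloc[0]
    r_clay = table[(table["covariate"] == "soil_clay_pct")
                   & (table["era"] == "precolonial")]["r_m"].iloc[0]
    assert r_gdd > r_clay
    assert r_gdd > 0.5


def test_env_distance_is_absolute_difference():
    towns = towns_frame([42.0, 43.0, 44.0], [-72.0] * 3)
    towns["gdd"] = [3000.0, 3500.0, 2800.0]
    e = env_distance(towns, "gdd")
    assert e.values[0, 1] == 500.0
    assert e.values[1, 2] == 700.0
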