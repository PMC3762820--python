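"""Generator: niche responses, era shift, sampling distributions, determinism."""

import numpy as np
import pandas as pd
import pytest

from forestchange.datamodel import DataError
from forestchange.simulate import (SimConfig, ShiftRule, generate,
                                   sample_witness_trees, shift_profile,
                                   true_composition, write_landscape,
                                   _dirichlet)
from forestchange.taxa import TaxonSet


@pytest.fixture(scope="module")
def taxa():
    return TaxonSet()


def niche_config(niches, **kw):
    return SimConfig(taxa_niches=niches, era_shift={}, **kw)


def test_single_taxon_at_optimum(taxa):
    cfg = niche_config({"OAK": (4000, 300, 1.0)})
    comp = true_composition(4000.0, cfg, taxa)
    assert comp[taxa.index("OAK")] == 1.0
    assert comp.sum() == pytest.approx(1.0)


def test_equidistant_equal_peaks_split_evenly(taxa):
    cfg = niche_config({"OAK": (3900, 300, 0.7), "BEECH": (4100, 300, 0.7)})
    comp = true_composition(4000.0, cfg, taxa)
    assert comp[taxa.index("OAK")] == pytest.approx(0.5)
    assert comp[taxa.index("BEECH")] == pytest.approx(0.5)


def test_three_taxon_formula(taxa):
    """Abundances follow peak·exp(−(g−opt)²/2w²), normalized."""
    niches = {"OAK": (4000, 300, 1.0), "BEECH": (3500, 400, 0.8),
              "MAPLE": (3800, 200, 0.5)}
    g = 3700.0
    cfg = niche_config(niches)
    comp = true_composition(g, cfg, taxa)
    raw = {c: p * np.exp(-((g - o) ** 2) / (2 * w * w))
           for c, (o, w, p) in niches.items()}
    total = sum(raw.values())
    for c in niches:
        assert comp[taxa.index(c)] == pytest.approx(raw[c] / total, abs=1e-12)


def test_era_shift_identity_and_renormalization(taxa):
    pre = true_composition(3800.0, SimConfig(era_shift={}), taxa)
    # all multipliers 1 -> identity
    same = shift_profile(pre, 0.5, SimConfig(era_shift={}), taxa)
    np.testing.assert_allclose(same, pre, atol=1e-12)
    # chestnut extirpation rescales the rest by 1/(1-p_chestnut)
    p = np.zeros(len(taxa))
    p[taxa.index("CHESTNUT")] = 0.10
    p[taxa.index("OAK")] = 0.90
    out = shift_profile(p, 0.0, SimConfig(era_shift={"CHESTNUT": ShiftRule(0.0)}), taxa)
    assert out[taxa.index("CHESTNUT")] == 0.0
    assert out[taxa.index("OAK")] == pytest.approx(1.0)


def test_era_shift_linear_in_agriculture(taxa):
    p = np.zeros(len(taxa))
    p[taxa.index("BEECH")] = 0.4
    p[taxa.index("OAK")] = 0.6
    cfg = SimConfig(era_shift={"BEECH": ShiftRule(1.0, -0.8)})
    out = shift_profile(p, 0.5, cfg, taxa)
    # beech multiplier 1-0.8*0.5 = 0.6 -> 0.24 before renormalizing by 0.84
    assert out[taxa.index("BEECH")] == pytest.approx(0.24 / 0.84)
    assert out[taxa.index("OAK")] == pytest.approx(0.60 / 0.84)


def test_shift_annihilation_raises(taxa):
    p = np.zeros(len(taxa))
    p[taxa.index("CHESTNUT")] = 1.0
    with pytest.raises(DataError):
        shift_profile(p, 0.0, SimConfig(era_shift={"CHESTNUT": ShiftRule(0.0)}), taxa)


def test_witness_sampling_matches_profile(taxa, rng):
    """Empirical proportions within 3 binomial SEs at n = 1e5."""
    cfg = SimConfig(seed=0)
    profile = true_composition(3500.0, cfg, taxa)
    n = 100_000
    recs = sample_witness_trees("T", profile, n, rng, taxa)
    counts = recs["raw_name"].value_counts()
    from forestchange.simulate import _WT_NAME
    for i, code in enumerate(taxa.codes):
        p = profile[i]
        obs = counts.get(_WT_NAME[code], 0) / n
        se = np.sqrt(p * (1 - p) / n)
        assert abs(obs - p) <= max(3 * se, 1e-9), code


def test_theta_controls_plot_dispersion(taxa):
    """Plot-profile variance around the town profile shrinks as θ grows."""
    profile = true_composition(3500.0, SimConfig(), taxa)
    spreads = []
    for theta in (5.0, 50.0, 500.0):
        rng = np.random.default_rng(99)
        draws = np.array([_dirichlet(rng, theta * profile) for _ in range(400)])
        spreads.append(np.linalg.norm(draws - profile, axis=1).mean())
    assert spreads[0] > spreads[1] > spreads[2]


def test_generation_is_deterministic(tmp_path):
    cfg = SimConfig(nx=3, ny=3, seed=42)
    a, b = generate(cfg), generate(cfg)
    pd.testing.assert_frame_equal(a.witness, b.witness)
    pd.testing.assert_frame_equal(a.modern, b.modern)
    pd.testing.assert_frame_equal(a.towns, b.towns)
    # byte-identical files
    pa = write_landscape(a, tmp_path / "a")
    pb = write_landscape(b, tmp_path / "b")
    for key in pa:
        assert pa[key].read_bytes() == pb[key].read_bytes(), key


def test_config_validation():
    with pytest.raises(DataError):
        SimConfig(taxa_niches={"OAK": (4000, -1.0, 1.0)})
    with pytest.raises(DataError):
        SimConfig(theta=0.0)


def test_spatial_gradient_by_construction(small_landscape):
    """GDD decreases with latitude, so near towns are compositionally
    closer than far towns (the landscape carries spatial structure)."""
    towns = small_landscape.towns
    assert towns["gdd"].corr(towns["centroid_lat"]) < -0.8
    tp = small_landscape.truth_pre.to_numpy()
    from forestchange.change import sorensen
    lat = towns.set_index("town_id")["centroid_lat"]
    ids = list(small_landscape.truth_pre.index)
    near, far = [], []
    for i in range(0, len(ids), 7):
        for j in range(i + 1, len(ids), 7):
            d = sorensen(tp[i], tp[j])
            (near if abs(lat[ids[i]] - lat[ids[j]]) < 0.2 else far).append(d)
    assert np.mean(near) < np.mean(far)
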