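"""Segregation screening, two-point estimation, grouping, ordering, Kosambi."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cucsyn.linkage import (GenotypeMatrix, PopulationType, _em_rf_f2, _f2_loglik,
                            build_map, estimate_rf_f2, estimate_rf_ril,
                            group_markers, haldane_waddington,
                            kosambi_distance, kosambi_inverse, order_markers,
                            pairwise_estimates, sarf)
from cucsyn.linkage import test_segregation as segregation_test
from cucsyn.simulate import simulate_population


# ---------------------------------------------------------------------------
# segregation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "counts, chi2, p, distorted",
    [
        # exact 1:2:1 ratio
        ((25, 50, 25), 0.0, 1.0, False),
        # Pearson sum (30-25)^2/25 + (40-50)^2/50 + (30-25)^2/25 = 4
        ((30, 40, 30), 4.0, np.exp(-2.0), False),
        # 18 = 2 * 15^2/25; survival of chi2(2) at 18 is e^-9 < 0.01
        ((10, 50, 40), 18.0, np.exp(-9.0), True),
    ],
)
def test_f2_segregation_against_closed_form(counts, chi2, p, distorted):
    res = segregation_test(counts, PopulationType.F2)
    assert res.chi2 == pytest.approx(chi2, abs=1e-10)
    assert res.df == 2
    assert res.p_value == pytest.approx(p, abs=1e-8)
    assert res.distorted is distorted


def test_ril_segregation_is_one_to_one_on_homozygotes():
    res = segregation_test((30, 2, 50), PopulationType.RIL)
    assert res.df == 1
    assert res.chi2 == pytest.approx((30 - 40) ** 2 / 40 + (50 - 40) ** 2 / 40)


def test_segregation_rejects_empty_marker():
    with pytest.raises(ValueError, match="empty marker"):
        segregation_test((0, 0, 0), PopulationType.F2)


# ---------------------------------------------------------------------------
# F2 EM estimator
# ---------------------------------------------------------------------------

def test_identical_homozygote_columns_give_zero_rf():
    calls = np.array([0, 2, 0, 2, 0, 2, 0, 2, 0, 2] * 2, dtype=np.int8)
    est = estimate_rf_f2(calls, calls)
    assert est.r_hat == pytest.approx(0.0, abs=1e-9)
    assert est.lod > 0


def test_em_equals_grid_search_mle(rng):
    """EM fixed point matches an exhaustive likelihood grid on random tables."""
    grid = np.linspace(0.0, 0.5, 5001)
    for _ in range(100):
        table = rng.multinomial(20, np.full(9, 1 / 9)).reshape(3, 3)
        r_em = float(_em_rf_f2(table.reshape(1, 3, 3))[0])
        ll = _f2_loglik(np.broadcast_to(table.reshape(1, 3, 3), (grid.size, 3, 3)), grid)
        r_grid = float(grid[np.argmax(ll)])
        assert abs(r_em - r_grid) <= 1e-3


def test_em_loglikelihood_nondecreasing(rng):
    for _ in range(20):
        table = rng.multinomial(30, np.full(9, 1 / 9)).reshape(1, 3, 3)
        lls = [
            float(_f2_loglik(table, _em_rf_f2(table, max_iter=k))[0])
            for k in range(1, 15)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


def test_f2_estimator_recovers_true_rf():
    """1,000 simulated F2 meioses at r = 0.2 land within ~3 binomial SE."""
    import pandas as pd
    d = -50.0 * np.log(1.0 - 2 * 0.2)  # Haldane distance giving r = 0.2
    table = pd.DataFrame({
        "marker_id": ["m1", "m2"], "chrom": ["c", "c"], "pos_cM": [0.0, d],
    })
    pop = simulate_population(table, PopulationType.F2, 1000, seed=5)
    est = estimate_rf_f2(pop.calls[:, 0], pop.calls[:, 1])
    assert 0.17 <= est.r_hat <= 0.23


def test_low_information_pairs_are_flagged():
    calls = np.array([0, 2, 0, 2, 0], dtype=np.int8)
    assert not estimate_rf_f2(calls, calls).reliable


# ---------------------------------------------------------------------------
# RIL estimator and the Haldane-Waddington map
# ---------------------------------------------------------------------------

def test_ril_estimator_closed_form():
    # 20 recombinant of 80 scored: R = 0.25 -> r = 0.25/1.5
    a = np.zeros(80, dtype=np.int8)
    b = np.zeros(80, dtype=np.int8)
    b[:20] = 2
    est = estimate_rf_ril(a, b)
    assert est.r_hat == pytest.approx(0.25 / 1.5, abs=1e-12)
    assert est.lod > 0


def test_ril_estimator_zero_and_unlinked():
    a = np.array([0, 2] * 40, dtype=np.int8)
    assert estimate_rf_ril(a, a).r_hat == 0.0
    b = np.roll(a, 1)  # every pair discordant: R = 1 -> clamped
    est = estimate_rf_ril(a, b)
    assert est.r_hat == 0.5
    assert est.lod == 0.0


def test_selfing_to_fixation_recovers_expected_R():
    """Selfed lines at meiotic r = 1/6 show observed R near 2r/(1+2r) = 0.25."""
    import pandas as pd
    r = 1.0 / 6.0
    d = -50.0 * np.log(1.0 - 2 * r)
    table = pd.DataFrame({
        "marker_id": ["m1", "m2"], "chrom": ["c", "c"], "pos_cM": [0.0, d],
    })
    pop = simulate_population(table, PopulationType.RIL, 4000, seed=3,
                              n_selfing=12)
    a, b = pop.calls[:, 0], pop.calls[:, 1]
    ok = np.isin(a, (0, 2)) & np.isin(b, (0, 2))
    big_r = float(np.mean(a[ok] != b[ok]))
    assert big_r == pytest.approx(0.25, abs=0.025)


def test_ril_estimate_at_study_scale():
    import pandas as pd
    d = -50.0 * np.log(1.0 - 2 * 0.10)
    table = pd.DataFrame({
        "marker_id": ["m1", "m2"], "chrom": ["c", "c"], "pos_cM": [0.0, d],
    })
    pop = simulate_population(table, PopulationType.RIL, 80, seed=17)
    est = estimate_rf_ril(pop.calls[:, 0], pop.calls[:, 1])
    assert 0.04 <= est.r_hat <= 0.18


@given(st.floats(min_value=0.0, max_value=0.4999))
@settings(deadline=None, max_examples=200)
def test_haldane_waddington_properties(big_r):
    r = haldane_waddington(big_r)
    assert 0.0 <= r <= 0.5
    assert r <= big_r + 1e-15
    eps = 1e-6
    if big_r + eps < 0.5:
        assert haldane_waddington(big_r + eps) > r  # strictly increasing


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def _brute_force_components(ids, edges):
    comps = {m: {m} for m in ids}
    for a, b in edges:
        merged = comps[a] | comps[b]
        for m in merged:
            comps[m] = merged
    seen, out = set(), []
    for m in ids:
        key = frozenset(comps[m])
        if key not in seen:
            seen.add(key)
            out.append(sorted(key))
    return sorted(out, key=lambda c: (-len(c), c[0]))


def test_grouping_examples():
    ids = ["a", "b", "c"]
    lod = np.array([[0, 5, 1], [5, 0, 5], [1, 5, 0]], dtype=float)
    r = np.full((3, 3), 0.1)
    rel = np.ones((3, 3), dtype=bool)
    np.fill_diagonal(rel, False)
    assert group_markers(ids, r, lod, rel, 4.0) == [["a", "b", "c"]]


def test_grouping_matches_brute_force_on_random_instances(rng):
    for _ in range(25):
        m = int(rng.integers(3, 15))
        ids = [f"m{i:02d}" for i in range(m)]
        lod = rng.uniform(0, 8, (m, m))
        lod = (lod + lod.T) / 2
        r = rng.uniform(0, 0.5, (m, m))
        r = (r + r.T) / 2
        rel = np.ones((m, m), dtype=bool)
        np.fill_diagonal(rel, False)
        edges = [(ids[i], ids[j]) for i in range(m) for j in range(i + 1, m)
                 if lod[i, j] >= 4.0 and r[i, j] < 0.5]
        assert group_markers(ids, r, lod, rel, 4.0) == \
            _brute_force_components(ids, edges)


def test_unlinked_markers_become_singletons(rng):
    m = 30
    calls = rng.integers(0, 3, size=(100, m)).astype(np.int8)
    matrix = GenotypeMatrix(PopulationType.F2, [f"i{k}" for k in range(100)],
                            [f"m{k:02d}" for k in range(m)], calls)
    r, lod, n, rel = pairwise_estimates(matrix)
    groups = group_markers(matrix.marker_ids, r, lod, rel, 4.0)
    assert all(len(g) == 1 for g in groups)
    assert len(groups) == m


# ---------------------------------------------------------------------------
# ordering
# ---------------------------------------------------------------------------

def _simulated_chain(n_loci, gap_cm, n_ind, seed):
    import pandas as pd
    table = pd.DataFrame({
        "marker_id": [f"L{i:02d}" for i in range(n_loci)],
        "chrom": ["c"] * n_loci,
        "pos_cM": [i * gap_cm for i in range(n_loci)],
    })
    return simulate_population(table, PopulationType.F2, n_ind, seed=seed)


def test_order_two_markers_normalized():
    pop = _simulated_chain(2, 10.0, 100, 1)
    r, lod, n, rel = pairwise_estimates(pop)
    assert order_markers(["L01", "L00"], pop.marker_ids, r, rel) == ["L00", "L01"]


def test_order_five_loci_matches_exhaustive_minimum():
    pop = _simulated_chain(5, 10.0, 200, 2)
    r, lod, n, rel = pairwise_estimates(pop)
    got = order_markers(list(pop.marker_ids), pop.marker_ids, r, rel)
    idx = {m: i for i, m in enumerate(pop.marker_ids)}
    d = r[np.ix_([idx[m] for m in pop.marker_ids], [idx[m] for m in pop.marker_ids])]
    best = min(sarf(list(p), d) for p in itertools.permutations(range(5)))
    assert sarf([idx[m] for m in got], d) == pytest.approx(best, abs=1e-12)


def test_planted_order_recovered():
    pop = _simulated_chain(8, 5.3, 500, 3)  # ~ r = 0.05 gaps
    r, lod, n, rel = pairwise_estimates(pop)
    got = order_markers(list(pop.marker_ids), pop.marker_ids, r, rel)
    planted = [f"L{i:02d}" for i in range(8)]
    assert got in (planted, planted[::-1])


# ---------------------------------------------------------------------------
# Kosambi
# ---------------------------------------------------------------------------

def test_kosambi_closed_form_values():
    assert kosambi_distance(0.0) == 0.0
    assert kosambi_distance(0.2) == pytest.approx(25 * np.log(1.4 / 0.6), rel=1e-12)
    assert kosambi_distance(0.2) == pytest.approx(21.18, abs=0.005)


@pytest.mark.parametrize("r", np.arange(0.01, 0.50, 0.01))
def test_kosambi_round_trip(r):
    assert kosambi_inverse(kosambi_distance(r)) == pytest.approx(r, abs=1e-10)


def test_kosambi_rejects_unlinked():
    with pytest.raises(ValueError, match="unlinked"):
        kosambi_distance(0.5)
    with pytest.raises(ValueError):
        kosambi_inverse(-1.0)


# ---------------------------------------------------------------------------
# whole-map construction
# ---------------------------------------------------------------------------

def test_map_positions_invariant_under_marker_shuffling(f2_small, rng):
    gmap, _ = build_map(f2_small)
    perm = rng.permutation(len(f2_small.marker_ids))
    shuffled = GenotypeMatrix(
        PopulationType.F2, f2_small.individuals,
        [f2_small.marker_ids[i] for i in perm], f2_small.calls[:, perm])
    gmap2, _ = build_map(shuffled)
    by_group = lambda g: sorted(
        tuple(sorted((m, round(p, 6)) for m, p in loci))
        for loci in g.groups.values())
    assert by_group(gmap) == by_group(gmap2)


def test_build_map_recovers_chromosome_partition(f2_small):
    gmap, unplaced = build_map(f2_small)
    # each group's markers come from one simulated chromosome
    for loci in gmap.groups.values():
        chroms = {m.split("_")[0] for m, _ in loci}
        assert len(chroms) == 1
    placed = {m for loci in gmap.groups.values() for m, _ in loci}
    assert len(placed) + len(unplaced) == len(f2_small.marker_ids)


def test_positions_start_at_zero_and_increase(f2_small):
    gmap, _ = build_map(f2_small)
    for loci in gmap.groups.values():
        pos = [p for _, p in loci]
        assert pos[0] == 0.0
        assert all(b >= a for a, b in zip(pos, pos[1:]))
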