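import math
from itertools import combinations

import numpy as np
import pytest

from vlsm.errors import ConfigError, ValidationError
from vlsm.inference import (
    PermutationConfig,
    build_null,
    build_null_summaries,
    p_map_fwe,
    p_map_pervoxel,
    parametric_p_map,
    permute_labels,
    q_values,
    randomized_uniform_pvalues,
    threshold_map,
)
from vlsm.voxelstats import RRConfig, rr_map, t_map

from conftest import make_cohort, make_random_cohort
from test_voxelstats import oracle_t


def _groups(cohort, k):
    return cohort.subject_ids[:k], cohort.subject_ids[k:]


# ---------------------------------------------------------------------------
# label assignments


def test_permute_labels_exhaustive_enumeration():
    A, exhaustive = permute_labels(2, 2, k=999, seed=0)
    assert exhaustive and A.shape == (6, 4)  # C(4,2) = 6
    assert len({tuple(row) for row in A}) == 6
    assert (A.sum(axis=1) == 2).all()


def test_permute_labels_monte_carlo_preserves_sizes():
    A, exhaustive = permute_labels(78, 22, k=1000, seed=1)
    assert not exhaustive and A.shape == (1000, 100)
    assert (A.sum(axis=1) == 78).all()


def test_permute_labels_deterministic():
    A1, _ = permute_labels(10, 10, k=50, seed=7, exhaustive_limit=1)
    A2, _ = permute_labels(10, 10, k=50, seed=7, exhaustive_limit=1)
    np.testing.assert_array_equal(A1, A2)
    A3, _ = permute_labels(10, 10, k=50, seed=8, exhaustive_limit=1)
    assert not np.array_equal(A1, A3)


# ---------------------------------------------------------------------------
# whole-brain nulls


def _enumerated_t_summaries(cohort, n_a, q=5.0):
    """Independent oracle: loop over all label assignments, t via the
    textbook formula per voxel, then min and q-th percentile summaries."""
    data = cohort.data.reshape(len(cohort), -1)
    mins, pcts = [], []
    for combo in combinations(range(len(cohort)), n_a):
        a = np.array(combo)
        c = np.array([i for i in range(len(cohort)) if i not in combo])
        ts = np.array(
            [oracle_t(data[a, v], data[c, v]) for v in range(data.shape[1])]
        )
        ts = ts[np.isfinite(ts)]
        mins.append(ts.min())
        pcts.append(np.percentile(ts, q))
    return np.array(mins), np.array(pcts)


def test_null_summaries_match_hand_enumeration_2v2():
    cohort = make_random_cohort(4, shape=(3, 3, 3), seed=10)
    affected, control = _groups(cohort, 2)
    observed = t_map(cohort, affected, control)
    config = PermutationConfig(n_permutations=5, seed=0)
    nulls = build_null_summaries(cohort, affected, control, observed, config)
    oracle_min, oracle_pct = _enumerated_t_summaries(cohort, 2)
    assert nulls["min_stat"].exhaustive
    np.testing.assert_allclose(
        np.sort(nulls["min_stat"].summary_values), np.sort(oracle_min), atol=1e-10
    )
    np.testing.assert_allclose(
        np.sort(nulls["perm_percentile"].summary_values), np.sort(oracle_pct), atol=1e-10
    )


def test_min_summary_never_exceeds_percentile_summary():
    cohort = make_random_cohort(12, shape=(4, 4, 4), seed=11)
    affected, control = _groups(cohort, 6)
    observed = t_map(cohort, affected, control)
    config = PermutationConfig(n_permutations=100, seed=3, exhaustive_limit=1)
    nulls = build_null_summaries(cohort, affected, control, observed, config)
    assert (
        nulls["min_stat"].summary_values <= nulls["perm_percentile"].summary_values + 1e-12
    ).all()


def test_single_valid_voxel_degeneracy():
    """With one informative voxel the min and percentile nulls coincide."""
    rng = np.random.default_rng(12)
    vols = []
    for _ in range(8):
        v = np.zeros((3, 3, 3))
        v[1, 1, 1] = rng.random()
        vols.append(v)
    cohort = make_cohort(vols, shape=(3, 3, 3))
    affected, control = _groups(cohort, 4)
    observed = t_map(cohort, affected, control)
    assert observed.valid.sum() == 1
    config = PermutationConfig(n_permutations=30, seed=4)
    nulls = build_null_summaries(cohort, affected, control, observed, config)
    np.testing.assert_allclose(
        nulls["min_stat"].summary_values, nulls["perm_percentile"].summary_values
    )


def test_fwe_p_values_monte_carlo_floor_and_ceiling():
    cohort = make_random_cohort(12, shape=(4, 4, 4), seed=13)
    affected, control = _groups(cohort, 6)
    observed = t_map(cohort, affected, control)
    config = PermutationConfig(n_permutations=99, seed=5, exhaustive_limit=1)
    null = build_null(cohort, affected, control, observed, config)
    pmap = p_map_fwe(observed, null)
    p = pmap.values[pmap.valid]
    assert p.min() >= 1.0 / 100.0  # never zero with the (+1)/(+1) correction
    assert p.max() <= 1.0
    # an artificial +5 observation is milder than every left-tail summary
    fake_values = observed.values.copy()
    fake_values[observed.valid] = 5.0
    from vlsm.voxelstats import StatMap

    fake = StatMap(
        values=fake_values,
        valid=observed.valid,
        statistic_kind="t",
        group_sizes=observed.group_sizes,
    )
    assert (p_map_fwe(fake, null).values[observed.valid] == 1.0).all()


def test_exhaustive_p_of_perfectly_separating_voxel():
    """2v2 toy with one informative voxel: only the identity assignment is
    as extreme as the observation, so p = 1/6 under the min-stat null."""
    vols = []
    for value in (0.9, 1.0, 0.0, 0.1):  # affected lesioned, controls not
        v = np.zeros((3, 3, 3))
        v[0, 0, 0] = value
        vols.append(v)
    cohort = make_cohort(vols, shape=(3, 3, 3))
    affected, control = _groups(cohort, 2)
    observed = t_map(cohort, affected, control)
    config = PermutationConfig(n_permutations=10, seed=0, mode="min_stat")
    null = build_null(cohort, affected, control, observed, config)
    assert null.exhaustive and null.permutation_count == 6
    pmap = p_map_fwe(observed, null)
    assert pmap.values[0, 0, 0] == pytest.approx(1.0 / 6.0)


def test_fwe_rejects_mismatched_provenance():
    cohort = make_random_cohort(10, shape=(3, 3, 3), seed=14)
    observed = t_map(cohort, *_groups(cohort, 5))
    other = t_map(cohort, *_groups(cohort, 4))
    config = PermutationConfig(n_permutations=20, seed=0, exhaustive_limit=1)
    null = build_null(cohort, *_groups(cohort, 5), observed, config)
    with pytest.raises(ValidationError):
        p_map_fwe(other, null)
    rr_observed = rr_map(cohort, *_groups(cohort, 5))
    with pytest.raises(ValidationError):
        p_map_fwe(rr_observed, null)


# ---------------------------------------------------------------------------
# per-voxel permutation test


def _enumerated_rr_p(cohort, n_a, threshold=0.03):
    """Oracle: exhaustive per-voxel RR permutation p with ties extreme."""
    data = cohort.data.reshape(len(cohort), -1)
    B = data >= threshold
    n = len(cohort)
    n_c = n - n_a
    combos = list(combinations(range(n), n_a))
    obs_a = B[:n_a].sum(axis=0)
    obs_c = B[n_a:].sum(axis=0)
    p = np.full(data.shape[1], np.nan)
    for v in range(data.shape[1]):
        if obs_a[v] + obs_c[v] == 0:
            continue

        def rr(a_count, c_count):
            if c_count == 0:
                return math.inf
            return (a_count / n_a) / (c_count / n_c)

        observed = rr(obs_a[v], obs_c[v])
        count = 0
        for combo in combos:
            a_count = int(B[list(combo), v].sum())
            c_count = int(obs_a[v] + obs_c[v] - a_count)
            if rr(a_count, c_count) >= observed:
                count += 1
        p[v] = count / len(combos)
    return p


def test_pervoxel_rr_p_matches_enumeration_3v3():
    cohort = make_random_cohort(6, shape=(3, 3, 3), seed=15)
    affected, control = _groups(cohort, 3)
    observed = rr_map(cohort, affected, control)
    config = PermutationConfig(n_permutations=7, seed=0)
    pmap = p_map_pervoxel(cohort, affected, control, observed, config)
    assert pmap.exhaustive and pmap.n_permutations == 20  # C(6,3)
    oracle = _enumerated_rr_p(cohort, 3).reshape(3, 3, 3)
    np.testing.assert_allclose(pmap.values[pmap.valid], oracle[pmap.valid])
    # exhaustive p-values are exact multiples of 1/20
    assert np.allclose(np.mod(pmap.values[pmap.valid] * 20, 1.0), 0.0)


def test_pervoxel_constant_statistic_gives_p_one():
    # every subject lesioned at the voxel -> RR = 1 under all relabelings
    cohort = make_cohort([1.0] * 6)
    affected, control = _groups(cohort, 3)
    observed = rr_map(cohort, affected, control)
    config = PermutationConfig(n_permutations=15, seed=1)
    pmap = p_map_pervoxel(cohort, affected, control, observed, config)
    assert (pmap.values[pmap.valid] == 1.0).all()


def test_pervoxel_monte_carlo_floor():
    rng = np.random.default_rng(16)
    vols = [rng.random((3, 3, 3)) * 0.2 for _ in range(12)]
    for i in range(6):
        vols[i][0, 0, 0] = 0.9  # affected all lesioned at the target voxel
    for i in range(6, 12):
        vols[i][0, 0, 0] = 0.0
    cohort = make_cohort(vols, shape=(3, 3, 3))
    affected, control = _groups(cohort, 6)
    observed = rr_map(cohort, affected, control)
    config = PermutationConfig(n_permutations=50, seed=2, exhaustive_limit=1)
    pmap = p_map_pervoxel(cohort, affected, control, observed, config)
    # +inf observed; only relabelings reproducing the exact split tie it
    assert pmap.values[0, 0, 0] <= (1 + 5) / 51.0
    assert pmap.values[0, 0, 0] >= 1.0 / 51.0


def test_pervoxel_deterministic_given_seed():
    cohort = make_random_cohort(14, shape=(4, 4, 4), seed=17)
    affected, control = _groups(cohort, 7)
    observed = rr_map(cohort, affected, control)
    config = PermutationConfig(n_permutations=40, seed=9, exhaustive_limit=1)
    p1 = p_map_pervoxel(cohort, affected, control, observed, config)
    p2 = p_map_pervoxel(cohort, affected, control, observed, config)
    np.testing.assert_array_equal(p1.values[p1.valid], p2.values[p2.valid])


def test_randomized_pvalues_between_strict_and_conservative():
    cohort = make_random_cohort(10, shape=(4, 4, 4), seed=18)
    affected, control = _groups(cohort, 5)
    observed = rr_map(cohort, affected, control)
    config = PermutationConfig(n_permutations=60, seed=3, exhaustive_limit=1)
    pmap = p_map_pervoxel(cohort, affected, control, observed, config)
    smoothed = randomized_uniform_pvalues(pmap, np.random.default_rng(0))
    conservative = pmap.values[pmap.valid]
    strict_floor = pmap.strict_counts[pmap.valid] / (pmap.n_permutations + 1)
    assert (smoothed <= conservative + 1e-12).all()
    assert (smoothed >= strict_floor - 1e-12).all()


# ---------------------------------------------------------------------------
# q-values, thresholding, parametric reference


def _pmap_from_vector(p):
    from vlsm.inference import PValueMap

    values = np.full((len(p), 1, 1), np.nan)
    values[:, 0, 0] = p
    return PValueMap(values=values, valid=np.isfinite(values), method="test")


def test_bh_step_up_hand_example():
    qmap = q_values(_pmap_from_vector([0.01, 0.02, 0.03, 0.04]))
    np.testing.assert_allclose(qmap.values[qmap.valid], [0.04, 0.04, 0.04, 0.04])


def test_bh_equal_p_and_dominance():
    qmap = q_values(_pmap_from_vector([0.2, 0.2, 0.2]))
    np.testing.assert_allclose(qmap.values[qmap.valid], [0.2, 0.2, 0.2])
    rng = np.random.default_rng(19)
    p = rng.random(50)
    qmap = q_values(_pmap_from_vector(p))
    assert (qmap.values[qmap.valid] >= p - 1e-15).all()
    # agreement with an independent step-up implementation
    order = np.argsort(p)
    m = len(p)
    staircase = p[order] * m / np.arange(1, m + 1)
    oracle = np.minimum.accumulate(staircase[::-1])[::-1].clip(max=1.0)
    np.testing.assert_allclose(qmap.values[qmap.valid][order], oracle, atol=1e-12)


def test_threshold_map_strict_inequality():
    pmap = _pmap_from_vector([0.049, 0.05, 0.2, 0.9])
    sig = threshold_map(pmap, 0.05)
    assert sig[0, 0, 0] and not sig[1, 0, 0]
    assert threshold_map(pmap, 0.05).sum() == 1
    with pytest.raises(ConfigError):
        threshold_map(pmap, 1.5)


def test_threshold_of_all_invalid_map_is_empty():
    from vlsm.inference import PValueMap

    values = np.full((2, 2, 2), np.nan)
    pmap = PValueMap(values=values, valid=np.zeros((2, 2, 2), bool), method="x")
    assert not threshold_map(pmap, 0.2).any()


def test_parametric_p_left_tail_orientation():
    cohort = make_random_cohort(12, shape=(4, 4, 4), seed=20)
    observed = t_map(cohort, *_groups(cohort, 6))
    pmap = parametric_p_map(observed)
    t = observed.values[observed.valid]
    p = pmap.values[pmap.valid]
    # more negative t must mean smaller p
    order = np.argsort(t)
    assert (np.diff(p[order]) >= -1e-12).all()
    assert p[np.argmin(t)] == p.min()
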