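"""OMI/WitOMI niche statistics: decomposition, ordination, permutation tests."""

import numpy as np
import pandas as pd
import pytest

from isgarden.niche import (
    SubsetPartition,
    delineate_subsets,
    environment_pca,
    omi,
    omi_permutation_test,
    standardize_env,
    subset_significance,
    variable_significance,
    witomi,
)

GARDENS = [f"g{i}" for i in range(9)]


def _random_tables(seed, n_is=6, n_var=5, n_gardens=9):
    rng = np.random.default_rng(seed)
    env = pd.DataFrame(
        rng.normal(size=(n_gardens, n_var)),
        index=[f"g{i}" for i in range(n_gardens)],
        columns=[f"v{j}" for j in range(n_var)],
    )
    abund = pd.DataFrame(
        rng.integers(0, 20, size=(n_is, n_gardens)),
        index=[f"is{i}" for i in range(n_is)],
        columns=env.index,
    )
    abund.iloc[:, 0] += 1  # ensure nonzero rows
    return env, abund


# ---------------------------------------------------------------------------
# standardization


def test_standardize_small_column():
    env = pd.DataFrame({"v": [1.0, 2.0, 3.0]}, index=list("abc"))
    z = standardize_env(env)["v"].values
    assert z == pytest.approx([-1.224745, 0.0, 1.224745], abs=1e-6)


def test_standardize_idempotent():
    env, _ = _random_tables(0)
    z1 = standardize_env(env)
    z2 = standardize_env(z1)
    assert np.allclose(z1.values, z2.values)


def test_standardize_drops_constant_columns():
    env = pd.DataFrame({"v": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]}, index=list("abc"))
    with pytest.warns(UserWarning, match="constant"):
        z = standardize_env(env)
    assert list(z.columns) == ["v"]
    with pytest.raises(ValueError):
        standardize_env(env[["c"]])


# ---------------------------------------------------------------------------
# OMI decomposition


def test_omi_indifferent_species_has_zero_marginality():
    env = pd.DataFrame({"v": [1.0, 2.0, 3.0]}, index=list("abc"))
    abund = pd.DataFrame([[4, 4, 4]], index=["is1"], columns=list("abc"))
    res = omi(abund, standardize_env(env))
    assert res.params.loc["is1", "omi"] == pytest.approx(0.0, abs=1e-12)


def test_omi_single_garden_toy_value():
    # all counts in the garden at z = +1.2247 -> OMI = 1.5
    env = pd.DataFrame({"v": [1.0, 2.0, 3.0]}, index=list("abc"))
    abund = pd.DataFrame([[0, 0, 4]], index=["is1"], columns=list("abc"))
    res = omi(abund, standardize_env(env))
    assert res.params.loc["is1", "omi"] == pytest.approx(1.5)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_omi_inertia_decomposition_identity(seed):
    env, abund = _random_tables(seed)
    res = omi(abund, standardize_env(env))
    p = res.params
    resid = (p["inertia"] - (p["omi"] + p["tol"] + p["rtol"])).abs()
    assert (resid <= 1e-10 * p["inertia"].clip(lower=1.0)).all()


def test_omi_eigenvalue_sum_is_mean_marginality():
    env, abund = _random_tables(7)
    res = omi(abund, standardize_env(env))
    mean_marg = (res.params["weight"] * res.params["omi"]).sum()
    assert res.eigenvalues.sum() == pytest.approx(mean_marg, rel=1e-10)
    assert res.variance_explained.sum() == pytest.approx(100.0, abs=1e-8)
    # axes orthonormal
    A = res.axes.values
    assert np.allclose(A.T @ A, np.eye(A.shape[1]), atol=1e-10)


def test_omi_excludes_empty_rows():
    env, abund = _random_tables(3)
    abund.iloc[2] = 0
    with pytest.warns(UserWarning, match="zero total"):
        res = omi(abund, standardize_env(env))
    assert "is2" not in res.params.index


def test_environment_pca_shares():
    env, _ = _random_tables(5)
    Z = standardize_env(env)
    evals, pct, scores = environment_pca(Z)
    assert pct.sum() == pytest.approx(100.0)
    assert evals.sum() == pytest.approx(Z.shape[1], rel=1e-10)  # standardized total
    assert (np.diff(pct) <= 1e-12).all()


# ---------------------------------------------------------------------------
# permutation tests


def test_permutation_uniform_species_never_significant():
    env = pd.DataFrame({"v": np.arange(9.0)}, index=GARDENS)
    abund = pd.DataFrame([[3] * 9], index=["is1"], columns=GARDENS)
    out = omi_permutation_test(abund, standardize_env(env), n_perm=199, seed=0)
    assert out.loc["is1", "p"] == 1.0


def test_permutation_uniquely_optimal_arrangement_reaches_floor():
    # counts graded to match the env gradient: only the identity arrangement
    # (up to reflection) attains the observed marginality, so the empirical
    # p-value sits at its 1/(n_perm+1) floor.
    env = pd.DataFrame({"v": np.arange(9.0)}, index=GARDENS)
    abund = pd.DataFrame(
        [[1, 2, 3, 4, 6, 9, 16, 40, 128]], index=["is1"], columns=GARDENS
    )
    out = omi_permutation_test(abund, standardize_env(env), n_perm=999, seed=1)
    assert out.loc["is1", "p"] == pytest.approx(1 / 1000)


def test_permutation_reproducible_bit_for_bit():
    env, abund = _random_tables(11)
    Z = standardize_env(env)
    a = omi_permutation_test(abund, Z, n_perm=299, seed=5)
    b = omi_permutation_test(abund, Z, n_perm=299, seed=5)
    pd.testing.assert_frame_equal(a, b)
    c = omi_permutation_test(abund, Z, n_perm=299, seed=6)
    assert not a["p"].equals(c["p"])


# ---------------------------------------------------------------------------
# delineation


def test_delineation_separated_pairs():
    Z = pd.DataFrame({"v": [0.0, 0.1, 10.0, 10.1]}, index=list("abcd"))
    part = delineate_subsets(Z, 2)
    assert part.labels.tolist() == [1, 1, 2, 2]
    assert part.origins.loc[1, "v"] == pytest.approx(0.05)


def test_delineation_three_triplets():
    Z = pd.DataFrame(
        {"v": [0, 0.2, 0.1, 5, 5.1, 5.2, 10, 10.1, 10.2]}, index=GARDENS
    )
    part = delineate_subsets(Z, 3)
    assert part.labels.tolist() == [1, 1, 1, 2, 2, 2, 3, 3, 3]


def test_delineation_k_bounds():
    Z = pd.DataFrame({"v": [0.0, 1.0, 2.0]}, index=list("abc"))
    with pytest.raises(ValueError):
        delineate_subsets(Z, 3)


# ---------------------------------------------------------------------------
# WitOMI


def _one_block_partition(Z):
    labels = pd.Series(1, index=Z.index, name="subset")
    origins = pd.DataFrame([Z.mean(axis=0)], index=pd.Index([1], name="subset"))
    return SubsetPartition(labels=labels, origins=origins, linkage_matrix=None, k=1)


def test_witomi_degenerate_partition_equals_omi():
    env, abund = _random_tables(2)
    Z = standardize_env(env)
    res = omi(abund, Z)
    wit = witomi(abund, Z, _one_block_partition(Z), n_perm=99, seed=0)
    for is_id in abund.index:
        assert wit.loc[(is_id, 1), "witomi_g"] == pytest.approx(
            res.params.loc[is_id, "omi"], rel=1e-10
        )


def test_witomi_uniform_within_subset_is_central():
    env, _ = _random_tables(4)
    Z = standardize_env(env)
    part = delineate_subsets(Z, 2)
    counts = pd.Series(0, index=Z.index)
    counts.loc[part.members(1)] = 5  # uniform over subset 1's gardens
    abund = pd.DataFrame([counts.values], index=["is1"], columns=Z.index)
    wit = witomi(abund, Z, part, n_perm=99, seed=0)
    assert wit.loc[("is1", 1), "witomi_gk"] == pytest.approx(0.0, abs=1e-12)
    assert not wit.loc[("is1", 2), "present"]
    assert np.isnan(wit.loc[("is1", 2), "witomi_g"])


def test_witomi_subcentroid_decomposition_identity():
    env, abund = _random_tables(8)
    Z = standardize_env(env)
    res = omi(abund, Z)
    part = delineate_subsets(Z, 3)
    for is_id, y in abund.iterrows():
        total = y.sum()
        u = np.zeros(Z.shape[1])
        for kk in range(1, 4):
            members = part.members(kk)
            y_k = y.loc[members]
            if y_k.sum() == 0:
                continue
            w = y_k.values / y_k.sum()
            u += (y_k.sum() / total) * (w @ Z.loc[members].values)
        assert u == pytest.approx(res.centroids.loc[is_id].values, abs=1e-10)


# ---------------------------------------------------------------------------
# subset / variable significance


def test_subset_significance_floor_on_separated_clusters():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 0.2, (5, 3)), rng.normal(8, 0.2, (4, 3))])
    Z = standardize_env(pd.DataFrame(X, index=GARDENS, columns=list("uvw")))
    part = delineate_subsets(Z, 2)
    res = subset_significance(Z, part, n_perm=199, seed=0)
    assert all(r.p <= 5 / 200 for r in res.values())
    # the labelled Gaussian tail approximation is far smaller than the floor
    assert all(r.p_normal_approx < r.p for r in res.values())


def test_variable_significance_constant_column():
    env = pd.DataFrame(
        {"v": [0, 0, 0, 0, 9, 9, 9, 9, 9.0], "c": np.zeros(9)}, index=GARDENS
    )
    Z = env.copy()  # bypass standardization to keep the constant column
    part = SubsetPartition(
        labels=pd.Series([1] * 4 + [2] * 5, index=GARDENS, name="subset"),
        origins=pd.DataFrame(
            {1: env.iloc[:4].mean(), 2: env.iloc[4:].mean()}
        ).T,
        linkage_matrix=None,
        k=2,
    )
    res = variable_significance(Z, part, n_perm=199, seed=0)
    assert res["c"].p == 1.0
    assert res["v"].p == pytest.approx(1 / 200)
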