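"""Outlying mean index (OMI) niche statistics for IS communities.

The nine common gardens are sites, the intracellular variables (reporter
GC%, replicon GC%, enzyme activity, IS copy numbers, available target
sites) are niche dimensions, and the IS-by-garden insertion counts are the
species-by-sites abundance table.  For each IS the abundance-weighted mean
position of the gardens it occupies — its realized-niche centroid — is
compared with the origin of the standardized environmental space (the
average habitat, G).  The squared distance of the centroid from G is the
outlying mean index (marginality); the remaining inertia splits into
tolerance (spread along the marginality direction) and residual tolerance.

Subniche (WitOMI) statistics repeat the computation after the environmental
space is delineated into subsets of gardens by Ward clustering, measuring
each IS's centroid within a subset against either the global origin G or
the subset origin G_K.

Significance is assessed by Monte-Carlo permutation: each IS's count vector
is shuffled across gardens (or across a subset's gardens), under the null
hypothesis that the IS is indifferent to its intracellular environment, and
p = (1 + exceedances) / (n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import norm

__all__ = [
    "OMIResult",
    "SubsetPartition",
    "PermutationTestResult",
    "standardize_env",
    "environment_pca",
    "omi",
    "omi_permutation_test",
    "delineate_subsets",
    "witomi",
    "subset_significance",
    "variable_significance",
]


@dataclass
class OMIResult:
    """OMI ordination output.

    ``params`` has one row per IS: total inertia, OMI (marginality),
    tolerance, residual tolerance, and weight (share of all counts).
    ``centroids`` holds the niche centroids u_i in standardized variable
    space; ``axes`` the ordination eigenvectors (variables x axes);
    ``variance_explained`` is in percent and sums to 100.
    """

    Z: pd.DataFrame
    params: pd.DataFrame
    centroids: pd.DataFrame
    eigenvalues: np.ndarray
    axes: pd.DataFrame
    variance_explained: np.ndarray
    is_scores: pd.DataFrame
    garden_scores: pd.DataFrame


@dataclass
class SubsetPartition:
    """Garden -> subset labels from Ward delineation, with subset origins G_k."""

    labels: pd.Series
    origins: pd.DataFrame
    linkage_matrix: np.ndarray | None
    k: int

    def members(self, subset: int) -> list[str]:
        return list(self.labels.index[self.labels == subset])


@dataclass
class PermutationTestResult:
    statistic: str
    observed: float
    n_perm: int
    seed: int
    p: float
    null_mean: float
    null_sd: float
    null_max: float
    #: Gaussian tail approximation from the null mean/sd; reported because an
    #: empirical p cannot fall below 1/(n_perm+1). Approximate — use with care.
    p_normal_approx: float = field(default=float("nan"))


# ---------------------------------------------------------------------------


def standardize_env(env: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each variable (uniform garden weights, 1/n divisor).

    Constant columns carry no gradient and are dropped with a warning; an
    all-constant table is an error.  After standardization the grand
    centroid G is the origin and every column has variance 1.
    """
    env = env.astype(float)
    if env.isna().any().any():
        raise ValueError("environment table contains missing entries")
    sd = env.std(axis=0, ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        if len(constant) == env.shape[1]:
            raise ValueError("all environment columns are constant")
        warnings.warn(f"dropping constant environment columns: {constant}")
        env = env.drop(columns=constant)
        sd = sd.drop(index=constant)
    return (env - env.mean(axis=0)) / sd


def environment_pca(Z: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """PCA of the standardized environmental space (uniform garden weights).

    Returns ``(eigenvalues, percent_variance, garden_scores)`` for the
    1/n-weighted covariance of the standardized table — the intracellular
    environmental gradients on which niches are read.
    """
    Zv = Z.values.astype(float)
    C = Zv.T @ Zv / Zv.shape[0]
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    rank = min(Zv.shape[0] - 1, Zv.shape[1])
    evals, evecs = evals[:rank], evecs[:, :rank]
    pct = 100.0 * evals / evals.sum()
    scores = pd.DataFrame(
        Zv @ evecs,
        index=Z.index,
        columns=[f"PC{k + 1}" for k in range(evecs.shape[1])],
    )
    return evals, pct, scores


def _check_aligned(abund: pd.DataFrame, Z: pd.DataFrame) -> None:
    if list(abund.columns) != list(Z.index):
        raise ValueError(
            "abundance columns and environment rows must list the same gardens "
            f"in the same order; got {list(abund.columns)} vs {list(Z.index)}"
        )


def _drop_empty(abund: pd.DataFrame) -> pd.DataFrame:
    empty = abund.index[abund.sum(axis=1) == 0].tolist()
    if empty:
        warnings.warn(f"excluding ISs with zero total count: {empty}")
        abund = abund.drop(index=empty)
    if abund.empty:
        raise ValueError("no IS has a nonzero count")
    return abund


def _omi_components(w: np.ndarray, Zv: np.ndarray):
    """(centroid, inertia, omi, tol, rtol) for one weight vector w (sums to 1)."""
    u = w @ Zv
    omi_i = float(u @ u)
    inertia = float(w @ (Zv * Zv).sum(axis=1))
    if omi_i > 0:
        uhat = u / np.sqrt(omi_i)
        proj = (Zv - u) @ uhat
        tol = float(w @ proj**2)
    else:
        # marginality direction undefined: all breadth is residual
        tol = 0.0
    rtol = inertia - omi_i - tol
    return u, inertia, omi_i, tol, rtol


def omi(abund: pd.DataFrame, Z: pd.DataFrame) -> OMIResult:
    """OMI ordination: per-IS marginality decomposition and niche axes.

    For IS i with garden counts y_ij, profile weights w_ij = y_ij / y_i+
    give the niche centroid u_i = sum_j w_ij z_j.  The per-IS inertia
    I_i = sum_j w_ij ||z_j||^2 decomposes exactly as
    I_i = OMI_i + Tol_i + Rtol_i.  The ordination axes are the eigenvectors
    of the abundance-weighted centroid cross-product sum_i pi_i u_i u_i^T
    (pi_i = IS i's share of all counts), so the eigenvalue sum equals the
    weighted mean marginality and each axis's share is its percentage of
    separability explained.
    """
    _check_aligned(abund, Z)
    abund = _drop_empty(abund.astype(float))
    Zv = Z.values.astype(float)
    n_var = Zv.shape[1]

    rows, centroids = [], []
    for is_id, y in abund.iterrows():
        w = y.values / y.values.sum()
        u, inertia, omi_i, tol, rtol = _omi_components(w, Zv)
        centroids.append(u)
        rows.append(
            {"inertia": inertia, "omi": omi_i, "tol": tol, "rtol": rtol}
        )
    params = pd.DataFrame(rows, index=abund.index)
    params["weight"] = abund.sum(axis=1) / abund.values.sum()
    centroids = pd.DataFrame(centroids, index=abund.index, columns=Z.columns)

    U = centroids.values
    pi = params["weight"].values
    S = (U * pi[:, None]).T @ U
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    n_axes = min(n_var, len(abund))
    evals, evecs = evals[:n_axes], evecs[:, :n_axes]
    # sign convention: largest-loading variable positive on each axis
    for k in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    total = evals.sum()
    var_explained = 100.0 * evals / total if total > 0 else np.zeros_like(evals)

    axis_names = [f"OMI{k + 1}" for k in range(len(evals))]
    axes = pd.DataFrame(evecs, index=Z.columns, columns=axis_names)
    is_scores = pd.DataFrame(U @ evecs, index=abund.index, columns=axis_names)
    garden_scores = pd.DataFrame(Zv @ evecs, index=Z.index, columns=axis_names)
    return OMIResult(
        Z=Z,
        params=params,
        centroids=centroids,
        eigenvalues=evals,
        axes=axes,
        variance_explained=var_explained,
        is_scores=is_scores,
        garden_scores=garden_scores,
    )


def _perm_null_omi(
    y: np.ndarray, Zv: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null OMI values from uniform random permutations of one count vector."""
    n = len(y)
    w = y / y.sum()
    idx = np.tile(np.arange(n), (n_perm, 1))
    idx = rng.permuted(idx, axis=1)
    U = w[idx] @ Zv  # (n_perm, n_var) null centroids
    return (U * U).sum(axis=1)


def omi_permutation_test(
    abund: pd.DataFrame,
    Z: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-IS Monte-Carlo test of niche marginality.

    Null: the IS is indifferent to its environment — its count vector is
    randomly permuted across gardens.  One seeded generator is used and
    permutations are drawn IS-by-IS in row order, so results are
    bit-reproducible given (seed, n_perm).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    _check_aligned(abund, Z)
    abund = _drop_empty(abund.astype(float))
    Zv = Z.values.astype(float)
    rng = np.random.default_rng(seed)
    rows = []
    for is_id, y in abund.iterrows():
        w = y.values / y.values.sum()
        u = w @ Zv
        obs = float(u @ u)
        null = _perm_null_omi(y.values, Zv, n_perm, rng)
        r = _test_result("omi", obs, null, n_perm, seed)
        rows.append(
            {
                "is_id": is_id,
                "omi": obs,
                "p": r.p,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "null_max": r.null_max,
                "p_normal_approx": r.p_normal_approx,
            }
        )
    return pd.DataFrame(rows).set_index("is_id")


def _test_result(
    label: str, obs: float, null: np.ndarray, n_perm: int, seed: int
) -> PermutationTestResult:
    p = (1.0 + float((null >= obs - 1e-12).sum())) / (n_perm + 1.0)
    mean, sd = float(null.mean()), float(null.std(ddof=0))
    p_gauss = float(norm.sf((obs - mean) / sd)) if sd > 0 else float("nan")
    return PermutationTestResult(
        statistic=label,
        observed=obs,
        n_perm=n_perm,
        seed=seed,
        p=p,
        null_mean=mean,
        null_sd=sd,
        null_max=float(null.max()),
        p_normal_approx=p_gauss,
    )


# ---------------------------------------------------------------------------
# Subset delineation and WitOMI


def delineate_subsets(Z: pd.DataFrame, k: int) -> SubsetPartition:
    """Split the environmental space into k subsets by Ward clustering.

    Agglomerative minimum-variance (Ward) linkage on Euclidean distances
    between standardized garden rows, cut at k clusters.  Labels are
    renumbered 1..k in order of first appearance along the input row order,
    making the partition deterministic.
    """
    n = Z.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < {n} gardens")
    lm = linkage(Z.values, method="ward")
    raw = fcluster(lm, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    labels = pd.Series([relabel[lab] for lab in raw], index=Z.index, name="subset")
    origins = pd.DataFrame(
        {kk: Z.loc[labels == kk].mean(axis=0) for kk in range(1, k + 1)}
    ).T
    origins.index.name = "subset"
    return SubsetPartition(labels=labels, origins=origins, linkage_matrix=lm, k=k)


def witomi(
    abund: pd.DataFrame,
    Z: pd.DataFrame,
    part: SubsetPartition,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Subniche (WitOMI) statistics per IS per subset.

    Within subset K the IS's counts are restricted to K's gardens and
    renormalized; the sub-centroid u_iK is scored against the global origin
    G (``witomi_g``) and against the subset origin G_K (``witomi_gk``).
    Permutation nulls shuffle the restricted counts within the subset's
    gardens only.  An IS with no counts in a subset is reported as absent
    (NaN statistics) — absence is not indifference.

    The sub-centroids decompose the global centroid exactly:
    sum_K f_iK * u_iK = u_i, with f_iK the IS's count share in subset K.
    """
    _check_aligned(abund, Z)
    abund = _drop_empty(abund.astype(float))
    rng = np.random.default_rng(seed)
    rows = []
    for is_id, y in abund.iterrows():
        total = y.values.sum()
        for kk in range(1, part.k + 1):
            gardens = part.members(kk)
            y_k = y.loc[gardens].values
            g_k = part.origins.loc[kk].values
            Zk = Z.loc[gardens].values
            row = {
                "is_id": is_id,
                "subset": kk,
                "present": bool(y_k.sum() > 0),
                "count_share": float(y_k.sum() / total),
            }
            if y_k.sum() == 0:
                row.update(
                    {
                        "witomi_g": float("nan"),
                        "witomi_gk": float("nan"),
                        "p_g": float("nan"),
                        "p_gk": float("nan"),
                    }
                )
            else:
                w = y_k / y_k.sum()
                u = w @ Zk
                wg = float(u @ u)
                d = u - g_k
                wgk = float(d @ d)
                if len(gardens) > 1:
                    idx = rng.permuted(
                        np.tile(np.arange(len(gardens)), (n_perm, 1)), axis=1
                    )
                    Unull = w[idx] @ Zk
                    null_g = (Unull * Unull).sum(axis=1)
                    Dnull = Unull - g_k
                    null_gk = (Dnull * Dnull).sum(axis=1)
                    p_g = _test_result("witomi_g", wg, null_g, n_perm, seed).p
                    p_gk = _test_result("witomi_gk", wgk, null_gk, n_perm, seed).p
                else:
                    p_g = p_gk = 1.0
                row.update({"witomi_g": wg, "witomi_gk": wgk, "p_g": p_g, "p_gk": p_gk})
            rows.append(row)
    return pd.DataFrame(rows).set_index(["is_id", "subset"])


def _between_inertia_per_subset(Zv: np.ndarray, labels: np.ndarray, k: int):
    """Per-subset contribution n_k * ||g_k||^2 to the between-subset inertia."""
    out = np.empty(k)
    for kk in range(1, k + 1):
        members = Zv[labels == kk]
        if len(members) == 0:
            out[kk - 1] = 0.0
        else:
            g = members.mean(axis=0)
            out[kk - 1] = len(members) * float(g @ g)
    return out


def subset_significance(
    Z: pd.DataFrame,
    part: SubsetPartition,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[int, PermutationTestResult]:
    """Monte-Carlo test of each subset's environmental distinctness.

    Statistic: the subset's contribution n_k ||g_k - G||^2 to the
    between-subset inertia (G is the origin of the standardized space).
    Null: garden -> subset labels are randomly permuted.
    """
    Zv = Z.values.astype(float)
    labels = part.labels.values
    rng = np.random.default_rng(seed)
    observed = _between_inertia_per_subset(Zv, labels, part.k)
    null = np.empty((n_perm, part.k))
    for b in range(n_perm):
        null[b] = _between_inertia_per_subset(Zv, rng.permutation(labels), part.k)
    return {
        kk: _test_result(f"subset_{kk}_between_inertia", observed[kk - 1], null[:, kk - 1], n_perm, seed)
        for kk in range(1, part.k + 1)
    }


def variable_significance(
    Z: pd.DataFrame,
    part: SubsetPartition,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, PermutationTestResult]:
    """Monte-Carlo test of each variable's contribution to the delineation.

    Statistic: the between-subset variance share of the column (the
    fraction of the variable's total sum of squares explained by subset
    membership).  Null: permuted garden -> subset labels.  A constant
    column has no information: p = 1.
    """
    labels = part.labels.values
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(labels) for _ in range(n_perm)]
    results: dict[str, PermutationTestResult] = {}
    for col in Z.columns:
        z = Z[col].values.astype(float)
        sst = float(z @ z)
        if sst == 0:
            results[col] = PermutationTestResult(
                statistic=f"variable_{col}_r2",
                observed=0.0,
                n_perm=n_perm,
                seed=seed,
                p=1.0,
                null_mean=0.0,
                null_sd=0.0,
                null_max=0.0,
            )
            continue

        def r2(lab: np.ndarray) -> float:
            ssb = 0.0
            for kk in range(1, part.k + 1):
                zz = z[lab == kk]
                if len(zz):
                    ssb += len(zz) * float(zz.mean() ** 2)
            return ssb / sst

        obs = r2(labels)
        null = np.array([r2(lab) for lab in perms])
        results[col] = _test_result(f"variable_{col}_r2", obs, null, n_perm, seed)
    return results
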