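"""Multivariate community-change battery.

Annual mean abundance matrix -> Bray-Curtis resemblance -> (i) non-metric
multidimensional scaling by majorization with isotonic regression of the
dissimilarity ranks (Kruskal stress-1), (ii) a seriation (RELATE-style)
permutation test of sequential temporal structure via the Spearman matrix
correlation between the community dissimilarities and an ideal time-ordered
distance model, and (iii) a similarity-profile (SIMPROF) permutation test on
a group-average dendrogram to delimit statistically significant year groups.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.optimize import isotonic_regression
from scipy.stats import rankdata

from .synth import CELL_COLUMNS

TRANSFORMS = ("none", "sqrt", "fourth_root")


# ---------------------------------------------------------------------------
# Community matrix and resemblance
# ---------------------------------------------------------------------------

@dataclass
class CommunityMatrix:
    """Samples (years, increasing) x species mean-abundance matrix."""

    labels: list[int]
    species: list[str]
    values: np.ndarray  # shape (n_samples, n_species), >= 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("community matrix entries must be non-negative")
        if list(self.labels) != sorted(self.labels):
            raise ValueError("sample labels (years) must be increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.species)


@dataclass
class DissimilarityMatrix:
    labels: list
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("dissimilarity diagonal must be zero")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def annual_mean_matrix(fish: pd.DataFrame) -> CommunityMatrix:
    """Mean count of each species over the transects sampled in each year.

    The per-year denominator is the number of distinct transects with any
    record in that year (visual-census transects always yield records, so
    the table's distinct transects are the sampled roster); species absent
    from a sampled transect contribute zeros to the mean.
    """
    years = sorted(fish["year"].unique())
    if len(years) < 2:
        raise ValueError("need at least 2 years for a community matrix")
    key = fish[CELL_COLUMNS].astype(str).agg("|".join, axis=1)
    n_transects = fish.assign(_cell=key).groupby("year")["_cell"].nunique()
    totals = fish.pivot_table(index="year", columns="species", values="count",
                              aggfunc="sum", fill_value=0)
    means = totals.div(n_transects, axis=0)
    means = means.loc[years]
    return CommunityMatrix(labels=[int(y) for y in years],
                           species=list(means.columns),
                           values=means.to_numpy())


def _apply_transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform not in TRANSFORMS:
        raise ValueError(f"transform must be one of {TRANSFORMS}")
    if transform == "sqrt":
        return np.sqrt(values)
    if transform == "fourth_root":
        return values ** 0.25
    return values


def _bc_condensed(x: np.ndarray) -> np.ndarray:
    """Condensed Bray-Curtis distances of the rows of ``x`` (2-D) or of each
    dataset in a batch (3-D, leading axis = datasets). All-zero row pairs
    are 0 by convention."""
    batched = x.ndim == 3
    X = x if batched else x[None]
    n = X.shape[1]
    i_idx, j_idx = np.triu_indices(n, k=1)
    num = np.abs(X[:, i_idx] - X[:, j_idx]).sum(axis=-1)
    den = (X[:, i_idx] + X[:, j_idx]).sum(axis=-1)
    with np.errstate(invalid="ignore"):
        d = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return d if batched else d[0]


def bray_curtis(matrix: CommunityMatrix, transform: str = "none") -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity between samples after an optional
    abundance transform; d = sum|x - y| / sum(x + y), 0 for two empty rows."""
    x = _apply_transform(matrix.values, transform)
    n = x.shape[0]
    cond = _bc_condensed(x)
    full = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    full[iu] = cond
    full += full.T
    return DissimilarityMatrix(labels=list(matrix.labels), values=full)


# ---------------------------------------------------------------------------
# Non-metric MDS
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    coords: np.ndarray           # (n, dims), centred, unit RMS
    stress: float                # Kruskal stress-1 of the best restart
    labels: list
    n_restarts: int
    best_restart: int
    converged: bool
    stress_traces: list[np.ndarray] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coords.shape[1])]
        return pd.DataFrame(self.coords, index=self.labels, columns=cols)


def _pairwise_dist(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff ** 2).sum(-1))
    iu = np.triu_indices(X.shape[0], k=1)
    return D[iu]


def _stress1(dist: np.ndarray, order: np.ndarray) -> tuple[float, np.ndarray]:
    """Kruskal stress-1 and the monotone disparities for configuration
    distances ``dist`` given the ascending dissimilarity ``order``."""
    disp = np.empty_like(dist)
    disp[order] = isotonic_regression(dist[order], increasing=True).x
    denom = float((dist ** 2).sum())
    if denom <= 0:
        return 0.0, disp
    return math.sqrt(float(((dist - disp) ** 2).sum()) / denom), disp


def _classical_mds(full: np.ndarray, dims: int) -> np.ndarray:
    n = full.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (full ** 2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:dims]
    lam = np.clip(w[idx], 0.0, None)
    return V[:, idx] * np.sqrt(lam)


def nmds(
    d: DissimilarityMatrix,
    dims: int = 2,
    restarts: int = 50,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | np.random.Generator | None = None,
) -> OrdinationResult:
    """Kruskal-style non-metric MDS.

    Each restart alternates isotonic regression of the dissimilarity ranks
    onto configuration distances with a Guttman majorization update (with a
    step-halving guard so stress-1 never increases along the trace). The
    first restart is initialised from classical (metric) scaling, the rest
    at random; the lowest-stress configuration is returned, centred and
    scaled to unit RMS.
    """
    n = d.n
    if n < 3:
        raise ValueError("nMDS needs at least 3 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    diss = d.condensed()
    order = np.argsort(diss, kind="stable")
    iu = np.triu_indices(n, k=1)

    best = None
    traces: list[np.ndarray] = []
    any_converged = False
    for r in range(restarts):
        if r == 0:
            X = _classical_mds(d.values, dims)
            if np.allclose(X, 0):
                X = rng.normal(size=(n, dims))
        else:
            X = rng.normal(size=(n, dims))
        dist = _pairwise_dist(X)
        stress, disp = _stress1(dist, order)
        trace = [stress]
        converged = False
        for _ in range(max_iter):
            # Guttman transform with current disparities
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dist > 0, disp / np.maximum(dist, 1e-300), 0.0)
            B = np.zeros((n, n))
            B[iu] = -ratio
            B += B.T
            np.fill_diagonal(B, -B.sum(axis=1))
            X_new = B @ X / n
            dist_new = _pairwise_dist(X_new)
            stress_new, disp_new = _stress1(dist_new, order)
            # step-halving guard: stress-1 must not increase
            halved = 0
            while stress_new > stress and halved < 12:
                X_new = 0.5 * (X_new + X)
                dist_new = _pairwise_dist(X_new)
                stress_new, disp_new = _stress1(dist_new, order)
                halved += 1
            if stress_new > stress:
                converged = True
                break
            X, dist, disp = X_new, dist_new, disp_new
            improvement = stress - stress_new
            stress = stress_new
            trace.append(stress)
            if improvement < tol:
                converged = True
                break
        traces.append(np.array(trace))
        any_converged = any_converged or converged
        # a configuration that merges samples whose dissimilarity is not
        # itself near zero satisfies the rank criterion vacuously (classic
        # nMDS cluster collapse); prefer non-degenerate restarts
        scale = dist.max()
        diss_scale = diss.max()
        degenerate = bool(scale == 0 or np.any(
            (dist < 1e-4 * scale) & (diss > 1e-4 * diss_scale)))
        key = (degenerate, stress)
        if best is None or key < best[0]:
            best = (key, X.copy(), r)

    (_, stress), X, best_r = best
    X = X - X.mean(axis=0)
    rms = math.sqrt(float((X ** 2).sum()) / n)
    if rms > 0:
        X = X / rms
    return OrdinationResult(coords=X, stress=float(stress), labels=list(d.labels),
                            n_restarts=restarts, best_restart=best_r,
                            converged=any_converged, stress_traces=traces)


# ---------------------------------------------------------------------------
# Seriation (RELATE) test
# ---------------------------------------------------------------------------

@dataclass
class SeriationResult:
    rho: float
    p: float
    n_perm: int
    exact: bool
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {"rho": self.rho, "p": self.p, "n_perm": self.n_perm,
                "exact": self.exact, "degenerate": self.degenerate}


def _spearman_to_model(cond: np.ndarray, model_ranks: np.ndarray) -> float:
    r = rankdata(cond)
    rc = r - r.mean()
    mc = model_ranks - model_ranks.mean()
    denom = math.sqrt(float((rc ** 2).sum()) * float((mc ** 2).sum()))
    return float((rc * mc).sum() / denom)


def relate_seriation(
    d: DissimilarityMatrix,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    method: str = "auto",
) -> SeriationResult:
    """Test for sequential temporal structure in a dissimilarity matrix.

    The seriation model matrix is m(i, j) = |i - j| over the rank positions
    of the samples' declared temporal order (the matrix label order). rho is
    the Spearman (midrank) correlation between the off-diagonal upper
    triangles of d and m; the null distribution comes from relabelling the
    samples. ``method`` 'exact' enumerates all n! relabellings (automatic
    for n <= 7), 'sampled' draws n_perm random ones with the add-one
    correction p = (1 + #{rho_perm >= rho_obs}) / (1 + n_perm).
    """
    n = d.n
    if n < 3:
        raise ValueError("seriation test needs at least 3 samples")
    iu = np.triu_indices(n, k=1)
    model = np.abs(iu[0] - iu[1]).astype(float)
    model_ranks = rankdata(model)
    cond = d.values[iu]
    if np.allclose(cond, cond[0]):
        return SeriationResult(rho=0.0, p=1.0, n_perm=0, exact=True, degenerate=True)

    rho_obs = _spearman_to_model(cond, model_ranks)
    if method not in ("auto", "exact", "sampled"):
        raise ValueError("method must be auto, exact or sampled")
    exact = method == "exact" or (method == "auto" and math.factorial(n) <= 5040)

    if exact:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            p_arr = np.array(perm)
            cond_p = d.values[np.ix_(p_arr, p_arr)][iu]
            if _spearman_to_model(cond_p, model_ranks) >= rho_obs - 1e-12:
                count += 1
            total += 1
        return SeriationResult(rho=rho_obs, p=count / total, n_perm=total, exact=True)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        cond_p = d.values[np.ix_(perm, perm)][iu]
        if _spearman_to_model(cond_p, model_ranks) >= rho_obs - 1e-12:
            count += 1
    return SeriationResult(rho=rho_obs, p=(1 + count) / (1 + n_perm),
                           n_perm=n_perm, exact=False)


# ---------------------------------------------------------------------------
# SIMPROF
# ---------------------------------------------------------------------------

@dataclass
class SimprofNode:
    node_id: int
    members: list
    pi: float | None
    p: float | None
    tested: bool
    significant: bool


@dataclass
class SimprofResult:
    groups: list[list]           # partition of the sample labels
    alpha: float
    linkage_matrix: np.ndarray
    labels: list
    nodes: list[SimprofNode] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_groups": self.n_groups,
            "groups": [[int(x) if isinstance(x, (int, np.integer)) else x for x in g]
                       for g in self.groups],
            "nodes": [{"node_id": nd.node_id, "members": list(nd.members),
                       "pi": nd.pi, "p": nd.p, "tested": nd.tested,
                       "significant": nd.significant} for nd in self.nodes],
        }


def _permuted_profiles(x: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Sorted Bray-Curtis profiles of ``n_perm`` datasets obtained by
    permuting each species' values independently across samples."""
    m, p = x.shape
    idx = np.argsort(rng.random((n_perm, m, p)), axis=1)
    permuted = x[idx, np.arange(p)[None, None, :]]
    d = _bc_condensed(permuted)
    d.sort(axis=1)
    return d


def _simprof_test(x: np.ndarray, n_perm_profile: int, n_perm_test: int,
                  rng: np.random.Generator) -> tuple[float, float]:
    obs = np.sort(_bc_condensed(x))
    mean_profile = _permuted_profiles(x, n_perm_profile, rng).mean(axis=0)
    pi_obs = float(np.abs(obs - mean_profile).sum())
    pi_null = np.abs(_permuted_profiles(x, n_perm_test, rng) - mean_profile).sum(axis=1)
    p = (1 + int((pi_null >= pi_obs - 1e-12).sum())) / (1 + n_perm_test)
    return pi_obs, p


def simprof(
    matrix: CommunityMatrix,
    transform: str = "none",
    alpha: float = 0.05,
    n_perm_profile: int = 999,
    n_perm_test: int = 999,
    seed: int | np.random.Generator | None = None,
) -> SimprofResult:
    """Similarity-profile test for statistically significant sample groups.

    Group-average hierarchical clustering on Bray-Curtis dissimilarities;
    at each node (root first) the similarity-profile statistic
    pi = sum_k |s_(k) - sbar_(k)| compares the node's ordered dissimilarities
    with their expectation under independent permutation of each species
    across the node's samples (first permutation set); the node p-value
    comes from a second, independent permutation set. Recursion descends
    only through significant nodes; the leaves of the stopped recursion are
    the groups at level ``alpha``.
    """
    if matrix.values.shape[0] < 2:
        raise ValueError("SIMPROF needs at least 2 samples")
    max_p = 1.0 / (1 + n_perm_test)
    if max_p > alpha:
        warnings.warn(
            f"n_perm_test={n_perm_test} cannot attain p < alpha={alpha}; "
            "no split can be declared significant", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = _apply_transform(matrix.values, transform)
    cond = _bc_condensed(x)
    Z = linkage(cond, method="average")
    root = to_tree(Z)

    labels = list(matrix.labels)
    groups: list[list] = []
    nodes: list[SimprofNode] = []

    def visit(node):
        members_idx = node.pre_order(lambda leaf: leaf.id)
        members = [labels[i] for i in sorted(members_idx)]
        if node.is_leaf() or len(members_idx) < 2:
            groups.append(members)
            return
        sub = x[sorted(members_idx)]
        if np.allclose(sub.std(axis=0), 0.0):
            # identical rows: nothing to test, one homogeneous group
            nodes.append(SimprofNode(node.get_id(), members, 0.0, 1.0, True, False))
            groups.append(members)
            return
        pi_obs, p = _simprof_test(sub, n_perm_profile, n_perm_test, rng)
        significant = p < alpha
        nodes.append(SimprofNode(node.get_id(), members, pi_obs, p, True, significant))
        if significant:
            visit(node.get_left())
            visit(node.get_right())
        else:
            groups.append(members)

    visit(root)
    return SimprofResult(groups=groups, alpha=alpha, linkage_matrix=Z,
                         labels=labels, nodes=nodes)
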