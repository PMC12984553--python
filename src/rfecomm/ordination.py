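"""Distance matrices, principal coordinates, and PERMANOVA.

Community dissimilarity is Bray-Curtis, ``d(u, v) = sum|u_i - v_i| /
sum(u_i + v_i)``; trait and abundance dissimilarities are Euclidean
(absolute differences for scalar traits). PCoA embeds a distance matrix by
eigendecomposition of the Gower-centered squared-distance matrix
``-1/2 J D^2 J``; negative eigenvalues are reported and excluded from the
proportion-explained denominator (Lingoes correction available).

PERMANOVA follows Anderson's one-way pseudo-F computed directly from
pairwise squared distances::

    SS_total  = sum_{i<j} d_ij^2 / N
    SS_within = sum_g sum_{i<j in g} d_ij^2 / n_g
    F = (SS_between / (a - 1)) / (SS_within / (N - a))

with significance from label permutations: ``p = (1 + #{F_perm >= F_obs})
/ (1 + n_permutations)``, deterministic under a seed. Pairwise PERMANOVA
runs every unordered group pair on its sub-matrix, with optional
Benjamini-Hochberg adjustment across pairs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .io import sample_groups

__all__ = [
    "bray_curtis",
    "euclidean",
    "species_profiles",
    "PcoaResult",
    "pcoa",
    "PermanovaResult",
    "permanova",
    "pairwise_permanova",
    "group_centroids",
]


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between the rows of an abundance table."""
    values = table.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative abundances")
    zero = values.sum(axis=1) == 0
    if zero.any():
        raise ValueError(
            "all-zero row(s) make Bray-Curtis undefined: "
            + ", ".join(map(str, table.index[zero]))
        )
    d = squareform(pdist(values, metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(i) for i in table.index])


def euclidean(values: pd.Series | pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance between items; absolute difference for scalars."""
    if isinstance(values, pd.Series):
        frame = values.to_frame()
    else:
        frame = values
    arr = frame.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        bad = frame.index[~np.isfinite(arr).all(axis=1)]
        raise ValueError("non-finite value(s) for item(s): " + ", ".join(map(str, bad)))
    d = squareform(pdist(arr, metric="euclidean"))
    return DistanceMatrix(d, ids=[str(i) for i in frame.index])


def species_profiles(
    table: pd.DataFrame, metadata: pd.DataFrame, how: str = "mean"
) -> pd.DataFrame:
    """Aggregate replicate samples to one community profile per species.

    ``how="mean"`` (default) averages per-sample relative abundances over a
    species' replicates; ``how="pool"`` sums raw counts and renormalizes.
    """
    species = metadata["species"].reindex(table.index)
    if species.isna().any():
        raise ValueError("samples missing from metadata")
    if how == "mean":
        rel = table.div(table.sum(axis=1), axis=0)
        return rel.groupby(species.to_numpy()).mean()
    if how == "pool":
        pooled = table.groupby(species.to_numpy()).sum()
        return pooled.div(pooled.sum(axis=1), axis=0)
    raise ValueError("how must be 'mean' or 'pool'")


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # items x axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # per retained axis, over positive eigenvalues
    negative_eigenvalues: np.ndarray
    correction: str | None = None


def pcoa(d: DistanceMatrix, n_axes: int | None = None, correction: str | None = None) -> PcoaResult:
    """Principal coordinates of a distance matrix.

    Eigendecomposition of ``-1/2 J D^2 J`` with ``J = I - 11'/n``. Axes are
    ordered by descending eigenvalue and scaled by the square root of the
    eigenvalue; negative eigenvalues are excluded from both the coordinates
    and the proportion-explained denominator. ``correction="lingoes"`` adds
    the constant that renders all eigenvalues nonnegative.
    """
    D = np.asarray(d.data, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 items")
    D2 = D**2
    if correction == "lingoes":
        # provisional eigenvalues to find the additive constant
        B0 = _gower_center(D2)
        eig0 = np.linalg.eigvalsh(B0)
        c = max(0.0, -eig0.min())
        if c > 0:
            off = ~np.eye(n, dtype=bool)
            D2 = D2 + 2.0 * c * off
    elif correction is not None:
        raise ValueError("correction must be None or 'lingoes'")
    B = _gower_center(D2)
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10 * max(abs(eigvals[0]), 1.0), 0.0)
    positive = eigvals > tol
    n_pos = int(positive.sum())
    if n_axes is None:
        n_axes = n_pos
    elif n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        n_axes = n_pos
    coords = eigvecs[:, :n_axes] * np.sqrt(eigvals[:n_axes])
    pos_sum = eigvals[positive].sum()
    proportion = eigvals[:n_axes] / pos_sum if pos_sum > 0 else np.zeros(n_axes)
    return PcoaResult(
        coordinates=pd.DataFrame(
            coords, index=list(d.ids), columns=[f"PCo{i + 1}" for i in range(n_axes)]
        ),
        eigenvalues=eigvals,
        proportion_explained=proportion,
        negative_eigenvalues=eigvals[eigvals < -tol],
        correction=correction,
    )


def _gower_center(D2: np.ndarray) -> np.ndarray:
    n = D2.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * J @ D2 @ J


def group_centroids(coordinates: pd.DataFrame, grouping: pd.Series) -> pd.DataFrame:
    """Group centroids and standard errors in ordination axis space."""
    g = grouping.reindex(coordinates.index)
    agg = coordinates.groupby(g.to_numpy()).agg(["mean", "sem"])
    agg.columns = [f"{axis}_{stat}" for axis, stat in agg.columns]
    return agg


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    statistic: float  # pseudo-F
    r_squared: float  # SS_between / SS_total
    p_value: float
    n_permutations: int
    groups: tuple[str, ...] = field(default_factory=tuple)
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        self.groups = tuple(self.groups)


def _group_codes(grouping, ids) -> tuple[np.ndarray, list]:
    g = pd.Series(grouping)
    if set(g.index.astype(str)) >= set(map(str, ids)):
        g.index = g.index.astype(str)
        g = g.reindex([str(i) for i in ids])
    elif len(g) != len(ids):
        raise ValueError("grouping does not cover the distance matrix ids")
    codes, levels = pd.factorize(g.to_numpy())
    return codes, list(levels)


def _ss_parts(D2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = D2.shape[0]
    ss_total = D2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        members = codes == g
        n_g = int(members.sum())
        ss_within += D2[np.ix_(members, members)].sum() / (2.0 * n_g)
    return ss_total, ss_within


def _pseudo_f(ss_total: float, ss_within: float, n: int, a: int) -> float:
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    d: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``grouping`` is a mapping/Series from item id to group label (or a
    sequence aligned with ``d.ids``). The permutation test permutes labels
    only; the p-value has resolution ``1 / (n_permutations + 1)``.
    """
    codes, levels = _group_codes(grouping, d.ids)
    a = len(levels)
    n = len(codes)
    if a < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes, minlength=a)
    if (counts < 2).any():
        small = [levels[i] for i in np.flatnonzero(counts < 2)]
        raise ValueError("group(s) with fewer than 2 members: " + ", ".join(map(str, small)))
    D2 = np.asarray(d.data, dtype=float) ** 2
    ss_total, ss_within = _ss_parts(D2, codes, a)
    if ss_total <= 1e-300:
        # all items identical: no variation to partition
        return PermanovaResult(
            statistic=0.0,
            r_squared=0.0,
            p_value=1.0,
            n_permutations=n_permutations,
            groups=tuple(map(str, levels)),
        )
    f_obs = _pseudo_f(ss_total, ss_within, n, a)
    r2 = (ss_total - ss_within) / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    # one batched matrix product per group across all permutations
    perms = rng.permuted(np.tile(codes, (n_permutations, 1)), axis=1)
    ss_within_perm = np.zeros(n_permutations)
    for g in range(a):
        M = (perms == g).astype(float)  # R x N membership
        quad = np.einsum("rn,rn->r", M @ D2, M)  # sum of D2 within group g
        ss_within_perm += quad / (2.0 * counts[g])
    f_perm = ((ss_total - ss_within_perm) / (a - 1)) / (ss_within_perm / (n - a))
    p = (1.0 + np.sum(f_perm >= f_obs)) / (1.0 + n_permutations)
    return PermanovaResult(
        statistic=float(f_obs),
        r_squared=float(r2),
        p_value=float(p),
        n_permutations=n_permutations,
        groups=tuple(map(str, levels)),
    )


def pairwise_permanova(
    d: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int | None = None,
    adjust: str = "bh",
) -> list[PermanovaResult]:
    """Two-group PERMANOVA for every unordered group pair.

    Each pair's test runs on the sub-matrix of that pair's members.
    ``adjust="bh"`` (default) adds Benjamini-Hochberg adjusted p-values
    across pairs; raw p-values are always reported.
    """
    if adjust not in ("bh", "none"):
        raise ValueError("adjust must be 'bh' or 'none'")
    codes, levels = _group_codes(grouping, d.ids)
    ids = np.asarray(d.ids)
    rng = np.random.default_rng(seed)
    results = []
    for a, b in itertools.combinations(range(len(levels)), 2):
        members = np.isin(codes, [a, b])
        sub = d.filter(ids[members])
        sub_groups = pd.Series(codes[members], index=ids[members]).map(
            {a: str(levels[a]), b: str(levels[b])}
        )
        res = permanova(
            sub,
            sub_groups,
            n_permutations=n_permutations,
            seed=int(rng.integers(2**31 - 1)),
        )
        results.append(res)
    if adjust == "bh" and results:
        adjusted = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, p_adj in zip(results, adjusted):
            r.p_adjusted = float(p_adj)
    return results
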