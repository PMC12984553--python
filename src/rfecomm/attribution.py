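"""Attribution of community turnover to trait and abundance differences.

The design has one row per unordered species pair drawn from *different*
functional groups: the response is the Bray-Curtis dissimilarity between
the two species' replicate-aggregated community profiles, and each
predictor is the absolute difference of one trait (nitrogen, root length,
root biomass, C:N, water content) or of field abundance.

Importance is estimated with a random-forest regression: %IncMSE is the
mean percentage increase in out-of-bag (OOB) mean squared error when a
predictor's values are permuted among each tree's OOB rows. Significance
comes from refitting the forest on response-permuted copies of the design
and comparing null importances with the observed one::

    p = (1 + #{null %IncMSE >= observed}) / (1 + n_null_reps)

Pair-level rows are not independent (each species enters many pairs); the
test is reported as-is with that caveat attached to the result.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .io import TRAIT_COLUMNS, validate_traits
from .ordination import bray_curtis, species_profiles

__all__ = ["build_pair_design", "ImportanceResult", "fit_importance"]

NONINDEPENDENCE_NOTE = (
    "Species-pair rows are non-independent (each species enters many pairs); "
    "p-values are anti-conservative in that respect."
)


def build_pair_design(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    traits: pd.DataFrame,
    profile_how: str = "mean",
) -> pd.DataFrame:
    """Cross-group species-pair design for the importance model.

    One row per unordered pair of species from different groups; columns
    ``species_a/species_b/group_a/group_b``, the Bray-Curtis response, and
    one absolute-difference predictor per trait column.
    """
    traits = validate_traits(traits)
    species_group = metadata.drop_duplicates("species").set_index("species")["group"]
    missing = pd.Index(species_group.index).difference(traits.index)
    if len(missing):
        raise ValueError("species missing trait records: " + ", ".join(map(str, missing)))
    profiles = species_profiles(table, metadata, how=profile_how)
    dm = bray_curtis(profiles)
    rows = []
    species = list(profiles.index)
    for sa, sb in itertools.combinations(species, 2):
        ga, gb = species_group[sa], species_group[sb]
        if ga == gb:
            continue
        row = {
            "species_a": sa,
            "species_b": sb,
            "group_a": ga,
            "group_b": gb,
            "bray_curtis": dm[sa, sb],
        }
        for trait in TRAIT_COLUMNS:
            row[trait] = abs(traits.loc[sa, trait] - traits.loc[sb, trait])
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ImportanceResult:
    """Per-predictor %IncMSE with permutation significance."""

    importance: pd.DataFrame  # predictor, pct_inc_mse, p_value, significance
    oob_mse: float
    n_trees: int
    mtry: int
    n_null_reps: int
    seed: int | None
    note: str = NONINDEPENDENCE_NOTE

    def top_predictor(self) -> str:
        return str(self.importance.iloc[0]["predictor"])


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


class _Forest:
    """Bagged regression trees with per-tree bootstrap bookkeeping."""

    def __init__(self, n_trees: int, mtry: int, rng: np.random.Generator):
        self.n_trees = n_trees
        self.mtry = mtry
        self.rng = rng
        self.trees: list[DecisionTreeRegressor] = []
        self.oob_masks: list[np.ndarray] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_Forest":
        n = len(y)
        self.trees.clear()
        self.oob_masks.clear()
        for _ in range(self.n_trees):
            idx = self.rng.integers(0, n, n)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            tree = DecisionTreeRegressor(
                max_features=self.mtry,
                random_state=int(self.rng.integers(2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            self.trees.append(tree)
            self.oob_masks.append(oob)
        return self

    def oob_importance(self, X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
        """Raw OOB permutation importance per predictor and overall OOB MSE.

        Returns mean over trees of (permuted OOB MSE - OOB MSE) per
        predictor, plus the mean per-tree OOB MSE.
        """
        n, p = X.shape
        X32 = np.ascontiguousarray(X, dtype=np.float32)
        inc = np.zeros(p)
        base = 0.0
        used = 0
        for tree, oob in zip(self.trees, self.oob_masks):
            m = int(oob.sum())
            if m == 0:
                continue
            Xo = X32[oob]
            yo = y[oob]
            pred = tree.predict(Xo, check_input=False)
            mse0 = float(np.mean((yo - pred) ** 2))
            # one stacked predict call covers all predictors' permutations
            Xp = np.repeat(Xo[None, :, :], p, axis=0)
            for j in range(p):
                Xp[j, :, j] = self.rng.permutation(Xo[:, j])
            preds = tree.predict(
                np.ascontiguousarray(Xp.reshape(p * m, p)), check_input=False
            ).reshape(p, m)
            msep = np.mean((yo[None, :] - preds) ** 2, axis=1)
            inc += msep - mse0
            base += mse0
            used += 1
        if used == 0:
            raise RuntimeError("no out-of-bag rows; increase the design size")
        return inc / used, base / used


def _importance_once(
    X: np.ndarray, y: np.ndarray, n_trees: int, mtry: int, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    forest = _Forest(n_trees, mtry, rng).fit(X, y)
    inc, mse = forest.oob_importance(X, y)
    return 100.0 * inc / mse, mse  # percent increase relative to OOB MSE


def fit_importance(
    design: pd.DataFrame,
    n_trees: int = 500,
    mtry: int | None = None,
    n_null_reps: int = 100,
    seed: int | None = None,
    response: str = "bray_curtis",
    predictors: tuple[str, ...] | None = None,
) -> ImportanceResult:
    """Random-forest %IncMSE with response-permutation p-values.

    ``mtry`` defaults to ``max(1, n_predictors // 3)`` (the regression
    convention). Deterministic under ``seed``. p-values are bounded below
    by ``1 / (n_null_reps + 1)``.
    """
    if predictors is None:
        predictors = tuple(c for c in TRAIT_COLUMNS if c in design.columns)
        if not predictors:
            predictors = tuple(
                c
                for c in design.columns
                if c not in ("species_a", "species_b", "group_a", "group_b", response)
            )
    if len(predictors) < 2:
        raise ValueError("need at least 2 predictors")
    if len(design) < 30:
        raise ValueError("need at least 30 pair rows")
    X = design[list(predictors)].to_numpy(dtype=float)
    y = design[response].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    p = X.shape[1]
    if mtry is None:
        mtry = max(1, p // 3)
    if mtry > p:
        raise ValueError("mtry exceeds the number of predictors")

    rng = np.random.default_rng(seed)
    observed, oob_mse = _importance_once(X, y, n_trees, mtry, rng)
    exceed = np.zeros(p)
    for _ in range(n_null_reps):
        y_null = rng.permutation(y)
        null_imp, _ = _importance_once(X, y_null, n_trees, mtry, rng)
        exceed += null_imp >= observed
    pvals = (1.0 + exceed) / (1.0 + n_null_reps)

    frame = pd.DataFrame(
        {
            "predictor": predictors,
            "pct_inc_mse": observed,
            "p_value": pvals,
            "significance": [_stars(v) for v in pvals],
        }
    ).sort_values("pct_inc_mse", ascending=False, ignore_index=True)
    return ImportanceResult(
        importance=frame,
        oob_mse=float(oob_mse),
        n_trees=n_trees,
        mtry=mtry,
        n_null_reps=n_null_reps,
        seed=seed,
    )
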