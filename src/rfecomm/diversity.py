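"""Rarefaction, alpha diversity, and group-difference GLMs.

Rarefaction subsamples each sample's reads without replacement (a
multivariate hypergeometric draw) down to a common depth, by default the
minimum observed sample depth. Alpha diversity is OTU richness and Shannon
entropy in nats. Group differences are tested with generalized linear
models — Poisson/log for richness, Gaussian/identity for Shannon — and
summarized as a compact letter display: groups sharing a letter do not
differ at the chosen alpha.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import sample_groups, validate_otu_table

__all__ = [
    "rarefy",
    "alpha_diversity",
    "GlmFit",
    "fit_group_glm",
    "pairwise_group_pvalues",
    "LetterDisplay",
    "letters",
    "group_summary",
]


def rarefy(table: pd.DataFrame, depth: int | str = "min", seed: int | None = None) -> pd.DataFrame:
    """Subsample every sample to a common depth without replacement.

    ``depth="min"`` resolves to the minimum sample total. Samples whose total
    is below an explicit requested depth raise, naming the offenders. The
    draw is multivariate hypergeometric per sample (each retained read drawn
    from the sample's reads), deterministic under ``seed``.
    """
    table = validate_otu_table(table)
    totals = table.sum(axis=1)
    if depth == "min":
        target = int(totals.min())
    else:
        target = int(depth)
        if target <= 0:
            raise ValueError("rarefaction depth must be positive")
        shallow = totals.index[totals < target]
        if len(shallow):
            raise ValueError(
                f"sample(s) below requested depth {target}: "
                + ", ".join(map(str, shallow))
            )
    rng = np.random.default_rng(seed)
    out = np.empty(table.shape, dtype=np.int64)
    values = table.to_numpy()
    for i in range(values.shape[0]):
        out[i] = rng.multivariate_hypergeometric(values[i], target)
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def alpha_diversity(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample OTU richness and Shannon entropy (nats).

    Richness counts OTUs with nonzero counts; Shannon is
    ``H = -sum p_i ln p_i`` over the nonzero count proportions. An all-zero
    sample yields richness 0 and Shannon 0 with a warning.
    """
    table = validate_otu_table(table, allow_empty_samples=True)
    values = table.to_numpy(dtype=float)
    totals = values.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(
            "all-zero sample(s): " + ", ".join(map(str, table.index[empty])),
            stacklevel=2,
        )
    richness = (values > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = values / np.where(empty, 1.0, totals)[:, None]
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    shannon[empty] = 0.0
    return pd.DataFrame(
        {"richness": richness.astype(np.int64), "shannon": shannon}, index=table.index
    )


@dataclass
class GlmFit:
    """A fitted one-factor GLM of a per-sample metric on functional group."""

    family: str  # "poisson" or "gaussian"
    result: "sm.regression.linear_model.RegressionResultsWrapper"
    groups: list[str]
    reference: str

    @property
    def coefficients(self) -> pd.Series:
        return self.result.params

    @property
    def pvalues(self) -> pd.Series:
        return self.result.pvalues

    def deviance_path(self) -> list[float]:
        """Deviance at each IRLS iteration (monotone nonincreasing)."""
        hist = self.result.fit_history
        return [float(d) for d in hist["deviance"]]


_FAMILIES = {
    "poisson": lambda: sm.families.Poisson(),
    "gaussian": lambda: sm.families.Gaussian(),
}


def _design(groups: pd.Series, levels: list[str]) -> pd.DataFrame:
    X = pd.DataFrame({"intercept": 1.0}, index=groups.index)
    for level in levels[1:]:
        X[f"group[{level}]"] = (groups == level).astype(float)
    return X


def fit_group_glm(
    values: pd.Series,
    metadata: pd.DataFrame | None,
    family: str = "poisson",
) -> GlmFit:
    """Fit ``metric ~ group`` by IRLS with the requested family.

    Poisson (log link) for integer responses such as richness; Gaussian
    (identity link) for continuous responses such as Shannon diversity.
    The first group in sorted order is the reference level.
    ``metadata=None`` fits the intercept-only model (no group factor).
    """
    if family not in _FAMILIES:
        raise ValueError(f"family must be one of {sorted(_FAMILIES)}")
    y = values.astype(float)
    if family == "poisson" and not np.allclose(y, np.round(y)):
        raise ValueError("poisson family requires integer responses")
    if metadata is None:
        X = pd.DataFrame({"intercept": 1.0}, index=values.index)
        model = sm.GLM(y, X, family=_FAMILIES[family]())
        result = model.fit(tol=1e-8)
        if not result.converged:
            raise RuntimeError("GLM did not converge")
        return GlmFit(family=family, result=result, groups=[], reference="")
    groups = sample_groups(metadata, values.index)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    counts = groups.value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    if family == "poisson" and any(y[groups == g].sum() == 0 for g in levels):
        warnings.warn("group with all-zero response: log-link estimate diverges", stacklevel=2)
    X = _design(groups, levels)
    model = sm.GLM(y, X, family=_FAMILIES[family]())
    result = model.fit(tol=1e-8)
    if not result.converged:
        raise RuntimeError("GLM did not converge")
    return GlmFit(family=family, result=result, groups=levels, reference=levels[0])


def pairwise_group_pvalues(fit: GlmFit) -> pd.DataFrame:
    """Symmetric matrix of unadjusted pairwise Wald p-values between groups.

    Each pair's contrast is the difference of group coefficients from the
    single full-factor fit (z test under Poisson, t under Gaussian).
    """
    levels = fit.groups
    names = list(fit.result.params.index)
    pmat = pd.DataFrame(np.ones((len(levels), len(levels))), index=levels, columns=levels)
    for a, b in itertools.combinations(levels, 2):
        L = np.zeros(len(names))
        if a != fit.reference:
            L[names.index(f"group[{a}]")] = 1.0
        if b != fit.reference:
            L[names.index(f"group[{b}]")] -= 1.0
        test = fit.result.t_test(L)
        p = float(np.atleast_1d(test.pvalue)[0])
        pmat.loc[a, b] = pmat.loc[b, a] = p
    np.fill_diagonal(pmat.values, 1.0)
    return pmat


@dataclass
class LetterDisplay:
    """Compact letter display over groups at a significance threshold."""

    letters: dict[str, str]
    pvalues: pd.DataFrame
    alpha: float

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


def _absorb(columns: list[set[str]]) -> list[set[str]]:
    """Drop empty, duplicate, and strictly-absorbed letter columns."""
    uniq: list[set[str]] = []
    for c in columns:
        if c and c not in uniq:
            uniq.append(c)
    return [c for c in uniq if not any(c < d for d in uniq)]


def letters(pairwise_p: pd.DataFrame, alpha: float = 0.05) -> LetterDisplay:
    """Insert-and-absorb compact letter display.

    Two groups share a letter exactly when their pairwise test is
    nonsignificant at ``alpha``.
    """
    if not np.allclose(pairwise_p.to_numpy(), pairwise_p.to_numpy().T):
        raise ValueError("pairwise p-value matrix must be symmetric")
    groups = list(pairwise_p.index)
    columns: list[set[str]] = [set(groups)]
    for a, b in itertools.combinations(groups, 2):
        if pairwise_p.loc[a, b] >= alpha:
            continue
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend([col - {a}, col - {b}])
        columns = _absorb(columns)
    # assign letters in order of each column's first group
    columns.sort(key=lambda c: min(groups.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, col in zip(alphabet, columns):
        for g in col:
            out[g] += letter
    out = {g: "".join(sorted(s)) for g, s in out.items()}
    return LetterDisplay(letters=out, pvalues=pairwise_p, alpha=alpha)


def group_summary(
    values: pd.Series,
    metadata: pd.DataFrame,
    family: str = "poisson",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group means, standard errors, and significance letters for a metric."""
    fit = fit_group_glm(values, metadata, family=family)
    pmat = pairwise_group_pvalues(fit)
    disp = letters(pmat, alpha=alpha)
    groups = sample_groups(metadata, values.index)
    stats = values.groupby(groups.to_numpy()).agg(["mean", "sem", "count"])
    stats.columns = ["mean", "se", "n"]
    stats["letter"] = [disp.letters[g] for g in stats.index]
    return stats
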