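"""Specificity-occupancy (SPEC-OCCU) marker-OTU analysis.

For each OTU and each plant functional group H::

    specificity(OTU, H) = mean abundance of the OTU over H's samples
                          / sum over all groups of those group means
    occupancy(OTU, H)   = fraction of H's samples in which the OTU occurs

Specificity sums to 1 across groups for any OTU observed at least once;
occupancy lies in [0, 1]. An OTU is a *marker* of H when both statistics
are >= a threshold (0.7 by default, inclusive). Marker sets feed a
trophic-mode (guild) composition summary and a functional PERMANOVA.

Abundance here means counts as given — pass a rarefied table (recommended;
group means are depth-confounded otherwise) or relative abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io import UNASSIGNED, sample_groups, validate_otu_table
from .ordination import PermanovaResult, bray_curtis, pairwise_permanova

__all__ = [
    "spec_occu",
    "MarkerSet",
    "marker_sets",
    "recover_markers",
    "functional_composition",
    "functional_permanova",
]


def spec_occu(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    threshold: float = 0.7,
) -> pd.DataFrame:
    """Per-(OTU, group) specificity, occupancy, and marker flag.

    Returns a tidy frame with columns ``otu_id, group, specificity,
    occupancy, is_marker, undefined`` — one row per OTU x group. OTUs absent
    from every sample get specificity 0 in all groups and are flagged
    ``undefined``.
    """
    table = validate_otu_table(table, allow_empty_samples=True)
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    groups = sample_groups(metadata, table.index)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")

    codes = groups.to_numpy()
    group_means = table.groupby(codes).mean()  # group x OTU mean counts
    group_presence = (table > 0).groupby(codes).mean()  # group x OTU occupancy
    totals = group_means.sum(axis=0)  # per OTU, sum of group means
    undefined = totals == 0
    denom = totals.replace(0, 1.0)
    specificity = group_means.div(denom, axis=1)
    specificity.loc[:, undefined] = 0.0

    records = []
    for g in levels:
        spec_g = specificity.loc[g]
        occ_g = group_presence.loc[g]
        records.append(
            pd.DataFrame(
                {
                    "otu_id": table.columns,
                    "group": g,
                    "specificity": spec_g.to_numpy(),
                    "occupancy": occ_g.to_numpy(),
                    "undefined": undefined.to_numpy(),
                }
            )
        )
    out = pd.concat(records, ignore_index=True)
    out["is_marker"] = (out["specificity"] >= threshold) & (out["occupancy"] >= threshold)
    return out


@dataclass
class MarkerSet:
    """Per-group marker OTU lists and marker sequence fractions."""

    markers: dict[str, list[str]]  # group -> ordered marker otu ids
    sequence_fraction: dict[str, float]  # marker counts / total counts, per group


def marker_sets(records: pd.DataFrame, table: pd.DataFrame, metadata: pd.DataFrame) -> MarkerSet:
    """Collect flagged markers per group and their share of group sequences."""
    groups = sample_groups(metadata, table.index)
    markers: dict[str, list[str]] = {}
    fractions: dict[str, float] = {}
    for g, sub in records.groupby("group", sort=False):
        ids = sorted(sub.loc[sub["is_marker"], "otu_id"])
        markers[str(g)] = ids
        group_counts = table.loc[groups == g]
        total = group_counts.to_numpy().sum()
        fractions[str(g)] = float(group_counts[ids].to_numpy().sum() / total) if total else 0.0
    return MarkerSet(markers=markers, sequence_fraction=fractions)


def recover_markers(records: pd.DataFrame, truth: Mapping[str, list[str] | set[str]]) -> dict:
    """Score the marker flag against planted ground truth.

    Sensitivity = recovered planted (OTU, group) pairs / planted pairs;
    FDR = flagged pairs that were not planted / flagged pairs (0 when
    nothing is flagged).
    """
    flagged = {
        (row.otu_id, row.group) for row in records.loc[records["is_marker"]].itertuples()
    }
    planted = {(o, g) for g, otus in truth.items() for o in otus}
    tp = len(flagged & planted)
    sensitivity = tp / len(planted) if planted else float("nan")
    fdr = (len(flagged) - tp) / len(flagged) if flagged else 0.0
    return {
        "sensitivity": sensitivity,
        "fdr": fdr,
        "n_planted": len(planted),
        "n_flagged": len(flagged),
        "n_recovered": tp,
    }


def functional_composition(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    guilds: pd.Series,
    markers: MarkerSet,
    level: str = "group",
) -> pd.DataFrame:
    """Relative abundance over trophic-mode categories, marker OTUs only.

    Every distinct mode combination (e.g. ``Pathotroph-Saprotroph-Symbiotroph``)
    is its own category; multi-mode OTUs are not split across modes. Marker
    OTUs missing from the guild table count as ``Unassigned``. Rows are
    groups (``level="group"``, counts pooled within group) or samples
    (``level="sample"``); each nonzero row sums to 1.
    """
    if level not in ("group", "sample"):
        raise ValueError("level must be 'group' or 'sample'")
    marker_ids = sorted({o for ids in markers.markers.values() for o in ids})
    if not marker_ids:
        raise ValueError("no marker OTUs to summarize")
    sub = table[marker_ids]
    modes = guilds.reindex(marker_ids).fillna(UNASSIGNED)
    by_mode = sub.T.groupby(modes.to_numpy()).sum().T  # samples x mode categories
    if level == "group":
        groups = sample_groups(metadata, table.index)
        by_mode = by_mode.groupby(groups.to_numpy()).sum()
    totals = by_mode.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(
            "unit(s) with zero marker counts: " + ", ".join(map(str, by_mode.index[empty])),
            stacklevel=2,
        )
    return by_mode.div(totals.replace(0, 1.0), axis=0)


def functional_permanova(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    guilds: pd.Series,
    markers: MarkerSet,
    n_permutations: int = 999,
    seed: int | None = None,
    adjust: str = "bh",
) -> list[PermanovaResult]:
    """Pairwise PERMANOVA on Bray-Curtis distances of per-sample
    marker-OTU functional profiles."""
    fc = functional_composition(table, metadata, guilds, markers, level="sample")
    nonzero = fc.sum(axis=1) > 0
    if not nonzero.all():
        fc = fc.loc[nonzero]
    dm = bray_curtis(fc)
    grouping = sample_groups(metadata, fc.index)
    return pairwise_permanova(
        dm, grouping, n_permutations=n_permutations, seed=seed, adjust=adjust
    )
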