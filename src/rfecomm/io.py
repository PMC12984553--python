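"""Reading, validation, and writing of the pipeline's tabular inputs.

Five table kinds circulate through the pipeline, all tab-separated on disk
with a single header row and the identifier in the first column:

* **OTU table** — integer read counts, samples as rows, OTUs as columns.
* **Sample metadata** — sample -> (species, functional group, replicate).
* **Species traits** — per-species root traits and field abundance.
* **Taxonomy** — OTU -> phylum label (missing OTUs fall back to ``"Other"``).
* **Guilds** — OTU -> trophic-mode annotation (FUNGuild-style mode strings).

Tables are plain :class:`pandas.DataFrame`/:class:`~pandas.Series` objects;
the ``validate_*`` functions enforce the structural invariants and
``validate_dataset`` cross-checks label consistency between them.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TRAIT_COLUMNS",
    "METADATA_COLUMNS",
    "TROPHIC_MODES",
    "UNASSIGNED",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "read_traits",
    "write_traits",
    "read_taxonomy",
    "write_taxonomy",
    "read_guilds",
    "write_guilds",
    "validate_otu_table",
    "validate_metadata",
    "validate_traits",
    "validate_dataset",
    "canonical_modes",
    "water_content",
    "sample_groups",
    "phylum_relative_abundance",
]

#: Trait columns expected in a species-trait table, in canonical order.
#: Units: root_length cm, root_biomass g dry mass, water_content % fresh
#: mass, nitrogen mg g^-1 dry mass, cn_ratio dimensionless, abundance
#: individuals m^-2.
TRAIT_COLUMNS = (
    "root_length",
    "root_biomass",
    "water_content",
    "nitrogen",
    "cn_ratio",
    "abundance",
)

METADATA_COLUMNS = ("species", "group", "replicate")

#: Recognized single trophic modes, in the canonical rendering order.
TROPHIC_MODES = ("Pathotroph", "Saprotroph", "Symbiotroph")

UNASSIGNED = "Unassigned"


# ---------------------------------------------------------------------------
# validation


def _check_unique(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dupes = sorted(set(index[index.duplicated()].astype(str)))
        raise ValueError(f"duplicate {what} id(s): {', '.join(dupes)}")


def validate_otu_table(table: pd.DataFrame, allow_empty_samples: bool = False) -> pd.DataFrame:
    """Validate an OTU count table (samples x OTUs).

    Checks unique labels, nonnegative integer counts, and (by default) that
    every sample has at least one nonzero entry.
    """
    _check_unique(table.index, "sample")
    _check_unique(table.columns, "OTU")
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("OTU table contains non-numeric entries")
    if np.isnan(values.astype(float)).any():
        raise ValueError("OTU table contains missing values")
    if (values < 0).any():
        bad = table.index[(values < 0).any(axis=1)]
        raise ValueError(f"negative counts in sample(s): {', '.join(map(str, bad))}")
    if not np.allclose(values, np.round(values)):
        raise ValueError("OTU table contains non-integer counts")
    table = table.astype(np.int64)
    if not allow_empty_samples:
        empty = table.index[table.sum(axis=1) == 0]
        if len(empty):
            raise ValueError(
                f"sample(s) with no nonzero counts: {', '.join(map(str, empty))}"
            )
    return table


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Validate sample metadata (index sample, columns species/group/replicate)."""
    _check_unique(metadata.index, "sample")
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing column(s): {', '.join(missing)}")
    # each species maps to exactly one group
    per_species = metadata.groupby("species")["group"].nunique()
    bad = per_species.index[per_species > 1]
    if len(bad):
        raise ValueError(
            f"species mapped to multiple groups: {', '.join(map(str, bad))}"
        )
    dup = metadata.duplicated(subset=["species", "replicate"])
    if dup.any():
        bad_s = metadata.loc[dup, "species"].unique()
        raise ValueError(
            f"duplicate replicate index within species: {', '.join(map(str, bad_s))}"
        )
    return metadata[list(METADATA_COLUMNS)].copy()


def validate_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Validate a species-trait table against range invariants."""
    _check_unique(traits.index, "species")
    missing = [c for c in TRAIT_COLUMNS if c not in traits.columns]
    if missing:
        raise ValueError(f"trait table missing column(s): {', '.join(missing)}")
    traits = traits[list(TRAIT_COLUMNS)].astype(float)
    if traits.isna().any().any():
        bad = traits.index[traits.isna().any(axis=1)]
        raise ValueError(f"missing trait value(s) for species: {', '.join(map(str, bad))}")
    wc = traits["water_content"]
    if ((wc < 0) | (wc > 100)).any():
        raise ValueError("water_content outside [0, 100]")
    if (traits["cn_ratio"] <= 0).any():
        raise ValueError("cn_ratio must be positive")
    if (traits["abundance"] < 0).any():
        raise ValueError("abundance must be nonnegative")
    return traits


def validate_dataset(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    traits: pd.DataFrame | None = None,
) -> None:
    """Cross-check label consistency between OTU table, metadata, and traits."""
    missing_samples = table.index.difference(metadata.index)
    if len(missing_samples):
        raise ValueError(
            "samples absent from metadata: " + ", ".join(map(str, missing_samples))
        )
    if traits is not None:
        missing_species = pd.Index(metadata["species"].unique()).difference(traits.index)
        if len(missing_species):
            raise ValueError(
                "species absent from trait table: " + ", ".join(map(str, missing_species))
            )


# ---------------------------------------------------------------------------
# readers / writers


def read_otu_table(path, transpose: bool = False) -> pd.DataFrame:
    """Read a TSV OTU count table; ``transpose=True`` accepts OTUs-as-rows files."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        table = table.T
    table.index = table.index.astype(str).rename(None)
    table.columns = table.columns.astype(str).rename(None)
    return validate_otu_table(table)


def write_otu_table(table: pd.DataFrame, path, transpose: bool = False) -> None:
    out = table.T if transpose else table
    out.to_csv(path, sep="\t", index_label="sample_id" if not transpose else "otu_id")


def read_metadata(path) -> pd.DataFrame:
    metadata = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    metadata.index = metadata.index.astype(str)
    return validate_metadata(metadata)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def read_traits(path) -> pd.DataFrame:
    traits = pd.read_csv(path, sep="\t", index_col=0)
    traits.index = traits.index.astype(str)
    return validate_traits(traits)


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, sep="\t", index_label="species")


def read_taxonomy(path) -> pd.Series:
    tax = pd.read_csv(path, sep="\t", index_col=0)
    tax.index = tax.index.astype(str)
    _check_unique(tax.index, "OTU")
    return tax.iloc[:, 0].astype(str).rename("phylum")


def write_taxonomy(taxonomy: pd.Series, path) -> None:
    taxonomy.rename("phylum").to_csv(path, sep="\t", index_label="otu_id")


def read_guilds(path) -> pd.Series:
    guilds = pd.read_csv(path, sep="\t", index_col=0)
    guilds.index = guilds.index.astype(str)
    _check_unique(guilds.index, "OTU")
    modes = guilds.iloc[:, 0].astype(str).map(canonical_modes)
    return modes.rename("trophic_modes")


def write_guilds(guilds: pd.Series, path) -> None:
    guilds.rename("trophic_modes").to_csv(path, sep="\t", index_label="otu_id")


# ---------------------------------------------------------------------------
# derived quantities


def canonical_modes(modes: str | Iterable[str]) -> str:
    """Render a trophic-mode annotation as a canonical mode string.

    Components are deduplicated and sorted into the fixed order
    Pathotroph, Saprotroph, Symbiotroph, joined with ``-``; empty or
    unannotated input renders as ``"Unassigned"``.
    """
    if isinstance(modes, str):
        parts = [p for p in modes.replace("–", "-").split("-") if p]
    else:
        parts = list(modes)
    parts = [p.strip().capitalize() for p in parts if p.strip()]
    if not parts or parts == [UNASSIGNED]:
        return UNASSIGNED
    unknown = set(parts) - set(TROPHIC_MODES) - {UNASSIGNED}
    if unknown:
        raise ValueError(f"unknown trophic mode(s): {', '.join(sorted(unknown))}")
    ordered = [m for m in TROPHIC_MODES if m in parts]
    return "-".join(ordered)


def water_content(fresh_weight: float, dry_weight: float) -> float:
    """Root water content as percent of fresh mass lost on drying.

    ``(fresh - dry) / fresh * 100`` for a root sample weighed fresh and
    after oven-drying.
    """
    if fresh_weight <= 0:
        raise ValueError("fresh_weight must be positive")
    if dry_weight < 0:
        raise ValueError("dry_weight must be nonnegative")
    if dry_weight > fresh_weight:
        raise ValueError("dry_weight exceeds fresh_weight: negative water content")
    return (fresh_weight - dry_weight) / fresh_weight * 100.0


def sample_groups(metadata: pd.DataFrame, samples: Iterable | None = None) -> pd.Series:
    """Functional-group label per sample (ordered like ``samples`` if given)."""
    groups = metadata["group"]
    if samples is not None:
        groups = groups.reindex(list(samples))
        if groups.isna().any():
            bad = groups.index[groups.isna()]
            raise ValueError("samples absent from metadata: " + ", ".join(map(str, bad)))
    return groups


def phylum_relative_abundance(
    table: pd.DataFrame,
    taxonomy: pd.Series,
    metadata: pd.DataFrame,
    pooled: bool = True,
) -> pd.DataFrame:
    """Per-group relative abundance over phyla.

    OTU counts are mapped to phyla (OTUs absent from ``taxonomy`` fall into
    ``"Other"``). With ``pooled=True`` (default) counts are summed across each
    group's samples before normalizing; otherwise per-sample fractions are
    averaged within the group. Rows (groups) sum to 1.
    """
    validate_dataset(table, metadata)
    phyla = taxonomy.reindex(table.columns).fillna("Other")
    by_phylum = table.T.groupby(phyla.to_numpy()).sum().T  # samples x phyla
    groups = sample_groups(metadata, table.index)
    if pooled:
        pooled_counts = by_phylum.groupby(groups.to_numpy()).sum()
        totals = pooled_counts.sum(axis=1)
        if (totals == 0).any():
            empty = pooled_counts.index[totals == 0]
            raise ValueError("group(s) with zero total counts: " + ", ".join(map(str, empty)))
        return pooled_counts.div(totals, axis=0)
    fractions = by_phylum.div(by_phylum.sum(axis=1), axis=0)
    return fractions.groupby(groups.to_numpy()).mean()
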