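"""Microbial community dissimilarity from guild-labeled feature-count tables.

Feature-count (ASV x sample) tables are rarefied to a common depth,
restricted to a functional guild (putative plant pathogens), and collapsed
to species-by-species Bray-Curtis dissimilarity matrices: the predictors of
the pairwise plant-soil feedback model.  A small "dilution signature"
operation tracks how each plant species' most abundant pathogen changes in
relative abundance between its monoculture and mixed plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


@dataclass
class FeatureCountTable:
    """Nonnegative integer counts, features x samples, with metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by feature id with one column per sample.
    samples
        Per-sample metadata indexed by sample id.  The column ``species``
        names the plant species of origin for monoculture samples.
    features
        Per-feature metadata indexed by feature id.  Guild labels live in
        the ``primary_lifestyle`` / ``secondary_lifestyle`` columns.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)
    features: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("feature and sample identifiers must be unique")

    @property
    def totals(self) -> pd.Series:
        """Library size per sample."""
        return self.counts.sum(axis=0)


@dataclass
class DissimilarityMatrix:
    """Symmetric species x species Bray-Curtis dissimilarity for one group.

    ``d`` is a square DataFrame with identical index and columns (species),
    zero diagonal, entries in [0, 1].
    """

    group: str
    d: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.d.to_numpy(dtype=float)
        if m.shape[0] != m.shape[1] or not self.d.index.equals(self.d.columns):
            raise ValueError("dissimilarity matrix must be square with matching labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix must have zero diagonal")
        if (m < -1e-12).any() or (m > 1 + 1e-12).any():
            raise ValueError("dissimilarities must lie in [0, 1]")

    @property
    def species(self) -> list[str]:
        return list(self.d.index)

    def value(self, a: str, b: str) -> float:
        return float(self.d.loc[a, b])


def rarefy(
    table: FeatureCountTable, depth: int | str = "min", seed: int = 0
) -> FeatureCountTable:
    """Subsample every sample without replacement to a common depth.

    ``depth="min"`` uses the smallest library size.  Samples below the
    requested depth are dropped with a warning.  The draw is a multivariate
    hypergeometric sample, seeded and deterministic.
    """
    totals = table.totals
    if depth == "min":
        depth = int(totals.min())
    depth = int(depth)
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    keep = totals.index[totals >= depth]
    dropped = totals.index.difference(keep)
    if len(dropped):
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below depth {depth}: "
            + ", ".join(map(str, dropped))
        )
    rng = np.random.default_rng(seed)
    out = {}
    for s in keep:
        col = table.counts[s].to_numpy(dtype=np.int64)
        if col.sum() == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(out, index=table.counts.index)
    counts.columns.name = table.counts.columns.name
    if len(table.samples):
        samples = table.samples.loc[keep]
        samples.index.name = table.samples.index.name
    else:
        samples = table.samples
    return FeatureCountTable(counts=counts, samples=samples, features=table.features)


def guild_filter(table: FeatureCountTable, guild: str = "plant_pathogen") -> FeatureCountTable:
    """Restrict features to a guild (union of primary and secondary lifestyle)."""
    feats = table.features
    if feats.empty or "primary_lifestyle" not in feats.columns:
        raise ValueError("feature metadata with lifestyle columns required")
    primary = feats["primary_lifestyle"].astype(str) == guild
    secondary = (
        feats["secondary_lifestyle"].astype(str) == guild
        if "secondary_lifestyle" in feats.columns
        else pd.Series(False, index=feats.index)
    )
    keep = feats.index[primary | secondary]
    if keep.empty:
        warnings.warn(f"no features matched guild {guild!r}; returning empty table")
    counts = table.counts.loc[table.counts.index.intersection(keep)]
    return FeatureCountTable(
        counts=counts, samples=table.samples, features=feats.loc[counts.index]
    )


def bray_curtis(a: np.ndarray, b: np.ndarray) -> float:
    """Bray-Curtis dissimilarity sum|a-b| / sum(a+b) between two count vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    denom = (a + b).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(a - b).sum() / denom)


def species_pair_dissimilarity(table: FeatureCountTable, group: str = "") -> DissimilarityMatrix:
    """Mean Bray-Curtis over all cross pairs of samples of two species.

    Each species must have at least one sample (column of ``table`` whose
    ``species`` metadata names it); species without samples are excluded with
    a warning.  The diagonal is forced to zero.
    """
    if "species" not in table.samples.columns:
        raise ValueError("sample metadata must have a 'species' column")
    by_species: dict[str, np.ndarray] = {}
    for sp, grp in table.samples.groupby("species", sort=True):
        cols = [c for c in grp.index if c in table.counts.columns]
        if not cols:
            warnings.warn(f"species {sp!r} has no samples; excluded")
            continue
        by_species[sp] = table.counts[cols].to_numpy(dtype=float).T
    species = sorted(by_species)
    n = len(species)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm = cdist(by_species[species[i]], by_species[species[j]], metric="braycurtis")
            d[i, j] = d[j, i] = float(np.nanmean(dm))
    frame = pd.DataFrame(d, index=species, columns=species)
    return DissimilarityMatrix(group=group, d=frame)


def dilution_signature(
    table: FeatureCountTable,
    monoculture_samples: dict[str, str],
    mixture_plots: pd.DataFrame,
) -> pd.DataFrame:
    """Change in relative abundance of each species' most abundant pathogen.

    For each species, the most abundant pathogen feature in its monoculture
    sample is identified (ties broken by lexicographically smallest feature
    id); the signature in a mixture plot is that feature's relative abundance
    in the mixture sample minus its relative abundance in the monoculture.

    Parameters
    ----------
    table
        Pathogen-filtered count table containing monoculture and mixture
        samples.
    monoculture_samples
        Map species -> monoculture sample id.
    mixture_plots
        One row per mixture sample with columns ``sample`` (sample id),
        ``richness`` and ``composition`` ('|'-joined species list).

    Returns
    -------
    DataFrame with columns plot sample, species, richness, feature,
    mono_ra, mix_ra, change.
    """
    rel = table.counts / table.counts.sum(axis=0)
    rows = []
    top_feature: dict[str, str] = {}
    for sp, sample in sorted(monoculture_samples.items()):
        if sample not in rel.columns:
            warnings.warn(f"species {sp!r}: monoculture sample {sample!r} missing; omitted")
            continue
        col = rel[sample]
        if col.sum() == 0 or col.isna().all():
            warnings.warn(f"species {sp!r} has no pathogen features; omitted")
            continue
        best = col.max()
        # deterministic tie-break: lexicographically smallest feature id
        top_feature[sp] = sorted(col.index[col == best])[0]
    for _, plot in mixture_plots.iterrows():
        sample = plot["sample"]
        if sample not in rel.columns:
            continue
        members = str(plot["composition"]).split("|")
        for sp in members:
            if sp not in top_feature:
                continue
            feat = top_feature[sp]
            mono_ra = float(rel.loc[feat, monoculture_samples[sp]])
            mix_ra = float(rel.loc[feat, sample])
            rows.append(
                {
                    "sample": sample,
                    "species": sp,
                    "richness": int(plot["richness"]),
                    "feature": feat,
                    "mono_ra": mono_ra,
                    "mix_ra": mix_ra,
                    "change": mix_ra - mono_ra,
                }
            )
    return pd.DataFrame(rows)
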