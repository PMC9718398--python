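"""CRISPR-screen integration: drugZ-style scoring, threshold rules, clustering.

Gene-level screen results are NormZ scores: negative values mean the
knockout was depleted (the gene is essential for growth, or its loss
sensitises to the screened drug). Published screens are consumed directly as
gene x screen NormZ tables; the in-house essential screen is scored from
guide-level D0/D14 counts with a drugZ-style scheme:

1. scale each sample's counts to a fixed library size (1e7);
2. per replicate, guide fold change fc = log2((D14 + pseudo) / (D0 + pseudo));
3. z-score guide fold changes against the replicate's empirical mean and SD;
4. gene score = sum of its guide z-scores across guides and replicates,
   divided by sqrt(number summed);
5. rank-based inverse-normal transform of gene scores -> NormZ.

This is a deliberately simplified variant of the published drugZ algorithm
(no empirical-Bayes variance moderation, no paired-sample handling); the
downstream analyses consume only NormZ ranks and thresholds, and external
gene-level NormZ tables can be supplied to bypass this scorer entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .abundance import DifferentialResult

GUIDE_COLUMNS = ("guide", "gene", "replicate", "count_d0", "count_d14")

#: Fixed target library size for depth normalisation (as in drugZ).
NORM_LIBRARY_SIZE = 1e7


@dataclass
class ScreenProfile:
    """Gene x screen NormZ matrix; missing cells are NaN."""

    normz: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.normz.index)

    @property
    def screens(self) -> list[str]:
        return list(self.normz.columns)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "ScreenProfile":
        """Build from a long table with columns gene, screen, normz."""
        wide = df.pivot_table(
            index="gene", columns="screen", values="normz", aggfunc="first"
        )
        wide.index = wide.index.astype(str)
        return cls(normz=wide)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ScreenProfile":
        return cls.from_long(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path: str | Path) -> None:
        long = self.normz.stack().rename("normz").reset_index()
        long.columns = ["gene", "screen", "normz"]
        long.to_csv(path, sep="\t", index=False)


def read_guide_counts(path: str | Path) -> pd.DataFrame:
    """Read a guide-count table (TSV: guide, gene, replicate, count_d0, count_d14)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GUIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"guide-count table missing column(s): {missing}")
    return df


def rank_essentiality(guides: pd.DataFrame, pseudo: float = 0.5) -> pd.Series:
    """drugZ-style gene NormZ from guide D0/D14 counts (negative = depleted).

    ``guides`` needs columns guide, gene, replicate, count_d0, count_d14.
    A guide must map to exactly one gene. A sample (replicate x timepoint)
    with zero total counts raises :class:`ValueError`.
    """
    missing = [c for c in GUIDE_COLUMNS if c not in guides.columns]
    if missing:
        raise ValueError(f"guide table missing column(s): {missing}")
    multi = guides.groupby("guide")["gene"].nunique()
    if (multi > 1).any():
        bad = multi[multi > 1].index.tolist()
        raise ValueError(f"guide(s) mapped to more than one gene: {bad[:5]}")

    z_parts: list[pd.DataFrame] = []
    for rep, sub in guides.groupby("replicate"):
        tot0 = float(sub["count_d0"].sum())
        tot14 = float(sub["count_d14"].sum())
        if tot0 <= 0 or tot14 <= 0:
            raise ValueError(f"replicate {rep!r} has zero total counts in a sample")
        n0 = sub["count_d0"].to_numpy(float) * (NORM_LIBRARY_SIZE / tot0)
        n14 = sub["count_d14"].to_numpy(float) * (NORM_LIBRARY_SIZE / tot14)
        fc = np.log2((n14 + pseudo) / (n0 + pseudo))
        sd = fc.std(ddof=1)
        if sd == 0:
            # degenerate null screen: all fold changes identical
            z = np.zeros_like(fc)
        else:
            z = (fc - fc.mean()) / sd
        z_parts.append(pd.DataFrame({"gene": sub["gene"].to_numpy(), "z": z}))

    allz = pd.concat(z_parts, ignore_index=True)
    grouped = allz.groupby("gene")["z"]
    score = grouped.sum() / np.sqrt(grouped.count())
    # rank-based inverse-normal transform (Blom offsets)
    ranks = score.rank(method="average")
    normz = pd.Series(
        stats.norm.ppf((ranks - 0.375) / (len(score) + 0.25)),
        index=score.index,
        name="normz",
    )
    return normz.sort_index()


def classify_sensitizers(
    profile: ScreenProfile,
    screen_ids: Sequence[str],
    threshold: float = -1.0,
    min_screens: int = 2,
) -> set[str]:
    """Genes with NormZ strictly below ``threshold`` in >= ``min_screens`` screens.

    Missing cells never count toward the tally.
    """
    for sid in screen_ids:
        if sid not in profile.normz.columns:
            raise ValueError(f"unknown screen {sid!r}; available: {profile.screens}")
    if min_screens > len(screen_ids):
        raise ValueError(
            f"min_screens={min_screens} exceeds the {len(screen_ids)} named screens"
        )
    sub = profile.normz[list(screen_ids)]
    hits = (sub < threshold).sum(axis=1) >= min_screens
    return set(sub.index[hits])


def classify_essentials(
    profile: ScreenProfile, screen_id: str, threshold: float = -1.5
) -> set[str]:
    """Genes with NormZ strictly below ``threshold`` in one screen."""
    return classify_sensitizers(profile, [screen_id], threshold, min_screens=1)


def differential_hu_hits(
    diffs: Iterable[DifferentialResult],
    profile: ScreenProfile,
    hu_screen: str,
    fc_cut: float = 1.0,
    z_cut: float = 2.0,
) -> set[str]:
    """Preys both HU-modulated in a BioID and scoring in the HU CRISPR screen.

    A gene is included iff |log2FC| > ``fc_cut`` in at least one bait's
    differential table AND |NormZ| > ``z_cut`` in the HU screen. Genes missing
    from the screen are excluded.
    """
    if hu_screen not in profile.normz.columns:
        raise ValueError(f"unknown screen {hu_screen!r}; available: {profile.screens}")
    modulated = {d.prey for d in diffs if abs(d.log2fc) > fc_cut}
    z = profile.normz[hu_screen]
    scoring = set(z.index[z.abs() > z_cut])
    return modulated & scoring


@dataclass
class ClusterAssignment:
    """Cut of an agglomerative clustering: gene -> cluster id (1..k)."""

    labels: dict[str, int]
    leaf_order: list[str]
    linkage_description: str

    def members(self, cluster: int) -> set[str]:
        return {g for g, c in self.labels.items() if c == cluster}

    def to_frame(self) -> pd.DataFrame:
        pos = {g: i for i, g in enumerate(self.leaf_order)}
        return pd.DataFrame(
            {
                "gene": list(self.labels),
                "cluster": [self.labels[g] for g in self.labels],
                "leaf_position": [pos[g] for g in self.labels],
            }
        ).sort_values("leaf_position", ignore_index=True)


def _pairwise_distances(x: np.ndarray, metric: str) -> np.ndarray:
    """Condensed distance vector tolerating NaN cells (pairwise exclusion)."""
    if not np.isnan(x).any():
        if metric == "euclidean":
            return pdist(x, metric="euclidean")
        return pdist(x, metric="correlation")
    if metric == "euclidean":
        from sklearn.metrics.pairwise import nan_euclidean_distances

        d = nan_euclidean_distances(x)
    else:
        # pandas computes pearson correlation with pairwise NaN exclusion
        corr = pd.DataFrame(x).T.corr().to_numpy()
        d = 1.0 - corr
    d = np.nan_to_num(d, nan=float(np.nanmax(d)) if np.isfinite(np.nanmax(d)) else 1.0)
    np.fill_diagonal(d, 0.0)
    return squareform((d + d.T) / 2.0, checks=False)


def cluster_profiles(
    profile: ScreenProfile,
    k: int,
    distance: str = "euclidean",
    linkage: str = "complete",
    standardize: bool = False,
    missing: str = "pairwise",
) -> ClusterAssignment:
    """Agglomerative clustering of genes on their NormZ profiles, cut at k.

    ``distance`` is ``euclidean`` or ``correlation``; ``linkage`` is
    ``complete``, ``average`` or ``ward`` (ward requires euclidean).
    ``missing`` handles NaN cells: ``pairwise`` exclusion or ``zero``
    imputation. Rows that are entirely missing are dropped with a warning.
    Cluster ids are relabelled 1..k by first appearance in input order, so
    the assignment is deterministic given data and parameters.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if distance not in ("euclidean", "correlation"):
        raise ValueError(f"unknown distance {distance!r}")
    if linkage not in ("complete", "average", "ward"):
        raise ValueError(f"unknown linkage {linkage!r}")
    if linkage == "ward" and distance != "euclidean":
        raise ValueError("ward linkage requires euclidean distance")

    mat = profile.normz.copy()
    all_missing = mat.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} gene(s) with no NormZ values",
            stacklevel=2,
        )
        mat = mat.loc[~all_missing]
    genes = list(mat.index)
    if k > len(genes):
        raise ValueError(f"k={k} exceeds the {len(genes)} clusterable genes")

    if missing == "zero":
        mat = mat.fillna(0.0)
    x = mat.to_numpy(float)
    if standardize:
        mu = np.nanmean(x, axis=1, keepdims=True)
        sd = np.nanstd(x, axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd

    if len(genes) == 1:
        return ClusterAssignment(
            labels={genes[0]: 1},
            leaf_order=genes,
            linkage_description=f"{linkage} linkage, {distance} distance, k=1",
        )
    dvec = _pairwise_distances(x, distance)
    z = hierarchy.linkage(dvec, method=linkage)
    raw = hierarchy.fcluster(z, t=k, criterion="maxclust")
    # relabel by first appearance for determinism
    remap: dict[int, int] = {}
    labels: dict[str, int] = {}
    for gene, c in zip(genes, raw):
        if c not in remap:
            remap[c] = len(remap) + 1
        labels[gene] = remap[c]
    leaf_order = [genes[i] for i in hierarchy.leaves_list(z)]
    return ClusterAssignment(
        labels=labels,
        leaf_order=leaf_order,
        linkage_description=f"{linkage} linkage, {distance} distance, k={k}",
    )
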