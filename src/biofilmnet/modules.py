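"""Module detection on topological-overlap dissimilarity.

Taxa are clustered by average-linkage hierarchical clustering on dissTOM;
branches below a static cut height containing at least ``min_module_size``
taxa become modules, labeled with colors in decreasing size order from the
conventional palette (turquoise, blue, brown, ...). Taxa in no qualifying
branch are "grey" (unassigned). Each module is summarized by its
eigenspecies — the first principal component of the standardized member
profiles — which drives module membership and module-trait correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

#: color order assigned to modules by decreasing size
COLOR_PALETTE = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]

GREY = "grey"


@dataclass
class ModulePartition:
    """Taxon -> module color assignment plus the dendrogram behind it.

    ``colors`` covers every taxon ("grey" = unassigned); ``linkage`` is the
    scipy linkage matrix; ``cut_height`` the static threshold used.
    """

    colors: pd.Series
    linkage: np.ndarray | None = field(default=None, repr=False)
    cut_height: float | None = None
    min_module_size: int | None = None

    def members(self, color: str) -> list[str]:
        return self.colors.index[self.colors == color].tolist()

    def module_colors(self, include_grey: bool = False) -> list[str]:
        """Module colors in size order (as assigned)."""
        seen = [c for c in COLOR_PALETTE if (self.colors == c).any()]
        if include_grey and (self.colors == GREY).any():
            seen.append(GREY)
        return seen

    def sizes(self) -> pd.Series:
        return self.colors.value_counts()


@dataclass
class Eigenspecies:
    """Per-module summary profile (first principal component).

    ``profiles`` is samples x modules, columns unit-norm with sign fixed so
    the mean correlation with member taxa is positive;
    ``variance_explained`` maps color -> fraction of member variance carried
    by the first component.
    """

    profiles: pd.DataFrame
    variance_explained: dict[str, float]


@dataclass
class TraitAssociation:
    """Module-trait Pearson correlations and two-sided p-values."""

    correlation: pd.DataFrame
    p_value: pd.DataFrame


@dataclass
class ConsensusResult:
    """Outcome of a consensus-module attempt across datasets."""

    found: bool
    partition: ModulePartition | None
    message: str


def cluster_taxa(disstom: pd.DataFrame) -> np.ndarray:
    """Average-linkage hierarchical clustering of taxa on dissTOM.

    Returns a scipy linkage matrix over the taxa in ``disstom`` row order.
    """
    d = disstom.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissTOM must be a symmetric square matrix")
    if d.shape[0] == 1:
        return np.empty((0, 4))
    dz = d.copy()
    np.fill_diagonal(dz, 0.0)
    return linkage(squareform(dz, checks=False), method="average")


def cut_modules(
    link: np.ndarray,
    taxa: list[str],
    min_module_size: int = 5,
    cut_height: float | None = None,
) -> ModulePartition:
    """Cut the dendrogram into color-labeled modules.

    A static cut at ``cut_height`` (default 0.99 x the maximum merge height)
    defines candidate branches; branches with at least ``min_module_size``
    leaves become modules, colored in decreasing size order. All other taxa
    are grey. Ties in size break by the lexicographically smallest member
    taxon, keeping the labeling deterministic.
    """
    if min_module_size < 2:
        raise ValueError(f"min_module_size must be >= 2, got {min_module_size}")
    if len(link) == 0:
        # single taxon: too small to be a module
        return ModulePartition(
            colors=pd.Series([GREY], index=list(taxa), name="module"),
            linkage=link,
            cut_height=cut_height,
            min_module_size=min_module_size,
        )
    max_h = float(link[:, 2].max())
    if cut_height is None:
        cut_height = 0.99 * max_h
    branch = fcluster(link, t=cut_height, criterion="distance")

    groups: dict[int, list[str]] = {}
    for taxon, b in zip(taxa, branch):
        groups.setdefault(int(b), []).append(taxon)
    modules = [g for g in groups.values() if len(g) >= min_module_size]
    modules.sort(key=lambda g: (-len(g), min(g)))
    if len(modules) > len(COLOR_PALETTE):
        raise ValueError(
            f"{len(modules)} modules exceed the {len(COLOR_PALETTE)}-color palette"
        )

    colors = pd.Series(GREY, index=list(taxa), name="module")
    for color, members in zip(COLOR_PALETTE, modules):
        colors.loc[members] = color
    return ModulePartition(
        colors=colors,
        linkage=link,
        cut_height=cut_height,
        min_module_size=min_module_size,
    )


def _standardized(rows: np.ndarray) -> np.ndarray:
    centered = rows - rows.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return centered / sd


def module_eigenspecies(
    matrix: pd.DataFrame, partition: ModulePartition
) -> Eigenspecies:
    """First principal component of each module's standardized members.

    Member profiles are z-scored across samples; the eigenspecies is the
    first right-singular vector (unit norm over samples), its sign chosen so
    the mean Pearson correlation with the member taxa is positive.
    Variance explained is s_1^2 / sum(s^2). A single-member module's
    eigenspecies is that taxon's standardized profile (unit-normalized).
    """
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values; impute first")
    cols: dict[str, np.ndarray] = {}
    varexp: dict[str, float] = {}
    for color in partition.module_colors(include_grey=False):
        members = partition.members(color)
        z = _standardized(matrix.loc[members].to_numpy(dtype=float))
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        v = vt[0]
        cors = np.array([np.corrcoef(row, v)[0, 1] for row in z])
        if cors.mean() < 0:
            v = -v
        cols[color] = v
        varexp[color] = float(s[0] ** 2 / max((s**2).sum(), 1e-300))
    profiles = pd.DataFrame(cols, index=matrix.columns)
    return Eigenspecies(profiles=profiles, variance_explained=varexp)


def module_membership(
    matrix: pd.DataFrame, eigen: Eigenspecies
) -> pd.DataFrame:
    """Pearson correlation of every taxon with every module eigenspecies."""
    x = _standardized(matrix.to_numpy(dtype=float))
    e = eigen.profiles.to_numpy(dtype=float)
    ez = (e - e.mean(axis=0)) / e.std(axis=0)
    mm = x @ ez / x.shape[1]
    return pd.DataFrame(
        np.clip(mm, -1, 1), index=matrix.index, columns=eigen.profiles.columns
    )


def module_trait_correlation(
    eigen: Eigenspecies, traits: pd.DataFrame
) -> TraitAssociation:
    """Correlate each eigenspecies with each clinical trait.

    Pearson r per (module, trait); two-sided p-value from the Student-t
    transform t = r * sqrt((n - 2) / (1 - r^2)) with n - 2 degrees of
    freedom, n being the number of samples.
    """
    common = eigen.profiles.index.intersection(traits.index)
    if len(common) != len(eigen.profiles.index) or len(common) != len(traits.index):
        raise ValueError("eigenspecies and traits must cover the same samples")
    n = len(common)
    if n < 3:
        raise ValueError(f"need at least 3 samples for trait correlation, got {n}")
    e = eigen.profiles.loc[common].to_numpy(dtype=float)
    tr = traits.loc[common].to_numpy(dtype=float)
    ez = (e - e.mean(axis=0)) / e.std(axis=0)
    tz = (tr - tr.mean(axis=0)) / np.where(tr.std(axis=0) == 0, 1, tr.std(axis=0))
    r = np.clip(ez.T @ tz / n, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * t_dist.sf(np.abs(tstat), df=n - 2)
    p = np.maximum(p, np.finfo(float).tiny)
    cols = traits.columns
    mods = eigen.profiles.columns
    return TraitAssociation(
        correlation=pd.DataFrame(r, index=mods, columns=cols),
        p_value=pd.DataFrame(p, index=mods, columns=cols),
    )


def consensus_modules(
    networks: list, min_module_size: int = 5, quantile: float = 0.95
) -> ConsensusResult:
    """Attempt consensus modules across datasets sharing a taxon set.

    Each dataset's TOM is rescaled so its ``quantile`` quantile matches the
    smallest such quantile across datasets (removing dataset-scale
    differences), and the consensus TOM is the elementwise minimum — a taxon
    pair is only as similar as its weakest dataset makes it. The consensus
    dissTOM is clustered and cut as usual. A candidate branch only counts as
    a consensus module if it is cohesive in the consensus matrix — its mean
    within-module TOM must be at least twice the mean over all remaining
    (complement) pairs — since a static cut always produces branches, even
    in structureless data. If no module survives, an explicit "no
    consensus" report is returned.
    """
    if len(networks) < 2:
        raise ValueError("need at least 2 networks for a consensus")
    taxa = networks[0].taxa
    for net in networks[1:]:
        if net.taxa != taxa:
            extra = sorted(set(net.taxa) ^ set(taxa))
            raise ValueError(f"taxon sets disagree between networks: {extra}")
    toms = []
    for net in networks:
        if net.tom is None:
            raise ValueError("all networks need TOM computed first")
        toms.append(net.tom)
    offdiag = ~np.eye(len(taxa), dtype=bool)
    qs = [np.quantile(tom[offdiag], quantile) for tom in toms]
    target = min(qs)
    scaled = [
        np.clip(tom * (target / q if q > 0 else 1.0), 0.0, 1.0)
        for tom, q in zip(toms, qs)
    ]
    consensus = np.minimum.reduce(scaled)
    np.fill_diagonal(consensus, 1.0)
    diss = pd.DataFrame(1.0 - consensus, index=taxa, columns=taxa)
    link = cluster_taxa(diss)
    partition = cut_modules(link, taxa, min_module_size=min_module_size)

    # cohesion filter: drop branches no tighter than the consensus background
    taxa_arr = np.asarray(taxa)
    surviving: list[list[str]] = []
    for color in partition.module_colors():
        members = partition.members(color)
        idx = np.flatnonzero(np.isin(taxa_arr, members))
        in_module = np.zeros((len(taxa), len(taxa)), dtype=bool)
        in_module[np.ix_(idx, idx)] = True
        within = consensus[in_module & offdiag].mean()
        complement = consensus[~in_module & offdiag].mean()
        if within >= 2.0 * complement:
            surviving.append(members)
    surviving.sort(key=lambda g: (-len(g), min(g)))
    colors = pd.Series(GREY, index=list(taxa), name="module")
    for color, members in zip(COLOR_PALETTE, surviving):
        colors.loc[members] = color
    partition = ModulePartition(
        colors=colors,
        linkage=link,
        cut_height=partition.cut_height,
        min_module_size=min_module_size,
    )
    n_modules = len(partition.module_colors())
    if n_modules == 0:
        return ConsensusResult(
            found=False,
            partition=None,
            message="no consensus: no module shared across all datasets "
            f"survives at min_module_size={min_module_size}",
        )
    return ConsensusResult(
        found=True,
        partition=partition,
        message=f"{n_modules} consensus module(s) found",
    )
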