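"""Unsigned weighted co-occurrence network construction.

The network is built WGCNA-style: pairwise Pearson correlations between
taxon abundance profiles are raised elementwise to a soft-threshold power
beta >= 1, a_ij = |cor(x_i, x_j)|^beta, so large correlations are emphasized
at the expense of small ones without imposing a hard cutoff. The power is
chosen by the scale-free topology criterion: the smallest beta whose
connectivity distribution approximates a power law, measured by the R^2 of
a log-log degree-frequency regression. Adjacency is then transformed into
the topological overlap matrix (TOM), whose dissimilarity 1 - TOM is the
clustering distance for module detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class WeightedNetwork:
    """Weighted taxon network: adjacency, soft power, and (optionally) TOM.

    ``adjacency`` is symmetric with entries in [0, 1] and unit diagonal;
    the diagonal is excluded from connectivity. ``tom``/``disstom`` are
    filled by :func:`topological_overlap`.
    """

    taxa: list[str]
    adjacency: np.ndarray
    beta: float
    tom: np.ndarray | None = field(default=None, repr=False)
    disstom: np.ndarray | None = field(default=None, repr=False)

    @property
    def connectivity(self) -> pd.Series:
        """Per-taxon connectivity k_i = sum_{j != i} a_ij."""
        a = self.adjacency.copy()
        np.fill_diagonal(a, 0.0)
        return pd.Series(a.sum(axis=1), index=self.taxa, name="k")

    def adjacency_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.adjacency, index=self.taxa, columns=self.taxa)

    def tom_frame(self) -> pd.DataFrame:
        if self.tom is None:
            raise ValueError("TOM not computed; call topological_overlap first")
        return pd.DataFrame(self.tom, index=self.taxa, columns=self.taxa)


@dataclass
class ScaleFreeFit:
    """Scale-free topology fit across candidate soft powers.

    ``table`` has one row per candidate beta with the fit index R^2 and the
    mean/median connectivity; ``beta`` is the chosen power.
    """

    table: pd.DataFrame
    beta: int
    r_squared: float
    n_bins: int


def correlation_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """All pairwise Pearson correlations between taxon profiles.

    The input must be complete (impute first) and every taxon must have
    nonzero variance across samples.
    """
    vals = matrix.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("matrix contains missing values; impute first")
    sd = vals.std(axis=1)
    dead = matrix.index[sd == 0].tolist()
    if dead:
        raise ValueError(f"zero-variance taxa: {', '.join(map(str, dead))}")
    cor = np.corrcoef(vals)
    cor = np.clip(cor, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=matrix.index, columns=matrix.index)


def soft_threshold_adjacency(cor: pd.DataFrame, beta: float) -> WeightedNetwork:
    """Unsigned soft-threshold adjacency a_ij = |cor_ij|^beta."""
    if beta < 1:
        raise ValueError(f"soft threshold power beta must be >= 1, got {beta}")
    a = np.abs(cor.to_numpy(dtype=float)) ** beta
    np.fill_diagonal(a, 1.0)
    return WeightedNetwork(taxa=list(cor.index), adjacency=a, beta=beta)


def scale_free_fit_index(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log regression of degree frequency on degree.

    Connectivities are binned into ``n_bins`` log-spaced bins; the fit index
    is the squared Pearson correlation between log10(frequency) and
    log10(mean bin connectivity) over non-empty bins.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size == 0 or np.ptp(k) == 0:
        raise ValueError(
            "all connectivities equal: scale-free fit is undefined for a "
            "degenerate (single-bin) connectivity distribution"
        )
    edges = np.logspace(np.log10(k.min()), np.log10(k.max()), n_bins + 1)
    edges[-1] *= 1 + 1e-12  # keep the max in the last bin
    which = np.digitize(k, edges) - 1
    freq = np.array([(which == b).sum() for b in range(n_bins)], dtype=float)
    mean_k = np.array(
        [k[which == b].mean() if freq[b] else np.nan for b in range(n_bins)]
    )
    ok = freq > 0
    if ok.sum() < 2:
        raise ValueError(
            "all connectivities equal: scale-free fit is undefined for a "
            "degenerate (single-bin) connectivity distribution"
        )
    lx = np.log10(mean_k[ok])
    ly = np.log10(freq[ok])
    if np.ptp(lx) == 0 or np.ptp(ly) == 0:
        return 0.0
    r = np.corrcoef(lx, ly)[0, 1]
    return float(r**2)


def pick_soft_threshold(
    cor: pd.DataFrame,
    candidate_betas: list[int] | None = None,
    target_r2: float = 0.85,
    n_bins: int = 10,
) -> ScaleFreeFit:
    """Choose the soft power by the scale-free topology criterion.

    For each candidate beta the taxon connectivities of the resulting
    adjacency are computed and their distribution scored by
    :func:`scale_free_fit_index`. The chosen beta is the smallest one whose
    R^2 reaches ``target_r2``; if none does, the beta with the maximum R^2
    is used (mirroring analyses that report "the maximum for these
    samples").
    """
    if candidate_betas is None:
        candidate_betas = list(range(1, 21))
    if len(candidate_betas) == 0:
        raise ValueError("candidate_betas must be nonempty")
    if cor.shape[0] < 5:
        raise ValueError("need at least 5 taxa for a scale-free fit")

    abscor = np.abs(cor.to_numpy(dtype=float))
    np.fill_diagonal(abscor, 0.0)
    rows = []
    for b in candidate_betas:
        k = (abscor**b).sum(axis=1)
        r2 = scale_free_fit_index(k, n_bins=n_bins)
        rows.append(
            {
                "beta": b,
                "r_squared": r2,
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
            }
        )
    table = pd.DataFrame(rows)
    reaching = table[table["r_squared"] >= target_r2]
    if len(reaching):
        row = reaching.iloc[0]
    else:
        row = table.loc[table["r_squared"].idxmax()]
    return ScaleFreeFit(
        table=table,
        beta=int(row["beta"]),
        r_squared=float(row["r_squared"]),
        n_bins=n_bins,
    )


def topological_overlap(net: WeightedNetwork) -> WeightedNetwork:
    """Fill the network's topological overlap matrix and its dissimilarity.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), where
    l_ij = sum_{u != i,j} a_iu * a_uj counts shared-neighbor adjacency, with
    unit diagonal; dissTOM = 1 - TOM.
    """
    a = net.adjacency.copy()
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("adjacency entries must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # zero diagonal makes u=i and u=j terms vanish
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    net.tom = tom
    net.disstom = 1.0 - tom
    return net
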