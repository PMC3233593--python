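"""Array preprocessing: normalization, probe averaging, BPCA imputation,
and outlier-sample detection.

The imputer is a Bayesian principal component analysis (BPCA) estimator:
probabilistic PCA fitted by variational expectation-maximization with an
automatic relevance determination (ARD) prior on the factor loadings, so
superfluous latent axes are shrunk away rather than chosen by hand. Missing
entries are replaced by their posterior means; observed entries are never
altered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

_TAU_MAX = 1e12
_EPS = 1e-12


def normalize_by_universal_probe(
    raw: pd.DataFrame, universal_row_id: str
) -> pd.DataFrame:
    """Divide each sample by its universal-probe signal.

    Every value in a sample (column) is divided by that sample's fluorescence
    on the universal 16S rRNA probe row, which is then removed from the
    output. Samples whose universal value is missing or non-positive make
    per-sample normalization undefined and raise an error naming them.
    """
    if universal_row_id not in raw.index:
        raise KeyError(f"universal probe row {universal_row_id!r} not in matrix")
    universal = raw.loc[universal_row_id]
    bad = universal.index[~(universal > 0)].tolist()
    if bad:
        raise ValueError(
            f"universal probe {universal_row_id!r} is zero or missing in "
            f"samples: {', '.join(map(str, bad))}"
        )
    out = raw.drop(index=universal_row_id)
    return out / universal


def average_probes(raw: pd.DataFrame, probe_map: dict[str, str]) -> pd.DataFrame:
    """Collapse a probe-level matrix to species level by averaging.

    Each species row is the arithmetic mean of its probes per sample;
    missing probe values are excluded from the mean, and a species whose
    probes are all missing in a sample stays missing there.
    """
    unmapped = [p for p in raw.index if p not in probe_map]
    if unmapped:
        raise KeyError(f"probes not covered by the probe map: {unmapped}")
    species = raw.groupby([probe_map[p] for p in raw.index]).mean()
    species.index.name = raw.index.name
    return species


@dataclass
class ImputationResult:
    """Completed matrix plus imputation diagnostics.

    ``matrix`` has no missing entries and equals the input exactly wherever
    the input was observed; ``imputed_mask`` marks the filled cells.
    ``n_axes_used`` counts latent axes that survived ARD shrinkage.
    """

    matrix: pd.DataFrame
    n_axes_used: int
    n_iterations: int
    converged: bool
    imputed_mask: pd.DataFrame


def bpca_impute(
    matrix: pd.DataFrame,
    q: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int = 0,
) -> ImputationResult:
    """Impute missing entries by Bayesian PCA.

    Samples (columns) are treated as observations of a ``n_taxa``-dimensional
    Gaussian factor model y = W x + mu + eps. Each iteration alternates the
    posterior over latent scores x given the observed part of each sample
    with updates of the loadings W, mean mu, noise precision tau and
    per-axis ARD precisions; missing cells are filled with posterior means.
    Convergence is declared when the largest absolute change in any imputed
    value drops below ``tol``.

    Parameters
    ----------
    q:
        Number of latent axes; default ``min(n_taxa, n_samples) - 1`` with
        ARD pruning deciding the effective dimension.
    """
    vals = matrix.to_numpy(dtype=float)
    if np.isinf(vals).any():
        raise ValueError("matrix contains non-finite (infinite) values")
    obs = ~np.isnan(vals)
    empty_rows = matrix.index[~obs.any(axis=1)].tolist()
    empty_cols = matrix.columns[~obs.any(axis=0)].tolist()
    if empty_rows or empty_cols:
        raise ValueError(
            f"rows/columns with no observed entries: rows={empty_rows}, "
            f"columns={empty_cols}"
        )

    imputed_mask = pd.DataFrame(~obs, index=matrix.index, columns=matrix.columns)
    if obs.all():
        return ImputationResult(matrix.copy(), 0, 0, True, imputed_mask)

    # observations are samples: Y is n_samples x n_taxa
    y = vals.T.copy()
    observed = obs.T
    n, d = y.shape
    q_max = min(n, d) - 1
    if q is None:
        q = q_max
    if not (1 <= q <= q_max):
        raise ValueError(f"q must be in [1, {q_max}], got {q}")

    rng = np.random.default_rng(seed)
    mu = np.array([y[observed[:, j], j].mean() for j in range(d)])
    yfill = np.where(observed, y, mu[None, :])

    centered = yfill - mu
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    w = (vt[:q].T * (s[:q] / np.sqrt(n))) + 1e-9 * rng.standard_normal((d, q))
    resid = centered - (u[:, :q] * s[:q]) @ vt[:q]
    tau = 1.0 / max((resid**2).sum() / (n * d), _EPS)
    alpha = d / (np.sum(w**2, axis=0) + _EPS)

    missing = ~observed
    complete = observed.all(axis=1)
    prev_imp = yfill[missing]
    n_iter = 0
    converged = False
    eye_q = np.eye(q)

    for n_iter in range(1, max_iter + 1):
        tau = min(tau, _TAU_MAX)
        sxx = np.zeros((q, q))
        xs = np.zeros((n, q))

        if complete.any():
            m = w.T @ w + (1.0 / tau) * eye_q
            minv = np.linalg.inv(m)
            xc = (yfill[complete] - mu) @ w @ minv.T
            xs[complete] = xc
            sxx += xc.T @ xc + complete.sum() * (1.0 / tau) * minv
        for i in np.flatnonzero(~complete):
            o = observed[i]
            wo = w[o]
            m = wo.T @ wo + (1.0 / tau) * eye_q
            minv = np.linalg.inv(m)
            x = minv @ wo.T @ (y[i, o] - mu[o])
            xs[i] = x
            yfill[i, ~o] = w[~o] @ x + mu[~o]
            sxx += np.outer(x, x) + (1.0 / tau) * minv
        yfill[observed] = y[observed]
        syx = (yfill - mu).T @ xs

        w = syx @ np.linalg.inv(sxx + (1.0 / tau) * np.diag(alpha))
        mu = yfill.mean(axis=0)
        resid = yfill - mu - xs @ w.T
        tau = (n * d) / max((resid**2).sum(), _EPS)
        alpha = d / (np.sum(w**2, axis=0) + _EPS)

        new_imp = yfill[missing]
        delta = np.max(np.abs(new_imp - prev_imp))
        prev_imp = new_imp.copy()
        if delta < tol:
            converged = True
            break

    norms = np.sum(w**2, axis=0)
    n_axes = int(np.sum(norms > 1e-8 * max(norms.max(), _EPS)))

    out = matrix.copy()
    out.iloc[:, :] = yfill.T
    out.iloc[:, :] = np.where(obs, vals, yfill.T)  # observed entries exact
    return ImputationResult(out, n_axes, n_iter, converged, imputed_mask)


def _leaf_merge_heights(link: np.ndarray, n_leaves: int) -> np.ndarray:
    """Height at which each original leaf first joins the tree."""
    heights = np.full(n_leaves, np.nan)
    for a, b, h, _ in link:
        for node in (int(a), int(b)):
            if node < n_leaves and np.isnan(heights[node]):
                heights[node] = h
    return heights


def detect_outlier_samples(
    matrix: pd.DataFrame,
    cut_height: float | None = None,
    mad_factor: float = 12.0,
    n_clusters: int = 2,
) -> tuple[list[str], pd.Series]:
    """Flag outlier samples and partition the rest into sample clusters.

    Samples are clustered by average-linkage hierarchical clustering on the
    Euclidean distance between abundance profiles. A sample is an outlier if
    the height at which it first joins the dendrogram exceeds ``cut_height``,
    or, by default, the median joining height plus ``mad_factor`` times its
    (raw) median absolute deviation. Joining heights of homogeneous samples
    have a heavy right tail (late joiners merge near the root), so the
    default factor is deliberately large; genuine outliers sit an order of
    magnitude further out. Remaining samples are re-clustered and the tree
    cut into ``n_clusters`` major sample clusters.

    Returns the outlier sample ids and a Series of cluster labels (1-based)
    over the non-outlier samples; together they partition the samples.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples to detect outliers")
    profiles = matrix.to_numpy(dtype=float).T
    if np.isnan(profiles).any():
        raise ValueError("matrix must be complete (impute first)")
    link = linkage(pdist(profiles), method="average")
    heights = _leaf_merge_heights(link, profiles.shape[0])
    if cut_height is None:
        med = np.median(heights)
        mad = np.median(np.abs(heights - med))
        if mad == 0:  # all joining heights identical: nothing stands out
            mad = np.finfo(float).eps * max(abs(med), 1.0)
        cut_height = med + mad_factor * mad
    outlier_idx = np.flatnonzero(heights > cut_height)
    outliers = [matrix.columns[i] for i in outlier_idx]

    keep = np.setdiff1d(np.arange(profiles.shape[0]), outlier_idx)
    kept_cols = matrix.columns[keep]
    if keep.size == 1:
        labels = pd.Series([1], index=kept_cols, name="sample_cluster")
    else:
        sublink = linkage(pdist(profiles[keep]), method="average")
        k = min(n_clusters, keep.size)
        lab = fcluster(sublink, t=k, criterion="maxclust")
        labels = pd.Series(lab, index=kept_cols, name="sample_cluster")
    return outliers, labels
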