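"""Synthetic microbial communities with planted co-occurrence modules.

Abundance profiles are generated on a latent Gaussian scale: every taxon in
planted module ``m`` follows

    x_i = sqrt(w) * L_m + sqrt(1 - w) * eps_i + noise_sd * eta_i

where ``L_m`` is the module's standardized latent profile, ``w`` the target
within-module correlation, and ``eps_i``, ``eta_i`` iid standard Gaussian
noise. Background taxa are pure noise. A constant positive baseline is added
to mimic fluorescence positivity; Pearson correlation (the only scale the
downstream pipeline is sensitive to) is unaffected by the shift.

Clinical traits are linear combinations of the latent module profiles plus
noise; one pure-noise trait is always appended as a negative control for
module-trait correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: constant added to latent-scale values so abundances are typically positive
BASELINE = 10.0

BACKGROUND_LABEL = -1


class SyntheticSpecError(ValueError):
    """Raised when a SyntheticSpec violates one of its invariants."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-module synthetic community.

    Parameters
    ----------
    n_taxa:
        Total number of taxa (rows), planted plus background.
    n_samples:
        Number of samples (columns).
    module_sizes:
        Taxa per planted module; ``sum(module_sizes) + background_taxa``
        must equal ``n_taxa``.
    background_taxa:
        Number of unassigned pure-noise taxa.
    within_module_cor:
        Target pairwise Pearson correlation ``w`` within a module, in (0, 1].
    noise_sd:
        Standard deviation of additional measurement noise (latent units).
    missing_rate:
        Fraction of entries masked by :func:`inject_missing`, in [0, 1).
    n_outliers:
        Number of outlier samples shifted by :func:`inject_outliers`.
    outlier_shift:
        Outlier shift in units of per-taxon standard deviation.
    trait_loadings:
        Map module index -> loading of that module's latent profile on the
        corresponding trait.
    seed:
        RNG seed; identical specs produce bit-identical outputs.
    """

    n_taxa: int
    n_samples: int
    module_sizes: tuple[int, ...]
    background_taxa: int = 0
    within_module_cor: float = 0.8
    noise_sd: float = 0.3
    missing_rate: float = 0.0
    n_outliers: int = 0
    outlier_shift: float = 0.0
    trait_loadings: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "module_sizes", tuple(self.module_sizes))
        # JSON round-trips stringify dict keys; accept both
        object.__setattr__(
            self,
            "trait_loadings",
            {int(k): float(v) for k, v in self.trait_loadings.items()},
        )
        if sum(self.module_sizes) + self.background_taxa != self.n_taxa:
            raise SyntheticSpecError(
                "sum(module_sizes) + background_taxa must equal n_taxa: "
                f"{sum(self.module_sizes)} + {self.background_taxa} != {self.n_taxa}"
            )
        if not (0.0 < self.within_module_cor <= 1.0):
            raise SyntheticSpecError(
                f"within_module_cor must be in (0, 1], got {self.within_module_cor}"
            )
        if not (0.0 <= self.missing_rate < 1.0):
            raise SyntheticSpecError(
                f"missing_rate must be in [0, 1), got {self.missing_rate}"
            )
        if self.noise_sd < 0:
            raise SyntheticSpecError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_outliers >= self.n_samples:
            raise SyntheticSpecError(
                f"n_outliers ({self.n_outliers}) must be < n_samples ({self.n_samples})"
            )
        for m in self.trait_loadings:
            if not (0 <= m < len(self.module_sizes)):
                raise SyntheticSpecError(
                    f"trait_loadings refers to unknown module index {m}"
                )


@dataclass
class GroundTruth:
    """Planted structure behind a synthetic community.

    Attributes
    ----------
    labels:
        Per-taxon planted module index (``-1`` for background), indexed by
        taxon id.
    latent_profiles:
        modules x samples matrix of standardized latent profiles.
    outlier_ids:
        Sample identifiers shifted as outliers.
    trait_matrix:
        samples x traits matrix (one ``trait_m<i>`` per loaded module plus a
        pure-noise ``trait_noise`` negative control).
    """

    labels: pd.Series
    latent_profiles: pd.DataFrame
    outlier_ids: list[str]
    trait_matrix: pd.DataFrame


def _standardize_rows(a: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    sd = a.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return a / sd


def generate_community(spec: SyntheticSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate an abundance matrix with planted module structure.

    Returns the taxa x samples abundance DataFrame (with missing values and
    outliers already applied if the spec requests them) and the
    :class:`GroundTruth` describing the planted structure.
    """
    rng = np.random.default_rng(spec.seed)
    n_mod = len(spec.module_sizes)
    taxa = [f"taxon_{i:03d}" for i in range(spec.n_taxa)]
    samples = [f"sample_{j:04d}" for j in range(spec.n_samples)]

    latent = _standardize_rows(rng.standard_normal((max(n_mod, 1), spec.n_samples)))
    latent = latent[:n_mod]

    w = spec.within_module_cor
    x = np.empty((spec.n_taxa, spec.n_samples))
    labels = np.full(spec.n_taxa, BACKGROUND_LABEL, dtype=int)
    row = 0
    for m, size in enumerate(spec.module_sizes):
        eps = rng.standard_normal((size, spec.n_samples))
        x[row : row + size] = np.sqrt(w) * latent[m] + np.sqrt(1.0 - w) * eps
        labels[row : row + size] = m
        row += size
    if spec.background_taxa:
        x[row:] = rng.standard_normal((spec.background_taxa, spec.n_samples))
    if spec.noise_sd > 0:
        x += spec.noise_sd * rng.standard_normal(x.shape)
    x += BASELINE

    matrix = pd.DataFrame(x, index=taxa, columns=samples)

    trait_cols = {}
    for m, loading in sorted(spec.trait_loadings.items()):
        trait_cols[f"trait_m{m}"] = loading * latent[m] + rng.standard_normal(
            spec.n_samples
        )
    trait_cols["trait_noise"] = rng.standard_normal(spec.n_samples)
    traits = pd.DataFrame(trait_cols, index=samples)

    outlier_ids: list[str] = []
    if spec.n_outliers:
        matrix, outlier_ids = inject_outliers(
            matrix,
            spec.n_outliers,
            spec.outlier_shift,
            seed=int(rng.integers(2**31)),
        )
    if spec.missing_rate > 0:
        matrix = inject_missing(
            matrix, spec.missing_rate, seed=int(rng.integers(2**31))
        )

    truth = GroundTruth(
        labels=pd.Series(labels, index=taxa, name="module"),
        latent_profiles=pd.DataFrame(
            latent,
            index=[f"module_{m}" for m in range(n_mod)],
            columns=samples,
        ),
        outlier_ids=outlier_ids,
        trait_matrix=traits,
    )
    return matrix, truth


def inject_missing(matrix: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Mask an exact count of entries missing-completely-at-random.

    Exactly ``round(rate * n_entries)`` cells are set to NaN, chosen
    uniformly among cells whose removal cannot empty a row or column: every
    row and column is guaranteed to retain at least one observed entry
    (downstream imputation requires it). Non-masked entries are preserved
    bit-identically.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"missing rate must be in [0, 1), got {rate}")
    if rate == 0.0:
        return matrix.copy()
    rng = np.random.default_rng(seed)
    n, p = matrix.shape
    total = n * p
    k = int(round(rate * total))

    # protect one random cell per row, extending cover to any column missed
    protected = np.zeros((n, p), dtype=bool)
    cols_for_rows = rng.integers(0, p, size=n)
    protected[np.arange(n), cols_for_rows] = True
    for j in np.flatnonzero(~protected.any(axis=0)):
        protected[rng.integers(0, n), j] = True

    candidates = np.flatnonzero(~protected.ravel())
    if k > candidates.size:
        raise ValueError(
            f"cannot mask {k} of {total} entries while keeping every row and "
            "column observed; lower the rate"
        )
    chosen = rng.choice(candidates, size=k, replace=False)
    out = matrix.copy()
    flat = out.to_numpy().ravel()
    flat[chosen] = np.nan
    out.iloc[:, :] = flat.reshape(n, p)
    return out


def inject_outliers(
    matrix: pd.DataFrame, n_outliers: int, shift: float, seed: int
) -> tuple[pd.DataFrame, list[str]]:
    """Shift randomly chosen samples by ``shift`` per-taxon standard deviations.

    Returns the modified matrix and the shifted sample identifiers. A
    negative shift is allowed and displaces samples symmetrically.
    """
    n, p = matrix.shape
    if n_outliers >= p:
        raise ValueError(f"n_outliers ({n_outliers}) must be < n_samples ({p})")
    out = matrix.copy()
    if n_outliers == 0:
        return out, []
    rng = np.random.default_rng(seed)
    idx = rng.choice(p, size=n_outliers, replace=False)
    sd = out.to_numpy().std(axis=1)
    vals = out.to_numpy()
    vals[:, idx] = vals[:, idx] + shift * sd[:, None]
    out.iloc[:, :] = vals
    return out, [matrix.columns[i] for i in sorted(idx)]
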