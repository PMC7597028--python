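"""Diffusion maps and dual-rooted diffusion pseudotime.

The diffusion map is built from a symmetrized kNN graph with a Gaussian
kernel under per-point adaptive bandwidths (the distance to the k-th
neighbor), density-normalized anisotropically (alpha = 1) and row-normalized
into a transition operator. Diffusion pseudotime from a root is the
Euclidean distance between accumulated-transition representations,
sum_i (lambda_i / (1 - lambda_i)) * psi_i, of the root and each sample.

Rooting the pseudotime in each normal tissue in turn and intersecting the
two time lines tests whether tumors sit between the two candidate origins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import pairwise_distances
from sklearn.neighbors import NearestNeighbors

from .methyl import MethylCohort

__all__ = [
    "DiffusionResult",
    "PseudotimeResult",
    "DiffusionMap",
    "diffusion_map",
    "diffusion_pseudotime",
    "select_root",
    "intersection_analysis",
]

_EIG_CLIP = 1e-10  # guard for lambda -> 1 in the pseudotime accumulation


@dataclass
class DiffusionResult:
    """Eigenpairs of the diffusion operator over a fitted sample set.

    ``eigenvalues`` are the nontrivial eigenvalues in decreasing order (the
    trivial unit eigenvalue is dropped); ``components`` holds the right
    eigenvectors scaled by their eigenvalues (samples x components);
    ``psi`` holds the unscaled right eigenvectors, orthonormal under the
    stationary-distribution inner product.
    """

    eigenvalues: np.ndarray
    components: pd.DataFrame
    psi: pd.DataFrame = field(repr=False)
    stationary: np.ndarray = field(repr=False)
    transition_row_sums: np.ndarray = field(repr=False)
    knn_k: int = 0

    @property
    def sample_ids(self) -> pd.Index:
        return self.components.index


@dataclass
class PseudotimeResult:
    """Diffusion pseudotime from one root sample."""

    root_sample_id: str
    dpt: pd.Series
    scaled_dpt: pd.Series


def diffusion_map(x, knn_k: int = 20, n_comps: int = 15) -> DiffusionResult:
    """Compute the diffusion map of a sample x feature matrix.

    Raises if ``knn_k`` is not smaller than the number of samples. Duplicate
    samples (zero distances) are handled by the kernel and are not an error.
    """
    X = x if isinstance(x, pd.DataFrame) else pd.DataFrame(np.asarray(x, dtype=float))
    values = X.to_numpy(dtype=float)
    n = values.shape[0]
    if knn_k >= n:
        raise ValueError(f"knn_k={knn_k} must be < n_samples={n}")
    n_comps = min(n_comps, n - 1)

    dist = pairwise_distances(values)
    nn = NearestNeighbors(n_neighbors=knn_k + 1).fit(values)
    knn_dist, knn_idx = nn.kneighbors(values)
    sigma = knn_dist[:, -1]  # distance to the k-th neighbor (self excluded)
    sigma = np.where(sigma > 0, sigma, np.min(sigma[sigma > 0]) if (sigma > 0).any() else 1.0)

    mask = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), knn_k + 1)
    mask[rows, knn_idx.ravel()] = True
    mask |= mask.T  # symmetrized neighborhood
    np.fill_diagonal(mask, True)

    with np.errstate(over="ignore"):
        kernel = np.exp(-(dist ** 2) / (sigma[:, None] * sigma[None, :]))
    kernel = np.where(mask, kernel, 0.0)

    # anisotropic normalization (alpha = 1) removes sampling-density bias
    q = kernel.sum(axis=1)
    k1 = kernel / (q[:, None] * q[None, :])
    d1 = k1.sum(axis=1)
    transition = k1 / d1[:, None]

    # symmetric conjugate shares the spectrum; eigh is stable
    d_isqrt = 1.0 / np.sqrt(d1)
    sym = k1 * d_isqrt[:, None] * d_isqrt[None, :]
    sym = (sym + sym.T) / 2.0
    evals, evecs = eigh(sym)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    stationary = d1 / d1.sum()
    # right eigenvectors of the transition operator, orthonormal under the
    # stationary distribution: psi = v / sqrt(pi)
    psi_all = evecs / np.sqrt(stationary)[:, None]

    lam = np.clip(evals[1:n_comps + 1], -1.0, 1.0)
    psi = psi_all[:, 1:n_comps + 1]
    comps = psi * lam[None, :]

    return DiffusionResult(
        eigenvalues=lam,
        components=pd.DataFrame(comps, index=X.index),
        psi=pd.DataFrame(psi, index=X.index),
        stationary=stationary,
        transition_row_sums=transition.sum(axis=1),
        knn_k=knn_k,
    )


class DiffusionMap(TransformerMixin, BaseEstimator):
    """Estimator wrapper around :func:`diffusion_map` (transductive)."""

    def __init__(self, knn_k: int = 20, n_comps: int = 15):
        self.knn_k = knn_k
        self.n_comps = n_comps

    def fit(self, X, y=None):
        self.result_ = diffusion_map(X, knn_k=self.knn_k, n_comps=self.n_comps)
        self.eigenvalues_ = self.result_.eigenvalues
        self.embedding_ = self.result_.components
        return self

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X).embedding_

    def transform(self, X):  # pragma: no cover - transductive embedding
        raise NotImplementedError("diffusion map is transductive; refit on all samples")


def diffusion_pseudotime(result: DiffusionResult, root) -> PseudotimeResult:
    """Diffusion pseudotime of every sample from the given root."""
    if root not in result.sample_ids:
        raise KeyError(f"root sample {root!r} not in the diffusion result")
    lam = np.clip(result.eigenvalues, -1.0 + _EIG_CLIP, 1.0 - _EIG_CLIP)
    weight = lam / (1.0 - lam)
    rep = result.psi.to_numpy() * weight[None, :]
    root_pos = result.sample_ids.get_loc(root)
    diff = rep - rep[root_pos]
    dpt = pd.Series(np.linalg.norm(diff, axis=1), index=result.sample_ids)
    rng = dpt.max() - dpt.min()
    scaled = (dpt - dpt.min()) / rng if rng > 0 else dpt * 0.0
    return PseudotimeResult(root_sample_id=str(root), dpt=dpt, scaled_dpt=scaled)


def select_root(result: DiffusionResult, tissue, tissue_class: str) -> str:
    """Pick the most peripheral sample of a tissue class as pseudotime root.

    Peripherality is the extremity (maximal absolute value) of the first
    diffusion component; ties break deterministically by sample id order.
    """
    tissue = pd.Series(tissue).reindex(result.sample_ids)
    candidates = result.sample_ids[tissue == tissue_class]
    if len(candidates) == 0:
        raise ValueError(f"no samples of class {tissue_class!r}")
    comp1 = result.components.iloc[:, 0].loc[candidates].abs()
    winners = sorted(comp1.index[comp1 == comp1.max()])  # id-order tie break
    return str(winners[0])


def intersection_analysis(dpt_fi: PseudotimeResult, dpt_ose: PseudotimeResult,
                          classes) -> dict:
    """Locate where the FI-rooted and OSE-rooted time lines intersect.

    The intersection sample minimizes |scaled FI pseudotime - scaled OSE
    pseudotime|. Tumor intermediacy is the fraction of tumors whose
    FI-rooted pseudotime rank lies strictly between the median ranks of the
    FI and OSE normals — the operational reading of tumors being a
    mandatory step between the two origins.
    """
    if not dpt_fi.dpt.index.equals(dpt_ose.dpt.index):
        raise ValueError("pseudotime results cover different sample sets")
    classes = pd.Series(classes).reindex(dpt_fi.dpt.index)
    if classes.isna().any():
        raise ValueError("classes must cover every sample")

    gap = (dpt_fi.scaled_dpt - dpt_ose.scaled_dpt).abs()
    degenerate = bool(gap.max() - gap.min() < 1e-12)
    if degenerate:
        intersection = sorted(gap.index)[0]
    else:
        best = gap.min()
        intersection = sorted(gap.index[gap == best])[0]

    ranks = dpt_fi.scaled_dpt.rank(method="average")
    med_fi = ranks[classes == "FI"].median()
    med_ose = ranks[classes == "OSE"].median()
    lo, hi = min(med_fi, med_ose), max(med_fi, med_ose)
    tumor_ranks = ranks[classes == "TUMOR"]
    intermediacy = float(((tumor_ranks > lo) & (tumor_ranks < hi)).mean()) \
        if len(tumor_ranks) else float("nan")

    return {
        "intersection_sample": str(intersection),
        "intersection_is_tumor": bool(classes.loc[intersection] == "TUMOR"),
        "tumor_intermediacy": intermediacy,
        "degenerate": degenerate,
        "median_rank_fi": float(med_fi),
        "median_rank_ose": float(med_ose),
    }
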