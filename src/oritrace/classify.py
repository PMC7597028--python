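"""Origin classification of tumors in OriPrint space.

Three clustering routes (Pearson-correlation Ward hierarchical, Louvain on
top principal components, density-based on diffusion-map coordinates) plus a
Gaussian-mixture check bipartition the cohort; cluster sides are named by
normal anchoring (which cluster holds the FI vs OSE normals, with a
nearest-centroid correlation fallback), and per-tumor votes are fused into a
consensus call with an "uncertain" category below the consistency threshold.

All classifiers are transductive clusterers in the scikit-learn sense:
``fit(X, tissue)`` sets ``labels_`` over the fitted samples (there is no
out-of-sample ``predict``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import HDBSCAN
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import kneighbors_graph

from .methyl import MethylCohort
from .params import PipelineConfig
from .signature import OriPrintSignature

__all__ = [
    "NormalSpacePCA",
    "PearsonWardOriginClassifier",
    "LouvainOriginClassifier",
    "DensityOriginClassifier",
    "GMMOriginClassifier",
    "consensus_call",
    "classify_cohort",
    "ConsensusResult",
]

FI_SIDE = "FI-like"
OSE_SIDE = "OSE-like"
UNCERTAIN = "uncertain"


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


def _pearson_to_centroids(X: np.ndarray, cent_fi: np.ndarray,
                          cent_ose: np.ndarray) -> np.ndarray:
    """Per-row Pearson correlation difference corr(x, FI) - corr(x, OSE)."""
    def corr(a, b):
        a = a - a.mean(axis=-1, keepdims=True)
        b = b - b.mean()
        denom = np.sqrt((a ** 2).sum(axis=-1) * (b ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, (a * b).sum(axis=-1) / denom, 0.0)
    return corr(X, cent_fi) - corr(X, cent_ose)


def anchor_cluster_sides(cluster: np.ndarray, tissue: np.ndarray,
                         X: np.ndarray) -> dict[int, str]:
    """Name the two clusters FI-like / OSE-like by their normal content.

    A cluster holding more FI than OSE normals is FI-like (and conversely);
    clusters without normals, or with tied/clashing majorities, fall back to
    the Pearson correlation of the cluster centroid against the FI and OSE
    normal centroids. The two clusters always receive different sides.
    """
    ids = np.unique(cluster)
    if len(ids) != 2:
        raise ValueError(f"expected exactly 2 clusters, got {len(ids)}")
    fi_mask = tissue == "FI"
    ose_mask = tissue == "OSE"
    if not fi_mask.any() or not ose_mask.any():
        raise ValueError("anchoring requires both FI and OSE normals")
    cent_fi = X[fi_mask].mean(axis=0)
    cent_ose = X[ose_mask].mean(axis=0)

    scores = {}
    for c in ids:
        members = cluster == c
        n_fi = int((members & fi_mask).sum())
        n_ose = int((members & ose_mask).sum())
        corr_diff = float(_pearson_to_centroids(X[members].mean(axis=0)[None, :],
                                                cent_fi, cent_ose)[0])
        scores[c] = (n_fi - n_ose, corr_diff)

    a, b = ids
    fi_cluster = a if scores[a] >= scores[b] else b
    return {fi_cluster: FI_SIDE, (b if fi_cluster == a else a): OSE_SIDE}


def _merge_to_two(labels: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Agglomerate clusters by nearest-centroid merging until 2 remain."""
    labels = labels.copy()
    while len(np.unique(labels)) > 2:
        ids = np.unique(labels)
        cents = np.vstack([X[labels == c].mean(axis=0) for c in ids])
        d = np.linalg.norm(cents[:, None, :] - cents[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        labels[labels == ids[j]] = ids[i]
    return labels


class _OriginClustererBase(ClusterMixin, BaseEstimator):
    """Shared fit plumbing: validate inputs, cluster, anchor, store labels."""

    def _prepare(self, X, tissue):
        X = _as_frame(X)
        tissue = np.asarray(pd.Series(tissue), dtype=object)
        if len(tissue) != X.shape[0]:
            raise ValueError("tissue labels must match the number of samples (rows)")
        return X, tissue

    def _finish(self, X: pd.DataFrame, tissue: np.ndarray,
                cluster: np.ndarray, anchor_X: Optional[np.ndarray] = None):
        side_of = anchor_cluster_sides(cluster, tissue,
                                       X.to_numpy() if anchor_X is None else anchor_X)
        self.cluster_ = pd.Series(cluster, index=X.index)
        self.labels_ = pd.Series([side_of[c] for c in cluster], index=X.index)
        return self

    def fit_predict(self, X, y=None, **kwargs):
        self.fit(X, y, **kwargs)
        return self.labels_


class PearsonWardOriginClassifier(_OriginClustererBase):
    """Ward hierarchical clustering on 1 - Pearson correlation distances.

    The Lance-Williams Ward update on a precomputed distance matrix is the
    "ward.D2" convention. The tree is cut at two clusters and sides are
    named by normal anchoring.
    """

    def fit(self, X, y=None):
        X, tissue = self._prepare(X, y)
        values = X.to_numpy(dtype=float)
        sd = values.std(axis=1)
        if np.any(sd == 0):
            bad = X.index[sd == 0].tolist()
            raise ValueError(f"constant profile, Pearson correlation undefined: {bad}")
        corr = np.corrcoef(values)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        z = linkage(squareform(dist, checks=False), method="ward")
        cluster = fcluster(z, t=2, criterion="maxclust")
        return self._finish(X, tissue, cluster)


class LouvainOriginClassifier(_OriginClustererBase):
    """Louvain community detection on the top principal components.

    A symmetrized unweighted kNN graph is built over the first
    ``n_pcs`` principal components of all samples; Louvain communities are
    agglomerated by nearest-centroid merging until exactly two remain.
    """

    def __init__(self, n_pcs: int = 50, knn_k: int = 20, random_state: int = 0):
        self.n_pcs = n_pcs
        self.knn_k = knn_k
        self.random_state = random_state

    def fit(self, X, y=None):
        X, tissue = self._prepare(X, y)
        n = X.shape[0]
        if n < self.knn_k + 1:
            raise ValueError(f"need more than knn_k={self.knn_k} samples, got {n}")
        n_comp = min(self.n_pcs, n - 1, X.shape[1])
        coords = PCA(n_components=n_comp, random_state=self.random_state).fit_transform(
            X.to_numpy(dtype=float))
        adj = kneighbors_graph(coords, n_neighbors=self.knn_k, mode="connectivity")
        adj = adj.maximum(adj.T)
        graph = nx.from_scipy_sparse_array(adj)

        if not nx.is_connected(graph):
            comps = list(nx.connected_components(graph))
            normal_mask = np.isin(tissue, ("FI", "OSE"))
            for comp in comps:
                idx = np.fromiter(comp, dtype=int)
                if len(idx) == 1 and normal_mask[idx[0]]:
                    raise ValueError(
                        "kNN graph is disconnected with an isolated normal sample; "
                        "increase knn_k")

        communities = nx.community.louvain_communities(
            graph, weight="weight", seed=self.random_state)
        labels = np.empty(n, dtype=int)
        for c, members in enumerate(communities):
            labels[list(members)] = c
        labels = _merge_to_two(labels, coords)
        self.coords_ = pd.DataFrame(coords, index=X.index)
        return self._finish(X, tissue, labels, anchor_X=X.to_numpy())


class DensityOriginClassifier(_OriginClustererBase):
    """Hierarchical density clustering on diffusion-map coordinates.

    HDBSCAN proposes density clusters; the hierarchy is reduced to exactly
    two clusters by nearest-centroid agglomeration, and noise points are
    assigned to the nearer surviving centroid.
    """

    def __init__(self, min_cluster_size: int = 5):
        self.min_cluster_size = min_cluster_size

    def fit(self, X, y=None):
        """``X`` are diffusion-map coordinates (samples x components)."""
        X, tissue = self._prepare(X, y)
        coords = X.to_numpy(dtype=float)
        mcs = min(self.min_cluster_size, max(2, X.shape[0] // 4))
        raw = HDBSCAN(min_cluster_size=mcs, allow_single_cluster=False,
                      copy=True).fit_predict(coords)
        clusters = np.unique(raw[raw >= 0])
        if len(clusters) < 2:
            raise ValueError(
                f"density clustering found {len(clusters)} cluster(s); "
                "cannot impose a bipartition")
        labels = raw.copy()
        core = labels >= 0
        labels[core] = _merge_to_two(labels[core], coords[core])
        ids = np.unique(labels[core])
        cents = np.vstack([coords[labels == c].mean(axis=0) for c in ids])
        for i in np.where(~core)[0]:
            labels[i] = ids[np.argmin(np.linalg.norm(cents - coords[i], axis=1))]
        return self._finish(X, tissue, labels, anchor_X=coords)


class GMMOriginClassifier(_OriginClustererBase):
    """Two-component full-covariance Gaussian mixture, best of many restarts.

    The mixture is fit on the tumor samples' coordinates (the bipartition
    of interest is among tumors; normals are then assigned by posterior
    argmax and used only to name the two components). Each restart runs EM
    from a random initialization drawn from its own seeded stream; the
    restart with the highest total log-likelihood wins, so the best
    log-likelihood is non-decreasing in the number of restarts for a fixed
    seed. Degenerate fits are discarded.
    """

    def __init__(self, n_restarts: int = 2000, n_components: int = 2,
                 random_state: int = 0):
        self.n_restarts = n_restarts
        self.n_components = n_components
        self.random_state = random_state

    def fit(self, X, y=None):
        X, tissue = self._prepare(X, y)
        coords = X.to_numpy(dtype=float)
        if coords.shape[0] < 4:
            raise ValueError("need >= 4 samples for the mixture fit")
        tumor_mask = tissue == "TUMOR"
        fit_coords = coords[tumor_mask] if tumor_mask.sum() >= 4 else coords
        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_restarts)
        best, best_ll = None, -np.inf
        for child in seeds:
            seed_i = int(child.generate_state(1)[0] % (2 ** 31))
            gm = GaussianMixture(
                n_components=self.n_components, covariance_type="full",
                init_params="random_from_data", n_init=1, max_iter=200,
                reg_covar=1e-9, random_state=seed_i)
            try:
                gm.fit(fit_coords)
            except ValueError:
                continue  # degenerate covariance: discard this restart
            ll = float(gm.score(fit_coords) * fit_coords.shape[0])
            if np.isfinite(ll) and ll > best_ll:
                best, best_ll = gm, ll
        if best is None:
            raise ValueError("all mixture restarts were degenerate")
        self.best_loglik_ = best_ll
        self.model_ = best
        cluster = best.predict(coords)
        return self._finish(X, tissue, cluster, anchor_X=coords)


class NormalSpacePCA(BaseEstimator):
    """PCA fit on normal samples only; tumors are projected, never fitted.

    The embedding is the "space defined by normal samples": loadings and
    centering come from FI+OSE beta profiles restricted to the signature,
    and any sample can then be projected into it.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        """``X``: normals x features; ``y`` ignored."""
        X = _as_frame(X)
        n, p = X.shape
        if n < 3:
            raise ValueError("need >= 3 normal samples to define the space")
        if self.n_components > min(n - 1, p):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(n_normals-1, n_features)"
                f"={min(n - 1, p)}")
        self._pca = PCA(n_components=self.n_components)
        self._pca.fit(X.to_numpy(dtype=float))
        self.center_ = pd.Series(self._pca.mean_, index=X.columns)
        self.loadings_ = pd.DataFrame(self._pca.components_.T, index=X.columns)
        self.explained_variance_ = self._pca.explained_variance_
        return self

    def transform(self, X) -> pd.DataFrame:
        X = _as_frame(X)
        coords = self._pca.transform(X.to_numpy(dtype=float))
        return pd.DataFrame(coords, index=X.index)

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)


@dataclass
class ConsensusResult:
    """Per-tumor consensus origin calls plus the method vote matrix."""

    calls: pd.DataFrame            # tumor rows: per-method votes, consistency, consensus
    concordance: float             # fraction of tumors on which ALL methods agree
    votes_all_samples: pd.DataFrame  # every sample's side per method (incl. normals)


def consensus_call(votes: pd.DataFrame, threshold: float = 0.75
                   ) -> tuple[pd.DataFrame, float]:
    """Fuse per-method votes into consensus calls.

    Per sample, consistency is the largest label share among methods; the
    consensus is the majority label when consistency reaches ``threshold``
    and "uncertain" otherwise. The overall concordance is the fraction of
    samples on which every method agrees.
    """
    if votes.shape[1] < 2:
        raise ValueError("need >= 2 methods")
    if votes.isna().any().any():
        bad = votes.index[votes.isna().any(axis=1)].tolist()
        raise ValueError(f"methods voted over different sample sets; missing votes for {bad}")

    def one(row: pd.Series) -> pd.Series:
        counts = row.value_counts()
        consistency = counts.iloc[0] / len(row)
        label = counts.index[0] if consistency >= threshold else UNCERTAIN
        return pd.Series({"consistency": consistency, "consensus": label})

    fused = votes.apply(one, axis=1)
    calls = pd.concat([votes, fused], axis=1)
    concordance = float((votes.nunique(axis=1) == 1).mean())
    return calls, concordance


def classify_cohort(cohort: MethylCohort, signature: OriPrintSignature,
                    config: Optional[PipelineConfig] = None,
                    methods: Sequence[str] = ("pearson", "louvain", "density"),
                    space: str = "oriprint") -> ConsensusResult:
    """Run the requested classifiers in signature (or global) space and fuse votes.

    ``space="oriprint"`` restricts beta values to the signature CpGs (the
    default analysis space); ``space="global"`` uses all CpGs, which probes
    whether the origin signal survives the dominant tumor-vs-normal variance.
    """
    from .trajectory import diffusion_map  # local import avoids a cycle

    config = config or PipelineConfig()
    if space == "oriprint":
        if len(signature) == 0:
            raise ValueError("signature is empty; cannot classify in OriPrint space")
        beta = cohort.beta.loc[signature.cpgs]
    elif space == "global":
        beta = cohort.beta
    else:
        raise ValueError("space must be 'oriprint' or 'global'")

    X = beta.T  # samples x features
    tissue = cohort.samples["tissue_class"]
    knn_k = min(config.knn_k, X.shape[0] - 1)

    votes = {}
    for method in methods:
        if method == "pearson":
            est = PearsonWardOriginClassifier()
            votes[method] = est.fit_predict(X, tissue)
        elif method == "louvain":
            est = LouvainOriginClassifier(n_pcs=config.n_pcs_louvain, knn_k=knn_k,
                                          random_state=config.seed)
            votes[method] = est.fit_predict(X, tissue)
        elif method == "density":
            dm = diffusion_map(X, knn_k=knn_k,
                               n_comps=min(config.n_diffusion_comps, X.shape[0] - 2))
            est = DensityOriginClassifier()
            votes[method] = est.fit_predict(dm.components, tissue)
        elif method == "gmm":
            pcs = PCA(n_components=2, random_state=config.seed).fit_transform(
                X.to_numpy(dtype=float))
            est = GMMOriginClassifier(n_restarts=config.gmm_restarts,
                                      random_state=config.seed)
            votes[method] = est.fit_predict(pd.DataFrame(pcs, index=X.index), tissue)
        else:
            raise ValueError(f"unknown method: {method}")

    votes_all = pd.DataFrame(votes)
    tumor_votes = votes_all.loc[cohort.tumors]
    calls, concordance = consensus_call(tumor_votes, config.consistency_threshold)
    return ConsensusResult(calls=calls, concordance=concordance,
                           votes_all_samples=votes_all)
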