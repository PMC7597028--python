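"""Transcriptomic translation of the methylation-defined subtypes.

TMM library-size normalization, moderated differential expression, the
coherent two-evidence signature, external-cohort stratification with an
"uncertain" category, and the bagging-consistency robustness procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import kneighbors_graph
from sklearn.tree import DecisionTreeClassifier

from .params import PipelineConfig
from .signature import moderated_t_test

__all__ = [
    "ExprCohort",
    "TranscriptomicSignature",
    "tmm_normalize",
    "differential_expression",
    "build_signature",
    "classify_external_cohort",
    "bagging_consistency",
    "BaggingConsistencyClassifier",
]

FI_SIDE = "FI-like"
OSE_SIDE = "OSE-like"
UNCERTAIN = "uncertain"


@dataclass
class ExprCohort:
    """Gene x sample counts with TMM-normalized logCPM and a sample sheet."""

    counts: pd.DataFrame
    logcpm: pd.DataFrame
    size_factors: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if not self.counts.columns.equals(self.logcpm.columns):
            raise ValueError("counts and logcpm must share samples")
        if not self.samples.index.is_unique or not self.counts.index.is_unique:
            raise ValueError("sample and gene ids must be unique")


def tmm_normalize(counts: pd.DataFrame, logratio_trim: float = 0.3,
                  sum_trim: float = 0.05, prior_count: float = 0.5
                  ) -> tuple[pd.Series, pd.DataFrame]:
    """Trimmed-mean-of-M-values normalization factors and logCPM.

    The reference library is the one whose 75th-percentile count fraction is
    closest to the mean across libraries. For each library, gene-wise
    log-ratios (M) against the reference are doubly trimmed — 30% of each
    tail on M, 5% of each tail on absolute intensity (A) — and averaged with
    inverse-asymptotic-variance weights. Factors are rescaled to geometric
    mean 1. logCPM uses effective library sizes with a library-size-scaled
    prior count, so exactly proportional libraries get identical logCPM.
    """
    y = counts.to_numpy(dtype=float)
    if y.shape[1] < 2:
        raise ValueError("need >= 2 libraries")
    lib = y.sum(axis=0)
    if (lib == 0).any():
        bad = counts.columns[lib == 0].tolist()
        raise ValueError(f"all-zero libraries: {bad}")

    f75 = np.array([np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    log2_factors = np.zeros(y.shape[1])
    yr, nr = y[:, ref], lib[ref]
    for j in range(y.shape[1]):
        if j == ref:
            continue
        yk, nk = y[:, j], lib[j]
        ok = (yk > 0) & (yr > 0)
        if ok.sum() == 0:
            continue
        m = np.log2((yk[ok] / nk) / (yr[ok] / nr))
        a = 0.5 * np.log2((yk[ok] / nk) * (yr[ok] / nr))
        w = (nk - yk[ok]) / (nk * yk[ok]) + (nr - yr[ok]) / (nr * yr[ok])

        n_ok = ok.sum()
        lo_m = np.floor(n_ok * logratio_trim) + 1
        hi_m = n_ok + 1 - lo_m
        lo_a = np.floor(n_ok * sum_trim) + 1
        hi_a = n_ok + 1 - lo_a
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.sum() == 0 or not np.isfinite(w[keep]).all():
            log2_factors[j] = 0.0
        else:
            with np.errstate(divide="ignore"):
                inv_w = 1.0 / w[keep]
            log2_factors[j] = float(np.sum(m[keep] * inv_w) / np.sum(inv_w))

    factors = np.exp2(log2_factors)
    factors = factors / np.exp(np.mean(np.log(factors)))  # geometric mean 1
    size_factors = pd.Series(factors, index=counts.columns, name="size_factor")

    eff_lib = factors * lib
    prior = prior_count * eff_lib / eff_lib.mean()
    logcpm = np.log2((y + prior[None, :]) / (eff_lib + 2.0 * prior)[None, :] * 1e6)
    return size_factors, pd.DataFrame(logcpm, index=counts.index, columns=counts.columns)


def differential_expression(logcpm: pd.DataFrame, labels,
                            de_fdr: float = 0.05, de_min_lfc: float = 0.8,
                            groups: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Moderated two-group test on logCPM with FDR and effect thresholds.

    Returns the full gene table with ``logFC`` (alternative minus
    reference), moderated ``t_stat``, ``p``, ``p_adj`` and a boolean
    ``significant`` column (p_adj < de_fdr and |logFC| > de_min_lfc).
    """
    table = moderated_t_test(logcpm, labels, groups=groups)
    table = table.rename(columns={"delta_m": "logFC"})
    table["significant"] = (table["p_adj"] < de_fdr) & (table["logFC"].abs() > de_min_lfc)
    return table


@dataclass
class TranscriptomicSignature:
    """Genes coherently differential in both evidence sets, with direction.

    ``genes`` maps gene id -> +1 (up in OSE-like) or -1 (down in OSE-like).
    """

    genes: pd.Series
    evidence: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def to_dict(self) -> dict:
        return {"genes": {str(g): float(d) for g, d in self.genes.items()},
                "evidence": self.evidence}


def build_signature(de_cells: pd.DataFrame, de_ffpe: pd.DataFrame
                    ) -> TranscriptomicSignature:
    """Intersect two DE tables: significant in both with the same sign."""
    for name, t in [("cells", de_cells), ("ffpe", de_ffpe)]:
        if "significant" not in t or "logFC" not in t:
            raise ValueError(f"{name} table must carry 'significant' and 'logFC' columns")
    sig_a = de_cells.index[de_cells["significant"]]
    sig_b = de_ffpe.index[de_ffpe["significant"]]
    common = sig_a.intersection(sig_b)
    same_sign = common[
        np.sign(de_cells.loc[common, "logFC"]) == np.sign(de_ffpe.loc[common, "logFC"])]
    genes = pd.Series(np.sign(de_cells.loc[same_sign, "logFC"]), index=same_sign)
    if len(genes) == 0:
        warnings.warn("coherent signature is empty", stacklevel=2)
    return TranscriptomicSignature(
        genes=genes,
        evidence={"n_cells": int(len(sig_a)), "n_ffpe": int(len(sig_b))},
    )


def classify_external_cohort(logcpm: pd.DataFrame, signature: TranscriptomicSignature,
                             resolution_range: tuple[float, float] = (0.1, 1.5),
                             n_resolutions: int = 15, knn_k: int = 15,
                             random_state: int = 0) -> pd.DataFrame:
    """Stratify an external cohort on the coherent signature.

    Samples are z-scored per signature gene; Louvain partitions are scanned
    over a resolution grid and the most stable one (maximal adjusted-Rand
    agreement with its grid neighbors, among partitions with >= 2
    communities) is kept. The two communities with the most distant
    centroids in diffusion-map coordinates are retained as robustly
    stratified; all other samples are "uncertain". The retained cluster
    with the higher signed signature-concordance score (mean over signature
    genes of sign(cluster mean z) x direction) is OSE-like.
    """
    from .trajectory import diffusion_map

    present = signature.genes.index.intersection(logcpm.index)
    if len(present) < 3:
        raise ValueError(f"only {len(present)} signature genes present in the cohort")
    if logcpm.shape[1] < 10:
        raise ValueError("need >= 10 samples")
    direction = signature.genes.loc[present]

    x = logcpm.loc[present].to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    X = z.T  # samples x genes
    samples = logcpm.columns

    k = min(knn_k, X.shape[0] - 1)
    adj = kneighbors_graph(X, n_neighbors=k, mode="connectivity")
    adj = adj.maximum(adj.T)
    graph = nx.from_scipy_sparse_array(adj)

    resolutions = np.linspace(resolution_range[0], resolution_range[1], n_resolutions)
    partitions = []
    for res in resolutions:
        comms = nx.community.louvain_communities(graph, weight="weight",
                                                 resolution=float(res),
                                                 seed=random_state)
        labels = np.empty(X.shape[0], dtype=int)
        for c, members in enumerate(comms):
            labels[list(members)] = c
        partitions.append(labels)

    eligible = [i for i, p in enumerate(partitions) if len(np.unique(p)) >= 2]
    if not eligible:
        raise ValueError("no resolution produced >= 2 communities")
    stability = {}
    for i in eligible:
        neigh = [j for j in (i - 1, i + 1) if 0 <= j < len(partitions)]
        stability[i] = float(np.mean([
            adjusted_rand_score(partitions[i], partitions[j]) for j in neigh]))
    chosen = max(eligible, key=lambda i: (stability[i], -i))
    labels = partitions[chosen]

    # the diffusion embedding needs a connected graph: a k that is good for
    # community detection can leave well-separated clusters as disconnected
    # components with degenerate (rotation-arbitrary) eigenvectors
    from scipy.sparse.csgraph import connected_components
    k_diff = k
    while k_diff < X.shape[0] - 1:
        g = kneighbors_graph(X, n_neighbors=k_diff, mode="connectivity")
        if connected_components(g.maximum(g.T), directed=False)[0] == 1:
            break
        k_diff = min(2 * k_diff, X.shape[0] - 1)
    dm = diffusion_map(pd.DataFrame(X, index=samples), knn_k=k_diff,
                       n_comps=min(15, X.shape[0] - 2))
    coords = dm.components.to_numpy()
    ids = np.unique(labels)
    cents = {c: coords[labels == c].mean(axis=0) for c in ids}
    best_pair, best_d = None, -np.inf
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            d = float(np.linalg.norm(cents[a] - cents[b]))
            if d > best_d:
                best_pair, best_d = (a, b), d
    kept_a, kept_b = best_pair

    def concordance(c: int) -> float:
        mean_z = z[:, labels == c].mean(axis=1)
        return float(np.mean(np.sign(mean_z) * direction.to_numpy()))

    side = {}
    if concordance(kept_a) >= concordance(kept_b):
        side[kept_a], side[kept_b] = OSE_SIDE, FI_SIDE
    else:
        side[kept_a], side[kept_b] = FI_SIDE, OSE_SIDE

    out = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    out["cluster"] = labels
    out["label"] = [side.get(c, UNCERTAIN) for c in labels]
    out.attrs["resolution"] = float(resolutions[chosen])
    return out


class BaggingConsistencyClassifier(BaseEstimator):
    """Bagged-tree consistency filter over repeated splits and gene subsets.

    Starting from an initial two-class stratification, the procedure
    perturbs both the gene set fed to the model (``n_gene_permutations``
    redraws) and the stratified 70/30 train/test split
    (``n_split_shuffles`` redraws); every iteration redraws both, so each
    sample's held-out predictions span many splits and many gene subsets
    and the consistency score measures robustness to the two perturbation
    sources jointly. Each iteration trains a bagged ensemble of decision
    trees on random patches (random sample x feature subsets) of the
    training data, grown by doubling until its test predictions stabilize,
    and predicts the held-out samples. A sample's consistency is the
    fraction of its held-out appearances predicted with its modal label;
    samples below ``consistency_threshold`` are "uncertain".
    """

    def __init__(self, n_gene_permutations: int = 100, n_split_shuffles: int = 100,
                 train_fraction: float = 0.7, consistency_threshold: float = 0.75,
                 gene_fraction: float = 0.5, max_trees: int = 64,
                 min_class_size: int = 10, random_state: int = 0):
        self.n_gene_permutations = n_gene_permutations
        self.n_split_shuffles = n_split_shuffles
        self.train_fraction = train_fraction
        self.consistency_threshold = consistency_threshold
        self.gene_fraction = gene_fraction
        self.max_trees = max_trees
        self.min_class_size = min_class_size
        self.random_state = random_state

    def _stratified_split(self, y: np.ndarray, rng: np.random.Generator):
        train_idx = []
        for cls in np.unique(y):
            idx = np.where(y == cls)[0]
            rng.shuffle(idx)
            n_train = max(1, int(round(self.train_fraction * len(idx))))
            n_train = min(n_train, len(idx) - 1)  # keep at least one in test
            train_idx.append(idx[:n_train])
        train = np.concatenate(train_idx)
        mask = np.zeros(len(y), dtype=bool)
        mask[train] = True
        return mask

    def _converged_ensemble(self, xtr, ytr, xte, rng: np.random.Generator):
        seed = int(rng.integers(2 ** 31))
        prev = None
        n = 16
        while True:
            model = BaggingClassifier(
                estimator=DecisionTreeClassifier(random_state=0),
                n_estimators=n, max_samples=0.8, max_features=0.8,
                bootstrap=True, bootstrap_features=False, random_state=seed)
            model.fit(xtr, ytr)
            pred = model.predict(xte)
            if prev is not None and (np.mean(pred == prev) >= 0.99 or n >= self.max_trees):
                return pred
            prev, n = pred, n * 2

    def fit(self, X, y):
        """``X``: samples x genes logCPM; ``y``: initial two-class labels."""
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        y = pd.Series(np.asarray(pd.Series(y), dtype=object), index=X.index)
        classes = sorted(y.unique())
        if len(classes) != 2:
            raise ValueError(f"initial labels must have exactly 2 classes, got {classes}")
        counts = y.value_counts()
        if (counts < self.min_class_size).any():
            raise ValueError(
                f"need >= {self.min_class_size} samples per class, got {counts.to_dict()}")

        values = X.to_numpy(dtype=float)
        yv = y.to_numpy()
        n_samples, n_genes = values.shape
        n_subset = max(1, int(round(self.gene_fraction * n_genes)))
        rng = np.random.default_rng(np.random.SeedSequence(self.random_state))

        votes: list[list] = [[] for _ in range(n_samples)]

        def run_iteration(train_mask: np.ndarray):
            gene_idx = rng.choice(n_genes, size=n_subset, replace=False)
            test_idx = np.where(~train_mask)[0]
            pred = self._converged_ensemble(
                values[np.ix_(train_mask, gene_idx)], yv[train_mask],
                values[np.ix_(test_idx, gene_idx)], rng)
            for i, p in zip(test_idx, pred):
                votes[i].append(p)

        for _ in range(self.n_gene_permutations + self.n_split_shuffles):
            run_iteration(self._stratified_split(yv, rng))

        consistency = np.full(n_samples, np.nan)
        labels = np.array([UNCERTAIN] * n_samples, dtype=object)
        for i, v in enumerate(votes):
            if not v:
                continue
            vc = pd.Series(v).value_counts()
            consistency[i] = vc.iloc[0] / len(v)
            if consistency[i] >= self.consistency_threshold:
                labels[i] = vc.index[0]
        self.classes_ = np.asarray(classes, dtype=object)
        self.consistency_ = pd.Series(consistency, index=X.index, name="consistency")
        self.n_votes_ = pd.Series([len(v) for v in votes], index=X.index, name="n_votes")
        self.labels_ = pd.Series(labels, index=X.index, name="label")
        return self

    def fit_predict(self, X, y):
        return self.fit(X, y).labels_


def bagging_consistency(logcpm: pd.DataFrame, initial_labels,
                        config: Optional[PipelineConfig] = None,
                        n_gene_permutations: Optional[int] = None,
                        n_split_shuffles: Optional[int] = None,
                        random_state: Optional[int] = None) -> pd.DataFrame:
    """Functional wrapper: returns a frame with label, consistency, n_votes.

    ``logcpm`` is gene x sample (pipeline orientation); labels cover its
    columns. Iteration counts default to the config (scaled-down 100+100 by
    default at package level; the published 1000+1000 is reachable).
    """
    config = config or PipelineConfig(n_gene_permutations=100, n_split_shuffles=100)
    est = BaggingConsistencyClassifier(
        n_gene_permutations=n_gene_permutations or config.n_gene_permutations,
        n_split_shuffles=n_split_shuffles or config.n_split_shuffles,
        train_fraction=config.train_fraction,
        consistency_threshold=config.consistency_threshold,
        random_state=config.seed if random_state is None else random_state,
    )
    est.fit(logcpm.T, pd.Series(initial_labels).reindex(logcpm.columns))
    return pd.DataFrame({
        "label": est.labels_,
        "consistency": est.consistency_,
        "n_votes": est.n_votes_,
    })
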