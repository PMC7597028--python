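"""Origin classifiers: separable recovery, anchoring, determinism, consensus."""

import numpy as np
import pandas as pd
import pytest

from oritrace import (DensityOriginClassifier, GMMOriginClassifier,
                      LouvainOriginClassifier, NormalSpacePCA,
                      PearsonWardOriginClassifier, consensus_call,
                      diffusion_map)


def _two_blobs(n_per=16, n_feat=25, sep=3.0, seed=0):
    """Two Gaussian blobs with opposite feature patterns, each seeded with
    normals of one class (pattern contrast keeps them correlation-separable)."""
    rng = np.random.default_rng(seed)
    pattern = rng.choice([-1.0, 1.0], n_feat)
    a = rng.normal(0.0, 1.0, size=(n_per, n_feat)) - sep / 2 * pattern
    b = rng.normal(0.0, 1.0, size=(n_per, n_feat)) + sep / 2 * pattern
    X = pd.DataFrame(np.vstack([a, b]),
                     index=[f"s{i:02d}" for i in range(2 * n_per)])
    tissue = np.array(["FI"] * 3 + ["TUMOR"] * (n_per - 3) +
                      ["OSE"] * 3 + ["TUMOR"] * (n_per - 3), dtype=object)
    truth = np.array(["FI-like"] * n_per + ["OSE-like"] * n_per, dtype=object)
    return X, tissue, truth


def test_pearson_duplicated_fi_sample_is_fi_like():
    X, tissue, _ = _two_blobs(seed=1)
    X.loc["dup"] = X.iloc[0] + 1e-6  # near-copy of an FI normal
    tissue = np.append(tissue, "TUMOR")
    labels = PearsonWardOriginClassifier().fit_predict(X, tissue)
    assert labels["dup"] == "FI-like"


def test_pearson_separable_recovery_and_permutation_invariance():
    X, tissue, truth = _two_blobs(seed=2)
    labels = PearsonWardOriginClassifier().fit_predict(X, tissue)
    assert (labels.to_numpy() == truth).all()
    perm = np.random.default_rng(0).permutation(len(X))
    labels_p = PearsonWardOriginClassifier().fit_predict(
        X.iloc[perm], tissue[perm])
    assert labels_p.sort_index().equals(labels.sort_index())


def test_pearson_constant_profile_named_in_error():
    X, tissue, _ = _two_blobs(seed=3)
    X.loc["s00"] = 1.0
    with pytest.raises(ValueError, match="s00"):
        PearsonWardOriginClassifier().fit(X, tissue)


def test_louvain_separable_recovery_and_determinism():
    X, tissue, truth = _two_blobs(n_per=20, seed=4)
    est = LouvainOriginClassifier(n_pcs=10, knn_k=8, random_state=3)
    labels = est.fit_predict(X, tissue)
    assert (labels.to_numpy() == truth).all()
    again = LouvainOriginClassifier(n_pcs=10, knn_k=8, random_state=3).fit_predict(X, tissue)
    assert again.equals(labels)


def test_density_separable_recovery_and_outlier_assignment():
    X, tissue, truth = _two_blobs(n_per=20, seed=5)
    coords = diffusion_map(X, knn_k=8, n_comps=5).components
    labels = DensityOriginClassifier().fit_predict(coords, tissue)
    assert (labels.to_numpy() == truth).all()
    # one far outlier joins its nearest cluster; other labels unchanged
    X2 = X.copy()
    X2.loc["outlier"] = X.iloc[0] + np.where(np.arange(X.shape[1]) == 0, 30.0, 0.0)
    coords2 = diffusion_map(X2, knn_k=8, n_comps=5).components
    labels2 = DensityOriginClassifier().fit_predict(
        coords2, np.append(tissue, "TUMOR"))
    assert labels2["outlier"] in {"FI-like", "OSE-like"}
    assert (labels2.drop("outlier").to_numpy() == truth).all()


def test_gmm_separable_recovery_and_restart_monotonicity():
    X, tissue, truth = _two_blobs(n_per=12, n_feat=2, sep=8.0, seed=6)
    small = GMMOriginClassifier(n_restarts=10, random_state=11).fit(X, tissue)
    assert (small.labels_.to_numpy() == truth).all()
    large = GMMOriginClassifier(n_restarts=100, random_state=11).fit(X, tissue)
    # the first 10 restarts are a prefix of the 100-restart stream
    assert large.best_loglik_ >= small.best_loglik_ - 1e-9


def test_gmm_oriprint_space_at_least_as_accurate_as_global(default_cohort,
                                                           default_signature):
    """The origin signal concentrates in OriPrint space (global-space check)."""
    from sklearn.decomposition import PCA
    cohort, truth = default_cohort
    tissue = cohort.samples["tissue_class"]

    def gmm_accuracy(beta):
        X = beta.T
        pcs = PCA(n_components=2, random_state=0).fit_transform(X.to_numpy())
        est = GMMOriginClassifier(n_restarts=100, random_state=0)
        labels = est.fit_predict(pd.DataFrame(pcs, index=X.index), tissue)
        tumor_labels = labels.loc[cohort.tumors].str.replace("-like", "", regex=False)
        return float((tumor_labels == truth.origin_of_tumor).mean())

    acc_sig = gmm_accuracy(cohort.beta.loc[default_signature.cpgs])
    acc_all = gmm_accuracy(cohort.beta)
    assert acc_sig >= acc_all


def test_normal_anchoring_on_default_cohort(default_consensus, default_cohort):
    """Every FI normal lands on the FI side, every OSE normal on the OSE side."""
    cohort, _ = default_cohort
    votes = default_consensus.votes_all_samples
    for method in votes.columns:
        sides = votes.loc[cohort.normals, method].str.replace("-like", "", regex=False)
        assert (sides == cohort.samples.loc[cohort.normals, "tissue_class"]).all()


# ---------------------------------------------------------------------------
# normal-space PCA

def test_normal_space_pca_centering_and_orthonormality():
    rng = np.random.default_rng(7)
    X = pd.DataFrame(rng.normal(size=(20, 100)))
    est = NormalSpacePCA(n_components=5).fit(X)
    load = est.loadings_.to_numpy()
    assert np.abs(load.T @ load - np.eye(5)).max() < 1e-8
    assert (np.diff(est.explained_variance_) <= 1e-12).all()
    mean_profile = pd.DataFrame([X.mean(axis=0)])
    assert np.abs(est.transform(mean_profile).to_numpy()).max() < 1e-8


def test_normal_space_pca_two_points_give_difference_direction():
    X = pd.DataFrame([[0.0, 0.0, 0.0], [2.0, 0.0, 2.0]])
    est = NormalSpacePCA(n_components=1)
    with pytest.raises(ValueError):
        est.fit(X)  # needs >= 3 normals
    X3 = pd.DataFrame([[0.0, 0.0, 0.0], [2.0, 0.0, 2.0], [4.0, 0.0, 4.0]])
    est = NormalSpacePCA(n_components=1).fit(X3)
    direction = est.loadings_.to_numpy().ravel()
    expected = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
    assert min(np.abs(direction - expected).max(),
               np.abs(direction + expected).max()) < 1e-9


def test_normal_space_pca_reconstruction_improves_with_components():
    rng = np.random.default_rng(8)
    X = pd.DataFrame(rng.normal(size=(20, 100)))
    errors = []
    for k in (2, 5, 10, 15):
        est = NormalSpacePCA(n_components=k).fit(X)
        proj = est.transform(X).to_numpy()
        recon = proj @ est.loadings_.to_numpy().T + est.center_.to_numpy()
        errors.append(float(((X.to_numpy() - recon) ** 2).sum()))
    assert all(a > b for a, b in zip(errors, errors[1:]))


# ---------------------------------------------------------------------------
# consensus

def test_consensus_unanimous():
    votes = pd.DataFrame({"m1": ["FI-like"] * 10, "m2": ["FI-like"] * 10,
                          "m3": ["FI-like"] * 10})
    calls, concordance = consensus_call(votes, threshold=0.75)
    assert concordance == 1.0
    assert (calls["consensus"] == "FI-like").all()
    assert (calls["consistency"] == 1.0).all()


def test_consensus_single_dissent_counts_exactly():
    votes = pd.DataFrame({"m1": ["FI-like"] * 10, "m2": ["FI-like"] * 10,
                          "m3": ["FI-like"] * 9 + ["OSE-like"]})
    calls, concordance = consensus_call(votes, threshold=0.75)
    assert concordance == pytest.approx(0.9)
    # a 2-of-3 majority (consistency 2/3) falls below the 0.75 threshold
    assert calls["consensus"].iloc[-1] == "uncertain"
    # ... but a 0.66 threshold reproduces strict-majority behavior
    calls_majority, _ = consensus_call(votes, threshold=0.66)
    assert calls_majority["consensus"].iloc[-1] == "FI-like"


def test_consensus_rejects_mismatched_sample_sets():
    votes = pd.DataFrame({"m1": ["FI-like", "OSE-like"],
                          "m2": ["FI-like", None]})
    with pytest.raises(ValueError, match="different sample sets"):
        consensus_call(votes)
    with pytest.raises(ValueError, match=">= 2 methods"):
        consensus_call(pd.DataFrame({"m1": ["FI-like"]}))
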