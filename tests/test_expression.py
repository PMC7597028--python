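"""TMM, differential expression, coherent signature, external stratification,
bagging consistency."""

import numpy as np
import pandas as pd
import pytest

from oritrace import (BaggingConsistencyClassifier, SimParams,
                      TranscriptomicSignature, bagging_consistency,
                      build_signature, classify_external_cohort,
                      differential_expression, simulate_expression,
                      tmm_normalize)


# ---------------------------------------------------------------------------
# TMM

def _tmm_oracle(counts: np.ndarray, ref: int) -> np.ndarray:
    """Brute-force transliteration of the TMM definition (independent path)."""
    lib = counts.sum(axis=0)
    log2f = np.zeros(counts.shape[1])
    for k in range(counts.shape[1]):
        if k == ref:
            continue
        pairs = []
        for g in range(counts.shape[0]):
            yk, yr = counts[g, k], counts[g, ref]
            if yk > 0 and yr > 0:
                m = np.log2((yk / lib[k]) / (yr / lib[ref]))
                a = 0.5 * np.log2((yk / lib[k]) * (yr / lib[ref]))
                w = (lib[k] - yk) / (lib[k] * yk) + (lib[ref] - yr) / (lib[ref] * yr)
                pairs.append((m, a, w))
        n = len(pairs)
        ms = np.array([p[0] for p in pairs])
        as_ = np.array([p[1] for p in pairs])
        ws = np.array([p[2] for p in pairs])
        rank_m = pd.Series(ms).rank().to_numpy()
        rank_a = pd.Series(as_).rank().to_numpy()
        lo_m, hi_m = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
        lo_a, hi_a = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.sum():
            log2f[k] = np.sum(ms[keep] / ws[keep]) / np.sum(1.0 / ws[keep])
    f = 2.0 ** log2f
    return f / np.exp(np.mean(np.log(f)))


def test_tmm_identical_libraries_give_unit_factors():
    counts = pd.DataFrame(np.tile([[10], [200], [5], [60]], (1, 4)),
                          columns=list("abcd"))
    factors, _ = tmm_normalize(counts)
    assert np.abs(factors.to_numpy() - 1.0).max() < 1e-12


def test_tmm_doubled_library_gives_identical_logcpm():
    rng = np.random.default_rng(0)
    base = rng.poisson(50, size=200)
    counts = pd.DataFrame({"a": base, "b": 2 * base, "c": base + 0})
    factors, logcpm = tmm_normalize(counts)
    assert np.abs(logcpm["a"] - logcpm["b"]).max() < 1e-6


def test_tmm_factors_match_brute_force_oracle():
    rng = np.random.default_rng(1)
    counts = pd.DataFrame(rng.poisson([[30, 60, 25]] * 6 * 10).reshape(60, 3) + 1,
                          columns=list("xyz"))
    factors, _ = tmm_normalize(counts)
    lib = counts.to_numpy().sum(axis=0)
    f75 = np.array([np.quantile(counts.to_numpy()[:, j] / lib[j], 0.75)
                    for j in range(3)])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    expected = _tmm_oracle(counts.to_numpy().astype(float), ref)
    assert np.abs(factors.to_numpy() - expected).max() < 1e-9


def test_tmm_factor_geometric_mean_is_one():
    rng = np.random.default_rng(2)
    counts = pd.DataFrame(rng.poisson(40, size=(100, 5)) *
                          np.array([1, 2, 1, 3, 1]), columns=list("abcde"))
    factors, _ = tmm_normalize(counts)
    assert abs(np.log(factors.to_numpy()).mean()) < 1e-9


def test_tmm_rejects_zero_library():
    counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
    with pytest.raises(ValueError, match="all-zero"):
        tmm_normalize(counts)


# ---------------------------------------------------------------------------
# differential expression

def test_de_identical_groups_yield_nothing():
    rng = np.random.default_rng(3)
    half = pd.DataFrame(rng.normal(5, 1, size=(100, 4)),
                        columns=[f"a{i}" for i in range(4)])
    logcpm = pd.concat([half, half.rename(columns=lambda c: c.replace("a", "b"))],
                       axis=1)
    table = differential_expression(logcpm, ["A"] * 4 + ["B"] * 4)
    assert table["significant"].sum() == 0


def test_de_recovers_planted_genes():
    p = SimParams(seed=31, n_genes=2000, n_signature_genes=100, expr_log2fc=2.0)
    origins = pd.Series(["FI"] * 8 + ["OSE"] * 8,
                        index=[f"S{i:02d}" for i in range(16)])
    expr, truth = simulate_expression(origins, p)
    table = differential_expression(expr.logcpm, origins)
    called = set(table.index[table["significant"]])
    planted = set(truth.planted_de_genes.index)
    tp = len(called & planted)
    assert tp / len(planted) >= 0.9
    assert tp / len(called) >= 0.9


# ---------------------------------------------------------------------------
# coherent signature

def _de_table(sig_genes, logfcs, universe):
    table = pd.DataFrame({"logFC": 0.0, "significant": False},
                         index=pd.Index(universe))
    for g, f in zip(sig_genes, logfcs):
        table.loc[g, ["logFC", "significant"]] = f, True
    return table


def test_build_signature_same_sign_intersection():
    universe = [f"g{i}" for i in range(20)]
    cells = _de_table([f"g{i}" for i in range(7)], [1, 1, 1, 1, 1, -1, -1], universe)
    ffpe = _de_table([f"g{i}" for i in range(7)], [1, 1, 1, 1, 1, 1, 1], universe)
    sig = build_signature(cells, ffpe)
    assert len(sig) == 5
    assert set(sig.genes.index) == {f"g{i}" for i in range(5)}
    assert (sig.genes == 1.0).all()


def test_build_signature_disjoint_and_symmetric():
    universe = [f"g{i}" for i in range(10)]
    a = _de_table(["g0", "g1"], [1, 1], universe)
    b = _de_table(["g5", "g6"], [1, 1], universe)
    with pytest.warns(UserWarning, match="empty"):
        assert len(build_signature(a, b)) == 0
    c = _de_table(["g0", "g1", "g2"], [1, -1, 1], universe)
    d = _de_table(["g1", "g2", "g3"], [-1, 1, 1], universe)
    assert set(build_signature(c, d).genes.index) == set(build_signature(d, c).genes.index)


# ---------------------------------------------------------------------------
# external-cohort classification

def _signature(n_genes=30, seed=0):
    rng = np.random.default_rng(seed)
    direction = pd.Series(rng.choice([-1.0, 1.0], n_genes),
                          index=[f"g{i}" for i in range(n_genes)])
    return TranscriptomicSignature(genes=direction)


def _external_logcpm(signature, n_per, centers, noise=0.6, seed=0):
    """Blobs along the signature axis: center c means z = c * direction."""
    rng = np.random.default_rng(seed)
    cols, data = [], []
    for bi, c in enumerate(centers):
        for i in range(n_per):
            cols.append(f"b{bi}_{i}")
            data.append(c * signature.genes.to_numpy() +
                        rng.normal(0, noise, len(signature.genes)))
    return pd.DataFrame(np.array(data).T, index=signature.genes.index, columns=cols)


def test_external_bimodal_fully_classified():
    sig = _signature()
    logcpm = _external_logcpm(sig, 20, centers=[-2.0, 2.0], seed=1)
    calls = classify_external_cohort(logcpm, sig, random_state=0)
    assert (calls["label"] != "uncertain").all()
    # positive-center blob co-varies with the signature direction: OSE-like
    assert (calls.loc[calls.index.str.startswith("b1"), "label"] == "OSE-like").all()
    assert (calls.loc[calls.index.str.startswith("b0"), "label"] == "FI-like").all()


def test_external_intermediate_blob_uncertain():
    sig = _signature()
    logcpm = _external_logcpm(sig, 14, centers=[-2.5, 0.0, 2.5], seed=2)
    # k below the blob size so no cross-blob edges are forced
    calls = classify_external_cohort(logcpm, sig, knn_k=8, random_state=0)
    middle = calls.index.str.startswith("b1")
    assert (calls.loc[middle, "label"] == "uncertain").all()
    assert (calls.loc[~middle, "label"] != "uncertain").all()


def test_external_sign_flip_flips_labels():
    sig = _signature()
    logcpm = _external_logcpm(sig, 15, centers=[-2.0, 2.0], seed=3)
    calls = classify_external_cohort(logcpm, sig, random_state=0)
    flipped_sig = TranscriptomicSignature(genes=-sig.genes)
    flipped = classify_external_cohort(logcpm, flipped_sig, random_state=0)
    swap = {"FI-like": "OSE-like", "OSE-like": "FI-like", "uncertain": "uncertain"}
    assert (flipped["label"] == calls["label"].map(swap)).all()


def test_external_requires_overlap_and_samples():
    sig = _signature()
    logcpm = _external_logcpm(sig, 15, centers=[-2.0, 2.0], seed=4)
    with pytest.raises(ValueError, match="signature genes"):
        classify_external_cohort(logcpm.iloc[:0], sig)
    with pytest.raises(ValueError, match=">= 10 samples"):
        classify_external_cohort(logcpm.iloc[:, :6], sig)


# ---------------------------------------------------------------------------
# bagging consistency

def test_bagging_separable_data_fully_consistent():
    rng = np.random.default_rng(4)
    n_per, n_genes = 15, 40
    X = np.vstack([rng.normal(0, 1, (n_per, n_genes)),
                   rng.normal(4, 1, (n_per, n_genes))])
    logcpm = pd.DataFrame(X.T, columns=[f"s{i:02d}" for i in range(2 * n_per)])
    labels = pd.Series(["FI-like"] * n_per + ["OSE-like"] * n_per,
                       index=logcpm.columns)
    calls = bagging_consistency(logcpm, labels, n_gene_permutations=20,
                                n_split_shuffles=20, random_state=1)
    assert (calls["label"] != "uncertain").all()
    assert (calls["label"] == labels).all()
    assert calls["consistency"].min() == 1.0


def test_bagging_rejects_bad_inputs():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.normal(size=(30, 10)))
    est = BaggingConsistencyClassifier()
    with pytest.raises(ValueError, match="exactly 2 classes"):
        est.fit(X, ["A"] * 30)
    with pytest.raises(ValueError, match="per class"):
        est.fit(X, ["A"] * 25 + ["B"] * 5)
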