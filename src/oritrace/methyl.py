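"""Methylation matrix core: beta/M conversion, filtering, batch adjustment, I/O.

Matrices are feature x sample throughout (CpGs as rows), mirroring the array
convention. Beta values are methylation fractions in (0, 1); M values are
their log2-odds, M = log2(beta / (1 - beta)). Differential testing is done on
M values (approximately homoscedastic), clustering and embeddings on beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MethylCohort",
    "beta_to_m",
    "m_to_beta",
    "filter_features",
    "batch_adjust",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_sample_sheet",
    "write_sample_sheet",
]

TISSUE_CLASSES = ("FI", "OSE", "TUMOR")

#: beta values are clipped to this open interval before the logit so M stays finite
BETA_EPS = 1e-6


def beta_to_m(beta, clip: bool = False):
    """log2-odds transform of methylation fractions.

    Parameters
    ----------
    beta
        Array-like or DataFrame of methylation fractions.
    clip
        If True, clip values into ``[BETA_EPS, 1 - BETA_EPS]`` first; if
        False, values outside the open unit interval raise ``ValueError``.
    """
    values = beta.to_numpy() if isinstance(beta, pd.DataFrame) else np.asarray(beta, dtype=float)
    if clip:
        values = np.clip(values, BETA_EPS, 1.0 - BETA_EPS)
    elif np.any(values <= 0.0) or np.any(values >= 1.0):
        raise ValueError("beta values must lie strictly in (0, 1); pass clip=True to clip")
    m = np.log2(values / (1.0 - values))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (2^M + 1)."""
    values = m.to_numpy() if isinstance(m, pd.DataFrame) else np.asarray(m, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("M values must be finite")
    # expit in base 2, computed stably for large |M|
    beta = np.where(values >= 0,
                    1.0 / (1.0 + np.exp2(-values)),
                    np.exp2(values) / (np.exp2(values) + 1.0))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    return beta


@dataclass
class MethylCohort:
    """A methylation cohort: paired beta/M matrices plus a sample sheet.

    ``beta`` and ``m`` are CpG x sample DataFrames over identical axes;
    ``samples`` is indexed by sample_id with at least ``tissue_class``
    (one of FI / OSE / TUMOR) and ``batch`` columns.
    """

    beta: pd.DataFrame
    m: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.beta.shape != self.m.shape:
            raise ValueError("beta and m must have the same shape")
        if not self.beta.columns.equals(self.m.columns) or not self.beta.index.equals(self.m.index):
            raise ValueError("beta and m must share index and columns")
        if not self.samples.index.is_unique:
            raise ValueError("sample ids must be unique")
        if not self.beta.index.is_unique:
            raise ValueError("CpG ids must be unique")
        missing = set(self.beta.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples sheet lacks entries for {sorted(missing)[:5]} ...")
        bad = set(self.samples["tissue_class"]) - set(TISSUE_CLASSES)
        if bad:
            raise ValueError(f"unknown tissue classes: {sorted(bad)}")
        # align sheet to matrix column order
        self.samples = self.samples.loc[self.beta.columns]

    @classmethod
    def from_m(cls, m: pd.DataFrame, samples: pd.DataFrame) -> "MethylCohort":
        return cls(beta=m_to_beta(m), m=m, samples=samples)

    @classmethod
    def from_beta(cls, beta: pd.DataFrame, samples: pd.DataFrame,
                  clip: bool = True) -> "MethylCohort":
        return cls(beta=beta, m=beta_to_m(beta, clip=clip), samples=samples)

    @property
    def cpg_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    def tissue(self, *classes: str) -> pd.Index:
        """Sample ids belonging to the given tissue classes."""
        mask = self.samples["tissue_class"].isin(classes)
        return self.samples.index[mask]

    @property
    def normals(self) -> pd.Index:
        return self.tissue("FI", "OSE")

    @property
    def tumors(self) -> pd.Index:
        return self.tissue("TUMOR")

    def subset_cpgs(self, cpgs) -> "MethylCohort":
        return MethylCohort(beta=self.beta.loc[cpgs], m=self.m.loc[cpgs],
                            samples=self.samples.copy())

    def subset_samples(self, ids) -> "MethylCohort":
        ids = pd.Index(ids)
        return MethylCohort(beta=self.beta[ids], m=self.m[ids],
                            samples=self.samples.loc[ids])


def filter_features(cohort: MethylCohort, max_missing_fraction: float = 0.0,
                    min_sd: float = 0.0) -> MethylCohort:
    """Drop CpGs with too many missing values or too little variation.

    Rows whose missing fraction exceeds ``max_missing_fraction`` or whose
    standard deviation (over observed values, M scale) is below ``min_sd``
    are removed. Rows that survive must be complete: residual missing values
    raise (no imputation is performed).
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    if min_sd < 0:
        raise ValueError("min_sd must be >= 0")
    m = cohort.m
    missing_frac = m.isna().mean(axis=1)
    sd = m.std(axis=1, ddof=1).fillna(0.0)
    keep = (missing_frac <= max_missing_fraction) & (sd >= min_sd)
    n_missing_drop = int((missing_frac > max_missing_fraction).sum())
    n_sd_drop = int(((missing_frac <= max_missing_fraction) & (sd < min_sd)).sum())
    if keep.sum() == 0:
        raise ValueError(
            f"no CpGs survive filtering: {n_missing_drop} dropped for missingness, "
            f"{n_sd_drop} for low sd, of {len(m)} total"
        )
    kept = cohort.subset_cpgs(m.index[keep])
    if kept.m.isna().any().any():
        bad = kept.m.index[kept.m.isna().any(axis=1)]
        raise ValueError(
            f"{len(bad)} retained CpGs still contain missing values "
            f"(e.g. {list(bad[:3])}); no imputation is performed"
        )
    return kept


def _design_matrix(labels: np.ndarray) -> tuple[np.ndarray, list]:
    levels = sorted(pd.unique(labels))
    mat = np.column_stack([(labels == lv).astype(float) for lv in levels])
    return mat, levels


def batch_adjust(m: pd.DataFrame, batch, group) -> pd.DataFrame:
    """Two-moment batch adjustment with the biological grouping protected.

    A deterministic location/scale stand-in for empirical-Bayes batch
    correction. Per feature, group x batch cell means are computed; the
    protected group effect is the batch-averaged cell mean, so each sample
    is re-centered on its group's cross-batch mean (removing additive batch
    offsets and batch x group interactions), and cell-centered residuals
    are rescaled so every batch has the pooled residual scale. Exactly
    idempotent, and the identity for a single batch.

    Parameters
    ----------
    m
        feature x sample matrix (M values).
    batch, group
        per-sample labels, aligned with ``m``'s columns.
    """
    batch = np.asarray(pd.Series(batch).reindex(m.columns) if isinstance(batch, pd.Series)
                       else batch)
    group = np.asarray(pd.Series(group).reindex(m.columns) if isinstance(group, pd.Series)
                       else group)
    if len(batch) != m.shape[1] or len(group) != m.shape[1]:
        raise ValueError("batch/group labels must match the number of samples")
    batches = sorted(pd.unique(batch))
    if len(batches) == 1:
        return m.copy()
    counts = pd.Series(batch).value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"every batch needs >= 2 samples; too small: {small}")
    gmat, groups = _design_matrix(group)
    bmat, _ = _design_matrix(batch)
    rank = np.linalg.matrix_rank(np.hstack([gmat, bmat]))
    if rank < gmat.shape[1] + bmat.shape[1] - 1:
        raise ValueError("batch is confounded with the biological group; cannot adjust")

    x = m.to_numpy(dtype=float)
    n_feat, n = x.shape
    cell_mean = np.zeros_like(x)      # per-sample: mean of its (group, batch) cell
    alpha = {}                        # group -> cross-batch average profile
    for g in groups:
        cols_g = group == g
        batch_means = []
        for b in batches:
            cols = cols_g & (batch == b)
            if cols.any():
                mu = x[:, cols].mean(axis=1)
                cell_mean[:, cols] = mu[:, None]
                batch_means.append(mu)
        alpha[g] = np.mean(batch_means, axis=0)

    resid = x - cell_mean
    # within-batch scale with cell-count degrees of freedom, so the pooled
    # scale is a fixed point of the adjustment
    var_b, dof_b = {}, {}
    for b in batches:
        cols = batch == b
        n_cells = len(pd.unique(group[cols]))
        dof = int(cols.sum()) - n_cells
        dof_b[b] = dof
        var_b[b] = (resid[:, cols] ** 2).sum(axis=1) / dof if dof > 0 else None
    total_dof = sum(d for d in dof_b.values() if d > 0)
    if total_dof > 0:
        pooled = np.zeros(n_feat)
        for b in batches:
            if dof_b[b] > 0:
                pooled += dof_b[b] * var_b[b]
        pooled_sd = np.sqrt(pooled / total_dof)
    else:
        pooled_sd = None

    out = np.empty_like(x)
    for b in batches:
        cols = batch == b
        scaled = resid[:, cols]
        if pooled_sd is not None and dof_b[b] > 0:
            sd_b = np.sqrt(var_b[b])
            with np.errstate(divide="ignore", invalid="ignore"):
                factor = np.where(sd_b > 1e-12, pooled_sd / sd_b, 1.0)
            scaled = scaled * factor[:, None]
        out[:, cols] = scaled
    for g in groups:
        cols = group == g
        out[:, cols] += alpha[g][:, None]
    return pd.DataFrame(out, index=m.index, columns=m.columns)


# ---------------------------------------------------------------------------
# tab-separated I/O: first column = feature id, header = sample ids

def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
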