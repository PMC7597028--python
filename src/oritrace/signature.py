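"""Differentially methylated site calling and the OriPrint signature.

The test core is a limma-style moderated two-group t-statistic: per-feature
pooled variances are shrunk toward a common prior by empirical Bayes, with
the prior degrees of freedom and scale estimated by matching moments of the
log-variances across features (the scaled inverse-chi-square / F-distribution
fit). The same core is reused for expression differential testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .methyl import MethylCohort
from .params import PipelineConfig

__all__ = [
    "DmsTable",
    "OriPrintSignature",
    "moderated_t_test",
    "bh_adjust",
    "call_oriprint",
]

DmsTable = pd.DataFrame  # columns: delta_m, t_stat, df_total, p, p_adj


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior to observed pooled variances.

    Returns (d0, s0_sq); d0 = inf means no excess variability across
    features beyond sampling noise, i.e. full shrinkage to s0_sq.
    """
    positive = s2[s2 > 0]
    if positive.size < 2:
        return np.inf, float(np.median(s2)) if s2.size else 1.0
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    half_d0 = _trigamma_inverse(e_var)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_sq


def moderated_t_test(m: pd.DataFrame, labels, groups: Optional[Sequence[str]] = None,
                     d0: Optional[float] = None) -> DmsTable:
    """Empirical-Bayes moderated two-group t-test per feature.

    Parameters
    ----------
    m
        feature x sample matrix.
    labels
        Per-sample group labels with exactly two levels.
    groups
        Optional (reference, alternative) pair; the effect is
        mean(alternative) - mean(reference). Defaults to the sorted levels,
        so for FI/OSE the effect is mean(OSE) - mean(FI).
    d0
        Force the prior degrees of freedom; ``d0=0`` recovers the ordinary
        pooled-variance two-sample t-test exactly.

    Returns
    -------
    DataFrame indexed by feature with columns ``delta_m`` (the "logFC"),
    ``t_stat``, ``df_total``, ``p`` and ``p_adj`` (Benjamini-Hochberg).
    """
    labels = pd.Series(np.asarray(labels, dtype=object), index=m.columns)
    levels = sorted(labels.unique())
    if groups is None:
        if len(levels) != 2:
            raise ValueError(f"expected exactly 2 groups, got {levels}")
        ref, alt = levels
    else:
        ref, alt = groups
    idx1 = labels.index[labels == ref]
    idx2 = labels.index[labels == alt]
    n1, n2 = len(idx1), len(idx2)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 samples (got {ref}: {n1}, {alt}: {n2})")
    if m.shape[0] < 2 and d0 is None:
        raise ValueError("need >= 2 features to estimate the variance prior")

    x1 = m[idx1].to_numpy(dtype=float)
    x2 = m[idx2].to_numpy(dtype=float)
    delta = x2.mean(axis=1) - x1.mean(axis=1)
    df_resid = float(n1 + n2 - 2)
    s2 = ((x1.var(axis=1, ddof=1) * (n1 - 1)) + (x2.var(axis=1, ddof=1) * (n2 - 1))) / df_resid

    if d0 is None:
        d0_est, s0_sq = _fit_variance_prior(s2, df_resid)
    else:
        d0_est, s0_sq = float(d0), 0.0

    if np.isinf(d0_est):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0_est == 0.0:
        s2_post = s2
        df_total = df_resid
    else:
        s2_post = (d0_est * s0_sq + df_resid * s2) / (d0_est + df_resid)
        df_total = d0_est + df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t = np.zeros_like(delta)
    ok = se > 0
    t[ok] = delta[ok] / se[ok]
    degenerate = ~ok & (delta != 0)
    t[degenerate] = np.sign(delta[degenerate]) * np.inf
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)

    table = pd.DataFrame(
        {
            "delta_m": delta,
            "t_stat": t,
            "df_total": df_total,
            "p": p,
            "p_adj": bh_adjust(p),
        },
        index=m.index,
    )
    return table


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class OriPrintSignature:
    """The origin-differential CpG signature.

    ``hyper_in_ose`` are CpGs with higher methylation in OSE (delta_m > 0),
    ``hypo_in_ose`` the converse; both pass the adjusted-p and |delta-M|
    thresholds recorded in ``thresholds``.
    """

    hyper_in_ose: list
    hypo_in_ose: list
    thresholds: dict
    table: Optional[pd.DataFrame] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if set(self.hyper_in_ose) & set(self.hypo_in_ose):
            raise ValueError("hyper and hypo sets must be disjoint")

    @property
    def cpgs(self) -> pd.Index:
        return pd.Index(list(self.hyper_in_ose) + list(self.hypo_in_ose))

    @property
    def direction(self) -> pd.Series:
        """+1 for hyper-in-OSE CpGs, -1 for hypo-in-OSE."""
        return pd.Series(
            [1.0] * len(self.hyper_in_ose) + [-1.0] * len(self.hypo_in_ose),
            index=self.cpgs,
        )

    def __len__(self) -> int:
        return len(self.hyper_in_ose) + len(self.hypo_in_ose)

    def to_dict(self) -> dict:
        return {
            "hyper_in_ose": list(map(str, self.hyper_in_ose)),
            "hypo_in_ose": list(map(str, self.hypo_in_ose)),
            "thresholds": self.thresholds,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OriPrintSignature":
        return cls(hyper_in_ose=d["hyper_in_ose"], hypo_in_ose=d["hypo_in_ose"],
                   thresholds=d.get("thresholds", {}))


def call_oriprint(cohort: MethylCohort, config: Optional[PipelineConfig] = None,
                  alpha: Optional[float] = None,
                  min_abs_dm: Optional[float] = None) -> OriPrintSignature:
    """Call origin-differential CpGs between FI and OSE normals.

    Tests on M values (the pipeline convention), then selects CpGs with
    adjusted p below ``dms_alpha`` and |delta-M| above ``dms_min_abs_dm``,
    split by the sign of the OSE-minus-FI difference.
    """
    config = config or PipelineConfig()
    alpha = config.dms_alpha if alpha is None else alpha
    min_abs_dm = config.dms_min_abs_dm if min_abs_dm is None else min_abs_dm

    normals = cohort.normals
    fi = cohort.tissue("FI")
    ose = cohort.tissue("OSE")
    if len(fi) < 2 or len(ose) < 2:
        raise ValueError("cohort must contain >= 2 FI and >= 2 OSE samples")

    labels = cohort.samples.loc[normals, "tissue_class"]
    table = moderated_t_test(cohort.m[normals], labels, groups=("FI", "OSE"))
    passing = (table["p_adj"] < alpha) & (table["delta_m"].abs() > min_abs_dm)
    hyper = table.index[passing & (table["delta_m"] > 0)].tolist()
    hypo = table.index[passing & (table["delta_m"] < 0)].tolist()
    if not hyper and not hypo:
        warnings.warn("OriPrint signature is empty at the requested thresholds",
                      stacklevel=2)
    return OriPrintSignature(
        hyper_in_ose=hyper,
        hypo_in_ose=hypo,
        thresholds={"alpha": alpha, "min_abs_dm": min_abs_dm},
        table=table,
    )
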