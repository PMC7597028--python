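"""Synthetic two-origin cohort generator.

Emulates the statistical structure the tracing analysis relies on, with a
known truth channel for parameter-recovery tests:

* methylation: bimodal beta values; a planted set of origin-differential
  CpGs separating FI from OSE; tumors inheriting one origin's pattern at
  those CpGs with tunable fidelity, while a much larger tumor-common
  aberration field dominates global variance (so the normal-vs-tumor axis,
  not the origin axis, carries most variance genome-wide);
* expression: negative-binomial counts with origin-differential genes and
  4-fold library-size variation;
* survival: exponential event times with an origin-dependent hazard ratio
  and independent censoring.

Every generator is deterministic given ``SimParams.seed``; the three
generators draw from independent sub-streams of that seed, so simulating
expression does not perturb the methylation draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .methyl import MethylCohort, m_to_beta, beta_to_m, BETA_EPS
from .params import SimParams

__all__ = ["GroundTruth", "simulate_methylation", "simulate_expression",
           "simulate_survival"]


@dataclass
class GroundTruth:
    """Planted truth for a simulated cohort.

    ``origin_of_tumor`` maps each tumor sample id to "FI" or "OSE";
    ``planted_dms`` maps planted CpG ids to their direction (+1 = hyper in
    OSE, -1 = hypo in OSE); ``planted_de_genes`` maps planted gene ids to
    direction (+1 = up in OSE).
    """

    origin_of_tumor: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    planted_dms: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    planted_de_genes: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def _rng_for(params: SimParams, stage: int) -> np.random.Generator:
    # independent, reproducible sub-stream per generator
    return np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(stage,)))


def simulate_methylation(params: SimParams) -> tuple[MethylCohort, GroundTruth]:
    """Generate the methylation cohort with planted origin structure.

    Baseline per-CpG M values come from a two-component mixture (methylated
    and unmethylated modes at M = +/-3) so beta values are bimodal. OSE
    means are shifted by ``+/- origin_delta_m`` at the planted DMS. Each
    tumor copies its origin's mean at each planted DMS with probability
    ``origin_fidelity`` (otherwise the other origin's mean). All tumors
    share one common random shift field over ``tumor_fraction_aberrant`` of
    the non-planted CpGs; the planted subspace is left free of the shared
    aberration so that, at fidelity 1 and vanishing noise, a tumor's
    restriction to the planted CpGs equals its origin's pattern exactly.
    """
    p = params
    rng = _rng_for(p, 0)

    cpg_ids = pd.Index([f"cg{i:06d}" for i in range(p.n_cpg)])
    fi_ids = [f"FI_{i + 1:02d}" for i in range(p.n_fi)]
    ose_ids = [f"OSE_{i + 1:02d}" for i in range(p.n_ose)]
    tumor_ids = [f"T_{i + 1:02d}" for i in range(p.n_tumor)]

    # bimodal baseline
    mode = rng.random(p.n_cpg) < 0.5
    mu = np.where(mode, rng.normal(3.0, 1.0, p.n_cpg), rng.normal(-3.0, 1.0, p.n_cpg))

    dms_idx = rng.choice(p.n_cpg, size=p.n_origin_dms, replace=False)
    dms_idx.sort()
    dms_dir = rng.choice([-1.0, 1.0], size=p.n_origin_dms)

    mean_fi = mu.copy()
    mean_ose = mu.copy()
    mean_ose[dms_idx] = mean_ose[dms_idx] + dms_dir * p.origin_delta_m

    # balanced tumor origins, shuffled
    n_fi_like = (p.n_tumor + 1) // 2
    origins = np.array(["FI"] * n_fi_like + ["OSE"] * (p.n_tumor - n_fi_like), dtype=object)
    rng.shuffle(origins)

    # tumor means: origin pattern with per-tumor, per-DMS fidelity flips
    tumor_means = np.empty((p.n_cpg, p.n_tumor))
    for j, origin in enumerate(origins):
        own, other = (mean_fi, mean_ose) if origin == "FI" else (mean_ose, mean_fi)
        col = own.copy()
        if p.n_origin_dms:
            flip = rng.random(p.n_origin_dms) > p.origin_fidelity
            col[dms_idx[flip]] = other[dms_idx[flip]]
        tumor_means[:, j] = col

    # shared tumor aberration over non-planted CpGs
    non_planted = np.setdiff1d(np.arange(p.n_cpg), dms_idx)
    n_aberrant = int(round(p.tumor_fraction_aberrant * p.n_cpg))
    n_aberrant = min(n_aberrant, len(non_planted))
    aberrant_idx = rng.choice(non_planted, size=n_aberrant, replace=False)
    shift = np.zeros(p.n_cpg)
    shift[aberrant_idx] = rng.normal(0.0, p.tumor_shift_sd, n_aberrant)
    tumor_means = tumor_means + shift[:, None]

    means = np.column_stack(
        [np.tile(mean_fi[:, None], (1, p.n_fi)),
         np.tile(mean_ose[:, None], (1, p.n_ose)),
         tumor_means]
    )
    n_samples = p.n_fi + p.n_ose + p.n_tumor
    m_raw = means + rng.normal(0.0, p.noise_sd, size=(p.n_cpg, n_samples))

    # derive beta, clip to the open interval, and re-derive M so the
    # conversion identity holds exactly on the stored pair
    beta = np.clip(m_to_beta(m_raw), BETA_EPS, 1.0 - BETA_EPS)
    m = beta_to_m(beta)

    sample_ids = fi_ids + ose_ids + tumor_ids
    samples = pd.DataFrame(
        {
            "tissue_class": ["FI"] * p.n_fi + ["OSE"] * p.n_ose + ["TUMOR"] * p.n_tumor,
            "batch": "cohort1",
            "true_origin": ["FI"] * p.n_fi + ["OSE"] * p.n_ose + list(origins),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    cohort = MethylCohort(
        beta=pd.DataFrame(beta, index=cpg_ids, columns=sample_ids),
        m=pd.DataFrame(m, index=cpg_ids, columns=sample_ids),
        samples=samples,
    )
    truth = GroundTruth(
        origin_of_tumor=pd.Series(origins, index=tumor_ids, name="origin"),
        planted_dms=pd.Series(dms_dir, index=cpg_ids[dms_idx], name="direction"),
    )
    return cohort, truth


def simulate_expression(origins, params: SimParams, preparation: str = "cells"):
    """Generate negative-binomial counts for samples with known origins.

    Parameters
    ----------
    origins
        Mapping/Series of sample id -> origin label ("FI"/"OSE", with or
        without the "-like" suffix).
    params
        Generative parameters; ``expr_log2fc`` is split symmetrically
        between the two origins so the planted between-origin difference in
        expectation equals ``expr_log2fc`` exactly.

    Returns
    -------
    (ExprCohort, GroundTruth)
    """
    from .expression import ExprCohort, tmm_normalize  # local import avoids a cycle

    p = params
    origins = pd.Series(origins).astype(str).str.replace("-like", "", regex=False)
    levels = sorted(origins.unique())
    if set(levels) - {"FI", "OSE"}:
        raise ValueError(f"origin labels must be FI/OSE(-like), got {levels}")
    if len(levels) < 2:
        raise ValueError("need samples from both origins; differential structure "
                         "is undefined for a single-origin cohort")
    if (origins.value_counts() < 2).any():
        raise ValueError("need >= 2 samples per origin")

    rng = _rng_for(p, 1)
    gene_ids = pd.Index([f"G{i:05d}" for i in range(p.n_genes)])

    base_log2 = rng.uniform(3.0, 9.0, p.n_genes)
    lib_factor = np.exp2(rng.uniform(-1.0, 1.0, len(origins)))  # 4-fold range

    if p.expr_log2fc == 0.0 or p.n_signature_genes == 0:
        de_idx = np.array([], dtype=int)
        de_dir = np.array([])
    else:
        de_idx = rng.choice(p.n_genes, size=p.n_signature_genes, replace=False)
        de_idx.sort()
        de_dir = rng.choice([-1.0, 1.0], size=p.n_signature_genes)

    half = p.expr_log2fc / 2.0
    log2_mu = np.tile(base_log2[:, None], (1, len(origins)))
    is_ose = (origins.to_numpy() == "OSE")
    if len(de_idx):
        log2_mu[np.ix_(de_idx, np.where(is_ose)[0])] += (de_dir * half)[:, None]
        log2_mu[np.ix_(de_idx, np.where(~is_ose)[0])] -= (de_dir * half)[:, None]

    mu = np.exp2(log2_mu) * lib_factor[None, :]
    r = 1.0 / p.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=origins.index)
    size_factors, logcpm = tmm_normalize(counts_df)
    samples = pd.DataFrame(
        {"preparation": preparation, "origin": origins.to_numpy()},
        index=pd.Index(origins.index, name="sample_id"),
    )
    cohort = ExprCohort(counts=counts_df, logcpm=logcpm,
                        size_factors=size_factors, samples=samples)
    truth = GroundTruth(
        origin_of_tumor=origins.copy(),
        planted_de_genes=pd.Series(de_dir, index=gene_ids[de_idx], name="direction"),
    )
    return cohort, truth


def simulate_survival(origins, params: SimParams) -> pd.DataFrame:
    """Exponential survival with an origin-dependent hazard.

    OSE-origin samples have hazard ``hazard_ratio_ose`` times the FI hazard,
    whose rate is set so the FI median equals ``median_survival_fi_days``.
    Each record is independently censored with probability ``censor_rate``
    (censoring time uniform on the unobserved event time); any time beyond
    ``horizon_days`` is truncated there and censored.
    """
    p = params
    origins = pd.Series(origins).astype(str).str.replace("-like", "", regex=False)
    rng = _rng_for(p, 2)

    rate_fi = np.log(2.0) / p.median_survival_fi_days
    rates = np.where(origins.to_numpy() == "OSE", rate_fi * p.hazard_ratio_ose, rate_fi)
    times = rng.exponential(1.0 / rates)
    event = np.ones(len(origins), dtype=int)

    censored = rng.random(len(origins)) < p.censor_rate
    times = np.where(censored, times * rng.random(len(origins)), times)
    event[censored] = 0

    over = times > p.horizon_days
    times = np.where(over, p.horizon_days, times)
    event[over] = 0

    return pd.DataFrame(
        {"time_days": times, "event": event, "group": origins.to_numpy()},
        index=pd.Index(origins.index, name="sample_id"),
    )
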