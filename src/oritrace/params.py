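"""Parameter containers shared across the pipeline.

Two dataclasses hold every tunable knob: :class:`SimParams` configures the
synthetic cohort generator (the study conditions the pipeline is exercised
under) and :class:`PipelineConfig` holds the analysis thresholds used by the
signature, classification, translation and survival stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

__all__ = ["SimParams", "PipelineConfig", "spawn_rngs"]


@dataclass
class SimParams:
    """Generative parameters for the synthetic two-origin cohort.

    The methylation cohort consists of ``n_fi`` fimbrial (FI) and ``n_ose``
    ovarian-surface (OSE) normal samples plus ``n_tumor`` tumors, over
    ``n_cpg`` CpGs. ``n_origin_dms`` CpGs carry a planted FI-vs-OSE shift of
    ``origin_delta_m`` M units; each tumor inherits its origin's state at
    each of those CpGs with probability ``origin_fidelity``. All tumors
    additionally share one random aberration field of scale
    ``tumor_shift_sd`` over a ``tumor_fraction_aberrant`` fraction of CpGs,
    so that global variance is dominated by the normal-vs-tumor axis while
    the origin signal lives in the planted subspace.

    Expression counts are negative binomial with ``n_signature_genes``
    origin-differential genes at ``expr_log2fc``; survival is exponential
    with an OSE-vs-FI hazard ratio of ``hazard_ratio_ose`` and independent
    censoring.
    """

    n_fi: int = 12
    n_ose: int = 8
    n_tumor: int = 24
    n_cpg: int = 20_000
    n_origin_dms: int = 1_000
    origin_delta_m: float = 2.5
    tumor_fraction_aberrant: float = 0.3
    tumor_shift_sd: float = 1.5
    origin_fidelity: float = 0.9
    noise_sd: float = 0.5
    n_genes: int = 5_000
    n_signature_genes: int = 150
    expr_log2fc: float = 2.0
    nb_dispersion: float = 0.15
    hazard_ratio_ose: float = 2.0
    median_survival_fi_days: float = 1460.0
    censor_rate: float = 0.15
    horizon_days: float = 3652.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_fi": self.n_fi,
            "n_ose": self.n_ose,
            "n_tumor": self.n_tumor,
            "n_cpg": self.n_cpg,
            "n_origin_dms": self.n_origin_dms,
            "n_genes": self.n_genes,
            "n_signature_genes": self.n_signature_genes,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        for name, value in [
            ("origin_fidelity", self.origin_fidelity),
            ("censor_rate", self.censor_rate),
            ("tumor_fraction_aberrant", self.tumor_fraction_aberrant),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.origin_delta_m <= 0:
            raise ValueError("origin_delta_m must be > 0")
        if self.n_origin_dms > self.n_cpg:
            raise ValueError(
                f"n_origin_dms ({self.n_origin_dms}) exceeds n_cpg ({self.n_cpg})"
            )
        if self.n_signature_genes > self.n_genes:
            raise ValueError("n_signature_genes exceeds n_genes")
        if self.hazard_ratio_ose <= 0:
            raise ValueError("hazard_ratio_ose must be > 0")
        if self.median_survival_fi_days <= 0:
            raise ValueError("median_survival_fi_days must be > 0")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimParams":
        return cls(**d)


@dataclass
class PipelineConfig:
    """Analysis thresholds and sizes for every downstream stage.

    Defaults mirror the published analysis: DMS at adjusted p < 0.05 and
    |delta-M| > 1, Louvain on the first 50 principal components with
    20-neighbor graphs, a 2-component GMM taking the best of 2000 random
    restarts, a Louvain resolution scan over [0.1, 1.5], a 75% consistency
    threshold with 70/30 train-test splits, DE at FDR < 0.05 and
    |logFC| > 0.8, and a 5-year (1826-day) survival horizon.
    """

    dms_alpha: float = 0.05
    dms_min_abs_dm: float = 1.0
    n_pcs_louvain: int = 50
    knn_k: int = 20
    gmm_restarts: int = 2000
    gmm_components: int = 2
    resolution_range: tuple[float, float] = (0.1, 1.5)
    consistency_threshold: float = 0.75
    train_fraction: float = 0.7
    n_gene_permutations: int = 1000
    n_split_shuffles: int = 1000
    survival_horizon_days: float = 1826.0
    de_fdr: float = 0.05
    de_min_lfc: float = 0.8
    n_diffusion_comps: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.dms_alpha < 1:
            raise ValueError("dms_alpha must be in (0, 1)")
        if not 0 < self.de_fdr < 1:
            raise ValueError("de_fdr must be in (0, 1)")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0 < self.consistency_threshold <= 1:
            raise ValueError("consistency_threshold must be in (0, 1]")
        for name in ("n_pcs_louvain", "knn_k", "gmm_restarts", "gmm_components",
                     "n_gene_permutations", "n_split_shuffles", "n_diffusion_comps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.resolution_range
        if not (lo > 0 and hi > lo):
            raise ValueError("resolution_range must be an increasing positive pair")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["resolution_range"] = list(self.resolution_range)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "resolution_range" in d:
            d["resolution_range"] = tuple(d["resolution_range"])
        return cls(**d)


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Expand one seed into ``n`` independent generator streams.

    Per-stage streams keep stages decoupled: changing how one stage consumes
    randomness cannot perturb any other stage's draws.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]
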