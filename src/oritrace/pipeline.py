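"""End-to-end orchestration: simulate/ingest -> preprocess -> signature ->
classify -> trajectory -> translate -> survival, under one config and seed.

Each stage draws from its own sub-stream of the config seed, so a change in
one stage's internals cannot perturb another stage's randomness, and a rerun
with the same config reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .classify import classify_cohort, UNCERTAIN
from .expression import bagging_consistency, differential_expression
from .methyl import (MethylCohort, batch_adjust, filter_features,
                     read_matrix_tsv, read_sample_sheet, write_matrix_tsv,
                     write_sample_sheet)
from .params import PipelineConfig, SimParams
from .signature import call_oriprint
from .simulate import simulate_expression, simulate_methylation, simulate_survival
from .survival import kaplan_meier, logrank_test, median_difference, restrict_followup
from .trajectory import (diffusion_map, diffusion_pseudotime,
                         intersection_analysis, select_root)

__all__ = ["RunManifest", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, message: str, manifest: Optional["RunManifest"] = None):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class RunManifest:
    config: dict
    sim_params: Optional[dict]
    seed: int
    outputs: dict = field(default_factory=dict)
    hashes: dict = field(default_factory=dict)
    version: str = __version__

    def to_dict(self) -> dict:
        return {"config": self.config, "sim_params": self.sim_params,
                "seed": self.seed, "outputs": self.outputs,
                "hashes": self.hashes, "version": self.version}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(manifest: RunManifest, out_dir: Path, name: str, writer) -> None:
    path = out_dir / name
    writer(path)
    manifest.outputs[name] = str(path)
    manifest.hashes[name] = _sha256(path)


def run_pipeline(config: Optional[PipelineConfig] = None,
                 sim_params: Optional[SimParams] = None,
                 input_dir: Optional[str] = None,
                 out_dir: str = "oritrace_run",
                 n_retrospective: int = 150) -> RunManifest:
    """Run the full tracing pipeline and write all stage outputs.

    Exactly one of ``sim_params`` (simulate the cohort) or ``input_dir``
    (read ``beta.tsv``/``samples.tsv`` and, for the survival stage,
    ``counts.tsv``/``survival.tsv``) must be given. ``n_retrospective`` is
    the size of the simulated retrospective expression/survival cohort,
    emulating a clinical FFPE series stratified by the transcriptomic
    classifier.
    """
    config = config or PipelineConfig()
    if (sim_params is None) == (input_dir is None):
        raise ValueError("provide exactly one of sim_params or input_dir")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(config=config.to_dict(),
                           sim_params=sim_params.to_dict() if sim_params else None,
                           seed=config.seed)
    report: dict = {}
    rng_origins = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(10,)))

    # ---- stage: methylation cohort -------------------------------------
    stage = "methylation"
    try:
        if sim_params is not None:
            cohort, truth = simulate_methylation(sim_params)
        else:
            indir = Path(input_dir)
            beta_path, sheet_path = indir / "beta.tsv", indir / "samples.tsv"
            if not beta_path.exists() or not sheet_path.exists():
                raise FileNotFoundError(f"missing {beta_path.name} or {sheet_path.name}")
            cohort = MethylCohort.from_beta(read_matrix_tsv(beta_path),
                                            read_sample_sheet(sheet_path))
            truth = None
        cohort = filter_features(cohort)
        if cohort.samples["batch"].nunique() > 1:
            adjusted = batch_adjust(cohort.m, cohort.samples["batch"],
                                    cohort.samples["tissue_class"])
            cohort = MethylCohort.from_m(adjusted, cohort.samples)
        _write(manifest, out, "beta.tsv", lambda p: write_matrix_tsv(cohort.beta, p))
        _write(manifest, out, "samples.tsv", lambda p: write_sample_sheet(cohort.samples, p))
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, str(exc), manifest) from exc

    # ---- stage: OriPrint signature -------------------------------------
    stage = "signature"
    try:
        signature = call_oriprint(cohort, config)
        report["signature_size"] = len(signature)
        report["signature_hyper_in_ose"] = len(signature.hyper_in_ose)
        report["signature_hypo_in_ose"] = len(signature.hypo_in_ose)
        _write(manifest, out, "oriprint.json",
               lambda p: p.write_text(json.dumps(signature.to_dict(), indent=1)))
        _write(manifest, out, "dms_table.tsv",
               lambda p: signature.table.to_csv(p, sep="\t", index_label="cpg_id"))
    except Exception as exc:
        raise PipelineError(stage, str(exc), manifest) from exc

    # ---- stage: consensus classification -------------------------------
    stage = "classify"
    try:
        result = classify_cohort(cohort, signature, config)
        report["concordance"] = result.concordance
        report["consensus_counts"] = result.calls["consensus"].value_counts().to_dict()
        _write(manifest, out, "origin_calls.tsv",
               lambda p: result.calls.to_csv(p, sep="\t", index_label="sample_id"))
        _write(manifest, out, "concordance.json",
               lambda p: p.write_text(json.dumps({"concordance": result.concordance})))
    except Exception as exc:
        raise PipelineError(stage, str(exc), manifest) from exc

    # ---- stage: trajectory ---------------------------------------------
    stage = "trajectory"
    try:
        X = cohort.beta.loc[signature.cpgs].T
        dm = diffusion_map(X, knn_k=min(config.knn_k, X.shape[0] - 1),
                           n_comps=min(config.n_diffusion_comps, X.shape[0] - 2))
        tissue = cohort.samples["tissue_class"]
        root_fi = select_root(dm, tissue, "FI")
        root_ose = select_root(dm, tissue, "OSE")
        dpt_fi = diffusion_pseudotime(dm, root_fi)
        dpt_ose = diffusion_pseudotime(dm, root_ose)
        intersection = intersection_analysis(dpt_fi, dpt_ose, tissue)
        report["intersection"] = intersection
        dpt_frame = pd.DataFrame({"dpt_fi": dpt_fi.scaled_dpt,
                                  "dpt_ose": dpt_ose.scaled_dpt})
        _write(manifest, out, "dpt.tsv",
               lambda p: dpt_frame.to_csv(p, sep="\t", index_label="sample_id"))
        _write(manifest, out, "intersection.json",
               lambda p: p.write_text(json.dumps(intersection)))
    except Exception as exc:
        raise PipelineError(stage, str(exc), manifest) from exc

    # ---- stage: transcriptomic translation ------------------------------
    stage = "translate"
    try:
        if sim_params is not None:
            origins = pd.Series(
                rng_origins.permutation(
                    np.array(["FI", "OSE"] * ((n_retrospective + 1) // 2))[:n_retrospective]),
                index=[f"P_{i + 1:03d}" for i in range(n_retrospective)])
            expr, expr_truth = simulate_expression(origins, sim_params,
                                                   preparation="FFPE")
            initial = (origins + "-like")
        else:
            indir = Path(input_dir)
            if not (indir / "counts.tsv").exists():
                raise FileNotFoundError("missing counts.tsv")
            from .expression import ExprCohort, tmm_normalize
            counts = read_matrix_tsv(indir / "counts.tsv").astype(int)
            sf, logcpm = tmm_normalize(counts)
            sheet = read_sample_sheet(indir / "samples.tsv")
            expr = ExprCohort(counts=counts, logcpm=logcpm, size_factors=sf,
                              samples=sheet.loc[counts.columns])
            initial = expr.samples["origin"].astype(str) + "-like"
        de = differential_expression(expr.logcpm, initial,
                                     de_fdr=config.de_fdr, de_min_lfc=config.de_min_lfc)
        report["n_de_genes"] = int(de["significant"].sum())
        # the model is built on the differential genes (all genes if too few)
        model_genes = de.index[de["significant"]]
        model_logcpm = expr.logcpm.loc[model_genes] if len(model_genes) >= 10 else expr.logcpm
        calls = bagging_consistency(model_logcpm, initial, config,
                                    n_gene_permutations=min(config.n_gene_permutations, 100),
                                    n_split_shuffles=min(config.n_split_shuffles, 100))
        report["uncertain_fraction"] = float((calls["label"] == UNCERTAIN).mean())
        _write(manifest, out, "de_table.tsv",
               lambda p: de.to_csv(p, sep="\t", index_label="gene_id"))
        _write(manifest, out, "expr_calls.tsv",
               lambda p: calls.to_csv(p, sep="\t", index_label="sample_id"))
    except Exception as exc:
        raise PipelineError(stage, str(exc), manifest) from exc

    # ---- stage: survival -------------------------------------------------
    stage = "survival"
    try:
        if sim_params is not None:
            surv = simulate_survival(origins, sim_params)
        else:
            indir = Path(input_dir)
            if not (indir / "survival.tsv").exists():
                raise FileNotFoundError("missing survival.tsv")
            surv = pd.read_csv(indir / "survival.tsv", sep="\t", index_col=0)
        labels = calls["label"].reindex(surv.index)
        surv = restrict_followup(surv, config.survival_horizon_days)
        fi_grp = surv[labels == "FI-like"]
        ose_grp = surv[labels == "OSE-like"]
        chi2, p = logrank_test(fi_grp, ose_grp)
        km_fi, km_ose = kaplan_meier(fi_grp), kaplan_meier(ose_grp)
        report["logrank_chi2"] = chi2
        report["logrank_p"] = p
        report["median_fi_days"] = km_fi.median
        report["median_ose_days"] = km_ose.median
        report["median_difference_days"] = median_difference(km_fi, km_ose)
        report["survival_fi_at_horizon"] = km_fi.survival_at(config.survival_horizon_days)
        report["survival_ose_at_horizon"] = km_ose.survival_at(config.survival_horizon_days)
        _write(manifest, out, "survival.tsv",
               lambda p_: surv.to_csv(p_, sep="\t", index_label="sample_id"))
    except Exception as exc:
        raise PipelineError(stage, str(exc), manifest) from exc

    _write(manifest, out, "report.json",
           lambda p: p.write_text(json.dumps(report, indent=1, default=float)))
    (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=1))
    manifest.outputs["manifest.json"] = str(out / "manifest.json")
    return manifest
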