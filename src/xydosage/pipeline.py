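"""End-to-end orchestration of the simulation study.

``run_simulation_study`` wires the stages together on synthetic data with
known ground truth: generate (design, truth, counts, annotation) ->
normalize and filter -> per-gene dosage GLM -> shared X/Y response
statistics -> escape meta-analysis -> repeat-depth copy number -> promoter
peak overlap. Every stage writes its table into the output directory and
the run ends with a manifest (config echo, seeds, thresholds applied, and
per-stage row counts) so a run is auditable and reproducible: the same
config yields bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as xio
from . import regulatory_overlap, shared_response, structural_variation, synthetic_data
from . import dosage_model
from . import xi_escape_meta

__all__ = ["RunConfig", "run_simulation_study", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Thresholds, sizes and seeds of a simulation run.

    Thresholds default to the study's cutoffs: adjusted p < 0.05 for
    dosage response, TPM >= 1 expression filter, FDR 0.05 for category
    enrichment, and the per-dataset escape-caller settings documented in
    :mod:`xydosage.xi_escape_meta`.
    """

    seed: int = 0
    out_dir: str = "results"
    n_genes: int = 2000
    cell_type: str = "LCL"
    alpha: float = 0.05
    tpm_cutoff: float = 1.0
    enrichment_fdr: float = 0.05
    library_size_mean: float = 2e6
    effect_sd: float = 0.2
    repeat_copy_factor: float = 202.5
    gc_bias_strength: float = 1.0
    promoter_half_width: int = 1000
    counts_path: str | None = None  # optional user counts (TSV) instead of simulation
    meta_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self):
        for name in ("alpha", "tpm_cutoff", "enrichment_fdr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("counts_path", "meta_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")


def run_simulation_study(config: RunConfig) -> dict:
    """Execute the full synthetic-data pipeline and write a manifest.

    Returns the manifest dict. Stage failures abort with
    :class:`StageError` naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": dataclasses.asdict(config),
        "thresholds": {
            "dosage_alpha": config.alpha,
            "tpm_cutoff": config.tpm_cutoff,
            "enrichment_fdr": config.enrichment_fdr,
            "sauteraud_alpha": 0.01,
            "garieri_ar_threshold": xi_escape_meta.GARIERI_AR_THRESHOLD,
        },
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            try:
                n = fn()
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise StageError(name, exc) from exc
            manifest["stages"][name] = {"rows": int(n)}
            return fn

        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        design = (
            synthetic_data.LCL_DESIGN
            if config.cell_type == "LCL"
            else synthetic_data.FIBROBLAST_DESIGN
        )
        truth = synthetic_data.generate_truth(
            config.n_genes, effect_sd=config.effect_sd, seed=config.seed
        )
        if config.counts_path is not None:
            counts = xio.read_counts_tsv(config.counts_path)
            meta = xio.read_table(config.meta_path)
        else:
            meta = synthetic_data.generate_design(design, seed=config.seed)
            counts = synthetic_data.generate_counts(
                meta, truth, library_size_mean=config.library_size_mean, seed=config.seed + 1
            )
        ann = synthetic_data.generate_annotation(truth, seed=config.seed + 2)
        state.update(truth=truth, meta=meta, counts=counts, ann=ann)
        xio.write_counts_tsv(counts, out / "counts.tsv")
        xio.write_table(meta, out / "meta.tsv")
        xio.write_table(ann, out / "annotation.tsv")
        xio.write_table(truth.genes, out / "truth.tsv")
        return len(counts)

    @stage("normalize_filter")
    def _normalize():
        counts, meta, ann = state["counts"], state["meta"], state["ann"]
        tpm = dosage_model.compute_tpm(counts, ann["length"])
        expressed = dosage_model.filter_expressed(tpm, meta)
        state["expressed"] = expressed
        (out / "expressed_genes.txt").write_text("\n".join(expressed) + "\n")
        return len(expressed)

    @stage("fit_dosage")
    def _fit():
        fit = dosage_model.fit_dosage_glm(
            state["counts"], state["meta"], gene_subset=state["expressed"]
        )
        state["fit"] = fit
        xio.write_table(fit, out / "dosage_fits.tsv", index=False)
        return len(fit)

    @stage("shared_response")
    def _shared():
        fit = state["fit"]
        sig = {
            coef: set(grp.loc[grp["padj"] < config.alpha, "gene"])
            for coef, grp in fit.groupby("coef")
        }
        universe = set(state["expressed"])
        ov = shared_response.overlap_test(
            sig["x_copies"], sig["y_copies"], universe, n_tests=1
        )
        result = {
            "n_x_responsive": ov.n_a,
            "n_y_responsive": ov.n_b,
            "n_shared": ov.n_overlap,
            "overlap_p": ov.p,
        }
        both = sorted(sig["x_copies"] & sig["y_copies"])
        if len(both) >= 3:
            fx = fit[fit["coef"] == "x_copies"].set_index("gene").loc[both]
            fy = fit[fit["coef"] == "y_copies"].set_index("gene").loc[both]
            r, p, _ = shared_response.correlate_effects(
                fit[fit["coef"] == "x_copies"], fit[fit["coef"] == "y_copies"], both
            )
            dem = shared_response.weighted_deming(
                fx["log2fc_per_copy"], fy["log2fc_per_copy"], fx["se"], fy["se"]
            )
            result.update(pearson_r=r, pearson_p=p, deming_slope=dem.slope)
        state["shared"] = result
        (out / "shared_response.json").write_text(json.dumps(result, indent=2))
        return len(both)

    @stage("escape_meta")
    def _escape():
        datasets = synthetic_data.generate_allelic_datasets(
            state["truth"], seed=config.seed + 3
        )
        calls = xi_escape_meta.evidence_to_calls(datasets)
        state["escape_calls"] = calls
        xio.write_table(calls, out / "escape_calls.tsv", index=False)
        return len(calls)

    @stage("repeat_depth")
    def _depth():
        profile = synthetic_data.generate_depth_profile(
            config.repeat_copy_factor,
            gc_bias_strength=config.gc_bias_strength,
            seed=config.seed + 4,
        )
        corrected = structural_variation.gc_correct(profile)
        factor = structural_variation.normalized_repeat_depth(corrected)
        state["repeat_factor"] = factor
        xio.write_table(corrected, out / "depth_corrected.tsv", index=False)
        (out / "repeat_factor.json").write_text(
            json.dumps({"normalized_repeat_depth": factor})
        )
        return len(profile)

    @stage("regulatory_overlap")
    def _peaks():
        truth, ann, fit = state["truth"], state["ann"], state["fit"]
        up = fit[(fit["coef"] == "x_copies") & (fit["padj"] < config.alpha) & (fit["log2fc_per_copy"] > 0)]["gene"]
        rng = np.random.default_rng(config.seed + 5)
        # peaks at promoters of positively X-responsive genes plus background
        background = rng.choice(ann.index, size=min(50, len(ann)), replace=False)
        bound = sorted(set(up) | set(background))
        peaks = synthetic_data.generate_peaks(
            ann, bound, window=config.promoter_half_width, seed=config.seed + 6
        )
        flags = regulatory_overlap.assign_peaks_to_tss(peaks, ann, config.promoter_half_width)
        targets = regulatory_overlap.direct_targets(
            flags, fit[fit["coef"] == "x_copies"], alpha=config.alpha
        )
        state["targets"] = targets
        xio.write_bed(peaks, out / "peaks.bed")
        (out / "direct_targets.txt").write_text("\n".join(sorted(targets)) + "\n")
        return len(peaks)

    manifest["n_stages_completed"] = len(manifest["stages"])
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
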