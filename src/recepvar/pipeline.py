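"""End-to-end orchestration: studies -> CV maps -> bootstrap -> consistency.

One config (YAML mapping, documented in ``PipelineConfig``) drives the full
analysis over a set of tracer studies — either the built-in synthetic suite
or studies loaded from regional tables / NIfTI volumes. Per-tracer failures
are fail-soft: the stage error is recorded with the study id and the run
continues across tracers.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import COMPARTMENTS, build_default_atlas
from .errors import ContractError
from .inference import (BootstrapResult, ConsistencyRecord, covariate_diagnostics,
                        derive_rng, bootstrap_compare, mean_consistency,
                        ratio_vs_consistency)
from .io import read_regional_table, write_regional_table
from .maps import CompartmentStats, RegionalMap, TracerStudy, VariabilityResult
from .parcellation import apply_exclusions
from .variability import (FilterPolicy, cv_ratio, interindividual_cv,
                          interregional_cv, mean_interindividual_cv,
                          minmax_scale)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run configuration.

    seed: master seed; per-tracer streams are derived from (seed, study id).
    n_boot: bootstrap resamples for the inter-regional vs inter-individual
        comparison (default 10,000).
    alpha: significance level for the comparison (default 0.05).
    ddof: delta degrees of freedom for the inter-regional standard
        deviation (default 1 = sample sd).
    policy: low-binding filter (see FilterPolicy).
    consistency_mode: "original_vs_others" (default) or "all_pairs".
    n_replicates: synthetic out-of-sample cohorts per study used as
        "other maps" for consistency scoring.
    templates: optional explicit synthetic template list (None = default
        suite); an empty list runs an empty suite.
    studies: optional list of file-backed study descriptions (dicts with
        study metadata plus a "table" path containing mean/std columns).
    n_perm: permutations for the cross-tracer correlation tests.
    """

    seed: int = 0
    n_boot: int = 10_000
    alpha: float = 0.05
    ddof: int = 1
    policy: FilterPolicy = field(default_factory=FilterPolicy)
    consistency_mode: str = "original_vs_others"
    n_replicates: int = 1
    templates: Optional[list] = None
    studies: Optional[list] = None
    n_perm: int = 10_000

    @classmethod
    def from_mapping(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        policy = FilterPolicy(**raw.pop("policy", {}))
        templates = raw.pop("templates", None)
        if templates is not None:
            from .synthetic import TracerTemplate

            templates = [t if isinstance(t, TracerTemplate) else TracerTemplate(**t)
                         for t in templates]
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ContractError(f"unknown config keys: {sorted(unknown)}")
        return cls(policy=policy, templates=templates, **raw)

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})


@dataclass
class PipelineResult:
    """Everything one run produced."""

    config: PipelineConfig
    studies: List[TracerStudy]
    variability: Dict[str, VariabilityResult]
    bootstraps: Dict[tuple, BootstrapResult]
    consistency: Dict[str, ConsistencyRecord]
    summary: pd.DataFrame
    ratio_consistency: Dict[str, dict]
    covariates: Optional[pd.DataFrame]
    errors: List[dict]

    @property
    def ok(self) -> bool:
        return not self.errors


def _load_table_study(entry: dict) -> TracerStudy:
    maps = read_regional_table(entry["table"])
    by_label = {m.units_label: m for m in maps}
    if "mean" not in by_label or "std" not in by_label:
        raise ContractError(f"study table {entry['table']} needs 'mean' and 'std' columns")
    meta = {k: v for k, v in entry.items() if k not in ("table",)}
    meta.setdefault("receptor", "unknown")
    meta.setdefault("tracer", "unknown")
    meta.setdefault("measure", "BP_ND")
    meta.setdefault("n_subjects", 2)
    meta["reference_exclusion"] = frozenset(meta.get("reference_exclusion", ()))
    return TracerStudy(mean_map=by_label["mean"], std_map=by_label["std"], **meta)


def _analyze_study(study: TracerStudy, config: PipelineConfig):
    """CV map + per-compartment statistics for one study."""
    mean_map = apply_exclusions(study.mean_map, study)
    std_map = apply_exclusions(study.std_map, study)
    cv_map, retained = interindividual_cv(mean_map, std_map, config.policy)
    compartments: Dict[str, CompartmentStats] = {}
    boots: Dict[str, BootstrapResult] = {}
    # inter-regional CV is computed over the same retained region set as the
    # CV map so the two sides of the ratio describe identical territory
    retained_mean = mean_map.with_values(mean_map.values, valid=retained)
    for compartment in COMPARTMENTS:
        try:
            ir_cv = interregional_cv(retained_mean, compartment, ddof=config.ddof)
            mean_cv = mean_interindividual_cv(cv_map, compartment)
            ratio = cv_ratio(ir_cv, cv_map, compartment)
            rng = derive_rng(config.seed, "bootstrap", study.study_id, compartment)
            boot = bootstrap_compare(
                cv_map, ir_cv, compartment, n_boot=config.n_boot,
                rng=rng, seed=config.seed, alpha=config.alpha,
            )
            compartments[compartment] = CompartmentStats(
                compartment=compartment, inter_regional_cv=ir_cv,
                mean_interindividual_cv=mean_cv, ratio=ratio,
                p_boot=boot.p_value, n_boot=boot.n_boot, seed=config.seed,
                n_regions=int(cv_map.valid_values(compartment).size),
                significant=boot.significant,
            )
            boots[compartment] = boot
        except ContractError as exc:
            # e.g. striatum-only tracer has no retained cortical regions
            logger.info("study %s, compartment %s skipped: %s",
                        study.study_id, compartment, exc)
    result = VariabilityResult(
        study_id=study.study_id, cv_map=cv_map, retained=retained,
        compartments=compartments,
    )
    return result, mean_map, boots


def _scaled_cv(cv_map: RegionalMap) -> RegionalMap:
    """Per-compartment min-max scaling merged back into one map."""
    out = np.full(cv_map.values.shape, np.nan)
    valid = np.zeros(cv_map.values.shape, dtype=bool)
    for compartment in COMPARTMENTS:
        try:
            scaled = minmax_scale(cv_map, compartment)
        except ContractError:
            continue
        out[scaled.valid] = scaled.values[scaled.valid]
        valid |= scaled.valid
    return RegionalMap(atlas=cv_map.atlas, values=out, valid=valid, quantity="scaled_cv")


def run_pipeline(config, out_dir: Optional[str] = None) -> PipelineResult:
    """Run the full analysis; optionally write TSV outputs + a manifest."""
    if isinstance(config, str):
        config = PipelineConfig.from_file(config)
    elif isinstance(config, dict):
        config = PipelineConfig.from_mapping(config)

    errors: List[dict] = []

    # ---- assemble studies -------------------------------------------------
    studies: List[TracerStudy] = []
    replicates: Dict[str, List[TracerStudy]] = {}
    if config.studies:
        for entry in config.studies:
            try:
                studies.append(_load_table_study(entry))
            except Exception as exc:  # fail-soft per study
                errors.append({"study": str(entry.get("study_id", entry)),
                               "stage": "load", "error": str(exc)})
    else:
        from .synthetic import make_tracer_suite

        studies, replicates = make_tracer_suite(
            templates=config.templates, seed=config.seed,
            n_replicates=config.n_replicates,
        )
    if not studies:
        raise ContractError("config names no tracer studies")

    # ---- per-tracer variability + bootstrap -------------------------------
    variability: Dict[str, VariabilityResult] = {}
    bootstraps: Dict[tuple, BootstrapResult] = {}
    excluded_means: Dict[str, RegionalMap] = {}
    for study in studies:
        try:
            result, mean_map, boots = _analyze_study(study, config)
            variability[study.study_id] = result
            excluded_means[study.study_id] = mean_map
            for compartment, boot in boots.items():
                bootstraps[(study.study_id, compartment)] = boot
        except ContractError as exc:
            errors.append({"study": study.study_id, "stage": "variability",
                           "error": str(exc)})

    # ---- spatial consistency ---------------------------------------------
    consistency: Dict[str, ConsistencyRecord] = {}
    for study in studies:
        if study.study_id not in excluded_means:
            continue
        others, other_ids = [], []
        for peer in studies:
            if peer.study_id != study.study_id and peer.family == study.family \
                    and peer.study_id in excluded_means:
                others.append(excluded_means[peer.study_id])
                other_ids.append(peer.study_id)
        for rep in replicates.get(study.study_id, []):
            others.append(apply_exclusions(rep.mean_map, rep))
            other_ids.append(rep.study_id)
        if not others:
            continue
        try:
            consistency[study.study_id] = mean_consistency(
                excluded_means[study.study_id], others, receptor=study.receptor,
                original_map_id=study.study_id, other_map_ids=other_ids,
                mode=config.consistency_mode,
            )
        except ContractError as exc:
            errors.append({"study": study.study_id, "stage": "consistency",
                           "error": str(exc)})

    # ---- cross-tracer: ratio vs consistency, covariates -------------------
    ratio_consistency: Dict[str, dict] = {}
    for compartment in COMPARTMENTS:
        pairs = [
            (variability[sid].compartments[compartment].ratio,
             consistency[sid].mean_consistency, sid)
            for sid in variability
            if compartment in variability[sid].compartments and sid in consistency
        ]
        if len(pairs) < 4:
            continue
        ratios = [p[0] for p in pairs]
        cons = [p[1] for p in pairs]
        try:
            r, p_perm, p_asym = ratio_vs_consistency(
                ratios, cons, n_perm=config.n_perm,
                rng=derive_rng(config.seed, "ratio-consistency", compartment),
            )
            ratio_consistency[compartment] = {
                "spearman_r": r, "p_perm": p_perm, "p_asymptotic": p_asym,
                "n_receptors": len(pairs), "study_ids": [p[2] for p in pairs],
            }
        except ContractError as exc:
            errors.append({"study": "<cross-tracer>", "stage": "ratio_vs_consistency",
                           "error": str(exc)})

    covariates = None
    cov_rows = [
        (next(s for s in studies if s.study_id == sid),
         variability[sid].compartments["cortex"].mean_interindividual_cv)
        for sid in variability if "cortex" in variability[sid].compartments
    ]
    if len(cov_rows) >= 4:
        covariates = covariate_diagnostics(
            [r[0] for r in cov_rows], [r[1] for r in cov_rows],
            n_perm=config.n_perm, seed=config.seed,
        )

    summary = report_summary(studies, variability, consistency)

    result = PipelineResult(
        config=config, studies=studies, variability=variability,
        bootstraps=bootstraps, consistency=consistency, summary=summary,
        ratio_consistency=ratio_consistency, covariates=covariates,
        errors=errors,
    )
    if out_dir is not None:
        _write_outputs(result, out_dir)
    return result


def report_summary(studies, variability, consistency) -> pd.DataFrame:
    """One row per tracer x compartment, plus significance counts.

    The DataFrame carries a ``significant_counts`` attribute mapping each
    compartment to a "k/N" string (tracers with p < alpha over tracers with
    a defined p), the analogue of the "3/16 cortical, 9/16 subcortical"
    style of reporting.
    """
    rows = []
    for study in studies:
        if study.study_id not in variability:
            continue
        result = variability[study.study_id]
        for compartment in COMPARTMENTS:
            stats_ = result.compartments.get(compartment)
            row = {
                "study_id": study.study_id, "receptor": study.receptor,
                "tracer": study.tracer, "measure": study.measure,
                "n_subjects": study.n_subjects, "compartment": compartment,
            }
            if stats_ is None:
                row.update({"inter_regional_cv": np.nan,
                            "mean_interindividual_cv": np.nan, "ratio": np.nan,
                            "p_boot": np.nan, "significant": pd.NA,
                            "n_regions": 0})
            else:
                row.update({
                    "inter_regional_cv": stats_.inter_regional_cv,
                    "mean_interindividual_cv": stats_.mean_interindividual_cv,
                    "ratio": stats_.ratio, "p_boot": stats_.p_boot,
                    "significant": stats_.significant,
                    "n_regions": stats_.n_regions,
                })
            record = consistency.get(study.study_id)
            row["mean_consistency"] = record.mean_consistency if record else np.nan
            rows.append(row)
    frame = pd.DataFrame(rows)
    counts = {}
    if not frame.empty:
        for compartment in COMPARTMENTS:
            sub = frame[(frame["compartment"] == compartment) & frame["p_boot"].notna()]
            counts[compartment] = f"{int((sub['significant'] == True).sum())}/{len(sub)}"
    frame.attrs["significant_counts"] = counts
    return frame


def format_summary(result: PipelineResult) -> str:
    """Human-readable run summary."""
    lines = ["tracer variability summary", "=" * 26]
    counts = result.summary.attrs.get("significant_counts", {})
    for compartment in COMPARTMENTS:
        if compartment in counts:
            lines.append(
                f"{compartment}: {counts[compartment]} tracers with inter-regional CV "
                f"significantly greater than inter-individual CV"
            )
        rc = result.ratio_consistency.get(compartment)
        if rc:
            lines.append(
                f"{compartment}: ratio vs consistency Spearman r = "
                f"{rc['spearman_r']:.3f} (perm p = {rc['p_perm']:.4f}, "
                f"n = {rc['n_receptors']})"
            )
    if result.errors:
        lines.append(f"{len(result.errors)} stage error(s); see manifest")
    return "\n".join(lines)


def _write_outputs(result: PipelineResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for sid, var in result.variability.items():
        scaled = _scaled_cv(var.cv_map)
        retained_map = RegionalMap(
            atlas=var.cv_map.atlas, values=var.retained.astype(float),
            valid=np.ones_like(var.retained), quantity="mean",
        )
        safe = sid.replace("/", "_").replace(":", "_").replace("#", "_")
        write_regional_table(
            [var.cv_map, retained_map, scaled],
            os.path.join(out_dir, f"{safe}_cv.tsv"),
            names=["cv", "retained", "scaled_cv"],
        )
    result.summary.to_csv(os.path.join(out_dir, "summary.tsv"), sep="\t",
                          index=False, na_rep="NaN", float_format="%.17g")
    if result.covariates is not None:
        result.covariates.to_csv(os.path.join(out_dir, "covariates.tsv"),
                                 sep="\t", index=False, na_rep="NaN",
                                 float_format="%.17g")
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": result.config.seed,
        "n_boot": result.config.n_boot,
        "alpha": result.config.alpha,
        "significant_counts": result.summary.attrs.get("significant_counts", {}),
        "ratio_consistency": {
            k: {kk: vv for kk, vv in v.items() if kk != "study_ids"}
            for k, v in result.ratio_consistency.items()
        },
        "config_hash": hashlib.sha256(
            repr(result.config).encode("utf-8")).hexdigest()[:16],
        "errors": result.errors,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
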