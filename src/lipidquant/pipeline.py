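"""End-to-end pipeline orchestration.

Runs annotation, isotope correction, normalization/quantitation and
statistics over a feature table, writing versioned TSV outputs whose
headers carry the effective configuration hash. Stages validate their
inputs and fail with stage-specific exit codes; intermediate files from a
different configuration are refused.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import pandas as pd
import yaml

from . import annotate as _annotate
from . import io as _io
from . import isocorrect as _isocorrect
from . import quantify as _quantify
from . import simulate as _simulate
from . import stats as _stats
from .annotate import FeatureTable, ResolutionModel
from .chem import LipidDatabase, default_database

log = logging.getLogger("lipidquant")

STAGE_CODES = {
    "simulate": 10,
    "annotate": 20,
    "correct": 30,
    "quantify": 40,
    "stats": 50,
    "enzyme": 60,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage's exit code."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = STAGE_CODES.get(stage, 1)


@dataclass
class PipelineConfig:
    """Effective configuration of a pipeline run.

    All defaults are serializable; the hash of the serialized form is
    embedded in every output header.
    """

    tolerance_ppm: float = 3.0
    max_shift: int = 3
    resolving_power: float = 280_000.0
    ref_mz: float = 200.0
    merge_multiple: float = 1.0
    solver: str = "nnls"
    test: str = "pooled"            # pooled | welch
    n_components: int = 2
    top_k: int = 30
    seed: int = 0
    simulate: Dict[str, float] = field(default_factory=dict)

    def resolution_model(self) -> ResolutionModel:
        return ResolutionModel(
            self.resolving_power, self.ref_mz, self.merge_multiple
        )

    def study_config(self) -> "_simulate.StudyConfig":
        return _simulate.StudyConfig(
            resolution=self.resolution_model(),
            max_shift=self.max_shift,
            **self.simulate,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        return _io.config_hash(self.to_dict())

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return PipelineConfig(**raw)


def stage_simulate(config: PipelineConfig, outdir: Path) -> FeatureTable:
    try:
        table, truth = _simulate.simulate_study(
            config.study_config(), seed=config.seed
        )
    except ValueError as exc:
        raise StageError("simulate", str(exc)) from exc
    outdir.mkdir(parents=True, exist_ok=True)
    _io.write_feature_table(
        table, outdir / "features.tsv", outdir / "samples.tsv", config.hash
    )
    import json

    truth_doc = {
        "schema_version": 1,
        "seed": truth.seed,
        "cv": truth.cv,
        "ppm_sd": truth.ppm_sd,
        "multipliers": truth.multipliers,
        "linkage": truth.linkage,
        "standards_nmol": truth.standards_nmol,
        "amounts": truth.amounts.to_dict(),
    }
    (outdir / "truth.json").write_text(json.dumps(truth_doc, indent=1))
    log.info(
        "simulate: %d features, %d samples", table.n_features,
        len(table.sample_ids),
    )
    return table


def stage_annotate(
    config: PipelineConfig, table: FeatureTable, db: LipidDatabase,
    outdir: Path,
) -> pd.DataFrame:
    try:
        ann = _annotate.match_features(
            table, db, tolerance_ppm=config.tolerance_ppm,
            max_shift=config.max_shift,
        )
    except ValueError as exc:
        raise StageError("annotate", str(exc)) from exc
    frac_unannotated = 1 - ann["feature_id"].nunique() / max(table.n_features, 1)
    if frac_unannotated > 0.5:
        log.warning(
            "annotate: %.0f%% of features unannotated", 100 * frac_unannotated
        )
    _io.write_table(ann, outdir / "annotations.tsv", config.hash, index=False)
    log.info(
        "annotate: %d features in, %d annotated", table.n_features,
        ann["feature_id"].nunique(),
    )
    return ann


def stage_correct(
    config: PipelineConfig, table: FeatureTable, ann: pd.DataFrame,
    db: LipidDatabase, outdir: Path,
) -> pd.DataFrame:
    try:
        groups = _annotate.build_overlap_groups(
            ann, db, config.resolution_model(), config.max_shift,
            features=table.features,
        )
        corrected, diag, unknowns = _isocorrect.correct_feature_table(
            table, groups, ann
        )
    except ValueError as exc:
        raise StageError("correct", str(exc)) from exc
    _io.write_table(corrected, outdir / "corrected.tsv", config.hash)
    _io.write_table(diag, outdir / "correction_diagnostics.tsv", config.hash,
                    index=False)
    _io.write_table(unknowns, outdir / "unknown_features.tsv", config.hash)
    log.info(
        "correct: %d groups, %d species out, %d unknown features",
        len(groups), len(corrected), len(unknowns),
    )
    return corrected


def stage_quantify(
    config: PipelineConfig, corrected: pd.DataFrame, table: FeatureTable,
    db: LipidDatabase, outdir: Path,
) -> "_quantify.AbundanceMatrix":
    bad = table.samples[table.samples["protein_mg"] <= 0]
    if len(bad):
        raise StageError(
            "quantify",
            f"non-positive protein_mg for sample(s): {list(bad.index)}",
        )
    try:
        ab = _quantify.normalize(corrected, db, table.samples)
        totals = _quantify.class_totals(ab)
    except ValueError as exc:
        raise StageError("quantify", str(exc)) from exc
    values = ab.values.copy()
    values.insert(0, "unit", ab.units)
    values.insert(0, "class", ab.species_class)
    _io.write_table(values, outdir / "abundance.tsv", config.hash)
    _io.write_table(totals, outdir / "class_totals.tsv", config.hash)
    log.info("quantify: %d species, %d classes", len(ab.values), len(totals))
    return ab


def stage_stats(
    config: PipelineConfig, ab: "_quantify.AbundanceMatrix",
    table: FeatureTable, outdir: Path,
) -> pd.DataFrame:
    try:
        values = ab.values.dropna(axis=0, how="any")
        groups = table.samples["group"]
        cond = table.samples["condition"]
        res = _stats.differential_stats(
            values, groups, control_label="control",
            equal_var=(config.test == "pooled"),
        )
        model = _stats.plsda_fit(
            values.T, cond, n_components=config.n_components
        )
        vip = _stats.vip_scores(model)
        res["VIP"] = vip
        fc = _quantify.fold_changes(values, cond)
        res["status"] = fc["status"]
        hm, order = _stats.heatmap_matrix(values, vip, k=config.top_k)
    except ValueError as exc:
        raise StageError("stats", str(exc)) from exc
    _io.write_table(res, outdir / "stats.tsv", config.hash)
    _io.write_table(
        vip.sort_values(ascending=False).to_frame(), outdir / "vip.tsv",
        config.hash,
    )
    _io.write_table(hm, outdir / "heatmap.tsv", config.hash)
    _stats.plot_heatmap(hm, outdir / "heatmap.png")
    log.info("stats: %d species tested, top-%d heat map", len(res),
             len(order))
    return res


def run_pipeline(
    config: PipelineConfig,
    outdir,
    table: Optional[FeatureTable] = None,
    db: Optional[LipidDatabase] = None,
) -> Dict[str, pd.DataFrame]:
    """Run simulate (if no table given) -> annotate -> correct -> quantify
    -> stats; returns the key frames and writes all outputs under
    ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    db = db or default_database()
    if table is None:
        table = stage_simulate(config, outdir)
    else:
        _io.write_feature_table(
            table, outdir / "features.tsv", outdir / "samples.tsv", config.hash
        )
    ann = stage_annotate(config, table, db, outdir)
    corrected = stage_correct(config, table, ann, db, outdir)
    ab = stage_quantify(config, corrected, table, db, outdir)
    res = stage_stats(config, ab, table, outdir)
    return {
        "features": table.features,
        "annotations": ann,
        "corrected": corrected,
        "abundance": ab.values,
        "stats": res,
    }
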