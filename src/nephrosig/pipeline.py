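"""End-to-end pipeline: simulate -> preprocess -> score -> signatures -> classify.

The configuration is schema-validated (unknown keys rejected) before any
stage runs; all randomness derives from the single global seed via
per-stage spawned seeds, and a JSON manifest (stage order, output hashes,
seeds, package versions) makes every artifact reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import classify as _classify
from . import io as _io
from . import power as _power
from . import preprocessing as _pre
from . import signatures as _sig
from . import scoring as _score
from . import synthetic as _syn

logger = logging.getLogger("nephrosig")

__all__ = ["PipelineConfig", "run_pipeline"]


class _Forbid(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StageToggles(_Forbid):
    simulate: bool = True
    preprocess: bool = True
    score: bool = True
    signatures: bool = True
    classify: bool = True
    power_sim: bool = False
    bulk_de: bool = False


class SyntheticSettings(_Forbid):
    n_cells: int = Field(2000, gt=0)
    n_genes: int = Field(2000, gt=0)
    n_donors: int = Field(8, ge=2)
    target_sparsity: float = Field(0.9, ge=0.0, lt=1.0)
    level: str = "detailed32"
    n_toxic: int = Field(215, gt=0)
    n_nontoxic: int = Field(641, gt=0)
    susceptible_cell_types: list[str] = Field(default_factory=list)
    enrichment_strength: float = Field(0.0, ge=0.0, le=1.0)


class QCSettings(_Forbid):
    min_umi: int = 500
    min_genes_per_cell: int = 250
    min_log10_genes_per_umi: float = 0.85
    min_cells_per_gene: int = 10
    scale_factor: float = 10_000.0
    n_hvg: int = 2000


class PowerSettings(_Forbid):
    effect_sizes: list[float] = Field(default_factory=_power._default_effects)
    response_rates: list[float] = Field(default_factory=lambda: [0.3, 0.8, 0.95])
    subsample_fraction: float = 0.10
    significance_threshold: float = _power.DEFAULT_SIGNIFICANCE
    abstraction_level: str = "abstract4"
    n_replicate_runs: int = 3
    mode: str = "pseudo_bulk"


class ClassifierSettings(_Forbid):
    families: list[str] = Field(default_factory=lambda: list(_classify.MODEL_FAMILIES))
    k: int = Field(5, ge=2)
    level: str = "detailed32"


class PipelineConfig(_Forbid):
    out_dir: str
    seed: int = 0
    stages: StageToggles = Field(default_factory=StageToggles)
    synthetic: SyntheticSettings = Field(default_factory=SyntheticSettings)
    qc: QCSettings = Field(default_factory=QCSettings)
    power: PowerSettings = Field(default_factory=PowerSettings)
    classifier: ClassifierSettings = Field(default_factory=ClassifierSettings)

    @model_validator(mode="after")
    def _check_stage_dependencies(self) -> "PipelineConfig":
        s = self.stages
        if s.preprocess and not s.simulate:
            raise ValueError("preprocess requires simulate")
        if s.score and not (s.simulate and s.preprocess):
            raise ValueError("score requires simulate and preprocess")
        if s.signatures and not s.score:
            raise ValueError("signatures requires score")
        if s.classify and not s.score:
            raise ValueError("classify requires score")
        return self


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] >> 1)
        for name, child in zip(
            ("simulate", "drugs", "power", "classify"), ss.spawn(4)
        )
    }
    manifest: dict = {"seed": config.seed, "stage_seeds": stage_seeds, "stages": []}

    syn = config.synthetic
    level = syn.level
    adata = scores_table = None
    specs = (
        _syn.detailed_cell_type_specs(syn.n_genes)
        if level == "detailed32"
        else _syn.abstract_cell_type_specs(syn.n_genes)
    )

    if config.stages.simulate:
        cfg = _syn.SyntheticConfig(
            n_cells=syn.n_cells,
            n_genes=syn.n_genes,
            n_donors=syn.n_donors,
            target_sparsity=syn.target_sparsity,
            seed=stage_seeds["simulate"],
            cell_type_specs=specs,
        )
        adata = _syn.generate_cell_matrix(cfg)
        _io.write_matrix(adata, out / "matrix")
        signal = _syn.SignalSpec(
            susceptible_cell_types=frozenset(syn.susceptible_cell_types),
            enrichment_strength=syn.enrichment_strength,
        )
        db = _syn.generate_drug_db(
            syn.n_toxic,
            syn.n_nontoxic,
            signal,
            _syn.gene_universe(syn.n_genes),
            stage_seeds["drugs"],
            cell_type_specs=specs,
        )
        _io.write_drug_db(db, out / "drugs.csv")
        manifest["stages"].append(
            {"stage": "simulate", "outputs": {
                "matrix.mtx": _sha256(out / "matrix" / "matrix.mtx"),
                "drugs.csv": _sha256(out / "drugs.csv"),
            }}
        )

    if config.stages.preprocess:
        thr = _pre.QCThresholds(**config.qc.model_dump())
        adata = _pre.qc_filter(adata, thr)
        adata = _pre.log_normalize(adata, thr.scale_factor)
        adata.uns["qc_report"].to_csv(out / "qc_report.tsv", sep="\t", index=False)
        manifest["stages"].append(
            {"stage": "preprocess", "outputs": {"qc_report.tsv": _sha256(out / "qc_report.tsv")}}
        )

    if config.stages.power_sim:
        grid = _power.SimulationGrid(
            effect_sizes=config.power.effect_sizes,
            response_rates=config.power.response_rates,
            subsample_fraction=config.power.subsample_fraction,
            significance_threshold=config.power.significance_threshold,
            abstraction_level=config.power.abstraction_level,
            n_replicate_runs=config.power.n_replicate_runs,
            seed=stage_seeds["power"],
        )
        results = _power.run_power_grid(adata, grid, config.power.mode)
        pd.DataFrame([r.__dict__ for r in results]).to_csv(
            out / "power.tsv", sep="\t", index=False
        )
        manifest["stages"].append(
            {"stage": "power_sim", "outputs": {"power.tsv": _sha256(out / "power.tsv")}}
        )

    if config.stages.score:
        db = _io.read_drug_db(out / "drugs.csv")
        T, ids, tox = _score.build_target_matrix(db, list(adata.var_names))
        raw = _score.score_cells(adata, T, ids, tox)
        logged = _score.log_transform_scores(raw)
        scores_table = _score.aggregate_by_cell_type(logged, level=level)
        if level == "detailed32":
            scores_table = pd.concat(
                [scores_table, _score.aggregate_by_cell_type(logged, level="abstract4")],
                ignore_index=True,
            )
        scores_table.to_csv(out / "celltype_scores.tsv", sep="\t", index=False)
        manifest["stages"].append(
            {"stage": "score", "outputs": {
                "celltype_scores.tsv": _sha256(out / "celltype_scores.tsv")
            }}
        )

    if config.stages.signatures:
        rows = _sig.compare_groups(scores_table)
        _sig.signature_frame(rows).to_csv(out / "signatures.tsv", sep="\t", index=False)
        manifest["stages"].append(
            {"stage": "signatures", "outputs": {"signatures.tsv": _sha256(out / "signatures.tsv")}}
        )

    if config.stages.classify:
        feats = _classify.build_feature_table(scores_table, config.classifier.level)
        report = _classify.evaluate_families(
            feats,
            families=config.classifier.families,
            k=config.classifier.k,
            seed=stage_seeds["classify"],
        )
        report.to_csv(out / "eval.tsv", sep="\t", index=False)
        manifest["stages"].append(
            {"stage": "classify", "outputs": {"eval.tsv": _sha256(out / "eval.tsv")}}
        )

    from importlib.metadata import version

    manifest["versions"] = {
        pkg: version(pkg)
        for pkg in ("numpy", "scipy", "pandas", "anndata", "scikit-learn")
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline: wrote %s", out / "manifest.json")
    return out
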