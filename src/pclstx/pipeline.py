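"""End-to-end orchestration of the analysis stages.

Stages (in dependency order): ``simulate`` (synthetic study generation),
``qc`` (PCA, outlier screen, clustering, CV), ``de`` (paired contrasts per
species), ``score`` (sign scoring and gene ranking), ``xspecies``
(ortholog-pair concordance).  Inputs are never mutated; every output is a
new TSV under the output directory with a provenance header, and a manifest
lists all outputs with content hashes so determinism is checkable by
comparing manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .de import PairedContrastModel, log_cpm
from .design import contrast_set
from .io import (
    EXCLUSION_COLUMNS,
    METADATA_COLUMNS,
    ORTHOLOG_COLUMNS,
    FormatError,
    config_hash,
    read_tsv,
    write_tsv,
)
from .qc import cv_by_condition, flag_outliers, hierarchical_cluster, run_pca
from .scoring import build_gene_scores, select_and_rank
from .simulate import SimulationConfig, simulate_ortholog_map, simulate_study
from .xspecies import (
    condition_correlations,
    correlation_vs_identity,
    donor_center,
    group_medians,
    pair_correlations,
    resolve_orthologs,
    top_pairs,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "MissingInputError",
    "SampleMismatchError",
    "run_pipeline",
    "ALL_STAGES",
]

log = logging.getLogger("pclstx")

ALL_STAGES = ("simulate", "qc", "de", "score", "xspecies")
SPECIES = ("human", "mouse")


class PipelineError(RuntimeError):
    """Base class for named pipeline failures."""


class MissingInputError(PipelineError):
    """A stage's required input file does not exist."""


class SampleMismatchError(PipelineError):
    """Counts and metadata disagree on sample identity."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, serialisable to/from YAML."""

    outdir: str = "pclstx_out"
    seed: int = 0
    alpha: float = 0.05
    lfc_threshold: float = 0.5
    min_abs_sum: int = 8
    pseudocount: float = 0.5
    count_filter: int = 10
    outlier_n_pcs: int = 3
    outlier_mad_mult: float = 5.0
    ortholog_coupling: float = 0.0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # optional external inputs; the simulate stage writes these paths
    counts_human: str | None = None
    counts_mouse: str | None = None
    metadata_human: str | None = None
    metadata_mouse: str | None = None
    orthologs: str | None = None

    def __post_init__(self):
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.lfc_threshold < 0 or self.pseudocount <= 0:
            raise ValueError("lfc_threshold must be >= 0 and pseudocount > 0")
        if self.min_abs_sum < 0 or self.min_abs_sum > 28:
            raise ValueError("min_abs_sum must lie in [0, 28]")
        self.simulation.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        """Hash of the scientific configuration (file locations excluded)."""
        d = self.to_dict()
        for k in ("outdir", "counts_human", "counts_mouse", "metadata_human",
                  "metadata_mouse", "orthologs"):
            d.pop(k, None)
        return config_hash(d)


def _default_paths(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    cfg.counts_human = cfg.counts_human or str(out / "counts_human.tsv")
    cfg.counts_mouse = cfg.counts_mouse or str(out / "counts_mouse.tsv")
    cfg.metadata_human = cfg.metadata_human or str(out / "metadata_human.tsv")
    cfg.metadata_mouse = cfg.metadata_mouse or str(out / "metadata_mouse.tsv")
    cfg.orthologs = cfg.orthologs or str(out / "orthologs.tsv")


def _load_inputs(cfg: PipelineConfig):
    counts, meta = {}, {}
    for sp in SPECIES:
        cpath = getattr(cfg, f"counts_{sp}")
        mpath = getattr(cfg, f"metadata_{sp}")
        for p in (cpath, mpath):
            if not Path(p).exists():
                raise MissingInputError(
                    f"required input {p} not found (run the simulate stage or "
                    f"point the config at existing files)"
                )
        counts[sp] = read_tsv(cpath, index_col="gene_id")
        meta[sp] = read_tsv(mpath, required_columns=METADATA_COLUMNS)
        included = set(meta[sp].loc[meta[sp]["status"] == "included", "sample_id"])
        absent = included - set(counts[sp].columns)
        if absent:
            raise SampleMismatchError(
                f"{sp}: metadata references sample(s) absent from counts: "
                f"{sorted(absent)[:5]}"
            )
    if not Path(cfg.orthologs).exists():
        raise MissingInputError(f"ortholog map {cfg.orthologs} not found")
    pairs = read_tsv(cfg.orthologs, required_columns=ORTHOLOG_COLUMNS)
    return counts, meta, resolve_orthologs(pairs)


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Run the requested stages in dependency order; return the manifest."""
    for s in stages:
        if s not in ALL_STAGES:
            raise ValueError(f"unknown stage {s!r}; valid: {ALL_STAGES}")
    stages = tuple(s for s in ALL_STAGES if s in stages)
    _default_paths(cfg)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed, h = cfg.seed, cfg.hash()
    outputs: list[Path] = []

    def emit(df: pd.DataFrame, name: str, index: bool = False) -> Path:
        p = write_tsv(df, out / name, seed=seed, cfg_hash=h, index=index)
        outputs.append(p)
        log.info("wrote %s", p)
        return p

    if "simulate" in stages:
        study = simulate_study(cfg.simulation)
        for sp in SPECIES:
            emit(study.counts[sp], f"counts_{sp}.tsv", index=True)
            emit(study.metadata[sp], f"metadata_{sp}.tsv")
        orth = simulate_ortholog_map(
            cfg.simulation.n_genes,
            seed=cfg.seed,
            truth=study.truth,
            coupling=cfg.ortholog_coupling,
        )
        emit(orth, "orthologs.tsv")
        truth = study.truth.genes.copy()
        truth["is_outlier_sample"] = ""
        emit(truth, "truth_genes.tsv")
        emit(
            pd.DataFrame(
                [
                    {"species": sp, "sample_id": sid}
                    for sp in SPECIES
                    for sid in study.truth.outliers.get(sp, [])
                ],
                columns=["species", "sample_id"],
            ),
            "truth_outlier_samples.tsv",
        )

    needs_data = {"qc", "de", "score", "xspecies"} & set(stages)
    if needs_data:
        counts, meta, pairs = _load_inputs(cfg)
        expr = {sp: log_cpm(counts[sp], cfg.pseudocount) for sp in SPECIES}

    if "qc" in stages:
        for sp in SPECIES:
            pca = run_pca(expr[sp], n_components=min(10, expr[sp].values.shape[1] - 1))
            scores = pca.scores.copy()
            scores.insert(0, "sample_id", scores.index)
            emit(scores.reset_index(drop=True), f"pca_scores_{sp}.tsv")
            emit(
                pd.DataFrame(
                    {
                        "component": [f"PC{i+1}" for i in range(pca.n_components)],
                        "variance_explained": pca.variance_explained,
                    }
                ),
                f"pca_variance_{sp}.tsv",
            )
            emit(flag_outliers(pca, cfg.outlier_n_pcs, cfg.outlier_mad_mult),
                 f"pca_outliers_{sp}.tsv")
            clus = hierarchical_cluster(expr[sp])
            (out / f"dendrogram_{sp}.nwk").write_text(clus.newick() + "\n")
            outputs.append(out / f"dendrogram_{sp}.nwk")
            emit(
                pd.DataFrame(clus.linkage, columns=["left", "right", "height", "size"]),
                f"linkage_{sp}.tsv",
            )
            cv = cv_by_condition(expr[sp].values, meta[sp])
            cv.insert(0, "gene_id", cv.index)
            emit(cv.reset_index(drop=True), f"cv_{sp}.tsv")

    results = {}
    if {"de", "score"} & set(stages):
        for sp in SPECIES:
            model = PairedContrastModel.from_counts(
                counts[sp], meta[sp], contrast_set(),
                pseudocount=cfg.pseudocount, count_filter=cfg.count_filter,
            )
            results[sp] = model.fit(alpha=cfg.alpha, lfc_threshold=cfg.lfc_threshold)
            if "de" in stages:
                emit(results[sp].table, f"de_{sp}.tsv")

    if "score" in stages:
        records = build_gene_scores(
            results["human"], results["mouse"], pairs,
            lfc_threshold=cfg.lfc_threshold, alpha=cfg.alpha,
        )
        emit(select_and_rank(records, cfg.min_abs_sum), "gene_scores.tsv")

    if "xspecies" in stages:
        centered = {sp: donor_center(expr[sp], meta[sp]) for sp in SPECIES}
        gm = {sp: group_medians(centered[sp], meta[sp]) for sp in SPECIES}
        pc = pair_correlations(gm["human"], gm["mouse"], pairs)
        emit(pc, "pair_correlations.tsv")
        emit(top_pairs(pc, k=15), "top_pairs.tsv")
        emit(
            condition_correlations(
                centered["human"], centered["mouse"],
                meta["human"], meta["mouse"], pairs,
            ),
            "condition_correlations.tsv",
        )
        tab, rho, p = correlation_vs_identity(pc)
        emit(tab, "correlation_vs_identity.tsv")
        (out / "correlation_vs_identity_test.json").write_text(
            json.dumps({"spearman_rho": rho, "p": p}, indent=1) + "\n"
        )
        outputs.append(out / "correlation_vs_identity_test.json")

    manifest = {
        "version_config": h,
        "seed": seed,
        "stages": list(stages),
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in outputs
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
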