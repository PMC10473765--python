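"""Config-driven orchestration of the cross-species analysis stages.

The pipeline mirrors the analysis order of the underlying study: per-species
standardized sex effects (with QC, optional batch harmonization, FDR and
variance tests), alignment of homologous regions and robust cross-species
correlation by compartment, anatomical similarity scores and quadrants, and
-- when expression inputs are available -- transcriptional similarity and
gene-subset permutation nulls. Every output table carries a header comment
with the config hash and seed; a ``summary.json`` collects the headline
numbers machine-readably.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._errors import ValidationError
from .congruence import (
    align_homologs,
    anatomical_similarity_scores,
    cross_species_effect_correlation,
    quadrant_classification,
)
from .expression import (
    GeneSubsetSpec,
    RegionGeneMatrix,
    gene_subset_null,
    similarity_vs_expression_correlation,
    transcriptional_similarity,
    zscore_genes_across_regions,
)
from .homology_atlas import (
    builtin_table1_fixture,
    default_region_map,
    load_homologous_regions,
    read_tsv,
    region_key,
)
from .volumetrics import (
    ModelSpec,
    apply_qc_exclusions,
    fit_sex_effects_table,
    harmonize_batches,
    levene_variance_test,
    residualize,
    subset_one_per_family,
)

logger = logging.getLogger(__name__)

COMPARTMENT_CHOICES = ("all", "cortical", "non_cortical")


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and constants for a pipeline run.

    Defaults carry the analysis constants: FDR level q = 0.05, human QC
    threshold -200, 10,000 gene-set resamples, bend constant 0.2.
    """

    human_subjects: str | None = None
    mouse_subjects: str | None = None
    human_expression: str | None = None
    mouse_expression: str | None = None
    homolog_map: str | None = None
    region_map: str | None = None
    gene_subsets: dict[str, str] = field(default_factory=dict)
    include_ttv: bool = True
    euler_threshold: int = -200
    q_level: float = 0.05
    bend_constant: float = 0.2
    n_resamples: int = 10_000
    seed: int = 0
    compartments: tuple[str, ...] = COMPARTMENT_CHOICES
    one_per_family: bool = False

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_KNOWN_KEYS = set(PipelineConfig.__dataclass_fields__)


def validate_config(raw: dict) -> tuple[PipelineConfig, list[str]]:
    """Check a raw mapping, fill defaults, return (config, warnings).

    Unknown keys warn; violated constraints are aggregated into a single
    :class:`ValidationError`.
    """
    warnings = [f"unknown config key {k!r} ignored" for k in raw if k not in _KNOWN_KEYS]
    known = {k: v for k, v in raw.items() if k in _KNOWN_KEYS}
    if "compartments" in known:
        known["compartments"] = tuple(known["compartments"])
    if "gene_subsets" in known:
        known["gene_subsets"] = dict(known["gene_subsets"])
    config = PipelineConfig(**known)

    errors = []
    if config.n_resamples < 1:
        errors.append(f"n_resamples must be >= 1, got {config.n_resamples}")
    if not 0 < config.q_level < 1:
        errors.append(f"q_level must be in (0, 1), got {config.q_level}")
    if not 0 < config.bend_constant <= 0.5:
        errors.append(f"bend_constant must be in (0, 0.5], got {config.bend_constant}")
    for comp in config.compartments:
        if comp not in COMPARTMENT_CHOICES:
            errors.append(f"unknown compartment {comp!r}")
    for label in ("human_subjects", "mouse_subjects", "human_expression",
                  "mouse_expression", "homolog_map", "region_map"):
        path = getattr(config, label)
        if path is not None and not Path(path).exists():
            errors.append(f"{label}: no such file {path!r}")
    for name, path in config.gene_subsets.items():
        if not Path(path).exists():
            errors.append(f"gene subset {name!r}: no such file {path!r}")
    if errors:
        raise ValidationError("; ".join(errors))
    return config, warnings


def _corr_record(res) -> dict:
    return {"r": res.r, "t": res.t, "p": res.p, "n": res.n, "method": res.method}


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# config={config.hash()} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def _region_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("vol_")]


def _species_effects(table: pd.DataFrame, config: PipelineConfig, species: str
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-region standardized sex effects + Levene variance tests."""
    if species == "human" and "euler" in table.columns:
        table = apply_qc_exclusions(table, euler_threshold=config.euler_threshold)
    if config.one_per_family and "family_id" in table.columns:
        table = subset_one_per_family(table, seed=config.seed)
    regions = _region_columns(table)
    if "batch" in table.columns and table["batch"].nunique() > 1:
        table = harmonize_batches(table, "batch", regions, preserve=("sex", "age"))
    qc_col = "euler" if "euler" in table.columns else (
        "strain" if "strain" in table.columns else None)
    spec = ModelSpec(response="", qc_col=qc_col,
                     qc_categorical=(qc_col == "strain"),
                     include_ttv=config.include_ttv)
    effects = fit_sex_effects_table(table, regions, spec, q_level=config.q_level)
    effects["region"] = [r.removeprefix("vol_") for r in effects["region"]]

    resid_covs = [c for c in ("ttv", "age", "euler") if c in table.columns]
    resid = residualize(table, resid_covs, regions)
    lev = [levene_variance_test(resid[r], table["sex"], region=r.removeprefix("vol_"))
           for r in regions]
    variance = pd.DataFrame({"region": [v.region for v in lev],
                             "F": [v.F for v in lev], "p": [v.p for v in lev]})
    return effects, variance


def _load_matrix(path: str, species: str) -> RegionGeneMatrix:
    df = read_tsv(path, index_col=0)
    return RegionGeneMatrix(species=species, data=df)


def _read_gene_list(path: str) -> tuple[str, ...]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return tuple(s.strip() for s in lines if s.strip() and not s.startswith("#"))


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 demo: bool = False) -> Path:
    """Execute every stage the config provides inputs for; return the outdir.

    With ``demo=True`` (or no subject tables) the anatomical stage runs on
    the bundled published effect-size table instead of refitting models.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "config_hash": config.hash(),
                     "version": __version__}
    region_map = (load_homologous_regions(config.region_map)
                  if config.region_map else default_region_map())

    # --- anatomical stage -------------------------------------------------
    if not demo and config.human_subjects and config.mouse_subjects:
        stage = "subject_tables"
        human = read_tsv(config.human_subjects)
        mouse = read_tsv(config.mouse_subjects)
        h_eff, h_var = _species_effects(human, config, "human")
        m_eff, m_var = _species_effects(mouse, config, "mouse")
        _write_tsv(h_eff, outdir / "human_effects.tsv", config)
        _write_tsv(m_eff, outdir / "mouse_effects.tsv", config)
        _write_tsv(h_var, outdir / "human_variance_tests.tsv", config)
        _write_tsv(m_var, outdir / "mouse_variance_tests.tsv", config)
        pairs = align_homologs(h_eff, m_eff, region_map)
    else:
        stage = "builtin_fixture"
        pairs = builtin_table1_fixture()
    summary["anatomical_source"] = stage
    _write_tsv(pairs, outdir / "pair_table.tsv", config)

    summary["congruence"] = {}
    for comp in config.compartments:
        res = cross_species_effect_correlation(pairs, comp,
                                               bend_constant=config.bend_constant)
        summary["congruence"][comp] = _corr_record(res)

    scores = anatomical_similarity_scores(pairs)
    quadrants = quadrant_classification(pairs)
    _write_tsv(scores, outdir / "similarity_scores.tsv", config)
    _write_tsv(quadrants, outdir / "quadrants.tsv", config)

    # --- expression stage -------------------------------------------------
    if config.human_expression and config.mouse_expression:
        human_z = zscore_genes_across_regions(
            _load_matrix(config.human_expression, "human"))
        mouse_z = zscore_genes_across_regions(
            _load_matrix(config.mouse_expression, "mouse"))
        avail = {r.key for r in region_map if r.expression_available}
        keys = scores.apply(
            lambda row: region_key(row["region"], row["hemisphere"]), axis=1)
        expr_scores = scores[keys.isin(avail)].copy()
        expr_keys = [region_key(r, h) for r, h in
                     zip(expr_scores["region"], expr_scores["hemisphere"])]
        present = [k for k in expr_keys if k in human_z.data.index]
        if len(present) < len(expr_keys):
            skipped = sorted(set(expr_keys) - set(present))
            logger.warning("expression stage: %d region(s) lack expression rows: %s",
                           len(skipped), ", ".join(skipped))
            keep = [k in present for k in expr_keys]
            expr_scores = expr_scores[keep]
            expr_keys = present
        human_z = replace(human_z, data=human_z.data.loc[expr_keys])
        mouse_z = replace(mouse_z, data=mouse_z.data.loc[
            [k for k in mouse_z.data.index if k in set(expr_keys)]])
        mouse_z = replace(mouse_z, data=mouse_z.data.loc[expr_keys])

        sim = transcriptional_similarity(human_z, mouse_z)
        expr_scores = expr_scores.assign(transcriptional=sim.to_numpy())
        _write_tsv(expr_scores, outdir / "transcriptional_similarity.tsv", config)

        summary["similarity_vs_expression"] = {}
        for comp in config.compartments:
            res = similarity_vs_expression_correlation(
                expr_scores, comp, bend_constant=config.bend_constant)
            summary["similarity_vs_expression"][comp] = _corr_record(res)

        summary["gene_subset_nulls"] = {}
        for name, path in config.gene_subsets.items():
            subset = GeneSubsetSpec(name=name, genes=_read_gene_list(path))
            null = gene_subset_null(
                human_z, mouse_z, expr_scores, subset_size=len(subset.genes),
                n_resamples=config.n_resamples, seed=config.seed,
                observed_genes=subset.genes, bend_constant=config.bend_constant)
            np.savetxt(outdir / f"null_{name}.tsv", null.values,
                       header=f"config={config.hash()} seed={config.seed}")
            summary["gene_subset_nulls"][name] = {
                "observed": null.observed, "p": null.p,
                "n_resamples": null.n_resamples, "size": len(subset.genes)}
    else:
        logger.info("expression stage skipped: no expression inputs configured")
        summary["expression_stage"] = "skipped"

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "run.log", "w", encoding="utf-8") as fh:
        fh.write(f"neurocongruence {__version__}\n"
                 f"seed={config.seed} config={config.hash()}\n"
                 f"numpy={np.__version__} pandas={pd.__version__}\n")
    return outdir
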