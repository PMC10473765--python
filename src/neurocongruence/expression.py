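"""Region-by-gene expression matrices and cross-species transcriptional similarity.

Starting from sample- (or voxel-) level expression, the module builds one
region x gene matrix per species (volume-weighted averaging for human
samples, plain averaging for mouse voxels), fills missing right-hemisphere
regions by reflecting the left hemisphere, restricts both matrices to a
shared set of one-to-one homologous genes, and z-scores every gene across
regions. Transcriptional similarity is then the per-region Pearson
correlation between the two species' z-scored expression profiles, computed
over the full homologous gene set or a biologically defined subset (X-linked,
hormone-signaling, ...). Subset-specific results are calibrated against a
null of randomly drawn gene sets of the same size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import MissingRegionsError, ValidationError
from .homology_atlas import filter_compartment
from .robust_stats import (
    CorrelationResult,
    NullDistribution,
    percentage_bend_correlation,
    permutation_p_value,
)

__all__ = [
    "RegionGeneMatrix",
    "GeneSubsetSpec",
    "NAMED_SUBSET_SIZES",
    "aggregate_expression_by_region",
    "reflect_hemisphere",
    "intersect_homologous_genes",
    "zscore_genes_across_regions",
    "transcriptional_similarity",
    "similarity_vs_expression_correlation",
    "gene_subset_null",
]

logger = logging.getLogger(__name__)

# expected sizes of the named homologous-gene subsets in the full-data analysis
NAMED_SUBSET_SIZES = {
    "all": 2835,
    "x_linked": 91,
    "hormone": 34,
    "androgen": 11,
    "estrogen_progesterone": 23,
}


@dataclass
class RegionGeneMatrix:
    """A region x gene expression matrix for one species.

    ``data`` has region keys as the index and gene symbols as columns.
    ``zscored`` records whether every gene has been standardized across
    regions.
    """

    species: str
    data: pd.DataFrame
    zscored: bool = False

    @property
    def regions(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    def __post_init__(self):
        if self.data.isna().any().any():
            raise ValidationError("expression matrix contains missing cells")


@dataclass(frozen=True)
class GeneSubsetSpec:
    """A named list of genes to restrict similarity computations to."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(self.genes) < 3:
            raise ValidationError(f"gene subset {self.name!r} has fewer than 3 genes")


def aggregate_expression_by_region(samples: pd.DataFrame, assignment: Mapping[str, str],
                                   weights: Mapping[str, float] | None = None,
                                   species: str = "human") -> RegionGeneMatrix:
    """Weighted per-region mean expression from sample-level data.

    ``samples`` is a sample x gene frame; ``assignment`` maps sample ids to
    region keys; ``weights`` gives non-negative per-sample weights (typically
    the volume of the structure a sample was drawn from), or None for uniform
    weights (the voxel-averaging path).
    """
    assignment = pd.Series({s: assignment[s] for s in samples.index if s in assignment})
    unassigned = set(samples.index) - set(assignment.index)
    if unassigned:
        samples = samples.loc[assignment.index]
    region_order = list(dict.fromkeys(assignment))
    rows = {}
    for region in region_order:
        ids = assignment.index[assignment == region]
        block = samples.loc[ids].to_numpy(dtype=float)
        if weights is None:
            w = np.ones(len(ids))
        else:
            w = np.array([weights[s] for s in ids], dtype=float)
            if np.any(w < 0):
                raise ValidationError(f"negative weight in region {region!r}")
        if w.sum() <= 0:
            raise MissingRegionsError([region], f"all-zero weights for region {region!r}")
        rows[region] = (w @ block) / w.sum()
    return RegionGeneMatrix(
        species=species,
        data=pd.DataFrame.from_dict(rows, orient="index", columns=samples.columns),
    )


def _side_key(key: str) -> tuple[str, str]:
    name, _, side = key.rpartition("/")
    return name, side


def reflect_hemisphere(matrix: RegionGeneMatrix, expected_regions: Sequence[str],
                       donor_side: str = "L") -> RegionGeneMatrix:
    """Fill missing right-hemisphere regions with the left counterpart's row."""
    data = matrix.data.copy()
    filled = []
    for key in expected_regions:
        if key in data.index:
            continue
        name, side = _side_key(key)
        donor = f"{name}/{donor_side}"
        if side == donor_side or donor not in data.index:
            raise MissingRegionsError([key], f"no {donor_side}-side donor for {key!r}")
        data.loc[key] = data.loc[donor]
        filled.append(key)
    if filled:
        logger.info("hemisphere reflection filled %d region(s): %s",
                    len(filled), ", ".join(filled))
    return replace(matrix, data=data.loc[list(expected_regions)])


def intersect_homologous_genes(human: RegionGeneMatrix, mouse: RegionGeneMatrix,
                               homolog_map: pd.DataFrame
                               ) -> tuple[RegionGeneMatrix, RegionGeneMatrix]:
    """Restrict both matrices to mapped one-to-one homolog pairs, same order.

    ``homolog_map`` needs columns ``human_gene`` and ``mouse_gene`` and must
    be one-to-one within itself.
    """
    for c in ("human_gene", "mouse_gene"):
        if c not in homolog_map.columns:
            raise ValidationError(f"homolog map missing column {c!r}")
    if homolog_map["human_gene"].duplicated().any() or homolog_map["mouse_gene"].duplicated().any():
        raise ValidationError("homolog map is not one-to-one")
    present = homolog_map[
        homolog_map["human_gene"].isin(human.data.columns)
        & homolog_map["mouse_gene"].isin(mouse.data.columns)
    ]
    if len(present) == 0:
        raise ValidationError("empty homologous-gene intersection")
    return (
        replace(human, data=human.data[list(present["human_gene"])]),
        replace(mouse, data=mouse.data[list(present["mouse_gene"])]),
    )


def zscore_genes_across_regions(matrix: RegionGeneMatrix) -> RegionGeneMatrix:
    """Standardize each gene across regions; constant genes are dropped."""
    if len(matrix.data) < 3:
        raise ValidationError("need at least 3 regions to z-score across regions")
    sd = matrix.data.std(ddof=1)
    constant = sd[sd == 0].index
    if len(constant) == len(matrix.data.columns):
        raise ValidationError("every gene is constant across regions")
    if len(constant):
        logger.info("dropping %d constant gene(s) before z-scoring", len(constant))
    kept = matrix.data.drop(columns=constant)
    z = (kept - kept.mean()) / kept.std(ddof=1)
    return replace(matrix, data=z, zscored=True)


def _check_aligned(human_z: RegionGeneMatrix, mouse_z: RegionGeneMatrix):
    if not (human_z.zscored and mouse_z.zscored):
        raise ValidationError("both matrices must be z-scored")
    if list(human_z.data.index) != list(mouse_z.data.index):
        raise ValidationError("matrices must share the same region set and order")
    if human_z.data.shape[1] != mouse_z.data.shape[1]:
        raise ValidationError("matrices must have the same number of aligned genes")


def _rowwise_pearson(H: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Pearson r between paired rows of two matrices."""
    Hc = H - H.mean(axis=1, keepdims=True)
    Mc = M - M.mean(axis=1, keepdims=True)
    num = np.sum(Hc * Mc, axis=1)
    den = np.sqrt(np.sum(Hc * Hc, axis=1) * np.sum(Mc * Mc, axis=1))
    return num / den


def _subset_positions(human_z: RegionGeneMatrix, subset) -> np.ndarray:
    if subset is None:
        return np.arange(human_z.data.shape[1])
    genes = subset.genes if isinstance(subset, GeneSubsetSpec) else tuple(subset)
    cols = human_z.data.columns
    missing = [g for g in genes if g not in cols]
    if missing:
        raise ValidationError(f"subset genes absent from matrix: {', '.join(missing[:5])}")
    idx = cols.get_indexer(list(genes))
    if len(idx) < 3:
        raise ValidationError("gene subset must contain at least 3 genes")
    return idx


def transcriptional_similarity(human_z: RegionGeneMatrix, mouse_z: RegionGeneMatrix,
                               subset: GeneSubsetSpec | Sequence[str] | None = None
                               ) -> pd.Series:
    """Per-region Pearson correlation of the species' expression profiles.

    Gene subsets are named by their human symbols; positions carry over to the
    mouse matrix through the shared homolog ordering.
    """
    _check_aligned(human_z, mouse_z)
    idx = _subset_positions(human_z, subset)
    r = _rowwise_pearson(human_z.data.to_numpy()[:, idx], mouse_z.data.to_numpy()[:, idx])
    return pd.Series(r, index=human_z.data.index, name="transcriptional")


def similarity_vs_expression_correlation(scores: pd.DataFrame, compartment: str = "all",
                                         bend_constant: float = 0.2) -> CorrelationResult:
    """Robust correlation of anatomical vs transcriptional similarity scores."""
    sub = filter_compartment(scores, compartment).dropna(
        subset=["anatomical", "transcriptional"]
    )
    if len(sub) < 4:
        raise ValidationError(
            f"compartment {compartment!r} leaves {len(sub)} scored regions; need >= 4"
        )
    return percentage_bend_correlation(sub["anatomical"], sub["transcriptional"],
                                       bend_constant=bend_constant)


def gene_subset_null(human_z: RegionGeneMatrix, mouse_z: RegionGeneMatrix,
                     scores: pd.DataFrame, subset_size: int, n_resamples: int,
                     seed: int, compartment: str = "all",
                     observed_genes: Sequence[str] | None = None,
                     bend_constant: float = 0.2,
                     direction: str = "two_sided") -> NullDistribution:
    """Null distribution of similarity-score correlations over random gene sets.

    Each resample draws ``subset_size`` genes uniformly without replacement,
    recomputes the per-region transcriptional similarity on that set, and
    correlates it (percentage-bend) with the anatomical scores. The observed
    statistic uses ``observed_genes`` when given, otherwise the full gene set.

    ``scores`` must carry ``region``/``hemisphere``/``compartment``/
    ``anatomical`` columns for the same regions (keys) as the matrices.
    """
    _check_aligned(human_z, mouse_z)
    G = human_z.data.shape[1]
    if not 3 <= subset_size <= G:
        raise ValidationError(f"subset_size must be in [3, {G}], got {subset_size}")
    if n_resamples < 1:
        raise ValidationError("n_resamples must be >= 1")

    sub_scores = filter_compartment(scores, compartment)
    keys = [f"{r}/{h[0].upper()}" for r, h in zip(sub_scores["region"], sub_scores["hemisphere"])]
    index = human_z.data.index
    missing = [k for k in keys if k not in index]
    if missing:
        raise MissingRegionsError(missing)
    rows = index.get_indexer(keys)
    H = human_z.data.to_numpy()[rows]
    M = mouse_z.data.to_numpy()[rows]
    anatomical = sub_scores["anatomical"].to_numpy(dtype=float)

    def stat(col_idx: np.ndarray) -> float:
        r_region = _rowwise_pearson(H[:, col_idx], M[:, col_idx])
        return percentage_bend_correlation(anatomical, r_region,
                                           bend_constant=bend_constant).r

    observed = stat(_subset_positions(human_z, observed_genes))
    rng = np.random.default_rng(seed)
    values = np.empty(n_resamples)
    for i in range(n_resamples):
        # sorted so a drawn set maps to one canonical summation order
        values[i] = stat(np.sort(rng.choice(G, size=subset_size, replace=False)))
    p = permutation_p_value(observed, values, direction=direction)
    return NullDistribution(values=values, observed=observed, p=p,
                            n_resamples=n_resamples, seed=seed)
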