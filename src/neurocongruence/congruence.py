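"""Cross-species comparison of regional sex effects.

Given per-species standardized sex effects for a set of homologous regions,
this module aligns them into a pair table, measures their overall agreement
with a robust (percentage-bend) correlation -- optionally stratified by
cortical vs non-cortical compartment -- and derives per-region summaries: the
anatomical sex-effect similarity score (the product of the two species'
betas, positive when the direction of sex bias is conserved) and a quadrant
label locating each region in the human-beta x mouse-beta plane.
"""

from __future__ import annotations

import pandas as pd

from ._errors import InsufficientDataError, MissingRegionsError
from .homology_atlas import HomologousRegionMap, filter_compartment
from .robust_stats import CorrelationResult, percentage_bend_correlation

__all__ = [
    "align_homologs",
    "cross_species_effect_correlation",
    "anatomical_similarity_scores",
    "quadrant_classification",
]


def align_homologs(human: pd.DataFrame, mouse: pd.DataFrame,
                   region_map: HomologousRegionMap) -> pd.DataFrame:
    """Join per-species effect-size results into a homologous pair table.

    ``human`` and ``mouse`` are effect-size tables with columns ``region``,
    ``beta_sex`` and ``significant``, keyed by the map's 'Name/H' region keys
    (constituent atlas labels are combined at the subject level before model
    fitting, so each homologous region resolves to exactly one result row).
    Regions missing from either species are reported together.
    """
    h = human.set_index("region")
    m = mouse.set_index("region")
    rows, missing = [], []
    for reg in region_map:
        key = reg.key
        if key not in h.index or key not in m.index:
            missing.append(key)
            continue
        rows.append(
            {
                "region": reg.name,
                "hemisphere": reg.hemisphere,
                "compartment": reg.compartment,
                "human_beta": float(h.loc[key, "beta_sex"]),
                "mouse_beta": float(m.loc[key, "beta_sex"]),
                "human_sig": bool(h.loc[key, "significant"]),
                "mouse_sig": bool(m.loc[key, "significant"]),
            }
        )
    if missing:
        raise MissingRegionsError(missing)
    return pd.DataFrame(rows)


def cross_species_effect_correlation(pairs: pd.DataFrame, compartment: str = "all",
                                     bend_constant: float = 0.2) -> CorrelationResult:
    """Percentage-bend correlation of human vs mouse betas over a compartment."""
    sub = filter_compartment(pairs, compartment)
    if len(sub) < 4:
        raise InsufficientDataError(
            f"compartment {compartment!r} has {len(sub)} rows; need at least 4"
        )
    return percentage_bend_correlation(sub["human_beta"], sub["mouse_beta"],
                                       bend_constant=bend_constant)


def anatomical_similarity_scores(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-region product of the two species' sex effects.

    The product is positive exactly when the two species agree on the
    direction of the sex difference, and its magnitude grows with the joint
    effect size, so it serves as a region-level congruence score.
    """
    out = pairs[["region", "hemisphere", "compartment"]].copy()
    out["anatomical"] = pairs["human_beta"] * pairs["mouse_beta"]
    return out


def _quadrant(hb: float, mb: float) -> str:
    if hb == 0 or mb == 0:
        return "indeterminate"
    if hb > 0 and mb > 0:
        return "both_male"
    if hb < 0 and mb < 0:
        return "both_female"
    if hb > 0:
        return "human_male_mouse_female"
    return "human_female_mouse_male"


def _significance(hs: bool, ms: bool) -> str:
    if hs and ms:
        return "both"
    if hs:
        return "human_only"
    if ms:
        return "mouse_only"
    return "neither"


def quadrant_classification(pairs: pd.DataFrame) -> pd.DataFrame:
    """Sign-pair quadrant and significance facet for every region."""
    out = pairs[["region", "hemisphere", "compartment"]].copy()
    out["quadrant"] = [
        _quadrant(hb, mb) for hb, mb in zip(pairs["human_beta"], pairs["mouse_beta"])
    ]
    out["significance"] = [
        _significance(hs, ms) for hs, ms in zip(pairs["human_sig"], pairs["mouse_sig"])
    ]
    return out
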