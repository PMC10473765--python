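"""Homologous-region map and the bundled cross-species effect-size table.

The package ships a nominal map of 60 human-mouse homologous brain regions
(28 bilateral pairs plus 4 midline structures) together with the published
standardized sex-effect sizes for each region in each species. Regions are
keyed by (name, hemisphere); a region's ``compartment`` classifies it as
cortical or non-cortical for stratified analyses. The cortical set comprises
13 bilateral neocortical/allocortical areas (insula, cingulate, entorhinal,
perirhinal, piriform, posterior parietal, auditory, motor, somatosensory,
visual, retrosplenial, temporal association, ventral orbital); hippocampal
subfields, cerebellar cortex and subcortical/midline structures are counted
as non-cortical. The assignment is configurable through the map file.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from ._errors import FormatError, ValidationError

__all__ = [
    "HomologousRegion",
    "HomologousRegionMap",
    "COMPARTMENTS",
    "HEMISPHERES",
    "load_homologous_regions",
    "default_region_map",
    "builtin_table1_fixture",
    "filter_compartment",
    "write_pair_table",
    "read_pair_table",
    "read_tsv",
]

HEMISPHERES = ("left", "right", "midline")
COMPARTMENTS = ("cortical", "non_cortical")

_MAP_COLUMNS = ["region", "hemisphere", "compartment", "human_labels", "mouse_labels"]
_FIXTURE_COLUMNS = _MAP_COLUMNS + ["human_beta", "mouse_beta", "human_sig", "mouse_sig"]
_PAIR_COLUMNS = ["region", "hemisphere", "compartment",
                 "human_beta", "mouse_beta", "human_sig", "mouse_sig"]


@dataclass(frozen=True)
class HomologousRegion:
    """One homologous region with its species-specific atlas labels."""

    name: str
    hemisphere: str
    compartment: str
    human_labels: tuple[str, ...]
    mouse_labels: tuple[str, ...]
    expression_available: bool = True

    def __post_init__(self):
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(
                f"{self.name}: hemisphere must be one of {HEMISPHERES}, got {self.hemisphere!r}"
            )
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"{self.name}: compartment must be one of {COMPARTMENTS}, got {self.compartment!r}"
            )

    @property
    def key(self) -> str:
        return region_key(self.name, self.hemisphere)


def region_key(name: str, hemisphere: str) -> str:
    """Stable string key 'Name/H' with H in {L, R, M}."""
    return f"{name}/{hemisphere[0].upper()}"


@dataclass(frozen=True)
class HomologousRegionMap:
    """A validated collection of homologous regions."""

    regions: tuple[HomologousRegion, ...] = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "regions", tuple(self.regions))
        keys = [r.key for r in self.regions]
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        if dupes:
            raise ValidationError(f"duplicate (region, hemisphere) keys: {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": [r.name for r in self.regions],
                "hemisphere": [r.hemisphere for r in self.regions],
                "compartment": [r.compartment for r in self.regions],
                "human_labels": [";".join(r.human_labels) for r in self.regions],
                "mouse_labels": [";".join(r.mouse_labels) for r in self.regions],
                "expression_available": [r.expression_available for r in self.regions],
            }
        )


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV, skipping leading '#' comment lines.

    Unlike pandas' ``comment=`` option this leaves '#' characters inside data
    cells (several atlas label names contain one) untouched.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines(keepends=True)
    start = 0
    while start < len(lines) and lines[start].startswith("#"):
        start += 1
    return pd.read_csv(io.StringIO("".join(lines[start:])), sep="\t", **kwargs)


def _split_labels(cell) -> tuple[str, ...]:
    if pd.isna(cell):
        return ()
    return tuple(s.strip() for s in str(cell).split(";") if s.strip())


def _read_map_frame(path) -> pd.DataFrame:
    df = read_tsv(path, dtype=str)
    missing = [c for c in _MAP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns: {', '.join(missing)}")
    return df


def load_homologous_regions(path: str | Path) -> HomologousRegionMap:
    """Read a region-map TSV and return a validated map.

    Required columns: region, hemisphere, compartment, human_labels,
    mouse_labels; label lists within a cell are ';'-joined. An optional
    ``expression_available`` column (0/1) marks regions lacking expression
    data. Duplicate (region, hemisphere) pairs are rejected.
    """
    df = _read_map_frame(path)
    regions = []
    for _, row in df.iterrows():
        avail = True
        if "expression_available" in df.columns and not pd.isna(row["expression_available"]):
            avail = bool(int(row["expression_available"]))
        regions.append(
            HomologousRegion(
                name=row["region"],
                hemisphere=row["hemisphere"],
                compartment=row["compartment"],
                human_labels=_split_labels(row["human_labels"]),
                mouse_labels=_split_labels(row["mouse_labels"]),
                expression_available=avail,
            )
        )
    return HomologousRegionMap(regions=tuple(regions))


def _bundled_path():
    return resources.files("neurocongruence").joinpath("data/homologous_regions.tsv")


def default_region_map() -> HomologousRegionMap:
    """The bundled 60-region human-mouse map (28 bilateral + 4 midline)."""
    with resources.as_file(_bundled_path()) as p:
        return load_homologous_regions(p)


def builtin_table1_fixture() -> pd.DataFrame:
    """The published 60-region effect-size pair table.

    Returns a DataFrame with one row per (region, hemisphere): the
    standardized sex-effect size in each species (exactly as printed, three
    decimals) and per-species FDR significance flags.
    """
    with resources.as_file(_bundled_path()) as p:
        df = read_tsv(p, dtype=str)
    missing = [c for c in _FIXTURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"bundled fixture missing columns: {', '.join(missing)}")
    out = df[_PAIR_COLUMNS].copy()
    out["human_beta"] = out["human_beta"].astype(float)
    out["mouse_beta"] = out["mouse_beta"].astype(float)
    out["human_sig"] = out["human_sig"].astype(int).astype(bool)
    out["mouse_sig"] = out["mouse_sig"].astype(int).astype(bool)
    return out


def filter_compartment(table: pd.DataFrame, compartment: str = "all") -> pd.DataFrame:
    """Rows of a pair table whose compartment matches; 'all' is the identity."""
    if compartment == "all":
        return table
    if compartment not in COMPARTMENTS:
        raise ValidationError(
            f"compartment must be one of {COMPARTMENTS + ('all',)}, got {compartment!r}"
        )
    return table[table["compartment"] == compartment]


def write_pair_table(table: pd.DataFrame, path: str | Path, header_comment: str | None = None):
    """Write an effect-size pair table as TSV, betas at three decimals."""
    out = table.copy()
    for col in ("human_beta", "mouse_beta"):
        out[col] = out[col].map(lambda v: f"{v:.3f}")
    for col in ("human_sig", "mouse_sig"):
        out[col] = out[col].astype(int)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_pair_table(path: str | Path) -> pd.DataFrame:
    """Inverse of :func:`write_pair_table`."""
    df = read_tsv(path, dtype=str)
    missing = [c for c in _PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns: {', '.join(missing)}")
    df["human_beta"] = df["human_beta"].astype(float)
    df["mouse_beta"] = df["mouse_beta"].astype(float)
    df["human_sig"] = df["human_sig"].astype(int).astype(bool)
    df["mouse_sig"] = df["mouse_sig"].astype(int).astype(bool)
    return df
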