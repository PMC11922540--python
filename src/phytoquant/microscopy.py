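"""Microscopy-side tables: species abundance/biomass, biovolume, anchor totals.

The microscopy table is the quantitative anchor of the whole analysis: per
sample it records each phytoplankton species with its absolute abundance
(cells L^-1) and biomass (mg L^-1).  Biomass is derived from cell biovolume
(computed from an assigned geometric shape) at a cell density of 1 g cm^-3.
Per-sample totals A_j / M_j and per-sample-per-class totals A_jc / M_jc are
the anchors by which ASV relative abundances are converted to absolute
values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SPECIES_COLUMNS",
    "CellGeometry",
    "AnchorTotals",
    "cell_biovolume",
    "species_biomass",
    "sem_split_pair",
    "validate_species_table",
    "drop_cyanobacteria",
    "anchor_totals",
    "read_species_table",
    "write_species_table",
]

#: required columns of a long-format species table
SPECIES_COLUMNS = ["sample_id", "species", "class_name", "abundance", "biomass"]


# ---------------------------------------------------------------------------
# cell geometry -> biovolume

def _vol_sphere(d: float) -> float:
    return math.pi * d**3 / 6.0


def _vol_cylinder(d: float, length: float) -> float:
    return math.pi * (d / 2.0) ** 2 * length


def _vol_prolate_spheroid(d: float, length: float) -> float:
    return math.pi / 6.0 * d**2 * length


def _vol_box(length: float, width: float, height: float) -> float:
    return length * width * height


def _vol_cone(d: float, height: float) -> float:
    return math.pi / 12.0 * d**2 * height


def _vol_double_cone(d: float, height: float) -> float:
    # two cones base to base; `height` is the total length of the cell
    return math.pi / 6.0 * d**2 * (height / 2.0)


def _vol_ellipsoid(length: float, width: float, height: float) -> float:
    return math.pi / 6.0 * length * width * height


#: shape registry: name -> (function, required dimension names).  Extensible:
#: ``SHAPE_REGISTRY["my_shape"] = (fn, ("d", "length"))``.
SHAPE_REGISTRY: dict[str, tuple] = {
    "sphere": (_vol_sphere, ("d",)),
    "cylinder": (_vol_cylinder, ("d", "length")),
    "prolate_spheroid": (_vol_prolate_spheroid, ("d", "length")),
    "box": (_vol_box, ("length", "width", "height")),
    "cone": (_vol_cone, ("d", "height")),
    "double_cone": (_vol_double_cone, ("d", "height")),
    "ellipsoid": (_vol_ellipsoid, ("length", "width", "height")),
}


@dataclass(frozen=True)
class CellGeometry:
    """A cell shape plus its linear dimensions in micrometres."""

    shape: str
    dimensions: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.shape not in SHAPE_REGISTRY:
            raise ValueError(
                f"unknown shape {self.shape!r}; known: {sorted(SHAPE_REGISTRY)}"
            )
        _, required = SHAPE_REGISTRY[self.shape]
        for name in required:
            if name not in self.dimensions:
                raise ValueError(f"shape {self.shape!r} requires dimension {name!r}")
            if not self.dimensions[name] > 0:
                raise ValueError(
                    f"dimension {name!r} must be positive, got {self.dimensions[name]}"
                )


def cell_biovolume(geometry: CellGeometry) -> float:
    """Cell volume in µm³ from a geometric shape assignment.

    Standard hydrobiological shape formulas: sphere πd³/6, cylinder π(d/2)²L,
    prolate spheroid (π/6)d²L, box LWH, cone (π/12)d²h, double cone
    (π/6)d²(h/2)·2 with h the total cell length, ellipsoid (π/6)LWH.
    """
    fn, required = SHAPE_REGISTRY[geometry.shape]
    return float(fn(*(geometry.dimensions[name] for name in required)))


def species_biomass(
    abundance: float,
    volume: float,
    density: float = 1.0,
    unit_scale: float = 1e-9,
) -> float:
    """Biomass from abundance (cells L^-1) and mean cell volume (µm³).

    biomass = abundance × volume × density × unit_scale.  At density
    1 g cm^-3 one µm³ weighs 1e-9 mg, so the default ``unit_scale`` of 1e-9
    converts µm³ · cells L^-1 to mg L^-1.  The scale is configurable because
    source datasets differ in whether biomass is reported per litre or per
    cubic metre.
    """
    for name, value in (("abundance", abundance), ("volume", volume),
                        ("density", density), ("unit_scale", unit_scale)):
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")
    return abundance * volume * density * unit_scale


def sem_split_pair(
    pair_counts: tuple[int, int],
    pair_total_abundance: float,
    pair_total_biomass: float,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Split a light-microscopy total between two cryptic species.

    Morphologically similar species pairs (e.g. araphid diatoms that light
    microscopy cannot separate) are resolved by counting cells under SEM;
    each species receives the pair total times its SEM relative count.
    Returns ``((abundance_1, biomass_1), (abundance_2, biomass_2))``; the
    two abundances sum exactly to ``pair_total_abundance``.

    A warning is emitted when fewer than 100 cells were counted, the
    customary minimum for a stable relative count.
    """
    c1, c2 = pair_counts
    if c1 < 0 or c2 < 0:
        raise ValueError("pair counts must be non-negative")
    total = c1 + c2
    if total == 0:
        raise ValueError("pair counts sum to zero; relative split undefined")
    if pair_total_abundance < 0 or pair_total_biomass < 0:
        raise ValueError("pair totals must be non-negative")
    if total < 100:
        warnings.warn(
            f"only {total} cells counted for SEM split; fewer than the "
            "customary minimum of 100",
            stacklevel=2,
        )
    f1 = c1 / total
    a1 = pair_total_abundance * f1
    m1 = pair_total_biomass * f1
    return (a1, m1), (pair_total_abundance - a1, pair_total_biomass - m1)


# ---------------------------------------------------------------------------
# species table validation and anchor totals

def validate_species_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format species table and return it.

    Checks: required columns present; abundance/biomass non-negative and
    finite; class names non-empty; no duplicate (sample, species) rows.
    """
    missing = [c for c in SPECIES_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"species table missing columns: {missing}")
    for col in ("abundance", "biomass"):
        vals = pd.to_numeric(table[col], errors="coerce")
        if vals.isna().any():
            bad = table.loc[vals.isna(), "species"].tolist()[:5]
            raise ValueError(f"non-numeric {col} for species {bad}")
        if (vals < 0).any():
            bad = table.loc[vals < 0, "species"].tolist()[:5]
            raise ValueError(f"negative {col} for species {bad}")
    if (table["class_name"].astype(str).str.len() == 0).any():
        raise ValueError("empty class_name entries in species table")
    dup = table.duplicated(subset=["sample_id", "species"])
    if dup.any():
        pairs = table.loc[dup, ["sample_id", "species"]].values.tolist()[:5]
        raise ValueError(f"duplicate (sample, species) rows: {pairs}")
    return table


def drop_cyanobacteria(
    table: pd.DataFrame, cyano_classes: tuple[str, ...] = ("Cyanophyceae", "Cyanobacteria")
) -> pd.DataFrame:
    """Remove cyanobacteria before any totals.

    Cyanobacteria are counted by light microscopy but carry no 18S rRNA gene,
    so they cannot appear in the metabarcoding table and must not contribute
    to the anchors.
    """
    mask = table["class_name"].isin(cyano_classes)
    return table.loc[~mask].reset_index(drop=True)


@dataclass
class AnchorTotals:
    """Per-sample and per-sample-per-class microscopy totals.

    ``total``: DataFrame indexed by sample_id with columns ``abundance``
    (A_j, cells L^-1) and ``biomass`` (M_j, mg L^-1).
    ``class_abundance`` / ``class_biomass``: sample × class DataFrames
    (A_jc, M_jc); a class absent from a sample holds 0.
    """

    total: pd.DataFrame
    class_abundance: pd.DataFrame
    class_biomass: pd.DataFrame

    @property
    def samples(self) -> pd.Index:
        return self.total.index

    @property
    def classes(self) -> pd.Index:
        return self.class_abundance.columns

    def validate(self) -> "AnchorTotals":
        if (self.total.values < 0).any():
            raise ValueError("negative anchor totals")
        if not np.allclose(
            self.class_abundance.sum(axis=1), self.total["abundance"], rtol=1e-9
        ):
            raise ValueError("class abundances do not sum to sample totals")
        if not np.allclose(
            self.class_biomass.sum(axis=1), self.total["biomass"], rtol=1e-9
        ):
            raise ValueError("class biomasses do not sum to sample totals")
        return self


def anchor_totals(table: pd.DataFrame, samples=None) -> AnchorTotals:
    """Compute A_j, M_j and A_jc, M_jc from a validated species table.

    A_j is the total phytoplankton abundance of sample j (the sum of every
    species' absolute abundance present in the sample); M_j the total
    biomass; A_jc / M_jc the same restricted to class c.  ``samples``
    optionally fixes the sample set (samples with no species get zero
    totals).
    """
    validate_species_table(table)
    if samples is None:
        samples = pd.Index(pd.unique(table["sample_id"]), name="sample_id")
    else:
        samples = pd.Index(samples, name="sample_id")

    by_class_a = (
        table.pivot_table(
            index="sample_id", columns="class_name", values="abundance",
            aggfunc="sum", fill_value=0.0,
        )
        .reindex(samples, fill_value=0.0)
    )
    by_class_m = (
        table.pivot_table(
            index="sample_id", columns="class_name", values="biomass",
            aggfunc="sum", fill_value=0.0,
        )
        .reindex(samples, fill_value=0.0)
    )
    total = pd.DataFrame(
        {"abundance": by_class_a.sum(axis=1), "biomass": by_class_m.sum(axis=1)},
        index=samples,
    )
    return AnchorTotals(total, by_class_a, by_class_m).validate()


def read_species_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_species_table(table)


def write_species_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
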