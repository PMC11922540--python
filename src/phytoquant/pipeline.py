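"""End-to-end orchestration: from paired tables to comparison report bundle.

One call runs the full consistency assessment between a microscopy species
table and an ASV table over the same samples: filtering, anchoring, the
class-level and species × ASV correlation grids under each quantitative
treatment (relative, rank-scaled, clr, absolute by total or class anchor),
the correlation-count summary, the RV/co-inertia table across treatments,
and per-sample diversity — all written as TSV/JSON with a provenance
record sufficient to reconstruct the run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .asv import (
    AsvTable,
    class_relative_abundance,
    filter_asvs,
    prevalence_filter,
    read_asv_table,
    relative_abundance,
    select_phytoplankton,
    top_n,
)
from .composition import clr_transform, diversity_table, rank01_transform
from .consistency import count_correlations, rv_coefficient, spearman_grid
from .microscopy import (
    anchor_totals,
    drop_cyanobacteria,
    read_species_table,
    validate_species_table,
)
from .quantify import absolute_by_class, absolute_by_total
from .synthetic import GeneratorConfig, generate_dataset

__all__ = ["RunConfig", "run_comparison", "validate_inputs"]

ALL_TRANSFORMS = ("relative", "rank01", "clr", "absolute_total", "absolute_class")


@dataclass
class RunConfig:
    """What to run and on what.

    Either ``generator`` (a synthetic-community config) or the three input
    paths must be set.  ``transforms`` selects which quantitative
    treatments are compared; ``min_prevalence`` is the minimum number of
    samples a feature must occupy to enter a correlation grid; ``top_n``
    optionally restricts the ASV side of the species-level grids to the n
    highest-read ASVs.
    """

    generator: GeneratorConfig | None = None
    species_path: str | None = None
    asv_counts_path: str | None = None
    taxonomy_path: str | None = None
    transforms: tuple = ALL_TRANSFORMS
    alpha: float = 0.05
    min_prevalence: int = 8
    top_n: int | None = None
    proxy_map: dict = field(default_factory=dict)
    outdir: str = "phytoquant_run"

    def __post_init__(self):
        if not self.transforms:
            raise ValueError("at least one transform must be selected")
        unknown = set(self.transforms) - set(ALL_TRANSFORMS)
        if unknown:
            raise ValueError(f"unknown transforms: {sorted(unknown)}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.generator is None and not (
            self.species_path and self.asv_counts_path and self.taxonomy_path
        ):
            raise ValueError(
                "either a generator config or all three input paths required"
            )


def _load_tables(config: RunConfig):
    if config.generator is not None:
        species, asv, _truth = generate_dataset(config.generator)
        return validate_species_table(species), asv
    species = read_species_table(config.species_path)
    asv = read_asv_table(config.asv_counts_path, config.taxonomy_path)
    return species, asv


def _species_matrices(species: pd.DataFrame, samples) -> dict[str, pd.DataFrame]:
    """Absolute and relative sample × species matrices for both quantities."""
    out = {}
    for quantity in ("abundance", "biomass"):
        absolute = (
            species.pivot_table(
                index="sample_id", columns="species", values=quantity,
                aggfunc="sum", fill_value=0.0,
            )
            .reindex(samples, fill_value=0.0)
        )
        out[f"absolute_{quantity}"] = absolute
        totals = absolute.sum(axis=1).replace(0, np.nan)
        out[f"relative_{quantity}"] = absolute.div(totals, axis=0)
    return out


def _to_class_matrix(matrix: pd.DataFrame, class_of: pd.Series) -> pd.DataFrame:
    """Aggregate feature columns to class columns by summation."""
    groups = matrix.T.groupby(class_of.reindex(matrix.columns)).sum(min_count=1).T
    return groups


def _clr_or_nan(matrix: pd.DataFrame) -> pd.DataFrame:
    """clr on the non-empty rows; all-zero rows stay NaN."""
    filled = matrix.fillna(0.0)
    nonzero = filled.sum(axis=1) > 0
    out = pd.DataFrame(np.nan, index=matrix.index, columns=matrix.columns)
    if nonzero.any():
        out.loc[nonzero] = clr_transform(filled.loc[nonzero]).values
    return out


def run_comparison(config: RunConfig) -> dict:
    """Run the full comparison; returns the report bundle as a dict.

    Writes, under ``config.outdir``: class-level grids (six pairings),
    species × ASV grids per selected transform, a correlation-count
    summary, an RV table across quantitative treatments, per-sample
    diversity and a provenance JSON.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    species, asv_raw = _load_tables(config)
    species = drop_cyanobacteria(species)

    mismatch = set(species["sample_id"]).symmetric_difference(asv_raw.samples)
    if mismatch:
        raise ValueError(
            f"sample IDs do not match between tables: {sorted(mismatch)}"
        )
    samples = asv_raw.samples

    asv_filtered = filter_asvs(asv_raw)
    phyto = select_phytoplankton(asv_filtered)
    anchors = anchor_totals(species, samples=samples)

    R = relative_abundance(phyto)
    Rc = class_relative_abundance(phyto)
    quantified = {
        ("total", q): absolute_by_total(R, anchors, quantity=q)
        for q in ("abundance", "biomass")
    }
    quantified.update({
        ("class", q): absolute_by_class(
            Rc, anchors, quantity=q, proxy_map=config.proxy_map or None
        )
        for q in ("abundance", "biomass")
    })

    mic = _species_matrices(species, samples)
    class_of = species.drop_duplicates("species").set_index("species")["class_name"]

    # --- class-level grids (six pairings) -------------------------------
    meta_class_rel = _to_class_matrix(R.values, phyto.taxonomy["class_name"])
    mic_class = {
        q: _to_class_matrix(mic[f"relative_{q}"], class_of)
        for q in ("abundance", "biomass")
    }
    class_grids = {
        "class_rel_abundance_x_rel_reads": (mic_class["abundance"], meta_class_rel),
        "class_rel_biomass_x_rel_reads": (mic_class["biomass"], meta_class_rel),
        "class_clr_abundance_x_clr_reads": (
            _clr_or_nan(mic_class["abundance"]), _clr_or_nan(meta_class_rel)),
        "class_clr_biomass_x_clr_reads": (
            _clr_or_nan(mic_class["biomass"]), _clr_or_nan(meta_class_rel)),
        "class_abs_abundance_x_abs_abundance": (
            anchors.class_abundance,
            _to_class_matrix(quantified[("total", "abundance")].values,
                             phyto.taxonomy["class_name"])),
        "class_abs_biomass_x_abs_biomass": (
            anchors.class_biomass,
            _to_class_matrix(quantified[("total", "biomass")].values,
                             phyto.taxonomy["class_name"])),
    }

    # --- species × ASV grids per transform ------------------------------
    # prevalence selection happens on presence (reads / cells observed),
    # before any transform, so every treatment sees the same feature set
    asv_for_grid = top_n(phyto, config.top_n) if config.top_n else phyto
    grid_cols = list(
        prevalence_filter(
            R.values[list(asv_for_grid.asv_ids)].fillna(0.0),
            config.min_prevalence,
        ).columns
    )
    R_grid = R.values[grid_cols]
    mic_cols = {
        q: list(
            prevalence_filter(mic[f"relative_{q}"].fillna(0.0),
                              config.min_prevalence).columns
        )
        for q in ("abundance", "biomass")
    }
    species_asv_grids = {}
    for quantity in ("abundance", "biomass"):
        mic_rel = mic[f"relative_{quantity}"][mic_cols[quantity]]
        mic_abs = mic[f"absolute_{quantity}"][mic_cols[quantity]]
        if "relative" in config.transforms:
            species_asv_grids[f"rel_{quantity}_x_rel_reads"] = (mic_rel, R_grid)
        if "rank01" in config.transforms:
            species_asv_grids[f"rank01_{quantity}_x_rank01_reads"] = (
                rank01_transform(mic_rel.fillna(0.0)).values,
                rank01_transform(R_grid.fillna(0.0)).values,
            )
        if "clr" in config.transforms:
            species_asv_grids[f"clr_{quantity}_x_clr_reads"] = (
                _clr_or_nan(mic_rel), _clr_or_nan(R_grid))
        if "absolute_total" in config.transforms:
            species_asv_grids[f"abs_{quantity}_x_total_anchored"] = (
                mic_abs, quantified[("total", quantity)].values[grid_cols])
        if "absolute_class" in config.transforms:
            qc = quantified[("class", quantity)].values
            cols = [c for c in grid_cols if c in qc.columns]
            species_asv_grids[f"abs_{quantity}_x_class_anchored"] = (
                mic_abs, qc[cols])

    # --- compute and write ----------------------------------------------
    counts_summary = {}
    grids = {}
    for name, (X, Y) in {**class_grids, **species_asv_grids}.items():
        Xf = prevalence_filter(X, config.min_prevalence) if name in class_grids else X
        Yf = prevalence_filter(Y, config.min_prevalence) if name in class_grids else Y
        if Xf.shape[1] == 0 or Yf.shape[1] == 0:
            continue
        grid = spearman_grid(Xf, Yf, alpha=config.alpha)
        grid.write(outdir / name)
        neg, pos = count_correlations(grid)
        counts_summary[name] = {"negative": neg, "positive": pos}
        grids[name] = grid
    with open(outdir / "correlation_counts.json", "w") as fh:
        json.dump(counts_summary, fh, indent=2)

    # --- RV table across quantitative treatments ------------------------
    rv_rows = {}
    for treatment in ("relative", "rank01", "clr", "absolute_total",
                      "absolute_class"):
        if treatment not in config.transforms:
            continue
        row = {}
        for quantity in ("abundance", "biomass"):
            Xm = mic[f"relative_{quantity}"].fillna(0.0)
            Ym = R_grid.fillna(0.0)
            if treatment == "rank01":
                Xm = rank01_transform(Xm).values
                Ym = rank01_transform(Ym).values
            elif treatment == "clr":
                Xm = _clr_or_nan(mic[f"relative_{quantity}"]).fillna(0.0)
                Ym = _clr_or_nan(R_grid).fillna(0.0)
            elif treatment == "absolute_total":
                Xm = mic[f"absolute_{quantity}"]
                Ym = quantified[("total", quantity)].values[grid_cols].fillna(0.0)
            elif treatment == "absolute_class":
                Xm = mic[f"absolute_{quantity}"]
                Ym = quantified[("class", quantity)].values.fillna(0.0)
            Xp = prevalence_filter(Xm, config.min_prevalence)
            Yp = prevalence_filter(Ym, config.min_prevalence)
            row[quantity] = rv_coefficient(Xp, Yp)
        rv_rows[treatment] = row
    rv_table = pd.DataFrame(rv_rows).T
    rv_table.to_csv(outdir / "rv_table.tsv", sep="\t")

    # --- diversity -------------------------------------------------------
    div_mic = diversity_table(
        mic["absolute_abundance"], chao1=False
    ).add_prefix("mic_")
    div_meta = diversity_table(phyto.counts, chao1=True).add_prefix("asv_")
    diversity = div_mic.join(div_meta)
    diversity.to_csv(outdir / "diversity.tsv", sep="\t")

    provenance = {
        "phytoquant_version": __version__,
        "config": {
            "transforms": list(config.transforms),
            "alpha": config.alpha,
            "min_prevalence": config.min_prevalence,
            "top_n": config.top_n,
            "proxy_map": dict(config.proxy_map),
            "generator": (
                config.generator.to_dict() if config.generator else None
            ),
            "inputs": {
                "species": config.species_path,
                "asv_counts": config.asv_counts_path,
                "taxonomy": config.taxonomy_path,
            },
        },
        "filter_trail": phyto.provenance,
        "n_samples": int(len(samples)),
        "mask_counts": {
            f"{scheme}_{q}": int(qt.mask_count)
            for (scheme, q), qt in quantified.items()
        },
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)

    return {
        "grids": grids,
        "counts": counts_summary,
        "rv_table": rv_table,
        "diversity": diversity,
        "quantified": quantified,
        "anchors": anchors,
        "provenance": provenance,
    }


def validate_inputs(species_path, asv_counts_path, taxonomy_path) -> dict:
    """Schema and cross-reference checks on the three input files.

    Returns ``{"errors": [...], "warnings": [...]}``; an empty error list
    means the files are usable.  Fatal structural problems (unreadable
    file, duplicate rows, counts/taxonomy mismatch) are errors; oddities
    that the pipeline tolerates are warnings.
    """
    errors: list[str] = []
    warnings_: list[str] = []
    species = asv = None
    try:
        species = read_species_table(species_path)
    except Exception as exc:  # surface the parse/validation failure verbatim
        errors.append(f"species table: {exc}")
    try:
        asv = read_asv_table(asv_counts_path, taxonomy_path)
    except Exception as exc:
        errors.append(f"asv table: {exc}")

    if species is not None and asv is not None:
        s1 = set(species["sample_id"])
        s2 = set(asv.samples)
        only_mic = sorted(s1 - s2)
        only_meta = sorted(s2 - s1)
        if only_mic:
            errors.append(f"samples only in species table: {only_mic}")
        if only_meta:
            errors.append(f"samples only in ASV table: {only_meta}")
    if asv is not None:
        if not np.allclose(asv.counts.values, np.round(asv.counts.values)):
            errors.append("non-integer read counts in ASV table")
        if asv.taxonomy["trophic"].isna().any():
            missing = list(
                asv.taxonomy.index[asv.taxonomy["trophic"].isna()])[:10]
            warnings_.append(
                f"ASVs with unresolved trophic mode (will need a lookup "
                f"entry): {missing}"
            )
    if species is not None and (species["abundance"] == 0).all():
        warnings_.append("species table has all-zero abundances")
    return {"errors": errors, "warnings": warnings_}
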