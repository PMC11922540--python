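"""ASV table handling: taxonomic filtering and relative-abundance matrices.

An ASV (amplicon sequence variant) table holds integer read counts per
sample with a ranked lineage per ASV (PR2-style, semicolon-delimited).
Filtering removes low-count ASVs and non-target lineages (metazoans, land
plants, nucleomorphs, prokaryotes, domain-unclassified reads); trophic
flagging then separates phytoplankton (autotrophs and mixotrophs) from
heterotrophic microeukaryotes.  Relative abundances are computed over the
phytoplankton scope — either all phytoplankton reads of a sample (R_ij) or
the reads of one class (R_ijc).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AsvTable",
    "RelAbundanceMatrix",
    "DEFAULT_TROPHIC_BY_CLASS",
    "EXCLUDED_LINEAGE_TOKENS",
    "filter_asvs",
    "select_phytoplankton",
    "top_n",
    "prevalence_filter",
    "relative_abundance",
    "class_relative_abundance",
    "read_asv_table",
    "write_asv_table",
]

#: lineage substrings whose presence disqualifies an ASV (non-phytoplankton
#: targets and nucleomorph sequences, flagged ":nucl" in PR2)
EXCLUDED_LINEAGE_TOKENS = ("Metazoa", "Streptophyta", ":nucl", "Bacteria", "Archaea")

#: default class -> trophic mode lookup.  Mixotrophic classes
#: (Chrysophyceae, Cryptophyceae, Dinophyceae) count as phytoplankton.
DEFAULT_TROPHIC_BY_CLASS = {
    "Bacillariophyceae": "phytoplankton",
    "Coscinodiscophyceae": "phytoplankton",
    "Mediophyceae": "phytoplankton",
    "Fragilariophyceae": "phytoplankton",
    "Chrysophyceae": "phytoplankton",
    "Cryptophyceae": "phytoplankton",
    "Dinophyceae": "phytoplankton",
    "Chlorophyceae": "phytoplankton",
    "Trebouxiophyceae": "phytoplankton",
    "Mamiellophyceae": "phytoplankton",
    "Prymnesiophyceae": "phytoplankton",
    "Eustigmatophyceae": "phytoplankton",
    "Dictyochophyceae": "phytoplankton",
    "Ciliophora": "heterotroph",
    "Cercozoa": "heterotroph",
    "Bicoecea": "heterotroph",
    "Rozellomycota": "heterotroph",
    "Aphelidiomycota": "heterotroph",
    "Chytridiomycota": "heterotroph",
    "Katablepharidaceae": "heterotroph",
}


@dataclass
class AsvTable:
    """Read counts (samples × ASVs) plus per-ASV taxonomy.

    ``counts``: integer DataFrame indexed by sample_id, columns asv_id.
    ``taxonomy``: DataFrame indexed by asv_id with columns ``lineage``
    (semicolon-delimited ranks, domain first), ``class_name`` and
    ``trophic`` ("phytoplankton" or "heterotroph"); the last two may be
    derived from the lineage via :meth:`with_derived_fields`.
    ``provenance``: list of dicts recording each filter applied (step name,
    ASVs in, ASVs out) for a machine-readable audit trail.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        missing = self.counts.columns.difference(self.taxonomy.index)
        if len(missing):
            raise ValueError(f"ASVs without taxonomy records: {list(missing)[:5]}")
        if "lineage" not in self.taxonomy.columns:
            raise ValueError("taxonomy requires a 'lineage' column")
        counts = self.counts
        if (counts.values < 0).any():
            raise ValueError("negative read counts")

    @property
    def asv_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def samples(self) -> pd.Index:
        return self.counts.index

    def subset(self, asv_ids, step: str | None = None) -> "AsvTable":
        """Restrict to the given ASVs (column order preserved as given)."""
        asv_ids = list(asv_ids)
        prov = list(self.provenance)
        if step is not None:
            prov.append(
                {"step": step, "asvs_in": int(self.counts.shape[1]),
                 "asvs_out": len(asv_ids)}
            )
        return AsvTable(
            self.counts[asv_ids], self.taxonomy.loc[asv_ids], prov
        )

    def with_derived_fields(
        self, trophic_by_class: dict | None = None, class_rank: int = 3
    ) -> "AsvTable":
        """Fill in class_name and trophic from the lineage where absent.

        The class is taken from rank ``class_rank`` (0-based) of the
        semicolon-delimited lineage; trophic mode from a class -> mode
        lookup.  Unresolvable entries stay NaN and are caught downstream.
        """
        lookup = DEFAULT_TROPHIC_BY_CLASS if trophic_by_class is None else trophic_by_class
        tax = self.taxonomy.copy()
        if "class_name" not in tax.columns:
            tax["class_name"] = np.nan
        derived = tax["lineage"].str.split(";").map(
            lambda ranks: ranks[class_rank].strip()
            if isinstance(ranks, list) and len(ranks) > class_rank
            else np.nan
        )
        tax["class_name"] = tax["class_name"].where(
            tax["class_name"].notna(), derived)
        if "trophic" not in tax.columns:
            tax["trophic"] = np.nan
        tax["trophic"] = tax["trophic"].where(
            tax["trophic"].notna(), tax["class_name"].map(lookup))
        return AsvTable(self.counts, tax, list(self.provenance))


def filter_asvs(table: AsvTable) -> AsvTable:
    """Remove low-count ASVs and excluded lineages.

    Rules: ASVs with ≤ 2 reads in total; ASVs whose lineage contains any of
    ``EXCLUDED_LINEAGE_TOKENS``; ASVs unclassified at the domain level
    (empty, missing or explicitly unclassified first rank).  Column order of
    the survivors is preserved; the operation is idempotent.
    """
    lineage = table.taxonomy["lineage"]
    if lineage.isna().any():
        bad = list(lineage.index[lineage.isna()])[:5]
        raise ValueError(f"ASVs without lineage: {bad}")

    totals = table.counts.sum(axis=0)
    keep_depth = totals > 2

    def lineage_ok(lin: str) -> bool:
        if any(tok in lin for tok in EXCLUDED_LINEAGE_TOKENS):
            return False
        domain = lin.split(";")[0].strip()
        return domain not in ("", "NA", "unclassified", "Unclassified", "Unassigned")

    keep_lineage = lineage.map(lineage_ok)
    keep = [a for a in table.asv_ids if keep_depth[a] and keep_lineage[a]]
    return table.subset(keep, step="filter_asvs")


def select_phytoplankton(table: AsvTable) -> AsvTable:
    """Retain ASVs flagged as phytoplankton (autotrophs and mixotrophs)."""
    trophic = table.taxonomy.loc[table.asv_ids, "trophic"]
    if trophic.isna().any():
        bad = list(trophic.index[trophic.isna()])
        raise ValueError(f"ASVs with no trophic flag: {bad}")
    keep = [a for a in table.asv_ids if trophic[a] == "phytoplankton"]
    if not keep:
        warnings.warn("no phytoplankton ASVs remain after trophic selection",
                      stacklevel=2)
    return table.subset(keep, step="select_phytoplankton")


def top_n(table: AsvTable, n: int) -> AsvTable:
    """Keep the n ASVs with the largest total read counts.

    Ties are broken by lexicographic asv_id so the selection is
    deterministic.  Asking for more ASVs than exist returns everything with
    a warning.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    totals = table.counts.sum(axis=0)
    if n > len(totals):
        warnings.warn(
            f"requested top {n} but only {len(totals)} ASVs available",
            stacklevel=2,
        )
        n = len(totals)
    order = sorted(table.asv_ids, key=lambda a: (-totals[a], a))
    return table.subset(order[:n], step=f"top_{n}")


def prevalence_filter(matrix: pd.DataFrame, min_samples: int = 8) -> pd.DataFrame:
    """Retain features (columns) with nonzero values in ≥ min_samples samples.

    The customary pre-filter before correlation analysis: a feature seen in
    too few samples cannot support a stable rank correlation.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    present = (matrix.fillna(0) != 0).sum(axis=0)
    return matrix.loc[:, present >= min_samples]


@dataclass
class RelAbundanceMatrix:
    """Row-stochastic relative abundances over a stated scope.

    ``values``: sample × ASV DataFrame; rows sum to 1 over the scope, or
    hold NaN when the scope has zero reads in that sample (those samples
    are listed in ``empty_samples``).  ``scope`` is ``"all_phyto"`` or
    ``"within_class"``; for the latter ``class_name`` names the class.
    """

    values: pd.DataFrame
    scope: str
    class_name: str | None = None
    empty_samples: list = field(default_factory=list)

    def __post_init__(self):
        filled = self.values.dropna(how="all")
        row_sums = filled.sum(axis=1)
        if len(filled) and not np.allclose(row_sums, 1.0, atol=1e-9):
            raise ValueError("non-empty rows of a relative-abundance matrix "
                             "must sum to 1")


def _close_rows(counts: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    totals = counts.sum(axis=1)
    empty = list(totals.index[totals == 0])
    values = counts.div(totals.replace(0, np.nan), axis=0)
    return values, empty


def relative_abundance(table: AsvTable) -> RelAbundanceMatrix:
    """R_ij: each ASV's share of its sample's total phytoplankton reads.

    Expects a table already restricted to phytoplankton ASVs, so that read
    shares correspond to shares of the total phytoplankton community.
    Samples with zero reads are flagged empty (NaN row), not propagated as
    errors.
    """
    values, empty = _close_rows(table.counts.astype(float))
    return RelAbundanceMatrix(values, scope="all_phyto", empty_samples=empty)


def class_relative_abundance(table: AsvTable) -> dict[str, RelAbundanceMatrix]:
    """R_ijc: within-class read shares, one matrix per class.

    For each class c, each ASV's reads are divided by the sample's total
    reads over class-c ASVs.  ASVs with an unresolvable class are excluded
    (with a warning); they remain usable in the total-phytoplankton scope.
    """
    classes = table.taxonomy.loc[table.asv_ids, "class_name"]
    if classes.isna().any():
        bad = list(classes.index[classes.isna()])
        warnings.warn(
            f"ASVs with unresolvable class excluded from class-specific "
            f"matrices: {bad}",
            stacklevel=2,
        )
    out: dict[str, RelAbundanceMatrix] = {}
    for cls in pd.unique(classes.dropna()):
        members = [a for a in table.asv_ids if classes[a] == cls]
        values, empty = _close_rows(table.counts[members].astype(float))
        out[cls] = RelAbundanceMatrix(
            values, scope="within_class", class_name=cls, empty_samples=empty
        )
    return out


# ---------------------------------------------------------------------------
# I/O

def read_asv_table(counts_path, taxonomy_path) -> AsvTable:
    """Read counts (samples × ASVs TSV) and taxonomy (asv_id, lineage TSV)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.index.name = "sample_id"
    tax = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
    return AsvTable(counts, tax).with_derived_fields()


def write_asv_table(table: AsvTable, counts_path, taxonomy_path) -> None:
    table.counts.to_csv(counts_path, sep="\t")
    table.taxonomy.to_csv(taxonomy_path, sep="\t")
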