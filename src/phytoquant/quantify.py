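"""Anchored quantification: read shares × microscopy totals -> absolute values.

The central conversion of this package.  Metabarcoding yields only relative
abundances R_ij of ASVs; microscopy yields absolute totals.  Two anchoring
schemes turn the former into absolute abundance/biomass:

* total anchoring:  ā_ij  = R_ij  × A_j   (and m̄_ij  = R_ij  × M_j),
  where A_j / M_j is the sample's total phytoplankton abundance / biomass;
* class anchoring:  ā_ijc = R_ijc × A_jc  (and m̄_ijc = R_ijc × M_jc),
  where R_ijc is the ASV's share of its class's reads and A_jc / M_jc the
  microscopy total of that class in that sample.

Class anchoring is the more accurate scheme when amplification bias is
class-structured (gene copy number and primer affinity vary mostly between
classes), but it is undefined wherever a class has reads in a sample while
microscopy saw no cells of that class: those cells are masked (NaN), never
coerced to zero, and excluded pairwise downstream.  Classes detected by
metabarcoding alone can be anchored by a morphologically similar proxy
class via ``proxy_map``.

Both schemes are exposed as sklearn-style transformers (fit on the anchors,
transform a relative-abundance matrix) and as plain functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .asv import RelAbundanceMatrix
from .microscopy import AnchorTotals

__all__ = [
    "QuantifiedAsvTable",
    "TotalAnchorQuantifier",
    "ClassAnchorQuantifier",
    "absolute_by_total",
    "absolute_by_class",
]


@dataclass
class QuantifiedAsvTable:
    """Estimated absolute values per sample × ASV.

    ``values``: real DataFrame; NaN marks undefined (masked) cells.
    ``quantity``: ``"abundance"`` (cells L^-1) or ``"biomass"`` (mg L^-1).
    ``method``: ``"asv_x_total"`` or ``"asv_x_class"``.
    ``mask_count``: number of masked cells.
    """

    values: pd.DataFrame
    quantity: str
    method: str
    mask_count: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        defined = self.values.values[~np.isnan(self.values.values)]
        if (defined < 0).any():
            raise ValueError("quantified values must be non-negative")
        if self.quantity not in ("abundance", "biomass"):
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if self.method not in ("asv_x_total", "asv_x_class"):
            raise ValueError(f"unknown method {self.method!r}")

    def write(self, values_path, sidecar_path=None) -> None:
        """TSV of values plus optional JSON sidecar with provenance."""
        import json

        self.values.to_csv(values_path, sep="\t")
        if sidecar_path is not None:
            doc = {
                "quantity": self.quantity,
                "method": self.method,
                "mask_count": int(self.mask_count),
                **self.meta,
            }
            with open(sidecar_path, "w") as fh:
                json.dump(doc, fh, indent=2)


class TotalAnchorQuantifier(BaseEstimator, TransformerMixin):
    """Convert R_ij to absolute values with sample totals: ā_ij = R_ij · A_j.

    Parameters
    ----------
    quantity : {"abundance", "biomass"}
        Which microscopy total anchors the conversion.
    correction_factors : mapping asv_id -> float, optional
        Per-taxon multiplicative correction (e.g. biovolume-based factors);
        off by default.  Rows are re-closed after correction so the
        per-sample total is still conserved.

    Attributes
    ----------
    anchors_ : pandas.Series
        Per-sample anchor totals (A_j or M_j) captured by :meth:`fit`.
    """

    def __init__(self, quantity: str = "abundance", correction_factors=None):
        self.quantity = quantity
        self.correction_factors = correction_factors

    def fit(self, anchors: AnchorTotals, y=None):
        if self.quantity not in ("abundance", "biomass"):
            raise ValueError(f"unknown quantity {self.quantity!r}")
        self.anchors_ = anchors.total[self.quantity].astype(float)
        return self

    def transform(self, R: RelAbundanceMatrix) -> QuantifiedAsvTable:
        if not hasattr(self, "anchors_"):
            raise RuntimeError("fit on AnchorTotals before transforming")
        values = R.values if isinstance(R, RelAbundanceMatrix) else R
        missing = values.index.difference(self.anchors_.index)
        if len(missing):
            raise ValueError(f"samples missing from anchors: {list(missing)}")
        work = values
        if self.correction_factors is not None:
            cf = pd.Series(self.correction_factors).reindex(work.columns).fillna(1.0)
            work = work.mul(cf, axis=1)
            work = work.div(work.sum(axis=1), axis=0)
        out = work.mul(self.anchors_.reindex(values.index), axis=0)
        mask_count = int(out.isna().values.sum())
        return QuantifiedAsvTable(
            out, quantity=self.quantity, method="asv_x_total",
            mask_count=mask_count,
            meta={"anchor": "total", "n_samples": int(len(out))},
        )


class ClassAnchorQuantifier(BaseEstimator, TransformerMixin):
    """Convert within-class shares with class totals: ā_ijc = R_ijc · A_jc.

    Parameters
    ----------
    quantity : {"abundance", "biomass"}
    proxy_map : mapping class -> class, optional
        Anchors a class seen only by metabarcoding with the microscopy
        totals of a morphologically similar class (e.g. Eustigmatophyceae
        anchored by Chlorophyceae).  Proxy classes must exist in the
        anchors; validated at fit time.

    Attributes
    ----------
    class_anchors_ : pandas.DataFrame
        sample × class anchor totals (A_jc or M_jc).

    Notes
    -----
    Cells where the ASV's class has reads but the class anchor is zero are
    masked (NaN): microscopy saw no cells of the class, so no absolute
    value can be assigned.  Masking, not zeroing, keeps downstream
    correlations unbiased.
    """

    def __init__(self, quantity: str = "abundance", proxy_map: dict | None = None):
        self.quantity = quantity
        self.proxy_map = proxy_map

    def fit(self, anchors: AnchorTotals, y=None):
        if self.quantity not in ("abundance", "biomass"):
            raise ValueError(f"unknown quantity {self.quantity!r}")
        self.class_anchors_ = (
            anchors.class_abundance if self.quantity == "abundance"
            else anchors.class_biomass
        ).astype(float)
        for asv_class, proxy in (self.proxy_map or {}).items():
            if proxy not in self.class_anchors_.columns:
                raise ValueError(
                    f"proxy class {proxy!r} for {asv_class!r} not present "
                    "in microscopy anchors"
                )
        return self

    def _anchor_for(self, class_name: str) -> pd.Series | None:
        proxy_map = self.proxy_map or {}
        target = proxy_map.get(class_name, class_name)
        if target not in self.class_anchors_.columns:
            return None
        return self.class_anchors_[target]

    def transform(
        self, Rc: dict[str, RelAbundanceMatrix]
    ) -> QuantifiedAsvTable:
        if not hasattr(self, "class_anchors_"):
            raise RuntimeError("fit on AnchorTotals before transforming")
        unmapped = [
            c for c in Rc
            if self._anchor_for(c) is None
        ]
        if unmapped:
            raise ValueError(
                f"classes with no anchor and no proxy mapping: {unmapped}; "
                "add proxy_map entries for classes seen only by metabarcoding"
            )
        pieces = []
        for class_name, R in Rc.items():
            anchor = self._anchor_for(class_name)
            values = R.values
            missing = values.index.difference(anchor.index)
            if len(missing):
                raise ValueError(
                    f"samples missing from anchors: {list(missing)}"
                )
            a = anchor.reindex(values.index)
            scaled = values.mul(a, axis=0)
            # reads present but microscopy anchor zero -> undefined, mask
            has_reads = values.notna() & (values > 0)
            undefined = has_reads.mul((a == 0), axis=0).astype(bool)
            scaled = scaled.mask(undefined)
            pieces.append(scaled)
        out = pd.concat(pieces, axis=1)
        mask_count = int(out.isna().values.sum())
        return QuantifiedAsvTable(
            out, quantity=self.quantity, method="asv_x_class",
            mask_count=mask_count,
            meta={
                "anchor": "class",
                "proxy_map": dict(self.proxy_map or {}),
                "n_samples": int(len(out)),
            },
        )


def absolute_by_total(
    R: RelAbundanceMatrix, anchors: AnchorTotals, quantity: str = "abundance"
) -> QuantifiedAsvTable:
    """ā_ij = R_ij × A_j (or m̄_ij = R_ij × M_j)."""
    return TotalAnchorQuantifier(quantity=quantity).fit(anchors).transform(R)


def absolute_by_class(
    Rc: dict[str, RelAbundanceMatrix],
    anchors: AnchorTotals,
    quantity: str = "abundance",
    proxy_map: dict | None = None,
) -> QuantifiedAsvTable:
    """ā_ijc = R_ijc × A_jc (or m̄_ijc = R_ijc × M_jc)."""
    return (
        ClassAnchorQuantifier(quantity=quantity, proxy_map=proxy_map)
        .fit(anchors)
        .transform(Rc)
    )
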