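"""Multi-cell-line cytotoxicity profiles and therapeutic-index estimation.

A panel report collects per-cell-line predicted pIC50/pGI50 values for one
query compound, grouped into non-tumor and tumor rows.  The therapeutic
index is the decimal ratio implied by the difference of the group means on
the log scale:

    delta = mean_tumor - mean_non_tumor        (log10 units)
    TI    = 10 ** delta

so a compound that is on average 0.613 log units more cytotoxic to tumor
cells than to non-tumor cells has TI = 10**0.613 ~ 4.1.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

__all__ = [
    "PanelRow",
    "PanelReport",
    "predict_panel",
    "group_mean",
    "therapeutic_index",
    "classify_ti",
]


@dataclass(frozen=True)
class PanelRow:
    cell_line: str
    tissue: str
    endpoint: str          # "pIC50" | "pGI50"
    value: float
    tumor: bool
    in_ad: bool | None = None  # None when AD was not assessed
    ad_flags: tuple[str, str, str] | None = None  # (similarity, leverage, accuracy)


@dataclass(frozen=True)
class PanelReport:
    query_key: str
    rows: tuple[PanelRow, ...]
    ad_strict: bool = False  # whether out-of-AD rows were excluded from means

    def _group_rows(self, tumor: bool) -> list[PanelRow]:
        rows = [r for r in self.rows if r.tumor == tumor]
        if self.ad_strict:
            rows = [r for r in rows if r.in_ad is not False]
        return rows

    @property
    def mean_non_tumor(self) -> float | None:
        rows = self._group_rows(False)
        return sum(r.value for r in rows) / len(rows) if rows else None

    @property
    def mean_tumor(self) -> float | None:
        rows = self._group_rows(True)
        return sum(r.value for r in rows) / len(rows) if rows else None

    @property
    def therapeutic_index(self) -> tuple[float, float] | None:
        if self.mean_tumor is None or self.mean_non_tumor is None:
            return None
        return therapeutic_index(self.mean_tumor, self.mean_non_tumor)

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["cell_line", "tissue", "endpoint", "value", "AD"])
            for r in self.rows:
                ad = "" if r.in_ad is None else ("in AD" if r.in_ad else "out of AD")
                w.writerow([r.cell_line, r.tissue, r.endpoint, repr(r.value), ad])


def predict_panel(models, mol, query_key: str = "", ad_strict: bool = False) -> PanelReport:
    """Apply every consensus model in ``models`` to one curated query.

    ``models`` is an iterable of consensus models carrying
    ``cell_line``/``endpoint`` metadata and an optional ``tumor``/``tissue``
    attribute.  Curation failures refuse the whole panel (no partial report).
    """
    from .chem import canonical_key, curate_structure
    from .consensus import consensus_predict

    models = list(models)
    if not models:
        raise ValueError("empty model collection")
    verdict = curate_structure(mol)
    if not verdict.accepted:
        raise ValueError(f"query rejected by structure curation: {verdict.reason}")
    rows = []
    for cm in models:
        res = consensus_predict(cm, mol, check_curation=False)
        rows.append(
            PanelRow(
                cell_line=cm.cell_line,
                tissue=getattr(cm, "tissue", ""),
                endpoint=cm.endpoint,
                value=res.value,
                tumor=bool(getattr(cm, "tumor", False)),
                in_ad=res.ad.in_domain,
                ad_flags=(res.ad.similarity, res.ad.leverage, res.ad.accuracy),
            )
        )
    return PanelReport(
        query_key=query_key or canonical_key(mol),
        rows=tuple(rows),
        ad_strict=ad_strict,
    )


def group_mean(report: PanelReport, group: str) -> float:
    """Arithmetic mean of the group's predicted values (pIC50/pGI50 pooled)."""
    if group == "non-tumor":
        value = report.mean_non_tumor
    elif group == "tumor":
        value = report.mean_tumor
    else:
        raise ValueError(f"unknown group {group!r}")
    if value is None:
        raise ValueError(f"group {group!r} is empty")
    return value


def therapeutic_index(mean_tumor: float, mean_non_tumor: float) -> tuple[float, float]:
    """(delta log units, decimal TI) for a pair of group means."""
    delta = mean_tumor - mean_non_tumor
    return delta, 10.0**delta


def classify_ti(ti: float) -> str:
    """Advisory label: preferable (>=10), candidate (>5), intermediate, narrow (<2)."""
    if ti <= 0 or not math.isfinite(ti):
        raise ValueError(f"TI must be positive and finite, got {ti}")
    if ti >= 10:
        return "preferable"
    if ti > 5:
        return "candidate"
    if ti < 2:
        return "narrow"
    return "intermediate"
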