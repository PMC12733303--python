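"""Bundled reference tables.

Two small datasets ship with the package:

* ``load_example_panel()`` — published per-cell-line pIC50/pGI50 predictions
  for three anticancer drugs (paclitaxel, trametinib, dabrafenib) across 11
  non-tumor and 11 tumor cell-line models; used as a worked example for the
  panel-profiling and therapeutic-index arithmetic.
* ``load_cv_accuracy(group)`` — 5-fold cross-validated accuracies
  (R**2, RMSE) of per-cell-line cytotoxicity QSAR models, for applying the
  final acceptance filter (R**2 > 0.5 and RMSE < 1).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .panel import PanelReport, PanelRow

__all__ = ["load_example_panel", "load_cv_accuracy", "example_panel_report"]

EXAMPLE_DRUGS = ("paclitaxel", "trametinib", "dabrafenib")


def _read(name: str) -> pd.DataFrame:
    with resources.files("cytoqsar.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_example_panel() -> pd.DataFrame:
    """Example panel predictions; one row per (cell line, endpoint) model."""
    return _read("example_panel_predictions.tsv")


def load_cv_accuracy(group: str) -> pd.DataFrame:
    """Cross-validated model accuracies for ``group`` in {non-tumor, tumor}.

    Rows where 5-fold modelling failed carry NA metrics.
    """
    if group == "non-tumor":
        return _read("cv_accuracy_nontumor.tsv")
    if group == "tumor":
        return _read("cv_accuracy_tumor.tsv")
    raise ValueError(f"unknown group {group!r}")


def example_panel_report(drug: str) -> PanelReport:
    """PanelReport for one of the three example drugs."""
    if drug not in EXAMPLE_DRUGS:
        raise ValueError(f"drug must be one of {EXAMPLE_DRUGS}")
    df = load_example_panel()
    rows = tuple(
        PanelRow(
            cell_line=r.cell_line,
            tissue=r.tissue,
            endpoint=r.endpoint,
            value=float(getattr(r, drug)),
            tumor=(r.group == "tumor"),
        )
        for r in df.itertuples()
    )
    return PanelReport(query_key=drug, rows=rows)
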