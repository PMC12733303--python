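"""Activity-table curation: raw IC50/GI50 records to per-cell-line training sets.

Concentrations are converted to the p-scale as -log10 of the molar value, so
10 uM -> 5.0 and 1 nM -> 9.0.  Replicate measurements of one compound on one
cell line and endpoint are consolidated by the median.  A cell line only
yields a training set when it has strictly more than ``min_compounds`` unique
curated compounds.
"""

from __future__ import annotations

import csv
import logging
import math
import statistics
from dataclasses import dataclass
from typing import Mapping, Sequence

from .chem import MoleculeGraph

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityRecord",
    "TrainingSet",
    "SetSummary",
    "UnitError",
    "to_p_value",
    "consolidate_duplicates",
    "build_training_set",
    "summarize",
    "read_activity_csv",
    "write_training_set_csv",
]

# mol/L per unit
_UNIT_FACTORS: Mapping[str, float] = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "μM": 1e-6,
    "nM": 1e-9,
}

_QUALIFIERS = (">", "<", "~", ">=", "<=")


class UnitError(ValueError):
    pass


@dataclass(frozen=True)
class ActivityRecord:
    compound_key: str
    cell_line: str
    endpoint: str  # "IC50" or "GI50"
    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"non-positive activity value {self.value}")
        if self.unit not in _UNIT_FACTORS:
            raise UnitError(f"unsupported unit {self.unit!r}")
        if self.endpoint not in ("IC50", "GI50"):
            raise ValueError(f"unsupported endpoint {self.endpoint!r}")


@dataclass(frozen=True)
class TrainingSet:
    cell_line: str
    endpoint: str  # "pIC50" or "pGI50"
    entries: tuple[tuple[str, MoleculeGraph, float], ...]  # (key, molecule, p-value)
    tissue: str = ""
    tumor: bool = False

    def __post_init__(self) -> None:
        keys = [k for k, _, _ in self.entries]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate compound keys in training set")
        if any(not math.isfinite(p) for _, _, p in self.entries):
            raise ValueError("non-finite p-value in training set")

    @property
    def n(self) -> int:
        return len(self.entries)

    def p_values(self) -> list[float]:
        return [p for _, _, p in self.entries]

    def molecules(self) -> list[MoleculeGraph]:
        return [m for _, m, _ in self.entries]

    def keys(self) -> list[str]:
        return [k for k, _, _ in self.entries]


@dataclass(frozen=True)
class SetSummary:
    n: int
    p_min: float
    p_max: float
    p_mean: float


def to_p_value(value: float, unit: str, endpoint: str = "IC50") -> float:
    """p-value (pIC50/pGI50) = -log10 of the concentration in mol/L."""
    if value <= 0:
        raise ValueError(f"concentration must be positive, got {value}")
    try:
        molar = value * _UNIT_FACTORS[unit]
    except KeyError:
        raise UnitError(f"unsupported unit {unit!r}") from None
    return -math.log10(molar)


def consolidate_duplicates(
    records: Sequence[ActivityRecord],
) -> dict[str, float]:
    """Median p-value per compound key.

    All records must share one cell line and endpoint; the median of an even
    number of replicates is the midpoint of the two central values.
    """
    if not records:
        return {}
    cell_lines = {r.cell_line for r in records}
    endpoints = {r.endpoint for r in records}
    if len(cell_lines) > 1 or len(endpoints) > 1:
        raise ValueError("records span multiple cell lines or endpoints")
    grouped: dict[str, list[float]] = {}
    for r in records:
        grouped.setdefault(r.compound_key, []).append(to_p_value(r.value, r.unit, r.endpoint))
    return {k: statistics.median(v) for k, v in grouped.items()}


def build_training_set(
    records: Sequence[ActivityRecord],
    molecules: Mapping[str, MoleculeGraph],
    cell_line: str,
    endpoint: str,
    min_compounds: int = 100,
    tissue: str = "",
    tumor: bool = False,
) -> TrainingSet | None:
    """Join records with curated structures and consolidate replicates.

    Records whose compound key has no accepted structure are logged and
    skipped.  Returns ``None`` (rejection) when the unique-compound count is
    not strictly greater than ``min_compounds``.
    """
    relevant = [r for r in records if r.cell_line == cell_line and r.endpoint == endpoint]
    with_structure = []
    skipped = 0
    for r in relevant:
        if r.compound_key in molecules:
            with_structure.append(r)
        else:
            skipped += 1
            logger.warning("no curated structure for %s; record skipped", r.compound_key)
    if skipped:
        logger.info("%s/%s: skipped %d records lacking structures", cell_line, endpoint, skipped)
    consolidated = consolidate_duplicates(with_structure)
    if len(consolidated) <= min_compounds:
        logger.info(
            "%s/%s rejected: %d unique compounds (need > %d)",
            cell_line, endpoint, len(consolidated), min_compounds,
        )
        return None
    entries = tuple(
        (key, molecules[key], p) for key, p in sorted(consolidated.items())
    )
    return TrainingSet(
        cell_line=cell_line,
        endpoint="p" + endpoint,
        entries=entries,
        tissue=tissue,
        tumor=tumor,
    )


def summarize(ts: TrainingSet) -> SetSummary:
    if ts.n == 0:
        raise ValueError("empty training set")
    ps = ts.p_values()
    return SetSummary(n=ts.n, p_min=min(ps), p_max=max(ps), p_mean=sum(ps) / len(ps))


# ---------------------------------------------------------------------------
# I/O


def read_activity_csv(path: str) -> tuple[list[dict], list[dict]]:
    """Read an activity table in the ChEMBL-export-like dialect.

    Expected header: compound_id, smiles, cell_line, standard_type,
    standard_value, standard_units (extra columns pass through).  Rows whose
    value carries a qualifier ('>', '<', '~') or is non-numeric/non-positive
    are excluded (only exact values train models).  Returns
    (usable rows, excluded rows).
    """
    usable: list[dict] = []
    excluded: list[dict] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            raw = (row.get("standard_value") or "").strip()
            relation = (row.get("standard_relation") or "=").strip().strip("'\"") or "="
            if relation != "=" or raw.startswith(_QUALIFIERS):
                excluded.append(row)
                continue
            try:
                value = float(raw.lstrip("="))
            except ValueError:
                excluded.append(row)
                continue
            if value <= 0 or (row.get("standard_units") or "") not in _UNIT_FACTORS:
                excluded.append(row)
                continue
            row = dict(row)
            row["standard_value"] = value
            usable.append(row)
    return usable, excluded


def write_training_set_csv(path: str, ts: TrainingSet) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_key", "smiles", "p_value"])
        for key, mol, p in ts.entries:
            w.writerow([key, mol.source, repr(p)])
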