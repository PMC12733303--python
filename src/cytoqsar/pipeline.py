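"""Glue from raw activity tables to curated training sets and trained models."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .activity import ActivityRecord, TrainingSet, build_training_set
from .chem import MoleculeGraph, ParseError, canonical_key, curate_structure, parse_structure
from .consensus import ConsensusModel, SelectionThresholds, build_consensus

logger = logging.getLogger(__name__)

__all__ = ["CurationLog", "curate_activity_table", "training_set_from_table", "train_from_table"]


@dataclass
class CurationLog:
    """Accept/reject accounting over one activity table."""

    n_input: int = 0
    n_accepted: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    def tally(self, reason: str, accepted: bool) -> None:
        self.n_input += 1
        if accepted:
            self.n_accepted += 1
        self.reasons[reason] = self.reasons.get(reason, 0) + 1


def curate_activity_table(
    df: pd.DataFrame, max_mass: float = 1250.0
) -> tuple[list[ActivityRecord], dict[str, MoleculeGraph], CurationLog]:
    """Parse, filter and canonicalise every row of an activity table.

    Returns activity records keyed by canonical structure, the molecule map
    for accepted structures, and the per-reason rejection tally.  Structures
    are parsed once per distinct SMILES.
    """
    log = CurationLog()
    mol_cache: dict[str, tuple[str | None, MoleculeGraph | None, str]] = {}
    records: list[ActivityRecord] = []
    molecules: dict[str, MoleculeGraph] = {}
    for row in df.itertuples():
        smiles = str(row.smiles)
        if smiles not in mol_cache:
            try:
                mol = parse_structure(smiles)
            except ParseError:
                mol_cache[smiles] = (None, None, "parse_error")
            else:
                verdict = curate_structure(mol, max_mass=max_mass)
                if verdict.accepted:
                    mol_cache[smiles] = (canonical_key(mol), mol, "ok")
                else:
                    mol_cache[smiles] = (None, None, verdict.reason)
        key, mol, reason = mol_cache[smiles]
        log.tally(reason, key is not None)
        if key is None or mol is None:
            continue
        molecules[key] = mol
        records.append(
            ActivityRecord(
                compound_key=key,
                cell_line=str(row.cell_line),
                endpoint=str(row.standard_type),
                value=float(row.standard_value),
                unit=str(row.standard_units),
            )
        )
    logger.info(
        "curation: %d/%d records accepted (%s)",
        log.n_accepted, log.n_input,
        ", ".join(f"{k}={v}" for k, v in sorted(log.reasons.items())),
    )
    return records, molecules, log


def training_set_from_table(
    df: pd.DataFrame,
    cell_line: str,
    endpoint: str = "IC50",
    min_compounds: int = 100,
    max_mass: float = 1250.0,
) -> tuple[TrainingSet | None, CurationLog]:
    records, molecules, log = curate_activity_table(df, max_mass=max_mass)
    ts = build_training_set(
        records, molecules, cell_line=cell_line, endpoint=endpoint, min_compounds=min_compounds
    )
    return ts, log


def train_from_table(
    df: pd.DataFrame,
    cell_line: str,
    endpoint: str = "IC50",
    min_compounds: int = 100,
    n_variants: int = 320,
    seed: int = 0,
    thresholds: SelectionThresholds = SelectionThresholds(),
    min_features: int = 5,
) -> ConsensusModel | None:
    """Activity table in, consensus model out (None if curation or selection fails)."""
    ts, _ = training_set_from_table(
        df, cell_line=cell_line, endpoint=endpoint, min_compounds=min_compounds
    )
    if ts is None:
        return None
    return build_consensus(
        ts, n_variants=n_variants, seed=seed, thresholds=thresholds, min_features=min_features
    )
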