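"""Synthetic structure-activity sets with known additive ground truth.

Compounds are assembled combinatorially from a frozen fragment alphabet:
8 disubstituted scaffolds x 12 substituents per slot.  The true activity of
a compound is

    p_true = offset + c(scaffold) + c(substituent 1) + c(substituent 2)

with per-fragment contributions drawn once from Uniform(-1.5, 1.5) at a
fixed alphabet seed and frozen, so fixtures are stable across runs.
Observed activities add homoscedastic Gaussian noise on the p-scale
(assay-like noise of a few tenths of a log unit); deliberate duplicates get
independent noise so median consolidation is exercised, and a configurable
fraction of invalid records (mixtures, charged species, overweight
compounds) tests the structure-curation filters.

The defaults emulate the shape of real per-cell-line training sets: mean
p-value near 5 (the 10 uM activity threshold) and a value range of well over
3 log units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "SCAFFOLDS",
    "SUBSTITUENTS",
    "fragment_contributions",
    "generate",
    "range_check",
    "indicator_matrix",
]

# Disubstituted scaffold templates; both slots take an atom-first fragment.
# Every scaffold is slot-asymmetric (no graph automorphism exchanges the two
# substitution positions), so all 8 x 12 x 12 combinations are distinct
# molecules and the combinatorial space supports >1000 unique structures.
SCAFFOLDS: tuple[tuple[str, str], ...] = (
    ("pyridine-2,5", "{a}c1ccc({b})cn1"),
    ("pyridine-2,4", "{a}c1cc({b})ccn1"),
    ("thiophene-2,4", "{a}c1cc({b})cs1"),
    ("furan-2,4", "{a}c1cc({b})co1"),
    ("pyrrole-2,4", "{a}c1cc({b})c[nH]1"),
    ("oxane-2,4", "{a}C1CCC({b})OC1"),
    ("thiane-2,4", "{a}C1CCC({b})SC1"),
    ("pyrimidine-2,5", "{a}c1ncc({b})cn1"),
)

# Substituents written as atom-first fragments valid in both slots.
SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "O", "N", "S", "F", "Cl", "Br", "I", "C#C", "CO",
)

_ALPHABET_SEED = 20240917  # frozen; changing it would change every fixture

_INVALID_TEMPLATES = (
    ("mixture", "CC(=O)O.[Na+].[Cl-]"),
    ("charged", "CC(=O)[O-]"),
    ("overweight", "C" * 90),  # C90 alkane, ~1264 Da
)


def fragment_contributions() -> tuple[dict[str, float], dict[str, float]]:
    """Frozen additive contributions (log units) per scaffold and substituent.

    Each table is centered to mean zero so that a uniform draw over the
    combinatorial space has expected activity equal to the spec's offset.
    """
    rng = np.random.default_rng(_ALPHABET_SEED)
    scaf_raw = rng.uniform(-1.5, 1.5, size=len(SCAFFOLDS))
    sub_raw = rng.uniform(-1.5, 1.5, size=len(SUBSTITUENTS))
    scaf_raw -= scaf_raw.mean()
    sub_raw -= sub_raw.mean()
    scaf = {name: float(c) for (name, _), c in zip(SCAFFOLDS, scaf_raw)}
    subs = {s: float(c) for s, c in zip(SUBSTITUENTS, sub_raw)}
    return scaf, subs


@dataclass(frozen=True)
class SyntheticSpec:
    n: int = 300
    sigma: float = 0.2
    offset: float = 5.0
    seed: int = 0
    duplicate_fraction: float = 0.0
    invalid_fraction: float = 0.0
    cell_line: str = "SYN-1"
    endpoint: str = "IC50"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        for frac in (self.duplicate_fraction, self.invalid_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    activity: pd.DataFrame       # ChEMBL-export-like dialect
    ground_truth: pd.DataFrame   # one row per unique valid compound
    contributions: tuple[dict[str, float], dict[str, float]] = field(
        default_factory=fragment_contributions
    )
    invalid_records: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_unique_valid(self) -> int:
        return len(self.ground_truth)


def _p_to_nM(p: float) -> float:
    return 10.0 ** (9.0 - p)


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate an activity table plus its ground-truth bookkeeping.

    Fully deterministic given ``spec.seed``.  Raises when the fragment
    alphabet cannot supply ``spec.n`` distinct compounds.
    """
    from rdkit import Chem

    scaf_c, sub_c = fragment_contributions()
    combos = [
        (sname, a, b)
        for sname, _ in SCAFFOLDS
        for a in SUBSTITUENTS
        for b in SUBSTITUENTS
    ]
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(combos))

    templates = dict(SCAFFOLDS)
    rows, seen_keys = [], set()
    for idx in order:
        if len(rows) >= spec.n:
            break
        sname, a, b = combos[idx]
        smiles = templates[sname].format(a=a, b=b)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # template/substituent combination that does not parse
            continue
        key = Chem.MolToSmiles(mol)
        if key in seen_keys:
            continue
        seen_keys.add(key)
        p_true = spec.offset + scaf_c[sname] + sub_c[a] + sub_c[b]
        rows.append(
            {
                "compound_id": f"SYN{len(rows):05d}",
                "smiles": smiles,
                "canonical_key": key,
                "scaffold": sname,
                "sub1": a,
                "sub2": b,
                "p_true": p_true,
            }
        )
    if len(rows) < spec.n:
        raise ValueError(
            f"fragment alphabet supplies only {len(rows)} distinct compounds, need {spec.n}"
        )
    truth = pd.DataFrame(rows)

    records = []

    def _record(cid: str, smiles: str, p_obs: float) -> None:
        records.append(
            {
                "compound_id": cid,
                "smiles": smiles,
                "cell_line": spec.cell_line,
                "standard_type": spec.endpoint,
                "standard_value": _p_to_nM(p_obs),
                "standard_units": "nM",
            }
        )

    for r in rows:
        _record(r["compound_id"], r["smiles"], r["p_true"] + rng.normal(0.0, spec.sigma))

    n_dup = int(round(spec.duplicate_fraction * spec.n))
    for i, idx in enumerate(rng.choice(spec.n, size=n_dup, replace=True)):
        r = rows[int(idx)]
        _record(r["compound_id"], r["smiles"], r["p_true"] + rng.normal(0.0, spec.sigma))

    n_bad = int(round(spec.invalid_fraction * spec.n))
    bad_rows = []
    for i in range(n_bad):
        reason, smiles = _INVALID_TEMPLATES[i % len(_INVALID_TEMPLATES)]
        cid = f"BAD{i:04d}_{reason}"
        _record(cid, smiles, spec.offset)
        bad_rows.append({"compound_id": cid, "smiles": smiles, "expected_reason": reason})

    activity = pd.DataFrame(records)
    return SyntheticDataset(
        spec=spec,
        activity=activity,
        ground_truth=truth,
        invalid_records=pd.DataFrame(bad_rows),
    )


@dataclass(frozen=True)
class RangeSummary:
    applicable: bool
    mean: float
    value_range: float
    mean_ok: bool
    range_ok: bool


def range_check(p_values, offset: float = 5.0) -> RangeSummary:
    """Check that a generated set has the expected dataset shape.

    Mean within offset +/- 0.2 and a value range of at least 3 log units;
    reported not-applicable for singleton sets.
    """
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        raise ValueError("empty set")
    if len(p) == 1:
        return RangeSummary(False, float(p[0]), 0.0, False, False)
    mean = float(p.mean())
    rng_ = float(p.max() - p.min())
    return RangeSummary(True, mean, rng_, abs(mean - offset) <= 0.2, rng_ >= 3.0)


def indicator_matrix(truth: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Fragment indicator design matrix aligned with the ground-truth rows.

    Scaffold columns are one-hot; substituent columns count occurrences over
    both slots (0, 1 or 2).
    """
    scaf_names = [name for name, _ in SCAFFOLDS]
    cols = [f"scaffold:{s}" for s in scaf_names] + [f"sub:{s}" for s in SUBSTITUENTS]
    x = np.zeros((len(truth), len(cols)))
    for i, r in enumerate(truth.itertuples()):
        x[i, scaf_names.index(r.scaffold)] = 1.0
        x[i, len(scaf_names) + SUBSTITUENTS.index(r.sub1)] += 1.0
        x[i, len(scaf_names) + SUBSTITUENTS.index(r.sub2)] += 1.0
    return x, cols
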