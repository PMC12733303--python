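"""Consensus model construction and applicability-domain assessment.

For each training set an ensemble of candidate single models is trained under
systematically varied descriptor/regression configurations (default 320
variants).  Candidates pass the acceptance filter only when all three
training statistics are strictly above 0.5 (R**2 train, leave-one-out Q**2,
internal leave-many-out R**2).  The consensus prediction is the unweighted
mean of the accepted models.

The applicability domain (AD) of a query is assessed by three methods, any
one of which can flag the query as out of domain:

* **similarity** — out if the maximum Tanimoto similarity between the
  query's level-2 atom-neighborhood descriptor set and any training
  compound's set is below 0.70;
* **leverage** — out if the query's hat value exceeds 3(p+1)/n in the
  reduced linear space of any accepted single model;
* **accuracy** — out if the consensus prediction deviates from the mean
  experimental value of the three most similar training compounds by more
  than the consensus RMSE (from 5-fold cross-validation).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .activity import TrainingSet
from .chem import CurationVerdict, MoleculeGraph, curate_structure
from .descriptors import DescriptorConfig, mna_descriptors
from .engine import SingleModel, train_single_model

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionThresholds",
    "AdVerdict",
    "PredictionResult",
    "ConsensusModel",
    "EnsembleBuildError",
    "variant_configs",
    "build_ensemble",
    "select_models",
    "build_consensus",
    "consensus_predict",
    "assess_ad",
    "tanimoto",
    "ad_fingerprint",
]

DEFAULT_N_VARIANTS = 320
SIMILARITY_THRESHOLD = 0.70
AD_FINGERPRINT_LEVEL = 2
RESAMPLE_FRACTION = 0.9


class EnsembleBuildError(RuntimeError):
    pass


@dataclass(frozen=True)
class SelectionThresholds:
    r2_min: float = 0.5
    q2_min: float = 0.5
    lmo_min: float = 0.5


@dataclass(frozen=True)
class AdVerdict:
    in_domain: bool
    similarity: str   # "in" | "out"
    leverage: str     # "in" | "out"
    accuracy: str     # "in" | "out" | "unavailable"
    max_similarity: float
    nearest3_deviation: float

    def __post_init__(self) -> None:
        any_out = "out" in (self.similarity, self.leverage, self.accuracy)
        if self.in_domain != (not any_out):
            raise ValueError("in_domain must be the NOR of the per-method flags")


@dataclass(frozen=True)
class PredictionResult:
    value: float
    ad: AdVerdict
    per_model: tuple[float, ...]


def tanimoto(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def ad_fingerprint(mol: MoleculeGraph) -> frozenset[str]:
    """Binary presence set of level-2 atom-neighborhood strings."""
    return frozenset(mna_descriptors(mol, AD_FINGERPRINT_LEVEL))


@dataclass
class ConsensusModel:
    cell_line: str
    endpoint: str
    models: list[SingleModel]
    train_keys: tuple[str, ...]
    train_fingerprints: tuple[frozenset[str], ...]
    train_p_values: np.ndarray
    consensus_rmse: float | None = None  # attached by 5-fold cross-validation
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("a consensus model needs at least one accepted single model")
        if not (len(self.train_keys) == len(self.train_fingerprints) == len(self.train_p_values)):
            raise ValueError("AD reference arrays must align")

    @property
    def n_models(self) -> int:
        return len(self.models)

    def predict_molecule(self, mol: MoleculeGraph) -> float:
        """Consensus mean without AD assessment (use consensus_predict for AD)."""
        return float(np.mean([m.predict_molecules([mol])[0] for m in self.models]))


def variant_configs(
    n_variants: int, seed: int
) -> list[tuple[DescriptorConfig, float, int]]:
    """Deterministic draw of (descriptor config, scr lambda, resample seed).

    Configurations cycle through the grid of descriptor-family subsets, MNA
    levels and vocabulary sizes, QNA grid resolutions, and selection-stage
    ridge penalties; the resampling seed differs per variant so repeats of a
    grid point still see different training subsamples.
    """
    families = [
        frozenset({"MNA", "QNA", "wholemol"}),
        frozenset({"MNA", "wholemol"}),
        frozenset({"MNA", "QNA"}),
        frozenset({"QNA", "wholemol"}),
        frozenset({"MNA"}),
    ]
    grid = list(itertools.product(families, (1, 2), (128, 256), (4, 6), (0.1, 1.0)))
    rng = np.random.default_rng(seed)
    out = []
    for v in range(n_variants):
        fam, level, top_k, res, lam = grid[v % len(grid)]
        cfg = DescriptorConfig(
            families=fam,
            mna_level=level,
            mna_top_k=top_k,
            qna_resolution=res,
            variant_seed=v,
        )
        out.append((cfg, lam, int(rng.integers(0, 2**31 - 1))))
    return out


def build_ensemble(
    ts: TrainingSet,
    n_variants: int = DEFAULT_N_VARIANTS,
    seed: int = 0,
    min_features: int = 5,
) -> list[SingleModel]:
    """Train the candidate ensemble; failed variants are logged, not fatal."""
    mols = ts.molecules()
    y = np.asarray(ts.p_values())
    n = len(y)
    candidates: list[SingleModel] = []
    for cfg, scr_lam, rs_seed in variant_configs(n_variants, seed):
        rng = np.random.default_rng(rs_seed)
        m = max(int(round(RESAMPLE_FRACTION * n)), min(n, 10))
        rows = np.sort(rng.choice(n, size=m, replace=False))
        try:
            model = train_single_model(
                [mols[i] for i in rows],
                y[rows],
                cfg,
                scr_lambda=scr_lam,
                min_features=min_features,
                seed=rs_seed % (2**31),
                train_rows=rows,
            )
        except Exception as exc:  # noqa: BLE001 - variant failure is recoverable
            logger.warning("variant %d failed: %s", cfg.variant_seed, exc)
            continue
        candidates.append(model)
    if not candidates:
        raise EnsembleBuildError("all ensemble variants failed to train")
    return candidates


def select_models(
    candidates: list[SingleModel],
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> list[SingleModel]:
    """Keep candidates whose three statistics strictly exceed the thresholds."""
    return [
        m
        for m in candidates
        if m.r2_train > thresholds.r2_min
        and m.q2_loo > thresholds.q2_min
        and m.r2_lmo > thresholds.lmo_min
    ]


def build_consensus(
    ts: TrainingSet,
    n_variants: int = DEFAULT_N_VARIANTS,
    seed: int = 0,
    thresholds: SelectionThresholds = SelectionThresholds(),
    min_features: int = 5,
) -> ConsensusModel | None:
    """End-to-end ensemble build + selection; None when no candidate passes."""
    candidates = build_ensemble(ts, n_variants=n_variants, seed=seed, min_features=min_features)
    accepted = select_models(candidates, thresholds)
    logger.info(
        "%s/%s: %d of %d candidates accepted",
        ts.cell_line, ts.endpoint, len(accepted), len(candidates),
    )
    if not accepted:
        logger.warning("%s/%s: no acceptable model", ts.cell_line, ts.endpoint)
        return None
    return ConsensusModel(
        cell_line=ts.cell_line,
        endpoint=ts.endpoint,
        models=accepted,
        train_keys=tuple(ts.keys()),
        train_fingerprints=tuple(ad_fingerprint(m) for m in ts.molecules()),
        train_p_values=np.asarray(ts.p_values()),
        seed=seed,
    )


class CurationRefusal(ValueError):
    def __init__(self, verdict: CurationVerdict):
        self.verdict = verdict
        super().__init__(f"query rejected by structure curation: {verdict.reason}")


def consensus_predict(
    cm: ConsensusModel, mol: MoleculeGraph, check_curation: bool = True
) -> PredictionResult:
    """Unweighted-mean consensus prediction with AD verdict."""
    if check_curation:
        verdict = curate_structure(mol)
        if not verdict.accepted:
            raise CurationRefusal(verdict)
    per_model = tuple(float(m.predict_molecules([mol])[0]) for m in cm.models)
    value = float(np.mean(per_model))
    ad = assess_ad(cm, mol, value)
    return PredictionResult(value=value, ad=ad, per_model=per_model)


def assess_ad(cm: ConsensusModel, mol: MoleculeGraph, prediction: float) -> AdVerdict:
    """Three-method applicability-domain check (similarity OR leverage OR accuracy)."""
    fp = ad_fingerprint(mol)
    sims = np.array([tanimoto(fp, t) for t in cm.train_fingerprints])
    max_sim = float(sims.max()) if len(sims) else 0.0
    similarity_flag = "in" if max_sim >= SIMILARITY_THRESHOLD else "out"

    # three most similar training compounds: similarity desc, then key asc
    order = sorted(range(len(sims)), key=lambda i: (-sims[i], cm.train_keys[i]))
    top3 = order[:3]
    nearest_mean = float(np.mean(cm.train_p_values[top3])) if top3 else np.nan
    deviation = abs(prediction - nearest_mean) if top3 else np.inf
    if cm.consensus_rmse is None:
        logger.warning(
            "%s/%s: consensus RMSE unavailable; accuracy AD method skipped",
            cm.cell_line, cm.endpoint,
        )
        accuracy_flag = "unavailable"
    else:
        accuracy_flag = "out" if deviation > cm.consensus_rmse else "in"

    leverage_flag = "in"
    for m in cm.models:
        x = m.featurizer.transform([mol])
        if float(m.leverage(x)[0]) > m.leverage_threshold:
            leverage_flag = "out"
            break

    in_domain = "out" not in (similarity_flag, leverage_flag, accuracy_flag)
    return AdVerdict(
        in_domain=in_domain,
        similarity=similarity_flag,
        leverage=leverage_flag,
        accuracy=accuracy_flag,
        max_similarity=max_sim,
        nearest3_deviation=float(deviation),
    )
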