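"""Model-bundle serialization.

A consensus model is stored as one directory of JSON files:

    manifest.json           schema version, cell line, endpoint, RMSE, seed
    ad_reference.json       training keys, fingerprints, experimental p-values
    model_000.json, ...     per-single-model parameters (descriptor config,
                            frozen vocabulary/grid/scalers, selected columns,
                            linear weights, RBF centers/width/weights, stats)

JSON floats round-trip exactly through Python's repr, so a reloaded bundle
reproduces predictions bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .consensus import ConsensusModel
from .descriptors import DescriptorConfig, Featurizer, QnaGrid
from .engine import SingleModel

SCHEMA_VERSION = 1

__all__ = ["save_bundle", "load_bundle"]


def _arr(a: np.ndarray) -> list:
    return np.asarray(a).tolist()


def _featurizer_to_dict(f: Featurizer) -> dict:
    return {
        "config": {
            "families": sorted(f.config.families),
            "mna_level": f.config.mna_level,
            "mna_top_k": f.config.mna_top_k,
            "qna_resolution": f.config.qna_resolution,
            "variant_seed": f.config.variant_seed,
        },
        "mna_vocab": list(f.mna_vocab),
        "qna_grid": None
        if f.qna_grid is None
        else {
            "p_edges": list(f.qna_grid.p_edges),
            "q_edges": list(f.qna_grid.q_edges),
            "resolution": f.qna_grid.resolution,
        },
        "labels": list(f.labels),
        "kept": _arr(f.kept),
        "means": _arr(f.means),
        "stds": _arr(f.stds),
        "vocab_hash": f.vocab_hash,
    }


def _featurizer_from_dict(d: dict) -> Featurizer:
    cfg = DescriptorConfig(
        families=frozenset(d["config"]["families"]),
        mna_level=d["config"]["mna_level"],
        mna_top_k=d["config"]["mna_top_k"],
        qna_resolution=d["config"]["qna_resolution"],
        variant_seed=d["config"]["variant_seed"],
    )
    grid = None
    if d["qna_grid"] is not None:
        g = d["qna_grid"]
        grid = QnaGrid(tuple(g["p_edges"]), tuple(g["q_edges"]), g["resolution"])
    feat = Featurizer(
        config=cfg,
        mna_vocab=tuple(d["mna_vocab"]),
        qna_grid=grid,
        labels=tuple(d["labels"]),
        kept=np.asarray(d["kept"], dtype=int),
        means=np.asarray(d["means"], dtype=float),
        stds=np.asarray(d["stds"], dtype=float),
    )
    if feat.vocab_hash != d["vocab_hash"]:
        raise ValueError("vocabulary hash mismatch: bundle is corrupt or from another build")
    return feat


def _model_to_dict(m: SingleModel) -> dict:
    return {
        "featurizer": _featurizer_to_dict(m.featurizer),
        "selected": _arr(m.selected),
        "selected_labels": list(m.selected_labels),
        "linear_weights": _arr(m.linear_weights),
        "scr_lambda": m.scr_lambda,
        "centers": _arr(m.centers),
        "width": m.width,
        "alpha": _arr(m.alpha),
        "offset": m.offset,
        "rbf_lambda": m.rbf_lambda,
        "stats": {"r2_train": m.r2_train, "q2_loo": m.q2_loo, "r2_lmo": m.r2_lmo},
        "train_rows": _arr(m.train_rows),
    }


def _model_from_dict(d: dict) -> SingleModel:
    feat = _featurizer_from_dict(d["featurizer"])
    return SingleModel(
        config=feat.config,
        featurizer=feat,
        selected=np.asarray(d["selected"], dtype=int),
        selected_labels=tuple(d["selected_labels"]),
        linear_weights=np.asarray(d["linear_weights"], dtype=float),
        scr_lambda=float(d["scr_lambda"]),
        centers=np.asarray(d["centers"], dtype=float),
        width=float(d["width"]),
        alpha=np.asarray(d["alpha"], dtype=float),
        offset=float(d["offset"]),
        rbf_lambda=float(d["rbf_lambda"]),
        r2_train=float(d["stats"]["r2_train"]),
        q2_loo=float(d["stats"]["q2_loo"]),
        r2_lmo=float(d["stats"]["r2_lmo"]),
        train_rows=np.asarray(d["train_rows"], dtype=int),
    )


def save_bundle(cm: ConsensusModel, directory: str | Path) -> Path:
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "cell_line": cm.cell_line,
        "endpoint": cm.endpoint,
        "n_models": cm.n_models,
        "consensus_rmse": cm.consensus_rmse,
        "seed": cm.seed,
        "tissue": getattr(cm, "tissue", ""),
        "tumor": bool(getattr(cm, "tumor", False)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    ad = {
        "train_keys": list(cm.train_keys),
        "train_fingerprints": [sorted(fp) for fp in cm.train_fingerprints],
        "train_p_values": _arr(cm.train_p_values),
    }
    (out / "ad_reference.json").write_text(json.dumps(ad))
    for i, m in enumerate(cm.models):
        (out / f"model_{i:03d}.json").write_text(json.dumps(_model_to_dict(m)))
    return out


def load_bundle(directory: str | Path) -> ConsensusModel:
    src = Path(directory)
    manifest = json.loads((src / "manifest.json").read_text())
    if manifest["schema_version"] != SCHEMA_VERSION:
        raise ValueError(f"unsupported bundle schema {manifest['schema_version']}")
    ad = json.loads((src / "ad_reference.json").read_text())
    models = [
        _model_from_dict(json.loads(p.read_text()))
        for p in sorted(src.glob("model_*.json"))
    ]
    cm = ConsensusModel(
        cell_line=manifest["cell_line"],
        endpoint=manifest["endpoint"],
        models=models,
        train_keys=tuple(ad["train_keys"]),
        train_fingerprints=tuple(frozenset(fp) for fp in ad["train_fingerprints"]),
        train_p_values=np.asarray(ad["train_p_values"], dtype=float),
        consensus_rmse=manifest["consensus_rmse"],
        seed=manifest["seed"],
    )
    cm.tissue = manifest.get("tissue", "")  # type: ignore[attr-defined]
    cm.tumor = manifest.get("tumor", False)  # type: ignore[attr-defined]
    return cm
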