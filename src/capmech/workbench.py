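"""Evaluation metrics and parameter-recovery studies.

Ties the other modules into reproducible experiments: generate a training
and a held-out test set, optionally degrade the test inputs by pushing them
through the camera raster + boundary-extraction chain at a chosen image
resolution, train the network, and score it with the mean absolute
percentage error (MAPE) of the predicted capillary numbers and a per-law
confusion table. Studies sweep the number of membrane nodes and the image
resolution, averaging over seeds, and keep the per-seed raw values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .membrane_laws import LAW_ORDER
from .profile_synthesis import (
    ALPHA_DEFAULT,
    BETA_DEFAULT,
    CA_GS_RANGE,
    CA_KS_RANGE,
    generate_dataset,
    rasterize,
    background_image,
)
from .boundary_extraction import extract_profile, to_feature_vector, profile_from_vector
from .mlp_engine import TrainingConfig, predict_batch, train

__all__ = ["mape", "confusion_counts", "EvaluationReport", "run_recovery_study",
           "roundtrip_vector", "StudyConfig"]


def mape(predicted: Sequence[float], truth: Sequence[float]) -> float:
    """Mean absolute percentage error, as a percentage.

    MAPE = (100/M) * sum_i |(y_true_i - y_pred_i) / y_true_i|.
    """
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("predicted and truth must be equal-length, non-empty")
    if np.any(t == 0):
        raise ValueError("truth values must be nonzero for a relative error")
    return float(100.0 * np.mean(np.abs((t - p) / t)))


def confusion_counts(true_idx: np.ndarray, pred_idx: np.ndarray) -> np.ndarray:
    """3x3 confusion counts, rows = true law, columns = predicted law."""
    cm = np.zeros((3, 3), dtype=int)
    for t, p in zip(true_idx, pred_idx):
        cm[t, p] += 1
    return cm


@dataclass
class StudyConfig:
    """Generation side of a recovery study (the study conditions)."""

    n_train: int = 400
    n_test: int = 100
    ca_ks_range: Tuple[float, float] = CA_KS_RANGE
    ca_gs_range: Tuple[float, float] = CA_GS_RANGE
    beta: float = BETA_DEFAULT
    alpha: float = ALPHA_DEFAULT
    noise_sd: float = 0.0


@dataclass
class EvaluationReport:
    """Per-cell, per-seed study results plus aggregates and the manifest."""

    table: pd.DataFrame
    confusions: Dict[str, np.ndarray]
    manifest: Dict

    def aggregate(self) -> pd.DataFrame:
        keys = ["n_nodes", "resolution"]
        return (self.table.groupby(keys, dropna=False)
                .agg(mape_ca_ks_mean=("mape_ca_ks", "mean"),
                     mape_ca_ks_sd=("mape_ca_ks", "std"),
                     mape_ca_gs_mean=("mape_ca_gs", "mean"),
                     mape_ca_gs_sd=("mape_ca_gs", "std"),
                     nh_recall_mean=("nh_recall", "mean"))
                .reset_index())

    def save(self, directory: Union[str, Path]) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(d / "study_raw.csv", index=False)
        self.aggregate().to_csv(d / "study_aggregate.csv", index=False)
        payload = dict(self.manifest)
        payload["confusions"] = {k: v.tolist() for k, v in self.confusions.items()}
        (d / "report.json").write_text(json.dumps(payload, indent=2))


def roundtrip_vector(
    vector: np.ndarray,
    resolution: float,
    n_nodes: int,
    beta: float = BETA_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    window_px: int = 9,
) -> np.ndarray:
    """Push a clean feature vector through the camera + extraction chain.

    Rasterises the profile at ``resolution`` pixels per undeformed capsule
    diameter, subtracts the matching empty-field frame, re-extracts the
    boundary and resamples ``n_nodes`` membrane nodes.
    """
    profile = profile_from_vector(vector)
    diam_tr = 2.0 * beta * (1.0 + alpha)
    img = rasterize(profile, resolution, capsule_diameter_tr=diam_tr)
    scale = resolution / diam_tr
    tube_diameter_px = int(round(2.0 * scale))
    prof2 = extract_profile(img, background_image(img), tube_diameter_px,
                            n_nodes=n_nodes, window_px=window_px)
    return to_feature_vector(prof2).values


def _evaluate_cell(
    study: StudyConfig,
    train_cfg: TrainingConfig,
    n_nodes: int,
    resolution: Optional[float],
    seed: int,
) -> Tuple[Dict, np.ndarray]:
    ss = np.random.SeedSequence(seed)
    train_seed, test_seed, net_seed = (int(s.generate_state(1)[0] % (2**31 - 1))
                                       for s in ss.spawn(3))
    ds_train = generate_dataset(
        study.n_train, study.ca_ks_range, study.ca_gs_range,
        beta=study.beta, alpha=study.alpha, n_nodes=n_nodes,
        noise_sd=study.noise_sd, seed=train_seed,
    )
    ds_test = generate_dataset(
        study.n_test, study.ca_ks_range, study.ca_gs_range,
        beta=study.beta, alpha=study.alpha, n_nodes=n_nodes,
        noise_sd=study.noise_sd, seed=test_seed,
    )
    cfg = TrainingConfig(**{**train_cfg.__dict__, "seed": net_seed})
    params = train(ds_train, cfg)

    X, z_true, y_true = ds_test.matrices()
    if resolution is not None:
        X = np.stack([
            roundtrip_vector(x, resolution, n_nodes, study.beta, study.alpha)
            for x in X
        ])
    probs, ca = predict_batch(params, X)
    z_pred = np.argmax(probs, axis=1)
    cm = confusion_counts(z_true, z_pred)
    nh = z_true == 0
    row = {
        "n_nodes": n_nodes,
        "resolution": resolution,
        "seed": seed,
        "mape_ca_ks": mape(ca[:, 0], y_true[:, 0]),
        "mape_ca_gs": mape(ca[:, 1], y_true[:, 1]),
        "nh_recall": float(np.mean(z_pred[nh] == 0)) if nh.any() else np.nan,
        "accuracy": float(np.mean(z_pred == z_true)),
        "epochs": params.manifest.get("epochs_run"),
    }
    return row, cm


def run_recovery_study(
    study: Optional[StudyConfig] = None,
    train_cfg: Optional[TrainingConfig] = None,
    node_counts: Sequence[int] = (60,),
    resolutions: Sequence[Optional[float]] = (None,),
    seeds: Sequence[int] = (0, 1, 2),
) -> EvaluationReport:
    """Parameter-recovery study over node counts, resolutions and seeds.

    ``resolutions`` entries of ``None`` feed the clean synthetic vectors to
    the network directly; numeric entries round-trip the test inputs through
    rasterisation and boundary extraction at that many pixels per undeformed
    capsule diameter.
    """
    study = study or StudyConfig()
    train_cfg = train_cfg or TrainingConfig()
    rows: List[Dict] = []
    confusions: Dict[str, np.ndarray] = {}
    for n_nodes in node_counts:
        for resolution in resolutions:
            for seed in seeds:
                row, cm = _evaluate_cell(study, train_cfg, n_nodes, resolution, seed)
                rows.append(row)
                confusions[f"nodes{n_nodes}_res{resolution}_seed{seed}"] = cm
    manifest = {
        "study": study.__dict__ | {
            "ca_ks_range": list(study.ca_ks_range),
            "ca_gs_range": list(study.ca_gs_range),
        },
        "train_cfg": {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in train_cfg.__dict__.items()},
        "node_counts": list(node_counts),
        "resolutions": [r for r in resolutions],
        "seeds": list(seeds),
        "law_order": [k.value for k in LAW_ORDER],
    }
    return EvaluationReport(table=pd.DataFrame(rows), confusions=confusions,
                            manifest=manifest)
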