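"""Layer scoring and architecture reduction ("GCS cut").

Score the representation every hidden layer of a trained sequential
classifier produces (geometric classification score of its activation
vectors), truncate the network right after the best-scoring layer,
attach a fresh multiclass softmax head, retrain, and report parameter
counts and test errors before/after.  Layers whose representation is
already maximally classifiable make everything after them redundant, so
cutting there removes parameters with little or no loss in accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .gcs import GCSConfig, gcs
from .nn import (
    LayerSpec,
    SequentialModel,
    TrainConfig,
    build_model,
    count_parameters,
    evaluate,
    layer_activations,
    train,
)

__all__ = [
    "CutReport",
    "layer_gcs_profile",
    "select_cut_layer",
    "cut_and_head",
    "prune_below_threshold",
    "gcs_cut_pipeline",
]


@dataclass
class CutReport:
    """Per-layer score profile, chosen cut, and before/after comparison."""

    profile: list
    scored_layers: list
    cut_index: int
    params_before: int
    params_after: int
    error_before: float
    error_after: float
    train_config: dict
    gcs_config: dict

    def to_dict(self) -> dict:
        return {
            "profile": [float(v) for v in self.profile],
            "scored_layers": [int(i) for i in self.scored_layers],
            "cut_index": int(self.cut_index),
            "params_before": int(self.params_before),
            "params_after": int(self.params_after),
            "error_before": float(self.error_before),
            "error_after": float(self.error_after),
            "train_config": self.train_config,
            "gcs_config": self.gcs_config,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def _default_scored_layers(model: SequentialModel) -> list[int]:
    """All hidden layers (everything except the terminal output layer)."""
    return list(range(len(model.layers) - 1))


def layer_gcs_profile(
    model: SequentialModel,
    x: np.ndarray,
    y: np.ndarray,
    gcs_config: GCSConfig | None = None,
    layer_subset: list[int] | None = None,
    sample_cap: int = 2000,
    seed: int = 0,
) -> list[float]:
    """Aggregate GCS of each scored layer's activation set, in layer order."""
    gcs_config = gcs_config or GCSConfig()
    subset = _default_scored_layers(model) if layer_subset is None else list(layer_subset)
    scores = []
    for li in subset:
        data = layer_activations(model, x, y, li, sample_cap=sample_cap, seed=seed)
        scores.append(gcs(data, gcs_config).aggregate)
    return scores


def select_cut_layer(profile: list[float]) -> int:
    """Position of the maximum score; ties break toward the earliest layer."""
    if len(profile) == 0:
        raise ValueError("empty profile")
    return int(np.argmax(profile))


def cut_and_head(
    model: SequentialModel, id_layer: int, num_classes: int, seed: int = 0
) -> SequentialModel:
    """Truncate after ``id_layer`` and attach a fresh softmax head.

    Layers ``0..id_layer`` keep their trained weights bitwise; a flatten
    layer is inserted if the cut output is not flat; the new dense
    softmax head is freshly initialized from ``seed``.
    """
    if not 0 <= id_layer < len(model.layers):
        raise IndexError(f"id_layer {id_layer} out of range 0..{len(model.layers) - 1}")
    kept_specs = list(model.specs[: id_layer + 1])
    specs = list(kept_specs)
    if len(model.layers[id_layer].out_shape) != 1:
        specs.append(LayerSpec(kind="flatten"))
    specs.append(LayerSpec(kind="dense", units=num_classes, activation="softmax"))
    new = build_model(specs, model.input_shape, seed=seed)
    kept_weights = [np.copy(p) for layer in model.layers[: id_layer + 1] for p in layer.params]
    head_weights = [np.copy(p) for layer in new.layers[len(kept_specs) :] for p in layer.params]
    new.set_weights(kept_weights + head_weights)
    return new


def prune_below_threshold(
    model: SequentialModel,
    profile: list[float],
    scored_layers: list[int],
    num_classes: int,
    frac: float = 0.9,
    seed: int = 0,
) -> SequentialModel:
    """Drop every scored layer below ``frac`` times the maximum score.

    Emulates multi-layer removal: surviving layers keep their trained
    weights only where their input shape still matches after the
    removals; mismatched layers are re-initialized (seeded).  The
    terminal softmax head is always replaced by a fresh one.
    """
    if not 0 < frac <= 1:
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    best = max(profile)
    drop = {
        li
        for li, s in zip(scored_layers, profile)
        if s < frac * best and model.specs[li].kind != "flatten"
    }
    specs = [s for i, s in enumerate(model.specs[:-1]) if i not in drop]
    if not any(s.kind == "flatten" for s in specs):
        specs.append(LayerSpec(kind="flatten"))
    specs.append(LayerSpec(kind="dense", units=num_classes, activation="softmax"))
    new = build_model(specs, model.input_shape, seed=seed)
    # transfer weights for surviving layers whose shapes still line up
    survivors = [i for i in range(len(model.specs) - 1) if i not in drop]
    for new_idx, old_idx in enumerate(survivors):
        old_layer = model.layers[old_idx]
        new_layer = new.layers[new_idx]
        if not old_layer.params:
            continue
        if all(p.shape == q.shape for p, q in zip(new_layer.params, old_layer.params)):
            for p, q in zip(new_layer.params, old_layer.params):
                p[...] = q
    return new


def gcs_cut_pipeline(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
    architecture: list[LayerSpec | dict],
    train_config: TrainConfig | None = None,
    gcs_config: GCSConfig | None = None,
    retrain_config: TrainConfig | None = None,
    sample_cap: int = 2000,
    freeze_retained: bool = False,
    seed: int = 0,
) -> tuple[CutReport, SequentialModel, SequentialModel]:
    """End-to-end architecture reduction.

    Train the full model, score every hidden layer, cut at the argmax,
    attach a fresh head, retrain the cut model (whole network by
    default; ``freeze_retained`` trains the head only), and evaluate
    both.  Returns ``(report, original_model, cut_model)``; every
    stochastic step derives from ``seed``.
    """
    train_config = train_config or TrainConfig(seed=seed)
    gcs_config = gcs_config or GCSConfig(seed=seed)
    retrain_config = retrain_config or train_config
    num_classes = int(np.unique(y_train).size)
    input_shape = np.asarray(x_train).shape[1:]

    model = build_model(architecture, input_shape, seed=seed)
    params_before = count_parameters(model)
    train(model, x_train, y_train, train_config)
    error_before = evaluate(model, x_test, y_test)

    scored = _default_scored_layers(model)
    profile = layer_gcs_profile(
        model, x_train, y_train, gcs_config, scored, sample_cap=sample_cap, seed=seed
    )
    cut_index = scored[select_cut_layer(profile)]

    cut_model = cut_and_head(model, cut_index, num_classes, seed=seed + 1)
    if freeze_retained:
        for layer in cut_model.layers[: cut_index + 1]:
            layer.trainable = False
    train(cut_model, x_train, y_train, retrain_config)
    error_after = evaluate(cut_model, x_test, y_test)

    report = CutReport(
        profile=profile,
        scored_layers=scored,
        cut_index=cut_index,
        params_before=params_before,
        params_after=count_parameters(cut_model),
        error_before=error_before,
        error_after=error_after,
        train_config={
            "epochs": train_config.epochs,
            "batch_size": train_config.batch_size,
            "learning_rate": train_config.learning_rate,
            "momentum": train_config.momentum,
            "seed": train_config.seed,
        },
        gcs_config={
            "radius": gcs_config.radius if isinstance(gcs_config.radius, str) else float(gcs_config.radius),
            "tolerance": gcs_config.tolerance,
            "normalize": gcs_config.normalize,
            "min_neighbors": gcs_config.min_neighbors,
            "auto_fraction": gcs_config.auto_fraction,
            "seed": gcs_config.seed,
        },
    )
    return report, model, cut_model
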