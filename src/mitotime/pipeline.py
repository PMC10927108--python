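"""High-level experiment pipeline: simulate -> train -> predict -> evaluate.

This is the programmatic counterpart of the command-line interface and the
entry point used by the reproduction script: it wires the synthetic
generator, the model builders, the training protocol and the evaluation
suite into one reproducible run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import silhouette_score

from .evaluation import (
    confusion,
    embed_pca,
    mask_iou,
    metrics,
    segment_by_threshold,
)
from .networks import (
    BackboneSpec,
    FrameSpec,
    build_base_model,
    build_frame_classifier,
    build_time_encoded_model,
    forward_sequence,
)
from .synthetic_mitosis import DatasetSplit, SimConfig, generate_dataset
from .training import TrainConfig, frames_to_input, predict_sequence, train

__all__ = [
    "build_model",
    "evaluate_on",
    "tracker_stats",
    "embedding_silhouette",
    "run_experiment",
    "ExperimentResult",
]


def build_model(kind: str, frame_spec: FrameSpec, n_class: int,
                reduced: bool = True, seed: int = 0):
    if kind == "time_encoded":
        bs = BackboneSpec.reduced() if reduced else BackboneSpec.full()
        return build_time_encoded_model(frame_spec, bs, n_class, seed=seed)
    if kind == "frame_classifier":
        channels = (8, 16, 32, 64) if reduced else (64, 128, 256, 512)
        return build_frame_classifier(frame_spec, n_class,
                                      stage_channels=channels, seed=seed)
    if kind == "base":
        channels = (8, 16, 32) if reduced else (16, 32, 64)
        return build_base_model(frame_spec, n_class, channels, seed=seed)
    raise ValueError(f"unknown model kind {kind!r}")


def evaluate_on(model, seqs) -> dict:
    """Pooled frame-to-frame evaluation over a list of sequences."""
    true = np.concatenate([s.labels for s in seqs])
    pred = np.concatenate([predict_sequence(model, s.frames) for s in seqs])
    cm = confusion(true, pred, model.n_class)
    rep = metrics(cm)
    return {"accuracy": rep.accuracy, "report": rep, "confusion": cm,
            "true": true, "pred": pred, "n_frames": len(true)}


def tracker_stats(model, seqs, threshold: float = 0.5) -> dict:
    """Tracking-decoder quality on test sequences.

    * ``iou``: mean IoU between the thresholded reconstruction and the
      center-cell mask over all frames.
    * ``suppression``: mean reconstructed intensity over non-target bright
      structures (distractors and the departing sister, identified as
      bright pixels outside the center-cell mask) divided by the mean over
      the center-cell footprint.  Small is good: the decoder should
      reconstruct only the tracked cell.
    """
    ious, fg_means, bg_means = [], [], []
    for seq in seqs:
        out = forward_sequence(model, frames_to_input(
            seq.frames, model.frame_spec.channels_in))
        tracks = out["tracks"]                     # (T, 3, H, W)
        intens = tracks.mean(axis=1)               # channel-mean, in (0,1)
        pred_masks = segment_by_threshold(tracks, threshold)
        for t in range(len(seq)):
            true_mask = seq.masks[t]
            ious.append(mask_iou(pred_masks[t], true_mask))
            distractor = (seq.frames[t] > 60) & ~true_mask
            if distractor.any():
                bg_means.append(intens[t][distractor].mean())
            fg_means.append(intens[t][true_mask].mean())
    fg = float(np.mean(fg_means))
    bg = float(np.mean(bg_means)) if bg_means else 0.0
    return {"iou": float(np.mean(ious)), "suppression": bg / max(fg, 1e-9),
            "center_intensity": fg, "distractor_intensity": bg}


def embedding_silhouette(model, seqs) -> float:
    """Silhouette score (by true stage) of the 3-PC projection of the
    model's per-frame embeddings."""
    embs, labels = [], []
    for seq in seqs:
        out = forward_sequence(model, frames_to_input(
            seq.frames, model.frame_spec.channels_in))
        embs.append(out["embeddings"])
        labels.append(seq.labels)
    proj = embed_pca(np.concatenate(embs), np.concatenate(labels))
    return float(silhouette_score(proj.components, proj.labels))


@dataclass
class ExperimentResult:
    split: DatasetSplit
    models: dict
    evaluations: dict
    histories: dict


def run_experiment(seed: int, sim_config: SimConfig | None = None,
                   model_kinds=("time_encoded", "frame_classifier"),
                   n_sequences: int = 70, reduced: bool = True,
                   epochs: int | None = None, log=None) -> ExperimentResult:
    """One seeded end-to-end run at the desk-scale study conditions.

    Generates ``n_sequences`` synthetic sequences (85/15 split), trains
    each requested model kind on the training split, and evaluates pooled
    frame accuracy on the held-out test split.  All randomness derives
    from ``seed``.
    """
    sim_config = sim_config or SimConfig.desk()
    split = generate_dataset(n_sequences, sim_config, seed=seed)
    frame_spec = FrameSpec(sim_config.frame_size, sim_config.frame_size, 3)
    n_class = sim_config.n_class
    models, evals, hists = {}, {}, {}
    for i, kind in enumerate(model_kinds):
        overrides = {} if epochs is None else {"epochs": epochs}
        tc = TrainConfig.desk(kind, n_class, seed=seed + 1, **overrides)
        model = build_model(kind, frame_spec, n_class, reduced=reduced,
                            seed=seed + 2 + i)
        model, hist = train(model, split, tc,
                            log=(lambda m, k=kind: log(f"[{k}] {m}")) if log else None)
        models[kind] = model
        hists[kind] = hist
        evals[kind] = evaluate_on(model, split.test)
    return ExperimentResult(split, models, evals, hists)
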