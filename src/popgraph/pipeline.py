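"""End-to-end orchestration and evaluation.

``run`` executes the whole workflow on a synthetic cohort: radiomics on
the structural volumes -> Fisher top-k -> stacked-autoencoder
embedding -> sqrt-cosine similarity graph; summary derivatives on the
functional volumes -> multichannel 3D CNN node features; then
semi-supervised GCN classification of the test-mask subjects.  A
manifest records every intermediate shape and seed so two runs with the
same config are bit-identical (single-threaded).

``metrics`` converts confusion counts to percent accuracy, sensitivity,
specificity and precision; a metric whose denominator is zero is
reported as None (undefined), never as 0.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import brain_summaries, cnn_encoder, feature_selection, fixtures, gcn
from .errors import ValidationError
from .graph_build import PopulationGraph, similarity_matrix, threshold_adjacency
from .radiomics import RadiomicsConfig, extract_subject
from .volume_io import LabelMap

__all__ = ["RunConfig", "ConfusionCounts", "run", "metrics", "confusion"]

logger = logging.getLogger("popgraph")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run on a synthetic cohort.

    Defaults are a miniature-but-faithful setting that exercises every
    stage in minutes on one CPU; the full-scale values from the model
    description (k=2000, 150-dim embedding, 1024 CNN features) are the
    component defaults and can be restored per stage.
    """

    fixture: fixtures.FixtureConfig = fixtures.FixtureConfig(
        grid_shape=(12, 14, 12),
        n_timepoints=60,
        n_regions_per_hemisphere=4,
        n_templates=4,
        effect_size=6.0,
        noise_sd=1.0,
    )
    n_subjects: int = 40
    class_balance: float = 0.5
    functional_effect: float = 10.0
    summary: brain_summaries.SummaryConfig = brain_summaries.SummaryConfig()
    radiomics: RadiomicsConfig = RadiomicsConfig()
    selection_k: int = 256
    sae_hidden: tuple[int, ...] = (128, 64, 32, 16)
    sae_epochs: int = 150
    cnn: cnn_encoder.CNNConfig | None = None  # derived from fixture if None
    cnn_dense_units: int = 32
    cnn_epochs: int = 40
    gcn: gcn.GCNConfig = gcn.GCNConfig(epochs=200)
    train_fraction: float = 0.8
    seed: int = 0
    randomize_node_features: bool = False  # ablation: destroys CNN signal


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Percent accuracy, sensitivity, specificity and precision.

    A zero denominator yields None for that metric.
    """
    if counts.total == 0:
        raise ValidationError("no evaluated nodes")

    def _pct(num: int, den: int) -> float | None:
        return 100.0 * num / den if den > 0 else None

    return {
        "accuracy": _pct(counts.tp + counts.tn, counts.total),
        "sensitivity": _pct(counts.tp, counts.tp + counts.fn),
        "specificity": _pct(counts.tn, counts.tn + counts.fp),
        "precision": _pct(counts.tp, counts.tp + counts.fp),
    }


def _stratified_split(
    labels: np.ndarray, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    n = labels.shape[0]
    train = np.zeros(n, dtype=bool)
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        rng.shuffle(idx)
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 2), idx.size - 1)  # keep both splits usable
        train[idx[:n_train]] = True
    return train, ~train


def run(config: RunConfig = RunConfig()) -> dict:
    """Execute the full workflow; returns a results bundle.

    The bundle holds the metrics, the population graph, per-subject
    predictions and a provenance manifest of shapes, seeds and timings.
    """
    manifest: dict = {"seed": config.seed, "stages": {}}

    def _stage(name: str):
        t0 = time.perf_counter()

        def _done(**shapes):
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3),
                **shapes,
            }
            logger.info("stage %s done: %s", name, shapes)

        return _done

    fx = fixtures.FixtureConfig(
        **{**vars(config.fixture), "seed": config.seed}
    )
    done = _stage("fixtures")
    atlas: LabelMap = fixtures.make_atlas(fx)
    subjects, labels = fixtures.make_cohort(
        fx,
        config.n_subjects,
        config.class_balance,
        functional_effect=config.functional_effect,
        atlas=atlas,
    )
    templates = fixtures.make_templates(fx)
    train_mask, test_mask = _stratified_split(
        labels, config.train_fraction, config.seed
    )
    done(
        n_subjects=len(subjects),
        n_regions=len(atlas.region_ids),
        n_templates=len(templates),
        n_train=int(train_mask.sum()),
    )

    # --- structural branch: radiomics -> Fisher -> SAE -> graph edges
    done = _stage("radiomics")
    X_rad = np.stack(
        [extract_subject(s.smri, atlas, config.radiomics).values for s in subjects]
    )
    done(radiomics_matrix=list(X_rad.shape))

    done = _stage("fisher_selection")
    k = min(config.selection_k, X_rad.shape[1])
    ranking = feature_selection.fisher_score(X_rad[train_mask], labels[train_mask])
    _, kept = feature_selection.select_top_k(ranking, X_rad[train_mask], k)
    X_sel = X_rad[:, kept]
    done(selection_k=k, kept_indices=int(kept.size))

    done = _stage("sae_embedding")
    sae_sizes = (k,) + tuple(config.sae_hidden)
    sae = feature_selection.sae_fit(
        X_sel[train_mask],
        seed=config.seed,
        epochs=config.sae_epochs,
        layer_sizes=sae_sizes,
    )
    E = feature_selection.sae_encode(sae, X_sel)
    done(embedding=list(E.shape), embedding_dim=E.shape[1])

    done = _stage("similarity_graph")
    sim = similarity_matrix(E)
    adjacency = threshold_adjacency(sim)
    done(
        threshold=round(sim.threshold, 6),
        min_degree=int(adjacency.sum(axis=1).min()),
    )

    # --- functional branch: summaries -> CNN node features
    done = _stage("summaries")
    stacks = [
        brain_summaries.compute_all(s.fmri, templates, config.summary)
        for s in subjects
    ]
    done(
        stack_shape=list(stacks[0].data.shape),
        n_channels=stacks[0].n_channels,
    )

    done = _stage("cnn_features")
    cnn_cfg = config.cnn or cnn_encoder.CNNConfig(
        input_shape=tuple(fx.grid_shape) + (stacks[0].n_channels,),
        first_block_filters=8,
        repeated_blocks=1,
        repeated_start_filters=16,
        dense_units=config.cnn_dense_units,
        dropout=0.2,
        epochs=config.cnn_epochs,
        learning_rate=3e-3,
        seed=config.seed,
    )
    model = cnn_encoder.build_model(cnn_cfg)
    model = cnn_encoder.train(
        model,
        [stacks[i] for i in np.nonzero(train_mask)[0]],
        labels[train_mask],
    )
    node_features = cnn_encoder.encode(
        model, stacks, [s.subject_id for s in subjects]
    ).values
    if config.randomize_node_features:
        rng = np.random.default_rng(config.seed + 99)
        node_features = rng.standard_normal(node_features.shape)
    done(node_features=list(node_features.shape), cnn_feature_width=node_features.shape[1])

    # --- population graph + GCN
    done = _stage("gcn")
    graph = PopulationGraph(
        adjacency=adjacency,
        node_features=node_features,
        labels=labels,
        train_mask=train_mask,
        test_mask=test_mask,
        similarity=sim,
        subject_ids=[s.subject_id for s in subjects],
    )
    gcn_cfg = gcn.GCNConfig(**{**vars(config.gcn), "seed": config.seed})
    weights, log = gcn.fit(graph, gcn_cfg)
    predictions, probabilities = gcn.predict(graph, weights, gcn_cfg)
    counts = confusion(labels[test_mask], predictions[test_mask])
    result_metrics = metrics(counts)
    done(
        test_nodes=int(test_mask.sum()),
        final_train_loss=round(log["loss"][-1], 6),
    )

    manifest["widths"] = {
        "selection_k": k,
        "embedding_dim": E.shape[1],
        "cnn_feature_width": node_features.shape[1],
    }
    return {
        "metrics": result_metrics,
        "confusion": counts,
        "graph": graph,
        "predictions": predictions,
        "probabilities": probabilities,
        "labels": labels,
        "test_mask": test_mask,
        "manifest": manifest,
        "gcn_log": log,
    }
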