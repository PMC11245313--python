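"""Training protocol, metrics, multi-seed aggregation, and robustness.

Models are trained with the class-weighted binary cross-entropy loss
and Adam, optionally with random-rotation augmentation of each
molecule's coordinates.  The main benchmarking metric is Matthews'
correlation coefficient (MCC), suited to the heavy class imbalance of
interface prediction; AUC ROC and AUC PR are reported alongside, and
every headline number is aggregated across random seeds.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import special_ortho_group, wasserstein_distance
from sklearn.metrics import (
    average_precision_score,
    matthews_corrcoef,
    roc_auc_score,
)

from .nn import Adam, Tensor
from .types import ComplexSample, ResidueGraph, SurfaceBundle

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "weighted_bce",
    "augment_rotation",
    "train_model",
    "perturb_sample",
    "evaluate",
    "ensemble_combine",
    "aggregate_seeds",
    "metric_shift",
]

_EPS = 1e-7


@dataclass
class TrainConfig:
    lr: float = 1e-3
    epochs: int = 10
    class_weight: str = "global"  # or "batch"
    augment: bool = False
    seeds: list[int] = field(default_factory=lambda: [0, 1, 2, 3, 4])
    weight_decay: float = 0.0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if not self.seeds:
            raise ValueError("at least one seed is required")


@dataclass
class MetricsReport:
    """MCC / AUC ROC / AUC PR for one molecule side of one evaluation."""

    mcc: float
    auc_roc: float
    auc_pr: float
    single_class: bool = False  # labels had only one class; AUCs undefined


def _pos_weight(labels: np.ndarray) -> float:
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return 1.0
    return float(n_neg) / float(n_pos)


def weighted_bce(
    probs: Tensor | np.ndarray,
    labels: np.ndarray,
    weighting: str = "batch",
    global_pos_weight: float | None = None,
) -> Tensor:
    """Class-weighted binary cross-entropy, mean reduction.

    The positive-class term is weighted by w_pos = N_neg / N_pos,
    computed over the batch (``weighting="batch"``) or supplied from
    dataset-level counts (``weighting="global"``).  A single-class batch
    in batch mode falls back to the global weight with a warning.
    """
    y = np.asarray(labels, dtype=float).reshape(-1)
    if weighting == "batch":
        if 0 < y.sum() < y.size:
            w_pos = _pos_weight(y)
        else:
            warnings.warn(
                "single-class batch: falling back to global class weight",
                stacklevel=2,
            )
            w_pos = global_pos_weight if global_pos_weight is not None else 1.0
    elif weighting == "global":
        w_pos = global_pos_weight if global_pos_weight is not None else 1.0
    else:
        raise ValueError(f"unknown weighting mode {weighting!r}")

    p = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs, float))
    # affine squash into [eps, 1-eps]: keeps gradients alive even when a
    # sigmoid has saturated to exactly 0 or 1 in floating point
    p = p.reshape(-1) * (1.0 - 2.0 * _EPS) + _EPS
    w = Tensor(np.where(y > 0.5, w_pos, 1.0))
    yk = Tensor(y)
    ll = yk * p.log() + (1.0 - yk) * (1.0 - p).log()
    return -(w * ll).mean()


def _rotate(coords: np.ndarray, rot: np.ndarray) -> np.ndarray:
    center = coords.mean(axis=0)
    return (coords - center) @ rot.T + center


def augment_rotation(sample: ComplexSample, seed: int) -> ComplexSample:
    """Apply an independent Haar-uniform random rotation to each molecule.

    Graph node coordinates and surface points rotate together (about the
    molecule's centroid); features, labels, topology, and the intrinsic
    spectral quantities are untouched.
    """
    rng = np.random.default_rng(seed)
    rot_ab = special_ortho_group.rvs(3, random_state=rng)
    rot_ag = special_ortho_group.rvs(3, random_state=rng)

    def rot_graph(g: ResidueGraph, rot: np.ndarray) -> ResidueGraph:
        return ResidueGraph(
            node_coords=_rotate(g.node_coords, rot),
            node_features=g.node_features,
            edges=g.edges,
            residue_keys=g.residue_keys,
        )

    def rot_surface(s: SurfaceBundle, rot: np.ndarray) -> SurfaceBundle:
        return SurfaceBundle(
            points=_rotate(s.points, rot),
            faces=s.faces,
            point_features=s.point_features,
            point_to_residue=s.point_to_residue,
        )

    return replace(
        sample,
        ab_graph=rot_graph(sample.ab_graph, rot_ab),
        ag_graph=rot_graph(sample.ag_graph, rot_ag),
        ab_surface=rot_surface(sample.ab_surface, rot_ab),
        ag_surface=rot_surface(sample.ag_surface, rot_ag),
    )


def perturb_sample(sample: ComplexSample, sigma: float, seed: int) -> ComplexSample:
    """Gaussian coordinate perturbation emulating conformational change
    or reconstruction error.

    Residue and surface coordinates are jittered with independent
    N(0, sigma^2) noise per axis; the residue graph, spectral basis and
    HKS are rebuilt from the perturbed geometry, while binding labels
    keep their native-complex ground truth.  Used to measure how far a
    model's performance distribution shifts under structural variation.
    """
    from .representations import build_residue_graph
    from .spectral import compute_basis, compute_hks

    rng = np.random.default_rng(seed)

    def jitter_graph(g: ResidueGraph) -> ResidueGraph:
        coords = g.node_coords + rng.normal(0, sigma, g.node_coords.shape)
        return ResidueGraph(
            node_coords=coords,
            node_features=g.node_features,
            edges=build_residue_graph(coords),
            residue_keys=g.residue_keys,
        )

    def jitter_surface(s: SurfaceBundle) -> SurfaceBundle:
        return SurfaceBundle(
            points=s.points + rng.normal(0, sigma, s.points.shape),
            faces=s.faces,
            point_features=s.point_features,
            point_to_residue=s.point_to_residue,
        )

    ab_surface = jitter_surface(sample.ab_surface)
    ag_surface = jitter_surface(sample.ag_surface)
    k_ab = sample.ab_basis.evals.size if sample.ab_basis is not None else 32
    k_ag = sample.ag_basis.evals.size if sample.ag_basis is not None else 32
    ab_basis = compute_basis(ab_surface.points, k=k_ab)
    ag_basis = compute_basis(ag_surface.points, k=k_ag)
    n_scales = sample.ab_hks.shape[1] if sample.ab_hks is not None else 16
    from .spectral import HKSConfig

    hks_cfg = HKSConfig(num_scales=n_scales)
    return replace(
        sample,
        ab_graph=jitter_graph(sample.ab_graph),
        ag_graph=jitter_graph(sample.ag_graph),
        ab_surface=ab_surface,
        ag_surface=ag_surface,
        ab_basis=ab_basis,
        ag_basis=ag_basis,
        ab_hks=compute_hks(ab_basis, hks_cfg),
        ag_hks=compute_hks(ag_basis, hks_cfg),
    )


def dataset_pos_weights(samples: list[ComplexSample]) -> dict[str, float]:
    """Dataset-level N_neg/N_pos per molecule side."""
    ab = np.concatenate(
        [s.ab_labels.per_residue[s.cdr_mask] for s in samples]
    )
    ag = np.concatenate([s.ag_labels.per_residue for s in samples])
    return {"antibody": _pos_weight(ab), "antigen": _pos_weight(ag)}


def train_model(
    model_builder,
    train_samples: list[ComplexSample],
    val_samples: list[ComplexSample] | None,
    config: TrainConfig,
):
    """Train one model per seed; keep the best-validation-MCC checkpoint.

    ``model_builder()`` must return a fresh model exposing
    ``forward_sample(sample) -> dict`` with probability Tensors and
    matching label arrays, plus the ``Module`` train/eval interface.
    Without a validation set the final epoch's weights are kept.

    Returns the best model of the first seed and a history dict with
    per-seed, per-epoch losses and validation metrics.
    """
    if not train_samples:
        raise ValueError("empty training set")
    pos_w = dataset_pos_weights(train_samples)
    history: dict = {"seeds": {}, "config": config}
    best_model = None
    for seed in config.seeds:
        rng = np.random.default_rng(seed)
        model = model_builder()
        opt = Adam(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
        epoch_log = []
        best_mcc, best_state = -np.inf, None
        for epoch in range(config.epochs):
            model.train()
            order = rng.permutation(len(train_samples))
            total_loss = 0.0
            for i in order:
                s = train_samples[i]
                if config.augment:
                    s = augment_rotation(s, int(rng.integers(2**31 - 1)))
                out = model.forward_sample(s)
                loss = weighted_bce(
                    out["ab_probs"], out["ab_labels"], config.class_weight,
                    pos_w["antibody"],
                ) + weighted_bce(
                    out["ag_probs"], out["ag_labels"], config.class_weight,
                    pos_w["antigen"],
                )
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, sample {s.sample_id}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                total_loss += float(loss.data)
            entry = {"epoch": epoch, "loss": total_loss / len(train_samples)}
            if val_samples:
                rep = evaluate_model(model, val_samples)
                val_mcc = 0.5 * (rep["antibody"].mcc + rep["antigen"].mcc)
                entry["val_mcc"] = val_mcc
                if val_mcc > best_mcc:
                    best_mcc = val_mcc
                    best_state = [a.copy() for a in model.state_arrays()]
            epoch_log.append(entry)
            logger.debug("seed %d epoch %d: %s", seed, epoch, entry)
        if best_state is not None:
            model.load_state_arrays(best_state)
        history["seeds"][seed] = epoch_log
        if best_model is None:
            best_model = model
    best_model.eval()
    return best_model, history


def _collect_predictions(model, samples: list[ComplexSample]):
    """Pooled per-residue probabilities and labels over a sample list."""
    model.eval()
    probs = {"antibody": [], "antigen": []}
    labels = {"antibody": [], "antigen": []}
    for s in samples:
        if hasattr(model, "predict_residue_probs"):
            p = model.predict_residue_probs(s)
            ab_p, ag_p = p["antibody"], p["antigen"]
            ab_y = s.ab_labels.per_residue
            ag_y = s.ag_labels.per_residue
        else:
            out = model.forward_sample(s)
            ab_p, ag_p = out["ab_probs"].data, out["ag_probs"].data
            ab_y, ag_y = out["ab_labels"], out["ag_labels"]
        probs["antibody"].append(ab_p)
        probs["antigen"].append(ag_p)
        labels["antibody"].append(ab_y)
        labels["antigen"].append(ag_y)
    return (
        {k: np.concatenate(v) for k, v in probs.items()},
        {k: np.concatenate(v) for k, v in labels.items()},
    )


def evaluate_model(model, samples: list[ComplexSample]) -> dict[str, MetricsReport]:
    probs, labels = _collect_predictions(model, samples)
    return {
        side: evaluate(probs[side], labels[side]) for side in ("antibody", "antigen")
    }


def evaluate(
    per_residue_probs: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
) -> MetricsReport:
    """MCC at the given threshold plus threshold-free AUC ROC / AUC PR.

    Single-class label sets get MCC 0 with ``single_class=True`` and
    NaN AUCs (undefined).
    """
    p = np.asarray(per_residue_probs, dtype=float).reshape(-1)
    y = np.asarray(labels).reshape(-1).astype(int)
    if y.min() == y.max():
        return MetricsReport(mcc=0.0, auc_roc=np.nan, auc_pr=np.nan, single_class=True)
    pred = (p >= threshold).astype(int)
    return MetricsReport(
        mcc=float(matthews_corrcoef(y, pred)),
        auc_roc=float(roc_auc_score(y, p)),
        auc_pr=float(average_precision_score(y, p)),
    )


def ensemble_combine(
    probs_igep: np.ndarray | dict,
    probs_ogep: np.ndarray | dict,
    mode: str = "mean",
) -> np.ndarray | dict:
    """Combine graph- and surface-model predictions per residue.

    ``mode`` is "mean" or "product".  Dict inputs (side -> array) are
    combined per key; arrays must align elementwise.
    """
    if isinstance(probs_igep, dict) != isinstance(probs_ogep, dict):
        raise ValueError("cannot align a dict of predictions with a bare array")
    if isinstance(probs_igep, dict):
        if set(probs_igep) != set(probs_ogep):
            raise ValueError(
                f"prediction keys differ: {sorted(probs_igep)} vs {sorted(probs_ogep)}"
            )
        return {
            k: ensemble_combine(probs_igep[k], probs_ogep[k], mode) for k in probs_igep
        }
    a = np.asarray(probs_igep, dtype=float)
    b = np.asarray(probs_ogep, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"prediction shapes differ: {a.shape} vs {b.shape}")
    if mode == "mean":
        return 0.5 * (a + b)
    if mode == "product":
        return a * b
    raise ValueError(f"unknown ensemble mode {mode!r}")


def aggregate_seeds(reports: list[MetricsReport]) -> dict[str, float]:
    """Mean and standard deviation of each metric across seeds."""
    if not reports:
        raise ValueError("no reports to aggregate")
    out: dict[str, float] = {}
    for name in ("mcc", "auc_roc", "auc_pr"):
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        out[f"{name}_mean"] = float(np.mean(vals))
        out[f"{name}_std"] = float(np.std(vals))
    return out


def metric_shift(dist_a: np.ndarray, dist_b: np.ndarray) -> float:
    """1D Wasserstein distance between two per-complex metric samples.

    Used to quantify how much a model's performance distribution moves
    when structures are perturbed (conformational change, reconstruction
    error): smaller shift = more robust model.
    """
    a = np.asarray(dist_a, dtype=float).reshape(-1)
    b = np.asarray(dist_b, dtype=float).reshape(-1)
    if a.size == 0 or b.size == 0:
        raise ValueError("both distributions must be nonempty")
    return float(wasserstein_distance(a, b))
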