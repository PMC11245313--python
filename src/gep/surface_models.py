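"""Outer-structure (surface) models for epitope/paratope prediction.

A geometric module turns per-point surface features into a local
per-point representation and a pooled global protein vector.  Two
variants exist: a PointNet-style module (spatial transformer + shared
per-point MLP + max pooling) and a diffusion module that propagates
features across the surface through learned-time spectral heat
diffusion, which works identically on meshes and raw point clouds.
A segmentation module — a stack of width-1 convolutions (pointwise
MLP) shared between the two molecules — combines each point's local
features with both proteins' global vectors and emits a per-point
binding probability, which is averaged per residue afterwards.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .nn import Tensor
from .spectral import HKSConfig
from .types import ComplexSample, SpectralBasis, SurfaceBundle

__all__ = [
    "OgepConfig",
    "SurfaceFeatures",
    "assemble_input_features",
    "PointNetGeometric",
    "DiffusionGeometric",
    "SegmentationModule",
    "OGepModel",
    "OGepClassifier",
    "surface_to_residue",
]


@dataclass
class OgepConfig:
    geometric_variant: str = "diffnet"  # or "pointnet"
    local_dim: int = 48
    global_dim: int = 64
    n_diffusion_blocks: int = 4
    use_physchem: bool = True
    use_xyz: bool = False
    use_hks: bool = True
    hks: HKSConfig = field(default_factory=HKSConfig)
    representation: str = "point_cloud"  # or "mesh"

    def __post_init__(self) -> None:
        if self.geometric_variant not in ("pointnet", "diffnet"):
            raise ValueError(f"unknown geometric variant {self.geometric_variant!r}")
        if not (self.use_physchem or self.use_xyz or self.use_hks):
            raise ValueError("at least one input channel must be enabled")

    @property
    def input_dim(self) -> int:
        return (
            (28 if self.use_physchem else 0)
            + (3 if self.use_xyz else 0)
            + (self.hks.num_scales if self.use_hks else 0)
        )


@dataclass
class SurfaceFeatures:
    local: Tensor  # (P, local_dim)
    global_: Tensor  # (global_dim,)


def assemble_input_features(
    bundle: SurfaceBundle, config: OgepConfig, hks: np.ndarray | None = None
) -> np.ndarray:
    """Fixed-order concatenation [physicochemical | xyz | HKS] per point.

    Coordinates are centered per molecule; HKS channels are intrinsic,
    so an HKS-only input is rigid-motion invariant.
    """
    parts: list[np.ndarray] = []
    if config.use_physchem:
        parts.append(bundle.point_features)
    if config.use_xyz:
        centered = bundle.points - bundle.points.mean(axis=0)
        # unit-RMS-radius canonicalization keeps activations well scaled
        # across proteins of different size
        rms = np.sqrt(np.mean(np.sum(centered**2, axis=1)))
        parts.append(centered / max(rms, 1e-12))
    if config.use_hks:
        if hks is None:
            raise ValueError("use_hks set but no HKS channels supplied")
        if hks.shape[1] != config.hks.num_scales:
            raise ValueError(
                f"HKS has {hks.shape[1]} scales, config expects {config.hks.num_scales}"
            )
        parts.append(hks)
    return np.concatenate(parts, axis=1)


class _TNet(nn.Module):
    """Spatial transformer: predicts a (d x d) correction to identity."""

    def __init__(self, rng: np.random.Generator, d: int, hidden: int = 32):
        super().__init__()
        self.mlp = nn.MLP(rng, [d, hidden, hidden])
        self.head = nn.Linear(rng, hidden, d * d)
        self.head.weight.data[:] = 0.0  # start at the identity transform
        self.d = d

    def __call__(self, x: Tensor) -> Tensor:
        pooled = self.mlp(x).max(axis=0)
        mat = self.head(pooled.reshape(1, -1)).reshape(self.d, self.d)
        return mat + Tensor(np.eye(self.d))


class PointNetGeometric(nn.Module):
    """Shared per-point MLP with input/feature transforms and max pooling."""

    def __init__(self, rng: np.random.Generator, config: OgepConfig):
        super().__init__()
        self.config = config
        self.input_tnet = _TNet(rng, 3) if config.use_xyz else None
        self.mlp1 = nn.MLP(rng, [config.input_dim, 64, config.local_dim])
        self.feature_tnet = _TNet(rng, config.local_dim)
        self.mlp2 = nn.MLP(rng, [config.local_dim, 64, config.global_dim])

    def __call__(self, inputs: np.ndarray, basis: SpectralBasis | None = None) -> SurfaceFeatures:
        if inputs.shape[0] < 2:
            raise ValueError("need at least 2 surface points")
        x = Tensor(np.asarray(inputs, dtype=float))
        if self.input_tnet is not None:
            # xyz channels sit right after the physicochemical block
            lo = 28 if self.config.use_physchem else 0
            xyz = Tensor(x.data[:, lo : lo + 3])
            xyz_t = xyz @ self.input_tnet(xyz)
            cols = [Tensor(x.data[:, :lo]), xyz_t, Tensor(x.data[:, lo + 3 :])]
            x = nn.concat([c for c in cols if c.data.shape[1]], axis=1)
        h = self.mlp1(x).relu()
        h = h @ self.feature_tnet(h)
        local = h
        global_ = self.mlp2(local.relu()).max(axis=0)
        return SurfaceFeatures(local=local, global_=global_)


class _DiffusionBlock(nn.Module):
    """Learned per-channel heat diffusion + pointwise MLP with residual."""

    def __init__(self, rng: np.random.Generator, width: int, t_init: float = 0.1):
        super().__init__()
        # softplus(raw) = t, initialized at t_init for every channel
        raw0 = np.log(np.expm1(t_init))
        self.raw_times = nn.Parameter(np.full(width, raw0))
        self.mlp = nn.MLP(rng, [2 * width, width, width])

    def times(self) -> Tensor:
        return self.raw_times.softplus()

    def __call__(self, x: Tensor, basis: SpectralBasis) -> Tensor:
        phi_t_m = Tensor(basis.evecs.T * basis.mass[None, :])  # (K, P)
        coeff = phi_t_m @ x  # (K, C)
        decay = (-(Tensor(basis.evals.reshape(-1, 1)) * self.times().reshape(1, -1))).exp()
        diffused = Tensor(basis.evecs) @ (coeff * decay)  # (P, C)
        return x + self.mlp(nn.concat([x, diffused], axis=1))


class DiffusionGeometric(nn.Module):
    """Diffusion-based geometric module.

    The first MLP lifts inputs to ``local_dim`` channels; the diffusion
    block is applied once for the local representation and ``n`` times
    for the global one, which is then mass-weighted mean-pooled.
    """

    def __init__(self, rng: np.random.Generator, config: OgepConfig):
        super().__init__()
        self.config = config
        w = config.local_dim
        self.lift = nn.MLP(rng, [config.input_dim, w, w])
        self.blocks = [
            _DiffusionBlock(rng, w) for _ in range(config.n_diffusion_blocks)
        ]
        self.global_proj = nn.Linear(rng, w, config.global_dim)

    def __call__(self, inputs: np.ndarray, basis: SpectralBasis) -> SurfaceFeatures:
        if basis.evecs.shape[0] != inputs.shape[0]:
            raise ValueError("spectral basis and input point count disagree")
        x = self.lift(Tensor(np.asarray(inputs, dtype=float)))
        local = self.blocks[0](x, basis)
        h = local
        for block in self.blocks[1:]:
            h = block(h, basis)
        weights = Tensor((basis.mass / basis.mass.sum()).reshape(1, -1))
        global_ = (weights @ self.global_proj(h)).reshape(-1)
        return SurfaceFeatures(local=local, global_=global_)


class SegmentationModule(nn.Module):
    """Shared pointwise (width-1 convolution) stack ending in a sigmoid."""

    def __init__(self, rng: np.random.Generator, config: OgepConfig):
        super().__init__()
        d_in = config.local_dim + 2 * config.global_dim
        self.mlp = nn.MLP(rng, [d_in, 64, 32, 1])

    def __call__(self, feats: SurfaceFeatures, partner: SurfaceFeatures) -> Tensor:
        p = feats.local.shape[0]
        tile = np.zeros(p, dtype=int)
        g_self = nn.gather(feats.global_.reshape(1, -1), tile)
        g_partner = nn.gather(partner.global_.reshape(1, -1), tile)
        x = nn.concat([feats.local, g_self, g_partner], axis=1)
        return self.mlp(x).sigmoid().reshape(-1)


def surface_to_residue(
    per_point_probs: np.ndarray,
    point_to_residue: np.ndarray,
    n_residues: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Average per-point probabilities over each residue's surface points.

    Residues with no surface points (buried) get probability 0.0 and are
    flagged so evaluation may exclude them.

    Returns
    -------
    probs : (R,) float array in [0, 1]
    buried : (R,) bool array, True where a residue had no points
    """
    p2r = np.asarray(point_to_residue, dtype=int)
    counts = np.bincount(p2r, minlength=n_residues).astype(float)
    sums = np.bincount(p2r, weights=np.asarray(per_point_probs, float), minlength=n_residues)
    buried = counts == 0
    probs = np.where(buried, 0.0, sums / np.maximum(counts, 1.0))
    return probs, buried


class OGepModel(nn.Module):
    """Geometric module (shared between molecules) + shared segmentation."""

    def __init__(self, config: OgepConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        cls = PointNetGeometric if config.geometric_variant == "pointnet" else DiffusionGeometric
        self.geometric = cls(rng, config)
        self.segmentation = SegmentationModule(rng, config)

    def forward_surfaces(
        self,
        ab_inputs: np.ndarray,
        ag_inputs: np.ndarray,
        ab_basis: SpectralBasis | None = None,
        ag_basis: SpectralBasis | None = None,
    ) -> tuple[Tensor, Tensor]:
        """Per-point binding probabilities for antibody and antigen."""
        f_ab = self.geometric(ab_inputs, ab_basis)
        f_ag = self.geometric(ag_inputs, ag_basis)
        p_ab = self.segmentation(f_ab, f_ag)
        p_ag = self.segmentation(f_ag, f_ab)
        return p_ab, p_ag

    def forward_sample(self, sample: ComplexSample) -> dict:
        cfg = self.config
        ab_in = assemble_input_features(sample.ab_surface, cfg, sample.ab_hks)
        ag_in = assemble_input_features(sample.ag_surface, cfg, sample.ag_hks)
        if cfg.geometric_variant == "diffnet" and (
            sample.ab_basis is None or sample.ag_basis is None
        ):
            raise ValueError("diffusion variant requires precomputed spectral bases")
        p_ab, p_ag = self.forward_surfaces(
            ab_in, ag_in, sample.ab_basis, sample.ag_basis
        )
        # point-level labels: each point inherits its residue's label
        ab_pt_labels = sample.ab_labels.per_residue[sample.ab_surface.point_to_residue]
        ag_pt_labels = sample.ag_labels.per_residue[sample.ag_surface.point_to_residue]
        return {
            "ab_probs": p_ab,
            "ag_probs": p_ag,
            "ab_labels": ab_pt_labels,
            "ag_labels": ag_pt_labels,
        }

    def predict_residue_probs(self, sample: ComplexSample) -> dict[str, np.ndarray]:
        """Inference: per-point probabilities averaged back to residues."""
        r = self.forward_sample(sample)
        ab, _ = surface_to_residue(
            r["ab_probs"].data,
            sample.ab_surface.point_to_residue,
            sample.ab_graph.n_nodes,
        )
        ag, _ = surface_to_residue(
            r["ag_probs"].data,
            sample.ag_surface.point_to_residue,
            sample.ag_graph.n_nodes,
        )
        return {"antibody": ab, "antigen": ag}


class OGepClassifier(BaseEstimator):
    """Sklearn-style estimator for the surface-based models.

    Trains on per-point labels (each surface point inherits the
    interface label of its residue) and predicts per-residue
    probabilities by averaging point probabilities within residues.
    """

    def __init__(
        self,
        geometric_variant: str = "diffnet",
        local_dim: int = 48,
        global_dim: int = 64,
        n_diffusion_blocks: int = 4,
        use_physchem: bool = True,
        use_xyz: bool = False,
        use_hks: bool = True,
        lr: float = 5e-3,
        epochs: int = 10,
        class_weight: str = "global",
        augment: bool = False,
        seed: int = 0,
    ):
        self.geometric_variant = geometric_variant
        self.local_dim = local_dim
        self.global_dim = global_dim
        self.n_diffusion_blocks = n_diffusion_blocks
        self.use_physchem = use_physchem
        self.use_xyz = use_xyz
        self.use_hks = use_hks
        self.lr = lr
        self.epochs = epochs
        self.class_weight = class_weight
        self.augment = augment
        self.seed = seed

    def _config(self) -> OgepConfig:
        return OgepConfig(
            geometric_variant=self.geometric_variant,
            local_dim=self.local_dim,
            global_dim=self.global_dim,
            n_diffusion_blocks=self.n_diffusion_blocks,
            use_physchem=self.use_physchem,
            use_xyz=self.use_xyz,
            use_hks=self.use_hks,
        )

    def _build(self) -> OGepModel:
        return OGepModel(self._config(), seed=self.seed)

    def fit(self, X: list[ComplexSample], y=None, validation: list[ComplexSample] | None = None):
        from .training import TrainConfig, train_model

        cfg = TrainConfig(
            lr=self.lr,
            epochs=self.epochs,
            class_weight=self.class_weight,
            augment=self.augment,
            seeds=[self.seed],
        )
        self.model_, self.history_ = train_model(self._build, X, validation, cfg)
        self.n_features_in_ = self._config().input_dim
        return self

    def predict_proba(self, X: list[ComplexSample]) -> list[dict[str, np.ndarray]]:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        self.model_.eval()
        return [self.model_.predict_residue_probs(s) for s in X]

    def predict(self, X: list[ComplexSample], threshold: float = 0.5):
        return [
            {k: (v >= threshold).astype(int) for k, v in p.items()}
            for p in self.predict_proba(X)
        ]
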