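"""Inner-structure (residue graph) models for epitope/paratope prediction.

Each molecule's residue graph passes through a structural encoder — a
graph convolution over features that include the centered 3D residue
coordinates, or an E(n)-invariant message-passing layer that sees only
inter-residue distances — after which antibody and antigen exchange
information through a two-layer bipartite graph attention (GAT) fusion.
Per-residue binding probabilities come from a fully connected head over
the concatenated structural and attention embeddings.

The E(n)-invariant variant is, by construction, invariant to
translations, rotations, and reflections applied independently to
either molecule; the coordinate variant is only translation-invariant
(coordinates are centered per molecule).
"""
from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .nn import Tensor
from .types import ComplexSample, ResidueGraph

__all__ = [
    "IgepConfig",
    "normalized_adjacency",
    "GCNStructural",
    "EnInvariantLayer",
    "BipartiteGAT",
    "IGepModel",
    "IGepClassifier",
]

from dataclasses import dataclass


@dataclass
class IgepConfig:
    variant: str = "en_invariant"  # or "gcn_xyz"
    hidden_dim: int = 32
    gat_heads: int = 4
    dropout: float = 0.1
    feature_dim: int = 28

    def __post_init__(self) -> None:
        if self.variant not in ("gcn_xyz", "en_invariant"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def normalized_adjacency(n: int, edges: np.ndarray) -> np.ndarray:
    """Symmetric-normalized adjacency with self-loops, D^-1/2 (A+I) D^-1/2."""
    A = np.eye(n)
    if len(edges):
        A[edges[:, 0], edges[:, 1]] = 1.0
    d = A.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return A * dinv[:, None] * dinv[None, :]


def _elu(x: Tensor) -> Tensor:
    return x.relu() + ((-((-x).relu())).exp() - 1.0)


class GCNStructural(nn.Module):
    """One graph-convolution layer + batch norm + ReLU + dropout.

    Input features are the 28-dim physicochemical vectors concatenated
    with the molecule-centered 3D residue coordinates.
    """

    def __init__(self, rng: np.random.Generator, config: IgepConfig):
        super().__init__()
        in_dim = config.feature_dim + 3
        self.lin = nn.Linear(rng, in_dim, config.hidden_dim)
        self.bn = nn.BatchNorm(config.hidden_dim)
        self.drop = nn.Dropout(config.dropout, rng)

    def __call__(self, graph: ResidueGraph) -> Tensor:
        coords = graph.node_coords - graph.node_coords.mean(axis=0)
        # unit-RMS scaling keeps the coordinate channels commensurate
        # with the one-hot features (translation invariance unaffected)
        coords = coords / max(np.sqrt(np.mean(np.sum(coords**2, axis=1))), 1e-12)
        x = Tensor(np.concatenate([graph.node_features, coords], axis=1))
        adj = Tensor(normalized_adjacency(graph.n_nodes, graph.edges))
        h = adj @ self.lin(x)
        return self.drop(self.bn(h).relu())


class EnInvariantLayer(nn.Module):
    """E(n)-invariant message passing: messages see only squared distances.

    m_ij = MLP_e(h_i || h_j || d_ij^2);  h_i' = MLP_h(h_i || sum_j m_ij).
    Coordinates are never updated, so the output is exactly invariant to
    any rigid motion or reflection of the molecule.
    """

    def __init__(self, rng: np.random.Generator, config: IgepConfig):
        super().__init__()
        f, h = config.feature_dim, config.hidden_dim
        self.edge_mlp = nn.MLP(rng, [2 * f + 1, h, h])
        self.node_mlp = nn.MLP(rng, [f + h, h])
        self.drop = nn.Dropout(config.dropout, rng)

    def __call__(self, graph: ResidueGraph) -> Tensor:
        x = Tensor(graph.node_features)
        n = graph.n_nodes
        if len(graph.edges):
            src, dst = graph.edges[:, 0], graph.edges[:, 1]
            d2 = np.sum(
                (graph.node_coords[src] - graph.node_coords[dst]) ** 2,
                axis=1,
                keepdims=True,
            )
            m_in = nn.concat(
                [nn.gather(x, dst), nn.gather(x, src), Tensor(d2)], axis=1
            )
            msgs = self.edge_mlp(m_in)
            agg = nn.scatter_sum(msgs, dst, n)
        else:
            agg = Tensor(np.zeros((n, self.edge_mlp.layers[-1].weight.shape[1])))
        h = self.node_mlp(nn.concat([x, agg], axis=1))
        return self.drop(h.relu())


class _GATHead(nn.Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        super().__init__()
        self.W = nn.Linear(rng, d_in, d_out, bias=False)
        self.a_src = nn.Linear(rng, d_out, 1, bias=False)
        self.a_dst = nn.Linear(rng, d_out, 1, bias=False)

    def __call__(self, h_dst: Tensor, h_src: Tensor) -> Tensor:
        """Attend every destination node over all source nodes."""
        ws, wd = self.W(h_src), self.W(h_dst)
        scores = self.a_dst(wd) + self.a_src(ws).T  # (D, S) via broadcast
        alpha = nn.softmax(scores.leaky_relu(0.2), axis=1)
        return alpha @ ws


class BipartiteGAT(nn.Module):
    """One cross-molecule attention layer on the complete bipartite graph.

    Every antibody-scope residue attends over all antigen residues and
    vice versa; attention weights softmax-normalize over each node's
    in-neighborhood.  Heads are averaged, then passed through ELU.
    """

    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int, heads: int):
        super().__init__()
        self.heads = [_GATHead(rng, d_in, d_out) for _ in range(heads)]

    def _attend(self, h_dst: Tensor, h_src: Tensor) -> Tensor:
        outs = [head(h_dst, h_src) for head in self.heads]
        total = outs[0]
        for o in outs[1:]:
            total = total + o
        return _elu(total * (1.0 / len(outs)))

    def __call__(self, h_ab: Tensor, h_ag: Tensor) -> tuple[Tensor, Tensor]:
        return self._attend(h_ab, h_ag), self._attend(h_ag, h_ab)

    def attention_matrix(self, h_dst: Tensor, h_src: Tensor) -> np.ndarray:
        """Head-averaged attention coefficients (rows sum to 1)."""
        mats = []
        for head in self.heads:
            ws, wd = head.W(h_src), head.W(h_dst)
            scores = head.a_dst(wd) + head.a_src(ws).T
            mats.append(nn.softmax(scores.leaky_relu(0.2), axis=1).data)
        return np.mean(mats, axis=0)


class IGepModel(nn.Module):
    """Structural encoders + two-layer cross GAT + per-molecule FC heads."""

    def __init__(self, config: IgepConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        enc = GCNStructural if config.variant == "gcn_xyz" else EnInvariantLayer
        self.ab_encoder = enc(rng, config)
        self.ag_encoder = enc(rng, config)
        h = config.hidden_dim
        self.gat1 = BipartiteGAT(rng, h, h, config.gat_heads)
        self.gat2 = BipartiteGAT(rng, h, h, config.gat_heads)
        self.ab_head = nn.Linear(rng, 3 * h, 1)
        self.ag_head = nn.Linear(rng, 3 * h, 1)

    def forward_graphs(
        self,
        ab_graph: ResidueGraph,
        ag_graph: ResidueGraph,
        cdr_mask: np.ndarray | None = None,
    ) -> tuple[Tensor, Tensor]:
        """Per-residue binding probabilities (antibody scope, antigen)."""
        h_ab = self.ab_encoder(ab_graph)
        h_ag = self.ag_encoder(ag_graph)
        if cdr_mask is not None:
            scope = np.flatnonzero(cdr_mask)
            if scope.size == 0:
                raise ValueError("empty antibody scope")
            h_ab = nn.gather(h_ab, scope)
        a1, g1 = self.gat1(h_ab, h_ag)
        a2, g2 = self.gat2(a1, g1)
        p_ab = self.ab_head(nn.concat([h_ab, a1, a2], axis=1)).sigmoid()
        p_ag = self.ag_head(nn.concat([h_ag, g1, g2], axis=1)).sigmoid()
        if np.any(~np.isfinite(p_ab.data)) or np.any(~np.isfinite(p_ag.data)):
            raise FloatingPointError("non-finite probabilities in forward pass")
        return p_ab.reshape(-1), p_ag.reshape(-1)

    def forward_sample(self, sample: ComplexSample) -> dict:
        """Forward pass on one complex; probabilities + matching labels."""
        p_ab, p_ag = self.forward_graphs(
            sample.ab_graph, sample.ag_graph, sample.cdr_mask
        )
        scope = np.flatnonzero(sample.cdr_mask)
        return {
            "ab_probs": p_ab,
            "ag_probs": p_ag,
            "ab_labels": sample.ab_labels.per_residue[scope],
            "ag_labels": sample.ag_labels.per_residue,
            "ab_scope": scope,
        }


def igep_predict(
    ab_graph: ResidueGraph,
    ag_graph: ResidueGraph,
    config: IgepConfig,
    model: IGepModel | None = None,
    cdr_mask: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Functional entry point: probabilities from a fresh or given model."""
    if model is None:
        model = IGepModel(config, seed=seed)
    model.eval()
    p_ab, p_ag = model.forward_graphs(ab_graph, ag_graph, cdr_mask)
    return p_ab.data.copy(), p_ag.data.copy()


class IGepClassifier(BaseEstimator):
    """Sklearn-style estimator over lists of :class:`ComplexSample`.

    ``fit`` trains on complexes; ``predict_proba`` returns, per complex,
    a dict with full-length per-residue probability arrays for both
    molecules (antibody residues outside the CDR scope get 0.0).

    Parameters
    ----------
    variant : "en_invariant" or "gcn_xyz"
        Structural encoder type.
    hidden_dim, gat_heads, dropout :
        Architecture knobs (see :class:`IgepConfig`).
    lr, epochs, class_weight, augment :
        Training protocol (class-weighted binary cross-entropy, Adam,
        optional random-rotation augmentation).
    seed : int
        Controls initialization, dropout, and augmentation.
    """

    def __init__(
        self,
        variant: str = "en_invariant",
        hidden_dim: int = 32,
        gat_heads: int = 4,
        dropout: float = 0.1,
        lr: float = 5e-3,
        epochs: int = 10,
        class_weight: str = "global",
        augment: bool = False,
        seed: int = 0,
    ):
        self.variant = variant
        self.hidden_dim = hidden_dim
        self.gat_heads = gat_heads
        self.dropout = dropout
        self.lr = lr
        self.epochs = epochs
        self.class_weight = class_weight
        self.augment = augment
        self.seed = seed

    def _build(self) -> IGepModel:
        cfg = IgepConfig(
            variant=self.variant,
            hidden_dim=self.hidden_dim,
            gat_heads=self.gat_heads,
            dropout=self.dropout,
        )
        return IGepModel(cfg, seed=self.seed)

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
        self.n_features_in_ = 28
        return self

    def predict_proba(self, X: list[ComplexSample]) -> list[dict[str, np.ndarray]]:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        self.model_.eval()
        out = []
        for s in X:
            r = self.model_.forward_sample(s)
            ab = np.zeros(s.ab_graph.n_nodes)
            ab[r["ab_scope"]] = r["ab_probs"].data
            out.append({"antibody": ab, "antigen": r["ag_probs"].data.copy()})
        return out

    def predict(self, X: list[ComplexSample], threshold: float = 0.5):
        return [
            {k: (v >= threshold).astype(int) for k, v in p.items()}
            for p in self.predict_proba(X)
        ]
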