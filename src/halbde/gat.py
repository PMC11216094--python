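"""Graph attention network (GAT) regressor for BDE prediction.

The model maps an attributed molecular graph to a single bond dissociation
energy.  Each GAT layer updates every atom's representation as an
attention-weighted sum over its bonded neighbours (plus itself): per head,
``h_i' = ELU( sum_j alpha_ij * W h_j )`` with attention logits
``e_ij = LeakyReLU(a_src . W h_j + a_dst . W h_i)`` normalised by softmax
over the incoming edges of atom i; head outputs are concatenated.  A sum (or
mean) readout pools atoms to a molecule vector and a linear head produces
the prediction in min-max-scaled target space; results are reported in
kcal/mol after inverse scaling.

The network is implemented directly on NumPy arrays with hand-written
reverse-mode gradients (validated against finite differences in the test
suite) and trained full-batch with Adam, early-stopping on a validation
carve-out from the training split.  One joint model is trained per task
(homolytic or heterolytic) across all three halogen centers; the element
one-hot is the only halogen-identity signal in the features.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .correlation import Metrics, compute_metrics
from .dataset import DatasetSplit, ScalerParams, minmax_scale
from .errors import DivergenceError, HalBDEError
from .featurize import DescriptorConfig, MolecularGraph, mol_to_graph

FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimisation constants of the GAT regressor."""

    n_gat_layers: int = 2
    attention_heads: int = 4
    hidden_dim: int = 16          # width per attention head
    head_hidden: int = 64         # width of the post-readout MLP (0 = linear head)
    readout: str = "mean"         # "sum" | "mean"
    dropout: float = 0.0
    learning_rate: float = 1e-2
    lr_decay: float = 0.05        # cosine-decay floor as a fraction of learning_rate
    weight_decay: float = 1e-3    # decoupled L2 on weight matrices (not biases)
    batch_size: int = 32
    max_epochs: int = 400
    patience: int = 400           # epochs without validation improvement
    val_fraction: float = 0.1
    leaky_slope: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if min(self.n_gat_layers, self.attention_heads, self.hidden_dim) < 1:
            raise ValueError("layer, head, and width counts must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.readout not in ("sum", "mean"):
            raise ValueError(f"unknown readout {self.readout!r}")


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------

class GraphBatch:
    """A list of molecular graphs packed into one disjoint-union graph.

    Self-loops are appended so every atom attends to itself and no softmax
    denominator can be empty.
    """

    def __init__(self, graphs: Sequence[MolecularGraph]):
        if not graphs:
            raise ValueError("empty graph batch")
        widths = {g.node_features.shape[1] for g in graphs}
        if len(widths) != 1:
            raise HalBDEError(f"inconsistent feature lengths in batch: {widths}")
        feats, srcs, dsts, gids = [], [], [], []
        offset = 0
        for gi, g in enumerate(graphs):
            n = g.n_nodes
            feats.append(g.node_features)
            srcs.append(g.edge_index[0] + offset)
            dsts.append(g.edge_index[1] + offset)
            loop = np.arange(offset, offset + n)
            srcs.append(loop)
            dsts.append(loop)
            gids.append(np.full(n, gi))
            offset += n
        self.X = np.vstack(feats).astype(np.float64)
        self.src = np.concatenate(srcs)
        self.dst = np.concatenate(dsts)
        self.gid = np.concatenate(gids)
        self.n_nodes = offset
        self.n_graphs = len(graphs)
        self.counts = np.bincount(self.gid, minlength=self.n_graphs).astype(float)
        # sparse scatter operators: edge values -> nodes, nodes -> graphs
        n_edges = self.src.size
        ones = np.ones(n_edges)
        self.scatter_dst = sp.csr_matrix(
            (ones, (self.dst, np.arange(n_edges))), shape=(offset, n_edges))
        self.scatter_src = sp.csr_matrix(
            (ones, (self.src, np.arange(n_edges))), shape=(offset, n_edges))
        self.pool_sum = sp.csr_matrix(
            (np.ones(offset), (self.gid, np.arange(offset))),
            shape=(self.n_graphs, offset))
        self.pool_sum_T = self.pool_sum.T.tocsr()


# ---------------------------------------------------------------------------
# parameters and numerics
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape[-2:])) if len(shape) > 1 else np.sqrt(6.0 / shape[0])
    return rng.uniform(-limit, limit, size=shape)


def init_params(config: ModelConfig, n_features: int,
                rng: np.random.Generator) -> dict[str, np.ndarray]:
    params: dict[str, np.ndarray] = {}
    fin = n_features
    for layer in range(config.n_gat_layers):
        for head in range(config.attention_heads):
            p = f"l{layer}h{head}_"
            params[p + "W"] = _glorot(rng, (fin, config.hidden_dim))
            params[p + "Ws"] = _glorot(rng, (fin, config.hidden_dim))
            # attention starts uniform (zero logits) and differentiates
            # during training; random init destabilises small-sample fits
            params[p + "as"] = np.zeros(config.hidden_dim)
            params[p + "ad"] = np.zeros(config.hidden_dim)
            params[p + "b"] = np.zeros(config.hidden_dim)
        fin = config.hidden_dim * config.attention_heads
    if config.head_hidden > 0:
        params["head_W"] = _glorot(rng, (fin, config.head_hidden))
        params["head_b"] = np.zeros(config.head_hidden)
        fin = config.head_hidden
    params["out_w"] = _glorot(rng, (fin, 1))[:, 0]
    params["out_b"] = np.zeros(1)
    return params


def _elu(x):
    return np.where(x > 0, x, np.expm1(x))


def _leaky(x, slope):
    return np.where(x > 0, x, slope * x)


def _segment_softmax(e, dst, n_nodes):
    mx = np.full(n_nodes, -np.inf)
    np.maximum.at(mx, dst, e)
    ex = np.exp(e - mx[dst])
    denom = np.bincount(dst, weights=ex, minlength=n_nodes)
    return ex / denom[dst]


def forward(params: dict, config: ModelConfig, batch: GraphBatch,
            dropout_rng: np.random.Generator | None = None):
    """Forward pass; returns per-graph predictions (scaled space) and a cache."""
    X = batch.X
    src, dst, n = batch.src, batch.dst, batch.n_nodes
    layers = []
    for layer in range(config.n_gat_layers):
        if dropout_rng is not None and config.dropout > 0:
            mask = (dropout_rng.random(X.shape) >= config.dropout) / (1 - config.dropout)
            X = X * mask
        else:
            mask = None
        outs, heads = [], []
        for head in range(config.attention_heads):
            p = f"l{layer}h{head}_"
            W, a_s, a_d, b = (params[p + "W"], params[p + "as"],
                              params[p + "ad"], params[p + "b"])
            Z = X @ W
            s, t = Z @ a_s, Z @ a_d
            pre = s[src] + t[dst]
            e = _leaky(pre, config.leaky_slope)
            alpha = _segment_softmax(e, dst, n)
            # attention-weighted neighbour aggregation plus an explicit
            # self-connection outside the softmax, so the identity map is
            # representable exactly
            O = (batch.scatter_dst @ (alpha[:, None] * Z[src])
                 + X @ params[p + "Ws"] + b)
            outs.append(O)
            heads.append((Z, pre, alpha))
        H = np.concatenate(outs, axis=1)
        # hidden layers are ELU-activated; the last layer stays linear so a
        # linear readout of pooled embeddings can be exactly linear in counts
        last = layer == config.n_gat_layers - 1
        A = H if last else _elu(H)
        layers.append((X, mask, heads, H))
        X = A
    if config.readout == "mean":
        pool_w = 1.0 / batch.counts[batch.gid]
    else:
        pool_w = np.ones(n)
    P = batch.pool_sum @ (X * pool_w[:, None])
    if config.head_hidden > 0:
        Hh = P @ params["head_W"] + params["head_b"]
        Ah = _elu(Hh)
    else:
        Hh = Ah = P
    y = Ah @ params["out_w"] + params["out_b"][0]
    cache = (layers, X, P, pool_w, Hh, Ah)
    return y, cache


def backward(params: dict, config: ModelConfig, batch: GraphBatch,
             cache, dy: np.ndarray) -> dict[str, np.ndarray]:
    """Reverse-mode gradients of a scalar loss with per-graph gradient ``dy``."""
    layers, A_last, P, pool_w, Hh, Ah = cache
    src, dst, n = batch.src, batch.dst, batch.n_nodes
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    grads["out_w"] = Ah.T @ dy
    grads["out_b"] = np.array([dy.sum()])
    dAh = np.outer(dy, params["out_w"])
    if config.head_hidden > 0:
        dHh = dAh * np.where(Hh > 0, 1.0, np.exp(np.minimum(Hh, 0.0)))
        grads["head_W"] = P.T @ dHh
        grads["head_b"] = dHh.sum(axis=0)
        dP = dHh @ params["head_W"].T
    else:
        dP = dAh
    dA = (batch.pool_sum_T @ dP) * pool_w[:, None]
    D = config.hidden_dim
    for layer in reversed(range(config.n_gat_layers)):
        X, mask, heads, H = layers[layer]
        if layer == config.n_gat_layers - 1:
            dH = dA
        else:
            dH = dA * np.where(H > 0, 1.0, np.exp(np.minimum(H, 0.0)))
        dX = np.zeros_like(X)
        for head in range(config.attention_heads):
            p = f"l{layer}h{head}_"
            W, a_s, a_d = params[p + "W"], params[p + "as"], params[p + "ad"]
            Z, pre, alpha = heads[head]
            dO = dH[:, head * D:(head + 1) * D]
            grads[p + "b"] += dO.sum(axis=0)
            dO_dst = dO[dst]
            dalpha = np.einsum("ed,ed->e", Z[src], dO_dst)
            dZ = batch.scatter_src @ (alpha[:, None] * dO_dst)
            S = np.bincount(dst, weights=alpha * dalpha, minlength=n)
            de = alpha * (dalpha - S[dst])
            dpre = de * np.where(pre > 0, 1.0, config.leaky_slope)
            ds = np.bincount(src, weights=dpre, minlength=n)
            dt = np.bincount(dst, weights=dpre, minlength=n)
            dZ += ds[:, None] * a_s + dt[:, None] * a_d
            grads[p + "as"] += Z.T @ ds
            grads[p + "ad"] += Z.T @ dt
            grads[p + "W"] += X.T @ dZ
            grads[p + "Ws"] += X.T @ dO
            dX += dZ @ W.T + dO @ params[p + "Ws"].T
        if mask is not None:
            dX *= mask
        dA = dX
    return grads


class _Adam:
    """Adam with decoupled weight decay on multiplicative weights."""

    def __init__(self, params: dict, lr: float, weight_decay: float = 0.0,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.wd = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    @staticmethod
    def _decayable(name: str) -> bool:
        return name.endswith("_W") or name in ("head_W", "out_w")

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            if self.wd and self._decayable(k):
                params[k] -= self.lr * self.wd * params[k]


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class GATRegressor:
    """GAT regression model over a set of featurized molecules.

    Parameters
    ----------
    graphs : sequence of MolecularGraph
        Featurized molecules (all with the same descriptor configuration).
    targets : sequence of float
        BDE values in kcal/mol, aligned with ``graphs``.
    config, descriptor_config : optional
        Architecture/optimisation constants and the feature layout used to
        build ``graphs`` (stored with the trained model so prediction is
        self-contained).
    """

    def __init__(self, graphs: Sequence[MolecularGraph],
                 targets: Sequence[float],
                 config: ModelConfig | None = None,
                 descriptor_config: DescriptorConfig | None = None):
        self.graphs = list(graphs)
        self.targets = np.asarray(targets, dtype=float)
        if len(self.graphs) != self.targets.size:
            raise ValueError("graphs and targets must have equal length")
        if not np.all(np.isfinite(self.targets)):
            raise ValueError("targets must be finite (filter missing records)")
        self.config = config or ModelConfig()
        self.descriptor_config = descriptor_config or DescriptorConfig()

    @classmethod
    def from_smiles(cls, smiles: Sequence[str], targets: Sequence[float],
                    config: ModelConfig | None = None,
                    descriptor_config: DescriptorConfig | None = None
                    ) -> "GATRegressor":
        dc = descriptor_config or DescriptorConfig()
        graphs = [mol_to_graph(s, dc) for s in smiles]
        return cls(graphs, targets, config, dc)

    def _resolve_split(self, split, train_idx, test_idx):
        n = len(self.graphs)
        if split is not None:
            key_to_idx = {g.reagent_key: i for i, g in enumerate(self.graphs)}
            if None in key_to_idx and n > 1:
                raise ValueError("graphs need reagent keys to use a DatasetSplit")
            train_idx = np.array([key_to_idx[k] for k in split.train])
            test_idx = np.array([key_to_idx[k] for k in split.test])
        elif train_idx is None:
            train_idx = np.arange(n)
            test_idx = np.array([], dtype=int)
        else:
            train_idx = np.asarray(train_idx, dtype=int)
            test_idx = (np.array([], dtype=int) if test_idx is None
                        else np.asarray(test_idx, dtype=int))
        if set(train_idx) & set(test_idx):
            raise ValueError("train and test indices overlap")
        return train_idx, test_idx

    def fit(self, split: DatasetSplit | None = None,
            train_idx=None, test_idx=None) -> "GATResults":
        """Train with Adam on MSE over min-max-scaled targets.

        Scaler parameters are fitted on the training subset only.  A
        ``val_fraction`` carve-out of the training set drives early stopping
        (the best-validation-epoch weights are restored); training is
        deterministic for a fixed config seed.
        """
        cfg = self.config
        train_idx, test_idx = self._resolve_split(split, train_idx, test_idx)
        rng = np.random.default_rng(cfg.seed)

        _, scaler = minmax_scale(self.targets[train_idx])
        y_scaled = scaler.transform(self.targets)

        # z-score node features on training-set atoms (constant columns kept)
        train_nodes = np.vstack([self.graphs[i].node_features
                                 for i in train_idx])
        mu = train_nodes.mean(axis=0)
        sd = train_nodes.std(axis=0)
        sd[sd < 1e-8] = 1.0
        graphs = [MolecularGraph((g.node_features - mu) / sd, g.edge_index,
                                 g.reagent_key, g.smiles)
                  for g in self.graphs]

        n_val = int(np.floor(cfg.val_fraction * len(train_idx) + 0.5))
        order = rng.permutation(len(train_idx))
        val_idx = train_idx[order[:n_val]]
        fit_idx = train_idx[order[n_val:]]

        val_batch = GraphBatch([graphs[i] for i in val_idx]) if n_val else None
        y_val = y_scaled[val_idx] if n_val else None

        probe = GraphBatch([graphs[fit_idx[0]]])
        params = init_params(cfg, probe.X.shape[1], rng)
        opt = _Adam(params, cfg.learning_rate, cfg.weight_decay)
        drop_rng = np.random.default_rng(rng.integers(2 ** 31)) \
            if cfg.dropout > 0 else None

        history = []
        best_val = np.inf
        best_params = {k: v.copy() for k, v in params.items()}
        best_epoch = 0
        stale = 0
        bs = min(cfg.batch_size, len(fit_idx))
        n_batches = max(1, len(fit_idx) // bs)
        for epoch in range(cfg.max_epochs):
            # cosine learning-rate decay down to lr_decay * learning_rate
            frac = epoch / max(1, cfg.max_epochs - 1)
            floor = cfg.lr_decay * cfg.learning_rate
            opt.lr = floor + 0.5 * (cfg.learning_rate - floor) * (
                1 + np.cos(np.pi * frac))
            perm = rng.permutation(len(fit_idx))
            sse = 0.0
            for chunk in np.array_split(perm, n_batches):
                idx = fit_idx[chunk]
                batch = GraphBatch([graphs[i] for i in idx])
                pred, cache = forward(params, cfg, batch, drop_rng)
                resid = pred - y_scaled[idx]
                with np.errstate(over="ignore", invalid="ignore"):
                    sse += float(np.sum(resid ** 2))
                if not np.isfinite(sse):
                    raise DivergenceError(
                        f"loss became non-finite at epoch {epoch} "
                        f"(learning_rate={cfg.learning_rate})")
                grads = backward(params, cfg, batch, cache,
                                 2.0 * resid / resid.size)
                opt.step(params, grads)
            train_mse = sse / len(fit_idx)

            if val_batch is not None:
                val_pred, _ = forward(params, cfg, val_batch)
                val_mse = float(np.mean((val_pred - y_val) ** 2))
            else:
                val_mse = train_mse
            history.append((epoch, train_mse, val_mse))
            if val_mse < best_val - 1e-12:
                best_val = val_mse
                best_params = {k: v.copy() for k, v in params.items()}
                best_epoch = epoch
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break

        hist = pd.DataFrame(history, columns=["epoch", "train_mse", "val_mse"])
        return GATResults(self, best_params, scaler, hist, best_epoch,
                          train_idx, test_idx, feature_mu=mu, feature_sd=sd)


class GATResults:
    """A trained GAT regressor: weights, scaler, history, and evaluation."""

    def __init__(self, model: GATRegressor, params: dict,
                 scaler: ScalerParams, history: pd.DataFrame,
                 best_epoch: int, train_idx, test_idx,
                 feature_mu: np.ndarray | None = None,
                 feature_sd: np.ndarray | None = None):
        self.model = model
        self.params = params
        self.config = model.config
        self.descriptor_config = model.descriptor_config
        self.scaler = scaler
        self.history = history
        self.best_epoch = best_epoch
        self.train_idx = np.asarray(train_idx, dtype=int)
        self.test_idx = np.asarray(test_idx, dtype=int)
        width = self.descriptor_config.feature_length
        self.feature_mu = (np.zeros(width) if feature_mu is None
                           else np.asarray(feature_mu, dtype=float))
        self.feature_sd = (np.ones(width) if feature_sd is None
                           else np.asarray(feature_sd, dtype=float))

    # -- prediction ------------------------------------------------------
    def predict_graphs(self, graphs: Sequence[MolecularGraph]) -> np.ndarray:
        """Predict BDEs (kcal/mol) for featurized molecules (inference mode)."""
        if any(g.node_features.shape[1] != self.feature_mu.size for g in graphs):
            raise HalBDEError(
                "feature length mismatch: graphs were not featurized with "
                "this model's descriptor configuration")
        std = [MolecularGraph((g.node_features - self.feature_mu) / self.feature_sd,
                              g.edge_index, g.reagent_key, g.smiles)
               for g in graphs]
        batch = GraphBatch(std)
        pred, _ = forward(self.params, self.config, batch)
        return self.scaler.inverse_transform(pred)

    def predict_smiles(self, smiles: str | Sequence[str]) -> np.ndarray:
        single = isinstance(smiles, str)
        items = [smiles] if single else list(smiles)
        graphs = [mol_to_graph(s, self.descriptor_config) for s in items]
        out = self.predict_graphs(graphs)
        return out[0] if single else out

    def predict_bde(self, graph: MolecularGraph) -> float:
        return float(self.predict_graphs([graph])[0])

    # -- evaluation ------------------------------------------------------
    def evaluate(self, graphs: Sequence[MolecularGraph],
                 targets: Sequence[float]) -> Metrics:
        """R^2 / MAE / RMSE in kcal/mol space."""
        targets = np.asarray(targets, dtype=float)
        if len(graphs) == 0:
            raise ValueError("empty evaluation set")
        return compute_metrics(self.predict_graphs(graphs), targets)

    def _subset(self, idx):
        return [self.model.graphs[i] for i in idx], self.model.targets[idx]

    def evaluate_train(self) -> Metrics:
        return self.evaluate(*self._subset(self.train_idx))

    def evaluate_test(self) -> Metrics:
        if self.test_idx.size == 0:
            raise ValueError("model was fitted without a test set")
        return self.evaluate(*self._subset(self.test_idx))

    def summary(self) -> str:
        cfg = self.config
        tm = self.evaluate_train()
        lines = [
            "GAT regressor",
            f"  layers={cfg.n_gat_layers} heads={cfg.attention_heads} "
            f"hidden={cfg.hidden_dim} readout={cfg.readout} "
            f"features={self.descriptor_config.name}",
            f"  epochs run={len(self.history)} best epoch={self.best_epoch} "
            f"(patience {cfg.patience}) seed={cfg.seed}",
            f"  target scale: [{self.scaler.min_value:.1f}, "
            f"{self.scaler.max_value:.1f}] kcal/mol",
            f"  train (n={self.train_idx.size}): R^2={tm.r_squared:.3f} "
            f"MAE={tm.mae:.2f} RMSE={tm.rmse:.2f} kcal/mol",
        ]
        if self.test_idx.size:
            te = self.evaluate_test()
            lines.append(f"  test  (n={self.test_idx.size}): "
                         f"R^2={te.r_squared:.3f} MAE={te.mae:.2f} "
                         f"RMSE={te.rmse:.2f} kcal/mol")
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Write a self-contained model bundle (weights + configs + scaler)."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "weights.npz", **self.params,
                 __feature_mu=self.feature_mu, __feature_sd=self.feature_sd)
        manifest = {
            "format_version": FORMAT_VERSION,
            "model_config": asdict(self.config),
            "descriptor_config": {
                **asdict(self.descriptor_config),
                "element_vocab": list(self.descriptor_config.element_vocab),
            },
            "scaler": asdict(self.scaler),
            "best_epoch": int(self.best_epoch),
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
        self.history.to_csv(d / "history.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "GATResults":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        if manifest["format_version"] != FORMAT_VERSION:
            raise HalBDEError(
                f"unsupported bundle version {manifest['format_version']}")
        dc_kw = dict(manifest["descriptor_config"])
        dc_kw["element_vocab"] = tuple(dc_kw["element_vocab"])
        dc = DescriptorConfig(**dc_kw)
        cfg = ModelConfig(**manifest["model_config"])
        scaler = ScalerParams(**manifest["scaler"])
        arrays = dict(np.load(d / "weights.npz"))
        feature_mu = arrays.pop("__feature_mu")
        feature_sd = arrays.pop("__feature_sd")
        params = arrays
        history = pd.read_csv(d / "history.csv")
        # a bundle-loaded result keeps an empty placeholder model
        dummy = GATRegressor.__new__(GATRegressor)
        dummy.graphs = [MolecularGraph(np.zeros((1, dc.feature_length)),
                                       np.zeros((2, 0), dtype=np.int64))]
        dummy.targets = np.zeros(1)
        dummy.config = cfg
        dummy.descriptor_config = dc
        return cls(dummy, params, scaler, history,
                   manifest["best_epoch"], np.array([]), np.array([]),
                   feature_mu=feature_mu, feature_sd=feature_sd)


# ---------------------------------------------------------------------------
# descriptor ablation
# ---------------------------------------------------------------------------

def run_ablation(smiles: Sequence[str], targets: Sequence[float],
                 descriptor_configs: Sequence[DescriptorConfig],
                 model_config: ModelConfig | None = None,
                 n_seeds: int = 3, test_fraction: float = 0.1) -> pd.DataFrame:
    """Seed-averaged train/test metrics for each descriptor configuration.

    Every configuration sees identical random splits (seeded independently
    of the configuration), so rows differ only in the node features.  The
    returned table is sorted by mean test R^2, best first.
    """
    if len(descriptor_configs) < 1:
        raise ValueError("need at least one descriptor configuration")
    base = model_config or ModelConfig()
    targets = np.asarray(targets, dtype=float)
    n = len(smiles)
    n_test = max(1, int(np.floor(test_fraction * n + 0.5)))
    rows = []
    for dc in descriptor_configs:
        graphs = [mol_to_graph(s, dc) for s in smiles]
        per_seed = []
        for seed in range(n_seeds):
            order = np.random.default_rng(1000 + seed).permutation(n)
            test_i, train_i = order[:n_test], order[n_test:]
            cfg = replace(base, seed=seed)
            res = GATRegressor(graphs, targets, cfg, dc).fit(
                train_idx=train_i, test_idx=test_i)
            per_seed.append((res.evaluate_train(), res.evaluate_test()))
        rows.append({
            "descriptors": dc.name,
            "n_seeds": n_seeds,
            "train_r2_mean": float(np.mean([t.r_squared for t, _ in per_seed])),
            "test_r2_mean": float(np.mean([e.r_squared for _, e in per_seed])),
            "test_r2_std": float(np.std([e.r_squared for _, e in per_seed])),
            "test_mae_mean": float(np.mean([e.mae for _, e in per_seed])),
            "test_rmse_mean": float(np.mean([e.rmse for _, e in per_seed])),
        })
    return (pd.DataFrame(rows)
            .sort_values("test_r2_mean", ascending=False)
            .reset_index(drop=True))
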