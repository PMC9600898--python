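"""Auto-metric graph neural network for four-class GOLD staging.

The classifier operates on small episodic graphs rather than a fixed cohort
graph.  Each episode holds ``n_way * k_shot`` labelled support nodes (default
4-way-10-shot, i.e. 40 nodes) plus query node(s) to classify.  Per layer:

1. the *edge weight matrix* W is learned from the data itself: the pairwise
   block C'' of absolute feature differences ``|v_i - v_j|`` is pushed through
   a 1x1-kernel convolution stack (channels d -> h -> 1, LeakyReLU between)
   and squashed with a logistic so W_ij in (0, 1);
2. the *edge constraint matrix* E gates edges by risk-factor similarity:
   ``E_ij = prod_k exp(-(r_ik - r_jk)^2 / tau_k)``, so participants with
   dissimilar risk factors are nearly disconnected; E is symmetric with unit
   diagonal and is computed once per episode;
3. the adjacency ``A~ = row-normalize(W o E)`` is a convex-combination
   operator; the node update is ``Gn(V) = LeakyReLU(FC(A~ V))`` and the next
   representation is the concatenation ``[V || Gn(V)]``.

Two such layers (W recomputed from the current representation at each layer)
feed a linear head and softmax on the query rows.  Support labels enter the
initial representation as one-hot channels; query nodes carry the uniform
label distribution.  Meta-training samples a batch of independent episodes
per iteration and applies one Adam step on the mean query cross-entropy.

The public surface follows the Model/Results convention:
``AutoMetricGNN(...).fit()`` returns an :class:`AMGNNResults` that predicts,
summarises and serialises.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Adam, Tensor, concat, cross_entropy_with_logits, softmax
from .cohort import FeatureTable, StageLabels, N_STAGES
from .selection import CombinationVectorSpec

__all__ = [
    "AMGNNConfig",
    "Episode",
    "EpisodeError",
    "DegenerateGraphError",
    "sample_episode",
    "edge_weight_matrix",
    "edge_constraint_matrix",
    "adjacency",
    "layer_forward",
    "forward",
    "AutoMetricGNN",
    "AMGNNResults",
]


class EpisodeError(ValueError):
    pass


class DegenerateGraphError(ValueError):
    pass


@dataclass(frozen=True)
class AMGNNConfig:
    """Hyperparameters of the auto-metric GNN.

    Defaults follow the published training recipe where one is stated
    (600 iterations, batch 28, 4-way-10-shot, seed 42); the remaining knobs
    (hidden width 48, LeakyReLU slope 0.01, Adam 1e-3, tau=1 on standardized
    risk factors, metric hidden width max(32, d // 4), test-time ensemble of
    5 support draws) are this package's defaults.
    """

    n_way: int = 4
    k_shot: int = 10
    n_query: int = 1
    iterations: int = 600
    batch_size: int = 28
    hidden_dim: int = 48
    metric_hidden: int | None = None
    leaky_slope: float = 0.01
    learning_rate: float = 1e-3
    tau: float = 1.0
    ensemble_size: int = 5
    use_constraints: bool = True
    concat_risk_to_nodes: bool = False
    seed: int = 42

    def metric_width(self, d_in: int) -> int:
        return self.metric_hidden if self.metric_hidden is not None else max(32, d_in // 4)


@dataclass
class Episode:
    """One episodic graph: labelled support nodes plus query node(s).

    Node rows are ordered support-first; ``query_labels`` may be None at
    test time.
    """

    support_ids: list
    query_ids: list
    node_features: np.ndarray
    risk_values: np.ndarray
    support_labels: np.ndarray
    query_labels: np.ndarray | None = None

    def __post_init__(self):
        n_nodes = len(self.support_ids) + len(self.query_ids)
        if self.node_features.shape[0] != n_nodes or self.risk_values.shape[0] != n_nodes:
            raise EpisodeError("node_features/risk_values rows must cover support + query")
        if set(self.support_ids) & set(self.query_ids):
            raise EpisodeError("support and query must be disjoint")

    @property
    def n_support(self) -> int:
        return len(self.support_ids)

    @property
    def n_query(self) -> int:
        return len(self.query_ids)


def _matrices_from_pool(table: FeatureTable, spec: CombinationVectorSpec):
    node = table.select_features(spec.node_features).values
    risk = (
        table.select_features(spec.risk_factors).values
        if spec.K
        else np.zeros((table.n_samples, 0))
    )
    return node, risk


def sample_episode(
    table: FeatureTable,
    labels: StageLabels,
    spec: CombinationVectorSpec,
    n_way: int = 4,
    k_shot: int = 10,
    n_query: int = 1,
    rng: np.random.Generator | int = 0,
) -> Episode:
    """Draw one n_way-k_shot episode from a labelled pool.

    Support: ``k_shot`` samples per stage.  Query: ``n_query`` samples drawn
    from the remainder of the pool.
    """
    if not labels.aligned_with(table):
        raise EpisodeError("labels not aligned with feature table")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    stages = labels.stage
    support_idx: list = []
    for c in range(n_way):
        members = np.flatnonzero(stages == c)
        if members.size < k_shot:
            raise EpisodeError(f"stage {c} has {members.size} samples; k_shot={k_shot} required")
        support_idx.extend(rng.choice(members, size=k_shot, replace=False))
    support_idx = np.array(support_idx)
    remaining = np.setdiff1d(np.arange(len(labels)), support_idx)
    if remaining.size < n_query:
        raise EpisodeError("pool too small for the requested query count")
    query_idx = rng.choice(remaining, size=n_query, replace=False)

    node, risk = _matrices_from_pool(table, spec)
    all_idx = np.concatenate([support_idx, query_idx])
    return Episode(
        support_ids=[table.sample_ids[i] for i in support_idx],
        query_ids=[table.sample_ids[i] for i in query_idx],
        node_features=node[all_idx],
        risk_values=risk[all_idx],
        support_labels=stages[support_idx],
        query_labels=stages[query_idx],
    )


# ---------------------------------------------------------------------------
# Graph operations.  Each accepts numpy arrays (or Tensors, used internally
# during training) and returns the same kind it was given.


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _maybe_data(out, *inputs):
    if any(isinstance(x, Tensor) for x in inputs):
        return out
    return out.data


class _PairIndex:
    """Unordered node-pair bookkeeping for an N-node graph.

    The |v_i - v_j| block is symmetric, so the metric network only needs the
    N(N+1)/2 unordered pairs; these index arrays gather pairs and scatter the
    results (and gradients) back to the full N x N layout.
    """

    __slots__ = ("n", "iu", "ju", "pair_map", "i_bounds", "j_perm", "j_bounds", "diag")

    def __init__(self, n: int):
        iu, ju = np.triu_indices(n)
        self.n = n
        self.iu, self.ju = iu, ju
        self.pair_map = np.empty((n, n), dtype=np.intp)
        arange = np.arange(iu.size)
        self.pair_map[iu, ju] = arange
        self.pair_map[ju, iu] = arange
        self.i_bounds = np.searchsorted(iu, np.arange(n))
        self.j_perm = np.argsort(ju, kind="stable")
        self.j_bounds = np.searchsorted(ju[self.j_perm], np.arange(n))
        self.diag = iu == ju


_PAIR_CACHE: dict = {}


def _pairs(n: int) -> _PairIndex:
    if n not in _PAIR_CACHE:
        _PAIR_CACHE[n] = _PairIndex(n)
    return _PAIR_CACHE[n]


def _pairwise_metric(V: Tensor, W1, b1, W2, b2, idx: _PairIndex, slope: float) -> Tensor:
    """Fused metric network over unordered pairs: sigmoid(f_theta(|v_i - v_j|)).

    Computes the C'' rows for the M = N(N+1)/2 unordered pairs, pushes them
    through the 1x1 conv stack (d -> h, LeakyReLU, h -> 1) and the logistic
    squash, returning (..., M).  Forward and backward are hand-fused: the
    intermediate (..., M, d) blocks dominate the model's run time, so this op
    keeps the temporaries to the minimum the chain rule needs.
    """
    left = V.data[..., idx.iu, :]
    diff = np.subtract(left, V.data[..., idx.ju, :], out=left)
    sgn = np.sign(diff) if V.requires_grad else None
    np.abs(diff, out=diff)
    h1 = diff @ W1.data
    h1 += b1.data
    factor = np.where(h1 > 0, 1.0, slope)
    h1 *= factor  # h1 is now the post-LeakyReLU activation
    s = (h1 @ W2.data)[..., 0]
    s += b2.data[0]
    out = 1.0 / (1.0 + np.exp(-s))

    def backward(g, V=V, W1=W1, b1=b1, W2=W2, b2=b2, idx=idx,
                 diff=diff, sgn=sgn, act=h1, factor=factor, out=out):
        gs = g * out * (1.0 - out)  # (..., M)
        d, h = W1.data.shape
        b2._accum(np.array([gs.sum()]))
        W2._accum((act.reshape(-1, h).T @ gs.reshape(-1))[:, None])
        gh = gs[..., None] * W2.data[:, 0]
        gh *= factor
        flat_gh = gh.reshape(-1, h)
        b1._accum(flat_gh.sum(axis=0))
        W1._accum(diff.reshape(-1, d).T @ flat_gh)
        if sgn is not None:
            gdiff = gh @ W1.data.T
            gdiff *= sgn
            gV = np.add.reduceat(gdiff, idx.i_bounds, axis=-2)
            gV -= np.add.reduceat(gdiff[..., idx.j_perm, :], idx.j_bounds, axis=-2)
            V._accum(gV)

    return Tensor._make(out, (V, W1, b1, W2, b2), backward)


def _expand_pairs(w: Tensor, idx: _PairIndex) -> Tensor:
    """Scatter per-pair values (..., M) into the symmetric (..., N, N) matrix."""

    def backward(g, w=w, idx=idx):
        gv = g[..., idx.iu, idx.ju] + g[..., idx.ju, idx.iu]
        gv[..., idx.diag] -= g[..., idx.iu[idx.diag], idx.ju[idx.diag]]
        w._accum(gv)

    return Tensor._make(w.data[..., idx.pair_map], (w,), backward)


def edge_weight_matrix(V, params, slope: float = 0.01):
    """Learned-metric edge weights W from node representations V (..., N, d).

    ``params`` holds the 1x1 conv stack (W1: d x h, b1, W2: h x 1, b2).
    W_ij = sigmoid(f_theta(|v_i - v_j|)); symmetric by construction (f_theta
    is evaluated once per unordered pair), and the diagonal is computed like
    any pair (c''_ii = 0).
    """
    Vt = _wrap(V)
    if not np.all(np.isfinite(Vt.data)):
        raise ValueError("non-finite node features")
    idx = _pairs(Vt.shape[-2])
    wvec = _pairwise_metric(
        Vt, _wrap(params["W1"]), _wrap(params["b1"]),
        _wrap(params["W2"]), _wrap(params["b2"]), idx, slope,
    )
    W = _expand_pairs(wvec, idx)
    return _maybe_data(W, V)


def edge_constraint_matrix(R, tau=1.0):
    """Risk-factor edge constraints: E_ij = prod_k exp(-(r_ik - r_jk)^2 / tau_k).

    R is (..., N, K) of standardized risk values; tau is a scalar or length-K
    vector of positive bandwidths.  E is in (0, 1], symmetric, unit diagonal.
    With K = 0 the constraint is inactive (all-ones).
    """
    R = np.asarray(R, dtype=np.float64)
    K = R.shape[-1]
    tau_vec = np.broadcast_to(np.asarray(tau, dtype=np.float64), (K,)).copy()
    if K and np.any(tau_vec <= 0):
        raise ValueError("bandwidths tau must be positive")
    n = R.shape[-2]
    if K == 0:
        return np.ones(R.shape[:-2] + (n, n))
    diff = R[..., :, None, :] - R[..., None, :, :]
    return np.exp(-((diff**2) / tau_vec).sum(axis=-1))


def adjacency(W, E):
    """Row-normalized elementwise product: A~_ij = W_ij E_ij / sum_m W_im E_im."""
    Wt, Et = _wrap(W), _wrap(E)
    if Wt.shape != Et.shape:
        raise ValueError(f"shape mismatch: W {Wt.shape} vs E {Et.shape}")
    M = Wt * Et
    row_sums = M.data.sum(axis=-1)
    if np.any(row_sums <= 0):
        raise DegenerateGraphError("a node has zero total edge mass; cannot normalize")
    A = M / M.sum(axis=-1, keepdims=True)
    return _maybe_data(A, W, E)


def layer_forward(V, A, params, slope: float = 0.01):
    """One graph layer: V_{l+1} = [V || LeakyReLU(FC(A~ V))]."""
    Vt, At = _wrap(V), _wrap(A)
    if At.shape[-1] != Vt.shape[-2]:
        raise ValueError(f"adjacency {At.shape} does not conform with nodes {Vt.shape}")
    Gn = (At @ Vt @ _wrap(params["W"]) + _wrap(params["b"])).leaky_relu(slope)
    out = concat([Vt, Gn], axis=-1)
    return _maybe_data(out, V, A)


def _initial_representation(episode_features, support_labels, n_query, n_way):
    """Append label channels: one-hot for support rows, uniform for query rows."""
    feats = np.asarray(episode_features, dtype=np.float64)
    lead = feats.shape[:-2]
    n = feats.shape[-2]
    n_support = n - n_query
    lab = np.full(lead + (n, n_way), 1.0 / n_way)
    onehot = np.eye(n_way)[np.asarray(support_labels, dtype=np.int64)]
    lab[..., :n_support, :] = onehot
    return np.concatenate([feats, lab], axis=-1)


def _forward_graph(X0: np.ndarray, E: np.ndarray, params: dict, cfg: AMGNNConfig):
    """Shared forward over (..., N, d_in) batches; returns query logits Tensor."""
    V = Tensor(X0)
    Et = Tensor(E)
    for layer in (1, 2):
        p = {k.split("_", 1)[1]: params[k] for k in params if k.startswith(f"m{layer}_")}
        W = edge_weight_matrix(V, p, cfg.leaky_slope)
        A = adjacency(W, Et)
        V = layer_forward(V, A, {"W": params[f"fc{layer}_W"], "b": params[f"fc{layer}_b"]}, cfg.leaky_slope)
    # final update block feeds the head directly (no concatenation at the end)
    width = cfg.hidden_dim
    G2 = V[..., slice(V.shape[-1] - width, V.shape[-1])]
    logits = G2 @ params["head_W"] + params["head_b"]
    return logits


def forward(episode: Episode, params: dict, cfg: AMGNNConfig | None = None) -> np.ndarray:
    """Class probabilities (n_query x n_way) for one episode's query nodes."""
    cfg = cfg or AMGNNConfig()
    feats = episode.node_features
    if cfg.concat_risk_to_nodes and episode.risk_values.shape[-1]:
        feats = np.concatenate([episode.risk_values, feats], axis=-1)
    X0 = _initial_representation(feats, episode.support_labels, episode.n_query, cfg.n_way)
    if cfg.use_constraints and episode.risk_values.shape[-1] == 0:
        raise EpisodeError("edge constraints requested but the episode has no risk factors")
    E = (
        edge_constraint_matrix(episode.risk_values, cfg.tau)
        if cfg.use_constraints
        else np.ones((X0.shape[-2], X0.shape[-2]))
    )
    logits = _forward_graph(X0, E, params, cfg)
    q = logits.data[-episode.n_query :, :]
    return softmax(q, axis=-1)


# ---------------------------------------------------------------------------
# Model / Results


class AutoMetricGNN:
    """Auto-metric GNN staging model over a labelled training pool.

    Parameters
    ----------
    table, labels
        Training pool (features should already be standardized).
    spec
        Combination vector: risk-factor names (gate edges) and node-feature
        names (per-node representation).
    config / **overrides
        :class:`AMGNNConfig` fields.
    """

    def __init__(
        self,
        table: FeatureTable,
        labels: StageLabels,
        spec: CombinationVectorSpec,
        config: AMGNNConfig | None = None,
        **overrides,
    ):
        if not labels.aligned_with(table):
            raise EpisodeError("labels not aligned with feature table")
        cfg = config or AMGNNConfig()
        if overrides:
            cfg = AMGNNConfig(**{**asdict(cfg), **overrides})
        if cfg.use_constraints and spec.K == 0:
            raise EpisodeError("edge constraints enabled but the combination vector has K=0 risk factors")
        self.table = table
        self.labels = labels
        self.spec = spec
        self.config = cfg
        d_in = spec.d + (spec.K if cfg.concat_risk_to_nodes else 0) + cfg.n_way
        self._d_in = d_in

    @classmethod
    def from_dataframe(cls, df, spec: CombinationVectorSpec, stage_column: str = "gold_stage", **kw):
        labels = StageLabels(list(df.index), df[stage_column].to_numpy())
        table = FeatureTable.from_dataframe(df.drop(columns=[stage_column]))
        return cls(table, labels, spec, **kw)

    # -- parameters ----------------------------------------------------------
    def init_params(self, rng: np.random.Generator) -> dict:
        cfg = self.config
        d1 = self._d_in
        d2 = d1 + cfg.hidden_dim
        shapes = {}
        for layer, d in ((1, d1), (2, d2)):
            h = cfg.metric_width(d)
            shapes[f"m{layer}_W1"] = (d, h)
            shapes[f"m{layer}_b1"] = (h,)
            shapes[f"m{layer}_W2"] = (h, 1)
            shapes[f"m{layer}_b2"] = (1,)
            shapes[f"fc{layer}_W"] = (d, cfg.hidden_dim)
            shapes[f"fc{layer}_b"] = (cfg.hidden_dim,)
        shapes["head_W"] = (cfg.hidden_dim, cfg.n_way)
        shapes["head_b"] = (cfg.n_way,)
        params = {}
        for name, shape in shapes.items():
            if name.endswith("b") or name.endswith("b1") or name.endswith("b2"):
                params[name] = Tensor(np.zeros(shape), requires_grad=True)
            else:
                scale = np.sqrt(2.0 / (shape[0] + shape[-1]))
                params[name] = Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)
        return params

    # -- episode batching -----------------------------------------------------
    def _batch(self, rng: np.random.Generator, size: int):
        cfg = self.config
        episodes = [
            sample_episode(
                self.table, self.labels, self.spec, cfg.n_way, cfg.k_shot, cfg.n_query, rng
            )
            for _ in range(size)
        ]
        return self._stack(episodes)

    def _stack(self, episodes):
        cfg = self.config
        feats = np.stack(
            [
                np.concatenate([e.risk_values, e.node_features], axis=-1)
                if cfg.concat_risk_to_nodes and e.risk_values.shape[-1]
                else e.node_features
                for e in episodes
            ]
        )
        X0 = np.stack(
            [
                _initial_representation(f, e.support_labels, e.n_query, cfg.n_way)
                for f, e in zip(feats, episodes)
            ]
        )
        if cfg.use_constraints:
            E = np.stack([edge_constraint_matrix(e.risk_values, cfg.tau) for e in episodes])
        else:
            n = X0.shape[-2]
            E = np.ones((len(episodes), n, n))
        qlab = np.stack(
            [e.query_labels for e in episodes]
        ) if episodes[0].query_labels is not None else None
        return X0, E, qlab

    # -- meta-training ---------------------------------------------------------
    def fit(self, iterations: int | None = None, callback=None) -> "AMGNNResults":
        """Episodic meta-training: one Adam step per iteration on a batch of
        ``batch_size`` independent episodes; returns the fitted results."""
        cfg = self.config
        iterations = cfg.iterations if iterations is None else iterations
        rng = np.random.default_rng(cfg.seed)
        params = self.init_params(rng)
        opt = Adam(params, lr=cfg.learning_rate)
        history = np.empty(iterations)
        nq = cfg.n_query
        for it in range(iterations):
            X0, E, qlab = self._batch(rng, cfg.batch_size)
            logits = _forward_graph(X0, E, params, cfg)
            qlogits = logits[:, -nq:, :] if nq else logits
            loss = cross_entropy_with_logits(qlogits, qlab)
            opt.zero_grad()
            loss.backward()
            opt.step()
            history[it] = float(loss.data)
            if not np.isfinite(history[it]):
                raise FloatingPointError(f"non-finite loss at iteration {it}")
            if callback is not None:
                callback(it, history[it])
        return AMGNNResults(self, params, history)


class AMGNNResults:
    """Fitted auto-metric GNN: parameters, loss history, prediction, summary."""

    def __init__(self, model: AutoMetricGNN, params: dict, loss_history: np.ndarray):
        self.model = model
        self.params = params
        self.loss_history = np.asarray(loss_history, dtype=np.float64)

    @property
    def config(self) -> AMGNNConfig:
        return self.model.config

    # -- inference ---------------------------------------------------------
    def predict_proba(
        self,
        table: FeatureTable,
        ensemble: int | None = None,
        seed: int = 0,
    ) -> np.ndarray:
        """Mean query softmax over `ensemble` independently drawn support graphs.

        Each row of `table` is inserted as the single unknown node of each
        episode; supports are drawn from the training pool.
        """
        cfg = self.config
        ensemble = cfg.ensemble_size if ensemble is None else ensemble
        rng = np.random.default_rng(seed)
        node, risk = _matrices_from_pool(
            table.select_features(self.model.table.feature_names), self.model.spec
        )
        probs = np.zeros((table.n_samples, cfg.n_way))
        # each test row becomes the single unknown node of its own episodes;
        # forwards run in training-sized chunks to bound the working set
        for _ in range(ensemble):
            episodes = []
            for i in range(table.n_samples):
                ep = sample_episode(
                    self.model.table, self.model.labels, self.model.spec,
                    cfg.n_way, cfg.k_shot, 0, rng,
                )
                episodes.append(
                    Episode(
                        support_ids=ep.support_ids,
                        query_ids=[f"__query_{i}"],
                        node_features=np.vstack([ep.node_features, node[i]]),
                        risk_values=np.vstack([ep.risk_values, risk[i]])
                        if risk.shape[-1]
                        else np.zeros((ep.n_support + 1, 0)),
                        support_labels=ep.support_labels,
                    )
                )
            chunk = max(cfg.batch_size, 1)
            for lo in range(0, len(episodes), chunk):
                sub = episodes[lo : lo + chunk]
                X0, E, _ = self.model._stack(sub)
                logits = _forward_graph(X0, E, self.params, cfg)
                probs[lo : lo + chunk] += softmax(logits.data[:, -1, :], axis=-1)
        return probs / ensemble

    def predict(self, table: FeatureTable, ensemble: int | None = None, seed: int = 0):
        probs = self.predict_proba(table, ensemble=ensemble, seed=seed)
        return probs.argmax(axis=-1), probs  # argmax ties resolve to the lowest stage

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        cfg = self.config
        n_params = sum(p.data.size for p in self.params.values())
        lines = [
            "Auto-Metric Graph Neural Network Results",
            "=" * 46,
            f"{'episodes per step':<28}{cfg.batch_size}",
            f"{'episode shape':<28}{cfg.n_way}-way-{cfg.k_shot}-shot + {cfg.n_query} query",
            f"{'node features (d)':<28}{self.model.spec.d}",
            f"{'risk factors (K)':<28}{self.model.spec.K}",
            f"{'learnable parameters':<28}{n_params}",
            f"{'iterations run':<28}{self.loss_history.size}",
        ]
        if self.loss_history.size:
            k = min(50, self.loss_history.size)
            lines += [
                f"{'mean loss (first 50 it)':<28}{self.loss_history[:k].mean():.4f}",
                f"{'mean loss (last 50 it)':<28}{self.loss_history[-k:].mean():.4f}",
                f"{'final loss':<28}{self.loss_history[-1]:.4f}",
            ]
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(1, self.loss_history.size + 1), self.loss_history)
        ax.set_xlabel("iteration")
        ax.set_ylabel("mean episode cross-entropy")
        return ax

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "format": "copdstage-amgnn-checkpoint-v1",
            "config": asdict(self.config),
            "spec": {
                "risk_factors": list(self.model.spec.risk_factors),
                "node_features": list(self.model.spec.node_features),
            },
            "params": {k: p.data.tolist() for k, p in self.params.items()},
            "loss_history": self.loss_history.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path, table: FeatureTable, labels: StageLabels) -> "AMGNNResults":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        spec = CombinationVectorSpec(
            payload["spec"]["risk_factors"], payload["spec"]["node_features"]
        )
        cfg = AMGNNConfig(**payload["config"])
        model = AutoMetricGNN(table, labels, spec, config=cfg)
        params = {k: Tensor(np.array(v), requires_grad=True) for k, v in payload["params"].items()}
        return cls(model, params, np.array(payload["loss_history"]))
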