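"""Graph-transformer quality-assessment network.

Three components, each followed by learned top-k node pooling:

1. a GPS-style block mixing information globally (multi-head attention over
   every node pair) and locally (a GINE-style aggregation of each node's
   edge-featured neighborhood), with a residual sum;
2. a TransformerConv-style block: attention-weighted message passing along
   the remaining edges;
3. the same attention block run on the graph pruned to protein-RNA edges
   only, an inductive bias focusing capacity on the interface.

Three global-attention-pooling heads read out of the final node embeddings
concatenated with the raw interface and polymer indicator channels: a fold
head (3 outputs), an interface head (3 outputs) and a per-interface head (2
outputs, applied once per protein-RNA interface with attention masked to
that interface's surviving nodes). GraphNorm and ReLU are used throughout;
every output passes through a sigmoid, so predictions live in (0, 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, segment_softmax, segment_sum
from .graph import ComplexGraph

__all__ = ["ModelConfig", "QAOutput", "init_model", "forward", "predict", "ensemble_predict"]


@dataclass(frozen=True)
class ModelConfig:
    hidden_dim: int = 64
    attention_heads: int = 4
    topk_ratio: tuple[float, float, float] = (0.8, 0.8, 0.8)
    dropout: float = 0.1
    head_hidden: int = 32
    node_channels: int = 66
    edge_channels: int = 12
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dim <= 0 or self.head_hidden <= 0:
            raise ValueError("dimensions must be positive")
        if self.hidden_dim % self.attention_heads != 0:
            raise ValueError("hidden_dim must be divisible by attention_heads")
        if not all(0.0 < r <= 1.0 for r in self.topk_ratio):
            raise ValueError("topk ratios must lie in (0, 1]")


@dataclass
class QAOutput:
    """Predicted qualities, all in (0, 1).

    fold  = (bb-lDDT, GDT-TS, GDT-HA) estimates;
    iface = (iLDDT, IPS, ICS) estimates;
    per_interface = [(protein_chain, rna_chain), (IPS, ICS)] per interface.
    """

    fold: np.ndarray
    iface: np.ndarray
    per_interface: list[tuple[tuple[str, str], np.ndarray]] = field(default_factory=list)

    def detach(self) -> "QAOutput":
        def _d(x):
            return x.data.copy() if isinstance(x, Tensor) else np.asarray(x, float)

        return QAOutput(
            fold=_d(self.fold),
            iface=_d(self.iface),
            per_interface=[(k, _d(v)) for k, v in self.per_interface],
        )


def save_checkpoint(path, params: dict[str, Tensor], config: ModelConfig, layout_version: str):
    """Serialize parameters + config + feature-layout version (npz)."""
    import json

    meta = json.dumps({"config": {**config.__dict__}, "layout_version": layout_version})
    np.savez(path, __meta__=np.array(meta), **{k: v.data for k, v in params.items()})


def load_checkpoint(path, expect_layout_version: str | None = None):
    """Load a checkpoint; refuses to score across layout versions."""
    import json

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        params = {k: Tensor.param(z[k]) for k in z.files if k != "__meta__"}
    cfg_dict = meta["config"]
    cfg_dict["topk_ratio"] = tuple(cfg_dict["topk_ratio"])
    config = ModelConfig(**cfg_dict)
    if expect_layout_version and meta["layout_version"] != expect_layout_version:
        raise ValueError(
            f"checkpoint layout {meta['layout_version']!r} != expected {expect_layout_version!r}"
        )
    return params, config, meta["layout_version"]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    s = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


def init_model(config: ModelConfig) -> dict[str, Tensor]:
    """Deterministic parameter initialization from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    d, h = config.hidden_dim, config.attention_heads
    dh = d // h
    ec, nc = config.edge_channels, config.node_channels
    p: dict[str, np.ndarray] = {}

    p["embed.W"] = _glorot(rng, nc, d)
    p["embed.b"] = np.zeros(d)

    # component 1: GPS-style global attention + GINE-style local aggregation
    for head in range(h):
        for name in ("q", "k", "v"):
            p[f"c1.attn.{name}{head}"] = _glorot(rng, d, dh)
    p["c1.attn.out"] = _glorot(rng, d, d)
    p["c1.gine.We"] = _glorot(rng, ec, d)
    p["c1.gine.W"] = _glorot(rng, d, d)
    p["c1.gine.b"] = np.zeros(d)
    p["c1.gn.gamma"] = np.ones(d)
    p["c1.gn.beta"] = np.zeros(d)
    p["pool1.p"] = rng.normal(size=d) / math.sqrt(d)

    # components 2 and 3: TransformerConv-style edge attention
    for c in ("c2", "c3"):
        for head in range(h):
            for name in ("q", "k", "v"):
                p[f"{c}.{name}{head}"] = _glorot(rng, d, dh)
            p[f"{c}.ek{head}"] = _glorot(rng, ec, dh)
            p[f"{c}.ev{head}"] = _glorot(rng, ec, dh)
        p[f"{c}.skip"] = _glorot(rng, d, d)
        p[f"{c}.b"] = np.zeros(d)
        p[f"{c}.gn.gamma"] = np.ones(d)
        p[f"{c}.gn.beta"] = np.zeros(d)
    p["pool2.p"] = rng.normal(size=d) / math.sqrt(d)
    p["pool3.p"] = rng.normal(size=d) / math.sqrt(d)

    # heads: global attention pooling over [embedding | iface flag | polymer flag]
    zdim = d + 2
    for head_name, n_out in (("fold", 3), ("iface", 3), ("perif", 2)):
        p[f"{head_name}.gate.W1"] = _glorot(rng, zdim, config.head_hidden)
        p[f"{head_name}.gate.b1"] = np.zeros(config.head_hidden)
        p[f"{head_name}.gate.W2"] = _glorot(rng, config.head_hidden, 1)
        p[f"{head_name}.gate.b2"] = np.zeros(1)
        p[f"{head_name}.value.W"] = _glorot(rng, zdim, d)
        p[f"{head_name}.out.W"] = _glorot(rng, d, n_out)
        p[f"{head_name}.out.b"] = np.zeros(n_out)

    return {k: Tensor.param(v) for k, v in p.items()}


def parameter_count(params: dict[str, Tensor]) -> int:
    return sum(t.data.size for t in params.values())


def _graphnorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=0, keepdims=True)
    xc = x - mu
    var = xc.pow_const(2.0).mean(axis=0, keepdims=True)
    return xc / (var + eps).sqrt() * gamma + beta


def _mha(x: Tensor, p: dict, prefix: str, heads: int) -> Tensor:
    dh_scale = None
    outs = []
    for head in range(heads):
        q = x @ p[f"{prefix}.q{head}"]
        k = x @ p[f"{prefix}.k{head}"]
        v = x @ p[f"{prefix}.v{head}"]
        if dh_scale is None:
            dh_scale = 1.0 / math.sqrt(q.shape[1])
        scores = (q @ _transpose(k)) * dh_scale
        attn = scores.softmax(axis=1)
        outs.append(attn @ v)
    return concat(outs, axis=1) @ p[f"{prefix}.out"]


def _transpose(t: Tensor) -> Tensor:
    out = Tensor(t.data.T, parents=(t,))
    out._backward = lambda g: (g.T,)
    return out


def _transformer_conv(
    x: Tensor, e: np.ndarray, arcs: np.ndarray, p: dict, prefix: str, heads: int
) -> Tensor:
    n = x.shape[0]
    outs = []
    et = Tensor(e)
    if len(arcs):
        src, dst = arcs[:, 0], arcs[:, 1]
    for head in range(heads):
        if not len(arcs):
            outs.append(Tensor(np.zeros((n, p[f"{prefix}.v{head}"].shape[1]))))
            continue
        q = (x @ p[f"{prefix}.q{head}"]).gather_rows(dst)
        k = (x @ p[f"{prefix}.k{head}"]).gather_rows(src) + et @ p[f"{prefix}.ek{head}"]
        v = (x @ p[f"{prefix}.v{head}"]).gather_rows(src) + et @ p[f"{prefix}.ev{head}"]
        score = (q * k).sum(axis=1) * (1.0 / math.sqrt(q.shape[1]))
        alpha = segment_softmax(score, dst, n)
        outs.append(segment_sum(v * alpha.reshape(-1, 1), dst, n))
    agg = concat(outs, axis=1)
    return _graphnorm(
        (x @ p[f"{prefix}.skip"] + p[f"{prefix}.b"] + agg).relu(),
        p[f"{prefix}.gn.gamma"],
        p[f"{prefix}.gn.beta"],
    )


def _topk(x: Tensor, p_vec: Tensor, ratio: float, arcs: np.ndarray, e: np.ndarray):
    """Learned top-k pooling: keep ceil(ratio*N) nodes by projection score,
    gate survivors by sigmoid(score); ties broken by node index."""
    n = x.shape[0]
    k = math.ceil(ratio * n)
    norm = p_vec.pow_const(2.0).sum().sqrt() + 1e-12
    score = (x @ p_vec) / norm
    order = np.lexsort((np.arange(n), -score.data))
    keep = np.sort(order[:k])
    gate = score.gather_rows(keep).sigmoid()
    x_new = x.gather_rows(keep) * gate.reshape(-1, 1)
    remap = -np.ones(n, dtype=int)
    remap[keep] = np.arange(k)
    if len(arcs):
        ok = (remap[arcs[:, 0]] >= 0) & (remap[arcs[:, 1]] >= 0)
        arcs_new = remap[arcs[ok]]
        e_new = e[ok]
    else:
        arcs_new, e_new = arcs, e
    return x_new, arcs_new, e_new, keep


def _gap_head(z: Tensor, p: dict, prefix: str, mask: np.ndarray | None = None) -> Tensor:
    u = ((z @ p[f"{prefix}.gate.W1"] + p[f"{prefix}.gate.b1"]).relu()
         @ p[f"{prefix}.gate.W2"] + p[f"{prefix}.gate.b2"]).reshape(-1)
    alpha = u.softmax(axis=0, mask=mask)
    v = z @ p[f"{prefix}.value.W"]
    g = (v * alpha.reshape(-1, 1)).sum(axis=0)
    return (g @ p[f"{prefix}.out.W"] + p[f"{prefix}.out.b"]).sigmoid()


def forward(
    graph: ComplexGraph,
    params: dict[str, Tensor],
    config: ModelConfig,
    train_rng: np.random.Generator | None = None,
) -> QAOutput:
    """One pass of the network; returns sigmoid outputs as Tensors (keeps
    the autodiff graph alive for training; call ``.detach()`` to get plain
    arrays)."""
    if graph.node_feat is None or graph.edge_feat is None:
        raise ValueError("graph must be featurized first")
    n = graph.n_nodes
    if n == 0:
        raise ValueError("empty graph")
    heads = config.attention_heads

    flags = np.column_stack([graph.interface_mask.astype(float), graph.polymer_flags])

    def _dropout(t: Tensor) -> Tensor:
        if train_rng is None or config.dropout <= 0.0:
            return t
        keep = (train_rng.random(t.shape) >= config.dropout).astype(float)
        return t * (keep / (1.0 - config.dropout))

    x = Tensor(graph.node_feat) @ params["embed.W"] + params["embed.b"]
    arcs, e = graph.arcs, graph.edge_feat

    # component 1: global attention + local edge-featured aggregation
    attn = _mha(x, params, "c1.attn", heads)
    if len(arcs):
        src, dst = arcs[:, 0], arcs[:, 1]
        msg = (x.gather_rows(src) + Tensor(e) @ params["c1.gine.We"]).relu()
        local = (x + segment_sum(msg, dst, n)) @ params["c1.gine.W"] + params["c1.gine.b"]
    else:
        local = x @ params["c1.gine.W"] + params["c1.gine.b"]
    x1 = _graphnorm((x + attn + local).relu(), params["c1.gn.gamma"], params["c1.gn.beta"])
    x1 = _dropout(x1)
    x1p, arcs, e, keep1 = _topk(x1, params["pool1.p"], config.topk_ratio[0], arcs, e)
    orig = np.arange(n)[keep1]

    # component 2: attention message passing
    x2 = _dropout(_transformer_conv(x1p, e, arcs, params, "c2", heads))
    x2p, arcs, e, keep2 = _topk(x2, params["pool2.p"], config.topk_ratio[1], arcs, e)
    orig = orig[keep2]

    # prune to protein-RNA edges
    if len(arcs):
        pr = flags[orig[arcs[:, 0]], 1] != flags[orig[arcs[:, 1]], 1]
        arcs, e = arcs[pr], e[pr]

    # component 3 on the pruned graph
    x3_pre = _dropout(_transformer_conv(x2p, e, arcs, params, "c3", heads))
    x3, arcs, e, keep3 = _topk(x3_pre, params["pool3.p"], config.topk_ratio[2], arcs, e)
    orig_pre = orig
    orig = orig[keep3]

    def _z(embed: Tensor, node_ids: np.ndarray) -> Tensor:
        return concat([embed, Tensor(flags[node_ids])], axis=1)

    z = _z(x3, orig)
    fold = _gap_head(z, params, "fold")
    iface = _gap_head(z, params, "iface")

    per = []
    for idx, pair in enumerate(graph.interfaces):
        pc, rc = pair
        chain_ids = np.array([graph.residues[i].chain_id for i in orig])
        mask = (chain_ids == pc) | (chain_ids == rc)
        if mask.any():
            per.append((pair, _gap_head(z, params, "perif", mask=mask)))
            continue
        # all of this interface's nodes were pooled away: fall back to the
        # pre-pooling embeddings of the same component
        chain_pre = np.array([graph.residues[i].chain_id for i in orig_pre])
        mask_pre = (chain_pre == pc) | (chain_pre == rc)
        if mask_pre.any():
            z_pre = _z(x3_pre, orig_pre)
            per.append((pair, _gap_head(z_pre, params, "perif", mask=mask_pre)))
        else:
            # chains vanished earlier in the pipeline: pool over the raw
            # embedding of the interface's nodes (always present in G0/G1)
            chain_all = np.array([r.chain_id for r in graph.residues])
            mask_all = (chain_all == pc) | (chain_all == rc)
            z_all = _z(x1, np.arange(n))
            per.append((pair, _gap_head(z_all, params, "perif", mask=mask_all)))

    return QAOutput(fold=fold, iface=iface, per_interface=per)


def predict(graph: ComplexGraph, params: dict[str, Tensor], config: ModelConfig) -> QAOutput:
    """Inference pass returning plain numpy outputs."""
    return forward(graph, params, config).detach()


def ensemble_predict(
    graph: ComplexGraph, params_list: list[dict[str, Tensor]], config: ModelConfig
) -> QAOutput:
    """Arithmetic mean of member predictions, aligned by interface identity."""
    if not params_list:
        raise ValueError("need at least one parameter set")
    outs = [predict(graph, p, config) for p in params_list]
    ref_ifaces = [k for k, _ in outs[0].per_interface]
    for o in outs[1:]:
        if [k for k, _ in o.per_interface] != ref_ifaces:
            raise ValueError("ensemble members disagree on interface sets")
    per = [
        (pair, np.mean([dict(o.per_interface)[pair] for o in outs], axis=0))
        for pair in ref_ifaces
    ]
    return QAOutput(
        fold=np.mean([o.fold for o in outs], axis=0),
        iface=np.mean([o.iface for o in outs], axis=0),
        per_interface=per,
    )
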