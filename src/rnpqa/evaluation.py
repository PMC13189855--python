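"""Ranking and selection statistics for quality predictors.

Implements the benchmark statistics used to compare estimators of model
accuracy: ranking loss, outlier-robust Z-scores and their weighted
combination (fold block 0.3, interface block 0.7), top-k summed Z with
negative clipping, iRMSD-based quantile selection metrics, per-interface
weighted correlations, and a zeroing-based feature sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ZScorePanel",
    "ranking_loss",
    "zscores",
    "z_casp16",
    "topk_sum_z",
    "quantile_scores",
    "selection_metrics",
    "per_interface_eval",
    "feature_sensitivity",
]


def ranking_loss(true_scores, predicted_scores) -> float:
    """Gap between the best true score and the true score of the
    predictor's top pick: ``|max(M) - M[argmax(Mhat)]|``. Argmax ties break
    to the first index."""
    m = np.asarray(true_scores, float)
    mh = np.asarray(predicted_scores, float)
    if m.size == 0 or m.shape != mh.shape:
        raise ValueError("nonempty aligned score vectors required")
    return float(abs(m.max() - m[int(np.argmax(mh))]))


def zscores(values, outlier_cut: float = -2.0) -> np.ndarray:
    """Two-pass Z-scores: first-pass outliers (Z < outlier_cut) are removed
    from the mean/std used for the final scores. Zero variance -> all 0."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("need >=2 values")
    sd = v.std()
    if sd == 0.0:
        return np.zeros_like(v)
    z1 = (v - v.mean()) / sd
    keep = z1 >= outlier_cut
    ref = v[keep]
    sd2 = ref.std()
    if sd2 == 0.0:
        return np.zeros_like(v)
    return (v - ref.mean()) / sd2


@dataclass
class ZScorePanel:
    """Per-model Z-scores of the six underlying quality metrics."""

    z_tm: np.ndarray
    z_gdt_ts: np.ndarray
    z_lddt: np.ndarray
    z_ics: np.ndarray
    z_ips: np.ndarray
    z_ilddt: np.ndarray


FOLD_BLOCK_WEIGHT = 0.3
IFACE_BLOCK_WEIGHT = 0.7


def z_casp16(panel: ZScorePanel) -> np.ndarray:
    """Weighted combined Z: 0.3*(0.3 Z_TM + 0.3 Z_GDT_TS + 0.4 Z_lDDT)
    + 0.7*(Z_ICS + Z_IPS + Z_ilDDT)/3."""
    for name in ("z_tm", "z_gdt_ts", "z_lddt", "z_ics", "z_ips", "z_ilddt"):
        if getattr(panel, name) is None:
            raise ValueError(f"missing Z component {name}")
    fold = 0.3 * panel.z_tm + 0.3 * panel.z_gdt_ts + 0.4 * panel.z_lddt
    iface = (panel.z_ics + panel.z_ips + panel.z_ilddt) / 3.0
    return FOLD_BLOCK_WEIGHT * fold + IFACE_BLOCK_WEIGHT * iface


def topk_sum_z(predicted, z, k: int = 3) -> float:
    """Sum of max(Z, 0) over the k models ranked best by the predictor.
    Ties in the predicted score break by model index (stable)."""
    mh = np.asarray(predicted, float)
    zv = np.asarray(z, float)
    if k > mh.size:
        raise ValueError("k exceeds number of models")
    order = np.lexsort((np.arange(mh.size), -mh))
    top = order[:k]
    return float(np.clip(zv[top], 0.0, None).sum())


def quantile_scores(irmsd) -> np.ndarray:
    """Q(x) = 100 * count(iRMSD >= x) / N for each model's own iRMSD x
    (the model itself included, so the best model scores 100)."""
    x = np.asarray(irmsd, float)
    if x.size == 0:
        return x
    return 100.0 * (x[None, :] >= x[:, None]).sum(axis=1) / x.size


TRUE_TOP_QUANTILE = 99.0


def selection_metrics(predicted, irmsd, k: int):
    """Top-k selection statistics against iRMSD quantiles.

    True top models have Q >= 99. Returns (success, recall_pct,
    avg_quantile, best_quantile) where success is 1.0 when any top-k pick
    is a true top model and recall is the percentage of true top models
    retrieved within the top k.
    """
    mh = np.asarray(predicted, float)
    x = np.asarray(irmsd, float)
    if k > mh.size:
        raise ValueError("k exceeds number of models")
    q = quantile_scores(x)
    true_top = q >= TRUE_TOP_QUANTILE
    order = np.lexsort((np.arange(mh.size), -mh))
    top = order[:k]
    success = 1.0 if true_top[top].any() else 0.0
    n_true = int(true_top.sum())
    recall = 100.0 * true_top[top].sum() / n_true if n_true else float("nan")
    return success, float(recall), float(q[top].mean()), float(q[top].max())


def per_interface_eval(
    entries,
    coverage_min: float = 0.6,
    equal_target_weight: bool = True,
):
    """Weighted per-interface correlation/RL aggregation.

    ``entries``: list of (target_id, interface, preds, truths, coverage).
    Entries with coverage < ``coverage_min`` are dropped; negative
    correlations are clipped to zero. With ``equal_target_weight`` each
    entry is weighted by 1/(number of surviving interfaces of its target),
    so every target contributes equally; otherwise entries weigh by the raw
    interface count of their target.
    Returns (weighted_spearman, weighted_pearson, weighted_rl).
    """
    kept = [e for e in entries if e[4] >= coverage_min]
    if not kept:
        raise ValueError("no entries pass the coverage filter")
    per_target = {}
    for target, *_ in kept:
        per_target[target] = per_target.get(target, 0) + 1
    num_s = num_p = num_r = den = 0.0
    for target, _iface, preds, truths, _cov in kept:
        preds = np.asarray(preds, float)
        truths = np.asarray(truths, float)
        if truths.std() == 0 or preds.std() == 0:
            sp = pe = 0.0
        else:
            sp = stats.spearmanr(preds, truths).statistic
            pe = stats.pearsonr(preds, truths).statistic
        sp = max(float(sp), 0.0)
        pe = max(float(pe), 0.0)
        rl = ranking_loss(truths, preds)
        w = 1.0 / per_target[target] if equal_target_weight else float(per_target[target])
        num_s += w * sp
        num_p += w * pe
        num_r += w * rl
        den += w
    return num_s / den, num_p / den, num_r / den


def feature_sensitivity(params, config, graphs, channel, kind: str = "node") -> float:
    """Mean absolute change of the combined scores when one feature channel
    is zeroed across all nodes (or arcs) of every graph."""
    import copy

    from .combine import combined_scores
    from .model import predict

    if kind not in ("node", "edge"):
        raise ValueError("kind must be 'node' or 'edge'")
    width = graphs[0].node_feat.shape[1] if kind == "node" else graphs[0].edge_feat.shape[1]
    if not 0 <= channel < width:
        raise ValueError(f"channel {channel} outside {kind} layout width {width}")
    deltas = []
    for g in graphs:
        base = combined_scores(predict(g, params, config))
        g2 = copy.copy(g)
        if kind == "node":
            g2.node_feat = g.node_feat.copy()
            g2.node_feat[:, channel] = 0.0
        else:
            g2.edge_feat = g.edge_feat.copy()
            g2.edge_feat[:, channel] = 0.0
        alt = combined_scores(predict(g2, params, config))
        pairs = [
            (base.fold, alt.fold),
            (base.iface, alt.iface),
            (base.merged, alt.merged),
        ]
        if np.isfinite(base.rp) and np.isfinite(alt.rp):
            pairs.append((base.rp, alt.rp))
        deltas.extend(abs(a - b) for a, b in pairs)
    return float(np.mean(deltas))
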