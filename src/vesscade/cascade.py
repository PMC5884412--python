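"""Self-constructing cascade-AdaBoost-SVM classifier.

Samples carry a 5-feature vector per scale (6 scales by default → 30
channels addressed as (feature, scale)). Each cascade layer is, per scale, a
discrete-AdaBoost combination of interval weak classifiers
``h = 1 iff T_lower ≤ f ≤ T_upper``; the layer response is the maximum over
scales of the per-scale weighted vote sums, thresholded at a calibrated θ
(Viola–Jones-style: θ lowered until the layer's validation detection rate
meets the per-layer target d).

Training is self-constructing: layers are appended while the running product
of per-layer false-positive rates exceeds the overall target E_target. True
negatives rejected by a layer are removed from the negative pool; positives
always pass on. When an AdaBoost layer exhausts its weak-classifier budget
``n_th`` per scale without meeting (d, e), the layer is replaced by an RBF
SVM trained on exactly the feature channels AdaBoost had selected (the
layer's "feature queue") — the asymmetric class weighting and the kernel
non-linearity rescue the rear layers, where surviving negatives resemble the
positives and AdaBoost overfits.

Weight initialization is class-asymmetric: w_p = 1/(p+1), w_n = 1/(q(p+1)),
which satisfies w_p = q·w_n and p·w_p + q·w_n = 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CascadeTargets",
    "WeakClassifier",
    "AdaBoostLayer",
    "SVMLayer",
    "CascadeModel",
    "init_weights",
    "train_weak",
    "adaboost_round",
    "strong_response",
    "calibrate_layer_threshold",
    "train_adaboost_layer",
    "train_svm_layer",
    "train_cascade",
    "feature_utilization",
    "cascade_rates",
]

_EPS_CLAMP = 1e-10
_MAX_CUTS = 256


class CascadeTrainingError(RuntimeError):
    """Degenerate classes or a stalled layer during cascade construction."""


@dataclass(frozen=True)
class CascadeTargets:
    """Per-layer and overall rate targets of the self-constructing cascade.

    ``d``: minimum acceptable per-layer detection rate; ``e``: maximum
    acceptable per-layer false-positive rate; ``n_th``: weak-classifier
    budget per scale per layer; ``e_target``: overall false-positive target.
    """

    d: float = 0.99
    e: float = 0.3
    n_th: int = 15
    e_target: float = 6e-6


def init_weights(p: int, q: int) -> tuple[float, float]:
    """Class-asymmetric initial sample weights (w_p, w_n).

    Solves w_p = q·w_n with p·w_p + q·w_n = 1, giving positives jointly
    p/(p+1) of the total mass regardless of class imbalance.
    """
    if p < 1 or q < 1:
        raise CascadeTrainingError(f"degenerate class: p={p}, q={q}")
    w_p = 1.0 / (p + 1)
    w_n = 1.0 / (q * (p + 1))
    return w_p, w_n


@dataclass
class WeakClassifier:
    """Interval rule on one (feature, scale) channel: vote 1 inside [lo, hi]."""

    feature: int
    scale: int
    t_lower: float
    t_upper: float
    beta: float = 0.0
    degenerate: bool = False

    def votes(self, channel_values: np.ndarray) -> np.ndarray:
        x = np.asarray(channel_values)
        return ((x >= self.t_lower) & (x <= self.t_upper)).astype(np.float64)


def _interval_search(edges_lo: np.ndarray, edges_hi: np.ndarray,
                     signed_w: np.ndarray,
                     pos_total: float) -> tuple[float, float, float]:
    """Best interval over contiguous bins.

    A candidate interval covering bins a..b is [edges_lo[a], edges_hi[b]];
    the edges are chosen by the caller so that exactly the samples of those
    bins fall inside. ``signed_w`` is the per-bin (pos − neg) weight mass.
    Minimizes ε = pos_total − max_interval Σ signed_w; ties broken toward
    the wider interval, then the lower T_lower.
    """
    k = len(signed_w)
    prefix = np.concatenate([[0.0], np.cumsum(signed_w)])  # (k+1,)
    # gain[a, b] = prefix[b+1] - prefix[a]: mass of the interval of bins a..b.
    valid = np.triu(np.ones((k, k), dtype=bool))
    gain = np.where(valid, prefix[None, 1:] - prefix[:-1, None], -np.inf)
    best = gain.max()
    cand_a, cand_b = np.nonzero(gain >= best - 1e-15)
    widths = edges_hi[cand_b] - edges_lo[cand_a]
    wmax = widths.max()
    wide = widths >= wmax - 1e-15
    cand_a, cand_b = cand_a[wide], cand_b[wide]
    i = int(np.argmin(edges_lo[cand_a]))
    a, b = int(cand_a[i]), int(cand_b[i])
    eps = pos_total - float(gain[a, b])
    return float(edges_lo[a]), float(edges_hi[b]), eps


def train_weak(values: np.ndarray, labels: np.ndarray, weights: np.ndarray,
               feature: int = 0, scale: int = 0, *,
               max_cuts: int = _MAX_CUTS) -> tuple[WeakClassifier, float]:
    """Best interval weak classifier on one channel under sample weights.

    The semi-exhaustive search bins the channel at up to ``max_cuts``
    quantile cuts and searches all cut pairs with prefix sums, then refines
    the two chosen boundaries over the raw unique values adjacent to them.
    For ≤ ``max_cuts`` distinct values the search is exhaustive. A constant
    channel yields a degenerate classifier flagged as such, with
    ε = min(weighted class masses).
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    weights = np.asarray(weights, dtype=np.float64)
    signed = np.where(labels > 0, weights, -weights)
    pos_total = float(weights[labels > 0].sum())
    neg_total = float(weights[labels < 0].sum())
    uniq = np.unique(values)
    if len(uniq) == 1:
        wc = WeakClassifier(feature, scale, float(uniq[0]), float(uniq[0]),
                            degenerate=True)
        return wc, min(pos_total, neg_total)
    if len(uniq) <= max_cuts:
        # exhaustive: one bin per distinct value, thresholds halfway between
        cuts = uniq
        pad = max(1.0, abs(uniq[0]), abs(uniq[-1])) * 0.5
        mids = 0.5 * (uniq[1:] + uniq[:-1])
        edges_lo = np.concatenate([[uniq[0] - pad], mids])
        edges_hi = np.concatenate([mids, [uniq[-1] + pad]])
    else:
        qs = np.quantile(values, np.linspace(0.0, 1.0, max_cuts))
        cuts = np.unique(qs)
        pad = max(1.0, abs(cuts[0]), abs(cuts[-1])) * 0.5
        # bin i holds values in [cuts[i], cuts[i+1]): the interval edges must
        # include exactly those samples
        edges_lo = cuts.copy()
        edges_lo[0] = cuts[0] - pad
        edges_hi = np.concatenate([np.nextafter(cuts[1:], -np.inf),
                                   [cuts[-1] + pad]])
    bins = np.searchsorted(cuts, values, side="right") - 1
    bins = np.clip(bins, 0, len(cuts) - 1)
    signed_bins = np.bincount(bins, weights=signed, minlength=len(cuts))
    lo, hi, eps = _interval_search(edges_lo, edges_hi, signed_bins, pos_total)
    if len(uniq) > max_cuts:
        lo, hi, eps = _refine_interval(values, signed, pos_total, uniq, lo, hi, eps)
    # exact error of the returned thresholds (the contract the caller relies on)
    eps = pos_total - float(signed[(values >= lo) & (values <= hi)].sum())
    return WeakClassifier(feature, scale, lo, hi), eps


def _refine_interval(values, signed, pos_total, uniq, lo, hi, eps):
    """Local refinement: exhaustively try boundary candidates near (lo, hi)."""
    def window(edge: float) -> np.ndarray:
        i = np.searchsorted(uniq, edge)
        sel = uniq[max(0, i - 2):i + 2]
        if len(sel) == 0:
            return np.array([edge])
        mids = []
        for v in sel:
            j = np.searchsorted(uniq, v)
            left = uniq[j - 1] if j > 0 else v - 1.0
            right = uniq[j + 1] if j + 1 < len(uniq) else v + 1.0
            mids.extend([0.5 * (left + v), 0.5 * (v + right)])
        return np.unique(np.asarray(mids + [edge]))

    best = (lo, hi, eps)
    for cand_lo in window(lo):
        inside_lo = values >= cand_lo
        for cand_hi in window(hi):
            if cand_hi < cand_lo:
                continue
            gain = signed[inside_lo & (values <= cand_hi)].sum()
            e = pos_total - gain
            if e < best[2] - 1e-15:
                best = (float(cand_lo), float(cand_hi), float(e))
    return best


@dataclass
class AdaBoostLayer:
    """One cascade layer: per-scale boosted interval classifiers, max over scales."""

    weaks: list[list[WeakClassifier]]  # [scale][t]
    theta: float = 0.0
    achieved_d: float = float("nan")
    achieved_e: float = float("nan")
    queue: list[tuple[int, int]] = field(default_factory=list)  # (feature, scale)
    kind: str = "adaboost"

    @property
    def n_weaks(self) -> int:
        return sum(len(ws) for ws in self.weaks)

    def response(self, X: np.ndarray) -> np.ndarray:
        return strong_response(self, X)

    def passes(self, X: np.ndarray) -> np.ndarray:
        return self.response(X) >= self.theta


def strong_response(layer: AdaBoostLayer, X: np.ndarray) -> np.ndarray:
    """Multiscale strong-classifier response: max over scales of Σ_t β_t·h_t.

    ``X`` has shape (n, n_scales, 5).
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    best = np.full(n, -np.inf)
    any_scale = False
    for s, ws in enumerate(layer.weaks):
        if not ws:
            continue
        any_scale = True
        resp = np.zeros(n)
        for wc in ws:
            resp += wc.beta * wc.votes(X[:, wc.scale, wc.feature])
        best = np.maximum(best, resp)
    if not any_scale:
        return np.zeros(n)
    return best


def adaboost_round(X: np.ndarray, labels: np.ndarray, weights: np.ndarray,
                   scale: int) -> tuple[WeakClassifier, float, np.ndarray] | None:
    """One boosting round at one scale.

    Trains the five per-feature interval classifiers on the current weights,
    keeps the one with the lowest weighted error, computes
    β = ln((1−ε)/ε) (ε clamped to [1e−10, 0.5−1e−10]) and returns the
    reweighted, renormalized sample weights. Returns None when the best raw
    error reaches 0.5 (round rejected: boosting at this scale stops).
    """
    best: tuple[WeakClassifier, float] | None = None
    for f in range(X.shape[2]):
        wc, eps = train_weak(X[:, scale, f], labels, weights, f, scale)
        if wc.degenerate:
            continue
        if best is None or eps < best[1] - 1e-15:
            best = (wc, eps)
    if best is None:
        return None
    wc, eps = best
    if eps >= 0.5:
        return None
    eps_c = float(np.clip(eps, _EPS_CLAMP, 0.5 - _EPS_CLAMP))
    beta = float(np.log((1.0 - eps_c) / eps_c))
    wc.beta = beta
    votes = wc.votes(X[:, wc.scale, wc.feature])
    predicted_pos = votes > 0.5
    miscl = predicted_pos != (labels > 0)
    new_w = weights * np.exp(beta * miscl)
    new_w = new_w / new_w.sum()
    return wc, eps_c, new_w


def calibrate_layer_threshold(layer: AdaBoostLayer, X_val: np.ndarray,
                              y_val: np.ndarray, d_min: float) -> float:
    """Largest θ keeping the validation detection rate ≥ d_min.

    θ is placed at the response of the ⌈d_min·n⌉-th best validation positive,
    so lowering θ trades false positives for detections exactly as in an
    attentional cascade.
    """
    resp = layer.response(X_val)
    pos = resp[y_val > 0]
    if len(pos) == 0:
        raise CascadeTrainingError("validation set contains no positives")
    k = int(np.ceil(d_min * len(pos)))
    k = min(max(k, 1), len(pos))
    theta = float(np.sort(pos)[::-1][k - 1])
    layer.theta = theta
    layer.achieved_d = float(np.mean(pos >= theta))
    neg = resp[y_val < 0]
    layer.achieved_e = float(np.mean(neg >= theta)) if len(neg) else 0.0
    return theta


def _stratified_split(n_pos: int, n_neg: int, rng: np.random.Generator,
                      val_frac: float = 0.3) -> tuple[np.ndarray, np.ndarray]:
    """Boolean val-membership masks for positives and negatives."""
    def mask(n: int) -> np.ndarray:
        k = max(1, int(round(val_frac * n))) if n > 1 else 0
        m = np.zeros(n, dtype=bool)
        if n > 1:
            m[rng.choice(n, size=k, replace=False)] = True
        return m

    return mask(n_pos), mask(n_neg)


def train_adaboost_layer(pos: np.ndarray, neg: np.ndarray,
                         targets: CascadeTargets, rng: np.random.Generator,
                         ) -> tuple[AdaBoostLayer, bool]:
    """Train one AdaBoost layer; returns (layer, success).

    Rounds are added per scale (budget ``n_th`` per scale) until the
    calibrated layer meets d and e on a held-out stratified 30% split. On
    failure the returned layer carries the ordered feature queue for SVM
    substitution.
    """
    if len(pos) == 0 or len(neg) == 0:
        raise CascadeTrainingError("empty class")
    val_p, val_n = _stratified_split(len(pos), len(neg), rng)
    X_tr = np.concatenate([pos[~val_p], neg[~val_n]])
    y_tr = np.concatenate([np.ones((~val_p).sum()), -np.ones((~val_n).sum())])
    X_val = np.concatenate([pos[val_p], neg[val_n]])
    y_val = np.concatenate([np.ones(val_p.sum()), -np.ones(val_n.sum())])
    if not (y_val > 0).any():  # tiny positive pool: validate on training positives
        X_val = np.concatenate([X_val, pos])
        y_val = np.concatenate([y_val, np.ones(len(pos))])
    p, q = int((y_tr > 0).sum()), int((y_tr < 0).sum())
    w_p, w_n = init_weights(p, q)
    n_scales = pos.shape[1]
    weights = [np.where(y_tr > 0, w_p, w_n) for _ in range(n_scales)]
    layer = AdaBoostLayer(weaks=[[] for _ in range(n_scales)])
    active = [True] * n_scales
    for _ in range(targets.n_th):
        progressed = False
        for s in range(n_scales):
            if not active[s]:
                continue
            out = adaboost_round(X_tr, y_tr, weights[s], s)
            if out is None:
                active[s] = False
                continue
            wc, _, weights[s] = out
            layer.weaks[s].append(wc)
            layer.queue.append((wc.feature, wc.scale))
            progressed = True
        if not progressed:
            break
        calibrate_layer_threshold(layer, X_val, y_val, targets.d)
        if layer.achieved_e <= targets.e:
            return layer, True
    if layer.n_weaks == 0:
        raise CascadeTrainingError("no usable weak classifier (all channels degenerate)")
    calibrate_layer_threshold(layer, X_val, y_val, targets.d)
    return layer, layer.achieved_e <= targets.e


@dataclass
class SVMLayer:
    """RBF-SVM substitution layer on the AdaBoost-selected channels.

    Stores everything needed to evaluate the kernel machine without
    scikit-learn at predict time: standardization statistics, support
    vectors, dual coefficients, bias and the calibrated decision threshold.
    """

    channels: list[tuple[int, int]]  # unique (feature, scale), selection order
    mean: np.ndarray
    std: np.ndarray
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    theta: float = 0.0
    achieved_d: float = float("nan")
    achieved_e: float = float("nan")
    queue: list[tuple[int, int]] = field(default_factory=list)
    kind: str = "svm"

    def _decision(self, X: np.ndarray) -> np.ndarray:
        Z = _select_channels(X, self.channels)
        Z = (Z - self.mean) / self.std
        sv = self.support_vectors
        sv_norm = (sv * sv).sum(axis=1)
        out = np.empty(len(Z))
        chunk = max(1, 2_000_000 // max(len(sv), 1))
        for i in range(0, len(Z), chunk):
            z = Z[i:i + chunk]
            d2 = ((z * z).sum(axis=1)[:, None] + sv_norm[None, :]
                  - 2.0 * z @ sv.T)
            np.maximum(d2, 0.0, out=d2)
            out[i:i + chunk] = np.exp(-self.gamma * d2) @ self.dual_coef
        return out + self.intercept

    def response(self, X: np.ndarray) -> np.ndarray:
        return self._decision(np.asarray(X, dtype=np.float64))

    def passes(self, X: np.ndarray) -> np.ndarray:
        return self.response(X) >= self.theta


def _select_channels(X: np.ndarray, channels: list[tuple[int, int]]) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    return np.stack([X[:, s, f] for (f, s) in channels], axis=1)


def train_svm_layer(pos: np.ndarray, neg: np.ndarray,
                    channels: list[tuple[int, int]], targets: CascadeTargets,
                    rng: np.random.Generator, *, C: float = 1.0,
                    max_fit_per_class: int = 4000) -> SVMLayer:
    """Soft-margin RBF SVM on the feature channels a failed AdaBoost selected.

    Channels are standardized; classes are weighted inversely to their
    counts; the kernel bandwidth follows the median-pairwise-distance
    heuristic; the decision threshold is shifted so the validation detection
    rate meets the layer target d.
    """
    from sklearn.svm import SVC

    if not channels:
        raise CascadeTrainingError("SVM substitution requires a non-empty channel queue")
    if len(pos) == 0 or len(neg) == 0:
        raise CascadeTrainingError("empty class")
    uniq: list[tuple[int, int]] = []
    for ch in channels:
        if ch not in uniq:
            uniq.append(ch)
    val_p, val_n = _stratified_split(len(pos), len(neg), rng)
    tr_pos, tr_neg = pos[~val_p], neg[~val_n]
    if len(tr_pos) > max_fit_per_class:
        tr_pos = tr_pos[rng.choice(len(tr_pos), max_fit_per_class, replace=False)]
    if len(tr_neg) > max_fit_per_class:
        tr_neg = tr_neg[rng.choice(len(tr_neg), max_fit_per_class, replace=False)]
    X_tr = np.concatenate([tr_pos, tr_neg])
    y_tr = np.concatenate([np.ones(len(tr_pos)), -np.ones(len(tr_neg))])
    Z = _select_channels(X_tr, uniq)
    mean = Z.mean(axis=0)
    std = Z.std(axis=0)
    std[std < 1e-12] = 1.0
    Zs = (Z - mean) / std
    sub = Zs if len(Zs) <= 1500 else Zs[rng.choice(len(Zs), 1500, replace=False)]
    d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2)
    med = float(np.sqrt(np.median(d2[d2 > 0]))) if (d2 > 0).any() else 1.0
    gamma = 1.0 / (2.0 * med * med) if med > 0 else 1.0
    svc = SVC(C=C, kernel="rbf", gamma=gamma, class_weight="balanced")
    svc.fit(Zs, y_tr)
    layer = SVMLayer(
        channels=uniq, mean=mean, std=std,
        support_vectors=np.asarray(svc.support_vectors_, dtype=np.float64),
        dual_coef=np.asarray(svc.dual_coef_[0], dtype=np.float64),
        intercept=float(svc.intercept_[0]), gamma=gamma,
        queue=list(channels))
    X_val = np.concatenate([pos[val_p], neg[val_n]])
    y_val = np.concatenate([np.ones(val_p.sum()), -np.ones(val_n.sum())])
    if not (y_val > 0).any():
        X_val = np.concatenate([X_val, pos])
        y_val = np.concatenate([y_val, np.ones(len(pos))])
    resp = layer.response(X_val)
    vp = resp[y_val > 0]
    k = min(max(int(np.ceil(targets.d * len(vp))), 1), len(vp))
    layer.theta = float(np.sort(vp)[::-1][k - 1])
    layer.achieved_d = float(np.mean(vp >= layer.theta))
    vn = resp[y_val < 0]
    layer.achieved_e = float(np.mean(vn >= layer.theta)) if len(vn) else 0.0
    return layer


@dataclass
class CascadeModel:
    """Ordered cascade of AdaBoost / SVM layers with rate bookkeeping."""

    layers: list[AdaBoostLayer | SVMLayer]
    targets: CascadeTargets
    n_scales: int
    n_features: int = 5

    def overall_rates(self) -> tuple[float, float]:
        """(D, E): products of the per-layer achieved detection / FP rates."""
        d = float(np.prod([l.achieved_d for l in self.layers])) if self.layers else 1.0
        e = float(np.prod([l.achieved_e for l in self.layers])) if self.layers else 1.0
        return d, e

    def predict(self, X: np.ndarray) -> np.ndarray:
        pred, _ = self.predict_with_counts(X)
        return pred

    def predict_with_counts(self, X: np.ndarray) -> tuple[np.ndarray, list[int]]:
        """Classify samples; also return per-layer rejection counts.

        Rejection at any layer is final; later layers are only evaluated on
        survivors.
        """
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[1] != self.n_scales or X.shape[2] != self.n_features:
            raise ValueError(
                f"expected features of shape (n, {self.n_scales}, "
                f"{self.n_features}), got {X.shape}")
        if not self.layers:
            warnings.warn("empty cascade: vacuous pass for all samples")
            return np.ones(len(X), dtype=bool), []
        alive = np.ones(len(X), dtype=bool)
        counts: list[int] = []
        for layer in self.layers:
            idx = np.flatnonzero(alive)
            if len(idx) == 0:
                counts.append(0)
                continue
            ok = layer.passes(X[idx])
            rejected = idx[~ok]
            alive[rejected] = False
            counts.append(int(len(rejected)))
        return alive, counts

    def pass_depth(self, X: np.ndarray) -> np.ndarray:
        """Number of consecutive layers passed from the front, per sample.

        A sample with depth == n_layers is accepted by the full cascade; the
        depth profile along a ray decays from n_layers (inside the vessel)
        to 0 (background), which makes it a graded boundary indicator.
        """
        X = np.asarray(X, dtype=np.float64)
        depth = np.zeros(len(X))
        alive = np.ones(len(X), dtype=bool)
        for layer in self.layers:
            idx = np.flatnonzero(alive)
            if len(idx) == 0:
                break
            ok = layer.passes(X[idx])
            depth[idx[ok]] += 1
            alive[idx[~ok]] = False
        return depth

    # -- JSON serialization -------------------------------------------------

    def to_dict(self) -> dict:
        layers = []
        for l in self.layers:
            if isinstance(l, AdaBoostLayer):
                layers.append({
                    "kind": "adaboost",
                    "weaks": [[[w.feature, w.scale, w.t_lower, w.t_upper, w.beta]
                               for w in ws] for ws in l.weaks],
                    "theta": l.theta,
                    "achieved_d": l.achieved_d, "achieved_e": l.achieved_e,
                    "queue": [list(c) for c in l.queue],
                })
            else:
                layers.append({
                    "kind": "svm",
                    "channels": [list(c) for c in l.channels],
                    "mean": l.mean.tolist(), "std": l.std.tolist(),
                    "support_vectors": l.support_vectors.tolist(),
                    "dual_coef": l.dual_coef.tolist(),
                    "intercept": l.intercept, "gamma": l.gamma,
                    "theta": l.theta,
                    "achieved_d": l.achieved_d, "achieved_e": l.achieved_e,
                    "queue": [list(c) for c in l.queue],
                })
        return {"targets": {"d": self.targets.d, "e": self.targets.e,
                            "n_th": self.targets.n_th,
                            "e_target": self.targets.e_target},
                "n_scales": self.n_scales, "n_features": self.n_features,
                "layers": layers}

    @classmethod
    def from_dict(cls, obj: dict) -> "CascadeModel":
        targets = CascadeTargets(**obj["targets"])
        layers: list[AdaBoostLayer | SVMLayer] = []
        for ld in obj["layers"]:
            if ld["kind"] == "adaboost":
                weaks = [[WeakClassifier(int(f), int(s), lo, hi, beta)
                          for f, s, lo, hi, beta in ws] for ws in ld["weaks"]]
                layers.append(AdaBoostLayer(
                    weaks=weaks, theta=ld["theta"],
                    achieved_d=ld["achieved_d"], achieved_e=ld["achieved_e"],
                    queue=[tuple(c) for c in ld["queue"]]))
            else:
                layers.append(SVMLayer(
                    channels=[tuple(c) for c in ld["channels"]],
                    mean=np.asarray(ld["mean"]), std=np.asarray(ld["std"]),
                    support_vectors=np.asarray(ld["support_vectors"]),
                    dual_coef=np.asarray(ld["dual_coef"]),
                    intercept=ld["intercept"], gamma=ld["gamma"],
                    theta=ld["theta"],
                    achieved_d=ld["achieved_d"], achieved_e=ld["achieved_e"],
                    queue=[tuple(c) for c in ld["queue"]]))
        return cls(layers, targets, int(obj["n_scales"]), int(obj["n_features"]))

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str) -> "CascadeModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def train_cascade(pos: np.ndarray, neg: np.ndarray,
                  targets: CascadeTargets | None = None, seed: int = 0, *,
                  svm_enabled: bool = True, max_layers: int = 25,
                  stall_e: float | None = None,
                  verbose: bool = False) -> CascadeModel:
    """Self-constructing cascade training (the external loop).

    Layers are appended while the running false-positive product exceeds
    ``e_target``; true negatives are removed from the negative pool after
    each layer and positives always pass on. A failed AdaBoost layer is
    substituted by an SVM trained on its feature queue when ``svm_enabled``;
    otherwise (plain cascade-AdaBoost ablation) the best-effort AdaBoost
    layer is kept.

    Training also stops when the negative pool empties, at ``max_layers``,
    or when a layer stalls (validation false-positive rate ≥ ``stall_e``):
    the surviving negatives then sit inside the class-ambiguity band and a
    further layer would cost detection rate without reducing E. A stalled
    layer is discarded; a stall on the very first layer (the classes are
    inseparable outright) is an error. ``stall_e`` defaults to 0.98 with SVM
    substitution available, and to the pure no-progress guard (1 − 1e−9) in
    the AdaBoost-only ablation mode — the plain cascade has no second
    mechanism, so it keeps best-effort layers and grows deeper, as the
    reference architecture does. Fully deterministic for a fixed seed.
    """
    targets = targets or CascadeTargets()
    if stall_e is None:
        stall_e = 0.98 if svm_enabled else 1.0 - 1e-9
    pos = np.asarray(pos, dtype=np.float64)
    neg = np.asarray(neg, dtype=np.float64)
    if len(pos) == 0 or len(neg) == 0:
        raise CascadeTrainingError("both classes must be non-empty")
    rng = np.random.default_rng(seed)
    model = CascadeModel([], targets, pos.shape[1], pos.shape[2])
    e_running = 1.0
    while e_running > targets.e_target and len(neg) >= 2 and len(model.layers) < max_layers:
        layer, ok = train_adaboost_layer(pos, neg, targets, rng)
        if not ok and svm_enabled:
            layer = train_svm_layer(pos, neg, layer.queue, targets, rng)
        if layer.achieved_e >= stall_e:
            if not model.layers:
                raise CascadeTrainingError(
                    f"stalled at the first layer: kind={layer.kind}, "
                    f"achieved_e={layer.achieved_e:.4f}, negatives={len(neg)}")
            warnings.warn(
                f"cascade stalled at layer {len(model.layers) + 1} "
                f"(kind={layer.kind}, e={layer.achieved_e:.3f}); stopping with "
                f"E={e_running:.3g} above target {targets.e_target:g}")
            break
        model.layers.append(layer)
        e_running *= max(layer.achieved_e, 0.0)
        neg = neg[layer.passes(neg)]  # drop true negatives, keep false positives
        if verbose:
            print(f"layer {len(model.layers)}: kind={layer.kind} "
                  f"d={layer.achieved_d:.4f} e={layer.achieved_e:.4f} "
                  f"E={e_running:.3g} negatives left={len(neg)}")
        if e_running == 0.0:
            break
    return model


def feature_utilization(model: CascadeModel, rear_layer_count: int = 2) -> np.ndarray:
    """Percentage use of each feature f1..f5 in the rear layers' queues.

    Counts channel selections (scale ignored) over the feature queues of the
    last ``rear_layer_count`` layers; sums to 100. With fewer layers than
    requested, all layers are used and a warning is emitted.
    """
    if not model.layers:
        raise ValueError("empty cascade")
    if len(model.layers) < rear_layer_count:
        warnings.warn(f"cascade has only {len(model.layers)} layers; "
                      "computing utilization over all of them")
        rear = model.layers
    else:
        rear = model.layers[-rear_layer_count:]
    counts = np.zeros(model.n_features)
    for layer in rear:
        for f, _s in layer.queue:
            counts[f] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("rear layers have empty feature queues")
    return 100.0 * counts / total


def cascade_rates(d_i: float, e_i: float, n_layers: int) -> tuple[float, float]:
    """Overall (D, E) of an idealized cascade with identical per-layer rates."""
    dummy = CascadeModel(
        [AdaBoostLayer(weaks=[[]], achieved_d=d_i, achieved_e=e_i)
         for _ in range(n_layers)],
        CascadeTargets(), n_scales=1)
    return dummy.overall_rates()
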