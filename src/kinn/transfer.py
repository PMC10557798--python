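"""In vivo transfer learning around a frozen pretrained KINN.

The frozen KINN supplies in vitro log rate constants ``kappa(x)``.  A
trainable convolutional backbone reads the same 25 x 13 alignment encoding
and produces one modifier ``delta`` per kinetic rate; the in vivo rates
are ``k' = exp(kappa + delta)``.  These flow through the KINN's own
King-Altman and activity layers, and a sigmoid over an affine map of the
log activity gives the binary cleavage probability.  Gradients reach the
backbone and the output head only — the pretrained KINN weights never
move (verified by hashing them).

The backbone is assembled from a small discrete menu (first convolution,
optional second convolution, dropout rate, optional bidirectional
recurrent layer, flatten style); :func:`select_model` runs a seeded random
search over (backbone, candidate KINN) combinations and reports per-slot
selection frequencies and an optional prediction-averaging ensemble.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, log_loss

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .exceptions import DataError, SpecificationError, StructuralError
from .kinetics import RateAssignment, enumerate_ka_diagrams
from .model import (
    KinnArchitecture,
    KinnParameters,
    _ParamTensors,
    _log_rates_tensor,
    _ka_log_occupancy,
    _stack_inputs,
)

CONV1_OPTIONS = ("k1", "k3", "k5", "dilated", "inception", "linear")
CONV2_OPTIONS = CONV1_OPTIONS + ("identity",)
DROPOUT_OPTIONS = (0.1, 0.3, 0.5)
RECURRENT_OPTIONS = ("wide", "narrow", "identity")   # 32 / 16 hidden units
FLATTEN_OPTIONS = ("plain", "attention", "dense")
_RECURRENT_UNITS = {"wide": 32, "narrow": 16}


@dataclass(frozen=True)
class BackboneSpec:
    conv1: str = "k3"
    conv2: str = "identity"
    dropout: float = 0.1
    recurrent: str = "identity"
    flatten: str = "plain"
    conv_channels: int = 8

    def __post_init__(self) -> None:
        checks = [
            (self.conv1, CONV1_OPTIONS, "conv1"),
            (self.conv2, CONV2_OPTIONS, "conv2"),
            (self.recurrent, RECURRENT_OPTIONS, "recurrent"),
            (self.flatten, FLATTEN_OPTIONS, "flatten"),
        ]
        for value, options, slot in checks:
            if value not in options:
                raise SpecificationError(f"unknown {slot} option {value!r}")
        if not (0.0 <= self.dropout < 1.0):
            raise SpecificationError("dropout must be in [0, 1)")


def frozen_hash(params: KinnParameters) -> str:
    """SHA-256 over the frozen KINN parameter arrays (the freeze contract)."""
    h = hashlib.sha256()
    for key in sorted(params.kernels):
        h.update(key.encode())
        h.update(np.ascontiguousarray(params.kernels[key]).tobytes())
    for key in sorted(params.biases):
        h.update(key.encode())
        h.update(np.float64(params.biases[key]).tobytes())
    for arr in (params.Wt, params.bt, params.Wo,
                np.atleast_1d(np.asarray(params.bo, dtype=float))):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


def _conv_params(kind: str, cin: int, cout: int,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    def kern(k, ci, co):
        return rng.normal(0.0, np.sqrt(2.0 / (k * ci)), size=(k, ci, co))
    if kind in ("k1", "linear"):
        return {"w": kern(1, cin, cout), "b": np.zeros(cout)}
    if kind == "k3":
        return {"w": kern(3, cin, cout), "b": np.zeros(cout)}
    if kind == "k5":
        return {"w": kern(5, cin, cout), "b": np.zeros(cout)}
    if kind == "dilated":
        return {"w": kern(3, cin, cout), "b": np.zeros(cout)}
    if kind == "inception":
        third = max(1, cout // 3)
        sizes = [third, third, cout - 2 * third]
        return {
            "w1": kern(1, cin, sizes[0]),
            "w3": kern(3, cin, sizes[1]),
            "w5": kern(5, cin, sizes[2]),
            "b": np.zeros(cout),
        }
    raise SpecificationError(f"unknown conv kind {kind!r}")


def _apply_conv(kind: str, tensors: dict[str, Tensor], x: Tensor,
                linear: bool = False) -> Tensor:
    if kind == "inception":
        parts = [
            ad.conv1d(x, tensors["w1"]),
            ad.conv1d(x, tensors["w3"]),
            ad.conv1d(x, tensors["w5"]),
        ]
        out = ad.concatenate(parts, axis=2) + tensors["b"]
    else:
        dilation = 2 if kind == "dilated" else 1
        out = ad.conv1d(x, tensors["w"], tensors["b"], dilation=dilation)
    return out if (linear or kind == "linear") else out.relu()


@dataclass
class TransferModel:
    """Frozen KINN + trainable context backbone + binary output head."""

    frozen_arch: KinnArchitecture
    frozen_params: KinnParameters
    backbone_spec: BackboneSpec
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    frozen_checksum: str = ""

    def __post_init__(self) -> None:
        if not self.frozen_checksum:
            self.frozen_checksum = frozen_hash(self.frozen_params)
        if not self.params:
            self._init_params()

    # -- parameter construction -------------------------------------------

    def _init_params(self) -> None:
        rng = np.random.default_rng(self.seed)
        spec = self.backbone_spec
        cin = self.frozen_arch.n_channels
        c = spec.conv_channels
        p: dict[str, Any] = {"conv1": _conv_params(spec.conv1, cin, c, rng)}
        width = c
        if spec.conv2 != "identity":
            p["conv2"] = _conv_params(spec.conv2, width, c, rng)
        if spec.recurrent != "identity":
            h = _RECURRENT_UNITS[spec.recurrent]
            for direction in ("fwd", "bwd"):
                p[f"rnn_{direction}"] = {
                    "wx": rng.normal(0, np.sqrt(1.0 / width), size=(width, h)),
                    "wh": rng.normal(0, np.sqrt(1.0 / h), size=(h, h)),
                    "b": np.zeros(h),
                }
            width = 2 * h
        L = self.frozen_arch.input_length
        if spec.flatten == "attention":
            p["attn"] = {"wa": rng.normal(0, np.sqrt(1.0 / width), size=(width, width)),
                         "va": rng.normal(0, np.sqrt(1.0 / width), size=width)}
            flat_dim = width
        elif spec.flatten == "dense":
            p["dense"] = {"w": rng.normal(0, np.sqrt(1.0 / (L * width)),
                                          size=(L * width, 64)),
                          "b": np.zeros(64)}
            flat_dim = 64
        else:
            flat_dim = L * width
        n_edges = self.frozen_arch.scheme.n_edges
        # delta head starts at zero so training begins at the frozen KINN
        p["delta"] = {"w": np.zeros((flat_dim, n_edges)), "b": np.zeros(n_edges)}
        p["out"] = {"w": np.ones(1), "b": np.zeros(1)}
        self.params = p

    def _tensors(self) -> dict[str, dict[str, Tensor]]:
        return {
            block: {k: Tensor(v, requires_grad=True) for k, v in sub.items()}
            for block, sub in self.params.items()
        }

    def _store(self, tensors: dict[str, dict[str, Tensor]]) -> None:
        self.params = {
            block: {k: t.data for k, t in sub.items()}
            for block, sub in tensors.items()
        }

    # -- forward ------------------------------------------------------------

    def _backbone(self, tensors, X: np.ndarray, rng=None) -> Tensor:
        spec = self.backbone_spec
        h = _apply_conv(spec.conv1, tensors["conv1"], Tensor(X))
        if spec.conv2 != "identity":
            h = _apply_conv(spec.conv2, tensors["conv2"], h)
        if rng is not None and spec.dropout > 0:
            mask = (rng.random(h.shape) >= spec.dropout) / (1 - spec.dropout)
            h = h * Tensor(mask)
        if spec.recurrent != "identity":
            h = self._birnn(tensors, h)
        if spec.flatten == "attention":
            a = tensors["attn"]
            scores = (h @ a["wa"]).tanh() @ a["va"]        # (n, L)
            w = scores - Tensor(scores.data.max(axis=1, keepdims=True))
            w = w.exp()
            w = w / w.sum(axis=1, keepdims=True)
            flat = (h * w.reshape(w.shape[0], w.shape[1], 1)).sum(axis=1)
        elif spec.flatten == "dense":
            d = tensors["dense"]
            flat = (h.reshape(h.shape[0], -1) @ d["w"] + d["b"]).relu()
        else:
            flat = h.reshape(h.shape[0], -1)
        return flat

    def _birnn(self, tensors, h: Tensor) -> Tensor:
        outs = []
        n, L, _ = h.shape
        for direction in ("fwd", "bwd"):
            p = tensors[f"rnn_{direction}"]
            order = range(L) if direction == "fwd" else range(L - 1, -1, -1)
            state = Tensor(np.zeros((n, p["wh"].shape[0])))
            seq = [None] * L
            for t in order:
                state = (h[:, t, :] @ p["wx"] + state @ p["wh"] + p["b"]).tanh()
                seq[t] = state
            outs.append(ad.stack(seq, axis=1))             # (n, L, h)
        return ad.concatenate(outs, axis=2)

    def _delta(self, tensors, X: np.ndarray, rng=None) -> Tensor:
        flat = self._backbone(tensors, X, rng=rng)
        d = tensors["delta"]
        return flat @ d["w"] + d["b"]                      # (n, n_edges)

    def _forward(self, tensors, X: np.ndarray, rng=None) -> Tensor:
        """Probability tensor (n,) with gradients into backbone/head only."""
        frozen = _ParamTensors(self.frozen_params, trainable=False)
        kappa = _log_rates_tensor(self.frozen_arch, frozen, X)
        delta = self._delta(tensors, X, rng=rng)
        scheme = self.frozen_arch.scheme
        log_k_eff = kappa + delta + Tensor(np.log(scheme.effective_rate_scale()))
        diagrams = enumerate_ka_diagrams(scheme)
        log_s = _ka_log_occupancy(diagrams, log_k_eff)
        terms = []
        for a, b in scheme.activity_edges:
            e = scheme.edge_index((a, b))
            terms.append(log_k_eff[:, e] + log_s[:, a])
        log_nu = (ad.stack(terms, axis=1).logsumexp(axis=1)
                  if len(terms) > 1 else terms[0])
        o = tensors["out"]
        logit = log_nu * o["w"] + o["b"]
        return logit.sigmoid()

    # -- public API ---------------------------------------------------------

    def trainable_tensor_list(self, tensors) -> list[Tensor]:
        return [t for sub in tensors.values() for t in sub.values()]

    def predict_proba(self, xs: Any) -> np.ndarray:
        """Cleavage probabilities in (0, 1) for 25 x 13 encoded inputs."""
        X = _stack_inputs(xs if not isinstance(xs, np.ndarray) or xs.ndim == 3
                          else xs[None])
        if X.shape[1:] != (self.frozen_arch.input_length,
                           self.frozen_arch.n_channels):
            raise StructuralError(
                f"expected encodings of shape "
                f"({self.frozen_arch.input_length}, {self.frozen_arch.n_channels})"
            )
        tensors = self._tensors()
        return self._forward(tensors, X).data

    def frozen_rate_scores(self, xs: Any) -> np.ndarray:
        """Log activity of the frozen KINN alone (delta = 0) — the baseline
        ranking score used to measure the transfer gain."""
        X = _stack_inputs(xs)
        frozen = _ParamTensors(self.frozen_params, trainable=False)
        kappa = _log_rates_tensor(self.frozen_arch, frozen, X)
        scheme = self.frozen_arch.scheme
        log_k_eff = kappa + Tensor(np.log(scheme.effective_rate_scale()))
        diagrams = enumerate_ka_diagrams(scheme)
        log_s = _ka_log_occupancy(diagrams, log_k_eff)
        terms = []
        for a, b in scheme.activity_edges:
            e = scheme.edge_index((a, b))
            terms.append(log_k_eff[:, e] + log_s[:, a])
        out = (ad.stack(terms, axis=1).logsumexp(axis=1)
               if len(terms) > 1 else terms[0])
        return out.data


def combine_rates(kappa: np.ndarray, delta: np.ndarray) -> RateAssignment:
    """k' = exp(kappa + delta) as a RateAssignment-ready vector.

    Returns the raw positive rates (callers with a scheme use
    ``RateAssignment.from_vector``).
    """
    kappa = np.asarray(kappa, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if kappa.shape != delta.shape:
        raise StructuralError("kappa and delta must have equal length")
    return np.exp(kappa + delta)


@dataclass(frozen=True)
class TransferTrainConfig:
    epochs: int = 30
    learning_rate: float = 1e-2
    batch_size: int = 512
    seed: int = 0
    patience: int = 8
    positive_weight: float | None = None   # None -> n_neg / n_pos


def fit_transfer(
    model: TransferModel,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    config: TransferTrainConfig = TransferTrainConfig(),
) -> tuple[TransferModel, dict[str, list[float]]]:
    """Minimize class-weighted binary cross-entropy; track validation AUPR.

    The frozen KINN is untouched (its checksum is asserted before and
    after); early stopping restores the backbone/head parameters of the
    best validation epoch.  Deterministic under ``config.seed``.
    """
    Xtr, ytr = _stack_inputs(train[0]), np.asarray(train[1], dtype=float)
    Xv, yv = _stack_inputs(val[0]), np.asarray(val[1], dtype=float)
    if len(np.unique(ytr)) < 2:
        raise DataError("training labels are single-class")
    checksum = frozen_hash(model.frozen_params)
    rng = np.random.default_rng(config.seed)
    tensors = model._tensors()
    opt = Adam(model.trainable_tensor_list(tensors), lr=config.learning_rate)
    pos_w = (config.positive_weight if config.positive_weight is not None
             else float((ytr == 0).sum() / max(1, (ytr == 1).sum())))
    history: dict[str, list[float]] = {"loss": [], "val_aupr": []}
    best_aupr, best_params, stale = -np.inf, None, 0
    n = Xtr.shape[0]
    for _ in range(config.epochs):
        perm = rng.permutation(n)
        batches = np.array_split(perm, int(np.ceil(n / config.batch_size)))
        epoch_loss = 0.0
        for idx in batches:
            opt.zero_grad()
            p = model._forward(tensors, Xtr[idx], rng=rng)
            y = ytr[idx]
            w = np.where(y == 1, pos_w, 1.0)
            eps = 1e-9
            ll = (Tensor(y * w) * (p.clamp_min(eps)).log()
                  + Tensor((1 - y) * w) * ((1.0 - p).clamp_min(eps)).log())
            loss = -(ll.sum() / w.sum())
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        history["loss"].append(epoch_loss / n)
        model._store(tensors)
        pv = model._forward(model._tensors(), Xv).data
        aupr = float(average_precision_score(yv, pv))
        history["val_aupr"].append(aupr)
        if aupr > best_aupr:
            best_aupr = aupr
            best_params = {b: {k: v.copy() for k, v in sub.items()}
                           for b, sub in model.params.items()}
            stale = 0
        else:
            stale += 1
            if stale > config.patience:
                break
    if best_params is not None:
        model.params = best_params
    if frozen_hash(model.frozen_params) != checksum:
        raise RuntimeError("freeze contract violated: frozen KINN changed")
    return model, history


@dataclass
class ModelSpace:
    """Discrete (backbone, pretrained KINN) search space."""

    kinns: list[tuple[KinnArchitecture, KinnParameters]]
    conv1: tuple[str, ...] = CONV1_OPTIONS
    conv2: tuple[str, ...] = CONV2_OPTIONS
    dropout: tuple[float, ...] = DROPOUT_OPTIONS
    recurrent: tuple[str, ...] = RECURRENT_OPTIONS
    flatten: tuple[str, ...] = FLATTEN_OPTIONS

    def __post_init__(self) -> None:
        if not self.kinns:
            raise SpecificationError("model space needs >= 1 candidate KINN")
        for slot in ("conv1", "conv2", "dropout", "recurrent", "flatten"):
            if not getattr(self, slot):
                raise SpecificationError(f"empty option list for slot {slot}")

    def sample(self, rng: np.random.Generator) -> tuple[BackboneSpec, int]:
        spec = BackboneSpec(
            conv1=str(rng.choice(self.conv1)),
            conv2=str(rng.choice(self.conv2)),
            dropout=float(rng.choice(self.dropout)),
            recurrent=str(rng.choice(self.recurrent)),
            flatten=str(rng.choice(self.flatten)),
        )
        return spec, int(rng.integers(0, len(self.kinns)))


@dataclass
class SelectionResult:
    best: TransferModel
    best_aupr: float
    frequencies: dict[str, dict[str, float]]
    evaluated: list[dict]
    ensemble: list[TransferModel] = field(default_factory=list)

    def ensemble_proba(self, xs: Any) -> np.ndarray:
        members = self.ensemble or [self.best]
        return np.mean([m.predict_proba(xs) for m in members], axis=0)


def select_model(
    space: ModelSpace,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    budget: int = 10,
    seed: int = 0,
    config: TransferTrainConfig | None = None,
    ensemble_size: int = 5,
) -> SelectionResult:
    """Seeded random search over the discrete space; best model by
    validation AUPR, plus per-slot frequencies among the top models."""
    if budget < 1:
        raise SpecificationError("selection budget must be >= 1")
    rng = np.random.default_rng(seed)
    base_config = config or TransferTrainConfig()
    records = []
    for trial in range(budget):
        spec, kinn_idx = space.sample(rng)
        arch, params = space.kinns[kinn_idx]
        model = TransferModel(
            frozen_arch=arch, frozen_params=params, backbone_spec=spec,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cfg = replace(base_config, seed=int(rng.integers(0, 2**31 - 1)))
        model, history = fit_transfer(model, train, val, cfg)
        records.append({
            "trial": trial,
            "spec": spec,
            "kinn_index": kinn_idx,
            "val_aupr": max(history["val_aupr"]),
            "model": model,
        })
    ranked = sorted(records, key=lambda r: (-r["val_aupr"], r["trial"]))
    top = ranked[: max(1, min(ensemble_size, len(ranked)))]
    freqs: dict[str, dict[str, float]] = {}
    slots = {
        "conv1": lambda r: r["spec"].conv1,
        "conv2": lambda r: r["spec"].conv2,
        "dropout": lambda r: str(r["spec"].dropout),
        "recurrent": lambda r: r["spec"].recurrent,
        "flatten": lambda r: r["spec"].flatten,
        "kinn": lambda r: str(r["kinn_index"]),
    }
    for slot, getter in slots.items():
        counts: dict[str, int] = {}
        for r in top:
            counts[getter(r)] = counts.get(getter(r), 0) + 1
        total = sum(counts.values())
        freqs[slot] = {k: v / total for k, v in counts.items()}
    summary = [{k: (v if k != "model" else None) for k, v in r.items()}
               for r in records]
    return SelectionResult(
        best=ranked[0]["model"],
        best_aupr=ranked[0]["val_aupr"],
        frequencies=freqs,
        evaluated=summary,
        ensemble=[r["model"] for r in top],
    )


def ensemble_log_loss(models: Sequence[TransferModel],
                      xs: Any, y: np.ndarray) -> float:
    p = np.mean([m.predict_proba(xs) for m in models], axis=0)
    return float(log_loss(y, np.clip(p, 1e-9, 1 - 1e-9)))
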