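"""Kinetically interpretable neural networks (KINNs).

A KINN maps an encoded guide-target alignment to a cleavage rate through
three layers that mirror the kinetic theory in :mod:`kinn.kinetics`:

1. *Rate layer* — one single-filter convolution per scheme edge reads a
   sequence window ``[i, j)`` with kernel size ``d`` and outputs
   ``log k_{ab}``.  With ``d = 1`` this is a positionwise additive model
   (each nucleotide pair contributes independently to the free-energy
   barrier); with ``d = j - i`` it is a fully connected map of the window.
2. *King-Altman layer* — a static binary matrix ``B`` turns the log-rate
   vector into log diagram weights; grouped log-sum-exp normalization
   yields the steady-state occupancies (exactly the KA formula, written
   as a softmax over diagrams grouped by terminal state).
3. *Activity / output head* — the production flux through the activity
   edges (or, alternatively, the slow eigen-rate of the depleting-reservoir
   generator), passed through a small trainable link head.

Because every trained parameter is a window of per-pair free-energy
contributions, a fitted KINN *is* a kinetic model: :func:`extract_rates`
hands its predictions back to :mod:`kinn.kinetics` as rate constants.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Any, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .exceptions import DataError, DomainError, SpecificationError
from .kinetics import (
    KADiagramSet,
    KineticScheme,
    RateAssignment,
    StateOccupancy,
    edge_basis_matrices,
    enumerate_ka_diagrams,
    scheme_from_dict,
    scheme_to_dict,
)

_ACTIVATIONS = ("identity", "softplus", "exponential")


@dataclass(frozen=True)
class RateWindowSpec:
    """Sequence window and kernel size feeding one rate constant."""

    rate_symbol: str
    start: int
    end: int
    kernel_size: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise SpecificationError(
                f"{self.rate_symbol}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if not (1 <= self.kernel_size <= self.end - self.start):
            raise SpecificationError(
                f"{self.rate_symbol}: kernel size {self.kernel_size} outside "
                f"[1, {self.end - self.start}]"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LinkSpec:
    """The trainable scalar head y = sigma_o(sigma_nu(nu*Wt+bt)*Wo+bo)."""

    sigma_nu: str = "identity"
    sigma_o: str = "identity"
    hidden: int = 1

    def __post_init__(self) -> None:
        for name in (self.sigma_nu, self.sigma_o):
            if name not in _ACTIVATIONS:
                raise SpecificationError(f"unknown activation {name!r}")
        if self.hidden < 1:
            raise SpecificationError("hidden width must be >= 1")


@dataclass(frozen=True)
class KinnArchitecture:
    """Everything the architecture search varies: windows, head, link."""

    scheme: KineticScheme
    windows: tuple[RateWindowSpec, ...]
    input_length: int
    n_channels: int = 4
    output_head: str = "ka_steady_state"
    link_spec: LinkSpec = field(default_factory=LinkSpec)

    def __post_init__(self) -> None:
        syms = tuple(w.rate_symbol for w in self.windows)
        if sorted(syms) != sorted(self.scheme.edge_symbols):
            raise SpecificationError(
                "need exactly one window per scheme edge; "
                f"got {syms} for edges {self.scheme.edge_symbols}"
            )
        # keep windows in scheme edge order
        by_sym = {w.rate_symbol: w for w in self.windows}
        object.__setattr__(
            self, "windows", tuple(by_sym[s] for s in self.scheme.edge_symbols)
        )
        for w in self.windows:
            if w.end > self.input_length:
                raise SpecificationError(
                    f"{w.rate_symbol}: window [{w.start}, {w.end}) exceeds "
                    f"input length {self.input_length}"
                )
        if self.output_head not in ("ka_steady_state", "eigen_rate"):
            raise SpecificationError(f"unknown output head {self.output_head!r}")

    def n_parameters(self) -> int:
        n = sum(w.kernel_size * self.n_channels + 1 for w in self.windows)
        h = self.link_spec.hidden
        return n + h + h + h + 1  # Wt, bt, Wo, bo


@dataclass
class KinnParameters:
    """Named parameter arrays; shapes follow the architecture."""

    kernels: dict[str, np.ndarray]
    biases: dict[str, float]
    Wt: np.ndarray
    bt: np.ndarray
    Wo: np.ndarray
    bo: np.ndarray

    def copy(self) -> "KinnParameters":
        return KinnParameters(
            kernels={k: v.copy() for k, v in self.kernels.items()},
            biases=dict(self.biases),
            Wt=self.Wt.copy(), bt=self.bt.copy(),
            Wo=self.Wo.copy(), bo=np.array(self.bo, dtype=float).copy(),
        )

    def flat(self) -> np.ndarray:
        parts = [self.kernels[k].ravel() for k in sorted(self.kernels)]
        parts += [np.array([self.biases[k] for k in sorted(self.biases)])]
        parts += [self.Wt.ravel(), self.bt.ravel(), self.Wo.ravel(),
                  np.atleast_1d(np.asarray(self.bo, dtype=float))]
        return np.concatenate(parts)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    learning_rate: float = 1e-2
    batch_size: int | None = None
    loss: str = "mse_log"
    seed: int = 0
    patience: int = 10

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.learning_rate <= 0:
            raise SpecificationError("epochs and learning rate must be positive")
        if self.loss not in ("mse_log", "mse"):
            raise SpecificationError(f"unknown loss {self.loss!r}")


def init_params(
    arch: KinnArchitecture,
    rng: np.random.Generator,
    label_median: float | None = None,
    weight_scale: float = 0.05,
) -> KinnParameters:
    """Small symmetric kernel weights; biases place initial rates near the
    label scale (log median split evenly across edges) so the KA softmax
    starts unsaturated."""
    bias0 = 0.0
    if label_median is not None and label_median > 0:
        bias0 = float(np.log(label_median)) / arch.scheme.n_edges
    kernels, biases = {}, {}
    for w in arch.windows:
        kernels[w.rate_symbol] = rng.normal(
            0.0, weight_scale, size=(w.kernel_size, arch.n_channels)
        )
        biases[w.rate_symbol] = bias0
    h = arch.link_spec.hidden
    return KinnParameters(
        kernels=kernels,
        biases=biases,
        Wt=np.ones((1, h)),
        bt=np.zeros(h),
        Wo=np.ones((h, 1)) / h,
        bo=np.zeros(1),
    )


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

def _as_input_array(x: Any) -> np.ndarray:
    """Accept EncodedAlignment-like objects or plain (L, C) arrays."""
    for attr in ("matrix", "pairing_matrix"):
        m = getattr(x, attr, None)
        if m is not None:
            return np.asarray(m, dtype=float)
    return np.asarray(x, dtype=float)


def _stack_inputs(xs: Sequence[Any]) -> np.ndarray:
    if isinstance(xs, np.ndarray) and xs.ndim == 3:
        return xs.astype(float)
    return np.stack([_as_input_array(x) for x in xs])


def _window_design(X: np.ndarray, w: RateWindowSpec) -> np.ndarray:
    """Sum of sliding windows: conv-then-sum is linear in the kernel, so the
    per-edge head reduces to ``<design, W> + b`` with design (n, d, C)."""
    d = w.kernel_size
    acc = np.zeros((X.shape[0], d, X.shape[2]))
    for p in range(w.start, w.end - d + 1):
        acc += X[:, p:p + d, :]
    return acc


class _ParamTensors:
    """Tensor views of a KinnParameters (shared data arrays)."""

    def __init__(self, params: KinnParameters, trainable: bool = True):
        self.kernels = {k: Tensor(v, requires_grad=trainable)
                        for k, v in params.kernels.items()}
        self.biases = {k: Tensor(np.array(v, dtype=float), requires_grad=trainable)
                       for k, v in params.biases.items()}
        self.Wt = Tensor(params.Wt, requires_grad=trainable)
        self.bt = Tensor(params.bt, requires_grad=trainable)
        self.Wo = Tensor(params.Wo, requires_grad=trainable)
        self.bo = Tensor(np.atleast_1d(np.asarray(params.bo, dtype=float)),
                         requires_grad=trainable)

    def all(self) -> list[Tensor]:
        return (list(self.kernels.values()) + list(self.biases.values())
                + [self.Wt, self.bt, self.Wo, self.bo])

    def to_params(self) -> KinnParameters:
        return KinnParameters(
            kernels={k: t.data for k, t in self.kernels.items()},
            biases={k: float(t.data) for k, t in self.biases.items()},
            Wt=self.Wt.data, bt=self.bt.data, Wo=self.Wo.data, bo=self.bo.data,
        )


def _log_rates_tensor(arch: KinnArchitecture, pt: _ParamTensors,
                      X: np.ndarray) -> Tensor:
    cols = []
    for w in arch.windows:
        design = _window_design(X, w).reshape(X.shape[0], -1)   # (n, d*C)
        kern = pt.kernels[w.rate_symbol].reshape(-1)            # (d*C,)
        cols.append((Tensor(design) @ kern) + pt.biases[w.rate_symbol])
    return ad.stack(cols, axis=1)                               # (n, E)


def log_rates(arch: KinnArchitecture, params: KinnParameters, x: Any) -> np.ndarray:
    """Per-edge log rate constants for one encoded input (scheme edge order)."""
    X = _as_input_array(x)[None]
    return _log_rates_tensor(arch, _ParamTensors(params, trainable=False), X).data[0]


def _ka_log_occupancy(diagrams: KADiagramSet, log_k_eff: Tensor) -> Tensor:
    """Batched log steady-state occupancies, (n, n_states).

    This is the KA layer: ``B @ log k`` gives log diagram weights; grouping
    the softmax over diagrams by terminal state reproduces the KA steady
    state exactly (the ungrouped softmax is the special case of one diagram
    per state).
    """
    B = diagrams.binary_matrix
    logw = log_k_eff @ Tensor(B.T)                      # (n, D)
    denom = logw.logsumexp(axis=1, keepdims=True)       # (n, 1)
    per_state = []
    for a in range(diagrams.scheme.n_states):
        mask = np.flatnonzero(diagrams.terminal_states == a)
        if mask.size == 0:
            raise SpecificationError(f"state {a} has no KA diagram")
        per_state.append(logw[:, mask].logsumexp(axis=1, keepdims=True))
    return ad.concatenate(per_state, axis=1) - denom


def ka_layer(diagrams: KADiagramSet, log_k: np.ndarray) -> StateOccupancy:
    """Steady-state occupancy from a log-rate vector (effective rates)."""
    t = _ka_log_occupancy(diagrams, Tensor(np.asarray(log_k, float)[None]))
    s = np.exp(t.data[0])
    return StateOccupancy(vector=s / s.sum())


def slow_eigen_rate_layer(k_eff: Tensor, basis: np.ndarray) -> Tensor:
    """Differentiable slow eigen-rate of K' = sum_e k_eff[e] * basis[e].

    Forward: batched eigendecomposition, eigenvalue closest to zero.
    Backward: first-order eigenvalue perturbation
    ``d lambda = l . dK . r`` with ``l`` the matching left eigenvector
    (row of V^-1) and ``r`` the right eigenvector.
    """
    Kp = np.einsum("ne,eab->nab", k_eff.data, basis)
    vals, vecs = np.linalg.eig(Kp)
    n = Kp.shape[0]
    # per-sample slow mode: smallest |lambda|, ties to larger real part
    order = np.lexsort((-vals.real, np.abs(vals)), axis=1)
    sel = order[:, 0]
    rows = np.arange(n)
    lam = vals[rows, sel]
    Vinv = np.linalg.inv(vecs)
    left = Vinv[rows, sel, :]                           # (n, S)
    right = vecs[rows, :, sel]                          # (n, S)
    sens = -np.real(np.einsum("na,eab,nb->ne", left, basis, right))
    out_data = -lam.real

    def back(g):
        if k_eff.requires_grad:
            k_eff._accum(g[:, None] * sens)

    return ad.custom(out_data, (k_eff,), back)


def _apply_activation(t: Tensor, name: str) -> Tensor:
    if name == "identity":
        return t
    if name == "softplus":
        return t.softplus()
    return t.exp()


def _link_head(nu: Tensor, pt: _ParamTensors, link: LinkSpec) -> Tensor:
    h = nu.reshape(-1, 1) @ pt.Wt + pt.bt               # (n, hidden)
    h = _apply_activation(h, link.sigma_nu)
    y = h @ pt.Wo + pt.bo                               # (n, 1)
    return _apply_activation(y, link.sigma_o).reshape(-1)


def forward_batch(
    arch: KinnArchitecture,
    pt: _ParamTensors,
    X: np.ndarray,
    diagrams: KADiagramSet | None = None,
    delta: Tensor | None = None,
) -> tuple[Tensor, Tensor]:
    """Batched prediction; returns (y, log_nu_or_rate).

    ``delta`` is an optional additive log-rate modifier (the in vivo
    transfer mechanism: log k' = kappa + delta).
    """
    scheme = arch.scheme
    log_k = _log_rates_tensor(arch, pt, X)
    if delta is not None:
        log_k = log_k + delta
    log_scale = np.log(scheme.effective_rate_scale())
    log_k_eff = log_k + Tensor(log_scale)
    if arch.output_head == "eigen_rate":
        basis = edge_basis_matrices(scheme, conservative=False)
        rate = slow_eigen_rate_layer(log_k_eff.exp(), basis)
        log_nu = rate.clamp_min(1e-300).log()
        nu = rate
    else:
        if diagrams is None:
            diagrams = enumerate_ka_diagrams(scheme)
        log_s = _ka_log_occupancy(diagrams, log_k_eff)
        terms = []
        for a, b in scheme.activity_edges:
            e = scheme.edge_index((a, b))
            terms.append(log_k_eff[:, e] + log_s[:, a])
        log_nu = ad.stack(terms, axis=1).logsumexp(axis=1) if len(terms) > 1 else terms[0]
        nu = log_nu.exp()
    y = _link_head(nu, pt, arch.link_spec)
    return y, log_nu


def predict(arch: KinnArchitecture, params: KinnParameters, x: Any) -> float:
    """Cleavage-rate prediction for one encoded alignment."""
    X = _stack_inputs([x])
    pt = _ParamTensors(params, trainable=False)
    y, _ = forward_batch(arch, pt, X)
    val = float(y.data[0])
    if not np.isfinite(val):
        raise DomainError("non-finite prediction; check rate-layer parameters")
    return val


def predict_batch(arch: KinnArchitecture, params: KinnParameters,
                  xs: Sequence[Any]) -> np.ndarray:
    X = _stack_inputs(xs)
    pt = _ParamTensors(params, trainable=False)
    y, _ = forward_batch(arch, pt, X)
    return y.data


def extract_rates(arch: KinnArchitecture, params: KinnParameters, x: Any) -> RateAssignment:
    """Learned rate constants for one input — the mechanistic hand-off.

    The returned assignment plugs straight into ``kinn.kinetics``
    (``propagate``, ``slow_eigen_rate``); the reservoir concentration is
    not folded in (the scheme applies it).
    """
    lk = log_rates(arch, params, x)
    return RateAssignment.from_vector(arch.scheme, np.exp(lk))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r, defined as 0 (with a warning) for constant inputs."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        warnings.warn("constant vector in Pearson correlation; reporting 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _coerce_dataset(dataset: Any) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(dataset, tuple) and len(dataset) == 2:
        X, y = dataset
        return _stack_inputs(X), np.asarray(y, dtype=float)
    xs, ys = zip(*dataset)
    return _stack_inputs(xs), np.asarray(ys, dtype=float)


def _is_identity_link(link: LinkSpec) -> bool:
    return link.sigma_nu == "identity" and link.sigma_o == "identity"


def _loss_tensor(y: Tensor, log_nu: Tensor, target: np.ndarray, loss: str,
                 identity_link: bool) -> Tensor:
    if loss == "mse_log":
        # with the identity link y == nu up to the (identity-initialized)
        # affine head, so the stable log-space path is exact; otherwise
        # clamp to keep the log finite
        pred_log = log_nu if identity_link else y.clamp_min(1e-300).log()
        resid = pred_log - Tensor(np.log(target))
    else:
        resid = y - Tensor(target)
    return (resid * resid).mean()


def fit(
    arch: KinnArchitecture,
    dataset: Any,
    config: TrainConfig,
    val: Any = None,
    init: KinnParameters | None = None,
) -> tuple[KinnParameters, dict[str, list[float]]]:
    """Fit a KINN by Adam on (log-scale by default) squared error.

    ``dataset``/``val`` are ``(inputs, rates)`` pairs — either a tuple of
    arrays or a sequence of per-record pairs.  History records per-epoch
    training loss and, when a validation set is given, validation Pearson
    correlation used for early stopping.  Deterministic under
    ``config.seed``.
    """
    X, yobs = _coerce_dataset(dataset)
    if config.loss == "mse_log" and np.any(yobs <= 0):
        raise DataError("log-scale loss requires strictly positive rate labels")
    rng = np.random.default_rng(config.seed)
    pt = _ParamTensors(
        init.copy() if init is not None
        else init_params(arch, rng, label_median=float(np.median(yobs)))
    )
    diagrams = (enumerate_ka_diagrams(arch.scheme)
                if arch.output_head == "ka_steady_state" else None)
    Xv = yv = None
    if val is not None:
        Xv, yv = _coerce_dataset(val)
    opt = Adam(pt.all(), lr=config.learning_rate)
    identity_link = _is_identity_link(arch.link_spec)
    history: dict[str, list[float]] = {"loss": [], "val_pearson": []}
    best_params, best_score, stale = pt.to_params().copy(), -np.inf, 0
    n = X.shape[0]
    for _ in range(config.epochs):
        if config.batch_size is None or config.batch_size >= n:
            batches = [np.arange(n)]
        else:
            perm = rng.permutation(n)
            batches = np.array_split(perm, int(np.ceil(n / config.batch_size)))
        epoch_loss = 0.0
        for idx in batches:
            opt.zero_grad()
            y, log_nu = forward_batch(arch, pt, X[idx], diagrams=diagrams)
            loss = _loss_tensor(y, log_nu, yobs[idx], config.loss, identity_link)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        history["loss"].append(epoch_loss / n)
        if Xv is not None:
            yhat, log_nu_v = forward_batch(arch, pt, Xv, diagrams=diagrams)
            if config.loss == "mse_log":
                pred = (log_nu_v.data if identity_link
                        else np.log(np.clip(yhat.data, 1e-300, None)))
                score = pearson(pred, np.log(yv))
            else:
                score = pearson(yhat.data, yv)
            history["val_pearson"].append(score)
            if score > best_score:
                best_score, best_params, stale = score, pt.to_params().copy(), 0
            else:
                stale += 1
                if stale > config.patience:
                    break
    final = best_params if Xv is not None else pt.to_params().copy()
    return final, history


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def architecture_to_dict(arch: KinnArchitecture) -> dict:
    return {
        "scheme": scheme_to_dict(arch.scheme),
        "windows": [asdict(w) for w in arch.windows],
        "input_length": arch.input_length,
        "n_channels": arch.n_channels,
        "output_head": arch.output_head,
        "link_spec": asdict(arch.link_spec),
    }


def architecture_from_dict(d: dict) -> KinnArchitecture:
    return KinnArchitecture(
        scheme=scheme_from_dict(d["scheme"]),
        windows=tuple(RateWindowSpec(**w) for w in d["windows"]),
        input_length=d["input_length"],
        n_channels=d.get("n_channels", 4),
        output_head=d.get("output_head", "ka_steady_state"),
        link_spec=LinkSpec(**d.get("link_spec", {})),
    )


def save_checkpoint(path, arch: KinnArchitecture, params: KinnParameters) -> None:
    blob = {
        "architecture": architecture_to_dict(arch),
        "parameters": {
            "kernels": {k: v.tolist() for k, v in params.kernels.items()},
            "biases": params.biases,
            "Wt": params.Wt.tolist(),
            "bt": params.bt.tolist(),
            "Wo": params.Wo.tolist(),
            "bo": np.atleast_1d(np.asarray(params.bo, dtype=float)).tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(blob, fh, indent=1)


def load_checkpoint(path) -> tuple[KinnArchitecture, KinnParameters]:
    with open(path) as fh:
        blob = json.load(fh)
    arch = architecture_from_dict(blob["architecture"])
    p = blob["parameters"]
    params = KinnParameters(
        kernels={k: np.asarray(v, dtype=float) for k, v in p["kernels"].items()},
        biases={k: float(v) for k, v in p["biases"].items()},
        Wt=np.asarray(p["Wt"], dtype=float),
        bt=np.asarray(p["bt"], dtype=float),
        Wo=np.asarray(p["Wo"], dtype=float),
        bo=np.asarray(p["bo"], dtype=float),
    )
    return arch, params
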