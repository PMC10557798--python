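"""Probabilistic model-building genetic algorithm over KINN architectures.

Instead of crossover and mutation, the search keeps one categorical
distribution per architecture hyperparameter — the window start ``i``, the
window width ``j - i`` and the kernel size ``d`` of every rate constant —
samples a generation of architectures from them, trains each KINN briefly,
and performs a Dirichlet-categorical conjugate update using the survivors
(architectures whose validation Pearson exceeds the generation mean).

Priors are *anchored*: the start-position support is centred on
``phi(k)``, the position the anchor function assigns to the rate by
spreading the forward transitions uniformly along the input sequence
(for a four-state scheme on a 20-nt input: phi(k01)=5, phi(k12)=10,
phi(k23)=15).  Backward rates share their forward partner's anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .exceptions import SpecificationError
from .kinetics import KineticScheme, parse_rate_symbol
from .model import (
    KinnArchitecture,
    KinnParameters,
    LinkSpec,
    RateWindowSpec,
    TrainConfig,
    fit,
    forward_batch,
    pearson,
    _ParamTensors,
    _coerce_dataset,
)

MAX_WINDOW_WIDTH = 5


def anchor_position(rate_symbol: str, n_states: int, input_length: int) -> int:
    """Uniformly map each kinetic rate onto the input sequence.

    Forward rate ``k_{a,a+1}`` anchors at ``round(L * (a+1) / n_states)``;
    a backward rate anchors at its forward partner's position; the closing
    product step ``k_{n-1,0}`` anchors at the sequence end.
    """
    a, b = parse_rate_symbol(rate_symbol)
    if not (a < n_states and b < n_states):
        raise SpecificationError(
            f"rate {rate_symbol} does not belong to an {n_states}-state scheme"
        )
    if input_length < n_states:
        raise SpecificationError("input length must be at least n_states")
    if b == (a + 1) % n_states:      # forward (including the closing step)
        step = a + 1
    elif a == (b + 1) % n_states:    # backward: share the forward anchor
        step = b + 1
    else:
        raise SpecificationError(
            f"rate {rate_symbol} is not a cycle transition of an "
            f"{n_states}-state scheme"
        )
    return int(round(input_length * step / n_states))


def default_windows(
    scheme: KineticScheme,
    input_length: int,
    width: int = MAX_WINDOW_WIDTH,
    kernel_size: int = 1,
) -> tuple[RateWindowSpec, ...]:
    """Anchor-centred windows, one per edge — the prior's central point."""
    out = []
    for sym in scheme.edge_symbols:
        center = anchor_position(sym, scheme.n_states, input_length)
        start = int(np.clip(center - width // 2, 0, input_length - width))
        out.append(RateWindowSpec(sym, start, start + width,
                                  min(kernel_size, width)))
    return tuple(out)


@dataclass
class _Categorical:
    """Dirichlet-categorical over consecutive integers [lo, lo+len)."""

    lo: int
    counts: np.ndarray    # concentration parameters (pseudo-counts)

    @property
    def support(self) -> np.ndarray:
        return self.lo + np.arange(len(self.counts))

    def probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def sample(self, rng: np.random.Generator, upper: int | None = None) -> int:
        """Draw one value, truncating the support above ``upper`` if given."""
        p = self.probabilities()
        if upper is not None:
            mask = self.support <= upper
            if not mask.any():
                raise SpecificationError("empty categorical support after truncation")
            p = np.where(mask, p, 0.0)
            p = p / p.sum()
        return int(rng.choice(self.support, p=p))

    def observe(self, value: int) -> None:
        idx = value - self.lo
        if 0 <= idx < len(self.counts):
            self.counts[idx] += 1.0


@dataclass
class ArchitecturePrior:
    """Per-rate categoricals over start position, window width, kernel size."""

    scheme: KineticScheme
    input_length: int
    n_channels: int = 4
    half_width: int = 5           # w/2: start support is [phi - w/2, phi + w/2]
    output_head: str = "ka_steady_state"
    link_spec: LinkSpec = field(default_factory=LinkSpec)
    start: dict[str, _Categorical] = field(default_factory=dict)
    width: dict[str, _Categorical] = field(default_factory=dict)
    kernel: dict[str, _Categorical] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start:
            return
        L = self.input_length
        for sym in self.scheme.edge_symbols:
            phi = min(anchor_position(sym, self.scheme.n_states, L), L - 1)
            lo = max(0, phi - self.half_width)
            hi = min(L - 1, phi + self.half_width)
            self.start[sym] = _Categorical(lo, np.ones(hi - lo + 1))
            self.width[sym] = _Categorical(1, np.ones(MAX_WINDOW_WIDTH))
            self.kernel[sym] = _Categorical(1, np.ones(MAX_WINDOW_WIDTH))

    def copy(self) -> "ArchitecturePrior":
        cp = ArchitecturePrior(
            scheme=self.scheme, input_length=self.input_length,
            n_channels=self.n_channels, half_width=self.half_width,
            output_head=self.output_head, link_spec=self.link_spec,
            start={s: _Categorical(c.lo, c.counts.copy())
                   for s, c in self.start.items()},
            width={s: _Categorical(c.lo, c.counts.copy())
                   for s, c in self.width.items()},
            kernel={s: _Categorical(c.lo, c.counts.copy())
                    for s, c in self.kernel.items()},
        )
        return cp

    def tables(self) -> dict[str, dict[str, dict[int, float]]]:
        out: dict[str, dict[str, dict[int, float]]] = {}
        for sym in self.scheme.edge_symbols:
            out[sym] = {
                "start": dict(zip(map(int, self.start[sym].support),
                                  self.start[sym].probabilities())),
                "width": dict(zip(map(int, self.width[sym].support),
                                  self.width[sym].probabilities())),
                "kernel": dict(zip(map(int, self.kernel[sym].support),
                                   self.kernel[sym].probabilities())),
            }
        return out


def sample_architecture(
    prior: ArchitecturePrior, rng: np.random.Generator
) -> KinnArchitecture:
    """One architecture draw; supports are truncated so every sampled window
    fits the input and the kernel fits the window."""
    windows = []
    L = prior.input_length
    for sym in prior.scheme.edge_symbols:
        start = prior.start[sym].sample(rng)
        width = prior.width[sym].sample(rng, upper=L - start)
        kernel = prior.kernel[sym].sample(rng, upper=width)
        windows.append(RateWindowSpec(sym, start, start + width, kernel))
    return KinnArchitecture(
        scheme=prior.scheme,
        windows=tuple(windows),
        input_length=L,
        n_channels=prior.n_channels,
        output_head=prior.output_head,
        link_spec=prior.link_spec,
    )


def evaluate_fitness(
    arch: KinnArchitecture,
    train_data: Any,
    val_data: Any,
    train_config: TrainConfig,
) -> tuple[float, KinnParameters]:
    """Train briefly and score by validation Pearson (NaN-safe -> 0)."""
    params, _ = fit(arch, train_data, train_config, val=val_data)
    Xv, yv = _coerce_dataset(val_data)
    yhat, _ = forward_batch(arch, _ParamTensors(params, trainable=False), Xv)
    pred = yhat.data
    if train_config.loss == "mse_log":
        pred = np.log(np.clip(pred, 1e-300, None))
        yv = np.log(yv)
    r = pearson(pred, yv)
    return (0.0 if not np.isfinite(r) else r), params


@dataclass
class EvaluatedArchitecture:
    generation: int
    architecture: KinnArchitecture
    fitness: float
    params: KinnParameters | None = None


@dataclass
class SearchState:
    generation: int
    prior: ArchitecturePrior
    population: list[EvaluatedArchitecture]
    expected_fitness: float
    history: list[dict] = field(default_factory=list)
    best: EvaluatedArchitecture | None = None


def update_posterior(
    state: SearchState,
    survivors: Sequence[EvaluatedArchitecture],
) -> ArchitecturePrior:
    """Dirichlet-categorical update: one pseudo-count per survivor choice."""
    post = state.prior.copy()
    for ev in survivors:
        for w in ev.architecture.windows:
            post.start[w.rate_symbol].observe(w.start)
            post.width[w.rate_symbol].observe(w.width)
            post.kernel[w.rate_symbol].observe(w.kernel_size)
    return post


def select_survivors(
    population: list[EvaluatedArchitecture], expected_fitness: float
) -> list[EvaluatedArchitecture]:
    """Strictly-above-mean rule; if nothing clears the mean (e.g. all-equal
    fitness) fall back to the top half with deterministic tie-breaking."""
    above = [e for e in population if e.fitness > expected_fitness]
    if above:
        return above
    ranked = sorted(enumerate(population),
                    key=lambda t: (-t[1].fitness, t[0]))
    keep = max(1, int(np.ceil(len(population) / 2)))
    return [e for _, e in ranked[:keep]]


def search(
    prior: ArchitecturePrior,
    train_data: Any,
    val_data: Any,
    generations: int = 10,
    population_size: int = 10,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    update: bool = True,
    keep_params: bool = True,
) -> SearchState:
    """Run the PMBGA loop: sample -> train/evaluate -> select -> update.

    ``update=False`` freezes the prior, giving the matched-budget random-
    sampling baseline.  The returned state carries the per-generation mean
    and best-so-far fitness curves, the final posterior and the best
    architecture with its trained parameters.
    """
    if generations < 1 or population_size < 2:
        raise SpecificationError("need >= 1 generation and population >= 2")
    if train_config is None:
        train_config = TrainConfig(epochs=60, learning_rate=5e-2, patience=8)
    rng = np.random.default_rng(seed)
    state = SearchState(generation=0, prior=prior.copy(), population=[],
                        expected_fitness=float("nan"))
    best: EvaluatedArchitecture | None = None
    for gen in range(generations):
        population = []
        for _ in range(population_size):
            arch = sample_architecture(state.prior, rng)
            cfg = TrainConfig(
                epochs=train_config.epochs,
                learning_rate=train_config.learning_rate,
                batch_size=train_config.batch_size,
                loss=train_config.loss,
                seed=int(rng.integers(0, 2**31 - 1)),
                patience=train_config.patience,
            )
            fitness, params = evaluate_fitness(arch, train_data, val_data, cfg)
            ev = EvaluatedArchitecture(gen, arch, fitness,
                                       params if keep_params else None)
            population.append(ev)
            if best is None or ev.fitness > best.fitness:
                best = ev
        c_t = float(np.mean([e.fitness for e in population]))
        state.population = population
        state.expected_fitness = c_t
        state.generation = gen
        state.history.append({
            "generation": gen,
            "mean_fitness": c_t,
            "max_fitness": max(e.fitness for e in population),
            "best_so_far": best.fitness,
        })
        if update:
            survivors = select_survivors(population, c_t)
            state.prior = update_posterior(state, survivors)
    state.best = best
    return state
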