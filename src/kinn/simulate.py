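"""Ground-truth kinetic data generators.

Two benchmarks:

* **In vitro** — an Arrhenius rate model on random gRNA-DNA pairings.
  Each of the seven rate constants of the 4-state cleavage cycle is
  controlled by its own disjoint five-nucleotide window inside the active
  region [5, 40) of a 50-nt pairing; the per-position free-energy
  contribution depends on the pairing class (complementary pairs
  contribute -1, the three mismatch identities carry transition-specific
  values from {-0.1, 0.1, 1}, all in units of kT).  The label is the
  single-exponential cleavage rate: minus the slow eigenvalue of the
  depleting-reservoir generator K'.

* **In vivo** — a planted KINN reads the 25 x 13 alignment encoding and
  produces a log cleavage rate; a known sequence-context effect (an
  additive per-guanine bonus in the target region) perturbs it; a logistic
  link plus Bernoulli sampling yields rare binary edited/unedited labels.
  The true context effect is stored so transfer models can be scored
  against it.

Everything is reproducible from (config, seed): the free-energy table is
drawn once under the seed and frozen inside the config.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .encoding import (
    BASES,
    EncodedAlignment,
    GuideTargetAlignment,
    class_to_target,
    encode_invivo,
    encode_pairing,
)
from .exceptions import DataError, SpecificationError
from .kinetics import (
    KineticScheme,
    RateAssignment,
    cas9_cycle_scheme,
    edge_basis_matrices,
)
from .model import KinnArchitecture, KinnParameters, _ParamTensors, forward_batch

FORWARD_SIGN = -1.0  # Arrhenius exponent sign for forward transitions
N_PAIRING_CLASSES = 4
_MISMATCH_DG_CHOICES = (-0.1, 0.1, 1.0)
_COMPLEMENTARY_DG = -1.0


def _is_forward(edge: tuple[int, int], n_states: int) -> bool:
    a, b = edge
    return b == (a + 1) % n_states


@dataclass(frozen=True)
class SimulatorConfig:
    """Frozen description of the Arrhenius ground truth.

    ``dg_table[symbol]`` holds the four per-class free-energy values
    (kT units) for that transition's window; class 0 (complementary) is
    pinned at -1.
    """

    sequence_length: int = 50
    active_region: tuple[int, int] = (5, 40)
    n_windows: int = 7
    window_length: int = 5
    k0: float = 0.01           # baseline rate, s^-1 (s^-1 nMol^-1 for binding)
    kBT: float = 1.0           # free energies are expressed in kT units
    Du: float = 1.0            # unbound-DNA reservoir concentration, nMol
    n_sequences: int = 20000
    seed: int = 0
    dg_table: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.active_region
        if self.n_windows * self.window_length != hi - lo:
            raise SpecificationError(
                f"{self.n_windows} windows x {self.window_length} nt must tile "
                f"the active region [{lo}, {hi})"
            )
        if hi > self.sequence_length:
            raise SpecificationError("active region exceeds sequence length")
        if not self.dg_table:
            object.__setattr__(self, "dg_table", self._draw_dg_table())
        object.__setattr__(
            self, "dg_table",
            {k: tuple(float(x) for x in v) for k, v in self.dg_table.items()},
        )
        for sym, vals in self.dg_table.items():
            if len(vals) != N_PAIRING_CLASSES or vals[0] != _COMPLEMENTARY_DG:
                raise SpecificationError(
                    f"dG table for {sym} must have {N_PAIRING_CLASSES} entries "
                    f"with class 0 fixed at {_COMPLEMENTARY_DG}"
                )

    def _draw_dg_table(self) -> dict[str, tuple[float, ...]]:
        rng = np.random.default_rng(self.seed)
        table = {}
        for sym in self.scheme().edge_symbols:
            mism = rng.choice(_MISMATCH_DG_CHOICES, size=3)
            table[sym] = (_COMPLEMENTARY_DG, *map(float, mism))
        return table

    def scheme(self) -> KineticScheme:
        return cas9_cycle_scheme(4, reservoir_concentration=self.Du)

    def windows(self) -> dict[str, tuple[int, int]]:
        """Rate symbol -> [start, end) window, tiling the active region in
        scheme edge order (k01, k10, k12, k21, k23, k32, k30)."""
        lo, _ = self.active_region
        out = {}
        for i, sym in enumerate(self.scheme().edge_symbols):
            start = lo + i * self.window_length
            out[sym] = (start, start + self.window_length)
        return out

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimulatorConfig":
        d = json.loads(text)
        d["active_region"] = tuple(d["active_region"])
        return cls(**d)


def arrhenius_rates(
    config: SimulatorConfig, guide: str, target: str
) -> RateAssignment:
    """Rate constants for one pairing via the Arrhenius model.

    ``k = k0 * exp(-(1/kBT) * sum_{i in window} dG(class_i))`` for forward
    transitions; the exponent sign flips for backward transitions.  The
    binding rate additionally carries per-nMol units (the reservoir
    concentration is applied by the scheme, not here).
    """
    enc = encode_pairing(guide, target, L=config.sequence_length)
    classes = np.argmax(enc.pairing_matrix, axis=1)
    scheme = config.scheme()
    values = {}
    for sym, (lo, hi) in config.windows().items():
        dg = np.asarray(config.dg_table[sym])
        barrier = float(dg[classes[lo:hi]].sum())
        a, b = int(sym[1]), int(sym[2])
        sign = FORWARD_SIGN if _is_forward((a, b), scheme.n_states) else -FORWARD_SIGN
        values[sym] = config.k0 * float(np.exp(sign * barrier / config.kBT))
    return RateAssignment(values)


def _batch_rate_matrix_slow_rates(
    scheme: KineticScheme, rates: np.ndarray
) -> np.ndarray:
    """Vectorized slow eigen-rates of K' for rates (n, E) (raw, unscaled)."""
    k_eff = rates * scheme.effective_rate_scale()
    basis = edge_basis_matrices(scheme, conservative=False)
    Kp = np.einsum("ne,eab->nab", k_eff, basis)
    vals = np.linalg.eigvals(Kp)
    order = np.lexsort((-vals.real, np.abs(vals)), axis=1)
    lam = vals[np.arange(Kp.shape[0]), order[:, 0]]
    return -lam.real


def simulate_invitro(config: SimulatorConfig) -> pd.DataFrame:
    """Arrhenius benchmark: random pairings, exact rates, eigen-rate labels.

    Columns: ``guide``, ``target``, one column per rate symbol, and
    ``cleavage_rate``.  Deterministic under ``config.seed``; only pairings
    inside the active region influence the label.
    """
    rng = np.random.default_rng(config.seed)
    L = config.sequence_length
    scheme = config.scheme()
    n = config.n_sequences
    guide_idx = rng.integers(0, 4, size=(n, L))
    class_idx = rng.integers(0, N_PAIRING_CLASSES, size=(n, L))

    # per-edge barriers from pairing classes, vectorized over records
    windows = config.windows()
    symbols = scheme.edge_symbols
    rates = np.empty((n, scheme.n_edges))
    for e, sym in enumerate(symbols):
        lo, hi = windows[sym]
        dg = np.asarray(config.dg_table[sym])
        barrier = dg[class_idx[:, lo:hi]].sum(axis=1)
        a, b = int(sym[1]), int(sym[2])
        sign = FORWARD_SIGN if _is_forward((a, b), scheme.n_states) else -FORWARD_SIGN
        rates[:, e] = config.k0 * np.exp(sign * barrier / config.kBT)

    labels = _batch_rate_matrix_slow_rates(scheme, rates)
    guides = ["".join(BASES[i] for i in row) for row in guide_idx]
    targets = [
        "".join(class_to_target(g, int(c)) for g, c in zip(gs, cs))
        for gs, cs in zip(guides, class_idx)
    ]
    df = pd.DataFrame({"guide": guides, "target": targets})
    for e, sym in enumerate(symbols):
        df[sym] = rates[:, e]
    df["cleavage_rate"] = labels
    return df


def encode_invitro_dataset(df: pd.DataFrame, L: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """(n, L, 4) pairing encodings plus cleavage-rate labels."""
    X = np.stack([
        encode_pairing(g, t, L=L).pairing_matrix
        for g, t in zip(df["guide"], df["target"])
    ])
    return X, df["cleavage_rate"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# synthetic in vivo benchmark
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContextEffectSpec:
    """Known in vivo context effect: an additive per-guanine log-rate bonus
    over the target protospacer, plus Gaussian noise on the logit scale."""

    per_g_bonus: float = 0.35
    noise_scale: float = 0.5
    logit_slope: float = 1.0
    positive_fraction: float = 0.05


def _random_alignments(
    rng: np.random.Generator,
    n: int,
    mismatch_rate: float = 0.15,
    deletion_rate: float = 0.02,
    guides: Sequence[str] | None = None,
    n_guides: int = 20,
) -> list[GuideTargetAlignment]:
    if guides is None:
        guides = [
            "".join(rng.choice(list(BASES), size=20)) for _ in range(n_guides)
        ]
    out = []
    for _ in range(n):
        guide = guides[rng.integers(0, len(guides))]
        pam = "".join(rng.choice(list(BASES))) + "GG"
        target = []
        for gb in guide:
            u = rng.random()
            if u < deletion_rate:
                target.append("-")
            elif u < deletion_rate + mismatch_rate:
                target.append(rng.choice([b for b in BASES if b != gb]))
            else:
                target.append(gb)
        out.append(GuideTargetAlignment(
            guide=guide, pam=pam, target=pam + "".join(target)))
    return out


def planted_invivo_kinn(
    seed: int = 0,
    n_states: int = 4,
    weight_scale: float = 0.6,
) -> tuple[KinnArchitecture, KinnParameters]:
    """A ground-truth KINN over the 25 x 13 encoding with anchored windows."""
    from .search import default_windows  # local import: search builds on model

    scheme = cas9_cycle_scheme(n_states, reservoir_concentration=1.0)
    arch = KinnArchitecture(
        scheme=scheme,
        windows=default_windows(scheme, input_length=25, width=5, kernel_size=1),
        input_length=25,
        n_channels=13,
    )
    rng = np.random.default_rng(seed)
    kernels = {
        w.rate_symbol: rng.normal(0.0, weight_scale,
                                  size=(w.kernel_size, arch.n_channels))
        for w in arch.windows
    }
    biases = {w.rate_symbol: float(rng.normal(-1.0, 0.5)) for w in arch.windows}
    params = KinnParameters(
        kernels=kernels, biases=biases,
        Wt=np.ones((1, 1)), bt=np.zeros(1), Wo=np.ones((1, 1)), bo=np.zeros(1),
    )
    return arch, params


def simulate_invivo(
    config: SimulatorConfig,
    planted_kinn: tuple[KinnArchitecture, KinnParameters],
    context_effect_spec: ContextEffectSpec = ContextEffectSpec(),
    n_sequences: int | None = None,
    max_resamples: int = 5,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Binary edited/unedited labels from a planted KINN plus context effect.

    Returns ``(table, encodings)`` where encodings is the (n, 25, 13)
    array.  Cleavage probability is
    ``sigmoid(slope * (log rate + delta) + b)`` with the intercept ``b``
    calibrated so the expected positive fraction matches the spec'd rare-
    positive regime; ``delta`` (the true per-record context effect) and the
    planted log rate are stored for recovery tests.
    """
    n = n_sequences if n_sequences is not None else config.n_sequences
    rng = np.random.default_rng(config.seed)
    arch, params = planted_kinn
    spec = context_effect_spec
    for attempt in range(max_resamples):
        aligns = _random_alignments(rng, n)
        X = np.stack([encode_invivo(a).matrix for a in aligns])
        pt = _ParamTensors(params, trainable=False)
        _, log_nu = forward_batch(arch, pt, X)
        log_rate = log_nu.data
        g_counts = np.array([a.target.count("G") for a in aligns], dtype=float)
        delta = spec.per_g_bonus * (g_counts - g_counts.mean())
        score = spec.logit_slope * (log_rate + delta)
        score = score + rng.normal(0.0, spec.noise_scale, size=n)
        # calibrate the intercept so E[sigmoid(score + b)] hits the target
        # positive fraction (rare-positive regime)
        lo, hi = -float(score.max()) - 60.0, -float(score.min()) + 60.0
        for _ in range(80):
            b = 0.5 * (lo + hi)
            if np.mean(1.0 / (1.0 + np.exp(-(score + b)))) > spec.positive_fraction:
                hi = b
            else:
                lo = b
        prob = 1.0 / (1.0 + np.exp(-(score + b)))
        labels = (rng.random(n) < prob).astype(int)
        if 0 < labels.sum() < n:
            df = pd.DataFrame({
                "guide": [a.guide for a in aligns],
                "pam": [a.pam for a in aligns],
                "target_alignment": [a.target for a in aligns],
                "label": labels,
                "true_log_rate": log_rate,
                "true_delta": delta,
                "cleavage_prob": prob,
            })
            return df, X
        warnings.warn("degenerate single-class label draw; resampling",
                      RuntimeWarning, stacklevel=2)
    raise DataError("could not draw a two-class label set; check the link scale")


def write_dataset(df: pd.DataFrame, path, config: SimulatorConfig | None = None) -> None:
    """TSV output with the generating config alongside for provenance."""
    df.to_csv(path, sep="\t", index=False)
    if config is not None:
        with open(str(path) + ".config.json", "w") as fh:
            fh.write(config.to_json())
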