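"""Linear kinetic schemes, King-Altman steady states, and spectral rates.

A kinetic scheme is a strongly connected directed graph whose vertices are
enzymatic states and whose edges carry first-order rate constants
``k_{ab}``.  Occupancies evolve by the linear ODE ``ds/dt = K s`` where the
generator ``K`` has off-diagonal entries ``K[a, b] = k_{ba}`` (flux *into*
``a`` from ``b``) and diagonal entries ``-sum_g k_{ag}``; columns of the
conservative generator sum to zero, so total occupancy is conserved.

The King-Altman (KA) method expresses the steady state without solving the
linear system: for each terminal state ``a``, sum the weights ``kappa_l``
(products of rate constants) of every directed spanning tree of the scheme
whose edges all flow toward ``a``; ``s_inf[a]`` is that sum divided by the
grand total over all trees.  These trees are the KA *diagrams*; they have
exactly ``n_states - 1`` edges and every non-terminal state has exactly one
outgoing edge.

Two generators matter for cleavage assays.  The conservative ``K`` models a
closed cycle (substrate returns after product formation).  The
non-conservative ``K'`` models a depleting substrate reservoir: the return
flux of the product-forming ("activity") edges is cut, ``det K' != 0``, and
the observed single-exponential cleavage rate is minus the eigenvalue of
``K'`` closest to zero.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import scipy.linalg
from scipy.special import logsumexp

from .exceptions import (
    DegenerateSchemeError,
    DomainError,
    SpecificationError,
    StructuralError,
)

Edge = tuple[int, int]


def rate_symbol(a: int, b: int) -> str:
    """Canonical symbol for the rate constant of edge ``a -> b``."""
    return f"k{a}{b}"


def parse_rate_symbol(symbol: str) -> Edge:
    if not (symbol.startswith("k") and len(symbol) == 3 and symbol[1:].isdigit()):
        raise SpecificationError(f"unrecognized rate symbol {symbol!r}")
    return int(symbol[1]), int(symbol[2])


@dataclass(frozen=True)
class KineticScheme:
    """Directed graph of enzymatic states.

    Parameters
    ----------
    n_states:
        Number of states, labelled ``0 .. n_states-1``.
    edges:
        Ordered tuple of directed transitions ``(a, b)``.  The order fixes
        the column order of the KA binary matrix and of all rate vectors.
    activity_edges:
        Subset of ``edges`` whose flux is the experimentally measurable
        product-formation rate.  These are the edges whose return flux is
        removed in the non-conservative generator.
    reservoir_concentration:
        Optional substrate concentration (nMol) multiplying the binding
        edge's rate constant, giving it units of s^-1 nMol^-1.
    binding_edge:
        The edge scaled by ``reservoir_concentration``.
    """

    n_states: int
    edges: tuple[Edge, ...]
    activity_edges: tuple[Edge, ...] = ()
    reservoir_concentration: float | None = None
    binding_edge: Edge | None = None

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise SpecificationError("a scheme needs at least 2 states")
        seen = set()
        for a, b in self.edges:
            if a == b:
                raise SpecificationError(f"self-edge {a}->{b} not allowed")
            if not (0 <= a < self.n_states and 0 <= b < self.n_states):
                raise SpecificationError(f"edge {a}->{b} outside state range")
            if (a, b) in seen:
                raise SpecificationError(f"duplicate edge {a}->{b}")
            seen.add((a, b))
        for e in self.activity_edges:
            if e not in seen:
                raise SpecificationError(f"activity edge {e} not a scheme edge")
        if self.binding_edge is not None and self.binding_edge not in seen:
            raise SpecificationError(f"binding edge {self.binding_edge} not a scheme edge")
        if self.reservoir_concentration is not None and self.reservoir_concentration < 0:
            raise DomainError("reservoir concentration must be nonnegative")
        object.__setattr__(self, "edges", tuple(map(tuple, self.edges)))
        object.__setattr__(self, "activity_edges", tuple(map(tuple, self.activity_edges)))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def edge_symbols(self) -> tuple[str, ...]:
        return tuple(rate_symbol(a, b) for a, b in self.edges)

    def edge_index(self, edge: Edge) -> int:
        return self.edges.index(tuple(edge))

    def is_strongly_connected(self) -> bool:
        g = nx.DiGraph(list(self.edges))
        g.add_nodes_from(range(self.n_states))
        return nx.is_strongly_connected(g)

    def require_strong_connectivity(self) -> None:
        g = nx.DiGraph(list(self.edges))
        g.add_nodes_from(range(self.n_states))
        if not nx.is_strongly_connected(g):
            comps = sorted(nx.strongly_connected_components(g), key=len)
            raise StructuralError(
                "scheme is not strongly connected; "
                f"isolated component {sorted(comps[0])}"
            )

    def effective_rate_scale(self) -> np.ndarray:
        """Per-edge multiplier folding the reservoir concentration in."""
        scale = np.ones(self.n_edges)
        if self.binding_edge is not None and self.reservoir_concentration is not None:
            scale[self.edge_index(self.binding_edge)] = self.reservoir_concentration
        return scale


def cas9_cycle_scheme(
    n_states: int = 4,
    reservoir_concentration: float | None = 1.0,
) -> KineticScheme:
    """The reversible Cas9 cleavage cycle with an irreversible product step.

    States ``0 -> 1 -> ... -> n-1`` are connected reversibly; the final
    product-forming ("cut") edge ``n-1 -> 0`` closes the cycle and is the
    single activity edge.  Edge order is ``k01, k10, k12, k21, ...,
    k(n-1)0`` — forward/backward interleaved, cut edge last.  For
    ``n_states=4`` this is the canonical 4-state cleavage cycle whose
    conservative generator has the sparsity pattern with ``K[3, 0] = 0``
    (no direct ``0 -> 3`` transition).
    """
    edges: list[Edge] = []
    for a in range(n_states - 1):
        edges.append((a, a + 1))
        edges.append((a + 1, a))
    cut = (n_states - 1, 0)
    edges.append(cut)
    return KineticScheme(
        n_states=n_states,
        edges=tuple(edges),
        activity_edges=(cut,),
        reservoir_concentration=reservoir_concentration,
        binding_edge=(0, 1),
    )


@dataclass(frozen=True)
class RateAssignment:
    """A strictly positive rate constant for every edge of a scheme."""

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        for sym, v in self.values.items():
            if not (math.isfinite(v) and v > 0):
                raise DomainError(f"rate {sym} must be positive and finite, got {v}")
        object.__setattr__(self, "values", dict(self.values))

    def vector(self, scheme: KineticScheme) -> np.ndarray:
        """Rates ordered as ``scheme.edges`` (reservoir NOT folded in)."""
        out = np.empty(scheme.n_edges)
        for i, sym in enumerate(scheme.edge_symbols):
            if sym not in self.values:
                raise SpecificationError(f"missing rate for edge {sym}")
            out[i] = self.values[sym]
        return out

    @classmethod
    def from_vector(cls, scheme: KineticScheme, vector: Iterable[float]) -> "RateAssignment":
        vec = list(vector)
        if len(vec) != scheme.n_edges:
            raise SpecificationError("rate vector length != number of edges")
        return cls(dict(zip(scheme.edge_symbols, map(float, vec))))


@dataclass(frozen=True)
class RateMatrix:
    matrix: np.ndarray
    conservative: bool

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        off = m - np.diag(np.diag(m))
        if np.any(off < -1e-12 * max(1.0, np.abs(m).max())):
            raise DomainError("off-diagonal generator entries must be >= 0")


@dataclass(frozen=True)
class KADiagram:
    """A directed spanning tree of the scheme converging on one state."""

    edges: frozenset[Edge]
    terminal_state: int


@dataclass(frozen=True)
class KADiagramSet:
    """All KA diagrams of a scheme plus the static binary matrix B.

    ``binary_matrix[l, e] = 1`` iff scheme edge ``e`` belongs to diagram
    ``l``; ``terminal_states[l]`` is the state diagram ``l`` converges on.
    ``B @ log(k)`` is the vector of log diagram weights ``log kappa_l``.
    """

    scheme: KineticScheme
    diagrams: tuple[KADiagram, ...]
    binary_matrix: np.ndarray
    terminal_states: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.terminal_states is None:
            object.__setattr__(
                self,
                "terminal_states",
                np.array([d.terminal_state for d in self.diagrams], dtype=int),
            )

    @property
    def n_diagrams(self) -> int:
        return len(self.diagrams)

    def diagrams_for_terminal(self, state: int) -> list[KADiagram]:
        return [d for d in self.diagrams if d.terminal_state == state]

    def log_weights(self, log_rates: np.ndarray) -> np.ndarray:
        """log kappa_l for effective (reservoir-scaled) log rates."""
        return self.binary_matrix @ np.asarray(log_rates, dtype=float)


@dataclass(frozen=True)
class StateOccupancy:
    """Normalized occupancy vector, optionally time-stamped (seconds)."""

    vector: np.ndarray
    time: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        if np.any(v < -1e-9):
            raise DomainError("occupancies must be nonnegative")
        if abs(v.sum() - 1.0) > 1e-9:
            raise DomainError(f"occupancies must sum to 1, got {v.sum()!r}")
        object.__setattr__(self, "vector", v)
        if self.time is not None and self.time < 0:
            raise DomainError("time must be nonnegative")


# ---------------------------------------------------------------------------
# generator construction
# ---------------------------------------------------------------------------

def edge_basis_matrices(scheme: KineticScheme, conservative: bool = True) -> np.ndarray:
    """Constant matrices ``M_e`` with ``K = sum_e k_eff[e] * M_e``.

    Each ``M_e`` carries ``-1`` at ``(a, a)`` and, unless the edge is an
    activity edge of a non-conservative generator, ``+1`` at ``(b, a)``.
    The reservoir scale is *not* included here.
    """
    n = scheme.n_states
    mats = np.zeros((scheme.n_edges, n, n))
    cut = set(scheme.activity_edges) if not conservative else set()
    for i, (a, b) in enumerate(scheme.edges):
        mats[i, a, a] = -1.0
        if (a, b) not in cut:
            mats[i, b, a] = 1.0
    return mats


def build_rate_matrix(
    scheme: KineticScheme,
    rates: RateAssignment,
    conservative: bool = True,
) -> RateMatrix:
    """Assemble the generator K (conservative) or K' (depleting reservoir).

    The conservative generator satisfies ``ds/dt = K s`` with zero column
    sums.  With ``conservative=False`` the return flux of every activity
    edge is removed from the off-diagonal (the edge still drains its source
    state), modelling irreversible loss of substrate; ``det K' != 0``.
    """
    if not conservative and not scheme.activity_edges:
        raise SpecificationError(
            "non-conservative generator requires activity (product-forming) edges"
        )
    k = rates.vector(scheme) * scheme.effective_rate_scale()
    mats = edge_basis_matrices(scheme, conservative=conservative)
    return RateMatrix(np.tensordot(k, mats, axes=1), conservative=conservative)


# ---------------------------------------------------------------------------
# King-Altman diagram enumeration
# ---------------------------------------------------------------------------

def _diagrams_for_terminal(scheme: KineticScheme, terminal: int) -> list[frozenset[Edge]]:
    # Choose one outgoing edge per non-terminal state; keep choices whose
    # successor map reaches the terminal from every state (no cycles).
    out_edges: dict[int, list[Edge]] = {s: [] for s in range(scheme.n_states)}
    for a, b in scheme.edges:
        out_edges[a].append((a, b))
    nonterminal = [s for s in range((scheme.n_states)) if s != terminal]
    if any(not out_edges[s] for s in nonterminal):
        return []
    found = []
    for combo in itertools.product(*(out_edges[s] for s in nonterminal)):
        succ = {a: b for a, b in combo}
        ok = True
        for start in nonterminal:
            node, steps = start, 0
            while node != terminal:
                node = succ[node]
                steps += 1
                if steps > scheme.n_states:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            found.append(frozenset(combo))
    return found


def enumerate_ka_diagrams(scheme: KineticScheme) -> KADiagramSet:
    """Enumerate every KA diagram (convergent spanning tree) of the scheme.

    Exhaustive over per-state outgoing-edge choices; exact at the 3-6 state
    scale this package targets.  Diagrams that would need a directed edge
    absent from the scheme simply never arise.
    """
    scheme.require_strong_connectivity()
    diagrams: list[KADiagram] = []
    for terminal in range(scheme.n_states):
        for edge_set in _diagrams_for_terminal(scheme, terminal):
            diagrams.append(KADiagram(edges=edge_set, terminal_state=terminal))
    edge_pos = {e: i for i, e in enumerate(scheme.edges)}
    B = np.zeros((len(diagrams), scheme.n_edges))
    for row, diag in enumerate(diagrams):
        for e in diag.edges:
            B[row, edge_pos[e]] = 1.0
    return KADiagramSet(scheme=scheme, diagrams=tuple(diagrams), binary_matrix=B)


def steady_state_log_numerators(
    diagrams: KADiagramSet, log_rates_eff: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-state ``log sum_{l->a} kappa_l`` and the global log denominator.

    Computed entirely in log space (log-sum-exp) so rate ratios of many
    decades do not overflow.  States with no diagram get ``-inf``.
    """
    logw = diagrams.log_weights(log_rates_eff)
    n = diagrams.scheme.n_states
    nums = np.full(n, -np.inf)
    for a in range(n):
        mask = diagrams.terminal_states == a
        if mask.any():
            nums[a] = logsumexp(logw[mask])
    denom = logsumexp(logw)
    return nums, float(denom)


def steady_state_ka(
    scheme: KineticScheme,
    rates: RateAssignment,
    diagrams: KADiagramSet | None = None,
) -> StateOccupancy:
    """Steady-state occupancy via the King-Altman diagram sums."""
    if diagrams is None:
        diagrams = enumerate_ka_diagrams(scheme)
    if diagrams.scheme.edges != scheme.edges:
        raise SpecificationError("diagram set was enumerated from a different scheme")
    log_k = np.log(rates.vector(scheme) * scheme.effective_rate_scale())
    nums, denom = steady_state_log_numerators(diagrams, log_k)
    if not np.isfinite(denom):
        raise DegenerateSchemeError("total KA diagram weight is zero")
    s = np.exp(nums - denom)
    return StateOccupancy(vector=s / s.sum())


# ---------------------------------------------------------------------------
# dynamics and observables
# ---------------------------------------------------------------------------

def propagate(
    scheme: KineticScheme,
    rates: RateAssignment,
    s0: StateOccupancy,
    t: float,
) -> StateOccupancy:
    """Evolve ``ds/dt = K s`` for time ``t`` (conservative dynamics).

    Solution ``s(t) = expm(K t) s0``, which relaxes toward the steady state
    because every nonzero eigenvalue of a conservative generator has
    negative real part.
    """
    if t < 0:
        raise DomainError("propagation time must be nonnegative")
    K = build_rate_matrix(scheme, rates, conservative=True).matrix
    s = scipy.linalg.expm(K * t) @ s0.vector
    s = np.clip(s, 0.0, None)
    return StateOccupancy(vector=s / s.sum(), time=t)


def activity(
    scheme: KineticScheme,
    rates: RateAssignment,
    occupancy: StateOccupancy,
) -> float:
    """Production rate nu = sum over activity edges of k_eff * s_source."""
    if not scheme.activity_edges:
        raise SpecificationError("scheme declares no activity edges")
    k_eff = rates.vector(scheme) * scheme.effective_rate_scale()
    nu = 0.0
    for a, b in scheme.activity_edges:
        nu += k_eff[scheme.edge_index((a, b))] * occupancy.vector[a]
    return float(nu)


def _pick_slow_eigenvalue(eigvals: np.ndarray, zero_tol: float = 1e-12) -> complex:
    """The nonzero eigenvalue closest to zero (the slow decay mode).

    Numerically-zero modes (conserved subspaces) are excluded; ties in
    magnitude break toward the larger real part.
    """
    scale = np.abs(eigvals).max()
    nonzero = eigvals[np.abs(eigvals) > zero_tol * scale]
    if nonzero.size == 0:
        raise DegenerateSchemeError("all eigenvalues are numerically zero")
    order = np.lexsort((-nonzero.real, np.abs(nonzero)))
    return nonzero[order[0]]


def slow_eigen_rate(
    scheme: KineticScheme,
    rates: RateAssignment,
    imag_tol: float = 1e-8,
) -> float:
    """Minus the eigenvalue of K' closest to zero — the observed cleavage rate.

    All eigenvalues of the non-conservative generator lie in the closed left
    half-plane; the one of smallest magnitude is the slowest decay mode and
    sets the single-exponential rate seen in kinetic profiling.  A complex
    slow mode (over/damped oscillation) triggers a warning and the real part
    is returned.
    """
    Kp = build_rate_matrix(scheme, rates, conservative=False).matrix
    lam = _pick_slow_eigenvalue(np.linalg.eigvals(Kp))
    scale = max(abs(lam), 1e-300)
    if abs(lam.imag) > imag_tol * scale:
        warnings.warn(
            f"slow mode is complex: {lam.real:+.6g} {lam.imag:+.6g}i; "
            "returning -Re(lambda)",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(-lam.real)


# ---------------------------------------------------------------------------
# characteristic-polynomial identities for the 4-state cleavage cycle
# ---------------------------------------------------------------------------

def _exact_generator(
    scheme: KineticScheme, rates: RateAssignment, conservative: bool
) -> list[list[Fraction]]:
    """The generator with entries as exact rationals of the rate values.

    The determinant identities rest on exact algebraic cancellation (the
    diagonal entries are sums of the same rate constants that appear off
    the diagonal); float64 assembly plus LU resolves them only to ~1e-9
    relative when rates span decades, so the identity checker works over
    the rationals.
    """
    n = scheme.n_states
    k = rates.vector(scheme) * scheme.effective_rate_scale()
    M = [[Fraction(0)] * n for _ in range(n)]
    cut = set(scheme.activity_edges) if not conservative else set()
    for i, (a, b) in enumerate(scheme.edges):
        f = Fraction(k[i])
        M[a][a] -= f
        if (a, b) not in cut:
            M[b][a] += f
    return M


def _det_exact(M: list[list[Fraction]], rows: tuple[int, ...]) -> Fraction:
    """Exact determinant of a principal submatrix by Leibniz expansion."""
    total = Fraction(0)
    m = len(rows)
    for perm in itertools.permutations(range(m)):
        sign = 1
        seen = [False] * m
        for i in range(m):  # parity via cycle decomposition
            if seen[i]:
                continue
            j, length = i, 0
            while not seen[j]:
                seen[j] = True
                j = perm[j]
                length += 1
            if length % 2 == 0:
                sign = -sign
        term = Fraction(sign)
        for i in range(m):
            term *= M[rows[i]][rows[perm[i]]]
        total += term
    return total


def _char_poly_coeff(M: list[list[Fraction]], order: int) -> float:
    """Coefficient of x**order in det(xI - M), via principal minors:
    ``a_k = (-1)**(n-k) * E_{n-k}(M)`` with ``E_j`` summing the j x j
    principal minors, evaluated exactly."""
    n = len(M)
    j = n - order
    total = Fraction(0)
    for rows in itertools.combinations(range(n), j):
        total += _det_exact(M, rows)
    return float((-1) ** j * total)


def char_poly_identities(scheme: KineticScheme, rates: RateAssignment) -> dict[str, float]:
    """Both sides of the depleting-reservoir determinant and a1 identities.

    For the 4-state cleavage cycle: ``det K'`` equals the product of the
    forward-cycle rates (binding x 2 internal steps x cut, reservoir scale
    included), and the linear characteristic-polynomial coefficient is the
    same for K and K' and equals the total KA diagram weight.
    """
    expected = cas9_cycle_scheme(4).edges
    if scheme.n_states != 4 or tuple(scheme.edges) != expected:
        raise SpecificationError(
            "characteristic-polynomial identities require the 4-state "
            "cleavage cycle topology"
        )
    K = _exact_generator(scheme, rates, conservative=True)
    Kp = _exact_generator(scheme, rates, conservative=False)
    k_eff = rates.vector(scheme) * scheme.effective_rate_scale()
    forward = [(0, 1), (1, 2), (2, 3), (3, 0)]
    cycle = Fraction(1)
    for e in forward:
        cycle *= Fraction(k_eff[scheme.edge_index(e)])
    all_rows = tuple(range(4))
    return {
        "det_K": float(_det_exact(K, all_rows)),
        "det_Kprime": float(_det_exact(Kp, all_rows)),
        "a1_K": _char_poly_coeff(K, 1),
        "a1_Kprime": _char_poly_coeff(Kp, 1),
        "cycle_product": float(cycle),
    }


def scheme_to_dict(scheme: KineticScheme) -> dict:
    """JSON-ready description of a scheme (states 0-indexed)."""
    return {
        "n_states": scheme.n_states,
        "edges": [
            {"from": a, "to": b, "symbol": rate_symbol(a, b)}
            for a, b in scheme.edges
        ],
        "activity_edges": [
            {"from": a, "to": b, "symbol": rate_symbol(a, b)}
            for a, b in scheme.activity_edges
        ],
        "reservoir_concentration": scheme.reservoir_concentration,
        "binding_edge": (
            {"from": scheme.binding_edge[0], "to": scheme.binding_edge[1]}
            if scheme.binding_edge is not None else None
        ),
    }


def scheme_from_dict(d: Mapping) -> KineticScheme:
    return KineticScheme(
        n_states=int(d["n_states"]),
        edges=tuple((int(e["from"]), int(e["to"])) for e in d["edges"]),
        activity_edges=tuple(
            (int(e["from"]), int(e["to"])) for e in d.get("activity_edges", ())
        ),
        reservoir_concentration=d.get("reservoir_concentration"),
        binding_edge=(
            (int(d["binding_edge"]["from"]), int(d["binding_edge"]["to"]))
            if d.get("binding_edge") else None
        ),
    )


def total_ka_weight(scheme: KineticScheme, rates: RateAssignment,
                    diagrams: KADiagramSet | None = None) -> float:
    """Sum of all KA diagram weights (the King-Altman denominator)."""
    if diagrams is None:
        diagrams = enumerate_ka_diagrams(scheme)
    log_k = np.log(rates.vector(scheme) * scheme.effective_rate_scale())
    return float(np.exp(logsumexp(diagrams.log_weights(log_k))))
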