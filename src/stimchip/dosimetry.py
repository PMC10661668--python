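"""Analytic electro-fluidic dosimetry for a microfluidic stimulation chamber.

A rectangular electrolyte-filled microchannel of length ``L``, width ``w``
and height ``h`` behaves as an ohmic resistor ``R = L / (sigma * w * h)``
(Pouillet's law), so a constant input current ``i`` establishes a uniform
DC electric field ``E = i / (sigma * w * h)`` inside it.  A chamber built
as a network of such channels is therefore a resistor network: nodal
analysis gives the branch currents, and each geometry-carrying branch maps
its current back to a field.  The same module carries the electrode-side
bookkeeping: disk current density, delivered charge of DC and pulsed
protocols, the capacitive discharge window ``t = C * dV / i`` of a
polarizable electrode, integral capacitance from slow cyclic voltammetry,
and regime classification of constant-current voltage excursions
(capacitive ramp vs. faradaic plateau).

All quantities are SI internally (metres, siemens/metre, amperes, volts,
farads, seconds); unit conversion happens only at the CLI boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import DomainError, InsufficientDataError, SolverError, TopologyError

__all__ = [
    "ChannelGeometry",
    "Electrolyte",
    "Edge",
    "ResistorNetwork",
    "ElectrodeSpec",
    "StimulationProtocol",
    "SampledTrace",
    "ExcursionResult",
    "channel_resistance",
    "field_from_current",
    "solve_network",
    "section_fields",
    "disk_current_density",
    "delivered_charge",
    "capacitive_discharge_time",
    "capacitance_from_cv",
    "analyze_excursion",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular microchannel segment.

    Parameters
    ----------
    length, width, height:
        Channel dimensions in metres; all strictly positive.
    label:
        Section name used in field reports (e.g. ``"s1"``).
    """

    length: float
    width: float
    height: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.length > 0 and self.width > 0 and self.height > 0):
            raise DomainError(
                f"channel dimensions must be strictly positive, got "
                f"L={self.length}, w={self.width}, h={self.height}"
            )

    @property
    def cross_section(self) -> float:
        """Cross-sectional area A = w * h in square metres."""
        return self.width * self.height


@dataclass(frozen=True)
class Electrolyte:
    """Ohmic electrolyte characterised by its conductivity sigma (S/m)."""

    conductivity: float

    def __post_init__(self) -> None:
        if not self.conductivity > 0:
            raise DomainError(f"conductivity must be > 0, got {self.conductivity}")


@dataclass(frozen=True, eq=False)
class Edge:
    """Directed resistor branch between two named nodes.

    Exactly one of ``resistance`` (ohms) or ``geometry`` must be given; a
    geometry edge derives its resistance from the electrolyte at solve time
    and is treated as a stimulation section when reporting fields.  Edges
    compare by identity so that duplicate parallel branches (same nodes,
    same resistance) remain distinct keys in current mappings.
    """

    node_a: str
    node_b: str
    resistance: float | None = None
    geometry: ChannelGeometry | None = None

    def __post_init__(self) -> None:
        if (self.resistance is None) == (self.geometry is None):
            raise DomainError("edge needs exactly one of resistance or geometry")
        if self.resistance is not None and not self.resistance > 0:
            raise DomainError(f"resistance must be > 0, got {self.resistance}")
        if self.node_a == self.node_b:
            raise DomainError("self-loop edges are not allowed")

    def resolve_resistance(self, medium: Electrolyte | None) -> float:
        if self.resistance is not None:
            return self.resistance
        if medium is None:
            raise DomainError("geometry edge requires an electrolyte")
        return channel_resistance(self.geometry, medium)


@dataclass(frozen=True)
class ResistorNetwork:
    """Resistor network with a single constant-current source.

    ``source`` is ``(positive_node, negative_node, i_in)``: ``i_in`` amperes
    are injected at the positive terminal and withdrawn at the negative one.
    An :class:`Electrolyte` may be attached so geometry edges can resolve
    their resistance without passing the medium at every call.
    """

    edges: tuple[Edge, ...]
    source: tuple[str, str, float]
    electrolyte: Electrolyte | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", tuple(self.edges))
        pos, neg, i_in = self.source
        if pos == neg:
            raise DomainError("source terminals must be distinct nodes")
        if i_in < 0:
            raise DomainError(f"source current must be >= 0, got {i_in}")

    @property
    def nodes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for e in self.edges:
            seen.setdefault(e.node_a)
            seen.setdefault(e.node_b)
        seen.setdefault(self.source[0])
        seen.setdefault(self.source[1])
        return tuple(seen)


@dataclass(frozen=True)
class ElectrodeSpec:
    """Disk electrode with optional double-layer charge budget.

    ``capacitance`` (F) and ``voltage_window`` (V) bound the charge the
    electrode can pass capacitively: Q_cap = C * dV.
    """

    diameter: float
    capacitance: float | None = None
    voltage_window: float | None = None

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise DomainError(f"diameter must be > 0, got {self.diameter}")
        for name in ("capacitance", "voltage_window"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise DomainError(f"{name} must be > 0 when present, got {v}")

    @property
    def area(self) -> float:
        """Disk area in square metres."""
        return math.pi * (self.diameter / 2.0) ** 2


@dataclass(frozen=True)
class StimulationProtocol:
    """DC or pulsed constant-current stimulation waveform.

    DC mode: ``current`` for ``duration`` seconds.  Pulsed mode: ``n_pulses``
    rectangular pulses of ``pulse_on`` seconds at ``current``, separated by
    ``pulse_off`` seconds of zero current.
    """

    mode: str
    current: float
    duration: float = 0.0
    pulse_on: float = 0.0
    pulse_off: float = 0.0
    n_pulses: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("dc", "pulsed"):
            raise DomainError(f"mode must be 'dc' or 'pulsed', got {self.mode!r}")
        if not self.current > 0:
            raise DomainError(f"current must be > 0, got {self.current}")
        if min(self.duration, self.pulse_on, self.pulse_off) < 0:
            raise DomainError("durations must be >= 0")
        if self.n_pulses < 0:
            raise DomainError("n_pulses must be >= 0")


@dataclass(frozen=True)
class SampledTrace:
    """Two-column sampled signal (e.g. voltage excursion V(t), or a CV loop).

    ``x`` and ``y`` must have equal length >= 2 and be finite.  A time-domain
    excursion has strictly increasing ``x``; a cyclic voltammogram sampled
    over potential retraces its window, so monotonicity is checked by the
    consumers that need it rather than here.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or x.size != y.size or x.size < 2:
            raise DomainError("trace needs two equal-length 1-D columns of >= 2 samples")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise DomainError("trace contains non-finite samples")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def is_strictly_increasing(self) -> bool:
        return bool(np.all(np.diff(self.x) > 0))


# ---------------------------------------------------------------------------
# Channel / field primitives
# ---------------------------------------------------------------------------

def channel_resistance(geom: ChannelGeometry, medium: Electrolyte) -> float:
    """Ohmic resistance R = L / (sigma * w * h) of a rectangular channel."""
    return geom.length / (medium.conductivity * geom.cross_section)


def field_from_current(i: float, geom: ChannelGeometry, medium: Electrolyte) -> float:
    """Uniform field E = i / (sigma * w * h) in V/m for current ``i`` >= 0."""
    if i < 0:
        raise DomainError(f"current must be >= 0, got {i}")
    return i / (medium.conductivity * geom.cross_section)


# ---------------------------------------------------------------------------
# Network solution
# ---------------------------------------------------------------------------

def _connected(nodes: Sequence[str], edges: Sequence[Edge], start: str, goal: str) -> bool:
    adj: dict[str, list[str]] = {n: [] for n in nodes}
    for e in edges:
        adj[e.node_a].append(e.node_b)
        adj[e.node_b].append(e.node_a)
    stack, seen = [start], {start}
    while stack:
        n = stack.pop()
        if n == goal:
            return True
        for m in adj[n]:
            if m not in seen:
                seen.add(m)
                stack.append(m)
    return False


def solve_network(
    net: ResistorNetwork, medium: Electrolyte | None = None
) -> dict[Edge, float]:
    """Solve branch currents by nodal analysis.

    Returns a mapping edge -> signed current in amperes (positive in the
    ``node_a -> node_b`` direction).  Kirchhoff's current law holds at every
    node to solver tolerance and the full source current flows end to end.
    """
    medium = medium or net.electrolyte
    pos, neg, i_in = net.source
    nodes = net.nodes
    if not net.edges:
        raise TopologyError("network has no edges")
    if not _connected(nodes, net.edges, pos, neg):
        raise TopologyError(f"source terminals {pos!r} and {neg!r} are not connected")

    index = {n: k for k, n in enumerate(nodes)}
    n_unknown = len(nodes) - 1  # ground the negative terminal
    ground = index[neg]

    def row(k: int) -> int | None:
        if k == ground:
            return None
        return k if k < ground else k - 1

    G = np.zeros((n_unknown, n_unknown))
    rhs = np.zeros(n_unknown)
    resistances = [e.resolve_resistance(medium) for e in net.edges]
    for e, R in zip(net.edges, resistances):
        g = 1.0 / R
        a, b = row(index[e.node_a]), row(index[e.node_b])
        if a is not None:
            G[a, a] += g
        if b is not None:
            G[b, b] += g
        if a is not None and b is not None:
            G[a, b] -= g
            G[b, a] -= g
    src = row(index[pos])
    if src is not None:
        rhs[src] += i_in

    try:
        v = np.linalg.solve(G, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by topology check
        raise SolverError("singular nodal system") from exc

    potential = np.zeros(len(nodes))
    for k in range(len(nodes)):
        r = row(k)
        potential[k] = 0.0 if r is None else v[r]

    return {
        e: (potential[index[e.node_a]] - potential[index[e.node_b]]) / R
        for e, R in zip(net.edges, resistances)
    }


def kcl_residuals(net: ResistorNetwork, currents: Mapping[Edge, float]) -> dict[str, float]:
    """Net current into each non-terminal node (should vanish); terminals
    include the source contribution."""
    pos, neg, i_in = net.source
    res = {n: 0.0 for n in net.nodes}
    for e, i in currents.items():
        res[e.node_a] -= i
        res[e.node_b] += i
    res[pos] += i_in
    res[neg] -= i_in
    return res


def section_fields(
    net: ResistorNetwork, medium: Electrolyte | None = None
) -> dict[str, float]:
    """Electric field (V/m) in every geometry-carrying branch, keyed by its
    section label, ordered by descending field."""
    medium = medium or net.electrolyte
    if medium is None:
        raise DomainError("an electrolyte is required to compute fields")
    currents = solve_network(net, medium)
    fields: dict[str, float] = {}
    for e, i in currents.items():
        if e.geometry is not None:
            fields[e.geometry.label] = field_from_current(abs(i), e.geometry, medium)
    return dict(sorted(fields.items(), key=lambda kv: -kv[1]))


# ---------------------------------------------------------------------------
# Electrode / protocol bookkeeping
# ---------------------------------------------------------------------------

def disk_current_density(i: float, electrode: ElectrodeSpec) -> float:
    """Current density j = i / (pi (d/2)^2) in A/m^2 on a disk electrode."""
    if i < 0:
        raise DomainError(f"current must be >= 0, got {i}")
    return i / electrode.area


def delivered_charge(protocol: StimulationProtocol) -> float:
    """Total delivered charge in coulombs.

    DC: Q = i * duration.  Pulsed: Q = i * pulse_on * n_pulses; the off
    intervals carry no current and contribute nothing.
    """
    if protocol.mode == "dc":
        return protocol.current * protocol.duration
    return protocol.current * protocol.pulse_on * protocol.n_pulses


def capacitive_discharge_time(electrode: ElectrodeSpec, i: float) -> float:
    """Time t = C * dV / i the double layer can support current ``i``.

    Returns ``inf`` for i = 0 (a zero current never exhausts the window).
    """
    if electrode.capacitance is None or electrode.voltage_window is None:
        raise DomainError("electrode needs capacitance and voltage_window")
    if i < 0:
        raise DomainError(f"current must be >= 0, got {i}")
    if i == 0:
        return math.inf
    return electrode.capacitance * electrode.voltage_window / i


# ---------------------------------------------------------------------------
# Electrochemistry: CV capacitance and excursion regimes
# ---------------------------------------------------------------------------

def capacitance_from_cv(cv: SampledTrace, scan_rate: float) -> float:
    """Integral capacitance from a slow cyclic voltammogram.

    C = (closed-loop integral of |i| dV) / (2 * scan_rate * dV_window),
    evaluated by the trapezoidal rule over the sampled path.  For an ideal
    capacitor (rectangular CV of half-height i_c) this reduces to
    C = i_c / scan_rate.  ``cv.x`` is potential (V), ``cv.y`` current (A);
    the loop may retrace the window, so |dV| is used segment-wise.
    """
    if not scan_rate > 0:
        raise DomainError(f"scan rate must be > 0, got {scan_rate}")
    V, I = cv.x, cv.y
    window = float(V.max() - V.min())
    if window <= 0:
        raise DomainError("CV spans a zero potential window")
    seg = 0.5 * (np.abs(I[1:]) + np.abs(I[:-1])) * np.abs(np.diff(V))
    return float(seg.sum() / (2.0 * scan_rate * window))


@dataclass(frozen=True)
class ExcursionResult:
    """Outcome of constant-current voltage-excursion analysis."""

    slope: float
    c_eff: float | None
    regime: str  # capacitive | faradaic_onset | faradaic_dominant
    transition_time: float | None
    breakpoint_index: int | None = None
    r_squared: float = float("nan")


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line fit; returns (slope, intercept, sse)."""
    A = np.vstack([x, np.ones_like(x)]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def analyze_excursion(
    exc: SampledTrace,
    i: float,
    *,
    improvement_threshold: float = 0.10,
    linearity_r2: float = 0.99,
    flat_slope_fraction: float = 0.05,
    initial_window: int = 4,
) -> ExcursionResult:
    """Classify a constant-current voltage excursion V(t) at drive current ``i``.

    A purely capacitive electrode gives a strictly linear ramp dV/dt = i/C;
    faradaic charge transfer collapses the slope.  The trace is fit with one
    line and with the best two-segment piecewise line (brute-force breakpoint
    search); the two-segment fit is adopted only when it reduces the residual
    by more than ``improvement_threshold``.  Regimes:

    - ``capacitive``: single linear ramp (R^2 >= ``linearity_r2``), no
      transition; C_eff = i / slope.
    - ``faradaic_onset``: ramp followed by slope collapse (second-segment
      slope below ``flat_slope_fraction`` of the first); transition_time is
      the breakpoint abscissa; C_eff from the initial ramp.
    - ``faradaic_dominant``: flat from the start (whole-trace slope at or
      below ``flat_slope_fraction`` of the initial-window slope); C_eff not
      reported.
    """
    if not exc.is_strictly_increasing:
        raise DomainError("excursion time axis must be strictly increasing")
    if i <= 0:
        raise DomainError(f"drive current must be > 0, got {i}")
    t, V = exc.x, exc.y
    n = t.size
    if n < 4:
        raise InsufficientDataError(f"need >= 4 samples, got {n}")

    slope_all, _, sse1 = _ols(t, V)
    ss_tot = float(np.sum((V - V.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - sse1 / ss_tot

    # Best two-segment fit: breakpoint k splits samples [0:k] / [k:], each
    # side needs >= 2 points.
    best_k, best_sse = None, math.inf
    for k in range(2, n - 1):
        _, _, e1 = _ols(t[:k], V[:k])
        _, _, e2 = _ols(t[k:], V[k:])
        if e1 + e2 < best_sse:
            best_sse, best_k = e1 + e2, k

    w = min(max(initial_window, 4), n)
    slope_init, _, _ = _ols(t[:w], V[:w])

    two_segment_wins = best_k is not None and best_sse < (1.0 - improvement_threshold) * sse1
    if not two_segment_wins and r2 >= linearity_r2:
        if abs(slope_all) <= flat_slope_fraction * abs(slope_init) or slope_all <= 0:
            return ExcursionResult(slope_all, None, "faradaic_dominant", None, None, r2)
        return ExcursionResult(slope_all, i / slope_all, "capacitive", None, None, r2)

    if best_k is None:
        # Poor single-line fit but no admissible breakpoint: report the
        # whole-trace slope as capacitive-by-default.
        return ExcursionResult(slope_all, i / slope_all if slope_all > 0 else None,
                               "capacitive", None, None, r2)

    s1, _, _ = _ols(t[:best_k], V[:best_k])
    s2, _, _ = _ols(t[best_k:], V[best_k:])
    if s1 <= 0 or abs(slope_all) <= flat_slope_fraction * abs(slope_init):
        return ExcursionResult(slope_all, None, "faradaic_dominant", None, best_k, r2)
    if abs(s2) < flat_slope_fraction * abs(s1):
        return ExcursionResult(
            s1, i / s1, "faradaic_onset", float(t[best_k]), best_k, r2
        )
    # Slope changed but did not collapse: still capacitively dominated.
    return ExcursionResult(s1, i / s1, "capacitive", None, best_k, r2)
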