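"""Core 1-D neural-field machinery for the collicular saccade model.

The intermediate superior colliculus is abstracted as a one-dimensional
field of ``N`` nodes spanning 10 mm of collicular surface on a torus
(wrap-around boundary).  Each node carries an internal state ``u``
(membrane-potential-like, arbitrary units) mapped through a sigmoid to an
output activity ``a`` in (0, 1).  Nodes interact through a
lateral-inhibition kernel: a Gaussian shifted down by a fraction of its
peak, so that nearby nodes excite and distant nodes inhibit each other.
The field evolves as a discrete-time leaky integrator with a 1 ms step.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import expit


@dataclass(frozen=True)
class ModelConstants:
    """Fixed geometry and dynamics parameters of the field model.

    Parameters
    ----------
    n_nodes
        Number of field nodes (default 100).
    field_min_mm, field_max_mm
        Extent of the modelled collicular surface in mm; the field is
        periodic with period ``field_max_mm - field_min_mm``.
    dt_ms
        Integration time step in ms (the model is 1-ms resolved).
    tau_ms
        Leaky-integrator time constant in ms.
    beta
        Steepness of the sigmoidal output nonlinearity.
    sigma_mm
        Width of the Gaussian lateral-interaction kernel in mm.
    sf
        Scale factor (peak) of the interaction Gaussian.
    m_frac
        Inhibitory shift applied to the interaction Gaussian, as a
        fraction of its maximum (``m = m_frac * max(G)``).
    threshold
        Output activity at which a saccade is initiated when reached at
        any non-central node.
    reset_value
        Internal state every node is reset to at trial start (negative,
        representing a hyperpolarised membrane potential).
    noncentral_radius_mm
        Radius of the central (foveal/fixation) zone excluded from
        saccade-threshold detection; nodes with ``|x| > radius`` are
        eligible.
    timeout_ms
        Maximum simulated time after target onset before a trial is
        declared to contain no saccade.
    """

    n_nodes: int = 100
    field_min_mm: float = -5.0
    field_max_mm: float = 5.0
    dt_ms: float = 1.0
    tau_ms: float = 4.0
    beta: float = 0.09
    sigma_mm: float = 0.85
    sf: float = 74.7
    m_frac: float = 0.8
    threshold: float = 0.7
    reset_value: float = -30.0
    noncentral_radius_mm: float = 1.0
    timeout_ms: int = 500

    def __post_init__(self) -> None:
        if self.n_nodes <= 0:
            raise ValueError("n_nodes must be positive")
        if self.field_max_mm <= self.field_min_mm:
            raise ValueError("field extent must have positive span")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.tau_ms <= self.dt_ms:
            raise ValueError("tau_ms must exceed dt_ms")
        if self.reset_value >= 0.0:
            raise ValueError("reset_value must be negative")
        if self.sigma_mm <= 0.0 or self.sf <= 0.0 or self.beta <= 0.0:
            raise ValueError("sigma_mm, sf and beta must be positive")
        if self.timeout_ms <= 0:
            raise ValueError("timeout_ms must be positive")

    @property
    def period_mm(self) -> float:
        """Circumference of the toroidal feature space in mm."""
        return self.field_max_mm - self.field_min_mm

    @property
    def dx_mm(self) -> float:
        """Node spacing in mm (period / n_nodes)."""
        return self.period_mm / self.n_nodes

    def node_positions(self) -> np.ndarray:
        """Positions of the nodes in mm, ``field_min + i * dx``."""
        return self.field_min_mm + self.dx_mm * np.arange(self.n_nodes)

    def noncentral_mask(self) -> np.ndarray:
        """Boolean mask of nodes outside the central fixation zone."""
        return np.abs(self.node_positions()) > self.noncentral_radius_mm


@dataclass
class FieldState:
    """Instantaneous state of the field: internal state, activity, time."""

    u: np.ndarray
    a: np.ndarray
    t_ms: float

    @classmethod
    def at_reset(cls, constants: ModelConstants, t_ms: float = 0.0) -> "FieldState":
        u = np.full(constants.n_nodes, constants.reset_value, dtype=float)
        return cls(u=u, a=sigmoid_activation(u, constants.beta), t_ms=t_ms)


def sigmoid_activation(u: np.ndarray, beta: float) -> np.ndarray:
    """Sigmoidal output nonlinearity ``a_i = 1 / (1 + exp(-beta * u_i))``.

    Strictly increasing in each element and bounded in (0, 1).
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("internal state contains non-finite elements")
    return expit(beta * u)


def toroidal_distance(x1, x2, period: float):
    """Shortest distance between positions on a circle of given period.

    Symmetric in its arguments and never larger than ``period / 2``.
    Accepts scalars or arrays (broadcast).
    """
    if period <= 0:
        raise ValueError("period must be positive")
    d = np.abs(np.asarray(x1, dtype=float) - np.asarray(x2, dtype=float)) % period
    return np.minimum(d, period - d)


def build_interaction_matrix(constants: ModelConstants) -> np.ndarray:
    """Lateral-interaction weight matrix W of the field.

    ``G_ij = sf * exp(-(min(|i-j|, N-|i-j|) * dx)^2 / (2 sigma^2))`` and
    ``W = (G - m) * dx`` with ``m = m_frac * max(G)``.  W is symmetric and
    circulant on the torus, positive for nearby nodes and negative for
    distant ones (net lateral inhibition).
    """
    n = constants.n_nodes
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    d_mm = np.minimum(sep, n - sep) * constants.dx_mm
    g = constants.sf * np.exp(-(d_mm**2) / (2.0 * constants.sigma_mm**2))
    m = constants.m_frac * g.max()
    return (g - m) * constants.dx_mm


@lru_cache(maxsize=8)
def _cached_interaction_matrix(constants: ModelConstants) -> np.ndarray:
    w = build_interaction_matrix(constants)
    w.setflags(write=False)
    return w


def interaction_matrix(constants: ModelConstants) -> np.ndarray:
    """Cached, read-only view of the interaction matrix for ``constants``."""
    return _cached_interaction_matrix(constants)


def integrate_step(
    state: FieldState,
    c_ext: np.ndarray,
    w: np.ndarray,
    constants: ModelConstants,
) -> FieldState:
    """One 1-ms leaky-integrator update of the field.

    ``u(t+dt) = (1 - dt/tau) u(t) + (dt/tau) (c_ext + W a(t))`` followed by
    ``a(t+dt) = sigmoid(u(t+dt))``.  With W zeroed and constant drive the
    unique fixed point of the affine map is ``u = c_ext``.
    """
    c_ext = np.asarray(c_ext, dtype=float)
    if c_ext.shape != state.u.shape or w.shape != (state.u.size, state.u.size):
        raise ValueError("mismatched vector lengths")
    alpha = constants.dt_ms / constants.tau_ms
    u_new = (1.0 - alpha) * state.u + alpha * (c_ext + w @ state.a)
    return FieldState(
        u=u_new,
        a=sigmoid_activation(u_new, constants.beta),
        t_ms=state.t_ms + constants.dt_ms,
    )
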