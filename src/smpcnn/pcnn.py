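"""Pulse coupled neural network (PCNN) dynamics.

Each pixel is a neuron with a feedback input F (the stimulus), a coupling
link L fed by recently fired neighbours, an internal activity U = F(1 + beta L)
and a decaying dynamic threshold theta; the neuron fires (Y = 1) when U
exceeds theta, and firing recharges theta by V_theta.  Iterating produces a
sequence of binary ignition maps in which regions of similar grey value fire
together ("capture"), which is what makes the model usable as a segmenter.

Update order per iteration n (resolving the circular definition of theta and
Y in the standard way):

    F(n) = I
    L(n) = exp(-alpha_L) L(n-1) + V_L (W * Y(n-1))       # * = correlation
    U(n) = F(n) (1 + beta L(n))
    Y(n) = [U(n) > exp(-alpha_theta) theta(n-1)]
    theta(n) = exp(-alpha_theta) theta(n-1) + V_theta Y(n)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = ["PCNNParams", "PCNNState", "RunResult", "init_state", "step", "run",
           "DEFAULT_LINK_KERNEL"]

# inverse-Euclidean-distance 3x3 link kernel, zero centre
DEFAULT_LINK_KERNEL = np.array(
    [
        [1 / np.sqrt(2.0), 1.0, 1 / np.sqrt(2.0)],
        [1.0, 0.0, 1.0],
        [1 / np.sqrt(2.0), 1.0, 1 / np.sqrt(2.0)],
    ]
)


@dataclass
class PCNNParams:
    """Neuron parameters.

    alpha_L, alpha_theta : decay exponents (> 0) of the link channel and the
        dynamic threshold, per iteration.
    beta : link strength (>= 0) weighting the coupling channel.
    V_L, V_theta : amplification of the link input and of the threshold
        recharge after firing (>= 0); V_theta may be rewritten between
        iterations by the saliency-adaptive rule.
    W : small non-negative link kernel, zero centre by convention.
    theta0 : initial threshold; stimuli are normalized to [0, 1] so 1.0
        means "no neuron fires before its threshold has decayed".
    n_max : hard cap on iterations.
    """

    alpha_L: float = 0.7
    beta: float = 0.2
    alpha_theta: float = 0.3
    V_L: float = 1.0
    V_theta: float = 20.0
    W: np.ndarray = field(default_factory=lambda: DEFAULT_LINK_KERNEL.copy())
    theta0: float = 1.0
    n_max: int = 50

    def __post_init__(self) -> None:
        if self.alpha_L <= 0 or self.alpha_theta <= 0:
            raise ValueError("decay exponents alpha_L, alpha_theta must be > 0")
        if self.beta < 0 or self.V_L < 0 or self.V_theta < 0:
            raise ValueError("beta, V_L and V_theta must be >= 0")
        self.W = np.asarray(self.W, dtype=float)
        if np.any(self.W < 0):
            raise ValueError("link kernel W must be non-negative")

    def with_v_theta(self, v_theta: float) -> "PCNNParams":
        return replace(self, V_theta=float(v_theta), W=self.W.copy())


@dataclass
class PCNNState:
    F: np.ndarray
    L: np.ndarray
    U: np.ndarray
    theta: np.ndarray
    Y: np.ndarray
    n: int = 0


def normalize_stimulus(stimulus: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant band is clipped into [0, 1]."""
    stimulus = np.asarray(stimulus, dtype=float)
    lo, hi = stimulus.min(), stimulus.max()
    if hi > lo:
        return (stimulus - lo) / (hi - lo)
    return np.clip(stimulus, 0.0, 1.0)


def init_state(stimulus: np.ndarray, params: PCNNParams, normalize: bool = True) -> PCNNState:
    stimulus = np.asarray(stimulus, dtype=float)
    if stimulus.size == 0:
        raise ValueError("empty stimulus band")
    if not np.all(np.isfinite(stimulus)):
        raise ValueError("stimulus contains non-finite values")
    F = normalize_stimulus(stimulus) if normalize else stimulus.astype(float)
    zeros = np.zeros_like(F)
    return PCNNState(
        F=F,
        L=zeros.copy(),
        U=zeros.copy(),
        theta=np.full_like(F, params.theta0),
        Y=np.zeros(F.shape, dtype=np.uint8),
        n=0,
    )


def step(state: PCNNState, params: PCNNParams) -> PCNNState:
    """Advance the network by one iteration (returns a new state)."""
    if state.F.shape != state.Y.shape:
        raise ValueError("inconsistent state array shapes")
    link = ndimage.correlate(state.Y.astype(float), params.W, mode="constant", cval=0.0)
    L = np.exp(-params.alpha_L) * state.L + params.V_L * link
    U = state.F * (1.0 + params.beta * L)
    theta_decayed = np.exp(-params.alpha_theta) * state.theta
    Y = (U > theta_decayed).astype(np.uint8)
    theta = theta_decayed + params.V_theta * Y
    if not (np.all(np.isfinite(L)) and np.all(np.isfinite(theta))):
        raise FloatingPointError(f"non-finite PCNN state at iteration {state.n + 1}")
    return PCNNState(F=state.F, L=L, U=U, theta=theta, Y=Y, n=state.n + 1)


@dataclass
class RunResult:
    """Ignition-map history of a PCNN run."""

    maps: list
    truncated: bool = False


def run(stimulus, params: PCNNParams, termination=None, adapt=None,
        normalize: bool = True) -> RunResult:
    """Iterate the network until ``termination`` stops it or n_max is hit.

    termination(maps) -> bool: called after each iteration with the ignition
    history; return True to continue, False to stop.  ``adapt(maps, params)``
    may return replacement parameters for the next iteration (used for the
    saliency-driven V_theta update).  Hitting n_max with the termination
    still asking to continue sets ``truncated``.
    """
    state = init_state(stimulus, params, normalize=normalize)
    maps: list = []
    truncated = False
    while state.n < params.n_max:
        state = step(state, params)
        maps.append(state.Y.copy())
        if termination is not None and not termination(maps):
            break
        if adapt is not None:
            new_params = adapt(maps, params)
            if new_params is not None:
                params = new_params
    else:
        truncated = termination is not None
    return RunResult(maps=maps, truncated=truncated)
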