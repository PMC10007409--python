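"""Significance function over PCNN ignition maps.

Two ignition maps taken a fixed number of iterations apart are treated as
successive states of a first-order Markov chain over the per-pixel firing
states.  The significance of the transition is the mutual information (in
bits) between the two maps' empirical per-pixel state distributions; it is
used to terminate the PCNN iteration adaptively.  The Kullback-Leibler
divergence between the two marginal firing-state distributions provides the
dynamic threshold amplification V_theta for the next iteration: while the
segmentation is still changing the divergence (hence the recharge) is large,
and it shrinks as the ignition maps stabilize.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MarkovStateModel",
    "SaliencyConfig",
    "estimate_model",
    "conditional_entropy",
    "source_entropy",
    "significance",
    "marginal_entropy",
    "should_continue",
    "compute_v_theta",
    "V_THETA_FLOOR",
]

_KL_EPS = 1e-12
_V_THETA_FLOOR = 1e-3


@dataclass(frozen=True)
class SaliencyConfig:
    """Termination settings: threshold ``delta`` (bits), map separation
    ``lag`` and the loop convention (continue while significance > delta,
    or the inverted reading)."""

    delta: float = 0.2
    lag: int = 2
    convention: str = "continue_while_greater"

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if self.convention not in ("continue_while_greater", "stop_when_greater"):
            raise ValueError(f"unknown convention {self.convention!r}")


@dataclass
class MarkovStateModel:
    """Empirical joint/marginal distributions of per-pixel states of two
    ignition maps at a fixed iteration lag."""

    states: np.ndarray          # ordered observed state values
    p_u: np.ndarray             # marginal of the earlier map
    p_v: np.ndarray             # marginal of the later map
    p_joint: np.ndarray         # p_joint[i, j] = P(u = states[i], v = states[j])
    lag: int = 2

    def validate(self) -> None:
        for p in (self.p_u, self.p_v, self.p_joint):
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
                raise ValueError("distributions must be non-negative and sum to 1")
        if not np.allclose(self.p_joint.sum(axis=1), self.p_u, atol=1e-12):
            raise ValueError("p_u is not the row marginal of p_joint")
        if not np.allclose(self.p_joint.sum(axis=0), self.p_v, atol=1e-12):
            raise ValueError("p_v is not the column marginal of p_joint")


def estimate_model(map_a: np.ndarray, map_b: np.ndarray, lag: int = 2) -> MarkovStateModel:
    """Empirical joint over the per-pixel (state in map_a, state in map_b)."""
    map_a = np.asarray(map_a)
    map_b = np.asarray(map_b)
    if map_a.shape != map_b.shape:
        raise ValueError(f"map shapes differ: {map_a.shape} vs {map_b.shape}")
    states = np.unique(np.concatenate([map_a.ravel(), map_b.ravel()]))
    ia = np.searchsorted(states, map_a.ravel())
    ib = np.searchsorted(states, map_b.ravel())
    k = states.size
    joint = np.bincount(ia * k + ib, minlength=k * k).reshape(k, k).astype(float)
    joint /= map_a.size
    return MarkovStateModel(
        states=states,
        p_u=joint.sum(axis=1),
        p_v=joint.sum(axis=0),
        p_joint=joint,
        lag=lag,
    )


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def conditional_entropy(model: MarkovStateModel) -> float:
    """H(V | U) = -sum p(u, v) log2 p(v | u), in bits; zero-mass cells drop."""
    joint = model.p_joint
    out = 0.0
    for i, pu in enumerate(model.p_u):
        if pu <= 0:
            continue
        row = joint[i]
        mask = row > 0
        out -= float((row[mask] * np.log2(row[mask] / pu)).sum())
    return out


def source_entropy(model: MarkovStateModel) -> float:
    """Joint entropy H(U, V) of the two-map state pair, in bits."""
    return _entropy(model.p_joint.ravel())


def marginal_entropy(ignition_map: np.ndarray) -> float:
    """Shannon entropy (bits) of one map's firing-state distribution."""
    _, counts = np.unique(np.asarray(ignition_map).ravel(), return_counts=True)
    return _entropy(counts / counts.sum())


def significance(model: MarkovStateModel) -> float:
    """Mutual information I(U; V) = H(U) + H(V) - H(U, V), in bits.

    Equivalently H(U) - H(U | V): the information one ignition map carries
    about the other.  Non-negative; at most the smaller marginal entropy.
    """
    value = _entropy(model.p_u) + _entropy(model.p_v) - _entropy(model.p_joint.ravel())
    return max(value, 0.0)


def should_continue(history: list, config: SaliencyConfig | None = None) -> bool:
    """Adaptive termination test on the ignition-map history.

    Too-short histories always continue.  Under the default convention the
    loop keeps iterating while the significance between the maps ``lag``
    iterations apart stays above ``delta``.
    """
    if config is None:
        config = SaliencyConfig()
    if len(history) < config.lag + 1:
        return True
    model = estimate_model(history[-1 - config.lag], history[-1], lag=config.lag)
    greater = significance(model) > config.delta
    return greater if config.convention == "continue_while_greater" else not greater


def compute_v_theta(map_a: np.ndarray, map_b: np.ndarray, floor: float = 0.0) -> float:
    """KL divergence D(p_v || p_u) between the marginal firing-state
    distributions of two ignition maps, in bits.

    Distributions are epsilon-smoothed and renormalized, so a state present
    in one map only never raises an error; identical distributions give
    exactly 0.  The fusion pipeline passes ``floor = V_THETA_FLOOR`` so the
    threshold recharge stays positive and fired neurons cannot refire
    immediately.
    """
    model = estimate_model(map_a, map_b)
    pu = model.p_u + _KL_EPS
    pv = model.p_v + _KL_EPS
    pu /= pu.sum()
    pv /= pv.sum()
    kl = float((pv * (np.log2(pv) - np.log2(pu))).sum())
    return max(kl, floor)


#: positive floor applied to the adaptive V_theta inside the fusion pipeline
V_THETA_FLOOR = _V_THETA_FLOOR
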