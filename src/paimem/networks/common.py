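"""Shared numerics for the PAI memory networks.

Both network families share the same activation functions: feature-layer units
pass their net input through a logistic with a fixed offset ``theta0`` (chosen
so that an unstimulated, unconnected unit rests near 0.05 — an offset is
required for the mismatching-activity signal to have a meaningful floor), and
conjunctive units compete through a softmax at the shared network temperature.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, softmax

#: resting activation of an unstimulated, unconnected feature unit
REST_ACTIVATION = 0.05


def default_theta0(tau_net: float) -> float:
    """Offset such that ``logistic(-theta0 / tau_net) == REST_ACTIVATION``."""
    return float(tau_net * np.log((1.0 - REST_ACTIVATION) / REST_ACTIVATION))


def feature_activation(net_input: np.ndarray, theta0: float, tau_net: float) -> np.ndarray:
    return expit((net_input - theta0) / tau_net)


def conjunctive_activation(net_input: np.ndarray, tau_net: float) -> np.ndarray:
    """Softmax competition across the whole conjunctive layer (sums to 1)."""
    return softmax(net_input / tau_net)


def response_softmax_pair(r_target: float, r_foil: float, tau_net: float) -> float:
    """Two-option softmax over response-unit activities: P(choose target)."""
    return float(expit((r_target - r_foil) / tau_net))


def floored_mismatch(
    activations: np.ndarray, resting: np.ndarray, presented_mask: np.ndarray
) -> float:
    """Summed above-rest activity of feature units NOT externally presented.

    The resting activation is subtracted per unit and the difference floored at
    zero, isolating input-driven recall from the logistic floor.
    """
    excess = np.maximum(activations - resting, 0.0)
    return float(np.sum(excess[~presented_mask]))
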