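"""Mode/concentration parameterization of the beta distribution.

Subject-level accuracies are modeled as Beta with mode ``omega`` and
concentration ``kappa`` (> 2), the parameterization in which the group-level
regression acts on the mode:  a = omega * (kappa - 2) + 1,
b = (1 - omega) * (kappa - 2) + 1.  At kappa -> 2+ the distribution tends to
the uniform; larger kappa concentrates subjects around the mode.
"""

from __future__ import annotations

__all__ = ["beta_from_mode"]


def beta_from_mode(omega: float, kappa: float) -> tuple[float, float]:
    """Shape pair (a, b) of the Beta with mode ``omega``, concentration ``kappa``."""
    if not 0.0 < omega < 1.0:
        raise ValueError("omega must lie in (0, 1)")
    if kappa <= 2.0:
        raise ValueError("kappa must be > 2 for the mode parameterization")
    a = omega * (kappa - 2.0) + 1.0
    b = (1.0 - omega) * (kappa - 2.0) + 1.0
    return a, b
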