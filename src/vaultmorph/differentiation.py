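"""Stage-1 osteoblast differentiation law.

Mesenchymal cells differentiate into osteoblasts where the activator is
high, early in development, and low on the vault: the rate is the product of
a Hill gate on activator concentration, a decaying Hill window on elapsed
time, and a Heaviside gate on height above the inferior rim,

    dCo/dt = eta * Ca^n/(Ca^n + CaT^n) * Ta^n/(Ta^n + t^n) * H(x_ref - x_rel).

The height gate encodes the observation that cells on the inferior surface
differentiate faster than those near the apex; it is what leaves the top of
the vault unossified (the anterior fontanelle) even though an activator peak
sits there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

HOUR = 3600.0  # s


@dataclass
class DifferentiationParams:
    """Parameters of the osteoblast differentiation law.

    ``Ta`` is stored in seconds; the conventional tabulation is in hours
    (4.0e2 hr = 1.44e6 s), use :meth:`from_table` for that form.
    """

    eta: float = 1.0e-5       # differentiation constant, ng/(mm^3 s)
    CaT: float = 6.0          # activator threshold, ng/mm^3
    Ta: float = 4.0e2 * HOUR  # activator time limit, s
    n: float = 8.0            # Hill exponent
    x_ref: float = 1.85       # reference height, mm
    x_top: float = 2.49       # domain apex height, mm (metadata)

    @classmethod
    def from_table(cls, Ta_hours: float = 4.0e2, **kw) -> "DifferentiationParams":
        return cls(Ta=Ta_hours * HOUR, **kw)

    def validate(self) -> None:
        if not (self.eta > 0 and self.CaT > 0 and self.Ta > 0):
            raise ValueError("eta, CaT and Ta must be positive")
        if not self.n >= 1:
            raise ValueError("Hill exponent n must be >= 1")
        if not 0 < self.x_ref <= self.x_top:
            raise ValueError("require 0 < x_ref <= x_top")


def spatial_gate(
    x_rel: np.ndarray | float, x_ref: float
) -> np.ndarray | float:
    """Heaviside height gate: 1 where ``x_rel <= x_ref``, else 0.

    Cells above the reference height never differentiate in stage 1.
    """
    x = np.asarray(x_rel, dtype=float)
    if np.any(x < 0):
        raise ValueError("x_rel must be non-negative")
    g = (x <= x_ref).astype(float)
    return float(g) if g.ndim == 0 else g


def differentiation_rate(
    Ca: np.ndarray | float,
    t: float,
    x_rel: np.ndarray | float,
    p: DifferentiationParams,
) -> np.ndarray | float:
    """Osteoblast generation rate dCo/dt (ng mm^-3 s^-1), always in [0, eta].

    Product of the activator Hill gate, the decaying time window (both at
    half-saturation when Ca = CaT and t = Ta), and the height gate.
    """
    Ca = np.asarray(Ca, dtype=float)
    if np.any(Ca < 0):
        raise ValueError("Ca must be non-negative")
    if t < 0:
        raise ValueError("t must be non-negative")
    ca_n = Ca**p.n
    act = ca_n / (ca_n + p.CaT**p.n)
    ta_n = p.Ta**p.n
    window = ta_n / (ta_n + t**p.n)
    rate = p.eta * act * window * spatial_gate(x_rel, p.x_ref)
    return float(rate) if np.ndim(rate) == 0 else rate
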