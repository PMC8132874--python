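"""Heat-flux double-sensor core-temperature model.

The double sensor stacks two thermistors separated by an insulating layer:
``th1`` touches the skin, ``th2`` faces the environment. Assuming the heat
flux through the insulation equals the flux through the underlying tissue
(steady state), core body temperature follows from the measured gradient:

    Tcore = Th1 + (Ks/Kg) * (Th1 - Th2)

where Ks and Kg are the heat-transfer coefficients of the insulation and of
human tissue. Only their ratio enters the model; the device vendor does not
publish the individual coefficients, so the ratio is a configuration
parameter here and every downstream statistic is invariant to it as long as
the simulator uses the matched forward model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HeatFluxModel", "compute_core_temp", "forward_skin_temps"]


@dataclass(frozen=True)
class HeatFluxModel:
    """Steady-state heat-flux model parameterized by the ratio Ks/Kg.

    Parameters
    ----------
    ks_over_kg
        Ratio of the insulation to the tissue heat-transfer coefficient.
        Must be strictly positive and finite. Default 0.5.
    """

    ks_over_kg: float = 0.5

    def __post_init__(self) -> None:
        r = self.ks_over_kg
        if not np.isfinite(r) or r <= 0:
            raise ValueError(
                f"ks_over_kg must be strictly positive and finite, got {r!r}"
            )


def _require_finite(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite value in {name}")
    return arr


def compute_core_temp(th1, th2, model: HeatFluxModel):
    """Core temperature (°C) from the two sensor temperatures.

    Exact linear map ``th1 + ks_over_kg * (th1 - th2)``; no clamping.
    Accepts scalars or arrays (broadcast).
    """
    t1 = _require_finite("th1", th1)
    t2 = _require_finite("th2", th2)
    out = t1 + model.ks_over_kg * (t1 - t2)
    if out.ndim == 0:
        return float(out)
    return out


def forward_skin_temps(tcore, skin_offset, model: HeatFluxModel):
    """Invert the core-temperature formula for the simulator.

    Given a true core temperature and a core-to-skin gradient
    ``skin_offset`` (°C, >= 0 in the clinical regime modeled here), return
    the sensor pair ``(th1, th2)`` such that :func:`compute_core_temp`
    recovers ``tcore`` exactly:

        th1 = tcore - skin_offset
        th2 = th1 - skin_offset / ks_over_kg
    """
    tc = _require_finite("tcore", tcore)
    off = _require_finite("skin_offset", skin_offset)
    if np.any(off < 0):
        raise ValueError("skin_offset must be >= 0 (core at least as warm as skin)")
    th1 = tc - off
    th2 = th1 - off / model.ks_over_kg
    if th1.ndim == 0 and th2.ndim == 0:
        return float(th1), float(th2)
    th1, th2 = np.broadcast_arrays(th1, th2)
    return th1.copy(), th2.copy()
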