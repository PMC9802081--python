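"""Wind-shear profiles over the sea surface.

Two steady horizontal-wind profiles W(z) drive the dynamic-soaring stage:

* logarithmic — the flat-sea boundary-layer profile, anchored by the wind
  speed W10 at 10 m height and a roughness height h_min;
* sigmoidal — a wind-separation-like shear layer of asymptotic speed Wmax,
  centred at the shear height h_w with thickness parameter delta (the bulk
  of the speed change occurs within about |z - h_w| < 3*delta).

Both expose the analytic vertical gradient dW/dz, which enters the
equations of motion as the energy-extraction term.  The wind blows along
-y in the world frame, so "upwind" progress is +y displacement.

All evaluators accept numpy arrays and complex arguments; the latter keeps
complex-step differentiation available to the trajectory optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["WindModel", "wind_speed", "wind_gradient"]

H_MIN_DEFAULT = 0.03  # m, roughness height of the logarithmic profile


@dataclass(frozen=True)
class WindModel:
    kind: str  # "logarithmic" | "sigmoidal"
    W10: float | None = None
    Wmax: float | None = None
    hw: float | None = None
    delta: float | None = None
    hmin: float = H_MIN_DEFAULT

    def __post_init__(self) -> None:
        if self.kind == "logarithmic":
            if self.W10 is None or self.W10 < 0:
                raise ValueError("logarithmic model needs W10 >= 0")
            if self.hmin <= 0:
                raise ValueError("hmin must be positive")
        elif self.kind == "sigmoidal":
            if self.Wmax is None or self.Wmax < 0:
                raise ValueError("sigmoidal model needs Wmax >= 0")
            if self.hw is None or self.hw <= 0 or self.delta is None or self.delta <= 0:
                raise ValueError("sigmoidal model needs hw > 0 and delta > 0")
        else:
            raise ValueError(f"unknown wind model kind {self.kind!r}")

    # The speed parameter (W10 or Wmax) factors out of both profiles:
    # W(z) = param * shape(z).  The dynamic-soaring minimum-wind objective
    # treats the parameter as a decision variable and uses shape() directly.

    @property
    def param(self) -> float:
        return self.W10 if self.kind == "logarithmic" else self.Wmax

    def with_param(self, value: float) -> "WindModel":
        if self.kind == "logarithmic":
            return replace(self, W10=float(value))
        return replace(self, Wmax=float(value))

    def shape(self, z):
        """Dimensionless profile W(z)/param."""
        if self.kind == "logarithmic":
            self._check_log_domain(z)
            return np.log(z / self.hmin) / np.log(10.0 / self.hmin)
        u = (z - self.hw) / self.delta
        return 1.0 / (1.0 + np.exp(-u))

    def shape_gradient(self, z):
        """d(shape)/dz [1/m]."""
        if self.kind == "logarithmic":
            self._check_log_domain(z)
            return 1.0 / (z * np.log(10.0 / self.hmin))
        u = (z - self.hw) / self.delta
        e = np.exp(-u)
        return e / (self.delta * (1.0 + e) ** 2)

    def speed(self, z):
        return self.param * self.shape(z)

    def gradient(self, z):
        return self.param * self.shape_gradient(z)

    def _check_log_domain(self, z) -> None:
        zr = np.real(np.asarray(z))
        if np.any(zr <= self.hmin):
            raise ValueError(
                f"logarithmic wind profile undefined at z <= hmin = {self.hmin} m"
            )

    def label(self) -> str:
        if self.kind == "logarithmic":
            return "log"
        return f"sigmoid_hw{self.hw:g}_delta{self.delta:.3g}"


def wind_speed(model: WindModel, z):
    """Horizontal wind speed W(z) [m/s]."""
    return model.speed(z)


def wind_gradient(model: WindModel, z):
    """Vertical gradient dW/dz [1/s]."""
    return model.gradient(z)


def standard_wind_grid(param: float = 10.0) -> list[WindModel]:
    """The seven shear conditions of the comparison: one logarithmic profile
    plus the sigmoidal grid hw in {1, 3, 5} m x delta in {3/6, 7/6} m."""
    models = [WindModel("logarithmic", W10=param)]
    for delta in (3.0 / 6.0, 7.0 / 6.0):
        for hw in (1.0, 3.0, 5.0):
            models.append(WindModel("sigmoidal", Wmax=param, hw=hw, delta=delta))
    return models
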