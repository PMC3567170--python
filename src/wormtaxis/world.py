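"""Idealized worm body and chemical gradient environments.

The worm is a point ``(x, y)`` moving at constant speed ``v`` (0.022
cm/s on agar) whose heading ``mu`` is incremented each step by a
turning angle proportional to the dorsoventral difference in neck
motor-neuron output.  Pirouettes — abrupt heading randomizations — are
modeled as Bernoulli events at a fixed rate (baseline 0.033 Hz).

Gradients are either conical (concentration proportional to distance
from the peak, slope ``alpha`` < 0) or Gaussian-shaped like a typical
laboratory salt plate.  Sensing is purely differential, so an additive
baseline offset never changes behavior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

V_SPEED = 0.022  #: forward speed, cm/s
PIROUETTE_RATE = 0.033  #: baseline pirouette frequency, 1/s

__all__ = [
    "V_SPEED",
    "PIROUETTE_RATE",
    "WormPose",
    "GradientSpec",
    "BodyParams",
    "concentration_at",
    "gradient_at",
    "turning_angle",
    "update_pose",
    "maybe_pirouette",
    "wrap_angle",
]


def wrap_angle(a: float) -> float:
    """Wrap to (-pi, pi]."""
    a = (a + math.pi) % (2.0 * math.pi) - math.pi
    return math.pi if a == -math.pi else a


@dataclass
class WormPose:
    x: float
    y: float
    mu: float

    def __post_init__(self) -> None:
        self.mu = wrap_angle(self.mu)


@dataclass(frozen=True)
class GradientSpec:
    """Conical: c = baseline + alpha * dist;  Gaussian: c = amp * exp(-dist^2 / (2 sigma^2)).

    The Gaussian defaults (amp 1.71, sigma 3 cm) put the slope magnitude
    at the 4.5 cm start circle inside the conical steepness range used
    during evolution.
    """

    shape: str = "conical"
    peak: tuple[float, float] = (0.0, 0.0)
    alpha: float = -0.2
    amp: float = 1.71
    sigma: float = 3.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("conical", "gaussian"):
            raise ValueError(f"unknown gradient shape {self.shape!r}")
        if self.shape == "gaussian" and (self.amp <= 0 or self.sigma <= 0):
            raise ValueError("gaussian gradient requires amp > 0 and sigma > 0")


@dataclass(frozen=True)
class BodyParams:
    v: float = V_SPEED
    w_nmj: float = 1.0
    pirouette_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise ValueError("speed must be positive")
        if self.pirouette_rate < 0:
            raise ValueError("pirouette_rate must be >= 0")


def concentration_at(g: GradientSpec, x: float, y: float) -> float:
    dx, dy = x - g.peak[0], y - g.peak[1]
    dist = math.hypot(dx, dy)
    if g.shape == "conical":
        return g.baseline + g.alpha * dist
    return g.baseline + g.amp * math.exp(-dist * dist / (2.0 * g.sigma**2))


def gradient_at(g: GradientSpec, x: float, y: float) -> tuple[float, float]:
    """Spatial gradient (dc/dx, dc/dy); zero exactly at the peak."""
    dx, dy = x - g.peak[0], y - g.peak[1]
    dist = math.hypot(dx, dy)
    if dist == 0.0:
        return (0.0, 0.0)
    if g.shape == "conical":
        m = g.alpha / dist
    else:
        c = g.amp * math.exp(-dist * dist / (2.0 * g.sigma**2))
        m = -c / g.sigma**2
    return (m * dx, m * dy)


def turning_angle(
    o_dl: float, o_dr: float, o_vl: float, o_vr: float, w_nmj: float, dt: float
) -> float:
    """Per-step heading increment phi (radians).

    Muscle length is proportional to motor output and the turn is
    proportional to the dorsal-minus-ventral difference; left and right
    cells of each side add together.
    """
    return w_nmj * ((o_dl + o_dr) - (o_vl + o_vr)) * dt


def update_pose(p: WormPose, phi: float, body: BodyParams, dt: float) -> WormPose:
    """Apply the turn, then advance v*dt along the new heading."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    mu = wrap_angle(p.mu + phi)
    return WormPose(x=p.x + body.v * math.cos(mu) * dt,
                    y=p.y + body.v * math.sin(mu) * dt,
                    mu=mu)


def maybe_pirouette(p: WormPose, rate: float, dt: float, rng: np.random.Generator) -> WormPose:
    """With probability rate*dt, redraw the heading uniformly on (-pi, pi]."""
    if rate <= 0.0:
        return p
    if rng.random() < rate * dt:
        return WormPose(x=p.x, y=p.y, mu=rng.uniform(-math.pi, math.pi))
    return p
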