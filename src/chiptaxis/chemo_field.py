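"""Keller-Segel parameters and prescribed chemoattractant profiles.

The chemoattractant concentration ``c`` is normalized to [0, 1]; the
chemotaxis coefficient chi therefore carries units of um^2/h per unit of
normalized concentration. Absolute conditioned-media concentrations are
never needed because chi is only compared between conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import DeviceGeometry

PROFILE_KINDS = ("zero", "uniform", "linear_gradient")


@dataclass(frozen=True)
class KSParameters:
    """Random-motility and chemotaxis coefficients of the drift-diffusion model.

    ``D_um2_per_h`` is the random-motility (diffusion) coefficient;
    ``chi_um2_per_h`` the chemotaxis coefficient with respect to the
    normalized concentration. The directed drift induced by a gradient is
    ``v = chi * dc/dx`` (um/h).
    """

    D_um2_per_h: float
    chi_um2_per_h: float = 0.0

    def __post_init__(self) -> None:
        for name in ("D_um2_per_h", "chi_um2_per_h"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
        if self.D_um2_per_h < 0:
            raise ValueError(f"D_um2_per_h must be >= 0, got {self.D_um2_per_h!r}")

    def drift_um_per_h(self, dc_dx: float) -> float:
        """Directed drift for a given concentration gradient (1/um)."""
        return self.chi_um2_per_h * dc_dx


@dataclass(frozen=True)
class ConcentrationField:
    """Normalized chemoattractant profile sampled on a 1D grid over [0, L]."""

    x_grid_um: np.ndarray
    c: np.ndarray
    profile_kind: str

    def __post_init__(self) -> None:
        x = np.asarray(self.x_grid_um, dtype=float)
        c = np.asarray(self.c, dtype=float)
        object.__setattr__(self, "x_grid_um", x)
        object.__setattr__(self, "c", c)
        if x.ndim != 1 or x.size < 2 or c.shape != x.shape:
            raise ValueError("x_grid_um and c must be matching 1D arrays (>= 2 points)")
        if self.profile_kind not in PROFILE_KINDS:
            raise ValueError(
                f"unknown profile_kind {self.profile_kind!r}; expected one of {PROFILE_KINDS}"
            )
        if c.min() < -1e-12 or c.max() > 1 + 1e-12:
            raise ValueError("concentration values must lie in [0, 1]")
        if self.profile_kind == "linear_gradient" and np.any(np.diff(c) < -1e-12):
            raise ValueError("linear_gradient profile must be monotone nondecreasing")

    @property
    def length_um(self) -> float:
        return float(self.x_grid_um[-1] - self.x_grid_um[0])

    def gradient(self) -> np.ndarray:
        """dc/dx on the grid (1/um); identically zero for flat profiles."""
        if self.profile_kind in ("zero", "uniform"):
            return np.zeros_like(self.c)
        return np.gradient(self.c, self.x_grid_um)

    def gradient_at(self, x: np.ndarray) -> np.ndarray:
        """dc/dx interpolated at arbitrary positions."""
        if self.profile_kind in ("zero", "uniform"):
            return np.zeros_like(np.asarray(x, dtype=float))
        return np.interp(x, self.x_grid_um, self.gradient())

    @property
    def max_abs_gradient(self) -> float:
        return float(np.max(np.abs(self.gradient())))

    @property
    def has_gradient(self) -> bool:
        return self.max_abs_gradient > 0


def make_concentration(
    geometry: DeviceGeometry,
    profile_kind: str,
    n_points: int = 201,
) -> ConcentrationField:
    """Build a prescribed concentration profile over the gel channel.

    ``zero`` models the no-chemoattractant control, ``uniform`` the
    chemokinesis arm (conditioned media on both sides, c = 1 everywhere,
    no gradient), and ``linear_gradient`` the chemotaxis arm (source in the
    far channel only, c(x) = x / L).
    """
    if profile_kind not in PROFILE_KINDS:
        raise ValueError(
            f"unknown profile_kind {profile_kind!r}; expected one of {PROFILE_KINDS}"
        )
    L = geometry.gel_channel_length_um
    x = np.linspace(0.0, L, n_points)
    if profile_kind == "zero":
        c = np.zeros_like(x)
    elif profile_kind == "uniform":
        c = np.ones_like(x)
    else:
        c = x / L
    return ConcentrationField(x_grid_um=x, c=c, profile_kind=profile_kind)
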