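"""Finite-volume forward solver for the 1D Keller-Segel model.

Cell density n(x, t) in the gel channel obeys

    dn/dt = d/dx ( D dn/dx - chi n dc/dx ),   x in [0, L],

with zero-flux (reflecting) walls and all mass initially packed against
the entry interface at x = 0. The chemoattractant profile c(x) is
prescribed (see :mod:`chiptaxis.chemo_field`), not solved: the conditioned
media source is replenished and the channel is short, so a steady profile
is the appropriate regime.

Discretization: node-centred finite volumes (half cells at the walls),
Crank-Nicolson for the diffusive flux with Rannacher start-up smoothing of
the near-singular initial condition, first-order upwinding for the
advective flux. Updates are written in flux form, so total mass — which on
this grid equals the trapezoid integral of the nodal densities — is
conserved to rounding error by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.linalg import solve_banded

from .chemo_field import ConcentrationField, KSParameters
from .geometry import DeviceGeometry

#: Default number of grid intervals over the channel (dx = L/104).
DEFAULT_N_INTERVALS = 104
#: Default number of position bins used by the likelihood estimators.
DEFAULT_N_BINS = 26


class StabilityError(ValueError):
    """A requested step size violates the scheme's stability conditions."""


@dataclass(frozen=True)
class DensityField:
    """Nonnegative cell density on the channel grid, normalized to unit mass."""

    x_grid_um: np.ndarray
    n: np.ndarray
    time_h: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x_grid_um, dtype=float)
        n = np.asarray(self.n, dtype=float)
        object.__setattr__(self, "x_grid_um", x)
        object.__setattr__(self, "n", n)
        if n.min() < -1e-12:
            raise ValueError("density must be nonnegative")
        mass = np.trapezoid(n, x)
        if abs(mass - 1.0) > 1e-6:
            raise ValueError(f"density mass {mass} is not 1 within tolerance")

    @property
    def mass(self) -> float:
        return float(np.trapezoid(self.n, self.x_grid_um))

    def bin_masses(self, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
        """Mass in ``n_bins`` equal bins over [0, L] (sums to the total mass).

        Integrates the piecewise-linear density between bin edges via the
        cumulative trapezoid rule.
        """
        x = self.x_grid_um
        cum = np.concatenate([[0.0], cumulative_trapezoid(self.n, x)])
        edges = np.linspace(x[0], x[-1], n_bins + 1)
        return np.diff(np.interp(edges, x, cum))


def stable_dt(
    params: KSParameters,
    conc: ConcentrationField,
    dx_um: float,
    dt_max_h: float = 0.25,
) -> float:
    """Largest step meeting the advective Courant bound (v dt/dx <= 0.5)
    and the Crank-Nicolson positivity bound at the wall half-cells
    (D dt/dx^2 <= 0.5)."""
    dt = dt_max_h
    v_max = abs(params.chi_um2_per_h) * conc.max_abs_gradient
    if v_max > 0:
        dt = min(dt, 0.5 * dx_um / v_max)
    if params.D_um2_per_h > 0:
        dt = min(dt, 0.5 * dx_um**2 / params.D_um2_per_h)
    return dt


def _advance(
    mass: np.ndarray,
    n_steps: int,
    dt: float,
    dx: float,
    widths: np.ndarray,
    D: float,
    v_faces: np.ndarray,
    rannacher: int,
) -> np.ndarray:
    """March ``mass`` (per-node cell masses) forward ``n_steps`` steps."""
    N = mass.size
    vplus = np.maximum(v_faces, 0.0)
    vminus = np.minimum(v_faces, 0.0)

    def banded(theta: float, dt_eff: float) -> np.ndarray:
        # System matrix for masses: (I - theta*dt*B) m_new, where
        # (B m)_i = D/dx * (m_{i+1}/w_{i+1} - m_i/w_i) - ... in flux form.
        k = theta * dt_eff * D / dx
        ab = np.zeros((3, N))
        ab[1, :] = 1.0
        # flux between i and i+1 adds +k*(n_{i+1}-n_i) to cell i, opposite to i+1
        ab[0, 1:] -= k / widths[1:]      # coefficient of m_{i+1} in row i
        ab[1, :-1] += k / widths[:-1]    # coefficient of m_i in row i
        ab[1, 1:] += k / widths[1:]      # coefficient of m_{i+1} in row i+1
        ab[2, :-1] -= k / widths[:-1]    # coefficient of m_i in row i+1
        return ab

    def explicit_diffusion(m: np.ndarray, theta_dt: float) -> np.ndarray:
        n = m / widths
        flux = (theta_dt * D / dx) * np.diff(n)  # mass crossing each face
        out = m.copy()
        out[:-1] += flux
        out[1:] -= flux
        return out

    for step in range(n_steps):
        # Advection: explicit upwind, flux form.
        n = mass / widths
        adv_flux = (vplus * n[:-1] + vminus * n[1:]) * dt
        rhs = mass.copy()
        rhs[:-1] -= adv_flux
        rhs[1:] += adv_flux
        if D > 0:
            if step < rannacher:
                # Two implicit-Euler half steps damp the checkerboard mode
                # excited by the near-delta initial condition.
                half = banded(1.0, dt / 2)
                rhs = solve_banded((1, 1), half, rhs)
                mass = solve_banded((1, 1), half, rhs)
            else:
                rhs = explicit_diffusion(rhs, dt / 2)
                mass = solve_banded((1, 1), banded(0.5, dt), rhs)
        else:
            mass = rhs
    return mass


def solve_forward(
    params: KSParameters,
    conc: ConcentrationField,
    geometry: DeviceGeometry,
    t_end_h: float,
    dx_um: float | None = None,
    dt_h: float | None = None,
    initial: np.ndarray | None = None,
    record_times_h: list[float] | None = None,
    rannacher_steps: int = 2,
) -> DensityField | list[DensityField]:
    """Advance the density to ``t_end_h`` (or to each of ``record_times_h``).

    Parameters
    ----------
    dx_um:
        Grid spacing; must satisfy dx <= L/100. Default L/104.
    dt_h:
        Time step. If omitted, the largest stable step is used; an
        explicitly requested step violating the advective Courant bound
        raises :class:`StabilityError`.
    initial:
        Optional nodal density to start from (defaults to unit mass in the
        wall half-cell at x = 0, i.e. cells packed at the entry interface).
    record_times_h:
        If given, returns one :class:`DensityField` per time (sorted).
    """
    L = geometry.gel_channel_length_um
    if dx_um is None:
        n_int = DEFAULT_N_INTERVALS
    else:
        if dx_um > L / 100 + 1e-9:
            raise StabilityError(
                f"dx_um={dx_um:g} too coarse; need dx <= L/100 = {L / 100:g}"
            )
        n_int = int(round(L / dx_um))
    dx = L / n_int
    N = n_int + 1
    x = np.arange(N) * dx
    widths = np.full(N, dx)
    widths[0] = widths[-1] = dx / 2

    v_max = abs(params.chi_um2_per_h) * conc.max_abs_gradient
    if dt_h is None:
        dt_h = stable_dt(params, conc, dx)
    elif v_max * dt_h / dx > 0.5 + 1e-12:
        raise StabilityError(
            f"dt_h={dt_h:g} violates the advective Courant bound: "
            f"v*dt/dx = {v_max * dt_h / dx:.3f} > 0.5; need dt <= {0.5 * dx / v_max:g}"
        )

    x_faces = (np.arange(n_int) + 0.5) * dx
    v_faces = params.chi_um2_per_h * conc.gradient_at(x_faces)

    if initial is None:
        mass = np.zeros(N)
        mass[0] = 1.0
    else:
        dens0 = np.asarray(initial, dtype=float)
        if dens0.shape != (N,):
            raise ValueError(f"initial must have shape ({N},)")
        mass = dens0 * widths
        mass = mass / mass.sum()

    record = sorted(record_times_h) if record_times_h is not None else [t_end_h]
    if record and record[-1] > t_end_h + 1e-12:
        raise ValueError("record times must not exceed t_end_h")

    results: list[DensityField] = []
    t = 0.0
    steps_done = 0
    for t_target in record:
        span = t_target - t
        if span > 1e-12:
            n_steps = max(1, int(math.ceil(span / dt_h - 1e-12)))
            dt_local = span / n_steps
            mass = _advance(
                mass,
                n_steps,
                dt_local,
                dx,
                widths,
                params.D_um2_per_h,
                v_faces,
                rannacher=max(0, rannacher_steps - steps_done),
            )
            steps_done += n_steps
        t = t_target
        dens = np.maximum(mass, 0.0) / widths
        dens = dens / np.trapezoid(dens, x)
        results.append(DensityField(x_grid_um=x, n=dens, time_h=t_target))

    return results if record_times_h is not None else results[0]


def reflected_gaussian(x: np.ndarray, D: float, t_h: float, L: float) -> np.ndarray:
    """Closed-form density for pure diffusion from x=0 with reflecting walls.

    Method of images on [0, L]; for sqrt(2Dt) << L this reduces to the
    half-normal density 2*phi(x; sigma^2 = 2Dt).
    """
    if t_h <= 0 or D <= 0:
        raise ValueError("requires D > 0 and t > 0")
    var = 2.0 * D * t_h
    xs = np.asarray(x, dtype=float)
    dens = np.zeros_like(xs)
    for k in range(-6, 7):
        dens += np.exp(-((xs - 2 * k * L) ** 2) / (2 * var))
        dens += np.exp(-((xs + 2 * k * L) ** 2) / (2 * var))
    return dens / math.sqrt(2 * math.pi * var)
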