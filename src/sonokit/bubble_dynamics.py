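"""Radial dynamics of a lipid-shelled microbubble under low-frequency
insonation.

The governing equation is a modified Rayleigh-Plesset model for a coated
bubble (Marmottant-type): a polytropic gas core with first-order acoustic
radiation damping, liquid viscosity, a dilatational shell-viscosity term
``4 kappa_s Rdot / R^2``, and a piecewise surface tension law

    sigma(R) = 0                             R <= R_buckling   (buckled)
             = chi (R^2/R_buckling^2 - 1)    elastic branch
             = sigma_water                   R >= R_rupture    (ruptured)

so that a shell compressed below its buckling radius carries no tension
and a shell stretched past rupture behaves as a clean gas-water interface.
The momentum balance integrated here is

    rho (R Rddot + 3/2 Rdot^2) =
        P_g0 (R0/R)^{3k} (1 - 3k Rdot/c) + P_v - P_0 - P_ac(t)
        - 2 sigma(R)/R - 4 mu Rdot/R - 4 kappa_s Rdot/R^2

with ``P_g0`` the equilibrium gas pressure and ``P_ac`` the sinusoidal,
rarefaction-first drive.

The headline statistic is the expansion ratio ER = max R / R0 (equivalently
max diameter over resting diameter); ER bands 1.1-3.5 and >3.5 classify
stable and inertial cavitation respectively.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable, NamedTuple, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, minimize

from .params import (
    AcousticDrive,
    BubbleSystem,
    MediumProperties,
    RegimeThresholds,
    ShellProperties,
    config_hash,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Regime",
    "RadiusTrace",
    "SweepResult",
    "RegimeBoundaries",
    "surface_tension",
    "drive_pressure",
    "marmottant_rhs",
    "simulate_radius",
    "expansion_ratio",
    "classify_cavitation",
    "pressure_sweep",
    "find_regime_boundaries",
    "mechanical_index",
    "blake_threshold_estimate",
    "calibrate_shell",
    "ExpansionAnchor",
    "BoundaryAnchor",
    "CalibrationResult",
]

# Solver settings (test-pinned): stiff-capable adaptive method with tight
# tolerances; the absolute radius tolerance is scaled to R0.
RTOL = 1e-8
ATOL_RADIUS_REL = 1e-12  # times R0
ATOL_VELOCITY = 1e-6  # m/s
COLLAPSE_FLOOR = 0.05  # times R0; below this the trace is truncated
SAMPLES_PER_CYCLE = 400


class Regime(str, Enum):
    NEGLIGIBLE = "negligible"
    STABLE = "stable"
    INERTIAL = "inertial"


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails to converge."""


@dataclass(frozen=True)
class RadiusTrace:
    """Simulated radius-vs-time trajectory.

    ``truncated_at_collapse`` flags traces cut short by the collapse event
    (radius below ``COLLAPSE_FLOOR * R0``); the expansion-ratio statistic
    then uses the pre-collapse maximum.
    """

    times: np.ndarray  # s
    radii: np.ndarray  # m
    radial_velocities: np.ndarray  # m/s
    resting_radius: float  # m
    truncated_at_collapse: bool = False

    def __post_init__(self) -> None:
        if len(self.times) != len(self.radii):
            raise ValueError("times and radii must have equal length")


@dataclass(frozen=True)
class SweepResult:
    """Expansion ratio and cavitation regime on a PNP grid (ascending)."""

    pnp_grid: np.ndarray  # Pa
    expansion_ratios: np.ndarray
    regimes: list[Regime]


class RegimeBoundaries(NamedTuple):
    """PNP at the first upward crossing of each regime threshold;
    ``None`` when the sweep never reaches the threshold."""

    pnp_stable_low: Optional[float]
    pnp_inertial_onset: Optional[float]


def surface_tension(
    radius: float, shell: ShellProperties, medium: MediumProperties,
    resting_radius: float,
) -> float:
    """Piecewise shell surface tension sigma(R) in N/m.

    Zero in the buckled state, elastic in between, clamped at the clean
    water value past rupture; continuous at both regime boundaries.
    """
    if radius <= 0.0:
        raise ValueError("radius must be > 0")
    r_buck = shell.buckling_radius(resting_radius)
    r_rup = shell.rupture_radius(resting_radius, medium.water_surface_tension)
    if radius <= r_buck:
        return 0.0
    if radius >= r_rup:
        return medium.water_surface_tension
    return shell.elastic_modulus_chi * ((radius / r_buck) ** 2 - 1.0)


def drive_pressure(t: float | np.ndarray, drive: AcousticDrive):
    """Acoustic forcing p(t) = -PNP sin(2 pi f t), zero outside the burst.

    Rarefaction-first: the first half-cycle is negative, so the bubble is
    pulled outward before the first compression. The ``ramped`` envelope
    applies a linear ramp over the first two cycles.
    """
    t = np.asarray(t, dtype=float)
    p = -drive.peak_negative_pressure * np.sin(
        2.0 * math.pi * drive.center_frequency * t
    )
    if drive.envelope == "ramped":
        ramp = np.clip(t / (2.0 * drive.period), 0.0, 1.0)
        p = p * ramp
    active = (t >= 0.0) & (t <= drive.duration)
    p = np.where(active, p, 0.0)
    return float(p) if p.ndim == 0 else p


def marmottant_rhs(
    state: Sequence[float], t: float, system: BubbleSystem, drive: AcousticDrive
) -> tuple[float, float]:
    """Right-hand side (Rdot, Rddot) of the coated-bubble momentum balance.

    At rest (R = R0, Rdot = 0) with the drive off, the returned acceleration
    is zero: the equilibrium gas pressure is constructed from the mechanical
    balance at R0, so rest is a fixed point.
    """
    radius, velocity = state
    if radius <= 0.0:
        raise ValueError("radius must be > 0")
    med = system.medium
    gas = system.gas
    shell = system.shell
    r0 = system.resting_radius
    k = gas.polytropic_exponent

    gas_pressure = (
        system.equilibrium_gas_pressure
        * (r0 / radius) ** (3.0 * k)
        * (1.0 - 3.0 * k * velocity / med.sound_speed)
    )
    sigma = surface_tension(radius, shell, med, r0)
    p_liquid = (
        gas_pressure
        + gas.vapor_pressure
        - med.ambient_pressure
        - float(drive_pressure(t, drive))
        - 2.0 * sigma / radius
        - 4.0 * med.dynamic_viscosity * velocity / radius
        - 4.0 * shell.surface_viscosity_kappa_s * velocity / radius**2
    )
    acceleration = (p_liquid / med.density - 1.5 * velocity**2) / radius
    return velocity, acceleration


def simulate_radius(
    system: BubbleSystem,
    drive: AcousticDrive,
    rtol: float = RTOL,
    samples_per_cycle: int = SAMPLES_PER_CYCLE,
) -> RadiusTrace:
    """Integrate the radial dynamics over the drive window.

    Uses a stiff-capable adaptive solver (LSODA). An integration event
    truncates the trace when the radius falls below ``COLLAPSE_FLOOR * R0``
    (violent inertial collapse); the trace is then flagged and the
    expansion ratio is taken over the pre-collapse segment.
    """
    r0 = system.resting_radius

    def rhs(t, y):
        return marmottant_rhs(y, t, system, drive)

    def collapse(t, y):
        return y[0] - COLLAPSE_FLOOR * r0

    collapse.terminal = True
    collapse.direction = -1

    t_end = drive.duration
    t_eval = np.linspace(0.0, t_end, drive.n_cycles * samples_per_cycle + 1)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [r0, 0.0],
        method="LSODA",
        rtol=rtol,
        atol=[ATOL_RADIUS_REL * r0, ATOL_VELOCITY],
        t_eval=t_eval,
        events=collapse,
        max_step=drive.period / 50.0,
    )
    if sol.status == -1:
        raise IntegrationError(
            f"radial-dynamics integration failed at PNP="
            f"{drive.peak_negative_pressure:.0f} Pa: {sol.message}"
        )
    truncated = sol.status == 1
    times = sol.t
    radii = sol.y[0]
    velocities = sol.y[1]
    if truncated and sol.t_events[0].size:
        # append the event point so the trace ends exactly at the floor
        times = np.append(times, sol.t_events[0][0])
        radii = np.append(radii, sol.y_events[0][0][0])
        velocities = np.append(velocities, sol.y_events[0][0][1])
    logger.debug(
        "simulate_radius: pnp=%.0f Pa, config=%s, rtol=%g, truncated=%s",
        drive.peak_negative_pressure,
        config_hash(system, drive),
        rtol,
        truncated,
    )
    return RadiusTrace(
        times=times,
        radii=radii,
        radial_velocities=velocities,
        resting_radius=r0,
        truncated_at_collapse=truncated,
    )


def expansion_ratio(trace: RadiusTrace) -> float:
    """Maximum diameter over resting diameter, ER = max R(t) / R0."""
    if len(trace.radii) == 0:
        raise ValueError("empty radius trace")
    return float(np.max(trace.radii) / trace.resting_radius)


def classify_cavitation(
    er: float, thresholds: RegimeThresholds = RegimeThresholds()
) -> Regime:
    """Map an expansion ratio onto {negligible, stable, inertial}."""
    if er < thresholds.stable_lower:
        return Regime.NEGLIGIBLE
    if er <= thresholds.inertial_onset:
        return Regime.STABLE
    return Regime.INERTIAL


def pressure_sweep(
    system: BubbleSystem,
    center_frequency: float,
    pnp_min: float,
    pnp_max: float,
    step: float,
    n_cycles: int = 50,
    thresholds: RegimeThresholds = RegimeThresholds(),
    envelope: str = "rectangular",
) -> SweepResult:
    """Expansion ratio and regime at each PNP on a uniform grid.

    Each grid point is an independent single-shot simulation, so the sweep
    is exactly the pointwise composition of :func:`simulate_radius` and
    :func:`expansion_ratio`.
    """
    if pnp_min < 0 or step <= 0 or (pnp_max < pnp_min):
        raise ValueError("require pnp_min >= 0, step > 0, pnp_max >= pnp_min")
    grid = np.arange(pnp_min, pnp_max + step / 2.0, step)
    ers = np.empty_like(grid)
    regimes: list[Regime] = []
    for i, pnp in enumerate(grid):
        drive = AcousticDrive(
            center_frequency=center_frequency,
            peak_negative_pressure=float(pnp),
            n_cycles=n_cycles,
            envelope=envelope,
        )
        try:
            trace = simulate_radius(system, drive)
        except IntegrationError as err:
            raise IntegrationError(f"sweep failed at PNP={pnp:.0f} Pa") from err
        ers[i] = expansion_ratio(trace)
        regimes.append(classify_cavitation(ers[i], thresholds))
    return SweepResult(pnp_grid=grid, expansion_ratios=ers, regimes=regimes)


def _first_upward_crossing(
    grid: np.ndarray, values: np.ndarray, target: float
) -> Optional[float]:
    """Linearly interpolated abscissa of the first upward crossing of
    ``target``; None when never crossed. The first crossing wins."""
    for i in range(1, len(grid)):
        if values[i - 1] < target <= values[i]:
            frac = (target - values[i - 1]) / (values[i] - values[i - 1])
            return float(grid[i - 1] + frac * (grid[i] - grid[i - 1]))
    return None


def find_regime_boundaries(
    sweep: SweepResult, thresholds: RegimeThresholds = RegimeThresholds()
) -> RegimeBoundaries:
    """PNP values where the ER curve first crosses the stable (1.1) and
    inertial (3.5) thresholds, by linear interpolation on the sweep grid."""
    low = _first_upward_crossing(
        sweep.pnp_grid, sweep.expansion_ratios, thresholds.stable_lower
    )
    high = _first_upward_crossing(
        sweep.pnp_grid, sweep.expansion_ratios, thresholds.inertial_onset
    )
    return RegimeBoundaries(pnp_stable_low=low, pnp_inertial_onset=high)


def mechanical_index(pnp: float, frequency: float) -> float:
    """MI = PNP[MPa] / sqrt(f[MHz]); the FDA diagnostic limit is 1.9."""
    if frequency <= 0.0:
        raise ValueError("frequency must be > 0")
    if pnp < 0.0:
        raise ValueError("pnp must be >= 0")
    return (pnp / 1e6) / math.sqrt(frequency / 1e6)


def blake_threshold_estimate(
    system: BubbleSystem, effective_surface_tension: Optional[float] = None
) -> float:
    """Quasi-static Blake threshold for a clean bubble, as a diagnostic.

    For an isothermal gas core and constant surface tension ``sigma`` the
    quasi-static pressure balance loses its stable equilibrium at

        P_Blake = P0 + (4 sigma / 3) sqrt(2 sigma / (3 P_g0 R0^3)),

    with ``P_g0 = P0 + 2 sigma / R0``. This clean-bubble closed form is an
    order-of-magnitude reference for the onset of explosive growth well
    below resonance; it ignores the shell and inertia and is *not* used by
    the regime classification, which relies on the simulated sweep.
    """
    p0 = system.medium.ambient_pressure
    sigma = (
        system.medium.water_surface_tension
        if effective_surface_tension is None
        else effective_surface_tension
    )
    if sigma <= 0.0:
        return p0
    r0 = system.resting_radius
    p_g0 = p0 + 2.0 * sigma / r0
    return p0 + (4.0 * sigma / 3.0) * math.sqrt(2.0 * sigma / (3.0 * p_g0 * r0**3))


# ---------------------------------------------------------------------------
# Shell calibration


class ExpansionAnchor(NamedTuple):
    """Target expansion ratio at a given PNP (Pa). ``tolerance`` is the
    acceptable relative mismatch used to scale this anchor's residual in
    the calibration objective."""

    pnp: float
    target_er: float
    tolerance: float = 1.0


class BoundaryAnchor(NamedTuple):
    """Target PNP (Pa) at which the ER curve crosses ``threshold_er``.
    ``tolerance`` is the acceptable relative mismatch on the crossing
    pressure."""

    threshold_er: float
    target_pnp: float
    bracket: tuple[float, float] = (20e3, 280e3)
    tolerance: float = 1.0


@dataclass(frozen=True)
class CalibrationResult:
    shell: ShellProperties
    residuals: dict[str, float]  # relative error per anchor
    max_abs_residual: float
    converged: bool
    n_evaluations: int


def _anchor_predictions(
    system: BubbleSystem,
    drive_template: AcousticDrive,
    er_anchors: Sequence[ExpansionAnchor],
    boundary_anchors: Sequence[BoundaryAnchor],
) -> dict[str, float]:
    def er_at(pnp: float) -> float:
        drive = AcousticDrive(
            center_frequency=drive_template.center_frequency,
            peak_negative_pressure=pnp,
            n_cycles=drive_template.n_cycles,
            envelope=drive_template.envelope,
        )
        return expansion_ratio(simulate_radius(system, drive))

    preds: dict[str, float] = {}
    for a in er_anchors:
        preds[f"er@{a.pnp / 1e3:.0f}kPa"] = er_at(a.pnp)
    for b in boundary_anchors:
        lo, hi = b.bracket

        def g(p: float) -> float:
            return er_at(p) - b.threshold_er

        key = f"pnp@er={b.threshold_er:g}"
        try:
            preds[key] = brentq(g, lo, hi, xtol=200.0)
        except ValueError:
            preds[key] = math.nan
    return preds


def calibrate_shell(
    er_anchors: Sequence[ExpansionAnchor],
    boundary_anchors: Sequence[BoundaryAnchor] = (),
    system_template: Optional[BubbleSystem] = None,
    drive_template: Optional[AcousticDrive] = None,
    chi_bounds: tuple[float, float] = (0.01, 1.0),
    kappa_s_bounds: tuple[float, float] = (1e-10, 3e-8),
    sigma0_bounds: tuple[float, float] = (0.001, 0.072),
    x0: Optional[tuple[float, float, float]] = None,
    max_evaluations: int = 120,
    residual_tolerance: float = 1.0,
) -> CalibrationResult:
    """Fit shell parameters (chi, kappa_s, initial tension) to anchors.

    A single parameter set is optimized jointly against all anchors
    (Nelder-Mead in log-parameter space); there is no per-anchor tuning.
    The objective is the mean squared *tolerance-scaled* relative error:
    each anchor's relative residual is divided by its ``tolerance`` before
    squaring, so anchors with a tighter acceptable mismatch pull harder.
    With the default tolerance of 1 on every anchor this reduces to the
    plain mean squared relative error. Boundary-anchor predictions are
    located by root finding on the ER-vs-PNP curve inside the given
    bracket.

    Raises ``CalibrationError`` when the anchor list is empty or the search
    box is degenerate. The result is flagged ``converged`` when every
    residual lies within its anchor's tolerance scaled by
    ``residual_tolerance``; otherwise the best candidate is returned with
    ``converged=False``.
    """
    if len(er_anchors) + len(boundary_anchors) < 2:
        raise CalibrationError("need at least two anchors")
    for lo, hi in (chi_bounds, kappa_s_bounds, sigma0_bounds):
        if not (0 < lo < hi):
            raise CalibrationError("search box bounds must satisfy 0 < lo < hi")

    base = system_template or BubbleSystem()
    drv = drive_template or AcousticDrive(peak_negative_pressure=0.0)
    bounds = (chi_bounds, kappa_s_bounds, sigma0_bounds)
    if x0 is None:
        x0 = tuple(math.sqrt(lo * hi) for lo, hi in bounds)  # geometric centre

    targets: dict[str, float] = {}
    tolerances: dict[str, float] = {}
    for a in er_anchors:
        key = f"er@{a.pnp / 1e3:.0f}kPa"
        targets[key] = a.target_er
        tolerances[key] = a.tolerance
    for b in boundary_anchors:
        key = f"pnp@er={b.threshold_er:g}"
        targets[key] = b.target_pnp
        tolerances[key] = b.tolerance

    n_eval = 0

    def residuals_for(params: np.ndarray) -> Optional[dict[str, float]]:
        chi, ks, s0 = params
        if s0 > base.medium.water_surface_tension:
            return None
        system = BubbleSystem(
            resting_radius=base.resting_radius,
            gas=base.gas,
            medium=base.medium,
            shell=ShellProperties(
                elastic_modulus_chi=chi,
                surface_viscosity_kappa_s=ks,
                initial_surface_tension=s0,
            ),
        )
        preds = _anchor_predictions(system, drv, er_anchors, boundary_anchors)
        out = {}
        for key, tgt in targets.items():
            pred = preds[key]
            out[key] = math.inf if math.isnan(pred) else pred / tgt - 1.0
        return out

    def objective(logx: np.ndarray) -> float:
        nonlocal n_eval
        params = np.exp(logx)
        for p, (lo, hi) in zip(params, bounds):
            if not (lo <= p <= hi):
                return 1e3
        res = residuals_for(params)
        if res is None or any(math.isinf(v) for v in res.values()):
            return 1e3
        n_eval += 1
        return float(
            np.mean([(v / tolerances[k]) ** 2 for k, v in res.items()])
        )

    opt = minimize(
        objective,
        np.log(np.asarray(x0)),
        method="Nelder-Mead",
        options={"maxfev": max_evaluations, "xatol": 5e-3, "fatol": 1e-6},
    )
    best = np.clip(
        np.exp(opt.x), [lo for lo, _ in bounds], [hi for _, hi in bounds]
    )
    res = residuals_for(best)
    if res is None:
        raise CalibrationError("optimizer left the feasible region")
    max_abs = max(abs(v) for v in res.values())
    shell = ShellProperties(
        elastic_modulus_chi=float(best[0]),
        surface_viscosity_kappa_s=float(best[1]),
        initial_surface_tension=float(best[2]),
    )
    converged = all(
        abs(v) <= residual_tolerance * tolerances[k] for k, v in res.items()
    )
    if not converged:
        logger.warning(
            "calibration did not reach residual %.2f; best candidate %s "
            "with max |residual| %.3f",
            residual_tolerance,
            shell,
            max_abs,
        )
    return CalibrationResult(
        shell=shell,
        residuals=res,
        max_abs_residual=max_abs,
        converged=converged,
        n_evaluations=n_eval,
    )


class CalibrationError(RuntimeError):
    """Raised for unusable calibration inputs."""
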