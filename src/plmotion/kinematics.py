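"""Pendulum dynamics and the 21-profile velocity family.

The reference stimulus is the bob of a virtual simple pendulum (rod length
``L``, release angle ``theta0``) swinging through an amplitude ``A = 2*theta0``
with period ``T``.  Around the 1g solution, a family of 21 ordinal velocity
profiles ``K_0 .. K_20`` is constructed on a common half-period time grid: five
basic profiles (reverse-gravity −1g, constant 0g, pendular 1g, and amplified
2g/3g) plus linear interpolations between adjacent basics with weights
0.2/0.4/0.6/0.8.  Every profile traverses the same amplitude in the same time;
only the speed law differs.

Time base
---------
The exact pendulum period for the reference parameters is 1.67970 s.  Stimuli
are played out on a 100 Hz display, so profile grids live on the *design*
period: the exact period quantized to the frame grid (1.68 s, i.e. 840 ms per
sweep, 16800 samples per period at the 10 kHz generation rate).  The ODE
solution itself always uses the exact dynamics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import ellipk

__all__ = [
    "PendulumParams",
    "MotionTrace",
    "VelocityProfile",
    "ProfileFamily",
    "REFERENCE_PARAMS",
    "GENERATION_RATE_HZ",
    "REFRESH_RATE_HZ",
    "solve_pendulum",
    "measure_period",
    "design_period",
    "harmonic_deviation",
    "constant_profile",
    "one_g_profile",
    "reverse_gravity_profile",
    "amplified_profiles",
    "build_family",
    "integrate_profile",
    "acceleration_ratio",
    "detectability_ratios",
    "write_trace_csv",
    "read_trace_csv",
]

#: High-rate grid used to generate position samples (samples per second).
GENERATION_RATE_HZ = 10_000
#: Vertical refresh rate of the display; stimulus output grid.
REFRESH_RATE_HZ = 100.0

_LAMBDA_STEPS = 5  # interpolation weights in steps of 1/5 between basics


class IntegrationError(RuntimeError):
    """Non-finite state encountered while integrating the equation of motion."""


class CalibrationError(RuntimeError):
    """A shooting/root-finding calibration failed to converge."""


class InsufficientDataError(ValueError):
    """Trace too short for the requested measurement."""


@dataclass(frozen=True)
class PendulumParams:
    """Physical and design constants of the virtual pendulum.

    Parameters
    ----------
    L : float
        Rod length in metres.
    g : float
        Gravitational acceleration in m s^-2.
    theta0 : float
        Release angle (initial angular displacement from equilibrium), rad.
        Must lie in (0, pi/2).
    """

    L: float = 0.64823
    g: float = 9.81
    theta0: float = math.pi / 4

    def __post_init__(self) -> None:
        if not (self.L > 0 and np.isfinite(self.L)):
            raise ValueError(f"rod length L must be positive, got {self.L}")
        if not (self.g > 0 and np.isfinite(self.g)):
            raise ValueError(f"gravity g must be positive, got {self.g}")
        if not (0 < self.theta0 < math.pi / 2):
            raise ValueError(
                f"release angle theta0 must lie in (0, pi/2), got {self.theta0}"
            )

    @property
    def A(self) -> float:
        """Oscillation amplitude 2*theta0, rad."""
        return 2.0 * self.theta0

    @property
    def T(self) -> float:
        """Exact large-amplitude oscillation period, s.

        Closed form 4*sqrt(L/g)*K(sin(theta0/2)) with K the complete elliptic
        integral of the first kind.  The motion itself is always obtained by
        numerical integration; this constant is cross-checked against the
        measured period of the integrated solution in the test suite.
        """
        k = math.sin(self.theta0 / 2.0)
        return 4.0 * math.sqrt(self.L / self.g) * float(ellipk(k * k))

    @property
    def small_angle_period(self) -> float:
        """Harmonic (small-angle) period 2*pi*sqrt(L/g), s."""
        return 2.0 * math.pi * math.sqrt(self.L / self.g)

    @property
    def design_period(self) -> float:
        """Period quantized to the display frame grid (see module docstring)."""
        return design_period(self.T)

    @property
    def half_sweep(self) -> float:
        """Duration of one half-period sweep on the design grid, s."""
        return self.design_period / 2.0


REFERENCE_PARAMS = PendulumParams()


@dataclass
class MotionTrace:
    """Uniformly sampled angular motion: times, displacement, signed velocity."""

    t: np.ndarray
    theta: np.ndarray
    omega: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if not (len(self.t) == len(self.theta) == len(self.omega)):
            raise ValueError("t, theta, omega must have equal length")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if np.any(np.abs(dt - 1.0 / self.sample_rate) > 1e-9):
                raise ValueError("time grid spacing must equal 1/sample_rate")

    def __len__(self) -> int:
        return len(self.t)

    def energy(self, params: PendulumParams) -> np.ndarray:
        """Specific mechanical energy 0.5*L*omega^2 - g*cos(theta) along the trace."""
        return 0.5 * params.L * self.omega**2 - params.g * np.cos(self.theta)


def solve_pendulum(
    params: PendulumParams,
    sample_rate: float = GENERATION_RATE_HZ,
    gravity_sign: int = +1,
    initial_omega: float = 0.0,
    n_periods: float = 2.0,
) -> MotionTrace:
    """Integrate theta'' = -sign*(g/L)*sin(theta) with fixed-step RK4.

    Initial conditions are theta(0) = theta0, omega(0) = initial_omega.  The
    trace spans ``n_periods`` reference periods (at least one full period is
    required so that the period can be measured from it).

    Raises
    ------
    ValueError
        If ``sample_rate`` < 1000 Hz (too coarse for the stimulus grids) or
        ``gravity_sign`` is not +1/-1.
    IntegrationError
        If the state becomes non-finite (names the failing step).
    """
    if sample_rate < 1000:
        raise ValueError(f"sample_rate must be >= 1000 Hz, got {sample_rate}")
    if gravity_sign not in (+1, -1):
        raise ValueError(f"gravity_sign must be +1 or -1, got {gravity_sign}")
    if n_periods < 1.0:
        raise ValueError("trace must span at least one period")

    dt = 1.0 / sample_rate
    n_steps = int(round(n_periods * params.T * sample_rate))
    c = gravity_sign * params.g / params.L

    th = np.empty(n_steps + 1)
    om = np.empty(n_steps + 1)
    th[0], om[0] = params.theta0, initial_omega
    x, v = params.theta0, initial_omega
    sin = math.sin
    for i in range(n_steps):
        k1x, k1v = v, -c * sin(x)
        k2x, k2v = v + 0.5 * dt * k1v, -c * sin(x + 0.5 * dt * k1x)
        k3x, k3v = v + 0.5 * dt * k2v, -c * sin(x + 0.5 * dt * k2x)
        k4x, k4v = v + dt * k3v, -c * sin(x + dt * k3x)
        x += dt / 6.0 * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
        v += dt / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
        if not (math.isfinite(x) and math.isfinite(v)):
            raise IntegrationError(
                f"non-finite state at step {i + 1} (t = {(i + 1) * dt:.6f} s)"
            )
        th[i + 1], om[i + 1] = x, v

    t = np.arange(n_steps + 1) * dt
    return MotionTrace(t=t, theta=th, omega=om, sample_rate=sample_rate)


def measure_period(trace: MotionTrace) -> float:
    """Oscillation period from same-direction zero crossings of omega.

    Upward (negative-to-positive) crossings of the angular velocity are located
    by linear interpolation; the period is the mean spacing between successive
    crossings.  Raises :class:`InsufficientDataError` with fewer than two
    qualifying crossings.
    """
    om, t = trace.omega, trace.t
    up = np.where((om[:-1] < 0) & (om[1:] >= 0))[0]
    if len(up) < 2:
        raise InsufficientDataError(
            f"need >= 2 upward zero crossings of omega, found {len(up)}"
        )
    crossings = t[up] - om[up] * (t[up + 1] - t[up]) / (om[up + 1] - om[up])
    return float(np.mean(np.diff(crossings)))


def design_period(period: float, refresh_rate: float = REFRESH_RATE_HZ) -> float:
    """Quantize a period to the display frame grid (nearest whole frame)."""
    return round(period * refresh_rate) / refresh_rate


def harmonic_deviation(
    trace: MotionTrace, period: float | None = None
) -> tuple[float, float]:
    """Deviation of a pendulum trace from the equal-amplitude harmonic motion.

    The comparator is ``theta_h(t) = theta_max * cos(2*pi*t/T_h)`` over one
    period.  By default ``T_h`` is the trace's measured period quantized to the
    display frame grid -- the period the stimulus is actually generated on
    (1.68 s for the reference parameters); pass ``period`` explicitly for the
    raw measured period or any other comparator.

    Returns
    -------
    (position_pct, velocity_pct)
        Max absolute position deviation as % of the amplitude ``theta_max``,
        and max absolute velocity deviation as % of the trace's peak angular
        speed.
    """
    if period is None:
        period = design_period(measure_period(trace))
    n = int(round(period * trace.sample_rate))
    if n + 1 > len(trace):
        raise InsufficientDataError("trace shorter than one comparator period")
    t = trace.t[: n + 1]
    th = trace.theta[: n + 1]
    om = trace.omega[: n + 1]
    amp = float(np.max(np.abs(th)))
    w = 2.0 * math.pi / period
    th_h = amp * np.cos(w * t)
    om_h = -amp * w * np.sin(w * t)
    peak = float(np.max(np.abs(om)))
    pos_pct = float(np.max(np.abs(th - th_h)) / amp * 100.0)
    vel_pct = float(np.max(np.abs(om - om_h)) / peak * 100.0)
    return pos_pct, vel_pct


# ---------------------------------------------------------------------------
# Velocity profiles
# ---------------------------------------------------------------------------


@dataclass
class VelocityProfile:
    """Unsigned angular speed over one half-period sweep [0, T/2].

    ``index`` is the ordinal family label 0-20 (None for a free-standing basic
    profile), ``g_level`` the nominal label ("-1g", "0g", "1g", "2g", "3g" or
    "interp"), ``lam`` the interpolation weight toward the upper neighbour for
    interpolated profiles.
    """

    t: np.ndarray
    v: np.ndarray
    g_level: str
    index: int | None = None
    lam: float | None = None
    family: str | None = None  # construction flag, e.g. "sin-power" for 2g/3g

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if len(self.t) != len(self.v):
            raise ValueError("t and v must have equal length")
        if np.any(self.v < -1e-12):
            raise ValueError("profile speed must be non-negative")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def peak(self) -> float:
        """Speed at the sweep midpoint t = T/4 (trajectory midpoint theta = 0)."""
        return float(np.interp(self.duration / 2.0, self.t, self.v))

    @property
    def integral(self) -> float:
        """Swept amplitude: integral of v over the sweep (should equal A)."""
        return float(np.trapezoid(self.v, self.t))

    def symmetry_error(self) -> float:
        """Max relative asymmetry about t = T/4."""
        vr = self.v[::-1]
        return float(np.max(np.abs(self.v - vr)) / np.max(self.v))


def _half_sweep_grid(params: PendulumParams) -> np.ndarray:
    n = int(round(params.half_sweep * GENERATION_RATE_HZ))
    return np.arange(n + 1) / GENERATION_RATE_HZ


def constant_profile(params: PendulumParams) -> VelocityProfile:
    """0g profile: constant speed A/(T/2) throughout the sweep."""
    t = _half_sweep_grid(params)
    v0 = params.A / params.half_sweep
    return VelocityProfile(t=t, v=np.full_like(t, v0), g_level="0g")


def one_g_profile(params: PendulumParams, trace: MotionTrace | None = None) -> VelocityProfile:
    """1g profile: unsigned speed of the integrated pendulum over one sweep.

    The exact half-period sweep is resampled onto the design half-period grid
    with a uniform time rescaling (factor T_true/T_design, 0.99982 for the
    reference parameters) so that the amplitude integral is preserved.
    """
    if trace is None:
        trace = solve_pendulum(params)
    T_true = measure_period(trace)
    half_true = T_true / 2.0
    t = _half_sweep_grid(params)
    scale = half_true / params.half_sweep
    # speed at rescaled times; multiply by scale to keep integral = A
    v = np.interp(t * scale, trace.t, np.abs(trace.omega)) * scale
    v[0] = 0.0
    v[-1] = 0.0
    return VelocityProfile(t=t, v=v, g_level="1g")


def reverse_gravity_profile(
    params: PendulumParams,
    tol: float = 1e-6,
    method: str = "reflect",
    v1g: VelocityProfile | None = None,
) -> VelocityProfile:
    """-1g profile: fastest at the endpoints, slowest at the trajectory midpoint.

    Two constructions are available:

    ``"reflect"`` (default)
        The mirror image of the 1g profile about the constant profile,
        ``v(t) = 2*V0g - V1g(t)``.  It decelerates toward the midpoint exactly
        as much as the 1g profile accelerates, conserves the amplitude
        integral by construction, and makes the velocity-change magnitude of
        K_0 equal to that of K_10 -- which is what produces the symmetric
        detectability minima at K_4 and K_6 (both ~30%).
    ``"shooting"``
        The literal sweep of a pendulum under reversed gravity
        (theta'' = +(g/L)*sin(theta)) traversing +theta0 -> -theta0 in exactly
        T/2, with the (nonzero) endpoint speed found by bisection.  Kept as an
        alternative speed law; its endpoint/midpoint speeds (3.23 / 1.25 rad/s
        at reference parameters) give a much larger velocity change than the
        reflected profile.

    ``tol`` is the sweep-duration convergence tolerance in seconds for the
    shooting method (and the amplitude-integral tolerance for validation).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if method == "reflect":
        if v1g is None:
            v1g = one_g_profile(params)
        v0 = params.A / params.half_sweep
        v = 2.0 * v0 - v1g.v
        if np.any(v < 0):
            raise CalibrationError("reflected -1g profile has negative speed")
        return VelocityProfile(t=v1g.t.copy(), v=v, g_level="-1g", family="reflect")
    if method == "shooting":
        return _reverse_gravity_shooting(params, tol)
    raise ValueError(f"unknown method {method!r}")


def _reverse_gravity_shooting(params: PendulumParams, tol: float) -> VelocityProfile:
    """Shooting solution of the reversed-gravity sweep (see reverse_gravity_profile)."""
    k = params.g / params.L
    th0 = params.theta0
    half = params.half_sweep
    # dense theta grid; energy gives v(theta), time by quadrature of 1/v
    th_grid = np.linspace(th0, -th0, 20001)

    def sweep(v_end: float) -> tuple[np.ndarray, np.ndarray] | None:
        v_sq = v_end**2 + 2.0 * k * (np.cos(th0) - np.cos(th_grid))
        if np.any(v_sq <= 0):
            return None  # not enough energy to pass the (unstable) midpoint
        v = np.sqrt(v_sq)
        dt = -np.diff(th_grid) / (0.5 * (v[:-1] + v[1:]))
        times = np.concatenate([[0.0], np.cumsum(dt)])
        return times, v

    def duration(v_end: float) -> float:
        s = sweep(v_end)
        return math.inf if s is None else float(s[0][-1])

    lo = (params.A / params.half_sweep) / 2.0  # V0g/2
    hi = 4.0 * params.A / params.half_sweep  # 4*V0g
    if duration(hi) > half:
        raise CalibrationError(f"shooting bracket [{lo}, {hi}] too slow at upper end")
    # bisect on endpoint speed: duration decreases monotonically with v_end
    a, b = lo, hi
    for _ in range(200):
        mid = 0.5 * (a + b)
        d = duration(mid)
        if abs(d - half) < tol:
            a = b = mid
            break
        if d > half:
            a = mid
        else:
            b = mid
    else:
        raise CalibrationError(
            f"shooting failed to converge in bracket [{lo}, {hi}]: "
            f"duration residual {duration(0.5 * (a + b)) - half:.2e} s"
        )
    v_end = 0.5 * (a + b)
    times, v_of_th = sweep(v_end)
    t = _half_sweep_grid(params)
    # map quadrature time onto the design grid (residual duration error < tol)
    v = np.interp(t * (times[-1] / half), times, v_of_th)
    return VelocityProfile(t=t, v=v, g_level="-1g", family="shooting")


def amplified_profiles(
    params: PendulumParams,
    tol: float = 1e-9,
    v1g: VelocityProfile | None = None,
) -> tuple[VelocityProfile, VelocityProfile]:
    """2g and 3g profiles: zero-endpoint speed laws with amplified peaks.

    Built from the single-parameter family ``v_p(t) = c * sin(2*pi*t/T)**p`` on
    [0, T/2]: zero at the endpoints, symmetric about T/4, with exactly the two
    degrees of freedom the constraints require.  ``c`` is the target peak and
    ``p`` is calibrated by root-finding so the amplitude integral equals A.
    Peaks are fixed by equal spacing at the midpoint:
    ``V2g(T/4) = 2*V1g(T/4) - V0g(T/4)`` and
    ``V3g(T/4) = V2g(T/4) + (V1g(T/4) - V0g(T/4))``.
    """
    if v1g is None:
        v1g = one_g_profile(params)
    v0_peak = params.A / params.half_sweep
    v1_peak = v1g.peak
    peak2 = 2.0 * v1_peak - v0_peak
    peak3 = peak2 + (v1_peak - v0_peak)
    t = _half_sweep_grid(params)
    base = np.sin(2.0 * math.pi * t / params.design_period)
    base[base < 0] = 0.0  # guard endpoint round-off
    base[0] = base[-1] = 0.0

    def make(peak: float, label: str) -> VelocityProfile:
        def residual(p: float) -> float:
            return float(np.trapezoid(peak * base**p, t)) - params.A

        try:
            p = brentq(residual, 0.05, 60.0, xtol=1e-12, rtol=8.9e-16)
        except ValueError as exc:
            raise CalibrationError(
                f"sin-power calibration failed for {label}: "
                f"residuals ({residual(0.05):.3e}, {residual(60.0):.3e})"
            ) from exc
        v = peak * base**p
        if abs(float(np.trapezoid(v, t)) - params.A) > max(tol, 1e-9) * params.A:
            raise CalibrationError(f"amplitude residual above tol for {label}")
        return VelocityProfile(t=t, v=v, g_level=label, family="sin-power")

    return make(peak2, "2g"), make(peak3, "3g")


@dataclass
class ProfileFamily:
    """The 21 ordinal velocity profiles K_0 .. K_20 on a common grid."""

    profiles: list[VelocityProfile]
    params: PendulumParams = field(default_factory=PendulumParams)

    def __post_init__(self) -> None:
        if len(self.profiles) != 21:
            raise ValueError(f"family must hold 21 profiles, got {len(self.profiles)}")
        for i, p in enumerate(self.profiles):
            if p.index != i:
                raise ValueError(f"profile at position {i} has index {p.index}")

    def __getitem__(self, index: int) -> VelocityProfile:
        return self.profiles[index]

    def __iter__(self):
        return iter(self.profiles)

    def to_json(self, path) -> None:
        """Export the family (SI units) with a metadata block."""
        payload = {
            "metadata": {
                "params": {
                    "L_m": self.params.L,
                    "g_m_s2": self.params.g,
                    "theta0_rad": self.params.theta0,
                    "period_s": self.params.T,
                    "design_period_s": self.params.design_period,
                    "amplitude_rad": self.params.A,
                },
                "generation_rate_hz": GENERATION_RATE_HZ,
                "refresh_rate_hz": REFRESH_RATE_HZ,
                "software": "plmotion 0.1.0",
            },
            "profiles": [
                {
                    "index": p.index,
                    "g_level": p.g_level,
                    "lambda": p.lam,
                    "family": p.family,
                    "t": p.t.tolist(),
                    "v": p.v.tolist(),
                }
                for p in self.profiles
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path, params: PendulumParams | None = None) -> "ProfileFamily":
        with open(path) as fh:
            payload = json.load(fh)
        meta = payload["metadata"]["params"]
        if params is None:
            params = PendulumParams(
                L=meta["L_m"], g=meta["g_m_s2"], theta0=meta["theta0_rad"]
            )
        profiles = [
            VelocityProfile(
                t=np.asarray(d["t"]),
                v=np.asarray(d["v"]),
                g_level=d["g_level"],
                index=d["index"],
                lam=d["lambda"],
                family=d.get("family"),
            )
            for d in payload["profiles"]
        ]
        return cls(profiles=profiles, params=params)


def build_family(
    params: PendulumParams, reverse_method: str = "reflect"
) -> ProfileFamily:
    """Construct all 21 profiles: basics at indices 0/5/10/15/20, interpolations between.

    An interpolated profile at index ``i`` between lower basic ``P_a`` and upper
    basic ``P_b`` is ``(1 - w)*P_a + w*P_b`` with ``w = (i - i_a)/5``, so e.g.
    K_6 = 0.8*K_5 + 0.2*K_10.  This convention makes peak speed monotone in the
    index over 5..20, matching the ordinal staircase semantics of the task.
    """
    trace = solve_pendulum(params)
    v1g = one_g_profile(params, trace)
    v0g = constant_profile(params)
    vm1g = reverse_gravity_profile(params, method=reverse_method, v1g=v1g)
    v2g, v3g = amplified_profiles(params, v1g=v1g)
    basics = {0: vm1g, 5: v0g, 10: v1g, 15: v2g, 20: v3g}

    profiles: list[VelocityProfile] = []
    t = v0g.t
    for i in range(21):
        lo = (i // 5) * 5 if i < 20 else 15
        hi = lo + 5
        if i in basics:
            b = basics[i]
            if len(b.t) != len(t) or np.max(np.abs(b.t - t)) > 1e-12:
                raise ValueError(f"grid mismatch for basic profile at index {i}")
            profiles.append(
                VelocityProfile(
                    t=t.copy(), v=b.v.copy(), g_level=b.g_level, index=i,
                    lam=None, family=b.family,
                )
            )
        else:
            w = (i - lo) / _LAMBDA_STEPS
            v = (1.0 - w) * basics[lo].v + w * basics[hi].v
            profiles.append(
                VelocityProfile(
                    t=t.copy(), v=v, g_level="interp", index=i, lam=w,
                )
            )
    return ProfileFamily(profiles=profiles, params=params)


def integrate_profile(
    profile: VelocityProfile,
    direction_pattern: str = "back_and_forth",
    sample_rate_high: float = GENERATION_RATE_HZ,
    sample_rate_out: float = REFRESH_RATE_HZ,
    theta_start: float | None = None,
) -> MotionTrace:
    """Positions from a velocity profile: high-rate cumulative integration, then decimation.

    Signed velocity is integrated by the cumulative trapezoidal rule on the
    high-rate grid (16800 samples per period for the reference timing at
    10 kHz), then every k-th sample starting at t = 0 is kept to match the
    output rate -- mirroring how the display sequences were generated.

    ``back_and_forth`` alternates sweep direction each half period and spans
    one full period starting at +theta0 (= A/2 above midpoint by default);
    ``unidirectional`` spans a single sweep.
    """
    ratio = sample_rate_high / sample_rate_out
    if sample_rate_high < sample_rate_out or abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"sample_rate_high/sample_rate_out must be a positive integer, got {ratio}"
        )
    if direction_pattern not in ("back_and_forth", "unidirectional"):
        raise ValueError(f"unknown direction_pattern {direction_pattern!r}")
    k = int(round(ratio))
    half = profile.duration
    if theta_start is None:
        theta_start = profile.integral / 2.0  # +theta0

    if direction_pattern == "back_and_forth":
        n_high = int(round(2.0 * half * sample_rate_high))
    else:
        n_high = int(round(half * sample_rate_high))
    t_high = np.arange(n_high) / sample_rate_high
    v_signed = np.empty(n_high)
    first = t_high < half - 0.5 / sample_rate_high
    v_signed[first] = -np.interp(t_high[first], profile.t, profile.v)
    if direction_pattern == "back_and_forth":
        v_signed[~first] = np.interp(t_high[~first] - half, profile.t, profile.v)
    theta = theta_start + _cumtrapz(v_signed, 1.0 / sample_rate_high)

    idx = np.arange(0, n_high, k)
    return MotionTrace(
        t=t_high[idx], theta=theta[idx], omega=v_signed[idx],
        sample_rate=sample_rate_out,
    )


def _cumtrapz(y: np.ndarray, dx: float) -> np.ndarray:
    out = np.empty_like(y)
    out[0] = 0.0
    np.cumsum(0.5 * (y[1:] + y[:-1]) * dx, out=out[1:])
    return out


def acceleration_ratio(profile: VelocityProfile) -> float:
    """Detectability statistic |V2 - V1| / V_average, percent.

    V1 is the speed at the trajectory midpoint (theta = 0, t = T/4), V2 the
    speed at the endpoint (theta = theta0, t = 0), and V_average the mean speed
    over that quarter segment (path A/2 in time T/4).  Constant profiles give
    0; the published threshold for acceleration detection is 25%.
    """
    v1 = profile.peak
    v2 = float(profile.v[0])
    half_dur = profile.duration / 2.0
    n_half = len(profile.t) // 2
    v_avg = float(
        np.trapezoid(profile.v[: n_half + 1], profile.t[: n_half + 1]) / half_dur
    )
    return abs(v2 - v1) / v_avg * 100.0


def detectability_ratios(family: ProfileFamily) -> dict[int, float]:
    """Acceleration ratio (percent) for every profile in the family."""
    return {p.index: acceleration_ratio(p) for p in family}


# ---------------------------------------------------------------------------
# Trace I/O
# ---------------------------------------------------------------------------


def write_trace_csv(trace: MotionTrace, path) -> None:
    """Write a trace as CSV with columns t_s, theta_rad, omega_rad_s."""
    header = "t_s,theta_rad,omega_rad_s"
    data = np.column_stack([trace.t, trace.theta, trace.omega])
    np.savetxt(path, data, delimiter=",", header=header, comments="")


def read_trace_csv(path) -> MotionTrace:
    """Read a trace written by :func:`write_trace_csv`."""
    with open(path) as fh:
        header = fh.readline().strip()
    if header != "t_s,theta_rad,omega_rad_s":
        raise ValueError(f"unexpected trace header line: {header!r}")
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    t = data[:, 0]
    rate = 1.0 / np.median(np.diff(t))
    # snap to a clean rate to survive decimal round-tripping
    rate = round(rate, 6)
    return MotionTrace(t=t, theta=data[:, 1], omega=data[:, 2], sample_rate=rate)
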