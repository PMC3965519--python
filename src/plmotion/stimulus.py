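"""Screen-space stimulus tracks for the six experimental conditions.

Converts angular motion traces into display coordinates (cm, origin at the
display midpoint, x rightward, y upward) with per-sample visibility flags:

* back-and-forth arcs at 0 deg / 90 deg / 180 deg orientation (pendulum
  conditions, always visible),
* unidirectional sweeps along an arc or a horizontal/vertical line, with a
  140 ms blank between 840 ms sweeps,
* anticlockwise motion on a full circle, visible only in the bottom and top
  quadrants (840 ms visible / 840 ms occluded).

Lengths are placed on screen with the flat-screen rule R = d*tan(angle);
instantaneous visual angular velocity is on-screen tangential speed divided by
the viewing distance (small-angle at the display midpoint), which reproduces
the published 32.3 deg/s peak for the 1g stimulus.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kinematics import REFRESH_RATE_HZ, MotionTrace, VelocityProfile

__all__ = [
    "DisplayGeometry",
    "StimulusTrack",
    "make_arc_track",
    "make_unidirectional_track",
    "make_circle_track",
    "peak_visual_speed_deg",
    "visual_speed_deg",
    "write_track",
    "read_track",
]


@dataclass(frozen=True)
class DisplayGeometry:
    """Viewing geometry of the display setup.

    ``trajectory_radius_deg`` is the visual angle subtended by the on-screen
    radius of the arc trajectory; ``virtual_distance`` is the distance at which
    the virtual pendulum appears to swing (metadata only).  ``secant_deg`` is
    the reported angular extent of the trajectory chord, stored as metadata.
    """

    viewing_distance: float = 0.58  # m
    trajectory_radius_deg: float = 10.74
    virtual_distance: float = 3.5  # m
    secant_deg: float = 16.51  # reported, metadata

    def __post_init__(self) -> None:
        if self.viewing_distance <= 0:
            raise ValueError("viewing_distance must be positive")
        if not (0 < self.trajectory_radius_deg < 90):
            raise ValueError("trajectory_radius_deg must lie in (0, 90)")

    @property
    def radius_cm(self) -> float:
        """On-screen trajectory radius R = d*tan(angle), cm."""
        return 100.0 * self.viewing_distance * math.tan(
            math.radians(self.trajectory_radius_deg)
        )

    @property
    def arc_length_cm(self) -> float:
        """Length of the quarter-circle trajectory R*pi/2, cm."""
        return self.radius_cm * math.pi / 2.0

    @property
    def chord_cm(self) -> float:
        """Chord between the two sweep endpoints, 2*R*sin(45 deg), cm."""
        return 2.0 * self.radius_cm * math.sin(math.pi / 4.0)

    def to_dict(self) -> dict:
        return {
            "viewing_distance_m": self.viewing_distance,
            "trajectory_radius_deg": self.trajectory_radius_deg,
            "virtual_distance_m": self.virtual_distance,
            "secant_deg": self.secant_deg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DisplayGeometry":
        return cls(
            viewing_distance=d["viewing_distance_m"],
            trajectory_radius_deg=d["trajectory_radius_deg"],
            virtual_distance=d["virtual_distance_m"],
            secant_deg=d.get("secant_deg", 16.51),
        )


EXPERIMENTS = (
    "arc_0",
    "arc_90",
    "arc_180",
    "arc_0_unidir",
    "circle_occluded",
    "linear_horizontal",
    "linear_vertical",
    "arc_0_fixation",
)

SWEEP_MS = 840.0
GAP_UNIDIR_MS = 140.0
GAP_CIRCLE_MS = 840.0


@dataclass
class StimulusTrack:
    """Sampled screen trajectory with visibility schedule for one condition."""

    experiment: str
    t: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    visible: np.ndarray
    profile_index: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment label {self.experiment!r}")
        self.t = np.asarray(self.t, dtype=float)
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.y_cm = np.asarray(self.y_cm, dtype=float)
        self.visible = np.asarray(self.visible, dtype=bool)
        n = len(self.t)
        if not (len(self.x_cm) == len(self.y_cm) == len(self.visible) == n):
            raise ValueError("t, x_cm, y_cm, visible must have equal length")

    def __len__(self) -> int:
        return len(self.t)

    def speed_cm_s(self) -> np.ndarray:
        """On-screen speed by central differences, cm/s."""
        return np.hypot(np.gradient(self.x_cm, self.t), np.gradient(self.y_cm, self.t))

    def sweep_speed_series(self) -> np.ndarray:
        """Per-sample tangential speed during the first visible sweep, cm/s.

        Recovers the speed from the track geometry itself (arc-length
        increments along the known path class), so tracks of different
        geometry but identical kinematics yield identical series.
        """
        vis = np.flatnonzero(self.visible)
        start = vis[0]
        stop = start
        while stop + 1 < len(self) and self.visible[stop + 1]:
            stop += 1
        x = self.x_cm[start : stop + 1]
        y = self.y_cm[start : stop + 1]
        rate = 1.0 / (self.t[1] - self.t[0])
        if self.experiment in ("linear_horizontal", "linear_vertical"):
            ds = np.hypot(np.diff(x), np.diff(y))
        else:
            pivot = np.asarray(self.metadata.get("pivot_cm") or [0.0, 0.0])
            R = float(np.hypot(x[0] - pivot[0], y[0] - pivot[1]))
            ang = np.unwrap(np.arctan2(y - pivot[1], x - pivot[0]))
            ds = R * np.abs(np.diff(ang))
        return ds * rate


def _orientation_unit(orientation_deg: float) -> np.ndarray:
    """Pivot-to-midpoint unit vector: down at 0, left at 90, up at 180."""
    units = {0: (0.0, -1.0), 90: (-1.0, 0.0), 180: (0.0, 1.0)}
    if orientation_deg not in units:
        raise ValueError(
            f"orientation must be one of 0, 90, 180; got {orientation_deg}"
        )
    return np.asarray(units[orientation_deg])


def _arc_xy(theta: np.ndarray, orientation_deg: float, geom: DisplayGeometry):
    """Screen coordinates of the bob: trajectory midpoint at display origin.

    theta is measured from the pivot-to-midpoint direction, positive clockwise
    as seen by the observer.  The pivot sits at distance R opposite the
    orientation unit vector, so the path midpoint (theta = 0) lies at the
    display origin.
    """
    R = geom.radius_cm
    e = _orientation_unit(orientation_deg)
    pivot = -R * e
    ct, st = np.cos(theta), np.sin(theta)
    # clockwise rotation of e by theta: (ex*c + ey*s, -ex*s + ey*c)
    x = pivot[0] + R * (e[0] * ct + e[1] * st)
    y = pivot[1] + R * (-e[0] * st + e[1] * ct)
    return x, y, pivot


def make_arc_track(
    trace: MotionTrace,
    orientation_deg: float,
    geom: DisplayGeometry,
    profile_index: int | None = None,
    experiment: str | None = None,
) -> StimulusTrack:
    """Back-and-forth arc stimulus (pendulum condition), always visible.

    The target kinematics is identical across orientations; the path is a
    rigid rotation of the 0 deg condition about the display midpoint.
    """
    x, y, pivot = _arc_xy(trace.theta, orientation_deg, geom)
    if experiment is None:
        experiment = f"arc_{int(orientation_deg)}"
    return StimulusTrack(
        experiment=experiment,
        t=trace.t.copy(),
        x_cm=x,
        y_cm=y,
        visible=np.ones(len(trace), dtype=bool),
        profile_index=profile_index,
        metadata={
            "orientation_deg": float(orientation_deg),
            "pivot_cm": [float(pivot[0]), float(pivot[1])],
            "geometry": geom.to_dict(),
        },
    )


def make_unidirectional_track(
    trace_half: MotionTrace,
    path: str,
    geom: DisplayGeometry,
    gap_ms: float = GAP_UNIDIR_MS,
    n_sweeps: int = 2,
    profile_index: int | None = None,
) -> StimulusTrack:
    """Repeated identical 840 ms sweeps separated by an invisible gap.

    ``path`` is one of ``"arc"`` (left-to-right along the 0 deg arc),
    ``"line_horizontal"`` (left to right) or ``"line_vertical"`` (top to
    bottom).  Linear paths reproduce the tangential speed of the arc at every
    instant: the arc-length coordinate s(t) = R*(theta0 - theta(t)) is laid
    out along the line, so the total path length equals the arc length.
    During the gap the target is invisible (held at the sweep end).
    """
    if path not in ("arc", "line_horizontal", "line_vertical"):
        raise ValueError(f"unknown path {path!r}")
    dur = trace_half.t[-1] - trace_half.t[0] + 1.0 / trace_half.sample_rate
    if abs(dur - SWEEP_MS / 1000.0) > 1.5 / trace_half.sample_rate:
        raise ValueError(
            f"trace_half must span one {SWEEP_MS:.0f} ms sweep, got {dur * 1000:.1f} ms"
        )
    R = geom.radius_cm
    theta = trace_half.theta
    theta0 = float(theta[0])
    if path == "arc":
        x1, y1, pivot = _arc_xy(theta, 0.0, geom)
        meta_pivot = [float(pivot[0]), float(pivot[1])]
    else:
        s = R * (theta0 - theta)  # arc-length coordinate, 0 .. R*pi/2
        half_len = geom.arc_length_cm / 2.0
        if path == "line_horizontal":
            x1, y1 = -half_len + s, np.zeros_like(s)
        else:
            x1, y1 = np.zeros_like(s), half_len - s
        meta_pivot = None

    rate = trace_half.sample_rate
    n_sweep = len(trace_half)
    n_gap = int(round(gap_ms / 1000.0 * rate))
    xs, ys, vis = [], [], []
    for _ in range(n_sweeps):
        xs.append(x1)
        ys.append(y1)
        vis.append(np.ones(n_sweep, dtype=bool))
        xs.append(np.full(n_gap, x1[-1]))
        ys.append(np.full(n_gap, y1[-1]))
        vis.append(np.zeros(n_gap, dtype=bool))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    visible = np.concatenate(vis)
    t = np.arange(len(x)) / rate
    experiment = {
        "arc": "arc_0_unidir",
        "line_horizontal": "linear_horizontal",
        "line_vertical": "linear_vertical",
    }[path]
    return StimulusTrack(
        experiment=experiment,
        t=t,
        x_cm=x,
        y_cm=y,
        visible=visible,
        profile_index=profile_index,
        metadata={
            "gap_ms": float(gap_ms),
            "n_sweeps": n_sweeps,
            "pivot_cm": meta_pivot,
            "geometry": geom.to_dict(),
            "nominal_path_angle_deg": 17.85 if path.startswith("line") else None,
        },
    )


def make_circle_track(
    profile: VelocityProfile,
    geom: DisplayGeometry,
    n_cycles: int = 1,
    sample_rate: float = REFRESH_RATE_HZ,
    profile_index: int | None = None,
) -> StimulusTrack:
    """Occluded-circle stimulus: anticlockwise rotation, visible in bottom/top quadrants.

    The circle (radius R) is centered on the display midpoint.  Each visible
    quadrant (pi/2 of arc) is traversed in 840 ms following the profile's
    speed law; the two occluded quadrants are crossed at constant speed in the
    same 840 ms, giving a 3.36 s rotation period -- twice the oscillation
    period of the back-and-forth conditions.
    """
    R = geom.radius_cm
    half = profile.duration  # 0.84 s
    n_q = int(round(half * sample_rate))  # samples per quadrant
    tq = np.arange(n_q) / sample_rate
    # angle swept within a visible quadrant (0 .. pi/2), profile speed law
    from .kinematics import _cumtrapz  # local reuse of the integration kernel

    v_dense = np.interp(
        np.arange(int(round(half * 10_000))) / 10_000.0, profile.t, profile.v
    )
    swept_dense = _cumtrapz(v_dense, 1e-4)
    swept_vis = np.interp(tq, np.arange(len(swept_dense)) * 1e-4, swept_dense)
    swept_occ = (math.pi / 2.0) * tq / half  # constant speed when occluded

    # anticlockwise screen angle, measured from +x axis; start of bottom
    # quadrant at -135 deg so the visible segments are centred on the bottom
    # (0 deg arc geometry) and top (180 deg) of the display
    segments = []
    vis_flags = []
    phi0 = -3.0 * math.pi / 4.0
    for seg in range(4):
        swept = swept_vis if seg % 2 == 0 else swept_occ
        segments.append(phi0 + swept)
        vis_flags.append(np.full(n_q, seg % 2 == 0))
        phi0 += math.pi / 2.0
    phi_cycle = np.concatenate(segments)
    vis_cycle = np.concatenate(vis_flags)
    phi = np.concatenate([phi_cycle + 2.0 * math.pi * c for c in range(n_cycles)])
    visible = np.tile(vis_cycle, n_cycles)
    t = np.arange(len(phi)) / sample_rate
    return StimulusTrack(
        experiment="circle_occluded",
        t=t,
        x_cm=R * np.cos(phi),
        y_cm=R * np.sin(phi),
        visible=visible,
        profile_index=profile_index,
        metadata={
            "rotation_period_s": 4.0 * half,
            "geometry": geom.to_dict(),
            "pivot_cm": [0.0, 0.0],
        },
    )


def visual_speed_deg(speed_cm_s: np.ndarray | float, geom: DisplayGeometry):
    """On-screen speed (cm/s) to visual angular velocity (deg/s), small-angle."""
    return np.degrees(np.asarray(speed_cm_s) / (100.0 * geom.viewing_distance))


def peak_visual_speed_deg(profile: VelocityProfile, geom: DisplayGeometry) -> float:
    """Maximum instantaneous visual angular velocity of the arc stimulus, deg/s.

    Tangential speed is R times the profile's angular speed; dividing by the
    viewing distance gives the visual rate at the display midpoint.
    """
    speed_cm = geom.radius_cm * float(np.max(profile.v))
    return float(visual_speed_deg(speed_cm, geom))


# ---------------------------------------------------------------------------
# Track I/O: CSV of samples plus JSON sidecar with condition metadata
# ---------------------------------------------------------------------------

_TRACK_HEADER = "t_s,x_cm,y_cm,visible"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_track(track: StimulusTrack, path) -> None:
    """Write track samples as CSV and condition metadata as a JSON sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_TRACK_HEADER + "\n")
        for i in range(len(track)):
            fh.write(
                f"{track.t[i]:.10g},{track.x_cm[i]:.10g},"
                f"{track.y_cm[i]:.10g},{int(track.visible[i])}\n"
            )
    side = {
        "experiment": track.experiment,
        "profile_index": track.profile_index,
        "metadata": track.metadata,
    }
    with open(_sidecar(path), "w") as fh:
        json.dump(side, fh, indent=1)


def read_track(path) -> StimulusTrack:
    """Read a track written by :func:`write_track`.

    Raises ValueError naming the offending line for malformed files.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if header != _TRACK_HEADER:
            raise ValueError(f"line 1: expected header {_TRACK_HEADER!r}, got {header!r}")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise ValueError(f"line {lineno}: expected 4 columns, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
    with open(_sidecar(path)) as fh:
        side = json.load(fh)
    if rows:
        arr = np.asarray(rows)
        t, x, y, vis = arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3] > 0.5
    else:
        t = x = y = np.empty(0)
        vis = np.empty(0, dtype=bool)
    return StimulusTrack(
        experiment=side["experiment"],
        t=t,
        x_cm=x,
        y_cm=y,
        visible=vis,
        profile_index=side.get("profile_index"),
        metadata=side.get("metadata", {}),
    )
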