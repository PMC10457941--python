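"""Signal containers and numerical primitives shared by both sensor pipelines.

Conventions
-----------
* Head frame: right-handed ISO-style anatomical frame — x anterior, y left,
  z superior. Sensor frames are related to it by a 3x3 rotation matrix.
* Units are SI internally (m/s^2, rad/s, rad/s^2). Accelerations expressed in
  gravitational units use 1 g = 9.80665 m/s^2 (:data:`G`).
* All series are uniformly sampled; a :class:`TimeSeries3` is an (N, 3) array
  plus a sample rate, a start time, a unit tag and a frame tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "G",
    "TimeSeries3",
    "Event",
    "HeadKinematics",
    "SaturationReport",
    "butterworth_lowpass",
    "five_point_stencil",
    "transform_accel_to_point",
    "resample_to_grid",
    "resample_to_times",
    "rotate",
    "resultant",
    "peak_resultant",
    "detect_saturation",
    "trigger_window",
    "validate_rotation",
]

#: Standard gravity, m/s^2 per g.
G = 9.80665

VALID_UNITS = {"m/s^2", "g", "rad/s", "rad/s^2"}
VALID_FRAMES = {"sensor", "head_ISO"}

# unit of the time-derivative of a signal in a given unit
_DERIV_UNIT = {"rad/s": "rad/s^2", "m/s": "m/s^2"}


@dataclass
class TimeSeries3:
    """A uniformly sampled tri-axial signal.

    Parameters
    ----------
    data
        Array of shape (N, 3); columns are the x, y, z components.
    rate
        Sample rate in Hz, strictly positive.
    start_time
        Time of the first sample, seconds.
    units
        One of ``m/s^2``, ``g``, ``rad/s``, ``rad/s^2``.
    frame
        ``sensor`` or ``head_ISO``.
    """

    data: np.ndarray
    rate: float
    start_time: float = 0.0
    units: str = "m/s^2"
    frame: str = "sensor"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2 or self.data.shape[1] != 3:
            raise InvalidInputError(
                f"tri-axial data must have shape (N, 3), got {self.data.shape}"
            )
        if not self.rate > 0:
            raise InvalidParameterError(f"sample_rate must be > 0, got {self.rate}")
        if self.units not in VALID_UNITS:
            raise InvalidParameterError(f"unknown units {self.units!r}")
        if self.frame not in VALID_FRAMES:
            raise InvalidParameterError(f"unknown frame {self.frame!r}")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def duration(self) -> float:
        return (self.n - 1) * self.dt

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.rate

    def with_data(self, data: np.ndarray, **changes) -> "TimeSeries3":
        """Copy of this series with new sample values (and optional tag changes)."""
        return replace(self, data=np.asarray(data, dtype=float), **changes)

    def slice(self, i0: int, i1: int) -> "TimeSeries3":
        """Samples ``[i0, i1)`` as a new series with the start time advanced."""
        i0 = max(i0, 0)
        return replace(
            self,
            data=self.data[i0:i1].copy(),
            start_time=self.start_time + i0 * self.dt,
        )

    def to_si(self) -> "TimeSeries3":
        """Convert g-unit acceleration to m/s^2 (other units pass through)."""
        if self.units == "g":
            return self.with_data(self.data * G, units="m/s^2")
        return self


@dataclass
class HeadKinematics:
    """Head centre-of-mass kinematics for one impact event.

    ``lin_acc_com`` (m/s^2), ``rot_vel`` (rad/s) and ``rot_acc`` (rad/s^2) are
    co-sampled tri-axial series in the head frame. ``peaks``, when present,
    holds peak resultant metrics measured on the native-rate processed data
    (before any decimation performed for paired comparisons): keys ``pla`` (g),
    ``prv`` (rad/s), ``pra`` (rad/s^2).
    """

    lin_acc_com: TimeSeries3
    rot_vel: TimeSeries3
    rot_acc: TimeSeries3
    peaks: dict = field(default_factory=dict)

    def peak_metrics(self) -> dict:
        """Peak resultant metrics; stored native-rate peaks take precedence."""
        if self.peaks:
            return dict(self.peaks)
        return {
            "pla": peak_resultant(self.lin_acc_com)[0] / G,
            "prv": peak_resultant(self.rot_vel)[0],
            "pra": peak_resultant(self.rot_acc)[0],
        }


@dataclass
class Event:
    """A triggered acquisition window.

    ``trigger_index`` is the sample index in the *original* record at which
    the trigger condition was met; the windowed channels carry their own
    start times, so the trigger sits ``pre_ms`` into the window unless the
    pre-trigger segment was truncated.
    """

    trigger_index: int
    pre_ms: float
    post_ms: float
    channels: dict
    qc_flags: set = field(default_factory=set)


@dataclass
class SaturationReport:
    """Outcome of a full-scale check on a tri-axial series."""

    flagged: bool
    axes: set
    indices: dict  # axis name -> np.ndarray of sample indices


def validate_rotation(R: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Check that ``R`` is a proper rotation (orthonormal, det +1)."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise InvalidInputError(f"rotation must be 3x3, got {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol):
        raise InvalidInputError("rotation matrix is not orthonormal")
    if not np.isclose(np.linalg.det(R), 1.0, atol=tol):
        raise InvalidInputError("rotation matrix must have determinant +1")
    return R


def rotate(ts: TimeSeries3, R: np.ndarray, frame: str | None = None) -> TimeSeries3:
    """Apply a constant rotation ``v -> R v`` to every sample."""
    R = validate_rotation(R)
    out = ts.with_data(ts.data @ R.T)
    if frame is not None:
        out.frame = frame
    return out


def butterworth_lowpass(ts: TimeSeries3, cutoff: float, order: int = 4) -> TimeSeries3:
    """Zero-phase low-pass Butterworth filter.

    The filter is applied forward and backward (``filtfilt``), which doubles
    the effective order and cancels phase lag so that symmetric pulses keep
    their peak timing. Edges are padded by reflection; pad length is at least
    three times the filter order.

    Parameters
    ----------
    cutoff
        -3 dB cutoff of the one-pass filter, Hz. Must be below Nyquist.
    order
        One-pass filter order (the paper-standard choice is 4).
    """
    nyq = ts.rate / 2.0
    if not 0 < cutoff < nyq:
        raise InvalidParameterError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={nyq} Hz)"
        )
    sos = _sig.butter(order, cutoff / nyq, output="sos")
    padlen = min(max(3 * order, 12), ts.n - 1)
    out = _sig.sosfiltfilt(sos, ts.data, axis=0, padtype="even", padlen=padlen)
    return ts.with_data(out)


def five_point_stencil(ts: TimeSeries3) -> TimeSeries3:
    """Component-wise time derivative via the five-point central stencil.

    Interior samples use ``(-f[i+2] + 8 f[i+1] - 8 f[i-1] + f[i-2]) / (12 dt)``,
    exact for polynomials of degree <= 4. The first two and last two samples
    use one-sided second-order differences so the output keeps the input
    length without extrapolation.
    """
    if ts.n < 5:
        raise InvalidInputError(f"need at least 5 samples to differentiate, got {ts.n}")
    f = ts.data
    h = ts.dt
    d = np.empty_like(f)
    d[2:-2] = (-f[4:] + 8.0 * f[3:-1] - 8.0 * f[1:-3] + f[:-4]) / (12.0 * h)
    # one-sided 3-point second-order differences at the edges
    for i in (0, 1):
        d[i] = (-3.0 * f[i] + 4.0 * f[i + 1] - f[i + 2]) / (2.0 * h)
    for i in (-1, -2):
        d[i] = (3.0 * f[i] - 4.0 * f[i - 1] + f[i - 2]) / (2.0 * h)
    units = _DERIV_UNIT.get(ts.units, ts.units)
    return ts.with_data(d, units=units)


def transform_accel_to_point(
    a_s: TimeSeries3,
    omega: TimeSeries3,
    alpha: TimeSeries3,
    r: np.ndarray,
) -> TimeSeries3:
    """Rigid-body transformation of linear acceleration to another point.

    For each sample, ``a_target = a_s + alpha x r + omega x (omega x r)``
    where ``r`` is the vector (metres) from the measurement point to the
    target point, expressed in the common frame of the three series.
    """
    if not (a_s.n == omega.n == alpha.n):
        raise InvalidInputError(
            f"series lengths differ: a={a_s.n}, omega={omega.n}, alpha={alpha.n}"
        )
    r = np.asarray(r, dtype=float).reshape(3)
    tangential = np.cross(alpha.data, r)
    centripetal = np.cross(omega.data, np.cross(omega.data, r[None, :]))
    return a_s.with_data(a_s.data + tangential + centripetal)


def resample_to_times(ts: TimeSeries3, times: np.ndarray, rate: float) -> TimeSeries3:
    """Linear interpolation of each component onto explicit sample times."""
    if ts.n == 0:
        raise InvalidInputError("cannot resample an empty series")
    times = np.asarray(times, dtype=float)
    src_t = ts.times()
    out = np.column_stack([np.interp(times, src_t, ts.data[:, k]) for k in range(3)])
    return replace(ts, data=out, rate=rate, start_time=float(times[0]))


def resample_to_grid(ts: TimeSeries3, target_rate: float) -> TimeSeries3:
    """Linearly interpolate onto a uniform grid at ``target_rate``.

    The new grid starts at the series start time and spans the same interval
    (the last grid point does not exceed the original end time).
    """
    if ts.n == 0:
        raise InvalidInputError("cannot resample an empty series")
    if target_rate > ts.rate:
        raise InvalidParameterError(
            f"target rate {target_rate} Hz exceeds source rate {ts.rate} Hz"
        )
    n_out = int(np.floor(ts.duration * target_rate + 1e-9)) + 1
    times = ts.start_time + np.arange(n_out) / target_rate
    return resample_to_times(ts, times, target_rate)


def resultant(ts: TimeSeries3) -> np.ndarray:
    """Per-sample Euclidean norm sqrt(x^2 + y^2 + z^2)."""
    return np.linalg.norm(ts.data, axis=1)


def peak_resultant(ts: TimeSeries3) -> tuple[float, float]:
    """Maximum of the resultant and the time at which it occurs.

    Ties are broken by the earliest instant (``argmax`` returns the first
    maximal sample).
    """
    if ts.n == 0:
        raise InvalidInputError("cannot take the peak of an empty series")
    res = resultant(ts)
    i = int(np.argmax(res))
    return float(res[i]), float(ts.start_time + i * ts.dt)


def detect_saturation(ts: TimeSeries3, full_scale: float) -> SaturationReport:
    """Flag samples at or beyond the sensor's full-scale range.

    A clipped sample reads exactly full scale, so the boundary counts as
    saturated: any sample with ``|component| >= full_scale`` on any axis is
    flagged. ``full_scale`` must be in the same units as the series.
    """
    if not full_scale > 0:
        raise InvalidParameterError("full_scale must be > 0")
    hits = np.abs(ts.data) >= full_scale
    axes = {name for k, name in enumerate("xyz") if hits[:, k].any()}
    indices = {
        name: np.flatnonzero(hits[:, k]) for k, name in enumerate("xyz") if hits[:, k].any()
    }
    return SaturationReport(flagged=bool(axes), axes=axes, indices=indices)


def trigger_window(
    raw: TimeSeries3,
    threshold_g: float = 10.0,
    pre_ms: float = 10.0,
    post_ms: float = 94.0,
) -> Event | None:
    """Detect an impact trigger on raw acceleration and cut the event window.

    The trigger is the first sample whose absolute value exceeds
    ``threshold_g`` on *any single axis* of the raw (unfiltered) signal. The
    window spans ``pre_ms`` before through ``post_ms`` after the trigger
    sample, the trigger sample itself belonging to the post segment
    (105 samples for the default 10 + 94 ms at 1 kHz). If fewer than
    ``pre_ms`` of data precede the trigger the window is truncated at the
    record start and ``missing_pretrigger`` is flagged; such events remain
    usable for peak analysis.

    Returns ``None`` when no sample exceeds the threshold (not an error).
    """
    data_g = raw.data / G if raw.units == "m/s^2" else raw.data
    over = np.abs(data_g) > threshold_g
    hit_rows = np.flatnonzero(over.any(axis=1))
    if hit_rows.size == 0:
        return None
    trig = int(hit_rows[0])
    n_pre = int(round(pre_ms * 1e-3 * raw.rate))
    n_post = int(round(post_ms * 1e-3 * raw.rate))
    i0 = trig - n_pre
    flags: set = set()
    if i0 < 0:
        flags.add("missing_pretrigger")
        i0 = 0
    i1 = min(trig + n_post + 1, raw.n)
    window = raw.slice(i0, i1)
    return Event(
        trigger_index=trig,
        pre_ms=pre_ms,
        post_ms=post_ms,
        channels={"accel": window},
        qc_flags=flags,
    )
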