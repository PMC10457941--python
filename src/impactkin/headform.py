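"""Reference-headform (ATD) processing: 3-2-2-2 accelerometer array to head
centre-of-mass kinematics.

The headform carries nine linear accelerometers: a tri-axial cluster at the
centre of mass plus a two-sensor pair at the end of each of three orthogonal
arms. Because the tangential term of rigid-body acceleration is linear in the
angular acceleration while the centripetal terms cancel pairwise between
opposing channel differences, the angular acceleration follows from channel
differences alone (Padgaonkar's nine-accelerometer method) — no gyroscope is
needed. Angular velocity is recovered by trapezoidal time integration from a
zero initial condition (a dropped headform starts from spin-free free fall).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig
from scipy.integrate import cumulative_trapezoid

from . import core
from .core import G, HeadKinematics, TimeSeries3
from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "ArrayGeometry",
    "CHANNEL_NAMES",
    "AtdChannels",
    "padgaonkar_angular_accel",
    "angular_velocity_from_accel",
    "process_atd_event",
]

#: Channel order: centre triax, then <sense-axis><arm-axis> pairs.
CHANNEL_NAMES = ("a0x", "a0y", "a0z", "axy", "axz", "ayx", "ayz", "azx", "azy")


@dataclass
class ArrayGeometry:
    """Arm lengths of the 3-2-2-2 nine-accelerometer array.

    ``rho_x``, ``rho_y``, ``rho_z`` are the distances (metres) from the
    centre of mass to the sensor pairs along +x, +y and +z. The default
    0.0635 m is a headform-scale nominal value; real arrays are configured
    explicitly.
    """

    rho_x: float = 0.0635
    rho_y: float = 0.0635
    rho_z: float = 0.0635

    def __post_init__(self) -> None:
        for name in ("rho_x", "rho_y", "rho_z"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0")

    def positions(self) -> dict:
        """Sensor positions (head frame, metres) keyed by channel name."""
        o = np.zeros(3)
        px = np.array([self.rho_x, 0.0, 0.0])
        py = np.array([0.0, self.rho_y, 0.0])
        pz = np.array([0.0, 0.0, self.rho_z])
        return {
            "a0x": o, "a0y": o, "a0z": o,
            # channel name = <sensed axis><arm axis>: e.g. azy senses z on the y-arm
            "axy": py, "axz": pz,
            "ayx": px, "ayz": pz,
            "azx": px, "azy": py,
        }


#: sensed axis index per channel (x=0, y=1, z=2); a0s senses s at the centre,
#: asA senses s on the A-arm
SENSE_AXIS = {
    name: "xyz".index(name[2] if name[1] == "0" else name[1]) for name in CHANNEL_NAMES
}


@dataclass
class AtdChannels:
    """Nine co-sampled scalar channels of the 3-2-2-2 array, m/s^2, head frame."""

    data: np.ndarray  # (N, 9) in CHANNEL_NAMES order
    rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 9:
            raise InvalidInputError(
                f"3-2-2-2 array data must have shape (N, 9), got {self.data.shape}"
            )

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, CHANNEL_NAMES.index(name)]

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.rate


def padgaonkar_angular_accel(channels: AtdChannels, geom: ArrayGeometry) -> TimeSeries3:
    """Angular acceleration from the nine-channel array.

    With ``a_sA`` the s-sensing channel on the A-arm and ``a0s`` the
    corresponding centre channel::

        alpha_x = [(azy - a0z)/rho_y - (ayz - a0y)/rho_z] / 2
        alpha_y = [(axz - a0x)/rho_z - (azx - a0z)/rho_x] / 2
        alpha_z = [(ayx - a0y)/rho_x - (axy - a0x)/rho_y] / 2

    The half-difference cancels the centripetal (omega-dependent) terms, so
    the output is exact for noise-free rigid motion and linear in the inputs.
    """
    c = channels.channel
    ax = ((c("azy") - c("a0z")) / geom.rho_y - (c("ayz") - c("a0y")) / geom.rho_z) / 2.0
    ay = ((c("axz") - c("a0x")) / geom.rho_z - (c("azx") - c("a0z")) / geom.rho_x) / 2.0
    az = ((c("ayx") - c("a0y")) / geom.rho_x - (c("axy") - c("a0x")) / geom.rho_y) / 2.0
    return TimeSeries3(
        np.column_stack([ax, ay, az]),
        rate=channels.rate,
        start_time=channels.start_time,
        units="rad/s^2",
        frame="head_ISO",
    )


def angular_velocity_from_accel(
    alpha: TimeSeries3, omega0: np.ndarray | None = None
) -> TimeSeries3:
    """Cumulative trapezoidal integration of angular acceleration.

    ``omega0`` is the angular velocity at the window start (default zero:
    a drop test begins in spin-free free fall).
    """
    w0 = np.zeros(3) if omega0 is None else np.asarray(omega0, dtype=float).reshape(3)
    w = cumulative_trapezoid(alpha.data, dx=alpha.dt, axis=0, initial=0.0) + w0
    return alpha.with_data(w, units="rad/s")


def process_atd_event(
    channels: AtdChannels,
    geom: ArrayGeometry,
    cutoff: float = 1000.0,
    filter_order: int = 4,
    out_rate: float = 1000.0,
) -> HeadKinematics:
    """Full headform chain: filter, invert the array, integrate, decimate.

    All nine channels are low-pass filtered (zero-phase 4th-order Butterworth,
    1 kHz cutoff at the native 50 kHz rate), angular acceleration is computed
    via the array inversion, angular velocity by trapezoidal integration, and
    the centre triax gives the centre-of-mass linear acceleration. Outputs are
    decimated to ``out_rate`` (every k-th sample; the cutoff is already at or
    below the decimated Nyquist) for comparison against the mouthguard, while
    the peak metrics stored on the result are read from the native-rate
    filtered series so that decimation phase cannot clip a narrow peak.
    """
    if channels.n < 5:
        raise InvalidInputError("ATD record too short to process")
    as_ts = TimeSeries3(
        channels.data[:, :3], rate=channels.rate, start_time=channels.start_time,
        units="m/s^2", frame="head_ISO",
    )
    # filter all nine channels identically (same zero-phase design as the
    # tri-axial helper, applied to the (N, 9) block at once)
    nyq = channels.rate / 2.0
    if not 0 < cutoff < nyq:
        raise InvalidParameterError(f"cutoff {cutoff} Hz must lie in (0, {nyq} Hz)")
    sos = _sig.butter(filter_order, cutoff / nyq, output="sos")
    padlen = min(max(3 * filter_order, 12), channels.n - 1)
    filt9 = _sig.sosfiltfilt(sos, channels.data, axis=0, padtype="even", padlen=padlen)
    fch = AtdChannels(filt9, rate=channels.rate, start_time=channels.start_time)

    alpha = padgaonkar_angular_accel(fch, geom)
    omega = angular_velocity_from_accel(alpha)
    a_com = as_ts.with_data(filt9[:, :3])

    peaks = {
        "pla": core.peak_resultant(a_com)[0] / G,
        "prv": core.peak_resultant(omega)[0],
        "pra": core.peak_resultant(alpha)[0],
    }

    step = int(round(channels.rate / out_rate))
    if step < 1:
        raise InvalidParameterError("out_rate exceeds the native channel rate")

    def _decimate(ts: TimeSeries3) -> TimeSeries3:
        out = ts.with_data(ts.data[::step])
        out.rate = ts.rate / step
        return out

    return HeadKinematics(
        lin_acc_com=_decimate(a_com),
        rot_vel=_decimate(omega),
        rot_acc=_decimate(alpha),
        peaks=peaks,
    )
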