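"""Instrumented-mouthguard (iMG) processing chain.

Raw dentition-mounted accelerometer and gyroscope channels are turned into
head centre-of-mass kinematics in five fixed stages:

1. resample the gyroscope (1666 Hz) onto the accelerometer grid (1 kHz);
2. rotate both channels from the sensor frame into the head frame;
3. low-pass filter the rotational velocity (zero-phase Butterworth, 160 Hz);
4. differentiate the *filtered* rotational velocity with the five-point
   stencil to obtain rotational acceleration;
5. low-pass filter the linear acceleration and transform it to the head
   centre of mass using the filtered rotational kinematics.

Stage order matters: differentiating before filtering amplifies broadband
sensor noise which the subsequent filter cannot fully undo, so the stencil is
always applied to the already-filtered velocity.

Saturation is assessed on the *raw* sensor-frame channels: a gyroscope sample
at or beyond +/-35 rad/s on any axis marks the whole event ``gyro_saturated``
and excludes it from analysis; the analogous accelerometer check uses the
+/-400 g range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import core
from .core import G, HeadKinematics, TimeSeries3
from .exceptions import ConfigError, InvalidInputError

__all__ = ["ImgSpec", "ImgEvent", "QCDecision", "process_img_event", "qc_event", "run_img_chain"]


@dataclass
class ImgSpec:
    """Sensor and mounting specification of the instrumented mouthguard.

    Defaults mirror a dentition-mounted device: +/-400 g, 1 kHz tri-axial
    accelerometer and +/-35 rad/s, 1666 Hz tri-axial gyroscope, both 12-bit,
    processed with a 160 Hz 4th-order low-pass. ``r_sensor_to_com`` is the
    vector (metres, head frame) from the sensor location to the head centre
    of mass; the default is a nominal dentition offset, not a measured value,
    and should be configured per device/headform.
    """

    accel_rate: float = 1000.0
    gyro_rate: float = 1666.0
    accel_range_g: float = 400.0
    gyro_range: float = 35.0
    resolution_bits: int = 12
    cutoff: float = 160.0
    filter_order: int = 4
    trigger_threshold_g: float = 10.0
    pre_ms: float = 10.0
    post_ms: float = 94.0
    r_sensor_to_com: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, -0.08])
    )
    R_sensor_to_head: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.r_sensor_to_com = np.asarray(self.r_sensor_to_com, dtype=float).reshape(3)
        try:
            self.R_sensor_to_head = core.validate_rotation(self.R_sensor_to_head)
        except InvalidInputError as exc:
            raise ConfigError(f"invalid sensor-to-head rotation: {exc}") from exc


@dataclass
class QCDecision:
    """Inclusion decision for one processed event."""

    include_peaks: bool
    include_timeseries: bool
    reasons: list


@dataclass
class ImgEvent:
    """A fully processed mouthguard event."""

    kinematics: HeadKinematics
    qc_flags: set
    raw_accel_window: TimeSeries3  # sensor frame, m/s^2; drives peak alignment
    trigger_time: float


def process_img_event(
    raw_accel: TimeSeries3, raw_gyro: TimeSeries3, spec: ImgSpec
) -> tuple[HeadKinematics, set]:
    """Run the five-stage mouthguard chain on raw (windowed) channels.

    ``raw_accel`` and ``raw_gyro`` are sensor-frame engineering-unit series
    covering the same event window (the gyroscope may be sampled at its own
    native rate). Returns head-frame kinematics at the accelerometer rate
    plus the set of QC flags raised by the raw-channel saturation checks.
    """
    if raw_accel.n < 5:
        raise InvalidInputError("accelerometer window too short to process")
    accel_si = raw_accel.to_si()
    gyro = raw_gyro
    if abs(gyro.start_time - accel_si.start_time) > 0.5:
        raise InvalidInputError("accelerometer and gyroscope windows do not overlap")

    flags: set = set()
    accel_fs = spec.accel_range_g if raw_accel.units == "g" else spec.accel_range_g * G
    if core.detect_saturation(raw_accel, accel_fs).flagged:
        flags.add("accel_saturated")
    if core.detect_saturation(raw_gyro, spec.gyro_range).flagged:
        flags.add("gyro_saturated")

    # (1) gyroscope onto the accelerometer's exact timebase
    gyro_1k = core.resample_to_times(gyro, accel_si.times(), accel_si.rate)
    # (2) rotate to the head frame
    R = spec.R_sensor_to_head
    a_head = core.rotate(accel_si, R, frame="head_ISO")
    w_head = core.rotate(gyro_1k, R, frame="head_ISO")
    # (3) filter rotational velocity, (4) differentiate it
    w_f = core.butterworth_lowpass(w_head, spec.cutoff, spec.filter_order)
    alpha = core.five_point_stencil(w_f)
    # (5) filter linear acceleration and transform to the centre of mass
    a_f = core.butterworth_lowpass(a_head, spec.cutoff, spec.filter_order)
    a_com = core.transform_accel_to_point(a_f, w_f, alpha, spec.r_sensor_to_com)

    hk = HeadKinematics(lin_acc_com=a_com, rot_vel=w_f, rot_acc=alpha)
    return hk, flags


def qc_event(flags: set) -> QCDecision:
    """Map QC flags to the analysis-inclusion policy.

    A gyroscope-saturated trial is excluded entirely (its rotational
    kinematics are unreliable on at least one axis). A trial missing its
    pre-trigger segment keeps its peaks (all axes still captured the peak)
    but is excluded from time-series error statistics, which need the full
    aligned window. Accelerometer saturation likewise excludes the trial.
    """
    reasons = []
    include_peaks = True
    include_ts = True
    if "gyro_saturated" in flags:
        include_peaks = False
        include_ts = False
        reasons.append("gyroscope range exceeded on at least one axis")
    if "accel_saturated" in flags:
        include_peaks = False
        include_ts = False
        reasons.append("accelerometer range exceeded on at least one axis")
    if "missing_pretrigger" in flags and include_peaks:
        include_ts = False
        reasons.append("pre-trigger samples missing; peaks only")
    return QCDecision(include_peaks=include_peaks, include_timeseries=include_ts, reasons=reasons)


def run_img_chain(
    raw_accel: TimeSeries3, raw_gyro: TimeSeries3, spec: ImgSpec | None = None
) -> ImgEvent | None:
    """Trigger, window and process a full mouthguard record.

    The trigger is evaluated on the raw sensor-frame accelerometer axes
    (threshold ``spec.trigger_threshold_g`` on any single axis). Returns
    ``None`` when the record never crosses the trigger threshold.
    """
    spec = ImgSpec() if spec is None else spec
    event = core.trigger_window(
        raw_accel, spec.trigger_threshold_g, spec.pre_ms, spec.post_ms
    )
    if event is None:
        return None
    accel_win = event.channels["accel"]
    t0, t1 = accel_win.start_time, accel_win.times()[-1]
    g_times = raw_gyro.times()
    j0 = int(np.searchsorted(g_times, t0 - raw_gyro.dt))
    j1 = int(np.searchsorted(g_times, t1 + raw_gyro.dt, side="right"))
    gyro_win = raw_gyro.slice(j0, j1)

    hk, flags = process_img_event(accel_win, gyro_win, spec)
    flags |= event.qc_flags
    trigger_time = raw_accel.start_time + event.trigger_index * raw_accel.dt
    return ImgEvent(
        kinematics=hk,
        qc_flags=flags,
        raw_accel_window=accel_win.to_si(),
        trigger_time=trigger_time,
    )
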