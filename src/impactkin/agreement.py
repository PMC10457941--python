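"""Sensor-agreement statistics for paired mouthguard/headform events.

Implements the standard method-comparison battery used to validate wearable
head-impact sensors against a laboratory reference:

* Lin's concordance correlation coefficient (CCC) with a Fisher-z 95% CI,
  and the unweighted mean of per-metric CCCs as the overall validity figure;
* coefficient of determination (R^2) of the simple linear regression;
* mean relative error of peak values (absolute-value convention by default,
  the signed version is reported alongside);
* Bland-Altman bias and 95% limits of agreement on percentage differences,
  with differences weighted towards the reference system (ATD - iMG, so a
  positive bias means the mouthguard underestimates);
* ordinary least products (reduced major axis) regression with analytic 95%
  CIs: fixed bias when the intercept CI excludes 0, proportional bias when
  the slope CI excludes 1;
* per-trial RMSE of resultant time-series over a 35 ms peak-aligned window,
  normalized (nRMSE) by the reference's range within that window.

The battery is exposed both as plain functions and as a statsmodels-style
``MethodAgreement(...).fit() -> AgreementResults`` pair whose ``summary()``
prints the per-metric table.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as _st

from .core import G, HeadKinematics, TimeSeries3, resultant
from .exceptions import (
    AlignmentError,
    DegenerateInputError,
    InsufficientDataError,
    InvalidInputError,
)
from .mouthguard import QCDecision

__all__ = [
    "METRICS",
    "AlignedPair",
    "TrialPair",
    "CCCResult",
    "BlandAltmanResult",
    "OLPResult",
    "MetricAgreement",
    "AgreementReport",
    "MethodAgreement",
    "AgreementResults",
    "ccc",
    "combine_ccc",
    "r_squared",
    "mean_relative_error",
    "bland_altman",
    "olp_regression",
    "align_threshold",
    "align_peak",
    "rmse_nrmse",
    "build_report",
]

#: metric key -> (HeadKinematics attribute, display unit, scale to display unit)
METRICS = {
    "pla": ("lin_acc_com", "g", 1.0 / G),
    "prv": ("rot_vel", "rad/s", 1.0),
    "pra": ("rot_acc", "rad/s^2", 1.0),
}


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def _check_pair(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise InvalidInputError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < min_n:
        raise InvalidInputError(f"need at least {min_n} pairs, got {x.size}")
    return x, y


@dataclass
class CCCResult:
    estimate: float
    ci95: tuple

    def __iter__(self):
        return iter((self.estimate, self.ci95))


def ccc(x, y, alpha: float = 0.05) -> CCCResult:
    """Lin's concordance correlation coefficient with a Fisher-z 95% CI.

    Uses population (1/n) moments, matching Lin's original estimator:
    ``rho_c = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2)``.
    """
    x, y = _check_pair(x, y)
    n = x.size
    sx2 = x.var()
    sy2 = y.var()
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0.0:
        raise DegenerateInputError("both series constant with equal means")
    est = 2.0 * sxy / denom

    if sx2 == 0.0 or sy2 == 0.0 or n < 4:
        return CCCResult(float(est), (float("nan"), float("nan")))
    r = sxy / np.sqrt(sx2 * sy2)
    if abs(est) >= 1.0 - 1e-15 or abs(r) >= 1.0 - 1e-15 or r == 0.0:
        return CCCResult(float(est), (float(est), float(est)))
    u = (x.mean() - y.mean()) / (sx2 * sy2) ** 0.25
    c2 = est ** 2
    var_z = (
        (1.0 - r ** 2) * c2 / ((1.0 - c2) * r ** 2)
        + 2.0 * est ** 3 * (1.0 - est) * u ** 2 / (r * (1.0 - c2) ** 2)
        - est ** 4 * u ** 4 / (2.0 * r ** 2 * (1.0 - c2) ** 2)
    ) / (n - 2)
    var_z = max(var_z, 0.0)
    z = np.arctanh(est)
    zc = _st.norm.ppf(1.0 - alpha / 2.0)
    lo, hi = np.tanh(z - zc * np.sqrt(var_z)), np.tanh(z + zc * np.sqrt(var_z))
    return CCCResult(float(est), (float(lo), float(hi)))


def combine_ccc(values) -> float:
    """Overall validity figure: unweighted arithmetic mean of per-metric CCCs."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise InvalidInputError("no CCC values to combine")
    return float(values.mean())


def r_squared(x, y) -> float:
    """Squared Pearson correlation (R^2 of the simple linear regression)."""
    x, y = _check_pair(x, y)
    if x.var() == 0.0 or y.var() == 0.0:
        raise DegenerateInputError("R^2 undefined for zero-variance input")
    r = np.corrcoef(x, y)[0, 1]
    return float(r ** 2)


@dataclass
class RelativeErrorResult:
    mean_pct: float
    sd_pct: float
    mean_signed_pct: float
    sd_signed_pct: float


def mean_relative_error(peaks_ref, peaks_test) -> RelativeErrorResult:
    """Mean +/- SD percentage difference of peaks relative to the reference.

    The headline figure uses the absolute-value convention
    ``|ref - test| / ref * 100``; the signed version (positive = test
    underestimates) is carried alongside.
    """
    x, y = _check_pair(peaks_ref, peaks_test, min_n=1)
    if np.any(x <= 0):
        raise InvalidInputError("reference peaks must be positive")
    signed = (x - y) / x * 100.0
    ab = np.abs(signed)
    sd = lambda v: float(v.std(ddof=1)) if v.size > 1 else 0.0
    return RelativeErrorResult(float(ab.mean()), sd(ab), float(signed.mean()), sd(signed))


@dataclass
class BlandAltmanResult:
    bias: float
    loa_lower: float
    loa_upper: float
    bias_ci95: tuple
    sd: float
    mode: str


def bland_altman(x_ref, y_test, mode: str = "percent") -> BlandAltmanResult:
    """Bland-Altman bias and 95% limits of agreement.

    Differences are ``d_i = ref_i - test_i`` (positive bias = the test method
    underestimates). In ``percent`` mode each difference is expressed
    relative to the reference value, ``d_i / ref_i * 100``. The limits are
    ``bias +/- 1.96 SD(d)`` (sample SD); the bias CI uses the t-distribution.
    """
    x, y = _check_pair(x_ref, y_test)
    d = x - y
    if mode == "percent":
        if np.any(x == 0):
            raise InvalidInputError("percent differences undefined at reference = 0")
        d = d / x * 100.0
    elif mode != "absolute":
        raise InvalidInputError(f"unknown mode {mode!r}")
    n = d.size
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_lo, loa_hi = bias - 1.96 * sd, bias + 1.96 * sd
    tcrit = _st.t.ppf(0.975, n - 1)
    half = tcrit * sd / np.sqrt(n)
    return BlandAltmanResult(bias, float(loa_lo), float(loa_hi),
                             (bias - half, bias + half), sd, mode)


@dataclass
class OLPResult:
    slope: float
    intercept: float
    slope_ci95: tuple
    intercept_ci95: tuple
    fixed_bias: bool
    proportional_bias: bool
    r: float


def olp_regression(x_ref, y_test, alpha: float = 0.05) -> OLPResult:
    """Ordinary least products (reduced major axis) regression.

    ``slope = sign(r) s_y / s_x``, ``intercept = ybar - slope xbar``. The
    slope CI uses the standard model-II analytic form
    ``b (sqrt(B + 1) +/- sqrt(B))`` with ``B = F_{1-alpha}(1, n-2)
    (1 - r^2) / (n - 2)``; the intercept CI is evaluated at the slope CI
    endpoints. A fixed bias is declared when the intercept CI excludes 0,
    a proportional bias when the slope CI excludes 1.
    """
    x, y = _check_pair(x_ref, y_test)
    n = x.size
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("OLP regression undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    sign = -1.0 if r < 0 else 1.0
    slope = sign * sy / sx
    intercept = float(y.mean() - slope * x.mean())

    F = _st.f.ppf(1.0 - alpha, 1, n - 2)
    B = F * (1.0 - r ** 2) / (n - 2)
    lo_f, hi_f = np.sqrt(B + 1.0) - np.sqrt(B), np.sqrt(B + 1.0) + np.sqrt(B)
    s_bounds = sorted((slope * lo_f, slope * hi_f))
    i_bounds = sorted((y.mean() - s_bounds[0] * x.mean(), y.mean() - s_bounds[1] * x.mean()))
    fixed = not (i_bounds[0] <= 0.0 <= i_bounds[1])
    proportional = not (s_bounds[0] <= 1.0 <= s_bounds[1])
    return OLPResult(float(slope), intercept, tuple(map(float, s_bounds)),
                     tuple(map(float, i_bounds)), fixed, proportional, r)


# ---------------------------------------------------------------------------
# time alignment of paired events
# ---------------------------------------------------------------------------

@dataclass
class AlignedPair:
    """Co-sampled windows of both systems' kinematics."""

    img: HeadKinematics
    atd: HeadKinematics
    alignment: str  # threshold_35ms | peak_rmse
    n: int
    window: float  # seconds


def _slice_hk(hk: HeadKinematics, i0: int, i1: int) -> HeadKinematics:
    return HeadKinematics(
        lin_acc_com=hk.lin_acc_com.slice(i0, i1),
        rot_vel=hk.rot_vel.slice(i0, i1),
        rot_acc=hk.rot_acc.slice(i0, i1),
        peaks=dict(hk.peaks),
    )


def _threshold_start(hk: HeadKinematics, threshold_g: float, pre_samples: int) -> int:
    res_g = resultant(hk.lin_acc_com) / G
    hits = np.flatnonzero(res_g > threshold_g)
    if hits.size == 0:
        raise AlignmentError(f"resultant never crosses {threshold_g} g")
    i0 = int(hits[0]) - pre_samples
    if i0 < 0:
        raise AlignmentError("fewer than 10 ms of data before the threshold crossing")
    return i0


def align_threshold(
    img: HeadKinematics,
    atd: HeadKinematics,
    threshold_g: float = 10.0,
    pre_ms: float = 10.0,
    window_ms: float = 35.0,
) -> AlignedPair:
    """Align both traces so 10 ms before their 10 g crossing is t = 0.

    The threshold is applied to the resultant centre-of-mass linear
    acceleration of each system independently; ``window_ms`` of data from
    that origin are kept (35 samples at 1 kHz).
    """
    n = int(round(window_ms * 1e-3 * img.lin_acc_com.rate))
    pre = int(round(pre_ms * 1e-3 * img.lin_acc_com.rate))
    out = []
    for hk in (img, atd):
        i0 = _threshold_start(hk, threshold_g, pre)
        if i0 + n > hk.lin_acc_com.n:
            raise AlignmentError("record too short for the comparison window")
        out.append(_slice_hk(hk, i0, i0 + n))
    return AlignedPair(out[0], out[1], "threshold_35ms", n, n / img.lin_acc_com.rate)


def align_peak(
    img_raw_accel: TimeSeries3,
    img: HeadKinematics,
    atd: HeadKinematics,
    pre_ms: float = 10.0,
    post_ms: float = 25.0,
) -> AlignedPair:
    """Peak-based alignment used for RMSE/nRMSE.

    The dominant axis is the raw (unfiltered) mouthguard accelerometer axis
    with the largest absolute value (ties broken in x, y, z order); the trial
    window spans 10 ms before to 25 ms after the raw absolute peak in that
    axis (35 samples at 1 kHz) and is applied to both systems' traces on the
    common timebase.
    """
    rate = img.lin_acc_com.rate
    n = int(round((pre_ms + post_ms) * 1e-3 * rate))

    absraw = np.abs(img_raw_accel.data)
    dominant = int(np.argmax(absraw.max(axis=0)))
    ipk = int(np.argmax(absraw[:, dominant]))
    t0 = img_raw_accel.start_time + ipk * img_raw_accel.dt - pre_ms * 1e-3

    out = []
    for hk in (img, atd):
        series = hk.lin_acc_com
        i0 = int(round((t0 - series.start_time) * series.rate))
        if i0 < 0 or i0 + n > series.n:
            raise AlignmentError("record too short for the peak-aligned window")
        out.append(_slice_hk(hk, i0, i0 + n))
    return AlignedPair(out[0], out[1], "peak_rmse", n, n / rate)


def rmse_nrmse(pair: AlignedPair, metric: str) -> tuple[float, float]:
    """Per-trial RMSE and normalized RMSE of resultant traces.

    ``RMSE = sqrt( sum_i (iMG_i - ATD_i)^2 / n )`` on the resultant of the
    chosen metric over the aligned window; ``nRMSE = RMSE / (ATD_max -
    ATD_min) * 100`` with the extrema taken over the reference resultant in
    the window. PLA is evaluated in g, rotational metrics in SI.
    """
    attr, _, scale = METRICS[metric]
    a = resultant(getattr(pair.img, attr)) * scale
    b = resultant(getattr(pair.atd, attr)) * scale
    if a.size != b.size:
        raise InvalidInputError("aligned windows have different lengths")
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    rng = float(b.max() - b.min())
    if rng == 0.0:
        raise InvalidInputError("flat reference trace: nRMSE undefined")
    return rmse, rmse / rng * 100.0


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class TrialPair:
    """One processed trial: both systems' kinematics plus QC bookkeeping."""

    img: HeadKinematics
    atd: HeadKinematics
    img_raw_accel: TimeSeries3
    qc: QCDecision
    trial_id: str = ""
    truth_peaks: dict = field(default_factory=dict)


@dataclass
class MetricAgreement:
    """Agreement statistics for one kinematic metric (a Table-2-style row)."""

    metric: str
    unit: str
    n_peaks: int
    ccc: float
    ccc_ci95: tuple
    r_squared: float
    mre_pct: float
    mre_sd_pct: float
    mre_signed_pct: float
    mre_signed_sd_pct: float
    bias_pct: float
    bias_ci95: tuple
    loa_lower_pct: float
    loa_upper_pct: float
    olp_slope: float
    olp_slope_ci95: tuple
    olp_intercept: float
    olp_intercept_ci95: tuple
    fixed_bias: bool
    proportional_bias: bool
    n_timeseries: int = 0
    rmse: float = float("nan")
    rmse_sd: float = float("nan")
    nrmse_pct: float = float("nan")
    nrmse_sd_pct: float = float("nan")


@dataclass
class AgreementReport:
    """Per-metric agreement statistics plus the combined validity figure."""

    metrics: dict  # metric name -> MetricAgreement
    combined_ccc: float
    counts: dict = field(default_factory=dict)
    schema_version: str = "1"

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "combined_ccc": self.combined_ccc,
            "counts": dict(self.counts),
            "metrics": {k: asdict(v) for k, v in self.metrics.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_frame(self) -> pd.DataFrame:
        """Display table, Table-2 style (CCC to 3 dp, the rest to 2 dp)."""
        rows = []
        for m in self.metrics.values():
            rows.append({
                "metric": f"{m.metric.upper()} ({m.unit})",
                "n": m.n_peaks,
                "CCC": round(m.ccc, 3),
                "CCC 95% CI": f"{m.ccc_ci95[0]:.3f}-{m.ccc_ci95[1]:.3f}",
                "MRE %": round(m.mre_pct, 2),
                "RMSE": round(m.rmse, 2),
                "nRMSE %": round(m.nrmse_pct, 2),
                "Bias %": round(m.bias_pct, 2),
                "LoA lower %": round(m.loa_lower_pct, 2),
                "LoA upper %": round(m.loa_upper_pct, 2),
                "OLP slope": round(m.olp_slope, 2),
                "OLP intercept": round(m.olp_intercept, 2),
                "fixed bias": m.fixed_bias,
                "prop. bias": m.proportional_bias,
            })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class MethodAgreement:
    """Method-comparison analysis of paired mouthguard/headform trials.

    Parameters
    ----------
    trials
        Processed :class:`TrialPair` objects. QC decisions on each trial
        control inclusion: peaks enter the peak statistics only when
        ``qc.include_peaks``; a trial enters the time-series (RMSE)
        statistics only when ``qc.include_timeseries``.
    """

    def __init__(self, trials):
        self.trials = list(trials)

    def fit(self) -> "AgreementResults":
        peak_trials = [t for t in self.trials if t.qc.include_peaks]
        ts_trials = [t for t in self.trials if t.qc.include_timeseries]
        if len(peak_trials) < 3:
            raise InsufficientDataError(
                f"need at least 3 QC-included trials, got {len(peak_trials)}"
            )

        peak_rows = []
        for t in peak_trials:
            row = {"trial_id": t.trial_id}
            imgp = t.img.peak_metrics()
            atdp = t.atd.peak_metrics()
            for m in METRICS:
                row[f"atd_{m}"] = atdp[m]
                row[f"img_{m}"] = imgp[m]
                if t.truth_peaks:
                    row[f"truth_{m}"] = t.truth_peaks[m]
            peak_rows.append(row)
        peaks = pd.DataFrame(peak_rows)

        ts_rows = []
        for t in ts_trials:
            try:
                pair = align_peak(t.img_raw_accel, t.img, t.atd)
            except AlignmentError:
                continue
            row = {"trial_id": t.trial_id}
            for m in METRICS:
                row[f"rmse_{m}"], row[f"nrmse_{m}"] = rmse_nrmse(pair, m)
            ts_rows.append(row)
        ts = pd.DataFrame(ts_rows)

        metrics = {}
        for m, (_, unit, _) in METRICS.items():
            x = peaks[f"atd_{m}"].to_numpy()
            y = peaks[f"img_{m}"].to_numpy()
            c = ccc(x, y)
            mre = mean_relative_error(x, y)
            ba = bland_altman(x, y, mode="percent")
            olp = olp_regression(x, y)
            ma = MetricAgreement(
                metric=m, unit=unit, n_peaks=x.size,
                ccc=c.estimate, ccc_ci95=c.ci95,
                r_squared=r_squared(x, y),
                mre_pct=mre.mean_pct, mre_sd_pct=mre.sd_pct,
                mre_signed_pct=mre.mean_signed_pct, mre_signed_sd_pct=mre.sd_signed_pct,
                bias_pct=ba.bias, bias_ci95=ba.bias_ci95,
                loa_lower_pct=ba.loa_lower, loa_upper_pct=ba.loa_upper,
                olp_slope=olp.slope, olp_slope_ci95=olp.slope_ci95,
                olp_intercept=olp.intercept, olp_intercept_ci95=olp.intercept_ci95,
                fixed_bias=olp.fixed_bias, proportional_bias=olp.proportional_bias,
            )
            if len(ts):
                r = ts[f"rmse_{m}"].to_numpy()
                nr = ts[f"nrmse_{m}"].to_numpy()
                sd = lambda v: float(v.std(ddof=1)) if v.size > 1 else 0.0
                ma.n_timeseries = r.size
                ma.rmse, ma.rmse_sd = float(r.mean()), sd(r)
                ma.nrmse_pct, ma.nrmse_sd_pct = float(nr.mean()), sd(nr)
            metrics[m] = ma

        report = AgreementReport(
            metrics=metrics,
            combined_ccc=combine_ccc([metrics[m].ccc for m in METRICS]),
            counts={
                "total": len(self.trials),
                "included_peaks": len(peak_trials),
                "included_timeseries": int(len(ts)),
                "excluded": len(self.trials) - len(peak_trials),
            },
        )
        return AgreementResults(report, peaks, ts)


class AgreementResults:
    """Fitted agreement analysis: the report plus per-trial tables."""

    def __init__(self, report: AgreementReport, peaks: pd.DataFrame, timeseries: pd.DataFrame):
        self.report = report
        self.peaks = peaks
        self.timeseries = timeseries

    @property
    def combined_ccc(self) -> float:
        return self.report.combined_ccc

    def summary(self) -> str:
        lines = [
            "Sensor agreement report (mouthguard vs reference headform)",
            f"trials: {self.report.counts}",
            f"combined CCC: {self.report.combined_ccc:.3f}",
            "",
            self.report.to_frame().to_string(index=False),
        ]
        return "\n".join(lines)

    def plot_scatter(self, metric: str, ax=None):
        """Identity-line scatter of reference vs mouthguard peaks."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.peaks[f"atd_{metric}"]
        y = self.peaks[f"img_{metric}"]
        ax.scatter(x, y, s=18)
        lim = [min(x.min(), y.min()), max(x.max(), y.max())]
        ax.plot(lim, lim, "k--", lw=1)
        unit = METRICS[metric][1]
        ax.set_xlabel(f"ATD {metric.upper()} ({unit})")
        ax.set_ylabel(f"iMG {metric.upper()} ({unit})")
        return ax

    def plot_bland_altman(self, metric: str, ax=None):
        """Bland-Altman percent-difference plot with bias and LoA lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.peaks[f"atd_{metric}"].to_numpy()
        y = self.peaks[f"img_{metric}"].to_numpy()
        mean = (x + y) / 2.0
        diff = (x - y) / x * 100.0
        m = self.report.metrics[metric]
        ax.scatter(mean, diff, s=18)
        ax.axhline(m.bias_pct, color="k")
        ax.axhline(m.loa_lower_pct, color="k", ls="--")
        ax.axhline(m.loa_upper_pct, color="k", ls="--")
        unit = METRICS[metric][1]
        ax.set_xlabel(f"mean of methods ({unit})")
        ax.set_ylabel("ATD - iMG difference (%)")
        return ax


def build_report(trials) -> AgreementReport:
    """Assemble the full per-metric agreement report from processed trials."""
    return MethodAgreement(trials).fit().report
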