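"""Pupil-trace preprocessing: from raw per-frame segmenter output to
volume-aligned seed regressors.

A video pupil segmenter emits, per camera frame, a pupil diameter and a
segmentation confidence in [0, 1]; frames where segmentation failed are
flagged missing.  This module turns such a trace into the two regressors
used to seed connectivity analysis:

1. quality-control gate on the fraction of unsuccessful and of
   high-confidence frames,
2. masking of low-confidence frames,
3. sliding-window smoothing (57 frames by default),
4. convolution with the canonical double-gamma haemodynamic response
   function (HRF),
5. linear interpolation to the acquisition time of each fMRI volume,
6. first temporal derivative of the interpolated series.

The diameter series tracks tonic arousal; its first derivative tracks
phasic arousal events.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "PupilTrace",
    "QCReport",
    "SeedSeries",
    "HRFParams",
    "SeedConfig",
    "RejectedSubjectError",
    "qc_evaluate",
    "mask_low_confidence",
    "smooth_sliding",
    "canonical_hrf",
    "convolve_hrf",
    "resample_to_volumes",
    "differentiate",
    "build_seed_pair",
    "default_volume_times",
    "read_trace_tsv",
    "write_trace_tsv",
    "write_seed_tsv",
    "read_seed_tsv",
]


class RejectedSubjectError(ValueError):
    """Raised when a trace fails the eye-tracking quality-control gate."""

    def __init__(self, report: "QCReport"):
        self.report = report
        super().__init__(
            "trace rejected by QC gate: "
            f"frac_unsuccessful={report.frac_unsuccessful:.3f} "
            f"(must be < {report.max_unsuccessful}), "
            f"frac_high_confidence={report.frac_high_confidence:.3f} "
            f"(must be >= {report.min_high_conf})"
        )


@dataclass
class PupilTrace:
    """Per-frame pupil record: time (s), diameter (a.u.), segmentation
    confidence in [0, 1] and a missing flag.

    ``diameter`` at missing frames is ignored by every downstream
    operation; it may be NaN.
    """

    time: np.ndarray
    diameter: np.ndarray
    confidence: np.ndarray
    missing: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        n = self.time.size
        if n == 0:
            raise ValueError("empty pupil trace")
        for name in ("diameter", "confidence", "missing"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"field {name!r} length does not match time")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.time.size

    @property
    def frame_interval(self) -> float:
        """Median inter-frame interval in seconds."""
        if self.n_frames < 2:
            raise ValueError("need at least two frames for a frame interval")
        return float(np.median(np.diff(self.time)))

    def is_uniform(self, rtol: float = 0.01) -> bool:
        """True when frame spacing is uniform to within ``rtol`` of the
        median interval."""
        if self.n_frames < 3:
            return True
        d = np.diff(self.time)
        med = np.median(d)
        return bool(np.all(np.abs(d - med) <= rtol * med))


@dataclass(frozen=True)
class QCReport:
    """Outcome of the eye-tracking quality gate.

    ``passed`` is true iff the unsuccessful-frame fraction is strictly
    below ``max_unsuccessful`` and the fraction of frames with confidence
    strictly above ``conf_thresh`` is at least ``min_high_conf``.
    """

    frac_unsuccessful: float
    frac_high_confidence: float
    passed: bool
    conf_thresh: float = 0.9
    max_unsuccessful: float = 0.20
    min_high_conf: float = 0.75

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SeedSeries:
    """One regressor value per fMRI volume.

    ``kind`` is ``"diameter"`` (tonic) or ``"derivative"`` (phasic).
    """

    value: np.ndarray
    volume_time: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=float)
        self.volume_time = np.asarray(self.volume_time, dtype=float)
        if self.value.shape != self.volume_time.shape:
            raise ValueError("value / volume_time length mismatch")
        if self.kind not in ("diameter", "derivative"):
            raise ValueError(f"unknown seed kind {self.kind!r}")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("seed series contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.value.size


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF parameters, all in seconds except the
    dimensionless undershoot ratio.

    Defaults are the standard canonical values: response peaking at 6 s,
    undershoot at 16 s, unit dispersions, undershoot one sixth of the
    peak, 32 s support.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length: float = 32.0

    def __post_init__(self) -> None:
        for name in (
            "peak_delay",
            "undershoot_delay",
            "peak_dispersion",
            "undershoot_dispersion",
            "undershoot_ratio",
            "length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"HRF parameter {name} must be positive")


@dataclass(frozen=True)
class SeedConfig:
    """Parameters of the full seed-construction chain."""

    conf_thresh: float = 0.9
    max_unsuccessful: float = 0.20
    min_high_conf: float = 0.75
    window: int = 57
    smoother: str = "mean"  # "mean" or "median"
    hrf: HRFParams = field(default_factory=HRFParams)


# ---------------------------------------------------------------------------
# operations


def qc_evaluate(
    trace: PupilTrace,
    conf_thresh: float = 0.9,
    max_unsuccessful: float = 0.20,
    min_high_conf: float = 0.75,
) -> QCReport:
    """Evaluate the quality-control gate on a raw trace.

    A subject passes when strictly less than ``max_unsuccessful`` of the
    frames are unsuccessful (missing) and at least ``min_high_conf`` of
    the frames have confidence above ``conf_thresh``.  The trace is never
    modified.
    """
    frac_unsuccessful = float(np.mean(trace.missing))
    frac_high = float(np.mean(trace.confidence > conf_thresh))
    passed = (frac_unsuccessful < max_unsuccessful) and (frac_high >= min_high_conf)
    return QCReport(
        frac_unsuccessful=frac_unsuccessful,
        frac_high_confidence=frac_high,
        passed=passed,
        conf_thresh=conf_thresh,
        max_unsuccessful=max_unsuccessful,
        min_high_conf=min_high_conf,
    )


def mask_low_confidence(trace: PupilTrace, conf_thresh: float = 0.9) -> PupilTrace:
    """Flag every frame with confidence strictly below ``conf_thresh`` as
    missing; all other fields are unchanged."""
    if not (0 < conf_thresh <= 1):
        raise ValueError("conf_thresh must be in (0, 1]")
    missing = trace.missing | (trace.confidence < conf_thresh)
    return replace(trace, missing=missing, meta=dict(trace.meta))


def smooth_sliding(trace: PupilTrace, window: int = 57, smoother: str = "mean") -> PupilTrace:
    """Centered sliding-window smoother over non-missing diameters.

    Each frame's diameter becomes the mean (or median) of the non-missing
    diameters inside the centered ``window``-frame window, truncated at
    the trace edges.  A frame whose whole window is missing stays
    missing; otherwise the smoothed value fills it and the missing flag
    is cleared.
    """
    if window % 2 == 0 or window <= 0:
        raise ValueError("window must be an odd positive integer")
    if window > trace.n_frames:
        raise ValueError("window larger than trace")
    valid = ~trace.missing
    vals = np.where(valid, trace.diameter, 0.0)
    if smoother == "mean":
        ones = np.ones(window)
        sums = np.convolve(vals, ones, mode="same")
        counts = np.convolve(valid.astype(float), ones, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = sums / counts
        still_missing = counts < 0.5
    elif smoother == "median":
        half = window // 2
        padded = np.full(trace.n_frames + 2 * half, np.nan)
        padded[half : half + trace.n_frames] = np.where(valid, trace.diameter, np.nan)
        win = np.lib.stride_tricks.sliding_window_view(padded, window)
        with np.errstate(invalid="ignore"):
            counts = np.sum(~np.isnan(win), axis=1)
            sm = np.where(counts > 0, np.nanmedian(win, axis=1), np.nan)
        still_missing = counts == 0
    else:
        raise ValueError(f"unknown smoother {smoother!r}")
    diameter = np.where(still_missing, trace.diameter, sm)
    return replace(trace, diameter=diameter, missing=still_missing, meta=dict(trace.meta))


def canonical_hrf(params: HRFParams | None = None, dt: float = 1.0 / 60.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds over the
    kernel support, peak-normalised to a maximum of 1.

    The kernel is a difference of two gamma densities: a positive
    response lobe and a delayed undershoot scaled by the undershoot
    ratio.  Peak normalisation makes the samples invariant to a common
    rescaling of all time parameters and ``dt``.
    """
    if params is None:
        params = HRFParams()
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, params.length + dt / 2, dt)
    peak = sp_stats.gamma.pdf(
        t, params.peak_delay / params.peak_dispersion, scale=params.peak_dispersion
    )
    under = sp_stats.gamma.pdf(
        t,
        params.undershoot_delay / params.undershoot_dispersion,
        scale=params.undershoot_dispersion,
    )
    kernel = peak - params.undershoot_ratio * under
    return kernel / kernel.max()


def convolve_hrf(trace: PupilTrace, kernel: np.ndarray, pad: str = "zero") -> PupilTrace:
    """Causal discrete convolution of a uniformly sampled trace with an
    HRF kernel; output has the input's length (kernel tail truncated).

    Missing frames are linearly bridged first (edge gaps take the nearest
    observed value) because discrete convolution needs a complete uniform
    series.  Indices of bridged frames are recorded in
    ``meta["bridged_frames"]``; the returned trace has no missing frames.

    ``pad`` selects the pre-recording assumption: ``"zero"`` is the pure
    convolution identity (signal zero before the first frame);
    ``"edge"`` assumes the signal sat at its initial value beforehand,
    which removes the onset transient (a constant trace then stays
    constant, up to the kernel's gain).
    """
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 1 or kernel.size == 0:
        raise ValueError("kernel must be a nonempty 1-D array")
    if kernel.size > trace.n_frames:
        raise ValueError("kernel longer than trace")
    if not trace.is_uniform():
        raise ValueError("trace must be uniformly sampled (1% tolerance)")
    if pad not in ("zero", "edge"):
        raise ValueError("pad must be 'zero' or 'edge'")
    valid = ~trace.missing
    if not valid.any():
        raise ValueError("cannot convolve an all-missing trace")
    bridged = trace.diameter.copy()
    if not valid.all():
        bridged[~valid] = np.interp(
            trace.time[~valid], trace.time[valid], trace.diameter[valid]
        )
    if pad == "edge":
        padded = np.concatenate([np.full(kernel.size - 1, bridged[0]), bridged])
        out = np.convolve(padded, kernel, mode="full")[
            kernel.size - 1 : kernel.size - 1 + trace.n_frames
        ]
    else:
        out = np.convolve(bridged, kernel, mode="full")[: trace.n_frames]
    meta = dict(trace.meta)
    meta["bridged_frames"] = np.flatnonzero(~valid)
    return replace(
        trace,
        diameter=out,
        missing=np.zeros(trace.n_frames, dtype=bool),
        meta=meta,
    )


def resample_to_volumes(trace: PupilTrace, volume_times: np.ndarray) -> SeedSeries:
    """Linearly interpolate the trace at each volume acquisition time."""
    volume_times = np.asarray(volume_times, dtype=float)
    lo, hi = trace.time[0], trace.time[-1]
    bad = np.flatnonzero((volume_times < lo) | (volume_times > hi))
    if bad.size:
        raise ValueError(
            f"volume {bad[0]} at t={volume_times[bad[0]]:.3f}s lies outside the "
            f"trace span [{lo:.3f}, {hi:.3f}]s"
        )
    value = np.interp(volume_times, trace.time, trace.diameter)
    return SeedSeries(value=value, volume_time=volume_times, kind="diameter")


def differentiate(seed: SeedSeries) -> SeedSeries:
    """First temporal derivative of a diameter seed: central differences
    on interior points, one-sided at the ends."""
    if seed.kind != "diameter":
        raise ValueError("differentiate expects a diameter seed")
    if seed.n_volumes < 3:
        raise ValueError("need at least 3 volumes to differentiate")
    deriv = np.gradient(seed.value, seed.volume_time, edge_order=2)
    return SeedSeries(
        value=deriv, volume_time=seed.volume_time.copy(), kind="derivative",
        meta=dict(seed.meta),
    )


def default_volume_times(n_volumes: int, tr: float, onset: float | None = None) -> np.ndarray:
    """Acquisition time of each volume; by default the slice-timing
    reference at TR/2 after scan start."""
    if n_volumes < 1 or tr <= 0:
        raise ValueError("need n_volumes >= 1 and tr > 0")
    if onset is None:
        onset = tr / 2.0
    return onset + tr * np.arange(n_volumes)


def build_seed_pair(
    trace: PupilTrace,
    volume_times: np.ndarray,
    config: SeedConfig | None = None,
) -> tuple[SeedSeries, SeedSeries]:
    """Run the full chain: QC gate, confidence masking, sliding-window
    smoothing, HRF convolution, interpolation to volume times,
    differentiation.  Returns (diameter seed, derivative seed).

    Raises :class:`RejectedSubjectError` (carrying the QC report) when
    the trace fails the gate.  All chain parameters are recorded in each
    seed's ``meta["provenance"]``.
    """
    if config is None:
        config = SeedConfig()
    report = qc_evaluate(
        trace,
        conf_thresh=config.conf_thresh,
        max_unsuccessful=config.max_unsuccessful,
        min_high_conf=config.min_high_conf,
    )
    if not report.passed:
        raise RejectedSubjectError(report)
    masked = mask_low_confidence(trace, conf_thresh=config.conf_thresh)
    smoothed = smooth_sliding(masked, window=config.window, smoother=config.smoother)
    kernel = canonical_hrf(config.hrf, dt=smoothed.frame_interval)
    convolved = convolve_hrf(smoothed, kernel, pad="edge")
    diameter = resample_to_volumes(convolved, volume_times)
    provenance = {
        "qc": report.to_dict(),
        "window": config.window,
        "smoother": config.smoother,
        "hrf": dataclasses.asdict(config.hrf),
        "n_bridged_frames": int(convolved.meta["bridged_frames"].size),
    }
    diameter.meta["provenance"] = provenance
    derivative = differentiate(diameter)
    derivative.meta["provenance"] = provenance
    return diameter, derivative


# ---------------------------------------------------------------------------
# text I/O (TSV traces and seeds)


def read_trace_tsv(path) -> PupilTrace:
    """Read a trace TSV with columns time_s, diameter, confidence.

    An empty or NaN diameter marks a missing frame.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"time_s", "diameter", "confidence"}
    if not required.issubset(df.columns):
        raise ValueError(f"trace TSV must have columns {sorted(required)}")
    diameter = df["diameter"].to_numpy(dtype=float)
    missing = ~np.isfinite(diameter)
    return PupilTrace(
        time=df["time_s"].to_numpy(dtype=float),
        diameter=diameter,
        confidence=df["confidence"].to_numpy(dtype=float),
        missing=missing,
    )


def write_trace_tsv(trace: PupilTrace, path) -> None:
    diameter = np.where(trace.missing, np.nan, trace.diameter)
    pd.DataFrame(
        {"time_s": trace.time, "diameter": diameter, "confidence": trace.confidence}
    ).to_csv(path, sep="\t", index=False, na_rep="")


def write_seed_tsv(seed: SeedSeries, path) -> None:
    pd.DataFrame(
        {
            "volume_index": np.arange(seed.n_volumes),
            "time_s": seed.volume_time,
            "value": seed.value,
        }
    ).to_csv(path, sep="\t", index=False)


def read_seed_tsv(path, kind: str = "diameter") -> SeedSeries:
    df = pd.read_csv(path, sep="\t")
    return SeedSeries(
        value=df["value"].to_numpy(dtype=float),
        volume_time=df["time_s"].to_numpy(dtype=float),
        kind=kind,
    )
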