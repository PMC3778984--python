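"""Motor-evoked-potential quantification from rectified EMG.

A TMS pulse at t=0 elicits an EMG burst (the MEP) in the target muscle.
Each trial is scored as the area of the rectified trace inside a
post-stimulus MEP window, normalized by the area of a pre-trigger window
(ongoing background activation), and trials are averaged per stimulus
intensity block to give one recruitment-curve point per intensity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: machine-epsilon guard below which a pre-trigger area cannot normalize
AREA_EPS = np.finfo(float).eps


@dataclass
class EMGTrial:
    """One rectified EMG trace with stimulus metadata.

    ``samples`` are amplitudes in mV on a uniform time grid;
    ``stimulus_index`` is the sample index of the TMS pulse (t=0);
    ``intensity`` is in % of motor threshold unless the trial still
    carries absolute stimulator output (see
    :func:`estimate_motor_threshold`).
    """

    samples: np.ndarray
    sampling_rate: float
    stimulus_index: int
    subject_id: str = ""
    stimulated_hemisphere: str = ""   # {"lesioned", "contralesional"}
    recorded_leg: str = ""            # {"paretic", "non-paretic"}
    intensity: float = float("nan")
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not (0 <= self.stimulus_index < self.samples.size):
            raise ValueError("stimulus_index must lie inside the trace")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to the stimulus."""
        idx = np.arange(self.samples.size) - self.stimulus_index
        return idx * 1000.0 / self.sampling_rate


@dataclass(frozen=True)
class CurvePoint:
    """One recruitment-curve point: block-mean normalized MEP at one intensity."""

    intensity: float          # %MT
    response: float           # mean(MEP area / pre-trigger area), unitless
    n_trials: int

    def __post_init__(self) -> None:
        if self.response < 0:
            raise ValueError("response must be >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def rectify(trace: np.ndarray) -> np.ndarray:
    """Full-wave rectification (element-wise absolute value); idempotent."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("cannot rectify an empty trace")
    return np.abs(trace)


def window_area(trial: EMGTrial, window_ms: tuple[float, float]) -> float:
    """Area of the rectified trace over a window, in mV·ms.

    ``window_ms`` is (start, end) relative to the stimulus at t=0.
    Integration is trapezoidal over the closed sample interval covering
    the window, so a constant 1 mV over a 10 ms window is exactly
    10 mV·ms at any sampling rate whose grid hits the bounds.
    """
    start_ms, end_ms = window_ms
    if start_ms >= end_ms:
        raise ValueError(f"window start {start_ms} must precede end {end_ms}")
    dt_ms = 1000.0 / trial.sampling_rate
    i0 = trial.stimulus_index + int(round(start_ms / dt_ms))
    i1 = trial.stimulus_index + int(round(end_ms / dt_ms))
    if i0 < 0:
        raise ValueError(
            f"window start {start_ms} ms falls {-i0} samples before the trace"
        )
    if i1 >= trial.samples.size:
        raise ValueError(
            f"window end {end_ms} ms falls {i1 - trial.samples.size + 1} "
            "samples past the trace"
        )
    seg = rectify(trial.samples[i0:i1 + 1])
    return float(np.trapezoid(seg, dx=dt_ms))


def normalized_mep(
    trial: EMGTrial,
    mep_window: tuple[float, float],
    pre_window: tuple[float, float],
) -> float | None:
    """MEP area divided by pre-trigger area; ``None`` flags an invalid trial.

    A pre-trigger area at or below machine epsilon cannot normalize; the
    trial is flagged invalid (and later excluded from its block mean)
    rather than propagating a division blow-up.
    """
    mep = window_area(trial, mep_window)
    pre = window_area(trial, pre_window)
    if pre <= AREA_EPS:
        logger.warning(
            "subject %s %s/%s %g%%MT trial %d: pre-trigger area %g <= eps; "
            "trial flagged invalid",
            trial.subject_id, trial.stimulated_hemisphere, trial.recorded_leg,
            trial.intensity, trial.trial_index, pre,
        )
        return None
    return mep / pre


def block_point(
    trials: Sequence[EMGTrial],
    mep_window: tuple[float, float],
    pre_window: tuple[float, float],
) -> CurvePoint:
    """Block mean of per-trial normalized MEPs at one intensity.

    Ratio first, then mean. Invalid trials (unnormalizable pre-trigger)
    are excluded; if every trial is invalid the block fails.
    """
    if not trials:
        raise ValueError("block_point needs at least one trial")
    intensities = {t.intensity for t in trials}
    if len(intensities) != 1:
        raise ValueError(f"block mixes intensities {sorted(intensities)}")
    ratios = [normalized_mep(t, mep_window, pre_window) for t in trials]
    valid = [r for r in ratios if r is not None]
    if not valid:
        raise ValueError(
            f"all {len(trials)} trials at {trials[0].intensity}%MT invalid "
            "(zero pre-trigger area)"
        )
    return CurvePoint(
        intensity=trials[0].intensity,
        response=float(np.mean(valid)),
        n_trials=len(valid),
    )


def session_curve_points(
    trials: Iterable[EMGTrial],
    mep_window: tuple[float, float],
    pre_window: tuple[float, float],
) -> dict[tuple[str, str], list[CurvePoint]]:
    """Group a session's trials by (hemisphere, leg) and block-average.

    Returns, per stimulation configuration, the recruitment-curve points
    sorted by intensity.
    """
    groups: dict[tuple[str, str, float], list[EMGTrial]] = {}
    for t in trials:
        groups.setdefault(
            (t.stimulated_hemisphere, t.recorded_leg, t.intensity), []
        ).append(t)
    out: dict[tuple[str, str], list[CurvePoint]] = {}
    for (hemi, leg, _inten), block in sorted(groups.items()):
        out.setdefault((hemi, leg), []).append(
            block_point(block, mep_window, pre_window)
        )
    return out


def estimate_motor_threshold(
    trials: Iterable[EMGTrial],
    mep_window: tuple[float, float],
    pre_window: tuple[float, float],
    criterion_mv_ms: float = 0.1,
) -> float:
    """Lowest stimulator intensity reliably eliciting MEPs.

    Trials are grouped by their (absolute) ``intensity``; the threshold is
    the lowest intensity at which at least half the trials have an MEP
    area exceeding the pre-trigger area by ``criterion_mv_ms`` (mV·ms).
    Recruitment-curve x-axes can then be re-expressed in % of this value.
    """
    by_intensity: dict[float, list[EMGTrial]] = {}
    for t in trials:
        by_intensity.setdefault(t.intensity, []).append(t)
    if len(by_intensity) < 2:
        raise ValueError("threshold estimation needs trials at >= 2 intensities")
    for intensity in sorted(by_intensity):
        block = by_intensity[intensity]
        hits = sum(
            window_area(t, mep_window) > window_area(t, pre_window) + criterion_mv_ms
            for t in block
        )
        if hits * 2 >= len(block):
            return intensity
    raise ValueError(
        "no intensity met the MEP criterion in >= 50% of trials; "
        "widen the intensity grid upward"
    )


def curve_points_to_frame(
    points: dict[tuple[str, str], list[CurvePoint]], subject_id: str = ""
) -> pd.DataFrame:
    """Flatten per-configuration curve points to a tidy table."""
    rows = [
        {
            "subject": subject_id,
            "hemisphere": hemi,
            "leg": leg,
            "intensity": p.intensity,
            "response": p.response,
            "n_trials": p.n_trials,
        }
        for (hemi, leg), pts in points.items()
        for p in pts
    ]
    return pd.DataFrame(rows)
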