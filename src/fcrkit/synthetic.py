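"""Synthetic stroke-cohort generator.

Emulates the three data streams the analysis consumes — per-trial rectified
EMG responses to TMS, FA phantom volumes with internal-capsule ROI masks,
and behavioral scores — around a single latent lesion-severity gradient.
Greater severity means a higher paretic-leg FCR (more ipsilateral control),
lower ipsilesional PLIC FA, a larger lesion, a lower Fugl-Meyer score and a
slower walk; the non-paretic FCR and the control-ROI (ALIC) asymmetry are
generated independent of severity so downstream null checks have a ground
truth.

Sampling of the latent uniforms is stratified (one draw per equal-width
bin, order shuffled): each draw is still marginally uniform and seeded
deterministically, but small cohorts match the configured population
means closely, which is what makes the generator's configured means
recoverable at desk-scale cohort sizes.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GeneratorConfig
from .dti import LabeledVolume
from .emg import EMGTrial

HEMISPHERES = ("lesioned", "contralesional")
LEGS = ("paretic", "non-paretic")

#: (stimulated hemisphere, leg) pairs in which stimulation is ipsilateral
#: to the leg: the paretic leg lies opposite the lesioned hemisphere, so
#: its ipsilateral cortex is the contralesional one, and vice versa.
IPSI_CONFIG = {"paretic": "contralesional", "non-paretic": "lesioned"}
CONTRA_CONFIG = {"paretic": "lesioned", "non-paretic": "contralesional"}


@dataclass(frozen=True)
class TrueSubjectState:
    """Latent ground truth for one synthetic subject.

    ``true_slopes`` maps (stimulated hemisphere, leg) to the recruitment
    slope in normalized response per %MT point; ``true_fa`` maps
    hemisphere to mean PLIC FA. The pipeline's job is to recover these.
    """

    subject_id: str
    severity: float
    lesioned_side: str                      # {"left", "right"}
    true_slopes: dict[tuple[str, str], float]
    true_fa: dict[str, float]
    true_alic_fa: float
    true_fm: int
    true_walk_time_s: float

    def __post_init__(self) -> None:
        if not 0 <= self.severity <= 1:
            raise ValueError("severity must lie in [0, 1]")
        if any(s <= 0 for s in self.true_slopes.values()):
            raise ValueError("true slopes must be positive")
        if any(not 0 < fa < 1 for fa in self.true_fa.values()):
            raise ValueError("true FA must lie in (0, 1)")
        if not 0 <= self.true_fm <= 34:
            raise ValueError("Fugl-Meyer score must lie in [0, 34]")
        if self.true_walk_time_s <= 0:
            raise ValueError("walk time must be positive")

    @property
    def true_fcr(self) -> dict[str, float]:
        """Ground-truth FCR per leg: ipsilateral / contralateral slope."""
        return {
            leg: self.true_slopes[(IPSI_CONFIG[leg], leg)]
            / self.true_slopes[(CONTRA_CONFIG[leg], leg)]
            for leg in LEGS
        }


def _power_map(u: np.ndarray | float, lo: float, hi: float, mean: float):
    """Monotone map of a uniform [0,1] draw onto [lo, hi] with given mean.

    u -> lo + (hi-lo) * u**gamma has expectation lo + (hi-lo)/(gamma+1)
    under u ~ U(0,1); gamma is solved so that expectation equals ``mean``.
    gamma = 1 recovers the linear map when mean is the midpoint.
    """
    if not lo < mean < hi:
        raise ValueError(f"mean {mean} outside ({lo}, {hi})")
    gamma = (hi - lo) / (mean - lo) - 1.0
    return lo + (hi - lo) * np.asarray(u, dtype=float) ** gamma


def _stratified_uniform(rng: np.random.Generator, n: int) -> np.ndarray:
    """n draws, one per equal-width bin of [0,1), in shuffled order."""
    u = (np.arange(n) + rng.random(n)) / n
    return rng.permutation(u)


def generate_cohort(config: GeneratorConfig) -> list[TrueSubjectState]:
    """Draw the latent states of a synthetic cohort.

    Deterministic given (config, seed). Severity spans
    ``config.severity_range``; the paretic-leg FCR increases monotonically
    with severity with the configured mean and range, the non-paretic FCR
    is independent of severity, ipsilesional PLIC FA decreases with
    severity around ``fa_lesioned_mean``, and Fugl-Meyer / walking speed
    decrease with severity plus noise.
    """
    if config.n_subjects < 3:
        raise ValueError(
            "need >= 3 subjects (the correlation battery is undefined below that)"
        )
    n = config.n_subjects
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))

    lo_s, hi_s = config.severity_range
    severity = lo_s + (hi_s - lo_s) * _stratified_uniform(rng, n)

    # severity itself is the map input: the configured trait means hold
    # exactly under the default full (0, 1) severity range, and a
    # degenerate range collapses every trait to a single value
    fcr_par = _power_map(severity, *config.paretic_fcr_range,
                         config.paretic_fcr_mean)
    u_np = _stratified_uniform(rng, n)
    fcr_nonpar = _power_map(u_np, *config.nonparetic_fcr_range,
                            config.nonparetic_fcr_mean)

    lo_c, hi_c = config.contra_slope_range
    contra_slopes = rng.uniform(lo_c, hi_c, size=(n, 2))

    fa_intact = np.full(n, config.fa_intact_mean)
    # linear decline from the intact value at severity 0 (zero asymmetry
    # for an undamaged tract) with mean fa_lesioned_mean over U(0,1)
    fa_span = 2.0 * (config.fa_intact_mean - config.fa_lesioned_mean)
    fa_lesioned = config.fa_intact_mean - fa_span * severity
    fa_lesioned = np.clip(fa_lesioned, 0.01, 0.99)
    alic_fa = np.full(n, config.fa_intact_mean)

    fm_true = _power_map(1.0 - severity, *config.fm_range, config.fm_mean)
    fm = np.rint(fm_true + rng.normal(0, config.fm_noise_sd, n))
    fm = np.clip(fm, 0, 34).astype(int)

    speed_true = _power_map(1.0 - severity, *config.walk_speed_range,
                            config.walk_speed_mean)
    speed = np.maximum(speed_true + rng.normal(0, config.walk_speed_noise_sd, n),
                       0.5)
    walk_time = 600.0 / speed  # 10 m at `speed` m/min

    sides = rng.choice(["left", "right"], size=n)

    cohort = []
    for i in range(n):
        slopes = {
            (IPSI_CONFIG["paretic"], "paretic"): fcr_par[i] * contra_slopes[i, 0],
            (CONTRA_CONFIG["paretic"], "paretic"): contra_slopes[i, 0],
            (IPSI_CONFIG["non-paretic"], "non-paretic"):
                fcr_nonpar[i] * contra_slopes[i, 1],
            (CONTRA_CONFIG["non-paretic"], "non-paretic"): contra_slopes[i, 1],
        }
        cohort.append(TrueSubjectState(
            subject_id=f"S{i + 1:03d}",
            severity=float(severity[i]),
            lesioned_side=str(sides[i]),
            true_slopes=slopes,
            true_fa={"lesioned": float(fa_lesioned[i]),
                     "contralesional": float(fa_intact[i])},
            true_alic_fa=float(alic_fa[i]),
            true_fm=int(fm[i]),
            true_walk_time_s=float(walk_time[i]),
        ))
    return cohort


# ---------------------------------------------------------------------------
# EMG sessions


def _subject_rng(config: GeneratorConfig, state: TrueSubjectState,
                 stream: int) -> np.random.Generator:
    sid = int(state.subject_id.lstrip("S"))
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream, sid]))


def generate_emg_session(
    state: TrueSubjectState, config: GeneratorConfig
) -> list[EMGTrial]:
    """Simulate one TMS session: all four stimulation configurations.

    Each trace carries Gaussian noise everywhere, a tonic background level
    before the stimulus only (voluntary pre-activation; the post-stimulus
    period outside the MEP burst is silent), and a Gaussian-envelope MEP
    burst inside the MEP window whose area equals

        true_slope * (intensity - 100) * pre_trigger_area * calibration

    so the normalized response at intensity I is true_slope * (I - 100)
    and an OLS recruitment fit recovers true_slope exactly when noise is
    off. Traces are rectified before being returned.
    """
    rng = _subject_rng(config, state, stream=1)
    fs = config.sampling_rate
    dt_ms = 1000.0 / fs
    t0_ms, t1_ms = config.trace_window
    n_samples = int(round((t1_ms - t0_ms) / dt_ms)) + 1
    stim_idx = int(round(-t0_ms / dt_ms))
    t_ms = (np.arange(n_samples) - stim_idx) * dt_ms

    pre_lo, pre_hi = config.pre_trigger_window
    pre_area = config.tonic_emg_mv * (pre_hi - pre_lo)  # deterministic part

    mep_lo, mep_hi = config.mep_window
    center = 0.5 * (mep_lo + mep_hi)
    sigma = (mep_hi - mep_lo) / 8.0  # burst comfortably inside the window
    envelope = np.exp(-0.5 * ((t_ms - center) / sigma) ** 2)
    envelope[(t_ms < mep_lo) | (t_ms > mep_hi)] = 0.0
    # normalize over exactly the samples the analysis window integrates,
    # so the noiseless burst area matches the target to machine precision
    i0 = stim_idx + int(round(mep_lo / dt_ms))
    i1 = stim_idx + int(round(mep_hi / dt_ms))
    env_area = float(np.trapezoid(envelope[i0:i1 + 1], dx=dt_ms))

    tonic = np.where(t_ms < 0.0, config.tonic_emg_mv, 0.0)

    trials: list[EMGTrial] = []
    for (hemi, leg), slope in sorted(state.true_slopes.items()):
        for intensity in config.intensity_grid:
            amp = slope * (intensity - 100.0) * pre_area * config.calibration
            amp /= env_area  # burst peak giving exactly the target area
            for k in range(config.trials_per_block):
                noise = rng.normal(0.0, config.emg_noise_sd, n_samples) \
                    if config.emg_noise_sd > 0 else 0.0
                raw = tonic + amp * envelope + noise
                trials.append(EMGTrial(
                    samples=np.abs(raw),
                    sampling_rate=fs,
                    stimulus_index=stim_idx,
                    subject_id=state.subject_id,
                    stimulated_hemisphere=hemi,
                    recorded_leg=leg,
                    intensity=float(intensity),
                    trial_index=k,
                ))
    return trials


# ---------------------------------------------------------------------------
# FA phantoms


def _roi_boxes(config: GeneratorConfig) -> dict[str, tuple[slice, slice, slice]]:
    """Disjoint box ROIs on the phantom grid, mirrored across the midline.

    Left hemisphere occupies x < nx//2. PLIC boxes sit posterior
    (smaller y), ALIC boxes anterior; both span the same axial range so
    the CST column descends through the PLIC.
    """
    nx, ny, nz = config.volume_shape
    half = nx // 2
    x_w = max(2, nx // 8)
    x_l = slice(half - 2 - x_w, half - 2)
    x_r = slice(half + 2, half + 2 + x_w)
    y_plic = slice(ny // 3, ny // 3 + max(2, ny // 8))
    y_alic = slice(2 * ny // 3, 2 * ny // 3 + max(2, ny // 8))
    z = slice(nz // 4, nz - nz // 4)
    boxes = {
        "plic_left": (x_l, y_plic, z), "plic_right": (x_r, y_plic, z),
        "alic_left": (x_l, y_alic, z), "alic_right": (x_r, y_alic, z),
    }
    # ROI disjointness check: refuse overlapping or out-of-grid definitions
    for sl, dim in ((s, d) for box in boxes.values()
                    for s, d in zip(box, config.volume_shape)):
        if sl.start < 0 or sl.stop > dim or sl.start >= sl.stop:
            raise ValueError(
                f"volume_shape {config.volume_shape} cannot fit the ROIs disjointly"
            )
    occupancy = np.zeros(config.volume_shape, dtype=int)
    for sl in boxes.values():
        occupancy[sl] += 1
    if occupancy.max() > 1:
        raise ValueError("ROI definitions overlap; enlarge volume_shape")
    if occupancy.sum() == 0:
        raise ValueError("volume_shape too small to place ROIs")
    return boxes


def generate_fa_volume(
    state: TrueSubjectState, config: GeneratorConfig
) -> dict[str, LabeledVolume]:
    """Build one subject's FA phantom, ROI/lesion masks and CST map.

    Returns a dict with keys ``fa``, ``plic_lesioned``, ``plic_intact``,
    ``alic_lesioned``, ``alic_intact``, ``lesion``, ``cst`` — all on one
    grid with shared voxel dimensions. PLIC voxels take the hemisphere's
    true FA plus truncated-Gaussian noise; ALIC FA is symmetric; the
    lesion is an ellipsoidal blob in the lesioned hemisphere whose radius
    scales with severity; the CST probability map is a column of in-plane
    Gaussian profile descending through each PLIC, maximal at the core.
    """
    rng = _subject_rng(config, state, stream=2)
    shape = config.volume_shape
    boxes = _roi_boxes(config)
    les = state.lesioned_side            # "left" or "right"
    intact = "right" if les == "left" else "left"

    def noisy(mean: float, sl) -> np.ndarray:
        block = np.full([s.stop - s.start for s in sl], mean)
        if config.fa_noise_sd > 0:
            block = block + rng.normal(0, config.fa_noise_sd, block.shape)
        return np.clip(block, 0.0, 1.0)

    fa = np.full(shape, 0.30)
    if config.fa_noise_sd > 0:
        fa = np.clip(fa + rng.normal(0, config.fa_noise_sd, shape), 0, 1)
    fa[boxes[f"plic_{les}"]] = noisy(state.true_fa["lesioned"], boxes[f"plic_{les}"])
    fa[boxes[f"plic_{intact}"]] = noisy(state.true_fa["contralesional"],
                                        boxes[f"plic_{intact}"])
    for side in (les, intact):
        fa[boxes[f"alic_{side}"]] = noisy(state.true_alic_fa, boxes[f"alic_{side}"])

    def mask_of(sl) -> np.ndarray:
        m = np.zeros(shape)
        m[sl] = 1.0
        return m

    # CST probability: in-plane Gaussian around each PLIC center, all z
    idx = np.indices(shape).astype(float)
    cst = np.zeros(shape)
    for side in ("left", "right"):
        xs, ys, zs = boxes[f"plic_{side}"]
        cx = 0.5 * (xs.start + xs.stop - 1)
        cy = 0.5 * (ys.start + ys.stop - 1)
        d2 = (idx[0] - cx) ** 2 + (idx[1] - cy) ** 2
        cst = np.maximum(cst, np.exp(-d2 / (2 * 2.0 ** 2)))

    # lesion: ellipsoid near the lesioned PLIC, radius grows with severity
    lesion = np.zeros(shape)
    if state.severity > 0:
        xs, ys, zs = boxes[f"plic_{les}"]
        cx = 0.5 * (xs.start + xs.stop - 1) + (1 if les == "right" else -1)
        cy = 0.5 * (ys.start + ys.stop - 1) + 2.0
        cz = 0.5 * (zs.start + zs.stop - 1)
        rx = ry = 1.0 + 3.0 * state.severity
        rz = 1.0 + 2.0 * state.severity
        d = ((idx[0] - cx) / rx) ** 2 + ((idx[1] - cy) / ry) ** 2 \
            + ((idx[2] - cz) / rz) ** 2
        lesion[d <= 1.0] = 1.0

    vd = config.voxel_dims
    return {
        "fa": LabeledVolume(fa, vd),
        "plic_lesioned": LabeledVolume(mask_of(boxes[f"plic_{les}"]), vd),
        "plic_intact": LabeledVolume(mask_of(boxes[f"plic_{intact}"]), vd),
        "alic_lesioned": LabeledVolume(mask_of(boxes[f"alic_{les}"]), vd),
        "alic_intact": LabeledVolume(mask_of(boxes[f"alic_{intact}"]), vd),
        "lesion": LabeledVolume(lesion, vd),
        "cst": LabeledVolume(cst, vd),
    }


# ---------------------------------------------------------------------------
# Behavior


def generate_behavior(state: TrueSubjectState) -> tuple[int, float]:
    """(Fugl-Meyer score, walking speed in m/min) for one subject.

    Walking speed converts the latent 10 m walk time: 10 m / t * 60.
    The FM score is already integer and clipped to [0, 34] by the latent
    state; re-clipped here defensively.
    """
    speed = 10.0 / state.true_walk_time_s * 60.0
    fm = int(np.clip(state.true_fm, 0, 34))
    return fm, speed


# ---------------------------------------------------------------------------
# On-disk export (columnar EMG + NIfTI + CSV)


def write_emg_session(trials: list[EMGTrial], outdir: str | Path) -> Path:
    """Write a session as columnar trace files plus a sidecar metadata CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for i, tr in enumerate(trials):
        fname = f"trial_{i:04d}.csv"
        t_s = (np.arange(tr.samples.size) - tr.stimulus_index) / tr.sampling_rate
        pd.DataFrame({"time_s": t_s, "amplitude_mV": tr.samples}).to_csv(
            outdir / fname, index=False)
        meta_rows.append({
            "file": fname, "subject": tr.subject_id,
            "hemisphere": tr.stimulated_hemisphere, "leg": tr.recorded_leg,
            "intensity_pct_mt": tr.intensity, "trial_index": tr.trial_index,
            "sampling_rate_hz": tr.sampling_rate,
            "stimulus_index": tr.stimulus_index,
        })
    meta = outdir / "trials.csv"
    pd.DataFrame(meta_rows).to_csv(meta, index=False)
    return meta


def read_emg_session(meta_csv: str | Path) -> list[EMGTrial]:
    """Read a session written by :func:`write_emg_session`."""
    meta_csv = Path(meta_csv)
    meta = pd.read_csv(meta_csv)
    trials = []
    for _, row in meta.iterrows():
        df = pd.read_csv(meta_csv.parent / row["file"])
        trials.append(EMGTrial(
            samples=df["amplitude_mV"].to_numpy(),
            sampling_rate=float(row["sampling_rate_hz"]),
            stimulus_index=int(row["stimulus_index"]),
            subject_id=str(row["subject"]),
            stimulated_hemisphere=str(row["hemisphere"]),
            recorded_leg=str(row["leg"]),
            intensity=float(row["intensity_pct_mt"]),
            trial_index=int(row["trial_index"]),
        ))
    return trials


def write_subject_volumes(volumes: dict[str, LabeledVolume],
                          outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, vol in volumes.items():
        vol.save(outdir / f"{name}.nii.gz")
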