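"""Configuration for the synthetic cohort generator.

The defaults encode the study conditions the package emulates: a chronic
stroke cohort in which the paretic leg's functional connectivity ratio
(FCR, the ipsilateral/contralateral recruitment-curve slope ratio) averages
1.7 over a 0.27-2.6 range, the non-paretic leg's averages 0.55 over
0.2-0.83, and mean fractional anisotropy (FA) in the posterior limb of the
internal capsule (PLIC) averages 0.42 ipsilesionally versus 0.54
contralesionally.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

DEFAULT_INTENSITY_GRID = (100.0, 110.0, 120.0, 130.0, 140.0, 150.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    Parameters
    ----------
    n_subjects:
        Cohort size. Defaults to 13, the number of analyzed subjects the
        packaged clinical table contains.
    seed:
        Master seed; identical (config, seed) pairs give bit-identical
        cohorts at every stage.
    severity_range:
        Interval in [0, 1] from which the latent lesion-severity gradient
        is drawn. Severity drives paretic FCR up, ipsilesional FA down,
        and behavior (Fugl-Meyer, walking speed) down.
    paretic_fcr_mean, paretic_fcr_range:
        Target population mean and range of the paretic-leg FCR.
    nonparetic_fcr_mean, nonparetic_fcr_range:
        Same for the non-paretic leg; independent of severity.
    fa_lesioned_mean, fa_intact_mean:
        Population mean FA of the ipsilesional / contralesional PLIC.
        Ipsilesional PLIC FA declines linearly with severity from the
        intact value at severity 0 (no damage, zero asymmetry) through
        ``fa_lesioned_mean`` at mid-severity.
    fa_noise_sd:
        Per-voxel truncated-Gaussian FA noise SD (not Rician; adequate at
        desk scale).
    emg_noise_sd:
        Additive Gaussian EMG noise SD in mV (trace is rectified after
        noise is added).
    tonic_emg_mv:
        Deterministic pre-stimulus background EMG level in mV (voluntary
        pre-activation); the post-stimulus segment outside the MEP burst
        is silent apart from noise.
    contra_slope_range:
        Range of the contralateral recruitment-curve slope (normalized
        response per %MT point) from which each leg's contralateral slope
        is drawn; the ipsilateral slope is FCR x contralateral.
    calibration:
        Multiplier mapping normalized response to MEP area in units of
        pre-trigger area; fixed at 1.0 so true and recovered slopes are
        directly comparable.
    sampling_rate, trials_per_block, intensity_grid:
        EMG acquisition emulation: Hz, trials per intensity block, and the
        stimulus intensity grid in % of motor threshold.
    mep_window, pre_trigger_window:
        Analysis windows in ms relative to the stimulus at t=0.
    trace_window:
        Extent of each generated trace in ms relative to the stimulus.
    volume_shape, voxel_dims:
        FA phantom grid (voxels) and voxel size (mm).
    fm_noise_sd, walk_speed_noise_sd:
        Additive noise on the Fugl-Meyer score (points) and walking speed
        (m/min).
    """

    n_subjects: int = 13
    seed: int = 0
    severity_range: tuple[float, float] = (0.0, 1.0)
    paretic_fcr_mean: float = 1.7
    paretic_fcr_range: tuple[float, float] = (0.27, 2.6)
    nonparetic_fcr_mean: float = 0.55
    nonparetic_fcr_range: tuple[float, float] = (0.2, 0.83)
    fa_lesioned_mean: float = 0.42
    fa_intact_mean: float = 0.54
    fa_noise_sd: float = 0.02
    emg_noise_sd: float = 0.005
    tonic_emg_mv: float = 0.02
    contra_slope_range: tuple[float, float] = (0.02, 0.05)
    calibration: float = 1.0
    sampling_rate: float = 2000.0
    trials_per_block: int = 8
    intensity_grid: tuple[float, ...] = DEFAULT_INTENSITY_GRID
    mep_window: tuple[float, float] = (20.0, 60.0)
    pre_trigger_window: tuple[float, float] = (-110.0, -10.0)
    trace_window: tuple[float, float] = (-150.0, 100.0)
    volume_shape: tuple[int, int, int] = (24, 24, 16)
    voxel_dims: tuple[float, float, float] = (2.0, 2.0, 2.0)
    fm_mean: float = 23.8
    fm_range: tuple[float, float] = (12.0, 34.0)
    walk_speed_mean: float = 39.8
    walk_speed_range: tuple[float, float] = (5.4, 89.75)
    fm_noise_sd: float = 1.0
    walk_speed_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def _ordered(name: str, pair, strict: bool = False) -> None:
            lo, hi = pair
            if (lo > hi) or (strict and lo >= hi):
                raise ValueError(f"{name} must be an ordered pair, got {pair}")

        _ordered("severity_range", self.severity_range)
        if not (0 <= self.severity_range[0] and self.severity_range[1] <= 1):
            raise ValueError("severity_range must lie within [0, 1]")
        for name in ("paretic_fcr", "nonparetic_fcr"):
            rng = getattr(self, f"{name}_range")
            mean = getattr(self, f"{name}_mean")
            _ordered(f"{name}_range", rng, strict=True)
            if not (rng[0] < mean < rng[1]):
                raise ValueError(
                    f"{name}_mean {mean} must lie inside {name}_range {rng}"
                )
        for name in ("fm", "walk_speed"):
            rng = getattr(self, f"{name}_range")
            mean = getattr(self, f"{name}_mean")
            _ordered(f"{name}_range", rng, strict=True)
            if not (rng[0] < mean < rng[1]):
                raise ValueError(f"{name}_mean {mean} outside {name}_range {rng}")
        _ordered("mep_window", self.mep_window, strict=True)
        _ordered("pre_trigger_window", self.pre_trigger_window, strict=True)
        _ordered("trace_window", self.trace_window, strict=True)
        _ordered("contra_slope_range", self.contra_slope_range, strict=True)
        for name in ("fa_noise_sd", "emg_noise_sd", "fm_noise_sd",
                     "walk_speed_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.trials_per_block < 1:
            raise ValueError("trials_per_block must be >= 1")
        grid = tuple(self.intensity_grid)
        if len(grid) < 3:
            raise ValueError(
                "intensity_grid needs >= 3 points (a line fit needs >= 2, "
                "fit quality r needs >= 3)"
            )
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("intensity_grid must be strictly increasing")
        if not (0 < self.fa_lesioned_mean < 1 and 0 < self.fa_intact_mean < 1):
            raise ValueError("FA means must lie in (0, 1)")
        if self.fa_lesioned_mean > self.fa_intact_mean:
            raise ValueError("fa_lesioned_mean cannot exceed fa_intact_mean")
        if self.trace_window[0] > self.pre_trigger_window[0] or \
                self.trace_window[1] < self.mep_window[1]:
            raise ValueError("trace_window must contain both analysis windows")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        d = yaml.safe_load(Path(path).read_text())
        tuple_fields = {
            "severity_range", "paretic_fcr_range", "nonparetic_fcr_range",
            "intensity_grid", "mep_window", "pre_trigger_window",
            "trace_window", "volume_shape", "voxel_dims", "fm_range",
            "walk_speed_range", "contra_slope_range",
        }
        for k in tuple_fields & set(d):
            d[k] = tuple(d[k])
        return cls(**d)
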