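"""Recruitment-curve fitting and the functional connectivity ratio (FCR).

The recruitment curve relates TMS intensity (% of motor threshold) to the
normalized MEP response; its fitted slope indexes the strength of the
corticospinal projection from the stimulated motor cortex to the recorded
leg. For each leg,

    FCR = slope(ipsilateral curve) / slope(contralateral curve)

so FCR > 1 reflects predominantly ipsilateral cortical control of that leg
and FCR < 1 predominantly contralateral (the healthy arrangement).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .emg import CurvePoint

#: fits at or below this Pearson r are flagged (not discarded)
FIT_QUALITY_R = 0.85

IPSILATERAL = "ipsilateral-predominant"
CONTRALATERAL = "contralateral-predominant"
BALANCED = "balanced"


@dataclass(frozen=True)
class RecruitmentFit:
    """A fitted recruitment line: response = intercept + slope * intensity.

    ``fit_r`` is the Pearson correlation between intensity and response;
    the ``flagged`` quality bit marks fits with fit_r <= 0.85 (including
    degenerate constant-response fits, where r is undefined and stored
    as NaN).
    """

    leg: str
    stimulated_hemisphere: str
    slope: float           # response per %MT point
    intercept: float
    fit_r: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("a recruitment fit needs >= 3 points")
        if not math.isnan(self.fit_r) and not -1.0 <= self.fit_r <= 1.0:
            raise ValueError(f"fit_r {self.fit_r} outside [-1, 1]")

    @property
    def flagged(self) -> bool:
        return math.isnan(self.fit_r) or self.fit_r <= FIT_QUALITY_R


@dataclass(frozen=True)
class FCRResult:
    """Ipsilateral/contralateral slope ratio for one leg, with laterality."""

    leg: str
    fcr: float
    slope_ipsilateral: float
    slope_contralateral: float

    @property
    def laterality(self) -> str:
        """Binary >1 / <1 reading; "balanced" only at exactly 1.0."""
        if self.fcr > 1.0:
            return IPSILATERAL
        if self.fcr < 1.0:
            return CONTRALATERAL
        return BALANCED


def fit_line(
    points: Sequence[CurvePoint],
    leg: str = "",
    stimulated_hemisphere: str = "",
) -> RecruitmentFit:
    """Unweighted OLS of response on intensity over block-mean points.

    Constant responses give slope 0 with undefined (NaN) fit_r and are
    flagged degenerate; identical intensities leave the slope undefined
    and raise.
    """
    if len(points) < 3:
        raise ValueError(f"need >= 3 curve points, got {len(points)}")
    x = np.array([p.intensity for p in points], dtype=float)
    y = np.array([p.response for p in points], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("all intensities identical; slope undefined")
    if np.allclose(y, y[0]):
        return RecruitmentFit(
            leg=leg, stimulated_hemisphere=stimulated_hemisphere,
            slope=0.0, intercept=float(y[0]), fit_r=float("nan"),
            n_points=len(points),
        )
    res = stats.linregress(x, y)
    return RecruitmentFit(
        leg=leg, stimulated_hemisphere=stimulated_hemisphere,
        slope=float(res.slope), intercept=float(res.intercept),
        fit_r=float(res.rvalue), n_points=len(points),
    )


def compute_fcr(fit_ipsi: RecruitmentFit, fit_contra: RecruitmentFit) -> FCRResult:
    """FCR = ipsilateral slope / contralateral slope for one leg."""
    if fit_ipsi.leg and fit_contra.leg and fit_ipsi.leg != fit_contra.leg:
        raise ValueError(
            f"fits are for different legs: {fit_ipsi.leg!r} vs {fit_contra.leg!r}"
        )
    if fit_contra.slope <= 0:
        raise ValueError(
            f"contralateral slope {fit_contra.slope} <= 0 invalidates the ratio"
        )
    if fit_ipsi.slope < 0:
        raise ValueError(f"negative ipsilateral slope {fit_ipsi.slope}")
    return FCRResult(
        leg=fit_ipsi.leg or fit_contra.leg,
        fcr=fit_ipsi.slope / fit_contra.slope,
        slope_ipsilateral=fit_ipsi.slope,
        slope_contralateral=fit_contra.slope,
    )


def fcr_swap_check(
    fit_a: RecruitmentFit, fit_b: RecruitmentFit
) -> tuple[float, float]:
    """Self-test: the two orderings of a slope pair are reciprocals.

    Returns (fcr(a,b), fcr(b,a)); their product is 1 within 1e-12 or the
    check raises.
    """
    ab = compute_fcr(fit_a, fit_b).fcr
    ba = compute_fcr(fit_b, fit_a).fcr
    if abs(ab * ba - 1.0) > 1e-12:
        raise AssertionError(f"reciprocity violated: {ab} * {ba} != 1")
    return ab, ba
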