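"""Score calibration: null score distribution and P-values.

Annotation scores on i.i.d. background sequence have an exponential upper
tail.  Fitting a shifted exponential (location mu = smallest observed
score, scale sigma = mean excess; the maximum-likelihood estimates) to the
null scores, and letting omega be the fraction of letters annotated
repetitive in the calibration run, a region scoring s gets

    P(s) = min(1, omega * exp((mu - s) / sigma)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelParams, background_from_at
from .decode import WindowPlan, annotate_codes


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class PvalModel:
    location: float       # mu, score units
    scale: float          # sigma, positive score units
    repeat_fraction: float  # omega, fraction of null letters annotated

    def __post_init__(self):
        if self.scale <= 0:
            raise CalibrationError("scale must be positive")
        if not 0.0 <= self.repeat_fraction <= 1.0:
            raise CalibrationError("repeat fraction must lie in [0, 1]")


def generate_background(length: int, at_richness: float = 0.5,
                        seed: int = 0) -> np.ndarray:
    """Seeded i.i.d. background sequence (encoded), AT-rich as requested."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    bg = background_from_at(at_richness)
    return rng.choice(4, size=length, p=bg).astype(np.int8)


def fit_null(scores, annotated_letters: int, total_letters: int) -> PvalModel:
    """Shifted-exponential MLE of the null score distribution."""
    scores = np.asarray(list(scores), dtype=np.float64)
    if total_letters <= 0:
        raise CalibrationError("total_letters must be positive")
    if scores.size == 0:
        raise CalibrationError(
            "no null scores to fit; supply P-value parameters explicitly "
            "via --ploc, --pscale and --pfreq")
    mu = float(scores.min())
    sigma = float(np.mean(scores - mu))
    if sigma <= 0:
        raise CalibrationError(
            "degenerate null score distribution (zero scale); supply "
            "--ploc/--pscale/--pfreq instead")
    omega = annotated_letters / total_letters
    return PvalModel(mu, sigma, omega)


def p_value(score: float, model: PvalModel) -> float:
    """Tail probability of a null region scoring >= ``score``."""
    return float(min(1.0, model.repeat_fraction
                     * np.exp((model.location - score) / model.scale)))


def calibrate(params: ModelParams, length: int = 10_000_000,
              at_richness: float = 0.5, seed: int = 0, min_unit: int = 2,
              plan: WindowPlan | None = None, threads: int = 1
              ) -> tuple[PvalModel, np.ndarray]:
    """Annotate seeded random background and fit the null model.

    Returns the fitted model and the raw null region scores.  The default
    10 Mb run is a desk-scale calibration; scale ``length`` up for
    production-grade parameters.
    """
    codes = generate_background(length, at_richness, seed)
    regions = annotate_codes(codes, params, plan=plan, min_unit=min_unit,
                             threads=threads)
    scores = np.array([r.score for r in regions])
    annotated = int(sum(len(r) for r in regions))
    return fit_null(scores, annotated, length), scores


def log_survival_fit(scores: np.ndarray, central: float = 0.9):
    """Least-squares line through the empirical log-survival of scores.

    Uses the central ``central`` quantile range (tail artifacts at both
    extremes excluded).  Returns (slope, intercept, r_squared).
    """
    from scipy import stats

    s = np.sort(np.asarray(scores, dtype=np.float64))
    n = s.size
    if n < 10:
        raise CalibrationError("too few scores for a survival fit")
    surv = 1.0 - (np.arange(1, n + 1) - 0.5) / n
    lo = (1.0 - central) / 2
    keep = (surv > lo) & (surv < 1.0 - lo)
    res = stats.linregress(s[keep], np.log(surv[keep]))
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)
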