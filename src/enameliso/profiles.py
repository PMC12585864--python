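"""Per-specimen time-series summaries and ontogenetic shift detection.

A serial enamel profile is a time series: groove position maps to formation
time through the enamel extension rate (about 8–21 mm yr⁻¹ in proboscideans;
1 mm groove spacing at the default 12 mm yr⁻¹ is roughly monthly).  Early
grooves of a juvenile tooth can carry a nursing signature — δ¹³C depleted by
milk fat (~1.5 ‰), δ¹⁸O enriched by milk water — that decays to the adult
dietary baseline as the animal weans.  ``detect_ontogenetic_shift``
operationalizes that visual pattern as a conservative two-window rule, and
``estimate_weaning_position`` locates the end of the transition by fitting a
decaying-ramp model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    AtmosphericReference,
    EmptyProfileError,
    EnrichmentConstant,
    InvalidInputError,
    SpecimenProfile,
    pooled_values,
)

__all__ = [
    "ProfileSummary",
    "ShiftReport",
    "summarize_profile",
    "pooled_summary",
    "position_to_age_offset",
    "detect_ontogenetic_shift",
    "estimate_weaning_position",
]

#: Default enamel extension rate (mm/yr): 1 mm groove spacing ≈ one month.
DEFAULT_EXTENSION_RATE = 12.0


@dataclass(frozen=True)
class ProfileSummary:
    """Summary statistics of one analyte over non-missing serial samples."""

    analyte: str
    n: int
    mean: float
    sd: float | None  # sample SD (n−1); None when n == 1
    min: float
    max: float


def _summary(values: list[float], analyte: str) -> ProfileSummary:
    if not values:
        raise EmptyProfileError(f"no usable {analyte} samples")
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else None
    return ProfileSummary(
        analyte=analyte,
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=sd,
        min=float(arr.min()),
        max=float(arr.max()),
    )


def summarize_profile(
    profile: SpecimenProfile,
    analyte: str,
    atm: AtmosphericReference | None = None,
    enrichment: EnrichmentConstant | None = None,
) -> ProfileSummary:
    """Mean / sample SD / range of one analyte for a single specimen.

    The standard deviation uses the n−1 denominator.  For a single usable
    sample the SD is undefined (``None``), never reported as zero.
    """
    return _summary(profile.values(analyte, atm, enrichment), analyte)


def pooled_summary(
    profiles: list[SpecimenProfile],
    analyte: str,
    atm: AtmosphericReference | None = None,
    enrichment: EnrichmentConstant | None = None,
) -> ProfileSummary:
    """Summary over the union of non-missing samples of several profiles."""
    return _summary(pooled_values(profiles, analyte, atm, enrichment), analyte)


def position_to_age_offset(
    distance_mm: float, extension_rate_mm_per_yr: float = DEFAULT_EXTENSION_RATE
) -> float:
    """Years of crown growth represented by ``distance_mm`` of enamel."""
    if extension_rate_mm_per_yr <= 0:
        raise InvalidInputError(
            f"extension rate must be > 0 mm/yr, got {extension_rate_mm_per_yr}"
        )
    return distance_mm / extension_rate_mm_per_yr


@dataclass(frozen=True)
class ShiftReport:
    """Outcome of the early-ontogeny shift test for one analyte.

    ``evaluable`` distinguishes "profile too short to test" from a genuine
    negative.  ``effect`` is |early mean − tail mean| in units of the tail
    sample SD.  ``monotone_early`` records whether the smoothed leading
    segment trends toward the tail without reversal.
    """

    analyte: str
    evaluable: bool
    detected: bool
    early_mean: float | None = None
    tail_mean: float | None = None
    effect: float | None = None
    direction: str | None = None  # "rising" | "falling"
    early_window: int = 3
    monotone_early: bool | None = None


def _smoothed_monotone(leading: np.ndarray, rising: bool, gap: float,
                       tol_frac: float = 0.15) -> bool:
    """Weak monotonicity of the 3-point moving average of ``leading``.

    Raw successive differences are dominated by analytical noise, so the
    trend is assessed on a 3-point smoother and reversals smaller than
    ``tol_frac`` of the early–tail gap are ignored.
    """
    if leading.size < 3:
        return True
    ma = np.convolve(leading, np.ones(3) / 3.0, mode="valid")
    diffs = np.diff(ma)
    if diffs.size == 0:
        return True
    tol = tol_frac * abs(gap)
    return bool(np.all(diffs >= -tol)) if rising else bool(np.all(diffs <= tol))


def detect_ontogenetic_shift(
    profile: SpecimenProfile,
    analyte: str,
    early_window: int = 3,
    threshold: float = 2.0,
    atm: AtmosphericReference | None = None,
    enrichment: EnrichmentConstant | None = None,
) -> ShiftReport:
    """Test for an early-life isotopic excursion (nursing/weaning signal).

    The first ``early_window`` (k) non-missing samples form the early
    window; the remainder is the tail.  A shift is flagged when

    * |mean(early) − mean(tail)| ≥ ``threshold`` × SD(tail), and
    * the smoothed leading segment (first k+2 samples) trends weakly
      monotonically toward the tail mean.

    Needs at least k+3 non-missing samples; shorter profiles return a
    non-evaluable report (distinct from "not detected").
    """
    vals = np.asarray(profile.values(analyte, atm, enrichment), dtype=float)
    k = early_window
    if k < 1:
        raise InvalidInputError("early_window must be >= 1")
    if vals.size < k + 3:
        return ShiftReport(analyte=analyte, evaluable=False, detected=False,
                           early_window=k)
    early = vals[:k]
    tail = vals[k:]
    early_mean = float(early.mean())
    tail_mean = float(tail.mean())
    tail_sd = float(tail.std(ddof=1))
    diff = tail_mean - early_mean
    if tail_sd == 0.0:
        effect = 0.0 if diff == 0.0 else math.inf
    else:
        effect = abs(diff) / tail_sd
    rising = diff > 0
    monotone = _smoothed_monotone(vals[: k + 2], rising, diff)
    return ShiftReport(
        analyte=analyte,
        evaluable=True,
        detected=bool(effect >= threshold and monotone and diff != 0.0),
        early_mean=early_mean,
        tail_mean=tail_mean,
        effect=float(effect),
        direction="rising" if rising else "falling",
        early_window=k,
        monotone_early=monotone,
    )


def _ramp(n: int, w: int) -> np.ndarray:
    """Linear nursing ramp: 1 at sample 1, 0 from sample ``w`` on (1-based)."""
    i = np.arange(1, n + 1, dtype=float)
    return np.clip((w - i) / (w - 1), 0.0, None)


# Direction of the nursing excursion per analyte: milk fat depletes δ¹³C,
# milk water enriches δ¹⁸O.
_NURSING_SIGN = {"d13C_enamel": -1.0, "d13C_diet_meq": -1.0, "d18O": +1.0}


def estimate_weaning_position(
    profile: SpecimenProfile,
    analytes: tuple[str, ...] = ("d13C_diet_meq", "d18O"),
    atm: AtmosphericReference | None = None,
    enrichment: EnrichmentConstant | None = None,
) -> int:
    """Estimate of the sample index where the weaning transition completes.

    Fits the decaying-ramp model ``y_i = c + b·ramp_i(w)`` (full nursing
    offset at the first sample, linearly reaching zero at sample ``w``)
    independently to each requested analyte and picks the shared ``w``
    maximizing the joint Gaussian profile likelihood.  Two domain priors
    sharpen the estimate: the amplitude sign is fixed by milk physiology
    (δ¹³C depleted, δ¹⁸O enriched — a wrong-sign fit falls back to a
    no-nursing model), and candidate positions are restricted to the first
    half of the profile since weaning is an early-ontogeny event.

    Using both analytes jointly (the default) roughly halves the estimator
    variance compared with a single channel, because the weaning signal is
    a paired excursion by definition.  A single-analyte estimate is
    available by passing a one-element tuple.
    """
    channels = []
    for analyte in analytes:
        vals = profile.values(analyte, atm, enrichment)
        if vals:
            channels.append((np.asarray(vals, dtype=float), _NURSING_SIGN[analyte]))
    if not channels:
        raise EmptyProfileError("no usable samples in any requested analyte")
    n = min(v.size for v, _ in channels)
    if n < 5:
        raise EmptyProfileError("need at least 5 usable samples to locate weaning")
    channels = [(v[:n], s) for v, s in channels]

    best_w, best_score = 2, math.inf
    for w in range(2, max(3, n // 2) + 1):
        X = np.column_stack([np.ones(n), _ramp(n, w)])
        score = 0.0
        for vals, sign in channels:
            beta, *_ = np.linalg.lstsq(X, vals, rcond=None)
            if beta[1] * sign < 0:  # nursing amplitude with impossible sign
                sse = float(np.sum((vals - vals.mean()) ** 2))
            else:
                sse = float(np.sum((vals - X @ beta) ** 2))
            score += n * math.log(max(sse, 1e-300))
        if score < best_score:
            best_score, best_w = score, w
    return best_w
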