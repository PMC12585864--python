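"""Vegetation classification and the C₃/C₄ two-end-member mixing model.

δ¹³C of herbivore enamel separates browsing on C₃ vegetation (trees, shrubs,
cool-climate grasses; strongly negative δ¹³C) from grazing on C₄ tropical
grasses (much less negative).  Two complementary readings are provided:

* a five-class vegetation scheme binning δ¹³C into habitat categories, on
  either the enamel scale or the modern-equivalent diet (diet-meq) scale,
* a linear two-end-member mixing model that converts a diet-meq δ¹³C into
  the fractional contribution of C₄ plants to the diet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    AtmosphericReference,
    ConfigurationError,
    EmptyProfileError,
    EnrichmentConstant,
    SpecimenProfile,
)

__all__ = [
    "VegetationScheme",
    "MixingModel",
    "C4Fraction",
    "classify_vegetation",
    "c4_fraction",
    "specimen_c4_range",
    "OUTSIDE_SCHEME",
]

OUTSIDE_SCHEME = "outside_scheme"

# Enamel-scale class boundaries (‰ VPDB); contiguous, ordered.
_ENAMEL_BINS: tuple[tuple[str, float, float], ...] = (
    ("closed-canopy forest", -20.5, -14.5),
    ("woodland-mesic C3 grassland", -14.5, -9.5),
    ("open woodland-xeric C3 grassland", -9.5, -6.5),
    ("mixed C3-C4 grassland", -6.5, -1.5),
    ("pure C4 grassland", -1.5, 6.5),
)


@dataclass(frozen=True)
class VegetationScheme:
    """Ordered contiguous δ¹³C bins mapping to vegetation classes.

    ``scale`` tags whether the bins apply to enamel δ¹³C or to diet-meq
    δ¹³C; the diet-meq scheme is the enamel scheme translated by the
    −14.1 ‰ diet–enamel enrichment, so bin widths are identical.
    Bins are half-open ``[lower, upper)``; the last bin is closed at the
    top so the scheme partitions its full range.
    """

    scale: str = "enamel"
    bins: tuple[tuple[str, float, float], ...] = _ENAMEL_BINS

    def __post_init__(self) -> None:
        if self.scale not in ("enamel", "diet_meq"):
            raise ConfigurationError(f"unknown scheme scale {self.scale!r}")
        for (_, lo, hi), (_, lo2, _) in zip(self.bins, self.bins[1:]):
            if hi != lo2:
                raise ConfigurationError("vegetation bins must be contiguous")
            if lo >= hi:
                raise ConfigurationError("vegetation bin bounds must increase")

    @classmethod
    def enamel(cls) -> "VegetationScheme":
        return cls()

    @classmethod
    def diet_meq(cls, enrichment: EnrichmentConstant | None = None) -> "VegetationScheme":
        """Enamel scheme shifted to the diet-meq scale by the enrichment."""
        shift = -(enrichment or EnrichmentConstant()).diet_to_enamel_enrichment
        shifted = tuple((name, lo + shift, hi + shift) for name, lo, hi in _ENAMEL_BINS)
        return cls(scale="diet_meq", bins=shifted)


def classify_vegetation(d13c: float, scheme: VegetationScheme) -> str:
    """Vegetation class containing ``d13c``, or ``"outside_scheme"``.

    The caller is responsible for passing a value on the scheme's scale.
    Values beyond the total range are flagged, never clamped.
    """
    last = len(scheme.bins) - 1
    for i, (name, lo, hi) in enumerate(scheme.bins):
        if lo <= d13c < hi or (i == last and d13c == hi):
            return name
    return OUTSIDE_SCHEME


@dataclass(frozen=True)
class MixingModel:
    """Linear C₃/C₄ mixing on the diet-meq δ¹³C scale.

    End members are the δ¹³C_diet-meq values of a pure-C₄ and a pure-C₃
    diet; defaults −7.6 ‰ and −34.6 ‰.  The C₄ fraction interpolates
    linearly between them.
    """

    c4_end_member: float = -7.6
    c3_end_member: float = -34.6

    def __post_init__(self) -> None:
        if self.c4_end_member <= self.c3_end_member:
            raise ConfigurationError(
                "C4 end member must exceed C3 end member "
                f"({self.c4_end_member} vs {self.c3_end_member})"
            )


@dataclass(frozen=True)
class C4Fraction:
    """A C₄ dietary fraction with truncation bookkeeping."""

    fraction: float
    clamped: bool = False

    @property
    def percent(self) -> float:
        return self.fraction * 100.0


def c4_fraction(
    d13c_diet_meq: float, model: MixingModel | None = None, clamp: bool = True
) -> C4Fraction:
    """C₄ dietary fraction of a diet-meq δ¹³C value.

    f = (δ − c3) / (c4 − c3).  Measurement noise can push values slightly
    beyond the end members; with ``clamp`` (default) the fraction is
    truncated to [0, 1] and the truncation recorded on the result.
    """
    model = model or MixingModel()
    f = (d13c_diet_meq - model.c3_end_member) / (
        model.c4_end_member - model.c3_end_member
    )
    if clamp and not 0.0 <= f <= 1.0:
        return C4Fraction(min(1.0, max(0.0, f)), clamped=True)
    return C4Fraction(f)


@dataclass(frozen=True)
class C4Range:
    """Per-specimen summary of C₄ fractions (percent)."""

    specimen_id: str
    n: int
    min_percent: float
    max_percent: float
    mean_percent: float
    any_clamped: bool


def specimen_c4_range(
    profile: SpecimenProfile,
    model: MixingModel | None = None,
    atm: AtmosphericReference | None = None,
    enrichment: EnrichmentConstant | None = None,
) -> C4Range:
    """Min/max/mean C₄ dietary percentage over a specimen's serial samples."""
    meq = profile.values("d13C_diet_meq", atm, enrichment)
    if not meq:
        raise EmptyProfileError(
            f"profile {profile.specimen_id} has no usable δ¹³C samples"
        )
    fracs = [c4_fraction(v, model) for v in meq]
    pct = [f.percent for f in fracs]
    return C4Range(
        specimen_id=profile.specimen_id,
        n=len(pct),
        min_percent=min(pct),
        max_percent=max(pct),
        mean_percent=sum(pct) / len(pct),
        any_clamped=any(f.clamped for f in fracs),
    )
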