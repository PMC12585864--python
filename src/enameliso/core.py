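"""Core domain types and isotope-scale conversions.

Serial enamel isotope profiles are ordered sequences of groove measurements
along a tooth's growth axis.  Two analytes are carried per groove: δ¹³C of
enamel carbonate and δ¹⁸O, both in per-mil (‰) on the VPDB scale.  This
module holds the shared vocabulary (samples, profiles, reference constants)
and the scale conversions every downstream stage relies on:

* delta notation from raw isotope ratios,
* the VSMOW ↔ VPDB affine transform for δ¹⁸O,
* conversion of enamel δ¹³C to the *modern-equivalent diet* value
  (δ¹³C_diet-meq), which subtracts the diet–enamel enrichment and corrects
  for the secular drift of atmospheric CO₂ δ¹³C between the epoch of tooth
  formation and the post-industrial atmosphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

__all__ = [
    "Epoch",
    "Analyte",
    "SerialSample",
    "SpecimenProfile",
    "AtmosphericReference",
    "EnrichmentConstant",
    "delta_from_ratios",
    "vsmow_to_vpdb",
    "vpdb_to_vsmow",
    "diet_meq_from_enamel",
    "enamel_from_diet_meq",
    "round_permil",
]

Epoch = Literal["pliocene", "pleistocene", "modern"]
EPOCHS: tuple[str, ...] = ("pliocene", "pleistocene", "modern")

#: Analyte identifiers used across the package.  ``d13C_diet_meq`` is a
#: derived analyte: it is computed on the fly from ``d13C_enamel``.
Analyte = Literal["d13C_enamel", "d13C_diet_meq", "d18O"]
ANALYTES: tuple[str, ...] = ("d13C_enamel", "d13C_diet_meq", "d18O")

# Sanity window for per-mil values; anything outside is almost certainly a
# ratio-scale or mis-parsed input rather than a real enamel measurement.
_PERMIL_LO, _PERMIL_HI = -40.0, 20.0

# VSMOW -> VPDB affine constants for δ¹⁸O (carbonate scale convention).
_VSMOW_OFFSET = 30.91
_VSMOW_SLOPE = 1.03091


class InvalidInputError(ValueError):
    """Raised when a physical precondition on an input is violated."""


class ConfigurationError(ValueError):
    """Raised when reference constants or model configuration are unusable."""


class EmptyProfileError(ValueError):
    """Raised when an operation needs data but the profile has none."""


def _check_permil(value: float, name: str) -> None:
    if not (_PERMIL_LO <= value <= _PERMIL_HI):
        raise InvalidInputError(
            f"{name} = {value} ‰ outside the plausible window "
            f"[{_PERMIL_LO}, {_PERMIL_HI}]; is this a ratio-scale value?"
        )


@dataclass(frozen=True)
class SerialSample:
    """One groove measurement along the growth axis.

    Position 1 is the groove nearest the occlusal (chewing) surface, i.e.
    the earliest-formed enamel sampled.  Either analyte may be missing
    (``None``); missing values never enter any statistic.
    """

    sample_label: str
    position_index: int
    d13C_enamel: float | None = None
    d18O: float | None = None
    distance_from_occlusal_mm: float | None = None

    def __post_init__(self) -> None:
        if self.position_index < 1:
            raise InvalidInputError(
                f"position_index must be >= 1, got {self.position_index}"
            )
        if self.d13C_enamel is not None:
            _check_permil(self.d13C_enamel, f"d13C_enamel[{self.sample_label}]")
        if self.d18O is not None:
            _check_permil(self.d18O, f"d18O[{self.sample_label}]")
        if self.distance_from_occlusal_mm is None:
            # default sampling geometry: grooves cut at 1 mm intervals
            object.__setattr__(
                self, "distance_from_occlusal_mm", float(self.position_index)
            )

    @property
    def is_missing(self) -> bool:
        return self.d13C_enamel is None and self.d18O is None


@dataclass(frozen=True)
class SpecimenProfile:
    """Ordered serial samples for one individual tooth.

    ``epoch`` is a profile-level attribute: a single molar forms within one
    epoch, so the atmospheric correction is constant along the profile.
    ``ontogenetic_age_years`` may be a point value or a (low, high) interval;
    it is carried as metadata only.
    """

    specimen_id: str
    taxon: str
    epoch: str
    samples: tuple[SerialSample, ...]
    ontogenetic_age_years: float | tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.epoch not in EPOCHS:
            raise ConfigurationError(
                f"unknown epoch {self.epoch!r} for specimen {self.specimen_id}; "
                f"expected one of {EPOCHS}"
            )
        object.__setattr__(
            self, "samples", tuple(sorted(self.samples, key=lambda s: s.position_index))
        )
        positions = [s.position_index for s in self.samples]
        if len(set(positions)) != len(positions):
            raise InvalidInputError(
                f"duplicate position_index in profile {self.specimen_id}"
            )

    def values(self, analyte: str, atm: "AtmosphericReference | None" = None,
               enrichment: "EnrichmentConstant | None" = None) -> list[float]:
        """Non-missing values of ``analyte`` in growth order.

        ``d13C_diet_meq`` is derived from the enamel values using ``atm`` and
        ``enrichment`` (package defaults when omitted).
        """
        if analyte == "d18O":
            return [s.d18O for s in self.samples if s.d18O is not None]
        if analyte == "d13C_enamel":
            return [s.d13C_enamel for s in self.samples if s.d13C_enamel is not None]
        if analyte == "d13C_diet_meq":
            atm = atm or AtmosphericReference()
            enrichment = enrichment or EnrichmentConstant()
            return [
                diet_meq_from_enamel(s.d13C_enamel, self.epoch, atm, enrichment)
                for s in self.samples
                if s.d13C_enamel is not None
            ]
        raise InvalidInputError(f"unknown analyte {analyte!r}")

    def n_samples(self, analyte: str) -> int:
        return len(self.values(analyte))


@dataclass(frozen=True)
class AtmosphericReference:
    """δ¹³C of atmospheric CO₂ per epoch, ‰ VPDB.

    Defaults: −6.3 (Pliocene), −6.5 (Pleistocene), −8.0 (post-industrial
    modern).  The modern entry anchors the modern-equivalent transform and
    must always be present.
    """

    values: dict[str, float] = field(
        default_factory=lambda: {"pliocene": -6.3, "pleistocene": -6.5, "modern": -8.0}
    )

    def __post_init__(self) -> None:
        if "modern" not in self.values:
            raise ConfigurationError(
                "atmospheric reference must contain a 'modern' entry"
            )
        for epoch, v in self.values.items():
            if not (-10.0 <= v <= 0.0):
                raise ConfigurationError(
                    f"atmospheric δ¹³C for {epoch!r} = {v} outside [-10, 0] ‰"
                )

    def __getitem__(self, epoch: str) -> float:
        try:
            return self.values[epoch]
        except KeyError:
            raise ConfigurationError(
                f"no atmospheric δ¹³C reference for epoch {epoch!r}"
            ) from None


@dataclass(frozen=True)
class EnrichmentConstant:
    """Diet → enamel ¹³C enrichment for large herbivores, ‰ (default 14.1)."""

    diet_to_enamel_enrichment: float = 14.1

    def __post_init__(self) -> None:
        if self.diet_to_enamel_enrichment <= 0:
            raise ConfigurationError("enrichment factor must be positive")


def delta_from_ratios(r_sample: float, r_standard: float) -> float:
    """δ value (‰) from raw isotope ratios: (R_sample/R_standard − 1) × 1000."""
    if not (math.isfinite(r_sample) and math.isfinite(r_standard)):
        raise InvalidInputError("isotope ratios must be finite")
    if r_standard <= 0:
        raise InvalidInputError(f"standard ratio must be > 0, got {r_standard}")
    if r_sample < 0:
        raise InvalidInputError(f"sample ratio must be >= 0, got {r_sample}")
    return (r_sample / r_standard - 1.0) * 1000.0


def vsmow_to_vpdb(d18o_vsmow: float) -> float:
    """Convert δ¹⁸O from the VSMOW scale to VPDB: (x − 30.91)/1.03091."""
    if not math.isfinite(d18o_vsmow):
        raise InvalidInputError("δ¹⁸O must be finite")
    return (d18o_vsmow - _VSMOW_OFFSET) / _VSMOW_SLOPE


def vpdb_to_vsmow(d18o_vpdb: float) -> float:
    """Inverse of :func:`vsmow_to_vpdb`: x × 1.03091 + 30.91."""
    if not math.isfinite(d18o_vpdb):
        raise InvalidInputError("δ¹⁸O must be finite")
    return d18o_vpdb * _VSMOW_SLOPE + _VSMOW_OFFSET


def diet_meq_from_enamel(
    d13c_enamel: float,
    epoch: str,
    atm: AtmosphericReference | None = None,
    enrichment: EnrichmentConstant | None = None,
) -> float:
    """Enamel δ¹³C → modern-equivalent diet δ¹³C (δ¹³C_diet-meq), ‰ VPDB.

    Subtracts the diet–enamel enrichment and shifts by the difference in
    atmospheric CO₂ δ¹³C between the formation epoch and the modern
    atmosphere::

        diet_meq = enamel − enrichment + (δ¹³C_atm[epoch] − δ¹³C_atm[modern])

    With the default constants the net offset is −12.6 ‰ for Pleistocene
    enamel (−14.1 + 1.5) and −14.1 ‰ for modern enamel.  The transform is a
    pure translation, so differences between samples are preserved.
    """
    atm = atm or AtmosphericReference()
    enrichment = enrichment or EnrichmentConstant()
    if not math.isfinite(d13c_enamel):
        raise InvalidInputError("δ¹³C_enamel must be finite")
    return (
        d13c_enamel
        - enrichment.diet_to_enamel_enrichment
        + (atm[epoch] - atm["modern"])
    )


def enamel_from_diet_meq(
    d13c_diet_meq: float,
    epoch: str,
    atm: AtmosphericReference | None = None,
    enrichment: EnrichmentConstant | None = None,
) -> float:
    """Inverse of :func:`diet_meq_from_enamel` (used by the simulator)."""
    atm = atm or AtmosphericReference()
    enrichment = enrichment or EnrichmentConstant()
    return (
        d13c_diet_meq
        + enrichment.diet_to_enamel_enrichment
        - (atm[epoch] - atm["modern"])
    )


def round_permil(value: float, ndigits: int = 2) -> float:
    """Round a ‰ value for reporting (correctly rounded decimal semantics).

    Tables report 2 decimals, prose summaries 1; internal computation always
    stays at full precision.
    """
    return round(value, ndigits)


def pooled_values(
    profiles: Iterable[SpecimenProfile],
    analyte: str,
    atm: AtmosphericReference | None = None,
    enrichment: EnrichmentConstant | None = None,
) -> list[float]:
    """Union of non-missing values of ``analyte`` across several profiles."""
    out: list[float] = []
    for p in profiles:
        out.extend(p.values(analyte, atm, enrichment))
    return out
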