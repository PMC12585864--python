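"""Readers/writers, run configuration, and the end-to-end pipeline.

The serial table format is delimited text (comma or tab) with header
columns ``specimen_id, taxon, epoch, age_years, sample_label,
position_index, d13C_enamel_vpdb, d18O_vpdb``; an empty cell is a missing
measurement.  A bundled dataset in this format carries the serial enamel
measurements of three Pleistocene *Palaeoloxodon* molars from the Taiwan
Strait and one modern *Elephas maximus* molar.

The comparative format is CSV with columns ``taxon, epoch, analyte,
individual_id, value_permil, provenance`` (one row per individual).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .core import (
    AtmosphericReference,
    EnrichmentConstant,
    InvalidInputError,
    SerialSample,
    SpecimenProfile,
    diet_meq_from_enamel,
    round_permil,
)
from .comparative import TaxonDataset, compare_focal_vs_all, collapse_serial_to_individual
from .diet import MixingModel, VegetationScheme, c4_fraction, classify_vegetation, specimen_c4_range
from .profiles import (
    DEFAULT_EXTENSION_RATE,
    detect_ontogenetic_shift,
    pooled_summary,
    summarize_profile,
)

log = logging.getLogger("enameliso")

__all__ = [
    "RunConfig",
    "SERIAL_COLUMNS",
    "bundled_serial_table_path",
    "read_serial_table",
    "write_serial_table",
    "read_comparative_table",
    "run_full_pipeline",
]

SERIAL_COLUMNS = [
    "specimen_id",
    "taxon",
    "epoch",
    "age_years",
    "sample_label",
    "position_index",
    "d13C_enamel_vpdb",
    "d18O_vpdb",
]

_UNICODE_MINUS = "−"
_EN_DASH = "–"


@dataclass(frozen=True)
class RunConfig:
    """All tunable constants of the pipeline, with field defaults.

    Round-trips losslessly through ``to_dict``/``from_dict`` (hence JSON).
    """

    atm_d13c: dict[str, float] = field(
        default_factory=lambda: {"pliocene": -6.3, "pleistocene": -6.5, "modern": -8.0}
    )
    enrichment_permil: float = 14.1
    c4_end_member: float = -7.6
    c3_end_member: float = -34.6
    shift_early_window: int = 3
    shift_threshold: float = 2.0
    extension_rate_mm_per_yr: float = DEFAULT_EXTENSION_RATE
    n_boot: int = 2000
    seed: int = 0
    table_decimals: int = 2
    summary_decimals: int = 1

    @property
    def atm(self) -> AtmosphericReference:
        return AtmosphericReference(dict(self.atm_d13c))

    @property
    def enrichment(self) -> EnrichmentConstant:
        return EnrichmentConstant(self.enrichment_permil)

    @property
    def mixing(self) -> MixingModel:
        return MixingModel(self.c4_end_member, self.c3_end_member)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


def bundled_serial_table_path() -> Path:
    """Path to the bundled Taiwan Strait / modern reference serial table."""
    return Path(resources.files("enameliso").joinpath("data/taiwan_strait_serial.csv"))


def _parse_age(text: str) -> float | tuple[float, float] | None:
    text = text.strip().replace(_EN_DASH, "-")
    if not text or text.upper() == "NA":
        return None
    # interval like "24-27" (leading '-' would be a negative age, rejected)
    if "-" in text[1:]:
        head, _, tail = text.partition("-") if not text.startswith("-") else (
            text[1:].partition("-")
        )
        try:
            return (float(head), float(tail))
        except ValueError:
            pass
    return float(text)


def _clean_number(cell) -> float | None:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None
    s = str(cell).strip().replace(_UNICODE_MINUS, "-")
    if s in ("", "_", "-", "NA", "nan"):
        return None
    return float(s)


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a comma- or tab-separated table (delimiter sniffed from header)."""
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.readline()
    sep = "\t" if head.count("\t") > head.count(",") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_serial_table(path: str | Path) -> list[SpecimenProfile]:
    """Parse a serial table into specimen profiles (growth order).

    Empty analyte cells become missing samples.  Duplicate (specimen,
    position) pairs and unrecognized epochs are hard errors reported with
    the offending row number; an empty file yields an empty list with a
    warning.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        log.warning("serial table %s is empty", path)
        return []
    df = _read_delimited(path)
    missing_cols = [c for c in SERIAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise InvalidInputError(
            f"serial table {path} lacks required columns {missing_cols}"
        )
    if df.empty:
        log.warning("serial table %s has a header but no rows", path)
        return []

    profiles: list[SpecimenProfile] = []
    for specimen_id, group in df.groupby("specimen_id", sort=False):
        samples = []
        seen_positions: set[int] = set()
        for row_ix, row in group.iterrows():
            pos = int(row["position_index"])
            if pos in seen_positions:
                raise InvalidInputError(
                    f"duplicate position {pos} for specimen {specimen_id!r} "
                    f"(row {row_ix + 2})"
                )
            seen_positions.add(pos)
            samples.append(
                SerialSample(
                    sample_label=row["sample_label"],
                    position_index=pos,
                    d13C_enamel=_clean_number(row["d13C_enamel_vpdb"]),
                    d18O=_clean_number(row["d18O_vpdb"]),
                )
            )
        epoch = group["epoch"].iloc[0].strip().lower()
        if epoch not in ("pliocene", "pleistocene", "modern"):
            first_row = int(group.index[0]) + 2
            raise InvalidInputError(
                f"unknown epoch {epoch!r} for specimen {specimen_id!r} "
                f"(row {first_row})"
            )
        profiles.append(
            SpecimenProfile(
                specimen_id=str(specimen_id),
                taxon=group["taxon"].iloc[0],
                epoch=epoch,
                samples=tuple(samples),
                ontogenetic_age_years=_parse_age(group["age_years"].iloc[0]),
            )
        )
    log.info("parsed %d profiles (%d rows) from %s", len(profiles), len(df), path)
    return profiles


def _format_age(age) -> str:
    if age is None:
        return ""
    if isinstance(age, tuple):
        return f"{age[0]:g}-{age[1]:g}"
    return f"{age:g}"


def write_serial_table(profiles: list[SpecimenProfile], path: str | Path) -> None:
    """Write profiles back to the serial table format (lossless round trip)."""
    rows = []
    for p in profiles:
        for s in p.samples:
            rows.append(
                {
                    "specimen_id": p.specimen_id,
                    "taxon": p.taxon,
                    "epoch": p.epoch,
                    "age_years": _format_age(p.ontogenetic_age_years),
                    "sample_label": s.sample_label,
                    "position_index": s.position_index,
                    "d13C_enamel_vpdb": "" if s.d13C_enamel is None else repr(float(s.d13C_enamel)),
                    "d18O_vpdb": "" if s.d18O is None else repr(float(s.d18O)),
                }
            )
    pd.DataFrame(rows, columns=SERIAL_COLUMNS).to_csv(path, index=False)


def read_comparative_table(path: str | Path) -> list[TaxonDataset]:
    """Parse a per-individual comparative table into taxon datasets."""
    df = _read_delimited(path)
    required = ["taxon", "epoch", "analyte", "individual_id", "value_permil"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise InvalidInputError(
            f"comparative table {path} lacks required columns {missing_cols}"
        )
    datasets = []
    for (taxon, epoch, analyte), g in df.groupby(
        ["taxon", "epoch", "analyte"], sort=False
    ):
        provenance = (
            g["provenance"].iloc[0] if "provenance" in g.columns else "bulk"
        )
        values = tuple(_clean_number(v) for v in g["value_permil"])
        if any(v is None for v in values):
            raise InvalidInputError(
                f"missing value_permil for taxon {taxon!r} in {path}"
            )
        datasets.append(
            TaxonDataset(
                taxon=taxon, epoch=epoch.strip().lower(), analyte=analyte,
                values=values, provenance=provenance,
            )
        )
    return datasets


def _summary_dict(s, decimals: int) -> dict:
    return {
        "analyte": s.analyte,
        "n": s.n,
        "mean": round_permil(s.mean, decimals),
        "sd": None if s.sd is None else round_permil(s.sd, decimals),
        "min": round_permil(s.min, decimals),
        "max": round_permil(s.max, decimals),
    }


def run_full_pipeline(
    config: RunConfig,
    serial_path: str | Path,
    comparative_path: str | Path | None = None,
    out_dir: str | Path | None = None,
    focal_taxon: str | None = None,
) -> dict:
    """Run every stage on one serial table; optionally write a report bundle.

    Produces per-sample conversions (diet-meq values, vegetation classes,
    C₄ percentages), per-specimen and pooled summaries, shift reports, and
    — when a comparative table is supplied — the cross-taxa comparison for
    both analytes.  Deterministic for a fixed config (seed included).
    """
    atm, enr, mix = config.atm, config.enrichment, config.mixing
    scheme = VegetationScheme.diet_meq(enr)
    profiles = read_serial_table(serial_path)

    sample_rows = []
    for p in profiles:
        for s in p.samples:
            if s.d13C_enamel is None:
                meq = veg = pct = None
            else:
                meq = diet_meq_from_enamel(s.d13C_enamel, p.epoch, atm, enr)
                veg = classify_vegetation(meq, scheme)
                pct = round_permil(c4_fraction(meq, mix).percent, 1)
            sample_rows.append(
                {
                    "specimen_id": p.specimen_id,
                    "sample_label": s.sample_label,
                    "position_index": s.position_index,
                    "d13C_enamel": s.d13C_enamel,
                    "d13C_diet_meq": None if meq is None else round_permil(meq, config.table_decimals),
                    "d18O": s.d18O,
                    "vegetation_class": veg,
                    "c4_percent": pct,
                }
            )

    per_specimen = {}
    for p in profiles:
        block: dict = {"taxon": p.taxon, "epoch": p.epoch, "summaries": {}, "shifts": {}}
        for analyte in ("d13C_enamel", "d13C_diet_meq", "d18O"):
            if p.values(analyte, atm, enr):
                block["summaries"][analyte] = _summary_dict(
                    summarize_profile(p, analyte, atm, enr), config.summary_decimals
                )
                rep = detect_ontogenetic_shift(
                    p, analyte, config.shift_early_window, config.shift_threshold,
                    atm, enr,
                )
                block["shifts"][analyte] = {
                    "evaluable": rep.evaluable,
                    "detected": rep.detected,
                    "effect": None if rep.effect is None else round(rep.effect, 2),
                    "direction": rep.direction,
                }
        if p.values("d13C_enamel", atm, enr):
            rng = specimen_c4_range(p, mix, atm, enr)
            block["c4_percent"] = {
                "min": round_permil(rng.min_percent, 1),
                "max": round_permil(rng.max_percent, 1),
                "mean": round_permil(rng.mean_percent, 1),
            }
        per_specimen[p.specimen_id] = block

    pooled = {}
    fossil = [p for p in profiles if p.epoch != "modern"]
    if fossil:
        for analyte in ("d13C_enamel", "d13C_diet_meq", "d18O"):
            pooled[analyte] = _summary_dict(
                pooled_summary(fossil, analyte, atm, enr), config.summary_decimals
            )

    report = {
        "config": config.to_dict(),
        "n_profiles": len(profiles),
        "per_specimen": per_specimen,
        "pooled_non_modern": pooled,
    }

    if comparative_path is not None:
        datasets = read_comparative_table(comparative_path)
        focal = focal_taxon or (profiles[0].taxon if profiles else None)
        comparisons = {}
        for analyte in ("d13C_diet_meq", "d18O"):
            serial_ds = [
                collapse_serial_to_individual(
                    [p], analyte, atm, enr, taxon=focal, epoch=p.epoch
                )
                for p in fossil
            ]
            literature = [d for d in datasets if d.analyte == analyte]
            if serial_ds and literature:
                merged = TaxonDataset(
                    taxon=focal,
                    epoch=serial_ds[0].epoch,
                    analyte=analyte,
                    values=tuple(v for d in serial_ds for v in d.values),
                    provenance="serial_collapsed",
                )
                pool = [merged] + literature
                comparisons[analyte] = [
                    dataclasses.asdict(r)
                    for r in compare_focal_vs_all(
                        pool, focal, analyte, n_boot=config.n_boot, seed=config.seed
                    )
                ]
        report["comparisons"] = comparisons

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(sample_rows).to_csv(out / "per_sample.csv", index=False)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        log.info("report bundle written to %s", out)

    report["per_sample"] = sample_rows
    return report
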