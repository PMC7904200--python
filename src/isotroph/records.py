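"""Domain records, delta-notation arithmetic, and delimited-text table IO.

Two tabular inputs drive the whole analysis: consumer records (one row per
tuna x tissue, bulk delta13C/delta15N plus optional amino-acid delta15N) and
zooplankton station records (coordinates, bulk isotopes, optional
phenylalanine delta15N, and a baseline-region flag).  Tables are plain CSV
with a header row; column names can be remapped through a dialect mapping.

Isotope values are carried in per-mil (permil) delta notation throughout:
delta15N relative to atmospheric N2, delta13C relative to VPDB.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

import pandas as pd


class Tissue(str, enum.Enum):
    MUSCLE = "muscle"
    LIVER = "liver"


class Region(str, enum.Enum):
    NORTH = "north"
    CENTRAL_SOUTH = "central_south"
    OUTSIDE = "outside"


class PheSource(str, enum.Enum):
    MEASURED = "measured"
    PREDICTED = "predicted"
    ABSENT = "absent"


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class RowError(ValueError):
    """A row failed validation; carries the zero-based row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


def delta_from_ratios(r_sample: float, r_standard: float) -> float:
    """Convert an absolute heavy/light isotope ratio to delta notation (permil).

    delta = (R_sample / R_standard - 1) * 1000.  Provided as a utility; the
    pipeline's inputs are already expressed in permil.
    """
    if r_standard <= 0:
        raise ValueError(f"standard ratio must be positive, got {r_standard}")
    if r_sample < 0:
        raise ValueError(f"sample ratio must be non-negative, got {r_sample}")
    return (r_sample / r_standard - 1.0) * 1000.0


@dataclass
class ConsumerRecord:
    """One tuna x tissue isotope measurement set."""

    id: str
    year: int
    tissue: Tissue
    d13C: float
    d15N: float
    cfl_cm: float | None = None
    cn_ratio: float | None = None
    d15N_phe: float | None = None
    d15N_glu: float | None = None

    def __post_init__(self):
        self.tissue = Tissue(self.tissue)
        if self.cfl_cm is not None and not self.cfl_cm > 0:
            raise ValueError(f"cfl_cm must be positive, got {self.cfl_cm}")
        if self.cn_ratio is not None and not self.cn_ratio > 0:
            raise ValueError(f"cn_ratio must be positive, got {self.cn_ratio}")
        for name in ("d13C", "d15N"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"{name} must be a finite permil value, got {v}")


@dataclass
class StationRecord:
    """One zooplankton station: coordinates, bulk isotopes, optional Phe."""

    cruise: str
    station: str
    lon: float
    lat: float
    d13C: float
    d15N: float
    d15N_phe: float | None = None
    phe_source: PheSource = PheSource.ABSENT
    region: Region = Region.OUTSIDE

    def __post_init__(self):
        self.phe_source = PheSource(self.phe_source)
        self.region = Region(self.region)
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range: {self.lon}")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat}")
        if self.phe_source is not PheSource.ABSENT and self.d15N_phe is None:
            raise ValueError("phe_source set but d15N_phe missing")
        if self.phe_source is PheSource.ABSENT and self.d15N_phe is not None:
            # a value with no provenance flag defaults to a measurement
            self.phe_source = PheSource.MEASURED


@dataclass
class TEF:
    """Bulk trophic enrichment factor (diet -> consumer tissue), per isotope."""

    tissue: Tissue
    dC_mean: float
    dC_sd: float
    dN_mean: float
    dN_sd: float

    def __post_init__(self):
        self.tissue = Tissue(self.tissue)
        if self.dC_sd < 0 or self.dN_sd < 0:
            raise ValueError("TEF standard deviations must be >= 0")


@dataclass
class AminoAcidTDF:
    """Trophic discrimination factor (Glu - Phe per trophic level) and beta.

    beta is the delta15N spread between trophic and source amino acids in
    primary producers (3.4 +/- 0.9 permil for aquatic photoautotrophs).
    """

    tdf_mean: float
    tdf_sd: float
    beta_mean: float = 3.4
    beta_sd: float = 0.9

    def __post_init__(self):
        if self.tdf_mean <= 0:
            raise ValueError("tdf_mean must be positive")
        if self.tdf_sd < 0 or self.beta_sd < 0:
            raise ValueError("sd fields must be >= 0")


@dataclass
class AnalyticalPrecision:
    """Analytical reproducibility (one SD) of the isotope measurements."""

    sd_bulk_d15N: float = 0.2
    sd_phe: float = 0.5
    sd_glu: float = 0.4

    def __post_init__(self):
        if min(self.sd_bulk_d15N, self.sd_phe, self.sd_glu) < 0:
            raise ValueError("analytical SDs must be >= 0")


def flag_lipid_bias(record: ConsumerRecord, threshold: float = 3.5) -> bool:
    """Flag a consumer record whose C:N ratio suggests lipid bias in delta13C.

    Returns True iff the C:N ratio is present and exceeds ``threshold``
    (default 3.5, the conventional cutoff for fish muscle).  The flag is
    advisory only: no arithmetic correction is ever applied to delta13C.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return record.cn_ratio is not None and record.cn_ratio > threshold


# --- table IO ---------------------------------------------------------------

_CONSUMER_REQUIRED = ("id", "year", "tissue", "d13C", "d15N")
_CONSUMER_OPTIONAL = ("cfl_cm", "cn_ratio", "d15N_phe", "d15N_glu")
_STATION_REQUIRED = ("cruise", "station", "lon", "lat", "d13C", "d15N")
_STATION_OPTIONAL = ("d15N_phe", "phe_source", "region")


def _remap(df: pd.DataFrame, columns: Mapping[str, str] | None) -> pd.DataFrame:
    if columns:
        df = df.rename(columns={v: k for k, v in columns.items()})
    return df


def _cell(row, name):
    if name not in row or pd.isna(row[name]):
        return None
    return row[name]


def _float_cell(row, name, idx):
    v = _cell(row, name)
    if v is None:
        return None
    try:
        return float(v)
    except (TypeError, ValueError):
        raise RowError(idx, f"column {name!r}: cannot parse {v!r} as a number")


def read_consumer_table(
    path, columns: Mapping[str, str] | None = None
) -> list[ConsumerRecord]:
    """Read a consumer CSV into validated records.

    ``columns`` maps canonical names (id, year, tissue, d13C, d15N, cfl_cm,
    cn_ratio, d15N_phe, d15N_glu) to the file's actual header names.
    Optional columns may be absent entirely; empty cells become None.
    """
    df = _remap(pd.read_csv(path), columns)
    missing = [c for c in _CONSUMER_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    out = []
    for idx, row in enumerate(df.to_dict(orient="records")):
        tissue = _cell(row, "tissue")
        try:
            tissue = Tissue(str(tissue).strip().lower())
        except ValueError:
            raise RowError(idx, f"invalid tissue {tissue!r}")
        year = _float_cell(row, "year", idx)
        if year is None:
            raise RowError(idx, "missing year")
        try:
            rec = ConsumerRecord(
                id=str(_cell(row, "id")),
                year=int(year),
                tissue=tissue,
                d13C=_float_cell(row, "d13C", idx),
                d15N=_float_cell(row, "d15N", idx),
                cfl_cm=_float_cell(row, "cfl_cm", idx),
                cn_ratio=_float_cell(row, "cn_ratio", idx),
                d15N_phe=_float_cell(row, "d15N_phe", idx),
                d15N_glu=_float_cell(row, "d15N_glu", idx),
            )
        except ValueError as e:
            if isinstance(e, RowError):
                raise
            raise RowError(idx, str(e))
        out.append(rec)
    return out


def read_station_table(
    path, columns: Mapping[str, str] | None = None
) -> list[StationRecord]:
    """Read a zooplankton station CSV into validated records.

    The ``region`` column holds the explicit baseline-region flags
    (north / central_south); rows without a flag are labelled ``outside``.
    """
    df = _remap(pd.read_csv(path), columns)
    missing = [c for c in _STATION_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    out = []
    for idx, row in enumerate(df.to_dict(orient="records")):
        region = _cell(row, "region")
        try:
            region = Region(str(region).strip().lower()) if region else Region.OUTSIDE
        except ValueError:
            raise RowError(idx, f"invalid region {region!r}")
        phe = _float_cell(row, "d15N_phe", idx)
        src = _cell(row, "phe_source")
        if src is not None:
            try:
                src = PheSource(str(src).strip().lower())
            except ValueError:
                raise RowError(idx, f"invalid phe_source {src!r}")
        else:
            src = PheSource.MEASURED if phe is not None else PheSource.ABSENT
        try:
            rec = StationRecord(
                cruise=str(_cell(row, "cruise")),
                station=str(_cell(row, "station")),
                lon=_float_cell(row, "lon", idx),
                lat=_float_cell(row, "lat", idx),
                d13C=_float_cell(row, "d13C", idx),
                d15N=_float_cell(row, "d15N", idx),
                d15N_phe=phe,
                phe_source=src,
                region=region,
            )
        except ValueError as e:
            if isinstance(e, RowError):
                raise
            raise RowError(idx, str(e))
        out.append(rec)
    return out


def consumers_to_frame(records: Iterable[ConsumerRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {f.name: getattr(r, f.name) for f in fields(r)}
        d["tissue"] = r.tissue.value
        rows.append(d)
    return pd.DataFrame(rows, columns=list(_CONSUMER_REQUIRED + _CONSUMER_OPTIONAL))


def stations_to_frame(records: Iterable[StationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {f.name: getattr(r, f.name) for f in fields(r)}
        d["region"] = r.region.value
        d["phe_source"] = r.phe_source.value
        rows.append(d)
    return pd.DataFrame(rows, columns=list(_STATION_REQUIRED + _STATION_OPTIONAL))


def write_consumer_table(records: Sequence[ConsumerRecord], path) -> None:
    consumers_to_frame(records).to_csv(path, index=False)


def write_station_table(records: Sequence[StationRecord], path) -> None:
    stations_to_frame(records).to_csv(path, index=False)
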