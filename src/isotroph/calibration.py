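"""Bulk-to-phenylalanine delta15N calibration.

Zooplankton delta15N of phenylalanine (the canonical source amino acid)
tracks bulk delta15N closely but sits roughly 2 permil lower.  A single
gulf-wide ordinary-least-squares line of Phe on bulk extends the Phe
isoscape to stations where CSIA-AA was not run; measured Phe values always
override predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .records import PheSource, StationRecord


@dataclass
class CalibrationResult:
    """Fitted Phe-on-bulk line: delta15N_Phe = slope * delta15N_bulk + intercept."""

    slope: float
    intercept: float
    r: float
    n: int

    def __post_init__(self):
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation out of range: {self.r}")
        if self.n < 3:
            raise ValueError("calibration needs at least 3 pairs")

    def predict(self, d15N_bulk):
        """Predicted delta15N_Phe (permil) for bulk delta15N values."""
        return self.slope * np.asarray(d15N_bulk, dtype=float) + self.intercept

    def summary(self) -> str:
        return (
            f"Phe calibration: d15N_Phe = {self.slope:.3f} * d15N_bulk "
            f"{self.intercept:+.3f}  (r = {self.r:.3f}, n = {self.n})"
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"slope": self.slope, "intercept": self.intercept,
                 "r": self.r, "n": self.n},
                fh, indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "CalibrationResult":
        with open(path) as fh:
            return cls(**json.load(fh))


class PheCalibrationModel:
    """OLS model of station Phe delta15N on bulk delta15N.

    The regression direction is Phe on bulk (bulk is the predictor): the
    fitted line fills in Phe for stations measured for bulk isotopes only.
    """

    def __init__(self, d15n_bulk, d15n_phe):
        self.bulk = np.asarray(d15n_bulk, dtype=float)
        self.phe = np.asarray(d15n_phe, dtype=float)
        if self.bulk.shape != self.phe.shape or self.bulk.ndim != 1:
            raise ValueError("bulk and phe must be 1-D arrays of equal length")
        if len(self.bulk) < 3:
            raise ValueError("calibration needs at least 3 pairs")
        if np.ptp(self.bulk) == 0:
            raise ValueError("bulk values are all identical; slope is undefined")

    @classmethod
    def from_stations(cls, stations: Iterable[StationRecord]) -> "PheCalibrationModel":
        """Build from stations carrying a *measured* Phe value."""
        pairs = [
            (s.d15N, s.d15N_phe)
            for s in stations
            if s.phe_source is PheSource.MEASURED and s.d15N_phe is not None
        ]
        if len(pairs) < 3:
            raise ValueError(
                f"need >= 3 stations with measured Phe, got {len(pairs)}"
            )
        bulk, phe = zip(*pairs)
        return cls(bulk, phe)

    def fit(self) -> CalibrationResult:
        res = stats.linregress(self.bulk, self.phe)
        return CalibrationResult(
            slope=float(res.slope),
            intercept=float(res.intercept),
            r=float(res.rvalue),
            n=len(self.bulk),
        )


def fit_phe_calibration(pairs: Sequence[tuple[float, float]]) -> CalibrationResult:
    """Fit the calibration from (bulk, phe) pairs (functional wrapper)."""
    arr = np.asarray(pairs, dtype=float)
    return PheCalibrationModel(arr[:, 0], arr[:, 1]).fit()


def predict_phe(model: CalibrationResult, d15N_bulk: float) -> float:
    return float(model.predict(d15N_bulk))


def apply_calibration(
    stations: Sequence[StationRecord], model: CalibrationResult
) -> list[StationRecord]:
    """Fill missing station Phe values from the calibration line.

    Stations with measured Phe are returned unchanged; filled stations are
    flagged ``phe_source = predicted``.
    """
    out = []
    for s in stations:
        if s.d15N_phe is None:
            out.append(
                replace(
                    s,
                    d15N_phe=float(model.predict(s.d15N)),
                    phe_source=PheSource.PREDICTED,
                )
            )
        else:
            out.append(replace(s))
    return out


def mean_phe_offset(pairs: Sequence[tuple[float, float]]) -> float:
    """Mean bulk-minus-Phe offset (permil); descriptive only (ca. 2 permil)."""
    arr = np.asarray(pairs, dtype=float)
    return float(np.mean(arr[:, 0] - arr[:, 1]))
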