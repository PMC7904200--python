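"""Synthetic stand-ins for the study's unpublished supplementary tables.

The raw per-station and per-fish tables behind the published analysis were
distributed only as supplementary word-processor documents and are not
machine-readable here.  These generators build *synthetic* tables whose
group-level summary statistics (group sizes, means and sample SDs, and for
the calibration pairs the OLS slope/intercept/correlation) match the
published summaries exactly, by affinely standardising Gaussian draws.
Any statistic of these tables that depends only on the matched moments
reproduces the published value; higher-order features (skew, outliers,
within-group spatial structure) are synthetic and carry no information.

Published summaries encoded here:

* zooplankton baselines - north (n=28): delta15N 6.8 +/- 2.6, delta13C
  -21.3 +/- 0.9; central-south (n=61): 2.7 +/- 0.9, -20.1 +/- 0.8
* tuna tissues by year (n=14 in 2017, n=58 in 2018), muscle and liver bulk
  values, C:N, fork length, and the Glu/Phe subset (14 + 22 fish)
* bulk-vs-Phe calibration: slope 0.87, intercept -2.74, r 0.96, n=20
"""

from __future__ import annotations

import numpy as np

from .records import ConsumerRecord, PheSource, Region, StationRecord, Tissue


def _exact_moments(rng, n, mean, sd):
    """Gaussian draws standardised to the exact sample mean and SD (ddof=1)."""
    z = rng.standard_normal(n)
    z = z - z.mean()
    s = z.std(ddof=1)
    z = z / s if s > 0 else z
    return mean + sd * z


# year -> tissue -> (d13C, d15N, C:N) as (mean, sd); Phe/Glu cover the CSIA
# subset only (all 14 fish from 2017, 22 of 58 from 2018)
_CONSUMER_MOMENTS = {
    2017: {
        "n": 14,
        "n_csia": 14,
        "cfl": (134.9, 8.0),
        Tissue.MUSCLE: {"d13C": (-18.5, 0.8), "d15N": (10.0, 0.4),
                        "cn": (3.6, 0.4), "phe": (6.0, 1.2), "glu": (26.4, 0.5)},
        Tissue.LIVER: {"d13C": (-19.3, 0.4), "d15N": (7.8, 0.5),
                       "cn": (4.1, 0.3), "phe": (4.6, 0.6), "glu": (20.2, 0.6)},
    },
    2018: {
        "n": 58,
        "n_csia": 22,
        "cfl": (140.5, 6.9),
        Tissue.MUSCLE: {"d13C": (-17.8, 0.4), "d15N": (10.1, 0.8),
                        "cn": (3.3, 0.2), "phe": (6.5, 1.4), "glu": (25.3, 1.4)},
        Tissue.LIVER: {"d13C": (-18.7, 0.4), "d15N": (7.8, 0.7),
                       "cn": (4.2, 0.3), "phe": (4.1, 1.3), "glu": (19.1, 0.8)},
    },
}

_STATION_MOMENTS = {
    Region.NORTH: {"n": 28, "d15N": (6.8, 2.6), "d13C": (-21.3, 0.9),
                   "lat": (27.0, 29.8), "lon": (-97.0, -85.0)},
    Region.CENTRAL_SOUTH: {"n": 61, "d15N": (2.7, 0.9), "d13C": (-20.1, 0.8),
                           "lat": (18.5, 25.5), "lon": (-97.0, -84.0)},
}

CALIBRATION_SLOPE = 0.87
CALIBRATION_INTERCEPT = -2.74
CALIBRATION_R = 0.96
CALIBRATION_N = 20


def synthetic_station_table(seed: int = 0) -> list[StationRecord]:
    """Synthetic station table matching the published regional summaries."""
    rng = np.random.default_rng(seed)
    out = []
    for region, m in _STATION_MOMENTS.items():
        n = m["n"]
        d15N = _exact_moments(rng, n, *m["d15N"])
        d13C = _exact_moments(rng, n, *m["d13C"])
        lat = rng.uniform(*m["lat"], n)
        lon = rng.uniform(*m["lon"], n)
        for i in range(n):
            out.append(
                StationRecord(
                    cruise="SYNTH",
                    station=f"{region.value[:1].upper()}{i + 1:03d}",
                    lon=float(lon[i]),
                    lat=float(lat[i]),
                    d13C=float(d13C[i]),
                    d15N=float(d15N[i]),
                    region=region,
                )
            )
    return out


def synthetic_consumer_table(seed: int = 0) -> list[ConsumerRecord]:
    """Synthetic tuna table matching the published year x tissue summaries."""
    rng = np.random.default_rng(seed)
    out = []
    for year, spec in _CONSUMER_MOMENTS.items():
        n, n_csia = spec["n"], spec["n_csia"]
        cfl = _exact_moments(rng, n, *spec["cfl"]).clip(100, 180)
        per_tissue = {}
        for tissue in (Tissue.MUSCLE, Tissue.LIVER):
            mm = spec[tissue]
            per_tissue[tissue] = {
                "d13C": _exact_moments(rng, n, *mm["d13C"]),
                "d15N": _exact_moments(rng, n, *mm["d15N"]),
                "cn": _exact_moments(rng, n, *mm["cn"]),
                "phe": _exact_moments(rng, n_csia, *mm["phe"]),
                "glu": _exact_moments(rng, n_csia, *mm["glu"]),
            }
        for i in range(n):
            for tissue in (Tissue.MUSCLE, Tissue.LIVER):
                v = per_tissue[tissue]
                in_csia = i < n_csia
                out.append(
                    ConsumerRecord(
                        id=f"YFT-{year}-{i + 1:03d}",
                        year=year,
                        tissue=tissue,
                        d13C=float(v["d13C"][i]),
                        d15N=float(v["d15N"][i]),
                        cfl_cm=float(cfl[i]),
                        cn_ratio=float(v["cn"][i]),
                        d15N_phe=float(v["phe"][i]) if in_csia else None,
                        d15N_glu=float(v["glu"][i]) if in_csia else None,
                    )
                )
    return out


def synthetic_calibration_pairs(seed: int = 0) -> np.ndarray:
    """Synthetic (bulk, phe) pairs with the published OLS fit, exactly.

    Residuals are orthogonalised against the predictor and rescaled so the
    fitted slope, intercept and Pearson r equal the published 0.87, -2.74
    and 0.96 to machine precision.  Returns a (20, 2) array.
    """
    rng = np.random.default_rng(seed)
    n = CALIBRATION_N
    bulk = _exact_moments(rng, n, 4.0, 2.6)
    xc = bulk - bulk.mean()
    e = rng.standard_normal(n)
    e = e - e.mean()
    e = e - xc * (e @ xc) / (xc @ xc)
    # with e orthogonal to x, r^2 = b^2 sx^2 / (b^2 sx^2 + se^2)
    se_target = (
        abs(CALIBRATION_SLOPE) * bulk.std(ddof=1)
        * np.sqrt(1.0 / CALIBRATION_R ** 2 - 1.0)
    )
    e *= se_target / e.std(ddof=1)
    phe = CALIBRATION_INTERCEPT + CALIBRATION_SLOPE * bulk + e
    return np.column_stack([bulk, phe])


def pooled_muscle_mean_d15N() -> float:
    """n-weighted pooled muscle bulk delta15N from the published year means."""
    m = _CONSUMER_MOMENTS
    n1, n2 = m[2017]["n"], m[2018]["n"]
    return (
        n1 * m[2017][Tissue.MUSCLE]["d15N"][0]
        + n2 * m[2018][Tissue.MUSCLE]["d15N"][0]
    ) / (n1 + n2)


def pooled_csia_means(tissue: Tissue = Tissue.MUSCLE) -> tuple[float, float]:
    """n-weighted (Glu, Phe) means over the CSIA subset (n = 14 + 22)."""
    m = _CONSUMER_MOMENTS
    n1, n2 = m[2017]["n_csia"], m[2018]["n_csia"]
    glu = (n1 * m[2017][tissue]["glu"][0] + n2 * m[2018][tissue]["glu"][0]) / (n1 + n2)
    phe = (n1 * m[2017][tissue]["phe"][0] + n2 * m[2018][tissue]["phe"][0]) / (n1 + n2)
    return glu, phe
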