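"""Phenotype aggregation: entry means, BLUEs, variance components, h2.

Operates on long-format plot records (line, year, replicate, score).
Random components (genotype, year, genotype-by-year, residual) are
estimated by method of moments from the expected mean squares of the
balanced two-way classification; the genotype effect is refit as fixed
(ordinary least squares with year as a covariate) to obtain per-line
best linear unbiased estimates on the score scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VarianceComponents",
    "validate_records",
    "year_correlation",
    "variance_components",
    "heritability",
    "compute_blues",
]

REQUIRED_COLUMNS = ("line", "year", "replicate", "score")


class PhenotypeError(ValueError):
    """Invalid phenotype records or inestimable quantity."""


class ZeroVarianceError(PhenotypeError):
    """Correlation undefined because one year has no variance."""


@dataclass(frozen=True)
class VarianceComponents:
    """Variance partition of the two-way (genotype x year) model.

    Inestimable components (single year, single replicate) are NaN.
    """

    sigma2_g: float
    sigma2_y: float
    sigma2_gy: float
    sigma2_r: float
    n_years: int
    n_replicates: int

    def __post_init__(self):
        if self.n_years < 1 or self.n_replicates < 1:
            raise PhenotypeError("n_years and n_replicates must be >= 1")
        for name in ("sigma2_g", "sigma2_y", "sigma2_gy", "sigma2_r"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise PhenotypeError(f"{name} must be >= 0 (or NaN if inestimable)")


def validate_records(records: pd.DataFrame, check_scale: bool = False) -> pd.DataFrame:
    """Check schema and key uniqueness; returns a typed copy."""
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise PhenotypeError(f"phenotype records missing columns: {missing}")
    rec = records[list(REQUIRED_COLUMNS)].copy()
    rec["line"] = rec["line"].astype(str)
    rec["year"] = rec["year"].astype(str)
    rec["replicate"] = rec["replicate"].astype(str)
    rec["score"] = rec["score"].astype(float)
    if rec.empty:
        raise PhenotypeError("phenotype records are empty")
    if rec["score"].isna().any():
        raise PhenotypeError("NaN scores in phenotype records")
    dup = rec.duplicated(subset=["line", "year", "replicate"])
    if dup.any():
        raise PhenotypeError(
            f"duplicate (line, year, replicate) keys: {rec.loc[dup].head(3).to_dict('records')}"
        )
    if check_scale and ((rec["score"] < 1) | (rec["score"] > 7)).any():
        raise PhenotypeError("scores outside the 1-7 scale")
    return rec


def year_correlation(records: pd.DataFrame) -> float:
    """Pearson correlation of per-line year means between the two years.

    With more than two years, the mean of all pairwise correlations is
    returned.  Lines must be present in both years of a pair to count.
    """
    rec = validate_records(records)
    means = rec.groupby(["line", "year"], sort=True)["score"].mean().unstack("year")
    years = list(means.columns)
    if len(years) < 2:
        raise PhenotypeError("year_correlation needs at least two years")
    cors = []
    for i in range(len(years)):
        for j in range(i + 1, len(years)):
            pair = means[[years[i], years[j]]].dropna()
            a = pair.iloc[:, 0].to_numpy()
            b = pair.iloc[:, 1].to_numpy()
            if len(pair) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
                raise ZeroVarianceError(
                    f"correlation undefined between {years[i]} and {years[j]}"
                )
            cors.append(float(np.corrcoef(a, b)[0, 1]))
    return float(np.mean(cors))


def _balanced_cube(rec: pd.DataFrame) -> np.ndarray | None:
    """Scores as a (lines, years, reps) array on the balanced subset.

    Keeps lines observed in every year and truncates each (line, year)
    cell to the smallest common replicate count.  Returns None if no
    balanced subset exists.
    """
    counts = rec.groupby(["line", "year"]).size().unstack("year")
    full = counts.dropna().index
    if len(full) == 0:
        return None
    r = int(counts.loc[full].min().min())
    sub = rec[rec["line"].isin(full)].sort_values(["line", "year", "replicate"])
    sub = sub.groupby(["line", "year"]).head(r)
    cube = (
        sub.set_index(["line", "year"])
        .groupby(["line", "year"])["score"]
        .apply(lambda s: s.to_numpy())
    )
    lines = sorted(full)
    years = sorted(rec["year"].unique())
    arr = np.empty((len(lines), len(years), r))
    for i, ln in enumerate(lines):
        for t, yr in enumerate(years):
            arr[i, t, :] = cube.loc[(ln, yr)][:r]
    return arr


def variance_components(records: pd.DataFrame) -> VarianceComponents:
    """Method-of-moments components from the balanced two-way ANOVA.

    Model: score = mu + G + Y + GxY + e, all effects random.  Expected
    mean squares of the balanced layout are solved for the components;
    negative solutions are truncated at zero.  With a single year the
    year and GxY components are inestimable (NaN); with a single
    replicate the residual is inestimable (NaN) and GxY absorbs it.
    """
    rec = validate_records(records)
    arr = _balanced_cube(rec)
    if arr is None:
        raise PhenotypeError("no line is observed in every year; cannot balance")
    g, y, r = arr.shape
    if g < 2:
        raise PhenotypeError("need at least two lines to estimate genetic variance")
    gm = arr.mean()
    m_g = arr.mean(axis=(1, 2))
    m_y = arr.mean(axis=(0, 2))
    m_gy = arr.mean(axis=2)

    ms_g = y * r * np.sum((m_g - gm) ** 2) / (g - 1)
    ms_y = g * r * np.sum((m_y - gm) ** 2) / (y - 1) if y > 1 else np.nan
    ms_gy = (
        r * np.sum((m_gy - m_g[:, None] - m_y[None, :] + gm) ** 2) / ((g - 1) * (y - 1))
        if y > 1
        else np.nan
    )
    ms_e = np.sum((arr - m_gy[:, :, None]) ** 2) / (g * y * (r - 1)) if r > 1 else np.nan

    if y == 1:
        s2_y = s2_gy = np.nan
        s2_r = ms_e if r > 1 else np.nan
        s2_g = (ms_g - (ms_e if r > 1 else 0.0)) / r
    elif r == 1:
        s2_r = np.nan
        s2_gy = np.nan  # confounded with residual at one replicate
        s2_g = (ms_g - ms_gy) / (y * r)
        s2_y = (ms_y - ms_gy) / (g * r)
    else:
        s2_r = ms_e
        s2_gy = (ms_gy - ms_e) / r
        s2_g = (ms_g - ms_gy) / (y * r)
        s2_y = (ms_y - ms_gy) / (g * r)

    def trunc(v):
        return v if math.isnan(v) else max(0.0, float(v))

    return VarianceComponents(
        sigma2_g=trunc(s2_g),
        sigma2_y=trunc(s2_y),
        sigma2_gy=trunc(s2_gy),
        sigma2_r=trunc(s2_r),
        n_years=y,
        n_replicates=r,
    )


def heritability(vc: VarianceComponents, as_percent: bool = False) -> float:
    """Broad-sense heritability on an entry-mean basis.

    h2 = s2_G / (s2_G + s2_GY / y + s2_R / (y * r)).
    """
    for name in ("sigma2_g", "sigma2_gy", "sigma2_r"):
        if math.isnan(getattr(vc, name)):
            raise PhenotypeError(f"{name} is inestimable; heritability undefined")
    denom = vc.sigma2_g + vc.sigma2_gy / vc.n_years + vc.sigma2_r / (vc.n_years * vc.n_replicates)
    if denom == 0:
        raise PhenotypeError("all variance components are zero; heritability undefined")
    h2 = vc.sigma2_g / denom
    return 100.0 * h2 if as_percent else h2


def compute_blues(records: pd.DataFrame, include_year: bool = True) -> pd.Series:
    """Per-line fixed-genotype estimates on the score scale.

    Fits score = genotype (fixed) + year (fixed) + e by least squares and
    reports, for each line, its fitted value averaged over all years
    (equal year weights).  For balanced data this equals the plain entry
    mean.  ``include_year=False`` drops the year covariate and returns
    raw entry means.
    """
    rec = validate_records(records)
    lines = pd.Index(sorted(rec["line"].unique()), name="line")
    if not include_year or rec["year"].nunique() == 1:
        blues = rec.groupby("line")["score"].mean()
        return blues.reindex(lines).rename("blue")
    line_d = pd.get_dummies(rec["line"], dtype=float)
    year_d = pd.get_dummies(rec["year"], dtype=float)
    X = np.hstack([line_d.to_numpy(), year_d.to_numpy()])
    beta, *_ = np.linalg.lstsq(X, rec["score"].to_numpy(), rcond=None)
    n_l, n_y = line_d.shape[1], year_d.shape[1]
    line_eff = pd.Series(beta[:n_l], index=line_d.columns)
    year_eff = beta[n_l : n_l + n_y]
    blues = line_eff + float(np.mean(year_eff))
    return blues.reindex(lines).rename("blue")
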