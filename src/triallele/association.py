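"""Spine-length association statistics.

Spine lengths scale with body size, so each trait is first residualized
on standard length (and sex, where estimable) by ordinary least squares;
all association statistics operate on the residuals.  Available
statistics: the first-vs-last quintile allele-count Fisher scan used for
coarse genome-wide localisation, per-marker one-way ANOVA F-tests for
fine mapping, conditional F-tests controlling for a peak marker, percent
variance explained (PVE) by genotype class, and extreme-phenotype fish
selection for pooled sequencing designs.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def residualize(phenos: pd.DataFrame, trait: str,
                covariates: tuple[str, ...] = ("standard_length", "sex")
                ) -> pd.Series:
    """OLS residuals of a trait on intercept + covariates.

    ``sex`` is coded M=1, F=0; fish with a missing trait value are
    dropped (the returned Series is indexed by the retained rows).  A
    covariate without variation (e.g. a single-sex sample) is dropped
    with a warning rather than producing a singular design.
    """
    data = phenos.dropna(subset=[trait])
    y = data[trait].to_numpy(dtype=float)
    cols = [np.ones(len(data))]
    for cov in covariates:
        if cov == "sex":
            x = (data["sex"] == "M").to_numpy(dtype=float)
        else:
            x = data[cov].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            logger.warning("covariate %r is constant; dropped", cov)
            continue
        cols.append(x)
    X = np.column_stack(cols)
    if len(data) < X.shape[1] + 1:
        raise ValueError("too few complete records to residualize")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(y - X @ beta, index=data.index, name=f"{trait}_resid")


def combined_spine_residuals(phenos: pd.DataFrame,
                             traits: tuple[str, ...] = ("DS1", "DS2", "PS"),
                             covariates: tuple[str, ...] = ("standard_length",
                                                            "sex")
                             ) -> pd.Series:
    """Per-fish sum of the major-spine residuals.

    Each trait is residualized separately; fish missing any trait are
    dropped from the sum.
    """
    parts = [residualize(phenos, t, covariates) for t in traits]
    combined = pd.concat(parts, axis=1).dropna().sum(axis=1)
    combined.name = "combined_resid"
    return combined


# ------------------------------------------------------------------ scans

def _allele_counts(genos: pd.Series) -> tuple[int, int]:
    """(A alleles, B alleles) in a vector of AA/AB/BB genotype strings."""
    a = int(2 * (genos == "AA").sum() + (genos == "AB").sum())
    b = int(2 * (genos == "BB").sum() + (genos == "AB").sum())
    return a, b


def quintile_scan(residuals: pd.Series, site_genotypes: pd.DataFrame
                  ) -> pd.Series:
    """First-vs-last quintile allele-count Fisher scan.

    Fish are ranked by residual; the lowest and highest fifths are
    compared at each site with a two-sided Fisher exact test on the 2x2
    table of allele counts (2 per homozygote, 1 per heterozygote).
    Monomorphic sites get p = 1.  ``site_genotypes`` is fish x site with
    AA/AB/BB/NaN entries sharing the residuals' index.
    """
    common = residuals.index.intersection(site_genotypes.index)
    if len(common) < 10:
        raise ValueError("need >= 10 fish with residuals and genotypes")
    res = residuals.loc[common].sort_values(kind="stable")
    q = len(common) // 5
    low, high = res.index[:q], res.index[-q:]
    out = {}
    for site in site_genotypes.columns:
        g_low = site_genotypes.loc[low, site].dropna()
        g_high = site_genotypes.loc[high, site].dropna()
        a1, b1 = _allele_counts(g_low)
        a2, b2 = _allele_counts(g_high)
        if (a1 + a2 == 0) or (b1 + b2 == 0):
            out[site] = 1.0  # monomorphic across the two quintiles
        else:
            out[site] = float(stats.fisher_exact([[a1, b1], [a2, b2]])[1])
    return pd.Series(out, name="quintile_p")


def _groups(residuals: pd.Series, genotypes: pd.Series
            ) -> list[np.ndarray]:
    joined = pd.concat([residuals, genotypes], axis=1, keys=["r", "g"]).dropna()
    return [grp["r"].to_numpy() for _, grp in joined.groupby("g", sort=True)]


def marker_ftest(residuals: pd.Series, genotypes: pd.Series
                 ) -> tuple[float, float]:
    """One-way ANOVA of residuals across genotype classes.

    Genotype classes are an unordered factor; returns (F, p) with p from
    the F distribution on (g-1, n-g) degrees of freedom, or (nan, nan)
    when fewer than two classes have two or more fish.
    """
    groups = [g for g in _groups(residuals, genotypes) if len(g) >= 2]
    if len(groups) < 2:
        return math.nan, math.nan
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def conditional_ftest(residuals: pd.Series, genotypes: pd.DataFrame,
                      control_marker: str) -> pd.Series:
    """Per-marker F-test after removing the control marker's class means.

    The residuals are regressed on indicator variables for the control
    marker's genotype classes (equivalently, class means are subtracted);
    every other marker is then F-tested on those second-stage residuals.
    """
    joined = pd.concat([residuals, genotypes[control_marker]], axis=1,
                       keys=["r", "g"]).dropna()
    class_means = joined.groupby("g")["r"].transform("mean")
    second = joined["r"] - class_means
    out = {}
    for marker in genotypes.columns:
        if marker == control_marker:
            continue
        _, p = marker_ftest(second, genotypes[marker])
        out[marker] = p
    return pd.Series(out, name="conditional_p")


def pve(residuals: pd.Series, genotypes: pd.Series) -> float:
    """Percent of residual variance explained by genotype class.

    100 x SS_between / SS_total of the one-way ANOVA layout; equals
    100 x (1 - SSE_full / SST).
    """
    groups = _groups(residuals, genotypes)
    values = np.concatenate(groups)
    sst = float(np.sum((values - values.mean())**2))
    if sst <= 0:
        raise ValueError("zero total variance; PVE undefined")
    ssb = float(sum(len(g) * (g.mean() - values.mean())**2 for g in groups))
    return 100.0 * ssb / sst


def select_extremes(residuals: pd.Series, n_low: int, n_high: int
                    ) -> tuple[list, list]:
    """IDs of the fish with the lowest / highest residuals (ties by id)."""
    if n_low + n_high > len(residuals):
        raise ValueError("asked for more fish than available")
    order = residuals.reset_index()
    order.columns = ["fish", "r"]
    order = order.sort_values(["r", "fish"], kind="stable")
    low = order["fish"].iloc[:n_low].tolist()
    high = order["fish"].iloc[len(order) - n_high:].tolist()
    return low, high
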