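"""Shell-color indices, coefficient optimization, and threshold grading.

Two indices are in industry use for eggshells: chroma C* = sqrt(a*^2 + b*^2)
and the shell color index SCI = L* - a* - b* (developed for brown shells).
For blue-green shells, one-parameter families L* - k b* and L* - k C* are
scanned over k for the strongest (most negative) Pearson correlation with
the mean visual score AveObs, and competing indices are compared with a
Fisher z-test on the correlation magnitudes.  The winning index L* - 4C*,
with a* as an auxiliary axis, yields simple grading thresholds for the four
visual classes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .data_model import Dataset, ValidationError, pearson_corr


class IndexFamily(str, enum.Enum):
    CHROMA = "CHROMA"
    SCI = "SCI"
    L_MINUS_KB = "L_MINUS_KB"
    L_MINUS_KC = "L_MINUS_KC"


@dataclass(frozen=True)
class IndexDefinition:
    """An index family plus its coefficient (ignored for CHROMA/SCI)."""

    family: IndexFamily
    k: float = 0.0

    def __post_init__(self):
        if not math.isfinite(self.k):
            raise ValidationError("k must be finite")


def chroma(a, b):
    """CIELab chroma C* = sqrt(a*^2 + b*^2)."""
    return np.sqrt(np.asarray(a, dtype=float) ** 2 + np.asarray(b, dtype=float) ** 2)


def sci(L, a, b):
    """Shell color index SCI = L* - a* - b*."""
    return np.asarray(L, dtype=float) - np.asarray(a, dtype=float) - np.asarray(
        b, dtype=float
    )


def index_value(definition: IndexDefinition, L, a, b):
    """Evaluate an index for scalar or array (L, a, b)."""
    L = np.asarray(L, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    fam = IndexFamily(definition.family)
    if fam is IndexFamily.CHROMA:
        return chroma(a, b)
    if fam is IndexFamily.SCI:
        return sci(L, a, b)
    if fam is IndexFamily.L_MINUS_KB:
        return L - definition.k * b
    if fam is IndexFamily.L_MINUS_KC:
        return L - definition.k * chroma(a, b)
    raise ValidationError(f"unknown index family {definition.family!r}")


# ---------------------------------------------------------------------------
# Coefficient scan
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    """Grid of (k, r) pairs with the grid argmin of r.

    r is the Pearson correlation of the index with AveObs; the best index is
    the most negative r.  Grid points where the index is constant across the
    dataset are recorded as NaN and excluded from the minimum.  Ties go to
    the smallest k (simpler formula).
    """

    family: IndexFamily
    k_grid: np.ndarray
    r_grid: np.ndarray
    best_k: float
    best_r: float


def k_scan(
    ds: Dataset,
    family: IndexFamily | str,
    k_min: float = 0.0,
    k_max: float = 10.0,
    step: float = 0.1,
) -> ScanResult:
    """Scan the coefficient grid for the strongest index-AveObs correlation."""
    fam = IndexFamily(family)
    if fam not in (IndexFamily.L_MINUS_KB, IndexFamily.L_MINUS_KC):
        raise ValidationError("k_scan applies to the L - k b* / L - k C* families")
    if not (k_min < k_max) or step <= 0:
        raise ValidationError("need k_min < k_max and step > 0")
    n_steps = int(round((k_max - k_min) / step))
    k_grid = np.round(k_min + step * np.arange(n_steps + 1), 10)
    L, a, b = ds.colors.T
    ave = ds.aveobs
    r_grid = np.full(len(k_grid), np.nan)
    for i, k in enumerate(k_grid):
        vals = index_value(IndexDefinition(fam, float(k)), L, a, b)
        if np.ptp(vals) == 0 or np.ptp(ave) == 0:
            continue  # degenerate grid point, stays NaN
        r_grid[i] = pearson_corr(vals, ave)
    if np.isnan(r_grid).all():
        raise ValidationError("index degenerate over the whole grid")
    best_i = int(np.nanargmin(r_grid))  # nanargmin takes the first (smallest k) tie
    return ScanResult(
        family=fam,
        k_grid=k_grid,
        r_grid=r_grid,
        best_k=float(k_grid[best_i]),
        best_r=float(r_grid[best_i]),
    )


# ---------------------------------------------------------------------------
# Fisher comparison of correlation magnitudes
# ---------------------------------------------------------------------------


@dataclass
class CorrelationComparison:
    r1: float
    r2: float
    n: int
    z: float
    p: float


def fisher_compare(r1: float, r2: float, n: int) -> CorrelationComparison:
    """Fisher z-test comparing two correlation magnitudes at shared n.

    z = (atanh|r2| - atanh|r1|) / sqrt(2/(n-3)); two-sided normal p-value.
    The magnitudes are compared, so the sign of either correlation is
    irrelevant (a strongly negative index correlation can beat a positive
    one).  Treats the correlations as if estimated on independent samples.
    """
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValidationError("|r| must be < 1")
    if n <= 3:
        raise ValidationError("n must exceed 3")
    z = (math.atanh(abs(r2)) - math.atanh(abs(r1))) / math.sqrt(2.0 / (n - 3))
    p = float(2.0 * norm.sf(abs(z)))
    return CorrelationComparison(r1=r1, r2=r2, n=n, z=float(z), p=p)


def fisher_compare_dependent(
    r1: float, r2: float, r12: float, n: int
) -> CorrelationComparison:
    """Steiger's test for two overlapping dependent correlations.

    Stricter variant accounting for the correlation r12 between the two
    indices measured on the same eggs; offered as an alternative to
    :func:`fisher_compare`, which is the default reading of a plain
    "Fisher z-test" on published summary tables.
    """
    for r in (r1, r2, r12):
        if abs(r) >= 1:
            raise ValidationError("|r| must be < 1")
    if n <= 3:
        raise ValidationError("n must exceed 3")
    a1, a2 = abs(r1), abs(r2)
    rbar2 = (a1**2 + a2**2) / 2.0
    f = (1.0 - r12) / (2.0 * (1.0 - rbar2))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    z = (math.atanh(a2) - math.atanh(a1)) * math.sqrt(
        (n - 3) / (2.0 * (1.0 - r12) * h)
    )
    p = float(2.0 * norm.sf(abs(z)))
    return CorrelationComparison(r1=r1, r2=r2, n=n, z=float(z), p=p)


def compare_indices(ds: Dataset, definitions: dict[str, IndexDefinition]):
    """r of each named index with AveObs plus the pairwise Fisher p matrix.

    Returns (r: dict name->r, p: DataFrame upper/lower symmetric).
    """
    import pandas as pd

    L, a, b = ds.colors.T
    ave = ds.aveobs
    r = {
        name: pearson_corr(index_value(d, L, a, b), ave)
        for name, d in definitions.items()
    }
    names = list(definitions)
    p = pd.DataFrame(np.nan, index=names, columns=names)
    for i, ni in enumerate(names):
        for nj in names[i + 1 :]:
            cmpr = fisher_compare(r[ni], r[nj], len(ds))
            p.loc[ni, nj] = p.loc[nj, ni] = cmpr.p
    return r, p


# ---------------------------------------------------------------------------
# Threshold grading
# ---------------------------------------------------------------------------


class Grade(str, enum.Enum):
    LIGHT = "LIGHT"
    BLUE = "BLUE"
    GREEN = "GREEN"
    OLIVE = "OLIVE"
    INDETERMINATE = "INDETERMINATE"


def grade_egg(L: float, a: float, b: float) -> Grade:
    """Grade one egg from L* - 4C* and a* thresholds.

    v = L - 4*C*: v > 40 separates light/blue shells from green/olive
    (v < 30), with [30, 40] a boundary band; a* > -5 separates light/olive
    from blue/green (a* < -6), with [-6, -5] a boundary band.  Anything in
    either band is INDETERMINATE, so the function is total.
    """
    v = float(L) - 4.0 * float(chroma(a, b))
    if v > 40:
        if a > -5:
            return Grade.LIGHT
        if a < -6:
            return Grade.BLUE
    elif v < 30:
        if a < -6:
            return Grade.GREEN
        if a > -5:
            return Grade.OLIVE
    return Grade.INDETERMINATE


def grade_dataset(ds: Dataset):
    """Vector of grades for every egg in the dataset."""
    return np.array(
        [grade_egg(L, a, b).value for L, a, b in ds.colors], dtype=object
    )
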