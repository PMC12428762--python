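"""Domain types and I/O for blue-green eggshell color tables.

An egg record couples a Minolta-style CIELab reading (L*, a*, b*) with four
independent observers' ordinal color classes (1 = Light, 2 = Blue, 3 = Green,
4 = Olive).  The mean of the four labels (AveObs) is the quasi-continuous
visual score the rest of the analysis regresses and classifies against; the
sorted four-digit code ("4-Obs") identifies unanimous ("consistent") eggs.

Tables are carried as pandas DataFrames wrapped in a thin :class:`Dataset`
that enforces the domain invariants once, at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: canonical column order of an egg table
COLUMNS = ["batch", "egg_id", "L", "a", "b", "obs1", "obs2", "obs3", "obs4"]
OBS_COLUMNS = ["obs1", "obs2", "obs3", "obs4"]
CHANNELS = ["L", "a", "b"]

#: the 13 admissible AveObs values (means of four labels in {1..4})
AVEOBS_GRID = tuple(np.arange(4, 17) / 4.0)

VALID_LABELS = frozenset({1, 2, 3, 4})


class ValidationError(ValueError):
    """Raised when an egg table violates a domain invariant."""


def compute_aveobs(obs: Sequence[int]) -> float:
    """Mean of the four observer labels.

    Always lands on the 0.25-spaced grid from 1.00 to 4.00.
    """
    obs = tuple(int(o) for o in obs)
    if len(obs) != 4:
        raise ValidationError(f"expected 4 observer labels, got {len(obs)}")
    if any(o not in VALID_LABELS for o in obs):
        raise ValidationError(f"observer labels must be in 1..4, got {obs}")
    return sum(obs) / 4.0


def four_obs_code(obs: Sequence[int]) -> str:
    """Canonical 4-Obs code: the four labels as digits, sorted ascending."""
    obs = tuple(int(o) for o in obs)
    if len(obs) != 4 or any(o not in VALID_LABELS for o in obs):
        raise ValidationError(f"invalid observer quadruple {obs}")
    return "".join(str(d) for d in sorted(obs))


@dataclass
class Dataset:
    """A validated egg color table.

    Parameters
    ----------
    df : DataFrame with columns ``batch, egg_id, L, a, b, obs1..obs4``.
    state : "raw" (as measured) or "corrected" (after batch correction).
    """

    df: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in ("raw", "corrected"):
            raise ValidationError(f"unknown state {self.state!r}")
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"missing column(s): {', '.join(missing)}")
        df = self.df.loc[:, COLUMNS].copy()
        df["batch"] = df["batch"].astype(str)
        df["egg_id"] = df["egg_id"].astype(str)
        for c in CHANNELS:
            vals = pd.to_numeric(df[c], errors="coerce")
            bad = vals.index[vals.isna()]
            if len(bad):
                raise ValidationError(f"non-numeric {c} value at row {bad[0]}")
            df[c] = vals.astype(float)
        for c in OBS_COLUMNS:
            vals = pd.to_numeric(df[c], errors="coerce")
            bad = vals.index[vals.isna() | ~vals.isin([1, 2, 3, 4])]
            if len(bad):
                raise ValidationError(
                    f"{c} outside {{1,2,3,4}} at row {bad[0]} "
                    f"(egg_id={df.loc[bad[0], 'egg_id']!r})"
                )
            df[c] = vals.astype(int)
        bad_L = df.index[(df["L"] < 0) | (df["L"] > 100)]
        if len(bad_L):
            raise ValidationError(f"L outside [0,100] at row {bad_L[0]}")
        for c in ("a", "b"):
            bad = df.index[(df[c] < -120) | (df[c] > 120)]
            if len(bad):
                raise ValidationError(f"{c} outside [-120,120] at row {bad[0]}")
        if df["egg_id"].duplicated().any():
            dup = df.loc[df["egg_id"].duplicated(), "egg_id"].iloc[0]
            raise ValidationError(f"duplicate egg_id {dup!r}")
        if df["batch"].nunique() < 1 or len(df) == 0:
            raise ValidationError("dataset must contain at least one batch")
        obs = df[OBS_COLUMNS].to_numpy()
        df["aveobs"] = obs.mean(axis=1)
        df["code"] = ["".join(str(d) for d in sorted(row)) for row in obs]
        self.df = df.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def colors(self) -> np.ndarray:
        """n x 3 array of (L, a, b)."""
        return self.df[CHANNELS].to_numpy(dtype=float)

    @property
    def aveobs(self) -> np.ndarray:
        return self.df["aveobs"].to_numpy(dtype=float)

    @property
    def batches(self) -> list[str]:
        """Batch labels in first-appearance order."""
        return list(dict.fromkeys(self.df["batch"]))

    def with_colors(self, colors: np.ndarray, state: str) -> "Dataset":
        """Copy of the dataset with replaced (L,a,b) values."""
        df = self.df[COLUMNS].copy()
        df[CHANNELS] = np.asarray(colors, dtype=float)
        return Dataset(df, state=state)

    def subset(self, mask: np.ndarray) -> "Dataset":
        return Dataset(self.df.loc[np.asarray(mask), COLUMNS], state=self.state)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self.state == other.state and self.df[COLUMNS].equals(
            other.df[COLUMNS]
        )


def read_dataset(path: str | Path, state: str = "raw") -> Dataset:
    """Read an egg table from CSV (comma separated, UTF-8, header required)."""
    df = pd.read_csv(path, dtype={"batch": str, "egg_id": str})
    return Dataset(df, state=state)


def write_dataset(ds: Dataset, path: str | Path, derived: bool = True) -> None:
    """Write an egg table to CSV; optionally include aveobs/code columns."""
    cols = COLUMNS + (["aveobs", "code"] if derived else [])
    ds.df[cols].to_csv(path, index=False)


def pearson_corr(x: Iterable[float], y: Iterable[float]) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Shared primitive for the color summary, the k-scan and the index
    comparison; errors out on constant input rather than returning NaN.
    """
    x = np.asarray(list(x) if not isinstance(x, np.ndarray) else x, dtype=float)
    y = np.asarray(list(y) if not isinstance(y, np.ndarray) else y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("pearson_corr needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("pearson_corr undefined for constant input")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    return float(np.clip(r, -1.0, 1.0))


CONSISTENT_CODES = ("1111", "2222", "3333", "4444")


def partition_consistency(
    ds: Dataset,
) -> tuple[Dataset, Dataset, pd.DataFrame]:
    """Split a dataset into unanimous ("consistent") and split-vote eggs.

    Returns (consistent, inconsistent, counts) where ``counts`` tabulates
    n by (aveobs, code) with a ``consistent`` flag; the two subsets
    partition the input exactly.  A side with no records is returned as
    ``None`` (a Dataset is never empty).
    """
    mask = ds.df["code"].isin(CONSISTENT_CODES).to_numpy()
    counts = (
        ds.df.groupby(["aveobs", "code"], sort=True)
        .size()
        .rename("n")
        .reset_index()
    )
    counts["consistent"] = counts["code"].isin(CONSISTENT_CODES)
    cons = ds.subset(mask) if mask.any() else None
    incons = ds.subset(~mask) if (~mask).any() else None
    return cons, incons, counts


@dataclass
class ColorSummary:
    """Per-channel moments and the correlation structure of an egg table."""

    n: int
    mean: pd.Series
    sd: pd.Series
    cv_percent: pd.Series
    corr: pd.DataFrame  # 3x3, channels x channels; NaN marks undefined
    corr_with_aveobs: pd.Series

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean.to_dict(),
            "sd": self.sd.to_dict(),
            "cv_percent": self.cv_percent.to_dict(),
            "corr": self.corr.to_dict(),
            "corr_with_aveobs": self.corr_with_aveobs.to_dict(),
        }


def summarize_colors(ds: Dataset) -> ColorSummary:
    """Means, sample SDs, CV% and Pearson correlations of L*, a*, b*.

    CV is reported as 100*SD/|mean| so channels with negative means (a* of
    green shells) still print a positive coefficient of variation.
    Correlations involving a zero-variance channel are reported as NaN.
    """
    if len(ds) < 3:
        raise ValidationError("summary needs at least 3 records")
    X = ds.colors
    mean = pd.Series(X.mean(axis=0), index=CHANNELS)
    sd = pd.Series(X.std(axis=0, ddof=1), index=CHANNELS)
    with np.errstate(divide="ignore"):
        cv = 100.0 * sd / mean.abs()
    cv[mean == 0] = np.nan
    corr = pd.DataFrame(np.eye(3), index=CHANNELS, columns=CHANNELS)
    ave = ds.aveobs
    r_ave = pd.Series(np.nan, index=CHANNELS)
    ave_const = np.ptp(ave) == 0
    for i, ci in enumerate(CHANNELS):
        for j in range(i):
            cj = CHANNELS[j]
            if sd[ci] == 0 or sd[cj] == 0:
                corr.loc[ci, cj] = corr.loc[cj, ci] = np.nan
            else:
                r = pearson_corr(X[:, i], X[:, j])
                corr.loc[ci, cj] = corr.loc[cj, ci] = r
        if sd[ci] == 0:
            corr.loc[ci, ci] = np.nan
        r_ave[ci] = (
            np.nan if (sd[ci] == 0 or ave_const) else pearson_corr(X[:, i], ave)
        )
    return ColorSummary(
        n=len(ds), mean=mean, sd=sd, cv_percent=cv, corr=corr,
        corr_with_aveobs=r_ave,
    )
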