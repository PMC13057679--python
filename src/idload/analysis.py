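"""Population diagnostics on posterior-mean inbreeding depression loads.

The favourable direction is trait configuration, never inferred from data:
higher IDL is favourable for dressage-like traits (less depression of the
score in inbred descendants), lower IDL for defect scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HIGHER = "higher_is_favorable"
LOWER = "lower_is_favorable"


@dataclass
class IdlProfile:
    """Posterior-mean IDL per animal and trait with favourable directions.

    ``values`` is an animal-indexed DataFrame with one column per trait;
    ``directions`` maps trait -> HIGHER/LOWER.
    """

    values: pd.DataFrame
    directions: dict = field(default_factory=dict)

    def __post_init__(self):
        for t in self.values.columns:
            if self.directions.get(t) not in (HIGHER, LOWER):
                raise ValueError(f"favourable direction missing or invalid "
                                 f"for trait '{t}'")


def favorable_threshold(idl: np.ndarray, F: np.ndarray,
                        reference_F: float = 0.10) -> tuple:
    """Reference-inbreeding IDL threshold from the IDL-on-F regression.

    Fits IDL = a + b F by OLS and evaluates the line at ``reference_F``
    (default 10% inbreeding).  Returns ``(threshold, slope, intercept)``.
    """
    idl = np.asarray(idl, dtype=float)
    F = np.asarray(F, dtype=float)
    if idl.size < 10:
        raise ValueError("need at least 10 animals with IDL and F")
    if np.ptp(F) == 0:
        raise ValueError("degenerate predictor: F is constant")
    slope, intercept = np.polyfit(F, idl, 1)
    return float(slope * reference_F + intercept), float(slope), float(intercept)


def favorable_mask(values: np.ndarray, threshold: float,
                   direction: str) -> np.ndarray:
    """Strictly-beyond-threshold indicator in the favourable direction."""
    values = np.asarray(values, dtype=float)
    if direction == HIGHER:
        return values > threshold
    if direction == LOWER:
        return values < threshold
    raise ValueError(f"unknown direction {direction!r}")


def favorable_proportion(values: np.ndarray, threshold: float,
                         direction: str) -> tuple:
    """Count and percentage of animals beyond the threshold (strict)."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    n_fav = int(favorable_mask(vals, threshold, direction).sum())
    return n_fav, 100.0 * n_fav / len(vals)


def idl_correlations(profile: IdlProfile, thresholds: dict) -> tuple:
    """Pearson correlations and coincident-favourable counts per trait pair.

    Returns ``(corr, coincidence)``: a symmetric unit-diagonal correlation
    matrix over animals with both traits defined, and a DataFrame of
    (pair, n_coincident, proportion) where coincidence means favourable in
    *both* traits of the pair.  Pairs with < 3 complete observations get NaN
    with a warning.
    """
    traits = list(profile.values.columns)
    corr = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    rows = []
    for a_i, ta in enumerate(traits):
        for tb in traits[a_i:]:
            sub = profile.values[[ta, tb]].dropna() if ta != tb \
                else profile.values[[ta]].dropna()
            if len(sub) < 3:
                warnings.warn(f"fewer than 3 complete pairs for ({ta}, {tb})")
                corr.loc[ta, tb] = corr.loc[tb, ta] = np.nan
                continue
            if ta != tb:
                r = float(np.corrcoef(sub[ta], sub[tb])[0, 1])
                corr.loc[ta, tb] = corr.loc[tb, ta] = r
                both = (favorable_mask(sub[ta], thresholds[ta],
                                       profile.directions[ta])
                        & favorable_mask(sub[tb], thresholds[tb],
                                         profile.directions[tb]))
            else:
                both = favorable_mask(sub[ta], thresholds[ta],
                                      profile.directions[ta])
            rows.append({"trait_a": ta, "trait_b": tb,
                         "n_coincident": int(both.sum()),
                         "proportion": float(both.sum()) / len(sub)})
    return corr, pd.DataFrame(rows)


def cohort_trends(frame: pd.DataFrame, birth_year_col: str = "birth_year",
                  bin_width: int = 1) -> pd.DataFrame:
    """Birth-cohort means of every numeric column (tidy long table).

    ``frame`` carries one row per animal with a birth-year column plus any
    number of quantity columns (F6, EBV, IDL per trait...).
    """
    if birth_year_col not in frame or frame[birth_year_col].isna().all():
        raise ValueError("no birth years available")
    df = frame.dropna(subset=[birth_year_col]).copy()
    cohort = (df[birth_year_col] // bin_width * bin_width).astype(int)
    df = df.drop(columns=[birth_year_col])
    out = df.groupby(cohort.rename("cohort")).agg(["mean", "size"])
    tidy = []
    for col in df.columns:
        sub = out[col].reset_index()
        sub["quantity"] = col
        tidy.append(sub.rename(columns={"mean": "mean_value", "size": "n"}))
    return pd.concat(tidy, ignore_index=True)[
        ["quantity", "cohort", "mean_value", "n"]]


def class_percentages(counts) -> np.ndarray:
    """Percentage distribution over ordinal classes from raw counts."""
    counts = np.asarray(counts, dtype=float)
    return 100.0 * counts / counts.sum()
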