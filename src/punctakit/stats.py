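"""Hemisphere-normalized group comparison.

The statistical pipeline used for unilateral-treatment histology designs:

1. per-site measurements (puncta count, fraction clustered, ...) are
   averaged to one value per (animal, hemisphere, brain area) — typically
   two to three sites in each of two sections per hemisphere;
2. each animal's treated-hemisphere value is divided by the same animal's
   control-hemisphere mean for the same area, removing inter-animal
   variability in staining and expression;
3. two groups of normalized values (e.g. enzyme-treated vs sham cohorts)
   are compared with a normality-gated test: Shapiro-Wilk on each group,
   then Student's t test if both groups look normal, otherwise the
   Mann-Whitney U test (exact null distribution for small samples, normal
   approximation with tie correction for larger ones).

Unpaired tests are used even though hemispheres are paired within an
animal: the control-hemisphere normalization already consumes the pairing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError

__all__ = [
    "SITE_COLUMNS",
    "ComparisonResult",
    "site_table",
    "aggregate_to_animal",
    "normalize_to_control",
    "compare_groups",
]

SITE_COLUMNS = ("animal_id", "hemisphere", "section_id", "site_id", "area", "value")

# Group sizes up to this use the exact Mann-Whitney null distribution;
# beyond it the normal approximation with tie correction is used.
MANN_WHITNEY_EXACT_MAX_N = 20


@dataclass
class ComparisonResult:
    """Outcome of the normality-gated two-group test.

    ``test_used`` is ``t_test`` iff both groups pass Shapiro-Wilk at
    ``alpha_normality``; ``normality_p_values`` records both gate p-values.
    """

    test_used: str
    statistic: float
    p_value: float
    group_means: tuple[float, float]
    group_n: tuple[int, int]
    normality_p_values: tuple[float, float]
    alpha_normality: float = 0.05
    normalized: bool = False

    def to_dict(self) -> dict:
        return {
            "test_used": self.test_used,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "group_means": list(self.group_means),
            "group_n": list(self.group_n),
            "normality_p_values": list(self.normality_p_values),
            "alpha_normality": self.alpha_normality,
            "normalized": self.normalized,
        }


def site_table(records) -> pd.DataFrame:
    """Build/validate a site-measurement table.

    Accepts a DataFrame or an iterable of mappings with columns
    ``animal_id, hemisphere, section_id, site_id, area, value`` (``area``
    defaults to "all" if absent); (animal, hemisphere, section, site, area)
    keys must be unique and values finite.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df = df.copy()
    if "area" not in df.columns:
        df["area"] = "all"
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"site table missing columns: {missing}")
    if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
        raise ParameterError("site values must be finite")
    bad_hemi = set(df["hemisphere"]) - {"control", "treated"}
    if bad_hemi:
        raise ParameterError(f"hemisphere must be 'control' or 'treated'; got {bad_hemi}")
    keys = ["animal_id", "hemisphere", "section_id", "site_id", "area"]
    if df.duplicated(subset=keys).any():
        raise ParameterError("duplicate (animal, hemisphere, section, site, area) keys")
    return df


def aggregate_to_animal(measurements) -> pd.DataFrame:
    """Plain mean over all sites of all sections within each
    (animal, hemisphere, area).

    Animals missing one hemisphere for an area cannot be normalized and are
    excluded with a warning.
    """
    df = site_table(measurements)
    means = (
        df.groupby(["animal_id", "area", "hemisphere"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    counts = means.groupby(["animal_id", "area"])["hemisphere"].nunique()
    incomplete = counts[counts < 2]
    if len(incomplete):
        for (animal, area), _ in incomplete.items():
            warnings.warn(
                f"animal {animal!r} lacks a hemisphere for area {area!r}; excluded",
                stacklevel=2,
            )
        keep = means.set_index(["animal_id", "area"]).index.isin(counts[counts == 2].index)
        means = means[keep]
    return means.reset_index(drop=True)


def normalize_to_control(animal_means: pd.DataFrame) -> pd.DataFrame:
    """Divide each animal's treated value by its own control-hemisphere mean
    for the same area.

    Returns one row per (animal, area) with the normalized treated value.
    A control mean of zero (or below) is an error for that animal: the ratio
    is undefined, and silently dropping or zeroing it would bias the group.
    """
    wide = animal_means.pivot_table(
        index=["animal_id", "area"], columns="hemisphere", values="value"
    )
    for hemi in ("control", "treated"):
        if hemi not in wide.columns:
            raise ParameterError(f"no {hemi!r} hemisphere values to normalize")
    bad = wide[wide["control"] <= 0]
    if len(bad):
        raise ParameterError(
            f"non-positive control mean for {list(bad.index)}; cannot normalize"
        )
    out = wide.reset_index()
    out["normalized_value"] = out["treated"] / out["control"]
    return out[["animal_id", "area", "normalized_value"]]


def compare_groups(
    x, y, alpha_normality: float = 0.05, test: str = "auto"
) -> ComparisonResult:
    """Normality-gated two-group comparison.

    Shapiro-Wilk is run on each group; if both p-values are at or above
    ``alpha_normality`` the groups are compared with an unpaired two-sided
    Student's t test, otherwise with a two-sided Mann-Whitney U test (exact
    for group sizes <= 20, normal approximation with tie correction above).
    ``test`` may force ``"t_test"`` or ``"mann_whitney"``; the gate p-values
    are reported either way.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ParameterError(
            f"need at least 3 values per group (got {len(x)}, {len(y)})"
        )
    if test not in ("auto", "t_test", "mann_whitney"):
        raise ParameterError(f"unknown test {test!r}")

    norm_p = tuple(_shapiro_p(v) for v in (x, y))
    if test == "auto":
        test_used = (
            "t_test"
            if norm_p[0] >= alpha_normality and norm_p[1] >= alpha_normality
            else "mann_whitney"
        )
    else:
        test_used = test

    if test_used == "t_test":
        res = sps.ttest_ind(x, y)
    else:
        method = (
            "exact"
            if max(len(x), len(y)) <= MANN_WHITNEY_EXACT_MAX_N and not _has_ties(x, y)
            else "asymptotic"
        )
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return ComparisonResult(
        test_used=test_used,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_means=(float(x.mean()), float(y.mean())),
        group_n=(len(x), len(y)),
        normality_p_values=norm_p,
        alpha_normality=alpha_normality,
    )


def _shapiro_p(values: np.ndarray) -> float:
    """Shapiro-Wilk p-value; constant samples are maximally non-normal
    (p = 0) rather than an error, so the gate sends them to Mann-Whitney."""
    if np.ptp(values) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns for n > 5000; irrelevant here
        return float(sps.shapiro(values).pvalue)


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)
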