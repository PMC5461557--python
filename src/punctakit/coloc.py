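"""Object-level colocalization between two marker channels.

Histology studies report colocalization between whole objects (e.g. the
fraction of parvalbumin-positive cells enwrapped by a WFA-stained
perineuronal net) as two directional percentages: % of A objects overlapping
a B object and vice versa.  This module automates that count with a centroid
distance criterion: an A object counts as overlapping if at least one B
centroid lies within the match radius.  Matching is not mutually exclusive
by default (two A may share one B), which is the semantics of visual overlap
counting; ``exclusive=True`` switches to a greedy one-to-one assignment.

The default match radius of 10 um is on the order of a neuronal soma
radius; it is configurable and is echoed into every output table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ParameterError

__all__ = ["ObjectSet", "ColocalizationTable", "match_objects", "format_coloc_table"]

DEFAULT_MATCH_RADIUS_UM = 10.0


@dataclass
class ObjectSet:
    """Centroids of segmented/counted objects of one marker, in physical um.

    2D centroids are accepted (z assumed 0); both sets of a comparison must
    share a coordinate frame.
    """

    centroids: np.ndarray
    marker: str
    radius_um: np.ndarray | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.centroids, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] not in (2, 3):
            raise ParameterError(f"centroids must be (n, 2) or (n, 3); got {pts.shape}")
        if pts.shape[1] == 2:
            pts = np.column_stack([pts, np.zeros(len(pts))])
        if not np.all(np.isfinite(pts)):
            raise ParameterError("centroids must be finite")
        if not self.marker:
            raise ParameterError("marker label must be non-empty")
        self.centroids = pts

    def __len__(self) -> int:
        return len(self.centroids)


@dataclass
class ColocalizationTable:
    """Bidirectional overlap counts and percentages for one section/site.

    Percentages are ``None`` (reported as missing, never as 0) when the
    corresponding set is empty.
    """

    n_a: int
    n_b: int
    n_a_matched: int
    n_b_matched: int
    pct_a_over_b: float | None
    pct_b_over_a: float | None
    match_radius_um: float
    marker_a: str = "A"
    marker_b: str = "B"


def match_objects(
    a: ObjectSet,
    b: ObjectSet,
    match_radius_um: float = DEFAULT_MATCH_RADIUS_UM,
    exclusive: bool = False,
) -> ColocalizationTable:
    """Count objects of each set having a partner of the other set within
    ``match_radius_um`` (centroid distance, boundary inclusive)."""
    if match_radius_um < 0:
        raise ParameterError("match_radius_um must be >= 0")
    n_a, n_b = len(a), len(b)
    if n_a and n_b:
        if exclusive:
            matched_a, matched_b = _greedy_one_to_one(
                a.centroids, b.centroids, match_radius_um
            )
        else:
            tree_b = cKDTree(b.centroids)
            dist_a, _ = tree_b.query(a.centroids, k=1)
            matched_a = int(np.count_nonzero(dist_a <= match_radius_um))
            tree_a = cKDTree(a.centroids)
            dist_b, _ = tree_a.query(b.centroids, k=1)
            matched_b = int(np.count_nonzero(dist_b <= match_radius_um))
    else:
        matched_a = matched_b = 0
    return ColocalizationTable(
        n_a=n_a,
        n_b=n_b,
        n_a_matched=matched_a,
        n_b_matched=matched_b,
        pct_a_over_b=100.0 * matched_a / n_a if n_a else None,
        pct_b_over_a=100.0 * matched_b / n_b if n_b else None,
        match_radius_um=match_radius_um,
        marker_a=a.marker,
        marker_b=b.marker,
    )


def _greedy_one_to_one(pa: np.ndarray, pb: np.ndarray, radius: float):
    """Greedy nearest-pair one-to-one assignment within the radius."""
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    d = np.where(d <= radius, d, np.inf)
    matched = 0
    while np.isfinite(d).any():
        i, j = np.unravel_index(np.argmin(d), d.shape)
        matched += 1
        d[i, :] = np.inf
        d[:, j] = np.inf
    return matched, matched


def format_coloc_table(
    tables_by_group: dict[str, list[ColocalizationTable]],
    direction: str = "pct_a_over_b",
    alpha_normality: float = 0.05,
) -> pd.DataFrame:
    """Group summary in the conventional reporting format: mean +/- SEM of a
    directional percentage per group, plus the two-group p-value.

    SEM needs at least two replicates and is reported missing (NaN)
    otherwise.  The p-value (for exactly two groups with >= 3 replicates
    each) comes from the normality-gated two-group test in
    :mod:`punctakit.stats`.
    """
    if direction not in ("pct_a_over_b", "pct_b_over_a"):
        raise ParameterError("direction must be pct_a_over_b or pct_b_over_a")
    from .stats import compare_groups

    rows = []
    values_by_group = {}
    for group, tables in tables_by_group.items():
        vals = [getattr(t, direction) for t in tables]
        vals = np.array([v for v in vals if v is not None], dtype=float)
        if len(vals) == 0:
            raise ParameterError(f"group {group!r} has no defined percentages")
        values_by_group[group] = vals
        sem = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        rows.append(
            {"group": group, "n": len(vals), "mean": float(vals.mean()), "sem": sem}
        )
    df = pd.DataFrame(rows).set_index("group")
    if len(values_by_group) == 2:
        (x, y) = values_by_group.values()
        if len(x) >= 3 and len(y) >= 3:
            result = compare_groups(x, y, alpha_normality=alpha_normality)
            df["p_value"] = result.p_value
            df["test_used"] = result.test_used
    return df
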