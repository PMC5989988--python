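"""Network-cognition correlation analysis.

Spearman partial correlations (midranked, controlling for a covariate —
education by default, age selectable) between network indices and
cognitive composites, Fisher z transforms, two-sample correlation
difference tests, and the per-node count matrices of strong correlations.
Controls contribute three cognitive composites (working memory,
processing speed, memory); the Parkinson groups additionally contribute
the UPDRS III motor score.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .topology import TopologyProfile

__all__ = [
    "COMPOSITES",
    "spearman_partial",
    "fisher_z",
    "correlation_diff_test",
    "strong_correlation_counts",
    "correlate_cohort",
]

logger = logging.getLogger(__name__)

#: cognitive measures per group: composites for everyone, UPDRS III for PD
COMPOSITES = ("working_memory", "processing_speed", "memory")
PD_MEASURES = COMPOSITES + ("updrs_iii",)

GLOBAL_INDICES = ("mean_strength", "mean_clustering", "mean_path_length", "small_worldness")
LOCAL_INDICES = ("strength", "clustering", "path_strength")


def spearman_partial(x, y, covariate) -> float:
    """Partial Spearman correlation of x and y controlling for a covariate.

    All three vectors are midrank-transformed; the partial correlation is
    (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)) on the ranks.
    Returns NaN (with a warning) when x or y is constant after ranking.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariate, dtype=float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ValueError("x, y and covariate must be equal-length vectors")
    if x.size < 4:
        raise ValueError("partial correlation needs n >= 4")
    if np.any(~np.isfinite(z)):
        raise ValueError("covariate must be finite")
    rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warnings.warn("zero variance after ranking: correlation undefined", stacklevel=2)
        return float("nan")
    if np.ptp(rz) == 0:
        # constant covariate carries no information: plain Spearman
        return float(np.corrcoef(rx, ry)[0, 1])
    r_xy = float(np.corrcoef(rx, ry)[0, 1])
    r_xz = float(np.corrcoef(rx, rz)[0, 1])
    r_yz = float(np.corrcoef(ry, rz)[0, 1])
    if abs(r_xz) > 1.0 - 1e-10 or abs(r_yz) > 1.0 - 1e-10:
        raise ValueError("degenerate covariate: perfectly rank-correlated with x or y")
    rho = (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    return float(np.clip(rho, -1.0, 1.0))


def fisher_z(rho: float) -> float:
    """Fisher z = atanh(rho); variance-stabilizing, odd in rho."""
    if not abs(rho) < 1.0:
        raise ValueError(f"|rho| must be < 1 for the Fisher transform, got {rho}")
    return float(np.arctanh(rho))


def correlation_diff_test(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sample correlation difference test on Fisher z scales.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided p
    from the standard normal.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both sample sizes must exceed 3")
    z = (fisher_z(r1) - fisher_z(r2)) / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def strong_correlation_counts(
    records: pd.DataFrame, threshold: float = 0.50
) -> tuple[pd.DataFrame, int]:
    """Per (node, index) count of measures with |rho| > threshold.

    ``records`` must belong to a single group. Returns the count matrix
    (rows = nodes, columns = indices) and the total number of evaluated
    correlations (nodes x indices x measures); undefined correlations
    (NaN rho) are excluded from counts with a logged tally.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if records["group"].nunique() > 1:
        raise ValueError("records span multiple groups; count one group at a time")
    nodes = list(dict.fromkeys(records["node"]))
    indices = list(dict.fromkeys(records["index"]))
    measures = list(dict.fromkeys(records["measure"]))
    n_undefined = int(records["rho"].isna().sum())
    if n_undefined:
        logger.info("excluding %d undefined correlations from counts", n_undefined)
    counts = pd.DataFrame(0, index=nodes, columns=indices)
    hits = records[records["rho"].abs() > threshold]
    for (node, index), sub in hits.groupby(["node", "index"], sort=False):
        counts.loc[node, index] = len(sub)
    total = len(nodes) * len(indices) * len(measures)
    return counts, total


def _measures_for(group: str) -> tuple[str, ...]:
    return PD_MEASURES if group.startswith("pd") else COMPOSITES


def correlate_cohort(
    profiles: Mapping[str, TopologyProfile],
    cohort: pd.DataFrame,
    scope: str = "global",
    covariate: str = "education",
    nodes: Sequence[str] | None = None,
    r_threshold: float = 0.50,
    z_threshold: float = 0.55,
) -> tuple[pd.DataFrame, dict[str, tuple[pd.DataFrame, int]]]:
    """Partial Spearman correlations per group, plus strong-count matrices.

    scope="global" correlates the four global indices with each group's
    cognitive measures and flags |z| > z_threshold; scope="local"
    correlates per-node strength, clustering and path strength over the
    ``nodes`` subset (default: all nodes) and flags |rho| > r_threshold.
    Groups with fewer than five subjects are flagged ``low_n`` with a
    warning.  Count matrices are computed for the local scope only.
    """
    if scope not in {"global", "local"}:
        raise ValueError(f"scope must be 'global' or 'local', got {scope!r}")
    rows: list[dict] = []
    for group, sub in cohort.groupby("group", sort=False):
        subjects = [str(s) for s in sub["subject_id"]]
        low_n = len(subjects) < 5
        if low_n:
            warnings.warn(f"group {group!r} has n={len(subjects)} < 5", stacklevel=2)
        cov = sub[covariate].to_numpy(dtype=float)
        measures = _measures_for(str(group))
        if scope == "global":
            for index in GLOBAL_INDICES:
                vals = np.array(
                    [
                        np.nan if getattr(profiles[s], index) is None
                        else getattr(profiles[s], index)
                        for s in subjects
                    ],
                    dtype=float,
                )
                if np.any(~np.isfinite(vals)):
                    continue
                for measure in measures:
                    rows.append(
                        _record(str(group), "global", index, measure, vals,
                                sub[measure].to_numpy(float), cov, covariate, low_n)
                    )
        else:
            all_labels = profiles[subjects[0]].labels
            node_set = list(nodes) if nodes is not None else list(all_labels)
            pos = {lab: k for k, lab in enumerate(all_labels)}
            for index in LOCAL_INDICES:
                mat = np.vstack([getattr(profiles[s], index) for s in subjects])
                for lab in node_set:
                    vals = mat[:, pos[lab]]
                    for measure in measures:
                        rows.append(
                            _record(str(group), lab, index, measure, vals,
                                    sub[measure].to_numpy(float), cov, covariate, low_n)
                        )
    records = pd.DataFrame(rows)
    if not records.empty:
        thr = z_threshold if scope == "global" else r_threshold
        col = "z" if scope == "global" else "rho"
        records["strong"] = records[col].abs() > thr
    counts: dict[str, tuple[pd.DataFrame, int]] = {}
    if scope == "local" and not records.empty:
        for group, sub in records.groupby("group", sort=False):
            counts[str(group)] = strong_correlation_counts(sub, r_threshold)
    return records, counts


def _record(group, node, index, measure, vals, comp, cov, covariate, low_n) -> dict:
    try:
        rho = spearman_partial(vals, comp, cov)
    except ValueError:
        # degenerate covariate in a tiny group: record as undefined
        logger.info("undefined partial correlation for %s/%s/%s/%s", group, node, index, measure)
        rho = float("nan")
    if np.isnan(rho):
        z = float("nan")
    elif abs(rho) >= 1.0:
        z = math.copysign(float("inf"), rho)
    else:
        z = fisher_z(rho)
    return {
        "group": group,
        "node": node,
        "index": index,
        "measure": measure,
        "rho": rho,
        "z": z,
        "covariate": covariate,
        "n": len(vals),
        "low_n": low_n,
    }
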