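"""Group comparison of topology indices.

Local (node-specific) indices are first residualized on each subject's
graph density (pooled ordinary least squares, residual plus grand mean) so
that global connectivity differences do not masquerade as local ones.
Group contrasts use the two-sided Mann-Whitney test; node-level families
are corrected with a Grenander-based procedure: the p-value distribution
function is estimated by the least concave majorant (LCM) of the empirical
CDF, the null proportion eta0 by the height of the density's dominant flat
step, and tail-area
adjusted p-values by q(t) = min(1, eta0 * t / F(t)).  The complementary
false-nondiscovery quantity FNDR(t) = (1 - eta0)(1 - F1(t)) / (1 - F(t)),
with F1 the estimated alternative CDF, is reported alongside.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .topology import TopologyProfile

__all__ = [
    "GROUPS",
    "mann_whitney",
    "density_adjust",
    "GrenanderFit",
    "grenander_density",
    "FnrResult",
    "fnr_adjust",
    "bh_adjust",
    "compare_groups",
]

#: canonical group labels in display order
GROUPS = ("control", "pd_well", "pd_mi")

LOCAL_INDICES = ("strength", "clustering", "path_strength")
GLOBAL_INDICES = (
    "density",
    "mean_strength",
    "mean_clustering",
    "mean_path_length",
    "small_worldness",
)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midranks for ties.

    The p-value is exact (full enumeration) when min(n_a, n_b) <= 8 and the
    pooled sample is tie-free, otherwise the normal approximation with tie
    and continuity corrections is used; the small-sample exact branch keeps
    comparisons against a 9-subject group reproducible.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def density_adjust(
    values: Sequence[float], densities: Sequence[float]
) -> np.ndarray:
    """Residualize values on graph density across pooled subjects.

    Returns OLS residuals plus the grand mean; when the densities carry no
    variance the values are returned unchanged.
    """
    y = np.asarray(values, dtype=float)
    d = np.asarray(densities, dtype=float)
    if y.shape != d.shape:
        raise ValueError("values and densities must have equal length")
    if y.size < 3:
        raise ValueError("density adjustment needs at least three subjects")
    if np.ptp(d) == 0:
        return y.copy()
    X = np.column_stack([np.ones_like(d), d])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta + float(np.mean(y))


# ---------------------------------------------------------------------------
# Grenander estimator and false-nondiscovery correction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrenanderFit:
    """Least concave majorant of a p-value ECDF.

    ``knots_x``/``knots_y`` are the LCM vertices (starting at x=0 and
    ending where the CDF reaches 1); ``slopes[k]`` is the density on the
    half-open interval (knots_x[k], knots_x[k+1]].  The density is a
    nonincreasing step function integrating to 1.
    """

    knots_x: np.ndarray
    knots_y: np.ndarray
    slopes: np.ndarray

    def cdf(self, t):
        return np.interp(np.asarray(t, dtype=float), self.knots_x, self.knots_y)

    def pdf(self, t):
        t = np.asarray(t, dtype=float)
        # interval (x_k, x_{k+1}] has density slopes[k]; at t=0 use the first
        k = np.clip(np.searchsorted(self.knots_x, t, side="left") - 1, 0, len(self.slopes) - 1)
        out = self.slopes[k]
        return out if out.ndim else float(out)

    @property
    def eta0(self) -> float:
        """Null proportion from the flat tail of the density.

        For a mixture of signal (mass near zero) and uniform nulls the LCM
        density flattens into one dominant step whose height is the null
        component; we take the slope of the widest positive-slope LCM
        segment, clipped to [0, 1].  Restricting to positive slopes keeps
        the estimate anchored to where p-values actually sit: when a
        family of correlated tests bunches all its p-values low, the empty
        interval up to 1 must not be read as "no nulls"."""
        widths = np.diff(self.knots_x)
        pos = self.slopes > 0
        if not np.any(pos):
            return 0.0  # all mass is an atom at zero
        k = int(np.argmax(np.where(pos, widths, -1.0)))
        return float(min(1.0, self.slopes[k]))


def _check_pvalues(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def grenander_density(pvalues) -> GrenanderFit:
    """Left-derivative of the least concave majorant of the p-value ECDF."""
    p = np.sort(_check_pvalues(pvalues))
    # fold numerically-zero p-values into the atom at zero so hull slopes
    # stay representable
    p = np.where(p < 1e-300, 0.0, p)
    n = p.size
    x, counts = np.unique(p, return_counts=True)
    y = np.cumsum(counts) / n
    if x[0] == 0.0:
        # an atom at zero: the LCM starts at (0, ecdf(0))
        pts = [(0.0, float(y[0]))]
        x, y = x[1:], y[1:]
    else:
        pts = [(0.0, 0.0)]
    for xi, yi in zip(x, y):
        pts.append((float(xi), float(yi)))
    if pts[-1][0] < 1.0:
        pts.append((1.0, 1.0))
    # upper concave hull by a monotone scan: pop while slopes increase
    hull: list[tuple[float, float]] = []
    for pt in pts:
        hull.append(pt)
        while len(hull) >= 3:
            (x0, y0), (x1, y1), (x2, y2) = hull[-3:]
            # middle point is below chord (x0,y0)-(x2,y2) => drop it
            if (y1 - y0) * (x2 - x0) <= (y2 - y0) * (x1 - x0):
                hull.pop(-2)
            else:
                break
    kx = np.array([q[0] for q in hull])
    ky = np.array([q[1] for q in hull])
    slopes = np.diff(ky) / np.diff(kx)
    return GrenanderFit(kx, ky, slopes)


@dataclass
class FnrResult:
    """Adjusted p-values plus the Grenander fit behind them."""

    p_adjusted: np.ndarray
    fndr: np.ndarray
    eta0: float
    fit: GrenanderFit


def fnr_adjust(pvalues) -> FnrResult:
    """Grenander tail-area multiple-comparison adjustment.

    q(t) = min(1, eta0 * t / F(t)) with F the concave-majorant CDF; the
    output order matches the input, monotone nondecreasing in the raw p.
    FNDR(t) estimates the proportion of missed true effects among
    non-rejections at threshold t (0 when eta0 = 1 or F(t) = 1).
    """
    p = _check_pvalues(pvalues)
    fit = grenander_density(p)
    eta0 = fit.eta0
    F = np.asarray(fit.cdf(p))
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(F > 0, eta0 * p / np.where(F > 0, F, 1.0), 0.0)
    q = np.minimum(q, 1.0)
    # enforce monotonicity in the raw p (ties share a p hence share a q)
    order = np.argsort(p, kind="stable")
    q[order] = np.maximum.accumulate(q[order])
    if eta0 >= 1.0:
        fndr = np.zeros_like(p)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            F1 = np.clip((F - eta0 * p) / (1.0 - eta0), 0.0, 1.0)
            fndr = np.where(F < 1.0, (1.0 - eta0) * (1.0 - F1) / (1.0 - F), 0.0)
        fndr = np.clip(fndr, 0.0, 1.0)
    return FnrResult(q, fndr, eta0, fit)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (comparison mode)."""
    p = _check_pvalues(pvalues)
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def _group_membership(cohort: pd.DataFrame) -> dict[str, list[str]]:
    members: dict[str, list[str]] = {}
    for _, row in cohort.iterrows():
        members.setdefault(str(row["group"]), []).append(str(row["subject_id"]))
    for g, subs in members.items():
        if len(subs) < 2:
            raise ValueError(f"group {g!r} has fewer than two subjects")
    return members


def _group_pairs(groups: Sequence[str]) -> list[tuple[str, str]]:
    ordered = [g for g in GROUPS if g in groups] + sorted(set(groups) - set(GROUPS))
    return list(itertools.combinations(ordered, 2))


def compare_groups(
    profiles: Mapping[str, TopologyProfile],
    cohort: pd.DataFrame,
    scope: str = "local",
    method: str = "grenander",
) -> pd.DataFrame:
    """Mann-Whitney group contrasts of topology indices.

    scope="global": raw global indices, one test per index per group pair,
    no multiplicity correction. scope="local": every node-level index is
    density-adjusted across all subjects pooled, tested per node, and the
    family of N node tests per (index, group pair) is corrected
    (``method``: "grenander" or "bh").  Returns a tidy frame with columns
    index, node, group_a, group_b, n_a, n_b, U, p_raw, density_adjusted,
    p_adj, direction.
    """
    if scope not in {"global", "local"}:
        raise ValueError(f"scope must be 'global' or 'local', got {scope!r}")
    members = _group_membership(cohort)
    missing = [s for subs in members.values() for s in subs if s not in profiles]
    if missing:
        raise ValueError(f"subjects without profiles: {missing}")
    pairs = _group_pairs(list(members))
    rows: list[dict] = []

    if scope == "global":
        for index in GLOBAL_INDICES:
            vals = {
                g: np.array(
                    [
                        np.nan if getattr(profiles[s], index) is None
                        else getattr(profiles[s], index)
                        for s in subs
                    ],
                    dtype=float,
                )
                for g, subs in members.items()
            }
            if any(np.any(~np.isfinite(v)) for v in vals.values()):
                continue  # index not computed for this run (e.g. no small-world)
            for ga, gb in pairs:
                U, p = mann_whitney(vals[ga], vals[gb])
                rows.append(
                    {
                        "index": index,
                        "node": "global",
                        "group_a": ga,
                        "group_b": gb,
                        "n_a": len(vals[ga]),
                        "n_b": len(vals[gb]),
                        "U": U,
                        "p_raw": p,
                        "density_adjusted": False,
                        "p_adj": p,
                        "direction": _direction(vals[ga], vals[gb], ga, gb),
                    }
                )
        return pd.DataFrame(rows)

    subjects = [s for subs in members.values() for s in subs]
    densities = np.array([profiles[s].density for s in subjects])
    labels = profiles[subjects[0]].labels
    for index in LOCAL_INDICES:
        raw = np.vstack([getattr(profiles[s], index) for s in subjects])
        adjusted = np.column_stack(
            [density_adjust(raw[:, k], densities) for k in range(raw.shape[1])]
        )
        by_subject = dict(zip(subjects, adjusted))
        for ga, gb in pairs:
            A = np.vstack([by_subject[s] for s in members[ga]])
            B = np.vstack([by_subject[s] for s in members[gb]])
            tests = [mann_whitney(A[:, k], B[:, k]) for k in range(len(labels))]
            p_raw = np.array([p for _, p in tests])
            p_adj = (
                fnr_adjust(p_raw).p_adjusted if method == "grenander" else bh_adjust(p_raw)
            )
            for k, lab in enumerate(labels):
                rows.append(
                    {
                        "index": index,
                        "node": lab,
                        "group_a": ga,
                        "group_b": gb,
                        "n_a": A.shape[0],
                        "n_b": B.shape[0],
                        "U": tests[k][0],
                        "p_raw": p_raw[k],
                        "density_adjusted": True,
                        "p_adj": float(p_adj[k]),
                        "direction": _direction(A[:, k], B[:, k], ga, gb),
                    }
                )
    return pd.DataFrame(rows)


def _direction(a: np.ndarray, b: np.ndarray, ga: str, gb: str) -> str:
    da = float(np.median(a) - np.median(b))
    if da > 0:
        return f"{ga}>{gb}"
    if da < 0:
        return f"{ga}<{gb}"
    return "equal"
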