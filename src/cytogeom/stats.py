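"""Geometry–activity statistics.

The association between a geometric descriptor and a signaling activity
is scored by the squared Pearson correlation R², with significance from
a permutation test: the response vector is shuffled uniformly at random
(default 10,000 permutations) to build a null distribution of R², and
the p-value is the fraction of null R² values at least as large as the
observed one. That fraction convention can return p = 0 (flagged); an
add-one convention ((k+1)/(n+1)) is available for a strictly positive
estimate. Spearman's ρ is reported alongside and can optionally serve
as the permutation statistic.

Descriptor distributions across phenotype classes are compared with
two-sided rank-sum (Mann–Whitney) tests over all class pairs, with
Holm (default) or Bonferroni adjustment, and significance codes
ns (p > 0.05), * (≤ 0.05), ** (≤ 0.01), *** (≤ 0.001).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .geomframe import GeometrySample

logger = logging.getLogger("cytogeom")

__all__ = [
    "PermutationResult",
    "GroupCompareResult",
    "permutation_correlation",
    "compare_groups",
    "descriptor_activity_summary",
    "significance_code",
]

DEFAULT_N_PERM = 10_000


@dataclass(frozen=True)
class PermutationResult:
    r_squared: float
    spearman_rho: float
    n_perm: int
    p_value: float
    seed: int
    convention: str = "fraction"
    statistic: str = "r2"
    p_is_zero: bool = False

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "spearman_rho": self.spearman_rho,
            "n_perm": self.n_perm,
            "p_value": self.p_value,
            "seed": self.seed,
            "convention": self.convention,
            "statistic": self.statistic,
        }


def _rank(v: np.ndarray) -> np.ndarray:
    return sps.rankdata(v)


def permutation_correlation(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    convention: str = "fraction",
    statistic: str = "r2",
) -> PermutationResult:
    """Correlation of (x, y) with a shuffled-response permutation null.

    ``statistic='r2'`` uses squared Pearson correlation as the null
    statistic; ``'spearman'`` uses squared Spearman ρ, which makes the
    p-value invariant to strictly monotone transforms of either vector.
    Deterministic given ``seed``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if convention not in ("fraction", "add_one"):
        raise ValueError(f"unknown convention {convention!r}")
    if statistic not in ("r2", "spearman"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    r = float(np.corrcoef(x, y)[0, 1])
    r_squared = r * r
    rho = float(sps.spearmanr(x, y).statistic)

    xs = _rank(x) if statistic == "spearman" else x
    ys = _rank(y) if statistic == "spearman" else y
    observed = float(np.corrcoef(xs, ys)[0, 1]) ** 2

    # one rng.permutation call per shuffle: the null stream is then
    # reproducible by any straightforward loop with the same seed
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(len(ys)) for _ in range(n_perm)])
    Y = ys[perms]
    xc = xs - xs.mean()
    xnorm = np.linalg.norm(xc)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    ynorm = np.linalg.norm(Yc, axis=1)
    null = (Yc @ xc / (xnorm * ynorm)) ** 2

    k = int(np.sum(null >= observed))
    if convention == "fraction":
        p = k / n_perm
    else:
        p = (k + 1) / (n_perm + 1)
    p_zero = p == 0.0
    if p_zero:
        logger.info(
            "permutation p-value is 0 under the fraction convention "
            "(true p < 1/%d); consider convention='add_one'", n_perm,
        )
    return PermutationResult(
        r_squared=r_squared,
        spearman_rho=rho,
        n_perm=n_perm,
        p_value=float(p),
        seed=seed,
        convention=convention,
        statistic=statistic,
        p_is_zero=p_zero,
    )


def significance_code(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupCompareResult:
    table: pd.DataFrame          # group_a, group_b, n_a, n_b, statistic, p_raw, p_adj, code
    method: str
    adjustment: str
    skipped_pairs: tuple[tuple[str, str], ...] = ()


def compare_groups(
    values: Sequence[float],
    labels: Sequence[str],
    method: str = "rank_sum",
    adjust: str = "holm",
    min_group_size: int = 3,
) -> GroupCompareResult:
    """All pairwise two-sided rank-sum comparisons of a descriptor across
    phenotype classes, with multiplicity adjustment across the pairs.

    Groups smaller than ``min_group_size`` are skipped with a warning.
    scipy's ``mannwhitneyu`` handles exact p-values for small tie-free
    groups and midrank/continuity-corrected normal approximation
    otherwise.
    """
    if method != "rank_sum":
        raise ValueError(f"unknown method {method!r}")
    if adjust not in ("holm", "bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    values = np.asarray(values, float)
    labels = np.asarray(labels, object)
    if values.shape != labels.shape:
        raise ValueError("values and labels must be parallel")

    order: dict[str, None] = {}
    for lab in labels:
        order.setdefault(lab, None)
    groups = {lab: values[labels == lab] for lab in order}
    usable = [lab for lab, v in groups.items() if len(v) >= min_group_size]
    skipped = []
    rows = []
    for a, b in combinations(order, 2):
        if a not in usable or b not in usable:
            skipped.append((a, b))
            warnings.warn(
                f"pair ({a}, {b}) skipped: group below {min_group_size} members",
                stacklevel=2,
            )
            continue
        res = sps.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        rows.append((a, b, len(groups[a]), len(groups[b]), float(res.statistic), float(res.pvalue)))
    if len(usable) < 2:
        raise ValueError("need at least two groups with enough members")

    df = pd.DataFrame(
        rows, columns=["group_a", "group_b", "n_a", "n_b", "statistic", "p_raw"]
    )
    if adjust == "none" or len(df) == 0:
        df["p_adj"] = df["p_raw"]
    else:
        df["p_adj"] = multipletests(df["p_raw"], method=adjust)[1]
    df["code"] = [significance_code(p) for p in df["p_adj"]]
    return GroupCompareResult(
        table=df, method=method, adjustment=adjust, skipped_pairs=tuple(skipped)
    )


DEFAULT_SUMMARY_DESCRIPTORS = ("termini_distance", "theta_z", "lateral_deviation")


def descriptor_activity_summary(
    samples: Iterable[GeometrySample],
    activities: Mapping[str, float] | pd.DataFrame,
    descriptors: Sequence[str] = DEFAULT_SUMMARY_DESCRIPTORS,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    convention: str = "fraction",
) -> tuple[pd.DataFrame, list[str]]:
    """Permutation-test each geometry descriptor against per-design
    activity (relative Emax); returns the summary table and the ids that
    could not be matched between the two inputs."""
    if isinstance(activities, pd.DataFrame):
        act = dict(zip(activities["design_id"], activities["activity"]))
    else:
        act = dict(activities)
    samples = list(samples)
    by_id = {s.id: s for s in samples}
    matched = sorted(set(by_id) & set(act))
    unmatched = sorted(set(by_id) ^ set(act))
    if len(matched) < 3:
        raise ValueError(f"only {len(matched)} matched design ids; need >= 3")
    if unmatched:
        logger.warning("%d unmatched design ids", len(unmatched))

    y = np.array([act[i] for i in matched])
    rows = []
    for j, name in enumerate(descriptors):
        x = np.array([getattr(by_id[i].descriptors, name) for i in matched])
        res = permutation_correlation(
            x, y, n_perm=n_perm, seed=seed + j, convention=convention
        )
        rows.append((name, res.r_squared, res.spearman_rho, res.p_value))
    table = pd.DataFrame(rows, columns=["descriptor", "r_squared", "spearman_rho", "p_value"])
    return table, unmatched
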