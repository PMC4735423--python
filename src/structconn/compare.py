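"""Group comparison of topology profiles and demographics.

Subject-level tractography profiles are compared per density with an
independent two-sample t-test (two-tailed, pooled variance by default),
mirroring the per-density significance reporting of the clinical
analysis.  Group-level correlation networks have no within-group
replicates — there is one network per group — so those are compared with
a subject-relabelling permutation test: both networks are rebuilt under
random reassignments of subjects to groups (group sizes preserved) and
the observed per-density metric difference is referred to that null.
Demographic variables are compared with a two-sided Mann-Whitney U test.

No multiple-testing correction is applied across densities: each density
is tested at alpha on its own, and the count of significant densities is
reported.  Treat that count descriptively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .metrics import topology_profile
from .networks import ROIFeatureTable, build_group_correlation


@dataclass
class ComparisonResult:
    """Per-density test outcomes for one metric and one group pair."""

    metric: str
    groups: tuple
    densities: np.ndarray
    statistic: np.ndarray  # t statistic, or observed difference (permutation)
    p_value: np.ndarray
    alpha: float = 0.05
    method: str = "ttest"
    significant: np.ndarray = field(default=None)
    n_significant_densities: int = field(default=0)

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        self.statistic = np.asarray(self.statistic, dtype=float)
        self.p_value = np.asarray(self.p_value, dtype=float)
        if not (self.densities.shape == self.statistic.shape == self.p_value.shape):
            raise ValueError("densities, statistic and p_value must align")
        if np.any((self.p_value < 0) | (self.p_value > 1)):
            raise ValueError("p values outside [0, 1]")
        self.significant = self.p_value < self.alpha
        self.n_significant_densities = int(self.significant.sum())


def _stack_metric(profiles: list, metric: str) -> tuple[np.ndarray, np.ndarray]:
    grids = [np.asarray(p.densities) for p in profiles]
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
            raise ValueError("profiles have mismatched density grids")
    return grids[0], np.vstack([p[metric] for p in profiles])


def compare_subject_profiles(
    profiles_a: list,
    profiles_b: list,
    metric: str,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> ComparisonResult:
    """Two-sample t-test per density on a metric of subject-level profiles.

    ``equal_var=True`` gives the pooled-variance (Student) test; set False
    for Welch.  The statistic is signed as group A minus group B.  A
    density where both groups are constant yields t=0, p=1 with a warning.
    """
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise ValueError("need at least 2 profiles per group")
    grid_a, xa = _stack_metric(profiles_a, metric)
    grid_b, xb = _stack_metric(profiles_b, metric)
    if grid_a.shape != grid_b.shape or not np.allclose(grid_a, grid_b):
        raise ValueError("the two groups use different density grids")
    t = np.zeros(grid_a.size)
    p = np.ones(grid_a.size)
    for di in range(grid_a.size):
        a, b = xa[:, di], xb[:, di]
        if a.std() == 0 and b.std() == 0:
            warnings.warn(
                f"zero variance in both groups at density {grid_a[di]:.4g}; "
                "reporting t=0, p=1",
                stacklevel=2,
            )
            continue
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        t[di], p[di] = res.statistic, res.pvalue
    return ComparisonResult(
        metric=metric,
        groups=("A", "B"),
        densities=grid_a,
        statistic=t,
        p_value=p,
        alpha=alpha,
        method="ttest" if equal_var else "welch",
    )


def permutation_compare_group_networks(
    table: ROIFeatureTable,
    groups: tuple,
    metric: str,
    densities,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    ranking: str = "signed",
) -> ComparisonResult:
    """Permutation test on metrics of two group-level correlation networks.

    The observed statistic at each density is metric(group A network) -
    metric(group B network).  The null is generated by shuffling the
    subject-to-group assignment (sizes preserved), rebuilding both
    correlation networks and recomputing the difference; the two-sided
    p value uses the add-one correction
    p = (1 + #{|null| >= |obs|}) / (n_perm + 1), so its lower bound is
    1/(n_perm+1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    ga, gb = groups
    densities = np.asarray(densities, dtype=float)

    idx_a = [i for i, g in enumerate(table.group_labels) if g == ga]
    idx_b = [i for i, g in enumerate(table.group_labels) if g == gb]
    if len(idx_a) < 3 or len(idx_b) < 3:
        raise ValueError("each group needs at least 3 subjects for correlation")

    def metric_diff(rows_a: np.ndarray, rows_b: np.ndarray) -> np.ndarray:
        out = np.empty(densities.size)
        for label, rows, sign in ((ga, rows_a, 1.0), (gb, rows_b, -1.0)):
            sub = ROIFeatureTable(
                subject_ids=[f"s{k}" for k in range(rows.shape[0])],
                group_labels=[str(label)] * rows.shape[0],
                region_names=list(table.region_names),
                values=rows,
                feature=table.feature,
            )
            corr = build_group_correlation(sub, str(label))
            prof = topology_profile(
                corr.r, densities, which=(metric,), ranking=ranking
            )
            if sign > 0:
                out = prof[metric].copy()
            else:
                out -= prof[metric]
        return out

    observed = metric_diff(table.values[idx_a], table.values[idx_b])

    rng = np.random.default_rng(seed)
    pool = np.array(idx_a + idx_b)
    n_a = len(idx_a)
    exceed = np.zeros(densities.size)
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        null = metric_diff(table.values[perm[:n_a]], table.values[perm[n_a:]])
        exceed += np.abs(null) >= np.abs(observed) - 1e-12
    p = (1.0 + exceed) / (n_perm + 1.0)
    return ComparisonResult(
        metric=metric,
        groups=(str(ga), str(gb)),
        densities=densities,
        statistic=observed,
        p_value=p,
        alpha=alpha,
        method="permutation",
    )


def compare_demographics(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (normal approximation, tie-corrected).

    Returns the U statistic of the first sample and the p value.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
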