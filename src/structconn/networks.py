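"""Network construction: feature tables, connectivity matrices, correlation
networks and density thresholding.

Two network families are built here.  Subject-level tractography networks
start from a directed streamline-count matrix ``PT`` (entry ``PT[i, j]`` =
streamlines seeded in region *i* that reached region *j*), which is
normalised by the number of streamlines drawn per seed and symmetrised
before thresholding.  Group-level structural covariance networks are
region-by-region Pearson correlation matrices of a morphometric feature
(cortical thickness or mean fractional anisotropy) computed across the
subjects of one group.

Both families are reduced to binary graphs at a fixed *link density*
``d = m / (n(n-1)/2)`` by keeping the ``round(d * n(n-1)/2)`` strongest
edges, so that group contrasts in topology are not confounded by a
different number of links.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DataError(ValueError):
    """Raised when input data violate a contract (bad counts, zero variance...)."""


@dataclass
class ROIFeatureTable:
    """Subjects x regions table of one scalar feature per atlas region.

    Parameters
    ----------
    subject_ids : list of str
    group_labels : list of str, one per subject
    region_names : list of str, unique
    values : (n_subjects, n_regions) float array; thickness in mm (> 0) or
        fractional anisotropy (unitless, in [0, 1]).
    feature : short tag, e.g. ``"thickness"`` or ``"fa"``.
    """

    subject_ids: list
    group_labels: list
    region_names: list
    values: np.ndarray
    feature: str = "feature"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D subjects x regions array")
        ns, nr = self.values.shape
        if len(self.subject_ids) != ns:
            raise DataError(f"{len(self.subject_ids)} subject ids for {ns} rows")
        if len(self.group_labels) != ns:
            raise DataError(f"{len(self.group_labels)} group labels for {ns} rows")
        if len(self.region_names) != nr:
            raise DataError(f"{len(self.region_names)} region names for {nr} columns")
        if len(set(self.region_names)) != nr:
            raise DataError("region names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise DataError("feature table contains missing or non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def groups(self) -> list:
        """Distinct group labels in order of first appearance."""
        seen: dict = {}
        for g in self.group_labels:
            seen.setdefault(g, None)
        return list(seen)

    def subset(self, group) -> "ROIFeatureTable":
        """Rows belonging to one group, order preserved."""
        idx = [i for i, g in enumerate(self.group_labels) if g == group]
        if not idx:
            raise DataError(f"no subjects with group label {group!r}")
        return ROIFeatureTable(
            subject_ids=[self.subject_ids[i] for i in idx],
            group_labels=[self.group_labels[i] for i in idx],
            region_names=list(self.region_names),
            values=self.values[idx],
            feature=self.feature,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.region_names)
        df.insert(0, "group", self.group_labels)
        df.insert(0, "subject", self.subject_ids)
        return df


@dataclass
class SubjectConnectivityMatrix:
    """One subject's region x region streamline connectivity.

    ``counts[i, j]`` is the number (or, after :func:`normalize_pt`, the
    fraction) of streamlines seeded in region *i* that reached region *j*.
    The raw matrix is directed; metrics require an undirected graph, so
    :func:`symmetrize` must be applied before thresholding.
    """

    region_names: list
    counts: np.ndarray
    normalized: bool = False
    symmetric: bool = False
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = len(self.region_names)
        if self.counts.shape != (n, n):
            raise DataError(
                f"matrix shape {self.counts.shape} does not match {n} regions"
            )
        if np.any(self.counts < 0):
            raise DataError("connectivity counts must be nonnegative")
        if np.any(np.diag(self.counts) != 0):
            raise DataError("connectivity diagonal must be zero")
        if self.normalized and np.any(self.counts > 1):
            raise DataError("normalized connectivity must lie in [0, 1]")
        if self.symmetric and not np.array_equal(self.counts, self.counts.T):
            raise DataError("symmetric flag set but matrix != its transpose")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)


@dataclass
class GroupCorrelationMatrix:
    """Structural covariance network of one group: across-subject Pearson
    correlations between every pair of regional feature values."""

    group_label: str
    region_names: list
    r: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.region_names)
        if self.r.shape != (n, n):
            raise DataError(f"r shape {self.r.shape} does not match {n} regions")
        if self.n_subjects < 3:
            raise DataError("a correlation network needs at least 3 subjects")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise DataError("correlation matrix must be symmetric")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise DataError("correlations must lie in [-1, 1]")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-12):
            raise DataError("correlation diagonal must be 1")


@dataclass
class ThresholdedGraph:
    """Binary undirected graph at a target link density.

    ``adjacency`` is the 0/1 symmetric matrix A with zero diagonal;
    ``edge_count`` m is half its sum and ``achieved_density`` is
    m / (n(n-1)/2), which can differ from ``target_density`` by at most one
    edge's worth of density because the edge count is an integer.
    """

    region_names: list
    adjacency: np.ndarray
    target_density: float
    achieved_density: float = field(default=0.0)
    edge_count: int = field(default=0)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        n = len(self.region_names)
        if self.adjacency.shape != (n, n):
            raise DataError("adjacency shape does not match region count")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise DataError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise DataError("adjacency must have no self-loops")
        vals = np.unique(self.adjacency)
        if not np.all(np.isin(vals, (0, 1))):
            raise DataError("adjacency must be binary")
        self.edge_count = int(self.adjacency.sum()) // 2
        max_edges = n * (n - 1) // 2
        self.achieved_density = self.edge_count / max_edges if max_edges else 0.0

    @property
    def n_nodes(self) -> int:
        return len(self.region_names)

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


# ---------------------------------------------------------------------------
# operations


def normalize_pt(
    matrix: SubjectConnectivityMatrix, total_samples: int
) -> SubjectConnectivityMatrix:
    """Convert streamline counts to connection probabilities.

    Each cell is divided by ``total_samples``, the number of streamlines
    drawn per seed region (5000 in the reference acquisition), so entries
    become the fraction of seeded streamlines reaching the target region.
    """
    if matrix.normalized:
        raise DataError("matrix is already normalized")
    if total_samples <= 0:
        raise DataError("total_samples must be positive")
    over = np.argwhere(matrix.counts > total_samples)
    if over.size:
        i, j = over[0]
        raise DataError(
            f"count {matrix.counts[i, j]:g} at cell ({i}, {j}) exceeds "
            f"total_samples={total_samples}"
        )
    return SubjectConnectivityMatrix(
        region_names=list(matrix.region_names),
        counts=matrix.counts / float(total_samples),
        normalized=True,
        symmetric=matrix.symmetric,
        subject_id=matrix.subject_id,
    )


_SYMMETRIZE_METHODS = {
    "mean": lambda a: (a + a.T) / 2.0,
    "max": lambda a: np.maximum(a, a.T),
    "min": lambda a: np.minimum(a, a.T),
}


def symmetrize(
    matrix: SubjectConnectivityMatrix, method: str = "mean"
) -> SubjectConnectivityMatrix:
    """Make a directed connectivity matrix undirected.

    ``output[i, j] = method(input[i, j], input[j, i])`` with method one of
    ``mean`` (default), ``max`` or ``min``.
    """
    if method not in _SYMMETRIZE_METHODS:
        raise ValueError(
            f"unknown symmetrization method {method!r}; "
            f"choose from {sorted(_SYMMETRIZE_METHODS)}"
        )
    return SubjectConnectivityMatrix(
        region_names=list(matrix.region_names),
        counts=_SYMMETRIZE_METHODS[method](matrix.counts),
        normalized=matrix.normalized,
        symmetric=True,
        subject_id=matrix.subject_id,
    )


def build_group_correlation(
    table: ROIFeatureTable, group
) -> GroupCorrelationMatrix:
    """Pearson correlation of every region pair across one group's subjects.

    This is the structural covariance network S: ``S[i, j]`` is the Pearson
    correlation between the feature values of regions *i* and *j* over the
    subjects of ``group``.  The diagonal is forced to exactly 1.
    """
    sub = table.subset(group)
    if sub.n_subjects < 3:
        raise DataError(
            f"group {group!r} has {sub.n_subjects} subjects; need >= 3"
        )
    sd = sub.values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DataError(
            f"region {sub.region_names[dead[0]]!r} has zero variance in "
            f"group {group!r}"
        )
    r = np.corrcoef(sub.values, rowvar=False)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return GroupCorrelationMatrix(
        group_label=str(group),
        region_names=list(sub.region_names),
        r=r,
        n_subjects=sub.n_subjects,
    )


def threshold_to_density(
    weights: np.ndarray,
    target_density: float,
    region_names: list | None = None,
    ranking: str = "signed",
) -> ThresholdedGraph:
    """Binarize a symmetric weight matrix at a fixed link density.

    Keeps the ``L = round(target_density * n(n-1)/2)`` largest off-diagonal
    weights as edges.  With ``ranking="signed"`` (default) weights are
    ranked by signed value, so strong positive correlations always win over
    negative ones; ``ranking="absolute"`` ranks by magnitude.  Ties at the
    cutoff are broken by lexicographic (i, j) upper-triangle order, which
    makes the result deterministic and the edge sets nested across
    densities.
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    if w.shape != (n, n):
        raise DataError("weights must be square")
    if not np.allclose(w, w.T, atol=1e-12, equal_nan=True):
        raise DataError("weights must be symmetric")
    if not 0 < target_density <= 1:
        raise ValueError(f"target_density {target_density} outside (0, 1]")
    if region_names is None:
        region_names = [f"R{k}" for k in range(n)]
    max_edges = n * (n - 1) // 2
    n_keep = int(round(target_density * max_edges))
    if n_keep == 0:
        raise ValueError(
            f"target_density {target_density} keeps zero edges at n={n}"
        )
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    if ranking == "absolute":
        vals = np.abs(vals)
    elif ranking != "signed":
        raise ValueError(f"unknown ranking {ranking!r}")
    # stable sort on -value keeps lexicographic (i, j) order among ties
    order = np.argsort(-vals, kind="stable")
    keep = order[:n_keep]
    adjacency = np.zeros((n, n), dtype=np.int8)
    adjacency[iu[keep], ju[keep]] = 1
    adjacency |= adjacency.T
    return ThresholdedGraph(
        region_names=list(region_names),
        adjacency=adjacency,
        target_density=float(target_density),
    )


def density_grid(d_min: float = 0.1, d_max: float = 0.6, k: int = 20) -> np.ndarray:
    """Evenly spaced link densities, inclusive of both endpoints.

    Defaults to the 20-point sweep over [0.1, 0.6] used throughout the
    topology analysis.
    """
    if not 0 < d_min < d_max <= 1:
        raise ValueError(f"require 0 < d_min < d_max <= 1, got [{d_min}, {d_max}]")
    if k < 2:
        raise ValueError("need at least 2 densities")
    return np.linspace(d_min, d_max, k)
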