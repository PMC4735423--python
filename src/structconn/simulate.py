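"""Synthetic three-group cohort generator.

Real inputs to the pipeline are (a) per-subject 116x116 probabilistic
tractography streamline-count matrices and (b) per-subject regional
morphometric features (cortical thickness, mean fractional anisotropy).
No such cohort is publicly deposited, so this module generates cohorts
carrying the statistical structure the analysis is designed to detect:

* connectivity follows a planted-module (stochastic block) model — each
  region belongs to one of a few modules, and the binomial success
  probability for a streamline to connect two regions is higher within a
  module than between modules, with the within-module probability
  depending on the clinical group;
* regional features are multivariate Gaussian with a block-structured
  correlation matrix — correlation ``rho`` within planted modules (group
  dependent) and zero between modules — so the group correlation networks
  downstream inherit a plantable modular contrast.

Group defaults mirror the reference cohort (20 CIS, 33 RRMS, 40 healthy
controls; 116 atlas regions; 5000 streamlines per seed region) with the
qualitative ordering RRMS > CIS > HC in modular strength, matching the
direction of the clinical findings the pipeline is meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .networks import ROIFeatureTable, SubjectConnectivityMatrix

DEFAULT_GROUPS = ("CIS", "RRMS", "HC")

#: feature moments used for the two morphometric channels (fixture choices:
#: cortical thickness ~ N(2.5 mm, 0.3 mm), FA ~ N(0.45, 0.05) before clipping)
FEATURE_MOMENTS = {"thickness": (2.5, 0.3), "fa": (0.45, 0.05)}


class ParameterError(ValueError):
    """A cohort parameter violates its bounds."""


def _default_modules(n_regions: int, n_modules: int = 4) -> np.ndarray:
    """Contiguous near-equal blocks of regions (default 4 planted modules)."""
    n_modules = min(n_modules, n_regions)
    sizes = [len(b) for b in np.array_split(np.arange(n_regions), n_modules)]
    return np.repeat(np.arange(n_modules), sizes)


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Attributes
    ----------
    n_per_group : subjects per group label.
    n_regions : atlas regions (network nodes).
    module_assignment : region -> planted module id; default 4 contiguous
        near-equal modules.
    within_module_p, between_module_p : per-group binomial success
        probability for a streamline connecting two regions in the same /
        different planted modules.
    feature_block_rho : per-group within-module correlation of regional
        features (zero between modules).
    feature_mean, feature_sd : per-feature Gaussian moments.
    streamline_total : streamlines drawn per seed region.
    subject_noise_sd : SD of the per-subject, per-region-pair Gaussian
        perturbation on the connection probabilities (clipped back to
        [0, 1]).  This is the dominant noise source: at 5000 streamlines
        the binomial sampling error on a proportion is ~0.007, far below
        anatomical and tracking variability between region pairs, so the
        crispness of the planted modules after density thresholding is
        set by the within/between probability gap relative to this SD.
    seed : RNG seed for :func:`generate_cohort`.
    """

    n_per_group: dict = field(
        default_factory=lambda: {"CIS": 20, "RRMS": 33, "HC": 40}
    )
    n_regions: int = 116
    module_assignment: np.ndarray | None = None
    within_module_p: dict = field(
        default_factory=lambda: {"CIS": 0.30, "RRMS": 0.40, "HC": 0.25}
    )
    between_module_p: dict = field(
        default_factory=lambda: {"CIS": 0.05, "RRMS": 0.05, "HC": 0.05}
    )
    feature_block_rho: dict = field(
        default_factory=lambda: {"CIS": 0.45, "RRMS": 0.60, "HC": 0.30}
    )
    feature_mean: dict = field(
        default_factory=lambda: {k: v[0] for k, v in FEATURE_MOMENTS.items()}
    )
    feature_sd: dict = field(
        default_factory=lambda: {k: v[1] for k, v in FEATURE_MOMENTS.items()}
    )
    streamline_total: int = 5000
    subject_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ParameterError("need at least 2 regions")
        if not self.n_per_group or any(
            (not isinstance(v, (int, np.integer))) or v < 1
            for v in self.n_per_group.values()
        ):
            raise ParameterError("n_per_group must map labels to positive integers")
        if self.module_assignment is None:
            self.module_assignment = _default_modules(self.n_regions)
        self.module_assignment = np.asarray(self.module_assignment, dtype=int)
        if self.module_assignment.shape != (self.n_regions,):
            raise ParameterError(
                "module_assignment must assign every region to a module"
            )
        for name, d in (
            ("within_module_p", self.within_module_p),
            ("between_module_p", self.between_module_p),
        ):
            for g in self.n_per_group:
                p = d.get(g)
                if p is None or not 0 <= p <= 1:
                    raise ParameterError(
                        f"{name}[{g!r}] = {p} is not a probability in [0, 1]"
                    )
        for g in self.n_per_group:
            rho = self.feature_block_rho.get(g)
            if rho is None or not -1 <= rho <= 1:
                raise ParameterError(
                    f"feature_block_rho[{g!r}] = {rho} outside [-1, 1]"
                )
        if self.streamline_total < 1:
            raise ParameterError("streamline_total must be positive")
        if self.subject_noise_sd < 0:
            raise ParameterError("subject_noise_sd must be nonnegative")

    @property
    def groups(self) -> list:
        return list(self.n_per_group)

    @property
    def region_names(self) -> list:
        return [f"R{k + 1:03d}" for k in range(self.n_regions)]

    @property
    def n_subjects(self) -> int:
        return int(sum(self.n_per_group.values()))

    def truth(self) -> dict:
        """Planted structure, sufficient to recompute expected block means."""
        return {
            "module_assignment": self.module_assignment.tolist(),
            "within_module_p": dict(self.within_module_p),
            "between_module_p": dict(self.between_module_p),
            "feature_block_rho": dict(self.feature_block_rho),
            "n_per_group": {k: int(v) for k, v in self.n_per_group.items()},
            "streamline_total": int(self.streamline_total),
            "subject_noise_sd": float(self.subject_noise_sd),
            "seed": int(self.seed),
        }


@dataclass
class SyntheticCohort:
    """Generated cohort: feature tables, per-subject PT matrices, and the
    planted truth needed to verify recovery downstream."""

    labels: dict
    thickness_table: ROIFeatureTable
    fa_table: ROIFeatureTable
    pt_matrices: dict
    truth: dict

    @property
    def n_subjects(self) -> int:
        return len(self.labels)


def generate_pt_matrix(
    config: CohortConfig, group, rng: np.random.Generator
) -> SubjectConnectivityMatrix:
    """One subject's directed streamline-count matrix under the planted
    block model.

    The count for the ordered pair (i, j) is Binomial(streamline_total, p)
    with p the group's within- or between-module probability depending on
    whether regions i and j share a planted module, perturbed per subject
    and per ordered pair by Gaussian noise of SD ``subject_noise_sd``
    (then clipped to [0, 1]).  The diagonal is zero and counts are
    bounded by ``streamline_total``, matching streamlines-passed /
    streamlines-drawn semantics.
    """
    if group not in config.n_per_group:
        raise ParameterError(f"unknown group {group!r}")
    mod = config.module_assignment
    same = mod[:, None] == mod[None, :]
    p = np.where(same, config.within_module_p[group], config.between_module_p[group])
    if config.subject_noise_sd > 0:
        noise = rng.normal(0.0, config.subject_noise_sd, size=p.shape)
        p = np.clip(p + noise, 0.0, 1.0)
    counts = rng.binomial(config.streamline_total, p).astype(float)
    np.fill_diagonal(counts, 0.0)
    return SubjectConnectivityMatrix(
        region_names=config.region_names, counts=counts
    )


def _block_correlation(
    modules: np.ndarray, rho: float
) -> np.ndarray:
    """Block-diagonal correlation: rho within modules, 0 between, 1 on the
    diagonal.  Raises if the implied matrix is not positive definite."""
    same = modules[:, None] == modules[None, :]
    corr = np.where(same, rho, 0.0)
    np.fill_diagonal(corr, 1.0)
    # equicorrelated block of size k needs rho > -1/(k-1)
    sizes = np.bincount(modules)
    kmax = int(sizes.max())
    if kmax > 1 and (rho <= -1.0 / (kmax - 1) or rho >= 1.0):
        raise ParameterError(
            f"feature_block_rho = {rho} makes a {kmax}-region block "
            "non-positive-definite"
        )
    return corr


def generate_feature_table(
    config: CohortConfig, feature: str, rng: np.random.Generator
) -> ROIFeatureTable:
    """Regional feature values for every subject of every group.

    Each group's rows are multivariate Gaussian with the group's
    block-structured correlation matrix; FA is clipped to [0, 1] and
    thickness to strictly positive values (the clipping slightly distorts
    the tails — see the methods note).
    """
    if feature not in config.feature_mean:
        raise ParameterError(f"unknown feature {feature!r}")
    mean = config.feature_mean[feature]
    sd = config.feature_sd[feature]
    rows, subject_ids, group_labels = [], [], []
    offset = 0
    for group, n_sub in config.n_per_group.items():
        corr = _block_correlation(config.module_assignment, config.feature_block_rho[group])
        chol = np.linalg.cholesky(corr)
        z = rng.standard_normal((n_sub, config.n_regions)) @ chol.T
        vals = mean + sd * z
        if feature == "fa":
            vals = np.clip(vals, 0.0, 1.0)
        else:
            vals = np.maximum(vals, 1e-6)
        rows.append(vals)
        subject_ids += [f"S{offset + s + 1:03d}" for s in range(n_sub)]
        group_labels += [group] * n_sub
        offset += n_sub
    return ROIFeatureTable(
        subject_ids=subject_ids,
        group_labels=group_labels,
        region_names=config.region_names,
        values=np.vstack(rows),
        feature=feature,
    )


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Full cohort: both feature tables plus one PT matrix per subject.

    Deterministic given ``config.seed``; the planted truth is recorded so
    downstream recovery can be verified.
    """
    rng = np.random.default_rng(config.seed)
    thickness = generate_feature_table(config, "thickness", rng)
    fa = generate_feature_table(config, "fa", rng)
    labels = dict(zip(thickness.subject_ids, thickness.group_labels))
    pt = {}
    for sid, group in labels.items():
        mat = generate_pt_matrix(config, group, rng)
        mat.subject_id = sid
        pt[sid] = mat
    return SyntheticCohort(
        labels=labels,
        thickness_table=thickness,
        fa_table=fa,
        pt_matrices=pt,
        truth=config.truth(),
    )
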