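"""Per-cell aggregation of lifetime / fraction maps and population statistics.

Each cell is a region of interest over which the valid pixels of the
mean-lifetime and f_D maps are averaged; populations of cells (e.g.
donor-only versus co-expression) are compared with a two-sample t-test,
and the independence of f_D from expression levels is checked with a
permutation test on the Spearman correlation between the per-cell
donor/acceptor intensity ratio and the per-cell mean f_D.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .maps import FractionMap, LifetimeMap

__all__ = [
    "CellSummary",
    "GroupComparison",
    "IndependenceResult",
    "summarize_cell",
    "compare_groups",
    "independence_check",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CellSummary:
    """Whole-cell averages over the valid pixels of a region of interest."""

    cell_id: str
    mean_tau: float
    mean_f_D: float
    donor_intensity: float
    acceptor_intensity: float | None
    intensity_ratio: float | None
    n_valid_pixels: int


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample t-test between per-cell values of two groups."""

    labels: tuple[str, str]
    means: tuple[float, float]
    sds: tuple[float, float]
    ns: tuple[int, int]
    t_statistic: float
    p_value: float
    test_variant: str


@dataclass(frozen=True)
class IndependenceResult:
    """Spearman correlation + permutation p for f_D vs intensity ratio."""

    rho: float
    p_value: float
    n_cells: int
    n_excluded: int
    n_permutations: int
    assessable: bool


def summarize_cell(
    lmap: LifetimeMap,
    fmap: FractionMap,
    roi_mask: np.ndarray,
    donor_image: np.ndarray | None = None,
    acceptor_image: np.ndarray | None = None,
    cell_id: str = "cell",
    photon_weighted: bool = False,
) -> CellSummary:
    """Average <tau> and f_D over the valid pixels of one cell ROI.

    Means are unweighted by default; ``photon_weighted=True`` weights each
    pixel by its photon count. The intensity ratio is donor total over
    acceptor total and is absent when no acceptor image is given.
    """
    roi = np.asarray(roi_mask, dtype=bool)
    sel = roi & lmap.valid_mask & fmap.valid_mask
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"ROI of {cell_id!r} contains no valid pixels")
    if photon_weighted:
        w = lmap.photon_count[sel].astype(float)
        mean_tau = float(np.average(lmap.tau_mean[sel], weights=w))
        mean_f = float(np.average(fmap.f_D[sel], weights=w))
    else:
        mean_tau = float(np.mean(lmap.tau_mean[sel]))
        mean_f = float(np.mean(fmap.f_D[sel]))
    donor = (
        float(np.sum(donor_image[roi]))
        if donor_image is not None
        else float(np.sum(lmap.photon_count[roi]))
    )
    acceptor = float(np.sum(acceptor_image[roi])) if acceptor_image is not None else None
    ratio = donor / acceptor if acceptor not in (None, 0.0) else None
    return CellSummary(
        cell_id=cell_id,
        mean_tau=mean_tau,
        mean_f_D=mean_f,
        donor_intensity=donor,
        acceptor_intensity=acceptor,
        intensity_ratio=ratio,
        n_valid_pixels=n,
    )


def compare_groups(
    group_a,
    group_b,
    variant: str = "student",
    labels: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Two-sided two-sample t-test between per-cell values.

    ``student`` pools variances (the classical Student's t-test); ``welch``
    drops the equal-variance assumption. Degenerate inputs (fewer than two
    finite values per group, or zero variance in both groups) raise.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown test variant {variant!r}")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 finite values")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return GroupComparison(
                labels=labels,
                means=(float(a.mean()), float(b.mean())),
                sds=(0.0, 0.0),
                ns=(a.size, b.size),
                t_statistic=0.0,
                p_value=1.0,
                test_variant=variant,
            )
        raise ValueError("zero variance in both groups: t statistic undefined")
    t, p = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return GroupComparison(
        labels=labels,
        means=(float(a.mean()), float(b.mean())),
        sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        ns=(int(a.size), int(b.size)),
        t_statistic=float(t),
        p_value=float(p),
        test_variant=variant,
    )


def independence_check(
    summaries,
    n_permutations: int = 9999,
    seed: int = 0,
) -> IndependenceResult:
    """Permutation test of association between expression and interaction.

    Spearman rho between the per-cell donor/acceptor intensity ratio and
    the per-cell mean f_D; the two-sided p-value is obtained by permuting
    the f_D values (``(1 + #{|rho*| >= |rho|}) / (n_permutations + 1)``).
    Cells without an intensity ratio are excluded (their count is logged
    and reported). A degenerate input (constant f_D or constant ratio)
    yields ``assessable=False`` rather than an exception.
    """
    pairs = [
        (s.intensity_ratio, s.mean_f_D)
        for s in summaries
        if s.intensity_ratio is not None and math.isfinite(s.intensity_ratio)
    ]
    n_excluded = len(list(summaries)) - len(pairs)
    if n_excluded:
        logger.info("independence_check: excluded %d cells without intensity ratio", n_excluded)
    if len(pairs) < 5:
        raise ValueError("need at least 5 cells with intensity ratios")
    ratio = np.array([p[0] for p in pairs])
    f_d = np.array([p[1] for p in pairs])
    if np.all(ratio == ratio[0]) or np.all(f_d == f_d[0]):
        return IndependenceResult(
            rho=float("nan"),
            p_value=float("nan"),
            n_cells=len(pairs),
            n_excluded=n_excluded,
            n_permutations=n_permutations,
            assessable=False,
        )
    rho_obs = float(stats.spearmanr(ratio, f_d).statistic)
    rng = np.random.default_rng(seed)
    # rank once; Spearman rho of permuted ranks is the Pearson r of ranks
    r_rank = stats.rankdata(ratio)
    f_rank = stats.rankdata(f_d)
    r_c = r_rank - r_rank.mean()
    norm_r = np.sqrt(np.sum(r_c**2))
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(f_rank)
        p_c = perm - perm.mean()
        rho_perm = float(np.dot(r_c, p_c) / (norm_r * np.sqrt(np.sum(p_c**2))))
        if abs(rho_perm) >= abs(rho_obs) - 1e-12:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return IndependenceResult(
        rho=rho_obs,
        p_value=float(p),
        n_cells=len(pairs),
        n_excluded=n_excluded,
        n_permutations=n_permutations,
        assessable=True,
    )
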