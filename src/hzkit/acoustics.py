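"""Bioacoustic divergence analysis.

Temperature adjustment of note duration, PCA of the four call variables,
three descriptive statistics comparing allopatric vs parapatric
species pairs — convex-hull overlap, weighted centroid distance and
weighted standard deviation — their allopatric/parapatric differences
(Delta), and a label-permutation significance test with an optional
down-sampled variant.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import pearsonr
from shapely.geometry import Polygon

from .genio import (
    CALL_GROUPS,
    GROUP_ALLO_A,
    GROUP_ALLO_B,
    GROUP_PARA_A,
    GROUP_PARA_B,
    CallTable,
)

STATISTIC_NAMES = ("overlap", "centroid_distance", "sd_A", "sd_B", "sd_cumulated")

_CONTEXT_GROUPS = {
    "allopatric": (GROUP_ALLO_A, GROUP_ALLO_B),
    "parapatric": (GROUP_PARA_A, GROUP_PARA_B),
}
_SPECIES_GROUPS = {
    "A": (GROUP_ALLO_A, GROUP_PARA_A),
    "B": (GROUP_ALLO_B, GROUP_PARA_B),
}


# ---------------------------------------------------------------------------
# preprocessing


@dataclass
class AdjustedTraits:
    """Call traits with note duration replaced by temperature residuals."""

    traits: np.ndarray  # (n, 4): DF, ND residual, RT, PR
    trait_names: tuple[str, ...]
    temperature_r: float
    slope: float


def temperature_adjust(calls: CallTable) -> AdjustedTraits:
    """Replace ND with the residuals of its OLS regression on temperature.

    DF, RT and PR pass through unchanged.  The Pearson correlation between
    temperature and raw ND is reported alongside.
    """
    t = calls.temperature_c
    if np.ptp(t) == 0:
        raise ValueError("temperature is constant; regression undefined")
    nd = calls.nd_s
    slope, intercept = np.polyfit(t, nd, 1)
    resid = nd - (slope * t + intercept)
    r = 0.0 if np.ptp(nd) == 0 else float(pearsonr(t, nd).statistic)
    traits = np.column_stack([calls.df_hz, resid, calls.rt_s, calls.pr_per_s])
    return AdjustedTraits(
        traits=traits,
        trait_names=("df_hz", "nd_resid_s", "rt_s", "pr_per_s"),
        temperature_r=r,
        slope=float(slope),
    )


@dataclass
class PcaResult:
    scores: np.ndarray  # (n, 4), centered per component
    explained: np.ndarray  # (4,), sums to 1
    loadings: np.ndarray  # (4 traits, 4 components)
    trait_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if np.any(self.explained < -1e-12):
            raise ValueError("negative explained variance")
        if abs(self.explained.sum() - 1.0) > 1e-8:
            raise ValueError("explained variances must sum to 1")


def run_pca(adjusted: AdjustedTraits | np.ndarray) -> PcaResult:
    """PCA on the correlation matrix of the (z-scored) call traits.

    The four variables have incommensurate units, so each is standardized
    before the eigendecomposition.  Component signs are fixed so the
    largest-magnitude loading of each component is positive.
    """
    if isinstance(adjusted, AdjustedTraits):
        x = adjusted.traits
        names = adjusted.trait_names
    else:
        x = np.asarray(adjusted, dtype=float)
        names = tuple(f"trait{i}" for i in range(x.shape[1]))
    if x.ndim != 2 or x.shape[1] != 4:
        raise ValueError("expected an (n, 4) trait matrix")
    if x.shape[0] < 5:
        raise ValueError("need at least 5 individuals for PCA")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant trait column(s): {bad}")
    z = (x - x.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    # sign convention: dominant loading positive
    for j in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    return PcaResult(
        scores=z @ eigvec,
        explained=eigval / eigval.sum(),
        loadings=eigvec,
        trait_names=names,
    )


# ---------------------------------------------------------------------------
# hull overlap


def _hull_polygon(points: np.ndarray) -> Polygon | None:
    try:
        hull = ConvexHull(points)
    except QhullError:
        return None
    return Polygon(points[hull.vertices])


def hull_overlap_2d(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Mean directed convex-hull overlap of two 2-D point sets.

    ``(I/area_a + I/area_b) / 2`` with ``I`` the intersection area of the
    two convex hulls; 0 when the hulls are disjoint.  Degenerate (zero
    area) hulls yield 0 with a warning.
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ValueError("each point set needs at least 3 points")
    pa, pb = _hull_polygon(a), _hull_polygon(b)
    if pa is None or pb is None or pa.area == 0 or pb.area == 0:
        warnings.warn("degenerate (zero-area) convex hull; overlap set to 0")
        return 0.0
    inter = pa.intersection(pb).area
    return float(0.5 * (inter / pa.area + inter / pb.area))


def hull_overlap_jaccard(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Intersection-over-union alternative to the mean directed overlap."""
    pa, pb = _hull_polygon(np.asarray(points_a)), _hull_polygon(np.asarray(points_b))
    if pa is None or pb is None or pa.area == 0 or pb.area == 0:
        warnings.warn("degenerate (zero-area) convex hull; overlap set to 0")
        return 0.0
    inter = pa.intersection(pb).area
    return float(inter / (pa.area + pb.area - inter))


# ---------------------------------------------------------------------------
# the three statistics


def _context_masks(labels: np.ndarray, context: str) -> tuple[np.ndarray, np.ndarray]:
    ga, gb = _CONTEXT_GROUPS[context]
    return labels == ga, labels == gb


def overlap_statistic(
    pca: PcaResult, labels, context: str, method: str = "mean_directed"
) -> float:
    """Species hull overlap in the given context, computed on the PC1/PC2
    and PC3/PC4 planes and averaged with weights proportional to the
    summed explained variance of each plane."""
    labels = np.asarray(labels)
    ma, mb = _context_masks(labels, context)
    if ma.sum() < 3 or mb.sum() < 3:
        raise ValueError(f"fewer than 3 individuals in a {context} species cell")
    overlap = hull_overlap_jaccard if method == "jaccard" else hull_overlap_2d
    v = pca.explained
    w12 = (v[0] + v[1]) / v.sum()
    w34 = (v[2] + v[3]) / v.sum()
    o12 = overlap(pca.scores[ma][:, :2], pca.scores[mb][:, :2])
    o34 = overlap(pca.scores[ma][:, 2:4], pca.scores[mb][:, 2:4])
    return float(w12 * o12 + w34 * o34)


def centroid_distance_statistic(pca: PcaResult, labels, context: str) -> float:
    """Euclidean distance between species centroids with each PC coordinate
    weighted by its explained-variance proportion."""
    labels = np.asarray(labels)
    ma, mb = _context_masks(labels, context)
    if not ma.any() or not mb.any():
        raise ValueError(f"empty species group in {context} context")
    ca = pca.scores[ma].mean(axis=0)
    cb = pca.scores[mb].mean(axis=0)
    return float(np.sqrt(np.sum((pca.explained * (ca - cb)) ** 2)))


def weighted_sd_statistic(pca: PcaResult, labels, species: str, context: str) -> float:
    """Sum over PCs of the group's sample SD weighted by explained variance."""
    labels = np.asarray(labels)
    group = {
        ("A", "allopatric"): GROUP_ALLO_A,
        ("B", "allopatric"): GROUP_ALLO_B,
        ("A", "parapatric"): GROUP_PARA_A,
        ("B", "parapatric"): GROUP_PARA_B,
    }[(species, context)]
    m = labels == group
    if m.sum() < 2:
        raise ValueError(f"group {group} has fewer than 2 individuals")
    sds = pca.scores[m].std(axis=0, ddof=1)
    return float(np.sum(pca.explained * sds))


# ---------------------------------------------------------------------------
# Delta suite and permutation test


@dataclass
class DeltaObserved:
    name: str
    allopatric: float
    parapatric: float
    delta: float  # parapatric minus allopatric


def delta_suite(pca: PcaResult, labels) -> dict[str, DeltaObserved]:
    """The five parapatric-minus-allopatric Delta statistics."""
    labels = np.asarray(labels)
    present = set(labels)
    missing = [g for g in CALL_GROUPS if g not in present]
    if missing:
        raise ValueError(f"missing call groups: {missing}")
    out: dict[str, DeltaObserved] = {}
    o_allo = overlap_statistic(pca, labels, "allopatric")
    o_para = overlap_statistic(pca, labels, "parapatric")
    out["overlap"] = DeltaObserved("overlap", o_allo, o_para, o_para - o_allo)
    d_allo = centroid_distance_statistic(pca, labels, "allopatric")
    d_para = centroid_distance_statistic(pca, labels, "parapatric")
    out["centroid_distance"] = DeltaObserved(
        "centroid_distance", d_allo, d_para, d_para - d_allo
    )
    for sp in ("A", "B"):
        s_allo = weighted_sd_statistic(pca, labels, sp, "allopatric")
        s_para = weighted_sd_statistic(pca, labels, sp, "parapatric")
        out[f"sd_{sp}"] = DeltaObserved(f"sd_{sp}", s_allo, s_para, s_para - s_allo)
    out["sd_cumulated"] = DeltaObserved(
        "sd_cumulated",
        out["sd_A"].allopatric + out["sd_B"].allopatric,
        out["sd_A"].parapatric + out["sd_B"].parapatric,
        out["sd_A"].delta + out["sd_B"].delta,
    )
    return out


def perm_pvalue(observed: float, null_sample: np.ndarray) -> float:
    """Plain-proportion permutation P: share of null draws whose absolute
    value reaches the observed absolute value."""
    null_sample = np.asarray(null_sample, dtype=float)
    if null_sample.size == 0:
        raise ValueError("empty null sample")
    return float(np.count_nonzero(np.abs(null_sample) >= abs(observed)) / null_sample.size)


@dataclass
class DeltaTestResult:
    name: str
    allopatric: float
    parapatric: float
    delta: float
    n_permutations: int
    null_deltas: np.ndarray
    p_value: float
    p_value_downsampled: float | None = None

    def __post_init__(self) -> None:
        if len(self.null_deltas) != self.n_permutations:
            raise ValueError("null sample size must equal the permutation count")


def _null_deltas(
    pca: PcaResult, labels: np.ndarray, B: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    nulls = {name: np.empty(B) for name in STATISTIC_NAMES}
    for b in range(B):
        perm = rng.permutation(labels)
        d = delta_suite(pca, perm)
        for name in STATISTIC_NAMES:
            nulls[name][b] = d[name].delta
    return nulls


def _downsample_mask(
    labels: np.ndarray, downsample_to: int, rng: np.random.Generator
) -> np.ndarray:
    keep = np.zeros(len(labels), dtype=bool)
    for g in CALL_GROUPS:
        idx = np.flatnonzero(labels == g)
        if len(idx) > downsample_to:
            idx = rng.choice(idx, size=downsample_to, replace=False)
        keep[idx] = True
    return keep


def permutation_test(
    pca: PcaResult,
    labels,
    B: int = 1000,
    seed: int = 0,
    downsample_to: int | None = 10,
) -> dict[str, DeltaTestResult]:
    """Permutation significance for the five Delta statistics.

    Each of the ``B`` permutations reshuffles the four-level group label
    across all individuals (group sizes preserved; PCA scores fixed, not
    refit) and recomputes all five statistics from the same shuffled
    labels.  ``P = #{|Delta_perm| >= |Delta_obs|} / B``.  When
    ``downsample_to`` is set, a second pass first reduces every group
    larger than the cutoff to that size and repeats observation and
    permutations on the reduced data.
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    obs = delta_suite(pca, labels)
    nulls = _null_deltas(pca, labels, B, rng)

    p_down: dict[str, float | None] = {name: None for name in STATISTIC_NAMES}
    if downsample_to is not None:
        keep = _downsample_mask(labels, downsample_to, rng)
        sizes = {g: int(np.sum(labels[keep] == g)) for g in CALL_GROUPS}
        too_small = [g for g, s in sizes.items() if s < 3]
        if too_small:
            raise ValueError(f"groups below 3 individuals after down-sampling: {too_small}")
        sub_pca = PcaResult(
            scores=pca.scores[keep],
            explained=pca.explained,
            loadings=pca.loadings,
            trait_names=pca.trait_names,
        )
        sub_labels = labels[keep]
        sub_obs = delta_suite(sub_pca, sub_labels)
        sub_nulls = _null_deltas(sub_pca, sub_labels, B, rng)
        for name in STATISTIC_NAMES:
            p_down[name] = perm_pvalue(sub_obs[name].delta, sub_nulls[name])

    out: dict[str, DeltaTestResult] = {}
    for name in STATISTIC_NAMES:
        o = obs[name]
        out[name] = DeltaTestResult(
            name=name,
            allopatric=o.allopatric,
            parapatric=o.parapatric,
            delta=o.delta,
            n_permutations=B,
            null_deltas=nulls[name],
            p_value=perm_pvalue(o.delta, nulls[name]),
            p_value_downsampled=p_down[name],
        )
    return out


def results_table(results: dict[str, DeltaTestResult]) -> pd.DataFrame:
    """Report table: one row per statistic with observed values and P."""
    rows = []
    for name in STATISTIC_NAMES:
        r = results[name]
        rows.append(
            {
                "statistic": name,
                "allopatric": r.allopatric,
                "parapatric": r.parapatric,
                "delta": r.delta,
                "p_value": r.p_value,
                "p_value_downsampled": r.p_value_downsampled,
            }
        )
    return pd.DataFrame(rows)


def null_samples_table(results: dict[str, DeltaTestResult]) -> pd.DataFrame:
    """Full permutation null samples, one column per statistic, for audit."""
    return pd.DataFrame({name: results[name].null_deltas for name in STATISTIC_NAMES})
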