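"""Two-parameter sigmoid geographic clines.

Model: ``p(x) = (1 + tanh(2 (x - c) / w)) / 2`` — center ``c`` is the
position of 50% frequency and width ``w`` is the inverse of the maximum
slope.  Fitting maximizes a binomial likelihood over localities via a
coarse grid followed by bounded local refinement; uncertainty is reported
as 2-log-likelihood-unit profile intervals.  Mitochondrial haplotype
frequencies, per-locality mean ancestry Q and per-SNP allele frequencies
all run through the same fit path.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln

from .genio import FrequencyProfile

_P_EPS = 1e-6
DEFAULT_BARRIER_WIDTH_KM = 2.0


def cline_predict(x, c: float, w: float):
    """Expected derived-allele frequency at transect position ``x`` (km)."""
    if w <= 0:
        raise ValueError("cline width must be positive")
    return 0.5 * (1.0 + np.tanh(2.0 * (np.asarray(x, dtype=float) - c) / w))


def cline_loglik(x, k, n, c: float, w: float) -> float:
    """Binomial log-likelihood of per-locality counts under a cline.

    ``k`` derived alleles out of ``n`` sampled at positions ``x``.  Real
    valued ``k`` is accepted so per-locality mean ancestry (scaled to an
    effective allele count) can reuse the same likelihood.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(k > n):
        raise ValueError("derived count exceeds total count")
    if np.any(k < 0) or np.any(n < 0):
        raise ValueError("negative counts")
    p = np.clip(cline_predict(x, c, w), _P_EPS, 1 - _P_EPS)
    const = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return float(np.sum(const + k * np.log(p) + (n - k) * np.log1p(-p)))


@dataclass
class ClineFit:
    center_km: float
    width_km: float
    loglik: float
    center_ci_km: tuple[float, float]
    width_ci_km: tuple[float, float]
    n_localities: int
    kind: str = "snp"
    flipped: bool = False  # allele polarity recoded so frequency rises with x

    def __post_init__(self) -> None:
        if self.width_km <= 0:
            raise ValueError("width must be positive")
        if not np.isfinite(self.loglik):
            raise ValueError("non-finite log-likelihood")
        lo, hi = self.center_ci_km
        if not (lo - 1e-9 <= self.center_km <= hi + 1e-9):
            raise ValueError("center outside its profile interval")
        lo, hi = self.width_ci_km
        if not (lo - 1e-9 <= self.width_km <= hi + 1e-9):
            raise ValueError("width outside its profile interval")


def _neg_ll(params, x, k, n):
    c, logw = params
    return -cline_loglik(x, k, n, c, float(np.exp(logw)))


def _profile_interval(
    grid: np.ndarray,
    profile_ll: np.ndarray,
    best: float,
    best_ll: float,
    drop: float = 2.0,
) -> tuple[float, float]:
    """Smallest/largest grid value whose profile LL is within ``drop`` of the
    maximum, linearly interpolated at the crossing."""
    thresh = best_ll - drop
    ok = profile_ll >= thresh
    if not ok.any():  # numerical corner: fall back to the point estimate
        return (best, best)
    lo_i = int(np.argmax(ok))
    hi_i = len(ok) - 1 - int(np.argmax(ok[::-1]))

    def cross(i_out: int, i_in: int) -> float:
        y0, y1 = profile_ll[i_out], profile_ll[i_in]
        if y1 == y0:
            return float(grid[i_in])
        t = (thresh - y0) / (y1 - y0)
        return float(grid[i_out] + t * (grid[i_in] - grid[i_out]))

    lo = float(grid[0]) if lo_i == 0 else cross(lo_i - 1, lo_i)
    hi = float(grid[-1]) if hi_i == len(grid) - 1 else cross(hi_i + 1, hi_i)
    return (min(lo, best), max(hi, best))


def fit_cline(
    x,
    k,
    n,
    *,
    center_bounds: tuple[float, float] | None = None,
    width_bounds: tuple[float, float] = (0.01, 1000.0),
    grid_starts: tuple[int, int] = (25, 25),
    compute_ci: bool = True,
    ci_grid: int = 101,
    kind: str = "snp",
    polarity: str = "auto",
) -> ClineFit:
    """Maximum-likelihood sigmoid cline fit to per-locality counts.

    When ``polarity='auto'`` and the frequency-distance trend is negative,
    the modeled allele is recoded (``k -> n - k``) so that frequency
    increases with ``x``; ``flipped`` records the recoding.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    has = n > 0
    x, k, n = x[has], k[has], n[has]
    if len(x) < 3:
        raise ValueError(f"need >= 3 localities with data, got {len(x)}")
    freq = k / n
    if np.all(freq == freq[0]):
        raise ValueError("degenerate data: identical frequency at all localities")

    flipped = False
    if polarity == "auto":
        trend = np.corrcoef(x, freq)[0, 1]
        if trend < 0:
            k = n - k
            flipped = True
    elif polarity not in ("increasing",):
        raise ValueError(f"unknown polarity {polarity!r}")

    if center_bounds is None:
        center_bounds = (float(x.min()), float(x.max()))
    w_lo, w_hi = width_bounds
    if w_lo <= 0:
        raise ValueError("width bounds must be positive")

    c_grid = np.linspace(center_bounds[0], center_bounds[1], grid_starts[0])
    w_grid = np.geomspace(w_lo, w_hi, grid_starts[1])
    # vectorized coarse scan
    p = 0.5 * (1 + np.tanh(2 * (x[None, None, :] - c_grid[:, None, None]) / w_grid[None, :, None]))
    p = np.clip(p, _P_EPS, 1 - _P_EPS)
    ll = (k * np.log(p) + (n - k) * np.log1p(-p)).sum(axis=2)
    ci0, wi0 = np.unravel_index(np.argmax(ll), ll.shape)

    res = minimize(
        _neg_ll,
        x0=np.array([c_grid[ci0], np.log(w_grid[wi0])]),
        args=(x, k, n),
        method="L-BFGS-B",
        bounds=[center_bounds, (np.log(w_lo), np.log(w_hi))],
    )
    c_hat, w_hat = float(res.x[0]), float(np.exp(res.x[1]))
    best_ll = cline_loglik(x, k, n, c_hat, w_hat)

    if compute_ci:
        c_ci = _profile_ci_center(
            x, k, n, c_hat, best_ll, center_bounds, width_bounds, ci_grid
        )
        w_ci = _profile_ci_width(
            x, k, n, w_hat, best_ll, center_bounds, width_bounds, ci_grid
        )
    else:
        c_ci = (c_hat, c_hat)
        w_ci = (w_hat, w_hat)

    return ClineFit(
        center_km=c_hat,
        width_km=w_hat,
        loglik=best_ll,
        center_ci_km=c_ci,
        width_ci_km=w_ci,
        n_localities=len(x),
        kind=kind,
        flipped=flipped,
    )


def _profile_ci_center(x, k, n, c_hat, best_ll, c_bounds, w_bounds, n_grid):
    grid = np.linspace(c_bounds[0], c_bounds[1], n_grid)
    log_w_bounds = (np.log(w_bounds[0]), np.log(w_bounds[1]))
    prof = np.empty(n_grid)
    for i, c in enumerate(grid):
        r = minimize_scalar(
            lambda lw: -cline_loglik(x, k, n, c, float(np.exp(lw))),
            bounds=log_w_bounds,
            method="bounded",
        )
        prof[i] = -r.fun
    return _profile_interval(grid, prof, c_hat, best_ll)


def _profile_ci_width(x, k, n, w_hat, best_ll, c_bounds, w_bounds, n_grid):
    grid = np.geomspace(w_bounds[0], w_bounds[1], n_grid)
    prof = np.empty(n_grid)
    for i, w in enumerate(grid):
        r = minimize_scalar(
            lambda c: -cline_loglik(x, k, n, c, w),
            bounds=c_bounds,
            method="bounded",
        )
        prof[i] = -r.fun
    return _profile_interval(grid, prof, w_hat, best_ll)


def fit_frequency_profile(
    profile: FrequencyProfile,
    *,
    compute_ci: bool = False,
    kind: str = "snp",
    **fit_kwargs,
) -> dict[str, ClineFit]:
    """Fit every locus in a frequency profile; loci whose data are
    degenerate (too few localities, constant frequency) are skipped with a
    warning and absent from the result."""
    fits: dict[str, ClineFit] = {}
    skipped = 0
    for locus in profile.loci:
        xd, kd, nd = profile.row(locus)
        try:
            fits[locus] = fit_cline(
                xd, kd, nd, compute_ci=compute_ci, kind=kind, **fit_kwargs
            )
        except ValueError:
            skipped += 1
    if skipped:
        warnings.warn(f"skipped {skipped} loci with degenerate data")
    return fits


def fit_mean_q_cline(
    mean_q: np.ndarray,
    n_individuals: np.ndarray,
    distances_km: np.ndarray,
    **fit_kwargs,
) -> ClineFit:
    """Cline on per-locality mean ancestry Q.

    Mean Q is treated as a binomial proportion with effective allele count
    ``2 x individuals`` (each diploid genome contributes two draws).
    """
    n_eff = 2 * np.asarray(n_individuals, dtype=float)
    k_eff = np.asarray(mean_q, dtype=float) * n_eff
    fit_kwargs.setdefault("kind", "ancestry_q")
    return fit_cline(distances_km, k_eff, n_eff, **fit_kwargs)


@dataclass
class MultilocusSummary:
    fits: dict[str, ClineFit]
    mean_width_km: float
    median_width_km: float
    sd_width_km: float
    mean_center_km: float
    delta_center_km: dict[str, float]
    barrier_flags: dict[str, bool]
    barrier_width_km: float = DEFAULT_BARRIER_WIDTH_KM

    def barrier_loci(self) -> list[str]:
        return [l for l, f in self.barrier_flags.items() if f]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for locus, f in self.fits.items():
            rows.append(
                {
                    "locus": locus,
                    "center_km": f.center_km,
                    "width_km": f.width_km,
                    "center_low_km": f.center_ci_km[0],
                    "center_high_km": f.center_ci_km[1],
                    "width_low_km": f.width_ci_km[0],
                    "width_high_km": f.width_ci_km[1],
                    "delta_center_km": self.delta_center_km[locus],
                    "barrier_flag": self.barrier_flags[locus],
                    "flipped": f.flipped,
                }
            )
        return pd.DataFrame(rows)


def summarize_multilocus(
    fits: dict[str, ClineFit],
    barrier_width_km: float = DEFAULT_BARRIER_WIDTH_KM,
) -> MultilocusSummary:
    """Mean/median/SD of widths, mean center, per-locus center deviations
    and barrier flags (width below ``barrier_width_km``)."""
    if not fits:
        raise ValueError("no cline fits to summarize")
    widths = np.array([f.width_km for f in fits.values()])
    centers = np.array([f.center_km for f in fits.values()])
    if len(widths) == 1:
        warnings.warn("single fit: width SD reported as 0")
        sd_w = 0.0
    else:
        sd_w = float(np.std(widths, ddof=1))
    mean_c = float(np.mean(centers))
    return MultilocusSummary(
        fits=dict(fits),
        mean_width_km=float(np.mean(widths)),
        median_width_km=float(np.median(widths)),
        sd_width_km=sd_w,
        mean_center_km=mean_c,
        delta_center_km={l: f.center_km - mean_c for l, f in fits.items()},
        barrier_flags={l: f.width_km < barrier_width_km for l, f in fits.items()},
        barrier_width_km=barrier_width_km,
    )
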