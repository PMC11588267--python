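"""K=2 genome-average ancestry estimation.

Maximum-likelihood admixture proportions under the binomial model
``g_il ~ Binomial(2, Q_i * f_Al + (1 - Q_i) * f_Bl)``, fitted by EM.  The
E-step attributes each observed gene copy to one of the two ancestral
clusters; the M-step re-estimates ``Q`` and the cluster allele frequencies
from those attributions.  The log-likelihood is non-decreasing across
iterations (standard EM guarantee, asserted by the test suite).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genio import MISSING, PANEL_REF_A, PANEL_REF_B, GenotypeDataset

_F_EPS = 1e-6


@dataclass
class QEstimates:
    individuals: list[str]
    q: np.ndarray  # (n,) ancestry toward cluster A
    f_a: np.ndarray  # (m,) cluster-A allele frequencies
    f_b: np.ndarray
    loglik: float
    loglik_path: np.ndarray
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        if np.any((self.q < 0) | (self.q > 1)):
            raise ValueError("Q outside [0, 1]")
        if not np.isfinite(self.loglik):
            raise ValueError("non-finite log-likelihood")


def _loglik(g: np.ndarray, obs: np.ndarray, q: np.ndarray, fa: np.ndarray,
            fb: np.ndarray) -> float:
    p = np.clip(q[:, None] * fa + (1 - q[:, None]) * fb, _F_EPS, 1 - _F_EPS)
    const = gammaln(3) - gammaln(g + 1) - gammaln(3 - g)
    ll = const + g * np.log(p) + (2 - g) * np.log1p(-p)
    return float(ll[obs].sum())


def fit_admixture_k2(
    ds: GenotypeDataset,
    tol: float = 1e-8,
    max_iter: int = 2000,
    seed: int = 0,
    anchors: tuple[str, str] | None = None,
) -> QEstimates:
    """EM fit of per-individual ancestry Q and per-cluster frequencies.

    Missing genotypes are skipped.  Cluster frequencies are initialised
    from reference-panel frequencies when the dataset carries panel labels,
    otherwise uniformly at random under ``seed``.  Label switching is
    resolved by forcing the anchor-A individual (or, absent anchors, the
    individual with the highest first-iteration Q) to cluster A.
    """
    if ds.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    g = ds.genotypes.astype(float)
    obs = ds.genotypes != MISSING
    if np.any(~obs.any(axis=1)):
        bad = [i for i, ok in zip(ds.individuals, obs.any(axis=1)) if not ok]
        raise ValueError(f"all genotypes missing for individuals: {bad}")
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(np.where(obs, g, np.nan), axis=0)
    if not np.any((col_mean > 0) & (col_mean < 2)):
        raise ValueError("no polymorphic loci")
    g = np.where(obs, g, 0.0)

    rng = np.random.default_rng(seed)
    if ds.panels is not None and PANEL_REF_A in ds.panels and PANEL_REF_B in ds.panels:
        pa = np.array([p == PANEL_REF_A for p in ds.panels])
        pb = np.array([p == PANEL_REF_B for p in ds.panels])

        def panel_freq(rows: np.ndarray) -> np.ndarray:
            calls = obs[rows].sum(axis=0)
            alt = g[rows].sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                f = alt / (2 * np.maximum(calls, 1))
            return np.where(calls > 0, f, 0.5)

        fa, fb = panel_freq(pa), panel_freq(pb)
    else:
        fa = rng.uniform(0.1, 0.9, ds.n_loci)
        fb = rng.uniform(0.1, 0.9, ds.n_loci)
    fa = np.clip(fa, _F_EPS, 1 - _F_EPS)
    fb = np.clip(fb, _F_EPS, 1 - _F_EPS)
    q = np.full(ds.n_individuals, 0.5)

    n_obs = obs.sum(axis=1)
    path = [_loglik(g, obs, q, fa, fb)]
    converged = False
    q_first = None
    it = 0
    for it in range(1, max_iter + 1):
        qc = q[:, None]
        p = np.clip(qc * fa + (1 - qc) * fb, _F_EPS, 1 - _F_EPS)
        pc = np.clip(qc * (1 - fa) + (1 - qc) * (1 - fb), _F_EPS, 1 - _F_EPS)
        # expected alt / ref gene copies attributed to cluster A
        a_alt = np.where(obs, g * (qc * fa) / p, 0.0)
        a_ref = np.where(obs, (2 - g) * (qc * (1 - fa)) / pc, 0.0)
        b_alt = np.where(obs, g * ((1 - qc) * fb) / p, 0.0)
        b_ref = np.where(obs, (2 - g) * ((1 - qc) * (1 - fb)) / pc, 0.0)

        q = (a_alt + a_ref).sum(axis=1) / (2 * n_obs)
        denom_a = (a_alt + a_ref).sum(axis=0)
        denom_b = (b_alt + b_ref).sum(axis=0)
        fa = np.where(denom_a > 0, a_alt.sum(axis=0) / np.maximum(denom_a, 1e-300), fa)
        fb = np.where(denom_b > 0, b_alt.sum(axis=0) / np.maximum(denom_b, 1e-300), fb)
        fa = np.clip(fa, _F_EPS, 1 - _F_EPS)
        fb = np.clip(fb, _F_EPS, 1 - _F_EPS)
        q = np.clip(q, 0.0, 1.0)
        if q_first is None:
            q_first = q.copy()

        path.append(_loglik(g, obs, q, fa, fb))
        rel = abs(path[-1] - path[-2]) / (abs(path[-2]) + 1e-12)
        if rel < tol:
            converged = True
            break

    # resolve label switching
    if anchors is not None:
        anchor_a = anchors[0]
        if anchor_a not in ds.individuals:
            raise KeyError(f"unknown anchor individual {anchor_a!r}")
        ia = ds.individuals.index(anchor_a)
    elif ds.panels is not None and PANEL_REF_A in ds.panels:
        ia = ds.panels.index(PANEL_REF_A)
    else:
        ia = int(np.argmax(q_first))
    if q[ia] < 0.5:
        q = 1 - q
        fa, fb = fb, fa

    return QEstimates(
        individuals=list(ds.individuals),
        q=q,
        f_a=fa,
        f_b=fb,
        loglik=path[-1],
        loglik_path=np.array(path),
        n_iter=it,
        converged=converged,
    )


def population_mean_q(est: QEstimates, localities) -> pd.DataFrame:
    """Arithmetic mean Q per locality, with sample sizes.

    ``localities`` maps each individual to its locality: either a parallel
    sequence of locality ids or a mapping ``individual id -> locality id``.
    """
    if hasattr(localities, "get") and not isinstance(localities, (list, tuple)):
        labels = []
        for ind in est.individuals:
            if ind not in localities:
                raise ValueError(f"individual {ind!r} not mapped to a locality")
            labels.append(str(localities[ind]))
    else:
        labels = list(map(str, localities))
        if len(labels) != len(est.individuals):
            raise ValueError("locality sequence must cover every individual")
    df = pd.DataFrame({"locality_id": labels, "q": est.q})
    out = (
        df.groupby("locality_id", sort=True)["q"]
        .agg(mean_q="mean", n_individuals="size")
        .reset_index()
    )
    return out


def write_q_csv(est: QEstimates, localities, path) -> None:
    if len(localities) != len(est.individuals):
        raise ValueError("locality sequence must cover every individual")
    pd.DataFrame(
        {
            "individual_id": est.individuals,
            "locality_id": list(map(str, localities)),
            "q": est.q,
        }
    ).to_csv(path, index=False)
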