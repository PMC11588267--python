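"""Seeded generators for hybrid-zone test data.

Three generators emulate the statistical structure the downstream analysis
assumes: a genotype transect whose per-locus allele frequencies follow
sigmoid clines (with optional near-zero-width "barrier" loci and missing
calls), unadmixed reference panels carrying planted fixed differences, and
advertisement-call datasets under three scenarios — no context effect,
character displacement (parapatric means pushed apart) and variance
reduction (parapatric spread shrunk).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clines import cline_predict
from .genio import (
    CALL_GROUPS,
    GROUP_ALLO_A,
    GROUP_ALLO_B,
    GROUP_PARA_A,
    GROUP_PARA_B,
    MISSING,
    PANEL_REF_A,
    PANEL_REF_B,
    PANEL_TRANSECT,
    CallTable,
    GenotypeDataset,
    LocalityTable,
)

# one degree of arc on the generating sphere, used to lay localities out
# west-to-east so haversine distances reproduce the transect distances
_KM_PER_DEGREE = np.pi * 6371.0 / 180.0


@dataclass
class TransectConfig:
    n_localities: int = 19
    transect_length_km: float = 170.0
    samples_per_locality: int = 3
    n_loci: int = 100
    true_center_km: float = 85.0
    true_width_mean_km: float = 20.6
    true_width_sd_km: float = 9.5
    center_sd_km: float = 5.0
    n_barrier_loci: int = 0
    barrier_width_km: float = 0.5
    mito_width_km: float = 9.8
    mito_center_km: float | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_localities < 2 or self.samples_per_locality < 1 or self.n_loci < 1:
            raise ValueError("non-positive dimensions")
        if self.transect_length_km <= 0:
            raise ValueError("transect length must be positive")
        if min(self.true_width_mean_km, self.barrier_width_km, self.mito_width_km) <= 0:
            raise ValueError("widths must be positive")
        if self.true_width_sd_km < 0 or self.center_sd_km < 0:
            raise ValueError("dispersions must be non-negative")
        if not (0 <= self.missing_rate <= 1):
            raise ValueError("missing_rate must be in [0, 1]")
        if self.n_barrier_loci > self.n_loci:
            raise ValueError("n_barrier_loci exceeds n_loci")


@dataclass
class TransectSimulation:
    """Synthetic transect plus the generating truth for recovery checks."""

    dataset: GenotypeDataset
    localities: LocalityTable
    mito: pd.DataFrame  # individual_id, locality_id, haplotype (0/1)
    true_centers_km: np.ndarray
    true_widths_km: np.ndarray
    barrier_loci: list[str]
    mito_center_km: float
    mito_width_km: float


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and SD."""
    if sd == 0:
        return np.log(mean), 0.0
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2, np.sqrt(sigma2)


def simulate_transect(config: TransectConfig) -> TransectSimulation:
    """Genotypes, localities and mitochondrial haplotypes along a transect.

    Localities are evenly spaced on ``[0, transect_length]``.  Each locus
    draws a width (log-normal around the configured mean) and a center
    (normal around the true center); the designated barrier loci get the
    barrier width exactly.  Every individual's genotype at locus ``l`` is a
    binomial draw of two alleles with derived-allele probability given by
    the cline at its locality; the mitochondrial haplotype is one binary
    draw from its own (typically narrower) cline.
    """
    rng = np.random.default_rng(config.seed)
    x = np.linspace(0.0, config.transect_length_km, config.n_localities)
    locality_ids = [f"loc{j + 1:02d}" for j in range(config.n_localities)]

    mu, sigma = _lognormal_params(config.true_width_mean_km, config.true_width_sd_km)
    widths = rng.lognormal(mu, sigma, config.n_loci)
    centers = rng.normal(config.true_center_km, config.center_sd_km, config.n_loci)
    barrier_idx = rng.choice(config.n_loci, size=config.n_barrier_loci, replace=False)
    widths[barrier_idx] = config.barrier_width_km
    loci = [f"rad{l + 1:04d}_1" for l in range(config.n_loci)]
    barrier_loci = [loci[i] for i in sorted(barrier_idx)]

    n_ind = config.n_localities * config.samples_per_locality
    ind_x = np.repeat(x, config.samples_per_locality)
    localities = np.repeat(locality_ids, config.samples_per_locality)
    individuals = [f"ind{i + 1:03d}" for i in range(n_ind)]

    p = np.stack(
        [cline_predict(ind_x, centers[l], widths[l]) for l in range(config.n_loci)],
        axis=1,
    )  # (n_ind, n_loci)
    geno = rng.binomial(2, p).astype(np.int16)
    if config.missing_rate > 0:
        miss = rng.random(geno.shape) < config.missing_rate
        geno[miss] = MISSING

    mito_center = (
        config.true_center_km if config.mito_center_km is None else config.mito_center_km
    )
    p_mito = cline_predict(ind_x, mito_center, config.mito_width_km)
    mito = pd.DataFrame(
        {
            "individual_id": individuals,
            "locality_id": localities,
            "haplotype": rng.binomial(1, p_mito),
        }
    )

    table = LocalityTable(
        ids=locality_ids,
        latitude=np.zeros(config.n_localities),
        longitude=x / _KM_PER_DEGREE,
        transect_distance_km=x,
        number=list(range(1, config.n_localities + 1)),
    )
    dataset = GenotypeDataset(
        individuals=individuals,
        localities=list(localities),
        loci=loci,
        genotypes=geno,
        panels=[PANEL_TRANSECT] * n_ind,
    )
    return TransectSimulation(
        dataset=dataset,
        localities=table,
        mito=mito,
        true_centers_km=centers,
        true_widths_km=widths,
        barrier_loci=barrier_loci,
        mito_center_km=mito_center,
        mito_width_km=config.mito_width_km,
    )


def simulate_reference_panels(
    n_a: int,
    n_b: int,
    n_fixed: int,
    n_shared: int,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> GenotypeDataset:
    """Two unadmixed reference panels with planted diagnostic loci.

    The ``n_fixed`` loci (ids ``fixed_####``) are fixed for opposite
    alleles between panels; the ``n_shared`` loci (ids ``shared_####``) are
    polymorphic with the same expected frequency in both panels.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("panel sizes must be >= 1")
    if n_fixed + n_shared < 1:
        raise ValueError("zero loci requested")
    if not (0 <= missing_rate <= 1):
        raise ValueError("missing_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_ind = n_a + n_b
    in_a = np.arange(n_ind) < n_a

    fixed = np.where(in_a[:, None], 2, 0) * np.ones((1, n_fixed), dtype=int)
    shared_freq = rng.uniform(0.05, 0.95, n_shared)
    shared = rng.binomial(2, np.broadcast_to(shared_freq, (n_ind, n_shared)))
    geno = np.concatenate([fixed, shared], axis=1).astype(np.int16)
    if missing_rate > 0:
        miss = rng.random(geno.shape) < missing_rate
        # keep every panel represented at every locus so fixed differences
        # stay observable: never blank out an entire panel
        for j in range(geno.shape[1]):
            for rows in (np.flatnonzero(in_a), np.flatnonzero(~in_a)):
                if miss[rows, j].all():
                    miss[rng.choice(rows), j] = False
        geno[miss] = MISSING

    loci = [f"fixed_{j:04d}" for j in range(n_fixed)] + [
        f"shared_{j:04d}" for j in range(n_shared)
    ]
    return GenotypeDataset(
        individuals=[f"ref{i + 1:03d}" for i in range(n_ind)],
        localities=["panelA" if a else "panelB" for a in in_a],
        loci=loci,
        genotypes=geno,
        panels=[PANEL_REF_A if a else PANEL_REF_B for a in in_a],
    )


# trait order: DF (Hz), ND (s), RT (s), PR (1/s)
DEFAULT_TRAIT_MEANS_A = (1250.0, 0.16, 0.055, 42.0)
DEFAULT_TRAIT_SDS = (120.0, 0.03, 0.012, 5.0)
#: species-B offset: PR and DF higher in species B
DEFAULT_SPECIES_SHIFT = (150.0, 0.0, 0.0, 8.0)
DEFAULT_DISPLACEMENT_SHIFT = (120.0, 0.0, 0.006, 5.0)
#: ND change per degree C, sized so r(T, ND) is about -0.64 over a 10 C range
DEFAULT_TEMP_SLOPE = -0.0087

SCENARIOS = ("null", "displacement", "variance_reduction")


@dataclass
class CallScenario:
    scenario: str = "null"
    group_sizes: tuple[int, int, int, int] = (27, 22, 9, 13)
    trait_means_a: tuple[float, ...] = DEFAULT_TRAIT_MEANS_A
    trait_sds: tuple[float, ...] = DEFAULT_TRAIT_SDS
    species_mean_shift: tuple[float, ...] = DEFAULT_SPECIES_SHIFT
    displacement_shift: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    variance_factor: float = 1.0
    trait_corr: np.ndarray | None = None
    temp_slope: float = DEFAULT_TEMP_SLOPE
    temp_range_c: tuple[float, float] = (10.0, 20.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if any(s < 3 for s in self.group_sizes):
            raise ValueError("group sizes must be >= 3")
        if self.variance_factor <= 0:
            raise ValueError("variance_factor must be positive")
        if self.scenario == "null":
            if any(d != 0 for d in self.displacement_shift) or self.variance_factor != 1:
                raise ValueError(
                    "null scenario requires zero displacement and variance_factor 1"
                )

    @classmethod
    def null(cls, **kw) -> "CallScenario":
        return cls(scenario="null", **kw)

    @classmethod
    def displacement(
        cls, shift: tuple[float, ...] = DEFAULT_DISPLACEMENT_SHIFT, **kw
    ) -> "CallScenario":
        return cls(scenario="displacement", displacement_shift=shift, **kw)

    @classmethod
    def variance_reduction(cls, rho: float = 0.6, **kw) -> "CallScenario":
        return cls(scenario="variance_reduction", variance_factor=rho, **kw)


def simulate_calls(scenario: CallScenario) -> CallTable:
    """Advertisement-call dataset for the four species-by-context groups.

    Traits are multivariate normal per group.  Parapatric groups have their
    means shifted by the displacement vector in opposite directions
    (species A down, species B up) and their SDs scaled by the variance
    factor.  ND additionally receives a linear temperature effect with
    temperatures uniform over the configured range.  Draws are clipped to
    the physical constraints (positive DF/ND/PR, 0 <= RT <= ND).
    """
    rng = np.random.default_rng(scenario.seed)
    means_a = np.asarray(scenario.trait_means_a, dtype=float)
    sds = np.asarray(scenario.trait_sds, dtype=float)
    shift = np.asarray(scenario.species_mean_shift, dtype=float)
    disp = np.asarray(scenario.displacement_shift, dtype=float)

    corr = np.eye(4) if scenario.trait_corr is None else np.asarray(scenario.trait_corr)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError("trait correlation matrix is not positive definite")

    group_params = {
        GROUP_ALLO_A: (means_a, sds),
        GROUP_ALLO_B: (means_a + shift, sds),
        GROUP_PARA_A: (means_a - disp, sds * scenario.variance_factor),
        GROUP_PARA_B: (means_a + shift + disp, sds * scenario.variance_factor),
    }

    rows_traits = []
    rows_groups = []
    for g, size in zip(CALL_GROUPS, scenario.group_sizes):
        mean, sd = group_params[g]
        z = rng.standard_normal((size, 4)) @ chol.T
        rows_traits.append(mean + z * sd)
        rows_groups.extend([g] * size)
    traits = np.vstack(rows_traits)
    n = traits.shape[0]

    t_lo, t_hi = scenario.temp_range_c
    temp = rng.uniform(t_lo, t_hi, n)
    traits[:, 1] += scenario.temp_slope * (temp - 0.5 * (t_lo + t_hi))

    df = np.maximum(traits[:, 0], 1.0)
    nd = np.maximum(traits[:, 1], 1e-3)
    rt = np.clip(traits[:, 2], 0.0, nd)
    pr = np.maximum(traits[:, 3], 1e-3)

    return CallTable(
        individuals=[f"call{i + 1:03d}" for i in range(n)],
        localities=rows_groups,
        groups=rows_groups,
        temperature_c=temp,
        df_hz=df,
        nd_s=nd,
        rt_s=rt,
        pr_per_s=pr,
    )
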