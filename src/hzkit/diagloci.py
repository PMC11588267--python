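"""Locus presence/call-rate filtering and species-diagnostic SNP selection.

Filtering mirrors population-genomics pipeline semantics: a locus passes
when at least ``min_groups_present`` groups each reach the per-group call
rate ``min_call_rate``.  Diagnostic selection compares per-panel allele
frequencies with exact rational arithmetic, so a "frequency difference of
1" means truly fixed differences, never a float-rounding artefact.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Mapping, Sequence

import numpy as np

from .genio import (
    MISSING,
    PANEL_REF_A,
    PANEL_REF_B,
    FrequencyProfile,
    GenotypeDataset,
)

NO_DATA = np.nan


@dataclass(frozen=True)
class LocusFilterSpec:
    """Presence/call-rate filter settings.

    ``min_groups_present`` (p): minimum number of groups in which the locus
    must be adequately called; ``min_call_rate`` (r): fraction of a group's
    individuals that must be called for the group to count.
    """

    min_groups_present: int
    min_call_rate: float
    one_snp_per_locus: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_groups_present < 1:
            raise ValueError("min_groups_present must be >= 1")
        if not (0 < self.min_call_rate <= 1):
            raise ValueError("min_call_rate must be in (0, 1]")


@dataclass
class GroupFrequencies:
    """Per-group alternate-allele counts and allele totals, per locus."""

    groups: list[str]
    loci: list[str]
    alt_counts: np.ndarray  # (n_groups, n_loci)
    allele_totals: np.ndarray  # (n_groups, n_loci); 0 marks no data

    def frequencies(self) -> np.ndarray:
        """Frequencies, NaN (explicit no-data marker) where no calls exist."""
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.alt_counts / np.maximum(self.allele_totals, 1)
        return np.where(self.allele_totals > 0, f, NO_DATA)

    def group_row(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        g = self.groups.index(group)
        return self.alt_counts[g], self.allele_totals[g]


def _resolve_grouping(
    ds: GenotypeDataset, grouping: str | Mapping[str, str] | Sequence[str]
) -> list[str]:
    """Return one group label per individual."""
    if isinstance(grouping, str):
        if grouping == "locality":
            return list(ds.localities)
        if grouping == "panel":
            if ds.panels is None:
                raise ValueError("dataset has no panel labels")
            return list(ds.panels)
        raise ValueError(f"unknown grouping {grouping!r}")
    if isinstance(grouping, Mapping):
        missing = [i for i in ds.individuals if i not in grouping]
        if missing:
            raise ValueError(f"grouping does not cover individuals: {missing[:5]}")
        return [str(grouping[i]) for i in ds.individuals]
    labels = list(map(str, grouping))
    if len(labels) != ds.n_individuals:
        raise ValueError("grouping sequence must cover all individuals")
    return labels


def allele_frequencies(
    ds: GenotypeDataset, grouping: str | Mapping[str, str] | Sequence[str] = "locality"
) -> GroupFrequencies:
    """Per-group alternate-allele frequency table.

    Frequency = (sum of alternate-allele copies) / (2 x non-missing
    individuals); a group with zero calls at a locus gets allele total 0 and
    reports NaN, never a silent 0 frequency.
    """
    labels = _resolve_grouping(ds, grouping)
    groups = sorted(set(labels))
    counts = {g: 0 for g in groups}
    for g in labels:
        counts[g] += 1
    empty = [g for g, c in counts.items() if c == 0]
    if empty:
        raise ValueError(f"empty groups: {empty}")
    idx = np.array([groups.index(g) for g in labels])
    called = ds.genotypes != MISSING
    alt = np.where(called, ds.genotypes, 0).astype(np.int64)
    n_groups = len(groups)
    alt_counts = np.zeros((n_groups, ds.n_loci), dtype=np.int64)
    totals = np.zeros_like(alt_counts)
    for g in range(n_groups):
        rows = idx == g
        alt_counts[g] = alt[rows].sum(axis=0)
        totals[g] = 2 * called[rows].sum(axis=0)
    return GroupFrequencies(groups, list(ds.loci), alt_counts, totals)


def default_rad_of(locus_id: str) -> str:
    """Map a SNP id to its RAD locus: strip a trailing ``_<digits>`` suffix."""
    stem, sep, tail = locus_id.rpartition("_")
    if sep and tail.isdigit():
        return stem
    return locus_id


def apply_presence_filters(
    ds: GenotypeDataset,
    spec: LocusFilterSpec,
    grouping: str | Mapping[str, str] | Sequence[str] = "locality",
    rad_of: Callable[[str], str] = default_rad_of,
) -> GenotypeDataset:
    """Drop loci failing the presence/call-rate filter; optionally thin to
    one SNP per RAD locus (chosen uniformly at random under ``spec.seed``).
    """
    labels = _resolve_grouping(ds, grouping)
    groups = sorted(set(labels))
    if spec.min_groups_present > len(groups):
        raise ValueError(
            f"min_groups_present={spec.min_groups_present} exceeds "
            f"{len(groups)} groups"
        )
    idx = np.array([groups.index(g) for g in labels])
    called = ds.genotypes != MISSING
    group_sizes = np.bincount(idx, minlength=len(groups))
    calls_per_group = np.stack(
        [called[idx == g].sum(axis=0) for g in range(len(groups))]
    )  # (n_groups, n_loci)
    rate = calls_per_group / group_sizes[:, None]
    # a group counts toward p only when its call rate reaches r
    adequate = (rate >= spec.min_call_rate) & (calls_per_group > 0)
    keep = adequate.sum(axis=0) >= spec.min_groups_present

    loci_kept = [l for l, k in zip(ds.loci, keep) if k]
    if spec.one_snp_per_locus:
        rng = np.random.default_rng(spec.seed)
        by_rad: dict[str, list[str]] = {}
        for l in loci_kept:
            by_rad.setdefault(rad_of(l), []).append(l)
        chosen = {snps[rng.integers(len(snps))] for snps in by_rad.values()}
        loci_kept = [l for l in loci_kept if l in chosen]
    return ds.subset_loci(loci_kept)


def select_diagnostic_loci(
    freqs: GroupFrequencies,
    group_a: str = PANEL_REF_A,
    group_b: str = PANEL_REF_B,
    min_difference: float = 1.0,
) -> list[str]:
    """Loci whose between-group allele-frequency difference is >= the
    threshold, compared exactly on the underlying integer counts.

    Loci lacking data in either group are excluded (not treated as fixed).
    """
    if not (0 < min_difference <= 1):
        raise ValueError("min_difference must be in (0, 1]")
    ka, na = freqs.group_row(group_a)
    kb, nb = freqs.group_row(group_b)
    thr = Fraction(min_difference).limit_denominator(10**9)
    out: list[str] = []
    for j, locus in enumerate(freqs.loci):
        if na[j] == 0 or nb[j] == 0:
            continue
        diff = abs(Fraction(int(ka[j]), int(na[j])) - Fraction(int(kb[j]), int(nb[j])))
        if diff >= thr:
            out.append(locus)
    return out


def frequency_profile(
    ds: GenotypeDataset,
    localities_km: Mapping[str, float],
    loci: Sequence[str] | None = None,
) -> FrequencyProfile:
    """Build an hzar-style frequency profile from transect genotypes.

    ``localities_km`` maps each locality id to its transect distance; rows
    are ordered by increasing distance.
    """
    if loci is not None:
        ds = ds.subset_loci(loci)
    freqs = allele_frequencies(ds, "locality")
    order = sorted(range(len(freqs.groups)), key=lambda g: localities_km[freqs.groups[g]])
    ids = [freqs.groups[g] for g in order]
    return FrequencyProfile(
        loci=list(freqs.loci),
        distances_km=np.array([localities_km[i] for i in ids]),
        counts=freqs.alt_counts[order].T.copy(),
        totals=freqs.allele_totals[order].T.copy(),
        locality_ids=ids,
    )


def write_whitelist(loci: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l}\n")


def read_whitelist(path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]
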