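"""Readers, writers and container types for genotype, locality, frequency
and call tables.

All on-disk formats are plain text: CSV with header rows for tabular data,
and a two-row-per-individual STRUCTURE-like text format for genotypes.
Genotypes are stored internally as counts of a designated alternate allele
(0/1/2) with ``-1`` marking missing calls; allele polarity is fixed at read
time.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1
EARTH_RADIUS_KM = 6371.0

#: canonical panel labels
PANEL_REF_A = "refA"
PANEL_REF_B = "refB"
PANEL_TRANSECT = "transect"

#: canonical call-group labels (species x geographic context)
GROUP_ALLO_A = "allopatric-A"
GROUP_ALLO_B = "allopatric-B"
GROUP_PARA_A = "parapatric-A"
GROUP_PARA_B = "parapatric-B"
CALL_GROUPS = (GROUP_ALLO_A, GROUP_ALLO_B, GROUP_PARA_A, GROUP_PARA_B)

CALL_TRAITS = ("df_hz", "nd_s", "rt_s", "pr_per_s")


class GenotypeFormatError(ValueError):
    """Raised when a genotype file cannot be parsed safely."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeDataset:
    """Individuals x loci matrix of alternate-allele counts.

    Parameters
    ----------
    individuals : sequence of str
        One id per row of ``genotypes``.
    localities : sequence of str
        Locality id of each individual (parallel to ``individuals``).
    loci : sequence of str
        One id per column of ``genotypes``.
    genotypes : ndarray of int
        Shape ``(n_individuals, n_loci)``; entries in {0, 1, 2, -1} where
        -1 is missing.
    panels : sequence of str, optional
        Panel membership per individual ('refA', 'refB' or 'transect').
    """

    individuals: list[str]
    localities: list[str]
    loci: list[str]
    genotypes: np.ndarray
    panels: list[str] | None = None

    def __post_init__(self) -> None:
        self.individuals = list(map(str, self.individuals))
        self.localities = list(map(str, self.localities))
        self.loci = list(map(str, self.loci))
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        if self.genotypes.ndim != 2:
            raise ValueError("genotype matrix must be 2-D")
        n, m = self.genotypes.shape
        if n != len(self.individuals):
            raise ValueError(
                f"{len(self.individuals)} individuals but {n} genotype rows"
            )
        if len(self.localities) != len(self.individuals):
            raise ValueError("localities must be parallel to individuals")
        if m != len(self.loci):
            raise ValueError(f"{len(self.loci)} loci but {m} genotype columns")
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError(
                f"{bad.sum()} genotype entries outside {{-1, 0, 1, 2}}"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual ids")
        if self.panels is not None:
            self.panels = list(map(str, self.panels))
            if len(self.panels) != len(self.individuals):
                raise ValueError("panels must be parallel to individuals")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def subset_loci(self, locus_ids: Sequence[str]) -> "GenotypeDataset":
        """Return a dataset restricted to ``locus_ids`` (order preserved)."""
        index = {l: j for j, l in enumerate(self.loci)}
        try:
            cols = [index[l] for l in locus_ids]
        except KeyError as e:
            raise KeyError(f"unknown locus id {e.args[0]!r}") from None
        return replace(
            self,
            loci=[self.loci[j] for j in cols],
            genotypes=self.genotypes[:, cols].copy(),
        )

    def subset_individuals(self, mask: np.ndarray) -> "GenotypeDataset":
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            individuals=[i for i, m in zip(self.individuals, mask) if m],
            localities=[l for l, m in zip(self.localities, mask) if m],
            genotypes=self.genotypes[mask].copy(),
            panels=None
            if self.panels is None
            else [p for p, m in zip(self.panels, mask) if m],
        )


@dataclass
class LocalityTable:
    """Locality ids with WGS84 coordinates and optional transect distances."""

    ids: list[str]
    latitude: np.ndarray
    longitude: np.ndarray
    transect_distance_km: np.ndarray | None = None
    number: list[int] | None = None

    def __post_init__(self) -> None:
        self.ids = list(map(str, self.ids))
        self.latitude = np.asarray(self.latitude, dtype=float)
        self.longitude = np.asarray(self.longitude, dtype=float)
        n = len(self.ids)
        if self.latitude.shape != (n,) or self.longitude.shape != (n,):
            raise ValueError("coordinate arrays must match id list length")
        if np.any(np.abs(self.latitude) > 90):
            raise ValueError("latitude outside [-90, 90]")
        if np.any(np.abs(self.longitude) > 180):
            raise ValueError("longitude outside [-180, 180]")
        if self.transect_distance_km is not None:
            self.transect_distance_km = np.asarray(
                self.transect_distance_km, dtype=float
            )
            if self.transect_distance_km.shape != (n,):
                raise ValueError("distance array must match id list length")
            finite = np.isfinite(self.transect_distance_km)
            if np.any(self.transect_distance_km[finite] < 0):
                raise ValueError("negative transect distance")
        if self.number is not None and len(self.number) != n:
            raise ValueError("number column must match id list length")

    def distance_of(self, locality_id: str) -> float:
        i = self.ids.index(locality_id)
        if self.transect_distance_km is None:
            raise ValueError("transect distances not set")
        return float(self.transect_distance_km[i])


@dataclass
class CallTable:
    """Per-individual advertisement-call parameters.

    Traits: dominant frequency DF (Hz), note duration ND (s), rising time
    RT (s) and pulse rate PR (1/s), plus recording temperature and an
    optional snout-vent length.
    """

    individuals: list[str]
    localities: list[str]
    groups: list[str]
    temperature_c: np.ndarray
    df_hz: np.ndarray
    nd_s: np.ndarray
    rt_s: np.ndarray
    pr_per_s: np.ndarray
    svl_mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.individuals = list(map(str, self.individuals))
        self.localities = list(map(str, self.localities))
        self.groups = list(map(str, self.groups))
        n = len(self.individuals)
        for name in ("temperature_c", "df_hz", "nd_s", "rt_s", "pr_per_s"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            setattr(self, name, arr)
        if self.svl_mm is not None:
            self.svl_mm = np.asarray(self.svl_mm, dtype=float)
            if self.svl_mm.shape != (n,):
                raise ValueError("svl_mm must match individual count")
        unknown = set(self.groups) - set(CALL_GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        if np.any(self.df_hz <= 0) or np.any(self.nd_s <= 0):
            raise ValueError("DF and ND must be positive")
        if np.any(self.pr_per_s <= 0):
            raise ValueError("PR must be positive")
        if np.any(self.rt_s < 0):
            raise ValueError("RT must be non-negative")
        if np.any(self.rt_s > self.nd_s + 1e-12):
            raise ValueError("RT cannot exceed ND")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def traits(self) -> np.ndarray:
        """Return the (n, 4) trait matrix in DF, ND, RT, PR order."""
        return np.column_stack([self.df_hz, self.nd_s, self.rt_s, self.pr_per_s])

    def group_sizes(self) -> dict[str, int]:
        out = {g: 0 for g in CALL_GROUPS}
        for g in self.groups:
            out[g] += 1
        return out


@dataclass
class FrequencyProfile:
    """Per-locality derived-allele counts along a transect, per locus.

    ``counts[l, j]`` derived-allele copies observed at locus ``l`` in
    locality ``j``; ``totals[l, j]`` alleles sampled there (0 = no data).
    """

    loci: list[str]
    distances_km: np.ndarray
    counts: np.ndarray
    totals: np.ndarray
    locality_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.loci = list(map(str, self.loci))
        self.distances_km = np.asarray(self.distances_km, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.totals = np.asarray(self.totals, dtype=np.int64)
        shape = (len(self.loci), len(self.distances_km))
        if self.counts.shape != shape or self.totals.shape != shape:
            raise ValueError("counts/totals must be (n_loci, n_localities)")
        if np.any(self.distances_km < 0):
            raise ValueError("negative transect distance")
        if np.any(self.totals < 0) or np.any(self.counts < 0):
            raise ValueError("negative allele counts")
        if np.any(self.counts > self.totals):
            raise ValueError("derived count exceeds total count")
        if self.locality_ids is not None and len(self.locality_ids) != len(
            self.distances_km
        ):
            raise ValueError("locality ids must match distances")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def frequencies(self) -> np.ndarray:
        """Frequencies with NaN where no alleles were sampled."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.totals > 0, self.counts / np.maximum(self.totals, 1), np.nan
            )

    def row(self, locus_id: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(distances, counts, totals) restricted to localities with data."""
        l = self.loci.index(locus_id)
        has = self.totals[l] > 0
        return self.distances_km[has], self.counts[l, has], self.totals[l, has]


# ---------------------------------------------------------------------------
# genotype I/O


def _csv_to_dataset(path: Path) -> GenotypeDataset:
    df = pd.read_csv(path, dtype={"individual_id": str, "locality_id": str})
    required = {"individual_id", "locality_id"}
    if not required.issubset(df.columns):
        raise GenotypeFormatError(
            f"genotype CSV must contain columns {sorted(required)}"
        )
    if df["individual_id"].duplicated().any():
        dupes = df["individual_id"][df["individual_id"].duplicated()].tolist()
        raise GenotypeFormatError(f"individuals listed twice: {dupes}")
    meta = ["individual_id", "locality_id"]
    panels = None
    if "panel" in df.columns:
        panels = df["panel"].astype(str).tolist()
        meta.append("panel")
    loci = [c for c in df.columns if c not in meta]
    if not loci:
        raise GenotypeFormatError("no locus columns found")
    geno = df[loci].to_numpy(dtype=float)
    geno = np.where(np.isnan(geno), MISSING, geno)
    if not np.all(np.isin(geno, (MISSING, 0, 1, 2))):
        raise GenotypeFormatError("genotype entries outside {0, 1, 2, missing}")
    return GenotypeDataset(
        individuals=df["individual_id"].tolist(),
        localities=df["locality_id"].tolist(),
        loci=loci,
        genotypes=geno.astype(np.int16),
        panels=panels,
    )


def _structure_to_dataset(path: Path) -> GenotypeDataset:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise GenotypeFormatError(f"empty genotype file: {path}")
    loci = lines[0].split()
    rows = [ln.split() for ln in lines[1:]]
    if len(rows) % 2 != 0:
        raise GenotypeFormatError("odd number of allele rows (need 2 per individual)")
    individuals: list[str] = []
    localities: list[str] = []
    allele_rows: list[np.ndarray] = []
    for r in rows:
        if len(r) != 2 + len(loci):
            raise GenotypeFormatError(
                f"row for {r[0]!r} has {len(r) - 2} allele columns, expected {len(loci)}"
            )
        individuals.append(r[0])
        localities.append(r[1])
        try:
            allele_rows.append(np.array([int(a) for a in r[2:]], dtype=np.int32))
        except ValueError:
            raise GenotypeFormatError(f"non-integer allele code in row {r[0]!r}")
    a1 = np.stack(allele_rows[0::2])
    a2 = np.stack(allele_rows[1::2])
    ids = individuals[0::2]
    if individuals[1::2] != ids or localities[1::2] != localities[0::2]:
        raise GenotypeFormatError("paired rows disagree on individual or locality")
    alleles = np.stack([a1, a2], axis=0)  # (2, n, m)
    valid = alleles > 0  # STRUCTURE missing codes are <= 0 (-9 or 0)
    geno = np.full(a1.shape, MISSING, dtype=np.int16)
    dropped = 0
    for j in range(len(loci)):
        col = alleles[:, :, j]
        obs = np.unique(col[valid[:, :, j]])
        if obs.size > 2:
            dropped += 1
            continue
        if obs.size == 0:
            continue
        alt = obs.max()  # polarity: highest allele code is the alternate
        both = valid[0, :, j] & valid[1, :, j]
        geno[both, j] = (col[0, both] == alt).astype(np.int16) + (
            col[1, both] == alt
        )
    if dropped:
        logger.warning("dropped %d multi-allelic loci while parsing %s", dropped, path)
        keep = [
            j
            for j in range(len(loci))
            if np.unique(alleles[:, :, j][valid[:, :, j]]).size <= 2
        ]
        return GenotypeDataset(
            ids, localities[0::2], [loci[j] for j in keep], geno[:, keep]
        )
    return GenotypeDataset(ids, localities[0::2], loci, geno)


def _vcf_to_dataset(path: Path) -> GenotypeDataset:
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    loci: list[str] = []
    rows: list[np.ndarray] = []
    dropped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            dropped += 1
            continue
        gts = np.asarray(var.gt_types)  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        geno = np.select(
            [gts == 0, gts == 1, gts == 3], [0, 1, 2], default=MISSING
        ).astype(np.int16)
        rows.append(geno)
        loci.append(var.ID or f"{var.CHROM}:{var.POS}")
    if dropped:
        logger.warning("dropped %d multi-allelic VCF records from %s", dropped, path)
    if not rows:
        raise GenotypeFormatError(f"no usable biallelic records in {path}")
    return GenotypeDataset(
        individuals,
        ["unknown"] * len(individuals),
        loci,
        np.stack(rows, axis=1),
    )


def read_genotype_matrix(path, format: str = "csv") -> GenotypeDataset:
    """Read a genotype matrix from ``path``.

    ``format`` is one of ``csv`` (wide CSV, one row per individual),
    ``structure_like`` (two allele rows per individual) or ``vcf_minimal``
    (GT field only, biallelic records; requires cyvcf2).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise GenotypeFormatError(f"empty genotype file: {path}")
    if format == "csv":
        return _csv_to_dataset(path)
    if format == "structure_like":
        return _structure_to_dataset(path)
    if format == "vcf_minimal":
        return _vcf_to_dataset(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotype_csv(ds: GenotypeDataset, path) -> None:
    cols: dict[str, object] = {
        "individual_id": ds.individuals,
        "locality_id": ds.localities,
    }
    if ds.panels is not None:
        cols["panel"] = ds.panels
    geno = ds.genotypes.astype(object)
    geno[ds.genotypes == MISSING] = ""
    df = pd.concat(
        [pd.DataFrame(cols), pd.DataFrame(geno, columns=ds.loci)], axis=1
    )
    df.to_csv(path, index=False)


def write_structure(ds: GenotypeDataset, path) -> None:
    """Write a two-row-per-individual STRUCTURE-like file.

    Reference allele coded 1, alternate 2, missing -9.  Heterozygotes get
    one copy of each code.
    """
    with open(path, "w") as fh:
        fh.write(" ".join(ds.loci) + "\n")
        for i, ind in enumerate(ds.individuals):
            g = ds.genotypes[i]
            row1 = np.where(g == MISSING, -9, np.where(g >= 1, 2, 1))
            row2 = np.where(g == MISSING, -9, np.where(g == 2, 2, 1))
            loc = ds.localities[i]
            fh.write(f"{ind} {loc} " + " ".join(map(str, row1)) + "\n")
            fh.write(f"{ind} {loc} " + " ".join(map(str, row2)) + "\n")


# ---------------------------------------------------------------------------
# locality I/O and transect distances


def read_locality_csv(path) -> LocalityTable:
    df = pd.read_csv(path, dtype={"locality_id": str})
    for col in ("locality_id", "latitude", "longitude"):
        if col not in df.columns:
            raise ValueError(f"locality CSV missing column {col!r}")
    dist = None
    if "transect_distance_km" in df.columns:
        dist = df["transect_distance_km"].to_numpy(dtype=float)
    number = df["number"].tolist() if "number" in df.columns else None
    return LocalityTable(
        ids=df["locality_id"].tolist(),
        latitude=df["latitude"].to_numpy(dtype=float),
        longitude=df["longitude"].to_numpy(dtype=float),
        transect_distance_km=dist,
        number=number,
    )


def write_locality_csv(table: LocalityTable, path) -> None:
    df = pd.DataFrame(
        {
            "locality_id": table.ids,
            "latitude": table.latitude,
            "longitude": table.longitude,
        }
    )
    if table.transect_distance_km is not None:
        df["transect_distance_km"] = table.transect_distance_km
    if table.number is not None:
        df["number"] = table.number
    df.to_csv(path, index=False)


def haversine_km(
    lat1: float, lon1: float, lat2: float, lon2: float, radius: float = EARTH_RADIUS_KM
) -> float:
    """Great-circle distance in km on a sphere of the given radius."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return float(2 * radius * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0))))


def transect_distance(localities: LocalityTable, origin: str) -> LocalityTable:
    """Fill missing transect distances with haversine distance from ``origin``.

    Distances already present in the table are kept untouched.
    """
    if origin not in localities.ids:
        raise KeyError(f"unknown origin locality {origin!r}")
    i0 = localities.ids.index(origin)
    lat0, lon0 = localities.latitude[i0], localities.longitude[i0]
    computed = np.array(
        [
            haversine_km(lat0, lon0, lat, lon)
            for lat, lon in zip(localities.latitude, localities.longitude)
        ]
    )
    if localities.transect_distance_km is None:
        dist = computed
    else:
        dist = localities.transect_distance_km.copy()
        fill = ~np.isfinite(dist)
        dist[fill] = computed[fill]
    return replace(localities, transect_distance_km=dist)


# ---------------------------------------------------------------------------
# call-table I/O


def read_call_csv(path) -> CallTable:
    df = pd.read_csv(path, dtype={"individual_id": str, "locality_id": str})
    required = ["individual_id", "locality_id", "group", "temperature_c", *CALL_TRAITS]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"call CSV missing column {col!r}")
    svl = df["svl_mm"].to_numpy(dtype=float) if "svl_mm" in df.columns else None
    return CallTable(
        individuals=df["individual_id"].tolist(),
        localities=df["locality_id"].tolist(),
        groups=df["group"].astype(str).tolist(),
        temperature_c=df["temperature_c"].to_numpy(dtype=float),
        df_hz=df["df_hz"].to_numpy(dtype=float),
        nd_s=df["nd_s"].to_numpy(dtype=float),
        rt_s=df["rt_s"].to_numpy(dtype=float),
        pr_per_s=df["pr_per_s"].to_numpy(dtype=float),
        svl_mm=svl,
    )


def write_call_csv(calls: CallTable, path) -> None:
    df = pd.DataFrame(
        {
            "individual_id": calls.individuals,
            "locality_id": calls.localities,
            "group": calls.groups,
            "temperature_c": calls.temperature_c,
            "df_hz": calls.df_hz,
            "nd_s": calls.nd_s,
            "rt_s": calls.rt_s,
            "pr_per_s": calls.pr_per_s,
        }
    )
    if calls.svl_mm is not None:
        df["svl_mm"] = calls.svl_mm
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# frequency-profile I/O (hzar-style: one row per locality)


def read_frequency_csv(path) -> FrequencyProfile:
    df = pd.read_csv(path, dtype={"locality_id": str})
    if "transect_distance_km" not in df.columns:
        raise ValueError("frequency CSV missing column 'transect_distance_km'")
    freq_cols = [c for c in df.columns if c.endswith(".freq")]
    loci = [c[: -len(".freq")] for c in freq_cols]
    if not loci:
        raise ValueError("no '<locus>.freq' columns found")
    n_loc = len(df)
    counts = np.zeros((len(loci), n_loc), dtype=np.int64)
    totals = np.zeros_like(counts)
    for l, locus in enumerate(loci):
        ncol = f"{locus}.n"
        if ncol not in df.columns:
            raise ValueError(f"frequency CSV missing column {ncol!r}")
        n = df[ncol].to_numpy(dtype=float)
        f = df[f"{locus}.freq"].to_numpy(dtype=float)
        n = np.where(np.isnan(n), 0, n).astype(np.int64)
        k = np.where(n > 0, np.rint(np.nan_to_num(f) * n), 0).astype(np.int64)
        counts[l], totals[l] = k, n
    ids = df["locality_id"].tolist() if "locality_id" in df.columns else None
    return FrequencyProfile(
        loci=loci,
        distances_km=df["transect_distance_km"].to_numpy(dtype=float),
        counts=counts,
        totals=totals,
        locality_ids=ids,
    )


def write_frequency_csv(profile: FrequencyProfile, path) -> None:
    cols: dict[str, object] = {}
    if profile.locality_ids is not None:
        cols["locality_id"] = profile.locality_ids
    cols["transect_distance_km"] = profile.distances_km
    freqs = profile.frequencies()
    for l, locus in enumerate(profile.loci):
        cols[f"{locus}.freq"] = freqs[l]
        cols[f"{locus}.n"] = profile.totals[l]
    pd.DataFrame(cols).to_csv(path, index=False)
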