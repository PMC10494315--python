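"""Readers, writers, and on-disk schemas for the pipeline's data objects.

All tabular formats are plain CSV (comma-separated, UTF-8, ``NA`` as the
missing token).  Genotypes travel either as a VCF subset (CHROM, POS, ID,
REF, ALT, GT) or as a "012" dosage CSV; environmental layers as long-format
grid tables (one row per cell); occurrences as (lon, lat, cluster) records.

Internal indexing is 0-based throughout; only VCF POS stays 1-based.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger("geniche")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    log.addHandler(_h)

#: Sentinel for a missing dosage in the in-memory matrix.
MISSING = np.nan

_CLUSTER_LABELS = {"north", "south", "unassigned"}


class SchemaError(ValueError):
    """A file is missing mandatory columns or violates the declared schema."""


class FormatError(ValueError):
    """A file could not be parsed as the requested format."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci ALT-allele dosage matrix with site metadata.

    ``dosage`` holds values in {0, 1, 2} with ``nan`` for missing calls.
    Every individual carries a site label, and every site has WGS84
    coordinates in ``site_coords`` (columns ``site``, ``lon``, ``lat``).
    """

    dosage: np.ndarray
    individual_ids: list[str]
    locus_ids: list[str]
    site_labels: np.ndarray
    site_coords: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.site_labels = np.asarray(self.site_labels, dtype=object)
        n, m = self.dosage.shape
        if len(self.individual_ids) != n or len(self.locus_ids) != m:
            raise ValueError("id lengths do not match dosage shape")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.locus_ids)) != m:
            raise ValueError("duplicate locus ids")
        if len(self.site_labels) != n:
            raise ValueError("one site label per individual required")
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosage values must be 0, 1, 2 or missing")
        if len(self.site_coords):
            known = set(self.site_coords["site"])
            unknown = set(self.site_labels) - known
            if unknown:
                raise ValueError(f"individuals reference unknown sites: {sorted(unknown)}")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    @property
    def sites(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.site_labels:
            seen.setdefault(s)
        return list(seen)

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to loci selected by a boolean/index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self,
            dosage=self.dosage[:, keep].copy(),
            locus_ids=[self.locus_ids[i] for i in keep],
        )

    def allele_freq_by_site(self) -> pd.DataFrame:
        """Per-site ALT allele frequencies (sites x loci), missing-aware."""
        rows = {}
        for site in self.sites:
            sub = self.dosage[self.site_labels == site]
            with np.errstate(invalid="ignore"):
                rows[site] = np.nanmean(sub, axis=0) / 2.0
        return pd.DataFrame.from_dict(rows, orient="index", columns=self.locus_ids)

    def imputed(self) -> np.ndarray:
        """Dosage with missing calls replaced by the per-locus mean."""
        out = self.dosage.copy()
        means = np.nanmean(out, axis=0)
        means = np.where(np.isnan(means), 0.0, means)
        idx = np.where(np.isnan(out))
        out[idx] = means[idx[1]]
        return out


@dataclass
class EnvTable:
    """Environmental predictor table for sites or grid cells, one scenario."""

    data: pd.DataFrame
    predictors: list[str]
    scenario: str = "present"

    def __post_init__(self) -> None:
        missing = [c for c in ("lon", "lat", *self.predictors) if c not in self.data.columns]
        if missing:
            raise SchemaError(f"env table missing columns: {missing}")

    def values(self) -> np.ndarray:
        return self.data[self.predictors].to_numpy(dtype=float)


@dataclass
class OccurrenceSet:
    """Species occurrence records with an optional genetic-cluster label."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("lon", "lat", "cluster") if c not in self.records.columns]
        if missing:
            raise SchemaError(f"occurrence table missing columns: {missing}")
        if len(self.records):
            lon = self.records["lon"].to_numpy(dtype=float)
            lat = self.records["lat"].to_numpy(dtype=float)
            if not (np.isfinite(lon).all() and np.isfinite(lat).all()):
                raise ValueError("occurrence coordinates must be finite")
            if (np.abs(lon) > 180).any() or (np.abs(lat) > 90).any():
                raise ValueError("occurrence coordinates out of WGS84 bounds")
            bad = set(self.records["cluster"]) - _CLUSTER_LABELS
            if bad:
                raise ValueError(f"unknown cluster labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# genotype readers


def read_genotypes(
    path: str,
    format: str = "csv012",
    site_coords: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Load a genotype matrix from a VCF subset or a 012 dosage CSV.

    The 012 CSV layout is one row per individual with columns
    ``individual``, ``site`` and one column per locus; missing dosages are
    the token ``NA``.  VCF records that are not biallelic SNP-like (more
    than one ALT allele) are dropped with a logged count; dosage is the
    count of ALT alleles in the GT field and ``./.`` maps to missing.
    """
    if format == "csv012":
        return _read_csv012(path, site_coords)
    if format == "vcf":
        return _read_vcf(path, site_coords)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_csv012(path: str, site_coords: pd.DataFrame | None) -> GenotypeMatrix:
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False)
    for col in ("individual", "site"):
        if col not in df.columns:
            raise SchemaError(f"012 CSV missing column: {col}")
    loci = [c for c in df.columns if c not in ("individual", "site")]
    gm = GenotypeMatrix(
        dosage=df[loci].to_numpy(dtype=float),
        individual_ids=df["individual"].astype(str).tolist(),
        locus_ids=loci,
        site_labels=df["site"].to_numpy(dtype=object),
        site_coords=site_coords if site_coords is not None else pd.DataFrame(),
    )
    log.info("read %d individuals x %d loci from %s", gm.n_individuals, gm.n_loci, path)
    return gm


def _read_vcf(path: str, site_coords: pd.DataFrame | None) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("cyvcf2 is required for VCF input") from exc

    try:
        vcf = VCF(path)
    except Exception as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    locus_ids: list[str] = []
    n_dropped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_dropped += 1
            continue
        gts = rec.genotype.array()  # (n_samples, ploidy+1)
        alleles = gts[:, :2].astype(float)
        alleles[alleles < 0] = np.nan
        dos = alleles.sum(axis=1)
        rows.append(dos)
        locus_ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
    vcf.close()
    if n_dropped:
        log.info("dropped %d non-biallelic VCF records", n_dropped)
    dosage = np.column_stack(rows) if rows else np.empty((len(samples), 0))
    labels, coords = _sites_for(samples, site_coords)
    gm = GenotypeMatrix(dosage, samples, locus_ids, labels, coords)
    gm.n_dropped_records = n_dropped  # type: ignore[attr-defined]
    return gm


def _sites_for(samples: list[str], site_coords: pd.DataFrame | None):
    if site_coords is None or "individual" not in getattr(site_coords, "columns", []):
        return np.array(["site0"] * len(samples), dtype=object), pd.DataFrame(
            {"site": ["site0"], "lon": [0.0], "lat": [0.0]}
        )
    mapping = dict(zip(site_coords["individual"], site_coords["site"]))
    unknown = [s for s in samples if s not in mapping]
    if unknown:
        raise ValueError(f"no site mapping for individuals: {unknown[:5]}")
    labels = np.array([mapping[s] for s in samples], dtype=object)
    coords = site_coords.drop_duplicates("site")[["site", "lon", "lat"]].reset_index(drop=True)
    return labels, coords


def write_genotypes_csv(gm: GenotypeMatrix, path: str) -> None:
    df = pd.DataFrame(gm.dosage, columns=gm.locus_ids)
    df.insert(0, "site", gm.site_labels)
    df.insert(0, "individual", gm.individual_ids)
    df.to_csv(path, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# env / grid / occurrence tables


def read_env_table(path: str, scenario: str = "present") -> EnvTable:
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False)
    missing = [c for c in ("lon", "lat") if c not in df.columns]
    if missing:
        raise SchemaError(f"env table {path} missing columns: {missing}")
    id_cols = [c for c in ("cell_id", "site", "coast") if c in df.columns]
    predictors = [c for c in df.columns if c not in ("lon", "lat", *id_cols)]
    if df[predictors].isna().any().any():
        raise SchemaError(f"env table {path} contains NA predictor values")
    log.info("read env table %s: %d rows, %d predictors", path, len(df), len(predictors))
    return EnvTable(df, predictors, scenario)


def write_grid(table: EnvTable | pd.DataFrame, path: str) -> None:
    df = table.data if isinstance(table, EnvTable) else table
    df.to_csv(path, index=False, na_rep="NA", float_format="%.17g")


def read_occurrences(path: str) -> OccurrenceSet:
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False)
    missing = [c for c in ("lon", "lat") if c not in df.columns]
    if missing:
        raise SchemaError(f"occurrence table {path} missing columns: {missing}")
    if "cluster" not in df.columns:
        df["cluster"] = "unassigned"
    return OccurrenceSet(df)


def write_occurrences(occ: OccurrenceSet, path: str) -> None:
    occ.records.to_csv(path, index=False, na_rep="NA", float_format="%.17g")
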