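"""Reading and writing the pipeline's tabular formats.

All tables are delimited text with a header row (comma by default, tab by
flag), UTF-8, with missing values written as ``NA``.  Growth tables are
long format (one measurement per row); dosage panels come either as a
delimited individuals-by-SNPs matrix or as a VCF with a per-genotype
``DS`` (dosage) FORMAT field.  Heights are stored in centimetres
throughout and every output labels its units explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .genotype_score import DosagePanel, load_snp_metadata

__all__ = [
    "read_growth_table",
    "read_individual_table",
    "read_dosage_panel",
    "write_results_table",
    "read_results_table",
    "write_growth_table",
    "RunConfig",
]

log = logging.getLogger(__name__)

GROWTH_COLUMNS = ("individual_id", "sex", "age", "measure", "value")
RESULT_COLUMNS = ("term", "beta", "se", "p", "n", "cohort")
SEXES = {"female", "male"}
MEASURES = {"bmi", "weight", "height"}
_NA = ["", "NA"]


def _sep(dialect: str) -> str:
    if dialect in {"csv", ","}:
        return ","
    if dialect in {"tsv", "tab", "\t"}:
        return "\t"
    raise ValueError(f"unknown dialect {dialect!r}")


def read_growth_table(path, dialect: str = "csv") -> pd.DataFrame:
    """Read a long-format anthropometry table.

    Required columns: individual_id, sex, age, measure, value; optional:
    source, cohort_id.  Rows with unparseable or missing age/value, a
    negative age or a non-positive value are dropped with a logged count.
    A missing required column is a configuration error.
    """
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str, na_values=_NA,
                     keep_default_na=False)
    missing = [c for c in GROWTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"growth table {path} missing required columns: "
                         f"{missing}")
    n0 = len(df)
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    df["sex"] = df["sex"].str.lower()
    df["measure"] = df["measure"].str.lower()
    ok = (df["age"].notna() & df["value"].notna() & (df["age"] >= 0)
          & (df["value"] > 0) & df["sex"].isin(SEXES)
          & df["measure"].isin(MEASURES))
    dropped = n0 - int(ok.sum())
    if dropped:
        log.info("dropped %d of %d growth rows (unparseable/invalid)",
                 dropped, n0)
    df = df[ok].reset_index(drop=True)
    if "source" not in df.columns:
        df["source"] = "clinic"
    if "cohort_id" not in df.columns:
        df["cohort_id"] = "cohort"
    return df


def write_growth_table(df: pd.DataFrame, path, dialect: str = "csv"):
    df.to_csv(path, sep=_sep(dialect), index=False, na_rep="NA")


def read_individual_table(path, dialect: str = "csv") -> pd.DataFrame:
    """Per-individual covariates: birth measures, gestational age, PCs.

    Principal-component columns are any named ``pc1``, ``pc2``, ...;
    gestational ages outside (20, 46) weeks are set to missing.
    """
    df = pd.read_csv(path, sep=_sep(dialect), na_values=_NA,
                     keep_default_na=False)
    if "individual_id" not in df.columns:
        raise ValueError(f"individual table {path} lacks 'individual_id'")
    df["individual_id"] = df["individual_id"].astype(str)
    for c in df.columns:
        if c not in {"individual_id", "sex", "cohort_id"}:
            df[c] = pd.to_numeric(df[c], errors="coerce")
    if "gestational_age" in df.columns:
        bad = df["gestational_age"].notna() & (
            (df["gestational_age"] <= 20) | (df["gestational_age"] >= 46))
        if bad.any():
            log.warning("%d implausible gestational ages set to missing",
                        int(bad.sum()))
            df.loc[bad, "gestational_age"] = np.nan
    return df


def _panel_from_matrix(ids, snp_ids, dosages, metadata) -> DosagePanel:
    known = [s for s in snp_ids if s in metadata.index]
    unknown = [s for s in snp_ids if s not in metadata.index]
    if unknown:
        log.warning("excluding %d SNPs not in the score set: %s",
                    len(unknown), unknown)
    keep = [snp_ids.index(s) for s in known]
    dosages = np.asarray(dosages, dtype=float)[:, keep]
    if np.nanmin(dosages, initial=0.0) < 0 or np.nanmax(dosages, initial=0.0) > 2:
        raise ValueError("dosage outside [0, 2] in input")
    return DosagePanel(list(ids), known, dosages, metadata=metadata)


def read_dosage_table(path, dialect: str = "csv",
                      metadata: pd.DataFrame | None = None) -> DosagePanel:
    metadata = metadata if metadata is not None else load_snp_metadata()
    df = pd.read_csv(path, sep=_sep(dialect), na_values=_NA,
                     keep_default_na=False)
    if "individual_id" not in df.columns:
        raise ValueError(f"dosage table {path} lacks 'individual_id'")
    ids = df["individual_id"].astype(str).tolist()
    snp_ids = [c for c in df.columns if c != "individual_id"]
    dosages = df[snp_ids].apply(pd.to_numeric, errors="coerce").to_numpy()
    return _panel_from_matrix(ids, snp_ids, dosages, metadata)


def read_dosage_vcf(path, metadata: pd.DataFrame | None = None) -> DosagePanel:
    """Read per-genotype DS dosages from a VCF (requires cyvcf2)."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF dosage ingestion requires cyvcf2") from exc
    metadata = metadata if metadata is not None else load_snp_metadata()
    vcf = VCF(str(path))
    ids = list(vcf.samples)
    snp_ids, rows = [], []
    for variant in vcf:
        ds = variant.format("DS")
        if ds is None:
            raise ValueError(f"site {variant.ID} has no DS field")
        snp_ids.append(variant.ID)
        rows.append(np.asarray(ds, dtype=float).reshape(-1))
    dosages = np.column_stack(rows) if rows else np.empty((len(ids), 0))
    return _panel_from_matrix(ids, snp_ids, dosages, metadata)


def read_dosage_panel(path, fmt: str = "table", dialect: str = "csv",
                      metadata: pd.DataFrame | None = None) -> DosagePanel:
    """Dispatch on ``fmt``: ``table`` (delimited matrix) or ``vcf_ds``."""
    if fmt == "table":
        return read_dosage_table(path, dialect=dialect, metadata=metadata)
    if fmt == "vcf_ds":
        return read_dosage_vcf(path, metadata=metadata)
    raise ValueError(f"unknown dosage format {fmt!r}")


def write_results_table(results, path, dialect: str = "csv"):
    """Write association results with the fixed column order
    (term, beta, se, p, n, cohort); extra columns follow those."""
    if not isinstance(results, pd.DataFrame):
        from .association import results_to_frame
        results = results_to_frame(results)
    if results.empty:
        log.warning("writing empty results table to %s", path)
        results = pd.DataFrame(columns=list(RESULT_COLUMNS))
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    cols += [c for c in results.columns if c not in cols]
    results[cols].to_csv(path, sep=_sep(dialect), index=False, na_rep="NA")


def read_results_table(path, dialect: str = "csv") -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep(dialect), na_values=_NA,
                       keep_default_na=False)


@dataclass
class RunConfig:
    """Structured run configuration (YAML on disk)."""

    seed: int = 0
    sd_threshold: float = 4.0
    out_dir: str = "results"
    spline: dict = field(default_factory=dict)        # per-measure SplineSpec kwargs
    random_terms: dict = field(default_factory=dict)  # per-measure tuple
    covariates: dict = field(default_factory=dict)    # per-cohort list
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ValueError("seed must be a non-negative integer")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)
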