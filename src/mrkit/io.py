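"""TSV readers/writers and the reproducibility manifest.

All files are UTF-8, tab-separated, dot-decimal, Unix newlines; floats
are written with 10 significant digits and scientific notation is
accepted on read.  Every writer has a paired reader that recovers equal
values (round-trip property).
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .types import SUMMARY_COLUMNS, ValidationError, validate_panel, validate_summary_stats
from .simulate import Cohort

FLOAT_FORMAT = "%.10g"


def _write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT, lineterminator="\n")


def write_dosage_matrix(dosages: pd.DataFrame, path) -> None:
    """Write a samples x SNPs dosage TSV (first column ``sample_id``)."""
    df = dosages.copy()
    df.index.name = "sample_id"
    _write_tsv(df, path, index=True)


def read_dosage_matrix(path) -> pd.DataFrame:
    """Read and validate a dosage TSV: header of SNP ids, values in [0, 2]."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"no samples: {path} is empty") from None
    if df.shape[0] == 0:
        raise ValidationError(f"no samples in dosage file {path}")
    df = df.astype(float)
    vals = df.to_numpy(float)
    bad = np.argwhere(np.isfinite(vals) & ((vals < 0) | (vals > 2)))
    if len(bad):
        i, j = bad[0]
        raise ValidationError(
            f"dosage {vals[i, j]} out of [0, 2] at row {df.index[i]}, SNP {df.columns[j]}"
        )
    return df


def write_panel(panel: pd.DataFrame, path) -> None:
    _write_tsv(validate_panel(panel), path)


def read_panel(path) -> pd.DataFrame:
    return validate_panel(pd.read_csv(path, sep="\t"))


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    df = phenotypes.copy()
    df.index.name = "sample_id"
    _write_tsv(df, path, index=True)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_cohort(cohort: Cohort, directory) -> dict[str, Path]:
    """Write a cohort as dosage + phenotype TSVs; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "dosages": directory / "dosages.tsv",
        "phenotypes": directory / "phenotypes.tsv",
    }
    write_dosage_matrix(cohort.dosages, paths["dosages"])
    write_phenotypes(cohort.phenotypes, paths["phenotypes"])
    return paths


def read_cohort(directory) -> Cohort:
    directory = Path(directory)
    return Cohort(
        dosages=read_dosage_matrix(directory / "dosages.tsv"),
        phenotypes=read_phenotypes(directory / "phenotypes.tsv"),
    )


def write_summary_stats(stats: pd.DataFrame, path) -> None:
    cols = [c for c in SUMMARY_COLUMNS if c in stats.columns] + [
        c for c in stats.columns if c not in SUMMARY_COLUMNS
    ]
    _write_tsv(stats[cols], path)


def read_summary_stats(path) -> pd.DataFrame:
    """Read a one-sided summary-statistics TSV.

    Requires columns snp, effect_allele, other_allele, beta, se (eaf,
    pval, n optional); lowercase alleles are accepted and uppercased,
    non-positive SEs and duplicate SNP ids are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    return validate_summary_stats(df)


#: Header synonyms for the common external GWAS summary format.
_GWAS_SYNONYMS = {
    "marker": "snp", "markername": "snp", "rsid": "snp",
    "allele1": "effect_allele", "a1": "effect_allele",
    "allele2": "other_allele", "a2": "other_allele",
    "effect": "beta", "b": "beta",
    "stderr": "se", "freq1": "eaf", "freq": "eaf",
    "p": "pval", "p.value": "pval",
    "samplesize": "n",
}


def read_gwas_summary(path) -> pd.DataFrame:
    """Read an external GWAS file with marker/allele1/allele2/effect/stderr/p
    style headers, mapping onto the package's summary-statistics columns."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [_GWAS_SYNONYMS.get(c.strip().lower(), c.strip().lower()) for c in df.columns]
    return validate_summary_stats(df)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(
    command: str,
    config: dict,
    seed: int | None,
    inputs: dict[str, Path] | None = None,
    outputs: dict[str, Path] | None = None,
    row_counts: dict[str, int] | None = None,
    defaults_in_effect: dict | None = None,
) -> dict:
    """Machine-readable record sufficient to re-run an analysis bit-identically."""
    from . import __version__

    manifest = {
        "package": "mrkit",
        "version": __version__,
        "python": platform.python_version(),
        "command": command,
        "seed": seed,
        "config": config,
        "inputs": {k: {"path": str(p), "sha256": file_sha256(p)} for k, p in (inputs or {}).items()},
        "outputs": {k: str(p) for k, p in (outputs or {}).items()},
        "row_counts": row_counts or {},
        "defaults_in_effect": defaults_in_effect or {},
    }
    return manifest


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
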