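"""Readers and writers for the on-disk artifacts of the epi-signature pipeline.

All tabular artifacts are plain text: beta matrices and probe manifests are
tab-delimited, sample sheets are comma-delimited, differentially methylated
regions are emitted as BED (0-based half-open), and trained classifier models
are JSON.  Every writer/reader pair round-trips field for field.

Coordinate convention: probe positions and DMR start/end are 1-based inclusive
internally (so width = end - start + 1); conversion to BED's 0-based half-open
intervals happens only in :func:`write_dmr_bed`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "BetaMatrix",
    "ISLAND_RELATIONS",
    "SAMPLE_GROUPS",
    "SAMPLE_ROLES",
    "SEX_LABELS",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_manifest",
    "write_manifest",
    "read_sample_sheet",
    "write_sample_sheet",
    "write_dmr_bed",
    "save_model",
    "load_model",
    "MODEL_FORMAT_VERSION",
]

MISSING_MARKER = "NA"

ISLAND_RELATIONS = ("island", "shore", "shelf", "open_sea")
SAMPLE_GROUPS = ("patient", "carrier", "control", "unknown")
SAMPLE_ROLES = ("discovery", "training", "testing", "external")
SEX_LABELS = ("M", "F")

MANIFEST_COLUMNS = [
    "probe_id",
    "chrom",
    "pos",
    "island_relation",
    "flag_xy",
    "flag_snp",
    "flag_crossreactive",
]
SHEET_COLUMNS = ["sample_id", "labeled_sex", "group", "age", "role"]

MODEL_FORMAT_VERSION = 1


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


def _check_unique(values: Sequence, what: str) -> None:
    seen = pd.Index(values)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()[:5]
        raise FormatError(f"duplicate {what}: {dups}")


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions in [0, 1].

    ``values`` is a DataFrame indexed by probe id with sample ids as columns;
    ``detection_p`` (optional) is a same-shaped matrix of detection p-values.
    Missing betas are NaN in memory and ``NA`` on disk.
    """

    values: pd.DataFrame
    detection_p: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe ids")
        _check_unique(self.values.columns, "sample ids")
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise FormatError("beta matrix contains non-numeric cells")
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise FormatError(
                "beta values outside [0, 1]: "
                f"range [{finite.min():.4g}, {finite.max():.4g}]"
            )
        if self.detection_p is not None:
            det = self.detection_p
            if det.shape != self.values.shape:
                raise FormatError(
                    f"detection matrix shape {det.shape} does not match "
                    f"beta matrix shape {self.values.shape}"
                )
            if not det.index.equals(self.values.index) or not det.columns.equals(
                self.values.columns
            ):
                raise FormatError("detection matrix ids do not match beta matrix ids")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def subset_probes(self, probes: Sequence[str]) -> "BetaMatrix":
        det = None if self.detection_p is None else self.detection_p.loc[probes]
        return BetaMatrix(self.values.loc[probes], det)

    def subset_samples(self, samples: Sequence[str]) -> "BetaMatrix":
        det = None if self.detection_p is None else self.detection_p[list(samples)]
        return BetaMatrix(self.values[list(samples)], det)


def _read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[MISSING_MARKER], keep_default_na=False
    )
    df.index = df.index.astype(str)
    df.index.name = None  # written as "probe_id"; in memory the index is anonymous
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise FormatError(
                f"non-numeric cell in column {col!r}: {bad.iloc[0]!r}"
                if len(bad)
                else f"non-numeric column {col!r}"
            )
    return df.astype(float)


def read_beta_matrix(path, detection_path=None) -> BetaMatrix:
    """Read a TSV beta matrix (first column probe ids, header sample ids)."""
    values = _read_matrix_tsv(path)
    detection = _read_matrix_tsv(detection_path) if detection_path is not None else None
    return BetaMatrix(values, detection)


def write_beta_matrix(beta: BetaMatrix, path, detection_path=None) -> None:
    beta.values.to_csv(path, sep="\t", na_rep=MISSING_MARKER, index_label="probe_id")
    if detection_path is not None and beta.detection_p is not None:
        beta.detection_p.to_csv(
            detection_path, sep="\t", na_rep=MISSING_MARKER, index_label="probe_id"
        )


def chrom_sort_key(chrom: str) -> tuple:
    """Order chromosomes numerically (chr1 < chr2 < ... < chr22 < chrX < chrY)."""
    m = re.fullmatch(r"(?:chr)?(\d+|X|Y|MT?)", str(chrom), flags=re.IGNORECASE)
    if m:
        token = m.group(1).upper()
        if token.isdigit():
            return (0, int(token), "")
        return (0, {"X": 23, "Y": 24, "M": 25, "MT": 25}[token], "")
    return (1, 0, str(chrom))


def sort_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    key = manifest["chrom"].map(chrom_sort_key)
    order = sorted(range(len(manifest)), key=lambda i: (key.iloc[i], manifest["pos"].iloc[i]))
    return manifest.iloc[order].reset_index(drop=True)


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise FormatError(f"manifest missing required columns: {missing}")
    manifest = manifest[MANIFEST_COLUMNS].copy()
    _check_unique(manifest["probe_id"], "probe ids")
    manifest["pos"] = manifest["pos"].astype(int)
    if (manifest["pos"] < 1).any():
        raise FormatError("manifest positions must be >= 1 (1-based)")
    bad = set(manifest["island_relation"]) - set(ISLAND_RELATIONS)
    if bad:
        raise FormatError(
            f"unknown island_relation values {sorted(bad)}; allowed: {ISLAND_RELATIONS}"
        )
    for col in ("flag_xy", "flag_snp", "flag_crossreactive"):
        manifest[col] = manifest[col].astype(bool)
    if manifest.duplicated(["chrom", "pos"]).any():
        dup = manifest[manifest.duplicated(["chrom", "pos"])].iloc[0]
        raise FormatError(f"duplicate manifest coordinate {dup['chrom']}:{dup['pos']}")
    return sort_manifest(manifest)


def read_manifest(path) -> pd.DataFrame:
    """Read a probe manifest TSV, returned sorted by (chrom, pos)."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    return validate_manifest(df)


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns and c != "age"]
    if missing:
        raise FormatError(f"sample sheet missing required columns: {missing}")
    sheet = sheet.copy()
    if "age" not in sheet.columns:
        sheet["age"] = np.nan
    sheet = sheet[SHEET_COLUMNS]
    _check_unique(sheet["sample_id"], "sample ids")
    for col, vocab in (
        ("labeled_sex", SEX_LABELS),
        ("group", SAMPLE_GROUPS),
        ("role", SAMPLE_ROLES),
    ):
        bad = set(sheet[col].astype(str)) - set(vocab)
        if bad:
            raise FormatError(
                f"unknown {col} values {sorted(bad)}; allowed values: {vocab}"
            )
    return sheet.reset_index(drop=True)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str})
    return validate_sample_sheet(df)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    cols = [c for c in SHEET_COLUMNS if c in sheet.columns]
    sheet[cols].to_csv(path, index=False)


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    """Write a DmrTable as BED (0-based half-open).

    Columns: chrom, start, end, name (overlapping gene or "."), score
    (round(1000 * |mean_diff|)), then probe_count, mean_diff, area, fwer.
    An empty table produces an empty file.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for _, row in dmrs.iterrows():
            gene = row.get("overlapping_gene", "")
            name = gene if isinstance(gene, str) and gene else "."
            score = int(round(1000 * abs(float(row["mean_diff"]))))
            fields = [
                str(row["chrom"]),
                str(int(row["start"]) - 1),
                str(int(row["end"])),
                name,
                str(score),
                str(int(row["probe_count"])),
                f"{float(row['mean_diff']):.6g}",
                f"{float(row['area']):.6g}",
                f"{float(row['fwer']):.6g}",
            ]
            fh.write("\t".join(fields) + "\n")


def save_model(model, path) -> None:
    """Serialize a trained SignatureModel to JSON."""
    payload = model.to_dict()
    payload["format_version"] = MODEL_FORMAT_VERSION
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def load_model(path):
    """Load a SignatureModel saved by :func:`save_model`."""
    from . import classifier  # local import: classifier does not import io_formats

    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"model file is not valid JSON: {exc}") from exc
    version = payload.pop("format_version", None)
    if version != MODEL_FORMAT_VERSION:
        raise FormatError(
            f"model format version {version!r} not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return classifier.SignatureModel.from_dict(payload)
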