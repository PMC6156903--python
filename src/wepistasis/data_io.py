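"""Tabular input/output and the validated core data model.

All tables are tab-delimited text with a header row unless a PLINK-style
dialect is requested. Missing values are carried as ``numpy.nan`` inside
float arrays — never as 0, because 0 is a valid genotype dosage and a valid
methylation beta value.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataValidationError",
    "TableParseError",
    "GenotypeMatrix",
    "MethylationMatrix",
    "MarkerMap",
    "PhenotypeTable",
    "read_genotype_table",
    "read_methylation_table",
    "read_marker_map",
    "read_phenotype_table",
    "write_results",
    "RESULT_COLUMNS",
]

DEFAULT_MISSING_CODES = ("", "NA", "NaN", "nan", ".")

#: columns of the ranked results file, mirroring a top-pairs table
RESULT_COLUMNS = [
    "rank",
    "snp_id",
    "cpg_id",
    "distance_bp",
    "snp_maf",
    "k",
    "W",
    "p_value",
    "lr_m1_p",
    "lr_m2_p",
]


class DataValidationError(ValueError):
    """A parsed table violates a data-model invariant."""


class TableParseError(ValueError):
    """A file could not be tokenized into a rectangular table."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DataValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs additive minor-allele dosages in {0, 1, 2}.

    ``values`` is a float matrix; missing entries are ``nan``.
    """

    subject_ids: list[str]
    snp_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise DataValidationError(
                f"genotype matrix shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs"
            )
        _check_unique(self.subject_ids, "subject")
        _check_unique(self.snp_ids, "SNP")
        finite = self.values[~np.isnan(self.values)]
        bad = ~np.isin(finite, (0.0, 1.0, 2.0))
        if bad.any():
            rows, cols = np.nonzero(~np.isnan(self.values))
            mask = ~np.isin(self.values[rows, cols], (0.0, 1.0, 2.0))
            r, c = rows[mask][0], cols[mask][0]
            raise DataValidationError(
                f"genotype value {self.values[r, c]!r} outside {{0,1,2}} at "
                f"subject {self.subject_ids[r]!r}, SNP {self.snp_ids[c]!r}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.snp_ids)


@dataclass
class MethylationMatrix:
    """Subjects x CpG sites methylation beta values in [0, 1]."""

    subject_ids: list[str]
    cpg_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.cpg_ids)):
            raise DataValidationError(
                f"methylation matrix shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.cpg_ids)} CpGs"
            )
        _check_unique(self.subject_ids, "subject")
        _check_unique(self.cpg_ids, "CpG")
        with np.errstate(invalid="ignore"):
            bad = (self.values < 0.0) | (self.values > 1.0)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise DataValidationError(
                f"beta value {self.values[r, c]!r} outside [0,1] at subject "
                f"{self.subject_ids[r]!r}, CpG {self.cpg_ids[c]!r}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.cpg_ids)


@dataclass
class MarkerMap:
    """Genomic coordinates for one marker kind (SNP or CpG).

    Positions are 1-based base pairs, following BIM convention.
    """

    kind: str  # "SNP" or "CpG"
    marker_ids: list[str]
    chromosomes: list[str]
    positions: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("SNP", "CpG"):
            raise DataValidationError(f"marker kind must be SNP or CpG, got {self.kind!r}")
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if not (len(self.marker_ids) == len(self.chromosomes) == len(self.positions)):
            raise DataValidationError("marker map columns have unequal lengths")
        _check_unique(self.marker_ids, self.kind)
        if (self.positions < 1).any():
            i = int(np.argmax(self.positions < 1))
            raise DataValidationError(
                f"position {self.positions[i]} for {self.marker_ids[i]!r} "
                "is not a 1-based coordinate"
            )
        self.chromosomes = [str(c) for c in self.chromosomes]

    def __len__(self) -> int:
        return len(self.marker_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "chromosome": self.chromosomes,
                "position": self.positions,
            }
        )


TG_COLUMNS = ["tg_visit1", "tg_visit2", "tg_visit3", "tg_visit4"]


@dataclass
class PhenotypeTable:
    """Per-subject triglyceride measurements and/or a binary response flag.

    ``tg`` holds the four clinical-visit TG levels (mg/dL; nan when absent),
    ``response`` the precomputed responder flag (nan when absent). Every
    subject must carry either all four TG visits or a response value.
    """

    subject_ids: list[str]
    tg: np.ndarray = field(default=None)  # (n, 4) float
    response: np.ndarray = field(default=None)  # (n,) float with nan

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        _check_unique(self.subject_ids, "subject")
        if self.tg is None:
            self.tg = np.full((n, 4), np.nan)
        self.tg = np.asarray(self.tg, dtype=float)
        if self.response is None:
            self.response = np.full(n, np.nan)
        self.response = np.asarray(self.response, dtype=float)
        if self.tg.shape != (n, 4) or self.response.shape != (n,):
            raise DataValidationError("phenotype table column shapes do not match subjects")
        with np.errstate(invalid="ignore"):
            if (self.tg <= 0).any():
                r, c = np.argwhere(self.tg <= 0)[0]
                raise DataValidationError(
                    f"TG value {self.tg[r, c]!r} <= 0 for subject {self.subject_ids[r]!r}"
                )
        finite_resp = self.response[~np.isnan(self.response)]
        if not np.isin(finite_resp, (0.0, 1.0)).all():
            raise DataValidationError("response values must be 0 or 1")
        has_tg = ~np.isnan(self.tg).any(axis=1)
        has_resp = ~np.isnan(self.response)
        orphan = ~(has_tg | has_resp)
        if orphan.any():
            i = int(np.argmax(orphan))
            raise DataValidationError(
                f"subject {self.subject_ids[i]!r} has neither four TG visits nor a response"
            )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.tg, index=self.subject_ids, columns=TG_COLUMNS)
        df["response"] = self.response
        return df


# ---------------------------------------------------------------------------
# file readers


def _read_rows(path, delimiter: str | None):
    """Tokenize a delimited text file, enforcing rectangularity.

    ``delimiter=None`` means any whitespace run (PLINK .raw style).
    """
    path = Path(path)
    rows: list[list[str]] = []
    with path.open(newline="") as fh:
        if delimiter is None:
            raw = [(i, line.split()) for i, line in enumerate(fh, start=1) if line.strip()]
        else:
            reader = csv.reader(fh, delimiter=delimiter)
            raw = [(i, row) for i, row in enumerate(reader, start=1) if any(f.strip() for f in row)]
    if not raw:
        raise TableParseError(f"{path}: empty file")
    width = len(raw[0][1])
    for lineno, row in raw:
        if len(row) != width:
            raise TableParseError(
                f"{path}: line {lineno} has {len(row)} fields, expected {width}"
            )
        rows.append([f.strip() for f in row])
    return rows


def _parse_numeric(value: str, missing_codes: Sequence[str]) -> float:
    if value in missing_codes:
        return np.nan
    try:
        return float(value)
    except ValueError:
        raise DataValidationError(f"non-numeric value {value!r}") from None


def read_genotype_table(
    path,
    dialect: str = "tsv",
    missing_codes: Sequence[str] = DEFAULT_MISSING_CODES,
) -> GenotypeMatrix:
    """Read a subjects x SNPs dosage table.

    ``dialect="tsv"``: tab-delimited, first column subject id, header of SNP
    ids. ``dialect="plink_raw"``: whitespace-delimited PLINK ``--recode A``
    output with FID/IID/PAT/MAT/SEX/PHENOTYPE lead columns; IID is taken as
    the subject id and ``-9`` is treated as an additional missing code.
    """
    if dialect == "tsv":
        rows = _read_rows(path, "\t")
        header, body = rows[0], rows[1:]
        snp_ids = header[1:]
        subject_ids = [r[0] for r in body]
        data_rows = [r[1:] for r in body]
    elif dialect == "plink_raw":
        rows = _read_rows(path, None)
        header, body = rows[0], rows[1:]
        lead = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        if [h.upper() for h in header[:6]] != lead:
            raise TableParseError(
                f"{path}: plink_raw header must start with {' '.join(lead)}"
            )
        snp_ids = header[6:]
        subject_ids = [r[1] for r in body]
        data_rows = [r[6:] for r in body]
        missing_codes = tuple(missing_codes) + ("-9",)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")

    if not data_rows:
        raise DataValidationError(f"{path}: no subjects")
    values = np.empty((len(data_rows), len(snp_ids)))
    for i, row in enumerate(data_rows):
        for j, cell in enumerate(row):
            try:
                values[i, j] = _parse_numeric(cell, missing_codes)
            except DataValidationError:
                raise DataValidationError(
                    f"{path}: non-numeric dosage {cell!r} at subject "
                    f"{subject_ids[i]!r}, SNP {snp_ids[j]!r}"
                ) from None
    try:
        return GenotypeMatrix(subject_ids, snp_ids, values)
    except DataValidationError as exc:
        raise DataValidationError(f"{path}: {exc}") from None


def read_methylation_table(path) -> MethylationMatrix:
    """Read a subjects x CpGs beta-value table (TSV, header of CpG ids)."""
    rows = _read_rows(path, "\t")
    header, body = rows[0], rows[1:]
    if not body:
        raise DataValidationError(f"{path}: no subjects")
    cpg_ids = header[1:]
    subject_ids = [r[0] for r in body]
    values = np.empty((len(body), len(cpg_ids)))
    for i, row in enumerate(body):
        for j, cell in enumerate(row[1:]):
            try:
                values[i, j] = _parse_numeric(cell, DEFAULT_MISSING_CODES)
            except DataValidationError:
                raise DataValidationError(
                    f"{path}: non-numeric beta {cell!r} at subject "
                    f"{subject_ids[i]!r}, CpG {cpg_ids[j]!r}"
                ) from None
    try:
        return MethylationMatrix(subject_ids, cpg_ids, values)
    except DataValidationError as exc:
        raise DataValidationError(f"{path}: {exc}") from None


def read_marker_map(path, kind: str) -> MarkerMap:
    """Read a marker map TSV with columns (id, chromosome, position)."""
    rows = _read_rows(path, "\t")
    body = rows[1:]
    ids, chroms, pos = [], [], []
    for lineno, row in enumerate(body, start=2):
        if len(row) < 3:
            raise TableParseError(f"{path}: line {lineno}: expected 3 columns")
        ids.append(row[0])
        chroms.append(row[1])
        try:
            p = int(row[2])
        except ValueError:
            raise DataValidationError(
                f"{path}: line {lineno}: position {row[2]!r} is not an integer"
            ) from None
        pos.append(p)
    try:
        return MarkerMap(kind, ids, chroms, np.array(pos, dtype=np.int64))
    except DataValidationError as exc:
        raise DataValidationError(f"{path}: {exc}") from None


def read_phenotype_table(path) -> PhenotypeTable:
    """Read the phenotype TSV: subject id plus TG visit and/or response columns."""
    rows = _read_rows(path, "\t")
    header = [h.lower() for h in rows[0]]
    body = rows[1:]
    if not body:
        raise DataValidationError(f"{path}: no subjects")
    col = {name: i for i, name in enumerate(header)}
    tg_cols = [col[c] for c in TG_COLUMNS if c in col]
    has_all_tg = len(tg_cols) == 4
    resp_col = col.get("response")
    if not has_all_tg and resp_col is None:
        raise TableParseError(
            f"{path}: need columns {TG_COLUMNS} and/or 'response' alongside the subject id"
        )
    subject_ids = [r[0] for r in body]
    n = len(body)
    tg = np.full((n, 4), np.nan)
    response = np.full(n, np.nan)
    for i, row in enumerate(body):
        if has_all_tg:
            for j, c in enumerate(tg_cols):
                tg[i, j] = _parse_numeric(row[c], DEFAULT_MISSING_CODES)
        if resp_col is not None:
            response[i] = _parse_numeric(row[resp_col], DEFAULT_MISSING_CODES)
    try:
        return PhenotypeTable(subject_ids, tg, response)
    except DataValidationError as exc:
        raise DataValidationError(f"{path}: {exc}") from None


def write_results(results, path) -> None:
    """Write ranked pair results as TSV.

    Rows are sorted by W-test p-value ascending, ties broken by
    (snp_id, cpg_id) lexicographic order; ``rank`` is 1-based after sorting.
    Accepts any iterable of objects with the PairResult fields.
    """
    recs = [
        {
            "snp_id": r.snp_id,
            "cpg_id": r.cpg_id,
            "distance_bp": r.distance_bp,
            "snp_maf": r.snp_maf,
            "k": r.k,
            "W": r.W,
            "p_value": r.p_value,
            "lr_m1_p": r.lr_m1_p,
            "lr_m2_p": r.lr_m2_p,
        }
        for r in results
    ]
    df = pd.DataFrame(recs, columns=RESULT_COLUMNS[1:])
    if len(df):
        df = df.sort_values(
            ["p_value", "snp_id", "cpg_id"], kind="mergesort", na_position="last"
        ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    df.to_csv(path, sep="\t", index=False)
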