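"""Subject-level feature tables and their delimited-text round trip.

A :class:`SubjectTable` is one row per subject: identifiers, site, diagnosis
label, covariates (age, sex), optional clinical fields (medication status,
symptom severity, age of onset, illness duration) and an ordered vector of
named real-valued brain measures (thickness in mm, area in mm^2, volume in
mm^3).  Missing feature cells are carried as NaN; ``missing_mask`` exposes
them as a boolean matrix.

Files are delimited text with a header row; comma and tab dialects are
auto-detected from the header line, and the missing token is the empty
string or ``NA``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

#: metadata columns, in canonical order
META_COLUMNS = [
    "subject_id",
    "site_id",
    "diagnosis",
    "age",
    "sex",
    "medicated",
    "ybocs",
    "age_of_onset",
    "illness_duration",
]

#: clinical columns that may be absent for controls
CLINICAL_COLUMNS = ["medicated", "ybocs", "age_of_onset", "illness_duration"]

_MISSING_TOKENS = ["", "NA"]


@dataclass
class SubjectTable:
    """One row per subject: metadata plus a named brain-feature matrix."""

    meta: pd.DataFrame
    features: pd.DataFrame
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self._validated:
            self.validate()
            self._validated = True

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        for col in ("subject_id", "site_id", "diagnosis"):
            if col not in self.meta.columns:
                raise SchemaError(f"required column missing: {col!r}")
        ids = self.meta["subject_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique().tolist())
            raise ValidationError(f"duplicate subject_id values: {dupes[:10]}")
        if self.meta["site_id"].isna().any() or self.meta["diagnosis"].isna().any():
            raise ValidationError("every row must carry site_id and diagnosis")
        dx = set(pd.unique(self.meta["diagnosis"]))
        if not dx <= {0, 1}:
            bad = self.meta.index[~self.meta["diagnosis"].isin([0, 1])].tolist()
            raise ValidationError(
                f"diagnosis must be binary (case=1/control=0); offending rows: {bad[:10]}"
            )
        if len(self.meta) != len(self.features):
            raise ValidationError("meta and features row counts differ")

    # -- accessors -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.meta)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n, n_features): True where a feature cell is missing."""
        return self.features.isna().to_numpy()

    @property
    def diagnosis(self) -> np.ndarray:
        return self.meta["diagnosis"].to_numpy(dtype=int)

    @property
    def site_id(self) -> np.ndarray:
        return self.meta["site_id"].to_numpy()

    def subset(self, index: np.ndarray) -> "SubjectTable":
        """Row subset by positional index (order preserved)."""
        return SubjectTable(
            meta=self.meta.iloc[index].reset_index(drop=True),
            features=self.features.iloc[index].reset_index(drop=True),
            _validated=True,
        )

    def copy(self) -> "SubjectTable":
        return SubjectTable(self.meta.copy(), self.features.copy(), _validated=True)


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_subject_table(path, schema: dict[str, str] | None = None) -> SubjectTable:
    """Read a delimited-text subject table.

    Parameters
    ----------
    path
        Delimited text file with a header row; comma or tab, auto-detected.
    schema
        Optional map from canonical column names (``subject_id`` ...) to the
        names used in the file.  Unmapped names are taken as-is.

    Raises
    ------
    SchemaError
        A required column is absent under its mapped name.
    ValidationError
        Duplicate subject ids or a non-binary diagnosis column.
    ParseError
        A brain-feature cell that is neither numeric nor a missing token.
    """
    schema = schema or {}
    with open(path) as fh:
        header = fh.readline()
    sep = _detect_delimiter(header)
    raw = pd.read_csv(
        path,
        sep=sep,
        dtype=str,
        keep_default_na=False,
        na_values=[],
    )
    rename = {v: k for k, v in schema.items()}
    raw = raw.rename(columns=rename)

    for col in ("subject_id", "site_id", "diagnosis"):
        if col not in raw.columns:
            raise SchemaError(f"required column missing: {col!r}")

    meta_cols = [c for c in META_COLUMNS if c in raw.columns]
    feat_cols = [c for c in raw.columns if c not in META_COLUMNS]

    meta = pd.DataFrame(index=raw.index)
    meta["subject_id"] = raw["subject_id"]
    meta["site_id"] = raw["site_id"]
    meta["diagnosis"] = _parse_numeric(raw, "diagnosis", integer=True)
    for col in meta_cols:
        if col in ("subject_id", "site_id", "diagnosis"):
            continue
        if col == "sex":
            meta[col] = raw[col].where(~raw[col].isin(_MISSING_TOKENS), other=pd.NA)
        else:
            meta[col] = _parse_numeric(raw, col)

    feats = {}
    for col in feat_cols:
        feats[col] = _parse_numeric(raw, col)
    features = pd.DataFrame(feats, index=raw.index, dtype=float)

    table = SubjectTable(meta.reset_index(drop=True), features.reset_index(drop=True))
    return table


def _parse_numeric(raw: pd.DataFrame, col: str, integer: bool = False) -> pd.Series:
    s = raw[col].astype(str).str.strip()
    missing = s.isin(_MISSING_TOKENS).to_numpy()
    vals = np.full(len(s), np.nan)
    good = np.flatnonzero(~missing)
    try:
        # numpy's parser is correctly rounded (unlike pandas' fast path),
        # which keeps the text round trip bit-identical
        vals[good] = s.to_numpy()[good].astype(np.float64)
    except ValueError:
        for i in good:
            try:
                vals[i] = float(s.iloc[i])
            except ValueError:
                raise ParseError(
                    f"non-numeric value {s.iloc[i]!r} in column {col!r}, row {i}"
                ) from None
    out = pd.Series(vals, index=raw.index)
    if integer and not np.isnan(vals).any():
        out = out.astype(int)
    return out


def write_subject_table(path, table: SubjectTable, sep: str = "\t") -> None:
    """Write a table so that ``read_subject_table`` round-trips it exactly.

    Floats are written with 17 significant digits (lossless for float64);
    missing cells as the empty string.
    """
    meta = table.meta.copy()
    out = pd.concat([meta, table.features], axis=1)
    out.to_csv(path, sep=sep, index=False, float_format="%.17g", na_rep="")
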