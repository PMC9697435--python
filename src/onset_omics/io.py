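"""Readers, writers and validated containers for the pipeline's file formats.

Everything downstream consumes the three containers defined here: a
:class:`SampleSheet` mapping samples to (person, tissue, onset group, clinical
covariates), an :class:`OmicsMatrix` of features x samples (log2 expression or
methylation beta values), and the feature-level metadata
(:class:`FeatureAnnotation`, :class:`GeneSetCollection`).

Canonical on-disk dialect: tab-separated text, no quoting, ``NA`` as the
missing-value token.  Matrices align to the sheet by sample identifier, never
by column position.
"""

from __future__ import annotations

import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampleSheet",
    "OmicsMatrix",
    "FeatureAnnotation",
    "GeneSetCollection",
    "FormatError",
    "PairingError",
    "ValidationError",
    "read_sample_sheet",
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "write_annotation",
    "read_gene_sets",
    "write_gene_sets",
    "write_results_table",
    "get_logger",
    "log_stage",
]

MISSING_TOKEN = "NA"
TISSUES = ("tumor", "normal")
ONSET_GROUPS = ("EOCRC", "LOCRC")
REGION_CLASSES = ("island", "shore", "shelf", "deep_sea", "na")
MATRIX_KINDS = ("expression_log2", "methylation_beta")

REQUIRED_SHEET_COLUMNS = ("sample_id", "person_id", "tissue", "onset_group")


class FormatError(ValueError):
    """Malformed input file (wrong columns, non-numeric cell, bad GMT line)."""


class PairingError(ValueError):
    """Sample sheet violates the paired tumor/normal design."""


class ValidationError(ValueError):
    """Values violate a container invariant (e.g. beta outside [0, 1])."""


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------


@dataclass
class SampleSheet:
    """Sample -> (person, tissue, onset group, clinical covariates) mapping.

    One row per assayed sample.  ``tissue`` is ``tumor`` or ``normal``;
    ``onset_group`` is ``EOCRC`` (age of onset <= 40 years) or ``LOCRC``
    (> 40 years) and is constant within a person.  Any additional columns are
    treated as categorical clinical covariates (stage, lvi, pni, msi, ...).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"sample sheet missing required columns: {missing}")
        dup = df["sample_id"][df["sample_id"].duplicated()]
        if len(dup):
            row = int(df.index[df["sample_id"] == dup.iloc[0]][0])
            raise FormatError(
                f"duplicate sample_id {dup.iloc[0]!r} (row {row})"
            )
        bad_tissue = sorted(set(df["tissue"]) - set(TISSUES))
        if bad_tissue:
            raise FormatError(f"unknown tissue value(s): {bad_tissue}")
        bad_onset = sorted(set(df["onset_group"]) - set(ONSET_GROUPS))
        if bad_onset:
            raise FormatError(f"unknown onset_group value(s): {bad_onset}")
        for person, sub in df.groupby("person_id"):
            for tissue in TISSUES:
                n = int((sub["tissue"] == tissue).sum())
                if n > 1:
                    raise PairingError(
                        f"person {person!r} has {n} {tissue} samples (at most one allowed)"
                    )
            if sub["onset_group"].nunique() > 1:
                raise PairingError(
                    f"person {person!r} has inconsistent onset_group labels"
                )
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def clinical_covariates(self) -> list[str]:
        return [c for c in self.data.columns if c not in REQUIRED_SHEET_COLUMNS]

    def complete_pairs(self, onset_group: str | None = None) -> pd.DataFrame:
        """Persons with both a tumor and a normal sample.

        Returns a frame with columns person_id, onset_group, tumor, normal
        (the latter two are sample ids).  Unpaired persons are excluded; they
        never enter a paired model.
        """
        wide = self.data.pivot_table(
            index="person_id", columns="tissue", values="sample_id", aggfunc="first"
        )
        for tissue in TISSUES:
            if tissue not in wide.columns:
                wide[tissue] = np.nan
        wide = wide.dropna(subset=list(TISSUES))
        onset = self.data.drop_duplicates("person_id").set_index("person_id")[
            "onset_group"
        ]
        out = pd.DataFrame(
            {
                "person_id": wide.index,
                "onset_group": onset.loc[wide.index].to_numpy(),
                "tumor": wide["tumor"].to_numpy(),
                "normal": wide["normal"].to_numpy(),
            }
        ).reset_index(drop=True)
        if onset_group is not None:
            out = out[out["onset_group"] == onset_group].reset_index(drop=True)
        return out

    def unpaired_samples(self) -> list[str]:
        paired = self.complete_pairs()
        keep = set(paired["tumor"]) | set(paired["normal"])
        return [s for s in self.data["sample_id"] if s not in keep]

    def persons(self) -> pd.DataFrame:
        """One row per person: onset group plus the clinical covariates.

        Clinical covariates are person-level attributes; the value from the
        person's first row is used (they are constant within a person in any
        valid sheet).
        """
        cols = ["person_id", "onset_group"] + self.clinical_covariates
        return (
            self.data[cols].drop_duplicates("person_id").reset_index(drop=True)
        )

    def subset(self, sample_ids: list[str]) -> "SampleSheet":
        keep = self.data[self.data["sample_id"].isin(set(sample_ids))]
        return SampleSheet(keep.copy())


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(
        path, sep="\t", dtype=str, na_values=[MISSING_TOKEN], keep_default_na=False
    )
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


# ---------------------------------------------------------------------------
# Omics matrix
# ---------------------------------------------------------------------------


@dataclass
class OmicsMatrix:
    """Features x samples numeric grid.

    ``kind`` is ``expression_log2`` (log2 intensities, unbounded) or
    ``methylation_beta`` (beta values; every non-missing cell must lie in
    [0, 1]).  Missing cells are NaN, never silently zero.
    """

    values: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in MATRIX_KINDS:
            raise ValidationError(f"unknown matrix kind {self.kind!r}")
        dup = self.values.index[self.values.index.duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate feature_id {dup[0]!r}")
        vals = self.values.to_numpy(dtype=float)
        if self.kind == "methylation_beta":
            bad = np.where((vals < 0) | (vals > 1))
            if bad[0].size:
                i, j = bad[0][0], bad[1][0]
                raise ValidationError(
                    f"beta value {vals[i, j]!r} outside [0, 1] at "
                    f"feature {self.values.index[i]!r}, sample "
                    f"{self.values.columns[j]!r}"
                )
        self.values = self.values.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def check_samples(self, sheet: SampleSheet) -> None:
        """Fail fast if any matrix column is absent from the sample sheet."""
        unknown = set(self.sample_ids) - set(sheet.sample_ids)
        if unknown:
            raise ValidationError(
                f"matrix samples not in sample sheet: {sorted(unknown)}"
            )


def read_matrix(path, kind: str) -> OmicsMatrix:
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str,
        na_values=[MISSING_TOKEN], keep_default_na=False,
    )
    coerced = raw.apply(pd.to_numeric, errors="coerce")
    bad = raw.notna() & coerced.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric cell {raw.iat[i, j]!r} at feature "
            f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    # astype(float) parses with correct rounding (bit-identical round trips),
    # unlike the fast to_numeric path.
    numeric = raw.astype(float)
    numeric.index.name = "feature_id"
    return OmicsMatrix(numeric, kind)


def write_matrix(matrix: OmicsMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "feature_id"
    # %.17g guarantees bit-identical float round-trips through text.
    out.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, float_format="%.17g")


# ---------------------------------------------------------------------------
# Feature annotation (probe -> gene, CpG region class)
# ---------------------------------------------------------------------------


@dataclass
class FeatureAnnotation:
    """Per-feature metadata: gene symbol and CpG region class.

    Region classes follow the distance-from-island zoning of 450K-style
    manifests: ``island``, ``shore`` (0-2 kb), ``shelf`` (2-4 kb),
    ``deep_sea`` (> 4 kb); ``na`` is reserved for expression features.
    Gene symbols are uppercased so GMT gene sets match case-insensitively.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ("feature_id", "gene_symbol", "region_class")
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise FormatError(f"annotation missing columns: {missing}")
        df = self.data.copy()
        df["gene_symbol"] = df["gene_symbol"].fillna("").astype(str).str.upper()
        df["region_class"] = df["region_class"].fillna("na")
        bad = sorted(set(df["region_class"]) - set(REGION_CLASSES))
        if bad:
            raise ValidationError(f"unknown region_class value(s): {bad}")
        dup = df["feature_id"][df["feature_id"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate feature_id {dup.iloc[0]!r} in annotation")
        self.data = df.reset_index(drop=True)

    def gene_of(self) -> pd.Series:
        return self.data.set_index("feature_id")["gene_symbol"]

    def region_of(self) -> pd.Series:
        return self.data.set_index("feature_id")["region_class"]

    def features_for_genes(self, genes: list[str]) -> dict[str, list[str]]:
        """Map each requested gene symbol to its feature (probe) ids."""
        wanted = {g.upper() for g in genes}
        sub = self.data[self.data["gene_symbol"].isin(wanted)]
        return {
            g: list(rows["feature_id"])
            for g, rows in sub.groupby("gene_symbol")
        }


def read_annotation(path) -> FeatureAnnotation:
    df = pd.read_csv(
        path, sep="\t", dtype=str, na_values=[MISSING_TOKEN], keep_default_na=False
    )
    return FeatureAnnotation(df)


def write_annotation(annotation: FeatureAnnotation, path) -> None:
    annotation.data.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets; symbols uppercased and de-duplicated on load."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            seen: list[str] = []
            for g in genes:
                gu = str(g).upper()
                if gu and gu not in seen:
                    seen.append(gu)
            if not seen:
                raise ValidationError(f"gene set {name!r} is empty")
            clean[name] = seen
        self.sets = clean

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


def read_gene_sets(path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno} has {len(fields)} column(s); "
                    "expected set_name, description, members..."
                )
            name = fields[0]
            members = [g for g in fields[2:] if g]
            if not members:
                raise FormatError(f"GMT line {lineno} ({name!r}) has no members")
            sets[name] = members
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as handle:
        for name, genes in collection:
            handle.write("\t".join([name, name] + genes) + "\n")


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

_DISPLAY_COLUMNS = ("p", "interaction_p", "q", "fdr", "fold_change")


def write_results_table(records: pd.DataFrame, path, display_decimals: int = 3) -> None:
    """Write a result table as TSV with stable column order.

    Floats are written at full (shortest round-trip) precision; for p-value
    and fold-change style columns an additional ``<name>_display`` column is
    appended, rounded to ``display_decimals`` for human reading.
    """
    out = records.copy()
    for col in records.columns:
        base = col.split("_")[-1]
        if col in _DISPLAY_COLUMNS or base in ("p", "q", "fdr") or col.startswith(
            "fold_change"
        ):
            if pd.api.types.is_numeric_dtype(records[col]):
                out[col + "_display"] = records[col].round(display_decimals)
    out.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN,
               float_format="%.17g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[MISSING_TOKEN], keep_default_na=False)


# ---------------------------------------------------------------------------
# Stage logging
# ---------------------------------------------------------------------------


def get_logger(path=None) -> logging.Logger:
    logger = logging.getLogger("onset_omics")
    if not logger.handlers:
        handler = logging.StreamHandler() if path is None else logging.FileHandler(path)
        handler.setFormatter(logging.Formatter("%(asctime)s\t%(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


@contextmanager
def log_stage(name: str, shape=None, logger: logging.Logger | None = None):
    """Log one line per pipeline stage: name, input shape, elapsed seconds."""
    logger = logger or get_logger()
    start = time.perf_counter()
    yield
    elapsed = time.perf_counter() - start
    logger.info(f"{name}\tshape={shape}\telapsed={elapsed:.3f}s")
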