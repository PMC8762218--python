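"""Readers/writers for the tabular formats the pipeline consumes.

All flat files are tab-delimited UTF-8 with a header row. Expression
matrices are stored genes-as-rows, samples-as-columns.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Unit",
    "ExpressionMatrix",
    "CohortClinical",
    "MutationTable",
    "CnvCalls",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "fpkm_to_tpm",
    "log_transform",
    "read_clinical",
    "write_clinical",
    "read_maf",
    "write_maf",
    "read_gmt",
    "write_gmt",
    "read_cnv_calls",
    "write_cnv_calls",
]


class Unit(str, enum.Enum):
    """Expression measurement unit."""

    FPKM = "FPKM"
    TPM = "TPM"
    LOG2_TPM = "LOG2_TPM"


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression matrix with a declared unit.

    Parameters
    ----------
    values
        DataFrame with unique gene symbols as index and unique sample
        identifiers as columns. Must be fully numeric and finite.
    unit
        One of :class:`Unit`.
    """

    values: pd.DataFrame
    unit: Unit = Unit.TPM

    def __post_init__(self) -> None:
        self.unit = Unit(self.unit)
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        if self.values.isna().any().any():
            bad = np.argwhere(self.values.isna().to_numpy())[0]
            raise ValueError(
                "missing value at gene "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[present].copy(), self.unit)


@dataclass
class CohortClinical:
    """Per-sample survival endpoint plus optional covariates.

    ``table`` is indexed by sample_id with mandatory columns ``os_time``
    (days, > 0) and ``os_event`` (0 censored / 1 dead); the covariates
    ``age``, ``gender``, ``grade``, ``stage`` may be present with missing
    values allowed.
    """

    table: pd.DataFrame

    COVARIATES = ("age", "gender", "grade", "stage")

    def __post_init__(self) -> None:
        for col in ("os_time", "os_event"):
            if col not in self.table.columns:
                raise ValueError(f"clinical table missing mandatory column {col!r}")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample_id in clinical table")
        t = self.table["os_time"]
        if (t <= 0).any() or t.isna().any():
            bad = self.table.index[(t <= 0) | t.isna()].tolist()
            raise ValueError(f"os_time must be > 0; offending samples: {bad}")
        ev = self.table["os_event"]
        if not ev.isin([0, 1]).all():
            raise ValueError("os_event must be 0 or 1")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def os_time(self) -> np.ndarray:
        return self.table["os_time"].to_numpy(dtype=float)

    @property
    def os_event(self) -> np.ndarray:
        return self.table["os_event"].to_numpy(dtype=int)

    def aligned_to(self, sample_ids: Sequence[str]) -> "CohortClinical":
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise KeyError(f"samples absent from clinical table: {missing}")
        return CohortClinical(self.table.loc[list(sample_ids)].copy())


#: MAF variant classes counted as non-silent (protein-affecting).
NON_SILENT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Nonstop_Mutation",
    }
)

#: Controlled vocabulary for Variant_Classification.
MAF_CLASSES = NON_SILENT_CLASSES | {
    "Silent",
    "Intron",
    "3'UTR",
    "5'UTR",
    "3'Flank",
    "5'Flank",
    "IGR",
    "RNA",
    "Targeted_Region",
}


@dataclass
class MutationTable:
    """MAF-style somatic mutation records (one row per variant call)."""

    records: pd.DataFrame

    REQUIRED = ("sample_id", "gene_symbol", "variant_classification", "variant_type")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.records.columns:
                raise ValueError(f"mutation table missing column {col!r}")
        bad = set(self.records["variant_classification"]) - MAF_CLASSES
        if bad:
            raise ValueError(f"unknown Variant_Classification values: {sorted(bad)}")

    def non_silent(self, classes: Iterable[str] = NON_SILENT_CLASSES) -> pd.DataFrame:
        keep = self.records["variant_classification"].isin(set(classes))
        return self.records[keep]


@dataclass
class CnvCalls:
    """Discrete copy-number calls per (gene, sample).

    ``calls`` is a genes x samples DataFrame of integers in {-1, 0, +1}
    (loss / neutral / gain). ``provenance`` records how the calls were
    derived (thresholds, source).
    """

    calls: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    GAIN_THRESHOLD = 0.3
    LOSS_THRESHOLD = -0.3

    def __post_init__(self) -> None:
        vals = set(np.unique(self.calls.to_numpy()))
        if not vals <= {-1, 0, 1}:
            raise ValueError(f"CNV calls must be in {{-1,0,1}}; saw {sorted(vals)}")

    @classmethod
    def from_segment_means(
        cls,
        seg_values: pd.DataFrame,
        gain_threshold: float = GAIN_THRESHOLD,
        loss_threshold: float = LOSS_THRESHOLD,
    ) -> "CnvCalls":
        """Threshold continuous gene x sample segment means into calls."""
        arr = seg_values.to_numpy(dtype=float)
        calls = np.where(arr >= gain_threshold, 1, np.where(arr <= loss_threshold, -1, 0))
        return cls(
            pd.DataFrame(calls, index=seg_values.index, columns=seg_values.columns),
            provenance={
                "source": "segment_means",
                "gain_threshold": gain_threshold,
                "loss_threshold": loss_threshold,
            },
        )


@dataclass
class GeneSetCollection:
    """Named gene sets with a category tag."""

    sets: dict[str, list[str]]
    category: str = "custom"

    CATEGORIES = ("immune_cell", "estimate_stromal", "estimate_immune", "pathway", "custom")

    def __post_init__(self) -> None:
        if self.category not in self.CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    @property
    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# expression


def read_expression(path: str | Path, unit: Unit | str) -> ExpressionMatrix:
    """Load a genes x samples TSV into an :class:`ExpressionMatrix`.

    Duplicate gene symbols are collapsed by keeping, per symbol, the row
    with the highest mean expression. Non-numeric cells are reported with
    their gene and sample coordinates.
    """
    unit = Unit(unit)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell {df.iat[bad[0], bad[1]]!r} at gene "
            f"{df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
        )
    numeric = _collapse_duplicate_symbols(numeric)
    return ExpressionMatrix(numeric, unit)


def _collapse_duplicate_symbols(df: pd.DataFrame) -> pd.DataFrame:
    if not df.index.duplicated().any():
        return df
    means = df.mean(axis=1).to_numpy()
    order = np.argsort(-means, kind="stable")
    picked = df.iloc[order]
    picked = picked[~picked.index.duplicated(keep="first")]
    # restore first-occurrence row order
    return picked.loc[df.index.drop_duplicates()]


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene")


def fpkm_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each sample so its values sum to 1e6.

    TPM(g, s) = FPKM(g, s) / sum_g' FPKM(g', s) * 1e6.
    """
    if m.unit is not Unit.FPKM:
        raise ValueError(f"expected FPKM input, got {m.unit.value}")
    colsums = m.values.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {zero.index.tolist()}")
    return ExpressionMatrix(m.values / colsums * 1e6, Unit.TPM)


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1); identity if already log-scale."""
    if m.unit is Unit.LOG2_TPM:
        return m
    if m.unit is Unit.FPKM:
        m = fpkm_to_tpm(m)
    return ExpressionMatrix(np.log2(m.values + 1.0), Unit.LOG2_TPM)


# ---------------------------------------------------------------------------
# clinical


def read_clinical(path: str | Path) -> CohortClinical:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: clinical table needs a sample_id column")
    return CohortClinical(df.set_index("sample_id"))


def write_clinical(c: CohortClinical, path: str | Path) -> None:
    c.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# mutations

_MAF_RENAMES: Mapping[str, str] = {
    "Tumor_Sample_Barcode": "sample_id",
    "Hugo_Symbol": "gene_symbol",
    "Variant_Classification": "variant_classification",
    "Variant_Type": "variant_type",
}


def read_maf(path: str | Path) -> MutationTable:
    """Read a tab-delimited MAF; only the four standard identifying
    columns are retained."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _MAF_RENAMES if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: MAF missing columns {missing}")
    return MutationTable(df[list(_MAF_RENAMES)].rename(columns=_MAF_RENAMES))


def write_maf(muts: MutationTable, path: str | Path) -> None:
    inv = {v: k for k, v in _MAF_RENAMES.items()}
    muts.records.rename(columns=inv).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path, category: str = "custom") -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then members.

    Duplicate members within a line are stored once (first occurrence).
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = list(dict.fromkeys(g for g in fields[2:] if g))
    return GeneSetCollection(sets, category=category)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in coll:
            fh.write("\t".join([name, coll.category, *members]) + "\n")


# ---------------------------------------------------------------------------
# CNV


def read_cnv_calls(path: str | Path) -> CnvCalls:
    """Read a genes x samples TSV of either discrete calls in {-1,0,1} or
    continuous segment means (thresholded with the default cutoffs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy(dtype=float)
    if np.isin(np.unique(arr), [-1.0, 0.0, 1.0]).all():
        return CnvCalls(df.astype(int), provenance={"source": "discrete"})
    return CnvCalls.from_segment_means(df)


def write_cnv_calls(cnv: CnvCalls, path: str | Path) -> None:
    cnv.calls.to_csv(path, sep="\t", index_label="gene")
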