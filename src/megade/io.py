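"""Reading and writing the on-disk formats used throughout the pipeline.

Formats handled here:

* expression matrix — TSV, first column gene symbol, remaining columns one
  sample each, log2-scale (or raw) intensities, blank/NA cells allowed;
* sample sheet — CSV with columns ``sample_id`` and ``group`` (case/control);
* study registry — CSV with columns ``study_id``, ``n_control``, ``n_case``,
  ``country``, ``year``; a bundled registry mirrors the 14 autism
  case/control GEO series used as the reference study design;
* gene list — plain text, one symbol per line;
* gene set collection — standard GMT (name, description, members...);
* results — TSV or JSON with a documented, stable column order.

Gene identity is plain symbol strings matched case-insensitively: symbols
are upper-cased and whitespace-trimmed on ingest, and duplicate rows are
collapsed by mean.  There is no probe-to-gene mapping layer; mapping is the
caller's concern.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StudyMeta",
    "ExpressionStudy",
    "GeneSetCollection",
    "read_expression_matrix",
    "read_sample_sheet",
    "read_gene_list",
    "read_gene_sets",
    "read_registry",
    "load_reference_registry",
    "write_expression_study",
    "write_results",
]


@dataclass(frozen=True)
class StudyMeta:
    """One registry row: a case/control expression study."""

    study_id: str
    n_control: int
    n_case: int
    country: str = ""
    year: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_case < 1:
            raise ValueError(
                f"{self.study_id}: n_control and n_case must be >= 1 "
                f"(got {self.n_control}, {self.n_case})"
            )

    @property
    def n_total(self) -> int:
        return self.n_control + self.n_case


@dataclass
class ExpressionStudy:
    """A gene x sample matrix of log2-scale values with case/control labels.

    ``values`` is indexed by gene symbol (unique, upper-case) with one column
    per sample; ``groups`` maps every sample id to ``"case"`` or
    ``"control"``.  Missing measurements are NaN and are propagated, never
    imputed.
    """

    values: pd.DataFrame
    groups: pd.Series
    meta: StudyMeta

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.groups.index):
            raise ValueError(
                f"{self.meta.study_id}: sample columns and group labels disagree"
            )
        bad = set(self.groups.unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"{self.meta.study_id}: unknown group labels {bad}")
        if self.values.index.has_duplicates:
            raise ValueError(f"{self.meta.study_id}: duplicate gene ids")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def case_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "case"])

    @property
    def control_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "control"])


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. one GMT file), used for overlap enrichment."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def _clean_symbol(symbol: str) -> str:
    return symbol.strip().upper()


def read_sample_sheet(path: str | Path) -> pd.Series:
    """Read a sample sheet CSV into a sample_id -> group Series."""
    sheet = pd.read_csv(path, dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(sheet.columns):
        raise ValueError(f"{path}: sample sheet needs columns {sorted(required)}")
    groups = sheet.set_index("sample_id")["group"].str.strip().str.lower()
    bad = set(groups.unique()) - {"case", "control"}
    if bad:
        raise ValueError(f"{path}: group labels must be case/control, got {bad}")
    return groups


def read_expression_matrix(
    path: str | Path,
    sample_sheet_path: str | Path,
    meta: StudyMeta,
) -> ExpressionStudy:
    """Read a genes x samples TSV plus its sample sheet into a study.

    Duplicate gene symbols are collapsed by mean; missing values stay NaN.
    Every matrix column must appear in the sheet and vice versa; non-numeric
    cells raise with a row/column report.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = [_clean_symbol(g) for g in raw.index]
    values = raw.apply(pd.to_numeric, errors="coerce")
    # cells that became NaN but were not blank/NA in the source are parse errors
    bad_cells = []
    for col in raw.columns:
        mask = (values[col].isna() & raw[col].notna()).to_numpy()
        for pos in mask.nonzero()[0]:
            cell = raw[col].iloc[pos]
            if str(cell).strip().upper() not in {"", "NA", "NAN", "NULL"}:
                bad_cells.append((raw.index[pos], col, cell))
    if bad_cells:
        gene, col, cell = bad_cells[0]
        raise ValueError(
            f"{path}: non-numeric cell {cell!r} at gene {gene!r}, sample {col!r} "
            f"({len(bad_cells)} offending cells total)"
        )
    n_before = len(values)
    values = values.groupby(level=0).mean()
    n_dup = n_before - len(values)
    if n_dup:
        logger.info("%s: collapsed %d duplicate gene rows by mean", path, n_dup)

    groups = read_sample_sheet(sample_sheet_path)
    missing_from_sheet = set(values.columns) - set(groups.index)
    if missing_from_sheet:
        raise ValueError(
            f"{path}: samples absent from sheet: {sorted(missing_from_sheet)}"
        )
    extra_in_sheet = set(groups.index) - set(values.columns)
    if extra_in_sheet:
        raise ValueError(
            f"{sample_sheet_path}: sheet lists samples not in matrix: "
            f"{sorted(extra_in_sheet)}"
        )
    groups = groups.loc[values.columns]
    return ExpressionStudy(values=values, groups=groups, meta=meta)


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line gene list; upper-case, dedup, keep order."""
    text = Path(path).read_text()
    symbols = [_clean_symbol(line) for line in text.splitlines() if line.strip()]
    if not symbols:
        raise ValueError(f"{path}: empty gene list")
    seen: dict[str, None] = {}
    for s in symbols:
        seen.setdefault(s)
    n_dup = len(symbols) - len(seen)
    if n_dup:
        logger.info("%s: dropped %d duplicate symbols", path, n_dup)
    return list(seen)


def read_gene_list_xlsx(path: str | Path, sheet: str, column: int = 0) -> list[str]:
    """Optional helper: read one column of an xlsx sheet as a gene list.

    Requires openpyxl.  The first row is treated as a header and skipped.
    """
    import openpyxl  # deferred: optional dependency

    wb = openpyxl.load_workbook(path, read_only=True)
    ws = wb[sheet]
    symbols = []
    for i, row in enumerate(ws.iter_rows(values_only=True)):
        if i == 0:
            continue
        cell = row[column] if column < len(row) else None
        if cell is not None and str(cell).strip():
            symbols.append(_clean_symbol(str(cell)))
    if not symbols:
        raise ValueError(f"{path}[{sheet}]: empty gene list")
    return list(dict.fromkeys(symbols))


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: tab-separated name, description, member symbols."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty GMT file")
    for ln in lines:
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: GMT line with <3 fields: {ln!r}")
        name, desc, members = parts[0], parts[1], parts[2:]
        if name in sets:
            raise ValueError(f"{path}: duplicate set name {name!r}")
        cleaned = frozenset(_clean_symbol(m) for m in members if m.strip())
        if not cleaned:
            raise ValueError(f"{path}: set {name!r} has no members")
        sets[name] = cleaned
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def read_registry(path: str | Path) -> list[StudyMeta]:
    """Read a study registry CSV into StudyMeta rows; ids must be unique."""
    table = pd.read_csv(path)
    required = {"study_id", "n_control", "n_case"}
    if not required.issubset(table.columns):
        raise ValueError(f"{path}: registry needs columns {sorted(required)}")
    if table["study_id"].duplicated().any():
        dups = table.loc[table["study_id"].duplicated(), "study_id"].tolist()
        raise ValueError(f"{path}: duplicate study ids {dups}")
    rows = []
    for _, r in table.iterrows():
        rows.append(
            StudyMeta(
                study_id=str(r["study_id"]),
                n_control=int(r["n_control"]),
                n_case=int(r["n_case"]),
                country=str(r.get("country", "")),
                year=int(r.get("year", 0)),
            )
        )
    return rows


def load_reference_registry() -> list[StudyMeta]:
    """The bundled 14-study case/control registry used as the default design.

    It mirrors the published summary table of the autism expression series
    pooled by the reference mega-analysis (GEO ids, arm sizes, country,
    publication year).  One series appears there twice with different case
    counts; the two rows are kept as sub-studies with suffixed ids.
    """
    with resources.as_file(
        resources.files("megade.data") / "table1_registry.csv"
    ) as p:
        return read_registry(p)


def write_expression_study(study: ExpressionStudy, matrix_path: str | Path,
                           sample_sheet_path: str | Path) -> None:
    """Write a study back to the matrix TSV + sample sheet CSV pair."""
    out = study.values.copy()
    out.index.name = "gene"
    out.to_csv(matrix_path, sep="\t", float_format="%.10g")
    sheet = pd.DataFrame(
        {"sample_id": study.groups.index, "group": study.groups.values}
    )
    sheet.to_csv(sample_sheet_path, index=False)


def write_results(results: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    """Write a results table as TSV (default) or JSON records.

    Column order is preserved exactly as given; floats are written with
    ``%.10g`` so that write/read round-trips at full useful precision.
    """
    path = Path(path)
    if format == "tsv":
        results.to_csv(path, sep="\t", index=False, float_format="%.10g")
    elif format == "json":
        path.write_text(json.dumps(results.to_dict(orient="records"), indent=1))
    else:
        raise ValueError(f"unknown results format {format!r} (tsv or json)")
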