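"""Readers and writers for every external representation the pipeline touches.

The pipeline consumes GenePix-style single-channel scan exports (``.gpr``-like
tab-delimited text with an optional ATF header block), a GAL-style probe
annotation table, a sample-to-group design table, and a flat YAML
configuration.  It emits tab-separated expression matrices and result tables.

Identifiers are case-sensitive except gene symbols, which are upper-cased on
ingestion so that cross-platform symbol matching works by plain identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml


class FormatError(ValueError):
    """A file does not have the structure its format requires."""


class ParseError(ValueError):
    """A structurally valid file contains an unparseable value."""


class ConfigError(ValueError):
    """A configuration document is invalid."""


#: Foreground/background columns of a single-channel (Cy3) GenePix export.
GPR_REQUIRED_COLUMNS = ("ID", "Name", "F532 Median", "B532 Median")
GPR_FLAG_COLUMN = "Flags"

#: Name-field contents that mean "no gene symbol for this spot".
SYMBOL_PLACEHOLDERS = frozenset({"", "---", "N/A", "NA"})


def _clean_field(s: str) -> str:
    s = s.strip()
    if len(s) >= 2 and s[0] == '"' and s[-1] == '"':
        s = s[1:-1]
    return s.strip()


def normalize_symbol(raw: Optional[str]) -> Optional[str]:
    """Upper-case a gene symbol; placeholders and empty fields become None."""
    if raw is None:
        return None
    s = _clean_field(str(raw))
    if s.upper() in SYMBOL_PLACEHOLDERS or s == "":
        return None
    return s.upper()


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ArrayScan:
    """One array's probe-level raw intensities, in file spot order.

    ``probes`` has columns ``probe_id``, ``gene_symbol`` (object, None when
    absent), ``foreground``, ``background`` (arbitrary intensity units) and
    ``flag`` (int).  Duplicate probe_ids are permitted: they are duplicate
    spots and are only collapsed late in preprocessing.
    """

    array_id: str
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"probe_id", "gene_symbol", "foreground", "background", "flag"}
        missing = required - set(self.probes.columns)
        if missing:
            raise ValueError(f"ArrayScan probes missing columns: {sorted(missing)}")
        if (self.probes["probe_id"].astype(str) == "").any():
            raise ValueError("ArrayScan contains an empty probe_id")
        for col in ("foreground", "background"):
            vals = np.asarray(self.probes[col], dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite {col} intensity in array {self.array_id}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.probes["probe_id"])


@dataclass(frozen=True)
class AnnotationTable:
    """probe_id -> gene symbol map; symbols upper-cased, absent symbols omitted."""

    symbols: Mapping[str, str]
    version_tag: str = ""

    def symbol_of(self, probe_id: str) -> Optional[str]:
        return self.symbols.get(probe_id)

    def annotated_probes(self) -> set[str]:
        return set(self.symbols)


@dataclass(frozen=True)
class DesignTable:
    """sample_id -> group label assignment."""

    assignments: "pd.Series"  # index: sample_id, values: group label

    def __post_init__(self) -> None:
        if self.assignments.index.has_duplicates:
            dup = self.assignments.index[self.assignments.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in design: {dup}")

    @property
    def samples(self) -> list[str]:
        return list(self.assignments.index)

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.assignments:
            seen.setdefault(g, None)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        return list(self.assignments.index[self.assignments == group])

    def require_replicates(self, minimum: int = 2) -> None:
        for g in self.groups:
            n = len(self.samples_in(g))
            if n < minimum:
                raise ValueError(
                    f"group {g!r} has {n} sample(s); at least {minimum} required"
                )

    def subset(self, samples: Sequence[str]) -> "DesignTable":
        return DesignTable(self.assignments.loc[list(samples)])


@dataclass
class ExpressionMatrix:
    """Probes-or-genes x samples matrix of log2 expression with its design.

    ``level`` is ``"probe"`` (duplicate row ids allowed, mirroring duplicate
    spots) or ``"gene"`` (row ids must be unique symbols).
    """

    values: pd.DataFrame  # rows x samples, float
    design: DesignTable
    level: str = "probe"

    def __post_init__(self) -> None:
        if self.level not in ("probe", "gene"):
            raise ValueError(f"unknown matrix level {self.level!r}")
        if list(self.values.columns) != self.design.samples:
            if set(self.values.columns) != set(self.design.samples):
                raise ValueError("matrix columns do not match design samples")
            self.values = self.values[self.design.samples]
        if self.level == "gene" and self.values.index.has_duplicates:
            raise ValueError("gene-level matrix has duplicate row ids")

    def validate_finite(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# GPR-style scan files
# ---------------------------------------------------------------------------


def _locate_header(lines: Sequence[str]) -> tuple[int, list[str]]:
    """Find the column-name row, skipping an optional ATF header block."""
    for i, line in enumerate(lines):
        fields = [_clean_field(f) for f in line.rstrip("\n").split("\t")]
        if "ID" in fields and "Name" in fields:
            return i, fields
    raise FormatError("missing column ID")


def read_gpr(path: str | Path, array_id: Optional[str] = None) -> ArrayScan:
    """Read a GenePix-style tab-delimited scan file.

    Accepts an optional ATF-style preamble (any lines before the row that
    names the columns).  Requires ``ID``, ``Name``, ``F532 Median`` and
    ``B532 Median``; an optional ``Flags`` column defaults to 0.  Spot order
    in the file is preserved exactly, including duplicate IDs.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_idx, header = _locate_header(lines)
    for col in GPR_REQUIRED_COLUMNS:
        if col not in header:
            raise FormatError(f"missing column {col}")
    pos = {c: header.index(c) for c in header}
    has_flags = GPR_FLAG_COLUMN in pos

    ids: list[str] = []
    symbols: list[Optional[str]] = []
    fg: list[float] = []
    bg: list[float] = []
    flags: list[int] = []
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if not line.strip():
            continue
        fields = [_clean_field(f) for f in line.split("\t")]
        if len(fields) < len(header):
            raise ParseError(f"{path.name}: line {lineno}: expected {len(header)} fields")
        probe_id = fields[pos["ID"]]
        if probe_id == "":
            raise ParseError(f"{path.name}: line {lineno}: empty ID")
        try:
            f = float(fields[pos["F532 Median"]])
            b = float(fields[pos["B532 Median"]])
        except ValueError as exc:
            raise ParseError(
                f"{path.name}: line {lineno}: non-numeric intensity ({exc})"
            ) from None
        flag = 0
        if has_flags and fields[pos[GPR_FLAG_COLUMN]] != "":
            try:
                flag = int(float(fields[pos[GPR_FLAG_COLUMN]]))
            except ValueError:
                raise ParseError(f"{path.name}: line {lineno}: non-numeric flag") from None
        ids.append(probe_id)
        symbols.append(normalize_symbol(fields[pos["Name"]]))
        fg.append(f)
        bg.append(b)
        flags.append(flag)

    probes = pd.DataFrame(
        {
            "probe_id": ids,
            "gene_symbol": symbols,
            "foreground": fg,
            "background": bg,
            "flag": flags,
        }
    )
    return ArrayScan(array_id or path.stem, probes)


def write_gpr(scan: ArrayScan, path: str | Path) -> None:
    """Write an ArrayScan as a minimal GenePix-style file with an ATF preamble."""
    path = Path(path)
    lines = [
        "ATF\t1.0",
        "2\t5",
        '"Type=GenePix Results 3"',
        f'"ScanName={scan.array_id}"',
        '\t'.join(f'"{c}"' for c in (*GPR_REQUIRED_COLUMNS, GPR_FLAG_COLUMN)),
    ]
    for row in scan.probes.itertuples(index=False):
        name = row.gene_symbol if row.gene_symbol is not None else ""
        lines.append(
            f"{row.probe_id}\t{name}\t{row.foreground:.10g}\t{row.background:.10g}\t{row.flag}"
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GAL-style annotation
# ---------------------------------------------------------------------------


def read_annotation(path: str | Path, version_tag: str = "") -> AnnotationTable:
    """Read a GAL-style probe annotation table.

    The file is tab-delimited ``ID``/``Name`` pairs after an optional header
    block.  Symbols are upper-cased; empty symbols are recorded as absent.
    The same probe may appear repeatedly with the same symbol, but conflicting
    symbols for one probe are an error.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        header_idx, header = _locate_header(lines)
        id_pos, name_pos = header.index("ID"), header.index("Name")
        data_lines = lines[header_idx + 1 :]
    except FormatError:
        # headerless two-column fallback: probe_id <tab> symbol
        id_pos, name_pos = 0, 1
        data_lines = lines

    symbols: dict[str, Optional[str]] = {}
    conflicts: dict[str, set[str]] = {}
    for line in data_lines:
        if not line.strip():
            continue
        fields = [_clean_field(f) for f in line.split("\t")]
        if len(fields) <= max(id_pos, name_pos):
            fields = fields + [""] * (max(id_pos, name_pos) + 1 - len(fields))
        probe_id = fields[id_pos]
        if probe_id == "":
            continue
        sym = normalize_symbol(fields[name_pos])
        if probe_id in symbols and symbols[probe_id] is not None and sym is not None:
            if symbols[probe_id] != sym:
                conflicts.setdefault(probe_id, {symbols[probe_id]}).add(sym)
        elif probe_id not in symbols or symbols[probe_id] is None:
            symbols[probe_id] = sym
    if conflicts:
        detail = "; ".join(
            f"{pid}: {sorted(syms)}" for pid, syms in sorted(conflicts.items())
        )
        raise FormatError(f"conflicting symbols for probe(s): {detail}")
    return AnnotationTable(
        symbols={p: s for p, s in symbols.items() if s is not None},
        version_tag=version_tag,
    )


def write_annotation(ann: AnnotationTable, path: str | Path,
                     all_probes: Optional[Iterable[str]] = None) -> None:
    """Write an annotation table; ``all_probes`` adds unannotated IDs with empty Name."""
    path = Path(path)
    lines = ["ID\tName"]
    if all_probes is None:
        all_probes = ann.symbols.keys()
    for pid in all_probes:
        lines.append(f"{pid}\t{ann.symbols.get(pid, '')}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Design tables
# ---------------------------------------------------------------------------


def read_design(path: str | Path) -> DesignTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"missing column {col}")
    series = pd.Series(df["group"].values, index=df["sample_id"].values, name="group")
    return DesignTable(series)


def write_design(design: DesignTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {"sample_id": design.assignments.index, "group": design.assignments.values}
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def write_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Serialize to TSV with row ids in column 1, at full float precision.

    Refuses matrices containing non-finite values: preprocessing guarantees a
    complete matrix and writers enforce that invariant.
    """
    m.validate_finite()
    path = Path(path)
    cols = "\t".join(["row_id", *map(str, m.values.columns)])
    lines = [cols]
    arr = m.values.to_numpy(dtype=float)
    for rid, row in zip(m.values.index, arr):
        lines.append(str(rid) + "\t" + "\t".join(f"{v:.17g}" for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_matrix(path: str | Path, design: Optional[DesignTable] = None,
                level: str = "probe") -> ExpressionMatrix:
    """Read a TSV expression matrix written by :func:`write_matrix`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path.name}: empty file")
    header = lines[0].split("\t")
    samples = header[1:]
    n = len(header)
    ids = []
    rows = []
    for i, line in enumerate(lines[1:], start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != n:
            raise ParseError(f"{path.name}: row {i}: {len(fields)} fields, expected {n}")
        ids.append(fields[0])
        try:
            rows.append([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise ParseError(f"{path.name}: row {i}: {exc}") from None
    values = pd.DataFrame(rows, index=ids, columns=samples, dtype=float)
    if values.empty:
        values = pd.DataFrame(np.empty((0, len(samples))), columns=samples, dtype=float)
    if design is None:
        design = DesignTable(pd.Series(["unknown"] * len(samples), index=samples, name="group"))
    return ExpressionMatrix(values, design, level=level)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Flat key-value configuration; defaults are the study's stated thresholds.
DEFAULT_CONFIG: dict = {
    "alpha": 0.05,              # adjusted-p significance level
    "lfc_threshold": 2.0,       # |log2 FC| cutoff applied after BH selection
    "score_threshold": 8.0,     # FC-score cutoff for signature membership
    "strict_cutoffs": True,     # strict (<, >) vs inclusive (<=, >=) comparisons
    "pool_bh": False,           # BH per contrast (default) or pooled across contrasts
    "lowess_span": 0.3,
    "lowess_iterations": 3,
    "log_offset": 16.0,         # added before log2 (variance stabilization of
                                # background-dominated probes)
    "use_local_background": False,  # subtract the scanner's B532 before normexp
    "exclude_flagged": False,   # drop spots with negative Flags
    "top_n": 1000,              # genes kept for the heatmap/tree stage
    "tree_distance": "correlation",
    "tree_linkage": "average",
}


def load_config(path: Optional[str | Path] = None) -> dict:
    """Load a flat YAML config, merged over :data:`DEFAULT_CONFIG`.

    Unknown keys are an error so that a typo in a threshold name cannot
    silently fall back to a default.
    """
    cfg = dict(DEFAULT_CONFIG)
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError("config must be a flat key-value mapping")
    unknown = set(user) - set(cfg)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(user)
    return cfg
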