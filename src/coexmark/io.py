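"""Readers and writers for the formats the pipeline touches.

Containers are deliberately plain:

* expression matrix — :class:`pandas.DataFrame`, genes in rows (index =
  gene ids), samples in columns (columns = sample ids), log2-scale values,
  ``NaN`` for missing;
* phenotype table — :class:`pandas.DataFrame` indexed by sample id with
  columns ``group`` (``"AS"``/``"HC"``), optional ``batch`` and
  ``severity`` (0–10 scale, cases only);
* gene sets — :class:`GeneSetCollection`;
* interaction edges — :class:`pandas.DataFrame` with columns
  ``node_a``/``node_b`` (lexicographically ordered) and ``score``.

All readers reject malformed input with a :class:`ParseError` naming the
offending line rather than silently coercing.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParseError",
    "GeneSetCollection",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_phenotypes_csv",
    "write_phenotypes_csv",
    "read_series_matrix",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_config_yaml",
]

#: missing-value tokens accepted on input (case-insensitive); GEO exports vary
MISSING_TOKENS = {"", "na", "nan", "null"}


class ParseError(ValueError):
    """Malformed input file; the message names the file and line."""


def _parse_float(token: str) -> float:
    if token.strip().lower() in MISSING_TOKENS:
        return math.nan
    return float(token)


# ---------------------------------------------------------------------------
# expression matrix TSV
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes × samples TSV (first column gene ids, header sample ids).

    Empty cells, ``NA`` and ``NaN`` (case-insensitive) become missing values.
    Duplicate ids, ragged rows and non-numeric cells raise :class:`ParseError`
    with the 1-based line number.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        sample_ids = header.split("\t")[1:]
        if len(sample_ids) != len(set(sample_ids)):
            dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise ParseError(f"{path}, line 1: duplicate sample ids {dups}")
        genes: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            gene, cells = fields[0], fields[1:]
            if gene in seen:
                raise ParseError(f"{path}, line {lineno}: duplicate gene id {gene!r}")
            seen.add(gene)
            if len(cells) != len(sample_ids):
                raise ParseError(
                    f"{path}, line {lineno}: expected {len(sample_ids)} values, got {len(cells)}"
                )
            try:
                rows.append([_parse_float(c) for c in cells])
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: non-numeric cell ({exc})") from None
            genes.append(gene)
    values = np.asarray(rows, dtype=float) if rows else np.empty((0, len(sample_ids)))
    return pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=sample_ids)


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a genes × samples matrix; missing values serialize as ``NA``."""
    matrix = matrix.copy()
    matrix.index.name = matrix.index.name or "gene"
    matrix.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


# ---------------------------------------------------------------------------
# phenotype table CSV
# ---------------------------------------------------------------------------

def read_phenotypes_csv(path: str | Path) -> pd.DataFrame:
    """Read a phenotype CSV with columns sample_id, group[, batch, severity]."""
    path = Path(path)
    pheno = pd.read_csv(path, dtype={"sample_id": str, "group": str}, na_values=["NA"])
    for col in ("sample_id", "group"):
        if col not in pheno.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if pheno["sample_id"].duplicated().any():
        dup = pheno.loc[pheno["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"{path}: duplicate sample ids {dup}")
    if pheno["group"].isna().any():
        raise ParseError(f"{path}: missing group labels")
    pheno = pheno.set_index("sample_id")
    if "batch" in pheno.columns:
        pheno["batch"] = pheno["batch"].astype(str)
    return pheno


def write_phenotypes_csv(phenotypes: pd.DataFrame, path: str | Path) -> None:
    out = phenotypes.copy()
    out.index.name = "sample_id"
    out.to_csv(path, na_rep="NA")


# ---------------------------------------------------------------------------
# GEO series matrix
# ---------------------------------------------------------------------------

def read_series_matrix(
    path: str | Path,
    group_pattern: str = r"\bAS\b",
    characteristics_key: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse a GEO series-matrix text file into (expression, phenotypes).

    The layout is ``!``-prefixed metadata lines followed by a probe × sample
    table between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end``. Case/control groups are inferred from the
    ``!Sample_characteristics_ch1`` lines: a sample whose characteristics
    match ``group_pattern`` (a regex) is labeled ``AS``, otherwise ``HC``.
    ``characteristics_key`` optionally restricts matching to the
    characteristics line whose ``key: value`` key equals it.
    """
    path = Path(path)
    char_lines: list[list[str]] = []
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table, saw_begin = True, True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table, saw_end = False, True
                continue
            if in_table:
                if line:
                    table_lines.append(line)
            elif line.startswith("!Sample_characteristics_ch1"):
                cells = [c.strip().strip('"') for c in line.split("\t")[1:]]
                char_lines.append(cells)
    if not (saw_begin and saw_end):
        raise ParseError(f"{path}: missing !series_matrix_table_begin/end sentinels")
    if not table_lines:
        raise ParseError(f"{path}: empty series-matrix table")

    header = [c.strip('"') for c in table_lines[0].split("\t")]
    sample_ids = header[1:]
    probes, rows = [], []
    for offset, line in enumerate(table_lines[1:], start=2):
        cells = [c.strip('"') for c in line.split("\t")]
        if len(cells) != len(header):
            raise ParseError(f"{path}: ragged table row {offset}")
        probes.append(cells[0])
        try:
            rows.append([_parse_float(c) for c in cells[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric table cell in row {offset} ({exc})") from None
    matrix = pd.DataFrame(
        np.asarray(rows, dtype=float), index=pd.Index(probes, name="gene"), columns=sample_ids
    )

    pattern = re.compile(group_pattern)
    groups = []
    for j, sid in enumerate(sample_ids):
        fields = [line[j] for line in char_lines if j < len(line)]
        if characteristics_key is not None:
            fields = [f for f in fields if f.lower().startswith(characteristics_key.lower() + ":")]
        groups.append("AS" if any(pattern.search(f) for f in fields) else "HC")
    phenotypes = pd.DataFrame({"group": groups}, index=pd.Index(sample_ids, name="sample_id"))
    return matrix, phenotypes


def collapse_probes(
    matrix: pd.DataFrame, probe_to_gene: dict[str, str], how: str = "max_variance"
) -> pd.DataFrame:
    """Collapse probe rows mapping to the same gene symbol.

    ``how``: ``max_variance`` keeps each gene's highest-variance probe
    (the default, standard for microarray summaries); ``mean`` averages.
    Probes without a mapping are dropped.
    """
    mapped = matrix.loc[matrix.index.isin(probe_to_gene)]
    genes = np.asarray([probe_to_gene[p] for p in mapped.index])
    if how == "mean":
        out = mapped.groupby(genes).mean()
        out.index = pd.Index(out.index, name="gene")
    elif how == "max_variance":
        variances = mapped.var(axis=1, ddof=1)
        order = pd.DataFrame(
            {"symbol": genes, "var": variances.to_numpy(), "probe": mapped.index}
        )
        keep = order.sort_values(["symbol", "var"]).groupby("symbol").tail(1)["probe"]
        out = mapped.loc[keep]
        out.index = pd.Index([probe_to_gene[p] for p in out.index], name="gene")
    else:
        raise ValueError(f"unknown collapse mode {how!r}")
    out.index.name = "gene"
    return out.sort_index()


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions, GMT round-trippable.

    ``sets`` maps set name → ordered member list (de-duplicated);
    ``descriptions`` maps set name → free-text description.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def add(self, name: str, members: list[str], description: str = "") -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        deduped = list(dict.fromkeys(members))
        if not deduped:
            raise ValueError(f"gene set {name!r} has no members")
        self.sets[name] = deduped
        self.descriptions[name] = description


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, name TAB description TAB members."""
    path = Path(path)
    collection = GeneSetCollection()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}, line {lineno}: expected name, description and ≥1 member"
                )
            collection.add(fields[0], fields[2:], description=fields[1])
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# interaction edge lists
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, score_threshold: float = 0.0) -> pd.DataFrame:
    """Read a 2–3 column TSV of undirected edges (STRING-export style).

    Edges with a score below ``score_threshold`` are dropped; self-loops are
    removed; (a, b) and (b, a) are canonicalized to lexicographic order and
    de-duplicated (keeping the first score seen). A 2-column file keeps every
    edge regardless of threshold.
    """
    path = Path(path)
    edges: dict[tuple[str, str], float] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}, line {lineno}: fewer than 2 columns")
            a, b = fields[0].strip(), fields[1].strip()
            if lineno == 1:
                if (a, b) == ("node_a", "node_b"):
                    continue  # our own writer's header
                if len(fields) >= 3 and fields[2].strip().lower() not in MISSING_TOKENS:
                    try:
                        float(fields[2])
                    except ValueError:
                        continue  # header row
            if a == b:
                continue
            score = math.nan
            if len(fields) >= 3:
                try:
                    score = _parse_float(fields[2])
                except ValueError as exc:
                    raise ParseError(f"{path}, line {lineno}: bad score ({exc})") from None
                if not math.isnan(score) and score < score_threshold:
                    continue
            key = (a, b) if a < b else (b, a)
            edges.setdefault(key, score)
    frame = pd.DataFrame(
        [(a, b, s) for (a, b), s in edges.items()], columns=["node_a", "node_b", "score"]
    )
    return frame


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("node_a", "node_b", "score") if c in edges.columns]
    edges[cols].to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def read_config_yaml(path: str | Path) -> dict:
    """Load a YAML key-value run configuration."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return cfg
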