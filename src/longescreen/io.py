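"""Readers and writers for the package's TSV/BED dialects.

All tables are tab-separated UTF-8 with a header row, ``NA`` or an empty
cell for missing values, no quoting.  Errors name the file, line and
column.  Coordinate conventions: BED segments are 0-based half-open;
TSS tables give 1-based positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .degs import GeneExpressionRecord, PromoterAnnotation
from .screen import ExpressionCompendium, StrainPhenotype
from .survival import DoseResponsePoint, LifespanRecord

__all__ = [
    "TableSchema",
    "SCHEMAS",
    "read_table",
    "read_phenotypes",
    "read_compendium",
    "read_lifespans",
    "read_dose_response",
    "read_expression_long",
    "read_deg_stats",
    "read_promoter_states",
    "read_gene_terms",
    "read_tss_table",
    "read_bed_states",
    "map_states_to_genes",
    "write_tsv",
    "write_phenotypes",
    "write_compendium",
    "write_lifespans",
    "write_expression_long",
    "write_promoter_states",
    "write_gene_terms",
]

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


@dataclass(frozen=True)
class TableSchema:
    """Column names and dtypes for one TSV dialect."""

    name: str
    columns: tuple[str, ...]
    dtypes: tuple[str, ...]  # 'str' | 'float' | 'int' | 'bool01'


SCHEMAS: dict[str, TableSchema] = {
    s.name: s
    for s in [
        TableSchema("phenotypes", ("strain_id", "lifespan_change_pct", "n_cells"), ("str", "float", "int")),
        TableSchema("lifespans", ("group", "lifespan", "observed"), ("str", "float", "bool01")),
        TableSchema("dose_response", ("dose", "response"), ("float", "float")),
        TableSchema("expression_long", ("gene_id", "group", "replicate", "fpkm"), ("str", "str", "int", "float")),
        TableSchema("deg_stats", ("gene_id", "log2fc", "p_value", "q_value"), ("str", "float", "float", "float")),
        TableSchema("promoter_states", ("gene_id", "state"), ("str", "str")),
        TableSchema("gene_terms", ("gene_id", "term_id"), ("str", "str")),
        TableSchema("tss", ("gene_id", "chrom", "tss", "strand"), ("str", "str", "int", "str")),
    ]
}

_CASTS = {
    "str": lambda v: v,
    "float": float,
    "int": int,
    "bool01": lambda v: {"0": False, "1": True}[v],
}


def read_table(path, schema: TableSchema | str) -> pd.DataFrame:
    """Read and validate a TSV against a schema.

    Returns a DataFrame with typed columns; ``NA``/empty cells become
    NaN (numeric) or None (string).  Raises ValueError naming the file,
    line and column on any malformed content.
    """
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in schema.columns if c not in header]
        if missing:
            raise ValueError(f"{path}: header missing column(s) {missing}")
        idx = [header.index(c) for c in schema.columns]
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            row = {}
            for col, dtype, i in zip(schema.columns, schema.dtypes, idx):
                if i >= len(cells):
                    raise ValueError(f"{path}:{lineno}: row has no value for column '{col}'")
                raw = cells[i].strip()
                if raw in ("", "NA"):
                    row[col] = np.nan if dtype in ("float", "int") else None
                    continue
                try:
                    row[col] = _CASTS[dtype](raw)
                except (ValueError, KeyError) as e:
                    raise ValueError(
                        f"{path}:{lineno}: cannot parse '{raw}' in column '{col}' as {dtype}"
                    ) from e
            rows.append(row)
    return pd.DataFrame(rows, columns=list(schema.columns))


def _require(df: pd.DataFrame, path, cols: Sequence[str]):
    for c in cols:
        if df[c].isna().any():
            bad = int(df.index[df[c].isna()][0]) + 2
            raise ValueError(f"{path}:{bad}: missing value in required column '{c}'")


def read_phenotypes(path) -> list[StrainPhenotype]:
    df = read_table(path, "phenotypes")
    _require(df, path, SCHEMAS["phenotypes"].columns)
    if df["strain_id"].duplicated().any():
        dup = df["strain_id"][df["strain_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate strain_id '{dup}'")
    return [
        StrainPhenotype(r.strain_id, float(r.lifespan_change_pct), int(r.n_cells))
        for r in df.itertuples(index=False)
    ]


def read_compendium(path) -> ExpressionCompendium:
    """Read the gene x strain log2FC matrix (first column ``gene_id``),
    transposed to the in-memory strain x gene orientation."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA", ""])
    if df.columns[0] != "gene_id":
        raise ValueError(f"{path}: first column must be 'gene_id', got '{df.columns[0]}'")
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id '{dup}'")
    mat = df.set_index("gene_id").T
    mat.index.name = "strain_id"
    return ExpressionCompendium(mat.astype(float))


def read_lifespans(path) -> list[LifespanRecord]:
    df = read_table(path, "lifespans")
    _require(df, path, SCHEMAS["lifespans"].columns)
    return [
        LifespanRecord(r.group, float(r.lifespan), bool(r.observed))
        for r in df.itertuples(index=False)
    ]


def read_dose_response(path) -> list[DoseResponsePoint]:
    df = read_table(path, "dose_response")
    _require(df, path, SCHEMAS["dose_response"].columns)
    return [DoseResponsePoint(float(r.dose), float(r.response)) for r in df.itertuples(index=False)]


def read_expression_long(
    path, control_group: str = "control", treatment_group: str = "treatment"
) -> list[GeneExpressionRecord]:
    """Long-form FPKM table -> per-gene records with replicate arrays."""
    df = read_table(path, "expression_long")
    _require(df, path, SCHEMAS["expression_long"].columns)
    groups = set(df["group"])
    for g in (control_group, treatment_group):
        if g not in groups:
            raise ValueError(f"{path}: group '{g}' absent (found {sorted(groups)})")
    records = []
    for gene, sub in df.groupby("gene_id", sort=True):
        ctrl = sub[sub["group"] == control_group].sort_values("replicate")["fpkm"].to_numpy()
        trt = sub[sub["group"] == treatment_group].sort_values("replicate")["fpkm"].to_numpy()
        records.append(GeneExpressionRecord(gene, fpkm_control=ctrl, fpkm_treatment=trt))
    return records


def read_deg_stats(path) -> list[GeneExpressionRecord]:
    """Precomputed per-gene DE statistics (no replicate FPKM needed)."""
    df = read_table(path, "deg_stats")
    _require(df, path, ("gene_id", "log2fc", "p_value"))
    return [
        GeneExpressionRecord(
            r.gene_id,
            log2fc=float(r.log2fc),
            p_value=float(r.p_value),
            q_value=float(r.q_value) if np.isfinite(r.q_value) else np.nan,
        )
        for r in df.itertuples(index=False)
    ]


def read_promoter_states(path) -> list[PromoterAnnotation]:
    df = read_table(path, "promoter_states")
    _require(df, path, SCHEMAS["promoter_states"].columns)
    return [PromoterAnnotation(r.gene_id, r.state) for r in df.itertuples(index=False)]


def read_gene_terms(path) -> dict[str, list[str]]:
    df = read_table(path, "gene_terms")
    _require(df, path, SCHEMAS["gene_terms"].columns)
    out: dict[str, list[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.gene_id, []).append(r.term_id)
    return out


def read_tss_table(path) -> pd.DataFrame:
    """Gene TSS table: 1-based position, strand in {+,-}."""
    df = read_table(path, "tss")
    _require(df, path, SCHEMAS["tss"].columns)
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        lineno = int(df.index[bad][0]) + 2
        raise ValueError(f"{path}:{lineno}: strand must be '+' or '-'")
    if (df["tss"] < 1).any():
        lineno = int(df.index[df["tss"] < 1][0]) + 2
        raise ValueError(f"{path}:{lineno}: TSS positions are 1-based (>= 1)")
    return df


def read_bed_states(path) -> pd.DataFrame:
    """BED4 chromatin-state segments (chrom, start, end, state), 0-based
    half-open; start < end enforced."""
    path = Path(path)
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) < 4:
                raise ValueError(f"{path}:{lineno}: BED4 needs 4 columns, got {len(cells)}")
            chrom, start, end, state = cells[0], cells[1], cells[2], cells[3]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from e
            if start_i < 0 or start_i >= end_i:
                raise ValueError(f"{path}:{lineno}: need 0 <= start < end, got {start_i}..{end_i}")
            rows.append({"chrom": chrom, "start": start_i, "end": end_i, "state": state})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def map_states_to_genes(
    segments: pd.DataFrame, tss: pd.DataFrame, window: int = 1000
) -> dict[str, str]:
    """Assign each gene the chromatin state overlapping its TSS window.

    The window is TSS +/- ``window`` bp (symmetric; the strand column is
    validated but the window does not depend on it).  The 1-based TSS ``t``
    maps to the 0-based half-open window ``[t-1-window, t+window)``.  When
    several segments overlap, the one with the largest overlap wins; ties
    prefer 'active', then the leftmost segment.  Genes with no overlap are
    omitted.
    """
    out: dict[str, str] = {}
    by_chrom = {c: g.sort_values("start") for c, g in segments.groupby("chrom")} if len(segments) else {}
    for r in tss.itertuples(index=False):
        segs = by_chrom.get(r.chrom)
        if segs is None:
            continue
        w0 = r.tss - 1 - window
        w1 = r.tss + window
        ov = np.minimum(segs["end"].to_numpy(), w1) - np.maximum(segs["start"].to_numpy(), w0)
        hit = ov > 0
        if not hit.any():
            continue
        cand = segs.loc[hit].assign(overlap=ov[hit])
        cand = cand.sort_values(
            ["overlap", "state", "start"], ascending=[False, True, True]
        )  # 'active' < 'inactive' lexically, so ties prefer active
        out[r.gene_id] = str(cand.iloc[0]["state"])
    return out


def write_tsv(df: pd.DataFrame, path) -> None:
    """Write a DataFrame in the package dialect (tab, NA, stable floats)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT)


def write_phenotypes(phenotypes: Sequence[StrainPhenotype], path) -> None:
    write_tsv(
        pd.DataFrame(
            {
                "strain_id": [p.strain_id for p in phenotypes],
                "lifespan_change_pct": [p.lifespan_change for p in phenotypes],
                "n_cells": [p.n_cells for p in phenotypes],
            }
        ),
        path,
    )


def write_compendium(compendium: ExpressionCompendium, path) -> None:
    mat = compendium.values.T  # file orientation: gene x strain
    mat.index.name = "gene_id"
    write_tsv(mat.reset_index(), path)


def write_lifespans(records: Sequence[LifespanRecord], path) -> None:
    write_tsv(
        pd.DataFrame(
            {
                "group": [r.group for r in records],
                "lifespan": [r.lifespan for r in records],
                "observed": [int(r.observed) for r in records],
            }
        ),
        path,
    )


def write_expression_long(records: Sequence[GeneExpressionRecord], path) -> None:
    rows = []
    for r in records:
        for group, arr in (("control", r.fpkm_control), ("treatment", r.fpkm_treatment)):
            if arr is None:
                continue
            for i, v in enumerate(arr, start=1):
                rows.append({"gene_id": r.gene_id, "group": group, "replicate": i, "fpkm": v})
    write_tsv(pd.DataFrame(rows, columns=["gene_id", "group", "replicate", "fpkm"]), path)


def write_promoter_states(annotations: Sequence[PromoterAnnotation], path) -> None:
    write_tsv(
        pd.DataFrame(
            {"gene_id": [a.gene_id for a in annotations], "state": [a.state for a in annotations]}
        ),
        path,
    )


def write_gene_terms(gene_terms: Mapping[str, Sequence[str]], path) -> None:
    rows = [
        {"gene_id": g, "term_id": t} for g in sorted(gene_terms) for t in gene_terms[g]
    ]
    write_tsv(pd.DataFrame(rows, columns=["gene_id", "term_id"]), path)
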