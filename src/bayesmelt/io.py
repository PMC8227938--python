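"""Read, validate and write meltome-style long-format measurement tables.

Canonical on-disk format is UTF-8 CSV with header
``run_name,protein_id,gene_name,temperature,fold_change`` — one row per
(run, protein, temperature), single replicate per temperature.  A
column-mapping option accommodates exports with different header names.
Proteins are identified by (run_name, protein_id) pairs everywhere
downstream: the same species measured as cells vs lysate counts as two
independent runs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of a measurement table
COLUMNS = ["run_name", "protein_id", "gene_name", "temperature", "fold_change"]

REQUIRED = ["run_name", "protein_id", "temperature", "fold_change"]


class SchemaError(ValueError):
    """A table is missing required columns or violates the schema."""


def _sniff_delimiter(path: Path) -> str:
    import csv

    sample = Path(path).open("r", encoding="utf-8").read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def validate_measurements(df: pd.DataFrame, *, min_temperatures: int = 2) -> pd.DataFrame:
    """Validate a measurement table, returning a clean canonical copy.

    Enforces: required columns present; temperature and fold_change numeric
    (non-numeric rows rejected with row numbers); (run, protein, temperature)
    unique; all temperatures > 0. Proteins observed at fewer than
    ``min_temperatures`` distinct temperatures are dropped with a warning —
    they cannot constrain a curve.
    """
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.copy()
    if "gene_name" not in df.columns:
        df["gene_name"] = ""
    df = df[COLUMNS]

    for col in ("temperature", "fold_change"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            rows = df.index[bad].tolist()
            raise SchemaError(f"non-numeric {col} in row(s) {rows[:10]}")
        df[col] = coerced
    df = df.dropna(subset=["temperature", "fold_change"])
    if df.empty:
        raise SchemaError("table has no valid measurement rows")
    if (df["temperature"] <= 0).any():
        raise SchemaError("temperatures must be positive (°C scale)")

    dup = df.duplicated(subset=["run_name", "protein_id", "temperature"])
    if dup.any():
        raise SchemaError(
            f"duplicate (run, protein, temperature) rows: {df.index[dup].tolist()[:10]} "
            "(single replicate per temperature expected)"
        )

    ntemp = df.groupby(["run_name", "protein_id"], sort=False)["temperature"].transform("nunique")
    thin = ntemp < min_temperatures
    if thin.any():
        n_dropped = df.loc[thin, ["run_name", "protein_id"]].drop_duplicates().shape[0]
        logger.warning(
            "dropping %d protein(s) with fewer than %d temperatures", n_dropped, min_temperatures
        )
        df = df[~thin]
    if df.empty:
        raise SchemaError("no protein has enough temperatures to constrain a curve")
    return df.reset_index(drop=True)


def read_measurements(
    path,
    *,
    delimiter: str | None = None,
    column_map: dict[str, str] | None = None,
    min_temperatures: int = 2,
) -> pd.DataFrame:
    """Read a delimiter-separated measurement table and validate it.

    Parameters
    ----------
    path : path-like
        CSV/TSV file with a header row.
    delimiter : str, optional
        Field delimiter; auto-detected (sniffed) when omitted.
    column_map : dict, optional
        Mapping from the file's header names to the canonical names
        (``run_name``, ``protein_id``, ``gene_name``, ``temperature``,
        ``fold_change``), for exports with different headers.
    min_temperatures : int
        Minimum distinct temperatures a protein needs to be kept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise SchemaError(f"empty file: {path}")
    sep = delimiter if delimiter is not None else _sniff_delimiter(path)
    # round_trip parsing: the default float parser can be off by one ulp,
    # which would break byte-identical write→read→write cycles
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if column_map:
        df = df.rename(columns={src: dst for src, dst in column_map.items()})
    return validate_measurements(df, min_temperatures=min_temperatures)


def write_table(df: pd.DataFrame, path) -> Path:
    """Write any result table as UTF-8 CSV with stable column order.

    Floats are written at full round-trip precision; fields containing the
    delimiter are quoted, so ``read_measurements`` inverts
    ``write_table`` for measurement tables.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)  # default float repr round-trips exactly
    return path
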