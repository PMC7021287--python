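"""CSV input/output with explicit typing and a self-consistent dialect.

Default dialect: comma separator, period decimal point, UTF-8, header row
required.  ``column_types`` overrides the inferred type per column
("numeric" or "categorical"); a ``decimal`` override handles
decimal-comma files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)


class DatasetError(ValueError):
    pass


def read_dataset(path, column_types: dict = None, sep: str = ",",
                 decimal: str = ".") -> pd.DataFrame:
    """Read a CSV table with typed columns.

    Numeric columns stay numeric, everything else becomes pandas
    ``category``; ``column_types`` forces a column either way.  Parse
    failures raise :class:`DatasetError` with the offending location.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=sep, decimal=decimal, encoding="utf-8")
    except Exception as exc:  # noqa: BLE001
        raise DatasetError(f"could not parse {path}: {exc}") from exc
    if df.columns.str.startswith("Unnamed").all():
        raise DatasetError(f"{path} appears to have no header row")
    for col, kind in (column_types or {}).items():
        if col not in df.columns:
            raise DatasetError(f"column_types names unknown column {col!r}")
        if kind == "numeric":
            try:
                df[col] = pd.to_numeric(df[col])
            except (TypeError, ValueError) as exc:
                raise DatasetError(
                    f"column {col!r} cannot be coerced to numeric: {exc}"
                ) from exc
        elif kind == "categorical":
            df[col] = df[col].astype("category")
        else:
            raise DatasetError(
                f"column type for {col!r} must be 'numeric' or 'categorical'"
            )
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]) and \
                not isinstance(df[col].dtype, pd.CategoricalDtype):
            df[col] = df[col].astype("category")
    logger.info("read %d rows x %d columns from %s", *df.shape, path)
    return df


def write_dataset(df: pd.DataFrame, path) -> Path:
    """Write a table in the package dialect (round-trips through read_dataset)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
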