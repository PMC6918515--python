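"""Delimited-text I/O for microdata, guideline tables, and packaged data.

Microdata files are comma-delimited with an optional ``#`` comment header
(tool version, seed, config hash).  Unparseable or out-of-range cells are
coerced to missing with a per-column tally, so a dirty file degrades into
missingness rather than failing.
"""

from __future__ import annotations

import importlib.resources
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .. import __version__
from .. import _schema as S
from ..income import REGIONS, PovertyGuidelineTable

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "read_microdata",
    "write_microdata",
    "write_table",
    "load_poverty_guidelines",
    "load_table2_fixture",
]


class SchemaError(ValueError):
    """The input file does not match the microdata schema."""


#: Closed-form validity checks per column (applied after numeric coercion).
_RANGE_CHECKS = {
    S.AGE: lambda x: np.isin(x, S.AGE_LEVELS),
    S.SEX: lambda x: np.isin(x, S.SEX_LEVELS),
    S.RACE: lambda x: np.isin(x, S.RACE_LEVELS),
    S.EDUCATION: lambda x: np.isin(x, S.EDUCATION_LEVELS),
    S.INCOME: lambda x: np.isin(x, S.INCOME_LEVELS),
    S.N_ADULTS: lambda x: (x >= 0) & (x == np.round(x)),
    S.N_CHILDREN: lambda x: (x >= 0) & (x == np.round(x)),
    S.BMI: lambda x: x > 0,
    S.PREGNANT: lambda x: np.isin(x, (0, 1)),
    S.WEIGHT: lambda x: x > 0,
}


def _header_lines(seed=None, config_hash=None, extra: dict | None = None) -> str:
    meta = {"tool": f"hwdi {__version__}"}
    if seed is not None:
        meta["seed"] = seed
    if config_hash is not None:
        meta["config_hash"] = config_hash
    meta.update(extra or {})
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_microdata(df: pd.DataFrame, path, seed=None, config_hash=None) -> None:
    """Write microdata as delimited text (empty string = missing) with a
    provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(seed, config_hash))
        df[list(S.MICRODATA_COLUMNS)].to_csv(fh, index=False)


def write_table(df: pd.DataFrame, path, seed=None, config_hash=None, **extra) -> None:
    """Write any result table as delimited text with a provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(seed, config_hash, extra))
        df.to_csv(fh, index=False)


def read_microdata(path) -> pd.DataFrame:
    """Read a microdata file into typed records.

    Header matching is case-insensitive; a missing mandatory column raises
    :class:`SchemaError` naming the column.  Cells that fail to parse or
    fall outside a column's valid range become missing markers; the
    per-column tally is logged and stored in ``df.attrs['coercion_tally']``.
    Row count is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    try:
        raw = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty microdata file: {path}") from exc
    if raw.shape[1] == 0 or len(raw) == 0:
        raise SchemaError(f"empty microdata file: {path}")
    rename = {c: c.strip().lower() for c in raw.columns}
    raw = raw.rename(columns=rename)
    for col in S.MICRODATA_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"missing mandatory column: {col}")

    out = pd.DataFrame(index=raw.index)
    tally: dict[str, int] = {}
    state = raw[S.STATE].str.strip()
    out[S.STATE] = state.where(state != "", other=pd.NA)
    for col in S.MICRODATA_COLUMNS[1:]:
        cells = raw[col].str.strip()
        nonempty = cells != ""
        vals = pd.to_numeric(cells.where(nonempty), errors="coerce")
        bad_parse = nonempty & vals.isna()
        ok = _RANGE_CHECKS[col](vals.to_numpy(dtype=float))
        bad_range = nonempty & ~bad_parse & ~pd.Series(ok, index=vals.index).fillna(False)
        n_bad = int(bad_parse.sum() + bad_range.sum())
        if n_bad:
            tally[col] = n_bad
        out[col] = vals.where(~(bad_parse | bad_range)).astype(float)
    if tally:
        logger.warning("coerced invalid cells to missing: %s", tally)
    out.attrs["coercion_tally"] = tally
    return out


def _package_data(name: str):
    return importlib.resources.files("hwdi").joinpath("data", name)


def load_poverty_guidelines(path=None) -> PovertyGuidelineTable:
    """Load a poverty-guideline table (columns region, year, base_dollars,
    increment_dollars); defaults to the packaged 2016 DHHS table."""
    source = Path(path) if path is not None else _package_data("poverty_guidelines_2016.csv")
    with importlib.resources.as_file(source) if path is None else _noop(source) as p:
        df = pd.read_csv(p, comment="#")
    missing = set(REGIONS) - set(df["region"])
    if missing:
        raise SchemaError(f"guideline table missing regions: {sorted(missing)}")
    year = int(df["year"].iloc[0])
    return PovertyGuidelineTable(
        year=year,
        base_dollars={r.region: float(r.base_dollars) for r in df.itertuples()},
        increment_dollars={r.region: float(r.increment_dollars) for r in df.itertuples()},
    )


class _noop:
    def __init__(self, value):
        self.value = value

    def __enter__(self):
        return self.value

    def __exit__(self, *exc):
        return False


def load_table2_fixture() -> pd.DataFrame:
    """Packaged per-state index/ranking fixture (49 states; two states absent
    due to documented data problems).

    Columns: state, rhwdi (printed magnitude), rhwdi_negative (bool),
    rhwdi_rank, hwdi, hwdi_rank.  Both rank columns are bijections onto
    1..49.
    """
    with importlib.resources.as_file(_package_data("table2_rankings.csv")) as p:
        df = pd.read_csv(p)
    df["rhwdi_negative"] = df["rhwdi_negative"].astype(bool)
    for col in ("rhwdi_rank", "hwdi_rank"):
        if sorted(df[col]) != list(range(1, len(df) + 1)):
            raise SchemaError(f"fixture column {col} is not a bijection onto 1..n")
    return df
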