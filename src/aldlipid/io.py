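"""Readers and writers for the pipeline's tabular schemas.

Canonical output format is TSV; CSV is accepted on input with a sniffed
delimiter. Abundance/feature tables follow the supplementary-data layout
(lipid names in the first column, sample ids in the header); metadata is a
patient-per-row CSV. Missing values are empty fields, never zero. Every
file written here starts with a provenance comment (config hash, seed),
which the readers skip.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "check_sample_ids",
    "write_results",
    "config_hash",
]

METADATA_COLUMNS = (
    "patient_id",
    "sample_id",
    "sex",
    "age",
    "cald",
    "adrenal_insufficiency",
    "edss",
)


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                return "\t" if "\t" in line else ","
    return "\t"


def config_hash(config: Mapping) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _atomic_write(path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_abundance_table(path) -> pd.DataFrame:
    """Read a lipid x sample table (first column lipid names).

    Rejects duplicate lipid rows (error names them) and decimal-comma
    number dialects (error says so).
    """
    path = Path(path)
    sep = _sniff_sep(path)
    table = pd.read_csv(path, sep=sep, comment="#", index_col=0, dtype=str)
    dup = table.index[table.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate lipid rows: {sorted(set(map(str, dup)))}")
    if sep == "\t":
        comma_cells = table.map(
            lambda v: isinstance(v, str) and bool(pd.Series([v]).str.fullmatch(r"\d+,\d+").iloc[0])
        )
        if comma_cells.to_numpy().any():
            raise ValueError(
                "decimal-comma numbers detected; use '.' as the decimal separator"
            )
    try:
        out = table.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric abundance values in {path}: {exc}") from exc
    out.index.name = "lipid"
    return out


def write_abundance_table(
    table: pd.DataFrame, path, meta: Mapping | None = None
) -> None:
    """Write a lipid x sample table as TSV with a provenance header."""
    header = ""
    if meta is not None:
        header = (
            f"# config_hash={config_hash(meta)} "
            f"seed={meta.get('seed', 'NA')}\n"
        )
    body = table.to_csv(sep="\t", index_label="lipid", na_rep="")
    _atomic_write(path, header + body)


write_results = write_abundance_table  # results tables share the layout


def read_metadata(path) -> pd.DataFrame:
    """Read the patient metadata table.

    Required columns: patient_id, sample_id, sex, age, cald,
    adrenal_insufficiency, edss. Optional: hct, months_post_hct,
    xci_fraction, group.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    missing = set(METADATA_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"metadata missing columns {sorted(missing)}")
    dup = frame["patient_id"][frame["patient_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate patient ids: {sorted(set(dup))}")
    return frame


def check_sample_ids(table: pd.DataFrame, metadata: pd.DataFrame) -> None:
    """Require every metadata sample id to appear in the table and vice
    versa; the error lists the difference."""
    table_ids = set(map(str, table.columns))
    meta_ids = set(map(str, metadata["sample_id"]))
    only_meta = sorted(meta_ids - table_ids)
    only_table = sorted(table_ids - meta_ids)
    if only_meta or only_table:
        raise ValueError(
            f"sample id mismatch: in metadata only {only_meta}; "
            f"in table only {only_table}"
        )
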