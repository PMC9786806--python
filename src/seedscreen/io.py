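"""Delimited-text readers/writers and run configuration.

All interchange is CSV with declared headers (UTF-8, LF or CRLF).  Readers
validate schemas up front — missing columns raise a :class:`SchemaError`
naming them — and report malformed rows with their file line numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ContractError, SchemaError

PEAK_COLUMNS = ["sample_id", "tissue", "peak_mean", "cv", "n_nuclei"]
FRUIT_COLUMNS = ["mother_id", "n_pyrenes", "n_seeds"]
SEED_COLUMNS = ["seed_id", "mother_id", "maternal_level", "status", "embryo_level", "endosperm_level"]


def _read_csv(path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            lines = [i + 2 for i in df.index[bad][:5]]  # +2: header + 1-based
            raise SchemaError(
                f"{path}: non-numeric values in column {col!r} at line(s) {lines}"
            )
        df[col] = coerced
    return df


def read_peaks(path) -> pd.DataFrame:
    """Read a peak table (sample_id, tissue, peak_mean, cv, n_nuclei)."""
    df = _read_csv(path, PEAK_COLUMNS, ["peak_mean", "cv", "n_nuclei"])
    if (df["peak_mean"] <= 0).any():
        rows = [i + 2 for i in df.index[df["peak_mean"] <= 0][:5]]
        raise SchemaError(f"{path}: non-positive peak_mean at line(s) {rows}")
    return df


def read_events(path) -> np.ndarray:
    """Read a one-value-per-line fluorescence event list."""
    values = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            try:
                values.append(float(text))
            except ValueError as exc:
                raise SchemaError(f"{path}: malformed event at line {lineno}: {text!r}") from exc
    return np.asarray(values, dtype=float)


def read_fruits(path) -> pd.DataFrame:
    """Read a fruit table (mother_id, n_pyrenes, n_seeds); contract-checks counts."""
    df = _read_csv(path, FRUIT_COLUMNS, ["n_pyrenes", "n_seeds"])
    bad = (df["n_seeds"] < 0) | (df["n_pyrenes"] < 1) | (df["n_pyrenes"] > 4) | (
        df["n_seeds"] > df["n_pyrenes"]
    )
    if bad.any():
        lines = [i + 2 for i in df.index[bad][:5]]
        raise ContractError(
            f"{path}: invalid fruit counts (0 <= n_seeds <= n_pyrenes <= 4) at line(s) {lines}"
        )
    return df.astype({"n_pyrenes": int, "n_seeds": int})


def read_seeds(path) -> pd.DataFrame:
    """Read a screened-seed table ready for classification."""
    df = _read_csv(path, SEED_COLUMNS, ["maternal_level"])
    for col in ("embryo_level", "endosperm_level"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_table(df: pd.DataFrame, path, *, index: bool = False) -> Path:
    """Write a tidy CSV (UTF-8, LF); returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, lineterminator="\n")
    return path


@dataclass
class RunConfig:
    """Validated configuration for the pipeline CLI."""

    seed: int = 0
    standard: str = "pisum"
    qc_embryo_cv: float = 6.0
    qc_endosperm_cv: float = 9.0
    min_nuclei_embryo: int = 1300
    sperm_set: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0, 4.0)
    tolerance: float = 0.25
    min_count: float = 4
    k: int = 2
    segments: int = 26
    n_trees: int = 12
    n_seeds_per_tree: int = 60
    cytotype_proportions: dict = field(default_factory=lambda: {3.0: 100.0})
    cv: float = 2.0
    p_missing_endosperm: float = 0.0
    p_multiple_endosperm: float = 0.0

    def __post_init__(self) -> None:
        if self.qc_endosperm_cv < self.qc_embryo_cv:
            raise ContractError("qc_endosperm_cv must be >= qc_embryo_cv")
        if self.tolerance <= 0 or self.tolerance > 0.25:
            raise ContractError("tolerance must be in (0, 0.25]")
        if self.k < 2:
            raise ContractError("k must be >= 2")
        if self.segments < 2:
            raise ContractError("segments must be >= 2")
        if not self.sperm_set:
            raise ContractError("sperm_set must be non-empty")


def load_config(path) -> RunConfig:
    """Load a YAML (plain key-value) configuration file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: configuration must be a mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"{path}: unknown configuration key(s): {sorted(unknown)}")
    if "sperm_set" in raw:
        raw["sperm_set"] = tuple(float(x) for x in raw["sperm_set"])
    if "cytotype_proportions" in raw:
        raw["cytotype_proportions"] = {
            float(k): float(v) for k, v in raw["cytotype_proportions"].items()
        }
    return RunConfig(**raw)
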