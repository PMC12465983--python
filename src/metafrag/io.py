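"""Corpus reading/writing and run configuration.

A corpus is one long-format CSV, one row per study, with the header
``ma_id,study_id,e1,n1,e0,n0`` (UTF-8, comma-separated).  Reading
validates every row against the 2x2-table invariants and rejects the
whole file on any violation, naming the offending line numbers.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Tuple

import numpy as np
import pandas as pd
import yaml

from .effects import TwoByTwoTable
from .errors import CorpusFormatError

CORPUS_COLUMNS = ["ma_id", "study_id", "e1", "n1", "e0", "n0"]


@dataclass(frozen=True)
class MetaAnalysisDataset:
    """One meta-analysis: an ordered list of (study_id, table) pairs."""

    ma_id: str
    studies: Tuple[Tuple[str, TwoByTwoTable], ...]

    def __post_init__(self) -> None:
        if len(self.studies) < 1:
            raise ValueError(f"meta-analysis {self.ma_id!r} has no studies")
        ids = [sid for sid, _ in self.studies]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate study ids within meta-analysis {self.ma_id!r}")
        object.__setattr__(self, "studies", tuple(self.studies))

    def __len__(self) -> int:
        return len(self.studies)

    @property
    def tables(self) -> List[TwoByTwoTable]:
        return [t for _, t in self.studies]

    @property
    def total_n(self) -> int:
        return sum(t.total_n for t in self.tables)

    @property
    def total_events(self) -> int:
        return sum(t.total_events for t in self.tables)

    def count_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (e1, n1, e0, n0) as 1-D integer arrays, study order preserved."""
        t = self.tables
        return (
            np.array([x.e1 for x in t]),
            np.array([x.n1 for x in t]),
            np.array([x.e0 for x in t]),
            np.array([x.n0 for x in t]),
        )


@dataclass
class RunConfig:
    """Analysis settings shared across pipeline stages."""

    measures: Tuple[str, ...] = ("OR",)
    scenarios: Tuple[str, ...] = ("FE", "S1", "S2", "S3", "S4")
    alpha: float = 0.05
    dz_policy: str = "exclude"
    cap: int | None = None
    exact: bool = False
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.cap is not None and self.cap < 1:
            raise ValueError(f"cap must be >= 1, got {self.cap}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("measures", "scenarios"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def read_corpus(path: str | Path) -> List[MetaAnalysisDataset]:
    """Read and validate a long-format corpus CSV.

    Line numbers in error messages are 1-based file lines (header is
    line 1).  Any invariant violation rejects the whole file.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise CorpusFormatError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in CORPUS_COLUMNS if c not in df.columns]
    if missing:
        raise CorpusFormatError(f"{path}: missing required columns {missing}")

    errors: List[str] = []
    datasets: dict[str, list[tuple[str, TwoByTwoTable]]] = {}
    seen: set[tuple[str, str]] = set()
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # header is line 1
        ma_id = getattr(row, "ma_id").strip()
        study_id = getattr(row, "study_id").strip()
        if not ma_id or not study_id:
            errors.append(f"line {line}: empty ma_id or study_id")
            continue
        counts = {}
        bad = False
        for col in ("e1", "n1", "e0", "n0"):
            raw = getattr(row, col).strip()
            try:
                counts[col] = int(raw)
            except ValueError:
                errors.append(f"line {line}: {col}={raw!r} is not an integer")
                bad = True
        if bad:
            continue
        if (ma_id, study_id) in seen:
            errors.append(f"line {line}: duplicate (ma_id, study_id) = ({ma_id!r}, {study_id!r})")
            continue
        seen.add((ma_id, study_id))
        try:
            table = TwoByTwoTable(**counts)
        except ValueError as exc:
            errors.append(f"line {line}: {exc}")
            continue
        datasets.setdefault(ma_id, []).append((study_id, table))

    if errors:
        raise CorpusFormatError([f"{path}:"] + errors)
    if not datasets:
        raise CorpusFormatError(f"{path}: no studies found")
    return [MetaAnalysisDataset(ma_id=m, studies=tuple(s)) for m, s in datasets.items()]


def write_corpus(datasets: Iterable[MetaAnalysisDataset], path: str | Path) -> None:
    """Write datasets in the long-format CSV schema (round-trips with read_corpus)."""
    rows = []
    for ds in datasets:
        for sid, t in ds.studies:
            rows.append((ds.ma_id, sid, t.e1, t.n1, t.e0, t.n0))
    df = pd.DataFrame(rows, columns=CORPUS_COLUMNS)
    df.to_csv(path, index=False, lineterminator="\n")


def to_json(obj, path: str | Path | None = None) -> str:
    """Serialize results deterministically (sorted keys, repr-exact floats)."""
    text = json.dumps(obj, indent=2, sort_keys=True, allow_nan=True)
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text
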