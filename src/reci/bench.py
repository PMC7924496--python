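"""Evaluation harness: pair-file I/O, weighted accuracy and decision-rate curves.

Pair files follow the plain layout used by curated cause-effect pair
collections: one whitespace-delimited two-column text file per dataset,
plus an optional metadata table listing, per pair, the column index of the
cause and effect variables and a weight that down-weights near-duplicate
datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, PairFormatError
from .inference import (
    RunProtocol,
    _effective_protocol,
    decide,
    directional_errors,
)
from .pair import Direction, ObservedPair
from .preprocess import DensityFilterSpec, preprocess_pair
from .regressors import FamilySpec

MIN_PAIR_ROWS = 10


@dataclass(frozen=True)
class PairFileRecord:
    """One metadata row: which column is the cause, and the dataset weight."""

    name: str
    cause_column: int
    weight: float
    path: Path | None = None

    def __post_init__(self) -> None:
        if self.cause_column not in (1, 2):
            raise PairFormatError("cause_column must be 1 or 2")
        if self.weight < 0:
            raise PairFormatError("weight must be nonnegative")

    @property
    def truth(self) -> Direction:
        return Direction.X_CAUSES_Y if self.cause_column == 1 else Direction.Y_CAUSES_X


def read_pair_file(
    path,
    name: str | None = None,
    truth: Direction = Direction.NONE,
    weight: float = 1.0,
) -> ObservedPair:
    """Load a two-column whitespace-delimited pair file.

    Rows with more than two columns are rejected: multivariate pairs are out
    of scope for a bivariate direction test.
    """
    path = Path(path)
    xs: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) > 2:
                raise PairFormatError(
                    f"{path.name}:{lineno}: {len(fields)} columns; only bivariate "
                    "pairs are supported"
                )
            if len(fields) < 2:
                raise PairFormatError(
                    f"{path.name}:{lineno}: expected 2 whitespace-separated columns"
                )
            try:
                xs.append(float(fields[0]))
                ys.append(float(fields[1]))
            except ValueError as exc:
                raise PairFormatError(f"{path.name}:{lineno}: {exc}") from None
    if len(xs) < MIN_PAIR_ROWS:
        raise PairFormatError(
            f"{path.name}: needs at least {MIN_PAIR_ROWS} rows, found {len(xs)}"
        )
    return ObservedPair(
        x=np.asarray(xs),
        y=np.asarray(ys),
        name=name if name is not None else path.stem,
        truth=truth,
        weight=weight,
    )


def write_pair_file(path, pair: ObservedPair) -> None:
    """Write a pair as plain two-column text (inverse of :func:`read_pair_file`)."""
    np.savetxt(path, np.column_stack([pair.x, pair.y]), fmt="%.10g")


def read_meta(path) -> list[PairFileRecord]:
    """Parse a metadata file: rows of
    ``pair-id cause-start cause-end effect-start effect-end weight``.

    Cause/effect spans wider than one column mark multivariate pairs and are
    rejected.
    """
    path = Path(path)
    records: list[PairFileRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6:
                raise PairFormatError(
                    f"{path.name}:{lineno}: expected 6 fields, found {len(fields)}"
                )
            name = fields[0]
            try:
                c0, c1, e0, e1 = (int(v) for v in fields[1:5])
                weight = float(fields[5])
            except ValueError as exc:
                raise PairFormatError(f"{path.name}:{lineno}: {exc}") from None
            if c0 != c1 or e0 != e1:
                raise PairFormatError(
                    f"{path.name}:{lineno}: multicolumn cause/effect span; "
                    "multivariate pairs are not supported"
                )
            if {c0, e0} != {1, 2}:
                raise PairFormatError(
                    f"{path.name}:{lineno}: cause/effect columns must be 1 and 2"
                )
            records.append(
                PairFileRecord(name=name, cause_column=c0, weight=weight, path=path.parent)
            )
    return records


@dataclass(frozen=True)
class BenchRow:
    """Per-dataset benchmark outcome."""

    name: str
    decision: Direction
    confidence: float
    truth: Direction
    weight: float
    family: str = ""
    note: str = ""


def weighted_accuracy(rows: Sequence[BenchRow], force_decisions: bool = True) -> float:
    """Weight-averaged fraction of correct direction decisions.

    ``force_decisions=True`` counts no-decision rows as incorrect (a forced
    decision protocol); ``False`` excludes them from both sums.
    """
    num = 0.0
    den = 0.0
    for row in rows:
        if row.decision is Direction.NONE and not force_decisions:
            continue
        den += row.weight
        if row.decision is not Direction.NONE and row.decision is row.truth:
            num += row.weight
    if den <= 0:
        raise ConfigurationError("total weight of scored rows is zero")
    return num / den


def decision_rate_curve(
    rows: Sequence[BenchRow],
    rates: Sequence[float] = tuple(r / 10 for r in range(1, 11)),
    force_decisions: bool = True,
) -> list[tuple[float, float]]:
    """Accuracy when only the most confident fraction of datasets is decided.

    For each rate r the ceil(r * M) rows of highest confidence are kept
    (ties broken by dataset order) and the weighted accuracy is computed on
    that subset.
    """
    m = len(rows)
    if m == 0:
        raise ConfigurationError("no rows")
    # stable sort on negated confidence keeps dataset order within ties
    order = np.argsort([-row.confidence for row in rows], kind="stable")
    curve = []
    for r in rates:
        k = min(max(math.ceil(r * m), 1), m)
        kept = [rows[i] for i in order[:k]]
        curve.append((float(r), weighted_accuracy(kept, force_decisions)))
    return curve


@dataclass(frozen=True)
class BenchmarkResult:
    """Suite-level outcome: per-dataset rows, weighted accuracy and the curve."""

    rows: tuple[BenchRow, ...]
    weighted_accuracy: float
    curve: tuple[tuple[float, float], ...]
    force_decisions: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [r.name for r in self.rows],
                "decision": [r.decision.value for r in self.rows],
                "confidence": [r.confidence for r in self.rows],
                "truth": [r.truth.value for r in self.rows],
                "weight": [r.weight for r in self.rows],
                "family": [r.family for r in self.rows],
                "note": [r.note for r in self.rows],
            }
        )


def run_benchmark(
    suite: Sequence[ObservedPair],
    candidates: Sequence[FamilySpec],
    protocol: RunProtocol,
    density_filter: DensityFilterSpec | None = None,
    scaling: str = "minmax",
    force_decisions: bool = True,
    rates: Sequence[float] = tuple(r / 10 for r in range(1, 11)),
) -> BenchmarkResult:
    """Run the full decision procedure on every pair of a suite.

    Per-pair failures (degenerate data, fit failures) are recorded as
    no-decision rows with a reason instead of aborting the suite.
    """
    if not suite:
        raise ConfigurationError("benchmark suite is empty")
    if not candidates:
        raise ConfigurationError("candidate family list is empty")
    rows: list[BenchRow] = []
    for pair in suite:
        try:
            working = preprocess_pair(pair, scaling, density_filter)
            best = None
            best_score = np.inf
            for cand in candidates:
                errs = directional_errors(
                    working, cand, _effective_protocol(protocol, cand)
                )
                score = errs.mean_y_given_x + errs.mean_x_given_y
                if score < best_score:
                    best, best_score = (cand, errs), score
            family, errs = best
            d = decide(errs)
            rows.append(
                BenchRow(
                    name=pair.name,
                    decision=d.direction,
                    confidence=d.confidence,
                    truth=pair.truth,
                    weight=pair.weight,
                    family=family.label,
                )
            )
        except Exception as exc:  # noqa: BLE001 - suite must not abort
            rows.append(
                BenchRow(
                    name=pair.name,
                    decision=Direction.NONE,
                    confidence=0.0,
                    truth=pair.truth,
                    weight=pair.weight,
                    note=f"{type(exc).__name__}: {exc}",
                )
            )
    acc = weighted_accuracy(rows, force_decisions)
    curve = tuple(decision_rate_curve(rows, rates, force_decisions))
    return BenchmarkResult(
        rows=tuple(rows),
        weighted_accuracy=acc,
        curve=curve,
        force_decisions=force_decisions,
    )
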