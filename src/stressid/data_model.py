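"""Core data types shared across the package.

A cohort is a :class:`Dataset`: one row per athlete, one numeric column per
stress factor.  Factors come in three blocks of four — ``A1..A4`` (physical
condition), ``B1..B4`` (competition state), ``C1..C4`` (cognitive state) —
scored on a nominal ``[0, 10]`` scale.  Clustering results are expressed as a
:class:`Partition` over sample ids.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_FACTOR_NAMES",
    "FACTOR_BLOCKS",
    "DEFAULT_CLASS_CODES",
    "AnxietyClass",
    "RiskLevel",
    "Sample",
    "Dataset",
    "Partition",
    "load_dataset",
    "write_dataset",
    "validate_scores",
]

#: Canonical factor labels, block by block.
DEFAULT_FACTOR_NAMES: tuple[str, ...] = (
    "A1", "A2", "A3", "A4",
    "B1", "B2", "B3", "B4",
    "C1", "C2", "C3", "C4",
)


class AnxietyClass(enum.Enum):
    """The three stress-source categories."""

    PHYSICAL = "physical"
    COMPETITION = "competition"
    COGNITIVE = "cognitive"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Factor-name prefix associated with each anxiety class.
FACTOR_BLOCKS: dict[AnxietyClass, str] = {
    AnxietyClass.PHYSICAL: "A",
    AnxietyClass.COMPETITION: "B",
    AnxietyClass.COGNITIVE: "C",
}

#: Default integer target code per class.  Only the physical code (3) is
#: fixed by convention; the others are configurable on the network.
DEFAULT_CLASS_CODES: dict[AnxietyClass, int] = {
    AnxietyClass.COMPETITION: 1,
    AnxietyClass.COGNITIVE: 2,
    AnxietyClass.PHYSICAL: 3,
}


class RiskLevel(enum.IntEnum):
    """Discretized network output: low / medium / high anxiety risk."""

    LOW = 1
    MEDIUM = 2
    HIGH = 3


@dataclass(frozen=True)
class Sample:
    """One athlete: an opaque id plus a vector of factor scores."""

    id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError(f"sample {self.id!r}: values must be 1-D")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"sample {self.id!r}: non-finite score")
        object.__setattr__(self, "values", values)


class Dataset:
    """An ordered collection of equally sized samples.

    Parameters
    ----------
    ids:
        Unique sample labels, one per row.
    values:
        ``(n, d)`` float matrix of scores; all entries must be finite.
    factor_names:
        ``d`` column labels.  Defaults to ``A1..C4`` when ``d == 12``,
        otherwise ``F1..Fd``.
    """

    def __init__(
        self,
        ids: Sequence[str],
        values: np.ndarray,
        factor_names: Sequence[str] | None = None,
    ) -> None:
        values = np.atleast_2d(np.asarray(values, dtype=float))
        ids = [str(i) for i in ids]
        if values.shape[0] != len(ids):
            raise ValueError(
                f"{len(ids)} ids but {values.shape[0]} score rows"
            )
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        if not np.all(np.isfinite(values)):
            raise ValueError("dataset contains non-finite scores")
        if factor_names is None:
            if values.shape[1] == len(DEFAULT_FACTOR_NAMES):
                factor_names = DEFAULT_FACTOR_NAMES
            else:
                factor_names = tuple(f"F{i+1}" for i in range(values.shape[1]))
        factor_names = tuple(str(f) for f in factor_names)
        if len(factor_names) != values.shape[1]:
            raise ValueError(
                f"{len(factor_names)} factor names for {values.shape[1]} columns"
            )
        self.ids: tuple[str, ...] = tuple(ids)
        self.values: np.ndarray = values
        self.factor_names: tuple[str, ...] = factor_names
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    # -- basic introspection -------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Dataset(n={self.n}, d={self.d})"

    def sample(self, sid: str) -> Sample:
        return Sample(sid, self.values[self._index[sid]].copy())

    def __iter__(self) -> Iterable[Sample]:
        for sid in self.ids:
            yield self.sample(sid)

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.factor_names.index(name)
        except ValueError:
            raise KeyError(f"unknown factor {name!r}") from None
        return self.values[:, j]

    def subset(self, ids: Iterable[str]) -> "Dataset":
        """Row subset, preserving this dataset's row order."""
        wanted = set(ids)
        missing = wanted - set(self.ids)
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)}")
        keep = [i for i, sid in enumerate(self.ids) if sid in wanted]
        return Dataset(
            [self.ids[i] for i in keep], self.values[keep], self.factor_names
        )

    def take(self, indices: Sequence[int]) -> "Dataset":
        """Row subset by positional indices (order as given)."""
        indices = list(indices)
        return Dataset(
            [self.ids[i] for i in indices],
            self.values[indices],
            self.factor_names,
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.values, columns=list(self.factor_names), index=list(self.ids)
        )
        frame.index.name = "id"
        return frame


@dataclass(frozen=True)
class Partition:
    """A disjoint cover of a dataset's sample ids.

    Invariants (checked on construction where possible):

    * no cluster is empty,
    * clusters are pairwise disjoint.

    Covering a specific dataset is checked by :meth:`validate_against`.
    """

    clusters: tuple[frozenset[str], ...]

    def __init__(self, clusters: Iterable[Iterable[str]]) -> None:
        sets = tuple(frozenset(str(i) for i in c) for c in clusters)
        if any(len(c) == 0 for c in sets):
            raise ValueError("empty cluster in partition")
        total = sum(len(c) for c in sets)
        union = frozenset().union(*sets) if sets else frozenset()
        if total != len(union):
            raise ValueError("clusters are not pairwise disjoint")
        object.__setattr__(self, "clusters", sets)

    @property
    def k(self) -> int:
        return len(self.clusters)

    def __len__(self) -> int:
        return len(self.clusters)

    def member_ids(self) -> frozenset[str]:
        if not self.clusters:
            return frozenset()
        return frozenset().union(*self.clusters)

    def validate_against(self, ds: Dataset) -> None:
        """Raise unless this partition exactly covers ``ds``."""
        got, want = self.member_ids(), frozenset(ds.ids)
        if got != want:
            raise ValueError(
                "partition does not cover the dataset: "
                f"missing={sorted(want - got)[:5]} extra={sorted(got - want)[:5]}"
            )

    def labels_for(self, ds: Dataset) -> np.ndarray:
        """Integer cluster label per dataset row (clusters numbered by first
        appearance in dataset order)."""
        self.validate_against(ds)
        by_id: dict[str, int] = {}
        order: dict[int, int] = {}
        for ci, cluster in enumerate(self.clusters):
            for sid in cluster:
                by_id[sid] = ci
        labels = np.empty(ds.n, dtype=int)
        for row, sid in enumerate(ds.ids):
            ci = by_id[sid]
            if ci not in order:
                order[ci] = len(order)
            labels[row] = order[ci]
        return labels

    def to_frame(self, ds: Dataset) -> pd.DataFrame:
        labels = self.labels_for(ds)
        return pd.DataFrame({"id": list(ds.ids), "cluster": labels})

    def write_csv(self, ds: Dataset, path: str | Path) -> None:
        self.to_frame(ds).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------

def load_dataset(path: str | Path) -> Dataset:
    """Read a cohort CSV: first column sample id, remaining columns numeric.

    Raises a descriptive :class:`ValueError` for empty files, ragged rows,
    non-numeric cells or duplicate ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty dataset") from None
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV ({exc})") from None
    if frame.shape[0] == 0 or frame.shape[1] < 2:
        raise ValueError(f"{path}: empty dataset")
    id_col = frame.columns[0]
    ids = frame[id_col].tolist()
    numeric = {}
    for col in frame.columns[1:]:
        try:
            numeric[col] = pd.to_numeric(frame[col], errors="raise")
        except (ValueError, TypeError):
            bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()]
            raise ValueError(
                f"{path}: non-numeric value {bad.iloc[0]!r} in column {col!r}"
            ) from None
    values = np.column_stack([numeric[c].to_numpy(dtype=float) for c in frame.columns[1:]])
    return Dataset(ids, values, factor_names=list(frame.columns[1:]))


def write_dataset(ds: Dataset, path: str | Path) -> None:
    """Write a cohort CSV readable by :func:`load_dataset` (full precision)."""
    ds.to_frame().to_csv(path)


def validate_scores(
    ds: Dataset, lo: float = 0.0, hi: float = 10.0
) -> list[tuple[str, str, float]]:
    """Return ``(sample id, factor, value)`` for every out-of-range score.

    An empty list means every score lies in ``[lo, hi]``.  Out-of-range
    scores are reported, not rejected: the downstream algorithms do not
    require the nominal scale.
    """
    if not lo < hi:
        raise ValueError(f"degenerate range: lo={lo} hi={hi}")
    violations: list[tuple[str, str, float]] = []
    rows, cols = np.nonzero((ds.values < lo) | (ds.values > hi))
    for r, c in zip(rows.tolist(), cols.tolist()):
        violations.append((ds.ids[r], ds.factor_names[c], float(ds.values[r, c])))
    return violations
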