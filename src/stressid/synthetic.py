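"""Synthetic athlete cohorts and the bundled reference tables.

The generator draws block-structured Gaussian cohorts: each athlete belongs
to one anxiety class and scores high (``elevated_mean``) on that class's
four factors and low (``baseline_mean``) on the other eight, with
independent per-factor noise, clipped to the ``[0, 10]`` scale.

Two small fixtures are embedded verbatim: a 10-athlete, 12-factor score
table and the matching per-athlete class assignments from two independent
analyses (model vs manual), which disagree on exactly one athlete (M10).
The last row of the score table is stored under the id ``M10``; the source
printed a duplicate ``M1`` label there, which context shows is a typo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import AnxietyClass, Dataset

__all__ = [
    "GeneratorConfig",
    "generate_cohort",
    "table3_fixture",
    "table4_fixture",
]

#: Class order used for cohort layout and proportions.
CLASS_ORDER: tuple[AnxietyClass, ...] = (
    AnxietyClass.PHYSICAL,
    AnxietyClass.COMPETITION,
    AnxietyClass.COGNITIVE,
)

#: Factor columns elevated for each class (canonical A/B/C blocks).
_BLOCK_COLUMNS: dict[AnxietyClass, slice] = {
    AnxietyClass.PHYSICAL: slice(0, 4),
    AnxietyClass.COMPETITION: slice(4, 8),
    AnxietyClass.COGNITIVE: slice(8, 12),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generator parameters.

    ``proportions`` are per class in the order physical, competition,
    cognitive (default 0.30/0.40/0.30, the reference cohort's manual
    split).  ``spread`` defaults to 0.7: large enough to overlap blocks,
    small enough that every factor's marginal stays bimodal and the
    planted structure is recoverable by histogram-valley splitting.
    """

    n: int = 500
    proportions: tuple[float, float, float] = (0.30, 0.40, 0.30)
    elevated_mean: float = 7.5
    baseline_mean: float = 4.5
    spread: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if len(self.proportions) != 3 or any(p < 0 for p in self.proportions):
            raise ValueError("proportions must be three non-negative fractions")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        for name in ("elevated_mean", "baseline_mean"):
            if not 0 <= getattr(self, name) <= 10:
                raise ValueError(f"{name} must lie in [0, 10]")
        if self.spread <= 0:
            raise ValueError("spread must be positive")

    def class_counts(self) -> dict[AnxietyClass, int]:
        counts = [round(self.n * p) for p in self.proportions]
        # rounding may drop/add a sample; charge the difference to the
        # largest class so counts always sum to n
        diff = self.n - sum(counts)
        counts[int(np.argmax(counts))] += diff
        return dict(zip(CLASS_ORDER, counts))


def generate_cohort(
    config: GeneratorConfig | None = None,
) -> tuple[Dataset, list[AnxietyClass]]:
    """Draw a cohort and its true class labels, deterministically per seed.

    Athletes are laid out class-by-class (physical, competition, cognitive);
    every score is clipped to ``[0, 10]``.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    counts = config.class_counts()
    n = config.n
    X = np.empty((n, 12))
    labels: list[AnxietyClass] = []
    row = 0
    for cls in CLASS_ORDER:
        c = counts[cls]
        block = rng.normal(config.baseline_mean, config.spread, size=(c, 12))
        block[:, _BLOCK_COLUMNS[cls]] = rng.normal(
            config.elevated_mean, config.spread, size=(c, 4)
        )
        X[row:row + c] = block
        labels.extend([cls] * c)
        row += c
    np.clip(X, 0.0, 10.0, out=X)
    width = max(3, len(str(max(n, 1))))
    ids = [f"S{i+1:0{width}d}" for i in range(n)]
    return Dataset(ids, X.reshape(n, 12)), labels


# ---------------------------------------------------------------------------
# embedded reference tables
# ---------------------------------------------------------------------------

# 10 athletes x 12 factors, columns in the published order.
_SCORE_COLUMNS = (
    "A1", "B1", "C1", "A2", "B2", "C2", "A3", "B3", "C3", "A4", "B4", "C4",
)
_SCORE_ROWS: tuple[tuple[str, tuple[float, ...]], ...] = (
    ("M1", (7.44, 4.56, 4.48, 7.98, 3.45, 7.89, 8.29, 4.55, 3.72, 7.31, 5.61, 8.56)),
    ("M2", (3.15, 7.38, 7.26, 5.01, 6.38, 5.06, 3.16, 8.26, 8.08, 4.61, 5.46, 7.38)),
    ("M3", (4.61, 3.80, 3.86, 8.93, 3.60, 8.43, 6.63, 5.90, 6.10, 6.53, 6.53, 3.80)),
    ("M4", (7.05, 4.55, 8.78, 4.44, 4.43, 6.61, 7.84, 7.34, 5.88, 4.92, 8.81, 8.55)),
    ("M5", (3.19, 4.94, 3.15, 6.27, 7.07, 5.65, 3.13, 8.98, 8.36, 6.53, 7.68, 4.94)),
    ("M6", (8.42, 8.29, 4.55, 3.72, 7.31, 5.61, 4.56, 4.48, 7.98, 3.45, 7.89, 8.29)),
    ("M7", (8.05, 3.16, 8.26, 8.08, 4.61, 5.46, 7.38, 7.26, 5.01, 6.38, 5.06, 8.16)),
    ("M8", (8.68, 6.63, 5.90, 6.10, 6.53, 6.53, 3.80, 3.86, 8.93, 3.60, 8.43, 6.63)),
    ("M9", (8.77, 7.84, 7.34, 5.88, 4.92, 8.81, 4.55, 8.78, 4.44, 4.43, 6.61, 7.84)),
    ("M10", (7.87, 3.13, 8.98, 8.36, 6.53, 7.68, 4.94, 3.15, 6.27, 7.07, 5.65, 8.13)),
)

#: Published per-column averages accompanying the score table.  Ten of the
#: twelve reproduce as two-decimal truncations of the column means; the C3
#: and C4 entries do not match any mean of their columns (recomputed 6.47
#: and 7.22) and are carried here only as printed.
PUBLISHED_COLUMN_AVERAGES: dict[str, float] = dict(
    zip(
        _SCORE_COLUMNS,
        (6.72, 5.42, 6.25, 6.47, 5.48, 6.77, 5.42, 6.25, 7.47, 5.48, 6.77, 8.42),
    )
)

#: Columns of the published average row whose values are verifiable from
#: the score table itself.
VERIFIABLE_AVERAGE_COLUMNS: tuple[str, ...] = tuple(
    c for c in _SCORE_COLUMNS if c not in ("C3", "C4")
)

_ASSIGNMENTS: tuple[tuple[str, AnxietyClass, AnxietyClass], ...] = (
    # (athlete, model analysis, manual analysis)
    ("M1", AnxietyClass.COMPETITION, AnxietyClass.COMPETITION),
    ("M2", AnxietyClass.COMPETITION, AnxietyClass.COMPETITION),
    ("M3", AnxietyClass.PHYSICAL, AnxietyClass.PHYSICAL),
    ("M4", AnxietyClass.COGNITIVE, AnxietyClass.COGNITIVE),
    ("M5", AnxietyClass.COMPETITION, AnxietyClass.COMPETITION),
    ("M6", AnxietyClass.COGNITIVE, AnxietyClass.COGNITIVE),
    ("M7", AnxietyClass.PHYSICAL, AnxietyClass.PHYSICAL),
    ("M8", AnxietyClass.PHYSICAL, AnxietyClass.PHYSICAL),
    ("M9", AnxietyClass.COMPETITION, AnxietyClass.COMPETITION),
    ("M10", AnxietyClass.COMPETITION, AnxietyClass.COGNITIVE),
)


def table3_fixture() -> Dataset:
    """The bundled 10-athlete, 12-factor score table, values as published."""
    ids = [row[0] for row in _SCORE_ROWS]
    values = np.array([row[1] for row in _SCORE_ROWS])
    return Dataset(ids, values, factor_names=_SCORE_COLUMNS)


def table4_fixture() -> tuple[dict[str, AnxietyClass], dict[str, AnxietyClass]]:
    """Per-athlete class assignments: ``(model_labels, manual_labels)``.

    The two columns agree on every athlete except M10.
    """
    model = {sid: rbf for sid, rbf, _ in _ASSIGNMENTS}
    manual = {sid: man for sid, _, man in _ASSIGNMENTS}
    return model, manual
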