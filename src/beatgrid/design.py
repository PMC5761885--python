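"""Fixed-effects design for the difficulty-rating regression.

Four predictors enter the model: number of missing beats (0–3), off-beat
accent category (few/some/many), accent type (temporal/intensity) and years
of musical training (continuous, centred).  Because the condition structure
is not factorial (zero missing beats occurs only with the "few" category,
and in the tighter stimulus set "many" occurs only with two missing beats),
the full four-way interaction basis is rank deficient; estimable columns are
selected by greedy rank-revealing elimination that prefers lower-order
terms, and each term's retained degrees of freedom are reported.

Codings
-------
* missing beats — a simple contrast (level 0 against the mean of levels
  1–3) plus orthonormal linear and quadratic polynomials over levels 1–3
  (zero for level 0): 3 columns;
* off-beat category — orthonormal linear and quadratic polynomials over
  (few, some, many): 2 columns;
* accent type — sum coding (+1 temporal, −1 intensity): 1 column;
* training — years centred at the sample mean (or a supplied centre).

The full expansion has 7 main-effect columns and 47 columns in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = ["ContrastScheme", "DesignInfo", "build_design", "FACTORS", "TERMS"]

FACTORS = ("missing_beats", "off_beat", "type", "training")

#: the 15 testable terms, lowest order first
TERMS: tuple[tuple[str, ...], ...] = tuple(
    term for k in (1, 2, 3, 4) for term in combinations(FACTORS, k))


def term_name(term: tuple[str, ...]) -> str:
    return ":".join(term)


_SQRT2, _SQRT6 = np.sqrt(2.0), np.sqrt(6.0)
OFF_CATEGORY_LEVELS = ("few", "some", "many")


@dataclass(frozen=True)
class ContrastScheme:
    """Contrast coding options; the defaults match the analysis above."""

    training_center: float | None = None  # None -> sample mean
    type_reference: str = "temporal"      # level coded +1 under sum coding


def _factor_columns(df: pd.DataFrame, scheme: ContrastScheme
                    ) -> dict[str, dict[str, np.ndarray]]:
    mb = df["missing_beats"].to_numpy()
    if not np.isin(mb, (0, 1, 2, 3)).all():
        raise ValueError("missing_beats must be in 0..3")
    cat = df["off_beat_category"].astype(str).to_numpy()
    if not np.isin(cat, OFF_CATEGORY_LEVELS).all():
        raise ValueError(f"off_beat_category must be one of {OFF_CATEGORY_LEVELS}")
    typ = df["accent_type"].astype(str).to_numpy()
    train = df["training_years"].to_numpy(dtype=float)

    # simple contrast: level 0 vs the mean of levels 1-3 (sum-to-zero scale)
    mb_simple = np.where(mb == 0, -0.75, 0.25)
    lin = {1: -1 / _SQRT2, 2: 0.0, 3: 1 / _SQRT2}
    quad = {1: 1 / _SQRT6, 2: -2 / _SQRT6, 3: 1 / _SQRT6}
    mb_lin = np.where(mb == 0, 0.0, np.vectorize(lambda m: lin.get(m, 0.0))(mb))
    mb_quad = np.where(mb == 0, 0.0, np.vectorize(lambda m: quad.get(m, 0.0))(mb))

    cat_idx = np.array([OFF_CATEGORY_LEVELS.index(c) for c in cat])
    off_lin = np.array([-1 / _SQRT2, 0.0, 1 / _SQRT2])[cat_idx]
    off_quad = np.array([1 / _SQRT6, -2 / _SQRT6, 1 / _SQRT6])[cat_idx]

    type_sum = np.where(typ == scheme.type_reference, 1.0, -1.0)

    center = scheme.training_center
    if center is None:
        center = float(train.mean())
    training_c = train - center

    return {
        "missing_beats": {"mb_simple": mb_simple, "mb_lin": mb_lin, "mb_quad": mb_quad},
        "off_beat": {"off_lin": off_lin, "off_quad": off_quad},
        "type": {"type": type_sum},
        "training": {"training": training_c},
    }


@dataclass
class DesignInfo:
    """A reduced model frame and the bookkeeping to interpret it."""

    matrix: np.ndarray                        # n x p_retained
    column_names: list[str]
    column_terms: list[str]                   # term name per retained column
    retained_df: dict[str, int]               # term name -> retained columns
    dropped_columns: list[str]
    training_center: float
    scheme: ContrastScheme = field(default_factory=ContrastScheme)

    def term_columns(self, term: str) -> np.ndarray:
        """Indices of the retained columns belonging to one term."""
        idx = [i for i, t in enumerate(self.column_terms) if t == term]
        if not idx:
            raise KeyError(f"term {term!r} has no retained columns")
        return np.asarray(idx)

    def column_index(self, name: str) -> int:
        try:
            return self.column_names.index(name)
        except ValueError:
            raise KeyError(f"column {name!r} was dropped as inestimable or does "
                           "not exist") from None


def expand_columns(records: pd.DataFrame, scheme: ContrastScheme = ContrastScheme()
                   ) -> tuple[list[str], list[str], list[np.ndarray]]:
    """The full 47-column interaction basis, before any rank reduction.

    Returns parallel lists of column names, owning-term names and value
    vectors.  Used both by :func:`build_design` and to evaluate the design
    at new prediction points.
    """
    base = _factor_columns(records, scheme)
    names: list[str] = []
    terms_of: list[str] = []
    cols: list[np.ndarray] = []
    for term in TERMS:
        parts = [base[f] for f in term]

        def expand(i: int, name: str, vec: np.ndarray) -> None:
            if i == len(parts):
                names.append(name)
                terms_of.append(term_name(term))
                cols.append(vec)
                return
            for cname, cvec in parts[i].items():
                expand(i + 1, f"{name}:{cname}" if name else cname, vec * cvec)

        expand(0, "", np.ones(len(records)))
    return names, terms_of, cols


def build_design(records: pd.DataFrame,
                 scheme: ContrastScheme = ContrastScheme(),
                 rank_tol: float = 1e-8) -> DesignInfo:
    """Expand the full four-way interaction basis and keep estimable columns.

    Columns are visited lowest-order term first, in a fixed factor order, and
    kept greedily whenever they add rank (pivoted-QR style, tolerance
    relative to each column's norm).  On a full factorial design all 47
    columns survive; on the observed non-factorial condition structures the
    dropped columns are exactly the aliased interaction directions, so each
    term's retained count is its likelihood-ratio df.
    """
    for col in ("missing_beats", "off_beat_category", "accent_type", "training_years"):
        if col not in records.columns:
            raise ValueError(f"records lack required column {col!r}")
        if records[col].nunique() < 2 and col != "off_beat_category":
            raise ValueError(f"factor {col!r} has a single observed level")
    center = scheme.training_center
    if center is None:
        center = float(records["training_years"].mean())
    names, terms_of, cols = expand_columns(records, scheme)

    # greedy rank-revealing selection via a running orthonormal basis;
    # the basis is seeded with the constant vector because the cumulative
    # model's thresholds play the intercept's role
    kept_idx: list[int] = []
    ones = np.ones(len(records))
    basis: list[np.ndarray] = [ones / np.linalg.norm(ones)]
    dropped: list[str] = []
    for i, v in enumerate(cols):
        norm0 = np.linalg.norm(v)
        r = v.astype(float).copy()
        for q in basis:
            r -= (q @ r) * q
        if np.linalg.norm(r) > rank_tol * max(norm0, 1.0):
            basis.append(r / np.linalg.norm(r))
            kept_idx.append(i)
        else:
            dropped.append(names[i])

    retained: dict[str, int] = {term_name(t): 0 for t in TERMS}
    for i in kept_idx:
        retained[terms_of[i]] += 1
    return DesignInfo(
        matrix=np.column_stack([cols[i] for i in kept_idx]),
        column_names=[names[i] for i in kept_idx],
        column_terms=[terms_of[i] for i in kept_idx],
        retained_df=retained,
        dropped_columns=dropped,
        training_center=center,
        scheme=scheme,
    )
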