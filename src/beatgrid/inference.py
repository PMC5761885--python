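"""Term tests, effect sizes and planned contrasts for the fitted model.

Each of the 15 model terms (4 main effects, 6 two-way, 4 three-way and the
four-way interaction) is tested by a likelihood-ratio comparison: the full
model against a model with that term's retained columns removed and all
other columns kept.  Effect sizes follow Friedman's chi-square convention —
``chi2 / N`` for one degree of freedom and ``chi2 / (chi2 + N)`` otherwise —
and planned contrasts are reported as Wald z with the companion effect size
``r = z / sqrt(N)``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .clmm import ClmmFit, ConvergenceError, fit_clmm
from .design import TERMS, term_name

__all__ = ["eta_squared", "lr_term_tests", "contrast_wald", "condition_estimates"]


def eta_squared(chi2: float, df: int, n: int) -> float:
    """Friedman-style effect size from a likelihood-ratio chi-square.

    ``chi2 / n`` for one degree of freedom, ``chi2 / (chi2 + n)`` for more.
    A (numerically) negative chi-square is clamped to zero with a warning.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if df < 1:
        raise ValueError("df must be >= 1")
    if chi2 < 0:
        warnings.warn(f"negative likelihood ratio ({chi2:.4g}) clamped to 0",
                      RuntimeWarning, stacklevel=2)
        chi2 = 0.0
    return chi2 / n if df == 1 else chi2 / (chi2 + n)


def lr_term_tests(records: pd.DataFrame, full_fit: ClmmFit,
                  terms: list[str] | None = None) -> pd.DataFrame:
    """Drop-one-term likelihood-ratio tests against the full model.

    Every reduced model keeps all columns except the tested term's retained
    columns and is warm-started from the full fit.  A reduced model that
    fails to converge is flagged (chi2/p set to NaN), never fabricated.
    """
    design = full_fit.design
    if design is None:
        raise ValueError("full fit must carry its design (fit via records)")
    if terms is None:
        terms = [term_name(t) for t in TERMS]
    N = full_fit.n_obs
    rows = []
    for term in terms:
        cols = design.term_columns(term)
        keep = np.setdiff1d(np.arange(design.matrix.shape[1]), cols)
        names = [design.column_names[i] for i in keep]
        spec = full_fit.spec
        try:
            red = fit_clmm(
                records, spec=spec,
                X=design.matrix[:, keep], column_names=names,
                start={"beta": full_fit.beta[keep], "theta": full_fit.theta,
                       "sigma_b": full_fit.sigma_b},
                compute_vcov=False)
            chi2 = 2.0 * (full_fit.loglik - red.loglik)
            df = int(cols.size)
            p = float(stats.chi2.sf(max(chi2, 0.0), df))
            eta2 = eta_squared(max(chi2, 0.0), df, N)
            rows.append({"term": term, "chi2": chi2, "df": df,
                         "eta2": eta2, "p": p, "converged": True})
        except ConvergenceError as err:
            rows.append({"term": term, "chi2": np.nan, "df": int(cols.size),
                         "eta2": np.nan, "p": np.nan, "converged": False,
                         "note": str(err)})
    return pd.DataFrame(rows)


def contrast_wald(fit: ClmmFit, column: str) -> tuple[float, float, float]:
    """Wald test of one retained contrast column: returns ``(z, p, r)``.

    ``z`` is estimate over standard error, ``p`` two-sided normal, and
    ``r = z / sqrt(N)`` with N the number of ratings.
    """
    if fit.design is not None:
        idx = fit.design.column_index(column)
    else:
        if column not in fit.column_names:
            raise KeyError(f"column {column!r} not in fit")
        idx = fit.column_names.index(column)
    est = fit.beta[idx]
    se = fit.se_beta[idx]
    if est == 0.0:
        return 0.0, 1.0, 0.0
    z = float(est / se)
    p = float(2.0 * stats.norm.sf(abs(z)))
    r = float(z / np.sqrt(fit.n_obs))
    return z, p, r


def condition_estimates(fit: ClmmFit, records: pd.DataFrame,
                        conditions: list[tuple[int, str]] | None = None,
                        accent_types: tuple[str, ...] = ("temporal", "intensity"),
                        training_levels: dict[str, float] | None = None) -> pd.DataFrame:
    """Latent-scale difficulty per condition cell with delta-method SEs.

    The estimate for a cell is its linear predictor ``x' beta`` (random
    effect at zero): negative values mean easier, positive harder to find
    the beat.  ``training_levels`` maps display-group labels to years of
    training; the default is the novice/expert split at two years, realised
    as the group means observed in ``records``.
    """
    design = fit.design
    if design is None:
        raise ValueError("fit must carry a design built from records")
    if conditions is None:
        conditions = sorted(
            set(zip(records["missing_beats"], records["off_beat_category"])))
    if training_levels is None:
        tr = records["training_years"]
        novice = tr[tr < 2.0]
        expert = tr[tr > 2.0]
        training_levels = {
            "novice": float(novice.mean()) if len(novice) else 0.0,
            "expert": float(expert.mean()) if len(expert) else float(tr.mean()),
        }
    tmin, tmax = records["training_years"].min(), records["training_years"].max()
    from .design import ContrastScheme, expand_columns

    scheme = ContrastScheme(training_center=design.training_center,
                            type_reference=design.scheme.type_reference)
    rows = []
    for mb, cat in conditions:
        for typ in accent_types:
            for label, years in training_levels.items():
                if not tmin <= years <= tmax:
                    warnings.warn(
                        f"training level {years} outside observed range "
                        f"[{tmin}, {tmax}]", RuntimeWarning, stacklevel=2)
                cell = pd.DataFrame([{
                    "missing_beats": mb, "off_beat_category": cat,
                    "accent_type": typ, "training_years": years,
                }])
                names, _, cols = expand_columns(cell, scheme)
                lookup = {n: c[0] for n, c in zip(names, cols)}
                x = np.array([lookup[name] for name in design.column_names])
                est = float(x @ fit.beta)
                se = float(np.sqrt(x @ fit.vcov[: x.size, : x.size] @ x))
                rows.append({
                    "missing_beats": mb, "off_beat_category": cat,
                    "accent_type": typ, "training_group": label,
                    "training_years": years, "estimate": est, "se": se,
                })
    return pd.DataFrame(rows)
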