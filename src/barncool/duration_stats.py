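"""Linear models for empty-headgate durations across videos and methods.

The observation unit is a section x video x detection-method cell whose
outcome is the mean empty duration (seconds). The model is ordinary
least squares with treatment-coded categorical factors (human rater and
first video as reference levels), optional interactions, and
backward-step elimination at alpha = 0.05: whole factors are dropped one
at a time by a partial F-test, largest p first, with main effects
protected while any interaction containing them remains (hierarchy).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ModelSpec",
    "FitResult",
    "encode_design",
    "fit_ols",
    "fit_model",
    "backward_eliminate",
    "coefficient_table",
]


@dataclass(frozen=True)
class ModelSpec:
    """Model formula: main effects, interactions, references, transform."""

    main_effects: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    references: dict[str, str] = field(default_factory=dict)
    outcome: str = "seconds"
    transform: Literal["identity", "sqrt"] = "identity"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for pair in self.interactions:
            for f in pair:
                if f not in self.main_effects:
                    raise ValueError(
                        f"interaction {pair} references undeclared factor {f!r}")

    @property
    def terms(self) -> tuple[str, ...]:
        return self.main_effects + tuple(f"{a}:{b}" for a, b in self.interactions)

    def protected(self) -> set[str]:
        """Main effects that must stay while an interaction contains them."""
        out: set[str] = set()
        for a, b in self.interactions:
            out.update((a, b))
        return out

    def drop_term(self, term: str) -> "ModelSpec":
        if ":" in term:
            a, b = term.split(":")
            return replace(self, interactions=tuple(
                p for p in self.interactions if p != (a, b)))
        return replace(self, main_effects=tuple(
            m for m in self.main_effects if m != term))


@dataclass(frozen=True)
class FitResult:
    """OLS fit: coefficient table, residual variance, and bookkeeping."""

    table: pd.DataFrame  # index = column names; estimate, std_error, t_value, p_value
    resid_var: float
    n: int
    df_resid: int
    term_map: dict[str, list[str]]
    rss: float

    @property
    def params(self) -> pd.Series:
        return self.table["estimate"]


def _factor_columns(values: pd.Series, factor: str, reference: str
                    ) -> pd.DataFrame:
    levels = sorted(map(str, values.unique()))
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not among levels "
                         f"{levels} of factor {factor!r}")
    cols = {}
    v = values.astype(str)
    for lev in levels:
        if lev == reference:
            continue
        cols[f"{factor}[{lev}]"] = (v == lev).astype(float)
    return pd.DataFrame(cols, index=values.index)


def encode_design(observations: pd.DataFrame, spec: ModelSpec
                  ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Treatment-coded design matrix with intercept and interaction columns.

    Interaction columns are elementwise products of the two factors'
    main-effect columns. Returns the design and a map from model term to
    its column names.
    """
    if len(observations) == 0:
        raise ValueError("need at least one observation")
    X = pd.DataFrame({"Intercept": np.ones(len(observations))},
                     index=observations.index)
    term_map: dict[str, list[str]] = {"Intercept": ["Intercept"]}
    blocks: dict[str, pd.DataFrame] = {}
    for f in spec.main_effects:
        if f not in observations:
            raise ValueError(f"factor {f!r} missing from observations")
        ref = spec.references.get(f, sorted(map(str, observations[f].unique()))[0])
        blk = _factor_columns(observations[f], f, ref)
        blocks[f] = blk
        term_map[f] = list(blk.columns)
        X = pd.concat([X, blk], axis=1)
    for a, b in spec.interactions:
        cols = {}
        for ca in blocks[a].columns:
            for cb in blocks[b].columns:
                cols[f"{ca}:{cb}"] = blocks[a][ca] * blocks[b][cb]
        blk = pd.DataFrame(cols, index=observations.index)
        term_map[f"{a}:{b}"] = list(blk.columns)
        X = pd.concat([X, blk], axis=1)
    return X, term_map


def _transformed_outcome(observations: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    y = observations[spec.outcome].to_numpy(float)
    if spec.transform == "sqrt":
        if np.any(y < 0):
            raise ValueError("sqrt transform requires non-negative outcome")
        return np.sqrt(y)
    return y


def fit_ols(design: pd.DataFrame, outcome: np.ndarray | pd.Series,
            term_map: dict[str, list[str]] | None = None) -> FitResult:
    """Least-squares fit with classical coefficient inference.

    Requires more rows than columns and full column rank; a rank-deficient
    design raises an error naming the collinear columns.
    """
    X = np.asarray(design, float)
    y = np.asarray(outcome, float)
    n, k = X.shape
    if n < k:
        raise ValueError(f"need at least as many rows ({n}) as columns ({k})")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name the offending columns: those whose removal restores rank
        bad = []
        for j, name in enumerate(design.columns):
            Xj = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xj) == rank:
                bad.append(name)
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    res = sm.OLS(y, X).fit()
    table = pd.DataFrame(
        {
            "estimate": res.params,
            "std_error": res.bse,
            "t_value": res.tvalues,
            "p_value": res.pvalues,
        },
        index=list(design.columns),
    )
    if term_map is None:
        term_map = {c: [c] for c in design.columns}
    return FitResult(
        table=table,
        resid_var=float(res.mse_resid),
        n=n,
        df_resid=int(res.df_resid),
        term_map=term_map,
        rss=float(res.ssr),
    )


def fit_model(observations: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Encode and fit in one step."""
    X, term_map = encode_design(observations, spec)
    y = _transformed_outcome(observations, spec)
    return fit_ols(X, y, term_map)


def _partial_f_pvalue(observations: pd.DataFrame, spec: ModelSpec,
                      full: FitResult, term: str) -> float:
    """p-value of dropping all of ``term``'s columns (partial F-test)."""
    reduced = spec.drop_term(term)
    red_fit = fit_model(observations, reduced)
    q = len(full.term_map[term])
    num = (red_fit.rss - full.rss) / q
    den = full.rss / full.df_resid
    if den <= 0:
        return 0.0
    f = num / den
    return float(stats.f.sf(f, q, full.df_resid))


def backward_eliminate(observations: pd.DataFrame, full_spec: ModelSpec
                       ) -> tuple[ModelSpec, FitResult]:
    """Backward-step elimination of whole factors by partial F-test.

    Each round drops the candidate term with the largest p-value above
    alpha (ties broken by term order) and refits; main effects stay while
    any interaction containing them remains; the intercept always stays.
    Stops when every remaining term is protected or significant.
    """
    spec = full_spec
    fit = fit_model(observations, spec)
    while True:
        protected = spec.protected()
        candidates = [t for t in spec.terms if t not in protected]
        if not candidates:
            return spec, fit
        pvals = [(_partial_f_pvalue(observations, spec, fit, t), t)
                 for t in candidates]
        worst_p, worst_t = max(pvals, key=lambda pt: pt[0])
        if worst_p <= spec.alpha:
            return spec, fit
        spec = spec.drop_term(worst_t)
        fit = fit_model(observations, spec)


def coefficient_table(fit: FitResult) -> pd.DataFrame:
    """Publication-style coefficient table (Estimate / Std. Error / T / p)."""
    out = fit.table.copy()
    out.columns = ["Estimate", "Std. Error", "T Value", "Pr(>|t|)"]
    return out
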