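"""Model comparison: scaled chi-square difference tests and BIC ranking.

Two catalog models are nested when one factor partition refines the other
(the coarser model equals the finer one with the correlations between the
split factors fixed at 1).  Nestedness is decided structurally from the
item partitions, never from a hard-coded table.  Nested pairs are compared
with the Satorra-Bentler scaled difference test; non-nested pairs by BIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .catalog import ModelSpec
from .cfa import FitResult


@dataclass(frozen=True)
class ComparisonResult:
    model_a: str
    model_b: str
    relation: str                 # "nested" | "non-nested"
    preferred: str
    TRd: float | None = None      # scaled difference statistic (nested)
    df_diff: int | None = None
    p_value: float | None = None
    delta_bic: float | None = None  # BIC(a) - BIC(b) (non-nested)
    scaled: bool = True           # False when the cd fallback was used


def _refines(fine: ModelSpec, coarse: ModelSpec) -> bool:
    """True if every factor group of `fine` lies inside one group of
    `coarse` (so `coarse` is obtained by merging factors of `fine`)."""
    coarse_groups = list(coarse.factor_partition().values())
    for group in fine.factor_partition().values():
        if not any(group <= cg for cg in coarse_groups):
            return False
    return True


def nesting_relation(spec_a: ModelSpec, spec_b: ModelSpec) -> str:
    """'nested' if one spec's partition refines the other's, else
    'non-nested'; identical partitions raise."""
    if set(spec_a.items) != set(spec_b.items):
        raise ValueError("specs cover different item sets")
    part_a, part_b = spec_a.factor_partition(), spec_b.factor_partition()
    if set(part_a.values()) == set(part_b.values()):
        raise ValueError(
            f"{spec_a.name!r} and {spec_b.name!r} have identical partitions")
    if _refines(spec_a, spec_b) or _refines(spec_b, spec_a):
        return "nested"
    return "non-nested"


def scaled_chisq_difference(fit_coarse: FitResult, fit_fine: FitResult):
    """Satorra-Bentler scaled difference test for a nested pair.

    cd = (df0*c0 - df1*c1) / (df0 - df1); TRd = (T_ml0 - T_ml1) / cd.
    A nonpositive cd triggers a warning and an unscaled fallback.
    """
    df0, df1 = fit_coarse.df, fit_fine.df
    if df0 <= df1:
        raise ValueError("first argument must be the coarser model")
    c0 = fit_coarse.c if fit_coarse.c is not None else 1.0
    c1 = fit_fine.c if fit_fine.c is not None else 1.0
    df_diff = df0 - df1
    cd = (df0 * c0 - df1 * c1) / df_diff
    scaled = True
    if cd <= 0:
        warnings.warn("nonpositive difference-test scaling; falling back to "
                      "the unscaled chi-square difference", stacklevel=2)
        cd = 1.0
        scaled = False
    trd = (fit_coarse.T_ml - fit_fine.T_ml) / cd
    trd = max(trd, 0.0)
    p = float(stats.chi2.sf(trd, df_diff))
    return trd, df_diff, p, scaled


def compare_pair(fit_a: FitResult, fit_b: FitResult,
                 alpha: float = 0.05) -> ComparisonResult:
    """Compare two fitted models with the appropriate test.

    Nested: the finer model is preferred iff the scaled difference test
    rejects; otherwise parsimony favors the coarser model.  Non-nested:
    lower BIC wins.
    """
    relation = nesting_relation(fit_a.spec, fit_b.spec)
    if relation == "nested":
        coarse, fine = (fit_a, fit_b) if fit_a.df > fit_b.df else (fit_b, fit_a)
        trd, dfd, p, scaled = scaled_chisq_difference(coarse, fine)
        preferred = fine.spec.name if p < alpha else coarse.spec.name
        return ComparisonResult(
            model_a=fit_a.spec.name, model_b=fit_b.spec.name,
            relation=relation, preferred=preferred, TRd=trd, df_diff=dfd,
            p_value=p, scaled=scaled)
    if fit_a.bic is None or fit_b.bic is None:
        raise ValueError("BIC required for non-nested comparison")
    dbic = fit_a.bic - fit_b.bic
    preferred = fit_a.spec.name if dbic < 0 else fit_b.spec.name
    return ComparisonResult(
        model_a=fit_a.spec.name, model_b=fit_b.spec.name, relation=relation,
        preferred=preferred, delta_bic=dbic)


@dataclass
class SelectionResult:
    comparisons: list[ComparisonResult]
    wins: dict[str, int]
    preferred: str | None        # None when no model is unbeaten
    ties: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.comparisons])


def select_best(fits, alpha: float = 0.05) -> SelectionResult:
    """All-pairs comparison; the preferred model is the one never beaten.

    Deterministic given the fits.  If no single unbeaten model exists
    (conflicting evidence), `preferred` is None and `ties` lists the
    undominated models.
    """
    fits = list(fits)
    names = [f.spec.name for f in fits]
    beaten: set[str] = set()
    comparisons: list[ComparisonResult] = []
    for i in range(len(fits)):
        for j in range(i + 1, len(fits)):
            try:
                comp = compare_pair(fits[i], fits[j], alpha=alpha)
            except ValueError:
                # identical partitions: no information either way
                continue
            comparisons.append(comp)
            loser = (comp.model_b if comp.preferred == comp.model_a
                     else comp.model_a)
            beaten.add(loser)
    unbeaten = [n for n in names if n not in beaten]
    wins = {n: sum(1 for c in comparisons if c.preferred == n) for n in names}
    if len(unbeaten) == 1:
        return SelectionResult(comparisons, wins, unbeaten[0], [])
    return SelectionResult(comparisons, wins, None, unbeaten)
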