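"""Specific vs non-specific symptom classification under distress control.

The selected factor model is refitted with every item additionally
regressed on the observed psychological-distress total (MIMIC-style, the
covariate orthogonal to the factors).  If an item's loading attenuates
significantly once distress is partialled out, the symptom shares its
variance with general distress and is labeled non-specific; otherwise it
is PTSD-specific.  Attenuation is tested with an Aroian-style z statistic
whose variance carries the third product term, under Holm or fixed
Bonferroni multiplicity control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import ModelSpec
from .cfa import FitResult


def build_combined_model(best: ModelSpec, covariate: str = "K10_total"
                         ) -> ModelSpec:
    """Augment a factor model with an observed distress covariate.

    Adds one observed variable with free variance, a regression path to
    every item, and zero covariance with all factors.
    """
    return best.with_covariate(covariate)


def aroian_z(lambda_before: float, se_before: float,
             lambda_after: float, se_after: float):
    """Aroian-style z test of a loading difference.

    z = (l1 - l2) / sqrt(se1^2 + se2^2 + se1^2 * se2^2); two-sided p from
    the standard normal.  The third (product) term in the variance is the
    Aroian correction; with typical SEs it is tiny but always included.
    """
    if se_before <= 0 or se_after <= 0:
        raise ValueError("standard errors must be positive")
    denom = np.sqrt(se_before**2 + se_after**2 + se_before**2 * se_after**2)
    z = (lambda_before - lambda_after) / denom
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def aroian_product_z(a: float, se_a: float, b: float, se_b: float):
    """Aroian test of an indirect (product) effect a*b.

    z = a*b / sqrt(b^2 se_a^2 + a^2 se_b^2 + se_a^2 se_b^2).  Offered as an
    alternative reading of the attenuation test; not the default.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    denom = np.sqrt(b**2 * se_a**2 + a**2 * se_b**2 + se_a**2 * se_b**2)
    z = a * b / denom
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def adjust_pvalues(p, method: str = "holm", alpha: float = 0.05):
    """Family-wise multiplicity control.

    'holm': step-down thresholds alpha/(m-k+1) on the sorted p-values.
    'bonferroni_fixed': one threshold alpha/m for every test (0.0025 for
    m=20 at alpha=0.05).  Returns a boolean rejection array.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if method == "holm":
        reject, _, _, _ = multipletests(p, alpha=alpha, method="holm")
        return reject
    if method == "bonferroni_fixed":
        return p < alpha / p.size
    raise ValueError(f"unknown method {method!r}")


@dataclass
class SpecificityReport:
    """Per-item attenuation results and specific/non-specific labels."""

    table: pd.DataFrame            # one row per item
    factor_correlations: pd.DataFrame  # pairwise before/after comparison
    fit_before: FitResult
    fit_after: FitResult
    method: str
    alpha: float

    @property
    def labels(self) -> dict[str, str]:
        return dict(zip(self.table["item"], self.table["label"]))

    @property
    def n_specific(self) -> int:
        return int((self.table["label"] == "specific").sum())


def classify_symptoms(fit_before: FitResult, fit_after: FitResult,
                      method: str = "holm", alpha: float = 0.05
                      ) -> SpecificityReport:
    """Label each item specific or non-specific from two fitted models.

    `fit_before` is the plain factor model, `fit_after` the same model with
    the distress covariate; both need standardized loadings with standard
    errors (fit with se=True).  An item is non-specific iff its loading
    attenuation is significant after multiplicity correction.  Factor
    correlations are compared with the same z machinery but not labeled.
    """
    spec_b, spec_a = fit_before.spec, fit_after.spec
    if tuple(spec_b.items) != tuple(spec_a.items):
        raise ValueError("fits cover different item sets")
    for f, which in ((fit_before, "before"), (fit_after, "after")):
        if f.std_lam is None or f.se_std_lam is None:
            raise ValueError(f"{which} fit lacks standardized SEs; "
                             "refit with se=True")
    rows = []
    for i, item in enumerate(spec_b.items):
        z, p = aroian_z(fit_before.std_lam[i], fit_before.se_std_lam[i],
                        fit_after.std_lam[i], fit_after.se_std_lam[i])
        rows.append({
            "item": item, "factor": spec_b.loading[item],
            "lambda_before": fit_before.std_lam[i],
            "lambda_after": fit_after.std_lam[i],
            "se_before": fit_before.se_std_lam[i],
            "se_after": fit_after.se_std_lam[i],
            "beta_distress": (np.nan if fit_after.std_beta is None
                              else fit_after.std_beta[i]),
            "z": z, "p": p,
        })
    table = pd.DataFrame(rows)
    reject = adjust_pvalues(table["p"].to_numpy(), method=method, alpha=alpha)
    table["rejected"] = reject
    table["label"] = np.where(reject, "non_specific", "specific")

    fc_rows = []
    m = spec_b.n_factors
    for a in range(m):
        for b in range(a + 1, m):
            phi_b = fit_before.params.phi[a, b]
            phi_a = fit_after.params.phi[a, b]
            se_b = fit_before.se.phi[a, b] if fit_before.se is not None else np.nan
            se_a = fit_after.se.phi[a, b] if fit_after.se is not None else np.nan
            if se_b > 0 and se_a > 0:
                z, p = aroian_z(phi_b, se_b, phi_a, se_a)
            else:
                z, p = np.nan, np.nan
            fc_rows.append({
                "factor_a": spec_b.factors[a], "factor_b": spec_b.factors[b],
                "phi_before": phi_b, "phi_after": phi_a, "z": z, "p": p})
    return SpecificityReport(
        table=table, factor_correlations=pd.DataFrame(fc_rows),
        fit_before=fit_before, fit_after=fit_after,
        method=method, alpha=alpha)
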