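"""Synthetic item-level data with the structure the analysis assumes.

Each respondent's 20 PCL-5 items follow the hybrid factor model: item_i =
lambda_i * F(item) + beta_i * X + e_i, with correlated unit-variance
factors F, an independent standard-normal distress score X, and normal
residuals sized so every latent item has unit variance.  Ten K10
indicators measure X with fixed loadings, so an observed distress total
can be formed as their sum.  Optional Likert discretization maps the
latent continuous responses to the instruments' 0-4 / 1-5 categories
through fixed right-skewed thresholds, and optional MCAR masking removes
exactly k items from randomly chosen respondents at configurable per-k
rates.  Defaults reproduce the study conditions of the reference sample:
N = 641, published hybrid loadings and distress paths, and the reference
per-k missingness rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import catalog, dataprep
from .catalog import ModelSpec, get_model, reference_estimates
from .cfa import Parameters, SampleMoments, fit, robust_se
from .comparison import select_best
from .specificity import build_combined_model, classify_symptoms

# Reference per-k MCAR rates (respondents missing exactly k items / N=641)
PCL_MISSING_RATES = {1: 107 / 641, 2: 32 / 641, 3: 7 / 641, 4: 2 / 641,
                     5: 1 / 641, 7: 28 / 641}
K10_MISSING_RATES = {1: 40 / 641, 2: 11 / 641, 3: 47 / 641}

# Right-skewed thresholds putting the simulated PCL total near 26 and the
# K10 total near 13 (the reference sample's scale means)
PCL_THRESHOLDS = (-0.55, 0.30, 0.95, 1.70)
K10_THRESHOLDS = (0.75, 1.55, 2.15, 2.65)


@dataclass
class SimulationConfig:
    """Generating truth and observation model for one synthetic dataset."""

    seed: int
    n: int = 641
    model: str = "hybrid"
    loadings: np.ndarray | None = None        # default: published estimates
    distress_paths: np.ndarray | None = None  # default: published estimates
    factor_corr: float | np.ndarray = 0.6
    k10_indicator_loading: float = 0.65
    likert: bool = True
    pcl_thresholds: tuple = PCL_THRESHOLDS
    k10_thresholds: tuple = K10_THRESHOLDS
    missing: bool = True
    pcl_missing_rates: dict = field(default_factory=lambda: dict(PCL_MISSING_RATES))
    k10_missing_rates: dict = field(default_factory=lambda: dict(K10_MISSING_RATES))

    def resolve(self) -> tuple[ModelSpec, np.ndarray, np.ndarray, np.ndarray]:
        """Spec, loadings, distress paths and factor correlation matrix."""
        spec = get_model(self.model)
        ref = reference_estimates()
        lam = (np.asarray(self.loadings, dtype=float)
               if self.loadings is not None
               else ref["lambda_before"].to_numpy())
        beta = (np.asarray(self.distress_paths, dtype=float)
                if self.distress_paths is not None
                else ref["beta_distress"].to_numpy())
        m = spec.n_factors
        if np.isscalar(self.factor_corr):
            phi = np.full((m, m), float(self.factor_corr))
            np.fill_diagonal(phi, 1.0)
        else:
            phi = np.asarray(self.factor_corr, dtype=float)
        if lam.shape != (spec.n_items,) or beta.shape != (spec.n_items,):
            raise ValueError("loadings/distress paths must have one entry "
                             "per item")
        if np.linalg.eigvalsh(phi).min() <= 0:
            raise ValueError("factor correlation matrix not positive definite")
        if self.n < 50:
            raise ValueError("need n >= 50")
        theta = 1.0 - lam**2 - beta**2
        if (theta <= 0).any():
            bad = spec.items[int(np.argmax(theta <= 0))]
            raise ValueError(
                f"infeasible residual variance for item {bad}: "
                "lambda^2 + beta^2 >= 1")
        return spec, lam, beta, phi

    def truth(self) -> Parameters:
        spec, lam, beta, phi = self.resolve()
        return Parameters(lam=lam, phi=phi, theta=1.0 - lam**2 - beta**2,
                          beta=beta, psi=1.0)


def preset(name: str, seed: int, **overrides) -> SimulationConfig:
    """Named study conditions: 'paper' (defaults), 'null' (no distress
    contamination), 'uniform' (beta = 0.4 on every item), 'continuous'
    (no discretization, no missingness — parameter-recovery world)."""
    base = SimulationConfig(seed=seed)
    if name == "paper":
        cfg = base
    elif name == "null":
        cfg = replace(base, distress_paths=np.zeros(20))
    elif name == "uniform":
        cfg = replace(base, distress_paths=np.full(20, 0.4))
    elif name == "continuous":
        cfg = replace(base, likert=False, missing=False)
    else:
        raise KeyError(f"unknown preset {name!r}; "
                       "valid: paper, null, uniform, continuous")
    return replace(cfg, **overrides) if overrides else cfg


def _discretize(latent: np.ndarray, thresholds, base: int) -> np.ndarray:
    out = np.full(latent.shape, base, dtype=float)
    for t in thresholds:
        out += latent > t
    return out


def _inject_mcar(rng, mask_block: np.ndarray, rates: dict) -> None:
    n, k_items = mask_block.shape
    ks = sorted(rates)
    probs = [rates[k] for k in ks]
    total = sum(probs)
    if total > 1:
        raise ValueError("per-k missingness rates sum to more than 1")
    counts = rng.multinomial(n, probs + [1 - total])
    order = rng.permutation(n)
    start = 0
    for k, cnt in zip(ks, counts[:-1]):
        for r in order[start:start + cnt]:
            cols = rng.choice(k_items, size=k, replace=False)
            mask_block[r, cols] = True
        start += cnt


def generate(config: SimulationConfig) -> tuple[dataprep.DataSet, Parameters]:
    """Draw one dataset; returns (DataSet, generating Parameters).

    Same seed, same config -> byte-identical output.
    """
    spec, lam, beta, phi = config.resolve()
    truth = config.truth()
    rng = np.random.default_rng(config.seed)
    n, k = config.n, spec.n_items
    fidx = {f: a for a, f in enumerate(spec.factors)}
    assign = np.array([fidx[spec.loading[it]] for it in spec.items])
    factors = rng.multivariate_normal(np.zeros(spec.n_factors), phi, size=n,
                                      method="cholesky")
    distress = rng.standard_normal(n)
    resid = rng.standard_normal((n, k)) * np.sqrt(truth.theta)
    pcl_latent = factors[:, assign] * lam + distress[:, None] * beta + resid
    lk = config.k10_indicator_loading
    k10_latent = (distress[:, None] * lk
                  + rng.standard_normal((n, 10)) * np.sqrt(1 - lk**2))
    if config.likert:
        pcl = _discretize(pcl_latent, config.pcl_thresholds, base=0)
        k10 = _discretize(k10_latent, config.k10_thresholds, base=1)
    else:
        pcl, k10 = pcl_latent, k10_latent
    mask = np.zeros((n, 30), dtype=bool)
    if config.missing:
        _inject_mcar(rng, mask[:, :k], config.pcl_missing_rates)
        _inject_mcar(rng, mask[:, k:], config.k10_missing_rates)
    values = np.column_stack([pcl, k10])
    values[mask] = np.nan
    schema = dataprep.default_schema()
    if not config.likert:
        # continuous mode: scores are unbounded latent responses
        schema = dataprep.Schema(
            groups=schema.groups,
            ranges={g: (-np.inf, np.inf) for g in schema.groups})
    frame = pd.DataFrame(values, columns=list(schema.variables))
    return dataprep.DataSet(values=frame, schema=schema), truth


# ---------------------------------------------------------------------------
# Pipeline helpers and the recovery harness
# ---------------------------------------------------------------------------

PCL_COLUMNS = tuple(f"PCL{i}" for i in range(1, 21))
K10_COLUMNS = tuple(f"K10_{i}" for i in range(1, 11))


def analysis_frame(ds: dataprep.DataSet) -> pd.DataFrame:
    """Complete-data frame of the 20 PCL items plus the K10 total."""
    if not ds.complete:
        raise ValueError("impute before analysis")
    out = ds.values[list(PCL_COLUMNS)].copy()
    out["K10_total"] = ds.values[list(K10_COLUMNS)].sum(axis=1)
    return out


def fit_on_dataset(ds: dataprep.DataSet, spec: ModelSpec, **kw):
    """Fit a catalog spec (item codes B1..E6) to a PCL/K10 DataSet.

    The PCL columns map onto the symptom codes in order (PCL1 -> B1, ...,
    PCL20 -> E6) so fit results report the familiar item labels.
    """
    frame = analysis_frame(ds)
    frame = frame.rename(columns=dict(zip(PCL_COLUMNS, catalog.ITEM_CODES)))
    moments = SampleMoments.from_data(frame[list(spec.observed_variables)])
    return fit(moments, spec, **kw), moments


@dataclass
class RecoverySummary:
    replicates: int
    n: int
    selection_counts: dict[str, int]
    selection_rate_target: float     # fraction selecting config.model
    loading_bias: float              # mean over items of (est - truth)
    loading_abs_bias: float
    loading_rmse: float
    non_specific_fraction: float | None
    label_accuracy: float | None     # vs the generating beta pattern
    failures: list[str]


def recovery_harness(config: SimulationConfig, replicates: int,
                     models: tuple[str, ...] = catalog.CATALOG_NAMES[:6],
                     do_specificity: bool = True,
                     method: str = "holm", alpha: float = 0.05
                     ) -> RecoverySummary:
    """End-to-end parameter/selection/label recovery over many replicates.

    Each replicate draws a dataset with a distinct derived seed, imputes if
    needed, fits the requested catalog models, selects the best, and (when
    requested) runs the distress-specificity classification.  Replicate
    failures are recorded, not fatal.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    seed_rng = np.random.default_rng(config.seed)
    seeds = seed_rng.integers(0, 2**31 - 1, size=replicates)
    truth = config.truth()
    truly_nonspecific = truth.beta != 0
    sel_counts: dict[str, int] = {}
    biases, rmses, abs_biases = [], [], []
    ns_frac, label_acc = [], []
    failures: list[str] = []
    for r, s in enumerate(seeds):
        try:
            ds, _ = generate(replace(config, seed=int(s)))
            if not ds.complete:
                ds = dataprep.em_impute(ds)
            fits = {}
            for name in models:
                res, moments = fit_on_dataset(ds, get_model(name),
                                              robust=True, indices=True)
                fits[name] = (res, moments)
            sel = select_best([f for f, _ in fits.values()], alpha=alpha)
            chosen = sel.preferred or "tie"
            sel_counts[chosen] = sel_counts.get(chosen, 0) + 1
            tgt, moments = fits.get(config.model, next(iter(fits.values())))
            robust_se(moments, tgt)
            err = tgt.std_lam - truth.lam
            biases.append(err.mean())
            abs_biases.append(np.abs(err).mean())
            rmses.append(np.sqrt((err**2).mean()))
            if do_specificity:
                comb = build_combined_model(get_model(config.model))
                after, m2 = fit_on_dataset(ds, comb, robust=True,
                                           indices=True, se=True)
                report = classify_symptoms(tgt, after, method=method,
                                           alpha=alpha)
                lab = report.table["label"].to_numpy() == "non_specific"
                ns_frac.append(lab.mean())
                label_acc.append((lab == truly_nonspecific).mean())
        except Exception as exc:  # noqa: BLE001 - record, do not abort
            failures.append(f"replicate {r}: {exc}")
    done = replicates - len(failures)
    return RecoverySummary(
        replicates=replicates, n=config.n, selection_counts=sel_counts,
        selection_rate_target=(sel_counts.get(config.model, 0) / done
                               if done else np.nan),
        loading_bias=float(np.mean(biases)) if biases else np.nan,
        loading_abs_bias=float(np.mean(abs_biases)) if abs_biases else np.nan,
        loading_rmse=float(np.mean(rmses)) if rmses else np.nan,
        non_specific_fraction=(float(np.mean(ns_frac)) if ns_frac else None),
        label_accuracy=(float(np.mean(label_acc)) if label_acc else None),
        failures=failures)
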