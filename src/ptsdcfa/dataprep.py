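"""Item-level data handling: reading, missingness screening, EM imputation.

The expected layout is one respondent per row with 20 PCL-5 columns scored
0-4 and 10 K10 columns scored 1-5; missing cells are allowed.  Screening
summarizes how many respondents miss exactly k items per instrument and
runs Little's MCAR test.  Imputation estimates the multivariate-normal
mean and covariance by expectation-maximization on the observed data and
fills each missing cell with its conditional mean — single imputation, so
the downstream factor analysis stays single-pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MISSING_TOKENS = ("", "NA", ".")


@dataclass(frozen=True)
class Schema:
    """Column groups and admissible score ranges per instrument."""

    groups: dict[str, tuple[str, ...]]
    ranges: dict[str, tuple[float, float]]  # group -> (min, max)

    @property
    def variables(self) -> tuple[str, ...]:
        out: list[str] = []
        for cols in self.groups.values():
            out.extend(cols)
        return tuple(out)

    def range_of(self, var: str) -> tuple[float, float]:
        for g, cols in self.groups.items():
            if var in cols:
                return self.ranges[g]
        raise KeyError(var)


def default_schema() -> Schema:
    """PCL1..PCL20 scored 0-4 plus K10_1..K10_10 scored 1-5."""
    return Schema(
        groups={
            "PCL": tuple(f"PCL{i}" for i in range(1, 21)),
            "K10": tuple(f"K10_{i}" for i in range(1, 11)),
        },
        ranges={"PCL": (0.0, 4.0), "K10": (1.0, 5.0)},
    )


@dataclass
class DataSet:
    """Respondent x variable score matrix with missingness mask."""

    values: pd.DataFrame  # NaN marks missing
    schema: Schema

    def __post_init__(self) -> None:
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 respondents")
        if len(set(self.values.columns)) != len(self.values.columns):
            raise ValueError("duplicate variable names")
        for var in self.values.columns:
            lo, hi = self.schema.range_of(var)
            col = self.values[var]
            bad = col[(col.notna()) & ((col < lo) | (col > hi))]
            if len(bad):
                r = bad.index[0]
                raise ValueError(
                    f"value {bad.iloc[0]} out of range [{lo}, {hi}] "
                    f"for {var} at row {r}"
                )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def mask(self) -> pd.DataFrame:
        """True where a cell is missing."""
        return self.values.isna()

    @property
    def complete(self) -> bool:
        return not bool(self.mask.to_numpy().any())

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[list(self.schema.groups[group])]


def read_dataset(
    path,
    schema: Schema | None = None,
    missing_tokens=DEFAULT_MISSING_TOKENS,
) -> DataSet:
    """Read a delimited text file into a DataSet.

    The header must contain every column the schema declares; extra columns
    are ignored.  Non-numeric cells that are not a recognized missing token
    and observed values outside the instrument range raise errors that name
    the offending cell.
    """
    schema = schema or default_schema()
    raw = pd.read_csv(
        path, na_values=list(missing_tokens), keep_default_na=False, dtype=str,
        skipinitialspace=True,
    )
    missing_cols = [v for v in schema.variables if v not in raw.columns]
    if missing_cols:
        raise ValueError(f"header lacks expected columns: {missing_cols}")
    if len(set(raw.columns)) != len(raw.columns):
        dupes = raw.columns[raw.columns.duplicated()].tolist()
        raise ValueError(f"duplicate header columns: {dupes}")
    frame = pd.DataFrame(index=raw.index)
    for var in schema.variables:
        try:
            frame[var] = pd.to_numeric(raw[var])
        except (ValueError, TypeError) as exc:
            bad = raw[var][pd.to_numeric(raw[var], errors="coerce").isna()
                           & raw[var].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric cell {bad.iloc[0]!r} in column {var} "
                f"at row {row}"
            ) from exc
    return DataSet(values=frame, schema=schema)


def write_dataset(ds: DataSet, path) -> None:
    ds.values.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Missingness screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LittleResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class MissingnessSummary:
    """Per-instrument tallies of respondents missing exactly k items."""

    per_count: dict[str, dict[int, int]]
    overall_missing_fraction: float
    mcar: dict[str, LittleResult | None] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for instr, tallies in self.per_count.items():
            n_total = sum(tallies.values())
            for k in sorted(t for t in tallies if t > 0):
                rows.append(
                    {"instrument": instr, "n_missing_items": k,
                     "n_respondents": tallies[k],
                     "fraction": tallies[k] / n_total}
                )
        return pd.DataFrame(rows)


def little_mcar_test(x: np.ndarray, max_iter: int = 200,
                     tol: float = 1e-6) -> LittleResult:
    """Little's chi-square test of the MCAR hypothesis.

    Rows are grouped by missingness pattern; the statistic sums, over
    patterns, n_j times the Mahalanobis distance between the pattern's
    observed-variable mean and the EM grand mean, under the EM covariance.
    df = (total observed variables across patterns) - p.
    """
    x = np.asarray(x, dtype=float)
    mu, sigma, _ = em_mvn(x, max_iter=max_iter, tol=tol)
    patterns: dict[tuple, list[int]] = {}
    for i, row in enumerate(np.isnan(x)):
        if row.all():
            continue
        patterns.setdefault(tuple(row), []).append(i)
    d2 = 0.0
    df = -x.shape[1]
    for patt, rows in patterns.items():
        obs = ~np.array(patt)
        xb = x[np.ix_(rows, obs)].mean(axis=0)
        diff = xb - mu[obs]
        soo = sigma[np.ix_(obs, obs)]
        d2 += len(rows) * float(diff @ np.linalg.solve(soo, diff))
        df += int(obs.sum())
    if df <= 0:
        raise ValueError("no missingness patterns beyond complete data")
    return LittleResult(statistic=d2, df=df,
                        p_value=float(stats.chi2.sf(d2, df)))


def missingness_summary(ds: DataSet) -> MissingnessSummary:
    """Tally respondents by number of missing items and screen for MCAR."""
    mask = ds.mask
    per_count: dict[str, dict[int, int]] = {}
    mcar: dict[str, LittleResult | None] = {}
    for instr, cols in ds.schema.groups.items():
        sub = mask[list(cols)]
        if sub.all(axis=0).any():
            bad = sub.columns[sub.all(axis=0)].tolist()
            raise ValueError(f"variables with no observed values: {bad}")
        counts = sub.sum(axis=1).value_counts().to_dict()
        per_count[instr] = {int(k): int(v) for k, v in counts.items()}
        if sub.to_numpy().any():
            try:
                mcar[instr] = little_mcar_test(
                    ds.values[list(cols)].to_numpy())
            except ValueError:
                # degenerate missingness (e.g. only all-missing rows):
                # no informative patterns, the test carries no evidence
                mcar[instr] = None
        else:
            mcar[instr] = None
    frac = float(mask.to_numpy().mean())
    return MissingnessSummary(per_count=per_count,
                              overall_missing_fraction=frac, mcar=mcar)


# ---------------------------------------------------------------------------
# EM imputation
# ---------------------------------------------------------------------------

class EMConvergenceError(RuntimeError):
    def __init__(self, message: str, trajectory: list[float]):
        super().__init__(message)
        self.trajectory = trajectory


def em_mvn(x: np.ndarray, tol: float = 1e-6, max_iter: int = 500):
    """ML mean and covariance of multivariate-normal data with missing cells.

    Returns (mu, sigma, loglik_trajectory); convergence is monitored on the
    observed-data log-likelihood.  Sigma uses the ML (1/N) divisor.
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    miss = np.isnan(x)
    if miss.all(axis=0).any():
        raise ValueError("column with all values missing")
    mu = np.nanmean(x, axis=0)
    filled = np.where(miss, mu, x)
    sigma = np.cov(filled, rowvar=False, bias=True)
    sigma += np.eye(p) * 1e-8
    patterns: dict[tuple, np.ndarray] = {}
    for patt in {tuple(r) for r in miss}:
        patterns[patt] = np.where((miss == np.array(patt)).all(axis=1))[0]
    traj: list[float] = []
    for _ in range(max_iter):
        ex = np.array(x)
        exx_corr = np.zeros((p, p))
        ll = 0.0
        for patt, rows in patterns.items():
            o = ~np.array(patt)
            m = np.array(patt)
            if not o.any():
                # fully missing rows contribute nothing to the likelihood
                ex[rows] = mu
                exx_corr += len(rows) * sigma
                continue
            xo = x[np.ix_(rows, np.where(o)[0])]
            soo = sigma[np.ix_(o, o)]
            ll += float(
                stats.multivariate_normal.logpdf(xo, mean=mu[o], cov=soo,
                                                 allow_singular=True).sum()
            )
            if not m.any():
                continue
            som = sigma[np.ix_(o, m)]
            reg = np.linalg.solve(soo, som)  # (|o| x |m|)
            cond_mean = mu[m] + (xo - mu[o]) @ reg
            ex[np.ix_(rows, np.where(m)[0])] = cond_mean
            cmm = sigma[np.ix_(m, m)] - som.T @ reg
            idx = np.where(m)[0]
            exx_corr[np.ix_(idx, idx)] += len(rows) * cmm
        mu = ex.mean(axis=0)
        sigma = (ex - mu).T @ (ex - mu) / n + exx_corr / n
        traj.append(ll)
        if len(traj) >= 2 and abs(traj[-1] - traj[-2]) < tol:
            return mu, sigma, traj
    if miss.any():
        raise EMConvergenceError(
            f"EM did not converge in {max_iter} iterations "
            f"(last change {abs(traj[-1] - traj[-2]):.3g})", traj)
    return mu, sigma, traj


def em_impute(ds: DataSet, tol: float = 1e-6, max_iter: int = 500,
              round_to_scale: bool = False) -> DataSet:
    """Replace missing cells with conditional means under the EM solution.

    Observed cells are never altered.  Variables missing in more than 30%
    of respondents trigger a warning (imputation quality degrades).  By
    default imputed values stay continuous; ``round_to_scale`` clips and
    rounds them to the instrument's admissible categories.
    """
    import warnings

    mask = ds.mask.to_numpy()
    if not mask.any():
        return DataSet(values=ds.values.copy(), schema=ds.schema)
    frac = mask.mean(axis=0)
    high = [v for v, f in zip(ds.values.columns, frac) if f >= 0.30]
    if high:
        warnings.warn(
            f"variables missing in >=30% of respondents: {high}; "
            "EM imputation may be unreliable", stacklevel=2)
    x = ds.values.to_numpy(dtype=float)
    mu, sigma, _ = em_mvn(x, tol=tol, max_iter=max_iter)
    if np.linalg.cond(sigma) > 1e12:
        raise np.linalg.LinAlgError("EM covariance estimate is singular")
    out = np.array(x)
    miss = np.isnan(x)
    for i in np.where(miss.any(axis=1))[0]:
        m = miss[i]
        o = ~m
        soo = sigma[np.ix_(o, o)]
        som = sigma[np.ix_(o, m)]
        out[i, m] = mu[m] + som.T @ np.linalg.solve(soo, x[i, o] - mu[o])
    frame = pd.DataFrame(out, columns=ds.values.columns, index=ds.values.index)
    if round_to_scale:
        for var in frame.columns:
            lo, hi = ds.schema.range_of(var)
            frame[var] = frame[var].round().clip(lo, hi)
    # validation in __post_init__ only applies to observed ranges; continuous
    # imputed values may fall slightly outside, so bypass via clipped schema
    result = DataSet.__new__(DataSet)
    result.values = frame
    result.schema = ds.schema
    return result


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

def cronbach_alpha(ds: DataSet, items) -> float:
    """Internal-consistency reliability of a sum score.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the total).
    """
    items = list(items)
    if len(items) < 2:
        raise ValueError("need at least 2 items")
    x = ds.values[items].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("complete (imputed) data required")
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero total-score variance")
    item_var = x.var(axis=0, ddof=1).sum()
    return k / (k - 1) * (1.0 - item_var / total_var)


def scale_descriptives(ds: DataSet, items) -> dict[str, float]:
    """Mean, SD (N-1 divisor), min and max of the row-sum total score."""
    x = ds.values[list(items)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("complete (imputed) data required")
    total = x.sum(axis=1)
    return {
        "mean": float(total.mean()),
        "sd": float(total.std(ddof=1)),
        "min": float(total.min()),
        "max": float(total.max()),
    }
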