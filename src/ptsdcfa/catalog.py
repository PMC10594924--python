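"""Catalog of competing factor structures for the 20-item PCL-5.

Six models from the PTSD structural literature are shipped as a YAML
resource: the DSM-5 four-factor model, the dysphoria model, the dysphoric
arousal model, the anhedonia model, the externalizing behaviors model, and
the seven-factor hybrid model.  A seventh entry, ``combined_distress``,
augments the hybrid model with an observed psychological-distress covariate
(the K10 total score) regressed on every item.

Identification fixes all factor variances to 1 (every loading free), so the
degrees of freedom of each model follow from the specification alone and
loadings are directly comparable to standardized estimates.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import yaml

FACTOR_CODES = frozenset(
    {"In", "Av", "NACM", "AAR", "Dy", "DA", "AA", "NA", "An", "EB"}
)

CATALOG_NAMES = (
    "dsm5",
    "dysphoria",
    "dysphoric_arousal",
    "anhedonia",
    "externalizing",
    "hybrid",
    "combined_distress",
)


@dataclass(frozen=True)
class ItemDef:
    """One PCL-5 symptom item and its factor assignment in each model."""

    code: str
    text: str
    cluster_per_model: dict[str, str]


@dataclass(frozen=True)
class ModelSpec:
    """A confirmatory factor structure over observed items.

    Each item loads on exactly one factor; all factors are free to
    correlate; correlated residuals are not permitted.  An optional
    observed covariate adds a regression path to every item, with the
    covariate constrained orthogonal to the factors and its variance free.
    """

    name: str
    items: tuple[str, ...]
    factors: tuple[str, ...]
    loading: dict[str, str]  # item code -> factor code
    covariate: str | None = None
    identification: str = "factor_variance_1"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [i for i in self.items if i not in self.loading]
        if missing:
            raise ValueError(f"items without a factor assignment: {missing}")
        unknown = sorted(set(self.loading.values()) - set(self.factors))
        if unknown:
            raise ValueError(f"loadings onto undeclared factors: {unknown}")
        if len(set(self.items)) != len(self.items):
            raise ValueError("duplicate item codes")

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def observed_variables(self) -> tuple[str, ...]:
        """Items plus the covariate column, in model order."""
        if self.covariate is None:
            return self.items
        return self.items + (self.covariate,)

    def factor_partition(self) -> dict[str, frozenset[str]]:
        """Factor code -> set of item codes loading on it."""
        out: dict[str, set[str]] = {f: set() for f in self.factors}
        for item, f in self.loading.items():
            out[f].add(item)
        return {f: frozenset(s) for f, s in out.items() if s}

    def with_covariate(self, name: str) -> "ModelSpec":
        """Return a copy with an observed covariate regressed on every item."""
        if self.covariate is not None:
            raise ValueError(f"{self.name!r} already has covariate {self.covariate!r}")
        return replace(self, name=f"{self.name}+{name}", covariate=name)


def _load_catalog() -> dict:
    ref = importlib.resources.files("ptsdcfa.resources").joinpath("models.yaml")
    return yaml.safe_load(ref.read_text())


_CATALOG = _load_catalog()

ITEM_CODES: tuple[str, ...] = tuple(d["code"] for d in _CATALOG["items"])


def item_definitions() -> list[ItemDef]:
    """The 20 PCL-5 items with their assignment in every catalog model."""
    return [
        ItemDef(
            code=d["code"],
            text=d["text"],
            cluster_per_model={
                m: _CATALOG["models"][m]["loading"][d["code"]]
                for m in _CATALOG["models"]
            },
        )
        for d in _CATALOG["items"]
    ]


def list_models() -> tuple[str, ...]:
    return CATALOG_NAMES


def get_model(name: str) -> ModelSpec:
    """Look up a catalog model by name.

    ``combined_distress`` is the hybrid model with a K10-total covariate
    regressed on all 20 items (covariate orthogonal to the factors).
    """
    if name == "combined_distress":
        spec = get_model("hybrid").with_covariate("K10_total")
        return replace(spec, name="combined_distress")
    if name not in _CATALOG["models"]:
        raise KeyError(
            f"unknown model {name!r}; valid names: {', '.join(CATALOG_NAMES)}"
        )
    entry = _CATALOG["models"][name]
    return ModelSpec(
        name=name,
        items=ITEM_CODES,
        factors=tuple(entry["factors"]),
        loading=dict(entry["loading"]),
    )


def count_free_parameters(spec: ModelSpec) -> int:
    """Free parameters under the unit-factor-variance convention.

    Loadings (one per item) + residual variances (one per item) + factor
    correlations C(m, 2) + covariate paths (one per item) and the covariate
    variance when a covariate is present.
    """
    m = spec.n_factors
    q = 2 * spec.n_items + m * (m - 1) // 2
    if spec.covariate is not None:
        q += spec.n_items + 1
    return q


def degrees_of_freedom(spec: ModelSpec) -> int:
    """Model df: distinct covariance moments minus free parameters."""
    p = len(spec.observed_variables)
    df = p * (p + 1) // 2 - count_free_parameters(spec)
    if df < 0:
        raise ValueError(
            f"model {spec.name!r} has negative df ({df}): overparameterized"
        )
    return df


def save_spec(spec: ModelSpec, path) -> None:
    """Write a spec as a YAML document (round-trips through load_spec)."""
    doc = {
        "name": spec.name,
        "items": list(spec.items),
        "factors": list(spec.factors),
        "loading": dict(spec.loading),
        "covariate": spec.covariate,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_spec(path) -> ModelSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return ModelSpec(
        name=doc["name"],
        items=tuple(doc["items"]),
        factors=tuple(doc["factors"]),
        loading=dict(doc["loading"]),
        covariate=doc.get("covariate"),
    )


def reference_estimates():
    """Published hybrid-model estimates used as simulation defaults.

    Returns a DataFrame with columns item, factor, lambda_before,
    lambda_after, z, p, beta_distress (standardized scale, N=641 sample).
    """
    import pandas as pd

    ref = importlib.resources.files("ptsdcfa.resources").joinpath(
        "reference_estimates.csv"
    )
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")
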