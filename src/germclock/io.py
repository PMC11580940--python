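"""Reading study specs and writing standardized tables.

Study specs are small YAML (or JSON) documents carrying a published
parental-age regression in one of the supported parameterizations; the
``kind`` field selects the standardization route:

* ``sex_specific`` — maternal/paternal slopes and intercepts
  (:class:`~germclock.standardize.SexSpecificRegressionSpec`);
* ``slope_intercept`` — a combined per-site slope and intercept
  (:class:`~germclock.standardize.SlopeInterceptPerSiteSpec`);
* ``mean_rate`` — rate at puberty plus a mean rate over the reproductive span
  (:class:`~germclock.standardize.MeanRateSpanSpec`);
* ``decomposition`` — already-standardized rates taken verbatim from the
  source study (used when the underlying trio data are not redistributable).

The specs for the eight pedigree studies ship with the package under
``germclock/studies`` and are loaded by :func:`load_builtin_studies`.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from .clock import total_generational_rate
from .standardize import (
    MeanRateSpanSpec,
    RateDecomposition,
    SexSpecificRegressionSpec,
    SlopeInterceptPerSiteSpec,
    StudySpecError,
    standardize_mean_rate,
    standardize_sex_specific,
    standardize_slope_intercept,
)

__all__ = [
    "load_study_spec",
    "standardize_study",
    "load_builtin_studies",
    "builtin_study_names",
    "decomposition_table",
    "write_table",
]

_KINDS = {"sex_specific", "slope_intercept", "mean_rate", "decomposition"}


def load_study_spec(source: str | Path | dict[str, Any]):
    """Parse a study spec from a YAML/JSON path or an already-loaded mapping."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        data = yaml.safe_load(text)
    else:
        data = dict(source)
    if not isinstance(data, dict) or "kind" not in data:
        raise StudySpecError(f"study spec must be a mapping with a 'kind' field: {source}")
    kind = data.pop("kind")
    data.pop("notes", None)
    # YAML 1.1 reads exponents without a sign ("2.36e9") as strings; coerce
    for key, val in data.items():
        if isinstance(val, str) and key not in ("species", "units"):
            data[key] = float(val)
        elif isinstance(val, (list, tuple)) and key.endswith("_bounds"):
            data[key] = [float(v) for v in val]
        elif isinstance(val, dict):
            data[key] = {k: float(v) for k, v in val.items()}
    if kind not in _KINDS:
        raise StudySpecError(f"unknown study spec kind {kind!r}")
    if kind == "sex_specific":
        return SexSpecificRegressionSpec(**data)
    if kind == "slope_intercept":
        return SlopeInterceptPerSiteSpec(**data)
    if kind == "mean_rate":
        return MeanRateSpanSpec(**data)
    bounds = {
        "mu_E_bounds": tuple(data.pop("mu_E_bounds")) if "mu_E_bounds" in data else None,
        "mu_gam_bounds": tuple(data.pop("mu_gam_bounds")) if "mu_gam_bounds" in data else None,
    }
    return RateDecomposition(**data, **bounds)


def standardize_study(spec) -> RateDecomposition:
    """Dispatch a parsed spec to its standardization operation."""
    if isinstance(spec, SexSpecificRegressionSpec):
        return standardize_sex_specific(spec)
    if isinstance(spec, SlopeInterceptPerSiteSpec):
        return standardize_slope_intercept(spec)
    if isinstance(spec, MeanRateSpanSpec):
        return standardize_mean_rate(spec)
    if isinstance(spec, RateDecomposition):
        return spec
    raise StudySpecError(f"cannot standardize object of type {type(spec).__name__}")


def builtin_study_names() -> list[str]:
    files = resources.files("germclock") / "studies"
    return sorted(p.name.removesuffix(".yaml") for p in files.iterdir() if p.name.endswith(".yaml"))


def load_builtin_studies(names: Sequence[str] | None = None) -> list[RateDecomposition]:
    """Standardize the packaged pedigree-study specs (alphabetical order)."""
    files = resources.files("germclock") / "studies"
    wanted = set(names) if names is not None else None
    out = []
    for name in builtin_study_names():
        if wanted is not None and name not in wanted:
            continue
        data = yaml.safe_load((files / f"{name}.yaml").read_text())
        out.append(standardize_study(load_study_spec(data)))
    return out


def decomposition_table(decs: Sequence[RateDecomposition]) -> pd.DataFrame:
    """Tabulate decompositions with the derived per-generation rate mu_total."""
    return pd.DataFrame(
        {
            "species": [d.species for d in decs],
            "mu_E": [d.mu_E for d in decs],
            "mu_gam": [d.mu_gam for d in decs],
            "puberty_age": [d.puberty_age for d in decs],
            "generation_time": [d.generation_time for d in decs],
            "mu_total": [total_generational_rate(d) for d in decs],
        }
    )


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config: dict[str, Any] | None = None,
    seed: int | None = None,
) -> None:
    """Write a TSV with a provenance header (config hash and seed) as comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        lines.append(f"# config_hash: {digest}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    body = df.to_csv(sep="\t", index=False)
    path.write_text("".join(f"{l}\n" for l in lines) + body)
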