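"""The decision grid of named missing-data scenarios and the end-to-end runner.

Each scenario is a combination of four decisions: whether to substitute days
from the following week, whether to impute partial days as censored, whether
to assume MAR (otherwise a delta-adjustment is applied after imputation),
and whether to include auxiliary variables in the imputation model.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Optional

import pandas as pd

from . import __version__ as _pkg_version
from .analysis import FitResult, PooledResult, contrasts, fit_primary, pool_rubin, week_average
from .errors import ParameterError, ScenarioStageError
from .imputation import ImputationSpec, ImputedSet, chained_impute
from .mnar import apply_delta
from .substitution import day_substitute
from .trial_data import TrialDataset


@dataclass(frozen=True)
class ScenarioConfig:
    name: str
    use_day_substitution: bool
    impute_partial_as_censored: bool
    assume_mar: bool
    use_auxiliaries: bool
    delta: float = 0.95


PRESETS = {
    "plausible": ScenarioConfig("plausible", False, True, True, True),
    "suspicious": ScenarioConfig("suspicious", False, True, False, True, delta=0.95),
    "plausible-no-aux": ScenarioConfig("plausible-no-aux", False, True, True, False),
    "replace-days": ScenarioConfig("replace-days", True, True, True, True),
    "dismissive": ScenarioConfig("dismissive", False, False, False, True, delta=0.95),
}


def get_scenario(name: str) -> ScenarioConfig:
    key = name.lower().replace("_", "-")
    if key not in PRESETS:
        raise ParameterError(f"unknown scenario {name!r}; choose from {sorted(PRESETS)}")
    return PRESETS[key]


@dataclass
class ScenarioResult:
    pooled: PooledResult
    contrasts: pd.DataFrame
    manifest: dict
    imputed: Optional[ImputedSet] = None


def run_scenario(
    dataset: TrialDataset,
    config: ScenarioConfig,
    spec: ImputationSpec,
    keep_imputed: bool = False,
) -> ScenarioResult:
    """Run one scenario end-to-end on a classified dataset.

    Pipeline: [day-substitution] -> bounds + chained imputation -> [delta
    adjustment] -> week averages -> per-imputation primary fits -> Rubin
    pooling -> arm contrasts. A manifest capturing everything needed to
    re-run the scenario bit-identically is attached.
    """
    spec = replace(
        spec,
        impute_partial_as_censored=config.impute_partial_as_censored,
        use_auxiliaries=config.use_auxiliaries,
    )

    ds = dataset
    if config.use_day_substitution:
        ds = _stage("day_substitute", day_substitute, ds)

    imputed = _stage("chained_impute", chained_impute, ds, spec)
    if not config.assume_mar:
        imputed = _stage("apply_delta", apply_delta, imputed, config.delta)

    weeks = _stage("week_average", week_average, imputed)
    fits = []
    for m, weeks_m in weeks.groupby("imp"):
        fits.append(
            _stage(
                "fit_primary",
                fit_primary,
                weeks_m.drop(columns="imp"),
                ds.participants,
                ds.age_center,
            )
        )
    pooled = _stage("pool_rubin", pool_rubin, fits)
    ctr = _stage("contrasts", contrasts, pooled)

    manifest = {
        "scenario": asdict(config),
        "imputation": {
            k: v for k, v in asdict(spec).items() if k != "store_diagnostics"
        },
        "n_participants": int(len(dataset.participants)),
        "software_version": _pkg_version,
    }
    return ScenarioResult(
        pooled=pooled,
        contrasts=ctr,
        manifest=manifest,
        imputed=imputed if keep_imputed else None,
    )


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as e:  # noqa: BLE001 - stage name is the diagnostic payload
        raise ScenarioStageError(name, e) from e
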