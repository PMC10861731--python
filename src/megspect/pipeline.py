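"""Cohort filtering and the two-stage statistical battery.

``apply_exclusions`` reproduces the roster filter (non-dementia diagnosis,
undiagnosed at examination, severe MEG artifact — applied in that order,
each record tallied once under the first matching rule).

``run_global_analysis`` bootstraps Spearman correlations for every MEG
parameter against the eZIS metrics, neuropsychological scores and age, plus
the between-modality covariate pairs; ``run_regional_analysis`` runs the
cluster-based permutation test per (parameter, covariate) pair and, for the
age-correlated covariates, the PLS/VIP confound screen.  Missing values are
deleted listwise per pair, so e.g. the FAB analyses use only subjects with
a FAB score.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, ConstantInputError, SchemaError
from .spectral import PARAMETER_NAMES
from .stats import (
    RegionAdjacency,
    bootstrap_spearman,
    cluster_permutation_correlation,
    confound_screen,
    pls1_vip,
)

__all__ = [
    "RunConfig",
    "apply_exclusions",
    "run_global_analysis",
    "run_regional_analysis",
    "EXCLUSION_RULES",
    "MEG_COVARIATE_NAMES",
    "AGE_CONFOUNDED_COVARIATES",
]

#: Covariates correlated against every MEG parameter.
MEG_COVARIATE_NAMES = ("severity", "extent", "ratio", "mmse", "fab", "age")

#: Between-modality covariate pairs (within-modality pairs among the three
#: eZIS metrics are deliberately not examined).
COVARIATE_PAIRS = (
    ("severity", "mmse"),
    ("severity", "fab"),
    ("severity", "age"),
    ("extent", "mmse"),
    ("extent", "fab"),
    ("extent", "age"),
    ("ratio", "mmse"),
    ("ratio", "fab"),
    ("ratio", "age"),
    ("mmse", "fab"),
    ("mmse", "age"),
    ("fab", "age"),
)

#: Covariates whose global correlation with age motivates the VIP screen.
AGE_CONFOUNDED_COVARIATES = ("ratio", "mmse", "fab")

EXCLUSION_RULES = ("non_dementia", "undiagnosed", "artifact")


@dataclass
class RunConfig:
    """Settings for one reproducible analysis run."""

    seed: int = 0
    n_boot: int = 5000
    n_perm: int = 5000
    alpha_tail: float = 0.025
    subgroup: tuple[str, ...] | None = None  # e.g. ("MCI", "AD")
    meg_params: tuple[str, ...] = PARAMETER_NAMES
    covariates: tuple[str, ...] = MEG_COVARIATE_NAMES
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_boot < 100:
            raise ConfigurationError("n_boot must be >= 100")
        if self.n_perm < 100:
            raise ConfigurationError("n_perm must be >= 100")
        if not 0 < self.alpha_tail < 0.5:
            raise ConfigurationError("alpha_tail must lie in (0, 0.5)")
        unknown = set(self.meg_params) - set(PARAMETER_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown MEG parameters {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("subgroup", "meg_params", "covariates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def manifest(self) -> dict:
        cfg = asdict(self)
        blob = json.dumps(cfg, sort_keys=True, default=str).encode()
        return {"config": cfg, "config_sha256": hashlib.sha256(blob).hexdigest()}


def apply_exclusions(roster: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter the roster; return (included records, tally per exclusion rule).

    Rules fire in order — non-dementia disease, undiagnosed, severe MEG
    artifact — and a record matching several is counted once, under the
    first applicable rule.
    """
    if "id" in roster.columns and roster["id"].duplicated().any():
        dupes = roster.loc[roster["id"].duplicated(), "id"].tolist()
        raise SchemaError(f"duplicate subject ids {dupes[:5]}")
    if roster.empty:
        raise SchemaError("roster is empty")
    diagnosis = roster.get("diagnosis", pd.Series("", index=roster.index)).astype(str)
    artifact = roster.get(
        "meg_artifact_severe", pd.Series(False, index=roster.index)
    ).astype(bool)

    rule_masks = {
        "non_dementia": diagnosis.str.replace("_", "-").eq("non-dementia"),
        "undiagnosed": diagnosis.eq("undiagnosed"),
        "artifact": artifact,
    }
    excluded = pd.Series(False, index=roster.index)
    tally: dict[str, int] = {}
    for rule in EXCLUSION_RULES:
        hits = rule_masks[rule] & ~excluded
        tally[rule] = int(hits.sum())
        excluded |= hits
    return roster.loc[~excluded].copy(), tally


def _subset(df: pd.DataFrame, roster: pd.DataFrame | None, config: RunConfig) -> pd.DataFrame:
    if config.subgroup is None or roster is None:
        return df
    keep = roster.loc[roster["diagnosis"].isin(config.subgroup), "id"]
    return df.loc[df.index.intersection(keep)]


def run_global_analysis(
    params_global: pd.DataFrame,
    covariates: pd.DataFrame,
    config: RunConfig,
    roster: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Bootstrap Spearman table over all between-modality pairs.

    ``params_global``: subjects x 11 region-averaged MEG parameters;
    ``covariates``: subjects x {severity, extent, ratio, mmse, fab, age}.
    Rows are joined on the subject index; each pair uses its own complete
    cases.  Constant inputs are flagged and skipped, not fatal.
    """
    missing = [p for p in config.meg_params if p not in params_global.columns]
    if missing:
        raise SchemaError(f"missing MEG parameter columns {missing}")
    missing = [c for c in config.covariates if c not in covariates.columns]
    if missing:
        raise SchemaError(f"missing covariate columns {missing}")
    params_global = _subset(params_global, roster, config)
    joined = params_global.join(covariates, how="inner", validate="one_to_one")

    pairs = [(p, c) for p in config.meg_params for c in config.covariates]
    pairs += [(a, b) for a, b in COVARIATE_PAIRS if a in config.covariates and b in config.covariates]

    rows = []
    for k, (xname, yname) in enumerate(pairs):
        x = joined[xname].to_numpy(dtype=float)
        y = joined[yname].to_numpy(dtype=float)
        n = int(np.sum(np.isfinite(x) & np.isfinite(y)))
        try:
            boot = bootstrap_spearman(
                x, y, n_boot=config.n_boot, seed=config.seed + k
            )
        except ConstantInputError:
            rows.append(
                {
                    "x": xname, "y": yname, "n": n,
                    "rho": np.nan, "rho_mean": np.nan,
                    "ci_low": np.nan, "ci_high": np.nan,
                    "significant": False, "note": "constant-input",
                }
            )
            continue
        rows.append(
            {
                "x": xname, "y": yname, "n": boot.n,
                "rho": boot.rho_plugin, "rho_mean": boot.rho_mean,
                "ci_low": boot.ci_low, "ci_high": boot.ci_high,
                "significant": boot.significant, "note": "",
            }
        )
    return pd.DataFrame(rows)


def _clusters_to_frame(
    clusters, meg_param: str, covariate: str, screened: bool
) -> list[dict]:
    return [
        {
            "meg_param": meg_param,
            "covariate": covariate,
            "screened": screened,
            "sign": cl.sign,
            "n_members": len(cl.members),
            "members": ",".join(cl.members),
            "sum_t": cl.sum_t,
            "mean_t": cl.mean_t,
            "mean_rho": cl.mean_rho,
            "p_value": cl.p_value,
            "n_subjects": cl.n_subjects,
            "n_perm": cl.n_perm,
            "n_excluded": cl.n_excluded,
        }
        for cl in clusters
    ]


def run_regional_analysis(
    params_regional: dict[str, pd.DataFrame],
    covariates: pd.DataFrame,
    adjacency: RegionAdjacency,
    config: RunConfig,
    roster: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Cluster permutation tests for every (MEG parameter, covariate) pair.

    For age-confounded covariates the VIP screen prunes cluster members
    where age carries the larger importance; both the raw and screened
    cluster tables are returned, together with the per-region VIP table.

    Returns ``{"clusters": ..., "screened": ..., "vip": ...}``.
    """
    cluster_rows: list[dict] = []
    screened_rows: list[dict] = []
    vip_rows: list[dict] = []
    for p_idx, meg_param in enumerate(config.meg_params):
        if meg_param not in params_regional:
            raise SchemaError(f"no regional table for parameter {meg_param!r}")
        P = _subset(params_regional[meg_param], roster, config)
        joined_cov = covariates.loc[P.index]
        for c_idx, covariate in enumerate(config.covariates):
            if covariate not in joined_cov.columns:
                raise SchemaError(f"missing covariate column {covariate!r}")
            c = joined_cov[covariate].to_numpy(dtype=float)
            seed = config.seed + 1000 * p_idx + c_idx
            clusters = cluster_permutation_correlation(
                P, c, adjacency,
                n_perm=config.n_perm,
                alpha_tail=config.alpha_tail,
                seed=seed,
            )
            cluster_rows += _clusters_to_frame(clusters, meg_param, covariate, False)
            if covariate in AGE_CONFOUNDED_COVARIATES and clusters:
                age = joined_cov["age"].to_numpy(dtype=float)
                members = sorted({m for cl in clusters for m in cl.members})
                vip = {}
                for region in members:
                    y = P[region].to_numpy(dtype=float)
                    comp = pls1_vip(y, np.column_stack([c, age]), region=region)
                    vip[region] = comp
                    vip_rows.append(
                        {
                            "meg_param": meg_param,
                            "covariate": covariate,
                            "region": region,
                            "vip_variable": comp.vip_variable,
                            "vip_age": comp.vip_age,
                            "exclude": comp.exclude,
                        }
                    )
                screened = confound_screen(clusters, vip)
                screened_rows += _clusters_to_frame(screened, meg_param, covariate, True)

    columns = [
        "meg_param", "covariate", "screened", "sign", "n_members", "members",
        "sum_t", "mean_t", "mean_rho", "p_value", "n_subjects", "n_perm", "n_excluded",
    ]
    vip_columns = ["meg_param", "covariate", "region", "vip_variable", "vip_age", "exclude"]
    return {
        "clusters": pd.DataFrame(cluster_rows, columns=columns),
        "screened": pd.DataFrame(screened_rows, columns=columns),
        "vip": pd.DataFrame(vip_rows, columns=vip_columns),
    }
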