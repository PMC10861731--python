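"""eZIS-style Z-scoring and VOI hypoperfusion metrics for SPECT maps.

Perfusion maps are z-scored against a normative control database as
``Z = (control mean - individual value) / control SD``, so a *higher* Z
means a *larger* reduction in regional cerebral blood flow.  Three scalar
summaries are taken over a predefined volume of interest (VOI; posterior
cingulate gyrus + precuneus + parietal lobe treated as a single, possibly
spatially discontinuous mask):

* ``severity`` — mean Z over the VOI,
* ``extent``   — percentage of VOI voxels with Z strictly above 2,
* ``ratio``    — VOI extent divided by the whole-brain extent
                 (specificity of the hypoperfusion to the VOI).

Clinical screening cut-offs of 1.19 / 14.2 / 2.22 respectively are attached
as boolean flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import DegenerateControlError, SchemaError, UndefinedRatioError

__all__ = [
    "ZScoreMap",
    "EzisResult",
    "zscore_map",
    "severity",
    "extent",
    "ratio",
    "ezis_result",
    "CUTOFFS",
]

#: Screening cut-offs for (severity, extent, ratio), discriminating
#: amnestic MCI due to AD from healthy ageing.
CUTOFFS = {"severity": 1.19, "extent": 14.2, "ratio": 2.22}

Z_THRESHOLD = 2.0  # strict "Z > 2" exceedance for extent


@dataclass
class ZScoreMap:
    """Flat Z-score map with VOI and whole-brain boolean masks."""

    z: np.ndarray
    voi_mask: np.ndarray
    brain_mask: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float).ravel()
        self.voi_mask = np.asarray(self.voi_mask, dtype=bool).ravel()
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool).ravel()
        if not (self.z.size == self.voi_mask.size == self.brain_mask.size):
            raise SchemaError("z, voi_mask and brain_mask must be congruent")
        if np.any(self.voi_mask & ~self.brain_mask):
            raise SchemaError("VOI mask must be a subset of the brain mask")
        if self.voi_mask.sum() < 1 or self.brain_mask.sum() < 1:
            raise SchemaError("VOI and brain masks must each contain >= 1 element")


@dataclass
class EzisResult:
    severity: float
    extent: float
    ratio: float  # NaN when the whole-brain extent is zero (undefined)
    severity_flag: bool
    extent_flag: bool
    ratio_flag: bool


def zscore_map(
    individual_map: np.ndarray,
    control_mean_map: np.ndarray,
    control_sd_map: np.ndarray,
    voi_mask: np.ndarray,
    brain_mask: np.ndarray,
) -> ZScoreMap:
    """Elementwise ``Z = (control mean - individual) / control SD``."""
    ind = np.asarray(individual_map, dtype=float).ravel()
    mu = np.asarray(control_mean_map, dtype=float).ravel()
    sd = np.asarray(control_sd_map, dtype=float).ravel()
    if not (ind.size == mu.size == sd.size):
        raise SchemaError("individual and control maps must be congruent")
    brain = np.asarray(brain_mask, dtype=bool).ravel()
    if np.any(sd[brain] <= 0):
        raise DegenerateControlError(
            "control SD must be strictly positive inside the brain mask"
        )
    z = np.zeros_like(ind)
    ok = sd > 0
    z[ok] = (mu[ok] - ind[ok]) / sd[ok]
    return ZScoreMap(z=z, voi_mask=voi_mask, brain_mask=brain)


def severity(zmap: ZScoreMap) -> float:
    """Mean Z over all VOI voxels (positive and negative alike)."""
    return float(zmap.z[zmap.voi_mask].mean())


def extent(zmap: ZScoreMap, mask: str = "voi") -> float:
    """Percentage of mask voxels with Z strictly greater than 2."""
    if mask == "voi":
        sel = zmap.voi_mask
    elif mask == "brain":
        sel = zmap.brain_mask
    else:
        raise SchemaError(f"unknown mask {mask!r}; expected 'voi' or 'brain'")
    z = zmap.z[sel]
    return float(100.0 * np.count_nonzero(z > Z_THRESHOLD) / z.size)


def ratio(zmap: ZScoreMap) -> float:
    """VOI extent over whole-brain extent; undefined when the latter is 0."""
    brain_extent = extent(zmap, mask="brain")
    if brain_extent == 0.0:
        raise UndefinedRatioError(
            "whole-brain extent is zero; the VOI/brain ratio is undefined"
        )
    return extent(zmap, mask="voi") / brain_extent


def ezis_result(zmap: ZScoreMap) -> EzisResult:
    """All three VOI metrics plus cut-off flags; an undefined ratio is NaN."""
    sev = severity(zmap)
    ext = extent(zmap, mask="voi")
    try:
        rat = ratio(zmap)
    except UndefinedRatioError:
        rat = float("nan")
    return EzisResult(
        severity=sev,
        extent=ext,
        ratio=rat,
        severity_flag=sev > CUTOFFS["severity"],
        extent_flag=ext > CUTOFFS["extent"],
        ratio_flag=bool(rat > CUTOFFS["ratio"]) if np.isfinite(rat) else False,
    )
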