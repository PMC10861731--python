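"""Synthetic cohort with known ground truth.

Emulates the statistical structure the analysis assumes, end to end:

* per-subject, per-region **target power spectra** built from a 1/f-like
  aperiodic floor plus Gaussian oscillatory peaks — an alpha peak near
  8-10 Hz and a theta bump whose amplitude grows with impairment;
* a subject-level latent **impairment** factor (standard normal) that
  drives theta augmentation, alpha-peak slowing and, through linear
  loadings, the clinical covariates (MMSE-like 0-30, FAB-like 0-18,
  eZIS-like severity/extent/ratio, age);
* region-level **time series** realized from the target spectra by
  inverse-FFT spectral shaping with i.i.d. random phases (a circularly
  stationary Gaussian surrogate, so the empirical PSD converges to the
  target as duration grows);
* a region **adjacency graph** standing in for atlas neighbourhoods
  (2-D lattice by default), and voxelwise **Z-score maps** for the
  hypoperfusion metrics.

Everything is deterministic given the configuration seed; per-region time
series additionally derive their streams from (seed, subject, region) so
subjects can be synthesized independently and in any order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, SchemaError
from .conditioning import RegionTimeSeries
from .ezis import ZScoreMap
from .spectral import NormalizedSpectrum, compute_parameters
from .stats import RegionAdjacency

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "generate_cohort",
    "shape_noise",
    "synthesize_timeseries",
    "generate_adjacency",
    "generate_zmap",
    "regional_parameters",
    "global_parameters",
    "contiguous_patch",
    "planted_patch_cohort",
    "DEFAULT_COVARIATE_LOADINGS",
]

#: covariate -> (intercept, slope on latent impairment, residual SD).
#: Intercepts and spreads sit near typical memory-clinic values: MMSE ~24±5,
#: FAB ~12±3, eZIS severity ~1.3, extent ~16%, ratio ~2, age late seventies.
#: Cognitive scores load negatively on impairment; hypoperfusion metrics and
#: age load positively.
DEFAULT_COVARIATE_LOADINGS: dict[str, tuple[float, float, float]] = {
    "age": (77.0, 2.0, 6.5),
    "mmse": (24.0, -4.0, 2.5),
    "fab": (12.0, -2.5, 1.8),
    "severity": (1.3, 0.4, 0.25),
    "extent": (16.0, 11.0, 6.0),
    "ratio": (2.1, 1.0, 0.9),
}

COVARIATE_RANGES: dict[str, tuple[float | None, float | None]] = {
    "age": (40.0, 100.0),
    "mmse": (0.0, 30.0),
    "fab": (0.0, 18.0),
    "severity": (0.0, None),
    "extent": (0.0, 100.0),
    "ratio": (0.0, None),
}

INTEGER_COVARIATES = frozenset({"mmse", "fab"})

#: Diagnosis mixture of the included cohort (healthy ageing, MCI, AD, other
#: dementias), assigned by latent-impairment rank.
DIAGNOSIS_PROPORTIONS = (("healthy", 9), ("MCI", 15), ("AD", 30), ("other-dementia", 10))


@dataclass
class CohortConfig:
    """Generator settings; defaults define the reference study conditions."""

    n_subjects: int = 64
    n_regions: int = 103
    fs: float = 500.0
    duration: float = 300.0
    seed: int = 0

    # aperiodic floor: offset / f**exponent, subject-level (mean, SD)
    aperiodic_offset: tuple[float, float] = (1.0, 0.15)
    aperiodic_exponent: tuple[float, float] = (1.0, 0.1)

    # oscillatory peaks
    alpha_peak_freq_mean: float = 9.5  # Hz
    alpha_peak_freq_slope: float = -0.5  # Hz per unit latent impairment (<0: slowing)
    alpha_peak_amp: tuple[float, float] = (0.4, 0.08)
    peak_width: float = 1.5  # Gaussian SD, Hz
    theta_freq: float = 5.5  # Hz
    theta_base: float = 0.1
    theta_bump_gain: float = 0.08  # peak amplitude per unit latent impairment
    theta_noise_sd: float = 0.03

    # within-subject regional variability
    alpha_freq_subject_sd: float = 0.3  # Hz
    alpha_freq_region_sd: float = 0.2  # Hz
    region_jitter_sd: float = 0.15  # lognormal sigma on peak amplitudes

    covariate_loadings: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_LOADINGS)
    )
    adjacency_scheme: str = "lattice"
    adjacency_path: str | None = None

    # extra roster records carrying exclusion flags (appended after the
    # n_subjects analyzable records)
    n_excluded_non_dementia: int = 0
    n_excluded_undiagnosed: int = 0
    n_excluded_artifact: int = 0
    fab_missing: int = 0  # included subjects without a FAB score

    freq_step: float = 0.25  # Hz, analytic spectrum grid over 1-70 Hz

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ConfigurationError("n_subjects must be >= 3")
        if self.n_regions < 1:
            raise ConfigurationError("n_regions must be >= 1")
        if self.fs <= 140.0:
            raise ConfigurationError("fs must exceed 140 Hz (Nyquist above 70 Hz)")
        if self.duration < 10.0:
            raise ConfigurationError("duration must be >= 10 s")
        for name, pair in (
            ("aperiodic_offset", self.aperiodic_offset),
            ("aperiodic_exponent", self.aperiodic_exponent),
            ("alpha_peak_amp", self.alpha_peak_amp),
        ):
            if pair[1] < 0:
                raise ConfigurationError(f"{name} SD must be >= 0")
        for name, sd in (
            ("theta_noise_sd", self.theta_noise_sd),
            ("alpha_freq_subject_sd", self.alpha_freq_subject_sd),
            ("alpha_freq_region_sd", self.alpha_freq_region_sd),
            ("region_jitter_sd", self.region_jitter_sd),
        ):
            if sd < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.peak_width <= 0:
            raise ConfigurationError("peak_width must be > 0")
        for cov, load in self.covariate_loadings.items():
            if len(load) != 3 or load[2] < 0:
                raise ConfigurationError(
                    f"covariate_loadings[{cov!r}] must be (intercept, slope, noise_sd >= 0)"
                )
        if self.freq_step <= 0 or self.freq_step > 5:
            raise ConfigurationError("freq_step must be in (0, 5] Hz")

    def frequency_grid(self) -> np.ndarray:
        return np.arange(1.0, 70.0 + self.freq_step / 2, self.freq_step)


@dataclass
class GroundTruth:
    """Everything the generator knows and the analysis tries to recover."""

    latent: np.ndarray  # per roster record
    freqs: np.ndarray
    spectra: np.ndarray  # (n_records, n_regions, n_freqs), strictly positive
    covariates: pd.DataFrame  # as generated, indexed by subject id
    planted_signs: dict[tuple[str, str], int]
    subject_ids: list[str]
    region_labels: list[str]
    config: CohortConfig


def _gaussian(freqs: np.ndarray, mu: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((freqs - mu) / sigma) ** 2)


def _clip_round(name: str, values: np.ndarray) -> np.ndarray:
    lo, hi = COVARIATE_RANGES.get(name, (None, None))
    values = np.clip(values, lo, hi)
    if name in INTEGER_COVARIATES:
        values = np.round(values)
    return values


def _planted_signs(config: CohortConfig) -> dict[tuple[str, str], int]:
    """Expected correlation sign for each (parameter, covariate) pair.

    The latent factor raises theta power (RPt up, MF down) and slows the
    alpha peak (IAF down); each covariate's sign follows from its loading.
    """
    param_sign = {
        "RPt": int(np.sign(config.theta_bump_gain)),
        "MF": -int(np.sign(config.theta_bump_gain)) or int(np.sign(config.alpha_peak_freq_slope)),
        "IAF": int(np.sign(config.alpha_peak_freq_slope)),
    }
    signs: dict[tuple[str, str], int] = {}
    for cov, (_, slope, _) in config.covariate_loadings.items():
        for param, ps in param_sign.items():
            signs[(param, cov)] = int(ps * np.sign(slope))
    return signs


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a cohort roster plus its spectral/covariate ground truth.

    The roster has ``n_subjects`` analyzable records followed by the
    configured number of exclusion-flagged records (non-dementia diagnosis,
    undiagnosed, severe MEG artifact), so the exclusion filter can be
    exercised on realistic input.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_extra = (
        config.n_excluded_non_dementia
        + config.n_excluded_undiagnosed
        + config.n_excluded_artifact
    )
    n_total = config.n_subjects + n_extra
    n_regions = config.n_regions

    latent = rng.standard_normal(n_total)

    # covariates: linear-Gaussian in the latent, clipped to instrument range
    cov_data: dict[str, np.ndarray] = {}
    for name, (intercept, slope, noise_sd) in config.covariate_loadings.items():
        raw = intercept + slope * latent + noise_sd * rng.standard_normal(n_total)
        cov_data[name] = _clip_round(name, raw)

    # subject-level spectral parameters
    o_mean, o_sd = config.aperiodic_offset
    e_mean, e_sd = config.aperiodic_exponent
    a_mean, a_sd = config.alpha_peak_amp
    offset = np.clip(o_mean + o_sd * rng.standard_normal(n_total), 0.05, None)
    exponent = e_mean + e_sd * rng.standard_normal(n_total)
    alpha_amp = np.clip(a_mean + a_sd * rng.standard_normal(n_total), 0.02, None)
    alpha_freq = (
        config.alpha_peak_freq_mean
        + config.alpha_peak_freq_slope * latent
        + config.alpha_freq_subject_sd * rng.standard_normal(n_total)
    )
    theta_amp = np.clip(
        config.theta_base
        + config.theta_bump_gain * latent
        + config.theta_noise_sd * rng.standard_normal(n_total),
        0.0,
        None,
    )

    # per-region jitter around the subject-level values
    shape = (n_total, n_regions)
    alpha_amp_r = alpha_amp[:, None] * np.exp(
        config.region_jitter_sd * rng.standard_normal(shape)
    )
    theta_amp_r = theta_amp[:, None] * np.exp(
        config.region_jitter_sd * rng.standard_normal(shape)
    )
    alpha_freq_r = np.clip(
        alpha_freq[:, None] + config.alpha_freq_region_sd * rng.standard_normal(shape),
        6.0,
        13.0,
    )

    freqs = config.frequency_grid()
    floor = offset[:, None, None] / freqs[None, None, :] ** exponent[:, None, None]
    spectra = (
        floor
        + alpha_amp_r[:, :, None] * _gaussian(freqs, alpha_freq_r[:, :, None], config.peak_width)
        + theta_amp_r[:, :, None] * _gaussian(freqs, config.theta_freq, config.peak_width)
    )

    subject_ids = [f"S{i + 1:03d}" for i in range(n_total)]
    region_labels = [f"R{i + 1:03d}" for i in range(n_regions)]

    # diagnoses for the analyzable records, by latent rank
    diagnosis = np.empty(n_total, dtype=object)
    order = np.argsort(latent[: config.n_subjects])
    counts = [c for _, c in DIAGNOSIS_PROPORTIONS]
    bounds = np.cumsum(
        np.round(np.array(counts) / sum(counts) * config.n_subjects).astype(int)
    )
    bounds[-1] = config.n_subjects
    start = 0
    for (label, _), stop in zip(DIAGNOSIS_PROPORTIONS, bounds):
        diagnosis[order[start:stop]] = label
        start = stop
    artifact = np.zeros(n_total, dtype=bool)
    k = config.n_subjects
    diagnosis[k : k + config.n_excluded_non_dementia] = "non-dementia"
    k += config.n_excluded_non_dementia
    diagnosis[k : k + config.n_excluded_undiagnosed] = "undiagnosed"
    k += config.n_excluded_undiagnosed
    # artifact-flagged records carry an ordinary dementia diagnosis
    diagnosis[k:] = "AD"
    artifact[k:] = True

    fab = cov_data["fab"].astype(float) if "fab" in cov_data else np.full(n_total, np.nan)
    for i in range(min(config.fab_missing, config.n_subjects)):
        fab[i] = np.nan

    roster = pd.DataFrame(
        {
            "id": subject_ids,
            "age": cov_data.get("age", np.full(n_total, np.nan)),
            "diagnosis": diagnosis,
            "mmse": cov_data.get("mmse", np.full(n_total, np.nan)),
            "fab": fab,
            "severity": cov_data.get("severity", np.full(n_total, np.nan)),
            "extent": cov_data.get("extent", np.full(n_total, np.nan)),
            "ratio": cov_data.get("ratio", np.full(n_total, np.nan)),
            "meg_artifact_severe": artifact,
        }
    )
    covariates = roster.drop(columns=["diagnosis", "meg_artifact_severe"]).set_index("id")
    truth = GroundTruth(
        latent=latent,
        freqs=freqs,
        spectra=spectra,
        covariates=covariates,
        planted_signs=_planted_signs(config),
        subject_ids=subject_ids,
        region_labels=region_labels,
        config=config,
    )
    return roster, truth


# ---------------------------------------------------------------------------
# time-series realization
# ---------------------------------------------------------------------------


def shape_noise(
    target_freqs: np.ndarray,
    target_psd: np.ndarray,
    fs: float,
    duration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One realization of a stationary Gaussian surrogate with a given PSD.

    Inverse-FFT spectral shaping: rFFT amplitudes are fixed by the target
    one-sided PSD (linearly interpolated onto the realization grid, held at
    its lowest-frequency value below the grid and tapered to zero above it)
    and phases are i.i.d. uniform.  The empirical PSD converges to the
    target as duration grows.
    """
    n_samples = int(round(duration * fs))
    grid = np.fft.rfftfreq(n_samples, 1.0 / fs)
    target = np.interp(grid, target_freqs, target_psd, left=target_psd[0], right=0.0)
    amp = np.sqrt(target * fs * n_samples / 2.0)
    amp[0] = 0.0
    if n_samples % 2 == 0:
        amp[-1] = 0.0
    phases = rng.uniform(0.0, 2.0 * np.pi, size=grid.size)
    return np.fft.irfft(amp * np.exp(1j * phases), n_samples)


def synthesize_timeseries(
    truth: GroundTruth,
    subject_index: int,
    duration: float | None = None,
    fs: float | None = None,
) -> RegionTimeSeries:
    """Realize one subject's region x time signal from the target spectra.

    Each region's phase stream is keyed by (cohort seed, subject, region),
    so realizations are bit-identical on rerun and independent across
    regions, subjects and the roster-level draws.
    """
    config = truth.config
    fs = config.fs if fs is None else fs
    duration = config.duration if duration is None else duration
    if fs / 2 < 70.0:
        raise ConfigurationError("fs/2 must reach 70 Hz to realize the target spectrum")
    rows = []
    for r in range(len(truth.region_labels)):
        rng = np.random.default_rng((config.seed, subject_index, r))
        rows.append(
            shape_noise(truth.freqs, truth.spectra[subject_index, r], fs, duration, rng)
        )
    return RegionTimeSeries(
        subject_id=truth.subject_ids[subject_index],
        fs=fs,
        region_labels=list(truth.region_labels),
        data=np.vstack(rows),
    )


# ---------------------------------------------------------------------------
# adjacency and Z maps
# ---------------------------------------------------------------------------


def generate_adjacency(
    n_regions: int,
    scheme: str = "lattice",
    seed: int | None = None,
    labels: list[str] | None = None,
    path: str | None = None,
) -> RegionAdjacency:
    """Region adjacency graph: 2-D lattice (default), random geometric, or file.

    The lattice embeds region indices row-major on a near-square grid with
    4-neighbour connectivity, which is connected for any n_regions >= 1.
    """
    if n_regions < 1:
        raise ConfigurationError("n_regions must be >= 1")
    if labels is None:
        labels = [f"R{i + 1:03d}" for i in range(n_regions)]
    if len(labels) != n_regions:
        raise SchemaError("labels length must equal n_regions")
    if scheme == "lattice":
        ncols = math.ceil(math.sqrt(n_regions))
        edges = []
        for i in range(n_regions):
            if (i + 1) % ncols != 0 and i + 1 < n_regions:
                edges.append((i, i + 1))
            if i + ncols < n_regions:
                edges.append((i, i + ncols))
        return RegionAdjacency(labels=labels, edges=np.array(edges, dtype=int).reshape(-1, 2))
    if scheme == "random-geometric":
        import networkx as nx

        radius = 2.0 / math.sqrt(max(n_regions, 2))
        g = nx.random_geometric_graph(n_regions, radius, seed=seed)
        return RegionAdjacency(
            labels=labels, edges=np.array(list(g.edges), dtype=int).reshape(-1, 2)
        )
    if scheme == "file":
        if path is None:
            raise ConfigurationError("adjacency_path is required for scheme='file'")
        table = pd.read_csv(path, sep="\t")
        pairs = list(zip(table.iloc[:, 0].astype(str), table.iloc[:, 1].astype(str)))
        return RegionAdjacency.from_edge_labels(labels, pairs)
    raise ConfigurationError(f"unknown adjacency scheme {scheme!r}")


def generate_zmap(
    latent: float,
    n_voxels_voi: int = 2000,
    n_voxels_brain: int = 20000,
    seed: int | None = None,
    voi_base: float = 1.3,
    voi_gain: float = 0.5,
    brain_base: float = 0.3,
    brain_gain: float = 0.1,
    sd: float = 1.0,
) -> ZScoreMap:
    """Voxelwise Z map whose VOI mean rises with latent impairment."""
    if n_voxels_voi > n_voxels_brain:
        raise ConfigurationError("n_voxels_voi cannot exceed n_voxels_brain")
    rng = np.random.default_rng(seed)
    z = np.empty(n_voxels_brain)
    z[:n_voxels_voi] = voi_base + voi_gain * latent + sd * rng.standard_normal(n_voxels_voi)
    z[n_voxels_voi:] = brain_base + brain_gain * latent + sd * rng.standard_normal(
        n_voxels_brain - n_voxels_voi
    )
    voi = np.zeros(n_voxels_brain, dtype=bool)
    voi[:n_voxels_voi] = True
    return ZScoreMap(z=z, voi_mask=voi, brain_mask=np.ones(n_voxels_brain, dtype=bool))


# ---------------------------------------------------------------------------
# analytic parameters (no time-series detour)
# ---------------------------------------------------------------------------


def _parameters_from_spectra(
    freqs: np.ndarray, spectra: np.ndarray
) -> dict[str, np.ndarray]:
    """Oscillatory parameters evaluated directly on target spectra.

    The target spectrum *is* the population PSD, so normalizing it on the
    analytic grid and applying the estimator's parameter definitions gives
    the noise-free parameter values the time-series route converges to.
    """
    n, r, f = spectra.shape
    flat = spectra.reshape(n * r, f)
    psdn = flat / flat.sum(axis=-1, keepdims=True)
    params = compute_parameters(NormalizedSpectrum(freqs=freqs, psdn=psdn))
    return {k: v.reshape(n, r) for k, v in params.items()}


def regional_parameters(truth: GroundTruth) -> dict[str, pd.DataFrame]:
    """Per-parameter subjects x regions tables from the target spectra."""
    params = _parameters_from_spectra(truth.freqs, truth.spectra)
    return {
        k: pd.DataFrame(v, index=truth.subject_ids, columns=truth.region_labels)
        for k, v in params.items()
    }


def global_parameters(truth: GroundTruth) -> pd.DataFrame:
    """Subjects x 11 table of region-averaged parameters."""
    params = _parameters_from_spectra(truth.freqs, truth.spectra)
    return pd.DataFrame(
        {k: v.mean(axis=1) for k, v in params.items()}, index=truth.subject_ids
    )


# ---------------------------------------------------------------------------
# planted regional effect
# ---------------------------------------------------------------------------


def contiguous_patch(adjacency: RegionAdjacency, size: int, start: int = 0) -> np.ndarray:
    """Indices of a connected patch of ``size`` regions grown from ``start``."""
    csr = adjacency.matrix()
    seen = [start]
    frontier = [start]
    in_patch = {start}
    while frontier and len(seen) < size:
        node = frontier.pop(0)
        for nb in csr[node].indices:
            if nb not in in_patch:
                in_patch.add(int(nb))
                seen.append(int(nb))
                frontier.append(int(nb))
                if len(seen) == size:
                    break
    if len(seen) < size:
        raise ConfigurationError("adjacency component smaller than requested patch")
    return np.array(sorted(seen), dtype=int)


def planted_patch_cohort(
    n_subjects: int = 64,
    n_regions: int = 103,
    patch_size: int = 10,
    target_spearman: float = 0.45,
    seed: int = 0,
    adjacency: RegionAdjacency | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, RegionAdjacency]:
    """Cohort with a theta-covariate effect planted in one contiguous patch.

    The covariate ``c`` is standard normal; inside the patch each region's
    theta-bump amplitude is a strictly increasing transform of a Gaussian
    latent correlated with ``c`` such that the population Spearman
    correlation between ``c`` and regional theta relative power equals
    ``target_spearman`` (the Gaussian rank-correlation identity
    ``r = 2 sin(pi * rho_s / 6)`` fixes the Pearson mixing weight; RPt is a
    strictly monotone function of the bump amplitude when the rest of the
    spectrum is held fixed, so ranks are preserved).  Off-patch regions use
    independent latents.

    Returns ``(P, c, patch_indices, adjacency)`` with ``P`` the subjects x
    regions RPt matrix.
    """
    if not 0.0 <= abs(target_spearman) < 1.0:
        raise ConfigurationError("target_spearman must lie in (-1, 1)")
    if adjacency is None:
        adjacency = generate_adjacency(n_regions)
    patch = contiguous_patch(adjacency, patch_size)
    rng = np.random.default_rng(seed)
    c = rng.standard_normal(n_subjects)
    r = 2.0 * np.sin(np.pi * target_spearman / 6.0)
    gain = rng.standard_normal((n_subjects, n_regions))
    gain[:, patch] = r * c[:, None] + np.sqrt(1.0 - r**2) * gain[:, patch]
    theta_amp = 0.15 * np.exp(0.4 * gain)  # strictly increasing in the latent

    freqs = np.arange(1.0, 70.25, 0.25)
    base = 1.0 / freqs + 0.4 * _gaussian(freqs, 9.5, 1.5)
    spectra = base[None, None, :] + theta_amp[:, :, None] * _gaussian(freqs, 5.5, 1.5)
    params = _parameters_from_spectra(freqs, spectra)
    return params["RPt"], c, patch, adjacency
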