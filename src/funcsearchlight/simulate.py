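"""Synthetic multi-subject fMRI with controllable signal dispersion.

The generator plants a known model signal into a controllable set of voxels:
signal locations are the top values of a Gaussian random field (GRF) whose
smoothness (FWHM) dials the signal from anatomically distributed (low FWHM)
to localized (high FWHM). Signal time courses are model feature units
convolved with a double-gamma HRF at a fixed percent signal change, added to
baseline plus spatially smoothed AR(1) noise. All randomness flows from one
seed, so cohorts are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve, lfilter
from scipy.stats import gamma as gamma_dist

from .kernels import FeatureSeries, LocalizerDesign
from .volume_io import BrainMask, MaskedBold

__all__ = [
    "NoiseSpec",
    "SimulationSpec",
    "GroundTruth",
    "sample_grf_signal_voxels",
    "double_gamma_hrf",
    "simulate_subject",
    "simulate_cohort",
    "synthetic_features",
    "synthetic_localizer_design",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class NoiseSpec:
    """Parametric BOLD noise: AR(1) in time, Gaussian-smoothed in space.

    ``sd`` is the noise standard deviation in baseline units. The default
    0.125 (0.125% of baseline against a 0.5% peak signal change) is the
    evidence-matched scaled-down operating point: the full-scale studies fit
    the shared space on roughly 37x more subject-timepoints than the default
    synthetic cohort, so the per-sample contrast-to-noise is raised by about
    the square root of that factor to keep the planted structure as
    recoverable as it is at full scale.
    """

    ar_coef: float = 0.3
    spatial_fwhm: float = 2.0
    baseline: float = 100.0
    sd: float = 0.125


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic cohort."""

    mask: BrainMask
    n_subjects: int = 16
    t: int = 200
    tr_seconds: float = 1.5
    fwhm_voxels: float = 0.5
    n_signal_voxels: int = 128
    percent_signal_change: float = 0.5
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    psc_scaling: str = "peak"  # "peak" | "std"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signal_voxels > self.mask.n_voxels:
            raise ValueError("more signal voxels than mask voxels")
        if self.fwhm_voxels <= 0:
            raise ValueError("fwhm_voxels must be positive")
        if self.percent_signal_change < 0:
            raise ValueError("percent_signal_change must be >= 0")
        if self.psc_scaling not in ("peak", "std"):
            raise ValueError("psc_scaling must be 'peak' or 'std'")


@dataclass(frozen=True)
class GroundTruth:
    """Where the signal went: planted voxel ids and the source features."""

    signal_voxel_ids: np.ndarray
    feature_series: FeatureSeries


def sample_grf_signal_voxels(
    mask: BrainMask,
    fwhm_voxels: float,
    n_signal: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Signal-voxel ids from the top values of a smoothed Gaussian field.

    White noise on the full bounding grid is smoothed with a Gaussian kernel
    of the given FWHM (sigma = FWHM / (2 sqrt(2 ln 2))); the ``n_signal``
    in-mask voxels with the highest field values are selected. High FWHM
    clusters the selection; FWHM near zero approaches uniform sampling.
    """
    if n_signal > mask.n_voxels:
        raise ValueError("n_signal exceeds the in-mask voxel count")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    field_grid = rng.standard_normal(mask.shape)
    field_grid = gaussian_filter(field_grid, sigma=fwhm_voxels * FWHM_TO_SIGMA)
    values = field_grid[tuple(mask.voxels.T)]
    ids = np.arange(mask.n_voxels)
    order = np.lexsort((ids, -values))  # ties broken by ascending id
    return np.sort(ids[order[:n_signal]])


def double_gamma_hrf(tr_seconds: float, duration_seconds: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at the TR.

    Response gamma peaks at 6 s, undershoot gamma at 16 s with a 1/6
    amplitude ratio; the kernel is normalized to peak 1 and starts at 0.
    """
    if duration_seconds < 30.0:
        raise ValueError("duration must cover the undershoot (>= 30 s)")
    t = np.arange(0.0, duration_seconds + 1e-9, tr_seconds)
    h = gamma_dist.pdf(t, a=7.0, scale=1.0) - gamma_dist.pdf(t, a=17.0, scale=1.0) / 6.0
    return h / h.max()


def _noise_volume(
    mask: BrainMask, t: int, noise: NoiseSpec, rng: np.random.Generator
) -> np.ndarray:
    """(v, t) noise: spatially smoothed white noise with AR(1) dynamics."""
    grid = rng.standard_normal(mask.shape + (t,))
    if noise.spatial_fwhm > 0:
        sigma = noise.spatial_fwhm * FWHM_TO_SIGMA
        grid = gaussian_filter(grid, sigma=(sigma, sigma, sigma, 0.0))
        grid /= grid.std()  # restore unit marginal variance after smoothing
    if noise.ar_coef:
        grid = lfilter([1.0], [1.0, -noise.ar_coef], grid, axis=-1)
        grid *= np.sqrt(1.0 - noise.ar_coef**2)  # stationary unit variance
    return noise.baseline + noise.sd * grid[tuple(mask.voxels.T)]


def _signal_block(
    features: FeatureSeries, spec: SimulationSpec
) -> np.ndarray:
    """HRF-convolved, amplitude-scaled signal time courses (n_signal, t)."""
    hrf = double_gamma_hrf(spec.tr_seconds)
    conv = fftconvolve(features.values, hrf[None, :], axes=1)[:, : spec.t]
    amp = spec.percent_signal_change / 100.0 * spec.noise.baseline
    if spec.psc_scaling == "peak":
        scale = np.abs(conv).max(axis=1)
    else:
        scale = conv.std(axis=1)
    scale[scale == 0] = 1.0
    return conv * (amp / scale)[:, None]


def simulate_subject(
    spec: SimulationSpec,
    features: FeatureSeries,
    seed: int | np.random.Generator = 0,
) -> tuple[MaskedBold, GroundTruth]:
    """One subject's volume: planted HRF-convolved signal plus noise.

    ``features`` must have one unit row per signal voxel; unit i drives the
    i-th selected signal voxel. The signal amplitude is
    ``percent_signal_change/100 * baseline`` at the convolved time course's
    peak (or its standard deviation with ``psc_scaling="std"``).
    """
    if features.n_features != spec.n_signal_voxels:
        raise ValueError(
            f"features have {features.n_features} units but spec plants "
            f"{spec.n_signal_voxels} signal voxels"
        )
    if features.n_trs < spec.t:
        raise ValueError("feature series shorter than the requested t")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signal_ids = sample_grf_signal_voxels(
        spec.mask, spec.fwhm_voxels, spec.n_signal_voxels, rng
    )
    data = _noise_volume(spec.mask, spec.t, spec.noise, rng)
    feats = FeatureSeries(values=features.values[:, : spec.t], label=features.label)
    data[signal_ids] += _signal_block(feats, spec)
    bold = MaskedBold(
        data=data,
        coords=spec.mask.voxels.copy(),
        tr_seconds=spec.tr_seconds,
        subject_id="sim",
        mask=spec.mask,
    )
    return bold, GroundTruth(signal_voxel_ids=signal_ids, feature_series=feats)


def simulate_cohort(
    spec: SimulationSpec,
    shared_rank: int | None = 8,
    seed: int | None = None,
) -> tuple[list[MaskedBold], list[GroundTruth], FeatureSeries]:
    """Multi-subject cohort driven by one common feature series.

    All subjects share the same signal time courses (guaranteeing the
    low-rank shared structure the SRM models) but receive subject-specific
    signal-voxel placements from independent GRF draws. ``shared_rank``
    limits the rank of the common feature series; ``shared_rank=0`` (or
    ``None``) plants no low-rank constraint / no signal respectively.
    """
    seed = spec.seed if seed is None else seed
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x5EED])
    feat_rng, *subject_rngs = [np.random.default_rng(s) for s in ss.spawn(spec.n_subjects + 1)]
    features = synthetic_features(
        kind="layer",
        dims=spec.n_signal_voxels,
        t=spec.t,
        seed=feat_rng,
        rank=shared_rank,
    )
    if shared_rank == 0:
        features = FeatureSeries(values=np.zeros_like(features.values), label="null")
    bolds, truths = [], []
    for i, rng in enumerate(subject_rngs):
        bold, truth = simulate_subject(spec, features, seed=rng)
        bolds.append(
            MaskedBold(
                data=bold.data,
                coords=bold.coords,
                tr_seconds=bold.tr_seconds,
                subject_id=f"sim{i:02d}",
                mask=spec.mask,
            )
        )
        truths.append(truth)
    return bolds, truths, features


def _smooth_latents(
    dims: int, t: int, rng: np.random.Generator, timescale_trs: float
) -> np.ndarray:
    """Gaussian-process-like rows: white noise smoothed along time."""
    x = rng.standard_normal((dims, t))
    if timescale_trs > 0:
        x = gaussian_filter(x, sigma=(0.0, timescale_trs))
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def synthetic_features(
    kind: str,
    dims: int,
    t: int | dict = 200,
    seed: int | np.random.Generator = 0,
    timescale_trs: float = 3.0,
    rank: int | None = None,
) -> FeatureSeries | LocalizerDesign:
    """Stand-in model features: DNN-layer-like or embedding-like series.

    ``layer`` and ``embedding`` kinds return smooth (temporally
    autocorrelated) unit time courses, optionally mixed from ``rank`` latent
    sources so the series has known low-rank structure. ``localizer``
    dispatches to :func:`synthetic_localizer_design` with ``t`` as a dict of
    design options.
    """
    if dims < 1:
        raise ValueError("dims must be >= 1")
    if kind == "localizer":
        opts = dict(t) if isinstance(t, dict) else {}
        return synthetic_localizer_design(n_voxels=dims, seed=seed, **opts)
    if kind not in ("layer", "embedding"):
        raise ValueError(f"unknown feature kind {kind!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rank is not None and 0 < rank < dims:
        latents = _smooth_latents(rank, int(t), rng, timescale_trs)
        mix = rng.standard_normal((dims, rank)) / np.sqrt(rank)
        values = mix @ latents
    else:
        values = _smooth_latents(dims, int(t), rng, timescale_trs)
    return FeatureSeries(values=values, label=kind)


def synthetic_localizer_design(
    n_voxels: int,
    n_categories: int = 6,
    blocks_per_category_per_run: int = 2,
    n_runs: int = 4,
    effect_sd: float = 1.0,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> LocalizerDesign:
    """Balanced block-design localizer patterns with category-specific means.

    Defaults mirror a standard 6-category localizer with two blocks per
    category in each of four runs (48 examples). ``effect_sd=0`` produces
    pure-noise examples (chance-level decodable).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prototypes = effect_sd * rng.standard_normal((n_categories, n_voxels))
    examples, labels, runs = [], [], []
    for run in range(n_runs):
        for cat in range(n_categories):
            for _ in range(blocks_per_category_per_run):
                examples.append(prototypes[cat] + noise_sd * rng.standard_normal(n_voxels))
                labels.append(f"cat{cat}")
                runs.append(run)
    return LocalizerDesign(
        examples=np.asarray(examples), labels=np.asarray(labels), run_ids=np.asarray(runs)
    )
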