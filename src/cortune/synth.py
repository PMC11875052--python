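"""Forward model: ground-truth tuned populations and synthetic imaging sessions.

Every analysis stage in this package is verified against sessions generated
here, with known (implanted) tuning structure:

* neurons carry a characteristic frequency (CF), a threshold at CF, and a
  V-shaped frequency-response area whose threshold rises linearly in octave
  distance from CF;
* responses are convolved with a slow-indicator (GCaMP6s-like)
  double-exponential kernel;
* raw traces add a baseline fluorescence, multiplicative slow drift, a
  shared low-pass neuropil signal, and white noise, mirroring what the
  extraction pipeline hands to the real analysis;
* genotype presets place CF mass and thresholds according to the hearing
  phenotypes under study (normal hearing, high-frequency threshold
  elevation, near-total loss).

Positions are laid out along a tonotopic axis: each preset's CF class
probabilities double as axis span fractions, so the implanted neuron-mass
fraction per frequency band and the implanted areal fraction coincide by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grid import StimulusGrid, StimulusLog

__all__ = [
    "GroundTruthNeuron",
    "GroundTruthPopulation",
    "NoiseConfig",
    "SessionData",
    "WidefieldMovie",
    "PRESETS",
    "generate_ground_truth",
    "mean_response",
    "calcium_kernel",
    "synthesize_session",
    "synthesize_widefield",
    "quantize_threshold",
]

RESPONSE_TYPES = ("onset", "offset", "onset_offset", "silent")

# fraction of neurons per response type (silent ones still fluoresce)
RESPONSE_TYPE_PROBS = {"onset": 0.60, "offset": 0.10, "onset_offset": 0.15, "silent": 0.15}

SENTINEL_DB = 110.0


@dataclass(frozen=True)
class GroundTruthNeuron:
    """Implanted tuning parameters for one simulated neuron."""

    position_um: tuple[float, float]
    cf_khz: float
    threshold_db: float  # threshold at CF, in [0, 110]
    slope_db_per_octave: float
    amplitude: float  # peak dF/F
    response_type: str
    f0: float  # baseline fluorescence, a.u.

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not (0 <= self.threshold_db <= SENTINEL_DB):
            raise ValueError("threshold_db must lie in [0, 110]")
        if self.response_type not in RESPONSE_TYPES:
            raise ValueError(f"unknown response type {self.response_type!r}")


@dataclass
class GroundTruthPopulation:
    neurons: list[GroundTruthNeuron]
    genotype_preset: str
    field_size_um: float
    tonotopic_axis: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        for n in self.neurons:
            x, y = n.position_um
            if not (0 <= x <= self.field_size_um and 0 <= y <= self.field_size_um):
                raise ValueError("neuron position outside field")

    def __len__(self) -> int:
        return len(self.neurons)

    @property
    def positions_um(self) -> np.ndarray:
        return np.array([n.position_um for n in self.neurons], dtype=float).reshape(-1, 2)

    @property
    def cf_khz(self) -> np.ndarray:
        return np.array([n.cf_khz for n in self.neurons], dtype=float)

    @property
    def thresholds_db(self) -> np.ndarray:
        return np.array([n.threshold_db for n in self.neurons], dtype=float)

    def to_records(self) -> list[dict]:
        return [
            {
                "x_um": n.position_um[0],
                "y_um": n.position_um[1],
                "cf_khz": n.cf_khz,
                "threshold_db": n.threshold_db,
                "slope_db_per_octave": n.slope_db_per_octave,
                "amplitude": n.amplitude,
                "response_type": n.response_type,
                "f0": n.f0,
            }
            for n in self.neurons
        ]


@dataclass(frozen=True)
class NoiseConfig:
    """Nuisance-process parameters for synthesized sessions."""

    trace_sigma: float = 2.0  # additive white noise SD, a.u.
    neuropil_gain: float = 0.7  # coupling of the shared background into ROI traces
    neuropil_baseline: float = 30.0  # mean neuropil fluorescence, a.u.
    drift_amplitude: float = 0.10  # multiplicative slow-drift amplitude
    drift_period_s: float = 300.0
    rise_s: float = 0.18  # indicator kernel rise time constant
    decay_s: float = 1.5  # indicator kernel decay time constant
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trace_sigma < 0:
            raise ValueError("trace_sigma must be >= 0")
        if self.rise_s <= 0 or self.decay_s <= 0:
            raise ValueError("kernel time constants must be positive")


# genotype presets: per-CF-class probability (== tonotopic axis span) and
# per-class (mean, sd) of the threshold at CF, in dB SPL.  Means and spreads
# follow the measured group statistics for each cohort; near-total loss is
# encoded by pushing the threshold mass to the 110 dB sentinel.
PRESETS: dict[str, dict] = {
    "ahl_b6_2p5mo": {
        "cf_probs": {4.0: 0.25, 8.0: 0.35, 16.0: 0.26, 32.0: 0.08, 64.0: 0.06},
        "thresholds": {4.0: (40, 20), 8.0: (30, 10), 16.0: (40, 10), 32.0: (80, 30), 64.0: (80, 20)},
    },
    "ahl_b6_6mo": {
        "cf_probs": {4.0: 0.40, 8.0: 0.30, 16.0: 0.20, 32.0: 0.06, 64.0: 0.04},
        "thresholds": {4.0: (70, 20), 8.0: (70, 20), 16.0: (80, 20), 32.0: (115, 5), 64.0: (115, 5)},
    },
    "ahl_plus_b6": {
        "cf_probs": {4.0: 0.20, 8.0: 0.20, 16.0: 0.20, 32.0: 0.20, 64.0: 0.20},
        "thresholds": {4.0: (40, 20), 8.0: (30, 10), 16.0: (40, 10), 32.0: (32, 5), 64.0: (34, 8)},
    },
    "ahl_plus_b6cba": {
        "cf_probs": {4.0: 0.20, 8.0: 0.20, 16.0: 0.20, 32.0: 0.20, 64.0: 0.20},
        "thresholds": {4.0: (40, 20), 8.0: (30, 10), 16.0: (40, 10), 32.0: (30, 0), 64.0: (33, 8)},
    },
    "uniform": {
        "cf_probs": {4.0: 0.20, 8.0: 0.20, 16.0: 0.20, 32.0: 0.20, 64.0: 0.20},
        "thresholds": {4.0: (45, 20), 8.0: (45, 20), 16.0: (45, 20), 32.0: (45, 20), 64.0: (45, 20)},
    },
}

DEFAULT_SLOPE_DB_PER_OCTAVE = 30.0
AMPLITUDE_MEDIAN = 0.5  # log-normal median peak dF/F
AMPLITUDE_LOG_SIGMA = 0.4
F0_MEDIAN = 100.0
F0_LOG_SIGMA = 0.3
POSITION_JITTER_UM = 30.0  # tonotopic scatter along the axis


def quantize_threshold(value: float, levels_db) -> float:
    """Quantize a threshold to the measurable grid.

    The measurable grid is the presented level set extended one 20 dB step
    below its minimum (a neuron that responds at the lowest presented level
    needs an implanted threshold strictly below it) plus the 110 dB sentinel
    for "no response at the highest presented level".
    """
    levels = np.sort(np.asarray(levels_db, dtype=float))
    step = levels[1] - levels[0] if len(levels) > 1 else 20.0
    targets = np.concatenate([[levels[0] - step], levels, [SENTINEL_DB]])
    targets = targets[targets >= 0]
    return float(targets[np.argmin(np.abs(targets - value))])


def generate_ground_truth(
    n_neurons: int,
    genotype_preset: str,
    grid: StimulusGrid,
    seed: int,
    field_size_um: float = 1000.0,
    slope_db_per_octave: float = DEFAULT_SLOPE_DB_PER_OCTAVE,
) -> GroundTruthPopulation:
    """Draw a tonotopically organized population from a genotype preset.

    Positions are uniform over the square field; the CF class of a neuron is
    the tonotopic-axis zone containing its (jittered) x coordinate, with
    zone widths equal to the preset's CF class probabilities.  Thresholds at
    CF are drawn from the preset's per-class Normal and quantized to the
    measurable level grid.
    """
    if n_neurons < 0:
        raise ValueError("n_neurons must be >= 0")
    if genotype_preset not in PRESETS:
        raise ValueError(f"unknown preset {genotype_preset!r}; known: {sorted(PRESETS)}")
    preset = PRESETS[genotype_preset]
    rng = np.random.default_rng(seed)

    cf_classes = np.array(sorted(preset["cf_probs"]), dtype=float)
    probs = np.array([preset["cf_probs"][c] for c in cf_classes], dtype=float)
    probs = probs / probs.sum()
    zone_edges = np.concatenate([[0.0], np.cumsum(probs)]) * field_size_um

    neurons: list[GroundTruthNeuron] = []
    for _ in range(n_neurons):
        x = rng.uniform(0, field_size_um)
        y = rng.uniform(0, field_size_um)
        x_tono = np.clip(x + rng.normal(0, POSITION_JITTER_UM), 0, field_size_um)
        ci = int(np.clip(np.searchsorted(zone_edges, x_tono, side="right") - 1, 0, len(cf_classes) - 1))
        cf = float(cf_classes[ci])
        mu, sd = preset["thresholds"][cf]
        theta = quantize_threshold(rng.normal(mu, sd), grid.levels_db)
        rtype = rng.choice(list(RESPONSE_TYPE_PROBS), p=list(RESPONSE_TYPE_PROBS.values()))
        amplitude = float(AMPLITUDE_MEDIAN * np.exp(rng.normal(0, AMPLITUDE_LOG_SIGMA)))
        f0 = float(F0_MEDIAN * np.exp(rng.normal(0, F0_LOG_SIGMA)))
        neurons.append(
            GroundTruthNeuron(
                position_um=(float(x), float(y)),
                cf_khz=cf,
                threshold_db=theta,
                slope_db_per_octave=slope_db_per_octave,
                amplitude=amplitude,
                response_type=str(rtype),
                f0=f0,
            )
        )
    return GroundTruthPopulation(
        neurons=neurons, genotype_preset=genotype_preset, field_size_um=field_size_um
    )


def mean_response(
    neuron: GroundTruthNeuron,
    freq_khz: float,
    level_db: float,
    saturation_range_db: float = 40.0,
) -> float:
    """V-shaped frequency-response area: mean dF/F amplitude for a tone.

    The threshold at frequency f is ``theta(f) = threshold_db +
    slope * |log2(f / cf)|``; above threshold the response grows linearly
    with level and saturates ``saturation_range_db`` above it.  The boundary
    is exclusive: ``level == theta(f)`` gives 0.
    """
    if freq_khz <= 0:
        raise ValueError("frequency must be positive")
    if level_db < 0:
        raise ValueError("level must be >= 0")
    theta = neuron.threshold_db + neuron.slope_db_per_octave * abs(
        np.log2(freq_khz / neuron.cf_khz)
    )
    if level_db <= theta:
        return 0.0
    return float(neuron.amplitude * min(1.0, (level_db - theta) / saturation_range_db))


def calcium_kernel(n_frames: int, frame_rate_hz: float, rise_s: float, decay_s: float) -> np.ndarray:
    """Double-exponential indicator kernel, normalized to unit peak."""
    t = np.arange(n_frames) / frame_rate_hz
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel (rise >= decay?)")
    return k / peak


def _randomized_log(grid: StimulusGrid, rng: np.random.Generator) -> StimulusLog:
    conditions = [
        (f, a) for f in grid.frequencies_khz for a in grid.levels_db for _ in range(grid.n_repeats)
    ]
    order = rng.permutation(len(conditions))
    onsets = np.arange(len(conditions)) * grid.trial_frames + grid.onset_frame
    freqs = np.array([conditions[i][0] for i in order])
    levels = np.array([conditions[i][1] for i in order])
    return StimulusLog(onset_frames=onsets, frequencies_khz=freqs, levels_db=levels)


@dataclass
class SessionData:
    """A synthesized two-photon session in extraction-pipeline layout."""

    roi_traces: np.ndarray  # (N, total_frames) raw F_roi
    neuropil_traces: np.ndarray  # (N, total_frames) F_np
    positions_um: np.ndarray  # (N, 2)
    log: StimulusLog
    grid: StimulusGrid
    clean_dff: np.ndarray  # noise-free implanted dF/F, for recovery tests


def _clean_dff(
    population: GroundTruthPopulation, grid: StimulusGrid, log: StimulusLog, noise: NoiseConfig
) -> np.ndarray:
    """Implanted dF/F signal (no nuisance processes), (N, total_frames).

    Responses decay across trial boundaries (slow-indicator bleed-through),
    as in real recordings; the kernel is truncated only once it has decayed
    to a negligible fraction of its peak.
    """
    n = len(population)
    total = grid.trial_frames * grid.n_trials
    dff = np.zeros((n, total))
    klen = int(np.ceil(6.0 * noise.decay_s * grid.frame_rate_hz))
    kernel = calcium_kernel(klen, grid.frame_rate_hz, noise.rise_s, noise.decay_s)
    for i, neuron in enumerate(population.neurons):
        if neuron.response_type == "silent":
            continue
        for onset, fk, lv in zip(log.onset_frames, log.frequencies_khz, log.levels_db):
            amp = mean_response(neuron, fk, lv)
            if amp == 0.0:
                continue
            if neuron.response_type in ("onset", "onset_offset"):
                avail = min(klen, total - onset)
                dff[i, onset : onset + avail] += amp * kernel[:avail]
            if neuron.response_type in ("offset", "onset_offset"):
                t0 = onset + grid.tone_frames
                avail = min(klen, total - t0)
                dff[i, t0 : t0 + avail] += amp * kernel[:avail]
    return dff


def synthesize_session(
    population: GroundTruthPopulation, grid: StimulusGrid, noise: NoiseConfig
) -> SessionData:
    """Generate raw ROI and neuropil traces for a randomized tone session.

    Raw trace model per neuron i with coupling c_i to the shared neuropil
    process NP(t):

        F_roi = f0 * (1 + dF/F) * drift(t) + gain * c_i * NP(t) + eps
        F_np  = c_i * NP(t) + eps'

    so that the analysis-side subtraction ``F_roi - 0.7 * F_np`` is
    consequential.  Deterministic given ``noise.seed``.
    """
    rng = np.random.default_rng(noise.seed)
    log = _randomized_log(grid, rng)
    n = len(population)
    total = grid.trial_frames * grid.n_trials
    if n == 0:
        return SessionData(
            roi_traces=np.zeros((0, total)),
            neuropil_traces=np.zeros((0, total)),
            positions_um=np.zeros((0, 2)),
            log=log,
            grid=grid,
            clean_dff=np.zeros((0, total)),
        )

    dff = _clean_dff(population, grid, log, noise)

    t = np.arange(total) / grid.frame_rate_hz
    phases = rng.uniform(0, 2 * np.pi, size=n)
    drift = 1.0 + noise.drift_amplitude * np.sin(
        2 * np.pi * t[None, :] / noise.drift_period_s + phases[:, None]
    )

    # shared low-pass neuropil process, positive around its baseline
    from scipy.ndimage import gaussian_filter1d

    smooth_frames = max(2.0 * grid.frame_rate_hz, 1.0)
    shared = gaussian_filter1d(rng.standard_normal(total), smooth_frames)
    shared = shared / (shared.std() + 1e-12)
    np_shared = noise.neuropil_baseline * (1.0 + 0.1 * shared)
    coupling = rng.uniform(0.5, 1.5, size=n)

    f0 = np.array([nr.f0 for nr in population.neurons])[:, None]
    roi = f0 * (1.0 + dff) * drift + noise.neuropil_gain * coupling[:, None] * np_shared[None, :]
    roi = roi + rng.normal(0, noise.trace_sigma, size=roi.shape)
    npil = coupling[:, None] * np_shared[None, :] + rng.normal(
        0, 0.5 * noise.trace_sigma, size=roi.shape
    )
    return SessionData(
        roi_traces=roi,
        neuropil_traces=npil,
        positions_um=population.positions_um,
        log=log,
        grid=grid,
        clean_dff=dff,
    )


@dataclass
class WidefieldMovie:
    """A synthesized widefield recording as a pixel x time array."""

    movie: np.ndarray  # (n_pixels, total_frames)
    pixel_positions_um: np.ndarray  # (n_pixels, 2)
    shape: tuple[int, int]  # (ny, nx)
    log: StimulusLog
    grid: StimulusGrid


def synthesize_widefield(
    population: GroundTruthPopulation,
    grid: StimulusGrid,
    pixel_grid_spec: int | tuple[int, int],
    noise: NoiseConfig,
    blur_sigma_um: float = 50.0,
    pixel_baseline: float = 100.0,
    spatial_noise_sigma_px: float = 2.0,
    global_sigma_dff: float = 0.01,
    global_tau_s: float = 1.0,
) -> WidefieldMovie:
    """Macroscopic view: pixel dF/F = Gaussian-blurred sum of neuron dF/F.

    ``pixel_grid_spec`` is the number of pixels per side (or (ny, nx));
    pixels tile the population's field.  Raw pixel fluorescence is
    ``B * (1 + dFF_pix + g(t)) + eps`` where ``g`` is a slow global
    fluctuation (hemodynamic/arousal-like, SD ``global_sigma_dff``) shared
    by all pixels and ``eps`` is sensor noise smoothed spatially over
    ``spatial_noise_sigma_px`` pixels, as in real widefield recordings
    where neighboring pixels are strongly correlated.  Deterministic per
    ``noise.seed``.
    """
    if isinstance(pixel_grid_spec, int):
        ny = nx = pixel_grid_spec
    else:
        ny, nx = pixel_grid_spec
    if ny < 1 or nx < 1:
        raise ValueError("pixel grid must be nonempty")

    rng = np.random.default_rng(noise.seed)
    log = _randomized_log(grid, rng)
    total = grid.trial_frames * grid.n_trials
    L = population.field_size_um
    xs = (np.arange(nx) + 0.5) * L / nx
    ys = (np.arange(ny) + 0.5) * L / ny
    gx, gy = np.meshgrid(xs, ys)
    pix_pos = np.column_stack([gx.ravel(), gy.ravel()])

    if len(population) == 0:
        dff_pix = np.zeros((ny * nx, total), dtype=np.float32)
    else:
        dff = _clean_dff(population, grid, log, noise).astype(np.float32)
        pos = population.positions_um
        d2 = (
            (pix_pos[:, 0:1] - pos[None, :, 0]) ** 2
            + (pix_pos[:, 1:2] - pos[None, :, 1]) ** 2
        )
        w = np.exp(-d2 / (2 * blur_sigma_um**2)).astype(np.float32)
        dff_pix = w @ dff

    if global_sigma_dff > 0:
        from scipy.ndimage import gaussian_filter1d

        g = gaussian_filter1d(rng.standard_normal(total), global_tau_s * grid.frame_rate_hz)
        g = (g / (g.std() + 1e-12) * global_sigma_dff).astype(np.float32)
        dff_pix = dff_pix + g[None, :]

    movie = pixel_baseline * (1.0 + dff_pix)
    if noise.trace_sigma > 0:
        eps = rng.normal(0, noise.trace_sigma, size=(ny, nx, total)).astype(np.float32)
        if spatial_noise_sigma_px > 0:
            from scipy.ndimage import gaussian_filter

            raw_sd = eps.std()
            eps = gaussian_filter(eps, sigma=(spatial_noise_sigma_px, spatial_noise_sigma_px, 0))
            eps *= noise.trace_sigma / (eps.std() + 1e-12)  # keep per-pixel SD
        movie = movie + eps.reshape(ny * nx, total)
    return WidefieldMovie(
        movie=movie, pixel_positions_um=pix_pos, shape=(ny, nx), log=log, grid=grid
    )
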