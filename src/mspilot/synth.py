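"""Synthetic EEG with planted microstate structure.

Every downstream stage of the pipeline (preprocessing, map fitting, group
aggregation, backfitting, temporal-dependency measures, statistics) is
validated against data produced here, because the generator knows the
ground truth: the template topographies, the per-sample class labels, the
GFP envelope and the injected noise level.

The forward model is deliberately simple.  A microstate sequence is a
semi-Markov chain over K classes (geometric or fixed dwell times); each
sample renders the active class's unit-norm topography, scaled by a
rectified-sinusoid GFP envelope (so GFP peaks exist, at twice the carrier
frequency) and by a per-run random polarity sign (so the pipeline's
polarity invariance is actually exercised); i.i.d. Gaussian sensor noise
is added at a controlled total-power SNR and the result is average
referenced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .recording import LabelSequence, Recording, spatial_correlation

__all__ = [
    "TemplateMaps",
    "SequenceModel",
    "ProtocolSpec",
    "TaskItem",
    "sensor_positions",
    "generate_template_maps",
    "uniform_sequence_model",
    "sample_label_sequence",
    "rectified_sine_envelope",
    "render_eeg",
    "simulate_protocol",
    "sample_correlated_pm1",
]

DEFAULT_CLASS_LABELS = tuple("ABCDEFG")


@dataclass
class TemplateMaps:
    """K unit-norm, zero-mean (average-referenced) scalp topographies."""

    maps: np.ndarray  # (K, n_channels)
    class_labels: tuple[str, ...]
    channel_names: list[str]
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        norms = np.linalg.norm(self.maps, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("template maps must be unit-norm")
        if not np.allclose(self.maps.sum(axis=1), 0.0, atol=1e-9):
            raise ValueError("template maps must sum to zero across channels")
        if len(self.class_labels) != self.maps.shape[0]:
            raise ValueError("class_labels length must equal K")

    @property
    def n_classes(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]

    def max_pairwise_similarity(self) -> float:
        """Largest absolute spatial correlation over all map pairs."""
        best = 0.0
        for i in range(self.n_classes):
            for j in range(i + 1, self.n_classes):
                best = max(best, abs(spatial_correlation(self.maps[i], self.maps[j])))
        return best


@dataclass
class SequenceModel:
    """Semi-Markov model generating microstate label sequences.

    ``transition_matrix`` governs which class follows which (zero diagonal,
    rows sum to 1); ``mean_dwell`` is the expected run length in samples per
    class.  Geometric dwell is memoryless (the simplest reading of
    quasi-stability); ``fixed`` makes every run exactly ``mean_dwell`` long.
    """

    n_classes: int
    transition_matrix: np.ndarray
    mean_dwell: np.ndarray  # (K,) expected run length, samples
    dwell_distribution: str = "geometric"

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.mean_dwell = np.broadcast_to(
            np.asarray(self.mean_dwell, dtype=float), (self.n_classes,)
        ).copy()
        T = self.transition_matrix
        if T.shape != (self.n_classes, self.n_classes):
            raise ValueError("transition_matrix must be K x K")
        if self.n_classes > 1:
            if not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError("transition_matrix rows must sum to 1")
            if np.any(np.diag(T) != 0):
                raise ValueError("transition_matrix diagonal must be zero")
        if np.any(T < 0):
            raise ValueError("transition probabilities must be non-negative")
        if np.any(self.mean_dwell < 1):
            raise ValueError("mean_dwell must be >= 1 sample")
        if self.dwell_distribution not in ("geometric", "fixed"):
            raise ValueError("dwell_distribution must be 'geometric' or 'fixed'")


@dataclass
class ProtocolSpec:
    """Session structure of the simulator training protocol.

    Defaults mirror a 22-session programme in three stages — Training (7
    sessions), PracticeA (8), PracticeB (7) — where each session holds a
    30 s Baseline task followed by a 90 s Trial task.
    """

    stages: tuple[tuple[str, int], ...] = (
        ("Training", 7),
        ("PracticeA", 8),
        ("PracticeB", 7),
    )
    baseline_duration: float = 30.0
    trial_duration: float = 90.0
    sampling_rate: float = 250.0

    def __post_init__(self) -> None:
        if self.baseline_duration <= 0 or self.trial_duration <= 0:
            raise ValueError("task durations must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        for _, n in self.stages:
            if n < 1:
                raise ValueError("every stage needs at least one session")

    @property
    def n_sessions(self) -> int:
        return sum(n for _, n in self.stages)


@dataclass
class TaskItem:
    """One simulated task: its recording plus the planted ground truth."""

    stage: str
    session: int  # 1-based, global across stages
    task_type: str  # "Baseline" | "Trial"
    recording: Recording
    labels: LabelSequence


def sensor_positions(
    n_channels: int, montage: str = "biosemi64"
) -> tuple[list[str], np.ndarray]:
    """Channel names and unit-sphere positions for a synthetic montage.

    Uses the named standard montage when the channel count matches it;
    otherwise falls back to a Fibonacci spiral over the upper hemisphere
    with generic channel names.
    """
    import mne

    std = mne.channels.make_standard_montage(montage)
    if n_channels == len(std.ch_names):
        pos = std.get_positions()["ch_pos"]
        names = list(std.ch_names)
        xyz = np.array([pos[ch] for ch in names], dtype=float)
        xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
        return names, xyz
    # Fibonacci spiral on the upper hemisphere (z >= 0)
    i = np.arange(n_channels, dtype=float)
    golden = (1 + math.sqrt(5)) / 2
    z = i / max(n_channels - 1, 1)  # 0..1
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    theta = 2 * math.pi * i / golden
    xyz = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
    names = [f"CH{k + 1:03d}" for k in range(n_channels)]
    return names, xyz


def generate_template_maps(
    n_classes: int,
    n_channels: int,
    max_similarity: float = 0.7,
    seed: int = 0,
    smoothness: float = 0.8,
    max_tries: int = 2000,
) -> TemplateMaps:
    """Draw K dissimilar smooth scalp topographies.

    Each candidate map is a Gaussian random field over the sensor sphere:
    white noise at the sensors smoothed with an ``exp(-d^2 / 2*ell^2)``
    kernel over great-circle distance ``d`` (``ell = smoothness`` radians),
    then average-referenced and unit-normalised.  Candidates are accepted
    only while every pairwise absolute spatial correlation with the maps
    already kept stays at or below ``max_similarity``.

    Raises
    ------
    ValueError
        If the similarity budget cannot be met within ``max_tries``
        candidate draws (the parameters are infeasible).
    """
    if not (2 <= n_classes < n_channels):
        raise ValueError("need 2 <= n_classes < n_channels")
    if not (0.0 < max_similarity < 1.0):
        raise ValueError("max_similarity must be in (0, 1)")
    rng = np.random.default_rng(seed)
    names, xyz = sensor_positions(n_channels)
    gram = np.clip(xyz @ xyz.T, -1.0, 1.0)
    dist = np.arccos(gram)  # great-circle distance, radians
    kernel = np.exp(-(dist**2) / (2 * smoothness**2))

    maps: list[np.ndarray] = []
    for _ in range(max_tries):
        cand = kernel @ rng.standard_normal(n_channels)
        cand -= cand.mean()
        nrm = np.linalg.norm(cand)
        if nrm == 0:
            continue
        cand /= nrm
        if all(abs(spatial_correlation(cand, m)) <= max_similarity for m in maps):
            maps.append(cand)
            if len(maps) == n_classes:
                break
    else:
        raise ValueError(
            f"could not draw {n_classes} maps with max |corr| <= "
            f"{max_similarity} in {max_tries} tries"
        )
    labels = tuple(
        DEFAULT_CLASS_LABELS[k] if k < len(DEFAULT_CLASS_LABELS) else f"M{k}"
        for k in range(n_classes)
    )
    # re-enforce exact invariants after float accumulation
    M = np.array(maps)
    M -= M.mean(axis=1, keepdims=True)
    M /= np.linalg.norm(M, axis=1, keepdims=True)
    return TemplateMaps(maps=M, class_labels=labels, channel_names=names, positions=xyz)


def uniform_sequence_model(
    n_classes: int, mean_dwell: float = 20.0, dwell_distribution: str = "geometric"
) -> SequenceModel:
    """Uniform off-diagonal transitions, equal dwell for every class."""
    if n_classes == 1:
        T = np.zeros((1, 1))
    else:
        T = np.full((n_classes, n_classes), 1.0 / (n_classes - 1))
        np.fill_diagonal(T, 0.0)
    return SequenceModel(
        n_classes=n_classes,
        transition_matrix=T,
        mean_dwell=np.full(n_classes, float(mean_dwell)),
        dwell_distribution=dwell_distribution,
    )


def sample_label_sequence(
    model: SequenceModel, n_samples: int, seed: int = 0, fs: float = 250.0
) -> LabelSequence:
    """Sample a microstate label sequence from a semi-Markov model."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    K = model.n_classes
    labels = np.empty(n_samples, dtype=int)
    state = int(rng.integers(K))
    pos = 0
    while pos < n_samples:
        mean = model.mean_dwell[state]
        if model.dwell_distribution == "fixed":
            dwell = int(round(mean))
        else:
            dwell = int(rng.geometric(1.0 / mean))
        dwell = max(dwell, 1)
        end = min(pos + dwell, n_samples)
        labels[pos:end] = state
        pos = end
        if K > 1:
            state = int(rng.choice(K, p=model.transition_matrix[state]))
    return LabelSequence(labels=labels, fs=fs, n_classes=K)


def rectified_sine_envelope(
    n_samples: int,
    fs: float,
    freq: float = 10.0,
    gfp_uv: float = 10.0,
    phase: float = np.pi / 2,
) -> np.ndarray:
    """Per-sample target GFP: ``gfp_uv * |sin(2*pi*freq*t + phase)|``.

    The rectification doubles the peak rate, so GFP peaks occur at
    ``2*freq`` per second — the moments the map fitter will consume.  The
    default cosine phase keeps the envelope's zero crossings between
    sample instants at the default 250 Hz / 10 Hz combination: a sample of
    exactly zero GFP carries no topographic information at all, and a
    run of them would be pure noise rather than an attenuated microstate.
    """
    t = np.arange(n_samples) / fs
    return gfp_uv * np.abs(np.sin(2 * np.pi * freq * t + phase))


def render_eeg(
    maps: TemplateMaps,
    labels: LabelSequence,
    gfp_envelope: np.ndarray,
    snr_db: float = 20.0,
    seed: int = 0,
    flip_polarity: bool = True,
) -> Recording:
    """Render a label sequence into an average-referenced EEG recording.

    Sample ``t`` is ``gfp_envelope[t] * sqrt(n_channels) * s_r *
    map[label[t]]`` where ``s_r`` is a per-run random sign (polarity is not
    meaningful for microstate maps, and flipping it exercises the
    pipeline's polarity invariance).  Because maps are unit-norm and
    zero-mean, the rendered GFP equals the envelope exactly before noise.

    Noise is i.i.d. Gaussian per channel, average-referenced, then scaled
    so that total signal power / total noise power equals ``snr_db``.
    ``snr_db=inf`` renders noiselessly.
    """
    env = np.asarray(gfp_envelope, dtype=float)
    if env.shape != (labels.n_samples,):
        raise ValueError("envelope length must equal label length")
    if np.any(env < 0):
        raise ValueError("GFP envelope must be non-negative")
    rng = np.random.default_rng(seed)
    n_ch = maps.n_channels
    lab = labels.labels

    from .recording import run_lengths

    vals, lens = run_lengths(lab)
    if flip_polarity:
        run_signs = rng.choice([-1.0, 1.0], size=len(vals))
    else:
        run_signs = np.ones(len(vals))
    signs = np.repeat(run_signs, lens)

    amp = env * math.sqrt(n_ch) * signs  # (n_samples,)
    data = maps.maps[lab].T * amp  # (n_channels, n_samples)

    p_sig = float(np.mean(data**2))
    if np.isfinite(snr_db) and p_sig > 0:
        noise = rng.standard_normal(data.shape)
        noise -= noise.mean(axis=0, keepdims=True)
        p_noise = float(np.mean(noise**2))
        target = p_sig / 10.0 ** (snr_db / 10.0)
        data = data + noise * math.sqrt(target / p_noise)

    rec = Recording(
        data=data,
        fs=labels.fs,
        channel_names=list(maps.channel_names),
        positions=None if maps.positions is None else maps.positions.copy(),
        reference="average",
    )
    return rec.average_reference()


def simulate_protocol(
    spec: ProtocolSpec,
    maps: TemplateMaps,
    baseline_model: SequenceModel,
    trial_model: SequenceModel,
    seed: int = 0,
    snr_db: float = 20.0,
    gfp_uv: float = 10.0,
    envelope_freq: float = 10.0,
) -> list[TaskItem]:
    """Simulate one participant's full training protocol.

    Yields one Baseline and one Trial item per session, in session order,
    each with its own recording and planted label sequence.
    """
    ss = np.random.SeedSequence(seed)
    items: list[TaskItem] = []
    session = 0
    fs = spec.sampling_rate
    for stage_name, n_sessions in spec.stages:
        for _ in range(n_sessions):
            session += 1
            for task_type, duration, model in (
                ("Baseline", spec.baseline_duration, baseline_model),
                ("Trial", spec.trial_duration, trial_model),
            ):
                child = ss.spawn(1)[0]
                seq_seed, render_seed = child.generate_state(2) % (2**31)
                n = int(round(duration * fs))
                labels = sample_label_sequence(model, n, seed=int(seq_seed), fs=fs)
                labels.stage = stage_name
                labels.task_type = task_type
                labels.task_id = f"S{session:02d}-{task_type}"
                env = rectified_sine_envelope(n, fs, freq=envelope_freq, gfp_uv=gfp_uv)
                rec = render_eeg(maps, labels, env, snr_db=snr_db, seed=int(render_seed))
                items.append(
                    TaskItem(
                        stage=stage_name,
                        session=session,
                        task_type=task_type,
                        recording=rec,
                        labels=labels,
                    )
                )
    return items


def _fractional_gaussian_noise(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Exact fGn via Davies–Harte circulant embedding."""
    k = np.arange(n + 1, dtype=float)
    acov = 0.5 * (
        (k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst)
    )
    first_row = np.concatenate([acov, acov[-2:0:-1]])  # length 2n
    lam = np.fft.fft(first_row).real
    # the embedding is non-negative definite for fGn; clip float dust
    lam = np.maximum(lam, 0.0)
    m = 2 * n
    z = np.empty(m, dtype=complex)
    z[0] = math.sqrt(lam[0]) * rng.standard_normal()
    z[n] = math.sqrt(lam[n]) * rng.standard_normal()
    u = rng.standard_normal(n - 1)
    v = rng.standard_normal(n - 1)
    z[1:n] = np.sqrt(lam[1:n] / 2.0) * (u + 1j * v)
    z[n + 1 :] = np.conj(z[1:n][::-1])
    x = np.fft.fft(z) / math.sqrt(m)
    return x[:n].real


def sample_correlated_pm1(
    hurst_target: float, n_samples: int, seed: int = 0, min_length: int = 500
) -> np.ndarray:
    """A +/-1 sequence with long-range dependence of known Hurst exponent.

    The sign of exact fractional Gaussian noise: hard clipping preserves
    the Hurst exponent of the underlying Gaussian process, so DFA applied
    to the output should recover ``hurst_target``.  ``hurst_target=0.5``
    gives an uncorrelated coin-flip sequence.
    """
    if not (0.0 < hurst_target < 1.0):
        raise ValueError("hurst_target must be in (0, 1)")
    if n_samples < min_length:
        raise ValueError(f"need at least {min_length} samples for a usable DFA fit")
    rng = np.random.default_rng(seed)
    g = _fractional_gaussian_noise(n_samples, hurst_target, rng)
    out = np.where(g >= 0, 1, -1).astype(int)
    return out
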