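"""Synthetic polysomnography generator.

Produces labelled, class-separable EEG+EOG recordings whose per-stage
spectral content follows the textbook stage signatures: wake shows
occipital alpha (8–12 Hz) with frequent eye blinks, N1 low-amplitude
theta with slow rolling eye movements, N2 theta plus 12–14 Hz spindle
bursts and K-complexes, N3 high-amplitude 0.5–2 Hz delta, and REM
low-amplitude mixed-frequency EEG with large saccadic EOG deflections.

The generator exists to make the staging network's assumptions testable
without any download: stages are separable by spectral shape (not
absolute amplitude, so per-epoch z-scoring keeps the label information),
subjects differ by a multiplicative jitter on recipe amplitudes and
frequencies (so cross-subject generalisation is non-trivial), and stage
labels are drawn as geometric-length runs so the hypnogram has the
temporal contiguity of real sleep.  It makes no claim of physiological
realism beyond class separability: there is no 1/f background, no
artifacts, no arousal microstructure.

Everything is deterministic given ``GeneratorConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import EPOCH_SAMPLES, SFREQ, Recording, Epoch, StageLabel

#: Empirical stage proportions of the 20-subject Sleep-EDF cassette
#: cohort (W, N1, N2, N3, REM) — the class imbalance the generator
#: reproduces by default.
SLEEP_EDF20_PROPORTIONS = (0.196, 0.066, 0.421, 0.135, 0.182)


@dataclass
class StageRecipe:
    """Spectral recipe for one stage.

    ``eeg_bands``/``eog_bands`` are (center_Hz, bandwidth_Hz, amplitude_µV)
    triples, each contributing a random-phase sinusoid whose frequency is
    drawn uniformly inside the band.  ``transient_events`` are
    (kind, rate_per_epoch, amplitude_µV) with kind one of ``spindle`` /
    ``k_complex`` (inserted into EEG) or ``rem_deflection`` (EOG).
    """

    stage: StageLabel
    eeg_bands: list[tuple[float, float, float]] = field(default_factory=list)
    eog_bands: list[tuple[float, float, float]] = field(default_factory=list)
    transient_events: list[tuple[str, float, float]] = field(default_factory=list)
    noise_sd: float = 10.0

    def __post_init__(self):
        nyquist = SFREQ / 2.0
        for c, bw, a in self.eeg_bands + self.eog_bands:
            if not (0.0 < c < nyquist):
                raise ValueError(f"band center {c} Hz outside (0, {nyquist})")
            if a < 0:
                raise ValueError("band amplitude must be >= 0")
        for _, rate, a in self.transient_events:
            if rate < 0 or a < 0:
                raise ValueError("event rates and amplitudes must be >= 0")


def default_recipes() -> dict[StageLabel, StageRecipe]:
    """Textbook per-stage signatures (amplitudes in µV)."""
    S = StageLabel
    return {
        S.W: StageRecipe(
            stage=S.W,
            eeg_bands=[(10.0, 4.0, 30.0), (22.0, 8.0, 8.0)],
            eog_bands=[(0.8, 0.6, 15.0)],
            transient_events=[("rem_deflection", 4.0, 60.0)],  # blinks
        ),
        S.N1: StageRecipe(
            stage=S.N1,
            eeg_bands=[(5.5, 3.0, 25.0)],
            eog_bands=[(0.4, 0.3, 35.0)],  # slow rolling eye movements
        ),
        S.N2: StageRecipe(
            stage=S.N2,
            eeg_bands=[(5.5, 3.0, 20.0)],
            eog_bands=[(0.3, 0.2, 8.0)],
            transient_events=[("spindle", 3.0, 30.0),
                              ("k_complex", 1.0, 75.0)],
        ),
        S.N3: StageRecipe(
            stage=S.N3,
            eeg_bands=[(1.25, 1.5, 75.0), (5.5, 3.0, 10.0)],
            eog_bands=[(0.3, 0.2, 8.0)],
        ),
        S.REM: StageRecipe(
            stage=S.REM,
            eeg_bands=[(5.5, 3.0, 15.0), (22.0, 8.0, 8.0)],
            eog_bands=[(0.3, 0.2, 8.0)],
            transient_events=[("rem_deflection", 5.0, 110.0)],  # saccades
        ),
    }


@dataclass
class GeneratorConfig:
    n_subjects: int = 10
    epochs_per_subject: int = 200
    class_proportions: tuple = SLEEP_EDF20_PROPORTIONS
    subject_jitter: float = 0.1
    mean_run_length: float = 10.0  # epochs; real hypnograms dwell in stages
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.class_proportions, dtype=np.float64)
        if p.shape != (5,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(
                "class_proportions must be 5 non-negative values summing to 1")
        self.class_proportions = tuple(p)


# ---------------------------------------------------------------------------
# transient waveforms


def _spindle(rng: np.random.Generator, amp: float) -> np.ndarray:
    """12–14 Hz burst, 0.5–1 s, Hann envelope."""
    dur = rng.uniform(0.5, 1.0)
    n = int(dur * SFREQ)
    t = np.arange(n) / SFREQ
    f = rng.uniform(12.0, 14.0)
    return amp * np.hanning(n) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))


def _k_complex(rng: np.random.Generator, amp: float) -> np.ndarray:
    """Large biphasic wave, ~0.7 s: one full low-frequency cycle."""
    dur = rng.uniform(0.6, 0.8)
    n = int(dur * SFREQ)
    t = np.linspace(0, 1, n)
    return -amp * np.hanning(n) * np.sin(2 * np.pi * t)


def _deflection(rng: np.random.Generator, amp: float) -> np.ndarray:
    """Sharp monophasic EOG deflection (blink / saccade), ~0.2–0.4 s."""
    dur = rng.uniform(0.2, 0.4)
    n = int(dur * SFREQ)
    sign = rng.choice([-1.0, 1.0])
    return sign * amp * np.hanning(n) ** 2


_EVENT_WAVEFORMS = {
    "spindle": (_spindle, "eeg"),
    "k_complex": (_k_complex, "eeg"),
    "rem_deflection": (_deflection, "eog"),
}


def _insert_events(target: np.ndarray, rng: np.random.Generator,
                   maker, rate: float, amp: float) -> None:
    for _ in range(rng.poisson(rate)):
        wave = maker(rng, amp)
        if len(wave) >= len(target):
            continue
        onset = rng.integers(0, len(target) - len(wave))
        target[onset:onset + len(wave)] += wave


def synth_epoch(stage: StageLabel, recipe: StageRecipe,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One 30 s epoch: random-phase band sinusoids + transients + noise."""
    if recipe.stage != stage:
        raise ValueError(f"recipe is for {recipe.stage.name}, not {stage.name}")
    t = np.arange(EPOCH_SAMPLES) / SFREQ
    eeg = np.zeros(EPOCH_SAMPLES)
    eog = np.zeros(EPOCH_SAMPLES)
    for target, bands in ((eeg, recipe.eeg_bands), (eog, recipe.eog_bands)):
        for center, bw, amp in bands:
            f = rng.uniform(center - bw / 2, center + bw / 2)
            f = min(max(f, 0.05), SFREQ / 2 - 0.5)
            target += amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    for kind, rate, amp in recipe.transient_events:
        maker, channel = _EVENT_WAVEFORMS[kind]
        _insert_events(eeg if channel == "eeg" else eog, rng, maker, rate, amp)
    if recipe.noise_sd > 0:
        eeg += rng.normal(0, recipe.noise_sd, EPOCH_SAMPLES)
        eog += rng.normal(0, recipe.noise_sd, EPOCH_SAMPLES)
    return eeg.astype(np.float32), eog.astype(np.float32)


def _jitter_recipes(base: dict[StageLabel, StageRecipe], jitter: float,
                    rng: np.random.Generator) -> dict[StageLabel, StageRecipe]:
    """Per-subject multiplicative perturbation of amplitudes and frequencies."""
    if jitter == 0:
        return base
    out = {}
    for stage, rec in base.items():
        def perturb_bands(bands):
            new = []
            for c, bw, a in bands:
                fc = c * max(0.2, 1.0 + jitter * rng.normal())
                fa = a * max(0.05, 1.0 + jitter * rng.normal())
                new.append((min(fc, SFREQ / 2 - 1.0), bw, fa))
            return new

        events = [(k, r * max(0.0, 1.0 + jitter * rng.normal()),
                   a * max(0.05, 1.0 + jitter * rng.normal()))
                  for k, r, a in rec.transient_events]
        out[stage] = replace(
            rec,
            eeg_bands=perturb_bands(rec.eeg_bands),
            eog_bands=perturb_bands(rec.eog_bands),
            transient_events=events,
        )
    return out


def label_sequence(n: int, proportions, mean_run_length: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Stage labels as geometric-length runs; stationary mix follows
    ``proportions`` because each new run's stage is drawn from it."""
    p = np.asarray(proportions, dtype=np.float64)
    p = p / p.sum()
    labels = np.empty(n, dtype=np.int64)
    i = 0
    while i < n:
        stage = rng.choice(5, p=p)
        run = rng.geometric(1.0 / mean_run_length)
        labels[i:i + run] = stage
        i += run
    return labels


def synth_recording(subject_id: str, n_epochs: int,
                    recipes: dict[StageLabel, StageRecipe],
                    proportions, mean_run_length: float,
                    rng: np.random.Generator) -> Recording:
    labels = label_sequence(n_epochs, proportions, mean_run_length, rng)
    epochs = []
    for i, lab in enumerate(labels):
        stage = StageLabel(int(lab))
        eeg, eog = synth_epoch(stage, recipes[stage], rng)
        epochs.append(Epoch(eeg=eeg, eog=eog, label=stage,
                            subject_id=subject_id, index_in_night=i))
    return Recording(subject_id=subject_id, epochs=epochs)


def synth_dataset(cfg: GeneratorConfig) -> list[Recording]:
    """Deterministic multi-subject synthetic dataset."""
    base = default_recipes()
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    recordings = []
    for s, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        recipes = _jitter_recipes(base, cfg.subject_jitter, rng)
        recordings.append(synth_recording(
            f"S{s:03d}", cfg.epochs_per_subject, recipes,
            cfg.class_proportions, cfg.mean_run_length, rng))
    return recordings


def band_power_features(x: np.ndarray, sfreq: float = SFREQ) -> np.ndarray:
    """Per-epoch log band powers in the five canonical EEG bands
    (delta 0.5–4, theta 4–8, alpha 8–12, sigma 12–16, beta 16–30 Hz),
    per channel.  Used by the separability check and as a simple
    reference feature set."""
    from scipy.signal import periodogram

    bands = [(0.5, 4), (4, 8), (8, 12), (12, 16), (16, 30)]
    freqs, psd = periodogram(x, fs=sfreq, axis=-1)
    feats = []
    for lo, hi in bands:
        mask = (freqs >= lo) & (freqs < hi)
        feats.append(np.log(psd[..., mask].sum(axis=-1) + 1e-12))
    out = np.stack(feats, axis=-1)  # (..., channels, bands)
    return out.reshape(*x.shape[:-2], -1) if x.ndim > 2 else out.reshape(-1)
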