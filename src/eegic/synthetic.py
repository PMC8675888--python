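"""Seeded synthetic IC datasets with class-specific topographies and
signals, plus multi-expert annotation simulation with controlled
disagreement.

Topographies are parametric channel-space patterns (Gaussians over
schematic 2-D 10-10 coordinates), not forward-modeled dipoles; they are
sufficient to exercise every topographic feature.  Signals follow simple
phenomenological recipes per class: occipital 8-12 Hz for alpha, central
arch-shaped 10 Hz (with second harmonic) for mu, 1/f background for brain,
sparse frontal humps for blinks, step deflections for horizontal eye
movements, >20 Hz broadband bursts for muscle, QRS-like periodicity for
heart, and a single dominant white-noise channel for channel noise.

Annotation simulation models the two labeling styles seen among human
experts: a *purist* reports only the dominant activity (missing it at rate
``1 - sensitivity``), a *splitter* reports every activity present plus
spurious labels at a false-label rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .aggregation import TARGET_CLASSES, Annotation
from .ic_model import ICComponent, ICDataset
from .montage import CHANNEL_POSITIONS, DEFAULT_MONTAGE

__all__ = [
    "CLASSES",
    "CLASS_LABELS",
    "GeneratorConfig",
    "ExpertProfile",
    "generate_component",
    "generate_dataset",
    "generate_annotations",
    "labels_from_truth",
]

#: Generator classes and the ground-truth label sets they carry
#: (dominant label first).
CLASS_LABELS: dict[str, tuple[str, ...]] = {
    "brain": ("Brain",),
    "alpha": ("Alpha", "Brain"),
    "mu": ("Mu", "Brain"),
    "eyes_blink": ("Eyes",),
    "eyes_horizontal": ("Eyes",),
    "muscle": ("Muscle",),
    "heart": ("Heart",),
    "channel_noise": ("Channel noise",),
}

CLASSES = tuple(CLASS_LABELS)

_DEFAULT_COUNTS = {cls: 25 for cls in CLASSES}


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic dataset parameters.

    Defaults emulate a pediatric ERP recording: a 31-channel 10-10
    montage, 250 Hz sampling, 100 one-second epochs per component.
    """

    montage: tuple[str, ...] = tuple(DEFAULT_MONTAGE)
    counts: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_COUNTS))
    sampling_rate: float = 250.0
    n_epochs: int = 100
    n_samples: int = 250
    mixed_fraction: float = 0.0
    #: events per second for blink/saccade recipes
    blink_rate: float = 0.3
    #: heart rate in Hz (beats per second)
    heart_rate: float = 1.2
    #: relative amplitude of the 1/f background
    background_amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("class counts must be >= 0")
        unknown = set(self.counts) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown generator classes: {sorted(unknown)}")
        if not self.sampling_rate > 40:
            raise ValueError("sampling_rate must exceed 40 Hz")
        if not (0 <= self.mixed_fraction <= 1):
            raise ValueError("mixed_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ExpertProfile:
    """A simulated annotator.

    ``purist`` experts report only the dominant activity of a component;
    ``splitter`` experts report everything present plus occasional
    spurious labels.
    """

    expert_id: str
    style: str = "splitter"
    sensitivity: float = 1.0
    false_label_rate: float = 0.0

    def __post_init__(self):
        if self.style not in ("purist", "splitter"):
            raise ValueError(f"unknown expert style {self.style!r}")
        for name in ("sensitivity", "false_label_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# topography recipes

def _positions(montage) -> np.ndarray:
    return np.array([CHANNEL_POSITIONS.get(ch, (0.0, 0.0)) for ch in montage])


def _gaussian_topo(montage, center, sigma) -> np.ndarray:
    pos = _positions(montage)
    d2 = np.sum((pos - np.asarray(center)) ** 2, axis=1)
    return np.exp(-d2 / (2 * sigma ** 2))


def _topography(cls: str, montage, rng: np.random.Generator) -> np.ndarray:
    n = len(montage)
    side = rng.choice([-1.0, 1.0])
    if cls == "alpha":
        w = _gaussian_topo(montage, (rng.uniform(-0.15, 0.15), -0.80), 0.35)
    elif cls == "mu":
        w = _gaussian_topo(montage, (side * 0.40, rng.uniform(0.0, 0.20)), 0.28)
    elif cls == "brain":
        c1 = (rng.uniform(-0.3, 0.3), rng.uniform(-0.3, 0.4))
        c2 = (-c1[0], -0.3 - c1[1] * 0.5)
        w = _gaussian_topo(montage, c1, 0.5) - 0.6 * _gaussian_topo(montage, c2, 0.5)
    elif cls == "eyes_blink":
        w = _gaussian_topo(montage, (0.0, 0.95), 0.30)
    elif cls == "eyes_horizontal":
        w = (_gaussian_topo(montage, (-0.6, 0.7), 0.28)
             - _gaussian_topo(montage, (0.6, 0.7), 0.28))
    elif cls == "muscle":
        w = _gaussian_topo(montage, (side * 0.85, rng.uniform(-0.3, 0.3)), 0.18)
    elif cls == "heart":
        theta = rng.uniform(0, 2 * np.pi)
        pos = _positions(montage)
        grad = pos[:, 0] * np.cos(theta) + pos[:, 1] * np.sin(theta)
        w = 1.0 + 0.4 * grad  # low spatial contrast
    elif cls == "channel_noise":
        mass = rng.uniform(0.85, 0.95)  # dominant channel: >= 80% of |w|
        dominant = rng.integers(n)
        rest = np.abs(rng.normal(size=n))
        rest[dominant] = 0.0
        w = rest / rest.sum() * (1.0 - mass)
        w[dominant] = mass
        return w
    else:
        raise ValueError(f"unknown generator class {cls!r}")
    return w + rng.normal(0, 0.01, n)


# ---------------------------------------------------------------------------
# signal recipes

def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-power noise via spectral shaping, unit variance."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    spec *= scale
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _signal(cls: str, cfg: GeneratorConfig, rng: np.random.Generator
            ) -> np.ndarray:
    fs = cfg.sampling_rate
    n_total = cfg.n_epochs * cfg.n_samples
    t = np.arange(n_total) / fs
    bg = cfg.background_amplitude * _pink_noise(n_total, rng)

    if cls == "alpha":
        f = rng.uniform(8.0, 12.0)
        mod = 1.0 + 0.6 * np.sin(2 * np.pi * rng.uniform(0.1, 0.3) * t
                                 + rng.uniform(0, 2 * np.pi))
        x = 2.5 * mod * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)) + 0.6 * bg
    elif cls == "mu":
        f = rng.uniform(9.0, 11.0)
        phase = 2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)
        arch = np.sin(phase) + 0.35 * np.sin(2 * phase)  # arch-shaped wave
        mod = 1.0 + 0.5 * np.sin(2 * np.pi * rng.uniform(0.05, 0.2) * t
                                 + rng.uniform(0, 2 * np.pi))
        x = 2.0 * mod * arch + 0.6 * bg
    elif cls == "brain":
        f = rng.uniform(4.0, 8.0)
        x = bg + 0.5 * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    elif cls == "eyes_blink":
        x = 0.4 * bg
        n_events = rng.poisson(cfg.blink_rate * n_total / fs)
        width = 0.10 * cfg.n_samples  # matches typical blink duration
        centers = rng.uniform(0, n_total, size=max(n_events, 3))
        idx = np.arange(n_total)
        for c in centers:
            x += 6.0 * np.exp(-0.5 * ((idx - c) / width) ** 2)
    elif cls == "eyes_horizontal":
        x = 0.4 * bg
        n_events = rng.poisson(cfg.blink_rate * n_total / fs)
        scale = 0.02 * cfg.n_samples
        level = 0.0
        edges = np.sort(rng.uniform(0, n_total, size=max(n_events, 3)))
        idx = np.arange(n_total)
        step = np.zeros(n_total)
        for e in edges:
            jump = rng.choice([-1.0, 1.0]) * rng.uniform(3.0, 6.0)
            z = np.clip((idx - e) / scale, -60.0, 60.0)
            step += jump / (1.0 + np.exp(-z))
            level += jump
        x += step - step.mean()
    elif cls == "muscle":
        white = rng.normal(size=n_total)
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n_total, d=1.0 / fs)
        band = (freqs >= 20) & (freqs <= min(100.0, fs / 2))
        spec[~band] = 0.0
        emg = np.fft.irfft(spec, n_total)
        emg /= emg.std()
        burst = 1.0 + 1.5 * (rng.random(cfg.n_epochs) < 0.5).astype(float)
        emg *= np.repeat(burst, cfg.n_samples)
        x = 3.0 * emg + 0.3 * bg
    elif cls == "heart":
        x = 0.5 * bg
        period = fs / cfg.heart_rate
        width = 0.03 * fs  # ~QRS width
        idx = np.arange(n_total)
        start = rng.uniform(0, period)
        centers = np.arange(start, n_total, period)
        for c in centers:
            z = (idx - c) / width
            x += 5.0 * z * np.exp(-0.5 * z ** 2)  # biphasic spike
    elif cls == "channel_noise":
        x = rng.normal(size=n_total)
    else:
        raise ValueError(f"unknown generator class {cls!r}")
    return x.reshape(cfg.n_epochs, cfg.n_samples)


def generate_component(cls: str, cfg: GeneratorConfig, seed: int,
                       component_id: str | None = None,
                       subject_id: str = "synthetic",
                       ) -> tuple[ICComponent, tuple[str, ...]]:
    """One synthetic component of class ``cls`` plus its true label set
    (dominant label first).  Deterministic given ``seed``."""
    if cls not in CLASS_LABELS:
        raise ValueError(f"unknown generator class {cls!r}; valid: {CLASSES}")
    rng = np.random.default_rng(seed)
    montage = list(cfg.montage)
    weights = _topography(cls, montage, rng)
    sig = _signal(cls, cfg, rng)
    flip = rng.choice([-1.0, 1.0])  # joint flip: the true ICA sign ambiguity
    weights = flip * weights
    sig = flip * sig
    comp = ICComponent(
        component_id=component_id or f"{cls}_{seed}",
        subject_id=subject_id,
        channel_labels=montage,
        weights=weights,
        signal=sig,
        sampling_rate=cfg.sampling_rate,
    )
    return comp, CLASS_LABELS[cls]


def generate_dataset(cfg: GeneratorConfig
                     ) -> tuple[ICDataset, dict[str, tuple[str, ...]]]:
    """A dataset honoring ``cfg.counts``, with optional mixed components.

    Returns the dataset and a mapping component_id -> true labels
    (dominant first).  A ``mixed_fraction`` of components are convex
    combinations of two different class recipes and carry both label sets.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    components: list[ICComponent] = []
    truth: dict[str, tuple[str, ...]] = {}
    counter = 0
    for cls in CLASSES:
        count = cfg.counts.get(cls, 0)
        for i in range(count):
            child_seed = int(rng.integers(2 ** 31))
            cid = f"ic{counter:04d}_{cls}"
            counter += 1
            if rng.random() < cfg.mixed_fraction:
                other = str(rng.choice([c for c in CLASSES if c != cls
                                        and cfg.counts.get(c, 0) > 0] or
                                       [c for c in CLASSES if c != cls]))
                lam = rng.uniform(0.55, 0.8)
                c1, labels1 = generate_component(cls, cfg, child_seed)
                c2, labels2 = generate_component(other, cfg,
                                                 int(rng.integers(2 ** 31)))
                comp = ICComponent(
                    component_id=cid, subject_id="synthetic",
                    channel_labels=list(cfg.montage),
                    weights=lam * c1.weights + (1 - lam) * c2.weights,
                    signal=lam * c1.signal + (1 - lam) * c2.signal,
                    sampling_rate=cfg.sampling_rate)
                seen = list(labels1) + [l for l in labels2 if l not in labels1]
                truth[cid] = tuple(seen)
            else:
                comp, labels = generate_component(cls, cfg, child_seed,
                                                  component_id=cid)
                truth[cid] = labels
            components.append(comp)
    ds = ICDataset(components=components,
                   metadata={"generator": "eegic.synthetic",
                             "seed": str(cfg.seed)})
    return ds, truth


def generate_annotations(truth: dict[str, tuple[str, ...]],
                         experts: list[ExpertProfile],
                         seed: int = 0) -> list[Annotation]:
    """Simulated expert annotations of the ground-truth labels.

    Purists report the dominant label only (or Uncertain when they miss
    it); splitters report every true label plus spurious target-class
    labels at their false-label rate.  Deterministic given ``seed``.
    """
    if not experts:
        raise ValueError("need at least one expert")
    rng = np.random.default_rng(seed)
    out = []
    for cid in truth:
        labels = truth[cid]
        for expert in experts:
            if expert.style == "purist":
                if rng.random() < expert.sensitivity:
                    reported = {labels[0]}
                else:
                    reported = {"Uncertain"}
            else:
                reported = set(labels)
                for cls in TARGET_CLASSES:
                    if cls not in reported and rng.random() < expert.false_label_rate:
                        reported.add(cls)
            out.append(Annotation(cid, expert.expert_id, frozenset(reported)))
    return out


def labels_from_truth(truth: dict[str, tuple[str, ...]],
                      classes=TARGET_CLASSES) -> pd.DataFrame:
    """Boolean component x class target table from ground-truth labels."""
    index = pd.Index(list(truth), name="component_id")
    data = {cls: [cls in truth[cid] for cid in index] for cls in classes}
    return pd.DataFrame(data, index=index)


def default_config(**overrides) -> GeneratorConfig:
    return replace(GeneratorConfig(), **overrides)
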