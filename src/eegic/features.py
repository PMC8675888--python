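"""Per-component spatio-spectral features for IC classification.

Temporal: epoch-averaged kurtosis, max-to-mean epoch variance ratio (top 1%
of epoch variances trimmed for robustness), correlations with blink/saccade
signal templates.  Spectral: myogenic identification feature (MIF, relative
20-100 Hz power) and the alpha-band amplitude ratio AMALB (average spectral
amplitude in 6-12 Hz over the average outside it; the band is widened down
to 6 Hz because children's alpha sits lower).  Topographic: ADJUST-style
frontal/posterior/periocular contrasts (SAD, SVD, SED) and the mu/alpha
topography scores

    MT = sum_{e in Mu} |w_e| - sum_{e not in Mu} |w_e|
    AT = sum_{e in A}  |w_e| - sum_{e not in A}  |w_e|

computed on weights normalized to unit absolute sum, with Mu the
frontal-central and A the central-posterior electrode set (C3/Cz/C4 belong
to both).

Spectra are Welch estimates (1-s Hann segments, 50% overlap) computed per
epoch and averaged, giving a frequency grid of <= 1 Hz resolution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .ic_model import ICComponent, ICDataset, epoch_view
from .montage import (ALPHA_SET, FRONTAL_SET, LEFT_EYE_SET, MU_SET,
                      POSTERIOR_SET, RIGHT_EYE_SET, ChannelSet)

__all__ = [
    "FeatureError",
    "FeatureConfig",
    "FeatureTable",
    "FEATURE_NAMES",
    "normalize_weights",
    "kurtosis_feature",
    "max_epoch_variance",
    "spatial_features",
    "mif",
    "amalb",
    "mu_topography",
    "alpha_topography",
    "pattern_correlations",
    "blink_template",
    "saccade_template",
    "extract_features",
]

FEATURE_NAMES = (
    "kurtosis", "max_epoch_variance", "SAD", "SVD", "SED", "MIF",
    "pattern_corr_blink", "pattern_corr_saccade", "MT", "AT", "AMALB",
)


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable feature parameters with the package defaults.

    ``sed_convention`` is ``"abs_of_means"`` (|mean left| - |mean right|,
    the literal reading) or ``"abs_diff"`` (|mean left - mean right|,
    which responds to dipolar saccade topographies).
    """

    welch_segment_seconds: float = 1.0
    welch_overlap: float = 0.5
    mif_band: tuple[float, float] = (20.0, 100.0)
    alpha_band: tuple[float, float] = (6.0, 12.0)
    excess_kurtosis: bool = False
    variance_trim_fraction: float = 0.01
    sed_convention: str = "abs_of_means"
    blink_sigma_fraction: float = 0.10
    saccade_rise_fraction: float = 0.02
    frontal: ChannelSet = FRONTAL_SET
    posterior: ChannelSet = POSTERIOR_SET
    left_eye: ChannelSet = LEFT_EYE_SET
    right_eye: ChannelSet = RIGHT_EYE_SET
    mu_set: ChannelSet = MU_SET
    alpha_set: ChannelSet = ALPHA_SET


DEFAULT_CONFIG = FeatureConfig()


def normalize_weights(c: ICComponent) -> np.ndarray:
    """Weights scaled to unit sum of absolute values, sign preserved."""
    total = np.sum(np.abs(c.weights))
    if total == 0:
        raise FeatureError(f"{c.component_id}: all-zero weights")
    return c.weights / total


def polarity(c: ICComponent) -> float:
    """Canonical component orientation: +1 if the largest-magnitude weight
    is non-negative, else -1.

    An ICA component is only defined up to a joint sign flip of its
    weights and source; orienting on the dominant channel makes the
    sign-sensitive features (SED's signed means, signed pattern
    correlations) invariant to that ambiguity.
    """
    w = np.asarray(c.weights)
    if not w.size or np.all(w == 0):
        return 1.0
    return 1.0 if w[int(np.argmax(np.abs(w)))] >= 0 else -1.0


def kurtosis_feature(c: ICComponent,
                     config: FeatureConfig = DEFAULT_CONFIG) -> float:
    """Fourth standardized moment per epoch, averaged over epochs.

    Pearson convention by default (a Gaussian scores 3, a sinusoid 1.5).
    Zero-variance epochs are skipped with a warning.
    """
    epochs = epoch_view(c)
    if epochs.shape[1] < 4:
        raise FeatureError(f"{c.component_id}: kurtosis needs >= 4 samples "
                           f"per epoch")
    variances = epochs.var(axis=1)
    keep = variances > 0
    if not keep.any():
        raise FeatureError(f"{c.component_id}: every epoch has zero variance")
    if not keep.all():
        warnings.warn(f"{c.component_id}: skipping "
                      f"{int((~keep).sum())} zero-variance epoch(s)",
                      stacklevel=2)
    k = stats.kurtosis(epochs[keep], axis=1, fisher=config.excess_kurtosis,
                       bias=True)
    return float(np.mean(k))


def max_epoch_variance(c: ICComponent,
                       config: FeatureConfig = DEFAULT_CONFIG) -> float:
    """Max over mean of per-epoch signal variance, after trimming the top
    1% largest variances (robustness to isolated artifacts)."""
    epochs = epoch_view(c)
    n = epochs.shape[0]
    if n < 2:
        raise FeatureError(f"{c.component_id}: max_epoch_variance needs >= 2 "
                           f"epochs")
    variances = np.sort(epochs.var(axis=1))
    n_drop = math.ceil(config.variance_trim_fraction * n)
    remaining = variances[:n - n_drop] if n_drop else variances
    if remaining.size < 2:
        raise FeatureError(f"{c.component_id}: fewer than 2 epochs remain "
                           f"after trimming")
    mean = remaining.mean()
    if mean == 0:
        raise FeatureError(f"{c.component_id}: zero mean epoch variance")
    return float(remaining.max() / mean)


def _set_values(c, w, cset: ChannelSet) -> np.ndarray:
    members = cset.applied_to(c.channel_labels)
    if not members:
        raise FeatureError(f"{c.component_id}: channel set {cset.name!r} has "
                           f"no members in the montage")
    idx = [c.channel_labels.index(ch) for ch in members]
    return w[idx]


def spatial_features(c: ICComponent,
                     config: FeatureConfig = DEFAULT_CONFIG
                     ) -> tuple[float, float, float]:
    """ADJUST-style (SAD, SVD, SED) on normalized weights.

    SAD/SVD contrast absolute weights between frontal and posterior
    regions; SED contrasts the periocular left/right mean weights under
    the configured convention.
    """
    w = normalize_weights(c)
    frontal = np.abs(_set_values(c, w, config.frontal))
    posterior = np.abs(_set_values(c, w, config.posterior))
    sad = float(frontal.mean() - posterior.mean())
    svd = float(frontal.var() - posterior.var())
    w = polarity(c) * w  # orient before the sign-sensitive SED means
    left = _set_values(c, w, config.left_eye)
    right = _set_values(c, w, config.right_eye)
    if config.sed_convention == "abs_of_means":
        sed = float(abs(left.mean()) - abs(right.mean()))
    elif config.sed_convention == "abs_diff":
        sed = float(abs(left.mean() - right.mean()))
    else:
        raise FeatureError(f"unknown SED convention "
                           f"{config.sed_convention!r}")
    return sad, svd, sed


def power_spectrum(c: ICComponent,
                   config: FeatureConfig = DEFAULT_CONFIG
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD per epoch, averaged over epochs: ``(freqs, psd)``."""
    epochs = epoch_view(c)
    fs = c.sampling_rate
    nperseg = min(int(round(config.welch_segment_seconds * fs)),
                  epochs.shape[1])
    noverlap = int(nperseg * config.welch_overlap)
    freqs, psd = sps.welch(epochs, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=noverlap, axis=1)
    return freqs, psd.mean(axis=0)


def mif(c: ICComponent, config: FeatureConfig = DEFAULT_CONFIG,
        spectrum=None) -> float:
    """Relative signal strength in the 20-100 Hz band (myogenic activity).

    Ratio of integrated PSD over [20, min(100, Nyquist)] to integrated PSD
    over all positive frequencies; lies in [0, 1].
    """
    if c.sampling_rate <= 40:
        raise FeatureError(f"{c.component_id}: MIF needs sampling_rate > 40 "
                           f"Hz")
    freqs, psd = spectrum if spectrum is not None else power_spectrum(c, config)
    nyquist = c.sampling_rate / 2
    lo, hi = config.mif_band
    hi = min(hi, nyquist)
    band = (freqs >= lo) & (freqs <= hi)
    total = freqs > 0
    denom = psd[total].sum()
    if denom == 0:
        raise FeatureError(f"{c.component_id}: zero total power")
    return float(psd[band].sum() / denom)


def amalb(c: ICComponent, config: FeatureConfig = DEFAULT_CONFIG,
          spectrum=None) -> float:
    """Ratio of average spectral amplitude inside the (child-widened)
    6-12 Hz alpha band to the average amplitude at all other estimated
    frequencies up to Nyquist."""
    freqs, psd = spectrum if spectrum is not None else power_spectrum(c, config)
    amplitude = np.sqrt(psd)
    lo, hi = config.alpha_band
    in_band = (freqs >= lo) & (freqs <= hi)
    out_band = ~in_band
    if not in_band.any():
        raise FeatureError(f"{c.component_id}: alpha band {config.alpha_band} "
                           f"not resolvable at fs={c.sampling_rate}")
    denom = amplitude[out_band].sum()
    if denom == 0:
        raise FeatureError(f"{c.component_id}: empty AMALB denominator")
    return float(amplitude[in_band].sum() / denom)


def _topography_contrast(c: ICComponent, cset: ChannelSet) -> float:
    w = np.abs(normalize_weights(c))
    members = set(cset.applied_to(c.channel_labels))
    if not members:
        raise FeatureError(f"{c.component_id}: set {cset.name!r} empty on "
                           f"this montage")
    inside = sum(w[i] for i, ch in enumerate(c.channel_labels) if ch in members)
    return float(inside - (w.sum() - inside))


def mu_topography(c: ICComponent,
                  config: FeatureConfig = DEFAULT_CONFIG) -> float:
    """MT: absolute normalized weight inside minus outside the
    frontal-central mu electrode set."""
    return _topography_contrast(c, config.mu_set)


def alpha_topography(c: ICComponent,
                     config: FeatureConfig = DEFAULT_CONFIG) -> float:
    """AT: absolute normalized weight inside minus outside the
    central-posterior alpha electrode set."""
    return _topography_contrast(c, config.alpha_set)


def blink_template(n_samples: int, sigma_fraction: float = 0.10) -> np.ndarray:
    """Unit-amplitude smooth positive hump (Gaussian, centered)."""
    t = np.arange(n_samples)
    center = (n_samples - 1) / 2
    sigma = max(sigma_fraction * n_samples, 1.0)
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def saccade_template(n_samples: int, rise_fraction: float = 0.02) -> np.ndarray:
    """Smoothed step: logistic rise at mid-epoch."""
    t = np.arange(n_samples)
    center = (n_samples - 1) / 2
    scale = max(rise_fraction * n_samples, 1.0)
    return 1.0 / (1.0 + np.exp(-(t - center) / scale))


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def pattern_correlations(c: ICComponent,
                         templates: dict[str, np.ndarray] | None = None,
                         config: FeatureConfig = DEFAULT_CONFIG
                         ) -> dict[str, float]:
    """Correlation of epochs with blink/saccade signal templates.

    For each template: Pearson correlation per epoch, then the maximum of
    the absolute correlation over epochs, signed by the correlation at the
    maximizing epoch.  Constant epochs are skipped.  Templates are
    z-scored and resampled to the epoch length if needed.
    """
    epochs = polarity(c) * epoch_view(c)  # orient signed correlations
    n = epochs.shape[1]
    if templates is None:
        templates = {
            "blink": blink_template(n, config.blink_sigma_fraction),
            "saccade": saccade_template(n, config.saccade_rise_fraction),
        }
    keep = epochs.std(axis=1) > 0
    if not keep.any():
        raise FeatureError(f"{c.component_id}: all epochs constant")
    z_epochs = np.apply_along_axis(_zscore, 1, epochs[keep])
    out = {}
    for name, tmpl in templates.items():
        tmpl = np.asarray(tmpl, dtype=float)
        if tmpl.shape[0] != n:
            tmpl = sps.resample(tmpl, n)
        zt = _zscore(tmpl)
        corrs = z_epochs @ zt / n
        best = int(np.argmax(np.abs(corrs)))
        out[name] = float(corrs[best])
    return out


@dataclass
class FeatureTable:
    """Named per-component features plus a per-component error log."""

    table: pd.DataFrame                      # index=component_id
    errors: dict[str, dict[str, str]] = field(default_factory=dict)

    @property
    def flagged(self) -> list[str]:
        """Components with at least one missing feature."""
        return self.table.index[self.table.isna().any(axis=1)].tolist()

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        return cls(pd.read_csv(path, index_col="component_id"))


def extract_features(ds: ICDataset,
                     config: FeatureConfig = DEFAULT_CONFIG) -> FeatureTable:
    """Compute the full feature vector for every component.

    Per-feature failures are recorded as NaN with the error message logged
    per component; such components appear in ``FeatureTable.flagged``.
    """
    rows = []
    errors: dict[str, dict[str, str]] = {}

    def attempt(cid, name, fn, row):
        try:
            row[name] = fn()
        except FeatureError as exc:
            row[name] = np.nan
            errors.setdefault(cid, {})[name] = str(exc)

    for c in ds:
        cid = c.component_id
        row: dict[str, float] = {}
        attempt(cid, "kurtosis", lambda: kurtosis_feature(c, config), row)
        attempt(cid, "max_epoch_variance",
                lambda: max_epoch_variance(c, config), row)
        try:
            sad, svd, sed = spatial_features(c, config)
            row.update(SAD=sad, SVD=svd, SED=sed)
        except FeatureError as exc:
            row.update(SAD=np.nan, SVD=np.nan, SED=np.nan)
            errors.setdefault(cid, {})["spatial"] = str(exc)
        try:
            spectrum = power_spectrum(c, config)
        except Exception as exc:  # pragma: no cover - defensive
            spectrum = None
            errors.setdefault(cid, {})["spectrum"] = str(exc)
        attempt(cid, "MIF", lambda: mif(c, config, spectrum=spectrum), row)
        try:
            pat = pattern_correlations(c, config=config)
            row["pattern_corr_blink"] = pat["blink"]
            row["pattern_corr_saccade"] = pat["saccade"]
        except FeatureError as exc:
            row["pattern_corr_blink"] = np.nan
            row["pattern_corr_saccade"] = np.nan
            errors.setdefault(cid, {})["pattern"] = str(exc)
        attempt(cid, "MT", lambda: mu_topography(c, config), row)
        attempt(cid, "AT", lambda: alpha_topography(c, config), row)
        attempt(cid, "AMALB", lambda: amalb(c, config, spectrum=spectrum), row)
        rows.append(pd.Series(row, name=cid))

    table = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    table.index.name = "component_id"
    return FeatureTable(table=table, errors=errors)


def with_config(**overrides) -> FeatureConfig:
    """A FeatureConfig with selected fields overridden."""
    return replace(DEFAULT_CONFIG, **overrides)
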