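"""Domain types for EEG independent components and their on-disk interchange.

An independent component (IC) couples a *topomap* — one mixing weight per
scalp channel — with a source time series (epoched ``epochs x samples`` or
continuous), plus the sampling rate.  A dataset is a list of components
sharing one channel ordering, so spatial features are comparable.

Interchange dialect (plain text, diff-able):

``manifest.csv``
    component_id, subject_id, n_epochs, n_samples, sampling_rate, signal_file
``weights.csv``
    rows = components (component_id first column), columns = channel labels
``signals/<id>.csv`` or ``signals/<id>.f64``
    per-component signal; CSV rows are epochs, or a raw little-endian
    float64 array whose shape the manifest records.

Ingesting ICA output from FIF/EDF pipelines is a conversion recipe for the
caller (export the mixing-matrix column and source time course per
component), not a responsibility of this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import canonicalize

__all__ = [
    "ICComponent",
    "ICDataset",
    "DatasetFormatError",
    "load_dataset",
    "save_dataset",
    "epoch_view",
]


class DatasetFormatError(ValueError):
    """Raised when on-disk data violate the interchange contract."""


@dataclass
class ICComponent:
    """One independent component: topomap weights + source signal.

    Parameters
    ----------
    component_id, subject_id
        Identifiers; ``component_id`` must be unique within a dataset.
    channel_labels
        Ordered 10-10/10-20 channel names; canonicalized on construction.
    weights
        One real ICA topomap weight per channel (arbitrary scale and sign).
    signal
        ``epochs x samples`` array, or a 1-D vector for a continuous
        recording (treated as a single epoch).
    sampling_rate
        In Hz, positive.
    """

    component_id: str
    subject_id: str
    channel_labels: list[str]
    weights: np.ndarray
    signal: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        self.channel_labels = canonicalize(self.channel_labels)
        self.weights = np.asarray(self.weights, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim == 1:
            self.signal = self.signal[np.newaxis, :]
        if self.signal.ndim != 2:
            raise ValueError(
                f"{self.component_id}: signal must be 1-D or 2-D, "
                f"got shape {self.signal.shape}"
            )
        if len(self.channel_labels) != len(set(self.channel_labels)):
            dupes = [c for c in set(self.channel_labels)
                     if self.channel_labels.count(c) > 1]
            raise ValueError(f"{self.component_id}: duplicate channel labels {dupes}")
        if self.weights.shape != (len(self.channel_labels),):
            raise ValueError(
                f"{self.component_id}: {len(self.weights)} weights for "
                f"{len(self.channel_labels)} channels"
            )
        if self.signal.shape[0] < 1 or self.signal.shape[1] < 2:
            raise ValueError(
                f"{self.component_id}: signal needs >= 1 epoch and >= 2 "
                f"samples, got {self.signal.shape}"
            )
        if not self.sampling_rate > 0:
            raise ValueError(f"{self.component_id}: sampling_rate must be > 0")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError(f"{self.component_id}: non-finite weights")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError(f"{self.component_id}: non-finite signal values")

    @property
    def n_epochs(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


def epoch_view(component: ICComponent) -> np.ndarray:
    """Epoched view of the signal (continuous data become ``1 x samples``)."""
    return component.signal


@dataclass
class ICDataset:
    """A collection of components sharing one channel ordering."""

    components: list[ICComponent] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        ids = [c.component_id for c in self.components]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate component ids: {dupes}")
        if self.components:
            ref = self.components[0].channel_labels
            for c in self.components[1:]:
                if c.channel_labels != ref:
                    raise ValueError(
                        f"component {c.component_id} channel ordering differs "
                        f"from {self.components[0].component_id}"
                    )

    @property
    def channel_labels(self) -> list[str]:
        if not self.components:
            return []
        return self.components[0].channel_labels

    def __len__(self) -> int:
        return len(self.components)

    def __iter__(self):
        return iter(self.components)

    def get(self, component_id: str) -> ICComponent:
        for c in self.components:
            if c.component_id == component_id:
                return c
        raise KeyError(component_id)


def save_dataset(ds: ICDataset, path, signal_format: str = "csv") -> None:
    """Write ``ds`` in the interchange dialect under directory ``path``.

    ``signal_format`` is ``"csv"`` (delimited text, default) or ``"f64"``
    (raw little-endian float64, shape recorded in the manifest).
    """
    if signal_format not in ("csv", "f64"):
        raise ValueError(f"unknown signal format {signal_format!r}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sig_dir = path / "signals"

    rows = []
    weight_rows = []
    for c in ds.components:
        sig_file = ""
        if True:  # always store the signal
            sig_dir.mkdir(exist_ok=True)
            sig_file = f"signals/{c.component_id}.{signal_format}"
            if signal_format == "csv":
                np.savetxt(path / sig_file, c.signal, delimiter=",", fmt="%.9e")
            else:
                c.signal.astype("<f8").tofile(path / sig_file)
        rows.append({
            "component_id": c.component_id,
            "subject_id": c.subject_id,
            "n_epochs": c.n_epochs,
            "n_samples": c.n_samples,
            "sampling_rate": repr(float(c.sampling_rate)),
            "signal_file": sig_file,
        })
        weight_rows.append(
            {"component_id": c.component_id,
             **{ch: repr(float(w)) for ch, w in zip(c.channel_labels, c.weights)}}
        )
    manifest = pd.DataFrame(
        rows, columns=["component_id", "subject_id", "n_epochs", "n_samples",
                       "sampling_rate", "signal_file"])
    manifest.to_csv(path / "manifest.csv", index=False)
    cols = ["component_id"] + ds.channel_labels
    pd.DataFrame(weight_rows, columns=cols if ds.components else ["component_id"]
                 ).to_csv(path / "weights.csv", index=False)
    if ds.metadata:
        meta = pd.DataFrame(sorted(ds.metadata.items()), columns=["key", "value"])
        meta.to_csv(path / "metadata.csv", index=False)


def load_dataset(path) -> ICDataset:
    """Load a dataset written by :func:`save_dataset`.

    Channel order is normalized to the weights-table header order; weight
    rows may appear in any order (matched by ``component_id``).
    """
    path = Path(path)
    manifest_path = path / "manifest.csv"
    if not manifest_path.exists():
        raise DatasetFormatError(f"missing manifest file: {manifest_path}")
    weights_path = path / "weights.csv"
    if not weights_path.exists():
        raise DatasetFormatError(f"missing weights file: {weights_path}")

    manifest = pd.read_csv(manifest_path, dtype={"component_id": str,
                                                 "subject_id": str})
    weights = pd.read_csv(weights_path, dtype={"component_id": str})
    channels = canonicalize([c for c in weights.columns if c != "component_id"])
    weights.columns = ["component_id"] + channels if len(weights.columns) else weights.columns
    weights = weights.set_index("component_id")

    components = []
    for row in manifest.itertuples(index=False):
        cid = row.component_id
        if cid not in weights.index:
            raise DatasetFormatError(
                f"component {cid}: no row in weights table")
        wrow = weights.loc[cid, channels].to_numpy(dtype=float)
        if np.isnan(wrow).any():
            bad = [ch for ch, w in zip(channels, wrow) if np.isnan(w)]
            raise DatasetFormatError(
                f"component {cid}: missing/non-numeric weights for {bad}")
        sig_path = path / row.signal_file
        if not sig_path.exists():
            raise DatasetFormatError(f"component {cid}: missing signal file "
                                     f"{sig_path}")
        shape = (int(row.n_epochs), int(row.n_samples))
        if sig_path.suffix == ".f64":
            signal = np.fromfile(sig_path, dtype="<f8")
            if signal.size != shape[0] * shape[1]:
                raise DatasetFormatError(
                    f"component {cid}: signal file holds {signal.size} values, "
                    f"manifest declares shape {shape}")
            signal = signal.reshape(shape)
        else:
            signal = np.loadtxt(sig_path, delimiter=",", ndmin=2)
            if signal.shape != shape:
                raise DatasetFormatError(
                    f"component {cid}: signal shape {signal.shape} does not "
                    f"match manifest {shape}")
        try:
            comp = ICComponent(
                component_id=cid,
                subject_id=str(row.subject_id),
                channel_labels=channels,
                weights=wrow,
                signal=signal,
                sampling_rate=float(row.sampling_rate),
            )
        except ValueError as exc:
            raise DatasetFormatError(str(exc)) from exc
        components.append(comp)

    metadata = {}
    meta_path = path / "metadata.csv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, dtype=str)
        metadata = dict(zip(meta["key"], meta["value"]))
    return ICDataset(components=components, metadata=metadata)
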