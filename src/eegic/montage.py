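"""Scalp channel naming, 10-10/10-20 montage handling and named electrode sets.

Channel labels are canonicalized to modern 10-10 names: legacy temporal
labels (``T3/T4/T5/T6``) map to ``T7/T8/P7/P8``, and capitalization is
normalized (``Fc3`` -> ``FC3``).  The default montage is a 31-electrode
10-10 layout common in pediatric ERP work.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

#: Legacy 10-20 temporal labels -> modern 10-10 equivalents.
LEGACY_ALIASES = {
    "T3": "T7",
    "T4": "T8",
    "T5": "P7",
    "T6": "P8",
}

#: Canonical 10-10 labels recognized by this package (superset of the
#: default montage; extendable -- unknown labels pass through with
#: capitalization normalized).
_CANONICAL = [
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F9", "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8", "F10",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T9", "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8", "T10",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
]

_CANONICAL_BY_UPPER = {name.upper(): name for name in _CANONICAL}


def canonical_channel(label: str) -> str:
    """Return the canonical modern 10-10 name for ``label``.

    Case-insensitive; resolves legacy aliases (T3 -> T7 etc.).  Labels not
    in the canonical table are returned stripped but otherwise untouched.
    """
    key = label.strip().upper()
    key = LEGACY_ALIASES.get(key, key)
    # aliases are stored upper-case keys -> canonical values already
    if key in _CANONICAL_BY_UPPER:
        return _CANONICAL_BY_UPPER[key]
    return label.strip()


def canonicalize(labels) -> list[str]:
    """Canonicalize a sequence of channel labels, preserving order."""
    return [canonical_channel(lab) for lab in labels]


#: The default 31-channel 10-10 montage (canonical names).
DEFAULT_MONTAGE = canonicalize([
    "Fp1", "Fpz", "Fp2", "F3", "Fz", "F4", "F7", "F8",
    "FC3", "FCz", "FC4", "FT7", "FT8",
    "C3", "Cz", "C4",
    "CP3", "CPz", "CP4",
    "P3", "Pz", "P4", "TP8", "TP7",
    "T3", "T4", "T5", "T6",
    "O1", "Oz", "O2",
])

#: Schematic 2-D scalp coordinates (x: left-negative/right-positive,
#: y: posterior-negative/anterior-positive), unit head radius.  Used by the
#: synthetic generator to shape parametric topographies.
CHANNEL_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.30, 0.90), "Fpz": (0.00, 0.95), "Fp2": (0.30, 0.90),
    "F7": (-0.75, 0.50), "F3": (-0.35, 0.55), "Fz": (0.00, 0.55),
    "F4": (0.35, 0.55), "F8": (0.75, 0.50),
    "FT7": (-0.80, 0.25), "FC3": (-0.35, 0.28), "FCz": (0.00, 0.28),
    "FC4": (0.35, 0.28), "FT8": (0.80, 0.25),
    "T7": (-0.85, 0.00), "C3": (-0.40, 0.00), "Cz": (0.00, 0.00),
    "C4": (0.40, 0.00), "T8": (0.85, 0.00),
    "TP7": (-0.80, -0.25), "CP3": (-0.35, -0.28), "CPz": (0.00, -0.28),
    "CP4": (0.35, -0.28), "TP8": (0.80, -0.25),
    "P7": (-0.75, -0.50), "P3": (-0.35, -0.55), "Pz": (0.00, -0.55),
    "P4": (0.35, -0.55), "P8": (0.75, -0.50),
    "O1": (-0.30, -0.90), "Oz": (0.00, -0.95), "O2": (0.30, -0.90),
}


@dataclass(frozen=True)
class ChannelSet:
    """A named set of scalp electrodes used by topographic features.

    When applied to a montage, members absent from the montage are dropped
    with a logged warning rather than raising, so feature definitions
    survive montage variation.
    """

    name: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"channel set {self.name!r} has no members")
        object.__setattr__(
            self, "members", frozenset(canonical_channel(m) for m in self.members)
        )

    def applied_to(self, montage) -> list[str]:
        """Members present in ``montage`` (canonical names, montage order)."""
        montage = canonicalize(montage)
        present = [ch for ch in montage if ch in self.members]
        missing = self.members - set(montage)
        if missing:
            msg = (f"channel set {self.name!r}: dropping members missing from "
                   f"montage: {sorted(missing)}")
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
        return present


def channel_set(name: str, members) -> ChannelSet:
    return ChannelSet(name, frozenset(members))


# Electrode sets for the mu/alpha topography features (10-10 names).
MU_SET = channel_set("mu", [
    "Fp1", "Fpz", "Fp2", "F3", "Fz", "F4",
    "FC3", "FCz", "FC4", "C3", "Cz", "C4",
])
ALPHA_SET = channel_set("alpha", [
    "C3", "Cz", "C4", "CP3", "CPz", "CP4",
    "P3", "Pz", "P4", "O1", "Oz", "O2",
])

# ADJUST-style regional sets for the SAD/SVD/SED eye features.
FRONTAL_SET = channel_set("frontal", ["Fp1", "Fpz", "Fp2", "F3", "Fz", "F4", "F7", "F8"])
POSTERIOR_SET = channel_set("posterior", ["P3", "Pz", "P4", "O1", "Oz", "O2", "P7", "P8"])
LEFT_EYE_SET = channel_set("left_eye", ["Fp1", "F7"])
RIGHT_EYE_SET = channel_set("right_eye", ["Fp2", "F8"])
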