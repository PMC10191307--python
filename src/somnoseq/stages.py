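"""Stage schemes and hypnograms.

Sleep is scored in 30-s epochs. The five AASM stages (W, N1, N2, N3, REM)
collapse onto coarser schemes: four-class merges N1+N2 into Light and keeps
N3 as Deep; three-class merges all NREM; two-class keeps only wake vs sleep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_SCHEME_LABELS: dict[str, tuple[str, ...]] = {
    "two": ("W", "Sleep"),
    "three": ("W", "NREM", "REM"),
    "four": ("W", "Light", "Deep", "REM"),
    "five": ("W", "N1", "N2", "N3", "REM"),
}

# label-level collapsing maps between adjacent granularities
_COLLAPSE: dict[tuple[str, str], dict[str, str]] = {
    ("five", "four"): {"W": "W", "N1": "Light", "N2": "Light", "N3": "Deep", "REM": "REM"},
    ("five", "three"): {"W": "W", "N1": "NREM", "N2": "NREM", "N3": "NREM", "REM": "REM"},
    ("four", "three"): {"W": "W", "Light": "NREM", "Deep": "NREM", "REM": "REM"},
    ("three", "two"): {"W": "W", "NREM": "Sleep", "REM": "Sleep"},
    ("four", "two"): {"W": "W", "Light": "Sleep", "Deep": "Sleep", "REM": "Sleep"},
    ("five", "two"): {"W": "W", "N1": "Sleep", "N2": "Sleep", "N3": "Sleep", "REM": "Sleep"},
}

_ORDER = ("five", "four", "three", "two")


@dataclass(frozen=True)
class StageScheme:
    """A declared stage label set (two/three/four/five-class)."""

    name: str
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.name not in _SCHEME_LABELS:
            raise ValueError(f"unknown stage scheme {self.name!r}; choose from {sorted(_SCHEME_LABELS)}")
        if not self.labels:
            object.__setattr__(self, "labels", _SCHEME_LABELS[self.name])
        if self.labels != _SCHEME_LABELS[self.name]:
            raise ValueError(f"labels {self.labels} do not match scheme {self.name!r}")

    @property
    def K(self) -> int:
        return len(self.labels)

    @property
    def wake_index(self) -> int:
        return self.labels.index("W")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValueError(f"unknown stage label {label!r} for scheme {self.name!r}") from None

    def collapse_map(self, other: "StageScheme") -> np.ndarray:
        """Index map m such that collapsed_code = m[code] under ``other``."""
        if other.name == self.name:
            return np.arange(self.K)
        src = _ORDER.index(self.name)
        dst = _ORDER.index(other.name)
        if dst < src:
            raise ValueError(f"cannot collapse {self.name!r} onto finer scheme {other.name!r}")
        labels = list(self.labels)
        for step in range(src, dst):
            m = _COLLAPSE[(_ORDER[step], _ORDER[step + 1])]
            labels = [m[lab] for lab in labels]
        return np.array([other.index(lab) for lab in labels])


TWO = StageScheme("two")
THREE = StageScheme("three")
FOUR = StageScheme("four")
FIVE = StageScheme("five")


def scheme(name: str | StageScheme) -> StageScheme:
    return name if isinstance(name, StageScheme) else StageScheme(name)


@dataclass
class Hypnogram:
    """Per-epoch stage labels (integer codes) under a declared scheme."""

    codes: np.ndarray
    scheme: StageScheme
    epoch_s: float = 30.0

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 1:
            raise ValueError("hypnogram codes must be one-dimensional")
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() >= self.scheme.K):
            raise ValueError("stage code out of range for scheme")

    def __len__(self) -> int:
        return self.codes.size

    @classmethod
    def from_labels(cls, labels, scheme_: str | StageScheme, epoch_s: float = 30.0) -> "Hypnogram":
        sch = scheme(scheme_)
        return cls(np.array([sch.index(str(lab)) for lab in labels]), sch, epoch_s)

    def to_labels(self) -> list[str]:
        return [self.scheme.labels[c] for c in self.codes]

    def fractions(self) -> np.ndarray:
        """Empirical stage fractions in scheme order."""
        return np.bincount(self.codes, minlength=self.scheme.K) / max(len(self), 1)

    def collapse(self, to: str | StageScheme) -> "Hypnogram":
        dst = scheme(to)
        m = self.scheme.collapse_map(dst)
        return Hypnogram(m[self.codes], dst, self.epoch_s)

    def is_sleep(self) -> np.ndarray:
        """Boolean mask of non-wake epochs."""
        return self.codes != self.scheme.wake_index
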