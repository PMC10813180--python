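"""Core data containers for SERS spectra.

A :class:`Spectrum` is a single wavenumber-indexed intensity trace with
acquisition metadata (sample id, replicate index, class label).  A
:class:`SpectraSet` holds many spectra aligned on one shared wavenumber grid
as an ``n_samples x n_points`` matrix, which is the object every pipeline
stage consumes and produces.

Class labels follow the study design: ``FM`` (fibromyalgia), ``NONFM``
(pooled rheumatic comparators: RA, SLE, OA, CLBP), ``NC`` (healthy controls)
and ``UNKNOWN``.  For discriminant modelling the two modelled classes are
coded FM = 1 and non-FM = 2; the midpoint 1.5 is the decision threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FM",
    "NONFM",
    "NC",
    "UNKNOWN",
    "LABELS",
    "CLASS_CODES",
    "CODE_FM",
    "CODE_NONFM",
    "DECISION_THRESHOLD",
    "Spectrum",
    "SpectraSet",
    "encode_labels",
    "decode_codes",
]

FM = "FM"
NONFM = "NONFM"
NC = "NC"
UNKNOWN = "UNKNOWN"
LABELS = (FM, NONFM, NC, UNKNOWN)

# Two-class coding used by the discriminant model: FM is class 1, pooled
# non-FM is class 2; a continuous prediction below 1.5 is called FM.
CODE_FM = 1.0
CODE_NONFM = 2.0
CLASS_CODES = {FM: CODE_FM, NONFM: CODE_NONFM}
DECISION_THRESHOLD = 0.5 * (CODE_FM + CODE_NONFM)


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class Spectrum:
    """One Raman/SERS trace on a strictly increasing wavenumber axis (cm^-1)."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    sample_id: str = ""
    replicate: int = 0
    label: str = UNKNOWN

    def __post_init__(self):
        wn = _as_float_array(self.wavenumbers, "wavenumbers")
        y = _as_float_array(self.intensities, "intensities")
        if wn.size != y.size:
            raise ValueError(
                f"axis and intensities differ in length: {wn.size} vs {y.size}"
            )
        if wn.size < 3:
            raise ValueError("a spectrum needs at least 3 points")
        if not np.all(np.diff(wn) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")
        if self.replicate < 0:
            raise ValueError("replicate index must be non-negative")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def spacing(self) -> float:
        """Median grid spacing in cm^-1."""
        return float(np.median(np.diff(self.wavenumbers)))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.wavenumbers)
        return bool(np.all(np.abs(d - d[0]) <= rtol * abs(d[0])))

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        return replace(self, intensities=np.asarray(intensities, dtype=float))


@dataclass
class SpectraSet:
    """Aligned spectra: shared grid, intensity matrix X, labels and ids.

    Rows of ``X`` correspond positionally to ``ids``, ``labels`` and
    ``replicates``.  Several rows may share a ``sample_id`` (one per
    replicate) until :func:`sersdx.io.average_replicates` collapses them.
    """

    grid: np.ndarray
    X: np.ndarray
    labels: np.ndarray
    ids: np.ndarray
    replicates: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.grid = _as_float_array(self.grid, "grid")
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {X.shape}")
        if X.shape[1] != self.grid.size:
            raise ValueError(
                f"X has {X.shape[1]} columns but the grid has {self.grid.size} points"
            )
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        self.X = X
        self.labels = np.asarray(self.labels, dtype=object)
        self.ids = np.asarray(self.ids, dtype=object)
        if self.replicates is None:
            self.replicates = np.zeros(X.shape[0], dtype=int)
        self.replicates = np.asarray(self.replicates, dtype=int)
        n = X.shape[0]
        for name, arr in (
            ("labels", self.labels),
            ("ids", self.ids),
            ("replicates", self.replicates),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}, got {arr.shape}")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels {sorted(map(str, bad))}")

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum]) -> "SpectraSet":
        """Stack spectra that already share a common grid."""
        if not spectra:
            raise ValueError("no spectra given")
        grid = spectra[0].wavenumbers
        for s in spectra[1:]:
            if s.wavenumbers.size != grid.size or not np.allclose(
                s.wavenumbers, grid, rtol=0, atol=1e-9
            ):
                raise ValueError(
                    "spectra are not on a shared grid; resample_to_grid first"
                )
        return cls(
            grid=grid.copy(),
            X=np.vstack([s.intensities for s in spectra]),
            labels=np.array([s.label for s in spectra], dtype=object),
            ids=np.array([s.sample_id for s in spectra], dtype=object),
            replicates=np.array([s.replicate for s in spectra], dtype=int),
        )

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_points(self) -> int:
        return self.grid.size

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(
            wavenumbers=self.grid,
            intensities=self.X[i],
            sample_id=str(self.ids[i]),
            replicate=int(self.replicates[i]),
            label=str(self.labels[i]),
        )

    def __iter__(self) -> Iterable[Spectrum]:
        return (self.spectrum(i) for i in range(len(self)))

    def subset(self, index) -> "SpectraSet":
        """Row subset by boolean mask or integer index array."""
        index = np.asarray(index)
        return SpectraSet(
            grid=self.grid.copy(),
            X=self.X[index].copy(),
            labels=self.labels[index].copy(),
            ids=self.ids[index].copy(),
            replicates=self.replicates[index].copy(),
        )

    def select_labels(self, *labels: str) -> "SpectraSet":
        mask = np.isin(self.labels, labels)
        if not mask.any():
            raise ValueError(f"no samples with labels {labels}")
        return self.subset(mask)

    def with_X(self, X: np.ndarray, grid: np.ndarray | None = None) -> "SpectraSet":
        return SpectraSet(
            grid=self.grid.copy() if grid is None else np.asarray(grid, dtype=float),
            X=np.asarray(X, dtype=float),
            labels=self.labels.copy(),
            ids=self.ids.copy(),
            replicates=self.replicates.copy(),
        )

    def class_codes(self) -> np.ndarray:
        """Coded response (FM = 1, non-FM = 2) for the modelled two classes."""
        return encode_labels(self.labels)


def encode_labels(labels) -> np.ndarray:
    """Map FM/NONFM labels to the (1, 2) class coding.

    Raises on NC or UNKNOWN rows: controls are not part of the two-class
    discriminant model and must be filtered out first.
    """
    labels = np.asarray(labels, dtype=object)
    out = np.empty(labels.size, dtype=float)
    for i, lab in enumerate(labels):
        try:
            out[i] = CLASS_CODES[lab]
        except KeyError:
            raise ValueError(
                f"label {lab!r} has no class code; model classes are {FM}/{NONFM}"
            ) from None
    return out


def decode_codes(y: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_labels` for hard class assignments."""
    y = np.asarray(y, dtype=float)
    out = np.where(y < DECISION_THRESHOLD, FM, NONFM)
    return out.astype(object)
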