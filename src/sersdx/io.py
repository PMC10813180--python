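"""Reading, writing, aligning and replicate-averaging spectra.

Two text formats are supported:

* **CSV wide table** (canonical interchange format): first column is the
  wavenumber axis, every further column one spectrum.  Column names follow
  ``<sample_id>_r<replicate>`` with an optional ``__<label>`` suffix as a
  fallback label encoding; the preferred way to carry labels is a sidecar
  metadata CSV with columns ``sample_id, replicate, label``.
* **JCAMP-DX** (read-only): uncompressed (AFFN) ``##XYDATA=(X++(Y..Y))``
  and ``##XYPOINTS=(XY..XY)`` tables with XFACTOR/YFACTOR scaling.
  ASDF-compressed tables (SQZ/DIF/DUP) are rejected with a clear message.

Every sample in the study was measured four times; `average_replicates`
collapses replicate rows to their arithmetic mean, the per-sample spectrum
used by all downstream modelling.
"""

from __future__ import annotations

import os
import re
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import LABELS, UNKNOWN, Spectrum, SpectraSet

__all__ = [
    "read_spectra",
    "write_spectra",
    "read_jcamp",
    "resample_to_grid",
    "common_grid",
    "align_spectra",
    "average_replicates",
]

_COLUMN_RE = re.compile(r"^(?P<id>.+?)(?:_r(?P<rep>\d+))?(?:__(?P<label>[A-Z]+))?$")


def _parse_column_name(name: str):
    m = _COLUMN_RE.match(str(name).strip())
    if m is None:  # pragma: no cover - regex matches any non-empty string
        return str(name), 0, None
    rep = int(m.group("rep")) if m.group("rep") is not None else 0
    label = m.group("label")
    if label is not None and label not in LABELS:
        # not a label suffix after all; fold it back into the id
        return str(name), rep, None
    return m.group("id"), rep, label


def _read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype={"sample_id": str, "label": str})
    required = {"sample_id", "label"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata file {path} lacks columns {sorted(missing)}")
    if "replicate" not in meta.columns:
        meta["replicate"] = 0
    meta["replicate"] = meta["replicate"].astype(int)
    return meta


def read_spectra(path, format: str = "csv", metadata=None) -> SpectraSet:
    """Read a :class:`SpectraSet` from a CSV wide table or JCAMP-DX file(s).

    Parameters
    ----------
    path
        CSV file for ``format='csv'``; a single ``.jdx``/``.dx`` file or a
        directory of them for ``format='jcamp'``.
    metadata
        Optional sidecar CSV with columns ``sample_id, replicate, label``.
        Overrides any label encoded in column names.
    """
    if format == "csv":
        spectra = _read_csv(path)
    elif format == "jcamp":
        spectra = _read_jcamp_any(path)
    else:
        raise ValueError(f"unknown format {format!r}; use 'csv' or 'jcamp'")

    if metadata is not None:
        meta = _read_metadata(metadata)
        lut = {
            (str(r.sample_id), int(r.replicate)): str(r.label)
            for r in meta.itertuples()
        }
        bysample = {str(r.sample_id): str(r.label) for r in meta.itertuples()}
        relabelled = []
        for s in spectra:
            label = lut.get((s.sample_id, s.replicate), bysample.get(s.sample_id))
            if label is None:
                raise ValueError(f"no metadata row for sample {s.sample_id!r}")
            if label not in LABELS:
                raise ValueError(f"metadata label {label!r} not in {LABELS}")
            relabelled.append(
                Spectrum(s.wavenumbers, s.intensities, s.sample_id, s.replicate, label)
            )
        spectra = relabelled
    return SpectraSet.from_spectra(spectra)


def _read_csv(path) -> list[Spectrum]:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("wide-table CSV needs a wavenumber column plus spectra")
    if df.isna().any().any():
        raise ValueError("ragged or missing values in CSV table")
    wn = df.iloc[:, 0].to_numpy(dtype=float)
    if not np.all(np.diff(wn) > 0):
        if np.all(np.diff(wn) < 0):  # descending axes are common instrument output
            df = df.iloc[::-1].reset_index(drop=True)
            wn = df.iloc[:, 0].to_numpy(dtype=float)
        else:
            raise ValueError("wavenumber column is not monotone")
    spectra = []
    for col in df.columns[1:]:
        sid, rep, label = _parse_column_name(col)
        spectra.append(
            Spectrum(
                wavenumbers=wn,
                intensities=df[col].to_numpy(dtype=float),
                sample_id=sid,
                replicate=rep,
                label=label or UNKNOWN,
            )
        )
    return spectra


def write_spectra(sset: SpectraSet, path, metadata=None) -> None:
    """Write a wide-table CSV (and optionally a metadata sidecar CSV)."""
    cols = {"wavenumber": sset.grid}
    for i in range(len(sset)):
        cols[f"{sset.ids[i]}_r{sset.replicates[i]}"] = sset.X[i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")
    if metadata is not None:
        pd.DataFrame(
            {
                "sample_id": sset.ids,
                "replicate": sset.replicates,
                "label": sset.labels,
            }
        ).to_csv(metadata, index=False)


# ---------------------------------------------------------------------------
# JCAMP-DX (AFFN subset)
# ---------------------------------------------------------------------------

_ASDF_LETTERS = re.compile(r"[A-DF-Za-df-z@%]")  # E/e allowed: exponents


def _read_jcamp_any(path) -> list[Spectrum]:
    if os.path.isdir(path):
        files = sorted(
            os.path.join(path, f)
            for f in os.listdir(path)
            if f.lower().endswith((".jdx", ".dx", ".jcm"))
        )
        if not files:
            raise ValueError(f"no JCAMP files in directory {path}")
        return [read_jcamp(f) for f in files]
    return [read_jcamp(path)]


def read_jcamp(path) -> Spectrum:
    """Read one spectrum from an uncompressed (AFFN) JCAMP-DX file."""
    with open(path) as fh:
        lines = fh.read().splitlines()

    fields: dict[str, str] = {}
    data_lines: list[str] = []
    mode = None  # None | 'xydata' | 'xypoints'
    for raw in lines:
        line = raw.split("$$", 1)[0].rstrip()  # strip JCAMP comments
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "XYDATA":
                mode = "xydata"
                if "X++" not in value.replace(" ", ""):
                    raise ValueError(f"unsupported XYDATA variable list {value!r}")
            elif key == "XYPOINTS":
                mode = "xypoints"
            elif key == "END":
                mode = None
            else:
                mode = None
                fields[key] = value
        elif mode is not None:
            data_lines.append(line)

    if mode is None and not data_lines:
        raise ValueError(f"{path}: no XYDATA/XYPOINTS table found")

    xfactor = float(fields.get("XFACTOR", 1.0))
    yfactor = float(fields.get("YFACTOR", 1.0))
    title = fields.get("TITLE", os.path.splitext(os.path.basename(path))[0])

    blob = " ".join(data_lines)
    if _ASDF_LETTERS.search(blob.replace("E+", " ").replace("E-", " ").replace("e+", " ").replace("e-", " ")):
        raise ValueError(
            f"{path}: compressed (SQZ/DIF/DUP) JCAMP data are not supported; "
            "export in AFFN (plain numeric) form"
        )

    # Determine which table we saw: XYPOINTS pairs vs XYDATA X++(Y..Y)
    if any("," in ln for ln in data_lines):
        xs, ys = [], []
        for pair in blob.split(";"):
            nums = [v for v in re.split(r"[,\s]+", pair.strip()) if v]
            if not nums:
                continue
            if len(nums) != 2:
                raise ValueError(f"malformed XYPOINTS pair {pair.strip()!r}")
            xs.append(float(nums[0]) * xfactor)
            ys.append(float(nums[1]) * yfactor)
        wn = np.asarray(xs)
        inten = np.asarray(ys)
    else:
        ys = []
        first_x = None
        for ln in data_lines:
            nums = [float(v) for v in re.split(r"[,\s]+", ln.strip()) if v]
            if not nums:
                continue
            if first_x is None:
                first_x = nums[0] * xfactor
            ys.extend(nums[1:])  # first number on each line is the line's x
        inten = np.asarray(ys) * yfactor
        npoints = int(fields.get("NPOINTS", inten.size))
        if npoints != inten.size:
            raise ValueError(
                f"{path}: NPOINTS={npoints} but {inten.size} ordinates decoded"
            )
        firstx = float(fields.get("FIRSTX", first_x if first_x is not None else 0.0))
        lastx = float(fields.get("LASTX", firstx + npoints - 1))
        wn = np.linspace(firstx, lastx, npoints)

    order = np.argsort(wn)
    return Spectrum(wavenumbers=wn[order], intensities=inten[order], sample_id=title)


# ---------------------------------------------------------------------------
# Alignment and replicate averaging
# ---------------------------------------------------------------------------


def resample_to_grid(s: Spectrum, grid) -> Spectrum:
    """Linearly interpolate a spectrum onto a new grid within its support."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] < s.wavenumbers[0] - 1e-9 or grid[-1] > s.wavenumbers[-1] + 1e-9:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] extends beyond the spectrum's support "
            f"[{s.wavenumbers[0]}, {s.wavenumbers[-1]}]; refusing to extrapolate"
        )
    inten = np.interp(grid, s.wavenumbers, s.intensities)
    return Spectrum(grid, inten, s.sample_id, s.replicate, s.label)


def common_grid(spectra: Sequence[Spectrum], step: float = 2.0) -> np.ndarray:
    """Uniform grid at `step` cm^-1 spanning the intersection of supports."""
    lo = max(s.wavenumbers[0] for s in spectra)
    hi = min(s.wavenumbers[-1] for s in spectra)
    if hi - lo < 2 * step:
        raise ValueError("spectral supports barely overlap; no common grid")
    n = int(np.floor((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def align_spectra(spectra: Sequence[Spectrum], step: float = 2.0) -> SpectraSet:
    """Resample a heterogeneous collection onto a shared uniform grid."""
    grid = common_grid(spectra, step=step)
    return SpectraSet.from_spectra([resample_to_grid(s, grid) for s in spectra])


def average_replicates(sset: SpectraSet) -> SpectraSet:
    """Collapse replicate rows to one arithmetic-mean spectrum per sample.

    Groups rows by ``sample_id`` (first-appearance order preserved) and
    errors if a group carries conflicting class labels.
    """
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, sid in enumerate(sset.ids):
        sid = str(sid)
        if sid not in groups:
            groups[sid] = []
            order.append(sid)
        groups[sid].append(i)

    X = np.empty((len(order), sset.n_points))
    labels = np.empty(len(order), dtype=object)
    for j, sid in enumerate(order):
        idx = groups[sid]
        labs = {str(sset.labels[i]) for i in idx}
        if len(labs) != 1:
            raise ValueError(
                f"sample {sid!r} has conflicting labels {sorted(labs)}"
            )
        labels[j] = labs.pop()
        X[j] = sset.X[idx].mean(axis=0)

    return SpectraSet(
        grid=sset.grid.copy(),
        X=X,
        labels=labels,
        ids=np.array(order, dtype=object),
        replicates=np.zeros(len(order), dtype=int),
    )
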