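"""Synthetic SERS cohort generator.

The study's patient spectra are not publicly deposited, so every pipeline
stage is exercised on synthetic cohorts that emulate the *statistical
structure* the analysis assumes: serum-like SERS spectra on a 600-2300
cm^-1 grid at 2 cm^-1 resolution, built from Lorentzian bands at the
literature band positions, riding on a smooth exponential fluorescence
background, with additive white noise, per-sample biological variability
and four replicate acquisitions per sample.

Class structure is planted multiplicatively: the eight discriminant bands
(991, 1013, 1202, 1222, 1348, 1370, 1566 and 1582 cm^-1 - aromatic amino
acid features) have their amplitudes raised in FM-like samples and lowered
in non-FM-like samples by a fractional effect, so vector normalization does
not trivially erase the signal.  ``effect_scale = 0`` produces an exact
null cohort (classes identically distributed) used for leakage checks.

Band amplitudes are free parameters of the generator chosen to mimic the
qualitative strong/medium intensity hierarchy of serum SERS spectra; they
are not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectra import FM, NC, NONFM, Spectrum, SpectraSet

__all__ = [
    "BandSpec",
    "SyntheticConfig",
    "default_band_table",
    "DISCRIMINANT_BANDS",
    "generate_cohort",
    "inject_photodegradation",
    "qc_flag_burned",
    "PHOTODEGRADATION_BAND",
]

#: Bands highlighted by the discriminant model's regression vector.
DISCRIMINANT_BANDS = (991.0, 1013.0, 1202.0, 1222.0, 1348.0, 1370.0, 1566.0, 1582.0)

#: Amorphous-carbon artifact band indicating laser-induced photodegradation.
PHOTODEGRADATION_BAND = 1535.0

#: Bands with qualitatively strong intensity in serum SERS spectra.
_STRONG = {1014.0, 1222.0, 1354.0, 1448.0, 1586.0}


@dataclass(frozen=True)
class BandSpec:
    """One Raman band of the synthetic template.

    ``class_effect`` is the fractional FM-minus-non-FM amplitude difference
    (relative); the generator's global ``effect_scale`` multiplies it.
    """

    position: float  # cm^-1
    width: float = 10.0  # half-width at half-maximum, cm^-1
    amplitude: float = 1.0  # arbitrary units
    class_effect: float = 0.0  # fractional FM - non-FM difference
    shape: str = "lorentzian"  # or "gaussian"
    mode: str = ""  # vibrational mode annotation
    assignment: str = ""  # molecular assignment annotation

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("band width must be > 0")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be >= 0")
        if abs(self.class_effect) > 1:
            raise ValueError("|class_effect| must be <= 1")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError("shape must be 'lorentzian' or 'gaussian'")

    def profile(self, grid: np.ndarray) -> np.ndarray:
        """Unit-peak line shape evaluated on the grid."""
        d = grid - self.position
        if self.shape == "lorentzian":
            return self.width**2 / (d**2 + self.width**2)
        sigma = self.width / np.sqrt(2 * np.log(2))  # HWHM -> gaussian sigma
        return np.exp(-0.5 * (d / sigma) ** 2)


# Band positions with mode/assignment annotations: the major serum SERS
# bands plus the bands that dominate the discriminant regression vector.
_MAJOR_BANDS = [
    (911.0, "C-C stretching", "Lys"),
    (967.0, "C-C Stretching", "Phe"),
    (1014.0, "Benzene ring breathing", "Trp"),
    (1129.0, "C-H bending", "Trp and Phe"),
    (1189.0, "C-H", "Tyr and Phe"),
    (1222.0, "C-H stretching", "Phe, Tyr, and Amide III"),
    (1305.0, "", "Amide III"),
    (1354.0, "C-H bending", "Trp"),
    (1453.0, "CH2, CH3 bending", "Phospholipids and lipids"),
    (1586.0, "C=C", "Phe and Tyr"),
    (1633.0, "Beta sheet", "Amide I"),
]
_REGRESSION_BANDS = [
    (918.0, "C-C backbone", "Ser"),
    (978.0, "OCH3 stretching", "Polysaccharides"),
    (991.0, "C-H bending", "Phe"),
    (1013.0, "C-H bending", "Trp"),
    (1202.0, "Amide III", "Phe, Trp, and Amide III"),
    (1222.0, "C-H stretching", "Phe and Tyr"),
    (1326.0, "CH2 twisting", "D-Ser"),
    (1348.0, "C-H bending", "Trp"),
    (1370.0, "C-C stretch", "Trp"),
    (1448.0, "CH2, CH3 bending", "Phospholipids and lipids"),
    (1474.0, "C-N stretching", "Aromatic ring"),
    (1566.0, "C=C bending", "Phe"),
    (1582.0, "C=C bending", "Phe and Tyr"),
]


def default_band_table() -> list[BandSpec]:
    """Union of the major-band and regression-vector band tables.

    Discriminant bands carry ``class_effect = 1`` (the full fractional
    effect, modulated by the config's ``effect_scale``); all other bands
    are class-neutral.  Where a position appears in both tables the
    regression-vector annotation wins.
    """
    merged: dict[float, tuple[str, str]] = {}
    for pos, mode, assign in _MAJOR_BANDS + _REGRESSION_BANDS:
        merged[pos] = (mode, assign)
    bands = []
    for pos in sorted(merged):
        mode, assign = merged[pos]
        bands.append(
            BandSpec(
                position=pos,
                width=10.0,
                amplitude=1.0 if pos in _STRONG else 0.45,
                class_effect=1.0 if pos in DISCRIMINANT_BANDS else 0.0,
                mode=mode,
                assignment=assign,
            )
        )
    return bands


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate the study cohort.

    83 FM, 54 non-FM and 9 healthy-control samples, four replicate spectra
    each, on a 600-2300 cm^-1 grid with 2 cm^-1 spacing.  The same seed
    always yields the bit-identical cohort; per-sample random streams are
    derived from the master seed by sample counter, so subsetting the
    cohort does not change individual samples.
    """

    grid_lo: float = 600.0
    grid_hi: float = 2300.0
    grid_step: float = 2.0
    bands: list[BandSpec] = field(default_factory=default_band_table)
    baseline_scale: float = 2.0  # median fluorescence amplitude (a.u.)
    baseline_sigma: float = 0.3  # lognormal sigma of per-sample amplitude
    baseline_tau: float = 800.0  # exponential decay constant (cm^-1)
    noise_sd: float = 0.02  # additive white noise (a.u.)
    band_jitter_sd: float = 0.1  # per-sample per-band lognormal variability
    intensity_sigma: float = 0.2  # per-sample overall lognormal scale
    replicate_sd: float = 0.05  # per-replicate multiplicative jitter
    n_fm: int = 83
    n_nonfm: int = 54
    n_nc: int = 9
    replicates: int = 4
    effect_scale: float = 0.5  # global multiplier on all class effects
    seed: int = 0

    def __post_init__(self):
        if min(self.n_fm, self.n_nonfm, self.n_nc) < 0 or self.replicates < 1:
            raise ValueError("cohort counts must be >= 0 and replicates >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.bands:
            raise ValueError("band list must not be empty")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_hi - self.grid_lo) / self.grid_step)) + 1
        return self.grid_lo + self.grid_step * np.arange(n)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["bands"] = [vars(b) | {} for b in self.bands]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "bands" in d:
            d["bands"] = [BandSpec(**b) for b in d["bands"]]
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


def _class_factor(label: str, effect: float) -> float:
    """Multiplicative amplitude factor for a band with planted effect."""
    if label == FM:
        return 1.0 + 0.5 * effect
    if label == NONFM:
        return 1.0 - 0.5 * effect
    return 1.0  # NC: unmodulated template


def generate_cohort(cfg: SyntheticConfig) -> SpectraSet:
    """Generate a labelled replicate-level cohort (deterministic in seed)."""
    grid = cfg.grid
    profiles = np.vstack([b.profile(grid) for b in cfg.bands])
    base_amp = np.array([b.amplitude for b in cfg.bands])
    effects = np.array([b.class_effect * cfg.effect_scale for b in cfg.bands])

    plan = (
        [(FM, f"FM{i + 1:03d}") for i in range(cfg.n_fm)]
        + [(NONFM, f"NF{i + 1:03d}") for i in range(cfg.n_nonfm)]
        + [(NC, f"NC{i + 1:03d}") for i in range(cfg.n_nc)]
    )

    spectra = []
    for idx, (label, sid) in enumerate(plan):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(idx,))
        )
        factors = np.array([_class_factor(label, e) for e in effects])
        jitter = np.exp(rng.normal(0.0, cfg.band_jitter_sd, size=len(cfg.bands)))
        scale = np.exp(rng.normal(0.0, cfg.intensity_sigma))
        amps = base_amp * factors * jitter * scale
        template = amps @ profiles
        bl_amp = cfg.baseline_scale * np.exp(rng.normal(0.0, cfg.baseline_sigma))
        baseline = bl_amp * np.exp(-(grid - grid[0]) / cfg.baseline_tau)
        for rep in range(cfg.replicates):
            rep_scale = 1.0 + cfg.replicate_sd * rng.standard_normal()
            noise = cfg.noise_sd * rng.standard_normal(grid.size)
            spectra.append(
                Spectrum(
                    wavenumbers=grid,
                    intensities=template * rep_scale + baseline + noise,
                    sample_id=sid,
                    replicate=rep,
                    label=label,
                )
            )
    if not spectra:
        raise ValueError("empty cohort: all counts are zero")
    return SpectraSet.from_spectra(spectra)


def inject_photodegradation(s: Spectrum, severity: float) -> Spectrum:
    """Add the broad 1535 cm^-1 amorphous-carbon artifact band.

    ``severity`` is the added peak amplitude in the spectrum's intensity
    units; 0 returns the spectrum unchanged.
    """
    if severity < 0:
        raise ValueError("severity must be >= 0")
    if not (s.wavenumbers[0] <= PHOTODEGRADATION_BAND <= s.wavenumbers[-1]):
        raise ValueError("grid does not cover the 1535 cm^-1 band")
    band = BandSpec(position=PHOTODEGRADATION_BAND, width=20.0, amplitude=1.0)
    return s.with_intensities(s.intensities + severity * band.profile(s.wavenumbers))


def qc_flag_burned(
    s: Spectrum, threshold: float = 2.0, window: float = 10.0
) -> bool:
    """Flag a baseline-corrected spectrum showing the photodegradation band.

    The local prominence of the 1535 +/- `window` cm^-1 region above the
    chord between the window's flanks (+/- 35 cm^-1) is compared against
    ``threshold`` times the median absolute intensity of the 750-1750
    fingerprint region.
    """
    wn, y = s.wavenumbers, s.intensities
    lo, hi = PHOTODEGRADATION_BAND - window, PHOTODEGRADATION_BAND + window
    flank = 35.0
    if wn[0] > PHOTODEGRADATION_BAND - flank or wn[-1] < PHOTODEGRADATION_BAND + flank:
        raise ValueError("grid does not cover the 1535 cm^-1 QC window")
    left = np.interp(PHOTODEGRADATION_BAND - flank, wn, y)
    right = np.interp(PHOTODEGRADATION_BAND + flank, wn, y)
    inwin = (wn >= lo) & (wn <= hi)
    chord = np.interp(
        wn[inwin],
        [PHOTODEGRADATION_BAND - flank, PHOTODEGRADATION_BAND + flank],
        [left, right],
    )
    prominence = float(np.max(y[inwin] - chord))
    region = (wn >= 750.0) & (wn <= 1750.0)
    ref = float(np.median(np.abs(y[region]))) if region.any() else float(
        np.median(np.abs(y))
    )
    return prominence > threshold * max(ref, 1e-12)
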