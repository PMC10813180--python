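"""End-to-end study replica: simulate (or load) -> QC -> preprocess ->
split -> train -> validate -> report.

`run_study` wires the whole diagnostic pipeline together the way the
original analysis ran it: replicate-level spectra are screened for the
1535 cm^-1 photodegradation artifact, baseline-corrected, averaged,
normalized, restricted to the 750-1750 cm^-1 fingerprint region and
second-derivatized; the FM/non-FM samples are split into a calibration
set (80%, or the exact 68+41 / 15+13 study split when cohort sizes match)
and an external validation set; a 1-OSC / 7-LV PLS-DA model is calibrated,
screened for influential samples (leverage + studentized residual, at most
3% removed), assessed by leave-one-out cross-validation, and deployed on
the untouched validation set with ROC/AUC; healthy-control samples only
enter the FM-minus-NC difference spectrum.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import __version__ as _pkg_version
from .spectra import FM, NC, NONFM, SpectraSet
from . import io as sio
from .preprocess import (
    PreprocessConfig,
    class_mean,
    difference_spectrum,
    preprocess_set,
    rubberband_baseline,
)
from .model import OSCPLSDA
from .synthetic import SyntheticConfig, generate_cohort, qc_flag_burned
from .validation import remove_outliers

__all__ = ["RunConfig", "split_dataset", "run_study", "save_report"]

# The study's calibration/validation head counts (FM cal, FM val, non-FM
# cal, non-FM val); used verbatim when the cohort sizes match 83/54.
TABLE1_SPLIT = {"fm_cal": 68, "fm_val": 15, "nonfm_cal": 41, "nonfm_val": 13}


@dataclass
class RunConfig:
    """Everything one study run depends on (hashable for provenance)."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    input_csv: str | None = None  # read spectra instead of simulating
    input_metadata: str | None = None
    n_osc: int = 1
    n_lv: int = 7
    split_mode: str = "auto"  # 'auto' | 'table1' | 'fraction'
    calibration_fraction: float = 0.8
    split_seed: int = 0
    outlier_screening: bool = True
    qc_threshold: float | None = 2.0  # None disables the burn check
    report_top_k: int = 10

    def __post_init__(self):
        if not 0.0 < self.calibration_fraction < 1.0:
            raise ValueError("calibration_fraction must be in (0, 1)")
        if self.split_mode not in ("auto", "table1", "fraction"):
            raise ValueError("split_mode must be auto/table1/fraction")

    def to_dict(self) -> dict:
        return {
            "synthetic": self.synthetic.to_dict(),
            "preprocess": self.preprocess.to_dict(),
            "input_csv": self.input_csv,
            "input_metadata": self.input_metadata,
            "n_osc": self.n_osc,
            "n_lv": self.n_lv,
            "split_mode": self.split_mode,
            "calibration_fraction": self.calibration_fraction,
            "split_seed": self.split_seed,
            "outlier_screening": self.outlier_screening,
            "qc_threshold": self.qc_threshold,
            "report_top_k": self.report_top_k,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d:
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        if "preprocess" in d:
            d["preprocess"] = PreprocessConfig.from_dict(d["preprocess"])
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def split_dataset(
    sset: SpectraSet, cfg: RunConfig
) -> tuple[SpectraSet, SpectraSet]:
    """Stratified calibration/validation split of an FM/NONFM set.

    In 'table1' mode (or 'auto' when the class sizes are exactly 83 FM /
    54 non-FM) the study's exact head counts are used; otherwise each class
    is split by ``calibration_fraction``.  Deterministic in ``split_seed``.
    """
    labels = sset.labels
    n_fm = int(np.sum(labels == FM))
    n_nonfm = int(np.sum(labels == NONFM))
    if n_fm == 0 or n_nonfm == 0:
        raise ValueError("both FM and NONFM must be present to split")

    use_table1 = cfg.split_mode == "table1" or (
        cfg.split_mode == "auto"
        and n_fm == TABLE1_SPLIT["fm_cal"] + TABLE1_SPLIT["fm_val"]
        and n_nonfm == TABLE1_SPLIT["nonfm_cal"] + TABLE1_SPLIT["nonfm_val"]
    )
    if cfg.split_mode == "table1" and (
        n_fm < TABLE1_SPLIT["fm_cal"] + TABLE1_SPLIT["fm_val"]
        or n_nonfm < TABLE1_SPLIT["nonfm_cal"] + TABLE1_SPLIT["nonfm_val"]
    ):
        raise ValueError("table1 split requests more samples per class than present")

    rng = np.random.default_rng(cfg.split_seed)
    cal_idx, val_idx = [], []
    for label, n_cal_fixed in ((FM, TABLE1_SPLIT["fm_cal"]), (NONFM, TABLE1_SPLIT["nonfm_cal"])):
        idx = np.nonzero(labels == label)[0]
        perm = rng.permutation(idx)
        if use_table1:
            n_cal = n_cal_fixed
        else:
            n_cal = int(round(cfg.calibration_fraction * idx.size))
            n_cal = min(max(n_cal, 1), idx.size - 1)
        cal_idx.extend(perm[:n_cal])
        val_idx.extend(perm[n_cal:])
    cal = sset.subset(np.sort(cal_idx))
    val = sset.subset(np.sort(val_idx))
    assert not (set(map(str, cal.ids)) & set(map(str, val.ids)))
    return cal, val


class StageError(RuntimeError):
    """Pipeline failure tagged with the stage it happened in."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[{stage}] {err}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def run(*a, **k):
            try:
                return fn(*a, **k)
            except StageError:
                raise
            except Exception as e:  # re-tag with the failing stage
                raise StageError(name, e) from e

        return run

    return deco


@_stage("load")
def _load_cohort(cfg: RunConfig) -> SpectraSet:
    if cfg.input_csv is not None:
        return sio.read_spectra(cfg.input_csv, "csv", metadata=cfg.input_metadata)
    return generate_cohort(cfg.synthetic)


@_stage("qc")
def _qc_screen(cohort: SpectraSet, cfg: RunConfig) -> tuple[SpectraSet, list[str]]:
    if cfg.qc_threshold is None:
        return cohort, []
    keep, burned = [], []
    for i in range(len(cohort)):
        s = cohort.spectrum(i)
        _, corrected = rubberband_baseline(s)
        if qc_flag_burned(corrected, threshold=cfg.qc_threshold):
            burned.append(f"{s.sample_id}_r{s.replicate}")
        else:
            keep.append(i)
    if not keep:
        raise ValueError("QC flagged every replicate as photodegraded")
    return cohort.subset(np.asarray(keep)), burned


def run_study(cfg: RunConfig | None = None) -> dict:
    """Execute the full pipeline; returns a JSON-serializable report bundle."""
    cfg = cfg or RunConfig()
    cohort = _load_cohort(cfg)
    cohort, burned = _qc_screen(cohort, cfg)

    try:
        processed = preprocess_set(cohort, cfg.preprocess)
    except Exception as e:
        raise StageError("preprocess", e) from e

    report: dict = {
        "provenance": {
            "package_version": _pkg_version,
            "config": cfg.to_dict(),
            "config_hash": cfg.config_hash(),
        },
        "qc": {"n_replicates_in": len(cohort) + len(burned),
               "burned_replicates": burned},
    }

    # FM-minus-NC difference spectrum on normalized averaged full-range
    # spectra (no derivative), the visual contrast of the two cohorts.
    if np.any(cohort.labels == NC) and np.any(cohort.labels == FM):
        flat_cfg = PreprocessConfig(
            region_lo=cohort.grid[0],
            region_hi=cohort.grid[-1],
            normalization=cfg.preprocess.normalization,
            do_baseline=cfg.preprocess.do_baseline,
            do_derivative=False,
        )
        flat = preprocess_set(cohort, flat_cfg)
        diff = difference_spectrum(class_mean(flat, FM), class_mean(flat, NC))
        report["difference_spectrum_fm_minus_nc"] = {
            "wavenumbers": diff.wavenumbers.tolist(),
            "values": diff.intensities.tolist(),
        }

    modelled = processed.select_labels(FM, NONFM)
    try:
        cal, val = split_dataset(modelled, cfg)
    except Exception as e:
        raise StageError("split", e) from e

    try:
        res = OSCPLSDA.from_spectra(cal, n_osc=cfg.n_osc, n_lv=cfg.n_lv).fit()
        removed: list[str] = []
        if cfg.outlier_screening:
            flags = res.outliers()
            cal_screened, removed = remove_outliers(cal, flags)
            if removed:
                cal = cal_screened
                res = OSCPLSDA.from_spectra(
                    cal, n_osc=cfg.n_osc, n_lv=cfg.n_lv
                ).fit()
        report["outliers"] = {"removed_ids": removed}
    except Exception as e:
        raise StageError("calibrate", e) from e

    try:
        cv = res.loocv()
    except Exception as e:
        raise StageError("loocv", e) from e
    try:
        ev = res.validate(val)
    except Exception as e:
        raise StageError("external-validation", e) from e

    band_df = res.band_report(top_k=cfg.report_top_k)
    report.update(
        {
            "calibration": {
                "n": len(cal),
                "summary": res.summary(),
                "explained_x_variance": res.explained_x_variance.tolist(),
                "explained_y_variance": res.explained_y_variance.tolist(),
                "loocv": cv.to_dict(),
            },
            "validation": ev.to_dict(),
            "roc": {
                "fpr": ev.roc_fpr.tolist(),
                "tpr": ev.roc_tpr.tolist(),
                "auc": ev.auc,
                "flipped": ev.roc_flipped,
            },
            "score_plot": {
                "scores_lv123": res.scores[:, : min(3, cfg.n_lv)].tolist(),
                "labels": [str(l) for l in cal.labels],
                "explained_x_variance_pct": (
                    100 * res.explained_x_variance[: min(3, cfg.n_lv)]
                ).tolist(),
            },
            "regression_vector_report": band_df.to_dict(orient="records"),
            "regression_vector": {
                "wavenumbers": cal.grid.tolist(),
                "coefficients": res.regression_vector.tolist(),
            },
        }
    )
    report["_results"] = res  # live handle for callers; stripped on save
    return report


def save_report(report: dict, outdir) -> None:
    """Write report.json plus CSV side files (ROC, bands, difference)."""
    import pandas as pd

    os.makedirs(outdir, exist_ok=True)
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(clean, fh, sort_keys=True, indent=1)
    if "roc" in clean:
        pd.DataFrame(
            {"fpr": clean["roc"]["fpr"], "tpr": clean["roc"]["tpr"]}
        ).to_csv(os.path.join(outdir, "roc_points.csv"), index=False)
    if "regression_vector_report" in clean:
        pd.DataFrame(clean["regression_vector_report"]).to_csv(
            os.path.join(outdir, "regression_vector_report.csv"), index=False
        )
    if "difference_spectrum_fm_minus_nc" in clean:
        d = clean["difference_spectrum_fm_minus_nc"]
        pd.DataFrame(
            {"wavenumber": d["wavenumbers"], "fm_minus_nc": d["values"]}
        ).to_csv(os.path.join(outdir, "difference_spectrum.csv"), index=False)
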