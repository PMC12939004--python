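"""End-to-end synthetic study: generate, select, assemble, fit, evaluate.

One call reproduces the whole modeling chain on a synthetic cohort:

  1. simulate a multi-group freeze-thaw cohort of phantom scans;
  2. pick one complete slice per sample;
  3. flatten into the pixel design matrix paired with pressing loss;
  4. split once into calibration/validation (seeded 8:2 holdout);
  5. fit PCR at the >= 95% cumulative-variance component count;
  6. choose the PLS order by Monte-Carlo cross-validation on the
     calibration part and fit the final PLS model;
  7. evaluate both models on the holdout and write metrics, the
     RMSE-vs-order curve, the residual table and a run manifest.

Identical configurations produce byte-identical metrics and manifest
files: every random draw flows from seeds recorded in the manifest and
no timestamps enter the outputs (wall times go to the log only).
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .phantom import PhantomSpec, simulate_cohort
from .imaging import select_best_slice, DEFAULT_THRESHOLD_FRACTION
from .dataset import build_design, center, random_split
from .chemometrics import pca_fit, select_k, pcr_fit, pls_nipals_fit, predict, \
    mccv_select_lv
from .evaluation import compute_metrics, Metrics

__all__ = ["RunConfig", "StudyResult", "run_study"]

log = logging.getLogger("meatwhc")


@dataclass(frozen=True)
class RunConfig:
    """Every knob of one synthetic study run.

    The defaults define the package's reference study: a 60-sample
    cohort (15 per freeze-thaw level) of 64 x 64 phantoms, an 8:2
    holdout, a 95% cumulative-variance PCR cut, and 1000-split
    Monte-Carlo cross-validation with up to 15 latent variables.
    """

    # phantom
    image_size: int = 64
    n_per_group: int = 15
    ft_levels: tuple[float, ...] = (0.0, 3.0, 5.0, 10.0)
    base_signal: float = 1000.0
    signal_decay: float = 0.05
    noise_sd: float = 30.0
    texture_amplitude: float = 0.05
    response_intercept: float = 15.75
    response_slope: float = 0.02648
    response_noise_sd: float = 1.0
    n_slices: int = 4
    clip_fraction: float = 0.25
    # imaging
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
    # split / models
    ratio: float = 0.8
    pca_threshold: float = 0.95
    mccv_splits: int = 1000
    a_max: int = 15
    # randomness & output
    seed: int = 0
    out_dir: str = "study_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "ft_levels" in raw:
            raw["ft_levels"] = tuple(float(v) for v in raw["ft_levels"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        d = asdict(self)
        d["ft_levels"] = list(d["ft_levels"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
        return Path(path)

    def phantom_spec(self) -> PhantomSpec:
        return PhantomSpec(
            image_size=self.image_size, base_signal=self.base_signal,
            signal_decay=self.signal_decay, noise_sd=self.noise_sd,
            texture_amplitude=self.texture_amplitude,
            response_intercept=self.response_intercept,
            response_slope=self.response_slope,
            response_noise_sd=self.response_noise_sd,
            n_slices=self.n_slices, clip_fraction=self.clip_fraction,
        )


@dataclass(frozen=True)
class StudyResult:
    """Everything run_study computes, plus the output directory."""

    pcr_metrics: Metrics
    pls_metrics: Metrics
    n_components: int
    cumulative_contribution: float
    chosen_lv: int
    rmse_curve: np.ndarray
    manifest: dict = field(repr=False)
    out_dir: Path | None = None


def _stage(name: str, t0: float, payload: str) -> None:
    log.info("stage=%s wall=%.2fs %s", name, time.perf_counter() - t0, payload)


def _hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_study(config: RunConfig, write_outputs: bool = True) -> StudyResult:
    """Run the full synthetic study described by ``config``."""
    out = Path(config.out_dir)

    t0 = time.perf_counter()
    samples, responses = simulate_cohort(
        config.n_per_group, list(config.ft_levels),
        spec_defaults=config.phantom_spec(), seed=config.seed)
    _stage("phantom", t0, f"n={len(samples)} seed={config.seed}")

    t0 = time.perf_counter()
    chosen = []
    flagged = 0
    for s in samples:
        sel = select_best_slice(s.slices, config.threshold_fraction)
        flagged += int(sel.flagged)
        chosen.append(next(g for g in s.slices if g.slice_index == sel.chosen_index))
    _stage("select", t0, f"flagged={flagged}")

    t0 = time.perf_counter()
    d = build_design(chosen, responses, sample_ids=[s.sample_id for s in samples])
    split = random_split(d.n, config.ratio, config.seed)
    from .dataset import DesignMatrix
    cal = DesignMatrix(X=d.X[split.calibration_indices],
                       y=d.y[split.calibration_indices],
                       sample_ids=[d.sample_ids[i] for i in split.calibration_indices])
    X_val = d.X[split.validation_indices]
    y_val = d.y[split.validation_indices]
    _stage("design", t0, f"n={d.n} p={d.p} xhash={_hash(d.X)}")

    t0 = time.perf_counter()
    cal_c = center(cal)
    pca = pca_fit(cal_c.X, column_means=cal_c.centering)
    k = select_k(pca.cumulative_ratio, config.pca_threshold)
    pcr = pcr_fit(cal_c, k)
    pcr_metrics = compute_metrics(cal.y, predict(pcr, cal.X),
                                  y_val, predict(pcr, X_val))
    _stage("pcr", t0, f"k={k} cum={pca.cumulative_ratio[k - 1]:.4f}")

    t0 = time.perf_counter()
    mccv = mccv_select_lv(cal, config.a_max, n_splits=config.mccv_splits,
                          ratio=config.ratio, seed=config.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls = pls_nipals_fit(cal_c, mccv.chosen_A)
    pls_metrics = compute_metrics(cal.y, predict(pls, cal.X),
                                  y_val, predict(pls, X_val))
    _stage("pls", t0, f"A={mccv.chosen_A} splits={config.mccv_splits}")

    cfg = asdict(config)
    cfg["ft_levels"] = list(cfg["ft_levels"])
    manifest = {
        "version": __version__,
        "config": cfg,
        "n_samples": d.n,
        "n_pixels": d.p,
        "flagged_samples": flagged,
        "split": {
            "calibration": split.calibration_indices.tolist(),
            "validation": split.validation_indices.tolist(),
            "ratio": config.ratio, "seed": config.seed,
        },
        "pcr": {"k": k,
                "cumulative_contribution": float(pca.cumulative_ratio[k - 1])},
        "pls": {"chosen_A": mccv.chosen_A, "mccv_splits": mccv.n_splits,
                "mccv_seed": mccv.seed},
        "design_hash": _hash(d.X),
    }
    result = StudyResult(
        pcr_metrics=pcr_metrics, pls_metrics=pls_metrics,
        n_components=k,
        cumulative_contribution=float(pca.cumulative_ratio[k - 1]),
        chosen_lv=mccv.chosen_A, rmse_curve=mccv.rmse_curve,
        manifest=manifest, out_dir=out if write_outputs else None)

    if write_outputs:
        _write_outputs(result, d, split, cal, y_val, out)
    return result


def _write_outputs(res: StudyResult, d, split, cal, y_val, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(
        json.dumps(res.manifest, indent=2, sort_keys=True) + "\n")
    metrics = {
        "pcr": res.pcr_metrics.summary(),
        "pls": res.pls_metrics.summary(),
        "n_components": res.n_components,
        "cumulative_contribution": res.cumulative_contribution,
        "chosen_lv": res.chosen_lv,
    }
    (out / "metrics.json").write_text(
        json.dumps(metrics, indent=2, sort_keys=True) + "\n")
    with open(out / "rmse_curve.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["latent_variables", "mean_rmse"])
        for i, v in enumerate(res.rmse_curve, start=1):
            w.writerow([i, f"{v:.6f}"])
    with open(out / "residuals.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "set", "model", "residual"])
        for model_name, m in (("pcr", res.pcr_metrics), ("pls", res.pls_metrics)):
            for i, r in zip(split.calibration_indices, m.residuals_cal):
                w.writerow([d.sample_ids[i], "calibration", model_name, f"{r:.6f}"])
            for i, r in zip(split.validation_indices, m.residuals_val):
                w.writerow([d.sample_ids[i], "validation", model_name, f"{r:.6f}"])
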