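"""End-to-end orchestration: simulate -> segment -> extract -> analyze.

A :class:`PipelineConfig` collects every tunable constant of the run (cohort
specification, segmentation thresholds, statistical thresholds, bootstrap
size and the root seed).  :func:`run_end_to_end` executes the full pipeline
deterministically and returns a serializable report; with an output
directory it also writes the feature table, cohort table, report JSON and a
manifest containing the configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, SitStandGoError, SubphaseNotFoundError
from .features import (
    ALL_FEATURES, CST30_FEATURES, MANUAL_FEATURES, NJS_FEATURES, TUG_FEATURES,
    extract_30cst_features, extract_tug_features,
)
from .segmentation import (
    DEFAULT_CONFIG, SegmentationConfig, detect_transitions_30cst, segment_tug,
)
from .stats import (
    RCS_KNOT_QUANTILES, SCREEN_ALPHA, STEPWISE_ALPHA, VIF_THRESHOLD,
    bootstrap_optimism, dichotomize_llfdi, group_to_binary,
    preprocess_features, run_sensitivity,
)
from .synthetic import DEFAULT_EFFECT_SIZES, generate_cohort
from .types import CohortSpec, SubphaseAnnotation, TriaxialRecording

log = logging.getLogger("sitstandgo")

_BOOT_TAG = 7


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable constant of one end-to-end run."""

    n_subjects: int = 160
    effect_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    llfdi_noise_sd: float = 4.0
    sampling_rate: float = 100.0
    seed: int = 0
    segmentation: SegmentationConfig = DEFAULT_CONFIG
    screen_alpha: float = SCREEN_ALPHA
    stepwise_alpha: float = STEPWISE_ALPHA
    vif_threshold: float = VIF_THRESHOLD
    knot_quantiles: tuple = RCS_KNOT_QUANTILES
    bootstrap_B: int = 1000
    run_bootstrap: bool = True
    check_linearity: bool = True

    def __post_init__(self):
        if not (0 < self.screen_alpha < 1 and 0 < self.stepwise_alpha < 1):
            raise ConfigurationError("alphas must lie in (0, 1)")
        if self.vif_threshold <= 1:
            raise ConfigurationError("VIF threshold must exceed 1")
        if self.bootstrap_B < 0:
            raise ConfigurationError("bootstrap_B must be >= 0")
        q = tuple(self.knot_quantiles)
        if len(q) != 3 or not (0 < q[0] < q[1] < q[2] < 1):
            raise ConfigurationError("knot_quantiles must be 3 increasing "
                                     "values in (0, 1)")

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(n_subjects=self.n_subjects,
                          effect_sizes=dict(self.effect_sizes),
                          llfdi_noise_sd=self.llfdi_noise_sd,
                          seed=self.seed,
                          sampling_rate=self.sampling_rate)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["knot_quantiles"] = list(self.knot_quantiles)
        d["segmentation"]["step_band_hz"] = list(self.segmentation.step_band_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        seg = d.pop("segmentation", None)
        if seg is not None:
            seg = dict(seg)
            if "step_band_hz" in seg:
                seg["step_band_hz"] = tuple(seg["step_band_hz"])
            d["segmentation"] = SegmentationConfig(**seg)
        if "knot_quantiles" in d:
            d["knot_quantiles"] = tuple(d["knot_quantiles"])
        return cls(**d)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def build_feature_table(pairs: list[tuple[TriaxialRecording, TriaxialRecording]],
                        cohort: pd.DataFrame,
                        config: SegmentationConfig = DEFAULT_CONFIG,
                        ) -> tuple[pd.DataFrame, dict]:
    """Segment every recording and extract the canonical feature rows.

    Returns the feature table (one row per subject, indexed by subject_id,
    canonical instrumented columns plus the manual standard measures) and a
    per-stage count log.
    """
    rows = []
    counts = {"subjects": len(pairs), "cst_transitions": 0,
              "tug_segmented": 0, "tug_failed": 0}
    manual = cohort.set_index("subject_id")[MANUAL_FEATURES]
    for (rec_cst, rec_tug), sid in zip(pairs, cohort["subject_id"]):
        row: dict[str, float] = {"subject_id": sid}
        ann_cst = detect_transitions_30cst(rec_cst, config)
        counts["cst_transitions"] += len(ann_cst.intervals)
        row.update(extract_30cst_features(rec_cst, ann_cst))
        try:
            ann_tug = segment_tug(rec_tug, config)
            counts["tug_segmented"] += 1
        except SubphaseNotFoundError as exc:
            log.warning("subject %s: TUG segmentation failed (%s)", sid, exc)
            counts["tug_failed"] += 1
            ann_tug = SubphaseAnnotation(test_type="TUG")
        row.update(extract_tug_features(rec_tug, ann_tug, config))
        row.update(manual.loc[sid].to_dict())
        rows.append(row)
    table = pd.DataFrame(rows).set_index("subject_id")
    return table[ALL_FEATURES + MANUAL_FEATURES], counts


def _instrumented_candidates(features: pd.DataFrame, test: str
                             ) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """(candidate table, manual standard measure, instrumented standard measure).

    The sensor-derived repetition count (30CST) / total duration (TUG) is
    excluded from the instrumented candidate set and returned separately for
    the combined model.
    """
    if test == "CST30":
        cand = [c for c in CST30_FEATURES if c != "cst_repetitions"]
        return (features[cand], features["cst30_repetitions_manual"],
                features["cst_repetitions"])
    cand = [c for c in TUG_FEATURES if c != "tug_total_duration"]
    return (features[cand], features["tug_duration_manual"],
            features["tug_total_duration"])


def _fit_to_dict(fit) -> dict:
    return {
        "features": fit.features,
        "coefficients": [float(c) for c in fit.coefficients],
        "standard_errors": [float(s) for s in fit.standard_errors],
        "pvalues": [float(p) for p in fit.pvalues],
        "odds_ratios": {k: list(v) for k, v in fit.odds_ratios.items()},
        "converged": fit.converged,
        "flags": fit.flags,
    }


def analyze_test(features: pd.DataFrame, y: np.ndarray, test: str,
                 config: PipelineConfig,
                 rng: np.random.Generator | None = None) -> dict:
    """Run the discrimination analysis for one test (CST30 or TUG)."""
    cand, manual_std, instr_std = _instrumented_candidates(features, test)
    complete = cand.notna().all(axis=1) & manual_std.notna() & instr_std.notna()
    cand = cand[complete]
    y_c = y[complete.to_numpy()]
    njs_cols = [c for c in cand.columns if c in NJS_FEATURES]
    z = preprocess_features(cand, njs_cols)
    sens = run_sensitivity(z, manual_std[complete], instr_std[complete], y_c,
                           config.screen_alpha, config.stepwise_alpha,
                           config.vif_threshold, config.check_linearity)
    report = {
        "test": test,
        "n_complete": int(complete.sum()),
        "n_dropped": int((~complete).sum()),
        "vif_removed": [[name, (v if np.isfinite(v) else "inf")]
                        for name, v in sens.instrumented.vif.removed],
        "vif_surviving": sens.instrumented.vif.surviving,
        "linearity_p": {k: (float(v) if np.isfinite(v) else None)
                        for k, v in sens.instrumented.linearity_p.items()},
        "screened": sens.instrumented.screened,
        "stepwise_trail": [[name, (float(p) if np.isfinite(p) else None)]
                           for name, p in sens.instrumented.trail],
        "models": {
            "standard": _fit_to_dict(sens.standard_fit),
            "instrumented": _fit_to_dict(sens.instrumented.fit),
            "combined": _fit_to_dict(sens.combined_fit),
        },
        "auc": {
            "standard": {"auc": sens.auc_standard[0],
                         "ci": list(sens.auc_standard[1])},
            "instrumented": {"auc": sens.auc_instrumented[0],
                             "ci": list(sens.auc_instrumented[1])},
            "combined": {"auc": sens.auc_combined[0],
                         "ci": list(sens.auc_combined[1])},
        },
        "delong": {
            name: {"auc_a": c.auc_a, "auc_b": c.auc_b,
                   "z": c.delong_z, "p": c.delong_p, "flags": c.flags}
            for name, c in sens.comparisons.items()
        },
    }
    if config.run_bootstrap and config.bootstrap_B > 0 and rng is not None:
        vif_cols = sens.instrumented.vif.surviving
        report["internal_validation"] = {
            "instrumented": bootstrap_optimism(
                z[vif_cols], y_c, config.bootstrap_B, rng,
                config.screen_alpha, config.stepwise_alpha),
        }
    return report


def run_end_to_end(config: PipelineConfig,
                   outdir: str | Path | None = None,
                   save_recordings: bool = False) -> dict:
    """Execute the whole pipeline and return the model report.

    The report is a plain-JSON-serializable dict; identical configurations
    produce byte-identical serialized reports.
    """
    from . import io as _io

    log.info("simulating cohort: n=%d seed=%d", config.n_subjects, config.seed)
    pairs, cohort = generate_cohort(config.cohort_spec())
    features, counts = build_feature_table(pairs, cohort, config.segmentation)
    log.info("segmentation counts: %s", counts)
    cohort_g = dichotomize_llfdi(cohort)
    y = group_to_binary(cohort_g["group"])

    rng_boot = np.random.default_rng(
        np.random.SeedSequence([config.seed, _BOOT_TAG]))
    report = {
        "package_version": __version__,
        "config_hash": config.content_hash(),
        "config": config.to_dict(),
        "counts": counts,
        "groups": {"HFS": int((y == 0).sum()), "VHFS": int((y == 1).sum()),
                   "llfdi_median": float(cohort["llfdi"].median())},
        "tests": {t: analyze_test(features, y, t, config, rng_boot)
                  for t in ("CST30", "TUG")},
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _io.write_features(features.reset_index(), outdir / "features.csv")
        _io.write_cohort(cohort_g, outdir / "cohort.csv")
        _io.write_report(report, outdir / "report.json")
        manifest = {"config_hash": config.content_hash(),
                    "seed": config.seed,
                    "package_version": __version__,
                    "counts": counts}
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        if save_recordings:
            rec_dir = outdir / "recordings"
            rec_dir.mkdir(exist_ok=True)
            for rec_cst, rec_tug in pairs:
                for rec in (rec_cst, rec_tug):
                    stem = f"{rec.subject_id}_{rec.test_type.lower()}"
                    _io.write_recording(rec, rec_dir / f"{stem}.csv")
    return report
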