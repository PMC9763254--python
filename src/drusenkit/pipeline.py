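"""One-command study orchestration: simulate -> segment -> quantify -> compare.

``run_study`` generates a synthetic cohort, measures every eye on every
configured modality with the modality's segmentation algorithm, and runs
the full comparison battery: agreement statistics per comparison and
subgroup, trend tests across AMD stages, ROC threshold selection,
high-risk-cut-off kappa, and the Deming conversion workflow.  Everything
is a pure function of the config (seed included): re-running reproduces
all numeric outputs bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    PairedMeasures,
    bland_altman,
    icc_two_way,
    jonckheere_terpstra,
    kappa_high_risk,
    paired_rmse,
    wilcoxon_signed_rank,
)
from .conversion import (
    HIGH_RISK_CUTOFF_CIRRUS_MM3,
    deming_fit,
    evaluate_conversion,
    select_optimal_subset,
    train_test_split_pairs,
)
from .io import cohort_manifest, measurements_frame
from .quantify import MeasureConfig, measure_eye
from .roc import optimal_threshold, roc_points, sens_spec_by_stage
from .synthetic import STAGES, SimCohortConfig, build_cohort

logger = logging.getLogger("drusenkit")

SUBGROUPS = ("all", "no_amd", "eamd", "iamd", "iamd_no_rpd", "iamd_rpd")

#: case definitions for the ROC analysis: label -> stages counted as cases
CASE_DEFINITIONS = {
    "e_and_iamd": ("eamd", "iamd"),
    "eamd_only": ("eamd",),
    "iamd_only": ("iamd",),
}


@dataclass
class StudyConfig:
    sim: SimCohortConfig = field(default_factory=SimCohortConfig)
    #: device name -> segmentation algorithm ("bm_offset" | "rpe_fit")
    algorithms: dict[str, str] = field(
        default_factory=lambda: {
            "spectralis_dense": "bm_offset",
            "spectralis_sparse": "bm_offset",
            "cirrus": "rpe_fit",
        }
    )
    #: comparison name -> (method_a device, method_b device); a is the
    #: denser/reference method, so differences are oriented a - b
    comparisons: dict[str, tuple[str, str]] = field(
        default_factory=lambda: {
            "inter_device": ("spectralis_dense", "cirrus"),
            "inter_scan": ("spectralis_dense", "spectralis_sparse"),
        }
    )
    high_risk_cutoffs: dict[str, float] = field(
        default_factory=lambda: {
            "cirrus": HIGH_RISK_CUTOFF_CIRRUS_MM3,
            "spectralis_dense": 0.083,
            "spectralis_sparse": 0.083,
        }
    )
    min_height_px: int = 5
    seed: int = 0
    train_frac: float = 0.8
    subset_mean_cap: float = 0.2

    def __post_init__(self) -> None:
        device_names = {d.name for d in self.sim.devices}
        for name, (a, b) in self.comparisons.items():
            if a not in device_names or b not in device_names:
                raise ValueError(
                    f"comparison {name!r} references unconfigured methods {a!r}/{b!r}"
                )


@dataclass
class StudyBundle:
    manifest: pd.DataFrame
    measurements: pd.DataFrame
    agreement: pd.DataFrame
    trend: pd.DataFrame
    roc_table: pd.DataFrame
    thresholds: dict
    conversion: dict
    run_log: dict


def _subgroup_mask(df: pd.DataFrame, subgroup: str) -> pd.Series:
    if subgroup == "all":
        return pd.Series(True, index=df.index)
    if subgroup == "iamd_no_rpd":
        return (df["stage"] == "iamd") & ~df["rpd"]
    if subgroup == "iamd_rpd":
        return (df["stage"] == "iamd") & df["rpd"]
    return df["stage"] == subgroup


def _paired(df: pd.DataFrame, dev_a: str, dev_b: str) -> PairedMeasures:
    wide = df.pivot_table(
        index=["eye_id", "subject_id", "stage", "rpd"],
        columns="device", values="volume_5mm_mm3",
    ).reset_index()
    return PairedMeasures(
        value_a=wide[dev_a].to_numpy(),
        value_b=wide[dev_b].to_numpy(),
        method_a=dev_a,
        method_b=dev_b,
        eye_id=list(wide["eye_id"]),
        subject_id=list(wide["subject_id"]),
        stage=list(wide["stage"]),
        rpd=wide["rpd"].to_numpy(),
    )


def compare_methods(
    df: pd.DataFrame,
    dev_a: str,
    dev_b: str,
    cutoff_a: float,
    cutoff_b: float,
    comparison: str = "",
) -> pd.DataFrame:
    """Agreement statistics for one method pair, per subgroup (tidy rows)."""
    rows = []
    for subgroup in SUBGROUPS:
        sub = df[_subgroup_mask(df, subgroup)]
        if sub["eye_id"].nunique() < 3:
            continue
        p = _paired(sub, dev_a, dev_b)
        row: dict = {
            "comparison": comparison, "subgroup": subgroup, "n": len(p),
        }
        for kind in ("consistency", "agreement"):
            icc = icc_two_way(p, kind)
            row[f"icc_{kind}"] = icc.estimate
            row[f"icc_{kind}_ci_low"] = icc.ci_low
            row[f"icc_{kind}_ci_high"] = icc.ci_high
            row[f"icc_{kind}_status"] = icc.status
        ba = bland_altman(p)
        row["mean_diff_mm3"] = ba.mean_diff
        row["standardized_mean_diff"] = ba.standardized_mean_diff
        row["loa_low"] = ba.loa_low
        row["loa_high"] = ba.loa_high
        row["rmse_mm3"] = paired_rmse(p)
        row["wilcoxon_p"] = wilcoxon_signed_rank(p).p_value
        kap = kappa_high_risk(p, cutoff_a, cutoff_b)
        row["kappa"] = kap.kappa
        row["percent_agreement"] = kap.percent_agreement
        rows.append(row)
    return pd.DataFrame(rows)


def run_study(config: StudyConfig) -> StudyBundle:
    """Run the full synthetic inter-device / inter-scan study."""
    sim = dataclasses.replace(config.sim, rng_seed=config.seed)
    cohort = build_cohort(sim)
    logger.info("simulated %d eyes on %d devices", len(cohort), len(sim.devices))

    finest = min(d.bscan_spacing_um for d in sim.devices)
    records, excluded = [], []
    for eye, scans in cohort:
        eye_records = []
        try:
            for dev_name, surfaces in scans.items():
                algo = config.algorithms.get(dev_name, "bm_offset")
                mc = MeasureConfig(
                    min_height_px=config.min_height_px,
                    target_row_spacing_um=finest,
                )
                eye_records.append((eye, dev_name, measure_eye(surfaces, algo, mc)))
        except Exception as exc:  # an eye failing any modality is dropped whole
            excluded.append({"eye_id": eye.eye_id, "reason": repr(exc)})
            logger.warning("excluding %s: %r", eye.eye_id, exc)
            continue
        records.extend(eye_records)

    meas = measurements_frame([(eye, m) for eye, _, m in records])
    meas["device"] = [dev for _, dev, _ in records]

    agreement = pd.concat(
        [
            compare_methods(
                meas, a, b,
                config.high_risk_cutoffs.get(a, HIGH_RISK_CUTOFF_CIRRUS_MM3),
                config.high_risk_cutoffs.get(b, HIGH_RISK_CUTOFF_CIRRUS_MM3),
                comparison=name,
            )
            for name, (a, b) in config.comparisons.items()
        ],
        ignore_index=True,
    ) if config.comparisons else pd.DataFrame()

    # volume trend across AMD stages, per modality
    trend_rows = []
    for dev in meas["device"].unique():
        sub = meas[meas["device"] == dev]
        groups = [
            sub.loc[sub["stage"] == s, "volume_5mm_mm3"].to_numpy() for s in STAGES
        ]
        if sum(len(g) > 0 for g in groups) >= 2:
            jt = jonckheere_terpstra([g for g in groups if len(g) > 0])
            trend_rows.append(
                {"device": dev, "jt_statistic": jt.statistic, "jt_p": jt.p_value}
            )
    trend = pd.DataFrame(trend_rows)

    # ROC threshold selection per modality and case definition
    roc_rows, thresholds = [], {}
    for dev in meas["device"].unique():
        sub = meas[meas["device"] == dev]
        stages = sub["stage"].to_numpy()
        values = sub["volume_5mm_mm3"].to_numpy()
        for case_name, case_stages in CASE_DEFINITIONS.items():
            keep = (stages == "no_amd") | np.isin(stages, case_stages)
            labels = np.isin(stages[keep], case_stages)
            if labels.all() or not labels.any():
                continue
            curve = roc_points(values[keep], labels)
            thr, se, sp = optimal_threshold(curve)
            roc_rows.append(
                {
                    "device": dev, "case_definition": case_name, "auc": curve.auc,
                    "threshold_mm3": thr, "sensitivity": 100 * se,
                    "specificity": 100 * sp,
                }
            )
            if case_name == "e_and_iamd":
                by_stage = sens_spec_by_stage(values, stages, thr)
                thresholds[dev] = {"threshold_mm3": thr, "auc": curve.auc, **by_stage}
    roc_table = pd.DataFrame(roc_rows)

    conversion = _conversion_analysis(meas, config)

    run_log = {
        "seed": config.seed,
        "drusenkit_version": __version__,
        "numpy_version": np.__version__,
        "n_eyes_generated": len(cohort),
        "n_eyes_included": meas["eye_id"].nunique(),
        "n_eyes_excluded": len(excluded),
        "excluded": excluded,
    }
    return StudyBundle(
        manifest=cohort_manifest([eye for eye, _ in cohort]),
        measurements=meas,
        agreement=agreement,
        trend=trend,
        roc_table=roc_table,
        thresholds=thresholds,
        conversion=conversion,
        run_log=run_log,
    )


def _conversion_analysis(meas: pd.DataFrame, config: StudyConfig) -> dict:
    """Deming conversion between the inter-device pair on iAMD eyes:
    whole-dataset vs optimal-subset fits, evaluated on a held-out split."""
    if "inter_device" not in config.comparisons:
        return {}
    dev_s, dev_c = config.comparisons["inter_device"]
    iamd = meas[meas["stage"] == "iamd"]
    if iamd["eye_id"].nunique() < 10:
        return {}
    p_all = _paired(iamd, dev_s, dev_c)
    out: dict = {"direction_labels": {"s": dev_s, "c": dev_c}, "seed": config.seed}
    for label, pairs in (
        ("whole", p_all),
        ("optimal", select_optimal_subset(p_all, config.subset_mean_cap)),
    ):
        tr, te = train_test_split_pairs(pairs, config.train_frac, config.seed)
        s_tr, c_tr = pairs.value_a[tr], pairs.value_b[tr]
        s_te, c_te = pairs.value_a[te], pairs.value_b[te]
        fit_sc = deming_fit(s_tr, c_tr)  # Spectralis-like -> Cirrus-like
        fit_cs = deming_fit(c_tr, s_tr)
        ev_cs = evaluate_conversion(fit_cs, c_te, s_te, "c_to_s", len(tr))
        ev_sc = evaluate_conversion(fit_sc, s_te, c_te, "s_to_c", len(tr))
        out[label] = {
            "n": len(pairs),
            "n_train": len(tr),
            "n_test": len(te),
            "slope_s_to_c": fit_sc.slope,
            "intercept_s_to_c": fit_sc.intercept,
            "slope_c_to_s": fit_cs.slope,
            "intercept_c_to_s": fit_cs.intercept,
            "mean_error_c_to_s": ev_cs.mean_error,
            "rmse_c_to_s": ev_cs.rmse,
            "mean_error_s_to_c": ev_sc.mean_error,
            "rmse_s_to_c": ev_sc.rmse,
        }
    return out


def write_report(
    bundle: StudyBundle, outdir: str | Path, format: str = "csv"
) -> list[Path]:
    """Write the report artifacts; returns the written paths.

    ``csv`` writes one CSV per table plus JSON for the nested results;
    ``json`` writes a single lossless ``report.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if format == "csv":
        for name in ("manifest", "measurements", "agreement", "trend", "roc_table"):
            path = outdir / f"{name}.csv"
            getattr(bundle, name).to_csv(path, index=False)
            written.append(path)
        for name in ("thresholds", "conversion", "run_log"):
            path = outdir / f"{name}.json"
            path.write_text(json.dumps(getattr(bundle, name), indent=1, default=float))
            written.append(path)
    elif format == "json":
        payload = {
            name: getattr(bundle, name).to_dict(orient="records")
            for name in ("manifest", "measurements", "agreement", "trend", "roc_table")
        }
        payload |= {
            name: getattr(bundle, name)
            for name in ("thresholds", "conversion", "run_log")
        }
        path = outdir / "report.json"
        path.write_text(json.dumps(payload, indent=1, default=float))
        written.append(path)
    else:
        raise ValueError(f"unknown report format: {format!r}")
    return written
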