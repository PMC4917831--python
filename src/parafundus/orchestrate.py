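"""End-to-end pipeline: simulate a cohort, score images, analyze the cohort.

The three stages mirror how the analysis runs on real data:

* ``cmd_simulate`` writes one PNG per synthetic eye plus a ground-truth
  CSV and a manifest carrying the seed and a parameter hash;
* ``cmd_score`` reads every image, extracts the green channel, crops the
  ROI, runs the skeletonization chain and writes one score row per eye
  (per-image failures are quarantined with a reason, never silently
  dropped);
* ``cmd_analyze`` joins scores with ground truth, drops eyes with
  undeterminable perfusion, and emits a JSON report with the group
  comparisons, the 2x2 pattern-by-perfusion association, the ROC block
  for perfusion differentiation, and the sample-size planning note.

All outputs embed the root seed and a hash of the configuration, so a
rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .metric import roi_parallelism
from .pipeline import (
    BandpassParams,
    RoiSpec,
    bandpass_filter,
    binarize_otsu,
    crop_roi,
    extract_dual_skeletons,
    extract_green_channel,
)
from .stats import (
    ContingencyTable2x2,
    chi2_association,
    fisher_exact_association,
    roc_analysis,
    sample_size_two_means,
    unpaired_t_test,
)
from .synth import CohortParams, generate_cohort

__all__ = [
    "PipelineConfig",
    "cmd_simulate",
    "cmd_score",
    "cmd_analyze",
    "render_report_text",
    "validate_report",
]

log = logging.getLogger("parafundus")

# Pilot inputs of the two-mean planning calculation: group parallelism
# 0.33 +/- 0.13 (nonischemic) vs 0.20 +/- 0.11 (ischemic), alpha 0.05,
# beta 0.20, ischemic:nonischemic allocation 0.75.
_PILOT_SAMPLE_SIZE_INPUTS = dict(
    m1=0.33, s1=0.13, m2=0.20, s2=0.11, alpha=0.05, beta=0.20, allocation_ratio=0.75
)


@dataclass
class PipelineConfig:
    """Paths, parameters and options shared by the pipeline stages."""

    output_dir: Path = Path("parafundus_out")
    images_subdir: str = "images"
    cohort_id: str = "cohort"
    bandpass: BandpassParams = field(default_factory=BandpassParams)
    # ROI source: "whole-image" for pre-cropped 200x200 inputs, else the
    # path of a CSV with columns eye_id, row, col of each ROI corner.
    roi_source: str = "whole-image"
    cohort: CohortParams = field(default_factory=CohortParams)
    fisher: bool = False
    positive_means_low_score: bool = True
    debug_dump: bool = False

    @property
    def images_dir(self) -> Path:
        return Path(self.output_dir) / self.images_subdir

    @property
    def truth_csv(self) -> Path:
        return Path(self.output_dir) / "truth.csv"

    @property
    def scores_csv(self) -> Path:
        return Path(self.output_dir) / "scores.csv"

    @property
    def report_json(self) -> Path:
        return Path(self.output_dir) / "report.json"

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["output_dir"] = str(payload["output_dir"])
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_json(path: Path, payload: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def cmd_simulate(config: PipelineConfig) -> pd.DataFrame:
    """Generate the synthetic cohort; write PNGs, truth CSV and manifest."""
    config.images_dir.mkdir(parents=True, exist_ok=True)
    eyes = generate_cohort(config.cohort)
    rows = []
    files = []
    for eye in eyes:
        name = f"{config.cohort_id}_{eye.record.eye_id}.png"
        iio.imwrite(config.images_dir / name, eye.image)
        files.append(name)
        rows.append(
            dict(
                eye_id=eye.record.eye_id,
                pattern_label=eye.record.pattern_label,
                perfusion_label=eye.record.perfusion_label,
                kappa=eye.kappa if eye.kappa is not None else "",
                n_blobs=eye.n_blobs if eye.n_blobs is not None else "",
                age_years=round(eye.record.age_years, 2),
                logmar_va=round(eye.record.logmar_va, 3),
                foveal_thickness_um=round(eye.record.foveal_thickness_um, 1),
                symptom_months=round(eye.record.symptom_months, 2),
                seed=eye.image_seed,
            )
        )
        log.info("simulate %s pattern=%s", eye.record.eye_id, eye.record.pattern_label)
    truth = pd.DataFrame(rows)
    truth.to_csv(config.truth_csv, index=False)
    _write_json(
        Path(config.output_dir) / "manifest.json",
        dict(
            cohort_id=config.cohort_id,
            seed=config.cohort.seed,
            n_eyes=config.cohort.n_eyes,
            config_hash=config.config_hash(),
            files=files,
        ),
    )
    return truth


def _load_roi_table(config: PipelineConfig) -> dict[str, RoiSpec] | None:
    if config.roi_source == "whole-image":
        return None
    tab = pd.read_csv(config.roi_source)
    return {
        str(r.eye_id): RoiSpec(row=int(r.row), col=int(r.col)) for r in tab.itertuples()
    }


def _dump_debug_planes(config: PipelineConfig, eye_id: str, roi: np.ndarray) -> None:
    dbg = Path(config.output_dir) / "debug" / eye_id
    dbg.mkdir(parents=True, exist_ok=True)
    resp = bandpass_filter(roi, config.bandpass)
    lo, hi = resp.min(), resp.max()
    scaled = np.zeros_like(resp) if hi == lo else (resp - lo) / (hi - lo) * 255
    iio.imwrite(dbg / "bandpass.png", scaled.astype(np.uint8))
    for tag, plane in (("neg", -resp), ("pos", resp)):
        binary = binarize_otsu(plane)
        iio.imwrite(dbg / f"binary_{tag}.png", (binary * 255).astype(np.uint8))
    hem, sparse = extract_dual_skeletons(roi, config.bandpass)
    iio.imwrite(dbg / "skeleton_hemorrhage.png", (hem.pixels * 255).astype(np.uint8))
    iio.imwrite(dbg / "skeleton_sparse.png", (sparse.pixels * 255).astype(np.uint8))


def cmd_score(config: PipelineConfig) -> pd.DataFrame:
    """Score every image in the images directory; write the scores CSV.

    One row per eye.  Images that cannot be read or scored get status
    "error" with the reason recorded; the run continues.
    """
    roi_table = _load_roi_table(config)
    rows = []
    paths = sorted(Path(config.images_dir).glob("*.png")) + sorted(
        Path(config.images_dir).glob("*.tif*")
    )
    for path in paths:
        eye_id = path.stem.split("_", 1)[-1]
        row: dict = dict(eye_id=eye_id, status="ok", error="")
        try:
            img = iio.imread(path)
            gray = extract_green_channel(img) if img.ndim == 3 else np.asarray(img)
            if roi_table is not None:
                if eye_id not in roi_table:
                    raise KeyError(f"no ROI specified for eye {eye_id}")
                gray = crop_roi(gray, roi_table[eye_id])
            if config.debug_dump:
                _dump_debug_planes(config, eye_id, gray)
            score = roi_parallelism(gray, config.bandpass)
            ch, cs = score.counts_hemorrhage, score.counts_sparse
            row.update(
                p_hemorrhage=score.p_hemorrhage,
                p_sparse=score.p_sparse,
                p_mean=score.p_mean,
                n0_hemorrhage=ch.n0, n45_hemorrhage=ch.n45,
                n90_hemorrhage=ch.n90, n135_hemorrhage=ch.n135,
                n0_sparse=cs.n0, n45_sparse=cs.n45,
                n90_sparse=cs.n90, n135_sparse=cs.n135,
            )
            log.info("score %s p_mean=%.3f", eye_id, score.p_mean)
        except Exception as exc:  # quarantine any per-image failure
            row.update(status="error", error=f"{type(exc).__name__}: {exc}")
            log.warning("score %s failed: %s", eye_id, exc)
        rows.append(row)
    columns = [
        "eye_id", "status", "error", "p_hemorrhage", "p_sparse", "p_mean",
        "n0_hemorrhage", "n45_hemorrhage", "n90_hemorrhage", "n135_hemorrhage",
        "n0_sparse", "n45_sparse", "n90_sparse", "n135_sparse",
    ]
    scores = pd.DataFrame(rows, columns=columns)
    Path(config.output_dir).mkdir(parents=True, exist_ok=True)
    scores.to_csv(config.scores_csv, index=False)
    return scores


def _two_group_block(x: np.ndarray, y: np.ndarray) -> dict:
    t, p, means, sds = unpaired_t_test(x, y)
    return dict(
        t=t, p=p,
        mean_a=means[0], sd_a=sds[0], n_a=int(len(x)),
        mean_b=means[1], sd_b=sds[1], n_b=int(len(y)),
    )


def _roc_block(res) -> dict:
    return dict(
        auroc=res.auroc,
        ci95=list(res.ci95),
        p_vs_half=res.p_vs_half,
        cutoff=res.cutoff,
        sensitivity_pct=res.sensitivity_pct,
        specificity_pct=res.specificity_pct,
        lr_pos=res.lr_pos,
        lr_neg=res.lr_neg,
        sens_at_spec90_pct=res.sens_at_spec90_pct,
        sens_at_spec95_pct=res.sens_at_spec95_pct,
        positive_means_low_score=res.positive_means_low_score,
        n_positive=res.n_positive,
        n_negative=res.n_negative,
    )


def cmd_analyze(config: PipelineConfig) -> dict:
    """Join scores with truth; write the cohort analysis report JSON."""
    scores = pd.read_csv(config.scores_csv)
    truth = pd.read_csv(config.truth_csv)
    s_ids = set(scores.eye_id)
    t_ids = set(truth.eye_id)
    if s_ids != t_ids:
        missing = sorted(s_ids.symmetric_difference(t_ids))
        raise KeyError(f"scores/truth eye_id mismatch for: {missing}")
    df = truth.merge(scores, on="eye_id", how="inner")
    n_total = len(df)
    failed = df[df.status != "ok"]
    df = df[df.status == "ok"]
    n_undet = int((df.perfusion_label == "undeterminable").sum())
    df = df[df.perfusion_label != "undeterminable"]

    flame = df[df.pattern_label == "flame"].p_mean.to_numpy()
    nonflame = df[df.pattern_label == "non_flame"].p_mean.to_numpy()
    nonisch = df[df.perfusion_label == "nonischemic"].p_mean.to_numpy()
    isch = df[df.perfusion_label == "ischemic"].p_mean.to_numpy()

    tab = ContingencyTable2x2(
        a=int(((df.pattern_label == "flame") & (df.perfusion_label == "nonischemic")).sum()),
        b=int(((df.pattern_label == "flame") & (df.perfusion_label == "ischemic")).sum()),
        c=int(((df.pattern_label == "non_flame") & (df.perfusion_label == "nonischemic")).sum()),
        d=int(((df.pattern_label == "non_flame") & (df.perfusion_label == "ischemic")).sum()),
    )
    chi2, chi2_p = chi2_association(tab)
    contingency = dict(
        table=[[tab.a, tab.b], [tab.c, tab.d]],
        chi2=chi2,
        p=chi2_p,
    )
    if config.fisher:
        _, fisher_p = fisher_exact_association(tab)
        contingency["fisher_p"] = fisher_p

    roc = roc_analysis(
        df.p_mean.to_numpy(),
        (df.perfusion_label == "ischemic").to_numpy(),
        positive_means_low_score=config.positive_means_low_score,
    )

    n1, n2, total = sample_size_two_means(**_PILOT_SAMPLE_SIZE_INPUTS)
    report = dict(
        seed=config.cohort.seed,
        config_hash=config.config_hash(),
        n_eyes_total=n_total,
        n_failed_images=int(len(failed)),
        failed_eye_ids=failed.eye_id.tolist(),
        n_excluded_undeterminable=n_undet,
        n_eyes_analyzed=int(len(df)),
        pattern_comparison=_two_group_block(flame, nonflame),
        perfusion_comparison=_two_group_block(nonisch, isch),
        contingency=contingency,
        roc_parallelism=_roc_block(roc),
        sample_size_note=dict(
            inputs=_PILOT_SAMPLE_SIZE_INPUTS,
            n_nonischemic=n2,
            n_ischemic=n1,
            total=total,
            method="two-sided normal approximation, unequal allocation",
        ),
    )
    _write_json(config.report_json, report)
    return report


_REPORT_SCHEMA_NAME = "report_schema.json"


def validate_report(report: dict) -> list[str]:
    """Check a report against the shipped schema; return problem list."""
    from importlib import resources

    with resources.files("parafundus.data").joinpath(_REPORT_SCHEMA_NAME).open() as fh:
        schema = json.load(fh)

    problems: list[str] = []

    def check(obj: dict, spec: dict, prefix: str) -> None:
        for key, kind in spec.items():
            if key not in obj:
                problems.append(f"missing key {prefix}{key}")
                continue
            val = obj[key]
            if isinstance(kind, dict):
                if not isinstance(val, dict):
                    problems.append(f"{prefix}{key} should be an object")
                else:
                    check(val, kind, f"{prefix}{key}.")
            elif kind == "number":
                if not isinstance(val, (int, float)) or isinstance(val, bool):
                    problems.append(f"{prefix}{key} should be a number")
            elif kind == "number_or_null":
                if val is not None and (
                    not isinstance(val, (int, float)) or isinstance(val, bool)
                ):
                    problems.append(f"{prefix}{key} should be a number or null")
            elif kind == "integer":
                if not isinstance(val, int) or isinstance(val, bool):
                    problems.append(f"{prefix}{key} should be an integer")
            elif kind == "string":
                if not isinstance(val, str):
                    problems.append(f"{prefix}{key} should be a string")
            elif kind == "boolean":
                if not isinstance(val, bool):
                    problems.append(f"{prefix}{key} should be a boolean")
            elif kind == "array":
                if not isinstance(val, list):
                    problems.append(f"{prefix}{key} should be an array")

    check(report, schema["required"], "")
    return problems


def render_report_text(report: dict) -> str:
    """Plain-text cohort summary from an analysis report."""
    pc = report["pattern_comparison"]
    fc = report["perfusion_comparison"]
    roc = report["roc_parallelism"]
    ct = report["contingency"]
    ss = report["sample_size_note"]
    lines = [
        f"parafundus cohort report (seed {report['seed']}, config {report['config_hash']})",
        f"eyes analyzed: {report['n_eyes_analyzed']} "
        f"(excluded undeterminable: {report['n_excluded_undeterminable']}, "
        f"failed images: {report['n_failed_images']})",
        "",
        "parallelism by hemorrhage pattern (flame vs non-flame):",
        f"  {pc['mean_a']:.3f} +/- {pc['sd_a']:.3f} (n={pc['n_a']}) vs "
        f"{pc['mean_b']:.3f} +/- {pc['sd_b']:.3f} (n={pc['n_b']}), "
        f"t={pc['t']:.2f}, p={pc['p']:.2e}",
        "parallelism by macular perfusion (nonischemic vs ischemic):",
        f"  {fc['mean_a']:.3f} +/- {fc['sd_a']:.3f} (n={fc['n_a']}) vs "
        f"{fc['mean_b']:.3f} +/- {fc['sd_b']:.3f} (n={fc['n_b']}), "
        f"t={fc['t']:.2f}, p={fc['p']:.2e}",
        "",
        f"pattern x perfusion table {ct['table']}: chi2={ct['chi2']:.2f}, p={ct['p']:.2e}"
        + (f", Fisher p={ct['fisher_p']:.2e}" if "fisher_p" in ct else ""),
        "",
        "ROC for ischemic macula (low parallelism = positive):",
        f"  AUROC={roc['auroc']:.3f} (95% CI {roc['ci95'][0]:.3f}-{roc['ci95'][1]:.3f}, "
        f"p vs 0.5 = {roc['p_vs_half']:.2e})",
        f"  cutoff={roc['cutoff']:.3f}: sens={roc['sensitivity_pct']:.2f}%, "
        f"spec={roc['specificity_pct']:.2f}%, "
        f"+LR={'undefined' if roc['lr_pos'] is None else format(roc['lr_pos'], '.2f')}, "
        f"-LR={'undefined' if roc['lr_neg'] is None else format(roc['lr_neg'], '.2f')}",
        f"  sens at 90%/95% spec: {roc['sens_at_spec90_pct']:.2f}% / "
        f"{roc['sens_at_spec95_pct']:.2f}%",
        "",
        f"sample-size planning (normal approximation): n_nonischemic={ss['n_nonischemic']}, "
        f"n_ischemic={ss['n_ischemic']}, total={ss['total']}",
    ]
    return "\n".join(lines) + "\n"
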