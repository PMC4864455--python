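"""End-to-end orchestration: growth -> scoring -> reference sets -> benchmark
-> fusion -> contamination, with one master seed and a written manifest.

The pipeline is deliberately file-oriented: every stage reads and writes
plain TSV/CSV so any stage can be rerun or inspected in isolation, and a
rerun with the same config and seed reproduces the non-stochastic artifacts
bitwise.  The master seed deterministically spawns one sub-seed per
stochastic stage (fold assignment, contamination resampling).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .benchmark import matched_recall_threshold, summarize, pr_curve
from .errors import CompscoreError, DegenerateSetError, InputError
from .fusion import COMBINE_METHODS, CalibrationModel, calibrate, combine
from .growth import average_replicates, estimate_rate, read_plate, relative_rate
from .refsets import REFSET_MODES, build_reference, records_from_frame, refset_frame
from .robustness import ContaminationConfig, simulate_contaminated
from .scoring import DELETERIOUS_THRESHOLD, ComplementationGrade, fcs_score
from .synthetic_data import read_cohort

STAGES = ("growth", "score", "refset", "bench", "fuse", "contaminate")


class PipelineStageError(CompscoreError):
    """A stage failed; ``stage`` names it and ``exit_code`` is stage-specific."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.exit_code = 10 + STAGES.index(stage)
        super().__init__(f"{stage} stage failed: {cause}")


@dataclass
class RunConfig:
    variants: str | None = None
    plate: str | None = None
    grades: str | None = None
    out_dir: str = "compscore_run"
    threshold: float = DELETERIOUS_THRESHOLD
    refset_modes: list[str] = field(default_factory=lambda: ["original", "dm_only"])
    scorers: list[str] = field(default_factory=lambda: ["fcs", "fct", "predictor"])
    fusion_methods: list[str] = field(default_factory=lambda: list(COMBINE_METHODS))
    fusion_scorers: tuple[str, str] = ("fcs", "predictor")
    contamination: float = 0.27
    contamination_sims: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise InputError("threshold must be in (0, 1]")
        for m in self.refset_modes:
            if m not in REFSET_MODES:
                raise InputError(f"unknown refset mode {m!r}")
        for m in self.fusion_methods:
            if m not in COMBINE_METHODS:
                raise InputError(f"unknown fusion method {m!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def compute_plate_rates(plate_path, detect_threshold: float = 0.05) -> pd.DataFrame:
    """Rates and relative rates (mu) for every well of a plate.

    mu is computed against the mean rate of the plate's wildtype wells;
    replicate wells of the same strain are averaged.
    """
    curves = read_plate(plate_path)
    rows = []
    estimates = {}
    for c in curves:
        est = estimate_rate(c, detect_threshold=detect_threshold)
        estimates.setdefault(c.strain_id, []).append((c.allele_class, est))
        rows.append(
            {
                "strain_id": c.strain_id,
                "allele_class": c.allele_class,
                "rate": est.rate,
                "detected": est.detected,
                "fit_r2": est.fit_r2,
            }
        )
    df = pd.DataFrame(rows)
    wt = df[(df.allele_class == "wildtype") & df.detected]
    if wt.empty:
        raise InputError("plate has no detected wildtype reference well")
    ref_rates = wt.groupby("strain_id")["rate"].mean()
    # one wildtype reference per plate is the common layout; fall back to the
    # mean over wildtype strains when strains do not share an id
    ref = float(ref_rates.mean())

    class _Ref:
        rate = ref
        detected = True

    mus = []
    for _, row in df.iterrows():
        reps = [e for ac, e in estimates[row.strain_id] if ac == row.allele_class]
        rel = average_replicates([relative_rate(e, _Ref) for e in reps])
        mus.append(rel.mu)
    df["mu"] = mus
    return df[["strain_id", "allele_class", "rate", "mu", "detected", "fit_r2"]]


def score_grades(grades_path) -> pd.DataFrame:
    """FCS scores from a grades TSV (gene, protein_change, grade, mode)."""
    df = pd.read_csv(grades_path, sep="\t")
    required = {"gene", "protein_change", "grade"}
    if not required <= set(df.columns):
        raise InputError(f"grades file {grades_path}: needs columns {sorted(required)}")
    modes = df["mode"] if "mode" in df.columns else ["standard"] * len(df)
    df = df.copy()
    df["fcs"] = [
        fcs_score(ComplementationGrade(value=g, mode=m)).value
        for g, m in zip(df["grade"], modes)
    ]
    return df


def run(config: RunConfig) -> dict:
    """Execute all configured stages; return the artifact manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "pr_curves").mkdir(exist_ok=True)
    manifest: dict = {"artifacts": [], "stages": []}
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(STAGES, np.random.SeedSequence(config.seed).spawn(len(STAGES)))
    }

    def _artifact(path: Path):
        manifest["artifacts"].append(str(path.relative_to(out)))

    # --- growth -----------------------------------------------------------
    if config.plate is not None:
        try:
            rates = compute_plate_rates(config.plate)
            rates.to_csv(out / "rates.tsv", sep="\t", index=False)
        except Exception as e:  # noqa: BLE001 - rewrapped with stage name
            raise PipelineStageError("growth", e) from e
        _artifact(out / "rates.tsv")
        manifest["stages"].append("growth")

    # --- score ------------------------------------------------------------
    if config.grades is not None:
        try:
            scored = score_grades(config.grades)
            scored.to_csv(out / "grade_scores.tsv", sep="\t", index=False)
        except Exception as e:
            raise PipelineStageError("score", e) from e
        _artifact(out / "grade_scores.tsv")
        manifest["stages"].append("score")

    if config.variants is None:
        _write_manifest(out, manifest, config, stage_seeds)
        return manifest

    try:
        cohort = read_cohort(config.variants)
        records = records_from_frame(cohort)
    except Exception as e:
        raise PipelineStageError("refset", e) from e

    # --- refset + bench ---------------------------------------------------
    summaries = []
    try:
        for mode in config.refset_modes:
            refset = build_reference(records, mode)
            rf = refset_frame(refset)
            rf.to_csv(out / f"refset_{mode}.tsv", sep="\t", index=False)
            _artifact(out / f"refset_{mode}.tsv")
            for scorer in config.scorers:
                scores = rf[scorer].to_numpy(dtype=float)
                labels = rf["label"].to_numpy(dtype=int)
                if scorer in ("fcs", "fct"):
                    summary = summarize(scores, labels, scorer, threshold=config.threshold)
                else:
                    counts = (scores[labels == 1] >= 0).any()  # noqa: F841
                    # computational scorers: binarize at the threshold matching
                    # the experimental scorer's recall at the 0.6 cutoff
                    fcs_scores = rf["fcs"].to_numpy(dtype=float)
                    from .benchmark import confusion_at_threshold

                    cc = confusion_at_threshold(fcs_scores, labels, config.threshold)
                    target = cc.sensitivity
                    try:
                        t = matched_recall_threshold(scores, labels, target)
                    except InputError:
                        t = float(np.nanmedian(scores))
                    summary = summarize(scores, labels, scorer, threshold=t)
                summaries.append({"refset": mode, **summary.__dict__})
                curve = pr_curve(scores[~np.isnan(scores)], labels[~np.isnan(scores)])
                pd.DataFrame(
                    {
                        "threshold": curve.thresholds,
                        "recall": curve.recall,
                        "precision": curve.precision,
                    }
                ).to_csv(out / "pr_curves" / f"{mode}_{scorer}.tsv", sep="\t", index=False)
                _artifact(out / "pr_curves" / f"{mode}_{scorer}.tsv")
        pd.DataFrame(summaries).to_csv(out / "summary.tsv", sep="\t", index=False)
        _artifact(out / "summary.tsv")
        manifest["stages"] += ["refset", "bench"]
    except DegenerateSetError as e:
        raise PipelineStageError("refset", e) from e
    except Exception as e:
        raise PipelineStageError("bench", e) from e

    # --- fuse --------------------------------------------------------------
    try:
        labels = cohort["label"].to_numpy(dtype=int)
        a_name, b_name = config.fusion_scorers
        model = CalibrationModel(seed=stage_seeds["fuse"])
        fused = cohort[["gene", "protein_change", "label", a_name, b_name]].copy()
        a_cal = np.array([c.value for c in calibrate(cohort[a_name], labels, model, a_name)])
        b_cal = np.array([c.value for c in calibrate(cohort[b_name], labels, model, b_name)])
        fused[f"{a_name}_prime"] = a_cal
        fused[f"{b_name}_prime"] = b_cal
        for method in config.fusion_methods:
            fused[f"fused_{method}"] = combine(a_cal, b_cal, method)
        fused.to_csv(out / "fused.tsv", sep="\t", index=False)
        _artifact(out / "fused.tsv")
        manifest["stages"].append("fuse")
    except Exception as e:
        raise PipelineStageError("fuse", e) from e

    # --- contaminate --------------------------------------------------------
    try:
        ccfg = ContaminationConfig(
            contamination=config.contamination,
            n_sims=config.contamination_sims,
            seed=stage_seeds["contaminate"],
        )
        rows = []
        for scorer in config.scorers:
            s = cohort[scorer].to_numpy(dtype=float)
            keep = ~np.isnan(s)
            res = simulate_contaminated(
                s[keep & (labels == 1)], s[keep & (labels == 0)], ccfg
            )
            pd.DataFrame({"auprc_norm": res.values}).to_csv(
                out / f"contamination_{scorer}.tsv", sep="\t", index=False
            )
            _artifact(out / f"contamination_{scorer}.tsv")
            rows.append(
                {
                    "scorer": scorer,
                    "clean_auprc_norm": res.clean_value,
                    "median_contaminated_auprc_norm": res.median,
                }
            )
        pd.DataFrame(rows).to_csv(out / "contamination_summary.tsv", sep="\t", index=False)
        _artifact(out / "contamination_summary.tsv")
        manifest["stages"].append("contaminate")
    except Exception as e:
        raise PipelineStageError("contaminate", e) from e

    _write_manifest(out, manifest, config, stage_seeds)
    return manifest


def _write_manifest(out: Path, manifest: dict, config: RunConfig, stage_seeds: dict) -> None:
    log = {
        "compscore_version": __version__,
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "config": {k: v for k, v in config.__dict__.items()},
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, default_flow_style=False)
    manifest["artifacts"].append("run_log.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
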