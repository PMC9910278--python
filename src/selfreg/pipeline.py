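"""Pipeline orchestration: simulate -> design -> score -> fit-ddm ->
associate -> recover -> report, with a content-hash manifest for
reproducibility.

All tables are TSV (header row, UTF-8, "." decimal); nested results are
JSON.  Re-running with the same config and seed reproduces every output
byte for byte.
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
import yaml

from . import __version__, ddm
from .association import (
    cross_task_association,
    parameter_recovery_experiment,
    score_cohort,
    two_stage_group_model,
)
from .cohort import generate_cohort
from .design import InsufficientChallengeError, build_choice_set
from .reappraisal import condition_means
from .scores import compute_trial_scores, fit_taste_health_weights
from .types import CohortConfig, DDMParams, RatingModel

logger = logging.getLogger("selfreg")

STAGES = ("simulate", "design", "score", "fit-ddm", "associate", "recover", "report")

#: upstream artifacts each stage requires (file names relative to outdir)
_STAGE_INPUTS = {
    "simulate": (),
    "design": ("ratings.tsv",),
    "score": ("choices.tsv", "emotion.tsv"),
    "fit-ddm": ("choices.tsv", "trial_scores.tsv"),
    "associate": ("participant_scores.tsv", "reappraisal_scores.tsv"),
    "recover": (),
    "report": (),
}


class DependencyError(RuntimeError):
    """An upstream artifact is missing; names the stage to run first."""


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    outdir: Path = Path("selfreg_out")
    steps: tuple = STAGES
    seed: int | None = None
    n_resamples: int = 10000
    recovery_ddm_trials: int = 200

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if not self.steps:
            raise ValueError("steps must be nonempty")
        unknown = set(self.steps) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.seed is not None:
            self.cohort = dataclasses.replace(self.cohort, seed=int(self.seed))


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML/JSON pipeline config mirroring the dataclasses."""
    raw = yaml.safe_load(Path(path).read_text())
    cohort_raw = raw.pop("cohort", {})
    if "rating_model" in cohort_raw:
        rm = cohort_raw["rating_model"]
        for key, val in list(rm.items()):
            if isinstance(val, list):
                rm[key] = tuple(val)
        cohort_raw["rating_model"] = RatingModel(**rm)
    if "ddm_defaults" in cohort_raw:
        cohort_raw["ddm_defaults"] = DDMParams(**cohort_raw["ddm_defaults"])
    return PipelineConfig(cohort=CohortConfig(**cohort_raw), **raw)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", encoding="utf-8")


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _require(outdir: Path, stage: str) -> None:
    for fname in _STAGE_INPUTS[stage]:
        if not (outdir / fname).exists():
            producer = {
                "ratings.tsv": "simulate",
                "choices.tsv": "simulate",
                "emotion.tsv": "simulate",
                "trial_scores.tsv": "score",
                "participant_scores.tsv": "score",
                "reappraisal_scores.tsv": "score",
            }[fname]
            raise DependencyError(
                f"stage '{stage}' needs {fname}; run stage '{producer}' first"
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_simulate(cfg: PipelineConfig) -> list[Path]:
    dataset = generate_cohort(cfg.cohort)
    out = []
    names = {
        "ratings": "ratings.tsv",
        "choiceset": "choiceset.tsv",
        "choices": "choices.tsv",
        "emotion": "emotion.tsv",
        "ground_truth": "ground_truth.tsv",
        "exclusions": "exclusions.tsv",
    }
    for key, df in dataset.tables().items():
        path = cfg.outdir / names[key]
        _write_tsv(df, path)
        out.append(path)
    n_excl = int(dataset.exclusions["excluded"].sum())
    logger.info("simulated %d participants (%d excluded at design stage)",
                cfg.cohort.n_participants, n_excl)
    return out


def stage_design(cfg: PipelineConfig) -> list[Path]:
    """Rebuild choice sets from ratings.tsv (supports externally
    supplied rating tables)."""
    _require(cfg.outdir, "design")
    ratings = _read_tsv(cfg.outdir / "ratings.tsv")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.cohort.seed, 7]))
    parts, excl = [], []
    for pid, g in ratings.groupby("participant_id"):
        try:
            cs = build_choice_set(
                g.reset_index(drop=True),
                n_trials=cfg.cohort.n_trials,
                n_challenge_target=cfg.cohort.n_challenge_target,
                min_challenge=cfg.cohort.min_challenge,
                rng=rng,
            )
            t = cs.trials.copy()
            t.insert(0, "participant_id", pid)
            parts.append(t)
        except (InsufficientChallengeError, ValueError) as err:
            excl.append({"participant_id": pid, "excluded": True, "reason": str(err)})
    path = cfg.outdir / "choiceset.tsv"
    _write_tsv(pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(), path)
    out = [path]
    if excl:
        epath = cfg.outdir / "exclusions.tsv"
        _write_tsv(pd.DataFrame(excl), epath)
        out.append(epath)
    return out


def stage_score(cfg: PipelineConfig) -> list[Path]:
    _require(cfg.outdir, "score")
    choices = _read_tsv(cfg.outdir / "choices.tsv")
    emotion = _read_tsv(cfg.outdir / "emotion.tsv")

    trial_parts = []
    for pid, g in choices.groupby("participant_id"):
        try:
            fit = fit_taste_health_weights(g)
            trial_parts.append(compute_trial_scores(g, fit))
        except ValueError:
            continue
    trial_scores = (
        pd.concat(trial_parts, ignore_index=True) if trial_parts else pd.DataFrame()
    )

    class _DS:  # lightweight shim so score_cohort can consume loaded tables
        pass

    ds = _DS()
    ds.choices = choices
    ds.emotion = emotion
    ds.exclusions = pd.DataFrame({"participant_id": [], "excluded": [], "reason": []})
    ps, rs = score_cohort(ds)

    cm = (
        emotion.groupby("participant_id")
        .apply(condition_means, include_groups=False)
        .reset_index(level=0)
        .reset_index(drop=True)
    )
    paths = []
    for df, name in (
        (trial_scores, "trial_scores.tsv"),
        (ps, "participant_scores.tsv"),
        (rs, "reappraisal_scores.tsv"),
        (cm, "condition_means.tsv"),
    ):
        p = cfg.outdir / name
        _write_tsv(df, p)
        paths.append(p)
    return paths


def stage_fit_ddm(cfg: PipelineConfig) -> list[Path]:
    _require(cfg.outdir, "fit-ddm")
    choices = _read_tsv(cfg.outdir / "choices.tsv")
    scores = _read_tsv(cfg.outdir / "trial_scores.tsv")
    merged = choices.merge(
        scores[["participant_id", "trial_idx", "sv"]],
        on=["participant_id", "trial_idx"],
    )
    rows = []
    ss = np.random.SeedSequence([cfg.cohort.seed, 13])
    for (pid, g), child in zip(merged.groupby("participant_id"),
                               ss.spawn(merged["participant_id"].nunique())):
        fit = ddm.fit_mle(
            g["rt_s"].to_numpy(),
            g["choice"].to_numpy(),
            g["sv"].to_numpy(),
            seed=np.random.default_rng(child),
        )
        rows.append(
            {
                "participant_id": pid,
                "a": fit.params.a,
                "z_rel": fit.params.z_rel,
                "t0": fit.params.t0,
                "drift_scale": fit.params.drift_scale,
                "neg_loglik": fit.neg_loglik,
                "converged": fit.converged,
                "n_used": fit.n_used,
            }
        )
    path = cfg.outdir / "ddm_fits.tsv"
    _write_tsv(pd.DataFrame(rows), path)
    return [path]


def stage_associate(cfg: PipelineConfig) -> list[Path]:
    _require(cfg.outdir, "associate")
    ps = _read_tsv(cfg.outdir / "participant_scores.tsv")
    rs = _read_tsv(cfg.outdir / "reappraisal_scores.tsv")
    assoc = cross_task_association(
        ps, rs, n_resamples=cfg.n_resamples, seed=cfg.cohort.seed
    )
    payload = {
        key: {
            "rho": r.rho,
            "interval_low": r.interval_low,
            "interval_high": r.interval_high,
            "pp_positive": r.pp_positive,
            "method": r.method,
            "n": r.n,
        }
        for key, r in assoc.items()
    }
    apath = cfg.outdir / "associations.json"
    apath.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    coef = ps[~ps["excluded_flag"].astype(bool)][
        ["w_taste", "w_health"]
    ].dropna()
    gm = two_stage_group_model(coef)
    rows = [
        {"term": term, **vals} for term, vals in gm["terms"].items()
    ]
    gpath = cfg.outdir / "group_models.tsv"
    _write_tsv(pd.DataFrame(rows), gpath)
    return [apath, gpath]


def stage_recover(cfg: PipelineConfig) -> list[Path]:
    report = parameter_recovery_experiment(
        cfg.cohort,
        ddm_trials_per_participant=cfg.recovery_ddm_trials,
        seed=cfg.cohort.seed,
    )
    path = cfg.outdir / "recovery_report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return [path]


def write_report(outdir: Path) -> Path:
    """Render a human-readable summary of whatever stages have run."""
    outdir = Path(outdir)
    lines = ["# selfreg pipeline report", ""]

    def _section(title):
        lines.extend(["", f"## {title}", ""])

    _section("Emotion ratings by condition")
    cm_path = outdir / "condition_means.tsv"
    if cm_path.exists():
        cm = _read_tsv(cm_path)
        agg = cm.groupby("block_type")[["mean", "sd"]].mean().round(3)
        lines.append(agg.to_string())
    else:
        lines.append("not run")

    _section("Dietary self-control success by challenge type")
    ps_path = outdir / "participant_scores.tsv"
    if ps_path.exists():
        ps = _read_tsv(ps_path)
        ok = ps[~ps["excluded_flag"].astype(bool)]
        lines.append(
            "overall: {:.1%}   HTLH (refuse tasty-unhealthy): {:.1%}   "
            "LTHH (accept healthy-untasty): {:.1%}   (n={})".format(
                ok["success_overall"].mean(),
                ok["success_htlh"].mean(),
                ok["success_lthh"].mean(),
                len(ok),
            )
        )
    else:
        lines.append("not run")

    _section("Drift-diffusion fits")
    dd_path = outdir / "ddm_fits.tsv"
    if dd_path.exists():
        dd = _read_tsv(dd_path)
        lines.append(
            dd[["a", "z_rel", "t0", "drift_scale"]].mean().round(3).to_string()
        )
    else:
        lines.append("not run")

    _section("Cross-task associations")
    a_path = outdir / "associations.json"
    if a_path.exists():
        assoc = json.loads(a_path.read_text())
        for key in sorted(assoc):
            r = assoc[key]
            lines.append(
                f"{key}: rho = {r['rho']:.3f}  "
                f"[{r['interval_low']:.3f}; {r['interval_high']:.3f}]  "
                f"PP(rho>0) = {r['pp_positive']:.3f}  (n={r['n']})"
            )
    else:
        lines.append("not run")

    _section("Exclusions")
    e_path = outdir / "exclusions.tsv"
    if e_path.exists():
        ex = _read_tsv(e_path)
        flagged = ex[ex["excluded"].astype(bool)]
        if len(flagged):
            for _, r in flagged.iterrows():
                lines.append(f"{r['participant_id']}: {r['reason']}")
        else:
            lines.append("none")
    else:
        lines.append("not run")

    ps_path = outdir / "participant_scores.tsv"
    if ps_path.exists():
        ps = _read_tsv(ps_path)
        flagged = ps[ps["excluded_flag"].astype(bool)]
        for _, r in flagged.iterrows():
            lines.append(f"{r['participant_id']}: {r['exclusion_reason']}")

    path = outdir / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    return path


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the requested stages in dependency order.

    Returns the artifact manifest: file name -> sha256 of content.  The
    manifest itself is written to ``manifest.json`` alongside a log of
    seed and package version.
    """
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    order = [s for s in STAGES if s in cfg.steps]
    runners = {
        "simulate": stage_simulate,
        "design": stage_design,
        "score": stage_score,
        "fit-ddm": stage_fit_ddm,
        "associate": stage_associate,
        "recover": stage_recover,
    }
    for stage in order:
        logger.info("running stage %s", stage)
        if stage == "report":
            written.append(write_report(cfg.outdir))
        else:
            written.extend(runners[stage](cfg))

    manifest = {
        "seed": cfg.cohort.seed,
        "version": __version__,
        "stages": order,
        "files": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    (cfg.outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
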