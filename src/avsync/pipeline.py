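"""End-to-end orchestration: simulate (or load) -> aggregate -> fit -> statistics.

One call produces a reproducible report bundle in an output directory:
trial/score CSVs (when simulated), synchrony profiles, per-participant fits
and windows, the exclusion summary, every statistics table, a plain-text
report echoing the conventional F(df1, df2), p, partial-eta-squared style,
and a manifest with the seed and a config hash. Identical configs (including
the seed) yield byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import avsync
from avsync import io as avio
from avsync.cohort import CohortConfig, default_cohort_config, generate_behavioral_scores, sample_cohort
from avsync.design import GROUPS, StudyDesign
from avsync.psychometric import FitConfig, fit_cohort, summarize_exclusions
from avsync import stats as avstats

log = logging.getLogger("avsync")

WINDOW_MEASURES = ("tbw", "av_tbw", "va_tbw", "pss")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source is active: ``cohort`` (simulate) or
    ``trials_csv`` (load). ``scores_csv`` is optional in load mode.
    """

    out_dir: Path
    seed: int = 0
    cohort: CohortConfig | None = None
    trials_csv: Path | None = None
    scores_csv: Path | None = None
    fit: FitConfig = field(default_factory=FitConfig)
    run_statistics: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.trials_csv is None):
            raise ValueError("exactly one of cohort (simulate) or trials_csv (load) must be set")

    @classmethod
    def simulate(cls, out_dir, seed: int = 0, **kwargs) -> "RunConfig":
        return cls(out_dir=Path(out_dir), seed=seed, cohort=default_cohort_config(seed), **kwargs)

    @classmethod
    def from_yaml(cls, path, out_dir=None, seed: int | None = None) -> "RunConfig":
        """Load a YAML run configuration.

        Recognized keys: seed, out_dir, simulate (bool), trials_csv,
        scores_csv, criterion, criterion_mode, censor_beyond_range,
        statistics (bool), group_sizes ({CD: n, TD: n, AD: n}).
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        use_seed = seed if seed is not None else int(raw.get("seed", 0))
        fit = FitConfig(
            criterion=float(raw.get("criterion", 0.70)),
            criterion_mode=raw.get("criterion_mode", "absolute"),
            censor_beyond_range=bool(raw.get("censor_beyond_range", False)),
        )
        out = Path(out_dir if out_dir is not None else raw.get("out_dir", "avsync_out"))
        if raw.get("simulate", True):
            cohort = default_cohort_config(use_seed)
            sizes = raw.get("group_sizes")
            if sizes:
                from dataclasses import replace

                groups = tuple(
                    replace(g, n_participants=int(sizes.get(g.label, g.n_participants)))
                    for g in cohort.groups
                )
                cohort = CohortConfig(
                    design=cohort.design, groups=groups,
                    score_model=cohort.score_model, seed=use_seed,
                )
            return cls(
                out_dir=out, seed=use_seed, cohort=cohort, fit=fit,
                run_statistics=bool(raw.get("statistics", True)),
            )
        return cls(
            out_dir=out, seed=use_seed,
            trials_csv=Path(raw["trials_csv"]),
            scores_csv=Path(raw["scores_csv"]) if raw.get("scores_csv") else None,
            fit=fit, run_statistics=bool(raw.get("statistics", True)),
        )


def _config_hash(config: RunConfig) -> str:
    payload = {
        "seed": config.seed,
        "simulate": config.cohort is not None,
        "criterion": config.fit.criterion,
        "criterion_mode": config.fit.criterion_mode,
        "statistics": config.run_statistics,
    }
    if config.cohort is not None:
        payload["groups"] = [(g.label, g.n_participants) for g in config.cohort.groups]
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _format_anova(table: pd.DataFrame) -> str:
    lines = []
    for row in table.itertuples(index=False):
        lines.append(
            f"  {row.effect}: F({row.df1}, {row.df2}) = {row.F:.2f}, "
            f"p = {row.p:.3g}, partial eta^2 = {row.np2:.3f}"
        )
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the in-memory bundle of results.

    On failure, files written during this run are removed and a
    ``PipelineError`` naming the failing stage is raised.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)

    stage = "setup"
    bundle: dict = {}
    report: list[str] = []
    try:
        if config.cohort is not None:
            stage = "simulate"
            log.info("simulating cohort (seed=%d)", config.seed)
            _, trials, truth = sample_cohort(config.cohort, criterion=config.fit.criterion)
            scores_list = generate_behavioral_scores(truth, config.cohort.score_model, config.cohort.seed)
            save(avio.trials_to_frame(trials), "trials.csv")
            save(truth, "truth.csv")
            scores = avio.scores_to_frame(scores_list)
            save(scores, "scores.csv")
        else:
            stage = "load"
            trials = avio.load_trials(config.trials_csv)
            scores = avio.load_scores(config.scores_csv) if config.scores_csv else None

        stage = "aggregate"
        sj_trials = [t for t in trials if t.task == "SJ"]
        toj_trials = [t for t in trials if t.task == "TOJ"]
        profiles = avio.aggregate_synchrony(sj_trials)
        order_errors = avio.aggregate_order_errors(toj_trials) if toj_trials else []
        save(avio.profiles_to_frame(profiles), "profiles.csv")
        bundle["profiles"] = profiles
        bundle["order_errors"] = order_errors

        stage = "fit"
        windows = fit_cohort(profiles, config.fit)
        save(windows, "fits_windows.csv")
        bundle["windows"] = windows
        statuses = {
            r.participant_id: (r.group, r.status) for r in windows.itertuples(index=False)
        }
        summary = summarize_exclusions(statuses)
        excl = pd.DataFrame(
            [
                {
                    "group": g.group,
                    "n_enrolled": g.n_enrolled,
                    "n_excluded": g.n_excluded,
                    "exclusion_percent": g.exclusion_percent,
                    "n_fitted": g.n_fitted,
                }
                for g in summary.groups
            ]
        )
        save(excl, "exclusions.csv")
        bundle["exclusions"] = excl
        report.append("== Fit exclusions ==")
        for g in summary.groups:
            report.append(
                f"  {g.group}: {g.n_excluded}/{g.n_enrolled} excluded "
                f"({g.exclusion_percent:.2f}%), {g.n_fitted} fitted"
            )

        ok = windows[windows["status"] == "ok"]
        report.append("\n== Window means (fitted participants) ==")
        means = ok.groupby("group")[list(WINDOW_MEASURES)].agg(["mean", "std"]).round(2)
        report.append(means.to_string())
        save(means.reset_index(), "window_means.csv")

        if config.run_statistics:
            stage = "statistics"
            for order in ("AV", "VA"):
                aov = avstats.mixed_anova_synchrony(profiles, order)
                save(aov, f"mixed_anova_{order.lower()}.csv")
                bundle[f"mixed_anova_{order}"] = aov
                report.append(f"\n== Mixed ANOVA (group x ISI), {order} ==")
                report.append(_format_anova(aov))
                simple = avstats.simple_effects_by_isi(profiles, order)
                simple_rows = pd.concat([v["anova"] for v in simple.values()])
                save(simple_rows, f"simple_effects_{order.lower()}.csv")
                bundle[f"simple_effects_{order}"] = simple

            report.append("\n== Window ANOVAs ==")
            for measure in WINDOW_MEASURES:
                res = avstats.window_anova(windows, measure)
                save(res["anova"], f"anova_{measure}.csv")
                save(res["lsd"], f"lsd_{measure}.csv")
                bundle[f"anova_{measure}"] = res
                report.append(_format_anova(res["anova"]))

            report.append("\n== VA vs AV half-window within group ==")
            for group in GROUPS:
                if (ok["group"] == group).any():
                    contrast = avstats.within_va_av_contrast(windows, group)
                    save(contrast, f"contrast_va_av_{group.lower()}.csv")
                    bundle[f"contrast_{group}"] = contrast
                    report.append(_format_anova(contrast))

            if order_errors:
                report.append("\n== TOJ error ANCOVA (covariate: SJ synchrony %) ==")
                for order in ("AV", "VA"):
                    anc = avstats.ancova_toj_errors(order_errors, profiles, order)
                    save(anc.table, f"ancova_toj_{order.lower()}.csv")
                    save(anc.adjusted_means, f"ancova_toj_{order.lower()}_adjmeans.csv")
                    bundle[f"ancova_{order}"] = anc
                    report.append(f" {order}:")
                    report.append(_format_anova(anc.table))

            if scores is not None:
                stage = "regression"
                demo = avstats.demographic_tests(scores)
                save(demo, "demographic_tests.csv")
                bundle["demographics"] = demo
                merged = scores.merge(
                    windows[windows["status"] == "ok"][["participant_id", "va_tbw", "av_tbw", "tbw"]],
                    on="participant_id",
                    how="inner",
                )
                hreg = avstats.hierarchical_regression(merged, "va_tbw", dv="reading_fluency")
                save(hreg.to_frame(), "hierarchical_regression_va_tbw.csv")
                bundle["hierarchical_regression"] = hreg
                report.append("\n== Hierarchical regression (reading fluency) ==")
                for k, blk in enumerate(hreg.blocks, start=1):
                    report.append(
                        f"  block {k} (+{', '.join(blk.predictors)}): "
                        f"R^2 = {blk.r2:.3f}, dR^2 = {blk.delta_r2:.3f}, p = {blk.p_change:.3g}"
                    )

        stage = "report"
        (out / "report.txt").write_text("\n".join(report) + "\n")
        written.append(out / "report.txt")
        manifest = {
            "package": "avsync",
            "version": avsync.__version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "files": sorted(p.name for p in written),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        bundle["manifest"] = manifest
        return bundle
    except Exception as exc:  # noqa: BLE001 - cleanup then re-raise with stage
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
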