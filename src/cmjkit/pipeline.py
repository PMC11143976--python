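"""End-to-end study orchestration.

``run_study`` takes a :class:`StudyConfig` (manifest of recorded trials, or a
synthetic-cohort specification), analyzes every trial (body weight -> onset ->
take-off -> kinematics -> segmentation -> variables -> normalized curves),
averages trials per participant x session, runs the repeated-measures ANOVA
with Bonferroni post hocs for every variable plus RPE, computes percent
changes of each condition against baseline, and performs the paired SPM of
the force- and power-time curves for every condition vs baseline.  All
tables are written as CSV into the output directory together with a serialized
copy of the configuration for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import CONDITIONS, GRAVITY
from .curves import NormalizedCurve, average_curves, normalize_curve
from .errors import CmjError
from .kinematics import detect_onset, detect_takeoff, integrate_motion, segment_phases
from .rm_stats import AnovaResult, bonferroni_posthoc, rm_anova
from .spm import SpmResult, spm_paired_test
from .synthetic import CohortSpec, JumpProfileParams, simulate_cohort
from .trial_io import (
    Dialect,
    ForceTrial,
    compute_body_weight,
    read_force_trial,
    read_manifest,
    write_force_trial,
    write_manifest,
)
from .variables import (
    VARIABLE_NAMES,
    SessionSummary,
    average_trials,
    compute_variables,
    percent_change,
)

__all__ = ["StudyConfig", "StudyReport", "run_study", "analyze_trial", "make_report_tables"]

logger = logging.getLogger(__name__)

#: Footnote letters for the 10 pairwise comparisons among 5 ordered
#: conditions, in the conventional a-j order (baseline vs 3min ... 1hr vs 24hr).
_PAIR_LETTERS = "abcdefghij"


@dataclass
class StudyConfig:
    """Everything needed to run (and re-run) a study analysis."""

    mode: str = "synthetic"  # "synthetic" | "manifest"
    manifest_path: str | None = None
    dialect: Dialect = field(default_factory=Dialect)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    baseline_profile: JumpProfileParams = field(default_factory=JumpProfileParams)
    output_dir: str | None = None
    weighing_window: float = 1.0
    onset_k: float = 5.0
    min_quiet_sd: float = 0.5  # N, floor on the onset noise band
    takeoff_threshold: float = 10.0  # N
    q_nodes: int = 100  # curve intervals (Q)
    alpha: float = 0.05
    two_tailed: bool = True
    g: float = GRAVITY
    jump_height_from: str = "peak"
    power_convention: str = "total"
    seed: int = 0
    write_figures: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(_serializable(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _serializable(obj) -> dict:
    d = asdict(obj) if hasattr(obj, "__dataclass_fields__") else dict(obj)
    return d


@dataclass
class StudyReport:
    summaries: list[SessionSummary]
    variables_table: pd.DataFrame  # long: participant x condition x variable
    anova: dict[str, AnovaResult]  # per variable (+ "rpe")
    posthoc: dict[str, pd.DataFrame]
    percent_changes: pd.DataFrame  # variable x condition (% vs baseline)
    curve_means: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]
    spm: dict[tuple[str, str], SpmResult]  # (quantity, condition) vs baseline
    config: StudyConfig
    config_hash: str


def analyze_trial(trial: ForceTrial, config: StudyConfig) -> tuple[object, dict]:
    """Run the single-trial chain; returns the per-trial variables plus the
    kinematic objects needed for curve construction."""
    bw = compute_body_weight(trial, config.weighing_window, g=config.g)
    mass = trial.body_mass if trial.body_mass else bw.body_mass_kg
    quiet_sd = max(bw.quiet_sd_N, config.min_quiet_sd)
    onset = detect_onset(trial, bw.body_weight_N, quiet_sd, k=config.onset_k)
    takeoff = detect_takeoff(
        trial, onset, threshold_N=config.takeoff_threshold
    )
    kin = integrate_motion(
        trial, mass, onset, g=config.g, power_convention=config.power_convention
    )
    seg = segment_phases(kin, onset, takeoff)
    variables = compute_variables(
        trial, kin, seg, g=config.g, jump_height_from=config.jump_height_from
    )
    curves = {
        quantity: normalize_curve(
            kin,
            seg,
            quantity,
            config.q_nodes,
            participant=trial.participant_id,
            condition=trial.condition,
            g=config.g,
        )
        for quantity in ("force", "power")
    }
    return variables, curves


def _load_trials(config: StudyConfig) -> tuple[list[ForceTrial], pd.DataFrame]:
    if config.mode == "synthetic":
        trials, truth = simulate_cohort(
            config.cohort, config.baseline_profile, g=config.g
        )
        manifest = truth[
            ["participant", "condition", "trial", "body_mass", "rpe"]
        ].copy()
        manifest["file"] = ""
        return trials, manifest
    if config.mode != "manifest":
        raise ValueError("mode must be 'synthetic' or 'manifest'")
    if not config.manifest_path:
        raise ValueError("manifest mode needs manifest_path")
    manifest = read_manifest(config.manifest_path)
    root = Path(config.manifest_path).parent
    trials = []
    for row in manifest.itertuples(index=False):
        path = Path(row.file)
        if not path.is_absolute():
            path = root / path
        trials.append(
            read_force_trial(
                path,
                config.dialect,
                participant_id=str(row.participant),
                condition=str(row.condition),
                trial_index=int(row.trial),
                body_mass=None if pd.isna(row.body_mass) else float(row.body_mass),
            )
        )
    return trials, manifest


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the whole pipeline; see module docstring.

    Any stage error aborts with a stage-tagged message; tables computed so
    far are still written to ``config.output_dir``.
    """
    cfg_hash = config.config_hash()
    stage = "load"
    try:
        trials, manifest = _load_trials(config)
        conditions = [
            c for c in CONDITIONS if c in {t.condition for t in trials}
        ]

        stage = "per-trial analysis"
        per_trial: list[dict] = []
        all_curves: list[NormalizedCurve] = []
        by_cell: dict[tuple[str, str], list] = {}
        for trial in trials:
            variables, curves = analyze_trial(trial, config)
            by_cell.setdefault((trial.participant_id, trial.condition), []).append(
                variables
            )
            all_curves.extend(curves.values())
            row = {
                "participant": trial.participant_id,
                "condition": trial.condition,
                "trial": trial.trial_index,
            }
            row.update({name: getattr(variables, name) for name in VARIABLE_NAMES})
            per_trial.append(row)

        stage = "session averaging"
        rpe_map = {
            (str(r.participant), str(r.condition)): float(r.rpe)
            for r in manifest.itertuples(index=False)
            if not pd.isna(r.rpe)
        }
        summaries = [
            average_trials(
                cell,
                participant=pid,
                condition=cond,
                rpe=rpe_map.get((pid, cond)),
            )
            for (pid, cond), cell in sorted(by_cell.items())
        ]
        var_table = pd.DataFrame(
            [
                {
                    "participant": s.participant,
                    "condition": s.condition,
                    "rpe": s.rpe,
                    **{name: getattr(s.variables, name) for name in VARIABLE_NAMES},
                }
                for s in summaries
            ]
        )

        stage = "repeated-measures ANOVA"
        anova: dict[str, AnovaResult] = {}
        posthoc: dict[str, pd.DataFrame] = {}
        analysis_vars = ["rpe"] + VARIABLE_NAMES if rpe_map else list(VARIABLE_NAMES)
        for name in analysis_vars:
            wide = var_table.pivot(
                index="participant", columns="condition", values=name
            )[conditions]
            if wide.isna().any().any():
                logger.warning("skipping ANOVA for %s: incomplete matrix", name)
                continue
            m = wide.to_numpy()
            anova[name] = rm_anova(m)
            posthoc[name] = bonferroni_posthoc(m, labels=list(conditions))

        stage = "percent changes"
        cond_means = var_table.groupby("condition")[analysis_vars].mean()
        pc_rows = {}
        for name in analysis_vars:
            base = cond_means.loc["baseline", name]
            pc_rows[name] = {
                cond: round(percent_change(base, cond_means.loc[cond, name]), 1)
                for cond in conditions
                if cond != "baseline"
            }
        pct = pd.DataFrame(pc_rows).T

        stage = "normalized curves"
        force_curves = [c for c in all_curves if c.quantity == "force"]
        power_curves = [c for c in all_curves if c.quantity == "power"]
        curve_means = {
            "force": average_curves(force_curves),
            "power": average_curves(power_curves),
        }

        stage = "SPM"
        spm: dict[tuple[str, str], SpmResult] = {}
        for quantity, curveset in (("force", force_curves), ("power", power_curves)):
            per_part = _participant_condition_matrix(curveset, conditions)
            base = per_part.get("baseline")
            for cond in conditions:
                if cond == "baseline" or base is None:
                    continue
                other = per_part[cond]
                spm[(quantity, cond)] = spm_paired_test(
                    base, other, config.alpha, two_tailed=config.two_tailed
                )

        report = StudyReport(
            summaries=summaries,
            variables_table=var_table,
            anova=anova,
            posthoc=posthoc,
            percent_changes=pct,
            curve_means=curve_means,
            spm=spm,
            config=config,
            config_hash=cfg_hash,
        )
        if config.output_dir:
            stage = "report writing"
            _write_outputs(report, trials, manifest)
        return report
    except CmjError as exc:
        raise CmjError(f"[stage: {stage}] {exc}") from exc


def _participant_condition_matrix(
    curves: list[NormalizedCurve], conditions: list[str]
) -> dict[str, np.ndarray]:
    """Trial-mean curve per participant, stacked into an (n, Q+1) array per
    condition with a fixed participant order."""
    participants = sorted({c.participant for c in curves})
    out = {}
    for cond in conditions:
        rows = []
        for p in participants:
            sel = [
                c.values for c in curves if c.condition == cond and c.participant == p
            ]
            if sel:
                rows.append(np.mean(np.vstack(sel), axis=0))
        if rows:
            out[cond] = np.vstack(rows)
    return out


def make_report_tables(
    report: StudyReport, conditions: list[str] | None = None
) -> dict[str, pd.DataFrame]:
    """Presentation tables: per-variable condition means +/- SD with F,
    partial eta-squared and pairwise significance letters, plus the
    percent-change table (one decimal).

    The letter scheme marks each significant pair on the earlier condition's
    column: a = baseline vs 3min, ..., j = 1hr vs 24hr.
    """
    vt = report.variables_table
    conditions = conditions or [
        c for c in CONDITIONS if c in set(vt["condition"])
    ]
    pairs = [
        (i, j)
        for i in range(len(conditions))
        for j in range(i + 1, len(conditions))
    ]
    rows = []
    for name, res in report.anova.items():
        ph = report.posthoc[name]
        sig = {
            (r.condition_a, r.condition_b)
            for r in ph.itertuples(index=False)
            if r.significant
        }
        letters = {c: "" for c in conditions}
        for letter, (i, j) in zip(_PAIR_LETTERS, pairs):
            if (conditions[i], conditions[j]) in sig:
                letters[conditions[i]] += letter
        row: dict[str, object] = {"variable": name}
        for cond in conditions:
            vals = vt.loc[vt["condition"] == cond, name].dropna()
            row[cond] = f"{vals.mean():.2f} ± {vals.std(ddof=1):.2f}"
            row[f"{cond}_sig"] = letters[cond]
        row["F"] = round(res.f_statistic, 2)
        row["partial_eta_sq"] = round(res.partial_eta_sq, 2)
        row["effect"] = res.effect_label
        rows.append(row)
    summary = pd.DataFrame(rows)
    return {"summary": summary, "percent_change": report.percent_changes}


def _write_outputs(
    report: StudyReport, trials: list[ForceTrial], manifest: pd.DataFrame
) -> None:
    out = Path(report.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# cmjkit config {report.config_hash}\n"

    def _save(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=index)

    with open(out / "config.json", "w") as fh:
        json.dump(_serializable(report.config), fh, indent=2, default=str)
    _save(report.variables_table, "session_variables.csv")
    tables = make_report_tables(report)
    _save(tables["summary"], "summary_table.csv")
    _save(report.percent_changes, "percent_changes.csv", index=True)
    for quantity, conds in report.curve_means.items():
        frames = {}
        for cond, (mean, sd) in conds.items():
            frames[f"{cond}_mean"] = mean
            frames[f"{cond}_sd"] = sd
        _save(pd.DataFrame(frames), f"curves_{quantity}.csv")
    spm_rows = []
    for (quantity, cond), res in report.spm.items():
        if not res.clusters:
            spm_rows.append(
                {"quantity": quantity, "condition": cond, "t_star": res.t_star}
            )
        for cl in res.clusters:
            spm_rows.append(
                {
                    "quantity": quantity,
                    "condition": cond,
                    "t_star": res.t_star,
                    "cluster_start_pct": cl.start_percent,
                    "cluster_end_pct": cl.end_percent,
                    "cluster_p": cl.p_value,
                }
            )
    if spm_rows:
        _save(pd.DataFrame(spm_rows), "spm_clusters.csv")
    if report.config.write_figures:
        _write_figures(report, out)


def _write_figures(report: StudyReport, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pct = np.linspace(0, 100, report.config.q_nodes + 1)
    for (quantity, cond), res in report.spm.items():
        fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(7, 6))
        mean_b, sd_b = report.curve_means[quantity]["baseline"]
        mean_c, sd_c = report.curve_means[quantity][cond]
        for mean, sd, label in ((mean_b, sd_b, "baseline"), (mean_c, sd_c, cond)):
            ax1.plot(pct, mean, label=label)
            ax1.fill_between(pct, mean - sd, mean + sd, alpha=0.2)
        unit = "N/kg" if quantity == "force" else "W/kg"
        ax1.set_ylabel(f"{quantity} ({unit})")
        ax1.legend()
        ax2.plot(pct, res.t_curve, "k")
        for thr in (res.t_star, -res.t_star):
            ax2.axhline(thr, ls=":", color="r")
        for cl in res.clusters:
            ax2.axvspan(cl.start_percent, cl.end_percent, alpha=0.3, color="grey")
        ax2.set_xlabel("normalized time (%)")
        ax2.set_ylabel("SPM{t}")
        fig.savefig(out / f"spm_{quantity}_{cond}.png", dpi=120)
        plt.close(fig)


def export_cohort(
    config: StudyConfig, out_dir: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort and write trial files + manifest + ground truth."""
    out = Path(out_dir)
    (out / "trials").mkdir(parents=True, exist_ok=True)
    trials, truth = simulate_cohort(
        config.cohort, config.baseline_profile, g=config.g
    )
    rows = []
    for t in trials:
        rel = f"trials/{t.participant_id}_{t.condition}_{t.trial_index}.csv"
        write_force_trial(t, out / rel, config.dialect)
        rows.append(
            {
                "participant": t.participant_id,
                "condition": t.condition,
                "trial": t.trial_index,
                "body_mass": t.body_mass,
                "rpe": truth.loc[
                    (truth["participant"] == t.participant_id)
                    & (truth["condition"] == t.condition),
                    "rpe",
                ].iloc[0],
                "file": rel,
            }
        )
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out / "manifest.csv")
    truth.to_csv(out / "ground_truth.csv", index=False)
    return manifest, truth
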