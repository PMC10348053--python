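"""End-to-end pipeline: severity tables, trend tests, transitions, reports.

Everything a cohort analysis run emits is computed by the library
modules and written as CSV; plots are a convenience layered on the
already-written numbers. A run log records the seed, permutation
count, package versions and input checksums so that two runs with the
same configuration and seed produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .assoc_stats import (
    ContingencyTable,
    GammaResult,
    gamma_asymptotic,
    gamma_cluster_permutation,
    pairwise_kappa,
)
from .fri_data import CohortDataset, ToothGroupName, group_waves, read_cohort
from .severity import (
    MeanFriCategory,
    align_zones,
    categorize_mean_fri_array,
    person_means,
    severity_contingency,
    summarize_severity,
    tooth_means,
)
from .transitions import bleaching_sensitivity, pairwise_unit_changes, transition_table

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "wave_kappas"]

GROUPS = [g.value for g in ToothGroupName]
LEVELS = ["person", "tooth", "generalized"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Inputs, analysis selections and output location for one run."""

    exam_path: str
    bleaching_path: str | None = None
    out_dir: str = "fritrend-report"
    groups: list[str] = field(default_factory=lambda: list(GROUPS))
    levels: list[str] = field(default_factory=lambda: list(LEVELS))
    n_perm: int = 2000
    seed: int = 0
    ci_level: float = 0.95
    make_plots: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown tooth groups {sorted(unknown)}")
        unknown = set(self.levels) - set(LEVELS)
        if unknown:
            raise ValueError(f"unknown levels {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def trend_gamma(
    data: CohortDataset,
    group: str,
    level: str,
    n_perm: int = 2000,
    seed: int = 0,
) -> GammaResult:
    """Age-vs-severity gamma for one tooth group and analysis level.

    Person and generalized levels use the asymptotic standard error;
    the tooth level uses the within-participant permutation scheme
    because teeth of one mouth are correlated.
    """
    summary = summarize_severity(data, group, level)
    table = ContingencyTable.from_counts(
        severity_contingency(summary).to_numpy(),
        row_levels=tuple(sorted(summary["age"].unique())),
    )
    if level != "tooth":
        return gamma_asymptotic(table)
    aligned = align_zones(data, group, mode="all_ages")
    means = tooth_means(aligned)
    long = pd.concat(
        [
            pd.DataFrame(
                {
                    "cluster_id": means.index.get_level_values("participant_id"),
                    "age": age,
                    "category": categorize_mean_fri_array(means[age]),
                }
            )
            for age in aligned.ages
        ],
        ignore_index=True,
    )
    return gamma_cluster_permutation(long, n_perm=n_perm, seed=seed)


def wave_kappas(data: CohortDataset, level: str = "person") -> pd.DataFrame:
    """Mean pairwise inter-examiner kappa per wave from duplicate exams.

    Each examiner's rating of a unit is the mean-FRI category computed
    from that examiner's own zone scores: the participant's mean over
    all scored zones (person level) or each tooth's mean (tooth level),
    restricted to units rated by at least two examiners at that wave.
    """
    dup = data.duplicate_exam_units()
    rows = []
    unit_cols = ["participant_id"] if level == "person" else ["participant_id", "tooth"]
    for age in data.waves:
        sub = dup[dup["exam_age"] == age]
        if sub.empty:
            continue
        means = sub.groupby(unit_cols + ["examiner_id"])["fri"].mean().reset_index()
        means["category"] = categorize_mean_fri_array(means["fri"])
        means["unit_id"] = (
            means[unit_cols].astype(str).agg(":".join, axis=1)
            if len(unit_cols) > 1
            else means["participant_id"]
        )
        try:
            res = pairwise_kappa(
                means[["unit_id", "examiner_id", "category"]],
                categories=[int(c) for c in MeanFriCategory],
            )
        except ValueError:
            continue
        rows.append(
            {
                "age": age,
                "level": level,
                "mean_kappa": res.mean_kappa,
                "n_pairs": len(res.pairwise_kappas),
                "n_units": sum(res.n_units.values()),
            }
        )
    return pd.DataFrame(rows)


def bleaching_changes(
    data: CohortDataset, group: str, level: str, age_pair: tuple[int, int]
) -> pd.DataFrame:
    """Per-unit mean-FRI changes labelled by any reported bleaching use."""
    aligned = align_zones(data, group, ages=age_pair, mode="pairwise")
    units = pairwise_unit_changes(aligned, level)
    users = data.bleaching_users()
    units["bleach_group"] = units["cluster_id"].isin(users)
    return units


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage and write the report bundle.

    Emits per group: severity summary CSVs annotated with gamma/se/p,
    transition CSVs (one row per cell with CIs) and per-stratum
    signed-rank CSVs for each adjacent age pair, plus a kappa report, a
    bleaching sensitivity report and ``run_log.json``. Any stage
    failure removes partial outputs and raises :class:`PipelineError`
    naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)

    stage = "read"
    try:
        data = read_cohort(config.exam_path, config.bleaching_path)

        stage = "summarize"
        gamma_rows = []
        for group in config.groups:
            for level in config.levels:
                summary = summarize_severity(data, group, level)
                emit(summary, f"severity_{group}_{level}.csv")
                res = trend_gamma(
                    data, group, level, n_perm=config.n_perm, seed=config.seed
                )
                gamma_rows.append(
                    {
                        "group": group,
                        "level": level,
                        "gamma": res.gamma,
                        "se": res.se,
                        "z": res.z,
                        "p_two_sided": res.p_two_sided,
                        "method": res.method,
                    }
                )
        emit(pd.DataFrame(gamma_rows), "gamma_trends.csv")

        stage = "transitions"
        tidy_frames, sr_rows = [], []
        for group in config.groups:
            ages = group_waves(group, data.waves)
            for pair in zip(ages, ages[1:]):
                for level in ("person", "tooth"):
                    if level not in config.levels:
                        continue
                    tab = transition_table(
                        data, group, level, pair, ci_level=config.ci_level
                    )
                    tidy_frames.append(tab.to_tidy())
                    for b, res in tab.signed_rank.items():
                        sr_rows.append(
                            {
                                "group": group,
                                "level": level,
                                "baseline_age": pair[0],
                                "followup_age": pair[1],
                                "baseline_cat": b,
                                "statistic": res.statistic,
                                "z": res.z,
                                "p_one_sided": res.p_one_sided,
                                "n_nonzero": res.n_nonzero,
                                "method": res.method,
                                "clustered": res.clustered,
                            }
                        )
        transitions_tidy = pd.concat(tidy_frames, ignore_index=True)
        emit(transitions_tidy, "transitions.csv")
        emit(pd.DataFrame(sr_rows), "signed_rank_tests.csv")

        stage = "kappa"
        kappas = pd.concat(
            [wave_kappas(data, "person"), wave_kappas(data, "tooth")],
            ignore_index=True,
        )
        emit(kappas, "kappa_report.csv")

        stage = "sensitivity"
        sens_frames = []
        if not data.bleaching.empty:
            for group in config.groups:
                ages = group_waves(group, data.waves)
                for pair in zip(ages, ages[1:]):
                    for level in ("person", "tooth"):
                        changes = bleaching_changes(data, group, level, pair)
                        res = bleaching_sensitivity(changes, level)
                        res.insert(0, "group", group)
                        res.insert(1, "baseline_age", pair[0])
                        res.insert(2, "followup_age", pair[1])
                        sens_frames.append(res)
            emit(pd.concat(sens_frames, ignore_index=True), "bleaching_sensitivity.csv")

        if config.make_plots:
            stage = "plots"
            _plot_transitions(transitions_tidy, out, written)

        stage = "log"
        log = {
            "fritrend_version": __version__,
            "seed": config.seed,
            "n_perm": config.n_perm,
            "ci_level": config.ci_level,
            "inputs": {
                str(p): _sha256(p)
                for p in [config.exam_path, config.bleaching_path]
                if p is not None
            },
            "outputs": sorted(p.name for p in written),
        }
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if not any(out.iterdir()):
            shutil.rmtree(out, ignore_errors=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
    return log


def _plot_transitions(tidy: pd.DataFrame, out: Path, written: list[Path]) -> None:
    """Grouped bar plots of transition proportions, one file per table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [c.label for c in MeanFriCategory]
    for (group, level, b_age, f_age), sub in tidy.groupby(
        ["group", "level", "baseline_age", "followup_age"]
    ):
        fig, ax = plt.subplots(figsize=(8, 4))
        width = 0.2
        for i, (f_cat, cell) in enumerate(sub.groupby("followup_cat")):
            cell = cell.set_index("baseline_cat").reindex(range(4))
            x = cell.index + (i - 1.5) * width
            ax.bar(x, cell["proportion"], width=width, label=f"to {labels[f_cat]}")
            has_ci = cell["ci_lo"].notna()
            ax.errorbar(
                x[has_ci],
                cell.loc[has_ci, "proportion"],
                yerr=[
                    cell.loc[has_ci, "proportion"] - cell.loc[has_ci, "ci_lo"],
                    cell.loc[has_ci, "ci_hi"] - cell.loc[has_ci, "proportion"],
                ],
                fmt="none",
                ecolor="black",
                capsize=2,
            )
        ax.set_xticks(range(4), labels)
        ax.set_xlabel(f"mean-FRI category at age {b_age}")
        ax.set_ylabel(f"proportion at age {f_age}")
        ax.set_title(f"{group}, {level} level, ages {b_age}-{f_age}")
        ax.legend(fontsize=8)
        path = out / f"transitions_{group}_{level}_{b_age}_{f_age}.svg"
        fig.savefig(path)
        plt.close(fig)
        written.append(path)
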