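"""End-to-end orchestration of the five classification tasks.

Each task (lesion vs healthy tissue, and the four pairwise grade
contrasts) runs the same per-task protocol on its own row subset:
Spearman redundancy filter -> Wilcoxon screening -> mutual-information
top-5 -> forward 0.632+ logistic model building over orders 1-5 ->
model-order selection -> pairwise DeLong comparisons of the per-order
models. The more aggressive class is coded positive throughout (HCC vs
HT; G3 vs G1+G2; G2 vs G1; G3 vs G1; G3 vs G2).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import InsufficientFeaturesError
from .feature_table import FeatureTable
from .modeling import (
    BootstrapConfig,
    LogisticModel,
    ModelPerformance,
    evaluate_model,
    forward_select,
    pairwise_delong,
    select_best_order,
)
from .selection import SelectionTrace, correlation_filter, mi_rank, wilcoxon_screen

logger = logging.getLogger("hccradiomics")


@dataclass(frozen=True)
class TaskDefinition:
    """A binary classification task over (tissue, grade) row labels."""

    name: str
    positive: Callable[[str, str], bool]
    negative: Callable[[str, str], bool]
    paired: bool = False
    order_tie_break: str = "parsimony"


def grade_task(name: str, positive_grades: Sequence[str], negative_grades: Sequence[str],
               tie_break: str = "parsimony") -> TaskDefinition:
    """A grading task restricted to HCC rows with the given grade sets."""
    pos = frozenset(positive_grades)
    neg = frozenset(negative_grades)
    if pos & neg:
        raise ValueError("positive and negative grade sets overlap")
    return TaskDefinition(
        name,
        positive=lambda tissue, grade: tissue == "HCC" and grade in pos,
        negative=lambda tissue, grade: tissue == "HCC" and grade in neg,
        paired=False,
        order_tie_break=tie_break,
    )


def default_tasks() -> list[TaskDefinition]:
    """The five study tasks; grading tasks use HCC rows only.

    The G1-vs-G2 contrast selects its model order by specificity among
    near-equal AUC orders, matching how near-flat AUC profiles are
    resolved for that contrast.
    """
    hcc_ht = TaskDefinition(
        "HCC_vs_HT",
        positive=lambda tissue, grade: tissue == "HCC",
        negative=lambda tissue, grade: tissue == "HT",
        paired=True,
    )
    return [
        hcc_ht,
        grade_task("G1G2_vs_G3", ["G3"], ["G1", "G2"]),
        grade_task("G1_vs_G2", ["G2"], ["G1"], tie_break="specificity"),
        grade_task("G1_vs_G3", ["G3"], ["G1"]),
        grade_task("G2_vs_G3", ["G3"], ["G2"]),
    ]


@dataclass(frozen=True)
class StudyConfig:
    """All tunable pipeline parameters (defaults are the study settings)."""

    rho_max: float = 0.8
    alpha: float = 0.05
    k: int = 5
    b: int = 1000
    max_order: int = 5
    epsilon: float = 0.01
    seed: int = 0
    imbalance_adjusted: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class TaskReport:
    """Everything a task produced, sufficient to re-apply its final model."""

    task_name: str
    paired: bool
    n_rows: int
    n_positive: int
    trace: SelectionTrace
    per_order: list[ModelPerformance]
    models: dict[int, LogisticModel]
    chosen_order: int
    final_model: LogisticModel
    delong: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "task": self.task_name,
            "paired": self.paired,
            "n_rows": self.n_rows,
            "n_positive": self.n_positive,
            "selection": {
                "step1_survivors": self.trace.step1_survivors,
                "step2_survivors": self.trace.step2_survivors,
                "step2_p_values": [float(p) for p in self.trace.step2["p_value"]],
                "step3_topk": self.trace.step3_topk,
                "step3_mi_nats": [float(m) for m in self.trace.step3["mi_nats"]],
            },
            "per_order": [p.to_dict() for p in self.per_order],
            "models": {str(o): m.to_dict() for o, m in self.models.items()},
            "chosen_order": self.chosen_order,
            "final_model": self.final_model.to_dict(),
            "delong": self.delong.to_dict(orient="records"),
        }

    def performance_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([p.to_dict() for p in self.per_order])
        df.insert(0, "task", self.task_name)
        df["chosen"] = df["order"] == self.chosen_order
        return df


def task_rows(table: FeatureTable, task: TaskDefinition) -> tuple[FeatureTable, np.ndarray]:
    """Subset the table to the task's rows and build the 0/1 label vector."""
    tissue = table.tissue.to_numpy()
    grade = table.grade.to_numpy()
    pos = np.array([task.positive(t, g) for t, g in zip(tissue, grade)])
    neg = np.array([task.negative(t, g) for t, g in zip(tissue, grade)])
    if (pos & neg).any():
        raise ValueError(f"task {task.name}: positive and negative predicates overlap")
    mask = pos | neg
    if pos.sum() < 3 or neg.sum() < 3:
        raise ValueError(
            f"task {task.name}: needs >= 3 rows per class, got {int(pos.sum())}/{int(neg.sum())}"
        )
    return table.subset_rows(mask), pos[mask].astype(int)


def run_task(table: FeatureTable, task: TaskDefinition, config: StudyConfig = StudyConfig()) -> TaskReport:
    """Run the full per-task protocol and return its report."""
    t0 = time.perf_counter()
    sub, labels = task_rows(table, task)
    logger.info("%s: %d rows (%d positive)", task.name, len(sub), int(labels.sum()))

    step1 = correlation_filter(sub, config.rho_max)
    logger.info("%s: step I kept %d/%d features", task.name, len(step1), len(sub.feature_names))

    screen = wilcoxon_screen(sub, labels, alpha=config.alpha, features=step1)
    step2 = screen[screen["selected"]].drop(columns="selected").reset_index(drop=True)
    paired_screen = None
    if task.paired:
        sub.check_pairing()
        paired_full = wilcoxon_screen(
            sub, labels, alpha=config.alpha, paired=True,
            subject_ids=sub.subject_ids.to_numpy(), features=step1,
        )
        paired_screen = (
            paired_full[paired_full["selected"]].drop(columns="selected").reset_index(drop=True)
        )
        logger.info(
            "%s: step II kept %d (unpaired) / %d (paired) features",
            task.name, len(step2), len(paired_screen),
        )
    else:
        logger.info("%s: step II kept %d features", task.name, len(step2))
    if len(step2) < 2:
        raise InsufficientFeaturesError(
            f"task {task.name}: only {len(step2)} feature(s) significant at alpha="
            f"{config.alpha}; increase alpha or collect more data"
        )

    top = mi_rank(sub, labels, k=config.k, features=list(step2["feature"]))
    trace = SelectionTrace(
        step1_survivors=step1,
        step2=step2,
        step3=top,
        rho_max=config.rho_max,
        alpha=config.alpha,
        k=config.k,
        paired=task.paired,
        paired_step2=paired_screen,
    )
    candidates = trace.step3_topk
    max_order = min(config.max_order, len(candidates))
    boot_cfg = BootstrapConfig(config.b, config.seed, config.imbalance_adjusted)
    built = forward_select(candidates, sub, labels, max_order=max_order, config=boot_cfg)
    per_order = [perf for _, _, perf in built]
    models = {order: model for order, model, _ in built}
    chosen = select_best_order(per_order, epsilon=config.epsilon, tie_break=task.order_tie_break)

    scores = {order: model.predict_proba(sub.values) for order, model in models.items()}
    delong = pairwise_delong(scores, labels)
    logger.info(
        "%s: chose order %d (AUC632 %.3f) in %.1fs",
        task.name, chosen, models and per_order[chosen - 1].auc632, time.perf_counter() - t0,
    )
    return TaskReport(
        task_name=task.name,
        paired=task.paired,
        n_rows=len(sub),
        n_positive=int(labels.sum()),
        trace=trace,
        per_order=per_order,
        models=models,
        chosen_order=chosen,
        final_model=models[chosen],
        delong=delong,
    )


@dataclass
class StudyResult:
    """Per-task reports plus isolated failures and a summary table."""

    reports: list[TaskReport]
    failures: dict[str, str] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        if not self.reports:
            return pd.DataFrame()
        return pd.concat([r.performance_frame() for r in self.reports], ignore_index=True)


def run_study(
    table: FeatureTable,
    tasks: Sequence[TaskDefinition] | None = None,
    config: StudyConfig = StudyConfig(),
) -> StudyResult:
    """Run all tasks, one derived seed per task (base seed + task index).

    Per-task errors are recorded, not fatal to sibling tasks, and adding a
    task never perturbs the seeds of the others.
    """
    if tasks is None:
        tasks = default_tasks()
    result = StudyResult(reports=[])
    for i, task in enumerate(tasks):
        task_config = replace(config, seed=config.seed + i)
        try:
            result.reports.append(run_task(table, task, task_config))
        except Exception as exc:  # noqa: BLE001 - error isolation is the contract
            logger.warning("%s failed: %s", task.name, exc)
            result.failures[task.name] = f"{type(exc).__name__}: {exc}"
    return result


# --- published final models -------------------------------------------------

#: Final logistic models as printed for the original cohort, on standardized
#: feature inputs. The G1-vs-G3 model is printed with one feature duplicated
#: under two coefficients; it is carried here with the distinct features only
#: and the duplicated coefficient summed.
_PUBLISHED = {
    "HCC_vs_HT": (
        0.18,
        [
            ("T2_gldm_DependenceNonUniformityNormalized", -21.4),
            ("T2_glrlm_LongRunHighGrayLevelEmphasis", 7.41),
        ],
    ),
    "G1G2_vs_G3": (
        -2.5,
        [
            ("PORT_gldm_LargeDependenceLowGrayLevelEmphasis", 0.62),
            ("PORT_glcm_MaximumProbability", -1.74),
            ("T2_glszm_LowGrayLevelZoneEmphasis", -7.17),
            ("ART_glszm_SizeZoneNonUniformityNormalized", 0.99),
        ],
    ),
    "G1_vs_G2": (
        9.38,
        [
            ("PORT_ngtdm_Strength", -10.39),
            ("T2_gldm_LowGrayLevelEmphasis", -11.34),
            ("ART_firstorder_10Percentile", -8.98),
            ("TARD_firstorder_Maximum", 4.58),
        ],
    ),
    "G1_vs_G3": (
        3.93,
        [
            ("T2_gldm_LargeDependenceHighGrayLevelEmphasis", 4.08 + 9.61),
            ("PORT_glcm_MaximumProbability", -7.52),
        ],
    ),
    "G2_vs_G3": (
        -0.31,
        [
            ("PORT_ngtdm_Complexity", 1.53),
            ("PORT_glszm_LargeAreaLowGrayLevelEmphasis", -1.59),
        ],
    ),
}


def published_models() -> dict[str, LogisticModel]:
    """The published per-task final models, expecting standardized inputs."""
    out = {}
    for task, (beta0, terms) in _PUBLISHED.items():
        features = [f for f, _ in terms]
        betas = np.array([b for _, b in terms])
        out[task] = LogisticModel(
            features, beta0, betas, np.zeros(len(terms)), np.ones(len(terms))
        )
    return out


# --- reporting --------------------------------------------------------------

def render_model_equation(model: LogisticModel, task_name: str) -> str:
    """Render a fitted model in the printed-equation style."""
    from .feature_table import parse_feature_name

    parts = []
    for f, b in zip(model.features, model.betas):
        try:
            display = parse_feature_name(f).display_name
        except Exception:
            display = f
        parts.append(f"{b:+.2f} x ({display})")
    body = " ".join(parts)
    return f"g_{task_name}(x_i) = {body} {model.beta0:+.2f}".replace("= +", "= ")


def plot_auc_profiles(result: StudyResult, path: str | Path) -> None:
    """One 0.632+ AUC-vs-order series per task (the study's profile figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for report in result.reports:
        orders = [p.order for p in report.per_order]
        aucs = [p.auc632 for p in report.per_order]
        ax.plot(orders, aucs, marker="o", label=report.task_name)
    ax.set_xlabel("model order")
    ax.set_ylabel("0.632+ AUC")
    ax.set_ylim(0.0, 1.0)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_report_bundle(result: StudyResult, directory: str | Path) -> None:
    """Per-task JSON, performance table, equations text and AUC profile plot."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for report in result.reports:
        (directory / f"{report.task_name}.json").write_text(
            json.dumps(report.to_dict(), indent=2)
        )
        report.trace.write(directory, prefix=f"{report.task_name}_selection")
    summary = result.summary()
    if not summary.empty:
        summary.to_csv(directory / "performance.tsv", sep="\t", index=False)
        plot_auc_profiles(result, directory / "auc_profiles.png")
    equations = [
        render_model_equation(r.final_model, r.task_name) for r in result.reports
    ]
    (directory / "final_models.txt").write_text("\n".join(equations) + "\n")
    if result.failures:
        (directory / "failures.json").write_text(json.dumps(result.failures, indent=2))
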