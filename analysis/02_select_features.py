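#!/usr/bin/env python
"""Run the three feature-selection steps for every classification task.

For each task: Spearman redundancy filter (|rho| > 0.8), two-sided
Wilcoxon screening at alpha = 0.05 (plus the paired signed-rank screen
for the lesion-vs-healthy task), and mutual-information top-5 ranking.
Writes one trace per task under the output directory and prints the
per-step survivor counts.
"""

import argparse
from pathlib import Path

from hccradiomics import (
    StudyConfig,
    build_default_catalog,
    correlation_filter,
    default_tasks,
    mi_rank,
    read_feature_table,
    wilcoxon_screen,
)
from hccradiomics.pipeline import task_rows


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/selection"))
    args = parser.parse_args()

    config = StudyConfig()
    table = read_feature_table(args.cohort, build_default_catalog())
    args.out_dir.mkdir(parents=True, exist_ok=True)

    for task in default_tasks():
        sub, labels = task_rows(table, task)
        step1 = correlation_filter(sub, config.rho_max)
        screen = wilcoxon_screen(sub, labels, alpha=config.alpha, features=step1)
        survivors = list(screen.loc[screen["selected"], "feature"])
        top = mi_rank(sub, labels, k=config.k, features=survivors) if len(survivors) else None

        task_dir = args.out_dir / task.name
        task_dir.mkdir(exist_ok=True)
        screen.to_csv(task_dir / "step2_screen.tsv", sep="\t", index=False)
        if top is not None:
            top.to_csv(task_dir / "step3_top5.tsv", sep="\t", index=False)
        line = f"{task.name}: step I {len(step1)}, step II {len(survivors)}"
        if task.paired:
            paired = wilcoxon_screen(
                sub, labels, alpha=config.alpha, paired=True,
                subject_ids=sub.subject_ids.to_numpy(), features=step1,
            )
            n_paired = int(paired["selected"].sum())
            paired.to_csv(task_dir / "step2_screen_paired.tsv", sep="\t", index=False)
            line += f" (paired screen: {n_paired})"
        if top is not None:
            line += f", step III top-{len(top)}: {', '.join(top['feature'].head(3))}..."
        print(line)


if __name__ == "__main__":
    main()
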