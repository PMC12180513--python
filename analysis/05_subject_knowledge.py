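#!/usr/bin/env python
"""Estimate each subject's micro- and meso-level knowledge (stage-1 fits).

For every task subject and wave, fits the logistic model
guess ~ b0 + b1*true_friendship + b2*true_community against the immediately
preceding survey's network and consensus communities, applies the 3-SD
outlier and convergence exclusions, and — because this cohort is synthetic —
reports how well the fitted coefficients track the agents' true weights.
"""

import argparse
from pathlib import Path

import pandas as pd
from scipy import stats

from netcog import (
    ConsensusConfig,
    build_design,
    build_network,
    consensus_communities,
    exclude_outliers,
    fit_subject_knowledge,
    meso_ties,
    run_base_partitions,
)
from netcog import io as nio
from netcog.models import knowledge_frame


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--responses", type=Path, default=Path("results/task/responses.csv"))
    parser.add_argument("--waves", type=int, nargs=2, default=(2, 4))
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/knowledge"))
    args = parser.parse_args()

    surveys = nio.read_survey_csv(args.cohort / "surveys.csv")
    truths = pd.read_csv(args.cohort / "agent_ground_truth.csv").set_index("subject")
    responses = nio.read_responses_csv(args.responses)
    args.out.mkdir(parents=True, exist_ok=True)

    for wave in args.waves:
        net = build_network(surveys[wave])
        partitions = run_base_partitions(net, ConsensusConfig(seed=args.seed))
        ties = meso_ties(consensus_communities(partitions, 5))
        design = build_design(responses[responses["wave"] == wave], net, ties)
        estimates = [
            fit_subject_knowledge(group, subject=subject, wave=wave, min_trials=0)
            for subject, group in design.groupby("subject", sort=True)
        ]
        estimates = exclude_outliers(estimates)
        frame = knowledge_frame(estimates)
        frame.to_csv(args.out / f"subject_knowledge_wave{wave}.csv", index=False)

        kept = frame[~frame["excluded"]]
        merged = kept.join(truths, on="subject")
        rho_micro, _ = stats.spearmanr(merged["beta_micro"], merged["true_beta_micro"])
        rho_meso, _ = stats.spearmanr(merged["beta_meso"], merged["true_beta_meso"])
        print(
            f"wave {wave}: {len(frame)} subjects fit, "
            f"{int(frame['excluded'].sum())} excluded "
            f"({', '.join(sorted(frame.loc[frame['excluded'], 'reason'].unique())) or 'none'})"
        )
        print(
            f"  recovery vs true agent weights: Spearman rho "
            f"micro {rho_micro:.2f}, meso {rho_meso:.2f}"
        )
    print(f"wrote subject-knowledge tables to {args.out}")


if __name__ == "__main__":
    main()
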