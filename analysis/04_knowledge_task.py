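#!/usr/bin/env python
"""Design the knowledge task and simulate agents' responses for both waves.

For each task wave: computes the network-wide base-rate target, draws each
subject's distance-stratified 30-alter stimulus sample, enumerates the
30-block / 870-trial structure, and simulates every agent's binary friendship
guesses from their true logistic weights.  Writes sample rosters and the
long-format response table that stage 05 consumes.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from netcog import (
    ConsensusConfig,
    build_network,
    compute_global_target,
    consensus_communities,
    run_base_partitions,
    select_stimulus_sample,
    simulate_agent_responses,
)
from netcog import io as nio


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--waves", type=int, nargs=2, default=(2, 4))
    parser.add_argument("--n-fall", type=int, default=100)
    parser.add_argument("--n-spring", type=int, default=80)
    parser.add_argument("--sampler-iters", type=int, default=100)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/task"))
    args = parser.parse_args()

    surveys = nio.read_survey_csv(args.cohort / "surveys.csv")
    truths = pd.read_csv(args.cohort / "agent_ground_truth.csv")
    rng = np.random.default_rng(np.random.SeedSequence([args.seed, 40]))
    args.out.mkdir(parents=True, exist_ok=True)

    fall_wave, spring_wave = args.waves
    fall_net = build_network(surveys[fall_wave])
    fall_subjects = sorted(
        rng.choice(sorted(fall_net.nodes()), size=args.n_fall, replace=False)
    )
    spring_subjects = sorted(rng.choice(fall_subjects, size=args.n_spring, replace=False))

    all_responses = []
    for wave, subjects in ((fall_wave, fall_subjects), (spring_wave, spring_subjects)):
        net = build_network(surveys[wave])
        partitions = run_base_partitions(net, ConsensusConfig(seed=args.seed))
        membership = consensus_communities(partitions, 5).membership()
        target = compute_global_target(
            net, subjects, n_iter=args.sampler_iters, seed=int(rng.integers(2**31))
        )
        samples = [
            select_stimulus_sample(
                net, s, n_iter=args.sampler_iters,
                seed=int(rng.integers(2**31)), global_target=target,
            )
            for s in subjects
        ]
        pd.DataFrame(
            [
                {"wave": wave, "subject": smp.subject, "member": m,
                 "true_friend_pairs": smp.true_friend_pairs}
                for smp in samples for m in smp.members
            ]
        ).to_csv(args.out / f"samples_wave{wave}.csv", index=False)
        responses = simulate_agent_responses(
            net, membership, truths, samples, seed=int(rng.integers(2**31))
        )
        responses.insert(0, "wave", wave)
        all_responses.append(responses)
        tfp = [smp.true_friend_pairs for smp in samples]
        print(
            f"wave {wave}: {len(samples)} subjects, base-rate target {target:.1f}, "
            f"selected samples hold {np.mean(tfp):.1f} true friendships on average "
            f"(range {min(tfp)}-{max(tfp)})"
        )

    responses = pd.concat(all_responses, ignore_index=True)
    nio.write_responses_csv(responses, args.out / "responses.csv")
    print(f"{len(responses)} trials written to {args.out / 'responses.csv'}")


if __name__ == "__main__":
    main()
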