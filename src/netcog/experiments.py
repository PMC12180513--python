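"""Verification studies: oracle checks, parameter recovery, power and error rates.

Every stage of the pipeline is validated against an independent reference on
synthetic data with known ground truth:

* the power-iteration influence measure against a dense eigendecomposition;
* the subject-level logistic knowledge estimator by Monte-Carlo recovery of
  known agent weights and Wald-interval coverage;
* the group-level change model by its power to detect a planted
  meso-knowledge effect (and its false-positive rate on the micro term);
* group-level type-I error with nothing planted;
* consensus community detection by exact recovery of planted blocks;
* the churn generator by the early-instability / late-stability signature in
  Jaccard edge similarity.

These functions are the computational core of ``scripts/acceptance.py`` and
of the acceptance test suite; each is a pure function of its seed.
"""

from __future__ import annotations

from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import models as km
from . import network as netcore
from .communities import ConsensusCommunities, ConsensusConfig, consensus_communities, run_base_partitions
from .models import SubjectKnowledge
from .synth import SyntheticConfig, generate_ground_truth, generate_longitudinal_network
from .task import enumerate_trials, select_stimulus_sample

#: planted group-level effect of true meso knowledge on influence change, and
#: the residual noise SD on the change score (the observed scale of influence
#: change in a cohort of this size)
PLANTED_SLOPE = 0.1
DELTA_NOISE_SD = 0.23


def dense_eigen_influence(net: nx.Graph) -> dict:
    """Oracle influence values from a full dense eigendecomposition.

    Independent of the power-iteration implementation: takes the eigenvector
    of the largest adjacency eigenvalue from ``numpy.linalg.eigh``, makes it
    nonnegative, and rescales the maximum to 1.
    """
    nodes = sorted(net.nodes())
    a = nx.to_numpy_array(net, nodelist=nodes)
    eigvals, eigvecs = np.linalg.eigh(a)
    v = eigvecs[:, np.argmax(eigvals)]
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    return dict(zip(nodes, (v / v.max()).tolist()))


def influence_oracle_error(n_graphs: int = 50, seed: int = 0, max_nodes: int = 200) -> float:
    """Max absolute influence discrepancy vs the dense oracle on random graphs.

    Each random draw is reduced to its giant component: connectedness makes
    the Perron eigenvalue simple, so the influence vector is unique and the
    two routes must agree.  (On a graph whose top eigenvalue is shared by two
    components the measure itself is non-unique and any comparison is
    ill-posed.)
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 20]))
    worst = 0.0
    for _ in range(n_graphs):
        n = int(rng.integers(10, max_nodes + 1))
        p = float(rng.uniform(0.03, 0.2))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() == 0:
            continue
        g = g.subgraph(max(nx.connected_components(g), key=len))
        ours = netcore.influence_centrality(g)
        oracle = dense_eigen_influence(g)
        worst = max(worst, max(abs(ours[v] - oracle[v]) for v in g.nodes()))
    return worst


def consensus_recovery_ari(
    consensus: ConsensusCommunities, blocks: Mapping[str, int]
) -> float:
    """Adjusted Rand index of consensus communities against planted blocks.

    Computed over assigned nodes only: an unassigned node is an abstention
    (the four algorithms could not agree, typically because the realized
    graph is genuinely ambiguous there), not a misassignment.
    """
    membership = consensus.membership()
    assigned = [s for s, c in membership.items() if c is not None]
    if not assigned:
        return float("nan")
    return float(
        adjusted_rand_score(
            [blocks[s] for s in assigned], [membership[s] for s in assigned]
        )
    )


def consensus_recovery_study(
    n_seeds: int = 100,
    seed: int = 0,
    n_subjects: int = 100,
    n_blocks: int = 4,
    p_in: float = 0.4,
    p_out: float = 0.02,
) -> dict:
    """Fraction of planted-partition draws recovered exactly by the consensus."""
    exact = 0
    for child in np.random.SeedSequence(seed).spawn(n_seeds):
        child_seed = int(child.generate_state(1)[0] % 2**31)
        cfg = SyntheticConfig(
            n_subjects=n_subjects, n_blocks=n_blocks, p_in=p_in, p_out=p_out,
            n_waves=2, churn_drop=(0.1,), seed=child_seed,
        )
        truths = generate_ground_truth(cfg)
        networks, blocks = generate_longitudinal_network(cfg, truths)
        parts = run_base_partitions(networks[0], ConsensusConfig(seed=child_seed))
        consensus = consensus_communities(parts, min_size=5)
        exact += consensus_recovery_ari(consensus, blocks) == 1.0
    return {"n_seeds": n_seeds, "exact_rate": exact / n_seeds}


def stability_dynamics_study(n_seeds: int = 100, seed: int = 0) -> dict:
    """How often late-wave Jaccard similarity exceeds early-wave similarity.

    Under the default declining churn schedule adjacent spring waves should be
    more similar than adjacent fall waves in nearly every cohort draw.
    """
    hits = 0
    for child in np.random.SeedSequence(seed).spawn(n_seeds):
        cfg = SyntheticConfig(seed=int(child.generate_state(1)[0] % 2**31))
        networks, _ = generate_longitudinal_network(cfg)
        early = netcore.jaccard_stability(networks[0], networks[1])
        late = netcore.jaccard_stability(networks[3], networks[4])
        hits += late > early
    return {"n_seeds": n_seeds, "late_exceeds_early_rate": hits / n_seeds}


def _trial_design(
    net: nx.Graph,
    blocks: Mapping[str, int],
    subject: str,
    sampler_iters: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial (true_friendship, same_block) indicators for one subject.

    Planted blocks serve as the veridical meso structure: they are the
    communities the generative response model conditions on.
    """
    sample = select_stimulus_sample(net, subject, n_iter=sampler_iters, seed=seed)
    trials = enumerate_trials(sample)
    friend = np.array([int(net.has_edge(a, b)) for a, b in trials])
    same = np.array([int(blocks[a] == blocks[b]) for a, b in trials])
    return friend, same


def subject_recovery_study(
    n_replicates: int = 200,
    seed: int = 0,
    truth: tuple[float, float, float] = (-2.0, 1.5, 1.0),
    sampler_iters: int = 100,
) -> dict:
    """Monte-Carlo recovery of one agent's known logistic weights.

    A fixed 30-alter stimulus sample (870 trials) is drawn from the default
    synthetic fall network; each replicate redraws the agent's Bernoulli
    guesses from the true weights and refits the subject-level model.
    Reports mean recovery error and 95% Wald-interval coverage for the micro
    and meso coefficients, over converged replicates.
    """
    b0, b1, b2 = truth
    cfg = SyntheticConfig(seed=seed)
    truths = generate_ground_truth(cfg)
    networks, blocks = generate_longitudinal_network(cfg, truths)
    net = networks[1]  # fall analysis wave
    subject = sorted(net.nodes())[0]
    friend, same = _trial_design(net, blocks, subject, sampler_iters, seed)
    prob = 1.0 / (1.0 + np.exp(-(b0 + b1 * friend + b2 * same)))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 21]))
    z = 1.959963984540054  # normal 97.5% quantile (Wald 95% interval)
    est_micro, est_meso = [], []
    cover_micro = cover_meso = n_converged = 0
    for _ in range(n_replicates):
        guesses = (rng.random(prob.size) < prob).astype(int)
        rows = pd.DataFrame(
            {"guess": guesses, "true_friendship": friend, "true_community": same}
        )
        est = km.fit_subject_knowledge(rows, subject=subject, min_trials=0)
        if not est.converged:
            continue
        n_converged += 1
        est_micro.append(est.beta_micro)
        est_meso.append(est.beta_meso)
        cover_micro += abs(est.beta_micro - b1) <= z * est.se_micro
        cover_meso += abs(est.beta_meso - b2) <= z * est.se_meso
    return {
        "n_replicates": n_replicates,
        "n_converged": n_converged,
        "n_trials": int(prob.size),
        "bias_micro": float(np.mean(est_micro) - b1),
        "bias_meso": float(np.mean(est_meso) - b2),
        "coverage_micro": cover_micro / n_converged,
        "coverage_meso": cover_meso / n_converged,
    }


def _simulated_cohort_knowledge(
    cfg: SyntheticConfig,
    n_subjects: int,
    sampler_iters: int,
    rng: np.random.Generator,
) -> tuple[list[SubjectKnowledge], pd.DataFrame, dict]:
    """Estimate a cohort's knowledge coefficients from simulated task runs."""
    truths = generate_ground_truth(cfg)
    networks, blocks = generate_longitudinal_network(cfg, truths)
    net = networks[1]
    subjects = list(
        rng.choice(sorted(net.nodes()), size=n_subjects, replace=False)
    )
    by_subject = truths.set_index("subject")
    estimates = []
    for s in subjects:
        friend, same = _trial_design(
            net, blocks, s, sampler_iters, int(rng.integers(2**31))
        )
        agent = by_subject.loc[s]
        eta = (
            float(agent["true_beta0"])
            + float(agent["true_beta_micro"]) * friend
            + float(agent["true_beta_meso"]) * same
        )
        prob = 1.0 / (1.0 + np.exp(-eta))
        guesses = (rng.random(prob.size) < prob).astype(int)
        rows = pd.DataFrame(
            {"guess": guesses, "true_friendship": friend, "true_community": same}
        )
        estimates.append(km.fit_subject_knowledge(rows, subject=s, min_trials=0))
    estimates = km.exclude_outliers(estimates)
    degrees = dict(net.degree())
    return estimates, truths, degrees


def planted_effect_study(
    n_cohorts: int = 200,
    n_subjects: int = 100,
    seed: int = 0,
    slope: float = PLANTED_SLOPE,
    noise_sd: float = DELTA_NOISE_SD,
    sampler_iters: int = 25,
) -> dict:
    """Power to detect a planted meso-knowledge effect on influence change.

    Each cohort simulates the full measurement chain — network, stimulus
    samples, task responses, subject-level fits, exclusions — then generates
    influence change as ``slope * true_meso_weight + noise`` with *no* micro
    effect, and fits the controlled change model (knowledge plus friend-count
    and extroversion controls).  Reports the fraction of cohorts with a
    significantly positive meso term (power) and the micro term's rejection
    rate (which should stay near the nominal 5%).
    """
    meso_hits = micro_rejections = 0
    for child in np.random.SeedSequence(seed).spawn(n_cohorts):
        child_seed = int(child.generate_state(1)[0] % 2**31)
        cfg = SyntheticConfig(seed=child_seed)
        rng = np.random.default_rng(np.random.SeedSequence([child_seed, 22]))
        estimates, truths, degrees = _simulated_cohort_knowledge(
            cfg, n_subjects, sampler_iters, rng
        )
        kept = [e.subject for e in estimates if not e.excluded]
        by_subject = truths.set_index("subject")
        beta_meso_true = by_subject.loc[kept, "true_beta_meso"].to_numpy(float)
        delta = slope * beta_meso_true + noise_sd * rng.standard_normal(len(kept))
        controls = pd.DataFrame(
            {
                "fall_friend_count": {s: float(degrees[s]) for s in kept},
                "extroversion": by_subject.loc[kept, "extroversion"],
            }
        )
        result = km.fit_change_model(
            estimates, dict(zip(kept, delta)), "delta_influence", controls=controls
        )
        meso = result.term("fall_meso")
        micro = result.term("fall_micro")
        meso_hits += meso.p_value < 0.05 and meso.beta > 0
        micro_rejections += micro.p_value < 0.05
    return {
        "n_cohorts": n_cohorts,
        "meso_power": meso_hits / n_cohorts,
        "micro_rejection_rate": micro_rejections / n_cohorts,
    }


def type1_error_study(
    n_cohorts: int = 500,
    n_subjects: int = 100,
    seed: int = 0,
    noise_sd: float = DELTA_NOISE_SD,
) -> dict:
    """Group-level false-positive rates with nothing planted.

    Cohorts draw subject knowledge coefficients from the agent weight
    distributions (no effect links them to the outcome), friend count and
    extroversion independently, and pure-noise influence change; each term of
    the controlled change model should reject at the nominal 5% rate.
    """
    cfg = SyntheticConfig()
    terms = ("fall_micro", "fall_meso", "fall_friend_count", "extroversion")
    rejections = dict.fromkeys(terms, 0)
    for child in np.random.SeedSequence(seed).spawn(n_cohorts):
        rng = np.random.default_rng(child)
        subjects = [f"s{i:03d}" for i in range(n_subjects)]
        estimates = [
            SubjectKnowledge(
                subject=s, wave=2, beta0=float(rng.normal(cfg.beta0_mean, cfg.beta0_sd)),
                beta_micro=float(rng.normal(cfg.beta_micro_mean, cfg.beta_micro_sd)),
                beta_meso=float(rng.normal(cfg.beta_meso_mean, cfg.beta_meso_sd)),
                se_micro=0.3, se_meso=0.3, converged=True,
            )
            for s in subjects
        ]
        delta = dict(zip(subjects, noise_sd * rng.standard_normal(n_subjects)))
        controls = pd.DataFrame(
            {
                "fall_friend_count": pd.Series(
                    rng.poisson(8.6, n_subjects).astype(float), index=subjects
                ),
                "extroversion": pd.Series(
                    rng.normal(cfg.extroversion_mean, cfg.extroversion_sd, n_subjects),
                    index=subjects,
                ),
            }
        )
        result = km.fit_change_model(estimates, delta, "delta_influence", controls=controls)
        for t in terms:
            rejections[t] += result.term(t).p_value < 0.05
    return {"n_cohorts": n_cohorts} | {
        f"rejection_{t}": r / n_cohorts for t, r in rejections.items()
    }


def task_combinatorics(seed: int = 0, sampler_iters: int = 50) -> dict:
    """Pair and trial counts of one sampler-produced stimulus set."""
    cfg = SyntheticConfig(seed=seed)
    truths = generate_ground_truth(cfg)
    networks, _ = generate_longitudinal_network(cfg, truths)
    net = networks[1]
    subject = sorted(net.nodes())[0]
    sample = select_stimulus_sample(net, subject, n_iter=sampler_iters, seed=seed)
    trials = enumerate_trials(sample)
    pairs = {frozenset(t) for t in trials}
    return {
        "sample_size": sample.size,
        "n_pairs": len(pairs),
        "n_trials": len(trials),
    }


def max_influence_check(seed: int = 0) -> dict:
    """Maximum influence on a connected synthetic network (must be exactly 1)."""
    cfg = SyntheticConfig(seed=seed)
    networks, _ = generate_longitudinal_network(cfg)
    net = networks[1]
    giant = net.subgraph(max(nx.connected_components(net), key=len)).copy()
    influence = netcore.influence_centrality(giant)
    return {"n_nodes": giant.number_of_nodes(), "max_influence": max(influence.values())}
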