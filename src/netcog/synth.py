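"""Synthetic longitudinal networks, agents, and knowledge-task responses.

The generator emulates the study conditions end to end so that every stage of
the pipeline can be verified by parameter recovery: a stochastic-block-model
network of ~190 subjects with planted communities evolves over six waves with
edge churn that is high early and declines as the network stabilises; each
agent carries known logistic weights (b0, b1 micro, b2 meso) from which their
knowledge-task responses are drawn; and a configurable attachment mechanism
(`plant_influence_link`) lets the expected gain in eigenvector centrality
increase with an agent's true meso weight, so the group-level models can be
power-tested against a known effect.

All generators are pure functions of (config, seed): re-running with the same
seed reproduces byte-identical networks and responses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network import RosterSurveyWave
from .task import StimulusSample, enumerate_trials


@dataclass
class SyntheticConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror the observed cohort: ~190 subjects over 6 waves, mean
    degree near 8.6, strong planted community structure, and a churn schedule
    with heavy early turnover that settles in spring.
    """

    n_subjects: int = 190
    n_waves: int = 6
    n_blocks: int = 6
    p_in: float = 0.25
    p_out: float = 0.01
    #: per-transition edge drop rates (wave t -> t+1); nonincreasing
    churn_drop: tuple[float, ...] = (0.4, 0.3, 0.1, 0.05, 0.05)
    #: per-wave probability that a subject switches planted block (off by default)
    membership_switch_rate: float = 0.0
    beta0_mean: float = -2.0
    beta0_sd: float = 0.5
    beta_micro_mean: float = 1.5
    beta_micro_sd: float = 0.75
    beta_meso_mean: float = 1.0
    beta_meso_sd: float = 1.0
    #: effect size linking true meso weight to late-wave centrality gain
    gamma: float = 0.0
    extroversion_mean: float = 3.5
    extroversion_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if len(self.churn_drop) < self.n_waves - 1:
            raise ValueError(
                f"churn_drop needs {self.n_waves - 1} rates, got {len(self.churn_drop)}"
            )
        if any(not (0.0 <= d <= 1.0) for d in self.churn_drop):
            raise ValueError("churn drop rates must lie in [0, 1]")
        if any(b > a for a, b in zip(self.churn_drop, self.churn_drop[1:])):
            raise ValueError("churn drop rates must be nonincreasing across waves")
        # stationarity requires the implied add rate d*p/(1-p) to stay <= 1
        for p in (self.p_in, self.p_out):
            if p < 1.0 and max(self.churn_drop) * p / (1.0 - p) > 1.0:
                raise ValueError("infeasible churn: implied edge-add rate exceeds 1")


def subject_ids(n: int) -> list[str]:
    return [f"s{i:03d}" for i in range(n)]


def generate_ground_truth(config: SyntheticConfig) -> pd.DataFrame:
    """Agent-level ground truth: block, logistic weights, extroversion.

    Extroversion is drawn independently of the knowledge weights so that
    control-variable regressions can be tested for null behaviour.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ids = subject_ids(config.n_subjects)
    blocks = np.repeat(np.arange(config.n_blocks), -(-config.n_subjects // config.n_blocks))
    blocks = blocks[: config.n_subjects]
    return pd.DataFrame(
        {
            "subject": ids,
            "block": blocks,
            "true_beta0": rng.normal(config.beta0_mean, config.beta0_sd, config.n_subjects),
            "true_beta_micro": rng.normal(
                config.beta_micro_mean, config.beta_micro_sd, config.n_subjects
            ),
            "true_beta_meso": rng.normal(
                config.beta_meso_mean, config.beta_meso_sd, config.n_subjects
            ),
            "extroversion": rng.normal(
                config.extroversion_mean, config.extroversion_sd, config.n_subjects
            ),
        }
    )


def _pair_probs(blocks: np.ndarray, p_in: float, p_out: float) -> np.ndarray:
    same = blocks[:, None] == blocks[None, :]
    return np.where(same, p_in, p_out)


def _graph_from_adj(adj: np.ndarray, ids: Sequence[str], wave_id: int) -> nx.Graph:
    g = nx.Graph(wave_id=wave_id)
    g.add_nodes_from(ids)
    iu = np.triu_indices_from(adj, k=1)
    for i, j in zip(*iu):
        if adj[i, j]:
            g.add_edge(ids[i], ids[j])
    return g


def _churn_step(
    adj: np.ndarray,
    blocks: np.ndarray,
    drop_rate: float,
    p_in: float,
    p_out: float,
    rng: np.random.Generator,
    add_weights: np.ndarray | None = None,
) -> np.ndarray:
    """One wave transition: drop edges at `drop_rate`, add non-edges.

    Non-edges are added at the block-dependent stationary rate
    ``drop * p / (1 - p)`` so expected within/between densities are preserved.
    ``add_weights`` (mean 1 over candidate non-edges) tilts *which* non-edges
    form without changing the expected count; uniform weights reduce exactly
    to the unbiased generator.
    """
    n = adj.shape[0]
    p = _pair_probs(blocks, p_in, p_out)
    add_rate = np.where(p < 1.0, drop_rate * p / (1.0 - p), 0.0)
    if add_weights is not None:
        add_rate = np.minimum(add_rate * add_weights, 1.0)
    u = rng.random((n, n))
    u = np.triu(u, k=1)
    u = u + u.T  # symmetric draws; diagonal zero
    keep = adj & (u >= drop_rate)
    born = (~adj) & (u < add_rate)
    np.fill_diagonal(born, False)
    return keep | born


def _attachment_weights(
    adj: np.ndarray, beta_meso: np.ndarray, gamma: float
) -> np.ndarray:
    """Edge-formation tilt: high-meso agents attach toward well-connected nodes.

    For candidate pair (u, v) the unnormalised weight is
    ``exp(gamma * (b2_u * s_v + b2_v * s_u))`` where ``s`` is the degree
    percentile (connectedness) in the current wave.  Weights are normalised to
    mean 1 over candidate non-edges so the expected edge count is unchanged;
    gamma = 0 gives uniform weights (the unmodified generator).
    """
    if not np.isfinite(gamma):
        raise ValueError("gamma must be finite")
    deg = adj.sum(axis=1).astype(float)
    order = deg.argsort(kind="stable").argsort(kind="stable")
    s = order / max(len(deg) - 1, 1)
    expo = gamma * (beta_meso[:, None] * s[None, :] + beta_meso[None, :] * s[:, None])
    expo = expo - expo.max()  # guard overflow; normalisation removes the shift
    w = np.exp(expo)
    candidates = ~adj
    np.fill_diagonal(candidates, False)
    mean_w = w[candidates].mean()
    return w / mean_w


def generate_longitudinal_network(
    config: SyntheticConfig,
    truths: pd.DataFrame | None = None,
) -> tuple[list[nx.Graph], dict[str, int]]:
    """Generate the wave-1..n friendship networks with declining churn.

    Wave 1 is a planted-partition (stochastic-block-model) draw; each later
    wave perturbs the previous one by dropping edges at that transition's
    churn rate and adding non-edges at the block-dependent stationary rate.
    When ``config.gamma`` is nonzero the *final* transition's edge formation
    is tilted by the agents' true meso weights (see `plant_influence_link`).

    Returns the list of networks and the planted block label per subject.
    """
    if truths is None:
        truths = generate_ground_truth(config)
    ids = list(truths["subject"])
    blocks = truths["block"].to_numpy()
    beta_meso = truths["true_beta_meso"].to_numpy(float)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = len(ids)
    p = _pair_probs(blocks, config.p_in, config.p_out)
    u = rng.random((n, n))
    u = np.triu(u, k=1)
    u = u + u.T
    adj = u < p
    np.fill_diagonal(adj, False)
    networks = [_graph_from_adj(adj, ids, wave_id=1)]
    for t in range(config.n_waves - 1):
        if config.membership_switch_rate > 0:
            switch = rng.random(n) < config.membership_switch_rate
            blocks = blocks.copy()
            blocks[switch] = rng.integers(0, config.n_blocks, switch.sum())
        last = t == config.n_waves - 2
        weights = (
            _attachment_weights(adj, beta_meso, config.gamma)
            if (last and config.gamma != 0.0)
            else None
        )
        adj = _churn_step(
            adj, blocks, config.churn_drop[t], config.p_in, config.p_out, rng, weights
        )
        networks.append(_graph_from_adj(adj, ids, wave_id=t + 2))
    return networks, dict(zip(ids, truths["block"].tolist()))


def plant_influence_link(
    networks: Sequence[nx.Graph],
    truths: pd.DataFrame,
    config: SyntheticConfig,
    gamma: float,
    seed: int,
) -> nx.Graph:
    """Re-form the final wave with meso-weighted preferential attachment.

    Regenerates the last wave transition from the second-to-last network with
    edge formation tilted so agents with larger true meso weights attach
    preferentially toward well-connected nodes (weight proportional to
    ``exp(gamma * b2)`` times the partner's connectedness percentile).  Their
    expected eigenvector-centrality gain then grows with ``gamma * b2``.
    ``gamma = 0`` reproduces the unmodified transition draw for the same seed.
    """
    if len(networks) < 2:
        raise ValueError("need at least 2 waves to rewire the final transition")
    if not np.isfinite(gamma):
        raise ValueError("gamma must be finite")
    ids = list(truths["subject"])
    index = {v: i for i, v in enumerate(ids)}
    blocks = truths["block"].to_numpy()
    beta_meso = truths["true_beta_meso"].to_numpy(float)
    prev = networks[-2]
    n = len(ids)
    adj = np.zeros((n, n), dtype=bool)
    for a, b in prev.edges():
        adj[index[a], index[b]] = adj[index[b], index[a]] = True
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    drop = config.churn_drop[len(networks) - 2]
    weights = _attachment_weights(adj, beta_meso, gamma) if gamma != 0.0 else None
    new_adj = _churn_step(adj, blocks, drop, config.p_in, config.p_out, rng, weights)
    return _graph_from_adj(new_adj, ids, wave_id=networks[-1].graph.get("wave_id"))


def simulate_agent_responses(
    net: nx.Graph,
    meso_membership: Mapping[Hashable, int | None],
    truths: pd.DataFrame,
    samples: Iterable[StimulusSample],
    seed: int = 0,
) -> pd.DataFrame:
    """Draw each agent's knowledge-task guesses from their true weights.

    For every trial of every sample the guess is Bernoulli with
    ``p = logistic(b0 + b1 * true_friendship + b2 * same_community)`` using
    the judging agent's true weights.  Returns a long-format response table
    (subject, block_target, probe, guess).
    """
    truth_by_subject = truths.set_index("subject")
    rows = []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    for sample in samples:
        if sample.subject not in truth_by_subject.index:
            raise ValueError(f"no ground-truth record for subject {sample.subject!r}")
        agent = truth_by_subject.loc[sample.subject]
        b0 = float(agent["true_beta0"])
        b1 = float(agent["true_beta_micro"])
        b2 = float(agent["true_beta_meso"])
        trials = enumerate_trials(sample)
        eta = np.empty(len(trials))
        for k, (target, probe) in enumerate(trials):
            friend = int(net.has_edge(target, probe))
            ca = meso_membership.get(target)
            cb = meso_membership.get(probe)
            comm = int(ca is not None and ca == cb)
            eta[k] = b0 + b1 * friend + b2 * comm
        prob = 1.0 / (1.0 + np.exp(-eta))
        guesses = (rng.random(len(trials)) < prob).astype(int)
        for (target, probe), guess in zip(trials, guesses):
            rows.append(
                {
                    "subject": sample.subject,
                    "block_target": target,
                    "probe": probe,
                    "guess": int(guess),
                }
            )
    return pd.DataFrame(rows, columns=["subject", "block_target", "probe", "guess"])


def surveys_from_networks(networks: Sequence[nx.Graph]) -> list[RosterSurveyWave]:
    """Emit roster surveys whose mutual-friend reconstruction is each network.

    Every subject rates every other subject; pairs joined by an edge rate each
    other "friend", all other pairs "not-friend" — the same long CSV dialect
    the real-data readers consume.
    """
    surveys = []
    for net in networks:
        nodes = sorted(net.nodes())
        records = [
            (a, b, "friend" if net.has_edge(a, b) else "not-friend")
            for a in nodes
            for b in nodes
            if a != b
        ]
        surveys.append(RosterSurveyWave(wave_id=net.graph.get("wave_id"), records=records))
    return surveys
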