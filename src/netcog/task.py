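"""Network-knowledge-task design: stimulus sampling and trial structure.

Each subject judges the friendship status of every pair within a tailored
sample of 30 other network members.  Samples are stratified by network
distance from the subject (about 5 friends, 10 friends-of-friends, 15
friends-of-friends-of-friends) — distant members are oversampled to probe the
parts of the network the subject knows least — and base-rate matched: among
many random candidate samples, the one whose number of true friendships is
closest to the network-wide average is kept, so that subjects face comparable
numbers of real friendships.  The task presents one block per sample member;
within a block the subject judges that member against each of the other 29,
so every unordered pair is judged exactly twice (once in each direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Iterator, Sequence

import networkx as nx
import numpy as np

#: distance key for alters beyond distance 3 or unreachable from the subject
FAR = 4

DEFAULT_QUOTAS = (5, 10, 15)


@dataclass
class StimulusSample:
    """A subject's tailored set of alters for the knowledge task."""

    subject: Hashable
    members: list
    #: members actually taken at distance 1, 2, 3, and beyond-3/unreachable
    stratum_counts: tuple[int, int, int, int]
    true_friend_pairs: int
    feasibility_flags: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


def distance_strata(net: nx.Graph, subject: Hashable) -> dict[int, set]:
    """Group alters by unweighted shortest-path distance from the subject.

    Keys 1, 2, 3 hold alters at those exact distances; key ``FAR`` (=4) holds
    alters at distance > 3 or unreachable.
    """
    if subject not in net:
        raise ValueError(f"subject {subject!r} not in network")
    lengths = nx.single_source_shortest_path_length(net, subject)
    strata: dict[int, set] = {1: set(), 2: set(), 3: set(), FAR: set()}
    for node in net.nodes():
        if node == subject:
            continue
        d = lengths.get(node)
        strata[d if d in (1, 2, 3) else FAR].add(node)
    return strata


def _adjacency(net: nx.Graph) -> tuple[np.ndarray, dict]:
    nodes = sorted(net.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    a = nx.to_numpy_array(net, nodelist=nodes, dtype=bool)
    return a, index


def count_friend_pairs(net: nx.Graph, members: Sequence[Hashable]) -> int:
    """Number of network edges among a set of members (brute pair count)."""
    a, index = _adjacency(net)
    idx = [index[m] for m in members]
    return int(a[np.ix_(idx, idx)].sum() // 2)


def _draw_candidate(
    strata: dict[int, set],
    quotas: Sequence[int],
    sample_size: int,
    rng: np.random.Generator,
) -> tuple[list, tuple[int, int, int, int]]:
    """One random quota-respecting draw with backfill for short strata.

    Shortfalls in a stratum are backfilled from the nearest richer stratum:
    leftover distance-2 alters first, then distance-3, then anything farther
    (unreachable nodes last).
    """
    pools = {d: sorted(strata[d], key=str) for d in (1, 2, 3, FAR)}
    chosen: list = []
    for d, quota in zip((1, 2, 3), quotas):
        pool = pools[d]
        take = min(quota, len(pool))
        picked = rng.choice(len(pool), size=take, replace=False) if take else []
        picked_set = {pool[i] for i in picked}
        chosen.extend(sorted(picked_set, key=str))
        pools[d] = [v for v in pool if v not in picked_set]
    # shortfalls: nearest richer strata first (2 then 3), then distance-1
    # leftovers, with unreachable/far nodes as the last resort
    deficit = sample_size - len(chosen)
    for d in (2, 3, 1, FAR):
        if deficit <= 0:
            break
        pool = pools[d]
        take = min(deficit, len(pool))
        if take:
            picked = rng.choice(len(pool), size=take, replace=False)
            picked_set = {pool[i] for i in picked}
            chosen.extend(sorted(picked_set, key=str))
            pools[d] = [v for v in pool if v not in picked_set]
            deficit -= take
    counts = [0, 0, 0, 0]
    for member in chosen:
        for slot, d in enumerate((1, 2, 3, FAR)):
            if member in strata[d]:
                counts[slot] += 1
                break
    return chosen, tuple(counts)


def candidate_stream(
    net: nx.Graph,
    subject: Hashable,
    quotas: Sequence[int] = DEFAULT_QUOTAS,
    n_iter: int = 1000,
    seed: int = 0,
) -> Iterator[tuple[list, tuple[int, int, int, int]]]:
    """The seeded stream of random candidate samples for one subject.

    Exposed so the selection rule can be audited: replaying the stream with
    the same seed reproduces exactly the candidates the sampler scored.
    """
    sample_size = int(sum(quotas))
    if net.number_of_nodes() < sample_size + 1:
        raise ValueError(
            f"network has {net.number_of_nodes()} nodes; "
            f"need at least {sample_size + 1} for a sample of {sample_size}"
        )
    strata = distance_strata(net, subject)
    rng = np.random.default_rng(seed)
    for _ in range(n_iter):
        yield _draw_candidate(strata, quotas, sample_size, rng)


def _members_all_have_friend(a: np.ndarray, idx: list[int]) -> bool:
    sub = a[np.ix_(idx, idx)]
    return bool(sub.any(axis=1).all())


def select_stimulus_sample(
    net: nx.Graph,
    subject: Hashable,
    quotas: Sequence[int] = DEFAULT_QUOTAS,
    n_iter: int = 1000,
    seed: int = 0,
    global_target: float | None = None,
) -> StimulusSample:
    """Pick the subject's stimulus sample by base-rate matching.

    Over ``n_iter`` seeded random quota-respecting draws, returns the
    candidate whose count of true friendships among members is closest to
    ``global_target`` (ties broken by draw order, so the sampler is
    deterministic given its arguments).  Whenever possible the chosen sample
    is restricted to candidates in which every member has at least one friend
    among the other members; if no candidate satisfies that, the best
    unrestricted candidate is returned and flagged.
    """
    if global_target is None:
        global_target = compute_global_target(net, [subject], quotas, n_iter, seed + 1)
    a, index = _adjacency(net)
    quota_total = int(sum(quotas))
    best = None  # (|delta|, order, members, counts, tfp, constraint_ok)
    best_unconstrained = None
    for order, (members, counts) in enumerate(
        candidate_stream(net, subject, quotas, n_iter, seed)
    ):
        idx = [index[m] for m in members]
        tfp = int(a[np.ix_(idx, idx)].sum() // 2)
        key = (abs(tfp - global_target), order)
        entry = (key, members, counts, tfp)
        if _members_all_have_friend(a, idx):
            if best is None or key < best[0]:
                best = entry
        if best_unconstrained is None or key < best_unconstrained[0]:
            best_unconstrained = entry
    constraint_met = best is not None
    key, members, counts, tfp = best if constraint_met else best_unconstrained
    return StimulusSample(
        subject=subject,
        members=list(members),
        stratum_counts=counts,
        true_friend_pairs=tfp,
        feasibility_flags={
            "friend_constraint_met": constraint_met,
            "quotas_met": counts[:3] == tuple(quotas) and sum(counts) == quota_total,
        },
    )


def compute_global_target(
    net: nx.Graph,
    subjects: Iterable[Hashable],
    quotas: Sequence[int] = DEFAULT_QUOTAS,
    n_iter: int = 1000,
    seed: int = 0,
) -> float:
    """Network-wide average true-friendship count in random samples.

    Mean over subjects of the mean true-friendship count across that
    subject's ``n_iter`` random quota-respecting samples; used as the
    base-rate matching target for sample selection.
    """
    a, index = _adjacency(net)
    subject_means = []
    seeds = np.random.SeedSequence(seed).spawn(len(list_subjects := list(subjects)))
    for subject, ss in zip(list_subjects, seeds):
        child_seed = int(ss.generate_state(1)[0] % (2**31))
        total = 0
        for members, _ in candidate_stream(net, subject, quotas, n_iter, child_seed):
            idx = [index[m] for m in members]
            total += int(a[np.ix_(idx, idx)].sum() // 2)
        subject_means.append(total / n_iter)
    if not subject_means:
        raise ValueError("no subjects given")
    return float(np.mean(subject_means))


def enumerate_trials(sample: StimulusSample) -> list[tuple[Hashable, Hashable]]:
    """Ordered (block_target, probe) trial list for one sample.

    One block per member; within a block every other member is probed once,
    so each unordered pair is judged exactly twice, once in each direction.
    For the default 30-member sample this is 870 trials over 435 pairs.
    """
    return [
        (target, probe)
        for target in sample.members
        for probe in sample.members
        if probe != target
    ]


#: raw ratings that bin to "friends"
_POSITIVE = {"friends", "friend", "likely", "very likely", "very_likely"}
_NEGATIVE = {"not friends", "not_friends", "not-friends", "unlikely",
             "very unlikely", "very_unlikely"}


def bin_response(raw_rating: str) -> int:
    """Bin a raw rating to a binary friendship guess.

    The binary dialect ("friends"/"not friends") passes through; on the
    4-point likelihood scale, "likely" and "very likely" bin to 1 and
    "unlikely"/"very unlikely" bin to 0.
    """
    token = str(raw_rating).strip().lower()
    if token in _POSITIVE:
        return 1
    if token in _NEGATIVE:
        return 0
    raise ValueError(f"unknown rating category: {raw_rating!r}")
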