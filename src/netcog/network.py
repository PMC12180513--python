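"""Per-wave mutual-friendship networks, centrality, and stability measures.

A friendship is an undirected tie that exists only when two subjects mutually
nominate each other as friends in the same roster survey wave.  Two centrality
measures are tracked across waves: *friend count* (degree) and *influence*
(eigenvector centrality, rescaled so the most influential node scores exactly 1).
Network change over time is summarised by the Jaccard similarity of edge sets
and by Spearman rank correlations of centrality between waves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: survey categories that count as a friendship nomination
FRIEND_RESPONSES = frozenset({"friend", "friends"})
#: categories normalised to "not a friend" (binary and 4-level survey dialects)
NOT_FRIEND_RESPONSES = frozenset(
    {"not-friend", "not_friend", "not friends", "acquaintance", "recognize", "unknown",
     "do not know", "do_not_know"}
)


class SurveyValidationError(ValueError):
    """Raised when roster survey records violate the survey contract."""


def normalize_response(response: str) -> str:
    """Map a survey response from either dialect onto {friend, not-friend}."""
    token = str(response).strip().lower()
    if token in FRIEND_RESPONSES:
        return "friend"
    if token in NOT_FRIEND_RESPONSES:
        return "not-friend"
    raise SurveyValidationError(f"unknown survey response category: {response!r}")


@dataclass
class RosterSurveyWave:
    """One wave of roster friendship-survey responses.

    Parameters
    ----------
    wave_id:
        Ordinal wave index (1-based).
    records:
        ``(rater, ratee, response)`` triples; at most one record per ordered
        pair, and never a self-rating.
    """

    wave_id: int
    records: list[tuple[Hashable, Hashable, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[Hashable, Hashable]] = set()
        for rater, ratee, _ in self.records:
            if rater == ratee:
                raise SurveyValidationError(
                    f"wave {self.wave_id}: self-rating by subject {rater!r}"
                )
            key = (rater, ratee)
            if key in seen:
                raise SurveyValidationError(
                    f"wave {self.wave_id}: duplicate record for ordered pair "
                    f"({rater!r}, {ratee!r})"
                )
            seen.add(key)

    @property
    def raters(self) -> set[Hashable]:
        return {r for r, _, _ in self.records}


def build_network(survey: RosterSurveyWave) -> nx.Graph:
    """Build the undirected mutual-friendship network for one survey wave.

    An edge {a, b} exists iff a nominated b as a friend *and* b nominated a.
    Every subject who submitted the wave's survey is a node, including subjects
    who end up with no mutual friendships (they are retained, degree 0).
    """
    net = nx.Graph(wave_id=survey.wave_id)
    net.add_nodes_from(survey.raters)
    nominated: set[tuple[Hashable, Hashable]] = set()
    for rater, ratee, response in survey.records:
        if normalize_response(response) == "friend":
            if (ratee, rater) in nominated:
                net.add_edge(rater, ratee)
            nominated.add((rater, ratee))
    return net


def degree_centrality(net: nx.Graph) -> dict[Hashable, int]:
    """Friend count: number of mutual friendships per subject."""
    return {node: deg for node, deg in net.degree()}


def influence_centrality(
    net: nx.Graph,
    *,
    tol: float = 1e-13,
    max_iter: int = 100_000,
) -> dict[Hashable, float]:
    """Influence: eigenvector centrality rescaled so the maximum is exactly 1.

    The leading eigenvector of the adjacency matrix is computed by a
    deterministic shifted power iteration (``A + I``; the shift keeps the
    iteration convergent on bipartite components without changing the
    eigenvectors).  On a disconnected network the vector is supported on the
    spectrally dominant component; nodes elsewhere receive values near 0.

    Raises
    ------
    ValueError
        If the network has no edges (the measure is undefined).
    """
    if net.number_of_edges() == 0:
        raise ValueError("no edges: influence undefined")
    nodes = sorted(net.nodes())
    a = nx.to_numpy_array(net, nodelist=nodes)
    n = len(nodes)
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        y = a @ x + x  # shifted: (A + I) x
        y /= np.linalg.norm(y)
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    x = np.clip(x, 0.0, None)
    x /= x.max()
    return dict(zip(nodes, x.tolist()))


def centrality_change(
    early: Mapping[Hashable, float],
    late: Mapping[Hashable, float],
) -> dict[Hashable, float]:
    """Late-minus-early change scores for subjects present in both waves.

    Subjects missing from either wave are omitted (and logged): a change score
    is only defined for subjects observed at both time points.
    """
    common = set(early) & set(late)
    dropped = (set(early) | set(late)) - common
    if dropped:
        log.info("centrality_change: omitting %d subjects absent from one wave", len(dropped))
    return {s: late[s] - early[s] for s in common}


def jaccard_stability(net_a: nx.Graph, net_b: nx.Graph) -> float:
    """Jaccard similarity of two waves' edge sets.

    The proportion of friendships consistent between the two time points,
    relative to the total number of unique friendships observed across both:
    ``|E_A ∩ E_B| / |E_A ∪ E_B|``.
    """
    edges_a = {frozenset(e) for e in net_a.edges()}
    edges_b = {frozenset(e) for e in net_b.edges()}
    union = edges_a | edges_b
    if not union:
        raise ValueError("both edge sets empty: Jaccard similarity undefined")
    return len(edges_a & edges_b) / len(union)


def rank_stability(
    metric_a: Mapping[Hashable, float],
    metric_b: Mapping[Hashable, float],
) -> float:
    """Spearman rank correlation of a centrality metric between two waves.

    Restricted to subjects present at both waves; ties receive average ranks.
    """
    common = sorted(set(metric_a) & set(metric_b))
    if len(common) < 3:
        raise ValueError(
            f"rank stability needs >=3 common subjects, got {len(common)}"
        )
    rho, _ = stats.spearmanr([metric_a[s] for s in common], [metric_b[s] for s in common])
    return float(rho)


def stability_matrices(networks: Sequence[nx.Graph]) -> dict[str, pd.DataFrame]:
    """All-pairs stability matrices across a sequence of wave networks.

    Returns a dict with keys ``jaccard_edges``, ``spearman_influence`` and
    ``spearman_friend_count``; each value is a symmetric wave-by-wave
    DataFrame with unit diagonal.
    """
    waves = [net.graph.get("wave_id", i + 1) for i, net in enumerate(networks)]
    influence = []
    friend_count = []
    for net in networks:
        friend_count.append(degree_centrality(net))
        influence.append(influence_centrality(net) if net.number_of_edges() else {})
    out = {
        name: pd.DataFrame(np.eye(len(networks)), index=waves, columns=waves)
        for name in ("jaccard_edges", "spearman_influence", "spearman_friend_count")
    }
    for i in range(len(networks)):
        for j in range(i + 1, len(networks)):
            jac = jaccard_stability(networks[i], networks[j])
            rho_inf = rank_stability(influence[i], influence[j])
            rho_deg = rank_stability(friend_count[i], friend_count[j])
            for name, value in (
                ("jaccard_edges", jac),
                ("spearman_influence", rho_inf),
                ("spearman_friend_count", rho_deg),
            ):
                out[name].iloc[i, j] = value
                out[name].iloc[j, i] = value
    return out


def centrality_table(networks: Iterable[nx.Graph]) -> pd.DataFrame:
    """Long-format per-subject centrality table across waves.

    Columns: subject, wave, friend_count, influence.  Degree-0 subjects are
    retained in the graph but get ``NaN`` influence (they are excluded from
    centrality summaries, matching the convention of reporting centrality only
    for members of the mutual-friendship network).
    """
    rows = []
    for net in networks:
        wave = net.graph.get("wave_id")
        degrees = degree_centrality(net)
        influence = influence_centrality(net) if net.number_of_edges() else {}
        for node in sorted(net.nodes()):
            deg = degrees[node]
            rows.append(
                {
                    "subject": node,
                    "wave": wave,
                    "friend_count": deg,
                    "influence": influence.get(node, np.nan) if deg > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["subject", "wave", "friend_count", "influence"])
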