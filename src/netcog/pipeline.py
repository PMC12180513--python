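"""End-to-end orchestration of the longitudinal knowledge-centrality analysis.

Stages: build per-wave mutual networks -> centrality and stability ->
consensus communities -> (synthetic only) stimulus sampling and response
simulation -> subject-level knowledge fits and exclusions -> group-level
models.  Each run writes its artifacts plus a manifest recording seeds,
parameters and per-stage counts, and is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import communities as comm
from . import io as nio
from . import models as km
from . import network as netcore
from . import synth
from . import task as ktask

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Either ``survey_csv``/``responses_csv`` point at real long-format data, or
    ``synthetic=True`` generates a cohort first.  The analysis compares an
    early (fall) and a late (spring) wave; the default pair (2, 4) matches
    the two waves at which the knowledge task is administered.
    """

    synthetic: bool = True
    survey_csv: str | None = None
    responses_csv: str | None = None
    extroversion_csv: str | None = None
    wave_pair: tuple[int, int] = (2, 4)
    out_dir: str = "results/pipeline"
    seed: int = 0
    # knowledge-task sampling
    quotas: tuple[int, int, int] = (5, 10, 15)
    sampler_iters: int = 100
    n_knowledge_fall: int = 100
    n_knowledge_spring: int = 80
    # consensus detection
    min_community_size: int = 5
    # synthetic cohort
    synthetic_config: synth.SyntheticConfig = field(default_factory=synth.SyntheticConfig)
    verbosity: int = 1

    def __post_init__(self) -> None:
        early, late = self.wave_pair
        if not early < late:
            raise ValueError(f"wave pair must be ordered, got {self.wave_pair}")


def _load_config_file(path: str | Path) -> dict:
    """Parse a flat key=value config file (blank lines and # comments ignored)."""
    values: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, value = line.split("=", 1)
        values[key.strip()] = value.strip()
    return values


def config_from_file(path: str | Path, **overrides) -> PipelineConfig:
    raw = _load_config_file(path)
    kwargs: dict = {}
    synth_kwargs: dict = {}
    synth_fields = {f.name: f for f in dataclasses.fields(synth.SyntheticConfig)}
    cfg_fields = {f.name: f for f in dataclasses.fields(PipelineConfig)}

    def _coerce(value: str, sample):
        if isinstance(sample, bool):
            return value.lower() in {"1", "true", "yes"}
        if isinstance(sample, int):
            return int(value)
        if isinstance(sample, float):
            return float(value)
        if isinstance(sample, tuple):
            return tuple(type(sample[0])(v) for v in value.split(","))
        return value

    defaults_cfg = PipelineConfig()
    defaults_synth = synth.SyntheticConfig()
    for key, value in raw.items():
        if key.startswith("synthetic.") and key.split(".", 1)[1] in synth_fields:
            name = key.split(".", 1)[1]
            synth_kwargs[name] = _coerce(value, getattr(defaults_synth, name))
        elif key in cfg_fields and key != "synthetic_config":
            kwargs[key] = _coerce(value, getattr(defaults_cfg, key))
        else:
            raise ValueError(f"unknown config key: {key}")
    kwargs.update(overrides)
    if synth_kwargs:
        kwargs["synthetic_config"] = synth.SyntheticConfig(**synth_kwargs)
    return PipelineConfig(**kwargs)


def _stage(manifest: dict, name: str, **counts) -> None:
    manifest["stages"].append({"stage": name, **counts})
    log.info("stage %s: %s", name, counts)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "wave_pair": list(config.wave_pair),
        "synthetic": config.synthetic,
        "parameters": {
            "quotas": list(config.quotas),
            "sampler_iters": config.sampler_iters,
            "min_community_size": config.min_community_size,
        },
        "stages": [],
    }
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10]))
    early_wave, late_wave = config.wave_pair

    # stage 1: surveys -> mutual networks
    truths = None
    if config.synthetic:
        scfg = dataclasses.replace(config.synthetic_config, seed=config.seed)
        manifest["parameters"]["synthetic_config"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(scfg).items()
        }
        truths = synth.generate_ground_truth(scfg)
        networks, _ = synth.generate_longitudinal_network(scfg, truths)
        surveys = synth.surveys_from_networks(networks)
        nio.write_survey_csv(surveys, out / "surveys.csv")
        truths.to_csv(out / "agent_ground_truth.csv", index=False)
    else:
        if not config.survey_csv or not Path(config.survey_csv).exists():
            raise FileNotFoundError(
                f"stage build_networks: survey file not found: {config.survey_csv!r}"
            )
        surveys = list(nio.read_survey_csv(config.survey_csv).values())
        networks = None
    networks = [netcore.build_network(s) for s in surveys]
    by_wave = {net.graph["wave_id"]: net for net in networks}
    for wave, net in by_wave.items():
        if wave not in (early_wave, late_wave):
            continue
        nio.write_graphml(net, out / f"network_wave{wave}.graphml")
    _stage(
        manifest, "build_networks",
        n_waves=len(networks),
        nodes={w: g.number_of_nodes() for w, g in by_wave.items()},
        edges={w: g.number_of_edges() for w, g in by_wave.items()},
    )
    if early_wave not in by_wave or late_wave not in by_wave:
        raise ValueError(f"stage build_networks: wave pair {config.wave_pair} not in surveys")

    # stage 2: centrality and stability
    metrics = netcore.centrality_table(networks)
    metrics.to_csv(out / "node_metrics.csv", index=False)
    stability = netcore.stability_matrices(networks)
    for name, mat in stability.items():
        mat.to_csv(out / f"stability_{name}.csv")
    early_net, late_net = by_wave[early_wave], by_wave[late_wave]
    influence = {
        w: netcore.influence_centrality(by_wave[w]) for w in (early_wave, late_wave)
    }
    friend_count = {
        w: netcore.degree_centrality(by_wave[w]) for w in (early_wave, late_wave)
    }
    delta_influence = netcore.centrality_change(influence[early_wave], influence[late_wave])
    delta_friends = netcore.centrality_change(friend_count[early_wave], friend_count[late_wave])
    _stage(
        manifest, "centrality_stability",
        n_change_subjects=len(delta_influence),
        jaccard_pair=netcore.jaccard_stability(early_net, late_net),
    )

    # stage 3: consensus communities per analysis wave
    consensus: dict[int, comm.ConsensusCommunities] = {}
    meso: dict[int, comm.MesoTieMatrix] = {}
    for wave in (early_wave, late_wave):
        parts = comm.run_base_partitions(
            by_wave[wave],
            comm.ConsensusConfig(min_size=config.min_community_size, seed=config.seed),
        )
        consensus[wave] = comm.consensus_communities(parts, config.min_community_size)
        meso[wave] = comm.meso_ties(consensus[wave])
        membership = consensus[wave].membership()
        pd.DataFrame(
            [
                {"subject": s, "wave": wave, "community_id": c if c is not None else "NA"}
                for s, c in sorted(membership.items(), key=lambda kv: str(kv[0]))
            ]
        ).to_csv(out / f"communities_wave{wave}.csv", index=False)
    _stage(
        manifest, "consensus_communities",
        n_communities={w: len(c.communities) for w, c in consensus.items()},
        n_unassigned={w: len(c.unassigned) for w, c in consensus.items()},
        unassigned_fraction={
            w: round(len(c.unassigned) / by_wave[w].number_of_nodes(), 4)
            for w, c in consensus.items()
        },
    )

    # stage 4: knowledge-task responses (simulate for synthetic; load for real)
    responses: dict[int, pd.DataFrame] = {}
    if config.synthetic:
        all_subjects = sorted(by_wave[early_wave].nodes())
        n_fall = min(config.n_knowledge_fall, len(all_subjects))
        fall_subjects = list(
            rng.choice(all_subjects, size=n_fall, replace=False)
        )
        spring_pool = [s for s in fall_subjects if s in by_wave[late_wave]]
        n_spring = min(config.n_knowledge_spring, len(spring_pool))
        spring_subjects = list(rng.choice(spring_pool, size=n_spring, replace=False))
        for wave, subjects in ((early_wave, fall_subjects), (late_wave, spring_subjects)):
            net = by_wave[wave]
            target = ktask.compute_global_target(
                net, subjects, config.quotas, n_iter=config.sampler_iters,
                seed=int(rng.integers(2**31)),
            )
            samples = [
                ktask.select_stimulus_sample(
                    net, s, config.quotas, n_iter=config.sampler_iters,
                    seed=int(rng.integers(2**31)), global_target=target,
                )
                for s in subjects
            ]
            pd.DataFrame(
                [
                    {"subject": smp.subject, "member": m, "wave": wave}
                    for smp in samples
                    for m in smp.members
                ]
            ).to_csv(out / f"samples_wave{wave}.csv", index=False)
            resp = synth.simulate_agent_responses(
                net, consensus[wave].membership(), truths, samples,
                seed=int(rng.integers(2**31)),
            )
            resp.insert(0, "wave", wave)
            responses[wave] = resp
        nio.write_responses_csv(pd.concat(responses.values()), out / "responses.csv")
    else:
        if not config.responses_csv or not Path(config.responses_csv).exists():
            raise FileNotFoundError(
                f"stage knowledge_task: responses file not found: {config.responses_csv!r}"
            )
        all_resp = nio.read_responses_csv(config.responses_csv)
        for wave in (early_wave, late_wave):
            responses[wave] = all_resp[all_resp["wave"] == wave].copy()
    _stage(
        manifest, "knowledge_task",
        n_trials={w: len(r) for w, r in responses.items()},
        n_subjects={w: r["subject"].nunique() for w, r in responses.items()},
    )

    # stage 5: subject-level knowledge fits + exclusions
    knowledge: dict[int, list[km.SubjectKnowledge]] = {}
    for wave in (early_wave, late_wave):
        design = km.build_design(responses[wave], by_wave[wave], meso[wave])
        estimates = [
            km.fit_subject_knowledge(group, subject=subj, wave=wave, min_trials=0)
            for subj, group in design.groupby("subject", sort=True)
        ]
        knowledge[wave] = km.exclude_outliers(estimates)
        km.knowledge_frame(knowledge[wave]).to_csv(
            out / f"subject_knowledge_wave{wave}.csv", index=False
        )
    _stage(
        manifest, "subject_knowledge",
        n_fit={w: len(k) for w, k in knowledge.items()},
        n_excluded={w: sum(e.excluded for e in k) for w, k in knowledge.items()},
        exclusion_reasons={
            w: sorted({e.reason for e in k if e.excluded}) for w, k in knowledge.items()
        },
    )

    # stage 6: group-level models
    fall_k, spring_k = knowledge[early_wave], knowledge[late_wave]
    controls = pd.DataFrame(
        {"fall_friend_count": pd.Series(friend_count[early_wave], dtype=float)}
    )
    if config.synthetic:
        controls = controls.join(
            truths.set_index("subject")["extroversion"], how="left"
        )
    elif config.extroversion_csv and Path(config.extroversion_csv).exists():
        extro = pd.read_csv(config.extroversion_csv).set_index("subject")["extroversion"]
        controls = controls.join(extro, how="left")
    results: dict[str, km.GroupModelResult] = {}
    results["change_influence_M1"] = km.fit_change_model(
        fall_k, delta_influence, "delta_influence"
    )
    results["change_influence_M2"] = km.fit_change_model(
        fall_k, delta_influence, "delta_influence", controls=controls
    )
    results["change_friend_count_M3"] = km.fit_change_model(
        fall_k, delta_friends, "delta_friend_count"
    )
    results["current_fall_influence_M1"] = km.fit_current_model(
        fall_k, influence[early_wave], "fall_influence", season="fall", model_id="current_M1"
    )
    results["current_spring_influence_M2"] = km.fit_current_model(
        spring_k, influence[late_wave], "spring_influence", season="spring", model_id="current_M2"
    )
    results["current_fall_friend_count_M3"] = km.fit_current_model(
        fall_k, {k: float(v) for k, v in friend_count[early_wave].items()},
        "fall_friend_count", season="fall", model_id="current_M3",
    )
    results["current_spring_friend_count_M4"] = km.fit_current_model(
        spring_k, {k: float(v) for k, v in friend_count[late_wave].items()},
        "spring_friend_count", season="spring", model_id="current_M4",
    )
    results["interaction_M1"] = km.fit_interaction_model(
        fall_k, spring_k, influence[late_wave], full=False
    )
    results["interaction_M2"] = km.fit_interaction_model(
        fall_k, spring_k, influence[late_wave], full=True
    )
    nio.write_results_json(results, out / "group_models.json")
    _stage(
        manifest, "group_models",
        n_models=len(results),
        n_subjects={name: res.n_subjects for name, res in results.items()},
    )

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest
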