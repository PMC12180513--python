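"""Readers and writers for the pipeline's text formats.

Survey and response tables travel as long-format UTF-8 CSV with headers;
networks as GraphML; model summaries and manifests as JSON.  Readers validate
as they parse and report malformed rows by line number, and every writer's
output is re-readable by the matching reader (lossless round trip on
canonicalised records).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .models import GroupModelResult
from .network import RosterSurveyWave, SurveyValidationError, normalize_response
from .task import bin_response

SURVEY_COLUMNS = ["wave", "rater", "ratee", "response"]
RESPONSE_COLUMNS = ["wave", "subject", "block_target", "probe", "rating"]


class ParseError(ValueError):
    """Malformed input row; message carries the file path and line number."""


def read_survey_csv(path: str | Path) -> dict[int, RosterSurveyWave]:
    """Read roster survey records, one `RosterSurveyWave` per wave.

    Expected header: ``wave,rater,ratee,response``.  Both survey dialects are
    accepted (binary friend/not-friend and the 4-category roster); categories
    are validated here and normalised downstream.
    """
    path = Path(path)
    by_wave: dict[int, list] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != SURVEY_COLUMNS:
            raise ParseError(
                f"{path}:1: expected header {','.join(SURVEY_COLUMNS)}, "
                f"got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                wave = int(row["wave"])
                rater = row["rater"].strip()
                ratee = row["ratee"].strip()
                normalize_response(row["response"])
            except (TypeError, ValueError, AttributeError, SurveyValidationError) as err:
                raise ParseError(f"{path}:{lineno}: {err}") from err
            if not rater or not ratee:
                raise ParseError(f"{path}:{lineno}: empty rater or ratee id")
            by_wave.setdefault(wave, []).append((rater, ratee, row["response"].strip()))
    return {
        wave: RosterSurveyWave(wave_id=wave, records=records)
        for wave, records in sorted(by_wave.items())
    }


def write_survey_csv(surveys: Iterable[RosterSurveyWave], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SURVEY_COLUMNS)
        for survey in surveys:
            for rater, ratee, response in survey.records:
                writer.writerow([survey.wave_id, rater, ratee, response])


def read_responses_csv(path: str | Path) -> pd.DataFrame:
    """Read knowledge-task responses; adds a binary ``guess`` column.

    Expected header: ``wave,subject,block_target,probe,rating``.  Ratings may
    come from either task dialect (binary or 4-point likelihood scale).
    """
    path = Path(path)
    rows = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != RESPONSE_COLUMNS:
            raise ParseError(
                f"{path}:1: expected header {','.join(RESPONSE_COLUMNS)}, "
                f"got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                rows.append(
                    {
                        "wave": int(row["wave"]),
                        "subject": row["subject"].strip(),
                        "block_target": row["block_target"].strip(),
                        "probe": row["probe"].strip(),
                        "rating": row["rating"].strip(),
                        "guess": bin_response(row["rating"]),
                    }
                )
            except (TypeError, ValueError, AttributeError) as err:
                raise ParseError(f"{path}:{lineno}: {err}") from err
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS + ["guess"])


def write_responses_csv(responses: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = responses.copy()
    if "rating" not in out.columns:
        out["rating"] = out["guess"].map({1: "friends", 0: "not friends"})
    out[RESPONSE_COLUMNS].to_csv(path, index=False)


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(net, path)


def read_graphml(path: str | Path) -> nx.Graph:
    net = nx.read_graphml(Path(path))
    if "wave_id" in net.graph:
        net.graph["wave_id"] = int(net.graph["wave_id"])
    return net


def group_result_dict(result: GroupModelResult) -> dict:
    """JSON-ready summary of one group model (term, beta, CI, p)."""
    return {
        "model_id": result.model_id,
        "outcome": result.outcome,
        "n_subjects": result.n_subjects,
        "terms": [
            {
                "term": t.name,
                "beta": t.beta,
                "ci_low": t.ci_low,
                "ci_high": t.ci_high,
                "p_value": t.p_value,
            }
            for t in result.terms
        ],
    }


def write_results_json(results: Mapping[str, GroupModelResult], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {name: group_result_dict(res) for name, res in results.items()}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")


def read_results_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
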