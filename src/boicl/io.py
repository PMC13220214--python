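"""Readers and writers for the plain-text campaign formats.

Pools are JSONL (one object per line: ``id``, ``text``, optional
``params``); seed labels and oracle tables are CSV with header
``id,label``; trajectories are CSV; memory snapshots and manifests are
JSON. Embeddings are re-derived from text on read, never persisted.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .campaign import TrajectoryRecord
from .memory import Candidate, Pool
from .retrieval import EmbeddingProvider

TRAJECTORY_COLUMNS = [
    "iteration", "candidate_id", "predicted_mu", "predicted_sigma",
    "observed_label", "best_so_far",
]


def read_pool_jsonl(path: str | Path, embedder: EmbeddingProvider) -> Pool:
    candidates = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            if "id" not in obj or "text" not in obj:
                raise ValueError(f"{path}:{line_no}: pool rows need 'id' and 'text'")
            candidates.append(
                Candidate(str(obj["id"]), obj["text"], embedder.embed(obj["text"]))
            )
    return Pool(candidates, provenance=str(path))


def write_pool_jsonl(pool: Pool, path: str | Path, params: dict[str, dict] | None = None) -> None:
    with open(path, "w") as fh:
        for cand in pool:
            obj: dict = {"id": cand.id, "text": cand.text}
            if params and cand.id in params:
                obj["params"] = params[cand.id]
            fh.write(json.dumps(obj) + "\n")


def read_labels_csv(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, dtype={"id": str})
    if not {"id", "label"}.issubset(df.columns):
        raise ValueError(f"{path}: labels CSV needs columns 'id,label'")
    return dict(zip(df["id"], df["label"].astype(float)))


def write_labels_csv(labels: dict[str, float], path: str | Path) -> None:
    pd.DataFrame({"id": list(labels), "label": list(labels.values())}).to_csv(
        path, index=False
    )


def trajectory_to_frame(trajectory: Sequence[TrajectoryRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(rec) for rec in trajectory], columns=TRAJECTORY_COLUMNS)


def write_trajectory_csv(trajectory: Sequence[TrajectoryRecord], path: str | Path) -> None:
    trajectory_to_frame(trajectory).to_csv(path, index=False, float_format="%.10g")


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"candidate_id": str})
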