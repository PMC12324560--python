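"""Plain-text persistence: cohort CSV, TSV matrices, feature CSVs, manifest.

One directory per cohort: ``cohort.csv`` (subject_id, family_id, sex, age,
targets, holdout), ``sc/<subject>.tsv`` and ``ts/<subject>.tsv`` matrices,
``distances.tsv`` / ``coords.csv``, and ``manifest.json`` recording shapes,
the generating seed/spec and the file list.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .connectivity import edge_labels
from .types import Cohort, ParcellatedTimeSeries, StructuralConnectome

__all__ = [
    "save_matrix",
    "load_matrix",
    "save_cohort",
    "load_cohort",
    "save_feature_csv",
]


def save_matrix(path: str | Path, matrix: np.ndarray) -> None:
    np.savetxt(path, np.asarray(matrix), delimiter="\t", fmt="%.10g")


def load_matrix(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


def save_cohort(cohort: Cohort, out_dir: str | Path,
                extra_manifest: Mapping | None = None) -> Path:
    out = Path(out_dir)
    (out / "ts").mkdir(parents=True, exist_ok=True)
    (out / "sc").mkdir(exist_ok=True)
    cohort.table.to_csv(out / "cohort.csv", index=False)
    files: dict[str, dict] = {}
    for i, sid in enumerate(cohort.subject_ids):
        if cohort.timeseries:
            ts = cohort.timeseries[i]
            save_matrix(out / "ts" / f"{sid}.tsv", ts.data)
            files[f"ts/{sid}.tsv"] = {
                "shape": list(ts.data.shape),
                "tr": ts.tr,
                "session_lengths": list(ts.session_lengths),
            }
        if cohort.connectomes:
            save_matrix(out / "sc" / f"{sid}.tsv", cohort.connectomes[i].weights)
            files[f"sc/{sid}.tsv"] = {
                "shape": list(cohort.connectomes[i].weights.shape)
            }
    if cohort.distances is not None:
        save_matrix(out / "distances.tsv", cohort.distances)
    if cohort.coords is not None:
        cohort.coords.to_csv(out / "coords.csv", index=False)
    manifest = {
        "n_subjects": int(cohort.n_subjects),
        "files": files,
        **(dict(extra_manifest) if extra_manifest else {}),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def load_cohort(in_dir: str | Path) -> Cohort:
    src = Path(in_dir)
    table = pd.read_csv(src / "cohort.csv")
    manifest = json.loads((src / "manifest.json").read_text())
    distances = (
        load_matrix(src / "distances.tsv")
        if (src / "distances.tsv").exists() else None
    )
    coords = (
        pd.read_csv(src / "coords.csv") if (src / "coords.csv").exists() else None
    )
    timeseries, connectomes = [], []
    for sid in table["subject_id"]:
        ts_meta = manifest["files"].get(f"ts/{sid}.tsv")
        if ts_meta is not None:
            timeseries.append(
                ParcellatedTimeSeries(
                    data=load_matrix(src / "ts" / f"{sid}.tsv"),
                    tr=float(ts_meta["tr"]),
                    session_lengths=ts_meta["session_lengths"],
                    subject_id=str(sid),
                )
            )
        if (src / "sc" / f"{sid}.tsv").exists():
            connectomes.append(
                StructuralConnectome(
                    weights=load_matrix(src / "sc" / f"{sid}.tsv"),
                    distances=distances,
                    subject_id=str(sid),
                )
            )
    return Cohort(
        table=table,
        timeseries=timeseries,
        connectomes=connectomes,
        distances=distances,
        coords=coords,
    )


def save_feature_csv(
    path: str | Path,
    feature_name: str,
    values: np.ndarray,
    subject_ids,
    n_regions: int | None = None,
) -> None:
    """Feature matrix as CSV (rows = subjects) with a JSON sidecar.

    Edge-wise features get 'i_j' 1-based edge-label columns, region-wise
    ones 'r<k>' columns.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if n_regions is not None and values.shape[1] == n_regions * (n_regions - 1) // 2:
        cols = edge_labels(n_regions)
    else:
        cols = [f"r{k + 1}" for k in range(values.shape[1])]
    df = pd.DataFrame(values, columns=cols)
    df.insert(0, "subject_id", list(subject_ids))
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = {
        "feature": feature_name,
        "dim": int(values.shape[1]),
        "n_subjects": int(values.shape[0]),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
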