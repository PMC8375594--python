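"""Plain-text persistence for cohorts and reports.

A cohort directory holds ``morphometry.csv`` (one row per subject, columns
``<REGION>_<measure>``), per-subject/band time-series TSV matrices under
``timeseries/``, and ``manifest.json`` with ids, groups and the generating
configuration.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .atlases import DK68_LABELS
from .cohort import CohortConfig, SubjectRecord

_MEASURE_ATTR = {"thickness": "thickness", "volume": "volume", "area": "area"}


def _config_to_jsonable(config: CohortConfig) -> dict:
    raw = dataclasses.asdict(config)
    raw["struct_effect"] = {
        g: {f"{region}:{measure}": shift for (region, measure), shift in eff.items()}
        for g, eff in config.struct_effect.items()
    }
    raw["conn_effect"] = {
        g: [[list(nodes), delta] for nodes, delta in pert]
        for g, pert in config.conn_effect.items()
    }
    raw["n_per_group"] = dict(config.n_per_group)
    raw["bands"] = {k: list(v) for k, v in config.bands.items()}
    return raw


def save_cohort(cohort: Sequence[SubjectRecord], path, config: CohortConfig | None = None) -> None:
    path = Path(path)
    (path / "timeseries").mkdir(parents=True, exist_ok=True)

    rows = []
    for s in cohort:
        row: dict = {"subject_id": s.subject_id, "group": s.group}
        for measure, attr in _MEASURE_ATTR.items():
            values = getattr(s, attr)
            for label, v in zip(DK68_LABELS, values):
                row[f"{label}_{measure}"] = v
        rows.append(row)
        for band, ts in s.timeseries.items():
            np.savetxt(
                path / "timeseries" / f"{s.subject_id}_{band}.tsv", ts, delimiter="\t"
            )
    pd.DataFrame(rows).to_csv(path / "morphometry.csv", index=False)

    manifest = {
        "subjects": [{"subject_id": s.subject_id, "group": s.group} for s in cohort],
        "bands": sorted(cohort[0].timeseries) if cohort else [],
        "config": None if config is None else _config_to_jsonable(config),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_cohort(path) -> list[SubjectRecord]:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    morpho = pd.read_csv(path / "morphometry.csv").set_index("subject_id")
    subjects = []
    for entry in manifest["subjects"]:
        sid = entry["subject_id"]
        row = morpho.loc[sid]
        record = SubjectRecord(
            subject_id=sid,
            group=entry["group"],
            thickness=np.array([row[f"{lbl}_thickness"] for lbl in DK68_LABELS]),
            volume=np.array([row[f"{lbl}_volume"] for lbl in DK68_LABELS]),
            area=np.array([row[f"{lbl}_area"] for lbl in DK68_LABELS]),
            timeseries={
                band: np.loadtxt(path / "timeseries" / f"{sid}_{band}.tsv", delimiter="\t")
                for band in manifest["bands"]
            },
        )
        record.validate()
        subjects.append(record)
    return subjects
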