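"""File round-tripping for all modules.

Formats: sensor arrays in HDF5 (dataset ``amplitudes`` with ``dt`` and
``seed`` attributes), situation matrices as CSV (rows = situations,
columns = objects), dual data as paired CSVs sharing a sample-id column
with blanks for a missing channel, ground truth and fit results as JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .cones import ConeParams, ConeScene, SensorArrayData
from .dual import DualData, DualGenConfig, DualTruth
from .situations import SituationData, SituationTruth


# -- sensor arrays ----------------------------------------------------------


def save_sensor_array(path, data: SensorArrayData, seed: int | None = None) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("amplitudes", data=data.amplitudes)
        ds.attrs["dt"] = data.dt
        ds.attrs["dims"] = data.dims
        if seed is not None:
            ds.attrs["seed"] = seed


def load_sensor_array(path) -> SensorArrayData:
    with h5py.File(path, "r") as fh:
        ds = fh["amplitudes"]
        return SensorArrayData(ds[()], dt=float(ds.attrs.get("dt", 5.0)))


# -- cone scenes ------------------------------------------------------------


def save_cone_scene(path, scene: ConeScene) -> None:
    Path(path).write_text(json.dumps(asdict(scene), indent=1))


def load_cone_scene(path) -> ConeScene:
    d = json.loads(Path(path).read_text())
    return ConeScene(
        cones=[ConeParams(**c) for c in d["cones"]],
        noise_sd=d["noise_sd"],
        seed=d["seed"],
    )


# -- situation data ---------------------------------------------------------


def save_situations_csv(path, data: SituationData) -> None:
    pd.DataFrame(data.matrix, columns=data.column_labels).to_csv(path, index=False)


def load_situations_csv(path) -> SituationData:
    df = pd.read_csv(path)
    return SituationData(df.to_numpy(dtype=np.int8), list(df.columns))


def save_situation_truth(path, truth: SituationTruth) -> None:
    Path(path).write_text(json.dumps({
        "relevant_sets": truth.relevant_sets,
        "type_of_row": truth.type_of_row.tolist(),
        "marginal_rand": truth.marginal_rand,
    }, indent=1))


def load_situation_truth(path) -> SituationTruth:
    d = json.loads(Path(path).read_text())
    return SituationTruth(
        relevant_sets=[list(map(int, s)) for s in d["relevant_sets"]],
        type_of_row=np.asarray(d["type_of_row"], dtype=int),
        marginal_rand=float(d["marginal_rand"]),
    )


# -- dual data --------------------------------------------------------------


def save_dual_csv(path_language, path_cognition, data: DualData) -> None:
    n = data.cognition.shape[0]
    ids = np.arange(n)
    dl = pd.DataFrame(data.language,
                      columns=[f"L{i}" for i in range(data.language.shape[1])])
    dl.insert(0, "sample_id", ids)
    dl.to_csv(path_language, index=False)
    dc = pd.DataFrame(data.cognition.astype(int),
                      columns=[f"C{i}" for i in range(data.cognition.shape[1])])
    dc.insert(0, "sample_id", ids)
    dc.to_csv(path_cognition, index=False)


def load_dual_csv(path_language, path_cognition) -> DualData:
    dl = pd.read_csv(path_language).set_index("sample_id").sort_index()
    dc = pd.read_csv(path_cognition).set_index("sample_id").sort_index()
    return DualData(dl.to_numpy(dtype=float), dc.to_numpy(dtype=float))


def save_dual_truth(path, truth: DualTruth) -> None:
    Path(path).write_text(json.dumps({
        "proto_language": truth.proto_language.tolist(),
        "proto_cognition": truth.proto_cognition.tolist(),
        "concept_of_row": truth.concept_of_row.tolist(),
        "config": asdict(truth.config),
    }, indent=1))


def load_dual_truth(path) -> DualTruth:
    d = json.loads(Path(path).read_text())
    return DualTruth(
        proto_language=np.asarray(d["proto_language"], dtype=float),
        proto_cognition=np.asarray(d["proto_cognition"], dtype=float),
        concept_of_row=np.asarray(d["concept_of_row"], dtype=int),
        config=DualGenConfig(**d["config"]),
    )
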