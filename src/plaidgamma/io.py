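"""Plain-text interchange: long-format CSV for spectra and response
matrices, JSON sidecars for ground truth and fit reports."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import ContrastGrid
from .interaction import ResponseMatrix
from .spectra import SpectrumSet


def spectra_to_frame(spectra: SpectrumSet) -> pd.DataFrame:
    """Long format: site_id, condition_c1, condition_c2, trial, frequency_hz, power."""
    n_t, n_f = spectra.trials.shape
    return pd.DataFrame({
        "site_id": np.repeat(spectra.site_id, n_t * n_f),
        "condition_c1": spectra.condition[0],
        "condition_c2": spectra.condition[1],
        "trial": np.repeat(np.arange(n_t), n_f),
        "frequency_hz": np.tile(spectra.freqs, n_t),
        "power": spectra.trials.ravel(),
    })


def frame_to_spectra(df: pd.DataFrame) -> SpectrumSet:
    site_id = str(df["site_id"].iloc[0])
    cond = (float(df["condition_c1"].iloc[0]), float(df["condition_c2"].iloc[0]))
    pivot = df.pivot(index="trial", columns="frequency_hz", values="power")
    pivot = pivot.sort_index(axis=1)
    return SpectrumSet(freqs=pivot.columns.to_numpy(dtype=float),
                       trials=pivot.to_numpy(dtype=float),
                       site_id=site_id, condition=cond)


def matrix_to_frame(matrix: ResponseMatrix, site_id: str = "") -> pd.DataFrame:
    """Long format: site_id, signal, c1, c2, trial, response (per replicate)."""
    c1, c2 = matrix.grid.pairs()
    if matrix.trials is None:
        trials = matrix.values[None]
    else:
        trials = matrix.trials
    n_t = trials.shape[0]
    return pd.DataFrame({
        "site_id": site_id,
        "signal": matrix.signal,
        "c1": np.tile(c1.ravel(), n_t),
        "c2": np.tile(c2.ravel(), n_t),
        "trial": np.repeat(np.arange(n_t), c1.size),
        "response": trials.reshape(n_t, -1).ravel(),
    })


def frame_to_matrix(df: pd.DataFrame) -> ResponseMatrix:
    levels = np.sort(df["c1"].unique())
    grid = ContrastGrid(tuple(float(v) for v in levels))
    n = grid.n
    trials = df.pivot_table(index="trial", columns=["c1", "c2"],
                            values="response").sort_index(axis=1)
    arr = trials.to_numpy(dtype=float).reshape(-1, n, n)
    return ResponseMatrix(arr.mean(axis=0), grid,
                          signal=str(df["signal"].iloc[0]), trials=arr)


def write_ground_truth(path, truths_by_site: dict) -> None:
    """JSON sidecar keyed by site_id; values are ground-truth dataclasses."""
    payload = {}
    for site_id, gt in truths_by_site.items():
        if isinstance(gt, dict):
            payload[site_id] = {k: asdict(v) for k, v in gt.items()}
        else:
            payload[site_id] = asdict(gt)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def selection_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])
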