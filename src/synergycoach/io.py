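"""CSV/JSON serialization for signals, cycles, models and similarity tables."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .nmf import SynergyModel
from .preprocess import CYCLE_POINTS, MUSCLES, CycleEnvelope, EmgSet
from .similarity import GroupIndex


def write_emg_csv(path, emg: np.ndarray, fs: float,
                  labels: list[str] | None = None) -> None:
    """Write a channels x samples signal as a time + one-column-per-channel CSV."""
    emg = np.atleast_2d(np.asarray(emg, dtype=float))
    labels = labels or list(MUSCLES)[:emg.shape[0]]
    t = np.arange(emg.shape[1]) / fs
    df = pd.DataFrame({"time": t, **{lb: emg[i] for i, lb in enumerate(labels)}})
    df.to_csv(path, index=False, float_format="%.6g")


def read_emg_csv(path) -> tuple[np.ndarray, float, list[str]]:
    """Read the dialect written by :func:`write_emg_csv`; infers fs from time."""
    df = pd.read_csv(path)
    t = df["time"].to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    labels = [c for c in df.columns if c != "time"]
    return df[labels].to_numpy().T, float(round(fs, 6)), labels


def write_barbell_csv(path, trace: np.ndarray, fs: float) -> None:
    t = np.arange(trace.size) / fs
    pd.DataFrame({"time": t, "z": trace}).to_csv(path, index=False,
                                                 float_format="%.6g")


def read_barbell_csv(path) -> tuple[np.ndarray, float]:
    df = pd.read_csv(path)
    t = df["time"].to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    return df["z"].to_numpy(), float(round(fs, 6))


def write_cycles_csv(path, cycles: list[CycleEnvelope],
                     labels: list[str] | None = None) -> None:
    """Write phase-normalized cycles as (cycle, point, muscle...) rows."""
    labels = labels or list(MUSCLES)[:cycles[0].values.shape[0]]
    rows = []
    for i, c in enumerate(cycles):
        df = pd.DataFrame(c.values.T, columns=labels)
        df.insert(0, "point", np.arange(CYCLE_POINTS))
        df.insert(0, "cycle", i)
        rows.append(df)
    pd.concat(rows).to_csv(path, index=False, float_format="%.6g")


def read_cycles_csv(path) -> tuple[list[CycleEnvelope], list[str]]:
    df = pd.read_csv(path)
    labels = [c for c in df.columns if c not in ("cycle", "point")]
    cycles = []
    for _, grp in df.groupby("cycle", sort=True):
        grp = grp.sort_values("point")
        cycles.append(CycleEnvelope(grp[labels].to_numpy().T))
    return cycles, labels


def model_to_json(path, model: SynergyModel, subject: str | None = None) -> None:
    payload = {
        "subject": subject,
        "W": model.W.tolist(),
        "C": model.C.tolist(),
        "vaf_total": model.vaf_total,
        "vaf_muscle": model.vaf_muscle.tolist(),
        "vaf_per_synergy": None if model.vaf_per_synergy is None
        else np.asarray(model.vaf_per_synergy).tolist(),
        "residual_norm": model.residual_norm,
        "n_iter": model.n_iter,
        "seed": model.seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def model_from_json(path) -> tuple[SynergyModel, str | None]:
    with open(path) as fh:
        d = json.load(fh)
    model = SynergyModel(
        W=np.asarray(d["W"], dtype=float), C=np.asarray(d["C"], dtype=float),
        vaf_total=d["vaf_total"], vaf_muscle=np.asarray(d["vaf_muscle"]),
        residual_norm=d["residual_norm"], n_iter=d["n_iter"], seed=d["seed"],
        vaf_per_synergy=None if d.get("vaf_per_synergy") is None
        else np.asarray(d["vaf_per_synergy"]))
    return model, d.get("subject")


def similarity_to_dataframe(indexes: list[GroupIndex]) -> pd.DataFrame:
    """Long-format pair table: group_pair, signal, pair ids, r_max, lag, r_vector."""
    rows = []
    for gi in indexes:
        for p in gi.pairs:
            rows.append({"group_pair": gi.group_pair, "signal": p.signal,
                         "id_a": p.id_a, "id_b": p.id_b, "r_max": p.r_max,
                         "lag_pct": p.lag_pct, "r_vector": p.r_vector})
    return pd.DataFrame(rows)
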