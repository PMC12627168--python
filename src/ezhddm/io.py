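"""Readers, writers and run configuration.

CSV dialects
------------
Trial-level:   participant, [condition], accuracy (0/1), rt (seconds), [x]
Summary-level: participant, [condition], [x], n_trials, n_correct (or an
               accuracy rate column), mean_rt, var_rt

Times are seconds throughout; ``rt_scale`` converts millisecond inputs.
Rows with non-positive or non-finite RTs are rejected individually and
reported; a non-binary accuracy value is a hard error (it indicates a
mislabelled column rather than a bad row).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["read_trials", "read_summaries", "summarize_trials", "RunConfig"]

# counts reconstructed from an accuracy rate must be this close to integer
RATE_TOL = 0.01


def read_trials(path, column_map: Mapping[str, str] | None = None,
                rt_scale: float = 1.0):
    """Load and validate a trial-level CSV.

    Parameters
    ----------
    path : CSV file with a header row.
    column_map : optional mapping from the canonical names
        (participant, condition, accuracy, rt, x) to the file's columns.
    rt_scale : multiply RTs by this (e.g. 0.001 for millisecond data).

    Returns
    -------
    (trials, report) : validated long-format DataFrame and a dict with the
    per-row rejection report (``n_rejected``, ``rejected_rows``).
    """
    df = pd.read_csv(path)
    if not len(df):
        raise ValueError(f"{path}: empty file")
    cmap = {k: k for k in ("participant", "condition", "accuracy", "rt", "x")}
    if column_map:
        cmap.update(column_map)
    for need in ("participant", "accuracy", "rt"):
        if cmap[need] not in df.columns:
            raise ValueError(f"{path}: missing required column {cmap[need]!r}")
    out = pd.DataFrame({"participant": df[cmap["participant"]]})
    out["condition"] = df[cmap["condition"]] if cmap["condition"] in df.columns \
        else 0
    acc = pd.to_numeric(df[cmap["accuracy"]], errors="coerce")
    bad_acc = ~acc.isin([0, 1])
    if bad_acc.any():
        val = df.loc[bad_acc.idxmax(), cmap["accuracy"]]
        raise ValueError(f"{path}: accuracy column contains a non-binary "
                         f"value {val!r}")
    out["accuracy"] = acc.astype(int)
    rt = pd.to_numeric(df[cmap["rt"]], errors="coerce") * rt_scale
    out["rt"] = rt
    if cmap["x"] in df.columns:
        out["x"] = pd.to_numeric(df[cmap["x"]], errors="coerce")
    valid = np.isfinite(rt) & (rt > 0)
    report = {"n_rows": int(len(out)), "n_rejected": int((~valid).sum()),
              "rejected_rows": out.index[~valid].tolist()}
    out = out.loc[valid].reset_index(drop=True)
    if not len(out):
        raise ValueError(f"{path}: all rows invalid")
    return out, report


def summarize_trials(trials: pd.DataFrame, min_correct: int = 2,
                     correct_only: bool = True) -> pd.DataFrame:
    """Per-(participant, condition) summary statistics from trial data.

    Cells with fewer than ``min_correct`` correct trials get NaN RT moments
    (downstream fitting drops them with a record) rather than failing the
    whole run.
    """
    if "condition" not in trials.columns:
        trials = trials.assign(condition=0)
    rows = []
    for (p, c), g in trials.groupby(["participant", "condition"], sort=True):
        sel = g.loc[g["accuracy"] == 1, "rt"] if correct_only else g["rt"]
        if len(sel) >= max(min_correct, 2):
            m, v = float(sel.mean()), float(sel.var(ddof=1))
        else:
            m, v = np.nan, np.nan
        row = {"participant": p, "condition": c, "n_trials": len(g),
               "n_correct": int(g["accuracy"].sum()), "mean_rt": m,
               "var_rt": v}
        if "x" in g.columns:
            row["x"] = float(g["x"].iloc[0])
        rows.append(row)
    return pd.DataFrame(rows)


def read_summaries(path) -> pd.DataFrame:
    """Load and validate a per-cell summary CSV.

    Accepts either an ``n_correct`` count or an ``accuracy`` rate column;
    rates are converted to integer counts and must land within ``RATE_TOL``
    of an integer (a farther value means the rate and N are inconsistent).
    """
    df = pd.read_csv(path)
    if not len(df):
        raise ValueError(f"{path}: empty file")
    for need in ("participant", "n_trials", "mean_rt", "var_rt"):
        if need not in df.columns:
            raise ValueError(f"{path}: missing required column {need!r}")
    if "condition" not in df.columns:
        df["condition"] = 0
    n = pd.to_numeric(df["n_trials"])
    if (n < 2).any():
        raise ValueError(f"{path}: every cell needs n_trials >= 2")
    if "n_correct" in df.columns:
        t = pd.to_numeric(df["n_correct"], errors="coerce")
    elif "accuracy" in df.columns:
        raw = pd.to_numeric(df["accuracy"], errors="coerce") * n
        t = raw.round()
        off = (raw - t).abs()
        if (off > RATE_TOL).any():
            i = off.idxmax()
            raise ValueError(
                f"{path}: row {i}: accuracy*N = {raw[i]:.4g} is not within "
                f"{RATE_TOL} of an integer count")
    else:
        raise ValueError(f"{path}: need an n_correct or accuracy column")
    if ((t < 0) | (t > n)).any():
        raise ValueError(f"{path}: n_correct outside [0, N]")
    v = pd.to_numeric(df["var_rt"])
    if (v < 0).any():
        raise ValueError(f"{path}: negative var_rt")
    out = pd.DataFrame({
        "participant": df["participant"], "condition": df["condition"],
        "n_trials": n.astype(int), "n_correct": t.astype(int),
        "mean_rt": pd.to_numeric(df["mean_rt"]), "var_rt": v})
    if "x" in df.columns:
        out["x"] = pd.to_numeric(df["x"])
    return out


@dataclass
class RunConfig:
    """Resolved settings of a fitting run, serialisable for provenance."""

    criterion: str = "drift"
    variance_law: str = "normal_approx"
    n_chains: int = 4
    n_warmup: int = 2000
    n_draws: int = 5000
    seed: int | None = None
    rt_scale: float = 1.0
    priors: dict | None = None
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        p = Path(path)
        text = p.read_text()
        if p.suffix in (".yaml", ".yml"):
            import yaml
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kw = {k: v for k, v in raw.items() if k in known}
        extra = dict(raw.get("extra", {}))
        extra.update({k: v for k, v in raw.items()
                      if k not in known and k != "extra"})
        return cls(**kw, extra=extra)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return d

    def round_trip(self) -> "RunConfig":
        d = json.loads(json.dumps(self.to_dict()))
        extra = d.pop("extra", {})
        return RunConfig(**d, extra=extra)
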