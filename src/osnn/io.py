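"""Plain-text I/O: datasets as CSV, ground truth and selections as JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GroundTruth, OrdinalDataset, build_interactions
from .training import SelectionResult

__all__ = [
    "dataset_to_csv",
    "dataset_from_csv",
    "truth_to_json",
    "truth_from_json",
    "selection_to_json",
    "selection_from_json",
]


def dataset_to_csv(data: OrdinalDataset, path: str | Path) -> None:
    """Columns x1..xp, z1..zq, y; interactions are recomputed on load."""
    cols = {f"x{j+1}": data.X[:, j] for j in range(data.p)}
    cols.update({f"z{d+1}": data.Z[:, d] for d in range(data.q)})
    cols["y"] = data.y
    pd.DataFrame(cols).to_csv(path, index=False)


def dataset_from_csv(path: str | Path) -> OrdinalDataset:
    df = pd.read_csv(path)
    x_cols = sorted((c for c in df.columns if c.startswith("x")), key=lambda c: int(c[1:]))
    z_cols = sorted((c for c in df.columns if c.startswith("z")), key=lambda c: int(c[1:]))
    X = df[x_cols].to_numpy(dtype=float)
    Z = df[z_cols].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=int)
    return OrdinalDataset(X, Z, build_interactions(X, Z), y)


def truth_to_json(truth: GroundTruth, path: str | Path) -> None:
    doc = {
        "important_main": [int(j) for j in truth.important_main],
        "important_inter": [[int(j), int(d)] for j, d in truth.important_inter],
        "main_coefs": truth.main_coefs.tolist(),
        "inter_coefs": truth.inter_coefs.tolist(),
        "e_coefs": truth.e_coefs.tolist(),
        "thresholds": truth.thresholds.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def truth_from_json(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        important_main=np.asarray(d["important_main"], dtype=int),
        important_inter=tuple((int(j), int(dd)) for j, dd in d["important_inter"]),
        main_coefs=np.asarray(d["main_coefs"], dtype=float),
        inter_coefs=np.asarray(d["inter_coefs"], dtype=float),
        e_coefs=np.asarray(d["e_coefs"], dtype=float),
        thresholds=np.asarray(d["thresholds"], dtype=float),
    )


def selection_to_json(sel: SelectionResult, path: str | Path) -> None:
    doc = {
        "main_selected": sorted(sel.main_selected),
        "inter_selected": sorted([list(t) for t in sel.inter_selected]),
    }
    Path(path).write_text(json.dumps(doc))


def selection_from_json(path: str | Path) -> SelectionResult:
    d = json.loads(Path(path).read_text())
    return SelectionResult(
        main_selected=frozenset(int(j) for j in d["main_selected"]),
        inter_selected=frozenset((int(j), int(dd)) for j, dd in d["inter_selected"]),
    )
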