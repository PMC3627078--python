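"""CSV/JSON helpers shared by the CLI.

Curve tables use the convention: header row = grid values, first column =
taxon/node id.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .kernel import HyperParams
from .synthesis import BasisSet, FunctionalDataset


def curves_to_frame(ids, grid, curves) -> pd.DataFrame:
    df = pd.DataFrame(np.asarray(curves), columns=[f"{g:.10g}" for g in grid])
    df.insert(0, "id", list(ids))
    return df


def write_curves(path, ids, grid, curves) -> None:
    curves_to_frame(ids, grid, curves).to_csv(path, index=False)


def read_curves(path):
    """Returns (ids, grid, curves)."""
    df = pd.read_csv(path)
    ids = df.iloc[:, 0].tolist()
    grid = np.array([float(c) for c in df.columns[1:]])
    return ids, grid, df.iloc[:, 1:].to_numpy(dtype=float)


def read_functional_dataset(path) -> FunctionalDataset:
    ids, grid, curves = read_curves(path)
    return FunctionalDataset(
        grid=grid, taxa_ids=np.arange(len(ids)), labels=[str(i) for i in ids],
        curves=curves,
    )


def read_basis(path) -> BasisSet:
    _, grid, curves = read_curves(path)
    return BasisSet(grid=grid, curves=curves)


def gammas_to_json(gammas, sds=None, diagnostics=None) -> str:
    out = []
    for i, g in enumerate(gammas):
        row = {"component": i, "sigma_f": g.sigma_f, "ell": g.ell, "sigma_n": g.sigma_n}
        if sds is not None:
            s = sds[i]
            row.update(
                sigma_f_sd=s.sigma_f, ell_sd=s.ell, sigma_n_sd=s.sigma_n
            )
        if diagnostics is not None:
            row["diagnostics"] = diagnostics[i]
        out.append(row)
    return json.dumps(out, indent=2)


def gammas_from_json(text: str):
    return tuple(
        HyperParams(row["sigma_f"], row["ell"], row["sigma_n"])
        for row in json.loads(text)
    )
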