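"""Plain-text readers and writers for trajectories and simulated datasets."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import BooleanNetwork
from .simulate import LabeledDataset


def read_trajectory_tsv(path: str | Path, genes: list[str] | None = None) -> np.ndarray:
    """Read an (m, n) expression trajectory from a TSV file.

    The header row carries gene names, one row per time point.  When
    ``genes`` is given the header must match it exactly (same names, same
    order) so trajectories cannot silently be fed to the wrong network.
    """
    df = pd.read_csv(path, sep="\t")
    if genes is not None and list(df.columns) != list(genes):
        raise ValueError(
            f"{path}: gene columns {list(df.columns)} do not match the network genes {list(genes)}"
        )
    Y = df.to_numpy(dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 1:
        raise ValueError(f"{path}: expected at least one time point")
    return Y


def write_trajectory_tsv(path: str | Path, Y: np.ndarray, genes: list[str]) -> None:
    pd.DataFrame(np.asarray(Y, dtype=float), columns=list(genes)).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def write_dataset(out_dir: str | Path, ds: LabeledDataset, net: BooleanNetwork) -> None:
    """Write a simulated dataset: one TSV per trajectory, labels.csv, manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = []
    for i, Y in enumerate(ds.trajectories):
        name = f"trajectory_{i:04d}.tsv"
        write_trajectory_tsv(out / name, Y, net.genes)
        names.append(name)
    pd.DataFrame({"trajectory": names, "label": ds.labels}).to_csv(out / "labels.csv", index=False)
    manifest = {"seed": ds.seed, "genes": net.genes, **ds.provenance}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
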