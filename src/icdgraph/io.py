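"""Readers/writers for the on-disk dataset formats and the run configuration.

A dataset directory holds:

* ``adjacency.mtx`` — Matrix Market sparse adjacency (symmetrized on load,
  explicit zeros pruned); alternatively ``edges.tsv`` with two integer
  columns, interpreted as undirected and deduplicated;
* ``features.tsv`` — dense node-feature matrix, tab-delimited, no header;
* ``labels.tsv`` — binary indicator matrix, one row per node;
* ``masks.tsv`` — two columns ``node<TAB>split`` with split in
  {train, val, test};
* ``manifest.yaml`` — generating config and seed (artifact reproducibility).

Configuration files are YAML with sections mirroring the library configs;
unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from scipy.io import mmread, mmwrite

from .graph import Graph, ValidationError
from .synthetic import SynthConfig
from .training import TrainConfig

__all__ = ["save_graph", "load_graph", "load_edge_list", "RunConfig", "load_config"]

SPLITS = ("train", "val", "test")


def save_graph(graph: Graph, outdir, manifest: dict | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "adjacency.mtx"), sp.coo_matrix(graph.adjacency))
    np.savetxt(outdir / "features.tsv", graph.features, delimiter="\t", fmt="%.10g")
    np.savetxt(outdir / "labels.tsv", graph.labels, delimiter="\t", fmt="%d")
    rows = []
    for split, mask in zip(SPLITS, (graph.train_mask, graph.val_mask, graph.test_mask)):
        rows += [(int(i), split) for i in mask]
    pd.DataFrame(rows, columns=["node", "split"]).to_csv(
        outdir / "masks.tsv", sep="\t", index=False
    )
    if manifest is not None:
        (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))


def load_edge_list(path) -> sp.csr_matrix:
    """TSV edge list (two integer columns) -> symmetrized binary adjacency."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"{path}: could not parse edge list ({exc})") from exc
    if df.shape[1] != 2:
        raise ValidationError(f"{path}: expected 2 columns, got {df.shape[1]}")
    for col in df.columns:
        bad = df[~df[col].astype(str).str.fullmatch(r"-?\d+")]
        if len(bad):
            raise ValidationError(
                f"{path}: non-integer edge endpoint at row {bad.index[0] + 1}"
            )
    e = df.astype(int).to_numpy()
    n = int(e.max()) + 1
    keep = e[:, 0] != e[:, 1]  # drop self-loops
    e = e[keep]
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    A = sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    A.data[:] = 1.0  # dedupe
    return A


def _load_matrix(path, name) -> np.ndarray:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None)
    except Exception as exc:
        raise ValidationError(f"{path}: could not parse {name} ({exc})") from exc
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                row = int(coerced.isna().idxmax()) + 1
                raise ValidationError(f"{path}: non-numeric {name} value at row {row}")
        arr = df.apply(pd.to_numeric).to_numpy()
    return arr.astype(float)


def load_graph(directory) -> Graph:
    """Load and validate a dataset directory written by :func:`save_graph`."""
    directory = Path(directory)
    mtx = directory / "adjacency.mtx"
    if mtx.exists():
        A = sp.csr_matrix(mmread(str(mtx)))
        A.eliminate_zeros()  # prune explicit zeros
        A = ((A + A.T) > 0).astype(float)  # symmetrize
        A.setdiag(0)
        A.eliminate_zeros()
    elif (directory / "edges.tsv").exists():
        A = load_edge_list(directory / "edges.tsv")
    else:
        raise ValidationError(f"{directory}: no adjacency.mtx or edges.tsv found")
    X = _load_matrix(directory / "features.tsv", "feature")
    Y = _load_matrix(directory / "labels.tsv", "label").astype(int)
    n = A.shape[0]
    if X.shape[0] != n:
        raise ValidationError(
            f"{directory / 'features.tsv'}: {X.shape[0]} rows but adjacency has {n} nodes"
        )
    if Y.shape[0] != n:
        raise ValidationError(
            f"{directory / 'labels.tsv'}: {Y.shape[0]} rows but adjacency has {n} nodes"
        )
    masks = {s: [] for s in SPLITS}
    mask_path = directory / "masks.tsv"
    if mask_path.exists():
        df = pd.read_csv(mask_path, sep="\t")
        for ridx, row in df.iterrows():
            split = str(row["split"])
            if split not in SPLITS:
                raise ValidationError(
                    f"{mask_path}: unknown split {split!r} at row {ridx + 2}"
                )
            masks[split].append(int(row["node"]))
    return Graph(
        adjacency=A, features=X, labels=Y,
        train_mask=np.array(masks["train"], dtype=int),
        val_mask=np.array(masks["val"], dtype=int),
        test_mask=np.array(masks["test"], dtype=int),
    )


# -- run configuration -------------------------------------------------

@dataclasses.dataclass
class RLSection:
    gamma: float = 0.9
    horizon: int | None = None
    beta_sparsity: float = 0.01
    episodes: int = 200


@dataclasses.dataclass
class DASection:
    alpha_da: float = 0.1
    critic_steps: int = 5
    adapt_rounds: int = 150
    batch: int = 64


@dataclasses.dataclass
class RunConfig:
    """Full run configuration; defaults match the study hyperparameters
    (delta=0.2, lambda=1.0, alpha_da=0.1, gamma=0.9, hidden=128,
    dropout=0.5, epochs=100, patience=10, batch=64)."""

    data_dir: str | None = None
    model: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    rl: RLSection = dataclasses.field(default_factory=RLSection)
    da: DASection = dataclasses.field(default_factory=DASection)
    synth: SynthConfig = dataclasses.field(default_factory=SynthConfig)
    seed: int = 0


def _fill(dc_type, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(dc_type)}
    unknown = set(data) - names
    if unknown:
        raise ValidationError(f"unknown config key(s) in {context}: {sorted(unknown)}")
    return dc_type(**data)


def load_config(path) -> RunConfig:
    """Parse a YAML run configuration, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {"data_dir", "model", "rl", "da", "synth", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown top-level config key(s): {sorted(unknown)}")
    cfg = RunConfig(
        data_dir=raw.get("data_dir"),
        model=_fill(TrainConfig, raw.get("model", {}), "model"),
        rl=_fill(RLSection, raw.get("rl", {}), "rl"),
        da=_fill(DASection, raw.get("da", {}), "da"),
        synth=_fill(SynthConfig, raw.get("synth", {}), "synth"),
        seed=int(raw.get("seed", 0)),
    )
    return cfg


def write_metrics_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
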