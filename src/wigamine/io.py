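"""Input/output: expression matrices, label files, network and result serialization.

Expression data travel as :class:`ExpressionDataset`, a thin wrapper around a
pandas DataFrame (genes x samples) plus a two-class label per sample.  Networks
are serialized as per-sample weighted edge lists (TSV) with a manifest, so a
mined run can be resumed without recomputing association statistics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "read_expression",
    "read_labels",
    "write_expression",
    "write_labels",
    "write_networks",
    "read_networks",
    "write_results_json",
    "write_results_tsv",
    "write_provenance",
]


@dataclasses.dataclass(frozen=True)
class ExpressionDataset:
    """A genes x samples expression matrix with a binary population label per sample.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier, columns = sample identifiers.
    labels
        Series mapping each sample identifier to one of exactly two class labels.
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        missing = [s for s in self.values.columns if s not in self.labels.index]
        if missing:
            raise ValueError(f"samples without a class label: {missing}")
        classes = sorted(set(self.labels.loc[list(self.values.columns)]))
        if len(classes) != 2:
            raise ValueError(
                f"exactly two class labels required, found {len(classes)}: {classes}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def classes(self) -> tuple[str, str]:
        """The two class labels, lexicographically sorted."""
        labels = self.labels.loc[list(self.values.columns)]
        a, b = sorted(set(labels))
        return (str(a), str(b))

    def samples_of(self, cls: str) -> list[str]:
        return [s for s in self.values.columns if self.labels[s] == cls]


def _sep_for(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression(path: str, labels_path: str, orientation: str = "genes-as-rows") -> ExpressionDataset:
    """Read an expression TSV/CSV (header row) plus a two-column label file.

    ``orientation`` is ``genes-as-rows`` (default) or ``samples-as-rows``.
    Non-numeric cells, ragged rows and duplicate identifiers are fatal.
    """
    if orientation not in ("genes-as-rows", "samples-as-rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index.name = None
    df.columns.name = None
    if orientation == "samples-as-rows":
        df = df.T
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if df.isna().any().any():
        n = int(df.isna().sum().sum())
        raise ValueError(f"{path}: {n} missing value(s); impute or drop before analysis")
    labels = read_labels(labels_path)
    missing = [s for s in df.columns if s not in labels.index]
    if missing:
        raise ValueError(f"{labels_path}: no label for sample(s) {missing}")
    return ExpressionDataset(values=df, labels=labels.loc[list(df.columns)])


def read_labels(path: str) -> pd.Series:
    """Read a two-column (sample, class) file; exactly two distinct classes required."""
    df = pd.read_csv(path, sep=_sep_for(path), header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample, class)")
    ser = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="class")
    if ser.index.has_duplicates:
        dups = ser.index[ser.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample identifiers {dups}")
    classes = sorted(ser.unique())
    if len(classes) != 2:
        raise ValueError(
            f"{path}: exactly two classes required (two-population comparison), found {classes}"
        )
    return ser


def write_expression(dataset: ExpressionDataset, path: str, labels_path: str) -> None:
    dataset.values.to_csv(path, sep=_sep_for(path), index_label="gene")
    write_labels(dataset.labels, labels_path)


def write_labels(labels: pd.Series, path: str) -> None:
    labels.to_csv(path, sep=_sep_for(path), header=False)


# ---------------------------------------------------------------------------
# network serialization


def write_networks(networks: Iterable, outdir: str) -> None:
    """Write one weighted edge-list TSV per network plus ``manifest.tsv``.

    Columns: gene_a, gene_b, eta, relevance.  The manifest records sample id,
    class label, file name and the shared node universe.
    """
    os.makedirs(outdir, exist_ok=True)
    networks = list(networks)
    rows = []
    for net in networks:
        fname = f"network_{net.sample_id}.tsv"
        with open(os.path.join(outdir, fname), "w") as fh:
            fh.write("gene_a\tgene_b\teta\trelevance\n")
            for (a, b) in sorted(net.weights):
                r = net.relevance.get((a, b), float("nan")) if net.relevance else float("nan")
                fh.write(f"{a}\t{b}\t{net.weights[(a, b)]:.12g}\t{r:.12g}\n")
        rows.append((net.sample_id, net.label, fname))
    with open(os.path.join(outdir, "manifest.tsv"), "w") as fh:
        fh.write("sample_id\tclass\tfile\n")
        for sid, lab, fname in rows:
            fh.write(f"{sid}\t{lab}\t{fname}\n")
    universe = sorted(networks[0].nodes) if networks else []
    with open(os.path.join(outdir, "nodes.txt"), "w") as fh:
        fh.write("\n".join(universe) + ("\n" if universe else ""))


def read_networks(indir: str):
    """Load networks written by :func:`write_networks`."""
    from .wiga import WigaNetwork

    manifest = pd.read_csv(os.path.join(indir, "manifest.tsv"), sep="\t", dtype=str)
    with open(os.path.join(indir, "nodes.txt")) as fh:
        nodes = tuple(line.strip() for line in fh if line.strip())
    out = []
    for _, row in manifest.iterrows():
        df = pd.read_csv(os.path.join(indir, row["file"]), sep="\t", dtype={"gene_a": str, "gene_b": str})
        weights = {}
        relevance = {}
        for a, b, eta, r in df.itertuples(index=False):
            edge = (a, b) if a <= b else (b, a)
            weights[edge] = float(eta)
            relevance[edge] = float(r)
        out.append(
            WigaNetwork(
                sample_id=row["sample_id"], label=row["class"], nodes=nodes,
                weights=weights, relevance=relevance,
            )
        )
    return out


# ---------------------------------------------------------------------------
# result serialization


def _pattern_record(sp, rank: int) -> dict:
    p = sp.profile
    return {
        "rank": rank,
        "edges": [list(e) for e in sp.pattern.edges],
        "nodes": list(sp.pattern.nodes),
        "pow": sp.pow,
        "upper_bound": sp.upper_bound,
        "direction": sp.direction,
        "support_1": p.support1,
        "support_2": p.support2,
        "incidence_1": p.incidence1,
        "incidence_2": p.incidence2,
        "s_hat_1": p.s_hat1,
        "s_hat_2": p.s_hat2,
        "s_hat_1_null": p.null1,
        "s_hat_2_null": p.null2,
    }


def write_results_json(results, path: str, meta: Mapping | None = None) -> None:
    payload = {
        "meta": dict(meta or {}),
        "patterns": [_pattern_record(sp, i + 1) for i, sp in enumerate(results)],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def write_results_tsv(results, path: str) -> None:
    cols = [
        "rank", "pow", "n_edges", "n_nodes", "support_1", "support_2",
        "incidence_1", "incidence_2", "s_hat_1", "s_hat_2", "edges",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i, sp in enumerate(results):
            p = sp.profile
            edges = ";".join(f"{a}-{b}" for a, b in sp.pattern.edges)
            fh.write(
                f"{i + 1}\t{sp.pow:.12g}\t{len(sp.pattern.edges)}\t{len(sp.pattern.nodes)}\t"
                f"{p.support1}\t{p.support2}\t{p.incidence1:.12g}\t{p.incidence2:.12g}\t"
                f"{p.s_hat1:.12g}\t{p.s_hat2:.12g}\t{edges}\n"
            )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def sha256_of(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(path: str, *, config: Mapping, seed: int | None, inputs: Iterable[str] = ()) -> None:
    """Write a machine-readable provenance record (config, versions, seed, checksums)."""
    import networkx
    import scipy

    from . import __version__

    record = {
        "wigamine": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
        "seed": seed,
        "config": dict(config),
        "inputs": {os.path.basename(p): sha256_of(p) for p in inputs},
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
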