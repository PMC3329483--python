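"""Plain-text readers and writers for every pipeline artifact.

Formats are deliberately simple and diffable: whitespace edge lists, tab
separated partitions, CSV feature tables, Newick dendrograms and key=value
configuration with ``[section]`` headers.  All writers sort labels so output
is byte-deterministic.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .measures import CORE_FEATURES, FeatureVector
from .netclust import Dendrogram

__all__ = [
    "read_edgelist",
    "write_edgelist",
    "read_partition",
    "write_partition",
    "read_features",
    "write_features",
    "write_newick",
    "read_config",
    "write_config",
]

logger = logging.getLogger("dupmod")

_FEATURE_COLUMNS = {"m": "m", "q": "Q", "s_rel": "S", "h_conn": "Hconn", "h_mod": "Hmod", "nmi": "nMI"}
_COLUMN_FEATURES = {v: k for k, v in _FEATURE_COLUMNS.items()}


def read_edgelist(path) -> nx.Graph:
    """Read an undirected edge list (two labels per line, ``#`` comments).

    Duplicate edges (including reversed repeats) are collapsed with a logged
    warning; self-loops are rejected.
    """
    g = nx.Graph()
    duplicates = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            comment = line.split("#", 1)[1].strip() if "#" in line else ""
            if comment.startswith("isolated "):
                g.add_node(comment.split(None, 1)[1])
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two whitespace-separated labels, got {line!r}"
                )
            u, v = parts
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop {u!r}-{v!r} is not allowed")
            if g.has_edge(u, v):
                duplicates += 1
            g.add_edge(u, v)
    if duplicates:
        logger.warning("%s: collapsed %d duplicate edge line(s)", path, duplicates)
    return g


def write_edgelist(net: nx.Graph, path) -> None:
    """One edge per line, endpoint labels sorted, edges sorted; lone nodes as comments."""
    lines = sorted(tuple(sorted((str(u), str(v)))) for u, v in net.edges)
    with open(path, "w") as handle:
        for u, v in lines:
            handle.write(f"{u} {v}\n")
        for v in sorted(map(str, nx.isolates(net))):
            handle.write(f"# isolated {v}\n")


def read_partition(path) -> dict:
    """Read ``node<TAB>module`` lines into a node -> int mapping."""
    part = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split("\t") if "\t" in text else text.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'node<TAB>module', got {line!r}")
            part[parts[0]] = int(parts[1])
    return part


def write_partition(partition: dict, path, q: float | None = None) -> None:
    """Write ``node<TAB>module`` lines plus a ``# Q=... m=...`` footer."""
    with open(path, "w") as handle:
        for node in sorted(partition, key=str):
            handle.write(f"{node}\t{partition[node]}\n")
        m = len(set(partition.values()))
        if q is not None:
            handle.write(f"# Q={q:.6f} m={m}\n")
        else:
            handle.write(f"# m={m}\n")


def features_to_frame(features) -> pd.DataFrame:
    rows = []
    for fv in features:
        row = {"name": fv.name, "class": fv.class_label}
        for feat, col in _FEATURE_COLUMNS.items():
            row[col] = getattr(fv, feat)
        row.update(fv.extras)
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["name", "class", *_FEATURE_COLUMNS.values()])
    return pd.DataFrame(rows)


def write_features(features, path) -> None:
    """CSV feature table: ``name,class,m,Q,S,Hconn,Hmod,nMI[,extras...]``."""
    frame = features_to_frame(features)
    float_cols = [c for c in frame.columns if c not in ("name", "class", "m")]
    for col in float_cols:
        frame[col] = frame[col].map(lambda v: f"{v:.6f}")
    frame.to_csv(path, index=False)


def read_features(path) -> list[FeatureVector]:
    frame = pd.read_csv(path)
    extras_cols = [c for c in frame.columns if c not in ("name", "class", *_COLUMN_FEATURES)]
    out = []
    for _, row in frame.iterrows():
        kwargs = {feat: row[col] for col, feat in _COLUMN_FEATURES.items()}
        kwargs["m"] = int(kwargs["m"])
        out.append(
            FeatureVector(
                name=str(row["name"]),
                class_label=str(row["class"]),
                extras={c: float(row[c]) for c in extras_cols},
                **kwargs,
            )
        )
    return out


def newick_string(dend: Dendrogram) -> str:
    """Newick with merge heights encoded as branch lengths.

    Each child branch carries ``parent_height - child_height`` (leaves sit at
    height 0), so root-to-leaf path lengths reproduce merge heights; inverted
    merges can produce negative branch lengths, which are kept as-is.
    """
    n = dend.n
    height = {i: 0.0 for i in range(n)}
    node = {i: str(dend.leaves[i]) for i in range(n)}
    rep = {i: str(dend.leaves[i]) for i in range(n)}  # smallest leaf label per subtree
    for t, (a, b, h, _s) in enumerate(dend.merges):
        new = n + t
        height[new] = h
        first, second = (a, b) if rep[a] <= rep[b] else (b, a)
        node[new] = (
            f"({node[first]}:{h - height[first]:.6f},{node[second]}:{h - height[second]:.6f})"
        )
        rep[new] = min(rep[a], rep[b])
        del node[a], node[b]
    (root,) = node.values()
    return root + ";"


def write_newick(dend: Dendrogram, path) -> None:
    Path(path).write_text(newick_string(dend) + "\n")


def read_config(path) -> dict:
    """Flat ``key=value`` config with ``[section]`` headers -> nested dict."""
    config: dict = {}
    section = config
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            if text.startswith("[") and text.endswith("]"):
                section = config.setdefault(text[1:-1], {})
                continue
            if "=" not in text:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, value = (part.strip() for part in text.split("=", 1))
            section[key] = _parse_scalar(value)
    return config


def _parse_scalar(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    if value.lower() in ("true", "false"):
        return value.lower() == "true"
    return value


def write_config(config: dict, path, json_path=None) -> None:
    """Write nested dict as sectioned key=value; optional JSON twin."""
    with open(path, "w") as handle:
        scalars = {k: v for k, v in config.items() if not isinstance(v, dict)}
        for key in sorted(scalars):
            handle.write(f"{key}={scalars[key]}\n")
        for section in sorted(k for k, v in config.items() if isinstance(v, dict)):
            handle.write(f"\n[{section}]\n")
            for key in sorted(config[section]):
                handle.write(f"{key}={config[section][key]}\n")
    if json_path is not None:
        Path(json_path).write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")
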