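"""Readers, writers and the bundled synthetic fixture.

Networks come in as SIF (Cytoscape's simple interaction format) or GraphML;
node annotations come either from GraphML data keys or from a tab-separated
attribute table. Clouds go out as JSON, TSV or SVG; word networks as GraphML
or SIF plus an edge-attribute sidecar.
"""

from __future__ import annotations

import json
import random
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .cloud_core import CloudEntry, TagCloud
from .cooccurrence import ClusteredCloud, WordCluster
from .errors import (
    DuplicateNode,
    InvalidParameters,
    ParseError,
    UnknownNode,
    UnsupportedFormat,
)
from .text_pipeline import RawDocument

#: Fixed qualitative palette for cluster coloring in SVG output.
PALETTE = (
    "#1f77b4", "#d62728", "#2ca02c", "#9467bd", "#ff7f0e",
    "#8c564b", "#e377c2", "#17becf", "#bcbd22", "#7f7f7f",
)


@dataclass
class AttributedNetwork:
    """A network plus per-node string (or list-of-string) attributes."""

    nodes: set[str] = field(default_factory=set)
    edges: list[tuple[str, str, str | None]] = field(default_factory=list)
    attributes: dict[str, dict[str, str | list[str]]] = field(default_factory=dict)

    def texts(self, node_id: str, attr_names: Iterable[str]) -> list[str]:
        """Flatten the named attributes of one node into a text list."""
        out: list[str] = []
        attrs = self.attributes.get(node_id, {})
        for name in attr_names:
            value = attrs.get(name)
            if value is None:
                continue
            if isinstance(value, list):
                out.extend(str(v) for v in value)
            else:
                out.append(str(value))
        return out

    def documents(self, attr_names: Iterable[str]) -> list[RawDocument]:
        names = list(attr_names)
        return [
            RawDocument(n, self.texts(n, names)) for n in sorted(self.nodes)
        ]


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("sif", "graphml"):
        return suffix
    raise UnsupportedFormat(f"cannot infer network format from {path.name!r}")


def read_network(path: str | Path, fmt: str | None = None) -> AttributedNetwork:
    """Read a SIF or GraphML network.

    SIF rows are ``source<tab>interaction<tab>target [target...]``; runs of
    spaces are accepted as separators when a line has no tab. A one-column
    row declares an isolated node. GraphML node data keys become attributes.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "sif":
        return _read_sif(path)
    if fmt == "graphml":
        return _read_graphml(path)
    raise UnsupportedFormat(f"unsupported network format: {fmt!r}")


def _read_sif(path: Path) -> AttributedNetwork:
    net = AttributedNetwork()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            fields = [f.strip() for f in fields if f.strip()]
            if len(fields) == 1:
                net.nodes.add(fields[0])
            elif len(fields) >= 3:
                src, interaction, *targets = fields
                net.nodes.add(src)
                for tgt in targets:
                    net.nodes.add(tgt)
                    net.edges.append((src, tgt, interaction))
            else:
                raise ParseError(
                    f"{path.name}:{lineno}: SIF line has 2 columns "
                    "(need 1 or >= 3)"
                )
    return net


def _read_graphml(path: Path) -> AttributedNetwork:
    try:
        g = nx.read_graphml(path)
    except Exception as exc:  # malformed XML or keys
        raise ParseError(f"{path.name}: {exc}") from exc
    net = AttributedNetwork()
    for node, data in g.nodes(data=True):
        node = str(node)
        net.nodes.add(node)
        if data:
            net.attributes[node] = {k: v for k, v in data.items()}
    for u, v, data in g.edges(data=True):
        net.edges.append((str(u), str(v), data.get("interaction")))
    return net


def read_attributes(
    path: str | Path, list_sep: str = "|"
) -> dict[str, dict[str, str | list[str]]]:
    """Read a node-attribute TSV: first column node id, header names attrs.

    Cells containing ``list_sep`` become list-of-string values. Duplicate
    node ids raise :class:`DuplicateNode`.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise ParseError(f"{path.name}: {exc}") from exc
    if frame.shape[1] < 2:
        raise ParseError(f"{path.name}: need a node-id column plus attributes")
    id_col = frame.columns[0]
    dupes = frame[id_col][frame[id_col].duplicated()].tolist()
    if dupes:
        raise DuplicateNode(f"duplicate node id(s): {', '.join(sorted(set(dupes)))}")
    table: dict[str, dict[str, str | list[str]]] = {}
    for _, row in frame.iterrows():
        attrs: dict[str, str | list[str]] = {}
        for col in frame.columns[1:]:
            cell = row[col]
            if cell == "":
                continue
            attrs[col] = cell.split(list_sep) if list_sep in cell else cell
        table[row[id_col]] = attrs
    return table


def attach_attributes(
    net: AttributedNetwork,
    table: dict[str, dict[str, str | list[str]]],
    strict: bool = True,
) -> AttributedNetwork:
    """Merge an attribute table into a network (table values win per key)."""
    unknown = sorted(set(table) - net.nodes)
    if unknown and strict:
        raise UnknownNode(f"attributed node(s) not in network: {', '.join(unknown)}")
    for node, attrs in table.items():
        if node in net.nodes:
            net.attributes.setdefault(node, {}).update(attrs)
    return net


# ---------------------------------------------------------------------------
# cloud writers / readers


def write_cloud(
    cloud: TagCloud | ClusteredCloud, path: str | Path, fmt: str | None = None
) -> None:
    """Write a simple or clustered cloud as JSON, TSV or SVG."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        path.write_text(json.dumps(_cloud_to_obj(cloud), indent=2) + "\n")
    elif fmt == "tsv":
        path.write_text(_cloud_to_tsv(cloud))
    elif fmt == "svg":
        path.write_text(_cloud_to_svg(cloud))
    else:
        raise UnsupportedFormat(f"unsupported cloud format: {fmt!r}")


def _iter_cluster_entries(cloud: TagCloud | ClusteredCloud):
    """Yield (cluster_index, CloudEntry) in display order."""
    if isinstance(cloud, TagCloud):
        for e in cloud.entries:
            yield 0, e
    else:
        for idx, cluster in enumerate(cloud.clusters):
            for pos, w in enumerate(cluster.words):
                entry = cloud.entry_map.get(w)
                if entry is None:
                    entry = CloudEntry(
                        w, w, cluster.score_vector[pos], cluster.size_vector[pos]
                    )
                yield idx, entry


def _cloud_to_obj(cloud: TagCloud | ClusteredCloud) -> dict:
    def entry_obj(e: CloudEntry) -> dict:
        return {
            "stem": e.stem,
            "display": e.display,
            "score": e.score,
            "font": e.font,
        }

    if isinstance(cloud, TagCloud):
        return {"kind": "simple", "entries": [entry_obj(e) for e in cloud.entries]}
    clusters = []
    by_cluster: dict[int, list[dict]] = {}
    for idx, e in _iter_cluster_entries(cloud):
        by_cluster.setdefault(idx, []).append(entry_obj(e))
    for idx in sorted(by_cluster):
        clusters.append({"words": by_cluster[idx]})
    return {"kind": "clustered", "threshold": cloud.threshold, "clusters": clusters}


def read_cloud_json(path: str | Path) -> TagCloud | ClusteredCloud:
    """Inverse of the JSON writer; reproduces the cloud exactly."""
    obj = json.loads(Path(path).read_text())
    def entry(d: dict) -> CloudEntry:
        return CloudEntry(d["stem"], d["display"], d["score"], d["font"])

    if obj["kind"] == "simple":
        return TagCloud([entry(d) for d in obj["entries"]])
    clusters = []
    entry_map: dict[str, CloudEntry] = {}
    for c in obj["clusters"]:
        entries = [entry(d) for d in c["words"]]
        clusters.append(
            WordCluster(
                [e.stem for e in entries],
                [e.font for e in entries],
                [e.score for e in entries],
            )
        )
        entry_map.update({e.stem: e for e in entries})
    return ClusteredCloud(clusters, obj["threshold"], entry_map)


def _cloud_to_tsv(cloud: TagCloud | ClusteredCloud) -> str:
    lines = ["cluster\tstem\tdisplay\tscore\tfont"]
    for idx, e in _iter_cluster_entries(cloud):
        lines.append(f"{idx}\t{e.stem}\t{e.display}\t{e.score!r}\t{e.font}")
    return "\n".join(lines) + "\n"


def _cloud_to_svg(cloud: TagCloud | ClusteredCloud, width: int = 800) -> str:
    """Left-to-right, cluster-by-cluster layout with line wrapping.

    Word width is estimated as 0.6 * font * len(display); one palette color
    per cluster. The layout is artifact-defined — only the per-word
    font-size semantics are meaningful.
    """
    pad = 10
    svg = ET.Element("svg", xmlns="http://www.w3.org/2000/svg")
    x, y = pad, pad
    line_height = 0
    for idx, e in _iter_cluster_entries(cloud):
        w_est = 0.6 * e.font * max(len(e.display), 1)
        if x > pad and x + w_est > width - pad:
            x = pad
            y += line_height + pad
            line_height = 0
        line_height = max(line_height, e.font)
        text = ET.SubElement(
            svg,
            "text",
            x=f"{x:.1f}",
            y=f"{y + e.font:.1f}",
            fill=PALETTE[idx % len(PALETTE)],
        )
        text.set("font-size", str(e.font))
        text.set("font-family", "sans-serif")
        text.text = e.display
        x += w_est + pad
    svg.set("width", str(width))
    svg.set("height", str(y + line_height + 2 * pad))
    return ET.tostring(svg, encoding="unicode") + "\n"


# ---------------------------------------------------------------------------
# word-network writers / readers


def write_word_network(
    net: nx.Graph, path: str | Path, fmt: str | None = None
) -> None:
    """Export a word-similarity network as GraphML or SIF + edge table.

    GraphML carries the node ``size`` and edge ``similarity`` (plus directed
    components and ``n_joint``) as typed data keys. SIF writes edges with
    interaction ``cooc`` and a ``<name>.edges.tsv`` sidecar of attributes.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "graphml":
        nx.write_graphml(net, path, named_key_ids=True)
    elif fmt == "sif":
        lines = []
        for n in sorted(net.nodes):
            if net.degree(n) == 0:
                lines.append(str(n))
        for u, v in sorted(net.edges):
            lines.append(f"{u}\tcooc\t{v}")
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        side = ["word1\tword2\tsimilarity\tsim_forward\tsim_reverse\tn_joint"]
        for u, v in sorted(net.edges):
            d = net[u][v]
            side.append(
                f"{u}\t{v}\t{d['similarity']!r}\t{d['sim_forward']!r}"
                f"\t{d['sim_reverse']!r}\t{d['n_joint']}"
            )
        path.with_suffix(path.suffix + ".edges.tsv").write_text(
            "\n".join(side) + "\n"
        )
    else:
        raise UnsupportedFormat(f"unsupported word-network format: {fmt!r}")


def read_word_network(path: str | Path) -> nx.Graph:
    """Read back an exported GraphML word network with typed attributes."""
    return nx.read_graphml(path, node_type=str)


# ---------------------------------------------------------------------------
# synthetic fixture

_ORC_PHRASE = "origin recognition complex component"
_MCM_PHRASE = "minichromosome maintenance complex component"

_BACKGROUND_NAMES = (
    "vacuolar membrane transporter",
    "mitochondrial ribosomal protein",
    "cell wall biogenesis factor",
    "ubiquitin ligase complex subunit",
    "heat shock protein chaperone",
    "golgi vesicle tethering factor",
    "histone acetyltransferase complex subunit",
    "plasma membrane proton pump",
    "ribosome biogenesis factor",
    "tRNA modification enzyme",
    "actin cytoskeleton organization protein",
    "glycolytic enzyme isoform",
)


def generate_fixture(
    seed: int,
    n_cluster_nodes: int = 8,
    n_background_nodes: int = 12,
) -> tuple[AttributedNetwork, list[str]]:
    """Deterministic synthetic protein-interaction network with a dense
    DNA-replication cluster.

    The cluster's ``name`` attributes alternate between the two phrase
    families "origin recognition complex component <i>" and "minichromosome
    maintenance complex component <i>"; background nodes carry unrelated
    functional names (some sharing the generic words "complex"/"subunit", so
    network weighting has something to penalize). The cluster is a clique,
    the background a sparse random graph, and the returned selection is the
    cluster. Pure function of its arguments.
    """
    if n_cluster_nodes < 4:
        raise InvalidParameters("n_cluster_nodes must be >= 4")
    if n_background_nodes < 0:
        raise InvalidParameters("n_background_nodes must be >= 0")
    rng = random.Random(seed)
    net = AttributedNetwork()

    cluster_ids = []
    for i in range(n_cluster_nodes):
        node = f"REP{i + 1:03d}"
        cluster_ids.append(node)
        phrase = _ORC_PHRASE if i % 2 == 0 else _MCM_PHRASE
        net.nodes.add(node)
        net.attributes[node] = {"name": f"{phrase} {i // 2 + 1}"}

    bg_ids = []
    for i in range(n_background_nodes):
        node = f"BG{i + 1:03d}"
        bg_ids.append(node)
        net.nodes.add(node)
        name = _BACKGROUND_NAMES[rng.randrange(len(_BACKGROUND_NAMES))]
        net.attributes[node] = {"name": f"{name} {i + 1}"}

    # dense cluster: clique
    for i, a in enumerate(cluster_ids):
        for b in cluster_ids[i + 1:]:
            net.edges.append((a, b, "pp"))
    # background: random chain plus a few extra edges
    for i in range(1, len(bg_ids)):
        net.edges.append((bg_ids[rng.randrange(i)], bg_ids[i], "pp"))
    for _ in range(max(n_background_nodes // 3, 0)):
        if len(bg_ids) >= 2:
            a, b = rng.sample(bg_ids, 2)
            net.edges.append((a, b, "pp"))
    # a couple of links between cluster and background
    if bg_ids:
        for _ in range(2):
            net.edges.append(
                (
                    cluster_ids[rng.randrange(len(cluster_ids))],
                    bg_ids[rng.randrange(len(bg_ids))],
                    "pp",
                )
            )
    return net, cluster_ids


def write_fixture(
    out_dir: str | Path,
    seed: int,
    n_cluster_nodes: int = 8,
    n_background_nodes: int = 12,
) -> dict[str, Path]:
    """Emit the fixture as <dir>/fixture.sif, fixture.attrs.tsv and
    fixture.selection.txt; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    net, selection = generate_fixture(seed, n_cluster_nodes, n_background_nodes)
    sif = out_dir / "fixture.sif"
    lines = [f"{a}\t{i or 'pp'}\t{b}" for a, b, i in net.edges]
    connected = {a for a, _, _ in net.edges} | {b for _, b, _ in net.edges}
    lines += sorted(net.nodes - connected)
    sif.write_text("\n".join(lines) + "\n")
    attrs = out_dir / "fixture.attrs.tsv"
    rows = ["node\tname"]
    rows += [f"{n}\t{net.attributes[n]['name']}" for n in sorted(net.nodes)]
    attrs.write_text("\n".join(rows) + "\n")
    sel = out_dir / "fixture.selection.txt"
    sel.write_text("\n".join(selection) + "\n")
    return {"network": sif, "attributes": attrs, "selection": sel}
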