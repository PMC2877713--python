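"""Regulatory double graphs.

A genetic regulatory network is described here by a *double graph*: a single
vertex set (genes/proteins/inputs) carrying two edge sets, one of
transcriptional activations and one of repressions.  Each ordered pair
``(source, target)`` states that the protein ``source`` activates (or
represses) the gene ``target``.

Vertex roles are inferred from connectivity rather than declared: a vertex
with incoming regulation edges stands simultaneously for a gene and the
protein it encodes, while a vertex with only outgoing edges is a pure
transcription-factor input.  mRNA vertices (e.g. maternal transcripts) may be
kept in the graph for bookkeeping and excluded from the kinetics via
annotations.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "DoubleGraph",
    "GraphValidationError",
    "parse_network",
    "regulators_of",
]


class GraphValidationError(ValueError):
    """Raised when a double graph violates a structural invariant."""


Edge = tuple[str, str]


@dataclass(frozen=True)
class VertexAnnotation:
    """Per-vertex flags and optional initial concentration.

    ``constant_input`` pins the species concentration in the compiled
    kinetics (it appears in fluxes but gets no rate equation).  ``is_mrna``
    marks bookkeeping vertices (maternal transcripts) that are excluded from
    the dynamics; their effect is folded into initial protein profiles.
    """

    constant_input: bool = False
    is_mrna: bool = False
    initial_concentration: float | None = None

    def __post_init__(self) -> None:
        if self.initial_concentration is not None and self.initial_concentration < 0:
            raise GraphValidationError(
                f"initial concentration must be non-negative, got "
                f"{self.initial_concentration}"
            )


@dataclass(frozen=True)
class DoubleGraph:
    """A vertex set with ordered activation and repression edge sets.

    Edge order is meaningful: it fixes the canonical regulator ordering used
    for operon-state naming everywhere downstream, so two graphs with the
    same edges in a different order compile to identically-structured but
    differently-labelled models.
    """

    vertices: tuple[str, ...]
    activations: tuple[Edge, ...]
    repressions: tuple[Edge, ...]
    annotations: Mapping[str, VertexAnnotation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for v in self.vertices:
            if not v or not isinstance(v, str):
                raise GraphValidationError(f"invalid vertex name: {v!r}")
            if v in seen:
                raise GraphValidationError(f"duplicate vertex name: {v!r}")
            seen.add(v)
        for label, edges in (("activation", self.activations),
                             ("repression", self.repressions)):
            dup = _first_duplicate(edges)
            if dup is not None:
                raise GraphValidationError(f"duplicate {label} edge: {dup}")
            for s, t in edges:
                if s not in seen or t not in seen:
                    raise GraphValidationError(
                        f"{label} edge {(s, t)} references unknown vertex"
                    )
        clash = set(self.activations) & set(self.repressions)
        if clash:
            raise GraphValidationError(
                f"edge(s) in both activation and repression sets: {sorted(clash)}"
            )
        for name in self.annotations:
            if name not in seen:
                raise GraphValidationError(f"annotation for unknown vertex {name!r}")

    # -- role inference -------------------------------------------------

    def annotation(self, vertex: str) -> VertexAnnotation:
        return self.annotations.get(vertex, VertexAnnotation())

    def is_gene(self, vertex: str) -> bool:
        """True if the vertex stands for a gene + protein pair.

        A vertex with at least one incoming regulation edge owns an operon
        and is produced from a gene template.  mRNA bookkeeping vertices are
        never genes.
        """
        if self.annotation(vertex).is_mrna:
            return False
        acts, reps = regulators_of(self, vertex)
        if not acts and not reps:
            return False
        # regulation arriving only from mRNA vertices is a translation
        # shorthand, not transcriptional control
        real = [r for r in acts + reps if not self.annotation(r).is_mrna]
        return bool(real)

    def dynamic_vertices(self) -> list[str]:
        """Vertices that take part in the kinetics (mRNA nodes excluded)."""
        return [v for v in self.vertices if not self.annotation(v).is_mrna]

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        ann = {}
        for name, a in self.annotations.items():
            d: dict = {}
            if a.constant_input:
                d["constant_input"] = True
            if a.is_mrna:
                d["is_mrna"] = True
            if a.initial_concentration is not None:
                d["initial_concentration"] = a.initial_concentration
            ann[name] = d
        return {
            "vertices": list(self.vertices),
            "activations": [list(e) for e in self.activations],
            "repressions": [list(e) for e in self.repressions],
            "annotations": ann,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, data: Mapping) -> "DoubleGraph":
        return parse_network(
            [tuple(e) for e in data.get("activations", [])],
            [tuple(e) for e in data.get("repressions", [])],
            annotations=data.get("annotations") or None,
            extra_vertices=data.get("vertices"),
        )

    @classmethod
    def from_json(cls, source: str | Path) -> "DoubleGraph":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))

    # -- graph exports ----------------------------------------------------

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.vertices)
        for s, t in self.activations:
            g.add_edge(s, t, sign="activation")
        for s, t in self.repressions:
            g.add_edge(s, t, sign="repression")
        return g

    def to_dot(self) -> str:
        lines = ["digraph regulatory_network {"]
        for v in self.vertices:
            lines.append(f'  "{v}";')
        for s, t in self.activations:
            lines.append(f'  "{s}" -> "{t}" [arrowhead=normal, color=black];')
        for s, t in self.repressions:
            lines.append(f'  "{s}" -> "{t}" [arrowhead=tee, color=red];')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))


def _first_duplicate(edges: Sequence[Edge]) -> Edge | None:
    seen: set[Edge] = set()
    for e in edges:
        if e in seen:
            return e
        seen.add(e)
    return None


def parse_network(
    activation_pairs: Iterable[Sequence[str]],
    repression_pairs: Iterable[Sequence[str]],
    annotations: Mapping[str, Mapping] | None = None,
    extra_vertices: Iterable[str] | None = None,
) -> DoubleGraph:
    """Build a validated :class:`DoubleGraph` from two edge lists.

    The vertex set is the union of all edge endpoints, annotated vertices
    and ``extra_vertices``, in first-appearance order (edge order is the
    canonical regulator order downstream).

    Raises
    ------
    GraphValidationError
        On duplicate edges, on a pair present in both edge sets, or on
        malformed vertex names.
    """
    acts = tuple((str(s), str(t)) for s, t in activation_pairs)
    reps = tuple((str(s), str(t)) for s, t in repression_pairs)
    for s, t in acts + reps:
        if not s or not t:
            raise GraphValidationError(f"edge with empty vertex name: {(s, t)}")

    vertices: list[str] = []
    seen: set[str] = set()

    def add(v: str) -> None:
        if v not in seen:
            seen.add(v)
            vertices.append(v)

    for s, t in acts:
        add(s)
        add(t)
    for s, t in reps:
        add(s)
        add(t)
    if extra_vertices:
        for v in extra_vertices:
            add(str(v))

    ann_objs: dict[str, VertexAnnotation] = {}
    if annotations:
        for name, raw in annotations.items():
            add(str(name))
            if isinstance(raw, VertexAnnotation):
                ann_objs[name] = raw
            else:
                ann_objs[name] = VertexAnnotation(
                    constant_input=bool(raw.get("constant_input", False)),
                    is_mrna=bool(raw.get("is_mrna", False)),
                    initial_concentration=raw.get("initial_concentration"),
                )

    return DoubleGraph(tuple(vertices), acts, reps, ann_objs)


def regulators_of(graph: DoubleGraph, gene: str) -> tuple[list[str], list[str]]:
    """Incoming activators and repressors of ``gene``, in edge-input order.

    The returned order is the canonical binding-site order used by the
    compiler: one binding site per incoming edge, named after its regulator.
    """
    if gene not in graph.vertices:
        raise KeyError(f"unknown vertex {gene!r}")
    activators = [s for s, t in graph.activations if t == gene]
    repressors = [s for s, t in graph.repressions if t == gene]
    return activators, repressors


# -- CSV edge-list IO -----------------------------------------------------

def edges_to_csv(edges: Sequence[Edge]) -> str:
    buf = io.StringIO()
    w = csv.writer(buf)
    w.writerow(["source", "target"])
    for s, t in edges:
        w.writerow([s, t])
    return buf.getvalue()


def edges_from_csv(text_or_path: str | Path) -> list[Edge]:
    p = Path(text_or_path)
    text = p.read_text() if p.exists() else str(text_or_path)
    rows = list(csv.reader(io.StringIO(text)))
    if rows and rows[0][:2] == ["source", "target"]:
        rows = rows[1:]
    return [(r[0], r[1]) for r in rows if r]


def parse_network_csv(
    activation_csv: str | Path,
    repression_csv: str | Path,
    annotations: Mapping[str, Mapping] | None = None,
) -> DoubleGraph:
    """Parse a network from two two-column (source, target) CSV edge lists."""
    return parse_network(
        edges_from_csv(activation_csv), edges_from_csv(repression_csv), annotations
    )


def gapgene_graph() -> DoubleGraph:
    """The Drosophila gap-gene cross-regulation graph.

    BCD activates both HB and KNI, HB and KNI mutually repress each other,
    and TLL represses KNI.  Maternal transcripts bcd and hb are kept as
    annotated mRNA vertices: their translation is folded into the initial
    BCD/HB protein profiles rather than modeled kinetically.
    """
    return parse_network(
        [("bcd", "BCD"), ("hb", "HB"), ("BCD", "HB"), ("BCD", "KNI")],
        [("HB", "KNI"), ("KNI", "HB"), ("TLL", "KNI")],
        annotations={
            "bcd": {"is_mrna": True},
            "hb": {"is_mrna": True},
            "BCD": {"constant_input": True},
            "TLL": {"constant_input": True},
        },
    )
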