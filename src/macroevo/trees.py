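"""Rooted time-calibrated trees: Newick I/O, metrics, pruning and regime paintings.

Conventions
-----------
Ages are expressed in Myr before present: tips of an ultrametric tree sit at
age 0 and the root at ``root_height``.  Process time runs the other way,
``t = root_height - age``.  Every painting is stored in ages; the model code
converts once.

A branch is identified by the id of its *child* node.  Node ids are assigned
in preorder and are stable across round-trips through the Newick writer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Node",
    "PhyloTree",
    "RegimePainting",
    "SharedTimeMatrix",
    "NewickError",
    "parse_newick",
    "write_newick",
    "prune_to_taxa",
    "shared_time_matrix",
    "paint_time_slice",
    "paint_from_node_states",
]

ULTRAMETRIC_RTOL = 1e-6


class NewickError(ValueError):
    """Malformed Newick input; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class Node:
    __slots__ = ("label", "length", "children", "parent", "id", "depth")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.id: int = -1
        self.depth: float = 0.0

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<Node {self.id} {kind} label={self.label!r} length={self.length}>"


class PhyloTree:
    """A rooted tree with branch lengths in Myr.

    Parameters
    ----------
    root : Node
        Root of a fully linked node structure; non-root nodes must carry
        branch lengths.
    require_ultrametric : bool
        If True, verify that all root-to-tip path lengths agree to a relative
        tolerance of 1e-6.
    """

    def __init__(self, root: Node, require_ultrametric: bool = False):
        self.root = root
        self._index()
        if any(
            n.length is None or n.length < 0 for n in self.nodes if n is not root
        ):
            bad = [n.id for n in self.nodes if n is not root and (n.length is None or n.length < 0)]
            raise ValueError(f"missing or negative branch lengths on nodes {bad}")
        labels = [t.label for t in self.tips]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        if require_ultrametric and not self.is_ultrametric():
            raise ValueError("tree is not ultrametric within relative tolerance 1e-6")

    # -- structure -----------------------------------------------------

    def _index(self) -> None:
        self.nodes: list[Node] = []
        stack = [self.root]
        self.root.parent = None
        self.root.depth = 0.0
        while stack:  # preorder
            node = stack.pop()
            node.id = len(self.nodes)
            self.nodes.append(node)
            for child in reversed(node.children):
                child.parent = node
                child.depth = node.depth + (child.length or 0.0)
                stack.append(child)
        self.tips: list[Node] = [n for n in self.nodes if n.is_tip]
        self.taxa: list[str] = [t.label for t in self.tips]
        self.root_height: float = max(t.depth for t in self.tips)
        self._tip_index = {t.label: i for i, t in enumerate(self.tips)}

    def postorder(self) -> Iterator[Node]:
        return reversed(self.nodes)

    def preorder(self) -> Iterator[Node]:
        return iter(self.nodes)

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def node_age(self, node: Node) -> float:
        return self.root_height - node.depth

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        depths = np.array([t.depth for t in self.tips])
        return bool(np.all(np.abs(depths - self.root_height) <= rtol * self.root_height))

    def tip_sets(self) -> dict[int, np.ndarray]:
        """Map node id -> sorted array of tip indices below it (tips included)."""
        out: dict[int, list[int]] = {}
        for node in self.postorder():
            if node.is_tip:
                out[node.id] = [self._tip_index[node.label]]
            else:
                acc: list[int] = []
                for c in node.children:
                    acc.extend(out[c.id])
                out[node.id] = acc
        return {k: np.array(sorted(v), dtype=np.intp) for k, v in out.items()}

    def copy(self) -> "PhyloTree":
        return parse_newick(write_newick(self))

    def newick(self) -> str:
        return write_newick(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return write_newick(self) == write_newick(other)

    def __hash__(self):
        return hash(write_newick(self))


# -- Newick ------------------------------------------------------------


def parse_newick(text: str, default_length: float | None = None) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Raises :class:`NewickError` naming the character offset on syntax errors;
    branch lengths are mandatory unless ``default_length`` is given.
    """
    s = text.strip()
    pos = 0

    def error(msg: str) -> NewickError:
        return NewickError(msg, pos)

    def parse_clade() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                child = parse_clade()
                child.parent = node
                node.children.append(child)
                if pos >= len(s):
                    raise error("unexpected end of input inside clade")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise error(f"expected ',' or ')', found {s[pos]!r}")
        node.label = parse_label()
        if pos < len(s) and s[pos] == ":":
            pos += 1
            node.length = parse_number()
        return node

    def parse_label() -> str | None:
        nonlocal pos
        if pos < len(s) and s[pos] in "'\"":
            quote = s[pos]
            end = s.find(quote, pos + 1)
            if end < 0:
                raise error("unterminated quoted label")
            label = s[pos + 1 : end]
            pos = end + 1
            return label
        start = pos
        while pos < len(s) and s[pos] not in "():,;[]":
            pos += 1
        return s[start:pos] or None

    def parse_number() -> float:
        nonlocal pos
        start = pos
        while pos < len(s) and (s[pos].isdigit() or s[pos] in ".-+eE"):
            pos += 1
        try:
            return float(s[start:pos])
        except ValueError:
            raise error("expected a branch length") from None

    if not s:
        raise NewickError("empty input", 0)
    root = parse_clade()
    if pos >= len(s) or s[pos] != ";":
        raise error("expected ';' at end of tree")
    pos += 1
    if s[pos:].strip():
        raise error("trailing characters after ';'")

    if default_length is not None:
        stack = [root]
        while stack:
            n = stack.pop()
            for c in n.children:
                if c.length is None:
                    c.length = default_length
                stack.append(c)
    missing = _find_missing_length(root)
    if missing is not None:
        raise ValueError(
            f"missing branch length on node labelled {missing.label!r}; "
            "pass default_length to supply one"
        )
    return PhyloTree(root)


def _find_missing_length(root: Node) -> Node | None:
    stack = list(root.children)
    while stack:
        n = stack.pop()
        if n.length is None:
            return n
        stack.extend(n.children)
    return None


def _quote_if_needed(label: str) -> str:
    if any(c in label for c in "():,;[] '\""):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: PhyloTree, precision: int = 17) -> str:
    def fmt(node: Node) -> str:
        if node.is_tip:
            core = _quote_if_needed(node.label or "")
        else:
            core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.label:
                core += _quote_if_needed(node.label)
        if node.length is not None:
            core += f":{node.length:.{precision}g}"
        return core

    return fmt(tree.root) + ";"


# -- metrics -----------------------------------------------------------


@dataclass
class SharedTimeMatrix:
    """Entry (i, j) = path length from the root to MRCA(i, j); diagonal = tip depth."""

    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")

    def reindex(self, taxa: Sequence[str]) -> "SharedTimeMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return SharedTimeMatrix(list(taxa), self.matrix[np.ix_(idx, idx)])


def shared_time_matrix(tree: PhyloTree) -> SharedTimeMatrix:
    n = tree.n_tips
    C = np.zeros((n, n))
    tipsets = tree.tip_sets()
    # preorder: deeper nodes overwrite shallower blocks
    for node in tree.preorder():
        if node.is_tip:
            continue
        for a_i, a in enumerate(node.children):
            for b in node.children[a_i + 1 :]:
                ia, ib = tipsets[a.id], tipsets[b.id]
                C[np.ix_(ia, ib)] = node.depth
                C[np.ix_(ib, ia)] = node.depth
    for t in tree.tips:
        C[tree._tip_index[t.label], tree._tip_index[t.label]] = t.depth
    return SharedTimeMatrix(list(tree.taxa), C)


def repair_ultrametry(tree: PhyloTree) -> PhyloTree:
    """Rescale terminal branches so every tip reaches the maximum depth.

    Off by default everywhere; use only when a tree fails the ultrametric
    check by rounding noise.
    """
    t = parse_newick(write_newick(tree))
    target = t.root_height
    for tip in t.tips:
        tip.length += target - tip.depth  # target is the max depth: never shrinks
    return PhyloTree(t.root)


def prune_to_taxa(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Induced subtree on ``keep``; unary nodes are suppressed with lengths summed."""
    keep = set(keep)
    unknown = sorted(keep - set(tree.taxa))
    if unknown:
        raise ValueError(f"unknown taxa: {unknown}")
    if len(keep) < 2:
        raise ValueError("need at least 2 taxa to keep")

    def rebuild(node: Node) -> Node | None:
        if node.is_tip:
            if node.label in keep:
                out = Node(node.label, node.length)
                return out
            return None
        kids = [k for k in (rebuild(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:  # suppress unary node
            child = kids[0]
            if node.length is not None:
                child.length = (child.length or 0.0) + node.length
            return child
        out = Node(node.label, node.length)
        for k in kids:
            k.parent = out
        out.children = kids
        return out

    new_root = rebuild(tree.root)
    assert new_root is not None
    new_root.length = None  # root carries no branch
    return PhyloTree(new_root)


# -- paintings ---------------------------------------------------------


@dataclass
class RegimePainting:
    """Per-branch age-interval regimes.

    ``segments[branch_id]`` is an ordered list of ``(start_age, end_age, state)``
    with ``start_age > end_age`` that exactly tiles the branch from its parent
    end (older) to its child end (younger).
    """

    states: list[str]
    segments: dict[int, list[tuple[float, float, str]]] = field(default_factory=dict)

    def validate(self, tree: PhyloTree, atol: float = 1e-9) -> None:
        used = set()
        for node in tree.nodes:
            if node is tree.root:
                continue
            segs = self.segments.get(node.id)
            if segs is None:
                raise ValueError(f"branch {node.id} unpainted")
            top = tree.node_age(node.parent)
            bottom = tree.node_age(node)
            cursor = top
            for start, end, state in segs:
                if abs(start - cursor) > atol or end > start + atol:
                    raise ValueError(f"segments on branch {node.id} do not tile it")
                cursor = end
                used.add(state)
            if abs(cursor - bottom) > atol:
                raise ValueError(f"segments on branch {node.id} do not reach the child")
        missing = used - set(self.states)
        if missing:
            raise ValueError(f"states used but not declared: {sorted(missing)}")

    def n_states_used(self) -> int:
        return len({s for segs in self.segments.values() for _, _, s in segs})

    def to_json(self) -> str:
        return json.dumps(
            {"states": self.states, "segments": {str(k): v for k, v in self.segments.items()}}
        )

    @classmethod
    def from_json(cls, text: str) -> "RegimePainting":
        d = json.loads(text)
        return cls(
            states=list(d["states"]),
            segments={
                int(k): [(float(a), float(b), s) for a, b, s in v]
                for k, v in d["segments"].items()
            },
        )


def single_state_painting(tree: PhyloTree, state: str = "0") -> RegimePainting:
    segs = {}
    for node in tree.nodes:
        if node is tree.root:
            continue
        segs[node.id] = [(tree.node_age(node.parent), tree.node_age(node), state)]
    return RegimePainting([state], segs)


def paint_time_slice(tree: PhyloTree, slice_age: float) -> RegimePainting:
    """Two-state painting: "pre" older than ``slice_age``, "post" younger.

    A branch spanning the slice age is split into two segments at that age.
    """
    if slice_age < 0:
        raise ValueError("slice_age must be >= 0")
    segs: dict[int, list[tuple[float, float, str]]] = {}
    for node in tree.nodes:
        if node is tree.root:
            continue
        top = tree.node_age(node.parent)
        bottom = tree.node_age(node)
        if bottom >= slice_age:
            segs[node.id] = [(top, bottom, "pre")]
        elif top <= slice_age:
            segs[node.id] = [(top, bottom, "post")]
        else:
            segs[node.id] = [(top, slice_age, "pre"), (slice_age, bottom, "post")]
    return RegimePainting(["pre", "post"], segs)


def paint_from_node_states(
    tree: PhyloTree,
    tip_states: Mapping[str, str],
    node_states: Mapping[int, str],
) -> RegimePainting:
    """Paint every branch in the state of its child node (stem-of-clade rule)."""
    segs: dict[int, list[tuple[float, float, str]]] = {}
    states: list[str] = []
    for node in tree.nodes:
        if node is tree.root:
            continue
        if node.is_tip:
            if node.label not in tip_states:
                raise ValueError(f"no state for tip {node.label!r}")
            state = tip_states[node.label]
        else:
            if node.id not in node_states:
                raise ValueError(f"no state for internal node {node.id}")
            state = node_states[node.id]
        segs[node.id] = [(tree.node_age(node.parent), tree.node_age(node), state)]
        if state not in states:
            states.append(state)
    return RegimePainting(states, segs)
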