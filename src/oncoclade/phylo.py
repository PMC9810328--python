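"""Time-calibrated phylogenies: reading, writing, validation, grafting, pruning.

Trees are rooted, with branch lengths in millions of years (My). Tips need
not be contemporaneous: a tip whose root-to-tip path is shorter than the
longest one is an extinct lineage with ``tip_age > 0`` (time before present).
Newick parsing and serialisation are delegated to :mod:`dendropy`; the
in-package :class:`TimeTree` adds the age bookkeeping, clade-replacement
grafting, and pruning that the comparative pipeline needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator

import dendropy

__all__ = [
    "TreeError",
    "Node",
    "TimeTree",
    "CladeGraftSpec",
    "read_newick",
    "write_newick",
    "read_synonym_table",
    "apply_synonyms",
]

#: Replacement for zero-length input branches (My). Zero branches make the
#: Brownian covariance singular downstream, so they are nudged, with a warning.
EPSILON_BRANCH = 1e-6

#: Tolerance for age arithmetic (My).
AGE_TOL = 1e-6

import re as _re

#: Auto-generated internal-node ids (assigned in preorder when unlabelled).
_AUTO_LABEL = _re.compile(r"^N\d+$")


class TreeError(ValueError):
    """Raised for malformed trees or invalid tree operations."""


class Node:
    """A node in a rooted time tree."""

    __slots__ = ("label", "parent", "children", "branch_length")

    def __init__(self, label=None, branch_length=None):
        self.label: str | None = label
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.branch_length: float | None = branch_length  # None only at root

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Node({self.label!r})"


class TimeTree:
    """Rooted, dated phylogeny with branch lengths in My.

    Node ages are derived quantities: the root age is the maximum
    root-to-tip path length, and every node's age is ``root_age`` minus its
    depth. Extant tips have age 0; extinct tips have positive age.
    """

    def __init__(self, root: Node):
        self.root = root
        self._autolabel()

    # ------------------------------------------------------------------ basics
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return reversed(out)

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def find(self, label: str) -> Node:
        for n in self.preorder():
            if n.label == label:
                return n
        raise TreeError(f"no node labelled {label!r}")

    def _autolabel(self) -> None:
        """Give unlabelled internal nodes stable preorder ids N0, N1, ..."""
        used = {n.label for n in self.preorder() if n.label is not None}
        i = 0
        for n in self.preorder():
            if n.label is None:
                while f"N{i}" in used:
                    i += 1
                n.label = f"N{i}"
                used.add(n.label)

    # -------------------------------------------------------------------- ages
    def depths(self) -> dict[Node, float]:
        """Root-to-node path lengths (root depth 0)."""
        d = {self.root: 0.0}
        for n in self.preorder():
            if n is not self.root:
                d[n] = d[n.parent] + n.branch_length
        return d

    @property
    def root_age(self) -> float:
        d = self.depths()
        return max(d[t] for t in self.tips())

    def node_ages(self) -> dict[str, float]:
        d = self.depths()
        ra = max(d[t] for t in self.tips())
        return {n.label: ra - d[n] for n in self.preorder()}

    def tip_ages(self) -> dict[str, float]:
        ages = self.node_ages()
        return {t.label: ages[t.label] for t in self.tips()}

    # -------------------------------------------------------------- validation
    def validate(self) -> None:
        seen: set[int] = set()
        labels: set[str] = set()
        for n in self.preorder():
            if id(n) in seen:
                raise TreeError("cycle detected in tree")
            seen.add(id(n))
            if n.label in labels:
                raise TreeError(f"duplicate node label {n.label!r}")
            labels.add(n.label)
            if n is self.root:
                if n.parent is not None:
                    raise TreeError("root must not have a parent")
            else:
                if n.parent is None:
                    raise TreeError(f"non-root node {n.label!r} lacks a parent")
                if n.branch_length is None:
                    raise TreeError(f"node {n.label!r} lacks a branch length")
                if n.branch_length <= 0:
                    raise TreeError(
                        f"node {n.label!r} has non-positive branch length "
                        f"{n.branch_length}"
                    )
        ages = self.node_ages()
        for label, age in ages.items():
            if age < -AGE_TOL:
                raise TreeError(f"node {label!r} has negative age {age}")

    # --------------------------------------------------------------------- ops
    def copy(self) -> "TimeTree":
        def rec(node: Node) -> Node:
            clone = Node(node.label, node.branch_length)
            for c in node.children:
                clone.add_child(rec(c))
            return clone

        return TimeTree(rec(self.root))

    def mrca(self, labels: Iterable[str]) -> Node:
        labels = set(labels)
        tip_map = {t.label: t for t in self.tips()}
        missing = labels - tip_map.keys()
        if missing:
            raise TreeError(f"unknown taxa: {sorted(missing)}")
        paths = []
        for lab in labels:
            path = []
            n = tip_map[lab]
            while n is not None:
                path.append(n)
                n = n.parent
            paths.append(list(reversed(path)))
        mrca = self.root
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                mrca = level[0]
            else:
                break
        return mrca

    def extract_clade(self, label: str) -> "TimeTree":
        """The subtree rooted at ``label`` as a standalone tree."""
        node = self.find(label)

        def rec(n: Node) -> Node:
            clone = Node(n.label, n.branch_length)
            for c in n.children:
                clone.add_child(rec(c))
            return clone

        root = rec(node)
        root.branch_length = None
        return TimeTree(root)

    def clade_tips(self, node: Node) -> set[str]:
        stack, out = [node], set()
        while stack:
            n = stack.pop()
            if n.is_tip:
                out.add(n.label)
            stack.extend(n.children)
        return out


@dataclass
class CladeGraftSpec:
    """Replace a monophyletic clade of a host tree with another tree.

    ``attachment`` is either a set of tip labels defining the clade or the
    label of an internal node. When the replacement tree's root age disagrees
    with the age of the replaced crown node by more than ``age_tol`` My, all
    replacement branch lengths are rescaled proportionally (if ``rescale``),
    otherwise the graft is refused.
    """

    attachment: set[str] | str
    replacement: TimeTree
    age_tol: float = 1e-3
    rescale: bool = True


# ---------------------------------------------------------------------- newick
def read_newick(text: str, epsilon: float = EPSILON_BRANCH) -> TimeTree:
    """Parse a Newick string (branch lengths required) into a :class:`TimeTree`.

    Zero-length branches are replaced by ``epsilon`` with a warning; missing
    branch lengths are an error.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label=label, branch_length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    root.branch_length = None  # root edge length, if any, is ignored
    for node in _preorder(root):
        if node is root:
            continue
        if node.branch_length is None:
            raise TreeError(
                f"missing branch length on node {node.label or '<internal>'!r}"
            )
        if node.branch_length == 0:
            warnings.warn(
                f"zero-length branch at {node.label or '<internal>'!r} "
                f"replaced by epsilon={epsilon}",
                stacklevel=2,
            )
            node.branch_length = epsilon
    tree = TimeTree(root)
    tree.validate()
    return tree


def _preorder(root: Node) -> Iterator[Node]:
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(reversed(n.children))


def write_newick(tree: TimeTree, internal_labels: bool = True) -> str:
    """Serialise a :class:`TimeTree` to a Newick string."""

    def rec(node: Node) -> str:
        if node.is_tip:
            s = _quote(node.label)
        else:
            inner = ",".join(rec(c) for c in node.children)
            lab = _quote(node.label) if internal_labels and node.label else ""
            s = f"({inner}){lab}"
        if node.branch_length is not None:
            s += f":{node.branch_length:.12g}"
        return s

    return rec(tree.root) + ";"


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]{}:;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


# --------------------------------------------------------------------- synonyms
def read_synonym_table(path) -> dict[str, str]:
    """Two-column delimited table (source label, canonical label)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            if len(parts) != 2:
                raise TreeError(f"synonym table line {i}: expected 2 columns")
            mapping[parts[0].strip()] = parts[1].strip()
    return mapping


def apply_synonyms(tree: TimeTree, mapping: dict[str, str]) -> TimeTree:
    out = tree.copy()
    for n in out.preorder():
        if n.label in mapping:
            n.label = mapping[n.label]
    out.validate()
    return out


# --------------------------------------------------------------------- grafting
def graft_clade(host: TimeTree, spec: CladeGraftSpec) -> TimeTree:
    """Replace a monophyletic clade of ``host`` with ``spec.replacement``.

    The stem branch (parent -> replaced crown node) of the host is retained;
    the replacement subtree is rescaled so its root age equals the replaced
    crown node's age when they disagree by more than ``spec.age_tol``.
    """
    host = host.copy()
    if isinstance(spec.attachment, str):
        target = host.find(spec.attachment)
    else:
        target = host.mrca(spec.attachment)
        clade = host.clade_tips(target)
        extra = clade - set(spec.attachment)
        if extra:
            raise TreeError(
                "attachment taxa are not monophyletic; clade also contains "
                f"{sorted(extra)}"
            )

    slot_age = host.node_ages()[target.label]
    repl = spec.replacement.copy()
    repl_age = repl.root_age
    if abs(repl_age - slot_age) > spec.age_tol:
        if not spec.rescale:
            raise TreeError(
                f"replacement root age {repl_age:g} does not match slot age "
                f"{slot_age:g} and rescaling is disabled"
            )
        if repl_age <= 0:
            raise TreeError("replacement tree has zero depth; cannot rescale")
        factor = slot_age / repl_age
        for n in repl.preorder():
            if n.branch_length is not None:
                n.branch_length *= factor

    new_root = repl.root
    if target is host.root:
        out = TimeTree(new_root)
    else:
        parent = target.parent
        new_root.branch_length = target.branch_length
        parent.children[parent.children.index(target)] = new_root
        new_root.parent = parent
        # re-generate colliding auto ids (N#) in the incoming subtree
        incoming = set(map(id, _preorder(new_root)))
        host_labels = {
            n.label for n in _preorder(host.root) if id(n) not in incoming
        }
        i = 0
        for n in _preorder(new_root):
            if n.label in host_labels:
                if not _AUTO_LABEL.match(n.label):
                    raise TreeError(
                        f"replacement label {n.label!r} collides with host"
                    )
                while f"N{i}" in host_labels:
                    i += 1
                n.label = f"N{i}"
                host_labels.add(n.label)
        out = TimeTree(host.root)
    out.validate()
    return out


# ---------------------------------------------------------------------- pruning
def prune_to_taxa(tree: TimeTree, taxa: Iterable[str]) -> TimeTree:
    """Induced subtree on ``taxa``; single-child internal nodes are suppressed.

    The root is always retained, so root-to-tip path lengths (and hence tip
    ages relative to the original root) are preserved.
    """
    taxa = set(taxa)
    known = set(tree.tip_labels())
    unknown = taxa - known
    if unknown:
        raise TreeError(f"unknown taxa: {sorted(unknown)}")
    if not taxa:
        raise TreeError("cannot prune to an empty taxon set")

    src = tree.copy()
    keep: set[int] = set()
    tip_map = {t.label: t for t in src.tips()}
    for lab in taxa:
        n = tip_map[lab]
        while n is not None and id(n) not in keep:
            keep.add(id(n))
            n = n.parent

    def rebuild(node: Node) -> Node | None:
        kept_children = [rebuild(c) for c in node.children]
        kept_children = [c for c in kept_children if c is not None]
        if node.is_tip:
            if id(node) in keep:
                return Node(node.label, node.branch_length)
            return None
        if not kept_children:
            return None
        if len(kept_children) == 1 and node.parent is not None:
            # suppress degree-2 node: merge branch lengths
            child = kept_children[0]
            child.branch_length += node.branch_length
            return child
        clone = Node(node.label, node.branch_length)
        for c in kept_children:
            clone.add_child(c)
        return clone

    new_root = rebuild(src.root)
    assert new_root is not None
    new_root.branch_length = None
    out = TimeTree(new_root)
    out.validate()
    return out
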