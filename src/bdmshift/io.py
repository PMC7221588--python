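"""Alignment and tree input/output.

Reads aligned protein FASTA into :class:`ProteinAlignment` and Newick trees
into :class:`Phylogeny`, validating both into the forms the likelihood
machinery expects.  Internal nodes receive deterministic post-order integer
labels so branches can be referred to as ``"<parent>-<child>"`` strings in
reports and on the command line.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterator

import dendropy
from Bio import SeqIO

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP_CHARS = frozenset("-X")
ALPHABET = frozenset(AMINO_ACIDS) | GAP_CHARS


class AlignmentError(ValueError):
    """Raised when a FASTA file does not validate as a protein alignment."""


class TreeError(ValueError):
    """Raised when a Newick file does not validate as a phylogeny."""


@dataclass
class ProteinAlignment:
    """Aligned protein sequences over the 20 amino acids plus '-' and 'X'.

    Rows are upper-case strings of identical length; names are unique,
    nonempty identifiers in file order.
    """

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.names:
            raise AlignmentError("alignment has no sequences")
        if len(self.names) != len(self.rows):
            raise AlignmentError("names and rows differ in count")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise AlignmentError(f"duplicate sequence identifiers: {dupes}")
        if any(not n for n in self.names):
            raise AlignmentError("empty sequence identifier")
        self.rows = [r.upper() for r in self.rows]
        L = len(self.rows[0])
        if L < 1:
            raise AlignmentError(f"zero-length alignment row for {self.names[0]!r}")
        for name, row in zip(self.names, self.rows):
            if len(row) != L:
                raise AlignmentError(
                    f"ragged alignment: {name!r} has length {len(row)}, expected {L}"
                )
            for pos, ch in enumerate(row):
                if ch not in ALPHABET:
                    raise AlignmentError(
                        f"illegal character {ch!r} in {name!r} at column {pos + 1}"
                    )

    @property
    def N(self) -> int:
        return len(self.rows)

    @property
    def L(self) -> int:
        return len(self.rows[0])

    def row(self, name: str) -> str:
        try:
            return self.rows[self.names.index(name)]
        except ValueError:
            raise KeyError(f"no sequence named {name!r}") from None

    def ungapped(self, name: str) -> str:
        return self.row(name).replace("-", "")


@dataclass
class Node:
    """A node in a rooted phylogeny.

    ``index`` is the deterministic post-order label; ``length`` is the branch
    to the parent in substitutions/site (0.0 at the root).
    """

    index: int
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Phylogeny:
    """Rooted tree with branch lengths and stable integer node labels.

    Unrooted Newick inputs are held at an arbitrary root; every likelihood
    computed downstream is invariant to that choice under reversible models.
    Node labels are assigned in post-order starting at ``offset`` so users can
    reproduce externally numbered branches (for example MEGA-style labels).
    """

    def __init__(self, root: Node):
        self.root = root
        self._by_index = {n.index: n for n in self.postorder()}
        if len(self._by_index) != sum(1 for _ in self.postorder()):
            raise TreeError("internal node labels are not unique")

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    @property
    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves]

    def node(self, index: int) -> Node:
        try:
            return self._by_index[index]
        except KeyError:
            raise KeyError(f"no node with label {index}") from None

    # -- branches ----------------------------------------------------------

    def branches(self) -> list[tuple[Node, Node]]:
        """All (parent, child) pairs."""
        return [(n.parent, n) for n in self.postorder() if n.parent is not None]

    def branch(self, parent_index: int, child_index: int) -> tuple[Node, Node]:
        child = self.node(child_index)
        parent = self.node(parent_index)
        if child.parent is not parent:
            # accept the pair in either order
            if parent.parent is child:
                parent, child = child, parent
            else:
                raise KeyError(
                    f"{parent_index}-{child_index} is not a branch of this tree"
                )
        return parent, child

    def parse_branch(self, text: str) -> tuple[Node, Node]:
        """Resolve a branch named ``"<id>-<id>"`` as printed in reports."""
        try:
            a, b = (int(part) for part in text.split("-"))
        except ValueError:
            raise TreeError(f"branch spec {text!r} is not of the form ID-ID") from None
        return self.branch(a, b)

    def copy(self) -> "Phylogeny":
        def clone(node: Node, parent: Node | None) -> Node:
            new = Node(node.index, node.name, node.length, node.support, [], parent)
            new.children = [clone(c, new) for c in node.children]
            return new

        return Phylogeny(clone(self.root, None))

    def bind(self, aln: ProteinAlignment) -> None:
        """Check that every leaf name has a row in the alignment."""
        missing = set(self.leaf_names) - set(aln.names)
        if missing:
            raise TreeError(f"leaves without alignment rows: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self._by_index)


# ---------------------------------------------------------------------------
# readers / writers


def read_fasta_alignment(path) -> ProteinAlignment:
    """Read an aligned protein FASTA file into a validated alignment."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return ProteinAlignment(
        names=[r.id for r in records], rows=[str(r.seq) for r in records]
    )


def _from_dendropy(tree: dendropy.Tree, offset: int) -> Phylogeny:
    index = offset
    mapping: dict[dendropy.Node, Node] = {}
    for dnode in tree.postorder_node_iter():
        support = None
        label = dnode.label
        if label is not None and not dnode.is_leaf():
            try:
                support = float(label)
            except ValueError:
                support = None
        node = Node(
            index=index,
            name=dnode.taxon.label if dnode.taxon is not None else None,
            length=float(dnode.edge.length) if dnode.edge.length is not None else 0.0,
            support=support,
        )
        if node.length < 0:
            raise TreeError(f"negative branch length {node.length} in tree")
        mapping[dnode] = node
        for child in dnode.child_nodes():
            mapping[child].parent = node
            node.children.append(mapping[child])
        index += 1
    root = mapping[tree.seed_node]
    root.length = 0.0
    return Phylogeny(root)


def read_newick(path, offset: int = 0) -> Phylogeny:
    """Read a Newick tree; missing branch lengths become 0.

    Internal-node numbering is post-order starting at ``offset``, so repeated
    reads of the same file give identical labels.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"could not parse Newick file {path}: {exc}") from exc
    return _from_dendropy(tree, offset)


def read_newick_string(text: str, offset: int = 0) -> Phylogeny:
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeError(f"could not parse Newick string: {exc}") from exc
    return _from_dendropy(tree, offset)


def to_newick(tree: Phylogeny, annotations: dict[int, str] | None = None) -> str:
    """Render as Newick, optionally with per-node bracket comments.

    ``annotations`` maps node labels to comment text emitted as
    ``[&label=...]`` after the node.  Unknown labels raise ``KeyError``.
    """
    annotations = dict(annotations or {})
    known = {n.index for n in tree.postorder()}
    unknown = set(annotations) - known
    if unknown:
        raise KeyError(f"annotations for nodes not in tree: {sorted(unknown)}")

    def render(node: Node) -> str:
        comment = f"[&{annotations[node.index]}]" if node.index in annotations else ""
        if node.is_leaf:
            return f"{node.name}{comment}:{node.length:.10g}"
        inner = ",".join(render(c) for c in node.children)
        support = "" if node.support is None else f"{node.support:g}"
        if node.parent is None:
            return f"({inner}){support}{comment}"
        return f"({inner}){support}{comment}:{node.length:.10g}"

    return render(tree.root) + ";"


def write_annotated_newick(tree: Phylogeny, path, annotations=None) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree, annotations) + "\n")


def write_fasta(names: list[str], rows: list[str], path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(names, rows):
            fh.write(f">{name}\n{row}\n")
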