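"""Trees, alignments, standard-format I/O and focal-split manipulation.

Trees are stored rooted (possibly with a trifurcating root) for traversal,
but all split/clade semantics are unrooted: a clade tag matches a branch if
the branch's leaf bipartition has the tagged leaf set on either side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from io import StringIO
from typing import Iterator

import dendropy
import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
GAP_CODE = 20
_AA_INDEX = {c: i for i, c in enumerate(AA_ALPHABET)}

__all__ = [
    "AA_ALPHABET",
    "GAP_CODE",
    "Node",
    "Tree",
    "Alignment",
    "BlmfSpec",
    "NewickParseError",
    "CladeError",
    "StructureError",
    "read_newick",
    "write_newick",
    "load_fixture_tree",
    "fixture_clade_config",
    "read_alignment",
    "write_alignment",
    "apply_blmf",
    "clade_branch_length",
    "focal_split_resolutions",
    "resolution_label",
    "bipartitions",
    "rf_distance",
]


class NewickParseError(ValueError):
    """Malformed Newick input."""


class CladeError(KeyError):
    """A clade tag is missing or does not resolve in the tree."""


class StructureError(ValueError):
    """Tags do not form the required structure (e.g. quartet around one edge)."""


class Node:
    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def copy(self) -> "Node":
        dup = Node(self.name, self.length)
        for c in self.children:
            dup.add_child(c.copy())
        return dup


class Tree:
    """Rooted container with unrooted split semantics and named clade tags."""

    def __init__(self, root: Node, clades: dict[str, frozenset[str]] | None = None):
        self.root = root
        self.clades: dict[str, frozenset[str]] = dict(clades or {})
        self._validate()

    def _validate(self) -> None:
        names = self.leaf_names
        if len(names) != len(set(names)):
            raise ValueError("duplicate leaf names in tree")
        for node in self.root.postorder():
            if node.length < 0:
                raise ValueError(f"negative branch length on node {node.name!r}")
        leafset = frozenset(names)
        for tag, members in self.clades.items():
            if not members <= leafset:
                raise CladeError(f"clade tag {tag!r} names leaves absent from tree")

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.postorder() if n.is_leaf]

    @property
    def leafset(self) -> frozenset[str]:
        return frozenset(self.leaf_names)

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def copy(self) -> "Tree":
        return Tree(self.root.copy(), dict(self.clades))

    def leafsets_below(self) -> dict[Node, frozenset[str]]:
        below: dict[Node, frozenset[str]] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                below[node] = frozenset([node.name])
            else:
                below[node] = frozenset().union(*(below[c] for c in node.children))
        return below

    def find_clade_node(self, leafset: frozenset[str]) -> Node | None:
        """Node whose branch subtends `leafset` (checks both edge sides)."""
        below = self.leafsets_below()
        all_leaves = self.leafset
        for node, s in below.items():
            if node is self.root:
                continue
            if s == leafset or all_leaves - s == leafset:
                return node
        return None

    def total_length(self) -> float:
        return sum(n.length for n in self.root.postorder() if n is not self.root)


@dataclass(frozen=True)
class BlmfSpec:
    """Branch-length multiplier applied to the branches subtending tagged clades."""

    factor: float
    target_tags: tuple[str, ...] = ("AB", "EF")

    def __post_init__(self):
        if self.factor <= 0:
            raise ValueError("BLMF factor must be positive")


# ---------------------------------------------------------------------------
# Newick I/O


def read_newick(text: str, clades: dict[str, frozenset[str]] | None = None) -> Tree:
    """Parse a Newick string (one tree) into a Tree."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as exc:  # dendropy raises several tokenizer error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label, dnode.edge.length or 0.0)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    root.length = 0.0
    return Tree(root, clades)


def write_newick(tree: Tree) -> str:
    """Serialize with 10 significant digits so round trips are lossless."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            body = node.name or ""
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")" + (node.name or "")
        if node.parent is None:
            return body
        return f"{body}:{node.length:.10g}"

    return fmt(tree.root) + ";"


def fixture_clade_config() -> dict:
    with resources.files("lbamix.data").joinpath("clades.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_fixture_tree(name: str) -> Tree:
    """Load a bundled fixture tree ('farris' or 'felsenstein') with clade tags."""
    cfg = fixture_clade_config()
    clades = {tag: frozenset(members) for tag, members in cfg["clades"].items()}
    path = resources.files("lbamix.data").joinpath(f"{name}.nwk")
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise CladeError(f"no bundled fixture tree named {name!r}")
    return read_newick(text, clades)


# ---------------------------------------------------------------------------
# Alignments


class Alignment:
    """Taxa x sites amino-acid matrix; residues stored as integer codes.

    Codes 0..19 index ``AA_ALPHABET``; 20 marks gap/ambiguity (input only:
    simulated alignments never contain it).  ``site_truth`` optionally records
    the generating mixture component and rate class per site.
    """

    def __init__(
        self,
        taxa: list[str],
        codes: np.ndarray,
        site_truth: dict[str, np.ndarray] | None = None,
    ):
        codes = np.asarray(codes, dtype=np.uint8)
        if codes.ndim != 2 or codes.shape[0] != len(taxa):
            raise ValueError("codes must be a (n_taxa, n_sites) matrix")
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon names")
        if codes.size and codes.max() > GAP_CODE:
            raise ValueError("invalid residue codes")
        self.taxa = list(taxa)
        self.codes = codes
        self.site_truth = site_truth

    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def sequence(self, taxon: str) -> str:
        row = self.codes[self.taxa.index(taxon)]
        return "".join((AA_ALPHABET + "-")[c] for c in row)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.taxa == other.taxa
            and np.array_equal(self.codes, other.codes)
        )

    def subset_sites(self, idx: np.ndarray) -> "Alignment":
        return Alignment(self.taxa, self.codes[:, idx])


def _encode(seq: str, taxon: str) -> np.ndarray:
    arr = np.empty(len(seq), dtype=np.uint8)
    flagged = False
    for i, ch in enumerate(seq.upper()):
        code = _AA_INDEX.get(ch)
        if code is None:
            arr[i] = GAP_CODE
            if ch not in "-.?X":
                flagged = True
        else:
            arr[i] = code
    if flagged:
        warnings.warn(f"unknown residue letters in {taxon!r} mapped to ambiguity")
    return arr


def _build_alignment(records: list[tuple[str, str]]) -> Alignment:
    if not records:
        raise ValueError("empty alignment input")
    names = [n for n, _ in records]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate taxon name(s): {dup}")
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment rows: lengths {sorted(lengths)}")
    codes = np.stack([_encode(seq, name) for name, seq in records])
    return Alignment(names, codes)


def _read_fasta(text: str) -> Alignment:
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(StringIO(text), "fasta")]
    return _build_alignment(records)


def _read_phylip(text: str) -> Alignment:
    """Relaxed sequential PHYLIP: header 'ntaxa nsites', then 'name sequence'."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty PHYLIP input")
    try:
        n_taxa, n_sites = (int(tok) for tok in lines[0].split())
    except ValueError as exc:
        raise ValueError(f"bad PHYLIP header: {lines[0]!r}") from exc
    records: list[tuple[str, str]] = []
    for ln in lines[1:]:
        parts = ln.split(None, 1)
        if len(parts) == 1 and records:
            # continuation line of the previous sequence
            records[-1] = (records[-1][0], records[-1][1] + parts[0].replace(" ", ""))
        else:
            name, seq = parts[0], (parts[1] if len(parts) > 1 else "")
            records.append((name, seq.replace(" ", "")))
    if len(records) != n_taxa:
        raise ValueError(f"PHYLIP header says {n_taxa} taxa, found {len(records)}")
    aln = _build_alignment(records)
    if aln.n_sites != n_sites:
        raise ValueError(f"PHYLIP header says {n_sites} sites, found {aln.n_sites}")
    return aln


def read_alignment(source, format: str = "fasta") -> Alignment:
    """Read an alignment from a path or string; format in {'fasta','phylip'}."""
    import os

    text = source
    if not (isinstance(source, str) and ("\n" in source or ">" in source)):
        text = open(os.fspath(source)).read()
    fmt = format.lower()
    if fmt == "fasta":
        return _read_fasta(text)
    if fmt in ("phylip", "phylip-relaxed"):
        return _read_phylip(text)
    raise ValueError(f"unsupported alignment format {format!r}")


def write_alignment(aln: Alignment, path=None, format: str = "fasta") -> str:
    fmt = format.lower()
    if fmt == "fasta":
        records = [
            SeqRecord(Seq(aln.sequence(t)), id=t, description="") for t in aln.taxa
        ]
        buf = StringIO()
        SeqIO.write(records, buf, "fasta")
        text = buf.getvalue()
    elif fmt in ("phylip", "phylip-relaxed"):
        out = [f"{aln.n_taxa} {aln.n_sites}"]
        out += [f"{t}  {aln.sequence(t)}" for t in aln.taxa]
        text = "\n".join(out) + "\n"
    else:
        raise ValueError(f"unsupported alignment format {format!r}")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Branch-length and split manipulation


def apply_blmf(tree: Tree, spec: BlmfSpec) -> Tree:
    """Multiply the branches subtending `spec.target_tags` by `spec.factor`."""
    out = tree.copy()
    below = out.leafsets_below()
    for tag in spec.target_tags:
        if tag not in out.clades:
            raise CladeError(f"unknown clade tag {tag!r}")
        target = out.clades[tag]
        node = next(
            (n for n, s in below.items() if n is not out.root and s == target), None
        )
        if node is None:
            node = out.find_clade_node(target)
        if node is None:
            raise CladeError(f"clade tag {tag!r} is not a branch of this tree")
        node.length *= spec.factor
    return out


def clade_branch_length(tree: Tree, tag: str) -> float | None:
    """Length of the branch subtending the tagged clade; None if non-monophyletic."""
    if tag not in tree.clades:
        return None
    node = tree.find_clade_node(tree.clades[tag])
    return None if node is None else node.length


def resolution_label(tag_a: str, tag_b: str) -> str:
    return "+".join(sorted((tag_a, tag_b)))


def focal_split_resolutions(tree: Tree, quartet: list[str]) -> dict[str, Tree]:
    """The three resolutions of the internal edge around which the four tagged
    clades sit.  Keys are ``resolution_label`` of the sister pair containing the
    first quartet tag; everything inside the four clades is preserved."""
    if len(quartet) != 4:
        raise StructureError("quartet must name exactly four clade tags")
    try:
        tagsets = {t: tree.clades[t] for t in quartet}
    except KeyError as exc:
        raise CladeError(f"unknown clade tag {exc.args[0]!r}") from exc
    union = frozenset().union(*tagsets.values())
    if union != tree.leafset or sum(map(len, tagsets.values())) != len(union):
        raise StructureError("quartet tags must partition the leaf set")

    below = tree.leafsets_below()
    # Locate each tag's subtree and the focal edge (bipartition = two tags vs two).
    subtree_nodes: dict[str, Node] = {}
    for tag, s in tagsets.items():
        node = next((n for n, b in below.items() if n is not tree.root and b == s), None)
        if node is None:
            raise StructureError(f"tagged clade {tag!r} is not a subtree of this tree")
        subtree_nodes[tag] = node
    focal = None
    for node, s in below.items():
        if node is tree.root or node.is_leaf:
            continue
        matched = [t for t in quartet if tagsets[t] <= s]
        if len(matched) == 2 and s == tagsets[matched[0]] | tagsets[matched[1]]:
            focal = node
            break
    if focal is None:
        raise StructureError("quartet tags do not surround a single internal edge")
    internal_length = focal.length

    first = quartet[0]
    out: dict[str, Tree] = {}
    for partner in quartet[1:]:
        others = [t for t in quartet[1:] if t != partner]
        root = Node()
        pair = Node(name=None, length=internal_length)
        pair.name = "".join(sorted((first, partner)))
        for t in (first, partner):
            pair.add_child(subtree_nodes[t].copy())
        root.add_child(pair)
        for t in others:
            root.add_child(subtree_nodes[t].copy())
        clades = dict(tagsets)
        clades[pair.name] = tagsets[first] | tagsets[partner]
        out[resolution_label(first, partner)] = Tree(root, clades)
    return out


# ---------------------------------------------------------------------------
# Split comparison


def bipartitions(tree: Tree) -> set[frozenset[str]]:
    """Non-trivial splits, each canonicalized as the side lacking a reference leaf."""
    ref = min(tree.leafset)
    out = set()
    all_leaves = tree.leafset
    for node, s in tree.leafsets_below().items():
        if node is tree.root or node.is_leaf or len(s) >= len(all_leaves) - 1:
            continue
        out.add(s if ref not in s else all_leaves - s)
    return out


def rf_distance(a: Tree, b: Tree) -> int:
    if a.leafset != b.leafset:
        raise ValueError("trees must share a leaf set")
    sa, sb = bipartitions(a), bipartitions(b)
    return len(sa ^ sb)
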