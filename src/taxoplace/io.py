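"""Readers and writers for every external format the tool touches.

Formats: decorated Newick (internal labels carrying ``support:taxon[;taxon...]``
inside single quotes), jplace v3 JSON, FASTA (plain or gzipped), the species
circumscription-radii TSV, and the tab-separated classification summary.
"""

from __future__ import annotations

import gzip
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import dendropy

from .errors import FormatError, NewickParseError, ValidationError

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Taxonomy strings
# ---------------------------------------------------------------------------

RANK_PREFIXES: tuple[str, ...] = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")
RANK_CODES: str = "dpcofgs"
RANK_NAMES: tuple[str, ...] = (
    "domain", "phylum", "class", "order", "family", "genus", "species",
)
N_RANKS = 7

_LABEL_RE = re.compile(r"^[dpcofgs]__")


def rank_index(label: str) -> int:
    """Rank position (0=domain ... 6=species) of a rank-prefixed taxon label."""
    if len(label) < 3 or label[1:3] != "__" or label[0] not in RANK_CODES:
        raise ValidationError(f"not a rank-prefixed taxon label: {label!r}")
    return RANK_CODES.index(label[0])


def is_rank_label(text: str) -> bool:
    return bool(_LABEL_RE.match(text))


@dataclass(frozen=True)
class TaxonomyString:
    """An ordered 7-rank taxonomy, domain through species.

    Each entry is a full rank-prefixed name (``p__Actinobacteriota``) or the
    empty string for an unresolved rank.  Resolution is prefix-closed: a
    non-empty rank is never allowed below an empty one.
    """

    names: tuple[str, ...] = ("",) * N_RANKS

    def __post_init__(self) -> None:
        if len(self.names) != N_RANKS:
            raise ValidationError(f"expected {N_RANKS} ranks, got {len(self.names)}")
        seen_empty = False
        for i, name in enumerate(self.names):
            if name:
                if rank_index(name) != i:
                    raise ValidationError(
                        f"label {name!r} at wrong rank position {i}")
                if seen_empty:
                    raise ValidationError(
                        f"taxonomy not prefix-closed: {self.names}")
            else:
                seen_empty = True

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "TaxonomyString":
        """Build from an unordered collection of rank-prefixed labels."""
        names = [""] * N_RANKS
        for lab in labels:
            idx = rank_index(lab)
            if names[idx] and names[idx] != lab:
                raise ValidationError(
                    f"conflicting labels at rank {RANK_NAMES[idx]}: "
                    f"{names[idx]!r} vs {lab!r}")
            names[idx] = lab
        return cls(tuple(names))

    @classmethod
    def from_string(cls, text: str) -> "TaxonomyString":
        parts = [p.strip() for p in text.split(";")]
        if len(parts) != N_RANKS:
            raise ValidationError(f"expected {N_RANKS} fields: {text!r}")
        names = []
        for i, p in enumerate(parts):
            if p == RANK_PREFIXES[i] or p == "":
                names.append("")
            else:
                names.append(p)
        return cls(tuple(names))

    def to_string(self) -> str:
        return ";".join(n if n else RANK_PREFIXES[i]
                        for i, n in enumerate(self.names))

    def deepest_rank(self) -> int:
        """Index of the deepest resolved rank, or -1 if fully unresolved."""
        deepest = -1
        for i, n in enumerate(self.names):
            if n:
                deepest = i
        return deepest

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


# ---------------------------------------------------------------------------
# Reference tree
# ---------------------------------------------------------------------------


@dataclass
class Node:
    id: str
    parent: Optional[str] = None
    length: Optional[float] = None
    support: Optional[float] = None
    taxa: tuple[str, ...] = ()
    name: Optional[str] = None  # plain (non rank-prefixed) internal label
    children: list[str] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class RefTree:
    """A rooted tree with branch lengths and rank-prefixed node labels.

    Leaf node ids double as genome ids.  Branch lengths are substitutions
    per site; every non-root edge must carry a length.
    """

    def __init__(self) -> None:
        self.nodes: dict[str, Node] = {}
        self.root_id: Optional[str] = None

    # -- construction ------------------------------------------------------

    def add_node(self, node_id: str, parent: Optional[str] = None,
                 length: Optional[float] = None,
                 support: Optional[float] = None,
                 taxa: Sequence[str] = (),
                 name: Optional[str] = None) -> Node:
        if node_id in self.nodes:
            raise ValidationError(f"duplicate node id {node_id!r}")
        if parent is None:
            if self.root_id is not None:
                raise ValidationError("tree already has a root")
            self.root_id = node_id
        else:
            if parent not in self.nodes:
                raise ValidationError(f"unknown parent {parent!r}")
            self.nodes[parent].children.append(node_id)
        node = Node(id=node_id, parent=parent, length=length,
                    support=support, taxa=tuple(taxa), name=name)
        self.nodes[node_id] = node
        return node

    def copy(self) -> "RefTree":
        t = RefTree()
        t.root_id = self.root_id
        for nid, nd in self.nodes.items():
            t.nodes[nid] = Node(id=nd.id, parent=nd.parent, length=nd.length,
                                support=nd.support, taxa=nd.taxa,
                                name=nd.name, children=list(nd.children))
        return t

    # -- traversal ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def root(self) -> Node:
        if self.root_id is None:
            raise ValidationError("empty tree")
        return self.nodes[self.root_id]

    def node(self, node_id: str) -> Node:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise ValidationError(f"no such node: {node_id!r}") from None

    def leaves(self) -> list[Node]:
        return [nd for nd in self.preorder() if nd.is_leaf]

    def preorder(self) -> Iterator[Node]:
        if self.root_id is None:
            return
        stack = [self.root_id]
        while stack:
            nd = self.nodes[stack.pop()]
            yield nd
            stack.extend(reversed(nd.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return iter(reversed(out))

    def path_to_root(self, node_id: str) -> list[Node]:
        """Nodes from ``node_id`` up to and including the root."""
        path = []
        nid: Optional[str] = node_id
        while nid is not None:
            nd = self.node(nid)
            path.append(nd)
            nid = nd.parent
        return path

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if self.root_id is None:
            raise ValidationError("empty tree")
        leaves = self.leaves()
        if len(leaves) != len({l.id for l in leaves}):
            raise ValidationError("duplicate leaf ids")
        seen = 0
        for nd in self.preorder():
            seen += 1
            if nd.parent is None and nd.id != self.root_id:
                raise ValidationError(f"orphan node {nd.id!r}")
            if nd.parent is not None:
                if nd.length is None:
                    raise ValidationError(f"missing branch length on {nd.id!r}")
                if nd.length < 0:
                    raise ValidationError(f"negative branch length on {nd.id!r}")
        if seen != len(self.nodes):
            raise ValidationError("disconnected nodes present")
        # rank order along every root->leaf path
        for leaf in leaves:
            deepest = -1
            for nd in reversed(self.path_to_root(leaf.id)):
                for lab in nd.taxa:
                    idx = rank_index(lab)
                    if idx < deepest:
                        raise ValidationError(
                            f"rank order violated at node {nd.id!r}: {lab}")
                if nd.taxa:
                    deepest = max(deepest,
                                  max(rank_index(t) for t in nd.taxa))


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"^-?\d+(\.\d*)?([eE][-+]?\d+)?$")


def _parse_internal_label(label: str) -> tuple[Optional[float], tuple[str, ...], Optional[str]]:
    """Split a decorated internal label into (support, taxa, plain name).

    Dialect: ``support:taxon[;taxon...]``; a bare numeric label is support
    only; a bare rank-prefixed label (or semicolon list) is taxa only; any
    other text is kept verbatim as a plain name.
    """
    if _NUM_RE.match(label):
        return float(label), (), None
    if ":" in label:
        head, rest = label.split(":", 1)
        if _NUM_RE.match(head) and all(is_rank_label(p) for p in rest.split(";")):
            return float(head), tuple(rest.split(";")), None
    parts = label.split(";")
    if all(is_rank_label(p) for p in parts):
        return None, tuple(parts), None
    return None, (), label


def _dendropy_to_reftree(dtree: "dendropy.Tree") -> tuple[RefTree, dict[int, str]]:
    """Convert a parsed dendropy tree; also collect jplace ``edge`` annotations.

    Returns the tree and a map of jplace edge number -> child node id (empty
    when the source had no edge annotations).
    """
    tree = RefTree()
    edge_map: dict[int, str] = {}
    counter = 0
    ids: dict[int, str] = {}

    for dnode in dtree.preorder_node_iter():
        if dnode.is_leaf():
            if dnode.taxon is None or not dnode.taxon.label:
                raise ValidationError("leaf without a name")
            nid = dnode.taxon.label
            support, taxa, name = None, (), None
        else:
            nid = f"N{counter}"
            counter += 1
            raw = dnode.label
            if raw:
                support, taxa, name = _parse_internal_label(raw)
            else:
                support, taxa, name = None, (), None
        ids[id(dnode)] = nid
        parent = ids[id(dnode.parent_node)] if dnode.parent_node is not None else None
        length = dnode.edge.length
        try:
            tree.add_node(nid, parent=parent, length=length,
                          support=support, taxa=taxa, name=name)
        except ValidationError as exc:
            raise ValidationError(f"invalid tree: {exc}") from exc
        for ann in dnode.annotations:
            if ann.name == "edge":
                edge_map[int(ann.value)] = nid
    return tree, edge_map


def parse_newick(text: str) -> RefTree:
    """Parse decorated Newick text into a validated :class:`RefTree`."""
    if not text.strip():
        raise NewickParseError("empty Newick document")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True, rooting="force-rooted",
        )
    except ValidationError:
        raise
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValidationError(f"duplicate leaf name: {exc}") from exc
    except Exception as exc:
        raise NewickParseError(f"Newick parse failed: {exc}") from exc
    tree, _ = _dendropy_to_reftree(dtree)
    # the root edge length in "(...)label:x;" is decorative; drop it
    tree.root.length = None
    tree.validate()
    if len(tree.leaves()) < 2:
        raise ValidationError("tree must have at least 2 leaves")
    return tree


def read_newick(path) -> RefTree:
    """Read a decorated Newick file (see module docstring for the dialect)."""
    return parse_newick(Path(path).read_text())


_NEEDS_QUOTE_RE = re.compile(r"[\s()\[\]{}:;,']")


def _quote_label(label: str) -> str:
    if _NEEDS_QUOTE_RE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_number(x: float) -> str:
    return repr(float(x))


def _compose_internal_label(nd: Node) -> str:
    if nd.support is not None and nd.taxa:
        return _quote_label(f"{_format_number(nd.support)}:{';'.join(nd.taxa)}")
    if nd.support is not None:
        return _format_number(nd.support)
    if nd.taxa:
        return _quote_label(";".join(nd.taxa))
    if nd.name:
        return _quote_label(nd.name)
    return ""


def write_newick(tree: RefTree, edge_numbers: Optional[dict[str, int]] = None) -> str:
    """Serialize a tree to decorated Newick text.

    ``edge_numbers`` (node id -> N) appends jplace-style ``{N}`` edge
    annotations; used when emitting the tree string of a jplace document.
    """
    if tree.root_id is None or not tree.nodes:
        raise ValidationError("cannot serialize an empty tree")

    def render(nid: str) -> str:
        nd = tree.nodes[nid]
        if nd.is_leaf:
            out = _quote_label(nd.id)
        else:
            inner = ",".join(render(c) for c in nd.children)
            out = f"({inner}){_compose_internal_label(nd)}"
        if nd.length is not None:
            out += f":{_format_number(nd.length)}"
        if edge_numbers is not None and nid in edge_numbers:
            out += "{%d}" % edge_numbers[nid]
        return out

    return render(tree.root_id) + ";"


# ---------------------------------------------------------------------------
# jplace
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Placement:
    """A query attachment point on a reference-tree edge.

    ``edge_id`` names the child node of the host edge; ``distal_length`` is
    measured from the edge's parent end and must not exceed the edge length;
    ``pendant_length`` is the query's own branch.
    """

    edge_id: str
    distal_length: float
    pendant_length: float
    like_weight_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        if self.distal_length < 0:
            raise ValidationError("distal_length must be >= 0")
        if self.pendant_length < 0:
            raise ValidationError("pendant_length must be >= 0")
        if self.like_weight_ratio is not None and not (
                0 <= self.like_weight_ratio <= 1):
            raise ValidationError("like_weight_ratio must be in [0, 1]")


_EDGE_NUM_RE = re.compile(r"\{(\d+)\}")


def parse_jplace_tree(tree_text: str) -> tuple[RefTree, dict[int, str]]:
    """Parse a jplace tree string with ``{N}`` edge numbers.

    Returns the tree plus edge number -> child node id.
    """
    annotated = _EDGE_NUM_RE.sub(lambda m: f"[&edge={m.group(1)}]", tree_text)
    try:
        dtree = dendropy.Tree.get(
            data=annotated, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True, rooting="force-rooted",
        )
    except Exception as exc:
        raise FormatError(f"bad jplace tree string: {exc}") from exc
    tree, edge_map = _dendropy_to_reftree(dtree)
    tree.root.length = None
    return tree, edge_map


def read_jplace(path) -> list[tuple[str, Placement]]:
    """Read a jplace v3 document; one best placement per query.

    When a query has several placements the one with the highest
    like_weight_ratio is kept; ties go to the lowest edge number with a
    logged warning.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"jplace is not valid JSON: {exc}") from exc
    for key in ("tree", "placements", "fields"):
        if key not in doc:
            raise FormatError(f"jplace missing required key {key!r}")
    fields = list(doc["fields"])
    for req in ("edge_num", "distal_length", "pendant_length"):
        if req not in fields:
            raise FormatError(f"jplace fields missing {req!r}")
    i_edge = fields.index("edge_num")
    i_distal = fields.index("distal_length")
    i_pendant = fields.index("pendant_length")
    i_lwr = fields.index("like_weight_ratio") if "like_weight_ratio" in fields else None

    tree, edge_map = parse_jplace_tree(doc["tree"])

    out: list[tuple[str, Placement]] = []
    for entry in doc["placements"]:
        if "n" in entry:
            names = list(entry["n"])
        elif "nm" in entry:
            names = [nm[0] for nm in entry["nm"]]
        else:
            raise FormatError("jplace placement without 'n' or 'nm'")
        rows = entry.get("p")
        if not rows:
            raise FormatError("jplace placement without 'p' rows")

        def key(row) -> tuple[float, float]:
            lwr = float(row[i_lwr]) if i_lwr is not None else 1.0
            return (-lwr, float(row[i_edge]))

        ranked = sorted(rows, key=key)
        best = ranked[0]
        if len(ranked) > 1 and key(ranked[0])[0] == key(ranked[1])[0]:
            logger.warning(
                "query %s: like_weight_ratio tie; keeping lowest edge %s",
                names, best[i_edge])
        edge_num = int(best[i_edge])
        if edge_num not in edge_map:
            raise ValidationError(f"edge_num {edge_num} not present in jplace tree")
        child_id = edge_map[edge_num]
        edge_len = tree.node(child_id).length or 0.0
        distal = float(best[i_distal])
        if distal > edge_len:
            if distal <= edge_len + 1e-9:
                distal = edge_len
            else:
                raise ValidationError(
                    f"distal_length {distal} exceeds edge length {edge_len}")
        placement = Placement(
            edge_id=child_id, distal_length=distal,
            pendant_length=float(best[i_pendant]),
            like_weight_ratio=(float(best[i_lwr]) if i_lwr is not None else None),
        )
        for name in names:
            out.append((name, placement))
    return out


def write_jplace(tree: RefTree, placements: dict[str, Placement], path) -> None:
    """Write a minimal jplace v3 document for ``placements`` on ``tree``."""
    order = [nd.id for nd in tree.preorder() if nd.parent is not None]
    numbers = {nid: i for i, nid in enumerate(order)}
    tree_text = write_newick(tree, edge_numbers=numbers)
    rows = []
    for qid, pl in sorted(placements.items()):
        rows.append({
            "p": [[numbers[pl.edge_id], pl.distal_length, pl.pendant_length,
                   pl.like_weight_ratio if pl.like_weight_ratio is not None else 1.0]],
            "n": [qid],
        })
    doc = {
        "version": 3,
        "tree": tree_text,
        "fields": ["edge_num", "distal_length", "pendant_length",
                   "like_weight_ratio"],
        "placements": rows,
        "metadata": {"invocation": "taxoplace"},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read a (optionally gzipped) FASTA file into an ordered id -> sequence map."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    out: dict[str, str] = {}
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise ValidationError(f"duplicate FASTA id {rec.id!r} in {path}")
            out[rec.id] = str(rec.seq)
    if not out:
        raise FormatError(f"no FASTA records in {path}")
    return out


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Radii TSV
# ---------------------------------------------------------------------------


def read_radii(path) -> dict:
    """Read the per-species circumscription radii TSV.

    Columns: species_name, representative_genome, radius_pct (an empty
    radius falls back to the 95% default).  Returns species name ->
    :class:`taxoplace.ani.SpeciesRadius`.
    """
    from .ani import DEFAULT_RADIUS_PCT, SpeciesRadius

    out: dict[str, SpeciesRadius] = {}
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"empty radii file {path}")
    header = lines[0].rstrip("\n").split("\t")
    required = ["species_name", "representative_genome", "radius_pct"]
    if header[:3] != required:
        raise FormatError(f"radii header must be {required}, got {header[:3]}")
    for ln in lines[1:]:
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) < 2:
            raise FormatError(f"short radii row: {ln!r}")
        species, rep = parts[0], parts[1]
        radius = float(parts[2]) if len(parts) > 2 and parts[2].strip() else DEFAULT_RADIUS_PCT
        if species in out:
            raise ValidationError(f"duplicate species in radii file: {species!r}")
        out[species] = SpeciesRadius(species_name=species,
                                     representative_genome=rep,
                                     radius_pct=radius)
    return out


def write_radii(radii: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("species_name\trepresentative_genome\tradius_pct\n")
        for sp in sorted(radii):
            r = radii[sp]
            fh.write(f"{r.species_name}\t{r.representative_genome}\t{r.radius_pct:g}\n")


# ---------------------------------------------------------------------------
# Classification results / summary report
# ---------------------------------------------------------------------------

METHOD_ANI = "ANI"
METHOD_TOPOLOGY = "TOPOLOGY"
METHOD_RED = "RED"
_METHODS = (METHOD_ANI, METHOD_TOPOLOGY, METHOD_RED)


@dataclass
class ClassificationResult:
    genome_id: str
    taxonomy: TaxonomyString
    method: str
    closest_reference: Optional[str] = None
    ani_pct: Optional[float] = None
    align_frac: Optional[float] = None
    red_value: Optional[float] = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValidationError(f"unknown method {self.method!r}")
        species = self.taxonomy.names[6]
        if self.method == METHOD_ANI:
            if not species or self.ani_pct is None:
                raise ValidationError(
                    "method=ANI requires a species assignment and an ANI value")
        else:
            if species:
                raise ValidationError(
                    f"method={self.method} must leave the species rank empty")


SUMMARY_COLUMNS = ("user_genome", "classification", "closest_reference",
                   "ani", "af", "red_value", "method", "warnings")


def _fmt_opt(x: Optional[float], digits: int) -> str:
    return "" if x is None else f"{x:.{digits}f}"


def write_summary(results: Sequence[ClassificationResult], path) -> None:
    """Write the classification summary TSV (fixed column order)."""
    with open(path, "w") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for res in results:
            row = (
                res.genome_id,
                res.taxonomy.to_string(),
                res.closest_reference or "",
                _fmt_opt(res.ani_pct, 2),
                _fmt_opt(res.align_frac, 3),
                _fmt_opt(res.red_value, 5),
                res.method,
                "; ".join(res.warnings),
            )
            fh.write("\t".join(row) + "\n")
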