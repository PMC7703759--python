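"""Synthetic reference packages and queries with known truth.

Generates a rank-stratified reference tree (taxon nodes at rank-specific
depths with small jitter, leaves at depth 1), evolves marker alignments and
genomes along it under i.i.d. substitution models, and derives queries for
the classification scenarios: a known species, a novel species within a
genus, a novel genus, a novel phylum, and an engineered rank-ambiguous
basal attachment.

All randomness flows from one top-level seed through named substreams (one
per node / query), so adding a genome never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .ani import DEFAULT_RADIUS_PCT, SpeciesRadius
from .errors import ValidationError
from .io import (Placement, RefTree, TaxonomyString, write_fasta,
                 write_jplace, write_newick, write_radii)
from .profile import ColumnMask, MarkerHit, MarkerHitTable, write_marker_hits, write_mask

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "ACGT"

#: target node depth (= approximate RED) per rank below the domain root
RANK_DEPTHS = {"p": 0.30, "c": 0.45, "o": 0.60, "f": 0.75, "g": 0.90}

MODES = ("known_species", "novel_species", "novel_genus", "novel_phylum",
         "basal_ambiguous")


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and model parameters of one synthetic reference package."""

    seed: int
    n_phyla: int = 2
    classes_per_phylum: int = 2
    orders_per_class: int = 1
    families_per_order: int = 2
    genera_per_family: int = 2
    species_per_genus: int = 3
    n_markers: int = 5
    marker_width: int = 60
    genome_length: int = 30_000
    genome_rate: float = 0.5   # nt substitutions per site per unit branch length
    marker_rate: float = 1.0   # aa substitutions per site per unit branch length
    mask_keep_frac: float = 0.85
    depth_jitter: float = 0.015

    def __post_init__(self) -> None:
        counts = (self.n_phyla, self.classes_per_phylum, self.orders_per_class,
                  self.families_per_order, self.genera_per_family,
                  self.species_per_genus)
        if any(c < 1 for c in counts):
            raise ValidationError("all rank counts must be >= 1")
        if self.n_species() < 2:
            raise ValidationError("fixture needs at least 2 species")

    def n_species(self) -> int:
        return (self.n_phyla * self.classes_per_phylum * self.orders_per_class
                * self.families_per_order * self.genera_per_family
                * self.species_per_genus)


@dataclass(frozen=True)
class TruthRecord:
    query_id: str
    mode: str
    taxonomy: TaxonomyString
    novel_rank: Optional[str]          # rank name, e.g. "species"; None if known
    expected_closest: Optional[str]
    divergence: float
    ambiguous: bool = False


@dataclass
class Query:
    query_id: str
    genome: str
    marker_rows: dict[str, str]
    placement: Placement
    truth: TruthRecord


@dataclass
class Reference:
    spec: FixtureSpec
    tree: RefTree
    marker_order: list[str]
    marker_widths: dict[str, int]
    mask: ColumnMask
    node_genomes: dict[str, str]            # every node, internal included
    node_marker_rows: dict[str, dict[str, str]]
    radii: dict[str, SpeciesRadius]
    species_of_leaf: dict[str, str]
    quality: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def genomes(self) -> dict[str, str]:
        return {lf.id: self.node_genomes[lf.id] for lf in self.tree.leaves()}

    def masked_rows(self) -> dict[str, str]:
        out = {}
        for leaf in self.tree.leaves():
            concat = "".join(self.node_marker_rows[leaf.id][m]
                             for m in self.marker_order)
            out[leaf.id] = "".join(
                ch for ch, keep in zip(concat, self.mask.keep) if keep)
        return out

    def lineage(self, node_id: str) -> TaxonomyString:
        labels: list[str] = []
        for nd in self.tree.path_to_root(node_id):
            labels.extend(nd.taxa)
        if node_id in self.species_of_leaf:
            labels.append(self.species_of_leaf[node_id])
        return TaxonomyString.from_labels(labels)


# ---------------------------------------------------------------------------
# named random substreams
# ---------------------------------------------------------------------------


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def _random_seq(rng: np.random.Generator, length: int, alphabet: str) -> str:
    chars = np.frombuffer(alphabet.encode(), dtype=np.uint8)
    return rng.choice(chars, size=length).tobytes().decode()


def mutate(seq: str, rate: float, alphabet: str,
           rng: np.random.Generator) -> str:
    """i.i.d. substitutions: each site mutates with probability ``rate`` to a
    uniformly chosen *different* symbol, so expected identity is 1 - rate."""
    if not 0 <= rate <= 1:
        raise ValidationError(f"rate out of range: {rate}")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n_mut = rng.binomial(arr.size, rate)
    if n_mut == 0:
        return seq
    pos = rng.choice(arr.size, size=n_mut, replace=False)
    chars = np.frombuffer(alphabet.encode(), dtype=np.uint8)
    lookup = np.zeros(256, dtype=np.int64)
    lookup[chars] = np.arange(chars.size)
    cur = lookup[arr[pos]]
    offset = rng.integers(1, chars.size, size=n_mut)
    arr[pos] = chars[(cur + offset) % chars.size]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------


def _build_tree(spec: FixtureSpec) -> tuple[RefTree, dict[str, str], dict[str, float]]:
    """Rank-stratified tree; returns (tree, leaf -> species name, node depths)."""
    rng = _stream(spec.seed, "tree")
    tree = RefTree()
    tree.add_node("root", taxa=("d__Bacteria",))
    depths = {"root": 0.0}
    species_of_leaf: dict[str, str] = {}
    counters = {"p": 0, "c": 0, "o": 0, "f": 0, "g": 0, "s": 0}
    plan = [
        ("p", "p__Phy", spec.n_phyla),
        ("c", "c__Cls", spec.classes_per_phylum),
        ("o", "o__Ord", spec.orders_per_class),
        ("f", "f__Fam", spec.families_per_order),
        ("g", "g__Gen", spec.genera_per_family),
    ]

    def expand(parent_id: str, level: int) -> None:
        if level == len(plan):
            code, stem, count = "s", "s__Sp", spec.species_per_genus
            for _ in range(count):
                counters["s"] += 1
                species = f"{stem}{counters['s']:04d}"
                leaf_id = f"G{counters['s']:04d}"
                length = 1.0 - depths[parent_id]
                tree.add_node(leaf_id, parent=parent_id, length=length)
                depths[leaf_id] = 1.0
                species_of_leaf[leaf_id] = species
            return
        code, stem, count = plan[level]
        base = RANK_DEPTHS[code]
        for _ in range(count):
            counters[code] += 1
            label = f"{stem}{counters[code]:03d}"
            depth = base + rng.uniform(-spec.depth_jitter, spec.depth_jitter)
            node_id = label
            tree.add_node(node_id, parent=parent_id,
                          length=depth - depths[parent_id],
                          support=100.0, taxa=(label,))
            depths[node_id] = depth
            expand(node_id, level + 1)

    expand("root", 0)
    tree.validate()
    return tree, species_of_leaf, depths


def gen_reference(spec: FixtureSpec) -> Reference:
    """Generate a full reference package; same seed -> identical output."""
    tree, species_of_leaf, _ = _build_tree(spec)

    marker_order = [f"m{i:03d}" for i in range(spec.n_markers)]
    marker_widths = {m: spec.marker_width for m in marker_order}

    root_rng = _stream(spec.seed, "seq/root")
    node_genomes: dict[str, str] = {
        "root": _random_seq(root_rng, spec.genome_length, NT_ALPHABET)}
    node_marker_rows: dict[str, dict[str, str]] = {
        "root": {m: _random_seq(root_rng, spec.marker_width, AA_ALPHABET)
                 for m in marker_order}}

    for nd in tree.preorder():
        if nd.parent is None:
            continue
        rng = _stream(spec.seed, f"seq/{nd.id}")
        p_nt = min(1.0, spec.genome_rate * nd.length)
        p_aa = min(1.0, spec.marker_rate * nd.length)
        node_genomes[nd.id] = mutate(node_genomes[nd.parent], p_nt,
                                     NT_ALPHABET, rng)
        node_marker_rows[nd.id] = {
            m: mutate(node_marker_rows[nd.parent][m], p_aa, AA_ALPHABET, rng)
            for m in marker_order}

    mask_rng = _stream(spec.seed, "mask")
    total_width = spec.n_markers * spec.marker_width
    keep = mask_rng.random(total_width) < spec.mask_keep_frac
    if not keep.any():
        keep[0] = True
    mask = ColumnMask(marker_set="synthetic",
                      keep=tuple(bool(k) for k in keep))

    radii = {
        sp: SpeciesRadius(species_name=sp, representative_genome=leaf,
                          radius_pct=DEFAULT_RADIUS_PCT)
        for leaf, sp in species_of_leaf.items()}

    quality = {leaf: (100.0, 0.0) for leaf in species_of_leaf}

    return Reference(spec=spec, tree=tree, marker_order=marker_order,
                     marker_widths=marker_widths, mask=mask,
                     node_genomes=node_genomes,
                     node_marker_rows=node_marker_rows, radii=radii,
                     species_of_leaf=species_of_leaf, quality=quality)


# ---------------------------------------------------------------------------
# query generation
# ---------------------------------------------------------------------------


def _labels_to(reference: Reference, node_id: str) -> list[str]:
    labels: list[str] = []
    for nd in reference.tree.path_to_root(node_id):
        labels.extend(nd.taxa)
    return labels


def _nodes_at_rank(reference: Reference, code: str) -> list[str]:
    return [nd.id for nd in reference.tree.preorder()
            if any(t.startswith(code + "__") for t in nd.taxa)]


def gen_query(reference: Reference, mode: str, seed: int,
              query_id: Optional[str] = None) -> Query:
    """Derive one query genome + marker rows + truth for a scenario mode."""
    if mode not in MODES:
        raise ValidationError(f"unknown query mode {mode!r}")
    qid = query_id or f"q_{mode}_{seed}"
    rng = _stream(reference.spec.seed, f"query/{qid}/{seed}")
    tree = reference.tree
    spec = reference.spec

    if mode in ("known_species", "novel_species"):
        leaves = sorted(l.id for l in tree.leaves())
        leaf_id = leaves[rng.integers(len(leaves))]
        leaf = tree.node(leaf_id)
        div = 0.02 if mode == "known_species" else float(rng.uniform(0.07, 0.09))
        base = leaf_id
        placement = Placement(edge_id=leaf_id,
                              distal_length=0.5 * leaf.length,
                              pendant_length=div)
        if mode == "known_species":
            taxonomy = reference.lineage(leaf_id)
            novel = None
        else:
            taxonomy = TaxonomyString.from_labels(_labels_to(reference, leaf_id))
            novel = "species"
        truth = TruthRecord(qid, mode, taxonomy, novel, leaf_id, div)
    elif mode == "novel_genus":
        genera = _nodes_at_rank(reference, "g")
        genus_id = genera[rng.integers(len(genera))]
        genus = tree.node(genus_id)
        base = genus.parent  # the family node
        div = float(rng.uniform(0.04, 0.06))
        placement = Placement(edge_id=genus_id,
                              distal_length=0.5 * genus.length,
                              pendant_length=div)
        taxonomy = TaxonomyString.from_labels(_labels_to(reference, base))
        truth = TruthRecord(qid, mode, taxonomy, "genus", None, div)
    elif mode == "novel_phylum":
        phyla = _nodes_at_rank(reference, "p")
        phylum_id = phyla[rng.integers(len(phyla))]
        phylum = tree.node(phylum_id)
        base = "root"
        div = float(rng.uniform(0.18, 0.25))
        placement = Placement(edge_id=phylum_id,
                              distal_length=0.5 * phylum.length,
                              pendant_length=div)
        taxonomy = TaxonomyString.from_labels(["d__Bacteria"])
        truth = TruthRecord(qid, mode, taxonomy, "phylum", None, div)
    else:  # basal_ambiguous: attachment engineered between rank depths
        classes = _nodes_at_rank(reference, "c")
        class_id = classes[rng.integers(len(classes))]
        cls = tree.node(class_id)
        base = cls.parent  # the phylum node
        div = float(rng.uniform(0.12, 0.18))
        placement = Placement(edge_id=class_id,
                              distal_length=float(rng.uniform(0.2, 0.8)) * cls.length,
                              pendant_length=div)
        taxonomy = TaxonomyString.from_labels(_labels_to(reference, base))
        truth = TruthRecord(qid, mode, taxonomy, "class", None, div,
                            ambiguous=True)

    genome = mutate(reference.node_genomes[base], div, NT_ALPHABET, rng)
    marker_rows = {
        m: mutate(reference.node_marker_rows[base][m], min(1.0, div),
                  AA_ALPHABET, rng)
        for m in reference.marker_order}
    _ = spec  # silence linters; spec drives rng naming only
    return Query(query_id=qid, genome=genome, marker_rows=marker_rows,
                 placement=placement, truth=truth)


def gen_queries(reference: Reference, counts: dict[str, int],
                seed: int) -> list[Query]:
    """A batch of queries; ids are serial and stable for a given counts map."""
    out: list[Query] = []
    serial = 0
    for mode in MODES:
        for _ in range(counts.get(mode, 0)):
            serial += 1
            out.append(gen_query(reference, mode, seed + serial,
                                 query_id=f"q{serial:03d}_{mode}"))
    return out


# ---------------------------------------------------------------------------
# on-disk package
# ---------------------------------------------------------------------------


def write_package(reference: Reference, queries: Sequence[Query],
                  outdir) -> None:
    """Write the reference package + queries + truth as plain-text files."""
    outdir = Path(outdir)
    ref_dir = outdir / "ref"
    genome_dir = ref_dir / "genomes"
    query_dir = outdir / "queries"
    for d in (ref_dir, genome_dir, query_dir):
        d.mkdir(parents=True, exist_ok=True)

    (ref_dir / "tree.nwk").write_text(write_newick(reference.tree) + "\n")
    write_fasta(reference.masked_rows(), ref_dir / "msa.fasta")
    write_mask(reference.mask, ref_dir / "mask.txt")
    write_radii(reference.radii, ref_dir / "radii.tsv")
    for leaf_id, genome in reference.genomes.items():
        write_fasta({leaf_id: genome}, genome_dir / f"{leaf_id}.fasta")

    with open(ref_dir / "quality.tsv", "w") as fh:
        fh.write("genome\tcompleteness\tcontamination\n")
        for g in sorted(reference.quality):
            comp, cont = reference.quality[g]
            fh.write(f"{g}\t{comp:g}\t{cont:g}\n")

    hits = MarkerHitTable(widths=dict(reference.marker_widths))
    for q in queries:
        write_fasta({q.query_id: q.genome}, query_dir / f"{q.query_id}.fasta")
        hits.hits[q.query_id] = {
            m: MarkerHit(present=True, row=q.marker_rows[m])
            for m in reference.marker_order}
    write_marker_hits(hits, query_dir / "markers.tsv")

    write_jplace(reference.tree,
                 {q.query_id: q.placement for q in queries},
                 outdir / "placements.jplace")

    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("query\tmode\ttaxonomy\tnovel_rank\texpected_closest\t"
                 "divergence\tambiguous\n")
        for q in queries:
            t = q.truth
            fh.write("\t".join([
                t.query_id, t.mode, t.taxonomy.to_string(),
                t.novel_rank or "", t.expected_closest or "",
                f"{t.divergence:.6f}", str(int(t.ambiguous)),
            ]) + "\n")
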