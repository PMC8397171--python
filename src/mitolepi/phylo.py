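"""13-PCG supermatrix construction, distance estimation, neighbor joining,
and monophyly queries.

The heavy phylogenetic machinery of a mitogenome study (partitioned ML,
Bayesian MCMC) belongs to external engines; this module writes their
standard inputs (relaxed PHYLIP, NEXUS, RAxML-style partition files) and
verifies topological claims with its own distance + neighbor-joining stage,
which is exact on additive distances.

Distances: uncorrected p or Kimura two-parameter,

    d_K2P = -1/2 ln( (1 - 2P - Q) * sqrt(1 - 2Q) ),

with P and Q the proportions of transitional and transversional differences
over pairwise-complete sites.  Saturated pairs (non-positive log argument)
are flagged and capped rather than returned as infinities.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import dendropy
import numpy as np

from .genome import PCG_ORDER, canonical_gene_name

__all__ = [
    "Supermatrix",
    "DistanceMatrix",
    "build_supermatrix",
    "distances",
    "nj_tree",
    "is_monophyletic",
    "MonophylyResult",
    "read_partitions",
]

log = logging.getLogger(__name__)

GAP_CHARS = frozenset("-?N")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass
class Supermatrix:
    """Concatenated per-gene alignment blocks in fixed 13-PCG order."""

    taxa: list
    genes: list  # genes actually present, in canonical order
    rows: dict  # taxon -> concatenated sequence
    block_ranges: dict  # gene -> (start, end), 1-based inclusive columns

    @property
    def nchar(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def partition_table(self, scheme: str = "gene") -> list[tuple[str, int, int, Optional[int]]]:
        """Partitions as (name, start, end, codon_interval).

        ``scheme="gene"`` yields one partition per gene (13 for a full
        matrix); ``scheme="codon"`` one per gene x codon position (39).
        """
        parts = []
        for gene in self.genes:
            a, b = self.block_ranges[gene]
            if scheme == "gene":
                parts.append((gene, a, b, None))
            elif scheme == "codon":
                for pos in (1, 2, 3):
                    parts.append((f"{gene}_pos{pos}", a + pos - 1, b, 3))
            else:
                raise ValueError(f"unknown partition scheme {scheme!r}")
        return parts

    def write_partitions(self, path: str | Path, scheme: str = "gene") -> None:
        """RAxML-style partition file ("DNA, nad2_pos1 = 1-1014\\3")."""
        lines = []
        for name, a, b, step in self.partition_table(scheme):
            spec = f"{a}-{b}" + (f"\\{step}" if step else "")
            lines.append(f"DNA, {name} = {spec}")
        Path(path).write_text("\n".join(lines) + "\n")

    def to_phylip(self, path: str | Path) -> None:
        lines = [f"{len(self.taxa)} {self.nchar}"]
        for taxon in self.taxa:
            lines.append(f"{taxon.replace(' ', '_')}  {self.rows[taxon]}")
        Path(path).write_text("\n".join(lines) + "\n")

    def to_nexus(self, path: str | Path) -> None:
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"  DIMENSIONS NTAX={len(self.taxa)} NCHAR={self.nchar};",
            "  FORMAT DATATYPE=DNA MISSING=? GAP=-;",
            "  MATRIX",
        ]
        for taxon in self.taxa:
            lines.append(f"    {taxon.replace(' ', '_')}  {self.rows[taxon]}")
        lines += ["  ;", "END;"]
        Path(path).write_text("\n".join(lines) + "\n")


def read_partitions(path: str | Path) -> list[tuple[str, int, int, Optional[int]]]:
    """Parse a RAxML-style partition file back to tuples."""
    parts = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        m = re.fullmatch(r"\w+,\s*(\S+)\s*=\s*(\d+)-(\d+)(?:\\(\d+))?", line)
        if not m:
            raise ValueError(f"malformed partition line: {line!r}")
        parts.append(
            (m.group(1), int(m.group(2)), int(m.group(3)),
             int(m.group(4)) if m.group(4) else None)
        )
    return parts


def build_supermatrix(
    gene_sets: dict,
    aligner: str | Callable = "pre-aligned",
) -> Supermatrix:
    """Concatenate per-taxon PCG sequences into a supermatrix.

    ``gene_sets`` maps taxon -> {gene -> sequence}.  Genes are concatenated
    in the canonical 13-PCG genome order; a taxon's missing genes become
    all-gap blocks.  With ``aligner="pre-aligned"`` each gene's sequences
    must already share one length; otherwise ``aligner(gene, {taxon: seq})``
    must return aligned equal-length sequences.
    """
    taxa = list(gene_sets)
    canon_sets: dict[str, dict[str, str]] = {}
    for taxon, genes in gene_sets.items():
        if not genes:
            raise ValueError(f"taxon {taxon!r} supplies no genes")
        canon_sets[taxon] = {canonical_gene_name(g): s.upper() for g, s in genes.items()}
    genes = [g for g in PCG_ORDER if any(g in gs for gs in canon_sets.values())]
    if not genes:
        raise ValueError("no protein-coding genes found in any taxon")

    blocks: dict[str, dict[str, str]] = {}
    for gene in genes:
        present = {t: gs[gene] for t, gs in canon_sets.items() if gene in gs}
        if callable(aligner):
            present = aligner(gene, present)
        lengths = {len(s) for s in present.values()}
        if len(lengths) != 1:
            bad = {t: len(s) for t, s in present.items()}
            raise ValueError(f"pre-aligned block for {gene} has unequal lengths: {bad}")
        width = lengths.pop()
        blocks[gene] = {t: present.get(t, "-" * width) for t in taxa}

    rows = {t: "".join(blocks[g][t] for g in genes) for t in taxa}
    ranges = {}
    pos = 1
    for gene in genes:
        width = len(next(iter(blocks[gene].values())))
        ranges[gene] = (pos, pos + width - 1)
        pos += width
    return Supermatrix(taxa=taxa, genes=genes, rows=rows, block_ranges=ranges)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    taxa: tuple
    matrix: np.ndarray  # symmetric, zero diagonal
    model: str  # "p" or "K2P"
    saturated: frozenset = frozenset()  # (taxon_i, taxon_j) pairs set to the cap

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.taxa.index(a), self.taxa.index(b)])

    def to_tsv(self, path: str | Path) -> None:
        lines = ["\t" + "\t".join(self.taxa)]
        for i, t in enumerate(self.taxa):
            lines.append(t + "\t" + "\t".join(f"{v:.6f}" for v in self.matrix[i]))
        Path(path).write_text("\n".join(lines) + "\n")


def k2p_distance(p_transition: float, q_transversion: float) -> float:
    """Closed-form Kimura two-parameter distance; ValueError when saturated."""
    arg = (1 - 2 * p_transition - q_transversion) * math.sqrt(1 - 2 * q_transversion)
    if arg <= 0:
        raise ValueError("saturated: log argument <= 0")
    return -0.5 * math.log(arg)


def distances(
    sm: Supermatrix,
    model: str = "K2P",
    complete_deletion: bool = False,
    saturation_cap: float = 5.0,
) -> DistanceMatrix:
    """Pairwise distances over the supermatrix.

    Sites with a gap/N in either row of a pair are excluded (pairwise
    deletion); ``complete_deletion`` instead drops every column with any
    gap/N before comparison.  A pair with zero comparable sites is an error.
    """
    if model not in ("p", "K2P"):
        raise ValueError(f"model must be 'p' or 'K2P', got {model!r}")
    taxa = tuple(sm.taxa)
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")
    arrs = {t: np.frombuffer(sm.rows[t].encode(), dtype="S1") for t in taxa}
    valid = {t: np.isin(arrs[t], np.array([b"A", b"C", b"G", b"T"])) for t in taxa}
    if complete_deletion:
        keep = np.logical_and.reduce([valid[t] for t in taxa])
        arrs = {t: a[keep] for t, a in arrs.items()}
        valid = {t: v[keep] for t, v in valid.items()}

    purine = {t: np.isin(arrs[t], np.array([b"A", b"G"])) for t in taxa}
    n = len(taxa)
    D = np.zeros((n, n))
    saturated = set()
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[taxa[i]] & valid[taxa[j]]
            m = int(ok.sum())
            if m == 0:
                raise ValueError(f"no comparable sites for pair {taxa[i]} / {taxa[j]}")
            diff = (arrs[taxa[i]] != arrs[taxa[j]]) & ok
            transversion = diff & (purine[taxa[i]] != purine[taxa[j]])
            q = int(transversion.sum()) / m
            p = int(diff.sum()) / m - q
            if model == "p":
                d = p + q
            else:
                try:
                    d = k2p_distance(p, q)
                except ValueError:
                    d = saturation_cap
                    saturated.add((taxa[i], taxa[j]))
                    log.warning("K2P saturated for %s/%s; capped at %g",
                                taxa[i], taxa[j], saturation_cap)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(taxa=taxa, matrix=D, model=model,
                          saturated=frozenset(saturated))


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Agglomerates by the standard Q criterion; among equal-Q pairs the pair
    with the lowest (row, column) indices in the current matrix order is
    joined.  Negative branch lengths are clamped to zero with a log notice.
    The result is an unrooted dendropy tree.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(dm.matrix, dm.matrix.T):
        raise ValueError("distance matrix is not symmetric")

    tns = dendropy.TaxonNamespace([str(t) for t in dm.taxa])
    nodes = [dendropy.Node(taxon=tns.get_taxon(str(t))) for t in dm.taxa]
    D = dm.matrix.astype(float).copy()
    active = list(range(n))

    def clamp(v: float, label: str) -> float:
        if v < 0:
            log.info("clamping negative NJ branch length %.4g on %s", v, label)
            return 0.0
        return v

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        li = 0.5 * sub[a, b] + (r[a] - r[b]) / (2 * (m - 2))
        lj = sub[a, b] - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = clamp(li, f"join {i}")
        nodes[j].edge.length = clamp(lj, f"join {j}")
        # distances from the new node to every other active node
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        D = np.vstack([D, dnew])
        D = np.hstack([D, np.append(dnew, 0.0)[:, None]])
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]

    i, j = active
    # the most recent join product is internal; make it the seed
    if len(nodes[i].child_nodes()) == 0:
        i, j = j, i
    seed = nodes[i]
    seed.add_child(nodes[j])
    nodes[j].edge.length = clamp(D[i, j], "final")
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = seed
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Monophyly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonophylyResult:
    monophyletic: bool
    clade: Optional[frozenset] = None  # leaf-label side of the splitting edge

    def __bool__(self) -> bool:
        return self.monophyletic


def is_monophyletic(
    tree: dendropy.Tree,
    taxa: Sequence[str],
    outgroup: str,
) -> MonophylyResult:
    """Does ``taxa`` form a clade when the tree is rooted at ``outgroup``?

    True iff some edge bipartition has exactly the query set on the side
    away from the outgroup.  Singletons and the full ingroup are trivially
    monophyletic.
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    query = {str(t) for t in taxa}
    unknown = (query | {outgroup}) - leaves
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)}")
    if outgroup in query:
        raise ValueError("outgroup cannot be part of the query set")

    below: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            below[id(node)] = frozenset().union(
                *(below[id(c)] for c in node.child_nodes())
            )
    for node in tree.preorder_node_iter():
        side = below[id(node)]
        away = side if outgroup not in side else leaves - side
        if away == query:
            return MonophylyResult(True, frozenset(away))
    return MonophylyResult(False, None)
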