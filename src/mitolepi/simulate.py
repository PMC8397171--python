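"""Synthetic mitogenomes and evolved sequence panels with known ground truth.

The genome generator emits an annotated circular sequence honouring a
layout template: gene order, strands, signed junction values, planted
start/stop codons (including the CGA cox1 initiator and truncated T stops),
the conserved junction motifs (ATGATAA across the atp8/atp6 overlap,
ATACTAA inside the trnS2-nad1 spacer), and a control region assembled from
the four conserved elements.  The default template reproduces the
H. persimilis layout shipped with the package, so the published accounting
numbers hold by construction.

Non-coding regions are i.i.d. draws under a per-region AT bias; PCG
interiors are drawn codon-wise from a stop-free codon profile whose
per-base AT content is solved to the region target.  Exact bookkeeping is
preferred over biological realism: every planted quantity is recorded in a
ground-truth object computed directly from the final base array by simple
slicing, independently of the analysis modules it is used to test.

The panel generator evolves gene sets down a guide tree under a two-rate
(transition/transversion) site-independent substitution process (Kimura's
two-parameter model, rate-normalised so branch lengths are expected
substitutions per site), for exercising the distance/NJ/monophyly stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np

from .control_region import microsatellite_scan, tandem_repeat_scan
from .genome import (
    CATEGORY,
    Anticodon,
    GeneFeature,
    MitogenomeAnnotation,
    MitogenomeRecord,
    invertebrate_mito_code,
    packaged_annotation,
    reverse_complement,
)

__all__ = [
    "ControlRegionPlan",
    "TemplateFeature",
    "GenomeTemplate",
    "GroundTruth",
    "default_template",
    "simulate_mitogenome",
    "EvolutionSpec",
    "evolve_panel",
    "write_fasta",
    "write_genbank",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class ControlRegionPlan:
    """Planted control-region elements, rrnS-proximal end first.

    Defaults mirror the conserved lepidopteran layout: ATAGA origin motif,
    a 19 bp poly-T immediately after it, an (AT)10 microsatellite, a 23 bp
    unit repeated twice, and a 9 bp poly-A abutting the trnM boundary.
    """

    origin_motif: str = "ATAGA"
    poly_t_length: int = 19
    microsat_motif: str = "AT"
    microsat_copies: int = 10
    tandem_unit_length: int = 23
    tandem_copies: int = 2
    poly_a_length: int = 9


@dataclass(frozen=True)
class TemplateFeature:
    name: str
    strand: str
    size: int
    category: str = ""
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    anticodon_triplet: Optional[str] = None  # sense-strand triplet, as annotated
    anticodon_offset: Optional[int] = None  # 0-based forward-strand offset from start


@dataclass
class GenomeTemplate:
    """Layout + statistical targets for one synthetic mitogenome."""

    species: str
    features: list  # TemplateFeature in genome order
    junctions: list  # signed ign after each feature; last entry wraps the origin
    at_whole: float = 0.80
    at_control_region: float = 0.91
    control_plan: Optional[ControlRegionPlan] = ControlRegionPlan()
    plant_junction_motifs: bool = True
    trns2_nad1_motif_offset: Optional[int] = None  # default: centred in the spacer

    def __post_init__(self) -> None:
        if len(self.junctions) != len(self.features):
            raise ValueError("need one junction value per feature (last one wraps)")
        if not (0 < self.at_whole < 1 and 0 < self.at_control_region < 1):
            raise ValueError("AT targets must lie in (0, 1)")
        for f, ign in zip(self.features, self.junctions):
            if ign < 0 and -ign >= f.size:
                raise ValueError(
                    f"overlap after {f.name} ({-ign} bp) is not shorter than the gene"
                )

    @property
    def genome_length(self) -> int:
        return sum(f.size for f in self.features) + sum(self.junctions)


@dataclass
class GroundTruth:
    """Everything the generator planted, recorded for plant-and-recover tests."""

    species: str
    seed: int
    genome_length: int
    igns: dict  # "upstream--downstream" -> signed ign, incl. the wrap pair
    spacer_count: int
    spacer_total: int
    overlap_count: int
    overlap_total: int
    codon_counts: dict  # RNA codon -> pooled count over PCGs (start incl., stop excl.)
    total_codons: int
    start_codons: dict
    stop_codons: dict
    base_counts: dict  # region -> {A,T,G,C} counts from the final array
    at_targets: dict
    junction_motif_offsets: dict  # motif -> 0-based offset within its window
    control_elements: Optional[dict]  # CR-relative 0-based positions/lengths


def default_template(species: str = "synthetic_hestina") -> GenomeTemplate:
    """Template transcribed from the packaged H. persimilis annotation.

    Sizes, strands, start/stop codons and junction values come straight
    from the shipped table (computed sizes, so the layout tiles exactly);
    anticodon triplets are kept, with the two typo positions recentred.
    """
    ann = packaged_annotation("hestina_persimilis")
    feats = []
    igns = []
    for idx, f in enumerate(ann.features):
        ac_off = None
        ac_triplet = None
        if f.anticodon is not None:
            ac_triplet = f.anticodon.triplet
            ac_off = f.anticodon.start - f.start
            if not (0 <= ac_off and f.anticodon.end <= f.end):
                ac_off = f.size // 2 - 1  # recentre the typo'd positions
        feats.append(
            TemplateFeature(
                name=f.name, strand=f.strand, size=f.size,
                category=CATEGORY.get(f.name, ""),
                start_codon=f.start_codon, stop_codon=f.stop_codon,
                anticodon_triplet=ac_triplet, anticodon_offset=ac_off,
            )
        )
        nxt = ann.features[idx + 1] if idx + 1 < len(ann.features) else None
        if nxt is not None:
            igns.append(nxt.start - f.end - 1)
        else:
            igns.append(ann.genome_length - f.end)  # wrap back to position 1
    return GenomeTemplate(species=species, features=feats, junctions=igns)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _iid_bases(rng: np.random.Generator, n: int, at: float) -> np.ndarray:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])  # A C G T
    return _BASES[rng.choice(4, size=n, p=p)]


def _solve_codon_base_at(at_target: float, code) -> float:
    """Per-base AT level whose stop-free codon distribution has the target
    AT content (excluding AT-rich stop codons depresses it slightly)."""
    sense = code.sense_codons

    def mean_at(q: float) -> float:
        pb = {"A": q / 2, "T": q / 2, "G": (1 - q) / 2, "C": (1 - q) / 2}
        w = [pb[c[0]] * pb[c[1]] * pb[c[2]] for c in sense]
        at = [sum(b in "AT" for b in c) / 3 for c in sense]
        total = sum(w)
        return sum(wi * ai for wi, ai in zip(w, at)) / total

    lo, hi = 0.05, 0.995
    for _ in range(60):
        mid = (lo + hi) / 2
        if mean_at(mid) < at_target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _codon_profile(at_target: float, code) -> tuple[list, np.ndarray]:
    q = _solve_codon_base_at(at_target, code)
    pb = {"A": q / 2, "T": q / 2, "G": (1 - q) / 2, "C": (1 - q) / 2}
    sense = list(code.sense_codons)
    w = np.array([pb[c[0]] * pb[c[1]] * pb[c[2]] for c in sense])
    return sense, w / w.sum()


def _write(arr: np.ndarray, pos0: int, text: str) -> None:
    arr[pos0:pos0 + len(text)] = np.frombuffer(text.encode(), dtype="S1")


def _expected_stop_remainder(stop: str) -> int:
    return {"TAA": 0, "TAG": 0, "T": 1, "TA": 2}[stop]


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

def simulate_mitogenome(
    tpl: GenomeTemplate,
    seed: int = 0,
) -> tuple[MitogenomeRecord, GroundTruth]:
    """Emit a sequence + annotation honouring the template, with ground truth.

    Deterministic under ``seed``: identical seeds give identical sequences,
    different seeds differ in sequence but share the annotation.
    """
    rng = np.random.default_rng(seed)
    code = invertebrate_mito_code()

    # coordinates from sizes + junction values
    starts, ends = [], []
    pos = 1
    for f, ign in zip(tpl.features, tpl.junctions):
        starts.append(pos)
        ends.append(pos + f.size - 1)
        pos = ends[-1] + 1 + ign
    length = tpl.genome_length
    if pos != length + 1:
        raise ValueError("junction values do not close the circle")

    arr = _iid_bases(rng, length, tpl.at_whole)
    by_name = {f.name: (f, s, e) for f, s, e in zip(tpl.features, starts, ends)}

    # tRNA anticodons: annotated triplet is on the tRNA's sense strand, its
    # position on the forward strand — R-strand genes store its complement
    for f, s, e in zip(tpl.features, starts, ends):
        if f.anticodon_triplet and f.anticodon_offset is not None:
            triplet = f.anticodon_triplet if f.strand == "F" \
                else reverse_complement(f.anticodon_triplet)
            _write(arr, s - 1 + f.anticodon_offset, triplet)

    # PCGs: start + profile-drawn interior + stop, sense strand
    sense_codons, weights = _codon_profile(tpl.at_whole, code)
    for f, s, e in zip(tpl.features, starts, ends):
        if f.category != "PCG":
            continue
        if not f.start_codon or not f.stop_codon:
            raise ValueError(f"PCG {f.name} needs start and stop codons in the template")
        rem = _expected_stop_remainder(f.stop_codon)
        if f.size % 3 != rem:
            raise ValueError(
                f"PCG {f.name}: size {f.size} inconsistent with stop {f.stop_codon!r}"
            )
        n_interior = (f.size - 3 - len(f.stop_codon)) // 3 if rem == 0 \
            else (f.size - 3 - rem) // 3
        interior = "".join(
            sense_codons[k] for k in rng.choice(len(sense_codons), size=n_interior, p=weights)
        )
        sense = f.start_codon + interior + f.stop_codon
        assert len(sense) == f.size
        _write(arr, s - 1, sense if f.strand == "F" else reverse_complement(sense))

    motif_offsets: dict[str, int] = {}
    if tpl.plant_junction_motifs:
        # ATGATAA across the canonical -7 atp8/atp6 overlap (atp6 sense strand)
        if "atp8" in by_name and "atp6" in by_name:
            f8, s8, e8 = by_name["atp8"]
            f6, s6, e6 = by_name["atp6"]
            if s6 - e8 - 1 == -7 and f6.strand == "F":
                _write(arr, s6 - 1, "ATGATAA")
                motif_offsets["ATGATAA"] = 0
        # ATACTAA inside the trnS2-nad1 spacer
        if "trnS2" in by_name and "nad1" in by_name:
            _, _, e_up = by_name["trnS2"]
            _, s_down, _ = by_name["nad1"]
            spacer = s_down - e_up - 1
            if spacer >= 7:
                off = tpl.trns2_nad1_motif_offset
                if off is None:
                    off = (spacer - 7) // 2
                if not 0 <= off <= spacer - 7:
                    raise ValueError("trnS2-nad1 motif offset does not fit the spacer")
                _write(arr, e_up + off, "ATACTAA")
                motif_offsets["ATACTAA"] = off

    control_truth = None
    if "control_region" in by_name and tpl.control_plan is not None:
        control_truth = _build_control_region(
            arr, by_name["control_region"], tpl.control_plan,
            tpl.at_control_region, rng,
        )

    # ---- annotation ----
    features = []
    for f, s, e in zip(tpl.features, starts, ends):
        ac = None
        if f.anticodon_triplet and f.anticodon_offset is not None:
            ac = Anticodon(f.anticodon_triplet, s + f.anticodon_offset,
                           s + f.anticodon_offset + 2)
        features.append(
            GeneFeature(
                name=f.name, strand=f.strand, start=s, end=e,
                category=f.category or CATEGORY.get(f.name, ""),
                size_declared=f.size, anticodon=ac,
                start_codon=f.start_codon, stop_codon=f.stop_codon,
            )
        )
    # declared ign column mirrors the printed-table convention: the value on
    # a row is the gap before that row's feature
    for idx, feat in enumerate(features):
        if idx > 0:
            feat.ign_declared = tpl.junctions[idx - 1]
    ann = MitogenomeAnnotation(species=tpl.species, genome_length=length, features=features)
    seq = arr.tobytes().decode()
    rec = MitogenomeRecord(annotation=ann, sequence=seq)

    # ---- ground truth from the final array ----
    igns = {}
    for idx, f in enumerate(tpl.features):
        nxt = tpl.features[(idx + 1) % len(tpl.features)]
        igns[f"{f.name}--{nxt.name}"] = tpl.junctions[idx]
    non_cr = {
        pair: v for pair, v in igns.items() if "control_region" not in pair.split("--")
    }
    spacers = [v for v in non_cr.values() if v > 0]
    overlaps = [-v for v in non_cr.values() if v < 0]

    codon_counts: dict[str, int] = {}
    start_codons, stop_codons = {}, {}
    total = 0
    for f, s, e in zip(tpl.features, starts, ends):
        if f.category != "PCG":
            continue
        sense = seq[s - 1:e]
        if f.strand == "R":
            sense = reverse_complement(sense)
        k, rem = divmod(len(sense), 3)
        triplets = [sense[i * 3:(i + 1) * 3] for i in range(k)]
        if rem == 0 and triplets[-1] in ("TAA", "TAG"):
            triplets = triplets[:-1]
        for c in triplets:
            key = c.replace("T", "U")
            codon_counts[key] = codon_counts.get(key, 0) + 1
            total += 1
        start_codons[f.name] = sense[:3]
        stop_codons[f.name] = sense[-rem:] if rem else sense[-3:]

    def region_counts(lo: int, hi: int) -> dict:
        sub = seq[lo:hi]
        return {b: sub.count(b) for b in "ATGC"}

    base_counts = {"whole": region_counts(0, length)}
    if "control_region" in by_name:
        _, cs, ce = by_name["control_region"]
        base_counts["control_region"] = region_counts(cs - 1, ce)

    truth = GroundTruth(
        species=tpl.species, seed=seed, genome_length=length, igns=igns,
        spacer_count=len(spacers), spacer_total=sum(spacers),
        overlap_count=len(overlaps), overlap_total=sum(overlaps),
        codon_counts=codon_counts, total_codons=total,
        start_codons=start_codons, stop_codons=stop_codons,
        base_counts=base_counts,
        at_targets={"whole": tpl.at_whole, "control_region": tpl.at_control_region},
        junction_motif_offsets=motif_offsets,
        control_elements=control_truth,
    )
    return rec, truth


def _clean_filler(rng: np.random.Generator, n: int, at: float) -> str:
    """AT-biased filler free of microsatellite runs and of long-unit tandem
    arrays, so the planted elements are unambiguous.  Short-period
    near-repeats are left in: they are intrinsic to AT-rich sequence and
    cannot be excluded without destroying the composition target."""
    if n <= 0:
        return ""
    for _ in range(200):
        chunk = _iid_bases(rng, n, at).tobytes().decode()
        if n >= 8 and microsatellite_scan(chunk, ("AT", "TA"), min_copies=4):
            continue
        if n >= 20 and tandem_repeat_scan(chunk, 10, min(50, n // 2), 1.9, 0.85):
            continue
        return chunk
    raise RuntimeError("could not draw clean control-region filler")


def _random_primitive_unit(rng: np.random.Generator, p: int, at: float, min_period: int) -> str:
    from .control_region import _smallest_period

    for _ in range(200):
        unit = _iid_bases(rng, p, at).tobytes().decode()
        if _smallest_period(unit) >= min_period and len(set(unit)) >= 2:
            return unit
    raise RuntimeError("could not draw a primitive repeat unit")


def _build_control_region(arr, cr_entry, plan: ControlRegionPlan,
                          at: float, rng: np.random.Generator) -> dict:
    _, cs, ce = cr_entry
    n = ce - cs + 1
    p = plan.tandem_unit_length
    unit = _random_primitive_unit(rng, p, at, min_period=5)

    # Mismatch guards flanking the tandem array: every guard base differs
    # from its p-shifted partner inside the array, so phase-shifted detector
    # candidates pick up one mismatch per shifted base and the reported
    # array boundary can drift by at most floor((1-identity)*p).
    g = min(6, p)
    pre_guard = "".join(
        "G" if unit[p - g + i] != "G" else "C" for i in range(g)
    )
    post_guard = "".join(
        "G" if unit[i] != "G" else "C" for i in range(g)
    )
    fixed = [
        plan.origin_motif,
        "T" * plan.poly_t_length,
        "C",  # terminates the poly-T run
        None,  # filler 1
        "G",
        plan.microsat_motif * plan.microsat_copies,
        "G",
        None,  # filler 2
        pre_guard,
        unit * plan.tandem_copies,
        post_guard,
        None,  # filler 3
        "G",  # keeps the poly-A run exact
        "A" * plan.poly_a_length,
    ]
    fixed_len = sum(len(x) for x in fixed if x is not None)
    free = n - fixed_len
    if free < 0:
        raise ValueError(
            f"control region of {n} bp too short for the planted elements ({fixed_len} bp)"
        )
    f1 = free // 3
    f2 = free // 3
    f3 = free - f1 - f2
    fillers = iter([_clean_filler(rng, f1, at), _clean_filler(rng, f2, at),
                    _clean_filler(rng, f3, at)])
    parts = [next(fillers) if x is None else x for x in fixed]
    cr_seq = "".join(parts)
    assert len(cr_seq) == n
    _write(arr, cs - 1, cr_seq)

    offsets = {}
    pos = 0
    keys = ["origin_motif", "poly_t", None, None, None, "microsat", None, None,
            None, "tandem", None, None, None, "poly_a"]
    for key, part in zip(keys, parts):
        if key:
            offsets[key] = pos
        pos += len(part)
    return {
        "origin_motif": plan.origin_motif,
        "origin_motif_offset": offsets["origin_motif"],
        "poly_t_offset": offsets["poly_t"],
        "poly_t_length": plan.poly_t_length,
        "microsat_motif": plan.microsat_motif,
        "microsat_copies": plan.microsat_copies,
        "microsat_offset": offsets["microsat"],
        "tandem_unit": unit,
        "tandem_unit_length": plan.tandem_unit_length,
        "tandem_copies": plan.tandem_copies,
        "tandem_offset": offsets["tandem"],
        "poly_a_offset": offsets["poly_a"],
        "poly_a_length": plan.poly_a_length,
    }


# ---------------------------------------------------------------------------
# Panel evolution
# ---------------------------------------------------------------------------

#: Computed 13-PCG lengths of the packaged H. persimilis annotation.
DEFAULT_GENE_LENGTHS = {
    "nad2": 1014, "cox1": 1536, "cox2": 679, "atp8": 162, "atp6": 675,
    "cox3": 789, "nad3": 354, "nad5": 1761, "nad4": 1339, "nad4L": 291,
    "nad6": 528, "cob": 1152, "nad1": 942,
}


@dataclass
class EvolutionSpec:
    """Guide tree + substitution parameters for a synthetic sequence panel."""

    newick: str
    kappa: float = 2.0  # transition/transversion rate ratio
    gene_lengths: dict = field(default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    at_bias: float = 0.80  # root base composition

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


def k80_transition_matrix(t: float, kappa: float) -> np.ndarray:
    """K80 transition-probability matrix P(t), rows/cols ordered A,C,G,T.

    Rate-normalised so that t is the expected number of substitutions per
    site; transitions are A<->G and C<->T.
    """
    if t < 0:
        raise ValueError("branch length must be >= 0")
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    same = 0.25 + 0.25 * e1 + 0.5 * e2
    ts = 0.25 + 0.25 * e1 - 0.5 * e2
    tv = 0.25 - 0.25 * e1
    P = np.full((4, 4), tv)
    np.fill_diagonal(P, same)
    P[0, 2] = P[2, 0] = ts  # A <-> G
    P[1, 3] = P[3, 1] = ts  # C <-> T
    return P


def _evolve_along(parent: np.ndarray, t: float, kappa: float,
                  rng: np.random.Generator) -> np.ndarray:
    if t == 0:
        return parent.copy()
    P = k80_transition_matrix(t, kappa)
    child = np.empty_like(parent)
    for b in range(4):
        mask = parent == b
        k = int(mask.sum())
        if k:
            child[mask] = rng.choice(4, size=k, p=P[b])
    return child


def evolve_panel(spec: EvolutionSpec, seed: int = 0) -> dict:
    """Per-taxon PCG sequence sets evolved down the guide tree.

    Root sequences are i.i.d. with the AT bias; each branch applies the K80
    process for its length.  Returns {taxon: {gene: sequence}} suitable for
    :func:`mitolepi.phylo.build_supermatrix` (same-length genes per gene, so
    the sets are pre-aligned by construction).
    """
    try:
        tree = dendropy.Tree.get(data=spec.newick, schema="newick",
                                 preserve_underscores=True)
    except Exception as e:
        raise ValueError(f"malformed Newick: {e}") from e
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) < 3:
        raise ValueError("guide tree needs at least 3 leaves")
    rng = np.random.default_rng(seed)
    p_root = np.array([spec.at_bias / 2, (1 - spec.at_bias) / 2,
                       (1 - spec.at_bias) / 2, spec.at_bias / 2])

    panel: dict[str, dict[str, str]] = {lf: {} for lf in leaves}
    for gene, glen in spec.gene_lengths.items():
        states: dict[int, np.ndarray] = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                states[id(node)] = rng.choice(4, size=glen, p=p_root)
            else:
                t = node.edge.length or 0.0
                states[id(node)] = _evolve_along(
                    states[id(node.parent_node)], t, spec.kappa, rng
                )
            if node.is_leaf():
                panel[node.taxon.label][gene] = (
                    _BASES[states[id(node)]].tobytes().decode()
                )
    return panel


#: Six-leaf guide tree with a long internal backbone: the benchmark design
#: for distance/NJ topology recovery (two cherries + one cherry outgroup-side).
SIX_LEAF_TREE = (
    "(((A:0.05,B:0.05):0.08,(C:0.05,D:0.05):0.08):0.08,(E:0.05,F:0.05):0.08);"
)


def same_topology(tree, guide_newick: str) -> bool:
    """Unrooted Robinson–Foulds identity between an inferred tree and a
    guide-tree Newick string."""
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(
        data=tree.as_string(schema="newick"), schema="newick",
        taxon_namespace=tns, preserve_underscores=True,
    )
    tb = dendropy.Tree.get(
        data=guide_newick, schema="newick",
        taxon_namespace=tns, preserve_underscores=True,
    )
    ta.is_rooted = tb.is_rooted = False
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    from dendropy.calculate import treecompare

    return treecompare.symmetric_difference(ta, tb) == 0


def nj_recovery_count(
    spec: EvolutionSpec,
    n_replicates: int = 100,
    seed: int = 0,
    model: str = "K2P",
) -> int:
    """How many of ``n_replicates`` simulated panels NJ resolves to the
    generating topology.  Each replicate evolves a fresh panel, builds the
    supermatrix, estimates distances and joins neighbors."""
    from .phylo import build_supermatrix, distances, nj_tree

    recovered = 0
    base = np.random.SeedSequence(seed).generate_state(n_replicates)
    for r in range(n_replicates):
        panel = evolve_panel(spec, seed=int(base[r] % (2**31)))
        sm = build_supermatrix(panel)
        tree = nj_tree(distances(sm, model=model))
        if same_topology(tree, spec.newick):
            recovered += 1
    return recovered


# ---------------------------------------------------------------------------
# Output formats
# ---------------------------------------------------------------------------

def write_fasta(rec: MitogenomeRecord, path: str | Path, width: int = 70) -> None:
    if rec.sequence is None:
        raise ValueError("record has no sequence")
    seq = rec.sequence
    lines = [f">{rec.annotation.species} {rec.annotation.genome_length} bp circular"]
    lines += [seq[i:i + width] for i in range(0, len(seq), width)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_genbank(rec: MitogenomeRecord, path: str | Path) -> None:
    """Emit a GenBank flat file (round-trippable through parse_genbank)."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    ann = rec.annotation
    seq = Seq(rec.sequence) if rec.sequence is not None else Seq("N" * ann.genome_length)
    record = SeqRecord(
        seq, id="SYNTH001", name="SYNTH001",
        description=f"{ann.species} mitochondrion, complete genome",
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular"
    record.annotations["organism"] = ann.species
    for f in ann.features:
        loc = FeatureLocation(f.start - 1, f.end, strand=-1 if f.strand == "R" else 1)
        if f.category == "PCG":
            ftype = "CDS"
        elif f.category == "tRNA":
            ftype = "tRNA"
        elif f.category == "rRNA":
            ftype = "rRNA"
        else:
            ftype = "D-loop"
        quals = {"gene": [f.name]}
        if f.anticodon is not None:
            quals["anticodon"] = [
                f"(pos:{f.anticodon.start}..{f.anticodon.end},"
                f"aa:Xaa,seq:{f.anticodon.triplet.lower()})"
            ]
        record.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    from Bio import SeqIO

    SeqIO.write([record], str(path), "genbank")
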