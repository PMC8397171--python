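"""Domain model for annotated circular mitochondrial genomes.

Coordinates are 1-based and inclusive on the forward (majority / J) strand
throughout, matching both GenBank convention and the way mitogenome
annotation tables are printed.  Minority-strand ("R") features are stored in
forward coordinates; sequence extraction reverse-complements.  Features that
wrap the origin are rejected: insect mitogenomes are conventionally
linearised at trnM, so no annotated feature spans the join.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "Anticodon",
    "GeneFeature",
    "MitogenomeAnnotation",
    "MitogenomeRecord",
    "GeneticCode",
    "ValidationIssue",
    "canonical_gene_name",
    "parse_feature_table",
    "write_feature_table",
    "parse_genbank",
    "validate_annotation",
    "feature_sequence",
    "reverse_complement",
    "packaged_annotation",
    "GENE_ORDER",
    "PCG_ORDER",
    "CATEGORY",
]

# Canonical lepidopteran gene order (37 genes + control region), linearised
# at trnM with the control region last.
GENE_ORDER = (
    "trnM", "trnI", "trnQ", "nad2", "trnW", "trnC", "trnY", "cox1",
    "trnL2", "cox2", "trnK", "trnD", "atp8", "atp6", "cox3", "trnG",
    "nad3", "trnA", "trnR", "trnN", "trnS1", "trnE", "trnF", "nad5",
    "trnH", "nad4", "nad4L", "trnT", "trnP", "nad6", "cob", "trnS2",
    "nad1", "trnL1", "rrnL", "trnV", "rrnS", "control_region",
)

#: The 13 protein-coding genes in genome order; also the fixed concatenation
#: order used by the supermatrix stage.
PCG_ORDER = (
    "nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3",
    "nad5", "nad4", "nad4L", "nad6", "cob", "nad1",
)

CATEGORY = {name: "PCG" for name in PCG_ORDER}
CATEGORY.update({name: "tRNA" for name in GENE_ORDER if name.startswith("trn")})
CATEGORY.update({"rrnL": "rRNA", "rrnS": "rRNA", "control_region": "control"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _load_synonyms() -> dict[str, str]:
    table: dict[str, str] = {}
    text = resources.files("mitolepi.data").joinpath("gene_synonyms.tsv").read_text()
    for line in text.splitlines()[1:]:
        parts = line.rstrip("\n").split("\t")
        canonical = parts[0]
        for syn in parts[1:]:
            if syn:
                table[syn.strip().lower()] = canonical
    return table


_SYNONYMS = _load_synonyms()


def canonical_gene_name(name: str) -> str:
    """Map a gene label (any common synonym) to its canonical identifier.

    Raises ``ValueError`` listing accepted synonyms for unknown names;
    silent misjoins here would corrupt every downstream stage.
    """
    key = " ".join(name.split()).lower()
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    # tolerate a missing space before a parenthesised codon family
    key2 = re.sub(r"\s*\(", " (", key)
    if key2 in _SYNONYMS:
        return _SYNONYMS[key2]
    known = ", ".join(sorted(set(_SYNONYMS.values())))
    raise ValueError(
        f"unknown gene name {name!r}; canonical names are: {known} "
        "(common synonyms such as COI, ND2, lrRNA, D-loop are accepted)"
    )


@dataclass(frozen=True)
class Anticodon:
    triplet: str
    start: int  # 1-based inclusive, forward-strand coordinates
    end: int


@dataclass
class GeneFeature:
    """One annotated feature: the row type of a mitogenome annotation table."""

    name: str
    strand: str = "F"  # F = majority/J strand
    start: int = 1
    end: int = 1
    category: str = ""
    size_declared: Optional[int] = None
    anticodon: Optional[Anticodon] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    ign_declared: Optional[int] = None  # printed column, checked but never trusted

    def __post_init__(self) -> None:
        if self.strand not in ("F", "R"):
            raise ValueError(f"{self.name}: strand must be 'F' or 'R', got {self.strand!r}")
        if self.end < self.start:
            raise ValueError(
                f"{self.name}: end ({self.end}) < start ({self.start}); "
                "wrap-spanning features are not supported"
            )
        if not self.category:
            self.category = CATEGORY.get(self.name, "")

    @property
    def size(self) -> int:
        """Computed length in bp (end − start + 1); never the declared size."""
        return self.end - self.start + 1


@dataclass
class MitogenomeAnnotation:
    species: str
    genome_length: int
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        if self.features:
            max_end = max(f.end for f in self.features)
            if self.genome_length < max_end:
                raise ValueError(
                    f"genome_length {self.genome_length} < max feature end {max_end}"
                )

    def feature(self, name: str) -> GeneFeature:
        name = canonical_gene_name(name)
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"no feature {name!r} in annotation of {self.species}")

    def by_category(self, category: str) -> list[GeneFeature]:
        return [f for f in self.features if f.category == category]

    def has_canonical_order(self) -> bool:
        """Check the canonical lepidopteran arrangement (trnM first,
        control region last).  Informative, not enforced."""
        names = tuple(f.name for f in self.features)
        return names == GENE_ORDER

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "genome_length": self.genome_length,
            "circular": self.circular,
            "features": [asdict(f) for f in self.features],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "MitogenomeAnnotation":
        feats = []
        for fd in d["features"]:
            fd = dict(fd)
            if fd.get("anticodon"):
                fd["anticodon"] = Anticodon(**fd["anticodon"])
            feats.append(GeneFeature(**fd))
        return cls(
            species=d["species"],
            genome_length=d["genome_length"],
            features=feats,
            circular=d.get("circular", True),
        )


@dataclass
class MitogenomeRecord:
    annotation: MitogenomeAnnotation
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.annotation.genome_length:
                raise ValueError(
                    f"sequence length {len(self.sequence)} != genome_length "
                    f"{self.annotation.genome_length}"
                )


# ---------------------------------------------------------------------------
# Genetic code
# ---------------------------------------------------------------------------

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


@dataclass(frozen=True)
class GeneticCode:
    """A codon table plus the synonymous-family partition used for RSCU.

    Families follow the convention of mitogenome codon-usage plots: Leu is
    split into Leu1 (CUN) and Leu2 (UUR), Ser into Ser1 (AGN) and Ser2
    (UCN).  Stop codons belong to no family.  Codons are DNA-alphabet
    uppercase triplets.
    """

    table_id: int
    codon_to_aa: dict  # 64 codons -> one-letter aa, '*' for stop
    families: dict  # family name -> tuple of codons
    stop_codons: frozenset

    @classmethod
    def from_ncbi_table(cls, table_id: int = 5) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        codon_to_aa = dict(t.forward_table)
        for stop in t.stop_codons:
            codon_to_aa[stop] = "*"
        families: dict[str, list[str]] = {}
        for codon, aa in sorted(codon_to_aa.items()):
            if aa == "*":
                continue
            fam = _AA3[aa]
            if aa == "L":
                fam = "Leu1" if codon.startswith("CT") else "Leu2"
            elif aa == "S":
                fam = "Ser1" if codon.startswith("AG") else "Ser2"
            families.setdefault(fam, []).append(codon)
        return cls(
            table_id=table_id,
            codon_to_aa=codon_to_aa,
            families={k: tuple(v) for k, v in families.items()},
            stop_codons=frozenset(t.stop_codons),
        )

    @property
    def family_of(self) -> dict:
        return {c: fam for fam, codons in self.families.items() for c in codons}

    @property
    def sense_codons(self) -> tuple:
        return tuple(c for fam in self.families.values() for c in fam)


def invertebrate_mito_code() -> GeneticCode:
    """NCBI translation table 5 (ATA=Met, TGA=Trp, AGA/AGG=Ser)."""
    return GeneticCode.from_ncbi_table(5)


# ---------------------------------------------------------------------------
# Feature-table parsing
# ---------------------------------------------------------------------------

_DASHES = "–—‒−"  # en dash, em dash, figure dash, minus sign


def _clean_int(tok: str) -> int:
    tok = tok.replace(",", "").replace("−", "-").strip()
    return int(tok)


def _parse_location(tok: str, row_label: str) -> tuple[int, int]:
    tok = tok.replace(",", "").strip()
    for d in _DASHES:
        tok = tok.replace(d, "-")
    m = re.fullmatch(r"(\d+)\s*-\s*(\d+)", tok)
    if not m:
        raise ValueError(f"row {row_label!r}: malformed location {tok!r} (expected 'start-end')")
    return int(m.group(1)), int(m.group(2))


_ANTICODON_RE = re.compile(
    r"([ACGTU]{3})\s*([\d,]+)\s*[" + _DASHES + r"\-]\s*([\d,]+)"
)


def _parse_anticodon(tok: str) -> Optional[Anticodon]:
    tok = tok.strip()
    if not tok:
        return None
    m = _ANTICODON_RE.fullmatch(tok)
    if not m:
        raise ValueError(f"malformed anticodon field {tok!r}")
    return Anticodon(m.group(1).replace("U", "T"), _clean_int(m.group(2)), _clean_int(m.group(3)))


def parse_feature_table(
    path: str | Path,
    species: str = "",
    genome_length: Optional[int] = None,
) -> MitogenomeAnnotation:
    """Read a tab-separated annotation table.

    Column order: Gene, Direction, Location, Size, Anticodon, Start Codon,
    Stop Codon, Intergenic Nucleotides.  Locations are 'start–end' (hyphen
    or dash, optional thousands separators).  The declared Size and
    Intergenic Nucleotides columns are retained for cross-checking by the
    validator but never enter any computation.  When ``genome_length`` is
    omitted it defaults to the largest feature end.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    features: list[GeneFeature] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        cells = line.rstrip("\n").split("\t")
        if lineno == 1 and cells and cells[0].strip().lower() in ("gene", "name"):
            continue  # header
        cells += [""] * (8 - len(cells))
        raw_name, direction, loc, size, anticodon, startc, stopc, ign = (
            c.strip() for c in cells[:8]
        )
        if not raw_name:
            continue
        row_label = f"{path.name}:{lineno} ({raw_name or '?'})"
        name = canonical_gene_name(raw_name)
        start, end = _parse_location(loc, row_label)
        features.append(
            GeneFeature(
                name=name,
                strand=direction if direction else "F",
                start=start,
                end=end,
                size_declared=_clean_int(size) if size else None,
                anticodon=_parse_anticodon(anticodon),
                start_codon=startc.upper() or None,
                stop_codon=stopc.upper() or None,
                ign_declared=_clean_int(ign) if ign != "" else None,
            )
        )
    if not features:
        raise ValueError(f"{path}: no feature rows found")
    if genome_length is None:
        genome_length = max(f.end for f in features)
    return MitogenomeAnnotation(
        species=species or path.stem, genome_length=genome_length, features=features
    )


def write_feature_table(ann: MitogenomeAnnotation, path: str | Path) -> None:
    """Serialize an annotation back to the seven-column TSV layout."""
    rows = ["Gene\tDirection\tLocation\tSize\tAnticodon\tStart Codon\tStop Codon\tIntergenic Nucleotides"]
    for f in ann.features:
        ac = f"{f.anticodon.triplet} {f.anticodon.start}-{f.anticodon.end}" if f.anticodon else ""
        rows.append(
            "\t".join(
                [
                    f.name,
                    f.strand,
                    f"{f.start}-{f.end}",
                    str(f.size_declared) if f.size_declared is not None else "",
                    ac,
                    f.start_codon or "",
                    f.stop_codon or "",
                    str(f.ign_declared) if f.ign_declared is not None else "",
                ]
            )
        )
    Path(path).write_text("\n".join(rows) + "\n")


def packaged_annotation(species: str) -> MitogenomeAnnotation:
    """Load one of the packaged annotation tables.

    ``species`` is ``"hestina_persimilis"`` or ``"hestinalis_nama"``; the
    tables are transcribed from the published annotations, typos included
    (see :func:`validate_annotation`).
    """
    ref = resources.files("mitolepi.data").joinpath(f"{species}.tsv")
    if not ref.is_file():
        raise ValueError(
            "unknown packaged species "
            f"{species!r}; available: hestina_persimilis, hestinalis_nama"
        )
    with resources.as_file(ref) as p:
        return parse_feature_table(p, species=species)


# ---------------------------------------------------------------------------
# GenBank I/O
# ---------------------------------------------------------------------------

_GB_FEATURE_TYPES = {"CDS", "tRNA", "rRNA", "D-loop", "misc_feature"}


def parse_genbank(path: str | Path) -> MitogenomeRecord:
    """Read a single-record GenBank flat file into a :class:`MitogenomeRecord`.

    Feature names are canonicalised from the ``gene``/``product`` qualifiers;
    ``complement(..)`` locations become strand R in forward coordinates.
    ``join``/wrap-spanning locations are rejected.  A record without sequence
    (no ORIGIN) yields an annotation-only record.
    """
    record = SeqIO.read(str(path), "genbank")
    try:
        sequence: Optional[str] = str(record.seq).upper()
        if not sequence:
            sequence = None
    except Exception:  # Bio.Seq.UndefinedSequenceError
        sequence = None

    features: list[GeneFeature] = []
    for feat in record.features:
        if feat.type not in _GB_FEATURE_TYPES:
            continue
        if len(feat.location.parts) > 1:
            raise ValueError(
                f"feature {feat.type} at {feat.location}: join/wrap-spanning "
                "locations are not supported"
            )
        quals = feat.qualifiers
        label = (quals.get("gene") or quals.get("product") or quals.get("note") or [None])[0]
        if feat.type == "D-loop":
            label = "control_region"
        if label is None:
            continue
        if feat.type == "misc_feature" and "control" not in label.lower() \
                and "a+t" not in label.lower():
            continue
        name = canonical_gene_name(label)
        start = int(feat.location.start) + 1
        end = int(feat.location.end)
        strand = "R" if feat.location.strand == -1 else "F"
        anticodon = None
        if "anticodon" in quals:
            m = re.search(r"pos:(\d+)\.\.(\d+).*seq:([a-zA-Z]{3})", quals["anticodon"][0])
            if m:
                anticodon = Anticodon(m.group(3).upper(), int(m.group(1)), int(m.group(2)))
        start_codon = stop_codon = None
        if feat.type == "CDS" and sequence is not None:
            sense = sequence[start - 1:end]
            if strand == "R":
                sense = reverse_complement(sense)
            start_codon = sense[:3]
            rem = len(sense) % 3
            if rem:
                stop_codon = sense[-rem:]
            elif sense[-3:] in ("TAA", "TAG"):
                stop_codon = sense[-3:]
        features.append(
            GeneFeature(
                name=name, strand=strand, start=start, end=end,
                size_declared=end - start + 1, anticodon=anticodon,
                start_codon=start_codon, stop_codon=stop_codon,
            )
        )
    features.sort(key=lambda f: f.start)
    ann = MitogenomeAnnotation(
        species=record.annotations.get("organism", record.id) or record.id,
        genome_length=len(record) if len(record) else max(f.end for f in features),
        features=features,
    )
    return MitogenomeRecord(annotation=ann, sequence=sequence)


# ---------------------------------------------------------------------------
# Validation and sequence extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationIssue:
    kind: str  # size_mismatch | anticodon_position | pcg_overlap | missing_anticodon | missing_codon
    gene: str
    message: str


def validate_annotation(
    ann: MitogenomeAnnotation,
    max_benign_pcg_overlap: int = 10,
) -> list[ValidationIssue]:
    """Cross-check an annotation's internal consistency.

    Reports, without raising: declared sizes that disagree with the
    coordinates, anticodon positions outside their gene span, missing
    anticodons/codons on tRNA/PCG rows, and same-strand PCG overlaps longer
    than ``max_benign_pcg_overlap``.  Short PCG overlaps (atp8/atp6,
    atp6/cox3) are canonical mitochondrial size economization, not errors.
    An empty list means clean.
    """
    issues: list[ValidationIssue] = []
    for f in ann.features:
        if f.size_declared is not None and f.size_declared != f.size:
            issues.append(
                ValidationIssue(
                    "size_mismatch", f.name,
                    f"declared size {f.size_declared} but {f.start}-{f.end} computes to {f.size}",
                )
            )
        if f.category == "tRNA":
            if f.anticodon is None:
                issues.append(ValidationIssue("missing_anticodon", f.name, "tRNA without anticodon"))
            elif not (f.start <= f.anticodon.start and f.anticodon.end <= f.end):
                issues.append(
                    ValidationIssue(
                        "anticodon_position", f.name,
                        f"anticodon at {f.anticodon.start}-{f.anticodon.end} lies outside "
                        f"gene span {f.start}-{f.end}",
                    )
                )
        if f.category == "PCG" and (f.start_codon is None or f.stop_codon is None):
            issues.append(ValidationIssue("missing_codon", f.name, "PCG without start/stop codon"))
    pcgs = [f for f in ann.features if f.category == "PCG"]
    for up, down in zip(pcgs, pcgs[1:]):
        if up.strand == down.strand:
            overlap = up.end - down.start + 1
            if overlap > max_benign_pcg_overlap:
                issues.append(
                    ValidationIssue(
                        "pcg_overlap", f"{up.name}/{down.name}",
                        f"same-strand PCGs overlap by {overlap} bp",
                    )
                )
    return issues


def feature_sequence(rec: MitogenomeRecord, name: str) -> str:
    """Sense-strand sequence of a named feature.

    Forward-strand features are sliced directly; R-strand features are
    returned as the reverse complement of the forward slice, so the result
    always reads 5'→3' on the coding strand.
    """
    if rec.sequence is None:
        raise ValueError("record has no sequence")
    f = rec.annotation.feature(name)
    seg = rec.sequence[f.start - 1:f.end]
    return reverse_complement(seg) if f.strand == "R" else seg
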