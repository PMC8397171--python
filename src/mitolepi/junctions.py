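"""Signed intergenic/overlap ledger over adjacent features of a circular
mitogenome.

Every adjacent feature pair, including the origin-wrapping pair, gets one
junction with a signed intergenic-nucleotide value: positive = spacer,
negative = overlap, zero = abutting.  The telescoping identity
``sum(feature sizes) + sum(signed ign) == genome_length`` holds on every
valid circular annotation and is the module's core invariant.

Summary statistics follow the convention of comparative mitogenome papers:
the control region is itself the largest non-coding stretch, so its two
junctions are excluded from the intergenic-spacer statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

from .genome import MitogenomeAnnotation, MitogenomeRecord, canonical_gene_name

__all__ = ["Junction", "LedgerSummary", "JunctionLedger", "build_ledger",
           "junction_motifs", "find_motif", "MotifHit"]

#: Conserved junction motifs of lepidopteran mitogenomes.
ATP8_ATP6_MOTIF = "ATGATAA"
TRNS2_NAD1_MOTIF = "ATACTAA"


@dataclass(frozen=True)
class Junction:
    upstream: str
    downstream: str
    ign: int  # signed bp: + spacer, - overlap, 0 abutting
    wraps_origin: bool = False
    spacer_sequence: Optional[str] = None


@dataclass(frozen=True)
class LedgerSummary:
    spacer_count: int
    spacer_min: int
    spacer_max: int
    spacer_total: int
    overlap_count: int
    overlap_min: int
    overlap_max: int
    overlap_total: int
    abutting_count: int
    excluded: tuple = ()  # junction (up, down) pairs excluded from spacer stats


@dataclass
class JunctionLedger:
    species: str
    genome_length: int
    junctions: list[Junction]
    summary: LedgerSummary = None  # filled by build_ledger

    def junction(self, upstream: str, downstream: str) -> Junction:
        up = canonical_gene_name(upstream)
        down = canonical_gene_name(downstream)
        for j in self.junctions:
            if j.upstream == up and j.downstream == down:
                return j
        raise KeyError(f"no junction {up} -> {down} in ledger of {self.species}")

    def to_tsv(self, path: str | Path) -> None:
        rows = ["upstream\tdownstream\tintergenic_nucleotides\twraps_origin"]
        for j in self.junctions:
            rows.append(f"{j.upstream}\t{j.downstream}\t{j.ign}\t{int(j.wraps_origin)}")
        Path(path).write_text("\n".join(rows) + "\n")

    def summary_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self.summary), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def spacer_fasta(self, path: str | Path) -> None:
        entries = [
            f">{j.upstream}--{j.downstream} {j.ign} bp\n{j.spacer_sequence}"
            for j in self.junctions
            if j.spacer_sequence
        ]
        Path(path).write_text("\n".join(entries) + "\n")


def build_ledger(
    ann: MitogenomeAnnotation,
    rec: Optional[MitogenomeRecord] = None,
) -> JunctionLedger:
    """Compute the full junction ledger of a circular annotation.

    One junction per adjacent pair in genome order plus the origin-wrapping
    junction (last feature -> first feature across position 1).  Spacer
    sequences are attached when ``rec`` carries sequence.  The summary
    excludes the control region's two junctions from spacer statistics.
    """
    feats = ann.features
    if any(b.start < a.start for a, b in zip(feats, feats[1:])):
        raise ValueError("features must be sorted by start coordinate")
    names = [f.name for f in feats]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names in annotation")

    seq = rec.sequence if rec is not None else None
    junctions: list[Junction] = []
    for up, down in zip(feats, feats[1:]):
        ign = down.start - up.end - 1
        spacer = None
        if seq is not None and ign > 0:
            spacer = seq[up.end:down.start - 1]
        junctions.append(Junction(up.name, down.name, ign, spacer_sequence=spacer))
    # wrap junction, computed on the circle
    last, first = feats[-1], feats[0]
    ign = (first.start + ann.genome_length) - last.end - 1
    spacer = None
    if seq is not None and ign > 0:
        spacer = (seq[last.end:] + seq[:first.start - 1])
    junctions.append(Junction(last.name, first.name, ign, wraps_origin=True, spacer_sequence=spacer))

    excluded = tuple(
        (j.upstream, j.downstream)
        for j in junctions
        if "control_region" in (j.upstream, j.downstream)
    )
    counted = [j for j in junctions if (j.upstream, j.downstream) not in excluded]
    spacers = [j.ign for j in counted if j.ign > 0]
    overlaps = [-j.ign for j in counted if j.ign < 0]
    summary = LedgerSummary(
        spacer_count=len(spacers),
        spacer_min=min(spacers, default=0),
        spacer_max=max(spacers, default=0),
        spacer_total=sum(spacers),
        overlap_count=len(overlaps),
        overlap_min=min(overlaps, default=0),
        overlap_max=max(overlaps, default=0),
        overlap_total=sum(overlaps),
        abutting_count=sum(1 for j in counted if j.ign == 0),
        excluded=excluded,
    )
    return JunctionLedger(
        species=ann.species, genome_length=ann.genome_length,
        junctions=junctions, summary=summary,
    )


@dataclass(frozen=True)
class MotifHit:
    upstream: str
    downstream: str
    motif: str
    present: bool
    offset: Optional[int] = None  # 0-based offset within the searched window
    window: Optional[str] = None


def find_motif(
    ledger: JunctionLedger,
    rec: MitogenomeRecord,
    upstream: str,
    downstream: str,
    motif: str,
    reverse_strand: bool = False,
) -> MotifHit:
    """Exact-match search for ``motif`` in one junction's window.

    For a spacer (ign > 0) the window is the spacer sequence; for an overlap
    (ign < 0) it is the overlapping stretch on the forward (J) strand.  An
    absent motif is an explicit result, not an error.  ``reverse_strand``
    searches the reverse complement of the window instead.
    """
    from .genome import reverse_complement

    j = ledger.junction(upstream, downstream)
    if rec.sequence is None:
        raise ValueError("record has no sequence")
    up = rec.annotation.feature(j.upstream)
    down = rec.annotation.feature(j.downstream)
    if j.ign > 0:
        window = j.spacer_sequence or rec.sequence[up.end:down.start - 1]
    elif j.ign < 0:
        window = rec.sequence[down.start - 1:up.end]
    else:
        window = ""
    if reverse_strand:
        window = reverse_complement(window)
    motif = motif.upper().replace("U", "T")
    pos = window.find(motif)
    return MotifHit(
        upstream=j.upstream, downstream=j.downstream, motif=motif,
        present=pos >= 0, offset=pos if pos >= 0 else None, window=window,
    )


def junction_motifs(ledger: JunctionLedger, rec: MitogenomeRecord) -> dict:
    """Report the two conserved lepidopteran junction motifs.

    Checks the ATACTAA heptamer in the trnS2(UCN)-nad1 spacer, and whether
    the atp8/atp6 junction is the canonical 7 bp overlap reading ATGATAA on
    the sense strand of atp6.
    """
    report = {}
    report["trnS2_nad1_ATACTAA"] = find_motif(ledger, rec, "trnS2", "nad1", TRNS2_NAD1_MOTIF)
    j = ledger.junction("atp8", "atp6")
    hit = find_motif(ledger, rec, "atp8", "atp6", ATP8_ATP6_MOTIF)
    report["atp8_atp6_overlap_bp"] = -j.ign
    report["atp8_atp6_canonical"] = (j.ign == -7 and hit.present and hit.offset == 0)
    report["atp8_atp6_ATGATAA"] = hit
    return report
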