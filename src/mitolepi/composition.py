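"""Base-composition and codon-usage statistics for mitogenomes.

Composition rows mirror the layout of published mitogenome base-composition
tables (whole genome, PCGs pooled, tRNAs pooled, each rRNA, control region),
reported on the majority (J) strand for the whole genome and on the coding
strand for gene and category rows.  AT/GC skews use the conventional
(A−T)/(A+T) and (G−C)/(G+C) definitions.

Codon usage pools the 13 protein-coding genes.  RSCU for codon c is

    RSCU(c) = count(c) * |family(c)| / sum over family of counts,

so uniform usage within a family gives RSCU = 1 everywhere and each family's
RSCU values sum to the family size.  CDspT (codons per thousand codons) is a
family's pooled count normalised to a per-1000 rate.  The default counting
convention includes start codons and excludes stop codons; the non-ATN cox1
initiation codon (CGA) is counted in the total but kept out of the Arg
family, where it would otherwise masquerade as an arginine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .genome import (
    GeneticCode,
    MitogenomeRecord,
    PCG_ORDER,
    canonical_gene_name,
    feature_sequence,
    invertebrate_mito_code,
)

__all__ = [
    "CompositionRow",
    "CodonExtraction",
    "CodonUsageTable",
    "UsagePanel",
    "base_composition",
    "composition_table",
    "extract_codons",
    "codon_usage",
    "usage_panel",
    "rna",
]

DEFAULT_REGIONS = ("whole", "PCGs", "tRNA", "rrnL", "rrnS", "control_region")


def rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


def dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


@dataclass(frozen=True)
class CompositionRow:
    region: str
    size: int
    count_a: int
    count_t: int
    count_g: int
    count_c: int
    count_n: int = 0

    @property
    def _denom(self) -> int:
        return self.count_a + self.count_t + self.count_g + self.count_c

    @property
    def pct_a(self) -> float:
        return 100.0 * self.count_a / self._denom

    @property
    def pct_t(self) -> float:
        return 100.0 * self.count_t / self._denom

    @property
    def pct_g(self) -> float:
        return 100.0 * self.count_g / self._denom

    @property
    def pct_c(self) -> float:
        return 100.0 * self.count_c / self._denom

    @property
    def pct_at(self) -> float:
        return self.pct_a + self.pct_t

    @property
    def pct_gc(self) -> float:
        return self.pct_g + self.pct_c

    @property
    def at_skew(self) -> float:
        at = self.count_a + self.count_t
        return (self.count_a - self.count_t) / at if at else math.nan

    @property
    def gc_skew(self) -> float:
        gc = self.count_g + self.count_c
        return (self.count_g - self.count_c) / gc if gc else math.nan


def _region_sequence(rec: MitogenomeRecord, region: str) -> str:
    if rec.sequence is None:
        raise ValueError("record has no sequence")
    if region == "whole":
        return rec.sequence
    if region in ("PCGs", "PCG"):
        return "".join(feature_sequence(rec, n) for n in PCG_ORDER
                       if _has_feature(rec, n))
    if region in ("tRNA", "rRNA"):
        feats = rec.annotation.by_category(region)
        if not feats:
            raise ValueError(f"no features of category {region!r}")
        return "".join(feature_sequence(rec, f.name) for f in feats)
    return feature_sequence(rec, canonical_gene_name(region))


def _has_feature(rec: MitogenomeRecord, name: str) -> bool:
    try:
        rec.annotation.feature(name)
        return True
    except KeyError:
        return False


def base_composition(
    rec: MitogenomeRecord,
    regions: Sequence[str] = DEFAULT_REGIONS,
) -> list[CompositionRow]:
    """One :class:`CompositionRow` per requested region.

    Regions are ``"whole"``, a category union (``"PCGs"``, ``"tRNA"``,
    ``"rRNA"``), or any gene name.  N bases are excluded from percentage
    denominators and counted separately.
    """
    rows = []
    for region in regions:
        seq = _region_sequence(rec, region)
        if not seq:
            raise ValueError(f"region {region!r} resolves to an empty sequence")
        rows.append(
            CompositionRow(
                region=region, size=len(seq),
                count_a=seq.count("A"), count_t=seq.count("T"),
                count_g=seq.count("G"), count_c=seq.count("C"),
                count_n=seq.count("N"),
            )
        )
    return rows


def composition_table(rows: Sequence[CompositionRow], path: str | Path | None = None) -> pd.DataFrame:
    """Rows as a DataFrame rounded to one decimal, optionally written as TSV."""
    df = pd.DataFrame(
        {
            "Region": [r.region for r in rows],
            "Size (bp)": [r.size for r in rows],
            "A%": [round(r.pct_a, 1) for r in rows],
            "T%": [round(r.pct_t, 1) for r in rows],
            "G%": [round(r.pct_g, 1) for r in rows],
            "C%": [round(r.pct_c, 1) for r in rows],
            "A+T%": [round(r.pct_at, 1) for r in rows],
            "G+C%": [round(r.pct_gc, 1) for r in rows],
            "AT skew": [round(r.at_skew, 3) for r in rows],
            "GC skew": [round(r.gc_skew, 3) for r in rows],
        }
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# Codon extraction and usage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonExtraction:
    gene: str
    codons: tuple  # complete triplets incl. the start codon, excl. a full stop
    start_codon: str
    stop_codon: Optional[str]  # TAA/TAG, truncated "T"/"TA", or None
    truncated_stop: bool
    noncanonical_start: bool
    internal_stops: tuple  # 0-based triplet indices of in-frame stops


def extract_codons(
    rec: MitogenomeRecord,
    gene: str,
    code: Optional[GeneticCode] = None,
) -> CodonExtraction:
    """Split a PCG's sense-strand sequence into codons.

    A trailing 1- or 2-nt remainder is the truncated stop ("T"/"TA",
    completed to TAA by transcript polyadenylation) and is excluded from the
    codon list; a final complete TAA/TAG triplet is classified as the stop.
    The start codon is the first triplet, flagged non-canonical unless it
    matches ATN — or CGA, the standard lepidopteran cox1 initiator.
    In-frame internal stops are reported, not raised.
    """
    code = code or invertebrate_mito_code()
    gene = canonical_gene_name(gene)
    seq = feature_sequence(rec, gene)
    if len(seq) < 6:
        raise ValueError(f"{gene}: length {len(seq)} too short for a coding gene")
    n_triplets, rem = divmod(len(seq), 3)
    triplets = [seq[i * 3:(i + 1) * 3] for i in range(n_triplets)]
    if rem:
        stop = seq[-rem:]
        truncated = True
        body = triplets
    else:
        truncated = False
        if triplets[-1] in code.stop_codons:
            stop = triplets[-1]
            body = triplets[:-1]
        else:
            stop = None
            body = triplets
    start = body[0]
    noncanonical = not (
        (start.startswith("AT") and len(start) == 3)
        or (start == "CGA" and gene == "cox1")
    )
    internal = tuple(i for i, c in enumerate(body[1:], start=1) if c in code.stop_codons)
    return CodonExtraction(
        gene=gene, codons=tuple(body), start_codon=start, stop_codon=stop,
        truncated_stop=truncated, noncanonical_start=noncanonical,
        internal_stops=internal,
    )


@dataclass
class CodonUsageTable:
    """Pooled codon counts, RSCU and CDspT for one species' 13 PCGs.

    ``counts`` covers every counted codon (RNA-alphabet keys) and sums to
    ``total_codons``; ``excluded_from_families`` tracks non-ATN start codons
    that contribute to the total but not to any synonymous family; ``rscu``
    is ``None`` for codons whose family has zero usable count.
    """

    species: str
    counts: dict
    total_codons: int
    rscu: dict
    cdspt: dict
    excluded_from_families: dict = field(default_factory=dict)

    def unused_codons(self, code: Optional[GeneticCode] = None) -> list[str]:
        code = code or invertebrate_mito_code()
        return [rna(c) for c in code.sense_codons if self.counts.get(rna(c), 0) == 0]

    def to_frame(self) -> pd.DataFrame:
        code = invertebrate_mito_code()
        fam = {rna(c): f for c, f in code.family_of.items()}
        codons = sorted(self.counts, key=lambda c: (fam.get(c, "zzStop"), c))
        return pd.DataFrame(
            {
                "codon": codons,
                "family": [fam.get(c, "Stop") for c in codons],
                "count": [self.counts[c] for c in codons],
                "rscu": [self.rscu.get(c) for c in codons],
            }
        )


def codon_usage(
    recs: Sequence[MitogenomeRecord],
    code: Optional[GeneticCode] = None,
    include_start: bool = True,
    include_stop: bool = False,
) -> dict[str, CodonUsageTable]:
    """Codon-usage table per species, pooled over the 13 PCGs.

    Codons containing N are skipped.  Truncated stops are never counted;
    full TAA/TAG stops are counted only under ``include_stop``.
    """
    code = code or invertebrate_mito_code()
    out: dict[str, CodonUsageTable] = {}
    for rec in recs:
        species = rec.annotation.species
        if rec.sequence is None:
            raise ValueError(f"{species}: record has no sequence")
        missing = [g for g in PCG_ORDER if not _has_feature(rec, g)]
        if missing:
            raise ValueError(f"{species}: missing PCG(s) {', '.join(missing)}")
        counts: dict[str, int] = {}
        excluded: dict[str, int] = {}
        total = 0

        def tally(codon: str, in_family: bool = True) -> None:
            nonlocal total
            if "N" in codon:
                return
            key = rna(codon)
            counts[key] = counts.get(key, 0) + 1
            total += 1
            if not in_family:
                excluded[key] = excluded.get(key, 0) + 1

        for gene in PCG_ORDER:
            ext = extract_codons(rec, gene, code)
            body = ext.codons
            if include_start:
                tally(body[0], in_family=not ext.noncanonical_start
                      and body[0] != "CGA")
            for codon in body[1:]:
                tally(codon)
            if include_stop and ext.stop_codon in code.stop_codons:
                tally(ext.stop_codon, in_family=False)

        family_counts = {fam: 0 for fam in code.families}
        usable = dict(counts)
        for codon, k in excluded.items():
            usable[codon] = usable.get(codon, 0) - k
        for fam, codons in code.families.items():
            family_counts[fam] = sum(usable.get(rna(c), 0) for c in codons)
        rscu: dict[str, Optional[float]] = {}
        for fam, codons in code.families.items():
            fam_total = family_counts[fam]
            for c in codons:
                key = rna(c)
                if fam_total == 0:
                    rscu[key] = None
                else:
                    rscu[key] = usable.get(key, 0) * len(codons) / fam_total
        cdspt = {fam: 1000.0 * family_counts[fam] / total for fam in code.families}
        out[species] = CodonUsageTable(
            species=species, counts=counts, total_codons=total,
            rscu=rscu, cdspt=cdspt, excluded_from_families=excluded,
        )
    return out


@dataclass
class UsagePanel:
    rscu_matrix: pd.DataFrame  # codon x species
    unused: dict  # species -> list of unused sense codons
    family_ranking: dict  # species -> list of (family, cdspt) sorted desc

    def to_tsv(self, path: str | Path) -> None:
        self.rscu_matrix.to_csv(path, sep="\t")


def usage_panel(
    tables: Sequence[CodonUsageTable],
    code: Optional[GeneticCode] = None,
) -> UsagePanel:
    """Comparative codon-usage matrix across species.

    Rows are the sense codons (RNA alphabet) in family order; columns are
    species; entries are RSCU.  Also reports each species' unused codons and
    its codon families ranked by CDspT.
    """
    code = code or invertebrate_mito_code()
    labels = [t.species for t in tables]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate species labels in panel")
    codons = [rna(c) for fam in code.families.values() for c in fam]
    matrix = pd.DataFrame(
        {t.species: [t.rscu.get(c) for c in codons] for t in tables}, index=codons
    )
    unused = {t.species: t.unused_codons(code) for t in tables}
    ranking = {
        t.species: sorted(t.cdspt.items(), key=lambda kv: (-kv[1], kv[0]))
        for t in tables
    }
    return UsagePanel(rscu_matrix=matrix, unused=unused, family_ranking=ranking)


def plot_rscu(tables: Sequence[CodonUsageTable], path: str | Path) -> None:
    """Grouped RSCU bar chart, one group per codon family."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    code = invertebrate_mito_code()
    fams = sorted(code.families)
    fig, ax = plt.subplots(figsize=(max(8, 1.2 * len(fams)), 4))
    width = 0.8 / max(1, len(tables))
    for ti, t in enumerate(tables):
        xs, ys = [], []
        for fi, fam in enumerate(fams):
            vals = [t.rscu.get(rna(c)) or 0.0 for c in code.families[fam]]
            xs.append(fi + ti * width)
            ys.append(sum(vals))
        ax.bar(xs, ys, width=width, label=t.species)
    ax.set_xticks(range(len(fams)))
    ax.set_xticklabels(fams, rotation=90)
    ax.set_ylabel("cumulative RSCU")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
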