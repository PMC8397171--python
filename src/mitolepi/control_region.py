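"""Dissection of the A+T-rich control region.

Lepidopteran control regions carry four conserved structures, read in J-strand
orientation from the rrnS-proximal end: an ATAGA motif (the putative
replication-origin signal) followed closely by a poly-T stretch, an (AT)n
microsatellite-like run, a tandem-repeated unit, and a poly-A stretch abutting
the downstream trnM.  This module locates each of them, plus arbitrary
microsatellites and tandem repeats, with every threshold exposed as a
parameter.

All offsets reported here are 0-based and relative to the scanned sequence
(the control region), which makes reports independent of flanking context;
the report also carries the region's genomic span for conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .genome import MitogenomeRecord, feature_sequence

__all__ = [
    "ScanParams",
    "MicrosatRun",
    "TandemArray",
    "PolyRun",
    "ControlRegionReport",
    "microsatellite_scan",
    "tandem_repeat_scan",
    "dissect_control_region",
    "dissect_sequence",
]


@dataclass(frozen=True)
class ScanParams:
    """Control-region scan configuration.

    ``adjacency_window`` bounds how far the poly-T may start after the ATAGA
    motif, and how far before the trnM boundary the poly-A may end; the
    conserved-structure descriptions give no exact linker lengths, so this
    is deliberately loose (default 10 bp) and configurable.
    """

    origin_motif: str = "ATAGA"
    adjacency_window: int = 10
    min_poly_run: int = 5
    microsat_motifs: tuple = ("AT", "TA")
    microsat_min_copies: int = 5
    tr_min_unit: int = 5
    tr_max_unit: int = 50
    tr_min_copies: float = 1.9
    tr_min_identity: float = 0.85


@dataclass(frozen=True)
class MicrosatRun:
    motif: str
    copies: int
    start: int  # 0-based
    length: int


@dataclass(frozen=True)
class TandemArray:
    unit_length: int
    unit: str  # consensus over full copies
    copies: float
    start: int  # 0-based
    length: int
    identity: float  # matches / compared positions over adjacent copies


@dataclass(frozen=True)
class PolyRun:
    base: str
    start: int  # 0-based
    length: int


@dataclass
class ControlRegionReport:
    species: str
    start: int  # genomic, 1-based inclusive
    end: int
    length: int
    pct_at: float
    origin_motif: Optional[int]  # 0-based offset of ATAGA within the region
    poly_t: Optional[PolyRun]
    poly_a: Optional[PolyRun]
    microsatellites: list = field(default_factory=list)
    tandem_repeats: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Microsatellites
# ---------------------------------------------------------------------------

def microsatellite_scan(
    seq: str,
    motifs: Sequence[str] = ("AT", "TA"),
    min_copies: int = 5,
) -> list[MicrosatRun]:
    """Maximal non-overlapping perfect runs of each motif, left-greedy.

    Copy number is the integer count of complete units.  Runs of different
    motifs that overlap (AT vs its phase shift TA) are resolved in favour of
    the longer run, ties to the earlier start.
    """
    if min_copies < 1:
        raise ValueError("min_copies must be >= 1")
    seq = seq.upper()
    candidates: list[MicrosatRun] = []
    for motif in motifs:
        motif = motif.upper()
        if not 1 <= len(motif) <= 6:
            raise ValueError(f"motif {motif!r} must be 1-6 bp")
        m = len(motif)
        i = 0
        while i + m * min_copies <= len(seq):
            copies = 0
            while seq[i + copies * m:i + (copies + 1) * m] == motif:
                copies += 1
            if copies >= min_copies:
                candidates.append(MicrosatRun(motif, copies, i, copies * m))
                i += copies * m
            else:
                i += 1
    candidates.sort(key=lambda r: (-r.length, r.start, r.motif))
    accepted: list[MicrosatRun] = []
    for run in candidates:
        span = range(run.start, run.start + run.length)
        if all(
            span.stop <= a.start or span.start >= a.start + a.length
            for a in accepted
        ):
            accepted.append(run)
    accepted.sort(key=lambda r: r.start)
    return accepted


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------

def tandem_repeat_scan(
    seq: str,
    min_unit: int = 2,
    max_unit: int = 50,
    min_copies: float = 1.9,
    min_identity: float = 0.85,
    resolve_overlaps: bool = True,
) -> list[TandemArray]:
    """Detect tandem arrays by self-comparison at every unit length.

    For unit length p and start s, copies accrete while each copy matches
    the previous one at >= ``min_identity`` of its p positions; a trailing
    partial copy contributes its exactly-matching prefix as a fraction.
    Arrays are anchored on a position matching its p-shifted partner —
    mismatching flank bases are never absorbed into an array boundary.
    Candidates are kept when left-maximal with copy number >=
    ``min_copies``; overlapping calls are resolved by highest
    copies x unit-length score, ties to the smaller unit, then the earlier
    start.  The reported unit is the column-majority consensus of the full
    copies.  ``resolve_overlaps=False`` returns the full left-maximal
    candidate set instead, in position order.
    """
    n = len(seq)
    if not (2 <= min_unit <= max_unit):
        raise ValueError("need 2 <= min_unit <= max_unit")
    if max_unit > n // 2:
        max_unit = n // 2
    if min_copies < 1 or not (0 < min_identity <= 1):
        raise ValueError("min_copies >= 1 and 0 < min_identity <= 1 required")
    seq = seq.upper()

    candidates: list[TandemArray] = []
    for p in range(min_unit, max_unit + 1):
        # match[i] == 1 iff seq[i] == seq[i + p]
        match = [1 if seq[i] == seq[i + p] else 0 for i in range(n - p)]
        cum = [0]
        for v in match:
            cum.append(cum[-1] + v)

        def ident(a: int) -> float:
            # identity between the copy starting at a and the next one
            return (cum[a + p] - cum[a]) / p

        for s in range(0, n - 2 * p + 1):
            if not match[s]:
                continue  # arrays anchor on a base that matches its partner
            if s >= p and ident(s - p) >= min_identity:
                continue  # not left-maximal: extends a copy to the left
            k = 1
            total_matches = 0
            while s + (k + 1) * p <= n and ident(s + (k - 1) * p) >= min_identity:
                total_matches += cum[s + k * p] - cum[s + (k - 1) * p]
                k += 1
            # exactly-matching prefix of the trailing partial copy
            a = s + k * p
            m = 0
            while m < p and a + m < n and match[a - p + m]:
                m += 1
            copies = k + m / p
            if copies < min_copies or k < 1 or (k == 1 and m == 0):
                continue
            compared = p * (k - 1) + m
            identity = (total_matches + m) / compared if compared else 1.0
            if identity < min_identity:
                continue
            full = [seq[s + j * p:s + (j + 1) * p] for j in range(k)]
            unit = "".join(
                max(set(col), key=lambda b: (col.count(b), b == full[0][ci]))
                for ci, col in enumerate(zip(*full))
            )
            candidates.append(
                TandemArray(
                    unit_length=p, unit=unit, copies=round(copies, 3),
                    start=s, length=k * p + m, identity=round(identity, 4),
                )
            )

    if not resolve_overlaps:
        candidates.sort(key=lambda t: (t.start, t.unit_length))
        return candidates
    candidates.sort(key=lambda t: (-t.copies * t.unit_length, t.unit_length, t.start))
    accepted: list[TandemArray] = []
    for cand in candidates:
        if all(
            cand.start + cand.length <= a.start or cand.start >= a.start + a.length
            for a in accepted
        ):
            accepted.append(cand)
    accepted.sort(key=lambda t: t.start)
    return accepted


def _smallest_period(s: str) -> int:
    # classic failure-function period
    fail = [0] * len(s)
    k = 0
    for i in range(1, len(s)):
        while k and s[i] != s[k]:
            k = fail[k - 1]
        if s[i] == s[k]:
            k += 1
        fail[i] = k
    return len(s) - fail[-1] if s else 0


# ---------------------------------------------------------------------------
# Dissection
# ---------------------------------------------------------------------------

def _poly_run(seq: str, base: str, window: range, anchored: str) -> Optional[PolyRun]:
    """Longest perfect run of ``base`` starting (anchored='start') or ending
    (anchored='end') inside ``window``; ties to the boundary-nearest run."""
    best: Optional[PolyRun] = None
    n = len(seq)
    for pos in window:
        if pos < 0 or pos >= n or seq[pos] != base:
            continue
        if anchored == "start":
            if pos > 0 and seq[pos - 1] == base:
                continue  # not a run start
            end = pos
            while end + 1 < n and seq[end + 1] == base:
                end += 1
            run = PolyRun(base, pos, end - pos + 1)
        else:
            if pos + 1 < n and seq[pos + 1] == base:
                continue  # not a run end
            start = pos
            while start - 1 >= 0 and seq[start - 1] == base:
                start -= 1
            run = PolyRun(base, start, pos - start + 1)
        if best is None or run.length > best.length:
            best = run
    return best


def dissect_sequence(
    cr_seq: str,
    params: ScanParams = ScanParams(),
    species: str = "",
    span: tuple[int, int] = (1, 0),
) -> ControlRegionReport:
    """Scan a control-region sequence (rrnS-proximal end first) for the four
    conserved structures plus microsatellites and tandem repeats."""
    cr_seq = cr_seq.upper()
    n = len(cr_seq)
    at = cr_seq.count("A") + cr_seq.count("T")
    acgt = at + cr_seq.count("G") + cr_seq.count("C")
    pct_at = 100.0 * at / acgt if acgt else 0.0

    motif_pos = cr_seq.find(params.origin_motif.upper())
    origin = motif_pos if motif_pos >= 0 else None

    poly_t = None
    if origin is not None:
        w0 = origin + len(params.origin_motif)
        poly_t = _poly_run(cr_seq, "T", range(w0, w0 + params.adjacency_window), "start")
    else:
        poly_t = _poly_run(cr_seq, "T", range(0, n), "start")
    if poly_t is not None and poly_t.length < params.min_poly_run:
        poly_t = None

    poly_a = _poly_run(cr_seq, "A", range(n - params.adjacency_window, n), "end")
    if poly_a is not None and poly_a.length < params.min_poly_run:
        poly_a = None

    microsats = microsatellite_scan(cr_seq, params.microsat_motifs, params.microsat_min_copies)
    tandems = tandem_repeat_scan(
        cr_seq, params.tr_min_unit, params.tr_max_unit,
        params.tr_min_copies, params.tr_min_identity,
    )
    # drop low-complexity artifacts: arrays whose consensus is itself a
    # repetition of a sub-minimum unit (homopolymers, (AT)n echoes), and
    # arrays living entirely inside a reported microsatellite run
    kept = []
    for t in tandems:
        if _smallest_period(t.unit) < params.tr_min_unit:
            continue
        inside = any(
            r.start <= t.start and t.start + t.length <= r.start + r.length
            for r in microsats
        )
        if not inside:
            kept.append(t)

    return ControlRegionReport(
        species=species, start=span[0], end=span[1], length=n, pct_at=pct_at,
        origin_motif=origin, poly_t=poly_t, poly_a=poly_a,
        microsatellites=microsats, tandem_repeats=kept,
    )


def dissect_control_region(
    rec: MitogenomeRecord,
    params: ScanParams = ScanParams(),
) -> ControlRegionReport:
    """Dissect the annotated control region of a mitogenome record.

    The region is read on the forward (J) strand from its rrnS-proximal
    boundary.  Each of the four conserved structures is reported, possibly
    as absent; missing control-region feature or sequence is an error.
    """
    try:
        feat = rec.annotation.feature("control_region")
    except KeyError as e:
        raise ValueError("annotation has no control-region feature") from e
    cr_seq = feature_sequence(rec, "control_region")
    return dissect_sequence(
        cr_seq, params, species=rec.annotation.species, span=(feat.start, feat.end)
    )
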