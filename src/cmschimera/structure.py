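"""Chimeric-architecture annotation of B-atp6-GSV sequences.

The locus is a four-part chimera: a duplicated atp6 copy (B-atp6, 619 bp),
a 52 bp conserved downstream segment (DS) — together a 671 bp conserved
block — then a 176 bp indel- and SNP-rich variable spacer (VS), then the ORF
family GSV (orfH79 and variants) whose first 34 bases match COXII. The
putative junction signature is a mirror repeat: GGGCGGGGG at the B-atp6
5' end and its character reversal GGGGGCGGG near the DS 3' end.

Anchor segments are located by semi-global (infix) alignment of each
reference against the query; a sequence legitimately lacking a segment (a
non-carrier individual) gets a "missing" annotation, not an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

MISSING_CHARS = frozenset("N?")

#: Junction mirror-repeat motif at the B-atp6 5' end; its character reversal
#: GGGGGCGGG closes the 671 bp conserved block.
JUNCTION_MOTIF = "GGGCGGGGG"


@dataclass
class Segment:
    name: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    identity: float  # anchor identity to its reference (1.0 for derived segments)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class MotifHit:
    motif: str
    start: int  # 1-based inclusive
    end: int
    orientation: str  # "forward" | "mirror"


@dataclass
class StructureAnnotation:
    """Segment coordinates, junction-motif hits and bookkeeping for one query."""

    segments: dict[str, Segment | None]
    motif_hits: list[MotifHit] = field(default_factory=list)
    coxii_prefix_len: int | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def missing(self) -> list[str]:
        return [k for k, v in self.segments.items() if v is None]

    def is_carrier(self) -> bool:
        """True when the full chimeric architecture was found."""
        return not self.missing

    def to_bed_rows(self):
        """Segment + motif rows as (name, start, end) 1-based inclusive tuples."""
        rows = [
            (s.name, s.start, s.end)
            for s in self.segments.values()
            if s is not None
        ]
        rows += [(f"motif_{h.orientation}:{h.motif}", h.start, h.end) for h in self.motif_hits]
        return rows


def _locate(ref: str, query: str, min_identity: float) -> Segment | None:
    """Best semi-global placement of ``ref`` inside ``query`` (edit distance)."""
    pos = query.find(ref)
    if pos >= 0:
        return Segment("", pos + 1, pos + len(ref), 1.0)
    max_ed = int(len(ref) * (1.0 - min_identity))
    res = edlib.align(ref, query, mode="HW", task="locations", k=max_ed)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]  # 0-based inclusive
    identity = 1.0 - res["editDistance"] / len(ref)
    if identity < min_identity:
        return None
    return Segment("", start + 1, end + 1, identity)


def annotate(query: str, refs: dict[str, str], min_anchor_identity: float = 0.95) -> StructureAnnotation:
    """Annotate the chimeric segments of one query sequence.

    ``refs`` must contain ``b_atp6`` and ``ds``; ``coxii_prefix`` and/or
    ``gsv_ref`` refine the GSV start. The VS is derived as the interval
    between the DS end and the GSV start. All coordinates are 1-based
    inclusive on the query.
    """
    for required in ("b_atp6", "ds"):
        if required not in refs:
            raise KeyError(f"annotate requires reference segment {required!r}")
    query = query.upper()
    ann = StructureAnnotation(segments={"b_atp6": None, "ds": None, "vs": None, "gsv": None})

    b = _locate(refs["b_atp6"].upper(), query, min_anchor_identity)
    if b:
        b.name = "b_atp6"
        ann.segments["b_atp6"] = b
    else:
        ann.notes.append("b_atp6 anchor not found above identity threshold")

    ds_from = b.end if b else 0
    ds = _locate(refs["ds"].upper(), query[ds_from:], min_anchor_identity)
    if ds:
        ds = Segment("ds", ds.start + ds_from, ds.end + ds_from, ds.identity)
        ann.segments["ds"] = ds
        if b and ds.start == b.end + 1 and b.identity == 1.0 and ds.identity == 1.0:
            conserved = ds.end - b.start + 1
            ann.notes.append(f"conserved B-atp6+DS block length {conserved}")
    else:
        ann.notes.append("ds anchor not found above identity threshold")

    gsv_start = None
    tail_from = ds.end if ds else (b.end if b else 0)
    if "gsv_ref" in refs:
        g = _locate(refs["gsv_ref"].upper(), query[tail_from:], min_anchor_identity)
        if g:
            gsv_start = g.start + tail_from
            gsv_end = g.end + tail_from
            gsv_identity = g.identity
    if gsv_start is None and "coxii_prefix" in refs:
        p = _locate(refs["coxii_prefix"].upper(), query[tail_from:], min_anchor_identity)
        if p:
            # GSV starts at the first ATG at/after the COXII-prefix match
            at = query.find("ATG", p.start + tail_from - 1)
            if at >= 0:
                gsv_start = at + 1
                gsv_end = len(query)
                gsv_identity = p.identity
    if gsv_start is not None:
        ann.segments["gsv"] = Segment("gsv", gsv_start, gsv_end, gsv_identity)
        if ds and gsv_start > ds.end + 1:
            ann.segments["vs"] = Segment("vs", ds.end + 1, gsv_start - 1, 1.0)
        elif ds:
            ann.notes.append("no VS interval between DS and GSV")
    else:
        ann.notes.append("gsv segment not located (no gsv_ref/coxii_prefix match)")

    present = [s for s in ann.segments.values() if s]
    order = [s.name for s in sorted(present, key=lambda s: s.start)]
    expected = [n for n in ("b_atp6", "ds", "vs", "gsv") if ann.segments[n]]
    if order != expected:
        ann.notes.append(f"segments out of canonical order: {order}")
    if present:
        first = min(s.start for s in present)
        last = max(s.end for s in present)
        if first > 1:
            ann.notes.append(f"unannotated 5' flank 1-{first - 1}")
        if last < len(query):
            ann.notes.append(f"unannotated 3' flank {last + 1}-{len(query)}")

    ann.motif_hits = find_mirror_motifs(query, JUNCTION_MOTIF)
    gsv = ann.segments["gsv"]
    if gsv and "coxii_prefix" in refs:
        ann.coxii_prefix_len = coxii_prefix_len(
            query[gsv.start - 1 : gsv.end], refs["coxii_prefix"]
        )
    return ann


def _find_all(query: str, pattern: str) -> list[int]:
    hits, start = [], 0
    while True:
        pos = query.find(pattern, start)
        if pos < 0:
            return hits
        hits.append(pos)
        start = pos + 1  # overlapping occurrences allowed


def find_mirror_motifs(query: str, motif: str) -> list[MotifHit]:
    """All exact hits of ``motif`` and of its character reversal.

    The reversal is a *mirror* (123456789 -> 987654321), not a reverse
    complement: the junction pair GGGCGGGGG / GGGGGCGGG is a mirror pair.
    Hits are labelled "forward"/"mirror"; when the motif equals its own
    reversal the coincident hits are deduplicated (kept as "forward").
    """
    if len(motif) < 5:
        raise ValueError("motif must be at least 5 bases long")
    query, motif = query.upper(), motif.upper()
    mirror = motif[::-1]
    hits = [MotifHit(motif, p + 1, p + len(motif), "forward") for p in _find_all(query, motif)]
    if mirror != motif:
        hits += [
            MotifHit(mirror, p + 1, p + len(mirror), "mirror")
            for p in _find_all(query, mirror)
        ]
    return sorted(hits, key=lambda h: (h.start, h.orientation))


# ---------------------------------------------------------------------------
# VS variation catalog
# ---------------------------------------------------------------------------


@dataclass
class VsVariationCatalog:
    """Indel/SNP tally of an aligned VS block.

    ``n_indel_events`` counts distinct maximal gap-column intervals (pooled
    across rows); ``n_gap_columns`` is the alternative column-wise count.
    ``edits`` lists per-haplotype differences from the reference row as
    ("snp", column, ref_state, alt_state) and ("gap", start_col, end_col,
    "ins"/"del") tuples, columns 1-based in alignment coordinates.
    """

    n_indel_events: int
    n_snp_sites: int
    n_gap_columns: int
    snp_columns: list[int]
    indel_intervals: list[tuple[int, int]]
    edits: dict[str, list[tuple]]


def _gap_runs(row: str) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, c in enumerate(row):
        if c == "-":
            start = i if start is None else start
        elif start is not None:
            runs.append((start + 1, i))
            start = None
    if start is not None:
        runs.append((start + 1, len(row)))
    return runs


def catalog_vs_variation(
    vs_alignment: dict[str, str], reference_label: str | None = None
) -> VsVariationCatalog:
    """Tally indel events and SNP sites in a pre-aligned VS block.

    An indel event is a maximal run of gap columns in any row, counted once
    per distinct (start, end) interval. A SNP site is a gap-free column with
    at least two distinct non-missing states.
    """
    if len(vs_alignment) < 2:
        raise ValueError("catalog_vs_variation needs at least 2 aligned rows")
    lengths = {len(s) for s in vs_alignment.values()}
    if len(lengths) != 1:
        raise ValueError("aligned VS rows must have equal lengths")
    labels = list(vs_alignment)
    if reference_label is None:
        reference_label = labels[0]
    rows = {l: vs_alignment[l].upper() for l in labels}
    (length,) = lengths

    intervals = sorted({run for row in rows.values() for run in _gap_runs(row)})
    gap_cols = {j for s, e in intervals for j in range(s, e + 1)}

    snp_columns = []
    for j in range(1, length + 1):
        if j in gap_cols:
            continue
        states = {row[j - 1] for row in rows.values()} - MISSING_CHARS
        if len(states) >= 2:
            snp_columns.append(j)

    ref = rows[reference_label]
    edits: dict[str, list[tuple]] = {}
    for label in labels:
        if label == reference_label:
            continue
        row = rows[label]
        my = []
        for j in snp_columns:
            if row[j - 1] != ref[j - 1] and row[j - 1] not in MISSING_CHARS:
                my.append(("snp", j, ref[j - 1], row[j - 1]))
        ref_runs = set(_gap_runs(ref))
        for run in _gap_runs(row):
            if run not in ref_runs:
                my.append(("gap", run[0], run[1], "del"))
        for run in ref_runs - set(_gap_runs(row)):
            my.append(("gap", run[0], run[1], "ins"))
        edits[label] = sorted(my, key=lambda e: e[1])

    return VsVariationCatalog(
        n_indel_events=len(intervals),
        n_snp_sites=len(snp_columns),
        n_gap_columns=len(gap_cols),
        snp_columns=snp_columns,
        indel_intervals=intervals,
        edits=edits,
    )


def coxii_prefix_len(gsv: str, coxii_ref: str) -> int:
    """Length of the exact common prefix of a GSV sequence and the COXII reference.

    Missing states ("N"/"?") break the match on either side.
    """
    if not gsv or not coxii_ref:
        raise ValueError("coxii_prefix_len requires two non-empty sequences")
    n = 0
    for a, b in zip(gsv.upper(), coxii_ref.upper()):
        if a != b or a in MISSING_CHARS:
            break
        n += 1
    return n
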