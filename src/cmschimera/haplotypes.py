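"""Haplotype collapsing, variable-site matrices, and global-alignment identity.

A haplotype here is an exact-sequence equivalence class: the survey collapses
identical (upper-cased, optionally end-trimmed) sequences and tabulates the
classes by population. Variable-site matrices reproduce the dot-notation
convention of population-genetics haplotype tables: "." means same state as
the reference row, "?" means unknown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = frozenset("N?")


@dataclass
class Haplotype:
    label: str
    sequence: str
    member_ids: list[str]


@dataclass
class HaplotypeSet:
    """Collapsed haplotypes and their per-population member counts."""

    haplotypes: list[Haplotype]
    counts: pd.DataFrame  # rows: haplotype labels; columns: population codes

    @property
    def labels(self) -> list[str]:
        return [h.label for h in self.haplotypes]

    def sequence_of(self, label: str) -> str:
        for h in self.haplotypes:
            if h.label == label:
                return h.sequence
        raise KeyError(label)

    def assignments(self) -> dict[str, str]:
        """Mapping record id -> haplotype label."""
        return {rid: h.label for h in self.haplotypes for rid in h.member_ids}

    def to_frame(self) -> pd.DataFrame:
        return self.counts.copy()


def _normalize(seq: str, trim_missing_ends: bool) -> str:
    s = seq.upper()
    if trim_missing_ends:
        s = s.strip("".join(MISSING | {"-"}))
    return s


def collapse(records, trim_missing_ends: bool = False, label_prefix: str = "H") -> HaplotypeSet:
    """Partition records into haplotypes by exact sequence equality.

    Labels are assigned in decreasing order of total member count; ties are
    broken lexicographically by representative sequence, so labelling is a
    pure function of the input multiset.
    """
    groups: dict[str, list] = {}
    for rec in records:
        groups.setdefault(_normalize(rec.sequence, trim_missing_ends), []).append(rec)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))

    haplotypes = []
    pops: dict[str, None] = {}
    for rec in records:
        pops.setdefault(rec.population)
    counts = pd.DataFrame(
        0, index=[f"{label_prefix}{i + 1}" for i in range(len(ordered))], columns=list(pops)
    )
    for i, (seq, members) in enumerate(ordered):
        label = f"{label_prefix}{i + 1}"
        haplotypes.append(Haplotype(label, seq, [m.id for m in members]))
        for m in members:
            counts.loc[label, m.population] += 1
    return HaplotypeSet(haplotypes, counts)


# ---------------------------------------------------------------------------
# Variable-site matrix (dot notation)
# ---------------------------------------------------------------------------


@dataclass
class VariableSiteMatrix:
    """Variable columns of an alignment in dot notation.

    ``positions`` are 1-based alignment coordinates. The reference row shows
    literal states; other rows show "." when equal to the reference, "?" for
    missing, and the literal state otherwise.
    """

    positions: list[int]
    reference_label: str
    states: pd.DataFrame  # rows: labels (reference first); columns: positions

    def to_frame(self) -> pd.DataFrame:
        return self.states.copy()


def variable_sites(aligned: dict[str, str], reference_label: str) -> VariableSiteMatrix:
    """Extract columns with >= 2 distinct non-missing states.

    ``aligned`` maps haplotype label to an equal-length (pre-aligned)
    sequence. Gap characters count as ordinary states (an indel column is
    variable); "N"/"?" are missing and never make a column variable.
    """
    if reference_label not in aligned:
        raise KeyError(f"reference label {reference_label!r} not in alignment")
    lengths = {len(s) for s in aligned.values()}
    if len(lengths) != 1:
        raise ValueError(
            "sequences have unequal lengths; align them first "
            f"(lengths seen: {sorted(lengths)})"
        )
    labels = [reference_label] + [l for l in aligned if l != reference_label]
    rows = [aligned[l].upper() for l in labels]
    (length,) = lengths

    positions = []
    for j in range(length):
        states = {row[j] for row in rows} - MISSING
        if len(states) >= 2:
            positions.append(j + 1)

    data = {}
    for label, row in zip(labels, rows):
        cells = []
        for pos in positions:
            c = row[pos - 1]
            if c in MISSING:
                cells.append("?")
            elif label != reference_label and c == aligned[reference_label][pos - 1].upper():
                cells.append(".")
            else:
                cells.append(c)
        data[label] = cells
    frame = pd.DataFrame.from_dict(data, orient="index", columns=positions)
    return VariableSiteMatrix(positions, reference_label, frame)


# ---------------------------------------------------------------------------
# Needleman-Wunsch global alignment and percent identity
# ---------------------------------------------------------------------------


@dataclass
class AlignmentScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0  # linear, end gaps penalised (true global alignment)


@dataclass
class IdentityResult:
    percent: float  # unrounded
    rounded: int
    score: float
    aligned_a: str
    aligned_b: str

    @property
    def alignment_length(self) -> int:
        return len(self.aligned_a)


def global_align(a: str, b: str, scoring: AlignmentScoring | None = None) -> tuple[float, str, str]:
    """Needleman-Wunsch with linear gap penalty and high-road traceback.

    Ties are resolved preferring diagonal, then up (gap in ``b``), then left,
    which makes the reported alignment — and hence the identity — a
    deterministic function of the inputs.
    """
    sc = scoring or AlignmentScoring()
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)

    F = np.empty((n + 1, m + 1), dtype=np.float64)
    F[0, :] = sc.gap * np.arange(m + 1)
    F[:, 0] = sc.gap * np.arange(n + 1)
    cols = np.arange(1, m + 1, dtype=np.float64)
    d = np.empty(m + 1, dtype=np.float64)
    for i in range(1, n + 1):
        sub = np.where(bv == av[i - 1], sc.match, sc.mismatch)
        cand = np.maximum(F[i - 1, :-1] + sub, F[i - 1, 1:] + sc.gap)
        # with a linear gap cost the horizontal chain closes to a running max:
        # F[i,j] = gap*j + max_{k<=j} (cand[k] - gap*k), with k=0 meaning F[i,0]
        d[0] = F[i, 0]
        d[1:] = cand - sc.gap * cols
        F[i, 1:] = np.maximum.accumulate(d)[1:] + sc.gap * cols

    # high-road traceback
    out_a, out_b = [], []
    i, j = n, m
    eps = 1e-9
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = sc.match if a[i - 1] == b[j - 1] else sc.mismatch
            if abs(F[i, j] - (F[i - 1, j - 1] + s)) < eps:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i, j = i - 1, j - 1
                continue
        if i > 0 and abs(F[i, j] - (F[i - 1, j] + sc.gap)) < eps:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            continue
        out_a.append("-")
        out_b.append(b[j - 1])
        j -= 1
    return float(F[n, m]), "".join(reversed(out_a)), "".join(reversed(out_b))


def identity_percent(
    a: str,
    b: str,
    scoring: AlignmentScoring | None = None,
    denominator: str = "alignment",
) -> IdentityResult:
    """Percent identity from a global alignment of two sequences.

    The default denominator is the full alignment length including gap
    columns; ``denominator="shorter"`` divides by the shorter input length
    instead. Identical aligned columns with missing states do not count as
    matches.
    """
    if not a or not b:
        raise ValueError("identity_percent requires two non-empty sequences")
    score, aa, bb = global_align(a, b, scoring)
    matches = sum(
        1 for x, y in zip(aa, bb) if x == y and x != "-" and x not in MISSING
    )
    if denominator == "alignment":
        denom = len(aa)
    elif denominator == "shorter":
        denom = min(len(a), len(b))
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    percent = 100.0 * matches / denom
    return IdentityResult(percent, int(round(percent)), score, aa, bb)


def identity_matrix(seqs: dict[str, str], **kwargs) -> pd.DataFrame:
    """Pairwise percent-identity table (unrounded values, 100 on the diagonal)."""
    labels = list(seqs)
    mat = pd.DataFrame(100.0, index=labels, columns=labels)
    for i, x in enumerate(labels):
        for y in labels[i + 1 :]:
            val = identity_percent(seqs[x], seqs[y], **kwargs).percent
            mat.loc[x, y] = mat.loc[y, x] = val
    return mat


def align_progressive(seqs: dict[str, str], scoring: AlignmentScoring | None = None) -> dict[str, str]:
    """Center-star progressive alignment (convenience wrapper around pairwise NW).

    The first sequence acts as the center; every other sequence is aligned to
    it pairwise and gaps are merged ("once a gap, always a gap"). Adequate for
    the handful of closely related haplotypes this survey handles; not a
    general MSA tool.
    """
    labels = list(seqs)
    if len(labels) == 1:
        return dict(seqs)
    center = labels[0]
    center_seq = seqs[center]
    # per-sequence list of (center-column gaps) via pairwise alignments
    pair = {}
    merged_cols: list[int] = [0] * (len(center_seq) + 1)  # gaps before center pos i
    for label in labels[1:]:
        _, ca, oa = global_align(center_seq, seqs[label], scoring)
        pair[label] = (ca, oa)
        gaps = [0] * (len(center_seq) + 1)
        pos = 0
        for c in ca:
            if c == "-":
                gaps[pos] += 1
            else:
                pos += 1
        for i, g in enumerate(gaps):
            merged_cols[i] = max(merged_cols[i], g)

    def expand(center_aln: str, other_aln: str) -> str:
        out = []
        pos = 0
        run = 0
        for c, o in zip(center_aln + "$", other_aln + "$"):
            if c == "-":
                run += 1
                out.append(o)
            else:
                out.append("-" * (merged_cols[pos] - run))
                if c != "$":
                    out.append(o)
                run = 0
                pos += 1
        return "".join(out)

    result = {center: expand(center_seq, center_seq)}
    for label in labels[1:]:
        ca, oa = pair[label]
        result[label] = expand(ca, oa)
    return result
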