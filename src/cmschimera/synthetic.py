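"""Synthetic survey data with the structural and statistical design of the study.

The generator emulates the wild-rice survey this package analyzes: 17
populations, five of which carry the chimeric mitochondrial locus; 15
sequenced individuals per carrier population except YJ with 5; one haplotype
per population (PS and GZ share H1, TL and HK share H2, YJ alone carries
H3). The reference chimera is B-atp6 (619 bp, starting with the junction
motif GGGCGGGGG and ending TGAGTAA) + DS (52 bp, starting TTTCATAA and
ending with the mirror motif GGGGGCGGG followed by ACAAA) + VS (176 bp) +
GSV (default 214 bp = 240 minus the 26 bp primer-trimmed tail; the first 34
bases are the COXII prefix and the ORF starts with ATG).

Haplotypes are reference plus planted edits; the default design plants 5
indel events and 32 SNP sites in the VS across haplotypes, and a small
synonymous/nonsynonymous SNP mix in the GSV. Ground truth (haplotype of
every record, segment boundaries, the true gapped VS alignment, edit
counts) is returned alongside the data so every downstream stage can be
checked exactly. A fixed seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io import SequenceRecord, SurveyBundle, write_fasta, write_table_map
from .orfs import translate
from .phylo import PhyloModel, PhyloTree, prob_matrix
from .structure import JUNCTION_MOTIF

B_ATP6_LEN = 619
DS_LEN = 52
VS_LEN = 176
GSV_DEFAULT_LEN = 214  # 240 bp ORF minus the 26 bp not covered by sequencing
COXII_PREFIX_LEN = 34

B_ATP6_END = "TGAGTAA"
DS_START = "TTTCATAA"
DS_TAIL = JUNCTION_MOTIF[::-1] + "ACAAA"  # GGGGGCGGG + ACAAA closes the 671 bp block

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class ReferenceChimera:
    """The four planted segments of the reference chimeric locus."""

    b_atp6: str
    ds: str
    vs: str
    gsv: str

    @property
    def sequence(self) -> str:
        return self.b_atp6 + self.ds + self.vs + self.gsv

    @property
    def coxii_prefix(self) -> str:
        return self.gsv[:COXII_PREFIX_LEN]

    @property
    def boundaries(self) -> dict[str, tuple[int, int]]:
        """True 1-based inclusive segment intervals on the reference."""
        b = len(self.b_atp6)
        d = b + len(self.ds)
        v = d + len(self.vs)
        return {
            "b_atp6": (1, b),
            "ds": (b + 1, d),
            "vs": (d + 1, v),
            "gsv": (v + 1, v + len(self.gsv)),
        }

    def segment_offset(self, segment: str) -> int:
        return self.boundaries[segment][0] - 1


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _random_codons(rng: np.random.Generator, n_codons: int) -> str:
    out = []
    while len(out) < n_codons:
        codon = _random_bases(rng, 3)
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def make_reference(seed: int, gsv_length: int = GSV_DEFAULT_LEN) -> ReferenceChimera:
    """Generate a reference chimera honouring all planted landmarks.

    The junction mirror pair must occur exactly once each in the assembled
    sequence; the random fill is redrawn (deterministically, from the same
    seeded stream) in the unlikely event a spurious copy arises.
    """
    if gsv_length < 40:
        raise ValueError(
            f"gsv_length must be >= 40 to host the {COXII_PREFIX_LEN}-base "
            f"COXII prefix plus an ORF, got {gsv_length}"
        )
    rng = np.random.default_rng(seed)
    for _ in range(100):
        b_atp6 = (
            JUNCTION_MOTIF
            + _random_bases(rng, B_ATP6_LEN - len(JUNCTION_MOTIF) - len(B_ATP6_END))
            + B_ATP6_END
        )
        ds = (
            DS_START
            + _random_bases(rng, DS_LEN - len(DS_START) - len(DS_TAIL))
            + DS_TAIL
        )
        vs = _random_bases(rng, VS_LEN)
        # GSV: ATG + stop-free codons; the first 34 bases are the COXII prefix
        n_codons = (gsv_length - 3) // 3
        tail = gsv_length - 3 - 3 * n_codons
        gsv = "ATG" + _random_codons(rng, n_codons) + _random_bases(rng, tail)
        ref = ReferenceChimera(b_atp6, ds, vs, gsv)
        seq = ref.sequence
        if (
            seq.count(JUNCTION_MOTIF) == 1
            and seq.count(JUNCTION_MOTIF[::-1]) == 1
        ):
            return ref
    raise RuntimeError("could not generate a motif-clean reference")  # pragma: no cover


# ---------------------------------------------------------------------------
# Haplotype edits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Edit:
    """One planted variant on the reference.

    ``pos`` is 1-based within ``segment``. SNPs carry ``base``; insertions
    carry ``seq`` (inserted after ``pos``); deletions carry ``length``
    (removing ``pos`` .. ``pos+length-1``).
    """

    kind: str  # "snp" | "ins" | "del"
    segment: str
    pos: int
    base: str = ""
    seq: str = ""
    length: int = 0


def apply_haplotype_edits(ref: ReferenceChimera, edits: list[Edit]) -> str:
    """Apply edits to the reference; positions refer to the unedited sequence.

    Edits are applied right-to-left in absolute coordinates so earlier edits
    never shift later ones.
    """
    seq = list(ref.sequence)
    total = len(seq)
    resolved = []
    for e in edits:
        seg_start, seg_end = ref.boundaries[e.segment]
        abs_pos = seg_start + e.pos - 1
        span = e.length if e.kind == "del" else 1
        if not (seg_start <= abs_pos and abs_pos + span - 1 <= seg_end) or abs_pos > total:
            raise ValueError(f"edit out of range for segment {e.segment!r}: {e}")
        resolved.append((abs_pos, e))
    for abs_pos, e in sorted(resolved, key=lambda t: -t[0]):
        i = abs_pos - 1
        if e.kind == "snp":
            seq[i] = e.base
        elif e.kind == "del":
            del seq[i : i + e.length]
        elif e.kind == "ins":
            seq[i + 1 : i + 1] = list(e.seq)
        else:
            raise ValueError(f"unknown edit kind {e.kind!r}")
    return "".join(seq)


def _other_base(base: str) -> str:
    return {"A": "C", "C": "G", "G": "T", "T": "A"}[base]


#: VS coordinates of the default planted design: 5 indel events and 32 SNP
#: sites across haplotypes, none overlapping an indel footprint.
_H1_VS_SNPS = [5, 10, 15, 30, 35, 40, 45, 50, 55, 70, 75, 80, 85, 100, 105, 110]
_H3_VS_SNPS = [6, 11, 16, 31, 36, 41, 46, 51, 56, 71, 76, 81, 86, 101, 106, 111]
_H1_VS_INDELS = [("del", 20, 4), ("ins", 60, "TAC")]
_H3_VS_INDELS = [("del", 90, 2), ("ins", 130, "GATTC"), ("del", 160, 1)]


def default_haplotype_specs(ref: ReferenceChimera) -> dict[str, list[Edit]]:
    """The study-design edit lists: H2 is the reference; H1 and H3 differ in
    VS (SNPs + indels) and carry a small GSV SNP mix (H1: one nonsynonymous
    and one synonymous; H3: two nonsynonymous)."""
    vs_off = ref.segment_offset("vs")
    gsv_off = ref.segment_offset("gsv")

    def vs_base(pos: int) -> str:
        return ref.sequence[vs_off + pos - 1]

    def gsv_base(pos: int) -> str:
        return ref.sequence[gsv_off + pos - 1]

    def snps(positions: list[int]) -> list[Edit]:
        return [
            Edit("snp", "vs", p, base=_other_base(vs_base(p))) for p in positions
        ]

    def indels(spec) -> list[Edit]:
        out = []
        for kind, pos, arg in spec:
            if kind == "del":
                out.append(Edit("del", "vs", pos, length=arg))
            else:
                out.append(Edit("ins", "vs", pos, seq=arg))
        return out

    # GSV SNPs: codon 2 of the ORF starts at GSV position 4 (after ATG).
    # First-position change = nonsynonymous for non-degenerate codons;
    # third-position pick below is verified synonymous by construction.
    h1_nonsyn = Edit("snp", "gsv", 40, base=_other_base(gsv_base(40)))
    syn_pos = _synonymous_site(ref)
    h1_syn = Edit("snp", "gsv", syn_pos, base=_synonymous_base(ref, syn_pos))
    h3_nonsyn = [
        Edit("snp", "gsv", 43, base=_other_base(gsv_base(43))),
        Edit("snp", "gsv", 52, base=_other_base(gsv_base(52))),
    ]
    return {
        "H1": snps(_H1_VS_SNPS) + indels(_H1_VS_INDELS) + [h1_nonsyn, h1_syn],
        "H2": [],
        "H3": snps(_H3_VS_SNPS) + indels(_H3_VS_INDELS) + h3_nonsyn,
    }


def _synonymous_site(ref: ReferenceChimera) -> int:
    """A third-codon-position GSV site with a synonymous substitute."""
    for codon_start in range(36, len(ref.gsv) - 3, 3):  # past the COXII prefix
        pos = codon_start + 3  # third position, 1-based
        if _synonymous_base(ref, pos) is not None:
            return pos
    raise RuntimeError("no synonymous site found")  # pragma: no cover


def _synonymous_base(ref: ReferenceChimera, pos: int) -> str | None:
    codon_start = (pos - 1) // 3 * 3
    codon = ref.gsv[codon_start : codon_start + 3]
    if len(codon) < 3:
        return None
    aa = translate(codon)
    offset = pos - 1 - codon_start
    for b in "ACGT":
        if b == codon[offset]:
            continue
        alt = codon[:offset] + b + codon[offset + 1 :]
        if alt not in _STOPS and translate(alt) == aa:
            return b
    return None


# ---------------------------------------------------------------------------
# Survey simulation
# ---------------------------------------------------------------------------


@dataclass
class PopulationSpec:
    code: str
    n_collected: int
    n_sequenced: int
    haplotype: str | None = None  # None => non-carrier

    def __post_init__(self) -> None:
        if self.n_sequenced > self.n_collected:
            raise ValueError(
                f"population {self.code}: n_sequenced > n_collected"
            )


@dataclass
class SurveyDesign:
    populations: list[PopulationSpec]
    groups: dict[str, str]
    haplotype_specs: dict[str, list[Edit]]
    seed: int = 0

    def validate(self) -> None:
        for p in self.populations:
            if p.haplotype is not None and p.haplotype not in self.haplotype_specs:
                raise ValueError(
                    f"population {p.code} carries unspecified haplotype {p.haplotype!r}"
                )


#: (code, n_collected, n_sequenced, haplotype) rows of the published survey:
#: 17 populations, carriers PS/GZ (H1, 15 each), TL/HK (H2, 15 each), YJ (H3, 5).
SURVEY_POPULATIONS = [
    ("PS", 26, 15, "H1"),
    ("GZ", 30, 15, "H1"),
    ("TL", 25, 15, "H2"),
    ("HK", 30, 15, "H2"),
    ("YJ", 5, 5, "H3"),
    ("NHNC", 15, 15, None),
    ("WN", 25, 15, None),
    ("QH", 25, 15, None),
    ("NN", 20, 15, None),
    ("LB", 30, 15, None),
    ("XZ", 30, 15, None),
    ("HZ", 30, 15, None),
    ("GP", 30, 15, None),
    ("YL", 30, 15, None),
    ("FC", 30, 15, None),
    ("BH", 27, 15, None),
    ("DX", 24, 15, None),
]


def published_design(ref: ReferenceChimera, seed: int = 0) -> SurveyDesign:
    """The published survey design: group 1 = YJ, group 2 = the other carriers."""
    groups = {code: ("G1" if code == "YJ" else "G2") for code, *_ in SURVEY_POPULATIONS}
    return SurveyDesign(
        populations=[PopulationSpec(*row) for row in SURVEY_POPULATIONS],
        groups=groups,
        haplotype_specs=default_haplotype_specs(ref),
        seed=seed,
    )


@dataclass
class SimulatedSurvey:
    """Generator output: data bundle plus exact ground truth."""

    bundle: SurveyBundle  # chimera-assay-positive records
    atp6_records: list[SequenceRecord]  # non-carrier, assay-negative records
    truth: dict

    def write(self, out_dir) -> None:
        """FASTA + population/group TSVs + ground-truth JSON under ``out_dir``."""
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.bundle.records, out / "chimera.fasta")
        write_fasta(self.atp6_records, out / "atp6_only.fasta")
        pop_map = {
            r.id: r.population for r in self.bundle.records + self.atp6_records
        }
        write_table_map(pop_map, out / "populations.tsv", "id", "pop")
        write_table_map(self.bundle.group_map, out / "groups.tsv", "pop", "group")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, default=str)


def _truth_vs_alignment(ref: ReferenceChimera, specs: dict[str, list[Edit]]) -> dict[str, str]:
    """Exact gapped alignment of the VS segment implied by the planted edits."""
    vs = ref.vs
    labels = sorted(specs)
    snps = {
        l: {e.pos: e.base for e in specs[l] if e.segment == "vs" and e.kind == "snp"}
        for l in labels
    }
    dels = {
        l: {
            p
            for e in specs[l]
            if e.segment == "vs" and e.kind == "del"
            for p in range(e.pos, e.pos + e.length)
        }
        for l in labels
    }
    ins = {
        l: {e.pos: e.seq for e in specs[l] if e.segment == "vs" and e.kind == "ins"}
        for l in labels
    }
    rows = {l: [] for l in labels}
    for pos in range(1, len(vs) + 1):
        for l in labels:
            if pos in dels[l]:
                rows[l].append("-")
            else:
                rows[l].append(snps[l].get(pos, vs[pos - 1]))
        for owner in labels:
            if pos in ins[owner]:
                seq = ins[owner][pos]
                for l in labels:
                    rows[l].append(seq if l == owner else "-" * len(seq))
    return {l: "".join(rows[l]) for l in labels}


def simulate_survey(design: SurveyDesign, ref: ReferenceChimera) -> SimulatedSurvey:
    """Generate survey records per the design, with exact ground truth.

    Carrier populations emit ``n_sequenced`` identical chimera records each
    (the survey found one haplotype per population); non-carriers emit
    atp6-only records that are negative for the chimera assay — absence is
    data, not an error. A shared seeded stream makes output reproducible.
    """
    design.validate()
    hap_seq = {
        label: apply_haplotype_edits(ref, edits)
        for label, edits in design.haplotype_specs.items()
    }
    atp6 = ref.b_atp6  # the shared atp6 copy amplified in every population

    records: list[SequenceRecord] = []
    atp6_records: list[SequenceRecord] = []
    truth_hap: dict[str, str] = {}
    for pop in design.populations:
        for i in range(pop.n_sequenced):
            rid = f"{pop.code}_{i + 1:02d}"
            if pop.haplotype is not None:
                records.append(SequenceRecord(rid, pop.code, hap_seq[pop.haplotype]))
                truth_hap[rid] = pop.haplotype
            else:
                atp6_records.append(SequenceRecord(rid, pop.code, atp6))
                truth_hap[rid] = "none"

    vs_aln = _truth_vs_alignment(ref, design.haplotype_specs)
    planted_vs_snps = sorted(
        {
            e.pos
            for edits in design.haplotype_specs.values()
            for e in edits
            if e.segment == "vs" and e.kind == "snp"
        }
    )
    planted_vs_indels = sum(
        1
        for edits in design.haplotype_specs.values()
        for e in edits
        if e.segment == "vs" and e.kind in ("ins", "del")
    )
    gsv_of = {
        label: _haplotype_gsv(ref, design.haplotype_specs[label])
        for label in design.haplotype_specs
    }
    protein_truth = len({translate(g) for g in gsv_of.values()})

    truth = {
        "haplotype_of": truth_hap,
        "haplotype_counts": {
            label: sum(
                p.n_sequenced for p in design.populations if p.haplotype == label
            )
            for label in design.haplotype_specs
        },
        "boundaries": ref.boundaries,
        "vs_alignment": vs_aln,
        "n_vs_indel_events": planted_vs_indels,
        "n_vs_snp_sites": len(planted_vs_snps),
        "vs_snp_positions": planted_vs_snps,
        "n_protein_haplotypes": protein_truth,
        "gsv_of": gsv_of,
        "seed": design.seed,
    }
    references = {
        "b_atp6": ref.b_atp6,
        "ds": ref.ds,
        "gsv_ref": ref.gsv,
        "coxii_prefix": ref.coxii_prefix,
    }
    bundle = SurveyBundle(records, dict(design.groups), references)
    return SimulatedSurvey(bundle, atp6_records, truth)


def _haplotype_gsv(ref: ReferenceChimera, edits: list[Edit]) -> str:
    """The GSV segment of an edited haplotype (edits never span segments)."""
    gsv = list(ref.gsv)
    for e in sorted(
        (e for e in edits if e.segment == "gsv"), key=lambda e: -e.pos
    ):
        i = e.pos - 1
        if e.kind == "snp":
            gsv[i] = e.base
        elif e.kind == "del":
            del gsv[i : i + e.length]
        else:
            gsv[i + 1 : i + 1] = list(e.seq)
    return "".join(gsv)


# ---------------------------------------------------------------------------
# Sequence simulation on a tree (HKY85)
# ---------------------------------------------------------------------------


def simulate_on_tree(
    tree: PhyloTree,
    ref_segment: str,
    kappa: float,
    freqs: tuple[float, float, float, float],
    seed: int,
) -> dict[str, str]:
    """Evolve ``ref_segment`` down a tree under HKY85, site-independently.

    The root state is the given segment; each branch applies the scaled
    HKY85 transition kernel for its length. Returns one equal-length
    sequence per leaf.
    """
    model = PhyloModel(kappa, freqs)
    rng = np.random.default_rng(seed)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    try:
        root_codes = np.array([base_idx[c] for c in ref_segment.upper()])
    except KeyError as exc:
        raise ValueError(f"ref_segment must be over ACGT, found {exc}") from None

    out: dict[str, str] = {}

    def descend(node, codes: np.ndarray) -> None:
        for child in node.children:
            t = child.length or 0.0
            if t < 0:
                raise ValueError("branch lengths must be nonnegative")
            P = prob_matrix(model, t)
            cum = np.cumsum(P, axis=1)
            draws = rng.random(codes.size)
            child_codes = (draws[:, None] > cum[codes]).sum(axis=1)
            if child.children:
                descend(child, child_codes)
            else:
                if not child.name:
                    raise ValueError("every leaf must be named")
                out[child.name] = "".join("ACGT"[i] for i in child_codes)

    descend(tree.root, root_codes)
    return out
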