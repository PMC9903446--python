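"""Translation of GSV open reading frames and protein-haplotype counting.

The GSV (orfH79 and its sequence variants) is translated under the standard
genetic code: plant mitochondria use the standard code for these codons, and
no RNA editing is modelled. Internal stops are rendered "*" and translation
continues; codons containing missing states translate to "X"; a trailing
partial codon is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq


@dataclass
class ProteinHaplotype:
    aa_sequence: str
    member_labels: list[str]


@dataclass
class ProteinHaplotypeSet:
    """Nucleotide haplotypes grouped by identical deduced protein."""

    proteins: list[ProteinHaplotype]

    @property
    def n_distinct(self) -> int:
        return len(self.proteins)

    def mapping(self) -> dict[str, int]:
        """Nucleotide-haplotype label -> protein-group index (1-based)."""
        return {
            label: i + 1
            for i, p in enumerate(self.proteins)
            for label in p.member_labels
        }


def translate(nt: str, frame: int = 1, code: int = 1) -> str:
    """Translate a nucleotide string in the given frame (1, 2 or 3).

    Missing states ("N", "?") and gaps make their codon an "X"; internal
    stops appear as "*" and translation continues to the end of the last
    complete codon.
    """
    if frame not in (1, 2, 3):
        raise ValueError(f"frame must be 1, 2 or 3, got {frame!r}")
    cleaned = nt.upper().replace("?", "N").replace("-", "N")
    sub = cleaned[frame - 1 :]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        raise ValueError("fewer than 3 bases in the chosen frame")
    return str(Seq(sub).translate(table=code, to_stop=False, stop_symbol="*"))


def protein_haplotypes(
    gsv_set: dict[str, str], frame: int = 1, code: int = 1
) -> ProteinHaplotypeSet:
    """Group labelled GSV nucleotide haplotypes by identical translation.

    Groups are sorted by decreasing size, ties by the lexicographically
    smallest member label, so the grouping is deterministic.
    """
    groups: dict[str, list[str]] = {}
    for label, nt in gsv_set.items():
        groups.setdefault(translate(nt, frame=frame, code=code), []).append(label)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), sorted(kv[1])[0]))
    return ProteinHaplotypeSet(
        [ProteinHaplotype(aa, sorted(labels)) for aa, labels in ordered]
    )
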