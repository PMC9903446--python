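"""Reading and writing survey data: FASTA sequences, metadata tables, Newick trees.

Survey inputs are DNA sequences (one per sequenced individual) plus two
tab-separated maps: sequence/individual -> population code and population ->
group label. The population label may also ride along in the FASTA description
line as a ``pop=CODE`` token; an explicit map file wins on conflict.

All coordinates reported anywhere in this package are 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

#: Permitted sequence characters. "?" and "N" are both missing nucleotide
#: states; "-" is an alignment gap.
ALPHABET = frozenset("ACGTN?-")

#: Recognised names for optional reference segments in a SurveyBundle.
REFERENCE_NAMES = ("b_atp6", "ds", "vs", "gsv_ref", "coxii_prefix", "atp6")


class ParseError(ValueError):
    """Malformed input file (bad FASTA entry, duplicate id, bad table)."""


class ConfigError(ValueError):
    """Invalid configuration or missing required column/key."""


@dataclass
class SequenceRecord:
    """One DNA sequence from a surveyed individual.

    Parameters
    ----------
    id : str
        Unique identifier within a dataset.
    population : str
        Population code (e.g. ``"PS"``); ``"NA"`` when unknown.
    sequence : str
        DNA over ``{A,C,G,T,N,?,-}``, upper-cased on construction.
    """

    id: str
    population: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("sequence record with empty id")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ParseError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ParseError(
                f"record {self.id!r}: illegal characters {sorted(bad)!r}"
            )


@dataclass
class SurveyBundle:
    """Everything one survey analysis needs: records, grouping, references."""

    records: list[SequenceRecord]
    group_map: dict[str, str] = field(default_factory=dict)
    references: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.references:
            if name not in REFERENCE_NAMES:
                raise ConfigError(
                    f"unknown reference segment {name!r}; "
                    f"expected one of {REFERENCE_NAMES}"
                )

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.population)
        return list(seen)

    def require_groups(self) -> None:
        """Check every record's population is group-mapped (AMOVA precondition)."""
        missing = [p for p in self.populations if p not in self.group_map]
        if missing:
            raise ConfigError(f"populations without group assignment: {missing}")


def _population_from_description(description: str) -> str:
    for token in description.split():
        if token.startswith("pop="):
            return token[4:]
    return "NA"


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    The population is taken from a ``pop=CODE`` token in the description line
    when present, else ``"NA"``. Sequences are upper-cased. Duplicate ids and
    empty sequences are rejected.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ParseError(f"duplicate sequence id {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(
            SequenceRecord(
                id=entry.id,
                population=_population_from_description(entry.description),
                sequence=str(entry.seq),
            )
        )
    return records


def write_fasta(records, path) -> None:
    """Write records as FASTA, carrying the population as a ``pop=`` token."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id} pop={r.population}\n")
            for i in range(0, len(r.sequence), 70):
                fh.write(r.sequence[i : i + 70] + "\n")


def read_table_map(path, key_col: str, value_col: str) -> dict[str, str]:
    """Read a two-column mapping from a tab-separated table with a header.

    Duplicate keys with conflicting values are rejected; duplicate consistent
    rows are tolerated. An empty file yields an empty mapping with a warning.
    """
    try:
        table = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty table, returning empty mapping")
        return {}
    for col in (key_col, value_col):
        if col not in table.columns:
            raise ConfigError(
                f"{path}: missing column {col!r} (have {list(table.columns)})"
            )
    if table.empty:
        warnings.warn(f"{path}: table has a header but no rows")
        return {}
    mapping: dict[str, str] = {}
    for key, value in zip(table[key_col], table[value_col]):
        if key in mapping and mapping[key] != value:
            raise ParseError(
                f"{path}: key {key!r} maps to both {mapping[key]!r} and {value!r}"
            )
        mapping[key] = value
    return mapping


def write_table_map(mapping: dict[str, str], path, key_col: str, value_col: str) -> None:
    pd.DataFrame(
        {key_col: list(mapping), value_col: list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick output
# ---------------------------------------------------------------------------

_NEWICK_UNSAFE = set(" \t\n()[]':;,")


def _newick_label(name: str) -> str:
    if any(c in _NEWICK_UNSAFE for c in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _newick_node(node) -> str:
    if not node.children:
        if not node.name:
            raise ParseError("unnamed leaf cannot be written to Newick")
        body = _newick_label(node.name)
    else:
        body = "(" + ",".join(_newick_node(c) for c in node.children) + ")"
        if getattr(node, "support", None) is not None:
            body += f"{node.support:g}"
    if node.length is not None:
        body += f":{node.length:.6f}"
    return body


def tree_to_newick(tree) -> str:
    """Serialise a :class:`~cmschimera.phylo.PhyloTree` (or bare node) to Newick."""
    root = getattr(tree, "root", tree)
    body = "(" + ",".join(_newick_node(c) for c in root.children) + ")"
    if getattr(root, "name", None):
        body += _newick_label(root.name)
    return body + ";"


def write_newick(tree, path) -> None:
    """Write a tree to a Newick file (branch lengths to 6 decimal places)."""
    root = getattr(tree, "root", tree)
    leaves = [n for n in _iter_nodes(root) if not n.children]
    if len(leaves) < 2:
        raise ParseError("tree must have at least 2 leaves")
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree) + "\n")


def _iter_nodes(node):
    yield node
    for child in node.children:
        yield from _iter_nodes(child)
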