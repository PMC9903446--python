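"""End-to-end orchestration of the survey analysis stages.

``run_all`` executes, on either simulated or user-supplied data: haplotype
collapsing -> structure annotation (segments, junction motifs, VS variation
catalog) -> ORF translation -> hierarchical AMOVA -> NJ/ML phylogeny.
Stage failures are isolated: an exception in one stage is recorded and
later independent stages still run. Reports carry no timestamps, so two
runs with the same config and seed produce identical output.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import dataclass, field

from . import haplotypes as hap_mod
from . import io as io_mod
from . import orfs as orf_mod
from . import phylo as phylo_mod
from . import structure as struct_mod
from . import synthetic as syn_mod
from .amova import amova as run_amova
from .amova import distance_matrix
from .io import ConfigError

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": ["haplotypes", "structure", "orfs", "amova", "phylo"],
    "simulate": {"enabled": True, "gsv_length": syn_mod.GSV_DEFAULT_LEN},
    "input": {"fasta": None, "pop_map": None, "group_map": None, "references": None},
    "haplotypes": {"trim_missing_ends": False, "label_prefix": "H"},
    "structure": {"min_anchor_identity": 0.95},
    "amova": {"mode": "haplotype_binary", "n_permutations": 1000},
    "phylo": {"bootstrap": 0},
}


def validate_config(config: dict) -> dict:
    """Merge a user config over the defaults; reject unknown keys."""
    bad = [k for k in config if k not in DEFAULT_CONFIG]
    for section, defaults in DEFAULT_CONFIG.items():
        if isinstance(defaults, dict) and isinstance(config.get(section), dict):
            bad += [f"{section}.{k}" for k in config[section] if k not in defaults]
    if bad:
        raise ConfigError(f"unknown configuration keys: {bad}")
    merged = {}
    for key, value in DEFAULT_CONFIG.items():
        if isinstance(value, dict):
            merged[key] = {**value, **config.get(key, {})}
        else:
            merged[key] = config.get(key, value)
    unknown_stages = [s for s in merged["stages"] if s not in DEFAULT_CONFIG["stages"]]
    if unknown_stages:
        raise ConfigError(f"unknown stages: {unknown_stages}")
    return merged


@dataclass
class RunReport:
    """Per-stage outputs plus provenance; one block per enabled stage."""

    blocks: dict[str, dict] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        payload = {
            "provenance": self.provenance,
            "blocks": self.blocks,
            "errors": self.errors,
            "warnings": self.warnings,
        }
        return json.dumps(payload, indent=1, sort_keys=True, default=str, **kwargs)


def _load_bundle(config: dict, report: RunReport):
    seed = config["seed"]
    if config["simulate"]["enabled"]:
        ref = syn_mod.make_reference(seed, config["simulate"]["gsv_length"])
        survey = syn_mod.simulate_survey(syn_mod.published_design(ref, seed), ref)
        report.blocks["simulate"] = {
            "n_chimera_records": len(survey.bundle.records),
            "n_atp6_only_records": len(survey.atp6_records),
            "seed": seed,
        }
        return survey.bundle, survey.truth
    paths = config["input"]
    if not paths["fasta"]:
        raise ConfigError("input.fasta required when simulate.enabled is false")
    records = io_mod.read_fasta(paths["fasta"])
    if paths["pop_map"]:
        pop_map = io_mod.read_table_map(paths["pop_map"], "id", "pop")
        for r in records:
            if r.id in pop_map:  # the map file wins over FASTA pop= tokens
                r.population = pop_map[r.id]
    group_map = (
        io_mod.read_table_map(paths["group_map"], "pop", "group")
        if paths["group_map"]
        else {}
    )
    references = {}
    if paths["references"]:
        for rec in io_mod.read_fasta(paths["references"]):
            references[rec.id] = rec.sequence
    return io_mod.SurveyBundle(records, group_map, references), None


def run_all(config: dict | None = None, out_dir=None) -> RunReport:
    """Run every enabled stage; isolate failures; return a :class:`RunReport`."""
    cfg = validate_config(config or {})
    report = RunReport()
    cfg_json = json.dumps(cfg, sort_keys=True, default=str)
    report.provenance = {
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg["seed"],
    }
    stages = cfg["stages"]
    if not stages:
        report.warnings.append("no stages enabled; empty report")
        return report

    try:
        bundle, truth = _load_bundle(cfg, report)
    except Exception as exc:  # input failure dooms everything downstream
        report.errors["input"] = str(exc)
        return report

    hapset = None
    if "haplotypes" in stages:
        try:
            hapset = hap_mod.collapse(
                bundle.records,
                trim_missing_ends=cfg["haplotypes"]["trim_missing_ends"],
                label_prefix=cfg["haplotypes"]["label_prefix"],
            )
            reps = {h.label: h.sequence for h in hapset.haplotypes}
            block = {
                "n_haplotypes": len(hapset.haplotypes),
                "counts": hapset.counts.to_dict(),
            }
            if len(reps) >= 2:
                block["identity_percent"] = hap_mod.identity_matrix(reps).to_dict()
            report.blocks["haplotypes"] = block
        except Exception as exc:
            report.errors["haplotypes"] = str(exc)

    annotations = {}
    if "structure" in stages:
        try:
            if not bundle.references:
                raise ConfigError("structure stage needs reference segments")
            reps = (
                {h.label: h.sequence for h in hapset.haplotypes}
                if hapset
                else {r.id: r.sequence for r in bundle.records}
            )
            refs = bundle.references
            block: dict = {"segments": {}, "motifs": {}}
            for label, seq in reps.items():
                ann = struct_mod.annotate(
                    seq, refs, cfg["structure"]["min_anchor_identity"]
                )
                annotations[label] = ann
                block["segments"][label] = {
                    name: ([seg.start, seg.end] if seg else None)
                    for name, seg in ann.segments.items()
                }
                block["motifs"][label] = [
                    [h.motif, h.start, h.end, h.orientation] for h in ann.motif_hits
                ]
            if truth is not None and "vs_alignment" in truth:
                vs_aln = truth["vs_alignment"]
            else:
                vs_segments = {
                    label: seq[ann.segments["vs"].start - 1 : ann.segments["vs"].end]
                    for label, seq in reps.items()
                    if (ann := annotations[label]).segments["vs"]
                }
                vs_aln = (
                    hap_mod.align_progressive(vs_segments)
                    if len(vs_segments) >= 2
                    else None
                )
            if vs_aln and len(vs_aln) >= 2:
                catalog = struct_mod.catalog_vs_variation(vs_aln)
                block["vs_variation"] = {
                    "n_indel_events": catalog.n_indel_events,
                    "n_snp_sites": catalog.n_snp_sites,
                    "n_gap_columns": catalog.n_gap_columns,
                }
            report.blocks["structure"] = block
        except Exception as exc:
            report.errors["structure"] = str(exc)

    gsv_set = {}
    if "orfs" in stages:
        try:
            if annotations:
                for label, ann in annotations.items():
                    seg = ann.segments["gsv"]
                    if seg:
                        seq = (
                            hapset.sequence_of(label)
                            if hapset
                            else dict((r.id, r.sequence) for r in bundle.records)[label]
                        )
                        gsv_set[label] = seq[seg.start - 1 : seg.end]
            elif truth is not None:
                gsv_set = dict(truth["gsv_of"])
            if len(gsv_set) < 1:
                raise ConfigError("orfs stage found no GSV segments (run structure)")
            proteins = orf_mod.protein_haplotypes(gsv_set)
            report.blocks["orfs"] = {
                "n_nucleotide_haplotypes": len(gsv_set),
                "n_protein_haplotypes": proteins.n_distinct,
                "mapping": proteins.mapping(),
            }
        except Exception as exc:
            report.errors["orfs"] = str(exc)

    if "amova" in stages:
        try:
            bundle.require_groups()
            d = distance_matrix(
                bundle.records,
                mode=cfg["amova"]["mode"],
                assignments=hapset.assignments() if hapset else None,
            )
            pop_map = {r.id: r.population for r in bundle.records}
            result = run_amova(
                d,
                pop_map,
                bundle.group_map,
                n_perm=cfg["amova"]["n_permutations"],
                seed=cfg["seed"],
            )
            report.blocks["amova"] = {
                "df": result.df,
                "ss": result.ss,
                "variance_components": result.variance_components,
                "percentages": result.percentages,
                "phi": result.phi,
                "p_values": result.p_values,
                "n_permutations": result.n_permutations,
            }
        except Exception as exc:
            report.errors["amova"] = str(exc)

    if "phylo" in stages:
        try:
            reps = (
                {h.label: h.sequence for h in hapset.haplotypes}
                if hapset
                else {r.id: r.sequence for r in bundle.records}
            )
            if len(reps) < 3:
                raise ConfigError("phylo stage needs at least 3 haplotypes")
            aligned = (
                reps
                if len({len(s) for s in reps.values()}) == 1
                else hap_mod.align_progressive(reps)
            )
            tree = phylo_mod.ml_search(
                aligned, phylo_mod.nj_tree(phylo_mod.jc_distance_matrix(aligned))
            )
            n_boot = cfg["phylo"]["bootstrap"]
            supports = None
            if n_boot:
                tree, supports = phylo_mod.bootstrap_supports(
                    aligned, n_boot, seed=cfg["seed"], point_tree=tree
                )
            report.blocks["phylo"] = {
                "newick": io_mod.tree_to_newick(tree),
                "loglik": tree.loglik,
                "kappa": tree.model.kappa,
                "freqs": list(tree.model.freqs),
                "bootstrap": (
                    {",".join(sorted(k)): v for k, v in supports.items()}
                    if supports
                    else None
                ),
            }
        except Exception as exc:
            report.errors["phylo"] = str(exc)

    if out_dir is not None:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json() + "\n")
        if hapset is not None:
            hapset.counts.to_csv(out / "haplotype_counts.tsv", sep="\t")
    return report
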