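"""End-to-end orchestration: encode -> assign -> reconstruct -> count -> report.

`run_full` drives the whole analysis from a :class:`PipelineConfig` and
writes a reproducible report bundle: assignments.tsv, one reconstruction
table per character, transitions.tsv, annotated trees and a JSON manifest
(inputs, seed, package version, decisions in force). A failed stage leaves
partial outputs plus a FAILED marker file and re-raises.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .alignment import read_fasta
from .ancestral import (
    AncestralReconstruction,
    TransitionSummary,
    annotate_tree,
    average_over_trees,
    count_transitions,
    encode_depth,
    encode_habitat,
)
from .assign import run_assignment, write_assignments
from .errors import BathyphyError
from .tables import ReferenceTable
from .trees import read_newick, read_tree_sample, write_newick

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and knobs for one full run; every referenced path must exist."""

    ref_table: str
    ref_alignment: str
    queries: str
    tree_sample: str
    out_dir: str
    placement_tree: str | None = None
    threshold: float = 0.02
    min_sites: int = 100
    characters: tuple[str, ...] = ("habitat", "depth")
    modal_threshold: float = 0.5
    per_tree_alpha: bool = True
    habitat_policy: str = "organic_priority"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "characters" in raw:
            raw["characters"] = tuple(raw["characters"])
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("ref_table", "ref_alignment", "queries", "tree_sample"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise BathyphyError(f"{name} path does not exist: {p}")
        if self.placement_tree and not Path(self.placement_tree).exists():
            raise BathyphyError(f"placement_tree path does not exist: {self.placement_tree}")


def run_full(config: PipelineConfig) -> dict[str, Path]:
    """Run the full analysis; returns a name -> path map of written outputs."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    try:
        refs = ReferenceTable.from_tsv(config.ref_table)
        ref_aln = read_fasta(config.ref_alignment, partition_name="refs")
        queries = read_fasta(config.queries, partition_name="queries")
        placement = (
            read_newick(config.placement_tree, rooted=True)
            if config.placement_tree
            else None
        )
        sample = read_tree_sample(config.tree_sample, rooted=True)

        results = run_assignment(
            queries, refs, ref_aln,
            threshold=config.threshold,
            placement=placement,
            min_sites=config.min_sites,
        )
        outputs["assignments"] = out / "assignments.tsv"
        write_assignments(results, outputs["assignments"])

        header = {
            "seed": config.seed,
            "threshold": config.threshold,
            "modal_threshold": config.modal_threshold,
            "per_tree_alpha": config.per_tree_alpha,
            "version": __version__,
        }
        transition_rows: list[str] = []
        for character in config.characters:
            if character == "habitat":
                chars = encode_habitat(refs, policy=config.habitat_policy)
            elif character == "depth":
                chars = encode_depth(refs)
            else:
                raise BathyphyError(f"unknown character {character!r}")
            # restrict to taxa present in the trees (queries are not in the sample)
            tree_taxa = {
                lf.taxon.label for lf in sample.trees[0].leaf_node_iter()
            }
            chars = dataclasses.replace(
                chars,
                assignments={
                    t: s for t, s in chars.assignments.items() if t in tree_taxa
                },
            )
            recon = average_over_trees(
                sample, chars, per_tree_alpha=config.per_tree_alpha
            )
            path = out / f"recon_{character}.tsv"
            recon.to_tsv(path, header_comments={**header, "character": character})
            outputs[f"recon_{character}"] = path
            annotated = out / f"annotated_{character}.nex"
            annotate_tree(recon).write(path=str(annotated), schema="nexus")
            outputs[f"annotated_{character}"] = annotated

            summary = count_transitions(recon, chars, config.modal_threshold)
            for (a, b), n in sorted(summary.counts.items()):
                transition_rows.append(f"{character}\t{a}\t{b}\t{n}")
            transition_rows.append(
                f"{character}\tunresolved\tunresolved\t{summary.unresolved_edges}"
            )
            outputs.setdefault("mcc_tree", out / "mcc.nwk")
            write_newick(recon.summary_tree, outputs["mcc_tree"])

        outputs["transitions"] = out / "transitions.tsv"
        with open(outputs["transitions"], "w") as fh:
            for key, value in header.items():
                fh.write(f"# {key}={value}\n")
            fh.write("character\tfrom_state\tto_state\tcount\n")
            fh.write("\n".join(transition_rows) + "\n")

        outputs["manifest"] = out / "manifest.json"
        manifest = {
            "config": dataclasses.asdict(config),
            "version": __version__,
            "outputs": {k: str(v) for k, v in outputs.items()},
            "decisions": {
                "threshold_boundary": "inclusive (d <= threshold assigns)",
                "deletion_scheme": "pairwise",
                "root_prior": "uniform 1/k",
                "clade_averaging": "trees lacking a clade contribute nothing",
            },
        }
        outputs["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception:
        (out / "FAILED").write_text("pipeline failed; partial outputs retained\n")
        raise
    return outputs


def report_transitions(
    summary: TransitionSummary, recon: AncestralReconstruction
) -> str:
    """Human-readable transition table listing the edges behind each count.

    Every observed direction is listed with its edges; the reverse of each
    observed direction is reported too (count 0 if absent) so directional
    asymmetries are explicit.
    """
    labels = summary.state_space or recon.state_space
    lines = ["from\tto\tcount\tedges"]
    directions = set(summary.counts)
    directions |= {(b, a) for (a, b) in summary.counts}
    for a, b in sorted(directions):
        n = summary.counts.get((a, b), 0)
        edges = [
            f"{{{','.join(sorted(pc))}}}->{{{','.join(sorted(cc))}}}"
            for pc, cc, ps, cs in summary.edges
            if (ps, cs) == (a, b)
        ]
        lines.append(f"{labels[a]}\t{labels[b]}\t{n}\t{'; '.join(edges)}")
    lines.append(f"unresolved edges\t\t{summary.unresolved_edges}\t")
    return "\n".join(lines)
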