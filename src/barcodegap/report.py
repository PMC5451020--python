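"""Full marker-evaluation pipeline: one run per gene x group.

For every combination of gene (e.g. COI, 16S, 18S) and analysis group
(e.g. Aphidiinae vs non-Aphidiinae) the run produces: a pseudogene QC table
(protein-coding genes only), the K2P distance matrix, within/between
distance summaries, the species-pair gap/cutoff table, the group gap
summary, identical-sequence species groups, Max-WSD/Min-BSD scatter data
and a bootstrapped NJ tree — plus a JSON manifest recording parameters,
seeds and bookkeeping counts.  The pipeline is a pure function of
(inputs, configuration, seed).

Group membership comes from the metadata table, never from taxonomy
strings: which species count as one analysis group is a domain judgment.
Short fragments (for COI, records with fewer than 400 ungapped sites by
default) are dropped from the distance analysis, as sub-length amplicons
carry too few diagnostic characters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from dataclasses import replace as dc_replace
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .distance import k2p_matrix, summarize_distances
from .gapstats import (
    cutoff_table,
    gap_summary,
    identical_species_groups,
    overall_max_wsd,
    write_pair_table,
)
from .njtree import bootstrap_support, write_support_table
from .qc import screen_alignment, write_qc_table
from .seqio import (
    GeneAlignment,
    read_labeled_fasta,
    read_metadata,
    trim_to_overlap,
    write_newick,
)

logger = logging.getLogger(__name__)

CODING_GENES = ("COI",)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    inputs: Mapping[str, str]  # gene -> aligned FASTA path
    outdir: str
    metadata: str | None = None
    groups: Sequence[str] = ()
    deletion: str = "pairwise"
    replicates: int = 2000
    seed: int = 0
    cutoff: float | None = None  # None: use the group's overall Max-WSD
    min_ungapped: Mapping[str, int] = field(default_factory=lambda: {"COI": 400})
    trim_genes: Sequence[str] = ("16S",)
    genetic_code: int = 5

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _summary_row(s) -> dict:
    return {
        "scope": s.scope,
        "min": s.min,
        "max": s.max,
        "mean": s.mean,
        "se": s.se,
        "n_pairs": s.n_pairs,
        "n_undefined": s.n_undefined,
    }


def _analyze_gene_group(
    alignment: GeneAlignment,
    gene: str,
    group: str,
    config: RunConfig,
    seed: int,
    outdir: Path,
) -> dict:
    tag = f"{gene}_{group}" if group else gene
    labels = alignment.species_map()
    info: dict = {
        "gene": gene,
        "group": group,
        "n_sequences": len(alignment),
        "n_species": len(set(labels.values())),
        "seed": seed,
    }

    if gene in CODING_GENES:
        reports = screen_alignment(alignment, config.genetic_code)
        write_qc_table(reports, outdir / f"qc_{tag}.tsv")
        info["n_pseudogene_suspects"] = sum(1 for r in reports if r.verdict != "clean")

    matrix = k2p_matrix(alignment, deletion=config.deletion)
    matrix.write_tsv(outdir / f"distances_{tag}.tsv")
    info["n_undefined_pairs"] = matrix.n_undefined()

    summaries = []
    for scope in ("within_species", "between_species"):
        try:
            summaries.append(
                summarize_distances(matrix, labels, scope, gene=gene, group=group)
            )
        except ValueError:
            logger.warning("%s: no %s pairs", tag, scope)
    info["distance_summaries"] = [_summary_row(s) for s in summaries]

    cutoff = config.cutoff
    if cutoff is None:
        cutoff = overall_max_wsd(matrix, labels)
    summary = gap_summary(matrix, labels, gene=gene, group=group)
    records = cutoff_table(matrix, labels, cutoff)
    write_pair_table(records, outdir / f"pairs_{tag}.tsv")
    with open(outdir / f"scatter_{tag}.tsv", "w", encoding="utf-8") as fh:
        fh.write("species_a\tspecies_b\tpair_max_wsd\tmin_bsd\n")
        for rec in records:
            if rec.pair_max_wsd is not None:
                fh.write(
                    f"{rec.species_a}\t{rec.species_b}\t"
                    f"{rec.pair_max_wsd:.8f}\t{rec.min_bsd:.8f}\n"
                )
    singletons = sorted(
        sp
        for sp in set(labels.values())
        if sum(1 for v in labels.values() if v == sp) < 2
    )
    if singletons:
        logger.info("%s: singletons excluded from gap analysis: %s", tag, singletons)
    info["singleton_species"] = singletons
    info["gap_summary"] = {
        "n_pairs_gap_analysis": summary.n_pairs_gap_analysis,
        "n_no_gap": summary.n_no_gap,
        "pct_no_gap": summary.pct_no_gap,
        "overall_max_wsd": summary.overall_max_wsd,
        "n_pairs_cutoff_analysis": summary.n_pairs_cutoff_analysis,
        "n_below_cutoff": summary.n_below_cutoff,
        "pct_below_cutoff": summary.pct_below_cutoff,
    }

    groups_identical = identical_species_groups(alignment)
    with open(outdir / f"identical_groups_{tag}.tsv", "w", encoding="utf-8") as fh:
        fh.write("group_index\tspecies\n")
        for idx, members in enumerate(groups_identical, 1):
            for sp in members:
                fh.write(f"{idx}\t{sp}\n")
    info["identical_species_groups"] = groups_identical

    if len(alignment) >= 3:
        tree = bootstrap_support(
            alignment,
            replicates=config.replicates,
            seed=seed,
            deletion=config.deletion,
        )
        write_newick(tree, outdir / f"njtree_{tag}.nwk")
        write_support_table(tree, outdir / f"supports_{tag}.tsv")
        info["tree"] = f"njtree_{tag}.nwk"
    return info


def run_marker_evaluation(config: RunConfig) -> dict:
    """Run the whole evaluation; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metadata = read_metadata(config.metadata) if config.metadata else None

    results = []
    counter = 0
    for gene in sorted(config.inputs):
        path = config.inputs[gene]
        if not Path(path).exists():
            raise FileNotFoundError(f"input for {gene} not found: {path}")
        alignment = read_labeled_fasta(
            path, defaults={"gene": gene}, metadata=metadata
        )
        # each input file is one gene: pin it regardless of sidecar rows that
        # describe the same specimen for other markers
        alignment = GeneAlignment(
            [dc_replace(s, gene=gene) for s in alignment], gene=gene
        )
        min_len = config.min_ungapped.get(gene, 0)
        if min_len:
            kept = [s for s in alignment if len(s.ungapped()) >= min_len]
            n_dropped = len(alignment) - len(kept)
            if n_dropped:
                logger.info("%s: dropped %d short sequences (<%d nt)", gene, n_dropped, min_len)
            if not kept:
                raise ValueError(f"{gene}: all sequences below {min_len} nt")
            alignment = GeneAlignment(kept, gene=gene)
        if gene in config.trim_genes:
            alignment = trim_to_overlap(alignment)
        groups = config.groups or sorted(
            {s.group for s in alignment if s.group}
        ) or [""]
        for group in groups:
            subset = (
                alignment
                if group == ""
                else GeneAlignment(
                    [s for s in alignment if s.group == group], gene=gene
                )
                if any(s.group == group for s in alignment)
                else None
            )
            if subset is None:
                raise ValueError(f"{gene}: group {group!r} has no sequences")
            seed = config.seed + counter
            counter += 1
            results.append(
                _analyze_gene_group(subset, gene, group, config, seed, outdir)
            )

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "deletion": config.deletion,
        "replicates": config.replicates,
        "cutoff": config.cutoff,
        "results": results,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
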