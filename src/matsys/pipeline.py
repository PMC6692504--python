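"""End-to-end orchestration: search -> annotate -> classify -> transitions.

The two analysis stages are deliberately separable: ``classify_assembly``
produces one species' mating-system call from its assembly, and the
transition stage consumes any state map (computed or hand-built), so
curated clade state maps can be run through the parsimony stage directly.

Species whose assemblies are too broken for automated classification (the
real survey resolved several such cases by synteny with close relatives)
are handled by manual overrides in the run configuration; every override is
flagged in the output evidence column and the log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy

from .classification import MatingSystemCall, ThresholdConfig, classify_species
from .genome_io import Assembly, Gff3Feature, export_results, read_assembly
from .homology_search import ProteinQuery, read_queries, search_mat_genes
from .locus_annotation import (
    AllelismEvidence,
    ContigLink,
    GeneCall,
    MatLocus,
    RepeatPair,
    TelomereAnnotation,
    assemble_mat_loci,
    assign_repeat_roles,
    call_genes,
    detect_allelism,
    detect_telomere,
    find_flanking_repeats,
    find_rdna,
    infer_collapsed_repeats,
)
from .transition_inference import (
    PhyloTree,
    Reconstruction,
    TransitionSummary,
    count_transitions,
    reconstruct_states,
)

logger = logging.getLogger(__name__)


@dataclass
class SpeciesEvidence:
    """Everything the classifier saw for one species."""

    assembly: Assembly
    calls: List[GeneCall]
    loci: List[MatLocus]
    repeats: List[RepeatPair]
    allelism: List[AllelismEvidence]
    links: List[ContigLink]
    telomeres: List[TelomereAnnotation]
    call: Optional[MatingSystemCall] = None


def annotate_assembly(
    assembly: Assembly,
    queries: Sequence[ProteinQuery],
    code: str = "standard",
    cfg: Optional[ThresholdConfig] = None,
    rdna_seq: Optional[str] = None,
) -> SpeciesEvidence:
    """Run search and all annotation stages for one assembly."""
    cfg = cfg or ThresholdConfig()
    hits, _regions = search_mat_genes(
        assembly,
        queries,
        code=code,
        e_max=cfg.e_max,
        region_join_window=cfg.region_join_window,
    )
    calls = call_genes(
        hits, intact_min_cover=cfg.intact_min_cover, max_chain_gap=cfg.max_chain_gap
    )
    telomeres = []
    for contig in assembly.contigs:
        telomeres.extend(
            detect_telomere(
                contig,
                unit_min=cfg.telomere_unit_min,
                unit_max=cfg.telomere_unit_max,
                min_copies=cfg.telomere_min_copies,
                end_window=cfg.telomere_end_window,
            )
        )
    rdna_hits = find_rdna(assembly, rdna_seq) if rdna_seq else []
    loci = assemble_mat_loci(
        calls,
        assembly,
        telomeres=telomeres,
        rdna_hits=rdna_hits,
        max_locus_gap=cfg.max_locus_gap,
        telomere_window=cfg.telomere_window,
        rdna_window=cfg.rdna_window,
    )
    repeats = find_flanking_repeats(
        assembly,
        loci,
        window=cfg.repeat_window,
        min_len=cfg.min_repeat_len,
        min_identity=cfg.min_repeat_identity,
    )
    assign_repeat_roles(repeats, loci, near=cfg.repeat_window)
    allelism = []
    for i, la in enumerate(loci):
        for lb in loci[i + 1 :]:
            if la.idiomorph == lb.idiomorph or "both" in (la.idiomorph, lb.idiomorph):
                continue
            allelism.append(
                detect_allelism(
                    assembly,
                    la,
                    lb,
                    flank_len=cfg.flank_len,
                    min_identity=cfg.allelism_min_identity,
                )
            )
    links = infer_collapsed_repeats(
        assembly, k=cfg.k, cov_lo=cfg.cov_lo, cov_hi=cfg.cov_hi
    )
    return SpeciesEvidence(
        assembly=assembly,
        calls=calls,
        loci=loci,
        repeats=repeats,
        allelism=allelism,
        links=links,
        telomeres=telomeres,
    )


def classify_assembly(
    assembly: Assembly,
    queries: Sequence[ProteinQuery],
    code: str = "standard",
    cfg: Optional[ThresholdConfig] = None,
    rdna_seq: Optional[str] = None,
) -> Tuple[MatingSystemCall, SpeciesEvidence]:
    """Search, annotate and classify one assembly."""
    cfg = cfg or ThresholdConfig()
    ev = annotate_assembly(assembly, queries, code=code, cfg=cfg, rdna_seq=rdna_seq)
    call = classify_species(
        ev.loci,
        ev.repeats,
        ev.allelism,
        ev.links,
        cfg,
        fragment_calls=[c for c in ev.calls if c.status != "intact"],
        searched=True,
    )
    ev.call = call
    for rule in call.evidence:
        logger.info("%s: %s", assembly.species, rule)
    return call, ev


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    assemblies_dir: str
    queries: str
    out_dir: str
    tree: Optional[str] = None
    genetic_code_table: Dict[str, str] = field(default_factory=dict)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    policy: str = "default"
    overrides: Dict[str, str] = field(default_factory=dict)
    rdna: Optional[str] = None
    tree_reconciliation: str = "strict"  # or 'lenient'
    seed: int = 0


def run_pipeline(cfg: RunConfig):
    """Classify every assembly in a directory and, when a tree is supplied,
    reconstruct transitions over the override-merged state map.

    Returns ``(calls, evidence, summary, reconstruction)``; ``summary`` is an
    empty TransitionSummary when no tree is given. Outputs are also written
    to ``cfg.out_dir`` (calls TSV, loci GFF3, transitions JSON, state tree).
    """
    queries = read_queries(cfg.queries)
    rdna_seq = None
    if cfg.rdna:
        from Bio import SeqIO

        rdna_seq = str(next(SeqIO.parse(cfg.rdna, "fasta")).seq)
    paths = sorted(
        p
        for p in Path(cfg.assemblies_dir).iterdir()
        if p.suffix in (".fa", ".fasta", ".fna")
    )
    if not paths:
        raise FileNotFoundError(f"no FASTA assemblies in {cfg.assemblies_dir}")
    calls: Dict[str, MatingSystemCall] = {}
    evidence: Dict[str, SpeciesEvidence] = {}
    for path in paths:
        species = path.stem
        assembly = read_assembly(str(path), species=species)
        code = cfg.genetic_code_table.get(species, "standard")
        call, ev = classify_assembly(
            assembly, queries, code=code, cfg=cfg.thresholds, rdna_seq=rdna_seq
        )
        calls[species] = call
        evidence[species] = ev
    for species, category in sorted(cfg.overrides.items()):
        logger.info("override: %s -> %s", species, category)
        calls[species] = MatingSystemCall(
            category=category,
            ploidy_note="unknown",
            provisional=False,
            evidence=["manual_override"],
        )

    summary = TransitionSummary()
    reconstruction: Optional[Reconstruction] = None
    tree_newick = None
    if cfg.tree:
        tree = PhyloTree(
            dendropy.Tree.get(
                path=cfg.tree,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        )
        states = {sp: c.category for sp, c in calls.items()}
        missing = set(tree.tip_names()) - set(states)
        if missing:
            if cfg.tree_reconciliation == "strict":
                raise ValueError(f"tree tips without calls: {sorted(missing)}")
            logger.warning("pruning tips without calls: %s", sorted(missing))
            tree.tree.prune_taxa_with_labels(sorted(missing))
            tree = PhyloTree(tree.tree)
        reconstruction = reconstruct_states(tree, states, policy=cfg.policy)
        summary = count_transitions(reconstruction)
        tree_newick = reconstruction.to_newick()

    features = _loci_features(evidence)
    export_results(calls, features, summary, cfg.out_dir, tree_newick=tree_newick)
    return calls, evidence, summary, reconstruction


def _loci_features(evidence: Dict[str, SpeciesEvidence]) -> List[Gff3Feature]:
    feats: List[Gff3Feature] = []
    for species in sorted(evidence):
        ev = evidence[species]
        for locus in ev.loci:
            feats.append(
                Gff3Feature(
                    seqid=locus.contig,
                    type="mat_locus",
                    start=locus.span[0],
                    end=locus.span[1],
                    attributes={
                        "species": species,
                        "idiomorph": locus.idiomorph,
                        "telomere_proximal": str(locus.telomere_proximal).lower(),
                        "rdna_proximal": str(locus.rdna_proximal).lower(),
                    },
                )
            )
        for p in ev.repeats:
            for tag, (contig, span) in (("copyA", p.copy_a), ("copyB", p.copy_b)):
                feats.append(
                    Gff3Feature(
                        seqid=contig,
                        type="repeat_pair",
                        start=span[0],
                        end=span[1],
                        attributes={
                            "species": species,
                            "copy": tag,
                            "orientation": p.orientation,
                            "role": p.role,
                            "identity": f"{p.identity:.1f}",
                        },
                    )
                )
        for tel in ev.telomeres:
            feats.append(
                Gff3Feature(
                    seqid=tel.contig,
                    type="telomere",
                    start=tel.span[0],
                    end=tel.span[1],
                    attributes={
                        "species": species,
                        "unit": tel.unit,
                        "copies": str(tel.copies),
                    },
                )
            )
    return feats
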