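"""Synthetic assemblies with planted MAT configurations, and curated fixtures.

Every pipeline stage is testable without downloads: this module plants MAT
cassettes in each of the seven mating-system configurations into seeded
random background DNA (40% GC, typical for yeast nuclear genomes), with
inverted repeats of controlled length and identity, telomeric tandem
arrays, rDNA arrays and, on request, the contig structure a de Bruijn
assembler produces when the two copies of an IR collapse into a single
2x-coverage contig with k-base end overlaps.

Planted invertible spans default to the 10-20 kb range rather than the
>100 kb spans of real flip/flop chromosomes, keeping generation and search
in seconds; the geometry (cassette order, repeat orientation, context) is
what the classifier consumes, not the absolute span length, and the scale
is configurable.

The bundled toy protein sequences that stand in for a1/a2/alpha1/alpha2 and
the SLA2/DIC1/APN2 neighbors are fixed and mutually <30% identical, so
cross-hits between queries cannot confound classification tests.

``clade_fixture`` returns curated subtree/state-map fixtures for the clades
of budding yeasts whose mating-system evolution is best documented
(Lipomyces, Ogataea, Saccharomycetaceae, Saturnispora, the PHN clades and a
condensed backbone of all switching clades).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome_io import Assembly, Contig, revcomp
from .homology_search import ProteinQuery, read_queries
from .transition_inference import (
    PhyloTree,
    STATES,
    parse_newick,
    parsimony_minimum,
    validate_state_map,
)

logger = logging.getLogger(__name__)

CATEGORIES = ("HET", "3LOC", "FF1", "FF2", "PHC", "PHN", "NOMAT")

# Deterministic reverse-translation table (one codon per residue, CTG never
# used so the planted genes read identically under all three nuclear codes).
_CODON = {
    "A": "GCT", "R": "AGA", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "TTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCA",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}


def toy_queries() -> List[ProteinQuery]:
    """The bundled toy MAT / neighbor protein query set."""
    with resources.as_file(
        resources.files("matsys").joinpath("data/toy_queries.faa")
    ) as p:
        return read_queries(str(p))


def rdna_landmark() -> str:
    """The bundled toy rDNA nucleotide landmark."""
    path = resources.files("matsys").joinpath("data/rdna_landmark.fna")
    seq = []
    for line in path.read_text().splitlines():
        if not line.startswith(">"):
            seq.append(line.strip())
    return "".join(seq)


def reverse_translate(peptide: str) -> str:
    return "".join(_CODON[aa] for aa in peptide)


def _gene_dna(name: str) -> str:
    for q in toy_queries():
        if q.name == name:
            return reverse_translate(q.seq)
    raise KeyError(name)


def _pseudogenize(dna: str, rng: np.random.Generator, n_stops: int = 3) -> str:
    """Insert premature stop codons at random internal codon positions."""
    codons = [dna[i : i + 3] for i in range(0, len(dna), 3)]
    n_codons = len(codons)
    sites = rng.choice(np.arange(2, n_codons - 2), size=n_stops, replace=False)
    for s in sites:
        codons[int(s)] = "TAA"
    return "".join(codons)


def _background(rng: np.random.Generator, n: int, gc: float = 0.40) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _mutate(seq: str, rng: np.random.Generator, identity: float) -> str:
    """Per-base substitution so the copy matches ``seq`` at ~identity%."""
    rate = 1.0 - identity / 100.0
    if rate <= 0:
        return seq
    chars = np.array(list(seq))
    mask = rng.random(len(chars)) < rate
    alphabet = np.array(list("ACGT"))
    for i in np.nonzero(mask)[0]:
        options = [b for b in "ACGT" if b != chars[i]]
        chars[i] = options[int(rng.integers(3))]
    return "".join(chars)


@dataclass
class PlantedFeature:
    name: str
    contig: str
    span: Tuple[int, int]
    strand: str = "+"
    family: str = ""


@dataclass
class GenomeTruth:
    """Ground-truth annotations for a planted genome."""

    category: str
    features: List[PlantedFeature] = field(default_factory=list)
    ir_families: Dict[str, List[Tuple[str, Tuple[int, int]]]] = field(
        default_factory=dict
    )
    collapsed_link: Optional[Tuple[str, List[str]]] = None

    def named(self, name: str) -> List[PlantedFeature]:
        return [f for f in self.features if f.name == name]


@dataclass
class PlantedGenomeSpec:
    """Parameters of a planted genome; defaults are the study conditions.

    ``ir_identity`` defaults to 97% (observed flip/flop IRs run 97-100%),
    ``ir_len`` to 2 kb (the repeatedly observed IR scale), ``locus_gap`` to
    5 kb for PHC (well under the 20-kb contiguity bound), the telomere unit
    to the 11-bp repeat seen at yeast chromosome ends, and the invertible
    span to 14 kb (a scaled-down flip/flop region).
    """

    category: str
    seed: int = 0
    ir_len: int = 2000
    ir_identity: float = 97.0
    inner_ir_len: int = 1500
    locus_gap: int = 5000
    invertible_span: int = 14000
    telomere_unit: str = "TTTTAGTAGGG"
    telomere_copies: int = 20
    plant_rdna: bool = False
    coverage_mean: float = 50.0
    coverage_noise: float = 2.0
    flank: int = 8000
    min_repeat_len: int = 200

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "PHC" and self.locus_gap >= 20000:
            raise ValueError("PHC requires locus_gap < 20000")
        if self.category in ("FF1", "FF2") and self.ir_len < self.min_repeat_len:
            raise ValueError(
                f"{self.category} requires ir_len >= min_repeat_len "
                f"({self.min_repeat_len})"
            )
        if self.category == "FF2" and self.inner_ir_len < self.min_repeat_len:
            raise ValueError("FF2 requires inner_ir_len >= min_repeat_len")


class _Builder:
    """Accumulates labelled segments into one contig."""

    def __init__(self, contig_id: str):
        self.id = contig_id
        self.parts: List[str] = []
        self.features: List[PlantedFeature] = []
        self.pos = 0

    def add(self, seq: str, name: Optional[str] = None, strand: str = "+",
            family: str = "") -> Tuple[int, int]:
        span = (self.pos, self.pos + len(seq))
        self.parts.append(seq)
        self.pos += len(seq)
        if name:
            self.features.append(
                PlantedFeature(name, self.id, span, strand, family)
            )
        return span

    def contig(self, coverage: Optional[float] = None) -> Contig:
        return Contig(id=self.id, seq="".join(self.parts), coverage=coverage)


def _cassette(b: _Builder, idio: str, rng: np.random.Generator) -> None:
    g1, g2 = (("MATa1", "MATa2") if idio == "a" else ("MATalpha1", "MATalpha2"))
    b.add(_gene_dna(g1), g1)
    b.add(_background(rng, 200))
    b.add(_gene_dna(g2), g2)


def generate_genome(spec: PlantedGenomeSpec) -> Tuple[Assembly, GenomeTruth]:
    """Build a seeded assembly realizing the spec's category.

    Identical spec+seed gives a byte-identical assembly and truth record.
    """
    rng = np.random.default_rng(spec.seed)
    truth = GenomeTruth(category=spec.category)
    builders: List[_Builder] = []

    def cov() -> float:
        return max(1.0, float(rng.normal(spec.coverage_mean, spec.coverage_noise)))

    cat = spec.category
    if cat == "NOMAT":
        b = _Builder("ctg0")
        b.add(_background(rng, spec.flank))
        b.add(_gene_dna("SLA2"), "SLA2")
        b.add(_background(rng, 2000))
        b.add(_gene_dna("DIC1"), "DIC1")
        b.add(_background(rng, spec.flank))
        builders.append(b)

    elif cat == "HET":
        idio = "a" if rng.random() < 0.5 else "alpha"
        b = _Builder("ctg0")
        b.add(_background(rng, spec.flank))
        b.add(_gene_dna("SLA2"), "SLA2")
        b.add(_background(rng, 300))
        _cassette(b, idio, rng)
        b.add(_background(rng, 300))
        b.add(_gene_dna("DIC1"), "DIC1")
        b.add(_background(rng, spec.flank))
        builders.append(b)

    elif cat == "PHC":
        b = _Builder("ctg0")
        b.add(_background(rng, spec.flank))
        b.add(_gene_dna("SLA2"), "SLA2")
        b.add(_background(rng, 300))
        _cassette(b, "a", rng)
        b.add(_background(rng, spec.locus_gap))
        _cassette(b, "alpha", rng)
        b.add(_background(rng, 300))
        b.add(_gene_dna("DIC1"), "DIC1")
        b.add(_background(rng, spec.flank))
        builders.append(b)

    elif cat == "PHN":
        b0 = _Builder("ctg0")
        b0.add(_background(rng, spec.flank))
        b0.add(_gene_dna("SLA2"), "SLA2")
        b0.add(_background(rng, 300))
        _cassette(b0, "alpha", rng)
        b0.add(_background(rng, 300))
        b0.add(_gene_dna("DIC1"), "DIC1")
        b0.add(_background(rng, spec.flank))
        builders.append(b0)
        b1 = _Builder("ctg1")
        if spec.plant_rdna:
            b1.add(_background(rng, 4000))
            b1.add(rdna_landmark() * 2, "rDNA")
            b1.add(_background(rng, 500))
            _cassette(b1, "a", rng)
            b1.add(_background(rng, spec.flank))
        else:
            b1.add(spec.telomere_unit * spec.telomere_copies, "telomere")
            b1.add(_background(rng, 2000))
            b1.add(_pseudogenize(_gene_dna("SLA2"), rng), "SLA2_pseudo")
            b1.add(_background(rng, 200))
            _cassette(b1, "a", rng)
            b1.add(_background(rng, spec.flank))
        builders.append(b1)

    elif cat == "FF1":
        b = _Builder("ctg0")
        ir = _background(rng, spec.ir_len)
        b.add(_background(rng, spec.flank))
        s1 = b.add(ir, "IR_copy1", family="IR")
        _cassette(b, "a", rng)
        b.add(_background(rng, spec.invertible_span))
        _cassette(b, "alpha", rng)
        s2 = b.add(
            _mutate(revcomp(ir), rng, spec.ir_identity), "IR_copy2", "-", "IR"
        )
        b.add(_background(rng, spec.flank))
        builders.append(b)
        truth.ir_families["IR"] = [(b.id, s1), (b.id, s2)]

    elif cat == "FF2":
        b = _Builder("ctg0")
        outer = _background(rng, spec.ir_len)
        inner = _background(rng, spec.inner_ir_len)
        b.add(_background(rng, spec.flank))
        o1 = b.add(outer, "IR_outer_copy1", family="IR_outer")
        _cassette(b, "a", rng)
        i1 = b.add(inner, "IR_inner_copy1", family="IR_inner")
        b.add(_background(rng, spec.invertible_span))
        i2 = b.add(
            _mutate(revcomp(inner), rng, spec.ir_identity),
            "IR_inner_copy2", "-", "IR_inner",
        )
        _cassette(b, "alpha", rng)
        o2 = b.add(
            _mutate(revcomp(outer), rng, spec.ir_identity),
            "IR_outer_copy2", "-", "IR_outer",
        )
        b.add(_background(rng, spec.flank))
        builders.append(b)
        truth.ir_families["IR_outer"] = [(b.id, o1), (b.id, o2)]
        truth.ir_families["IR_inner"] = [(b.id, i1), (b.id, i2)]

    elif cat == "3LOC":
        b = _Builder("ctg0")
        x_rep = _background(rng, 700)
        z_rep = _background(rng, 250)
        b.add(_background(rng, spec.flank))
        b.add(x_rep, "X_copy1", family="X")
        _cassette(b, "a", rng)  # active MAT
        b.add(z_rep, "Z_copy1", family="Z")
        b.add(_background(rng, 20000))
        b.add(_mutate(x_rep, rng, 99.0), "X_copy2", family="X")
        _cassette(b, "alpha", rng)  # HML-like silent cassette
        b.add(_mutate(z_rep, rng, 99.0), "Z_copy2", family="Z")
        b.add(_background(rng, 20000))
        b.add(_mutate(x_rep, rng, 99.0), "X_copy3", family="X")
        _cassette(b, "a", rng)  # HMR-like silent cassette
        b.add(_mutate(z_rep, rng, 99.0), "Z_copy3", family="Z")
        b.add(_background(rng, spec.flank))
        builders.append(b)

    else:
        raise ValueError(f"unhandled category {cat!r}")

    contigs = [b.contig(coverage=cov()) for b in builders]
    assembly = Assembly(species=f"planted_{cat}_{spec.seed}", contigs=contigs)
    for b in builders:
        truth.features.extend(b.features)
    return assembly, truth


def generate_het_diploid(
    seed: int = 0,
    flank_share: int = 1200,
    coverage_mean: float = 50.0,
    coverage_noise: float = 2.0,
) -> Tuple[Assembly, GenomeTruth]:
    """A diploid assembly of a heterothallic species: two contigs carrying
    the two idiomorphs of one locus, identical over both flanks."""
    rng = np.random.default_rng(seed)
    shared_left = _background(rng, flank_share)
    shared_right = _background(rng, flank_share)
    truth = GenomeTruth(category="HET")
    builders = []
    for idio, cid in (("a", "ctg0"), ("alpha", "ctg1")):
        b = _Builder(cid)
        b.add(shared_left, "shared_left_flank")
        _cassette(b, idio, rng)
        b.add(shared_right, "shared_right_flank")
        builders.append(b)
    contigs = [
        b.contig(coverage=max(1.0, float(rng.normal(coverage_mean, coverage_noise))))
        for b in builders
    ]
    for b in builders:
        truth.features.extend(b.features)
    return Assembly(species=f"planted_HETdip_{seed}", contigs=contigs), truth


# ---------------------------------------------------------------------------
# Assembler-collapse emulation
# ---------------------------------------------------------------------------


def emulate_assembler_collapse(
    assembly: Assembly,
    truth: GenomeTruth,
    k: int = 55,
    family: Optional[str] = None,
    seed: int = 0,
) -> Tuple[Assembly, GenomeTruth]:
    """Rebuild the assembly as a short-read assembler would when the two
    copies of one IR family co-assemble.

    The two planted IR copies are replaced by a single consensus contig at
    2x the baseline coverage; the contigs that flanked each copy end in
    exact k-base overlaps with it (the longest-k-mer signature), and the
    span between the copies is broken into two contigs so each cassette
    lands on its own contig. Assemblies without a planted IR are returned
    unchanged with a warning.
    """
    if not truth.ir_families:
        logger.warning("no planted IR family: assembly returned unchanged")
        return assembly, truth
    if family is None:
        family = "IR_inner" if "IR_inner" in truth.ir_families else (
            sorted(truth.ir_families)[0]
        )
    copies = truth.ir_families[family]
    if len(copies) != 2 or copies[0][0] != copies[1][0]:
        raise ValueError("collapse emulation needs two IR copies on one contig")
    contig_id = copies[0][0]
    (s1, e1), (s2, e2) = sorted([copies[0][1], copies[1][1]])
    source = assembly.get(contig_id)
    seq = source.seq
    rng = np.random.default_rng(seed)
    base = np.median(
        [c.coverage for c in assembly.contigs if c.coverage is not None]
    )
    rep = seq[s1:e1]  # consensus = first copy
    mid = seq[e1:s2]
    half = len(mid) // 2
    new_contigs = [
        Contig(f"{contig_id}_L", seq[:s1] + rep[:k], coverage=float(base)),
        Contig(f"{contig_id}_rep", rep, coverage=float(2 * base)),
        Contig(f"{contig_id}_M1", rep[-k:] + mid[:half], coverage=float(base)),
        Contig(
            f"{contig_id}_M2", mid[half:] + revcomp(rep[-k:]), coverage=float(base)
        ),
        Contig(f"{contig_id}_R", revcomp(rep[:k]) + seq[e2:], coverage=float(base)),
    ]
    contigs = [c for c in assembly.contigs if c.id != contig_id] + new_contigs
    collapsed = Assembly(species=assembly.species, contigs=contigs)
    new_truth = GenomeTruth(
        category=truth.category,
        features=[f for f in truth.features if f.contig != contig_id],
        ir_families={
            fam: c for fam, c in truth.ir_families.items() if fam != family
        },
        collapsed_link=(
            f"{contig_id}_rep",
            [f"{contig_id}_L", f"{contig_id}_M1", f"{contig_id}_M2", f"{contig_id}_R"],
        ),
    )
    return collapsed, new_truth


# ---------------------------------------------------------------------------
# History simulation
# ---------------------------------------------------------------------------


@dataclass
class PlantedHistory:
    tree: PhyloTree
    root_state: str
    events: List[Tuple[str, str, str]]  # (child node label, from, to)
    tip_states: Dict[str, str]
    seed: int
    parsimony_consistent: bool


def simulate_history(
    tree: PhyloTree,
    root_state: str,
    planted_events: Optional[Sequence[Tuple[str, str, str]]] = None,
    change_prob: Optional[float] = None,
    seed: int = 0,
    require_consistent: bool = True,
    max_attempts: int = 200,
) -> PlantedHistory:
    """Propagate a root state through planted (or sampled) branch events.

    Explicit events are ``(child_label, from_state, to_state)`` triples; with
    ``change_prob`` set, each branch instead mutates with that probability to
    a random different state. With ``require_consistent`` the planted change
    count must equal the parsimony minimum of the resulting tip states
    (sampled histories are rejection-sampled until it does; explicit
    homoplastic event lists raise).
    """
    if root_state not in STATES:
        raise ValueError(f"unknown root state {root_state!r}")
    labels = {PhyloTree.node_label(n) for n in tree.postorder()}
    rng = np.random.default_rng(seed)

    def apply_events(events) -> Dict[int, str]:
        node_state: Dict[int, str] = {}
        ev_by_child = {}
        for child, frm, to in events:
            if child not in labels:
                raise ValueError(f"event on nonexistent branch to {child!r}")
            ev_by_child[child] = (frm, to)
        for node in tree.preorder():
            if node is tree.root:
                node_state[node.index] = root_state
            else:
                parent_state = node_state[node.parent_node.index]
                label = PhyloTree.node_label(node)
                if label in ev_by_child:
                    frm, to = ev_by_child[label]
                    if frm != parent_state:
                        raise ValueError(
                            f"event on branch to {label!r} expects parent state "
                            f"{frm!r} but propagated state is {parent_state!r}"
                        )
                    node_state[node.index] = to
                else:
                    node_state[node.index] = parent_state
        return node_state

    if planted_events is not None:
        node_state = apply_events(planted_events)
        tips = {
            n.taxon.label: node_state[n.index]
            for n in tree.postorder()
            if n.is_leaf()
        }
        consistent = parsimony_minimum(tree, tips) == len(planted_events)
        if require_consistent and not consistent:
            raise ValueError(
                "planted events are homoplastic: change count exceeds the "
                "parsimony minimum of the resulting tip states"
            )
        return PlantedHistory(
            tree, root_state, list(planted_events), tips, seed, consistent
        )

    if change_prob is None:
        raise ValueError("provide planted_events or change_prob")
    for _ in range(max_attempts):
        events = []
        node_state: Dict[int, str] = {}
        for node in tree.preorder():
            if node is tree.root:
                node_state[node.index] = root_state
                continue
            parent_state = node_state[node.parent_node.index]
            if rng.random() < change_prob:
                options = [s for s in STATES if s != parent_state]
                to = options[int(rng.integers(len(options)))]
                events.append((PhyloTree.node_label(node), parent_state, to))
                node_state[node.index] = to
            else:
                node_state[node.index] = parent_state
        tips = {
            n.taxon.label: node_state[n.index]
            for n in tree.postorder()
            if n.is_leaf()
        }
        if not require_consistent or parsimony_minimum(tree, tips) == len(events):
            return PlantedHistory(
                tree, root_state, events, tips, seed,
                parsimony_consistent=True,
            )
    raise RuntimeError(
        f"no parsimony-consistent history sampled in {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# Curated clade fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = (
    "lipomyces",
    "ogataea",
    "saccharomycetaceae",
    "saturnispora",
    "switching_clades",
    "phn_clades",
    "full",
)


@dataclass
class CladeFixture:
    name: str
    tree: Optional[PhyloTree]
    states: Dict[str, str]
    provisional: frozenset
    table: Optional[pd.DataFrame] = None


def clade_fixture(name: str, full_tree: Optional[str] = None,
                  full_states: Optional[str] = None) -> CladeFixture:
    """Load a curated clade fixture by tag.

    ``phn_clades`` has no tree: it is a table of the PHN clades with the
    genomic context of the novel second MAT locus (telomere / rDNA /
    internal) and its inferred mechanism of origin. ``full`` (the complete
    332-species data set) must be supplied by the user as a Newick plus
    state-map TSV; it cannot be reconstructed from the bundled material.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(
            f"unknown fixture {name!r}; valid tags: {FIXTURE_NAMES}"
        )
    if name == "full":
        if full_tree is None or full_states is None:
            raise ValueError(
                "the 'full' 332-species fixture requires a user-supplied "
                "tree (Newick) and state map (TSV); pass full_tree= and "
                "full_states="
            )
        tree = parse_newick(open(full_tree).read())
        states = _read_fixture_tsv(open(full_states).read())[0]
        return CladeFixture(name, tree, states, frozenset())
    base = resources.files("matsys").joinpath("fixtures")
    if name == "phn_clades":
        import io

        table = pd.read_csv(
            io.StringIO(base.joinpath("phn_clades.tsv").read_text()),
            sep="\t", comment="#",
        )
        return CladeFixture(name, None, {}, frozenset(), table=table)
    tree = parse_newick(base.joinpath(f"{name}.nwk").read_text())
    states, provisional = _read_fixture_tsv(
        base.joinpath(f"{name}.tsv").read_text()
    )
    return CladeFixture(name, tree, states, frozenset(provisional))


def _read_fixture_tsv(text: str) -> Tuple[Dict[str, str], List[str]]:
    states: Dict[str, str] = {}
    provisional: List[str] = []
    header: Optional[List[str]] = None
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None and parts[0] == "species":
            header = parts
            continue
        states[parts[0]] = parts[1]
        if len(parts) > 2 and parts[2].strip().lower() == "true":
            provisional.append(parts[0])
    return validate_state_map(states), provisional


def uniform_clade_size(tree: PhyloTree, states: Dict[str, str], tip: str) -> int:
    """Size of the maximal clade containing ``tip`` whose tips all share
    ``tip``'s state (e.g., the extent of one flip/flop clade)."""
    target = states[tip]
    node = next(
        n for n in tree.postorder() if n.is_leaf() and n.taxon.label == tip
    )
    best = 1
    while node.parent_node is not None:
        parent = node.parent_node
        leaves = [l.taxon.label for l in parent.leaf_iter()]
        if all(states.get(l) == target for l in leaves):
            best = len(leaves)
            node = parent
        else:
            break
    return best
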