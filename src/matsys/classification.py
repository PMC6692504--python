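"""Seven-way mating-compatibility classification of one species' evidence.

Categories
----------
HET
    Heterothallic: only one idiomorph in the genome (haploid assembly), or
    both idiomorphs on allelic contigs (diploid assembly).
3LOC
    Three-locus secondary homothallism: an active MAT locus plus two or more
    silent cassettes, exchanged by copy-and-paste via direct X/Z repeats.
FF1 / FF2
    Flip/flop secondary homothallism: MATa and MATalpha loci at the two ends
    of an invertible chromosomal span, flanked by one (FF1) or two (FF2)
    sets of inverted repeats.
PHC / PHN
    Primary homothallism: both idiomorphs at non-allelic positions with no
    repeats near them, contiguous (gap < 20 kb) or non-contiguous.
NOMAT
    No intact canonical MAT gene anywhere in the assembly.

The rules are applied in a fixed order and every gate evaluated is recorded
in the call's evidence trail, so the automated decision is auditable the way
a manual curation would be.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import List, Optional, Sequence, Tuple

import yaml

from .locus_annotation import (
    AllelismEvidence,
    ContigLink,
    GeneCall,
    MatLocus,
    RepeatPair,
    flag_assembly_artifact,
)

CATEGORIES = ("HET", "3LOC", "FF1", "FF2", "PHC", "PHN", "NOMAT")


@dataclass
class ThresholdConfig:
    """All numeric gates of the pipeline in one serializable object.

    ``phc_max_gap`` is exactly 20,000 bp: primary homothallics with MATa and
    MATalpha genes closer than 20 kb are contiguous (PHC), farther apart or
    on different contigs non-contiguous (PHN). ``e_max`` keeps even very
    weak translated hits (E < 10), which diverged MAT genes require.
    """

    e_max: float = 10.0
    phc_max_gap: int = 20000
    region_join_window: int = 2000
    max_chain_gap: int = 1500
    intact_min_cover: float = 0.80
    max_locus_gap: int = 8000
    min_repeat_len: int = 200
    min_repeat_identity: float = 90.0
    repeat_window: int = 50000
    telomere_unit_min: int = 5
    telomere_unit_max: int = 30
    telomere_min_copies: int = 3
    telomere_end_window: int = 2000
    telomere_window: int = 20000
    rdna_window: int = 20000
    cov_lo: float = 1.6
    cov_hi: float = 2.6
    k: int = 55
    artifact_min_len: int = 50000
    artifact_max_mismatch: int = 3
    flank_len: int = 500
    allelism_min_identity: float = 95.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ValueError(f"threshold {name} must be positive, got {value}")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "ThresholdConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class MatingSystemCall:
    """The 7-way call for one species with its decision trail."""

    category: str
    ploidy_note: str = "unknown"  # 'haploid', 'diploid' or 'unknown'
    provisional: bool = False
    evidence: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


class NotSearchedError(RuntimeError):
    """Raised when a species is classified without having been searched."""


#: A MAT-gene fragment must align this much of its query to count as a
#: silent-cassette remnant; chance alignments retained by the permissive
#: E-value threshold stay below it.
_SILENT_FRAG_MIN_COVER = 0.4


def _repeat_families(pairs: Sequence[RepeatPair]) -> List[List[RepeatPair]]:
    """Group repeat pairs into families by copy overlap (same physical
    repeat found more than once)."""
    families: List[List[RepeatPair]] = []
    for p in pairs:
        placed = False
        for fam in families:
            if any(_pairs_share_copy(p, q) for q in fam):
                fam.append(p)
                placed = True
                break
        if not placed:
            families.append([p])
    return families


def _pairs_share_copy(p: RepeatPair, q: RepeatPair) -> bool:
    for a in (p.copy_a, p.copy_b):
        for b in (q.copy_a, q.copy_b):
            if a[0] == b[0]:
                ov = min(a[1][1], b[1][1]) - max(a[1][0], b[1][0])
                if ov > 0 and ov >= 0.5 * min(a[1][1] - a[1][0], b[1][1] - b[1][0]):
                    return True
    return False


def _unoriented_cross_families(
    repeats: Sequence[RepeatPair],
    loci: Sequence[MatLocus],
    fragment_calls: Sequence[GeneCall],
) -> List[List[RepeatPair]]:
    """Repeat families of undetermined orientation that still argue for a
    switching mechanism: same-strand pairs whose two copies sit on two
    different locus-bearing contigs (relative orientation is unknowable
    across a contig break). Families built from a degraded pseudogene copy
    are excluded — a decayed duplicate is evidence of an old introgression,
    not of a functional repeat, and those species are primary homothallics."""
    locus_contigs = {l.contig for l in loci}
    if len(locus_contigs) < 2:
        return []
    pseudo = [
        (c.contig, c.span) for c in fragment_calls if c.status == "pseudogene"
    ]

    def touches_pseudo(copy) -> bool:
        contig, span = copy
        return any(
            contig == pc and min(span[1], ps[1]) - max(span[0], ps[0]) > 0
            for pc, ps in pseudo
        )

    cands = [
        p
        for p in repeats
        if p.role == "XZ_like"
        and p.copy_a[0] != p.copy_b[0]
        and p.copy_a[0] in locus_contigs
        and p.copy_b[0] in locus_contigs
        and not (touches_pseudo(p.copy_a) or touches_pseudo(p.copy_b))
    ]
    return _repeat_families(cands)


def _qualifying_links(
    links: Sequence[ContigLink], loci: Sequence[MatLocus]
) -> List[ContigLink]:
    """Links whose collapsed repeat contig joins contigs that carry MAT
    loci — the coverage signature of an IR that the assembler merged."""
    locus_contigs = {l.contig for l in loci}
    out = []
    for link in links:
        touching = locus_contigs & set(link.neighbor_contigs)
        if len(touching) >= 1 and len(link.neighbor_contigs) >= 2:
            out.append(link)
    return out


def _min_idiomorph_gap(loci: Sequence[MatLocus]) -> Optional[Tuple[str, int]]:
    """Minimum gap between an a-side element and an alpha-side element,
    restricted to elements on the same contig. Returns (contig, gap) or
    None when the idiomorphs never share a contig."""
    a_elems: List[Tuple[str, Tuple[int, int]]] = []
    alpha_elems: List[Tuple[str, Tuple[int, int]]] = []
    for locus in loci:
        for g in locus.genes:
            if g.gene in ("MATa1", "MATa2"):
                a_elems.append((locus.contig, g.span))
            else:
                alpha_elems.append((locus.contig, g.span))
    best: Optional[Tuple[str, int]] = None
    for ca, sa in a_elems:
        for cb, sb in alpha_elems:
            if ca != cb:
                continue
            gap = max(0, max(sa[0], sb[0]) - min(sa[1], sb[1]))
            if best is None or gap < best[1]:
                best = (ca, gap)
    return best


def _count_extra_cassettes(
    fragment_calls: Sequence[GeneCall],
    loci: Sequence[MatLocus],
    repeats: Sequence[RepeatPair],
    links: Sequence[ContigLink],
    join: int,
) -> int:
    """Silent cassettes that exist only as repeat-associated fragments:
    substantial MAT-gene fragments away from every intact locus that sit
    beside X/Z-like repeat copies or inside a collapsed 2x repeat contig
    (collapsed repeats often contain duplicated parts of MAT genes). Weak
    low-coverage fragments — expected everywhere under the permissive E
    threshold — do not count."""
    from .homology_search import MAT_CORE_GENES

    mat_frags = [
        c
        for c in fragment_calls
        if c.status != "intact"
        and c.gene in MAT_CORE_GENES
        and c.query_cover >= _SILENT_FRAG_MIN_COVER
    ]
    link_contigs = {link.repeat_contig for link in links}
    xz_copies = [
        copy
        for p in repeats
        if p.role == "XZ_like"
        for copy in (p.copy_a, p.copy_b)
    ]
    count = 0
    used: List[Tuple[str, Tuple[int, int]]] = []
    for frag in sorted(mat_frags, key=lambda c: (c.contig, c.span[0])):
        if any(
            l.contig == frag.contig
            and min(l.span[1], frag.span[1]) - max(l.span[0], frag.span[0]) > 0
            for l in loci
        ):
            continue
        if any(
            c == frag.contig
            and min(s[1], frag.span[1]) - max(s[0], frag.span[0]) > -join
            for c, s in used
        ):
            continue
        near_xz = any(
            c == frag.contig
            and max(0, max(s[0], frag.span[0]) - min(s[1], frag.span[1])) <= join
            for c, s in xz_copies
        )
        if near_xz or frag.contig in link_contigs:
            count += 1
            used.append((frag.contig, frag.span))
    return count


def classify_species(
    loci: Sequence[MatLocus],
    repeats: Sequence[RepeatPair],
    allelism: Sequence[AllelismEvidence],
    links: Sequence[ContigLink],
    cfg: Optional[ThresholdConfig] = None,
    fragment_calls: Sequence[GeneCall] = (),
    searched: bool = True,
) -> MatingSystemCall:
    """Apply the decision rules in fixed order; the first match decides.

    1. no intact MAT gene anywhere -> NOMAT;
    2. a single idiomorph -> HET (haploid);
    3. both idiomorphs, every opposite-idiomorph locus pair allelic -> HET
       (diploid assembly of one locus);
    4. three or more non-allelic cassettes (counting repeat-linked silent
       fragment cassettes) -> 3LOC;
    5. both idiomorphs non-allelic with inverted-repeat evidence: one IR
       family -> FF1, two or more -> FF2 (provisional when the loci sit on
       unlinked contigs so the repeat orientation is undetermined;
       artifact-flagged IRs still count as IR evidence but force
       provisional);
    6. no qualifying repeats: same-contig gap below ``phc_max_gap`` -> PHC,
       otherwise -> PHN. Repeats trump distance: a repeat-linked pair of
       loci is never called PHC/PHN.
    """
    cfg = cfg or ThresholdConfig()
    evidence: List[str] = []

    if not searched and not loci:
        raise NotSearchedError("species not searched: cannot distinguish NOMAT")

    # Rule 1: NOMAT
    if not loci:
        evidence.append("rule1:no_intact_mat_genes")
        return MatingSystemCall("NOMAT", "unknown", False, evidence)
    evidence.append(f"rule1:loci={len(loci)}")

    has_a = any(l.has_a for l in loci)
    has_alpha = any(l.has_alpha for l in loci)

    # Rule 2: single idiomorph
    if not (has_a and has_alpha):
        idio = "a" if has_a else "alpha"
        evidence.append(f"rule2:single_idiomorph={idio}")
        return MatingSystemCall("HET", "haploid", False, evidence)
    evidence.append("rule2:both_idiomorphs")

    # Rule 3: diploid heterothallic (allelic contigs)
    verdicts = {}
    for ev in allelism:
        key = _locus_pair_key(ev.locus_a, ev.locus_b)
        verdicts[key] = ev.verdict
    opposite_pairs = [
        (la, lb)
        for i, la in enumerate(loci)
        for lb in loci[i + 1 :]
        if la.idiomorph != lb.idiomorph
        and "both" not in (la.idiomorph, lb.idiomorph)
    ]
    if opposite_pairs and not any(l.idiomorph == "both" for l in loci):
        pair_verdicts = [
            verdicts.get(_locus_pair_key(a, b), "non_allelic")
            for a, b in opposite_pairs
        ]
        if all(v == "allelic" for v in pair_verdicts):
            evidence.append(f"rule3:all_{len(opposite_pairs)}_pairs_allelic")
            return MatingSystemCall("HET", "diploid", False, evidence)
        evidence.append(f"rule3:verdicts={','.join(sorted(set(pair_verdicts)))}")

    # Rule 4: three or more cassettes
    extra = _count_extra_cassettes(
        fragment_calls, loci, repeats, links, cfg.region_join_window
    )
    n_cassettes = len(loci) + extra
    evidence.append(f"rule4:cassettes={n_cassettes}(intact={len(loci)},silent_frag={extra})")
    if n_cassettes >= 3:
        return MatingSystemCall("3LOC", "unknown", False, evidence)

    # Rule 5: inverted-repeat (flip/flop) evidence
    ir_pairs = [p for p in repeats if p.role == "IR"]
    ir_families = _repeat_families(ir_pairs)
    good_links = _qualifying_links(links, loci)
    unoriented = _unoriented_cross_families(repeats, loci, fragment_calls)
    n_families = len(ir_families) + len(good_links) + len(unoriented)
    artifact = any(
        flag_assembly_artifact(p, cfg.artifact_min_len, cfg.artifact_max_mismatch)
        for p in ir_pairs
    )
    cross_contig = len({l.contig for l in loci}) > 1
    same_contig_ir = any(
        p.copy_a[0] == p.copy_b[0] for fam in ir_families for p in fam
    )
    evidence.append(
        f"rule5:ir_families={len(ir_families)},collapsed_links={len(good_links)},"
        f"unoriented_families={len(unoriented)},artifact={str(artifact).lower()}"
    )
    if n_families >= 1:
        provisional = bool(
            artifact or unoriented or (cross_contig and not same_contig_ir)
        )
        category = "FF1" if n_families == 1 else "FF2"
        return MatingSystemCall(category, "unknown", provisional, evidence)

    # Rule 6: primary homothallism, contiguous or not
    best = _min_idiomorph_gap(loci)
    if best is not None and best[1] < cfg.phc_max_gap:
        evidence.append(f"rule6:gap={best[1]}<phc_max_gap={cfg.phc_max_gap}")
        return MatingSystemCall("PHC", "unknown", False, evidence)
    gap_txt = "different_contigs" if best is None else f"gap={best[1]}"
    evidence.append(f"rule6:{gap_txt}>=phc_max_gap={cfg.phc_max_gap}")
    return MatingSystemCall("PHN", "unknown", False, evidence)


def _locus_pair_key(a: MatLocus, b: MatLocus):
    ka = (a.contig, a.span)
    kb = (b.contig, b.span)
    return (min(ka, kb), max(ka, kb))
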