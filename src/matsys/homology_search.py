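"""Translated homology search of MAT and landmark proteins against assemblies.

This is a TBLASTN-style search: every contig is translated in six frames
(honouring the CUG-Ser and CUG-Ala alternative nuclear codes of the relevant
yeast clades), protein queries are matched by exact amino-acid seeding and
extended with Smith-Waterman local alignment, and hits are assigned
Karlin-Altschul E-values so that the permissive E < 10 retention rule used
for highly diverged MAT genes is meaningful. Genomic regions hit by more
than one distinct MAT protein are grouped into candidate MAT regions.

MAT idiomorph proteins diverge quickly, so searches are expected to be run
with several query sequences per gene symbol (distinguished by a source
suffix); the bundled toy query set is a stand-in for testing, and real
analyses should supply their own.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .genome_io import Assembly, revcomp

logger = logging.getLogger(__name__)

GENETIC_CODES = ("standard", "cug_ser", "cug_ala")

#: Gene symbols that identify a MAT idiomorph.
MAT_CORE_GENES = ("MATa1", "MATa2", "MATalpha1", "MATalpha2")

STOP = "*"

# Standard nuclear code; CUG-Ser and CUG-Ala clades reassign the CTG codon.
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
_STANDARD_TABLE: Dict[str, str] = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def codon_table(code: str) -> Dict[str, str]:
    if code not in GENETIC_CODES:
        raise ValueError(f"unknown genetic code {code!r}; valid: {GENETIC_CODES}")
    table = dict(_STANDARD_TABLE)
    if code == "cug_ser":
        table["CTG"] = "S"
    elif code == "cug_ala":
        table["CTG"] = "A"
    return table


@dataclass(frozen=True)
class FrameTranslation:
    """One reading frame of a contig with an exact residue->genome map."""

    strand: str  # '+' or '-'
    frame: int  # 0, 1 or 2
    peptide: str
    seq_len: int  # length of the source contig

    def residue_span(self, start: int, end: int) -> Tuple[int, int]:
        """Genomic span (0-based half-open, forward strand) of peptide
        residues [start, end)."""
        if self.strand == "+":
            return (self.frame + 3 * start, self.frame + 3 * end)
        # residues count along the reverse complement
        hi = self.seq_len - (self.frame + 3 * start)
        lo = self.seq_len - (self.frame + 3 * end)
        return (lo, hi)


def translate_frame(seq: str, table: Mapping[str, str]) -> str:
    out = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append(table.get(codon, "X"))  # codons containing N -> X
    return "".join(out)


def six_frame_translate(seq: str, code: str = "standard") -> List[FrameTranslation]:
    """Translate all six frames; stop codons become the sentinel ``*``.

    Frames +0/+1/+2 run along the forward strand, -0/-1/-2 along the reverse
    complement. The returned coordinate maps invert exactly to genomic spans.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    table = codon_table(code)
    frames: List[FrameTranslation] = []
    rc = revcomp(seq)
    for frame in range(3):
        frames.append(
            FrameTranslation("+", frame, translate_frame(seq[frame:], table), len(seq))
        )
    for frame in range(3):
        frames.append(
            FrameTranslation("-", frame, translate_frame(rc[frame:], table), len(seq))
        )
    return frames


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinQuery:
    """An amino-acid query with gene symbol and role family.

    ``family`` is one of ``mat_core`` (a1/a2/alpha1/alpha2), ``neighbor``
    (SLA2, DIC1, APN2 and friends) or ``landmark``. Several queries may share
    a gene symbol, distinguished by ``source``.
    """

    name: str
    family: str
    seq: str
    source: str = "default"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty query sequence for {self.name}")

    @property
    def qid(self) -> str:
        return f"{self.name}|{self.family}|{self.source}"


def read_queries(path: str) -> List[ProteinQuery]:
    """Read queries from FASTA with ``name|family|source`` headers."""
    out: List[ProteinQuery] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        name = parts[0]
        family = parts[1] if len(parts) > 1 else "mat_core"
        source = parts[2] if len(parts) > 2 else "default"
        out.append(ProteinQuery(name=name, family=family, seq=str(rec.seq), source=source))
    if not out:
        raise ValueError(f"no queries in {path}")
    return out


# ---------------------------------------------------------------------------
# Local alignment (Smith-Waterman via Biopython's C PairwiseAligner)
# ---------------------------------------------------------------------------

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _make_aligner(matrix, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # BLAST convention: a gap of length g costs open + g * extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align(
    q: str,
    t: str,
    matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> Tuple[float, Tuple[int, int], Tuple[int, int], int]:
    """Optimal Smith-Waterman local alignment of two peptides.

    Returns ``(raw_score, q_span, t_span, n_identities)``; the empty
    alignment scores 0 with empty spans.
    """
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    if not q or not t:
        return 0.0, (0, 0), (0, 0), 0
    matrix = _BLOSUM62 if matrix is None else matrix
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    score = aligner.score(q, t)
    if score <= 0:
        return 0.0, (0, 0), (0, 0), 0
    aln = aligner.align(q, t)[0]
    q_blocks, t_blocks = aln.aligned
    q_span = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    t_span = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    ident = 0
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        ident += sum(1 for a, b in zip(q[qs:qe], t[ts:te]) if a == b)
    return float(score), q_span, t_span, ident


def estimate_evalue(
    raw_score: float,
    m: int,
    n: int,
    K: float = 0.041,
    lam: float = 0.267,
) -> float:
    """Karlin-Altschul expected number of hits at or above ``raw_score``.

    ``E = K * m * n * exp(-lambda * S)`` with query length ``m`` and search
    space ``n``; strictly decreasing in the score and linear in both sizes.
    The default constants mirror common gapped BLOSUM62 search parameters.
    """
    if m <= 0 or n <= 0:
        raise ValueError("search-space dimensions must be positive")
    return K * m * n * math.exp(-lam * raw_score)


def bit_score(raw_score: float, K: float = 0.041, lam: float = 0.267) -> float:
    return (lam * raw_score - math.log(K)) / math.log(2.0)


# ---------------------------------------------------------------------------
# Hits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranslatedHit:
    """One local alignment of a protein query to a genomic region."""

    query: str  # gene symbol
    qid: str  # full query id (symbol|family|source)
    family: str
    contig: str
    span: Tuple[int, int]  # genomic, 0-based half-open, forward strand
    strand: str
    frame: int
    raw_score: float
    bit_score: float
    e_value: float
    query_cover: float
    q_span: Tuple[int, int]
    query_len: int
    n_internal_stops: int
    n_identities: int = 0


@dataclass
class CandidateRegion:
    """A genomic region hit by one or more distinct MAT core proteins."""

    contig: str
    span: Tuple[int, int]
    mat_queries: frozenset
    hits: List[TranslatedHit] = field(default_factory=list)

    @property
    def n_distinct_mat(self) -> int:
        return len(self.mat_queries)


_SEED_K = 4


def _seed_index(peptide: str, k: int = _SEED_K) -> Dict[str, List[int]]:
    index: Dict[str, List[int]] = defaultdict(list)
    for i in range(len(peptide) - k + 1):
        word = peptide[i : i + k]
        if STOP in word or "X" in word:
            continue
        index[word].append(i)
    return index


def _cluster_seeds(
    seeds: List[Tuple[int, int]], qlen: int, band: int = 16
) -> List[Tuple[int, int]]:
    """Group (qpos, tpos) seeds into target windows.

    Seeds are grouped when their diagonals agree within ``band`` residues and
    their target positions are within one query length; each group yields a
    target window padded by the query length.
    """
    if not seeds:
        return []
    seeds = sorted(seeds, key=lambda s: (s[1] - s[0], s[1]))
    windows: List[Tuple[int, int]] = []
    cur: List[Tuple[int, int]] = [seeds[0]]
    for s in seeds[1:]:
        d_prev = cur[-1][1] - cur[-1][0]
        d = s[1] - s[0]
        if abs(d - d_prev) <= band and s[1] - cur[-1][1] <= 2 * qlen:
            cur.append(s)
        else:
            windows.append((cur[0][1], cur[-1][1]))
            cur = [s]
    windows.append((cur[0][1], cur[-1][1]))
    # pad and merge overlapping windows
    padded = sorted((max(0, a - qlen - 8), b + qlen + 8) for a, b in windows)
    merged = [padded[0]]
    for a, b in padded[1:]:
        if a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def search_mat_genes(
    assembly: Assembly,
    queries: Sequence[ProteinQuery],
    code: str = "standard",
    e_max: float = 10.0,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    K: float = 0.041,
    lam: float = 0.267,
    region_join_window: int = 2000,
) -> Tuple[List[TranslatedHit], List[CandidateRegion]]:
    """Search every query against every contig in six frames.

    All hits with ``e_value < e_max`` are retained (the deliberately
    permissive default keeps very weak hits from diverged MAT genes).
    Overlapping or nearby hits from distinct MAT core queries within
    ``region_join_window`` are grouped into candidate regions. Output
    ordering is deterministic: (contig, start, query).
    """
    if not assembly.contigs:
        raise ValueError("empty assembly")
    if not queries:
        raise ValueError("empty query set")
    if code not in GENETIC_CODES:
        raise ValueError(f"unknown genetic code {code!r}")

    search_space = 6 * assembly.total_length
    hits: List[TranslatedHit] = []
    for contig in assembly.contigs:
        if contig.length < 3:
            continue
        frames = six_frame_translate(contig.seq, code)
        indexes = [_seed_index(fr.peptide) for fr in frames]
        for query in queries:
            qlen = len(query.seq)
            for fr, index in zip(frames, indexes):
                seeds: List[Tuple[int, int]] = []
                for qpos in range(qlen - _SEED_K + 1):
                    word = query.seq[qpos : qpos + _SEED_K]
                    for tpos in index.get(word, ()):
                        seeds.append((qpos, tpos))
                for w_start, w_end in _cluster_seeds(seeds, qlen):
                    window = fr.peptide[w_start:w_end]
                    score, q_span, t_span, ident = local_align(
                        query.seq, window, gap_open=gap_open, gap_extend=gap_extend
                    )
                    if score <= 0:
                        continue
                    e = estimate_evalue(score, qlen, search_space, K=K, lam=lam)
                    if e >= e_max:
                        continue
                    t_lo = w_start + t_span[0]
                    t_hi = w_start + t_span[1]
                    span = fr.residue_span(t_lo, t_hi)
                    stops = fr.peptide[t_lo:t_hi].count(STOP)
                    hits.append(
                        TranslatedHit(
                            query=query.name,
                            qid=query.qid,
                            family=query.family,
                            contig=contig.id,
                            span=span,
                            strand=fr.strand,
                            frame=fr.frame,
                            raw_score=score,
                            bit_score=bit_score(score, K=K, lam=lam),
                            e_value=e,
                            query_cover=(q_span[1] - q_span[0]) / qlen,
                            q_span=q_span,
                            query_len=qlen,
                            n_internal_stops=stops,
                            n_identities=ident,
                        )
                    )
    hits = _dedupe_hits(hits)
    hits.sort(key=lambda h: (h.contig, h.span[0], h.query, h.qid))
    regions = _candidate_regions(hits, region_join_window)
    return hits, regions


def _dedupe_hits(hits: List[TranslatedHit]) -> List[TranslatedHit]:
    """Collapse overlapping hits of the same query on the same contig/strand,
    keeping the highest-scoring one."""
    by_key: Dict[Tuple[str, str, str], List[TranslatedHit]] = defaultdict(list)
    for h in hits:
        by_key[(h.qid, h.contig, h.strand)].append(h)
    out: List[TranslatedHit] = []
    for group in by_key.values():
        group.sort(key=lambda h: -h.raw_score)
        kept: List[TranslatedHit] = []
        for h in group:
            if any(
                min(h.span[1], k.span[1]) - max(h.span[0], k.span[0]) > 0
                for k in kept
            ):
                continue
            kept.append(h)
        out.extend(kept)
    return out


def _candidate_regions(
    hits: Sequence[TranslatedHit], join_window: int
) -> List[CandidateRegion]:
    mat_hits = [h for h in hits if h.family == "mat_core"]
    by_contig: Dict[str, List[TranslatedHit]] = defaultdict(list)
    for h in mat_hits:
        by_contig[h.contig].append(h)
    regions: List[CandidateRegion] = []
    for contig in sorted(by_contig):
        chits = sorted(by_contig[contig], key=lambda h: h.span[0])
        cur: List[TranslatedHit] = [chits[0]]
        for h in chits[1:]:
            if h.span[0] - max(x.span[1] for x in cur) <= join_window:
                cur.append(h)
            else:
                regions.append(_make_region(contig, cur))
                cur = [h]
        regions.append(_make_region(contig, cur))
    return regions


def _make_region(contig: str, hits: List[TranslatedHit]) -> CandidateRegion:
    return CandidateRegion(
        contig=contig,
        span=(min(h.span[0] for h in hits), max(h.span[1] for h in hits)),
        mat_queries=frozenset(h.query for h in hits),
        hits=list(hits),
    )


# ---------------------------------------------------------------------------
# Chaining (frameshift / intron tolerance)
# ---------------------------------------------------------------------------


@dataclass
class HitChain:
    """Hits of one query on one contig and strand, chained across short
    genomic gaps before intact/fragment judgement."""

    query: str
    qid: str
    family: str
    contig: str
    strand: str
    span: Tuple[int, int]
    hits: List[TranslatedHit]
    query_cover: float
    n_internal_stops: int
    best_bit_score: float
    min_e_value: float


def chain_hits(hits: Sequence[TranslatedHit], max_chain_gap: int = 1500) -> List[HitChain]:
    """Chain hits of the same query/contig/strand whose genomic gap does not
    exceed ``max_chain_gap``; query coverage is the union of aligned query
    intervals, so split HSPs (introns, frameshifts) are reassembled."""
    by_key: Dict[Tuple[str, str, str], List[TranslatedHit]] = defaultdict(list)
    for h in hits:
        by_key[(h.qid, h.contig, h.strand)].append(h)
    chains: List[HitChain] = []
    for (qid, contig, strand), group in sorted(by_key.items()):
        group.sort(key=lambda h: h.span[0])
        cur: List[TranslatedHit] = [group[0]]
        for h in group[1:]:
            if h.span[0] - max(x.span[1] for x in cur) <= max_chain_gap:
                cur.append(h)
            else:
                chains.append(_make_chain(cur))
                cur = [h]
        chains.append(_make_chain(cur))
    chains.sort(key=lambda c: (c.contig, c.span[0], c.query))
    return chains


def _merge_intervals(ivs: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    ivs = sorted(ivs)
    out = [ivs[0]]
    for a, b in ivs[1:]:
        if a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _make_chain(hits: List[TranslatedHit]) -> HitChain:
    h0 = hits[0]
    covered = _merge_intervals([h.q_span for h in hits])
    cover = sum(b - a for a, b in covered) / h0.query_len
    return HitChain(
        query=h0.query,
        qid=h0.qid,
        family=h0.family,
        contig=h0.contig,
        strand=h0.strand,
        span=(min(h.span[0] for h in hits), max(h.span[1] for h in hits)),
        hits=list(hits),
        query_cover=min(1.0, cover),
        n_internal_stops=sum(h.n_internal_stops for h in hits),
        best_bit_score=max(h.bit_score for h in hits),
        min_e_value=min(h.e_value for h in hits),
    )
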