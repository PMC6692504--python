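"""Six-frame translation, local alignment, E-values and the MAT search."""

import math

import numpy as np
import pytest

from matsys.genome_io import Assembly, Contig, revcomp
from matsys.homology_search import (
    ProteinQuery,
    chain_hits,
    estimate_evalue,
    local_align,
    search_mat_genes,
    six_frame_translate,
)
from matsys.synthetic_data import PlantedGenomeSpec, generate_genome


def test_translation_standard_code():
    frames = six_frame_translate("ATGGCC", "standard")
    fwd0 = next(f for f in frames if f.strand == "+" and f.frame == 0)
    assert fwd0.peptide == "MA"


@pytest.mark.parametrize(
    "code, expected", [("standard", "L"), ("cug_ser", "S"), ("cug_ala", "A")]
)
def test_ctg_codon_by_clade_code(code, expected):
    fwd0 = next(
        f
        for f in six_frame_translate("CTG", code)
        if f.strand == "+" and f.frame == 0
    )
    assert fwd0.peptide == expected


def test_translation_too_short():
    with pytest.raises(ValueError):
        six_frame_translate("AT")


def test_coordinate_map_example():
    frames = six_frame_translate("AATGGCC")
    fwd1 = next(f for f in frames if f.strand == "+" and f.frame == 1)
    assert fwd1.residue_span(0, 1) == (1, 4)
    assert fwd1.peptide[0] == "M"


def test_coordinate_maps_invert_exactly():
    """Every residue's genomic span re-translates to that residue, on both
    strands (coordinate-map consistency)."""
    rng = np.random.default_rng(7)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
    table_frames = six_frame_translate(seq)
    for fr in table_frames:
        for i in range(0, len(fr.peptide), 17):
            lo, hi = fr.residue_span(i, i + 1)
            codon = seq[lo:hi]
            if fr.strand == "-":
                codon = revcomp(codon)
            sub = next(
                f
                for f in six_frame_translate(codon)
                if f.strand == "+" and f.frame == 0
            )
            assert sub.peptide == fr.peptide[i]


def test_local_align_identity_score():
    # BLOSUM62 diagonal: M=5, K=5, W=11, V=4
    score, q_span, t_span, ident = local_align("MKWV", "MKWV")
    assert score == 25
    assert q_span == (0, 4) and t_span == (0, 4) and ident == 4


def test_local_align_empty_and_symmetry():
    assert local_align("MKWV", "")[0] == 0
    a = local_align("MKWVADE", "MKAVWDE")[0]
    b = local_align("MKAVWDE", "MKWVADE")[0]
    assert a == b  # symmetric matrix => symmetric optimal score


def test_evalue_formula_and_monotonicity():
    e = estimate_evalue(50, 100, 10**6)
    assert e == pytest.approx(0.041 * 100 * 1e6 * math.exp(-0.267 * 50))
    assert e == pytest.approx(6.5, abs=0.1)
    assert estimate_evalue(60, 100, 10**6) < e
    assert estimate_evalue(50, 100, 2 * 10**6) == pytest.approx(2 * e)
    with pytest.raises(ValueError):
        estimate_evalue(50, 0, 10)


def _planted_assembly(seed=0):
    asm, truth = generate_genome(PlantedGenomeSpec(category="PHC", seed=seed))
    return asm, truth


def test_search_finds_planted_genes_with_high_cover(queries):
    asm, truth = _planted_assembly()
    hits, regions = search_mat_genes(asm, queries)
    for gene in ("MATa1", "MATa2", "MATalpha1", "MATalpha2", "SLA2", "DIC1"):
        planted = truth.named(gene)[0]
        matching = [
            h
            for h in hits
            if h.query == gene
            and min(h.span[1], planted.span[1]) - max(h.span[0], planted.span[0]) > 0
        ]
        assert matching, f"planted {gene} not hit"
        assert max(h.query_cover for h in matching) >= 0.9


def test_candidate_regions_group_distinct_mat_queries(queries):
    asm, _ = _planted_assembly()
    _, regions = search_mat_genes(asm, queries)
    multi = [r for r in regions if r.n_distinct_mat >= 2]
    assert multi, "expected a region hit by more than one MAT protein"


def test_evalue_threshold_gate_is_strict(queries):
    """Raising or lowering e_max through an observed hit's E-value retains
    or drops exactly the hits below the bound."""
    asm, _ = _planted_assembly()
    loose, _ = search_mat_genes(asm, queries, e_max=10.0)
    assert loose
    cut = sorted(h.e_value for h in loose)[len(loose) // 2]
    strict, _ = search_mat_genes(asm, queries, e_max=cut)
    assert {(h.qid, h.span) for h in strict} == {
        (h.qid, h.span) for h in loose if h.e_value < cut
    }
    assert len(strict) < len(loose)


def test_search_invariant_under_contig_reordering(queries):
    asm, _ = generate_genome(PlantedGenomeSpec(category="PHN", seed=3))
    hits_fwd, _ = search_mat_genes(asm, queries)
    rev = Assembly(asm.species, list(reversed(asm.contigs)))
    hits_rev, _ = search_mat_genes(rev, queries)
    key = lambda h: (h.qid, h.contig, h.span, h.strand)
    assert sorted(map(key, hits_fwd)) == sorted(map(key, hits_rev))


def test_no_similarity_gives_empty_results():
    asm = Assembly("sp", [Contig("c", "ACGT" * 300)])
    q = [ProteinQuery("MATa1", "mat_core", "WWWWWWWCCCCCWWWWW")]
    hits, regions = search_mat_genes(asm, q)
    assert hits == [] and regions == []


def test_chaining_reassembles_split_hits(queries):
    """Two HSPs of one query separated by a short genomic gap merge into a
    chain whose coverage is the union of the query intervals."""
    q = next(q for q in queries if q.name == "MATa1")
    from matsys.synthetic_data import reverse_translate

    dna = reverse_translate(q.seq)
    half = (len(q.seq) // 2) * 3
    contig = Contig("c", "AGC" * 400 + dna[:half] + "ACGT" * 100 + dna[half:] + "AGC" * 400)
    asm = Assembly("sp", [contig])
    hits, _ = search_mat_genes(asm, [q])
    chains = chain_hits(hits, max_chain_gap=1500)
    best = max(chains, key=lambda c: c.query_cover)
    assert best.query_cover >= 0.9
    assert len(best.hits) >= 2
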