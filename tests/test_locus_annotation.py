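"""Gene calling, locus assembly, repeats, telomeres, allelism, coverage links."""

import numpy as np
import pytest

from matsys.genome_io import Assembly, Contig, revcomp
from matsys.homology_search import TranslatedHit
from matsys.locus_annotation import (
    RepeatPair,
    assemble_mat_loci,
    assign_repeat_roles,
    call_genes,
    detect_allelism,
    detect_telomere,
    find_flanking_repeats,
    flag_assembly_artifact,
    infer_collapsed_repeats,
)
from matsys.pipeline import annotate_assembly
from matsys.synthetic_data import (
    PlantedGenomeSpec,
    emulate_assembler_collapse,
    generate_genome,
)


def _hit(query="MATa1", span=(100, 400), cover=1.0, stops=0, strand="+",
         contig="c", q_span=None, qlen=100):
    if q_span is None:
        q_span = (0, int(cover * qlen))
    return TranslatedHit(
        query=query, qid=f"{query}|mat_core|toy", family="mat_core",
        contig=contig, span=span, strand=strand, frame=0, raw_score=500,
        bit_score=190.0, e_value=1e-40, query_cover=cover, q_span=q_span,
        query_len=qlen, n_internal_stops=stops,
    )


@pytest.mark.parametrize(
    "cover, stops, expected",
    [
        (0.95, 0, "intact"),
        (0.80, 0, "intact"),  # boundary: threshold is inclusive
        (0.35, 0, "fragment"),  # gene piece duplicated into a repeat
        (0.79, 0, "fragment"),
        (1.00, 2, "pseudogene"),  # full length but stop-disrupted
        (0.35, 1, "fragment"),
    ],
)
def test_gene_status_is_total_in_cover_and_stops(cover, stops, expected):
    calls = call_genes([_hit(cover=cover, stops=stops)])
    assert len(calls) == 1
    assert calls[0].status == expected


def test_overlapping_chains_highest_bitscore_wins():
    weak = _hit(cover=0.5, span=(100, 250))
    strong = TranslatedHit(
        query="MATa1", qid="MATa1|mat_core|other", family="mat_core",
        contig="c", span=(100, 400), strand="+", frame=0, raw_score=900,
        bit_score=350.0, e_value=1e-80, query_cover=0.95, q_span=(0, 95),
        query_len=100, n_internal_stops=0,
    )
    calls = call_genes([weak, strong])
    assert len(calls) == 1
    assert calls[0].status == "intact"


def test_loci_from_phc_genome_merge_to_both(queries):
    asm, _ = generate_genome(PlantedGenomeSpec(category="PHC", seed=0))
    ev = annotate_assembly(asm, queries)
    assert len(ev.loci) == 1
    locus = ev.loci[0]
    assert locus.idiomorph == "both"
    assert "SLA2" in locus.neighbors and "DIC1" in locus.neighbors
    assert locus.neighbors["SLA2"] < 0 < locus.neighbors["DIC1"]


def test_no_intact_genes_no_loci():
    assert assemble_mat_loci([], Assembly("s", [Contig("c", "ACGT")])) == []


def test_subtelomeric_locus_flagged(queries):
    asm, _ = generate_genome(PlantedGenomeSpec(category="PHN", seed=0))
    ev = annotate_assembly(asm, queries)
    flags = {l.contig: l.telomere_proximal for l in ev.loci}
    assert flags["ctg1"] is True
    assert flags["ctg0"] is False


# ---------------------------------------------------------------------------
# Repeats
# ---------------------------------------------------------------------------


def test_planted_ir_detected_inverted(queries):
    asm, truth = generate_genome(
        PlantedGenomeSpec(category="FF1", seed=1, ir_len=2000, ir_identity=97.0)
    )
    ev = annotate_assembly(asm, queries)
    ir = [p for p in ev.repeats if p.orientation == "inverted"]
    assert len(ir) == 1
    pair = ir[0]
    assert pair.role == "IR"
    assert pair.identity >= 95.0
    (c1, s1), (c2, s2) = truth.ir_families["IR"]
    spans = sorted([pair.copy_a[1], pair.copy_b[1]])
    for found, planted in zip(spans, sorted([s1, s2])):
        assert abs(found[0] - planted[0]) < 50
        assert abs(found[1] - planted[1]) < 50


def test_repeat_detection_strand_symmetric(queries):
    asm, _ = generate_genome(PlantedGenomeSpec(category="FF1", seed=5))
    ev = annotate_assembly(asm, queries)
    flipped = Assembly(
        asm.species, [Contig(c.id, revcomp(c.seq), c.coverage) for c in asm.contigs]
    )
    ev2 = annotate_assembly(flipped, queries)
    assert len(ev.repeats) == len(ev2.repeats)
    n = asm.contigs[0].length
    for p, q in zip(ev.repeats, ev2.repeats):
        assert p.orientation == q.orientation
        mirrored = sorted(
            [(n - s[1], n - s[0]) for _, s in (q.copy_a, q.copy_b)]
        )
        original = sorted([p.copy_a[1], p.copy_b[1]])
        for a, b in zip(original, mirrored):
            assert abs(a[0] - b[0]) < 50 and abs(a[1] - b[1]) < 50


def test_repeat_free_genome_yields_nothing(queries):
    asm, _ = generate_genome(PlantedGenomeSpec(category="PHC", seed=2))
    ev = annotate_assembly(asm, queries)
    assert ev.repeats == []


def test_repeat_identity_filter_is_complete(queries):
    asm, _ = generate_genome(
        PlantedGenomeSpec(category="FF1", seed=3, ir_identity=96.0)
    )
    ev = annotate_assembly(asm, queries)
    assert all(p.identity >= 90.0 for p in ev.repeats)


# ---------------------------------------------------------------------------
# Telomeres
# ---------------------------------------------------------------------------


def _bg(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def test_telomere_at_end_detected():
    unit = "TTTTAGTAGGG"
    contig = Contig("c", _bg(80) + unit * 5 + _bg(5000))
    tels = detect_telomere(contig)
    assert len(tels) == 1
    assert tels[0].end == "left"
    assert tels[0].copies >= 5
    assert tels[0].unit == min(
        unit[i:] + unit[:i] for i in range(len(unit))
    )


def test_telomere_rotation_phase_invariance():
    unit = "TTTTAGTAGGG"
    canon = min(unit[i:] + unit[:i] for i in range(len(unit)))
    for phase in range(len(unit)):
        rot = unit[phase:] + unit[:phase]
        contig = Contig("c", rot * 6 + _bg(4000, seed=phase))
        tels = detect_telomere(contig)
        assert tels and tels[0].unit == canon


def test_telomere_at_contig_center_rejected():
    unit = "TTTGAGGG"
    contig = Contig("c", _bg(5000) + unit * 8 + _bg(5000))
    assert detect_telomere(contig) == []


def test_telomere_47bp_before_array():
    # a short offset between cassette end and the first repeat is tolerated
    unit = "TTTGAGGG"
    contig = Contig("c", _bg(6000) + _bg(47, seed=9) + unit * 6)
    tels = detect_telomere(contig)
    assert len(tels) == 1 and tels[0].end == "right"


# ---------------------------------------------------------------------------
# Allelism
# ---------------------------------------------------------------------------


def _allelism_fixture(share_left=True, share_right=True):
    rng = np.random.default_rng(11)
    bases = np.array(list("ACGT"))

    def bg(n):
        return "".join(bases[rng.integers(0, 4, n)])

    left, right = bg(1000), bg(1000)
    core_a, core_alpha = bg(1500), bg(1500)
    la = left if share_left else bg(1000)
    ra = right if share_right else bg(1000)
    asm = Assembly(
        "sp",
        [
            Contig("A", left + core_a + right),
            Contig("B", la + core_alpha + ra),
        ],
    )
    from matsys.locus_annotation import MatLocus

    locus_a = MatLocus("A", (1000, 2500), "a")
    locus_b = MatLocus("B", (1000, 2500), "alpha")
    return asm, locus_a, locus_b


@pytest.mark.parametrize(
    "share_left, share_right, verdict",
    [
        (True, True, "allelic"),
        (True, False, "ambiguous"),
        (False, False, "non_allelic"),
    ],
)
def test_allelism_verdicts(share_left, share_right, verdict):
    asm, la, lb = _allelism_fixture(share_left, share_right)
    ev = detect_allelism(asm, la, lb)
    assert ev.verdict == verdict


def test_allelism_overlapping_loci_error():
    asm, la, lb = _allelism_fixture()
    from matsys.locus_annotation import MatLocus

    other = MatLocus("A", (1500, 3000), "alpha")
    with pytest.raises(ValueError):
        detect_allelism(asm, la, other)


# ---------------------------------------------------------------------------
# Collapsed repeats and artifacts
# ---------------------------------------------------------------------------


def test_collapsed_link_recovered_and_ratio_gate():
    asm, truth = generate_genome(PlantedGenomeSpec(category="FF1", seed=4))
    collapsed, ctruth = emulate_assembler_collapse(asm, truth, k=55)
    links = infer_collapsed_repeats(collapsed, k=55)
    rep, neighbors = ctruth.collapsed_link
    assert len(links) == 1
    assert links[0].repeat_contig == rep
    assert set(neighbors) <= set(links[0].neighbor_contigs)
    assert links[0].overlap_len == 55
    # a 1.0x contig never links
    flat = Assembly(
        "sp",
        [Contig(c.id, c.seq, coverage=50.0) for c in collapsed.contigs],
    )
    assert infer_collapsed_repeats(flat) == []


def test_no_coverage_means_no_links():
    asm = Assembly("sp", [Contig("a", "ACGT" * 50), Contig("b", "TTAA" * 50)])
    assert infer_collapsed_repeats(asm) == []


@pytest.mark.parametrize(
    "length, mismatches, ends, expected",
    [
        (118_000, 1, (True, True), True),  # assembler-inflated IR signature
        (2_000, 60, (False, False), False),
        (60_000, 0, (False, False), False),  # long + perfect but internal
        (118_000, 10, (True, True), False),  # too divergent to be an artifact
    ],
)
def test_artifact_flag_rule_table(length, mismatches, ends, expected):
    pair = RepeatPair(
        copy_a=("c", (0, length)),
        copy_b=("c", (200_000, 200_000 + length)),
        length=length,
        identity=100.0 * (length - mismatches) / length,
        n_mismatches=mismatches,
        orientation="inverted",
        reaches_end=ends,
    )
    assert flag_assembly_artifact(pair) is expected
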