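"""Generator reproducibility, spec validation, collapse mechanics, fixtures."""

import itertools

import edlib
import pytest

from matsys.genome_io import revcomp
from matsys.synthetic_data import (
    FIXTURE_NAMES,
    PlantedGenomeSpec,
    clade_fixture,
    emulate_assembler_collapse,
    generate_genome,
    toy_queries,
    uniform_clade_size,
)


def test_generation_is_byte_reproducible():
    a1, t1 = generate_genome(PlantedGenomeSpec(category="FF2", seed=13))
    a2, t2 = generate_genome(PlantedGenomeSpec(category="FF2", seed=13))
    assert [c.seq for c in a1.contigs] == [c.seq for c in a2.contigs]
    assert [c.coverage for c in a1.contigs] == [c.coverage for c in a2.contigs]
    assert [(f.name, f.span) for f in t1.features] == [
        (f.name, f.span) for f in t2.features
    ]
    b, _ = generate_genome(PlantedGenomeSpec(category="FF2", seed=14))
    assert [c.seq for c in b.contigs] != [c.seq for c in a1.contigs]


@pytest.mark.parametrize(
    "kwargs",
    [
        {"category": "PHC", "locus_gap": 25_000},
        {"category": "FF1", "ir_len": 100},
        {"category": "FF2", "inner_ir_len": 50},
        {"category": "XYZ"},
    ],
)
def test_inconsistent_specs_rejected_before_generation(kwargs):
    with pytest.raises(ValueError):
        PlantedGenomeSpec(**kwargs)


def test_truth_annotations_match_sequence():
    asm, truth = generate_genome(PlantedGenomeSpec(category="3LOC", seed=2))
    contig = asm.contigs[0]
    for feat in truth.features:
        assert 0 <= feat.span[0] < feat.span[1] <= contig.length
    x1 = next(f for f in truth.features if f.name == "X_copy1")
    x2 = next(f for f in truth.features if f.name == "X_copy2")
    a = contig.seq[x1.span[0] : x1.span[1]]
    b = contig.seq[x2.span[0] : x2.span[1]]
    dist = edlib.align(a, b, mode="NW")["editDistance"]
    assert dist / len(a) < 0.05  # planted as near-identical direct copies


def test_collapse_overlaps_are_exactly_k():
    asm, truth = generate_genome(PlantedGenomeSpec(category="FF1", seed=8))
    collapsed, ctruth = emulate_assembler_collapse(asm, truth, k=55)
    rep = collapsed.get(f"{asm.contigs[0].id}_rep")
    left = collapsed.get(f"{asm.contigs[0].id}_L")
    m1 = collapsed.get(f"{asm.contigs[0].id}_M1")
    m2 = collapsed.get(f"{asm.contigs[0].id}_M2")
    right = collapsed.get(f"{asm.contigs[0].id}_R")
    assert left.seq[-55:] == rep.seq[:55]
    assert m1.seq[:55] == rep.seq[-55:]
    assert revcomp(m2.seq[-55:]) == rep.seq[-55:]
    assert revcomp(right.seq[:55]) == rep.seq[:55]
    base = [c.coverage for c in collapsed.contigs if c is not rep]
    assert rep.coverage == pytest.approx(2 * base[0])


def test_collapse_of_repeat_free_genome_is_identity():
    asm, truth = generate_genome(PlantedGenomeSpec(category="PHC", seed=1))
    out, _ = emulate_assembler_collapse(asm, truth)
    assert [c.id for c in out.contigs] == [c.id for c in asm.contigs]
    assert [c.seq for c in out.contigs] == [c.seq for c in asm.contigs]


def test_toy_queries_are_mutually_dissimilar():
    qs = toy_queries()
    assert len(qs) == 7
    for a, b in itertools.combinations(qs, 2):
        d = edlib.align(a.seq, b.seq, mode="NW")["editDistance"]
        ident = 1 - d / max(len(a.seq), len(b.seq))
        assert ident < 0.30


# ---------------------------------------------------------------------------
# Curated clade fixtures
# ---------------------------------------------------------------------------


def test_lipomyces_fixture_composition():
    fx = clade_fixture("lipomyces")
    assert fx.tree.n_tips == 9
    tally = {}
    for s in fx.states.values():
        tally[s] = tally.get(s, 0) + 1
    assert tally == {"PHC": 5, "PHN": 3, "HET": 1}


def test_saccharomycetaceae_fixture_composition():
    fx = clade_fixture("saccharomycetaceae")
    assert fx.tree.n_tips == 71
    assert set(fx.states) == set(fx.tree.tip_names())


def test_saturnispora_fixture_composition():
    fx = clade_fixture("saturnispora")
    tally = sorted(fx.states.values())
    assert tally.count("FF2") == 4 and tally.count("HET") == 3


def test_switching_backbone_marks_provisional():
    fx = clade_fixture("switching_clades")
    assert "Wickerhamomyces_canadensis" in fx.provisional
    assert fx.states["Wickerhamomyces_canadensis"] == "FF2"


def test_phn_clades_table_schema():
    fx = clade_fixture("phn_clades")
    assert fx.table is not None and len(fx.table) == 12
    assert set(fx.table.second_locus_context) <= {"telomere", "rdna", "internal"}


def test_unknown_fixture_tag_lists_valid_tags():
    with pytest.raises(ValueError, match="valid tags"):
        clade_fixture("nonsense")
    assert "full" in FIXTURE_NAMES


def test_full_fixture_requires_user_transcription():
    with pytest.raises(ValueError, match="user-supplied"):
        clade_fixture("full")


def test_uniform_clade_size():
    fx = clade_fixture("ogataea")
    assert uniform_clade_size(fx.tree, fx.states, "Ogataea_polymorpha") == 12
    assert uniform_clade_size(fx.tree, fx.states, "Ogataea_pilisensis") == 1
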