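"""The synthetic diploid universe: genome generation, read simulation,
truth-contig geometry, read assignment, and alignment emission."""

from __future__ import annotations

import math

import numpy as np
import pytest

from hapscaffold import formats
from hapscaffold.phasing import revcomp
from hapscaffold.simulate import (
    HETEROTIG,
    HOMOTIG,
    apply_variants,
    assign_reads,
    build_universe,
    depth_table_from_placements,
    emit_alignments,
    generate_diploid,
    simulate_paired_reads,
    simulate_truth_contigs,
)


# ---------------------------------------------------------------------------
# genome


def test_zero_het_rate_gives_identical_haplotypes():
    g = generate_diploid(5000, het_rate=0.0, seed=1)
    assert g.hap_a == g.hap_b
    assert g.variants == []


def test_haplotype_b_reconstructable_from_variants():
    for placement in ("uniform", "clustered"):
        g = generate_diploid(20_000, het_rate=0.02, indel_fraction=0.2, seed=2, placement=placement)
        assert apply_variants(g.hap_a, g.variants) == g.hap_b


def test_uniform_snp_count_within_binomial_bound():
    L, rate = 100_000, 0.04
    g = generate_diploid(L, het_rate=rate, indel_fraction=0.0, seed=3, placement="uniform")
    expected = L * rate
    tol = 3 * math.sqrt(L * rate * (1 - rate))
    assert abs(len(g.variants) - expected) <= tol


def test_clustered_rate_matches_target_overall():
    L, rate = 200_000, 0.04
    g = generate_diploid(L, het_rate=rate, indel_fraction=0.0, seed=4)
    assert abs(len(g.variants) / L - rate) < 0.01


def test_same_seed_identical_genomes():
    g1 = generate_diploid(10_000, seed=5)
    g2 = generate_diploid(10_000, seed=5)
    assert g1.hap_a == g2.hap_a and g1.hap_b == g2.hap_b


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(length=500),
        dict(length=2000, het_rate=0.6),
        dict(length=2000, indel_fraction=0.9),
        dict(length=2000, placement="poisson"),
    ],
)
def test_parameter_validation(kwargs):
    with pytest.raises(ValueError):
        generate_diploid(**kwargs)


# ---------------------------------------------------------------------------
# reads


def test_read_bases_hit_requested_coverage_within_one_percent():
    g = generate_diploid(50_000, het_rate=0.01, seed=6)
    reads = simulate_paired_reads(g, coverage=40, seed=6)
    total = sum(2 * r.read_len for r in reads)
    expected = 40 * (g.length_a + g.length_b)
    assert abs(total - expected) / expected < 0.01


def test_zero_insert_sd_gives_exact_inserts():
    g = generate_diploid(20_000, seed=7)
    reads = simulate_paired_reads(g, insert_mean=400, insert_sd=0, coverage=5, seed=7)
    assert {r.insert for r in reads} == {400}


def test_reads_are_error_free_substrings_of_their_origin():
    g = generate_diploid(20_000, seed=8)
    reads = simulate_paired_reads(g, coverage=2, seed=8)
    for r in reads[:50]:
        hap = g.hap_a if r.haplotype == "A" else g.hap_b
        s1, e1 = r.mate_interval(1)
        s2, e2 = r.mate_interval(2)
        assert r.mate_seq(g, 1) == hap[s1:e1]
        assert r.mate_seq(g, 2) == revcomp(hap[s2:e2])


def test_insert_mean_must_span_two_reads():
    g = generate_diploid(20_000, seed=9)
    with pytest.raises(ValueError):
        simulate_paired_reads(g, read_len=75, insert_mean=100)


# ---------------------------------------------------------------------------
# truth contigs


def test_zero_variants_single_homotig():
    g = generate_diploid(5000, het_rate=0.0, seed=10)
    truth = simulate_truth_contigs(g)
    assert len(truth.contigs) == 1
    (c,) = truth.contigs.values()
    assert c.cls == HOMOTIG and c.length == 5000


def test_single_snp_block_arithmetic():
    g = generate_diploid(10_000, het_rate=0.0, seed=11)
    from hapscaffold.simulate import DiploidGenome, Variant

    v = Variant(5000, "SNP", g.hap_a[5000], "A" if g.hap_a[5000] != "A" else "C")
    g2 = DiploidGenome(g.hap_a, apply_variants(g.hap_a, [v]), [v], 1e-4, 0)
    truth = simulate_truth_contigs(g2, pad=74)
    classes = [c.cls for c in truth.contigs.values()]
    assert classes.count(HOMOTIG) == 2
    assert classes.count(HETEROTIG) == 2
    het = next(c for c in truth.contigs.values() if c.cls == HETEROTIG)
    assert het.length == 74 + 1 + 74
    partner = truth.contigs[het.partner_id]
    assert partner.partner_id == het.id and partner.source != het.source


def test_nearby_snps_merge_into_one_block():
    g = generate_diploid(10_000, het_rate=0.0, seed=12)
    from hapscaffold.simulate import DiploidGenome, Variant

    vs = [
        Variant(5000, "SNP", g.hap_a[5000], "A" if g.hap_a[5000] != "A" else "C"),
        Variant(5050, "SNP", g.hap_a[5050], "A" if g.hap_a[5050] != "A" else "C"),
    ]
    g2 = DiploidGenome(g.hap_a, apply_variants(g.hap_a, vs), vs, 2e-4, 0)
    truth = simulate_truth_contigs(g2, pad=74)
    hets = [c for c in truth.contigs.values() if c.cls == HETEROTIG]
    assert len(hets) == 2  # one pair
    assert hets[0].length == 74 + 51 + 74


def test_min_homozygous_run_must_exceed_twice_pad():
    g = generate_diploid(5000, het_rate=0.0, seed=13)
    with pytest.raises(ValueError):
        simulate_truth_contigs(g, pad=74, min_homozygous_run=148)


def test_tilings_partition_each_haplotype():
    g = generate_diploid(50_000, het_rate=0.04, seed=14)
    truth = simulate_truth_contigs(g)
    for tiling, L in ((truth.tiling_a, g.length_a), (truth.tiling_b, g.length_b)):
        starts, ends, ids = tiling
        assert starts[0] == 0 and ends[-1] == L
        assert np.all(starts[1:] == ends[:-1])
    # heterotig count equals merged-block count computed independently
    pad = 74
    blocks = []
    for v in g.variants:
        s, e = max(0, v.pos_a - pad), min(g.length_a, v.pos_a + len(v.ref) + pad)
        if blocks and s <= blocks[-1][1]:
            blocks[-1][1] = max(blocks[-1][1], e)
        else:
            blocks.append([s, e])
    merged = []
    for b in blocks:
        if merged and b[0] - merged[-1][1] < 150:
            merged[-1][1] = b[1]
        else:
            merged.append(b)
    n_het_pairs = sum(1 for c in truth.contigs.values() if c.cls == HETEROTIG) // 2
    assert n_het_pairs == len(merged)


# ---------------------------------------------------------------------------
# read assignment and truth consistency


@pytest.fixture(scope="module")
def small_world():
    g = generate_diploid(40_000, het_rate=0.04, seed=15)
    truth = simulate_truth_contigs(g)
    reads = simulate_paired_reads(g, coverage=15, seed=15)
    return g, truth, reads, assign_reads(truth, reads)


def test_heterotig_members_share_one_haplotype(small_world):
    _, truth, _, placements = small_world
    for cid, members in placements.membership.items():
        contig = truth.contigs[cid]
        origins = {placements.provenance[r] for r in members}
        if contig.cls == HETEROTIG and members:
            assert origins == {contig.source}


def test_homotig_members_include_both_haplotypes(small_world):
    _, truth, _, placements = small_world
    for cid, members in placements.membership.items():
        contig = truth.contigs[cid]
        if contig.cls == HOMOTIG and contig.length >= 1000:
            origins = {placements.provenance[r] for r in members}
            assert origins == {"A", "B"}


def test_boundary_spanning_reads_are_unmapped(small_world):
    g, truth, reads, placements = small_world
    starts, ends, ids = truth.tiling_a
    checked = 0
    for r in reads:
        if r.haplotype != "A":
            continue
        for mate in (1, 2):
            s, e = r.mate_interval(mate)
            idx = np.searchsorted(starts, s, side="right") - 1
            spans = e > ends[idx]
            rid = f"{r.id}/{mate}"
            assert (rid in placements.unmapped) == spans
            checked += 1
    assert checked > 100


def test_depth_table_reflects_ploidy(small_world):
    _, truth, _, placements = small_world
    table = depth_table_from_placements(truth, placements)
    hom = [table[c.id] for c in truth.contigs.values() if c.cls == HOMOTIG and c.length > 1000 and c.id in table]
    het = [table[c.id] for c in truth.contigs.values() if c.cls == HETEROTIG and c.length > 1000 and c.id in table]
    if hom and het:
        ratio = (sum(hom) / len(hom)) / (sum(het) / len(het))
        assert ratio == pytest.approx(2.0, rel=0.15)


# ---------------------------------------------------------------------------
# alignment emission: lossless lift-over


def test_sam_round_trip_is_lossless(small_world, tmp_path):
    g, truth, reads, placements = small_world
    path = tmp_path / "lib.sam"
    emit_alignments(truth, reads, placements, path, "SAM")
    contig_set = truth.contig_set()
    parsed = formats.parse_alignments(path, "SAM", contig_set)
    assert len(parsed) == len(placements.placed)
    assert parsed.unmapped_read_ids == placements.unmapped
    by_id = {r.id: r for r in reads}
    for a in parsed.alignments[:500]:
        pair_id, mate = a.read_id.rsplit("/", 1)
        r = by_id[pair_id]
        # decoding the contig substring must reproduce the read exactly
        contig_seq = contig_set[a.contig_id].sequence[a.start : a.end]
        read_seq = r.mate_seq(g, int(mate))
        assert contig_seq == (read_seq if a.strand == "+" else revcomp(read_seq))


def test_bowtie_and_blast_dialect_emission_parse_back(small_world, tmp_path):
    g, truth, reads, placements = small_world
    contig_set = truth.contig_set()
    sub = reads[:300]
    results = {}
    for fmt in ("SAM", "BOWTIE", "BLAST"):
        path = tmp_path / f"lib.{fmt.lower()}"
        emit_alignments(truth, sub, placements, path, fmt)
        parsed = formats.parse_alignments(path, fmt, contig_set)
        results[fmt] = sorted(
            (a.read_id, a.contig_id, a.start, a.end, a.strand) for a in parsed
        )
    assert results["SAM"] == results["BOWTIE"] == results["BLAST"]


def test_universe_is_deterministic_for_fixed_seed():
    u1 = build_universe(length=20_000, coverage=5, seed=17)
    u2 = build_universe(length=20_000, coverage=5, seed=17)
    assert u1.genome.hap_b == u2.genome.hap_b
    assert list(u1.truth.contigs) == list(u2.truth.contigs)
    assert [r.id for r in u1.libraries[0].reads] == [r.id for r in u2.libraries[0].reads]
    assert u1.depth_table == u2.depth_table
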