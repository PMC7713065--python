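"""Operon merging, upstream extraction, center geometry, promoter classes."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from fnrscan.io import GeneRecord, PromoterClass, TSSRecord
from fnrscan.operons import (
    assign_promoter_class,
    build_operons,
    center_offset,
    extract_upstream,
)


def make_genome(length: int, seed: int = 0) -> dict[str, str]:
    rng = np.random.default_rng(seed)
    return {"chr": "".join(rng.choice(list("ACGT"), size=length))}


class TestBuildOperons:
    def test_small_gap_merges(self):
        genes = [GeneRecord("g1", "chr", 100, 400, "+"),
                 GeneRecord("g2", "chr", 451, 700, "+")]
        ops = build_operons(genes, [])
        assert len(ops) == 1
        assert ops[0].gene_ids == ["g1", "g2"]
        assert ops[0].lead_gene == "g1"

    def test_internal_tss_splits(self):
        genes = [GeneRecord("g1", "chr", 100, 400, "+"),
                 GeneRecord("g2", "chr", 451, 700, "+")]
        tss = [TSSRecord("t", 431, "+", "g2")]
        ops = build_operons(genes, tss)
        assert len(ops) == 2

    def test_divergent_pair_never_merges(self):
        genes = [GeneRecord("g1", "chr", 100, 400, "-"),
                 GeneRecord("g2", "chr", 420, 700, "+")]
        ops = build_operons(genes, [])
        assert len(ops) == 2

    def test_large_gap_splits(self):
        genes = [GeneRecord("g1", "chr", 100, 400, "+"),
                 GeneRecord("g2", "chr", 901, 1200, "+")]
        assert len(build_operons(genes, [])) == 2

    def test_minus_strand_transcription_order(self):
        genes = [GeneRecord("g1", "chr", 100, 400, "-"),
                 GeneRecord("g2", "chr", 431, 700, "-")]
        ops = build_operons(genes, [])
        assert len(ops) == 1
        assert ops[0].gene_ids == ["g2", "g1"]  # rightmost transcribed first
        assert ops[0].lead_gene == "g2"

    def test_overlapping_same_strand_merged_with_warning(self, caplog):
        genes = [GeneRecord("g1", "chr", 100, 400, "+"),
                 GeneRecord("g2", "chr", 380, 700, "+")]
        with caplog.at_level("WARNING", logger="fnrscan"):
            ops = build_operons(genes, [])
        assert len(ops) == 1
        assert any("overlapping" in r.message for r in caplog.records)

    def test_partition_property(self, sim_default):
        """Operon gene lists partition the annotation exactly."""
        ops = build_operons(sim_default.genes, sim_default.tss)
        all_ids = [g for op in ops for g in op.gene_ids]
        assert sorted(all_ids) == sorted(g.gene_id for g in sim_default.genes)

    def test_recovers_planted_operons(self, sim_default):
        ops = build_operons(sim_default.genes, sim_default.tss)
        got = {tuple(op.gene_ids) for op in ops}
        want = {tuple(o["gene_ids"]) for o in sim_default.truth.operons}
        assert got == want


class TestExtractUpstream:
    def test_plus_strand_interval(self):
        genome = make_genome(2000)
        genes = {"g": GeneRecord("g", "chr", 1000, 1500, "+")}
        ops = build_operons(list(genes.values()), [])
        region = extract_upstream(ops[0], genes, genome)
        assert (region.start, region.end) == (550, 999)
        assert region.sequence == genome["chr"][549:999]

    def test_minus_strand_reverse_complemented(self):
        genome = make_genome(3000)
        genes = {"g": GeneRecord("g", "chr", 1500, 2000, "-")}
        ops = build_operons(list(genes.values()), [])
        region = extract_upstream(ops[0], genes, genome)
        assert (region.start, region.end) == (2001, 2450)
        assert region.sequence == str(Seq(genome["chr"][2000:2450]).reverse_complement())

    def test_contig_edge_clipping(self, caplog):
        genome = make_genome(1000)
        genes = {"g": GeneRecord("g", "chr", 200, 600, "+")}
        ops = build_operons(list(genes.values()), [])
        with caplog.at_level("WARNING", logger="fnrscan"):
            region = extract_upstream(ops[0], genes, genome)
        assert len(region.sequence) == 199
        assert region.clipped

    def test_tss_anchor_and_fallback(self, caplog):
        genome = make_genome(2000)
        genes = {"g": GeneRecord("g", "chr", 1000, 1500, "+")}
        tss = [TSSRecord("t", 950, "+", "g")]
        ops = build_operons(list(genes.values()), tss)
        region = extract_upstream(ops[0], genes, genome, anchor="tss")
        assert region.end == 949 and region.anchor == "tss"
        ops_no = build_operons(list(genes.values()), [])
        with caplog.at_level("WARNING", logger="fnrscan"):
            fallback = extract_upstream(ops_no[0], genes, genome, anchor="tss")
        assert fallback.anchor == "start_codon"
        assert fallback.end == 999

    def test_strand_symmetry(self):
        """Reverse-complementing the genome and flipping coordinates leaves
        the promoter sequence unchanged."""
        genome = make_genome(5000, seed=3)
        L = 5000
        genes = {"g": GeneRecord("g", "chr", 2000, 2600, "+")}
        ops = build_operons(list(genes.values()), [])
        fwd = extract_upstream(ops[0], genes, genome)

        flipped = {"chr": str(Seq(genome["chr"]).reverse_complement())}
        genes2 = {"g": GeneRecord("g", "chr", L - 2600 + 1, L - 2000 + 1, "-")}
        ops2 = build_operons(list(genes2.values()), [])
        rev = extract_upstream(ops2[0], genes2, flipped)
        assert rev.sequence == fwd.sequence


class TestCenterGeometry:
    @pytest.mark.parametrize(
        "first,last,expected",
        [(-48, -35, -41.5), (-100, -87, -93.5), (-36, -23, -29.5)],
    )
    def test_half_integer_centers(self, first, last, expected):
        tss = 10_000
        # map axis positions back to genomic coordinates on the + strand
        start, end = tss + first, tss + last
        assert center_offset(start, end, tss, "+") == expected

    def test_minus_strand_mirror(self):
        tss = 10_000
        # positions -48..-35 downstream-to-upstream on the minus strand
        start, end = tss + 35, tss + 48
        assert center_offset(start, end, tss, "-") == -41.5

    def test_no_zero_axis(self):
        tss = 100
        # one base immediately upstream is -1; at the TSS itself +1
        assert center_offset(99, 99, tss, "+") == -1
        assert center_offset(100, 100, tss, "+") == 1

    def test_tss_spanning_site_uses_gapped_axis(self):
        tss = 100
        # 14-mer occupying -7..+7 on the gapped axis (no zero)
        c = center_offset(93, 106, tss, "+")
        assert c == 0.0  # mean of -7 and +7

    def test_center_invariant_to_window_origin(self, sim_default):
        """A planted site's center is the same whether computed from the
        450-bp window offset or directly from genomic coordinates."""
        from fnrscan.operons import annotate_site, extract_upstream

        genes = {g.gene_id: g for g in sim_default.genes}
        ops = {o["operon_id"]: o for o in sim_default.truth.operons}
        genome = {"chr": sim_default.genome}
        for box in sim_default.truth.boxes[:4]:
            op = ops[box.operon_id]
            from fnrscan.operons import Operon

            operon = Operon(box.operon_id, op["gene_ids"], op["strand"], "chr",
                            tss=TSSRecord("t", op["tss"], op["strand"],
                                          op["gene_ids"][0]))
            for length in (450, 300):
                region = extract_upstream(operon, genes, genome, length=length)
                if operon.strand == "+":
                    offset = box.start - region.start
                else:
                    offset = region.end - box.end
                site = annotate_site(region, offset, 14, box.site, 0.0, 1e-9)
                assert site.center_offset == box.center
                assert (site.start, site.end) == (box.start, box.end)


class TestPromoterClass:
    @pytest.mark.parametrize(
        "center,expected",
        [
            (-41.5, PromoterClass.CLASS_II),
            (-42.5, PromoterClass.CLASS_II),
            (-40.5, PromoterClass.CLASS_II),
            (-60.5, PromoterClass.CLASS_I),
            (-93.5, PromoterClass.CLASS_I),
            (-29.5, PromoterClass.CORE_OVERLAP),
            (-328.0, PromoterClass.DISTAL),
            (-49.5, PromoterClass.CLASS_II),
            (-50.5, PromoterClass.CLASS_I),
            (-35.5, PromoterClass.CLASS_II),
            (-35.0, PromoterClass.CORE_OVERLAP),
            (-20.5, PromoterClass.CORE_OVERLAP),
            (-19.5, PromoterClass.DISTAL),
            (-110.5, PromoterClass.CLASS_I),
            (-111.5, PromoterClass.DISTAL),
            (None, PromoterClass.NO_TSS),
        ],
    )
    def test_windows(self, center, expected):
        assert assign_promoter_class(center) is expected
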