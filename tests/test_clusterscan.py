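"""Conserved cluster integrity: assignment, order, blocks, completeness."""
import numpy as np
import pandas as pd
import pytest

from oxgrid import clusterscan
from oxgrid.core import AnnotationSet, AssemblyLayout, GeneModel


def hit_row(member, chrom, tstart, tend, evalue):
    return {
        "qseqid": member, "tseqid": chrom, "fident": 0.8, "alnlen": 60,
        "mismatch": 10, "gapopen": 0, "qstart": 1, "qend": 60,
        "tstart": tstart, "tend": tend, "evalue": evalue, "bits": 200.0, "qlen": 60,
    }


def plant_cluster(members, chrom="pchr_56", start=10_000, gap=100_000,
                  strand="-", reverse=False, multi_copy=None, gene_len=5_000):
    """Place member genes in order (or reversed) and emit matching hits."""
    layout = AssemblyLayout([(chrom, 10_000_000)])
    order = list(reversed(members)) if reverse else list(members)
    genes, rows = [], []
    pos = start
    for m in order:
        copies = multi_copy.get(m, 1) if multi_copy else 1
        for c in range(copies):
            gid = f"{m}_model" + (f"_{c}" if copies > 1 else "")
            genes.append(GeneModel(gid, chrom, pos, pos + gene_len, strand))
            rows.append(hit_row(m, chrom, pos + 10, pos + 100, 1e-30))
            pos += gene_len + gap
    annot = AnnotationSet(layout, genes)
    return annot, pd.DataFrame(rows)


class TestAssign:
    def test_hit_maps_to_overlapping_gene(self, toy_annotation):
        hits = pd.DataFrame([hit_row("Hox1", "chrA", 1_100, 1_400, 1e-30)])
        assignment, unmapped = clusterscan.assign_members_from_hits(hits, toy_annotation)
        assert [h.gene_id for h in assignment["Hox1"]] == ["gA1"]
        assert unmapped == []

    def test_two_pass_evalue_semantics(self, toy_annotation):
        hits = pd.DataFrame([hit_row("Hox1", "chrA", 1_100, 1_400, 1e-15)])
        strict, _ = clusterscan.assign_members_from_hits(hits, toy_annotation, 1e-20)
        assert "Hox1" not in strict
        relaxed, _ = clusterscan.assign_members_from_hits(hits, toy_annotation, 1e-10)
        assert "Hox1" in relaxed

    def test_unmapped_hit_recorded_not_fatal(self, toy_annotation):
        hits = pd.DataFrame([hit_row("Hox1", "chrA", 50_000, 50_100, 1e-30)])
        assignment, unmapped = clusterscan.assign_members_from_hits(hits, toy_annotation)
        assert assignment == {}
        assert unmapped == [("Hox1", "chrA", 50_000, 50_100)]

    def test_best_evalue_kept_per_member_gene(self, toy_annotation):
        hits = pd.DataFrame(
            [hit_row("Hox1", "chrA", 1_100, 1_400, 1e-30),
             hit_row("Hox1", "chrA", 1_500, 1_800, 1e-50)]
        )
        assignment, _ = clusterscan.assign_members_from_hits(hits, toy_annotation)
        assert assignment["Hox1"][0].evalue == 1e-50


class TestAssess:
    def test_intact_cluster_with_one_loss(self):
        members = [m for m in clusterscan.HOX_CLUSTER.members if m != "Hox9"]
        annot, hits = plant_cluster(members)
        assignment, _ = clusterscan.assign_members_from_hits(hits, annot)
        report = clusterscan.assess_cluster(assignment, clusterscan.HOX_CLUSTER)
        assert report.missing == ["Hox9"]
        assert report.single_chromosome and report.ordered
        assert report.orientation == "ascending"
        assert report.strand_uniform and report.strand == "-"
        assert report.span is not None and report.span > 0

    def test_all_members_present_nothing_missing(self):
        annot, hits = plant_cluster(clusterscan.HOX_CLUSTER.members)
        assignment, _ = clusterscan.assign_members_from_hits(hits, annot)
        report = clusterscan.assess_cluster(assignment, clusterscan.HOX_CLUSTER)
        assert report.missing == []

    def test_reversed_cluster_still_ordered(self):
        annot, hits = plant_cluster(clusterscan.HOX_CLUSTER.members, reverse=True)
        assignment, _ = clusterscan.assign_members_from_hits(hits, annot)
        report = clusterscan.assess_cluster(assignment, clusterscan.HOX_CLUSTER)
        assert report.ordered and report.orientation == "descending"

    def test_multi_copy_member_does_not_break_order(self):
        annot, hits = plant_cluster(
            clusterscan.HOX_CLUSTER.members, multi_copy={"Hox4": 3}
        )
        assignment, _ = clusterscan.assign_members_from_hits(hits, annot)
        report = clusterscan.assess_cluster(assignment, clusterscan.HOX_CLUSTER)
        assert report.copy_number["Hox4"] == 3
        assert report.ordered

    def test_shuffled_coordinates_match_permutation_oracle(self):
        rng = np.random.default_rng(0)
        members = clusterscan.HOX_CLUSTER.members
        for _ in range(30):
            perm = rng.permutation(len(members))
            assignment = {
                m: [clusterscan.MemberHit(f"g{i}", "c1", int(10_000 * (perm[i] + 1)),
                                          int(10_000 * (perm[i] + 1)) + 500, "+", 1e-30)]
                for i, m in enumerate(members)
            }
            report = clusterscan.assess_cluster(assignment, clusterscan.HOX_CLUSTER)
            coords = list(perm)
            sorted_asc = coords == sorted(coords)
            sorted_desc = coords == sorted(coords, reverse=True)
            assert report.ordered == (sorted_asc or sorted_desc)

    def test_translation_invariance(self):
        annot, hits = plant_cluster(clusterscan.HOX_CLUSTER.members, start=10_000)
        annot2, hits2 = plant_cluster(clusterscan.HOX_CLUSTER.members, start=500_000)
        r1 = clusterscan.assess_cluster(
            clusterscan.assign_members_from_hits(hits, annot)[0], clusterscan.HOX_CLUSTER
        )
        r2 = clusterscan.assess_cluster(
            clusterscan.assign_members_from_hits(hits2, annot2)[0], clusterscan.HOX_CLUSTER
        )
        assert (r1.ordered, r1.span, r1.missing) == (r2.ordered, r2.span, r2.missing)


class TestBlocks:
    def test_fragmented_cluster_blocks(self):
        # an NK-like fragmented cluster: the biggest block carries NK5,
        # NK1, Hhex and four Msx copies; smaller blocks elsewhere
        placements = {
            "pchr_6": ["NK5", "NK1", "Hhex", "Msx", "Msx", "Msx", "Msx"],
            "pchr_48": ["NK3", "NK4", "Tlx"],
            "pchr_16": ["Emx", "Emx"],
            "pchr_38": ["Lbx", "NK7"],
            "pchr_2": ["NK6"],
            "pchr_30": ["Noto"],
        }
        assignment = {}
        for chrom, members in placements.items():
            for i, m in enumerate(members):
                assignment.setdefault(m, []).append(
                    clusterscan.MemberHit(f"{chrom}_g{i}", chrom, 1000 * (i + 1),
                                          1000 * (i + 1) + 500, "+", 1e-30)
                )
        blocks = clusterscan.detect_syntenic_blocks(assignment)
        assert blocks["pchr_6"] == ["NK5", "NK1", "Hhex", "Msx", "Msx", "Msx", "Msx"]
        assert blocks["pchr_48"] == ["NK3", "NK4", "Tlx"]
        assert blocks["pchr_16"] == ["Emx", "Emx"]
        assert blocks["pchr_38"] == ["Lbx", "NK7"]
        # every assigned copy in exactly one block
        n_copies = sum(len(hs) for hs in assignment.values())
        assert sum(len(b) for b in blocks.values()) == n_copies

    def test_dispersed_members_make_singleton_blocks(self):
        assignment = {
            m: [clusterscan.MemberHit(f"g_{m}", f"pchr_{i + 1}", 100, 600, "+", 1e-30)]
            for i, m in enumerate(["Six1/2", "Six3/6", "Six4/5"])
        }
        blocks = clusterscan.detect_syntenic_blocks(assignment)
        assert all(len(b) == 1 for b in blocks.values())

    def test_empty_assignment(self):
        assert clusterscan.detect_syntenic_blocks({}) == {}


class TestIntervening:
    def _with_extra(self, extra_between=True):
        annot, hits = plant_cluster(["Hox3", "Hox4"], gap=50_000)
        pos = 200_000 if not extra_between else 40_000  # between the two members
        annot.add(GeneModel("r2_extra", "pchr_56", pos, pos + 2_000, "+", "braker2"))
        assignment, _ = clusterscan.assign_members_from_hits(hits, annot)
        report = clusterscan.assess_cluster(
            assignment, clusterscan.ExpectedCluster("pair", ["Hox3", "Hox4"])
        )
        return annot, assignment, report

    def test_extra_model_between_members_found_with_flanks(self):
        annot, assignment, report = self._with_extra(True)
        out = clusterscan.find_intervening_models(annot, assignment, report)
        assert out == [("r2_extra", "Hox3", "Hox4")]

    def test_extra_model_outside_span_excluded(self):
        annot, assignment, report = self._with_extra(False)
        assert clusterscan.find_intervening_models(annot, assignment, report) == []

    def test_span_undefined_is_error(self):
        report = clusterscan.ClusterReport(
            "x", {}, [], ["c1", "c2"], False, False, 0, None, False, None, None
        )
        with pytest.raises(ValueError, match="span undefined"):
            clusterscan.find_intervening_models(None, {}, report)


class TestCompleteness:
    @pytest.mark.parametrize(
        "n_found,expected_pct",
        [(45, 95.7), (47, 100.0), (42, 89.4)],
    )
    def test_family_tally(self, n_found, expected_pct):
        expected = {f"Mir-{i}" for i in range(47)}
        found = set(sorted(expected)[:n_found])
        pct, missing = clusterscan.completeness_score(found, expected)
        assert pct == expected_pct
        assert len(missing) == 47 - n_found

    def test_empty_expected_rejected(self):
        with pytest.raises(ValueError):
            clusterscan.completeness_score({"a"}, set())


class TestIdenticalDuplicates:
    def _annot(self):
        layout = AssemblyLayout([("c1", 100_000), ("c2", 100_000)])
        return AnnotationSet(
            layout,
            [
                GeneModel("h1", "c1", 1_000, 2_000, "+"),
                GeneModel("h2", "c1", 5_000, 6_000, "+"),
                GeneModel("h3", "c2", 1_000, 2_000, "+"),
            ],
        )

    def test_same_chromosome_identical_flagged(self):
        seqs = {"h1": "ACGT" * 10, "h2": "ACGT" * 10, "h3": "TTTT"}
        assert clusterscan.flag_identical_duplicates(self._annot(), seqs) == [("h1", "h2")]

    def test_cross_chromosome_not_flagged_by_default(self):
        seqs = {"h1": "ACGT", "h2": "GGGG", "h3": "ACGT"}
        assert clusterscan.flag_identical_duplicates(self._annot(), seqs) == []
        wide = clusterscan.flag_identical_duplicates(
            self._annot(), seqs, same_chromosome_only=False
        )
        assert wide == [("h1", "h3")]

    def test_near_identical_not_flagged(self):
        seqs = {"h1": "ACGTACGT", "h2": "ACGTACGA", "h3": "T"}
        assert clusterscan.flag_identical_duplicates(self._annot(), seqs) == []

    def test_missing_sequence_skipped_with_warning(self):
        seqs = {"h1": "ACGT", "h2": "ACGT"}
        with pytest.warns(UserWarning, match="no sequence"):
            out = clusterscan.flag_identical_duplicates(self._annot(), seqs)
        assert out == [("h1", "h2")]
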