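"""Self-synteny filtering, Oxford grid, and contribution-matrix statistics."""
import math

import numpy as np
import pandas as pd
import pytest

from oxgrid import selfsynteny, simdata
from oxgrid.core import AssemblyLayout
from oxgrid.formats_io import HIT_COLUMNS
from oxgrid.selfsynteny import GenePosition


def make_hits(rows):
    """rows: (qseqid, tseqid, evalue, bits) -> full 13-column frame."""
    full = [
        (q, t, 0.8, 100, 20, 0, 1, 100, 1, 100, e, b, 100) for q, t, e, b in rows
    ]
    return pd.DataFrame(full, columns=HIT_COLUMNS)


def brute_force_filter(rows, to_gene, positions, threshold, best_by="bits"):
    """Independent oracle: plain-dict reimplementation of the filter rules."""
    best_pair = {}
    for q, t, e, b in rows:
        gq, gt = to_gene(q), to_gene(t)
        key = (gq, gt)
        cur = best_pair.get(key)
        if best_by == "bits":
            better = cur is None or (b, -e) > (cur[1], -cur[0])
        else:
            better = cur is None or (-e, b) > (-cur[0], cur[1])
        if better:
            best_pair[key] = (e, b)
    survivors = {}
    for (gq, gt), (e, b) in best_pair.items():
        if gq == gt or e > threshold:
            continue
        chrom = positions[gt].chromosome
        cur = survivors.get((gq, chrom))
        if cur is None or (e, -b, gt) < (cur[1], -cur[2], cur[0]):
            survivors[(gq, chrom)] = (gt, e, b)
    return {(gq, v[0]) for gq, v in zip((k[0] for k in survivors), survivors.values())}


@pytest.fixture
def positions():
    return {
        f"g{i}": GenePosition(f"g{i}", f"c{(i - 1) // 5 + 1}", 1000 * i, 1000 * i + 500)
        for i in range(1, 16)
    }


class TestFilter:
    def test_self_hits_only_gives_empty(self, positions):
        hits = make_hits([(f"g{i}.t1", f"g{i}.t1", 0.0, 500) for i in range(1, 6)])
        out = selfsynteny.filter_self_hits(hits, simdata.transcript_to_gene, positions, 1e-5)
        assert out.empty

    def test_best_scoring_row_per_pair_survives(self, positions):
        hits = make_hits(
            [("g1.t1", "g6.t1", 1e-30, 80.0), ("g1.t2", "g6.t1", 1e-25, 100.0)]
        )
        out = selfsynteny.filter_self_hits(hits, simdata.transcript_to_gene, positions, 1e-5)
        assert len(out) == 1
        assert out.loc[0, "bits"] == 100.0

    def test_best_hit_per_target_chromosome(self, positions):
        # g6 and g7 are both on c2: only the better e-value survives
        hits = make_hits([("g1.t1", "g6.t1", 1e-30, 200), ("g1.t1", "g7.t1", 1e-10, 200)])
        out = selfsynteny.filter_self_hits(hits, simdata.transcript_to_gene, positions, 1e-5)
        assert list(out["target_gene"]) == ["g6"]

    def test_unresolvable_id_is_error(self, positions):
        hits = make_hits([("g1.t1", "mystery.t1", 1e-30, 200)])
        with pytest.raises(KeyError, match="mystery"):
            selfsynteny.filter_self_hits(hits, simdata.transcript_to_gene, positions, 1e-5)

    def test_evalue_zero_most_significant_ties_by_bits_then_id(self, positions):
        hits = make_hits(
            [("g1.t1", "g6.t1", 0.0, 100), ("g1.t1", "g7.t1", 0.0, 100),
             ("g1.t1", "g8.t1", 1e-70, 500)]
        )
        out = selfsynteny.filter_self_hits(hits, simdata.transcript_to_gene, positions, 1e-5)
        assert list(out["target_gene"]) == ["g6"]  # lexicographically smaller on the tie

    def test_matches_brute_force_on_random_tables(self, positions):
        genes = list(positions)
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(10, 300))
            rows = []
            for _ in range(n):
                q, t = rng.choice(genes, 2)
                iso_q, iso_t = rng.integers(1, 4, 2)
                e = 10.0 ** rng.uniform(-80, -1)
                b = float(np.round(rng.uniform(30, 500), 1))
                rows.append((f"{q}.t{iso_q}", f"{t}.t{iso_t}", e, b))
            threshold = 10.0 ** rng.uniform(-40, -2)
            out = selfsynteny.filter_self_hits(
                make_hits(rows), simdata.transcript_to_gene, positions, threshold
            )
            got = set(zip(out["query_gene"], out["target_gene"]))
            want = brute_force_filter(rows, simdata.transcript_to_gene, positions, threshold)
            assert got == want, f"seed {seed}"

    def test_threshold_monotonicity(self, positions):
        rng = np.random.default_rng(99)
        genes = list(positions)
        rows = [
            (f"{rng.choice(genes)}.t1", f"{rng.choice(genes)}.t1",
             10.0 ** rng.uniform(-80, -1), float(rng.uniform(30, 500)))
            for _ in range(400)
        ]
        hits = make_hits(rows)
        prev = None
        for t in (1e-2, 1e-5, 1e-20, 1e-60):
            out = selfsynteny.filter_self_hits(hits, simdata.transcript_to_gene, positions, t)
            cur = set(zip(out["query_gene"], out["target_gene"]))
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_query_coverage_filter(self, positions):
        df = make_hits([("g1.t1", "g6.t1", 1e-30, 200)])
        df.loc[0, "alnlen"] = 50  # qlen is 100 -> coverage 0.5
        kept = selfsynteny.filter_self_hits(
            df, simdata.transcript_to_gene, positions, 1e-5, min_query_coverage=0.8
        )
        assert kept.empty


class TestLinearCoordinate:
    def test_first_chromosome_is_midpoint(self):
        layout = AssemblyLayout([("c1", 100)])
        assert selfsynteny.linear_coordinate(GenePosition("g", "c1", 10, 20), layout) == 15

    def test_offset_added_for_later_chromosomes(self):
        layout = AssemblyLayout([("c1", 100), ("c2", 50), ("c3", 200)])
        assert selfsynteny.linear_coordinate(GenePosition("g", "c2", 10, 20), layout) == 115
        assert selfsynteny.linear_coordinate(GenePosition("g", "c3", 1, 30), layout) == 165.5

    def test_unknown_chromosome(self):
        layout = AssemblyLayout([("c1", 100)])
        with pytest.raises(KeyError):
            selfsynteny.linear_coordinate(GenePosition("g", "cX", 10, 20), layout)


class TestGrid:
    def test_empty_pairs_empty_grid(self):
        layout = AssemblyLayout([("c1", 100)])
        grid = selfsynteny.build_oxford_grid(pd.DataFrame(columns=selfsynteny.PAIR_COLUMNS), {}, layout)
        assert grid.empty

    def test_point_composition(self):
        layout = AssemblyLayout([("c1", 100), ("c2", 100)])
        positions = {
            "q": GenePosition("q", "c2", 10, 20),
            "t": GenePosition("t", "c1", 10, 20),
        }
        pairs = pd.DataFrame(
            [{"query_gene": "q", "target_gene": "t", "query_chromosome": "c2",
              "target_chromosome": "c1", "evalue": 1e-30, "bits": 100.0,
              "same_chromosome": False}]
        )
        grid = selfsynteny.build_oxford_grid(pairs, positions, layout)
        assert (grid.loc[0, "x"], grid.loc[0, "y"]) == (15.0, 115.0)

    def test_grid_pair_bijection_and_bounds(self, positions):
        layout = AssemblyLayout([("c1", 10_000), ("c2", 10_000), ("c3", 20_000)])
        hits = make_hits(
            [("g1.t1", "g6.t1", 1e-30, 100), ("g2.t1", "g11.t1", 1e-40, 100)]
        )
        pairs = selfsynteny.filter_self_hits(hits, simdata.transcript_to_gene, positions, 1e-5)
        grid = selfsynteny.build_oxford_grid(pairs, positions, layout)
        assert len(grid) == len(pairs)
        assert ((grid["x"] > 0) & (grid["x"] < layout.total_length)).all()
        assert ((grid["y"] > 0) & (grid["y"] < layout.total_length)).all()

    def test_symmetric_table_gives_symmetric_grid(self, positions):
        layout = AssemblyLayout([("c1", 10_000), ("c2", 10_000), ("c3", 20_000)])
        base = [("g1.t1", "g6.t1", 1e-30, 100.0), ("g2.t1", "g12.t1", 1e-40, 90.0)]
        mirrored = base + [(t, q, e, b) for q, t, e, b in base]
        pairs = selfsynteny.filter_self_hits(
            make_hits(mirrored), simdata.transcript_to_gene, positions, 1e-5
        )
        grid = selfsynteny.build_oxford_grid(pairs, positions, layout)
        points = set(zip(grid["x"], grid["y"]))
        assert points == {(y, x) for x, y in points}


class TestContributionMatrix:
    def test_no_pairs_zero_matrix(self):
        m = selfsynteny.contribution_matrix(
            pd.DataFrame(columns=selfsynteny.PAIR_COLUMNS), {"c1": 5, "c2": 5}
        )
        assert (m.to_numpy() == 0).all()

    def test_hand_count(self):
        pairs = pd.DataFrame(
            [
                {"query_gene": "a1", "target_gene": "b1", "query_chromosome": "A",
                 "target_chromosome": "B", "evalue": 1e-30, "bits": 1.0, "same_chromosome": False},
                {"query_gene": "a2", "target_gene": "b2", "query_chromosome": "A",
                 "target_chromosome": "B", "evalue": 1e-30, "bits": 1.0, "same_chromosome": False},
            ]
        )
        m = selfsynteny.contribution_matrix(pairs, {"A": 10, "B": 20})
        assert m.loc["A", "B"] == pytest.approx(20.0)
        assert m.loc["B", "A"] == 0.0

    def test_donor_normalization_mode(self):
        pairs = pd.DataFrame(
            [{"query_gene": "a1", "target_gene": "b1", "query_chromosome": "A",
              "target_chromosome": "B", "evalue": 1e-30, "bits": 1.0, "same_chromosome": False}]
        )
        m = selfsynteny.contribution_matrix(pairs, {"A": 10, "B": 20}, mode="donor")
        assert m.loc["A", "B"] == pytest.approx(5.0)

    def test_zero_gene_chromosome_with_pairs_is_error(self):
        pairs = pd.DataFrame(
            [{"query_gene": "a1", "target_gene": "b1", "query_chromosome": "A",
              "target_chromosome": "B", "evalue": 1e-30, "bits": 1.0, "same_chromosome": False}]
        )
        with pytest.raises(ValueError, match="zero genes"):
            selfsynteny.contribution_matrix(pairs, {"A": 10, "B": 0})


class TestSummaries:
    def test_diagonal_only_matrix_has_infinite_contrast(self):
        m = pd.DataFrame(np.diag([10.0, 20.0, 30.0]), index=list("abc"), columns=list("abc"))
        s = selfsynteny.summarize_contributions(m)
        assert s["offdiag_mean"] == 0.0
        assert math.isinf(s["contrast_ratio"])

    def test_uniform_matrix(self):
        m = pd.DataFrame(np.full((3, 3), 2.0), index=list("abc"), columns=list("abc"))
        s = selfsynteny.summarize_contributions(m)
        assert s["offdiag_mean"] == s["offdiag_min"] == s["offdiag_max"] == 2.0
        assert s["contrast_ratio"] == 1.0

    def test_one_by_one_matrix_rejected(self):
        with pytest.raises(ValueError):
            selfsynteny.summarize_contributions(pd.DataFrame([[1.0]]))


class TestParalogContent:
    def test_single_chromosome_genome_all_zero(self):
        positions = {f"g{i}": GenePosition(f"g{i}", "c1", 100 * i, 100 * i + 50) for i in range(1, 6)}
        hits = make_hits([("g1.t1", "g2.t1", 1e-30, 100)])
        out = selfsynteny.paralog_content_distribution(
            hits, simdata.transcript_to_gene, positions, {"c1": 5}, thresholds=[1e-5]
        )
        assert (out["fraction"] == 0).all()

    def test_toy_hand_count(self, positions):
        # 3 of the 5 genes on c1 pair off-chromosome
        hits = make_hits(
            [("g1.t1", "g6.t1", 1e-30, 100), ("g2.t1", "g7.t1", 1e-30, 100),
             ("g3.t1", "g11.t1", 1e-30, 100)]
        )
        counts = {"c1": 5, "c2": 5, "c3": 5}
        out = selfsynteny.paralog_content_distribution(
            hits, simdata.transcript_to_gene, positions, counts, thresholds=[1e-5]
        )
        row = out[(out["chromosome"] == "c1")]
        assert row["fraction"].iloc[0] == pytest.approx(3 / 5)

    def test_stricter_threshold_never_increases_fraction(self, positions):
        rng = np.random.default_rng(5)
        genes = list(positions)
        rows = [
            (f"{rng.choice(genes)}.t1", f"{rng.choice(genes)}.t1",
             10.0 ** rng.uniform(-80, -1), float(rng.uniform(30, 500)))
            for _ in range(300)
        ]
        counts = {"c1": 5, "c2": 5, "c3": 5}
        out = selfsynteny.paralog_content_distribution(
            make_hits(rows), simdata.transcript_to_gene, positions, counts,
            thresholds=[1e-2, 1e-10, 1e-40],
        )
        for chrom in counts:
            series = out[out["chromosome"] == chrom].sort_values("threshold", ascending=False)
            fr = series["fraction"].to_numpy()
            assert (np.diff(fr) <= 1e-12).all()


class TestDuplicationSignal:
    def test_block_matrix_recovers_homologs(self):
        names = ["c1", "c2", "c1_B", "c2_B"]
        m = pd.DataFrame(0.0, index=names, columns=names)
        m.loc["c1", "c1_B"] = m.loc["c1_B", "c1"] = 40.0
        m.loc["c2", "c2_B"] = m.loc["c2_B", "c2"] = 35.0
        partners, matching = selfsynteny.score_duplication_signal(m, min_cell=5.0)
        assert partners["c1"][0] == "c1_B" and partners["c2"][0] == "c2_B"
        assert matching == [("c1", "c1_B"), ("c2", "c2_B")]

    def test_diagonal_only_matrix_no_partners(self):
        names = ["c1", "c2", "c3"]
        m = pd.DataFrame(np.diag([30.0, 30.0, 30.0]), index=names, columns=names)
        partners, matching = selfsynteny.score_duplication_signal(m, min_cell=5.0)
        assert all(p is None for p in partners.values())
        assert matching == []
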