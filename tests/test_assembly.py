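"""Gene mapping, redundancy selection, coverage and accuracy statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tnarray as tn
from tnarray.assembly import (
    AccuracyModel,
    GeneModel,
    fraction_histogram,
    gene_fraction,
    percent,
    redundancy_counts,
    round_half_up,
    total_mutants,
)


GENES = [
    GeneModel("gA", 1001, 2000, "+", "non-essential"),
    GeneModel("gB", 3001, 4000, "-", "essential"),
]


class TestGeneFraction:
    @pytest.mark.parametrize(
        "position, gene_id, fraction",
        [
            (1001, "gA", 0.0),      # + strand translational start
            (2000, "gA", 0.999),    # (2000-1001)/1000
            (4000, "gB", 0.0),      # - strand translational start = gene end
            (3001, "gB", 0.999),
        ],
    )
    def test_strand_aware_fraction(self, position, gene_id, fraction):
        hits = tn.locate_in_gene(position, GENES)
        assert len(hits) == 1
        assert hits[0].gene_id == gene_id
        assert hits[0].fraction == pytest.approx(fraction)

    def test_intergenic(self):
        assert tn.locate_in_gene(500, GENES) == []

    def test_overlapping_genes_return_all_hits(self):
        genes = GENES + [GeneModel("gC", 1500, 2500, "+", "unknown")]
        hits = tn.locate_in_gene(1600, genes)
        assert {h.gene_id for h in hits} == {"gA", "gC"}

    @settings(derandomize=True, max_examples=50)
    @given(
        st.integers(1, 10_000), st.integers(1, 5_000),
        st.integers(0, 4_999),
    )
    def test_reflection_invariance(self, start, length, offset):
        """f(+, pos) on [s, e] equals f(-, s + e - pos)."""
        end = start + length - 1
        pos = start + (offset % length)
        mirrored = start + end - pos
        assert gene_fraction(pos, start, end, "+") == pytest.approx(
            gene_fraction(mirrored, start, end, "-")
        )
        assert 0 <= gene_fraction(pos, start, end, "+") < 1


def assignments_df(entries):
    """entries: (site_id, position, status) -> minimal assignments frame."""
    df = pd.DataFrame(
        [
            {
                "site_id": s, "position": p, "strand": "+", "status": st_,
                "plate_row": 1, "plate_col": 1, "well_row": "A", "well_col": i + 1,
            }
            for i, (s, p, st_) in enumerate(entries)
        ]
    )
    return df.set_index("site_id")


class TestBuildCollection:
    def test_keeps_three_most_upstream(self):
        # gA spans [1001, 2000] on +; fractions 0.9, 0.5, 0.1, 0.3, 0.7
        positions = [1901, 1501, 1101, 1301, 1701]
        adf = assignments_df(
            [(f"S{i}", p, "auto") for i, p in enumerate(positions)]
        )
        manifest = tn.build_collection(adf, GENES)
        kept = manifest[manifest["gene_id"] == "gA"]
        assert kept["gene_fraction"].tolist() == pytest.approx([0.1, 0.3, 0.5])
        assert kept["rank"].tolist() == [1, 2, 3]
        assert kept["consolidated"].tolist() == [True, False, False]

    def test_single_entry_gene(self):
        manifest = tn.build_collection(assignments_df([("S0", 1500, "auto")]), GENES)
        row = manifest.iloc[0]
        assert row["rank"] == 1 and row["consolidated"]

    def test_consolidated_minimizes_fraction(self):
        adf = assignments_df(
            [("S0", 3100, "auto"), ("S1", 3900, "triangulated"), ("S2", 3500, "auto")]
        )
        manifest = tn.build_collection(adf, GENES)
        cons = manifest[manifest["consolidated"]]
        assert len(cons) == 1
        assert cons.iloc[0]["position"] == 3900  # most upstream on the - strand

    def test_unassigned_statuses_excluded(self):
        adf = assignments_df(
            [("S0", 1500, "auto"), ("S1", 1600, "ambiguous"), ("S2", 1700, "multilocated")]
        )
        manifest = tn.build_collection(adf, GENES)
        assert manifest["site_id"].tolist() == ["S0"]

    def test_intergenic_controls_retained(self):
        adf = assignments_df([("S0", 1500, "auto"), ("S1", 500, "auto")])
        manifest = tn.build_collection(adf, GENES)
        inter = manifest[manifest["intergenic"]]
        assert len(inter) == 1 and not inter.iloc[0]["consolidated"]

    def test_redundancy_identity(self):
        # Sum over k of k * n_k equals the number of genic manifest entries
        positions = [1101, 1201, 1301, 1401, 3100, 3200, 500]
        adf = assignments_df(
            [(f"S{i}", p, "auto") for i, p in enumerate(positions)]
        )
        manifest = tn.build_collection(adf, GENES)
        counts = redundancy_counts(manifest)
        assert counts == {2: 1, 3: 1}
        assert total_mutants(counts) == len(manifest[~manifest["intergenic"]])


class TestCoverageReport:
    def test_stratified_percentages(self):
        genes = (
            [GeneModel(f"ne{i}", 10 * i + 1, 10 * i + 5, "+", "non-essential")
             for i in range(4)]
            + [GeneModel("es0", 101, 105, "+", "essential")]
        )
        report = tn.coverage_report(["ne0", "ne1", "ne2"], genes)
        assert report.loc["non-essential", "orfs_hit"] == 3
        assert report.loc["non-essential", "pct_hit"] == 75.0
        assert report.loc["essential", "orfs_hit"] == 0
        assert report.loc["total", "pct_hit"] == 60.0
        assert (report["orfs_hit"] + report["orfs_missing"] == report["total"]).all()

    def test_zero_assignments(self):
        report = tn.coverage_report([], GENES)
        assert (report["orfs_hit"] == 0).all()
        assert (report["pct_missing"] == 100.0).all()

    @pytest.mark.parametrize(
        "num, den, expected",
        [(2687, 3135, 85.7), (2902, 3767, 77.0), (3225, 3767, 85.6), (1, 8, 12.5)],
    )
    def test_percent_half_up(self, num, den, expected):
        assert percent(num, den) == expected

    def test_round_half_up_at_boundary(self):
        assert round_half_up(0.25, 1) == 0.3
        assert round_half_up(85.65, 1) == 85.7
        assert round_half_up(92.5, 0) == 93.0


class TestFractionHistogram:
    def test_all_at_start_fall_in_first_bin(self):
        hits = pd.DataFrame({"gene_fraction": [0.0] * 5, "essentiality": "non-essential"})
        h = fraction_histogram(hits)
        assert h["non-essential"].iloc[0] == 5
        assert h["non-essential"].sum() == 5

    def test_counts_conserved_and_binned(self):
        rng = np.random.default_rng(0)
        hits = pd.DataFrame(
            {"gene_fraction": rng.random(200), "essentiality": "non-essential"}
        )
        h = fraction_histogram(hits, bin_width=0.05)
        assert len(h) == 20
        assert h["non-essential"].sum() == 200

    def test_ends_only_simulation_leaves_central_bins_empty(self, small_design):
        ref = tn.generate_reference(
            n_genes=20, essentiality_proportions=(0, 0, 1.0),
            intergenic_fraction=0.05, seed=21,
        )
        pl = tn.simulate_picking(
            ref, small_design, 90, duplicate_rate=0.0,
            essential_policy="ends-only", seed=9,
        )
        adf = pl.sites.assign(status="auto")
        hits = tn.gene_hits_for_assignments(adf, ref.genes)
        h = fraction_histogram(hits[hits["gene_id"].notna()])
        central = h.loc[(h.index >= 0.1) & (h.index < 0.9), "essential"]
        assert (central == 0).all()
        assert h["essential"].sum() > 0

    def test_uneven_bin_width_rejected(self):
        with pytest.raises(ValueError):
            fraction_histogram(pd.DataFrame({"gene_fraction": [0.5]}), bin_width=0.3)


class TestAccuracyModel:
    def test_redundancy_accuracy_rounds_to_quoted_percentages(self):
        m = AccuracyModel(40 / 53)
        assert round_half_up(100 * m.a(2), 0) == 94.0
        assert round_half_up(100 * m.a(3), 0) == 99.0

    def test_share_weighted_expectation(self):
        m = AccuracyModel(40 / 53)
        value = tn.expected_accuracy(m, {1: 0.21, 2: 0.25, 3: 0.54}, round_ak=2)
        assert value == pytest.approx(0.9271)
        assert round_half_up(100 * value, 0) == 93.0

    def test_perfect_accuracy(self):
        assert tn.expected_accuracy(AccuracyModel(1.0), {1: 0.5, 2: 0.5}) == 1.0

    def test_a_k_nondecreasing(self):
        m = AccuracyModel(0.3)
        assert m.a(1) <= m.a(2) <= m.a(3)

    def test_invalid_shares_rejected(self):
        with pytest.raises(ValueError):
            tn.expected_accuracy(AccuracyModel(0.5), {1: 0.5, 2: 0.2})

    def test_table_identity(self):
        assert total_mutants({1: 625, 2: 717, 3: 1560}) == 6739
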