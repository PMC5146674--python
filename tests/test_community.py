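"""Alpha diversity, rarefaction, Venn sharing, ratios, abundance pooling.

The independent oracle for the diversity indices is a direct brute-force
evaluation of the formulas (and scikit-bio where it implements the same
definition).
"""

import math

import numpy as np
import pandas as pd
import pytest

from mecflux import (
    OtuTable,
    abundance_table,
    alpha_diversity,
    domain_ratio,
    rarefy,
    venn3,
)


def brute_force_alpha(counts, base=2.0):
    counts = [c for c in counts if c > 0]
    n = sum(counts)
    s_obs = len(counts)
    h = -sum((c / n) * math.log(c / n, base) for c in counts)
    d = 1.0 - sum((c / n) ** 2 for c in counts)
    f1 = sum(1 for c in counts if c == 1)
    f2 = sum(1 for c in counts if c == 2)
    chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    coverage = 100.0 * (1.0 - f1 / n)
    return s_obs, chao1, h, d, coverage


def single_sample_table(counts):
    idx = pd.Index([f"t{i}" for i in range(len(counts))], name="#OTU ID")
    return OtuTable(counts=pd.DataFrame({"s": counts}, index=idx))


class TestAlphaDiversity:
    def test_uniform_four_taxa_closed_form(self):
        report = alpha_diversity(single_sample_table([10, 10, 10, 10]))
        row = report.frame.loc["s"]
        assert row["shannon"] == pytest.approx(2.0)
        assert row["simpson"] == pytest.approx(0.75)
        assert row["observed_otus"] == 4

    def test_single_taxon_degenerate(self):
        row = alpha_diversity(single_sample_table([5, 0, 0])).frame.loc["s"]
        assert row["shannon"] == 0.0
        assert row["simpson"] == 0.0
        assert row["goods_coverage"] == 100.0

    def test_random_sample_matches_brute_force(self, rng):
        counts = rng.integers(0, 50, size=30)
        counts[0] = 1  # force a singleton
        report = alpha_diversity(single_sample_table(counts))
        expected = brute_force_alpha(counts)
        row = report.frame.loc["s"]
        for col, exp in zip(
            ["observed_otus", "chao1", "shannon", "simpson", "goods_coverage"], expected
        ):
            assert row[col] == pytest.approx(exp, abs=1e-9), col

    def test_matches_scikit_bio_oracle(self, rng):
        """Independent implementation check against scikit-bio's alpha
        diversity functions on the same definitions."""
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        counts = rng.integers(0, 40, size=50)
        counts[counts.argmax()] += 5
        row = alpha_diversity(single_sample_table(counts), shannon_base=2).frame.loc["s"]
        assert row["shannon"] == pytest.approx(
            float(skbio_alpha.shannon(counts, base=2)), abs=1e-9
        )
        assert row["simpson"] == pytest.approx(
            float(skbio_alpha.simpson(counts)), abs=1e-9
        )
        assert row["chao1"] == pytest.approx(
            float(skbio_alpha.chao1(counts, bias_corrected=True)), abs=1e-9
        )

    def test_change_of_base_identity(self, rng):
        counts = rng.integers(1, 30, size=20)
        h2 = alpha_diversity(single_sample_table(counts), shannon_base=2).frame
        he = alpha_diversity(single_sample_table(counts), shannon_base=math.e).frame
        assert h2.loc["s", "shannon"] == pytest.approx(
            he.loc["s", "shannon"] / math.log(2), rel=1e-12
        )

    def test_chao1_at_least_observed_and_equal_without_singletons(self, rng):
        counts = rng.integers(2, 30, size=25)  # no singletons
        row = alpha_diversity(single_sample_table(counts)).frame.loc["s"]
        assert row["chao1"] == row["observed_otus"]
        counts[0] = 1
        row2 = alpha_diversity(single_sample_table(counts)).frame.loc["s"]
        assert row2["chao1"] >= row2["observed_otus"]

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            alpha_diversity(single_sample_table([0, 0]))


class TestRarefy:
    def test_depth_equal_total_is_identity(self, small_otu_table):
        out = rarefy(small_otu_table, depth=100, seed=0)
        pd.testing.assert_frame_equal(
            out.counts[["s1"]], small_otu_table.counts[["s1"]]
        )

    def test_totals_exactly_at_depth_and_reproducible(self, small_otu_table):
        a = rarefy(small_otu_table, depth=50, seed=11)
        b = rarefy(small_otu_table, depth=50, seed=11)
        assert (a.counts.sum(axis=0) == 50).all()
        pd.testing.assert_frame_equal(a.counts, b.counts)
        c = rarefy(small_otu_table, depth=50, seed=12)
        assert not a.counts.equals(c.counts)

    def test_hypergeometric_expectation(self):
        """Depth 10 from {A:50, B:50}: mean A-count over 1000 seeds within
        the Monte-Carlo CI of the hypergeometric expectation 5."""
        table = single_sample_table([50, 50])
        draws = np.array(
            [rarefy(table, depth=10, seed=s).counts.iloc[0, 0] for s in range(1000)]
        )
        # Var of hypergeometric(100, 50, 10) = 10*.5*.5*(90/99) ≈ 2.27
        se = math.sqrt(10 * 0.25 * 90 / 99 / 1000)
        assert abs(draws.mean() - 5.0) < 4 * se

    def test_richness_monotone_in_depth_on_average(self, rng):
        counts = rng.integers(0, 60, size=40)
        counts[:10] = rng.integers(1, 3, size=10)  # rare taxa
        table = single_sample_table(counts)
        total = int(counts.sum())
        mean_rich = []
        for depth in (total // 8, total // 2, total):
            rich = [
                (rarefy(table, depth, seed=s).counts["s"] > 0).sum() for s in range(30)
            ]
            mean_rich.append(np.mean(rich))
        assert mean_rich[0] <= mean_rich[1] <= mean_rich[2]

    def test_shallow_sample_dropped_with_warning(self, small_otu_table):
        shallow = OtuTable(
            counts=small_otu_table.counts.assign(s4=[1, 0, 0, 0, 0]),
            taxonomy=small_otu_table.taxonomy,
        )
        with pytest.warns(UserWarning, match="s4"):
            out = rarefy(shallow, depth=50, seed=0)
        assert "s4" not in out.samples


class TestVenn3:
    def test_published_style_core_fraction(self):
        # 580 core OTUs of a 9400-OTU union -> 6.2%
        core = {f"c{i}" for i in range(580)}
        a = core | {f"a{i}" for i in range(3000)}
        b = core | {f"b{i}" for i in range(2900)}
        c = core | {f"x{i}" for i in range(2920)}
        counts, percents = venn3(a, b, c)
        assert len(a | b | c) == 9400
        assert counts["ABC"] == 580
        assert percents["ABC"] == 6.2

    def test_disjoint_sets(self):
        counts, _ = venn3({"a"}, {"b"}, {"c"})
        assert counts["ABC"] == 0
        assert counts["A"] == counts["B"] == counts["C"] == 1

    def test_regions_match_brute_force_membership(self, rng):
        universe = [f"t{i}" for i in range(200)]
        sets = [
            {t for t in universe if rng.random() < p} or {"t0"}
            for p in (0.3, 0.5, 0.4)
        ]
        counts, _ = venn3(*sets)
        # brute force: classify every element of the union by membership
        expected = dict.fromkeys(["A", "B", "C", "AB", "AC", "BC", "ABC"], 0)
        for t in set().union(*sets):
            key = "".join(
                label for label, s in zip("ABC", sets) if t in s
            )
            expected[key] += 1
        assert counts == expected

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            venn3(set(), {"a"}, {"b"})


class TestDomainRatio:
    def test_archaea_bacteria_arithmetic(self, small_otu_table):
        ratios = domain_ratio(small_otu_table)
        # s1: archaea 10 / bacteria 90
        assert ratios["s1"] == pytest.approx(10 / 90)
        # s3: archaea 94 / bacteria 6
        assert ratios["s3"] == pytest.approx(94 / 6)

    def test_all_bacteria_is_zero_and_zero_denominator_is_inf(self):
        idx = pd.Index(["t1", "t2"], name="#OTU ID")
        counts = pd.DataFrame({"s": [5, 5]}, index=idx)
        tax = pd.Series(["Bacteria;P;C;o;f;g", "Bacteria;P;C;o;f;g2"], index=idx)
        table = OtuTable(counts=counts, taxonomy=tax)
        assert domain_ratio(table)["s"] == 0.0
        tax_arch = pd.Series(["Archaea;P;C;o;f;g", "Archaea;P;C;o;f;g2"], index=idx)
        assert domain_ratio(OtuTable(counts=counts, taxonomy=tax_arch))["s"] == math.inf

    def test_missing_taxonomy_and_labels_rejected(self, small_otu_table):
        bare = OtuTable(counts=small_otu_table.counts)
        with pytest.raises(ValueError):
            domain_ratio(bare)
        with pytest.raises(ValueError):
            domain_ratio(small_otu_table, "Eukarya", "Viruses")


class TestAbundanceTable:
    def test_minor_taxa_pool_into_others(self):
        idx = pd.Index(["t1", "t2", "t3"], name="#OTU ID")
        counts = pd.DataFrame({"s": [600, 395, 5]}, index=idx)
        tax = pd.Series(
            ["Bacteria;P;C;o;f;Major1", "Bacteria;P;C;o;f;Major2", "Bacteria;P;C;o;f;Minor"],
            index=idx,
        )
        table = abundance_table(OtuTable(counts=counts, taxonomy=tax), "genus", 1.0)
        assert table.loc["others", "s"] == pytest.approx(0.5)
        assert table["s"].sum() == pytest.approx(100.0)

    def test_single_dominant_taxon_no_others(self):
        idx = pd.Index(["t1"], name="#OTU ID")
        table = abundance_table(
            OtuTable(
                counts=pd.DataFrame({"s": [100]}, index=idx),
                taxonomy=pd.Series(["Bacteria;P;C;o;f;G"], index=idx),
            ),
            "genus",
            1.0,
        )
        assert "others" not in table.index
        assert table.loc["G", "s"] == pytest.approx(100.0)

    def test_columns_sum_to_100_random(self, small_otu_table, rng):
        table = abundance_table(small_otu_table, "phylum", 1.0)
        assert np.allclose(table.sum(axis=0), 100.0, atol=1e-9)

    def test_unknown_rank_rejected(self, small_otu_table):
        with pytest.raises(ValueError, match="rank"):
            abundance_table(small_otu_table, "tribe", 1.0)
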