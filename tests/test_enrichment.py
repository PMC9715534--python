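"""Exact contingency testing, BH adjustment, and set-enrichment scans."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from stylemorph.datasets import pif_enrichment_tables
from stylemorph.enrichment import (ContingencyTable, bh_adjust,
                                   build_set_contingency, fisher_exact,
                                   pif_scan, read_gene_list, term_enrichment,
                                   write_gene_list)


def rational_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact-arithmetic enumeration over all tables with the observed margins."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    pmf = {k: Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
           for k in range(lo, hi + 1)}
    return float(sum(q for q in pmf.values() if q <= pmf[a]))


class TestFisherExact:
    def test_published_style_table_rounds_to_printed_value(self):
        t = ContingencyTable(12, 83, 513, 10262)
        assert round(fisher_exact(t, "greater"), 3) == 0.002

    def test_maximum_entropy_table(self):
        assert fisher_exact(ContingencyTable(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_enumeration_example_3113(self):
        # margins (4, 4); 5 candidate tables; two-sided mass 34/70
        assert fisher_exact(ContingencyTable(3, 1, 1, 3)) == pytest.approx(34 / 70)
        assert rational_two_sided(3, 1, 1, 3) == pytest.approx(34 / 70)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)

    def test_transposition_invariance(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, 4))
            if a + b + c + d == 0:
                continue
            t = ContingencyTable(a, b, c, d)
            flipped = ContingencyTable(d, c, b, a)  # both margins transposed
            for sided in ("two-sided",):
                assert fisher_exact(t, sided) == pytest.approx(
                    fisher_exact(flipped, sided), rel=1e-9)

    def test_matches_scipy_reference(self, rng):
        for _ in range(80):
            a, b, c, d = (int(x) for x in rng.integers(0, 60, 4))
            if a + b + c + d == 0:
                continue
            t = ContingencyTable(a, b, c, d)
            mat = [[a, b], [c, d]]
            for sided, alt in [("two-sided", "two-sided"), ("greater", "greater"),
                               ("less", "less")]:
                assert fisher_exact(t, sided) == pytest.approx(
                    sps.fisher_exact(mat, alternative=alt)[1], rel=1e-7, abs=1e-12)

    def test_exhaustive_enumeration_small_n(self):
        for n in range(1, 26):
            for r1 in range(n + 1):
                for c1 in range(n + 1):
                    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
                    for a in range(lo, hi + 1):
                        t = ContingencyTable(a, r1 - a, c1 - a, n - r1 - (c1 - a))
                        assert fisher_exact(t) == pytest.approx(
                            rational_two_sided(t.a, t.b, t.c, t.d), abs=1e-12)

    def test_odds_ratio_and_direction(self):
        t = ContingencyTable(10, 10, 5, 20)
        assert t.odds_ratio == pytest.approx(4.0)
        assert t.direction == "enriched"
        assert ContingencyTable(1, 9, 5, 5).direction == "depleted"
        assert np.isinf(ContingencyTable(3, 0, 2, 5).odds_ratio)


class TestBHAdjust:
    def test_hand_worked_examples(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_order_preserved_and_capped(self):
        adj = bh_adjust([0.9, 0.001, 0.5])
        assert adj[1] == min(adj)
        assert np.all(adj <= 1.0)

    def test_matches_statsmodels(self, rng):
        p = rng.random(200)
        assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30),
           st.integers(0, 29), st.floats(0.0, 0.5))
    @settings(max_examples=100, deadline=None)
    def test_monotone_coupling(self, p, idx, bump):
        idx = idx % len(p)
        bumped = list(p)
        bumped[idx] = min(1.0, bumped[idx] + bump)
        assert np.all(bh_adjust(bumped) >= bh_adjust(p) - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestContingencyConstruction:
    def test_hand_counted_example(self):
        universe = {f"g{i}" for i in range(10)}
        deg = {"g0", "g1", "g2"}
        label = {"g0", "g1", "g5", "g6"}
        t = build_set_contingency(deg, universe, label)
        assert (t.a, t.b, t.c, t.d) == (2, 1, 2, 5)

    def test_margin_identities_and_empty_label(self, rng):
        universe = {f"g{i}" for i in range(50)}
        deg = set(rng.choice(sorted(universe), 12, replace=False))
        label = set(rng.choice(sorted(universe), 20, replace=False))
        t = build_set_contingency(deg, universe, label)
        assert t.a + t.b == len(deg)
        assert t.a + t.c == len(label)
        assert t.n == len(universe)
        empty = build_set_contingency(deg, universe, set())
        assert (empty.a, empty.c) == (0, 0)

    def test_deg_outside_universe_is_integrity_error(self):
        with pytest.raises(ValueError, match="outside the universe"):
            build_set_contingency({"x"}, {"a", "b"}, set())


class TestTermEnrichment:
    def test_term_equal_to_universe_is_uninformative(self):
        universe = {f"g{i}" for i in range(20)}
        deg = {f"g{i}" for i in range(5)}
        out = term_enrichment(deg, universe, {"all": universe})
        assert out["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_fully_contained_term_hits_closed_form(self):
        universe = {f"g{i}" for i in range(20)}
        deg = {f"g{i}" for i in range(5)}
        out = term_enrichment(deg, universe, {"hit": set(deg)})
        assert out["pvalue"].iloc[0] == pytest.approx(1 / comb(20, 5), rel=1e-9)

    def test_bh_across_two_terms_and_zero_overlap_skipped(self):
        universe = {f"g{i}" for i in range(20)}
        deg = {"g0", "g1", "g2"}
        out = term_enrichment(deg, universe, {
            "t1": {"g0", "g1", "g5"}, "t2": {"g7", "g8"}, "absent": {"zz"}})
        assert list(out["term"]) == ["t1", "t2"]
        assert np.allclose(out["padj"], bh_adjust(out["pvalue"]))

    def test_empty_deg_rejected(self):
        with pytest.raises(ValueError):
            term_enrichment(set(), {"a"}, {"t": {"a"}})


class TestPifScan:
    @staticmethod
    def toy_maps(n: int = 1000):
        omap = {f"sp_{i}": f"at_{i}" for i in range(n)}
        return {"SpeciesX": omap}

    def test_composition_identity_with_known_table(self):
        # 5 labelled DEGs of 20, 50 labelled non-DEGs: table (5, 15, 50, 930)
        maps = self.toy_maps(1000)
        labels = [f"at_{i}" for i in range(5)] + [f"at_{i}" for i in range(20, 70)]
        deg = [f"sp_{i}" for i in range(20)]
        out = pif_scan([("toy", "SpeciesX", deg)], maps, labels)
        row = out.iloc[0]
        assert (row.a, row.b, row.c, row.d) == (5, 15, 50, 930)
        assert row.pvalue == pytest.approx(
            fisher_exact(ContingencyTable(5, 15, 50, 930), "greater"))

    def test_deg_without_ortholog_is_outside_universe(self):
        maps = self.toy_maps(10)
        out = pif_scan([("toy", "SpeciesX", ["nomap_1", "nomap_2"])], maps,
                       ["at_0"])
        assert not out["testable"].iloc[0]
        assert not out["significant"].iloc[0]

    def test_missing_map_is_input_error(self):
        with pytest.raises(ValueError):
            pif_scan([("toy", "Unknown", ["g"])], self.toy_maps(), [])

    def test_row_order_matches_input(self):
        maps = self.toy_maps(50)
        out = pif_scan([("b", "SpeciesX", ["sp_1"]), ("a", "SpeciesX", ["sp_2"])],
                       maps, ["at_1"])
        assert list(out["sample"]) == ["b", "a"]

    def test_gene_list_roundtrip_with_comments(self, tmp_path):
        path = tmp_path / "genes.txt"
        path.write_text("# header\nat_1\nat_2  # trailing\n\nat_3\n")
        assert read_gene_list(path) == ["at_1", "at_2", "at_3"]
        write_gene_list(["x", "y"], path)
        assert read_gene_list(path) == ["x", "y"]

    def test_null_label_permutation_controls_significance(self):
        """With unrelated labels, the significant fraction stays near alpha."""
        rng = np.random.default_rng(55)
        n, n_deg, reps = 2000, 100, 200
        maps = self.toy_maps(n)
        genes = sorted(maps["SpeciesX"])
        hits = 0
        for _ in range(reps):
            deg = rng.choice(genes, n_deg, replace=False)
            labels = [maps["SpeciesX"][g]
                      for g in rng.choice(genes, 100, replace=False)]
            out = pif_scan([("null", "SpeciesX", deg)], maps, labels)
            hits += int(out["significant"].iloc[0])
        frac = hits / reps
        # the exact test is valid (possibly conservative): level at most ~alpha
        assert frac <= 0.05 + 2.576 * np.sqrt(0.05 * 0.95 / reps)


class TestPublishedTables:
    def test_tables_are_internally_consistent(self):
        tables = pif_enrichment_tables()
        assert tables.shape[0] == 10
        # universes match the one-to-one ortholog counts of each species
        totals = tables.assign(n=lambda d: d.a + d.b + d.c + d.d)
        by_species = totals.groupby("species")["n"].max().to_dict()
        assert by_species["Primula veris"] == 10872
        assert by_species["Fagopyrum esculentum"] == 9660
        assert by_species["Turnera subulata"] == 9122
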