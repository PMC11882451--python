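"""PPM construction, KL information content, heatmaps, adjacency correlation."""

import re

import numpy as np
import pandas as pd
import pytest

from loopdms import (
    MutationWindow,
    build_ppm,
    heatmap_matrix,
    information_content,
    select_by_pattern,
    single_double_correlation,
)
from loopdms.enrichment import EnrichmentTable
from loopdms.library import AMINO_ACIDS, LibraryConfig, Variant, VariantLibrary, build_library, encode_protein
from loopdms.motifs import InsufficientDataError, MotifError, PositionProbabilityMatrix

from conftest import make_count_table


def enr_from_values(values: pd.Series) -> EnrichmentTable:
    data = pd.DataFrame({"enrichment_gfp_neg_wtnorm": values})
    data.index.name = "variant_id"
    return EnrichmentTable(data=data, wt_reference="wild_type")


def uniform_ppm(category, frame, population="unsorted", total=10_000.0):
    probs = pd.DataFrame(
        1.0 / 20, index=pd.RangeIndex(1, frame + 1, name="position"),
        columns=list(AMINO_ACIDS),
    )
    return PositionProbabilityMatrix(category, population, probs, total)


class TestBuildPpm:
    SPECS = [("u1", "unsorted", 1), ("n1", "gfp_neg", 1), ("p1", "gfp_pos", 1)]

    def _table(self, full_library, fill):
        vids = [v.variant_id for v in full_library]
        counts = np.zeros((3, len(vids)), dtype=int)
        table = make_count_table(vids, self.SPECS, counts)
        for vid, n in fill.items():
            table.counts.loc[:, vid] = n
        return table

    def test_point_mass_variant(self, full_library):
        table = self._table(full_library, {"single_substitution:I4F": 50})
        ppm = build_ppm(table, full_library, "single_substitution", "gfp_neg")
        assert ppm.frame_length == 7
        assert ppm.probs.loc[4, "F"] == pytest.approx(1.0)
        for pos, wt_aa in enumerate("GISIPRR", start=1):
            if pos != 4:
                assert ppm.probs.loc[pos, wt_aa] == pytest.approx(1.0)
        assert np.allclose(ppm.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_equal_counts_over_all_singles(self, full_library):
        singles = full_library.variants_in("single_substitution")
        table = self._table(full_library, {v.variant_id: 10 for v in singles})
        ppm = build_ppm(table, full_library, "single_substitution", "unsorted")
        for pos, wt_aa in enumerate("GISIPRR", start=1):
            for aa in AMINO_ACIDS:
                expected = 114 / 133 if aa == wt_aa else 1 / 133
                assert ppm.probs.loc[pos, aa] == pytest.approx(expected)

    def test_zero_category_reads_error_names_replicate(self, full_library):
        table = self._table(full_library, {"deletion:del1": 5})
        with pytest.raises(MotifError, match="replicate 1"):
            build_ppm(table, full_library, "single_substitution", "gfp_neg")

    def test_probabilities_sum_to_one(self, full_library):
        rng = np.random.default_rng(11)
        doubles = full_library.variants_in("double_insertion")
        table = self._table(
            full_library,
            {v.variant_id: int(n) for v, n in zip(doubles, rng.integers(0, 50, len(doubles)))},
        )
        ppm = build_ppm(table, full_library, "double_insertion", "unsorted")
        assert ppm.frame_length == 9
        assert np.allclose(ppm.probs.sum(axis=1), 1.0, atol=1e-9)


class TestInformationContent:
    def test_identical_distributions_have_zero_ic(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(20), size=7)
        fg = uniform_ppm("single_substitution", 7, "gfp_pos")
        fg.probs.iloc[:, :] = probs
        bg = uniform_ppm("single_substitution", 7)
        bg.probs.iloc[:, :] = probs.copy()
        ic = information_content(fg, bg)
        assert np.allclose(ic.values.to_numpy(), 0.0)

    def test_point_mass_against_uniform_gives_log2_20(self):
        fg = uniform_ppm("single_substitution", 7, "gfp_pos")
        fg.probs.iloc[:, :] = 0.0
        fg.probs["R"] = 1.0
        bg = uniform_ppm("single_substitution", 7)
        ic = information_content(fg, bg)
        assert np.allclose(ic.values["R"], np.log2(20))
        assert np.allclose(ic.values.drop(columns="R").to_numpy(), 0.0)
        assert np.allclose(ic.position_sums, np.log2(20))

    def test_gibbs_inequality_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            fg = uniform_ppm("single_insertion", 8, "gfp_pos")
            bg = uniform_ppm("single_insertion", 8)
            fg.probs.iloc[:, :] = rng.dirichlet(np.ones(20), size=8)
            bg.probs.iloc[:, :] = rng.dirichlet(np.ones(20), size=8)
            ic = information_content(fg, bg)
            assert (ic.position_sums >= -1e-12).all()

    def test_background_zero_is_floored_finite(self):
        fg = uniform_ppm("single_substitution", 7, "gfp_pos")
        bg = uniform_ppm("single_substitution", 7)
        bg.probs.loc[1, "A"] = 0.0
        bg.probs.loc[1, "C"] += 1.0 / 20  # keep a proper distribution
        ic = information_content(fg, bg)
        assert np.isfinite(ic.values.to_numpy()).all()

    def test_category_mismatch_rejected(self):
        with pytest.raises(MotifError, match="mismatch"):
            information_content(
                uniform_ppm("single_substitution", 7, "gfp_pos"),
                uniform_ppm("single_insertion", 7),
            )


@pytest.fixture(scope="module")
def seeded_enr(full_library):
    rng = np.random.default_rng(5)
    vids = [v.variant_id for v in full_library]
    return enr_from_values(
        pd.Series(rng.normal(size=len(vids)), index=pd.Index(vids, name="variant_id"))
    )


class TestHeatmapMatrix:
    def test_single_substitution_layout(self, full_library, seeded_enr):
        hm = heatmap_matrix(seeded_enr, full_library, "single_substitution")
        assert hm.values.shape == (20, 7)
        assert int(hm.mask.to_numpy().sum()) == 7  # one WT-identity cell per position
        for pos, wt_aa in enumerate("GISIPRR", start=1):
            assert hm.mask.loc[wt_aa, pos] or wt_aa in "IR"  # duplicated WT residues
        assert int((~hm.mask).to_numpy().sum()) == 133

    def test_merged_insertion_broadcasts_identical_values(self, full_library, seeded_enr):
        hm = heatmap_matrix(seeded_enr, full_library, "single_insertion")
        vals = [hm.values.loc["R", s] for s in (5, 6, 7)]
        assert vals[0] == vals[1] == vals[2]
        expected = seeded_enr.data.loc["single_insertion:ins5R", "enrichment_gfp_neg_wtnorm"]
        assert vals[0] == pytest.approx(expected)

    def test_double_insertion_single_site_fully_filled(self, full_library, seeded_enr):
        hm = heatmap_matrix(seeded_enr, full_library, "double_insertion", site_filter=[4])
        assert hm.values.shape == (400, 1)
        assert not hm.mask.to_numpy().any()

    def test_cell_lookup_consistency(self, full_library, seeded_enr):
        hm = heatmap_matrix(seeded_enr, full_library, "double_substitution")
        v = full_library.by_id["double_substitution:G1A+I2C"]
        assert hm.values.loc[("A", "C"), 1] == pytest.approx(
            seeded_enr.data.loc[v.variant_id, "enrichment_gfp_neg_wtnorm"]
        )

    def test_site_filter_out_of_range(self, full_library, seeded_enr):
        with pytest.raises(MotifError, match="range"):
            heatmap_matrix(seeded_enr, full_library, "single_insertion", site_filter=[9])


def _sub_library(seq="ACD"):
    return build_library(
        MutationWindow(seq, first_residue_number=1),
        LibraryConfig(
            include_deletions=False,
            include_single_insertions=False,
            include_double_insertions=False,
            n_scrambles=0,
            named_indels=(),
        ),
    )


class TestSingleDoubleCorrelation:
    def test_additive_construction_gives_r_one(self):
        # single values depend on position: p = (0, 1, 2); every double at
        # pair (i, i+1) is worth p(i) + p(i+1) boundary-matched so each
        # single's adjacent-double mean equals its own value + 1
        lib = _sub_library("ACD")
        pos_value = {1: 0.0, 2: 1.0, 3: 2.0}
        pair_value = {1: 1.0, 2: 3.0}  # p1+1 and p3+1; pos-2 mean = 2 = p2+1
        values = {}
        for v in lib:
            if v.category == "single_substitution":
                values[v.variant_id] = pos_value[int(v.edit[1])]
            elif v.category == "double_substitution":
                values[v.variant_id] = pair_value[int(v.edit[1])]
            else:
                values[v.variant_id] = 0.0
        res = single_double_correlation(
            enr_from_values(pd.Series(values)), lib, "substitution"
        )
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(1.0)

    def test_hand_computed_pearson_half(self):
        # 3 singles at (0, 1, 2) whose double means are (0, 2, 1): r = 0.5
        window = MutationWindow("ACD", first_residue_number=1)
        variants = []
        for edit in ("A1E", "C2E", "D3E"):
            pos, aa = int(edit[1]), edit[2]
            prot = "ACD"[: pos - 1] + aa + "ACD"[pos:]
            variants.append(
                Variant(f"single_substitution:{edit}", "single_substitution",
                        edit, prot, encode_protein(prot), "single_substitution")
            )
        doubles = [("A1E+C2F", "EFD"), ("A1F+C2E", "FED"), ("C2F+D3E", "AFE")]
        for edit, prot in doubles:
            variants.append(
                Variant(f"double_substitution:{edit}", "double_substitution",
                        edit, prot, encode_protein(prot), "double_substitution")
            )
        variants.append(
            Variant("wild_type", "wild_type", "wt", "ACD", encode_protein("ACD"), "wild_type")
        )
        from loopdms.library import DEFAULT_SUBPOOL_BARCODES

        lib = VariantLibrary(window, variants, dict(DEFAULT_SUBPOOL_BARCODES))
        values = pd.Series(
            {
                "single_substitution:A1E": 0.0,
                "single_substitution:C2E": 1.0,
                "single_substitution:D3E": 2.0,
                "double_substitution:A1E+C2F": 0.0,
                "double_substitution:A1F+C2E": 2.0,
                "double_substitution:C2F+D3E": 1.0,
                "wild_type": 0.0,
            }
        )
        res = single_double_correlation(enr_from_values(values), lib, "substitution")
        assert len(res.pairs) == 3
        assert res.r == pytest.approx(0.5)

    def test_no_doubles_is_insufficient_data(self, full_library):
        lib = build_library(
            MutationWindow(),
            LibraryConfig(
                include_deletions=False,
                include_double_substitutions=False,
                include_single_insertions=False,
                include_double_insertions=False,
                n_scrambles=0,
                named_indels=(),
            ),
        )
        vids = [v.variant_id for v in lib]
        enr = enr_from_values(pd.Series(0.0, index=vids))
        with pytest.raises(InsufficientDataError):
            single_double_correlation(enr, lib, "substitution")

    def test_insertion_pairs_share_site_and_residue(self, full_library, seeded_enr):
        res = single_double_correlation(seeded_enr, full_library, "insertion")
        assert len(res.pairs) == 134
        assert np.isfinite(res.r)


class TestSelectByPattern:
    def test_exact_pattern_hits_one_variant(self, full_library, seeded_enr):
        hits = select_by_pattern(seeded_enr, full_library, "GISIPRPRR")
        assert "named_indel:R313delinsPRR" not in hits.index  # not a default indel
        assert set(hits["mutant_window"]) == {"GISIPRPRR"}

    def test_all_wildcards_select_frame(self, full_library, seeded_enr):
        hits = select_by_pattern(seeded_enr, full_library, "?" * 9)
        expected = {
            v.variant_id
            for v in full_library
            if len(v.mutant_window) == 9
        }
        assert set(hits.index) == expected
        assert {"double_insertion", "named_indel"} <= set(hits["category"])

    def test_pattern_matches_brute_force(self, full_library, seeded_enr):
        pattern = "GISIP?R?R"
        hits = select_by_pattern(seeded_enr, full_library, pattern)
        regex = re.compile("^" + pattern.replace("?", ".") + "$")
        expected = {
            v.variant_id
            for v in full_library
            if len(v.mutant_window) == 9 and regex.match(v.mutant_window)
        }
        assert set(hits.index) == expected and expected

    def test_unmatched_length_rejected(self, full_library, seeded_enr):
        with pytest.raises(MotifError, match="length"):
            select_by_pattern(seeded_enr, full_library, "?" * 30)
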