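"""Marker QC, parental imputation and founder-probability calculation."""

import numpy as np
import pytest

from wgnam.probs import (
    clean_founder_genotypes,
    compute_founder_probabilities,
    impute_from_parents,
    load_external_probabilities,
    qc_filter_markers,
    write_probabilities,
)
from wgnam.types import (
    MISSING,
    DataError,
    Family,
    FounderGenotypes,
    GeneticMap,
    LineGenotypes,
    NamDesign,
)


class TestCleaning:
    def test_heterozygotes_become_missing(self):
        f = FounderGenotypes(("A", "B"), np.array([[1, 0], [2, 1]], dtype=np.int8))
        clean = clean_founder_genotypes(f)
        assert np.array_equal(clean.calls, [[MISSING, 0], [2, MISSING]])

    def test_homozygous_matrix_unchanged(self, toy_founders):
        clean = clean_founder_genotypes(toy_founders)
        assert np.array_equal(clean.calls, toy_founders.calls)

    def test_conversion_count_conserved(self):
        rng = np.random.default_rng(0)
        calls = rng.choice([0, 1, 2, MISSING], size=(4, 50)).astype(np.int8)
        f = FounderGenotypes(tuple(f"F{i}" for i in range(4)), calls)
        clean = clean_founder_genotypes(f)
        n_het = int((calls == 1).sum())
        assert int((clean.calls == MISSING).sum()) \
            == int((calls == MISSING).sum()) + n_het


def _qc_setup(line_calls: np.ndarray):
    n_m = line_calls.shape[1]
    gmap = GeneticMap(tuple(f"m{j}" for j in range(n_m)),
                      ("1A",) * n_m, np.arange(n_m, dtype=float))
    founders = FounderGenotypes(
        ("R", "D"), np.array([[0] * n_m, [2] * n_m], dtype=np.int8))
    n_g = line_calls.shape[0]
    design = NamDesign((Family("fam", "D", "R"),),
                       {f"L{i}": "fam" for i in range(n_g)})
    lines = LineGenotypes(tuple(f"L{i}" for i in range(n_g)), line_calls)
    return founders, lines, design, gmap


class TestQC:
    def test_fixed_marker_low_maf(self):
        calls = np.full((10, 1), 2, dtype=np.int8)
        report = qc_filter_markers(*_qc_setup(calls))
        assert report.table.loc[0, "reasons"] == ["LOW_MAF"]
        assert not report.table.loc[0, "kept"]

    def test_family_missing_rate(self):
        # 10-line family, 6 missing -> rate 0.6 > 0.5 (direct count oracle)
        calls = np.array([[0]] * 2 + [[2]] * 2 + [[MISSING]] * 6, dtype=np.int8)
        report = qc_filter_markers(*_qc_setup(calls))
        assert "FAMILY_MISSING" in report.table.loc[0, "reasons"]
        assert report.table.loc[0, "missing_fam"] == pytest.approx(0.6)

    def test_overall_missing_rate(self):
        # 100 lines, 12 missing -> 0.12 > 0.10 (direct count oracle)
        calls = np.array([[0]] * 44 + [[2]] * 44 + [[MISSING]] * 12,
                         dtype=np.int8)
        report = qc_filter_markers(*_qc_setup(calls))
        assert "OVERALL_MISSING" in report.table.loc[0, "reasons"]
        assert report.table.loc[0, "overall_missing"] == pytest.approx(0.12)

    def test_segregating_balanced_marker_kept(self):
        calls = np.array([[0]] * 5 + [[2]] * 5, dtype=np.int8)
        report = qc_filter_markers(*_qc_setup(calls))
        assert report.table.loc[0, "kept"]

    def test_parent_conflict(self):
        # parents share genotype 0 but the family segregates heavily
        n_m = 1
        gmap = GeneticMap(("m0",), ("1A",), np.array([0.0]))
        founders = FounderGenotypes(("R", "D"),
                                    np.array([[0], [0]], dtype=np.int8))
        calls = np.array([[0]] * 5 + [[2]] * 5, dtype=np.int8)
        design = NamDesign((Family("fam", "D", "R"),),
                           {f"L{i}": "fam" for i in range(10)})
        lines = LineGenotypes(tuple(f"L{i}" for i in range(10)), calls)
        report = qc_filter_markers(founders, lines, design, gmap)
        assert "PARENT_CONFLICT" in report.table.loc[0, "reasons"]

    def test_threshold_validation(self):
        calls = np.zeros((4, 1), dtype=np.int8)
        with pytest.raises(DataError):
            qc_filter_markers(*_qc_setup(calls), max_family_missing=1.5)


class TestImputation:
    def test_shared_parent_genotype_fills_missing(self, toy_founders,
                                                  toy_design):
        lines = LineGenotypes(("L1", "L2", "L3", "L4"), np.array([
            [MISSING, MISSING, 2, 0],
            [0, 0, MISSING, 0],
            [2, 2, MISSING, MISSING],
            [0, 0, 2, 0],
        ], dtype=np.int8))
        out = impute_from_parents(lines, toy_founders, toy_design)
        # famA parents (D1=2,0,0,2 / Ref=0,0,2,0): agree only at m2 (0)
        assert out.calls[0, 0] == MISSING          # parents differ
        assert out.calls[0, 1] == 0                # parents both 0
        assert out.calls[1, 2] == MISSING          # parents differ (0 vs 2)
        # famB parents (D2=2,2,2,0 / Ref=0,0,2,0): agree at m3 (2) and m4 (0)
        assert out.calls[2, 2] == 2
        assert out.calls[2, 3] == 0

    def test_imputed_cell_count_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        n_g, n_m = 30, 40
        founders = FounderGenotypes(
            ("R", "D"), rng.choice([0, 2, MISSING], size=(2, n_m)).astype(np.int8))
        design = NamDesign((Family("f", "D", "R"),),
                           {f"L{i}": "f" for i in range(n_g)})
        calls = rng.choice([0, 2, MISSING], size=(n_g, n_m)).astype(np.int8)
        lines = LineGenotypes(tuple(f"L{i}" for i in range(n_g)), calls)
        out = impute_from_parents(lines, founders, design)
        # brute-force oracle
        expected = 0
        for i in range(n_g):
            for j in range(n_m):
                if (calls[i, j] == MISSING
                        and founders.calls[0, j] == founders.calls[1, j]
                        and founders.calls[0, j] != MISSING):
                    expected += 1
        assert int((out.calls != calls).sum()) == expected


class TestFounderProbabilities:
    def test_table_rules(self, toy_map, toy_founders, toy_lines, toy_design):
        cube, diags = compute_founder_probabilities(
            toy_founders, toy_lines, toy_design, toy_map)
        p = cube.p
        fi = {f: i for i, f in enumerate(cube.founder_ids)}
        # L1 (famA, D1 x Ref) at m1: parents 2/0, line 2 -> donor with prob 1
        assert p[0, 0, fi["D1"]] == 1.0 and p[0, 0, fi["Ref"]] == 0.0
        # L2 at m1: parents differ, line 0 -> reference
        assert p[1, 0, fi["Ref"]] == 1.0
        # L2 at m4: heterozygous line at a segregating marker -> 0.5/0.5
        assert p[1, 3, fi["D1"]] == 0.5 and p[1, 3, fi["Ref"]] == 0.5
        # m2 in famA: parents share 0 -> 0.5/0.5 for every line
        assert p[0, 1, fi["D1"]] == 0.5 and p[0, 1, fi["Ref"]] == 0.5
        # L4 missing call at segregating m2 of famB (parents 2 vs 0) -> 0.5
        assert p[3, 1, fi["D2"]] == 0.5
        # non-parent founder always zero
        assert np.all(p[0, :, fi["D2"]] == 0.0)
        assert np.all(p[2, :, fi["D1"]] == 0.0)

    def test_rows_sum_to_one_and_values_are_half_integers(
            self, toy_map, toy_founders, toy_lines, toy_design):
        cube, _ = compute_founder_probabilities(
            toy_founders, toy_lines, toy_design, toy_map)
        assert np.allclose(cube.p.sum(axis=2), 1.0, atol=1e-12)
        assert set(np.unique(cube.p)) <= {0.0, 0.5, 1.0}

    def test_permutation_equivariance(self, toy_map, toy_founders, toy_lines,
                                      toy_design):
        cube, _ = compute_founder_probabilities(
            toy_founders, toy_lines, toy_design, toy_map)
        perm = [2, 0, 1]
        founders2 = FounderGenotypes(
            tuple(toy_founders.founder_ids[k] for k in perm),
            toy_founders.calls[perm])
        cube2, _ = compute_founder_probabilities(
            founders2, toy_lines, toy_design, toy_map)
        assert np.array_equal(cube2.p, cube.p[:, :, perm])

    def test_fully_informative_data_gives_indicators(self):
        n_m = 6
        gmap = GeneticMap(tuple(f"m{j}" for j in range(n_m)), ("1A",) * n_m,
                          np.arange(n_m, dtype=float))
        founders = FounderGenotypes(
            ("R", "D"), np.array([[0] * n_m, [2] * n_m], dtype=np.int8))
        rng = np.random.default_rng(9)
        calls = rng.choice([0, 2], size=(10, n_m)).astype(np.int8)
        lines = LineGenotypes(tuple(f"L{i}" for i in range(10)), calls)
        design = NamDesign((Family("f", "D", "R"),),
                           {f"L{i}": "f" for i in range(10)})
        cube, diags = compute_founder_probabilities(founders, lines, design, gmap)
        assert diags == []
        assert set(np.unique(cube.p)) == {0.0, 1.0}

    def test_inconsistent_call_warns_and_falls_back(self):
        gmap = GeneticMap(("m0",), ("1A",), np.array([0.0]))
        founders = FounderGenotypes(("R", "D"),
                                    np.array([[0], [0]], dtype=np.int8))
        lines = LineGenotypes(("L0",), np.array([[2]], dtype=np.int8))
        design = NamDesign((Family("f", "D", "R"),), {"L0": "f"})
        cube, diags = compute_founder_probabilities(founders, lines, design, gmap)
        assert cube.p[0, 0, 0] == 0.5 and cube.p[0, 0, 1] == 0.5
        assert any("inconsistent" in d.message for d in diags)


class TestExternalProbabilities:
    def test_writer_round_trip(self, tmp_path, toy_map, toy_founders,
                               toy_lines, toy_design):
        cube, _ = compute_founder_probabilities(
            toy_founders, toy_lines, toy_design, toy_map)
        write_probabilities(cube, tmp_path / "probs.csv")
        back, diags = load_external_probabilities(
            tmp_path / "probs.csv", toy_map, toy_lines, toy_design,
            toy_founders.founder_ids)
        assert np.allclose(back.p, cube.p)
        assert diags == []

    def test_near_one_rows_renormalized(self, tmp_path, toy_map, toy_lines,
                                        toy_founders, toy_design):
        cube, _ = compute_founder_probabilities(
            toy_founders, toy_lines, toy_design, toy_map)
        scaled = cube.p * 0.999999
        import pandas as pd

        n_g, n_m, n_f = scaled.shape
        df = pd.DataFrame({
            "line": np.repeat(cube.line_ids, n_m * n_f),
            "marker": np.tile(np.repeat(cube.marker_ids, n_f), n_g),
            "founder": np.tile(cube.founder_ids, n_g * n_m),
            "prob": scaled.reshape(-1)})
        df.to_csv(tmp_path / "p.csv", index=False)
        back, _ = load_external_probabilities(
            tmp_path / "p.csv", toy_map, toy_lines, toy_design,
            toy_founders.founder_ids)
        assert np.allclose(back.p.sum(axis=2), 1.0, atol=1e-12)

    def test_out_of_range_probability_rejected(self, tmp_path, toy_map,
                                               toy_lines, toy_founders,
                                               toy_design):
        (tmp_path / "bad.csv").write_text(
            "line,marker,founder,prob\nL1,m1,Ref,1.2\n")
        with pytest.raises(DataError, match="outside"):
            load_external_probabilities(tmp_path / "bad.csv", toy_map,
                                        toy_lines, toy_design,
                                        toy_founders.founder_ids)
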