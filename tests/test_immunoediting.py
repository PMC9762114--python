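"""Neoantigen enumeration, depletion accounting, editing and HERVs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mrith import immunoediting as ie

from .conftest import make_sheet


class TestEnumeratePeptides:
    def test_central_mutant_17mer_yields_32_windows(self):
        context = "ACDEFGHIKLMNPQRST"
        peptides = ie.enumerate_peptides(context, 8)
        assert len(peptides) == 32
        by_len = pd.Series([len(p) for p, _, _ in peptides]).value_counts()
        assert by_len.to_dict() == {8: 8, 9: 9, 10: 8, 11: 7}

    def test_count_matches_combinatorial_oracle(self):
        # windows of length L covering position m in a string of length n
        def oracle(n, m):
            return sum(
                1
                for L in range(8, 12)
                for s in range(n - L + 1)
                if s <= m < s + L
            )

        for n, m in [(17, 8), (17, 0), (17, 16), (12, 5), (8, 0)]:
            context = ("ACDEFGHIKLMNPQRSTVWY" * 2)[:n]
            if n < 17:
                with pytest.warns(UserWarning, match="shorter"):
                    got = ie.enumerate_peptides(context, m)
            else:
                got = ie.enumerate_peptides(context, m)
            assert len(got) == oracle(n, m)

    def test_every_window_contains_the_mutant(self):
        context = "ACDEFGHIKLMNPQRST"
        for m in range(17):
            for pep, start, pos in ie.enumerate_peptides(context, m):
                assert pep[pos] == context[m]
                assert context[start:start + len(pep)] == pep

    def test_eight_mer_terminus_single_window(self):
        with pytest.warns(UserWarning):
            got = ie.enumerate_peptides("ACDEFGHI", 0)
        assert len(got) == 1 and got[0][0] == "ACDEFGHI"

    def test_out_of_range_mutant_errors(self):
        with pytest.raises(ValueError):
            ie.enumerate_peptides("ACDEFGHIKLMNPQRST", 17)


def _neo(rows):
    return pd.DataFrame(rows, columns=["patient", "mutation_id", "gene",
                                       "peptide", "hla_allele", "percent_rank"])


class TestDetection:
    def test_rank_boundary_inclusive_tpm_boundary_strict(self):
        neo = _neo([("p", "m1", "g1", "PEPTIDEK", "A1", 2.0),
                    ("p", "m2", "g2", "PEPTIDER", "A1", 2.01)])
        calls = pd.DataFrame({"sample": ["s1", "s1"],
                              "mutation_id": ["m1", "m2"]})
        tpm = pd.DataFrame({"s1": {"g1": 1.0, "g2": 5.0}})
        det = ie.detect_neoantigens(neo, calls, tpm=tpm)
        assert bool(det.loc[("p", "m1"), "s1"])        # %Rank == 2 detected
        assert not bool(det.loc[("p", "m2"), "s1"])    # 2.01 is not
        assert not bool(det.loc[("p", "m1"), "expressed_s1"])  # TPM == 1

    def test_mutation_absent_means_undetected(self):
        # strong binder, but its supporting mutation is called in s2 only
        neo = _neo([("p", "m1", "g1", "PEPTIDEK", "A1", 0.1)])
        calls = pd.DataFrame({"sample": ["s1", "s2"],
                              "mutation_id": ["zz", "m1"]})
        det = ie.detect_neoantigens(neo, calls)
        assert not bool(det.loc[("p", "m1"), "s1"])
        assert bool(det.loc[("p", "m1"), "s2"])

    def test_missing_rank_errors(self):
        neo = _neo([("p", "m1", "g1", "PEPTIDEK", "A1", np.nan)])
        calls = pd.DataFrame({"sample": ["s1"], "mutation_id": ["m1"]})
        with pytest.raises(ValueError, match="PEPTIDEK"):
            ie.detect_neoantigens(neo, calls)


class TestDepletion:
    def test_forced_ratio(self):
        pre = {f"n{i}" for i in range(10)}
        post = {"r1": pre - {"n0", "n1", "n2", "n3"}}
        per_region, patient = ie.depletion_fraction(pre, post)
        assert per_region["r1"] == pytest.approx(0.4)
        assert patient == pytest.approx(0.4)

    def test_superset_post_zero(self):
        pre = {"a", "b"}
        per_region, _ = ie.depletion_fraction(pre, {"r": {"a", "b", "c"}})
        assert per_region["r"] == 0.0

    def test_monotone_in_post_set(self):
        pre = set("abcdefgh")
        fracs = [ie.depletion_fraction(pre, {"r": set(list(pre)[:k])})[0]["r"]
                 for k in range(9)]
        assert fracs == sorted(fracs, reverse=True)
        assert all(0 <= f <= 1 for f in fracs)

    def test_empty_pre_errors(self):
        with pytest.raises(ValueError):
            ie.depletion_fraction(set(), {"r": set()})

    def test_planted_fraction_recovered_exactly(self, mutation_stage):
        config, sheet, out = mutation_stage
        det = ie.detect_neoantigens(out["neoantigens"], out["mutations"])
        truth = out["truth"]["depletion_fraction"]
        for pid, region_truth in list(truth.items())[:4]:
            pre = set(det.xs(pid, level="patient")
                      .index[det.xs(pid, level="patient")[f"{pid}_PRE"]])
            for region, expected in region_truth.items():
                post = set(det.xs(pid, level="patient")
                           .index[det.xs(pid, level="patient")[region]])
                got, _ = ie.depletion_fraction(pre, {region: post})
                assert got[region] == pytest.approx(expected)


class TestClassifyEditing:
    def test_rule_grid_partition(self):
        fcs = np.arange(-3.0, 2.01, 0.1)
        for loh in (False, True):
            df = pd.DataFrame({"hla_loh": loh, "log2fc": fcs})
            classes = ie.classify_editing(df)
            for fc, cls in zip(fcs, classes):
                if loh:
                    assert cls == "evasion_loh"
                elif fc < -1:
                    assert cls == "evasion_expression"
                elif fc >= 0:
                    assert cls == "elimination"
                else:
                    assert cls == "ambiguous"

    def test_fold_change_purity_correction(self):
        # equal corrected expression -> FC 1 -> log2 0 -> elimination
        fc = ie.fold_change(5.0, 0.5, 10.0, 1.0)
        assert fc == pytest.approx(1.0)
        with pytest.raises(ValueError):
            ie.fold_change(1.0, 0.0, 1.0, 0.5)

    def test_classes_recovered_on_synthetic_truth(self, mutation_stage):
        config, sheet, out = mutation_stage
        det = ie.detect_neoantigens(out["neoantigens"], out["mutations"])
        truth = out["truth"]["editing_class"]
        pairs = []
        for pid, region_truth in out["truth"]["depletion_fraction"].items():
            sub = det.xs(pid, level="patient")
            pre = set(sub.index[sub[f"{pid}_PRE"]])
            for region in region_truth:
                post = set(sub.index[sub[region]])
                for nid in pre - post:
                    pairs.append((nid, region, f"{pid}_PRE"))
        pairs = pd.DataFrame(pairs, columns=["mutation_id", "region",
                                             "pre_sample"])
        calls = ie.editing_calls(out["neoantigens"], out["flags"],
                                 out["neo_tpm"], sheet, pairs)
        got = calls.set_index(["mutation_id"])["editing_class"]
        agree = (got == got.index.map(truth)).mean()
        assert agree == 1.0


class TestClonality:
    def test_counts_and_clonal_flag(self):
        pre = {"a", "b", "c"}
        post = {f"r{i}": ({"b", "c"} if i < 5 else {"a", "b", "c"})
                for i in range(5)}
        post["r4"] = {"b"}
        df = ie.depletion_clonality(pre, post)
        assert df.loc["a", "n_regions_depleted"] == 5
        assert bool(df.loc["a", "clonal"])
        assert df.loc["b", "n_regions_depleted"] == 0
        assert df.loc["c", "n_regions_depleted"] == 1

    def test_clonal_depletions_hit_most_regions(self, mutation_stage):
        # clonally depleted neoantigens disappear from every treated region
        config, sheet, out = mutation_stage
        det = ie.detect_neoantigens(out["neoantigens"], out["mutations"])
        pid = next(iter(out["truth"]["depletion_fraction"]))
        regions = list(out["truth"]["depletion_fraction"][pid])
        sub = det.xs(pid, level="patient")
        pre = set(sub.index[sub[f"{pid}_PRE"]])
        post = {r: set(sub.index[sub[r]]) for r in regions}
        df = ie.depletion_clonality(pre, post)
        n_dep = round(config.depletion_rate * config.n_neoantigens_per_patient)
        n_clonal = round(config.depletion_clonal_frac * n_dep)
        assert (df["n_regions_depleted"] == len(regions)).sum() >= n_clonal


class TestAaSelection:
    def test_balanced_composition_odds_one(self):
        df = ie.aa_selection(list("AACD"), list("AACD"))
        finite = df["odds_ratio"].dropna()
        assert np.allclose(finite[finite != np.inf], 1.0)

    def test_fisher_p_matches_hypergeometric_oracle(self):
        # depleted: 4 with F / 6 without; preserved: 1 with F / 9 without
        df = ie.aa_selection(list("FFFF") + list("AAAAAA"),
                             list("F") + list("AAAAAAAAA"))
        expected = sps.fisher_exact([[4, 6], [1, 9]])[1]
        assert df.loc["F", "p"] == pytest.approx(expected)

    def test_counts_conserved(self):
        dep, pres = list("FARWYC"), list("AAWW")
        df = ie.aa_selection(dep, pres)
        assert df["depleted_with"].sum() == len(dep)
        assert df["preserved_with"].sum() == len(pres)

    def test_planted_enrichment_recovered(self):
        rng = np.random.default_rng(7)
        other = list("ACDEGHIKLMNPQRSTVWY")
        dep = list(rng.choice(other, 60)) + ["F"] * 40
        pres = list(rng.choice(other, 90)) + ["F"] * 10
        df = ie.aa_selection(dep, pres)
        assert df["q"].idxmin() == "F"
        assert df.loc["F", "odds_ratio"] > 1

    def test_bad_residue_errors(self):
        with pytest.raises(ValueError):
            ie.aa_selection(["X"], ["A"])


class TestHerv:
    def _herv_matrix(self, n_loci=20, n_samples=12, seed=0):
        rng = np.random.default_rng(seed)
        til = pd.Series(rng.uniform(size=n_samples),
                        index=[f"s{i}" for i in range(n_samples)])
        data = rng.uniform(0, 10, size=(n_loci, n_samples))
        hervs = pd.DataFrame(data, index=[f"h{i}" for i in range(n_loci)],
                             columns=til.index)
        return hervs, til

    def test_perfect_tracker_retained_anticorrelated_excluded(self):
        hervs, til = self._herv_matrix()
        hervs.loc["h0"] = til.to_numpy()
        hervs.loc["h1"] = -til.to_numpy() + 20
        res = ie.herv_immunogenic(hervs, til)
        assert bool(res.loc["h0", "immunogenic"])
        assert res.loc["h1", "rho"] == pytest.approx(-1.0)
        assert not bool(res.loc["h1", "immunogenic"])

    def test_null_false_positive_control(self):
        hits, total = 0, 0
        for seed in range(30):
            hervs, til = self._herv_matrix(n_loci=15, seed=seed)
            res = ie.herv_immunogenic(hervs, til)
            hits += int(res["immunogenic"].sum())
            total += len(res)
        assert hits / total <= 0.05

    def test_constant_locus_skipped(self):
        hervs, til = self._herv_matrix()
        hervs.loc["h0"] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            res = ie.herv_immunogenic(hervs, til)
        assert "h0" not in res.index

    def _editing_setup(self, fold):
        sheet = make_sheet([
            ("p_pre", "p", "PRE", "pre", "tumor", 0.5),
            ("p_r1", "p", "R1", "post", "tumor", 0.5),
        ])
        pre = np.array([100.0, 200.0, 400.0])
        hervs = pd.DataFrame({"p_pre": pre, "p_r1": pre * fold},
                             index=["h1", "h2", "h3"])
        return hervs, sheet

    def test_unchanged_expression_zero_editing(self):
        hervs, sheet = self._editing_setup(1.0)
        out = ie.herv_editing(hervs, sheet, ["h1", "h2", "h3"])
        assert out["editing"]["p_r1"] == pytest.approx(0.0, abs=1e-3)

    def test_halved_expression_editing_minus_one(self):
        hervs, sheet = self._editing_setup(0.5)
        out = ie.herv_editing(hervs, sheet, ["h1", "h2", "h3"])
        assert out["editing"]["p_r1"] == pytest.approx(-1.0, abs=2e-3)

    def test_outlier_sample_flagged(self):
        sheet = make_sheet([
            ("a", "p1", "R1", "untreated", "tumor", 0.5),
            ("b", "p2", "R1", "untreated", "tumor", 0.5),
            ("c", "p3", "R1", "untreated", "tumor", 0.5),
            ("d", "p4", "R1", "untreated", "tumor", 0.5),
        ])
        hervs = pd.DataFrame(
            [[10, 10.1, 9.9, 50]] * 3, index=["h1", "h2", "h3"],
            columns=["a", "b", "c", "d"], dtype=float)
        out = ie.herv_editing(hervs, sheet, ["h1"])
        assert out["outlier_samples"] == ["d"]

    def test_no_immunogenic_loci_errors(self):
        hervs, sheet = self._editing_setup(1.0)
        with pytest.raises(ValueError):
            ie.herv_editing(hervs, sheet, ["zz"])
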