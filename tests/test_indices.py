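"""FL, CII, RFC, UV against hand enumeration and the brute-force oracle."""

from fractions import Fraction

import pytest

from ethnoassembly.indices import (cultural_importance, fidelity_level,
                                   index_table, relative_frequency,
                                   use_value)
from ethnoassembly.synthetic import SimulationConfig, generate_use_reports
from ethnoassembly.usedata import build_matrix

from conftest import brute_force_indices, make_report

# Hand enumeration of the toy dataset (see conftest):
#   cultures aaa, bbb, ccc -> N = 3
#   alpha: food x2 cultures, medicinal eye+kidney (aaa), ritual (ccc)
#   beta:  food (aaa), medicinal eye (bbb)
#   gamma: toxic only (ccc)


class TestFidelityLevel:
    def test_toy_values(self, toy_matrix):
        assert fidelity_level(toy_matrix, "food") == pytest.approx(3 / 3)
        assert fidelity_level(toy_matrix, "medicinal") == pytest.approx(3 / 3)
        assert fidelity_level(toy_matrix, "medicinal:eye") == pytest.approx(2 / 3)
        assert fidelity_level(toy_matrix, "ritual") == pytest.approx(1 / 3)

    def test_ratio_matches_printed_precision(self):
        # 46 report-units over 25 cultures renders as 1.84
        reports = [make_report(f"Genus s{i:02d}", "food",
                               chr(ord("a") + i % 25) * 3)
                   for i in range(46)]
        m = build_matrix(reports)
        assert m.N == 25
        assert round(fidelity_level(m, "food"), 2) == 1.84

    def test_zero_report_use_is_zero(self, toy_matrix):
        assert fidelity_level(toy_matrix, "cosmetic") == 0.0

    def test_single_everything_is_one(self):
        m = build_matrix([make_report("Genus alpha", "food", "aaa")])
        assert fidelity_level(m, "food") == 1.0

    def test_unknown_use_rejected(self, toy_matrix):
        with pytest.raises(KeyError):
            fidelity_level(toy_matrix, "medicinal:ghost")

    def test_per_use_culture_denominator_option(self, toy_matrix):
        # conservative reading: denominator = cultures recording that use
        assert fidelity_level(toy_matrix, "food",
                              per_use_cultures=True) == pytest.approx(3 / 2)


class TestCulturalImportance:
    def test_toy_values(self, toy_matrix):
        assert cultural_importance(toy_matrix, "Genus alpha",
                                   "medicinal") == pytest.approx(2 / 3)
        assert cultural_importance(toy_matrix, "Genus alpha",
                                   "food") == pytest.approx(2 / 3)
        assert cultural_importance(toy_matrix, "Genus beta",
                                   "ritual") == 0.0

    def test_unknown_species_rejected(self, toy_matrix):
        with pytest.raises(KeyError):
            cultural_importance(toy_matrix, "Genus ghost", "food")


class TestRelativeFrequency:
    def test_toy_values(self, toy_matrix):
        assert relative_frequency(toy_matrix, "Genus alpha") == 1.0
        assert relative_frequency(toy_matrix, "Genus beta") == pytest.approx(2 / 3)

    def test_monotone_under_new_culture(self, toy_reports):
        before = relative_frequency(build_matrix(toy_reports), "Genus beta")
        extra = toy_reports + [make_report("Genus beta", "food", "ddd")]
        after = relative_frequency(build_matrix(extra), "Genus beta")
        assert after >= before


class TestUseValue:
    def test_toy_values(self, toy_matrix):
        assert use_value(toy_matrix, "Genus alpha") == pytest.approx(2 / 3)
        assert use_value(toy_matrix, "Genus beta") == pytest.approx(1 / 2)

    def test_six_reports_three_cultures_is_two(self):
        reports = [
            make_report("Genus alpha", "medicinal", c, sub)
            for c, subs in [("aaa", ["eye", "skin"]), ("bbb", ["eye", "lung"]),
                            ("ccc", ["eye", "MSK"])]
            for sub in subs
        ]
        assert use_value(build_matrix(reports), "Genus alpha") == 2.0

    def test_food_only_species_has_uv_zero(self):
        m = build_matrix([make_report("Genus alpha", "food", "aaa")])
        assert use_value(m, "Genus alpha") == 0.0

    def test_toxic_only_species_is_null_with_reason(self, toy_matrix):
        with pytest.warns(UserWarning, match="N_s = 0"):
            assert use_value(toy_matrix, "Genus gamma") is None


class TestIndexTable:
    def test_toy_table_matches_hand_computation(self, toy_matrix):
        table = index_table(toy_matrix)
        per_sp = table.per_species.set_index("species")
        assert list(per_sp.index) == ["Genus alpha", "Genus beta"]  # CII rank
        assert per_sp.loc["Genus alpha", "CII_medicinal"] == pytest.approx(2 / 3)
        assert per_sp.loc["Genus alpha", "RFC"] == 1.0
        assert per_sp.loc["Genus beta", "UV_medicinal"] == pytest.approx(1 / 2)
        fl = dict(zip(table.per_use["use"], table.per_use["FL"]))
        assert fl["food"] == pytest.approx(1.0)
        assert fl["medicinal:kidney"] == pytest.approx(1 / 3)

    def test_toxic_domain_excluded_by_default(self, toy_matrix):
        table = index_table(toy_matrix)
        assert "Genus gamma" not in set(table.per_species["species"])
        assert not any(u.startswith("toxic") for u in table.per_use["use"])

    def test_permutation_invariance(self, toy_reports):
        a = index_table(build_matrix(toy_reports))
        b = index_table(build_matrix(list(reversed(toy_reports))))
        assert a.per_use.equals(b.per_use)
        assert a.per_species.equals(b.per_species)

    def test_conservation_invariants(self):
        cfg = SimulationConfig(seed=42, n_species=10, n_cultures=8)
        reports, _ = generate_use_reports(cfg)
        m = build_matrix(reports)
        table = index_table(m)
        total_nontoxic = m.total_units(include_toxic=False)
        # sum over domains of CII_s * N recovers each species' report-units
        for row in table.per_species.itertuples():
            by_cii = round((row.CII_medicinal + row.CII_food + row.CII_ritual)
                           * table.N)
            direct = row.R_medicinal + row.R_food + row.R_ritual
            assert by_cii == direct
        # FL over domain-level uses sums to the matrix total
        domain_rows = table.per_use[~table.per_use["use"].str.contains(":")]
        assert round(domain_rows["FL"].sum() * table.N) == total_nontoxic

    def test_oracle_equivalence_many_seeds(self):
        # brute-force recount from raw reports reproduces every index
        for seed in range(30):
            cfg = SimulationConfig(seed=seed, n_species=8, n_cultures=6)
            reports, _ = generate_use_reports(cfg)
            m = build_matrix(reports)
            oracle = brute_force_indices(reports)
            assert m.N == oracle["N"]
            table = index_table(m)
            for row in table.per_use.itertuples():
                assert Fraction(row.FL).limit_denominator(10**6) == \
                    oracle["FL"].get(row.use, Fraction(0))
            for row in table.per_species.itertuples():
                sp = row.species
                assert row.RFC == float(oracle["RFC"][sp])
                assert row.CII_medicinal == float(
                    oracle["CII"].get((sp, "medicinal"), Fraction(0)))
                assert row.UV_medicinal == float(oracle["UV"][sp])
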