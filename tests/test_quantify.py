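"""Normalization, class summation, fold changes, plasmalogen calls,
enzyme-activity quantitation."""

import numpy as np
import pandas as pd
import pytest

from lipidquant.chem import build_database, default_database
from lipidquant.quantify import (
    EnzymeAssayRecord,
    classify_hydrolysis_table,
    classify_sn1_linkage,
    class_totals,
    default_is_map,
    enzyme_activity,
    flag_pufa,
    fold_changes,
    normalize,
)


def _mini_setup(protein=(1.0, 1.0)):
    """Tiny database (PC + standard, CE without standard) and corrected
    matrix."""
    db = build_database(
        {"PC": {"carbons": [34], "double_bonds": [1], "adduct": "[M+H]+"},
         "CE": {"carbons": [18], "double_bonds": [1], "adduct": "[M+NH4]+"}},
        {"PC": ((28, 0), 2.0)},
    )
    keys = [e.key for e in db]
    samples = pd.DataFrame(
        {
            "group": ["control1", "patient1"],
            "condition": ["control", "patient"],
            "replicate": [1, 1],
            "protein_mg": list(protein),
            "treatment": "none",
            "matrix": "fibroblast",
        },
        index=pd.Index(["s1", "s2"], name="sample_id"),
    )
    corrected = pd.DataFrame(
        {"s1": [1e6, 5e5, 1e6], "s2": [1e6, 5e5, 1e6]},
        index=pd.Index(sorted(keys), name="entry_key"),
    )
    return db, corrected, samples


class TestNormalize:
    def test_ratio_one_gives_spiked_amount_per_mg(self):
        # species intensity equal to the PC standard intensity with 1 mg
        # protein: 2.0 nmol of standard => 2.0 nmol/mg
        db, corrected, samples = _mini_setup()
        pc_std = [e.key for e in db if e.is_standard][0]
        pc = [e.key for e in db
              if e.species.display_class == "PC" and not e.is_standard][0]
        corrected.loc[pc] = corrected.loc[pc_std]
        ab = normalize(corrected, db, samples)
        assert ab.values.loc["PC 34:1", "s1"] == pytest.approx(2.0)
        assert ab.units["PC 34:1"] == "nmol_per_mg"

    def test_doubling_protein_halves_values(self):
        db, corrected, samples1 = _mini_setup(protein=(1.0, 2.0))
        ab = normalize(corrected, db, samples1)
        assert ab.values["s1"].dropna().to_numpy() == pytest.approx(
            2 * ab.values["s2"].dropna().to_numpy()
        )

    def test_class_without_standard_is_protein_scaled_only(self):
        db, corrected, samples = _mini_setup()
        ab = normalize(corrected, db, samples)
        ce = [n for n in ab.values.index if n.startswith("CE")][0]
        key = [e.key for e in db if e.species.name == ce][0]
        assert ab.units[ce] == "rel_per_mg"
        assert ab.values.loc[ce, "s1"] == pytest.approx(
            corrected.loc[key, "s1"] / samples.loc["s1", "protein_mg"]
        )

    def test_zero_standard_intensity_flags_class_invalid(self):
        db, corrected, samples = _mini_setup()
        pc_std = [e.key for e in db if e.is_standard][0]
        corrected.loc[pc_std, "s1"] = 0.0
        ab = normalize(corrected, db, samples)
        assert ("PC", "s1") in ab.invalid
        assert np.isnan(ab.values.loc["PC 34:1", "s1"])
        assert not np.isnan(ab.values.loc["PC 34:1", "s2"])

    def test_nonpositive_protein_rejected(self):
        db, corrected, samples = _mini_setup(protein=(0.0, 1.0))
        with pytest.raises(ValueError, match="protein_mg"):
            normalize(corrected, db, samples)

    def test_standards_excluded_from_output(self):
        db, corrected, samples = _mini_setup()
        ab = normalize(corrected, db, samples)
        assert "PC 28:0" not in ab.values.index

    def test_ether_classes_use_diacyl_standard(self):
        m = default_is_map()
        assert m["PC[O]"] == m["PC"]
        assert m["PE[O]"][0] == "PE 28:0"


class TestClassTotals:
    def test_sums_members(self):
        ab_values = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0]}, index=["PC a", "PC b", "PC c"]
        )
        from lipidquant.quantify import AbundanceMatrix

        ab = AbundanceMatrix(
            values=ab_values,
            units=pd.Series("nmol_per_mg", index=ab_values.index),
            species_class=pd.Series("PC", index=ab_values.index),
        )
        totals = class_totals(ab)
        assert totals.loc["PC", "s1"] == 6.0
        assert totals.attrs["cross_class_comparable"] is False

    def test_single_species_class(self):
        from lipidquant.quantify import AbundanceMatrix

        ab = AbundanceMatrix(
            values=pd.DataFrame({"s1": [7.0]}, index=["CE 18:1"]),
            units=pd.Series("rel_per_mg", index=["CE 18:1"]),
            species_class=pd.Series("CE", index=["CE 18:1"]),
        )
        assert class_totals(ab).loc["CE", "s1"] == 7.0

    def test_mixed_units_within_class_rejected(self):
        from lipidquant.quantify import AbundanceMatrix

        ab = AbundanceMatrix(
            values=pd.DataFrame({"s1": [1.0, 2.0]}, index=["PC a", "PC b"]),
            units=pd.Series(
                ["nmol_per_mg", "rel_per_mg"], index=["PC a", "PC b"]
            ),
            species_class=pd.Series("PC", index=["PC a", "PC b"]),
        )
        with pytest.raises(ValueError, match="mixes unit"):
            class_totals(ab)

    def test_closed_loop_class_totals_recover_truth(self, study, processed):
        table, truth = study
        ab = processed["abundance"]
        totals = class_totals(ab).drop(columns="unit")
        truth_cs = truth.class_sums()
        errs = []
        for cls in truth_cs.index:
            if cls not in totals.index:
                continue
            if (ab.units[ab.species_class == cls] != "nmol_per_mg").any():
                continue
            est = totals.loc[cls]
            tru = truth_cs.loc[cls]
            mask = tru > 0
            errs.extend(np.abs(est[mask] / tru[mask] - 1.0).tolist())
        assert np.median(errs) < 0.10


class TestFoldChanges:
    def test_identical_groups_unity(self):
        v = pd.DataFrame({"a": [1.0], "b": [1.0]}, index=["x"])
        cond = pd.Series({"a": "control", "b": "patient"})
        assert fold_changes(v, cond).loc["x", "fold"] == 1.0

    def test_simple_ratio(self):
        v = pd.DataFrame({"a": [1.0], "b": [4.0]}, index=["x"])
        cond = pd.Series({"a": "control", "b": "patient"})
        assert fold_changes(v, cond).loc["x", "fold"] == 4.0

    def test_patients_only_sentinel(self):
        v = pd.DataFrame({"a": [0.0], "b": [3.0]}, index=["x"])
        cond = pd.Series({"a": "control", "b": "patient"})
        row = fold_changes(v, cond).loc["x"]
        assert row["status"] == "detected_in_patients_only"
        assert np.isnan(row["fold"])

    def test_undetected_sentinel(self):
        v = pd.DataFrame({"a": [0.0], "b": [0.0]}, index=["x"])
        cond = pd.Series({"a": "control", "b": "patient"})
        assert fold_changes(v, cond).loc["x", "status"] == "undetected"

    def test_scale_invariance(self, rng):
        v = pd.DataFrame(
            rng.uniform(1, 10, (5, 6)),
            columns=[f"s{i}" for i in range(6)],
        )
        cond = pd.Series(
            ["control"] * 3 + ["patient"] * 3, index=v.columns
        )
        f1 = fold_changes(v, cond)["fold"]
        f2 = fold_changes(v * 37.5, cond)["fold"]
        assert np.allclose(f1, f2)


class TestPufaFlag:
    @pytest.mark.parametrize(
        "carbons,dbs,expected",
        [(40, 5, True), (36, 2, False), (38, 5, True), (38, 4, False),
         (37, 6, False)],
    )
    def test_rule(self, carbons, dbs, expected):
        assert bool(flag_pufa(carbons, dbs)) is expected


class TestLinkageClassification:
    def test_low_survival_is_plasmenyl(self):
        assert classify_sn1_linkage(100.0, 2.0) == "plasmenyl"

    def test_high_survival_is_plasmanyl(self):
        assert classify_sn1_linkage(100.0, 98.0) == "plasmanyl"

    def test_undetected_untreated_is_indeterminate(self):
        assert classify_sn1_linkage(0.0, 0.0) == "indeterminate"

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_sn1_linkage(-1.0, 0.5)

    def test_table_form(self):
        pairs = pd.DataFrame(
            {"untreated": [100.0, 100.0, 0.0], "treated": [1.0, 99.0, 0.0]},
            index=["a", "b", "c"],
        )
        out = classify_hydrolysis_table(pairs)
        assert list(out["linkage_call"]) == [
            "plasmenyl", "plasmanyl", "indeterminate"
        ]


def _record(ratio, calibration=((0.0, 0.0), (100.0, 100.0 / 87.0)),
            protein=0.040):
    return EnzymeAssayRecord(
        product_area=ratio * 1000.0,
        is_area=1000.0,
        is_pmol=87.0,
        calibration=calibration,
        protein_mg=protein,
        incubation_h=1.0,
    )


class TestEnzymeActivity:
    def test_calibration_point_identity(self):
        # an area ratio equal to a calibration point returns that amount
        rec = _record(ratio=100.0 / 87.0)
        assert enzyme_activity(rec) == pytest.approx(100.0 / 0.040)

    def test_methods_constants_arithmetic(self):
        # 87 pmol product, 40 ug protein, 1 h -> 2175 pmol/h/mg
        rec = _record(ratio=1.0)
        assert enzyme_activity(rec) == pytest.approx(2175.0)

    def test_blank_subtraction(self):
        rec = _record(ratio=1.0)
        blank = _record(ratio=0.1)
        assert enzyme_activity(rec, blank=blank) == pytest.approx(
            (87.0 - 8.7) / 0.040
        )

    def test_zero_slope_calibration_rejected(self):
        rec = _record(ratio=1.0, calibration=((0.0, 0.0), (100.0, 0.0)))
        with pytest.raises(ValueError, match="slope"):
            enzyme_activity(rec)

    def test_too_few_calibration_points(self):
        rec = _record(ratio=1.0, calibration=((0.0, 0.0),))
        with pytest.raises(ValueError, match="calibration"):
            enzyme_activity(rec)

    def test_zero_is_area_rejected(self):
        rec = EnzymeAssayRecord(
            product_area=10.0, is_area=0.0,
            calibration=((0.0, 0.0), (100.0, 1.0)),
        )
        with pytest.raises(ValueError, match="internal-standard"):
            enzyme_activity(rec)
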