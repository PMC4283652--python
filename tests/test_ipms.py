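"""Stoichiometry pipeline: CV filter, protein sums, bait ratios, labels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfiihkit import ipms
from tfiihkit import synthetic as syn

from conftest import make_records


def _records_one_peptide(genotype, protein, values, pep="PEPTIDEK", charge=2):
    return make_records(
        [(genotype, protein, pep, charge, i + 1, v) for i, v in enumerate(values)]
    )


class TestComputePeptideCv:
    @pytest.mark.parametrize(
        "values, cv, accepted",
        [
            ((100, 100, 100), 0.0, True),
            ((100, 120, 80), 0.2, True),          # sd=20, mean=100
            ((10, 200, 300), 0.86651, False),     # sd~147.31, mean=170
        ],
    )
    def test_hand_computed_examples(self, values, cv, accepted):
        out = ipms.compute_peptide_cv(_records_one_peptide("g", "Xpd", values))
        assert out.loc[0, "cv"] == pytest.approx(cv, abs=1e-4)
        assert bool(out.loc[0, "accepted"]) is accepted

    def test_single_observation_has_no_cv_and_is_rejected(self):
        rec = _records_one_peptide("g", "Xpd", (100, np.nan, np.nan))
        out = ipms.compute_peptide_cv(rec)
        assert np.isnan(out.loc[0, "cv"]) and not out.loc[0, "accepted"]

    def test_zero_mean_rejected(self):
        out = ipms.compute_peptide_cv(_records_one_peptide("g", "Xpd", (0, 0, 0)))
        assert not out.loc[0, "accepted"]

    def test_negative_intensity_is_an_input_error(self):
        with pytest.raises(ValueError, match="negative"):
            ipms.compute_peptide_cv(_records_one_peptide("g", "Xpd", (10, -1, 10)))

    def test_accepted_implies_cv_below_threshold(self):
        rng = np.random.default_rng(0)
        rows = []
        for j in range(50):
            vals = rng.lognormal(5, rng.uniform(0.05, 1.2), size=3)
            rows.extend(
                ("g", "Xpd", f"PEP{j}K", 2, i + 1, v) for i, v in enumerate(vals)
            )
        out = ipms.compute_peptide_cv(make_records(rows), cv_threshold=0.5)
        acc = out[out["accepted"]]
        assert (acc["cv"] < 0.5).all() and acc["cv"].notna().all()


class TestAggregateProtein:
    def test_sums_accepted_peptide_injection_sums(self):
        rec = pd.concat(
            [
                _records_one_peptide("g", "Xpd", (100, 100, 100), pep="AAK"),
                _records_one_peptide("g", "Xpd", (300, 300, 300), pep="CCK"),
            ]
        )
        q = ipms.compute_peptide_cv(rec)
        out = ipms.aggregate_protein(q, rec)
        assert out.loc[0, "summed_intensity"] == pytest.approx(1200)
        assert out.loc[0, "n_peptides_used"] == 2
        assert not out.loc[0, "single_peptide_flag"]

    def test_all_rejected_reported_missing_and_flagged(self):
        rec = _records_one_peptide("g", "Hay", (10, 200, 300))
        q = ipms.compute_peptide_cv(rec)
        out = ipms.aggregate_protein(q, rec)
        assert np.isnan(out.loc[0, "summed_intensity"])
        assert out.loc[0, "n_peptides_used"] == 0

    def test_matches_brute_force_resummation(self, inventory):
        rec = syn.simulate_ip_intensities(
            syn.default_genotype_models(), inventory, seed=42
        )
        q = ipms.compute_peptide_cv(rec)
        out = ipms.aggregate_protein(q, rec).set_index(["genotype", "protein_id"])
        accepted = set(map(tuple, q.loc[q["accepted"], ipms.PEPTIDE_KEY].values))
        # independent oracle: python loop over raw records
        brute: dict = {}
        for row in rec.itertuples(index=False):
            key = (row.genotype, row.protein_id, row.peptide_sequence, row.charge_state)
            if key in accepted and not pd.isna(row.intensity):
                brute[(row.genotype, row.protein_id)] = (
                    brute.get((row.genotype, row.protein_id), 0.0) + row.intensity
                )
        for key, total in brute.items():
            assert out.loc[key, "summed_intensity"] == pytest.approx(total)


def _profile_from(mapping, genotype="g"):
    rows = []
    for protein, val in mapping.items():
        rows.append((genotype, protein, val, 3, False))
    df = pd.DataFrame(
        rows, columns=["genotype", "protein_id", "summed_intensity",
                       "n_peptides_used", "single_peptide_flag"],
    )
    return df


class TestBaitNormalize:
    def test_simple_division_and_self_ratio(self):
        prof = ipms.bait_normalize(_profile_from({"Cdk7": 1000, "Xpd": 250}))
        r = prof.set_index("protein_id")["ratio_to_bait"]
        assert r["Xpd"] == pytest.approx(0.25)
        assert r["Cdk7"] == 1.0

    @given(scale=st.floats(0.01, 1000))
    @settings(deadline=None, derandomize=True)
    def test_scale_invariance(self, scale):
        base = {"Cdk7": 900.0, "Xpd": 300.0, "Hay": 90.0}
        a = ipms.bait_normalize(_profile_from(base))
        b = ipms.bait_normalize(
            _profile_from({k: v * scale for k, v in base.items()})
        )
        np.testing.assert_allclose(a["ratio_to_bait"], b["ratio_to_bait"])

    def test_missing_bait_names_genotype(self):
        with pytest.raises(ValueError, match="'g'"):
            ipms.bait_normalize(_profile_from({"Xpd": 250}))
        with pytest.raises(ValueError, match="'g'"):
            ipms.bait_normalize(_profile_from({"Cdk7": np.nan, "Xpd": 1.0}))


def _two_genotype_profiles(wt_ratios, mut_ratios):
    frames = []
    for genotype, ratios in (("xpd_wt", wt_ratios), ("mut", mut_ratios)):
        df = _profile_from({k: v * 1000 for k, v in ratios.items()}, genotype)
        frames.append(ipms.bait_normalize(df))
    return pd.concat(frames, ignore_index=True)


class TestFoldReduction:
    def test_ratio_of_ratios(self):
        prof = _two_genotype_profiles(
            {"Cdk7": 1, "Xpd": 0.4}, {"Cdk7": 1, "Xpd": 0.1}
        )
        folds = ipms.fold_reduction(prof)
        mut = folds.query("genotype == 'mut' and protein_id == 'Xpd'").iloc[0]
        assert mut["fold_vs_wildtype"] == pytest.approx(0.25)
        assert mut["fold_vs_bait"] == pytest.approx(10.0)

    def test_identity_on_identical_profiles(self):
        prof = _two_genotype_profiles(
            {"Cdk7": 1, "Xpd": 0.5, "Hay": 0.2}, {"Cdk7": 1, "Xpd": 0.5, "Hay": 0.2}
        )
        folds = ipms.fold_reduction(prof)
        np.testing.assert_allclose(folds["fold_vs_wildtype"], 1.0)

    def test_zero_mutant_ratio_flagged_infinite(self):
        prof = _two_genotype_profiles({"Cdk7": 1, "Hay": 0.2}, {"Cdk7": 1, "Hay": 0.0})
        row = ipms.fold_reduction(prof).query(
            "genotype == 'mut' and protein_id == 'Hay'"
        ).iloc[0]
        assert row["fold_vs_wildtype"] == 0.0
        assert np.isinf(row["fold_vs_bait"]) and row["undetected_flag"]

    def test_mismatched_protein_sets_rejected(self):
        prof = _two_genotype_profiles({"Cdk7": 1, "Xpd": 0.5}, {"Cdk7": 1, "Xpd": 0.5})
        prof = prof[~((prof["genotype"] == "mut") & (prof["protein_id"] == "Xpd"))]
        with pytest.raises(ValueError, match="differs"):
            ipms.fold_reduction(prof)


def _simulate_and_classify(cak_factor, core_factor, seed, noise=None):
    wt = syn.ComplexPoolModel() if noise is None else syn.ComplexPoolModel(noise_sigma=noise)
    models = {"xpd_wt": wt, "mut": wt.perturbed(cak_factor, core_factor)}
    rec = syn.simulate_ip_intensities(models, syn.default_peptide_inventory(), seed=seed)
    q = ipms.compute_peptide_cv(rec)
    prof = ipms.bait_normalize(ipms.aggregate_protein(q, rec))
    folds = ipms.fold_reduction(prof)
    return ipms.classify_interactions(folds).set_index("genotype").loc["mut"]


class TestClassifyInteractions:
    def test_unchanged_profiles_labelled_none(self):
        row = _simulate_and_classify(1.0, 1.0, seed=0, noise=0.0)
        assert row["labels"] == ("none",)

    def test_cak_binding_reduction_recovered(self):
        row = _simulate_and_classify(1 / 3, 1.0, seed=1, noise=0.0)
        assert row["labels"] == ("reduced_xpd_cak",)
        assert row["xpd_fold_vs_wildtype"] == pytest.approx(1 / 3)

    def test_core_reduction_with_enhanced_cak_recovered(self):
        row = _simulate_and_classify(2.0, 1 / 4, seed=2, noise=0.0)
        assert set(row["labels"]) == {"enhanced_xpd_cak", "reduced_xpd_core_strong"}
        assert row["core_vs_xpd_fold_vs_wildtype"] == pytest.approx(0.25)

    def test_bad_thresholds_rejected(self):
        folds = ipms.fold_reduction(
            _two_genotype_profiles({"Cdk7": 1, "Xpd": 0.5, "Hay": 0.1, "Mrn": 0.1},
                                   {"Cdk7": 1, "Xpd": 0.5, "Hay": 0.1, "Mrn": 0.1})
        )
        with pytest.raises(ValueError):
            ipms.classify_interactions(folds, down_threshold=1.0)


class TestCakQc:
    def test_identical_profiles_pass_with_zero_deviation(self):
        prof = _two_genotype_profiles(
            {"Cdk7": 1, "CycH": 0.8, "Mat1": 1.2}, {"Cdk7": 1, "CycH": 0.8, "Mat1": 1.2}
        )
        qc = ipms.cak_stoichiometry_qc(prof)
        assert qc.max_cv == pytest.approx(0.0) and qc.passed

    def test_halved_mat1_fails(self):
        prof = _two_genotype_profiles(
            {"Cdk7": 1, "CycH": 0.8, "Mat1": 1.2}, {"Cdk7": 1, "CycH": 0.8, "Mat1": 0.6}
        )
        assert not ipms.cak_stoichiometry_qc(prof, tolerance=0.2).passed

    def test_needs_two_genotypes(self):
        prof = ipms.bait_normalize(_profile_from({"Cdk7": 1, "CycH": 0.8, "Mat1": 1}))
        with pytest.raises(ValueError):
            ipms.cak_stoichiometry_qc(prof)


class TestLoadingControlNormalize:
    @staticmethod
    def _bands(percents, ref=100.0):
        rows = []
        for rep, pct in enumerate(percents, start=1):
            rows.append(("xpd_wt", rep, 50.0, 50.0))
            rows.append(("mut", rep, 50.0 * pct / ref, 50.0))
        return pd.DataFrame(
            rows, columns=["sample", "replicate", "target_intensity",
                           "control_intensity"],
        )

    def test_single_replicate_percent(self):
        out = ipms.loading_control_normalize(self._bands([62.0]), "xpd_wt")
        assert out.set_index("sample").loc["mut", "mean_percent"] == pytest.approx(62.0)

    def test_reference_is_always_100(self):
        out = ipms.loading_control_normalize(self._bands([62, 58, 69]), "xpd_wt")
        ref = out.set_index("sample").loc["xpd_wt"]
        assert ref["mean_percent"] == pytest.approx(100.0)
        assert ref["sem_percent"] == pytest.approx(0.0)

    def test_mean_and_sem_over_replicates(self):
        # sd of (60,62,64) is 2 -> sem = 2/sqrt(3)
        out = ipms.loading_control_normalize(self._bands([60, 62, 64]), "xpd_wt")
        mut = out.set_index("sample").loc["mut"]
        assert mut["mean_percent"] == pytest.approx(62.0)
        assert mut["sem_percent"] == pytest.approx(2 / np.sqrt(3))

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            ipms.loading_control_normalize(self._bands([62]), "nope")


@given(scale=st.floats(0.1, 100))
@settings(deadline=None, derandomize=True, max_examples=20)
def test_full_chain_scale_invariance(scale, inventory):
    """Rescaling one genotype's raw intensities changes no downstream result."""
    rec = syn.simulate_ip_intensities(
        {"xpd_wt": syn.ComplexPoolModel(),
         "mut": syn.ComplexPoolModel().perturbed(0.5, 0.5)},
        inventory, seed=3,
    )
    scaled = rec.copy()
    scaled.loc[scaled["genotype"] == "mut", "intensity"] *= scale

    def chain(records):
        q = ipms.compute_peptide_cv(records)
        prof = ipms.bait_normalize(ipms.aggregate_protein(q, records))
        folds = ipms.fold_reduction(prof)
        return folds, ipms.classify_interactions(folds)

    folds_a, labels_a = chain(rec)
    folds_b, labels_b = chain(scaled)
    np.testing.assert_allclose(
        folds_a["fold_vs_wildtype"], folds_b["fold_vs_wildtype"], rtol=1e-9
    )
    assert labels_a["labels"].tolist() == labels_b["labels"].tolist()
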