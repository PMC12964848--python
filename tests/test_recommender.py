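"""Case-based recommender: similarity law, case DB, matching and overrides."""

import numpy as np
import pandas as pd
import pytest

from dfu_trajectory.recommender import (
    EmptyCaseDatabaseError,
    TierConfig,
    build_case_db,
    case_features,
    evaluate_recommender,
    integrate,
    offloading_match,
    recommend,
    similarity,
)

from conftest import make_cohort


def _tier(tiers):
    return TierConfig(tiers=tiers)


class TestSimilarity:
    def test_identical_presentations_score_one(self):
        cfg = _tier({"critical": (3.0, {"phase": "binary", "sev": "continuous"})})
        q = {"phase": "P", "sev": 2.0}
        assert similarity(q, dict(q), cfg, ranges={"sev": (0, 3)}) == 1.0

    def test_fully_opposed_presentations_score_zero(self):
        cfg = _tier({"a": (2.0, {"phase": "binary"}), "b": (1.0, {"sev": "continuous"})})
        q = {"phase": "I", "sev": 0.0}
        c = {"phase": "R", "sev": 3.0}
        assert similarity(q, c, cfg, ranges={"sev": (0, 3)}) == 0.0

    def test_hand_evaluated_two_tier_formula(self):
        # tier weights 3 (two binary: one match, one mismatch) and 1 (one
        # continuous at normalized distance 0.5):
        # (3*(1+0) + 1*0.5) / (3*2 + 1*1) = 3.5/7 = 0.5
        cfg = _tier({"hi": (3.0, {"f1": "binary", "f2": "binary"}), "lo": (1.0, {"g": "continuous"})})
        q = {"f1": "x", "f2": "y", "g": 0.25}
        c = {"f1": "x", "f2": "z", "g": 0.75}
        assert similarity(q, c, cfg, ranges={"g": (0.0, 1.0)}) == pytest.approx(0.5)

    def test_missing_feature_counts_in_denominator(self):
        cfg = _tier({"t": (1.0, {"a": "binary", "b": "binary"})})
        assert similarity({"a": "x", "b": np.nan}, {"a": "x", "b": "x"}, cfg) == 0.5

    def test_empty_tier_config_rejected(self):
        with pytest.raises(ValueError):
            similarity({}, {}, _tier({}))

    def test_bounds_symmetry_and_weight_monotonicity(self, rng):
        """1,000 random tier configs: similarity stays in [0,1], is symmetric,
        equals 1 iff every local similarity is 1, and raising the weight of a
        tier on which the presentations fully differ never raises the score."""
        for _ in range(1000):
            tiers, q, c = {}, {}, {}
            perfect = True
            n_tiers = int(rng.integers(1, 4))
            for t in range(n_tiers):
                feats = {}
                for f in range(int(rng.integers(1, 4))):
                    name = f"t{t}f{f}"
                    if rng.random() < 0.5:
                        feats[name] = "binary"
                        q[name] = "A"
                        c[name] = "A" if rng.random() < 0.5 else "B"
                        perfect &= q[name] == c[name]
                    else:
                        feats[name] = "continuous"
                        q[name], c[name] = rng.random(), rng.random()
                        perfect &= q[name] == c[name]
                tiers[f"tier{t}"] = (float(rng.uniform(0.5, 4.0)), feats)
            cfg = _tier(tiers)
            ranges = {n: (0.0, 1.0) for n, k in cfg.feature_kinds().items() if k == "continuous"}
            s = similarity(q, c, cfg, ranges)
            assert 0.0 <= s <= 1.0
            assert s == pytest.approx(similarity(c, q, cfg, ranges))
            assert (s == pytest.approx(1.0)) == perfect

            # find a tier with all-zero local sims, then double its weight
            for tname, (w, feats) in tiers.items():
                def local(n, kind):
                    return (q[n] == c[n]) if kind == "binary" else 1 - abs(q[n] - c[n])
                if all(local(n, k) == 0 for n, k in feats.items()):
                    bumped = dict(tiers)
                    bumped[tname] = (2 * w, feats)
                    assert similarity(q, c, _tier(bumped), ranges) <= s + 1e-12
                    break


class TestCaseDatabase:
    def test_no_improving_wound_means_empty_db(self):
        ct = make_cohort(
            {"A/W": [("2023-01-01", "P"), ("2023-02-15", "I")]},
            offloading_type="none", dressing_type="betadine",
        )
        with pytest.raises(EmptyCaseDatabaseError):
            build_case_db(ct)

    def test_single_improvement_enters_db(self):
        ct = make_cohort(
            {"A/W": [("2023-01-01", "I"), ("2023-01-20", "P"), ("2023-03-20", "P")]},
            offloading_type="removable_walker", dressing_type="foam",
        )
        db = build_case_db(ct)
        assert len(db.cases) == 1
        assert db.cases.iloc[0]["case_id"] == "A/W@0"
        assert db.cases.iloc[0]["offloading_type"] == "removable_walker"
        assert db.cases.iloc[0]["outcome"] == "progression"

    def test_maintained_remodeling_qualifies(self):
        ct = make_cohort(
            {"A/W": [("2023-01-01", "R"), ("2023-02-01", "R"), ("2023-03-01", "R")]},
            offloading_type="none", dressing_type="saline_gauze",
        )
        db = build_case_db(ct)
        assert len(db.cases) == 2  # both R->R maintenance visits qualify
        assert set(db.cases["outcome"]) == {"maintained_remodeling"}


def _clustered_db(rng):
    """Two treatment clusters: inflamed severe wounds get moderate offloading
    (level 2) + foam; quiet remodeling wounds get none + saline gauze."""
    wounds = {}
    extra = {}
    rows = []
    for i in range(30):
        for cluster, phases, dev, dress in (
            ("A", ("I", "P"), "removable_walker", "foam"),
            ("B", ("R", "R"), "none", "saline_gauze"),
        ):
            sev = 3 if cluster == "A" else 0
            rows.append(
                dict(
                    patient_id=f"{cluster}{i}", wound_id=f"{cluster}{i}-W",
                    appointment_date="2023-01-01", wound_onset_date="2022-12-20",
                    healing_phase=phases[0], wound_severity=sev,
                    exudate_amount=3 if cluster == "A" else 0,
                    age=60 + rng.integers(-5, 6), bmi=28.0,
                    claw_toe=cluster == "A", charcot=False, hammer_toe=False, bunion=False,
                    wound_location="heel" if cluster == "A" else "toe",
                    offloading_type=dev, dressing_type=dress,
                )
            )
            rows.append(
                dict(
                    patient_id=f"{cluster}{i}", wound_id=f"{cluster}{i}-W",
                    appointment_date="2023-01-25", wound_onset_date="2022-12-20",
                    healing_phase=phases[1], wound_severity=sev,
                    offloading_type=dev, dressing_type=dress,
                )
            )
    from dfu_trajectory.cohort_model import build_cohort

    return build_case_db(build_cohort(pd.DataFrame(rows)))


class TestRecommend:
    def test_single_case_db_returns_it(self):
        ct = make_cohort(
            {"A/W": [("2023-01-01", "I"), ("2023-01-20", "P")]},
            offloading_type="total_contact_cast", dressing_type="iodosorb",
        )
        db = build_case_db(ct)
        q = case_features(ct.data.iloc[0])
        rec = recommend(q, db, top_k=5)
        assert rec.offloading_device == "total_contact_cast"
        assert rec.dressing == "iodosorb"
        assert rec.confidence == pytest.approx(
            similarity(q, dict(db.cases.iloc[0]), db.tier_config, db.ranges)
        )

    def test_unanimous_top_k(self, rng):
        db = _clustered_db(rng)
        q = {
            "healing_phase": "I", "charcot": False, "deformity_severity": 2.0,
            "wound_location": "heel", "wound_severity": 3, "chronicity_stage": 0.0,
            "age": 60, "bmi": 28.0, "exudate_amount": 3, "moisture_need": 3.0,
            "infection_risk": 0.0, "mobility_risk": 0.0, "neuropathy": False,
        }
        rec = recommend(q, db, top_k=5)
        assert rec.offloading_device == "removable_walker"
        assert rec.dressing == "foam"
        assert len(rec.matched_case_ids) == 5

    def test_planted_cluster_recovered_for_noisy_queries(self, rng):
        db = _clustered_db(rng)
        hits = 0
        for _ in range(200):
            q = {
                "healing_phase": "I" if rng.random() < 0.7 else "P",
                "charcot": False,
                "deformity_severity": float(rng.integers(0, 4)),
                "wound_location": "heel" if rng.random() < 0.8 else "forefoot",
                "wound_severity": int(rng.integers(2, 4)),
                "chronicity_stage": 0.0,
                "age": float(rng.normal(60, 8)),
                "bmi": float(rng.normal(28, 3)),
                "exudate_amount": int(rng.integers(2, 4)),
                "moisture_need": float(rng.integers(2, 5)),
                "infection_risk": 0.0,
                "mobility_risk": float(rng.integers(0, 2)),
                "neuropathy": False,
            }
            rec = recommend(q, db, top_k=5)
            hits += rec.offloading_level == 2
        assert hits / 200 >= 0.90

    def test_empty_db_rejected(self):
        from dfu_trajectory.recommender import CaseDatabase

        empty = CaseDatabase(cases=pd.DataFrame(), ranges={}, tier_config=TierConfig())
        with pytest.raises(EmptyCaseDatabaseError):
            recommend({}, empty)


class TestOffloadingMatch:
    def test_adjacent_intensity_within_category(self):
        m = offloading_match("removable_walker", "therapeutic_footwear")
        assert m == {"exact": False, "within_category": True}

    def test_identical_devices(self):
        m = offloading_match("total_contact_cast", "total_contact_cast")
        assert m == {"exact": True, "within_category": True}

    def test_extreme_levels_not_within_category(self):
        m = offloading_match("none", "total_contact_cast")
        assert m == {"exact": False, "within_category": False}

    def test_unmapped_device_named_in_error(self):
        with pytest.raises(KeyError, match="hoverboard"):
            offloading_match("hoverboard", "none")


class TestEvaluateRecommender:
    def test_perfect_agreement_rates(self):
        ct = make_cohort(
            {"A/W": [("2023-01-01", "I"), ("2023-01-20", "P")]},
            offloading_type="removable_walker", dressing_type="foam",
        )
        db = build_case_db(ct)
        rep = evaluate_recommender(ct, db)
        assert rep["offloading_exact_rate"] == 1.0
        assert rep["offloading_within_category_rate"] == 1.0

    def test_per_chronicity_bin_counting(self):
        train = make_cohort(
            {"T/W": [("2023-06-01", "I"), ("2023-06-20", "P")]},
            offloading_type="none", dressing_type="betadine",
        )
        db = build_case_db(train)
        rows = []
        for wid, onset_age, dress in (
            ("V1", 30, "betadine"), ("V2", 120, "foam"),
            ("V3", 300, "betadine"), ("V4", 500, "foam"),
        ):
            date = np.datetime64("2023-06-01")
            rows.append(
                dict(
                    patient_id=wid, wound_id=wid, appointment_date=str(date),
                    wound_onset_date=str(date - onset_age), healing_phase="P",
                    offloading_type="none", dressing_type=dress,
                )
            )
        from dfu_trajectory.cohort_model import build_cohort

        rep = evaluate_recommender(build_cohort(pd.DataFrame(rows)), db)
        assert rep["dressing_match_rate_by_chronicity"] == {
            "acute": 1.0, "subacute": 0.0, "chronic": 1.0, "very_chronic": 0.0,
        }

    def test_empty_bin_reported_missing(self):
        ct = make_cohort(
            {"A/W": [("2023-01-01", "I"), ("2023-01-20", "P")]},
            offloading_type="none", dressing_type="betadine",
        )
        rep = evaluate_recommender(ct, build_case_db(ct))
        assert np.isnan(rep["dressing_match_rate_by_chronicity"]["very_chronic"])


class TestIntegrate:
    def _setup(self):
        ct = make_cohort(
            {"A/W": [("2023-01-01", "I"), ("2023-01-20", "P")]},
            offloading_type="none", dressing_type="betadine",
        )
        db = build_case_db(ct)
        q = case_features(ct.data.iloc[0])
        return db, {("W", 0): q, ("W", 1): q, ("W", 2): q}

    def _preds(self, cats):
        return pd.DataFrame(
            [{"wound_id": "W", "target_index": i, "y_pred": c} for i, c in enumerate(cats)]
        )

    def test_no_unfavorable_no_recommendations(self):
        db, queries = self._setup()
        out = integrate(self._preds(["favorable", "acceptable"]), queries, db)
        assert out.empty

    def test_all_unfavorable_all_recommended(self):
        db, queries = self._setup()
        out = integrate(self._preds(["unfavorable"] * 3), queries, db)
        assert len(out) == 3

    def test_mixed_predictions_flag_exact_subset(self):
        db, queries = self._setup()
        out = integrate(self._preds(["unfavorable", "favorable", "unfavorable"]), queries, db)
        assert sorted(out["target_index"]) == [0, 2]
        out_all = integrate(
            self._preds(["unfavorable", "favorable", "unfavorable"]), queries, db,
            only_unfavorable=False,
        )
        assert len(out_all) == 3


class TestPrintedCaseOne:
    """The worked clinical example: a 58-year-old woman with type 1 diabetes,
    an acute (33-day) mildly exuding proliferative toe wound and high
    structural deformity (claw + hammer toe). The system recommends moderate
    offloading (boot / removable cast walker) with betadine; the clinician
    chose therapeutic footwear + betadine."""

    def _case1_query(self):
        return {
            "healing_phase": "P", "charcot": False, "deformity_severity": 4.0,
            "wound_location": "toe", "wound_severity": 1, "chronicity_stage": 0.0,
            "age": 58.0, "bmi": 20.3, "exudate_amount": 1, "moisture_need": 1.0,
            "infection_risk": 0.0, "mobility_risk": 0.0, "neuropathy": False,
        }

    def _db(self):
        # successful proliferative toe wounds treated with a removable walker
        # and betadine - the presentations the printed recommendation matches
        return build_case_db(
            make_cohort(
                {f"D{i}/W": [("2023-01-01", "P"), ("2023-02-01", "R")] for i in range(6)},
                onset="2022-12-10",
                offloading_type="removable_walker", dressing_type="betadine",
                wound_severity=1, exudate_amount=1, age=60.0, bmi=22.0,
                wound_location="toe", charcot=False, claw_toe=True, hammer_toe=True,
                bunion=False,
            )
        )

    def test_offloading_within_category_but_not_exact_dressing_exact(self):
        rec = recommend(self._case1_query(), self._db(), top_k=5)
        assert rec.offloading_device == "removable_walker"
        assert rec.offloading_level == 2
        assert rec.dressing == "betadine"
        actual_offloading, actual_dressing = "therapeutic_footwear", "betadine"
        m = offloading_match(rec.offloading_device, actual_offloading)
        assert m["exact"] is False and m["within_category"] is True
        assert rec.dressing == actual_dressing

    def test_high_deformity_override_enforces_protection(self):
        """Even when the matched cases wore light footwear, deformity >= 4
        raises the recommendation to moderate protection."""
        db = build_case_db(
            make_cohort(
                {"L/W": [("2023-01-01", "P"), ("2023-02-01", "R")]},
                onset="2022-12-10",
                offloading_type="therapeutic_footwear", dressing_type="betadine",
            )
        )
        rec = recommend(self._case1_query(), db, top_k=5)
        assert rec.offloading_level >= 2
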