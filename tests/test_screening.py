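import numpy as np
import pandas as pd
import pytest

from phenoscreen import screening, synthetic_data as sd
from phenoscreen import phenoscore as ph
from phenoscreen.errors import InvalidInputError, MissingDataError
from phenoscreen.profile_core import StimulusEvent, StimulusTrain


def _noise_free_dmso(battery):
    return sd.generate_well_profile(
        sd.CLASS_DEFAULTS["dmso"], None, 0.0, battery, seed=0, noise_free=True
    )


class TestImmobilizationIndex:
    def test_vehicle_like_profile_scores_zero(self, battery):
        p = _noise_free_dmso(battery)
        median = screening.dmso_violet_median([p])
        assert screening.immobilization_index(p, median) == pytest.approx(0.0)

    def test_silent_profile_scores_one(self, battery):
        p = _noise_free_dmso(battery)
        median = screening.dmso_violet_median([p])
        silent = p.with_metadata(mi=np.zeros_like(p.mi))
        assert screening.immobilization_index(silent, median) == pytest.approx(1.0)

    def test_half_response_scores_half(self, battery):
        p = _noise_free_dmso(battery)
        median = screening.dmso_violet_median([p])
        halved = p.with_metadata(mi=0.5 * p.mi)
        assert screening.immobilization_index(halved, median) == pytest.approx(0.5)

    def test_battery_without_violet_events_is_an_error(self):
        train = StimulusTrain(
            (StimulusEvent("acoustic_low", 1.0, 0.1),), total_duration_s=30.0
        )
        p = sd.generate_well_profile(
            sd.CLASS_DEFAULTS["dmso"], None, 0.0, train, seed=0, noise_free=True
        )
        with pytest.raises(InvalidInputError):
            screening.immobilization_index(p, 1.0)


def _toy_table(scores: dict, immobilization: float = 0.0) -> pd.DataFrame:
    rows = [
        {"compound_id": cid, "well_id": f"{cid}_w", "phenoscore": s,
         "immobilization_index": immobilization, "total_mi": 1.0,
         "concentration_uM": 10.0, "call": ""}
        for cid, s in scores.items()
    ]
    return pd.DataFrame(rows, columns=screening.SCREEN_COLUMNS)


class TestRankAndCall:
    def test_top_k_rule_returns_exactly_k_hits(self):
        rng = np.random.default_rng(0)
        table = _toy_table({f"C{i:03d}": float(rng.uniform()) for i in range(200)})
        called = screening.rank_and_call(table, k_hits=125)
        assert (called["call"] == "hit").sum() == 125

    def test_ties_broken_lexicographically(self):
        table = _toy_table({f"C{i}": 0.5 for i in range(6)})
        called = screening.rank_and_call(table, k_hits=3)
        hits = sorted(called.loc[called["call"] == "hit", "compound_id"])
        assert hits == ["C0", "C1", "C2"]
        again = screening.rank_and_call(table, k_hits=3)
        assert called.equals(again)

    def test_recovers_planted_hits(self, screen_case):
        _, library, table = screen_case
        called = screening.rank_and_call(table, k_hits=20)
        hits = set(called.loc[called["call"] == "hit", "compound_id"])
        planted = set(
            library.truth.loc[library.truth["phenotype"] == "etomidate_like", "compound_id"]
        )
        precision = len(hits & planted) / len(hits)
        recall = len(hits & planted) / len(planted)
        assert precision >= 0.95 and recall >= 0.95

    def test_toxic_calls_catch_planted_toxics(self, screen_case):
        _, library, table = screen_case
        called = screening.rank_and_call(table, k_hits=20)
        toxic_called = set(called.loc[called["call"] == "toxic", "compound_id"])
        planted_toxic = set(
            library.truth.loc[library.truth["phenotype"] == "toxic", "compound_id"]
        )
        assert planted_toxic <= toxic_called

    def test_calls_partition_compounds(self, screen_case):
        _, _, table = screen_case
        called = screening.rank_and_call(table, k_hits=20)
        per_compound = called.groupby("compound_id")["call"].nunique()
        assert (per_compound == 1).all()
        calls = set(called["call"])
        assert calls <= {"hit", "toxic", "inactive", "control"}

    def test_monotone_in_phenoscore(self):
        rng = np.random.default_rng(1)
        scores = {f"C{i:03d}": float(rng.uniform()) for i in range(30)}
        table = _toy_table(scores)
        called = screening.rank_and_call(table, k_hits=10)
        hits = set(called.loc[called["call"] == "hit", "compound_id"])
        promoted = next(iter(hits))
        table.loc[table["compound_id"] == promoted, "phenoscore"] += 0.5
        called2 = screening.rank_and_call(table, k_hits=10)
        assert called2.loc[called2["compound_id"] == promoted, "call"].iloc[0] == "hit"

    def test_invalid_k_rejected(self):
        table = _toy_table({"A": 0.1, "B": 0.2})
        with pytest.raises(InvalidInputError):
            screening.rank_and_call(table, k_hits=0)
        with pytest.raises(InvalidInputError):
            screening.rank_and_call(table, k_hits=3)


class TestDoseResponseFit:
    def test_noise_free_recovery_within_one_percent(self):
        conc = np.array(sd.default_dose_ladder())
        y = 1.0 / (1.0 + (1.0 / conc) ** 2)
        fit = screening.fit_dose_response(conc, y)
        assert fit.converged
        assert fit.ec50_uM == pytest.approx(1.0, rel=0.01)
        assert fit.hill == pytest.approx(2.0, rel=0.05)

    def test_flat_response_not_reported_as_converged(self):
        conc = np.array(sd.default_dose_ladder())
        fit = screening.fit_dose_response(conc, np.full_like(conc, 0.3))
        assert not fit.converged

    def test_unit_relabeling_scales_ec50_only(self):
        conc = np.array(sd.default_dose_ladder())
        y = 1.0 / (1.0 + (1.0 / conc) ** 2)
        fit_uM = screening.fit_dose_response(conc, y)
        fit_nM = screening.fit_dose_response(conc * 1000.0, y)
        assert fit_nM.ec50_uM == pytest.approx(1000.0 * fit_uM.ec50_uM, rel=1e-6)
        assert fit_nM.hill == pytest.approx(fit_uM.hill, rel=1e-6)

    def test_noisy_recovery_median_log_error(self, ec50_recovery_errors):
        assert np.median(ec50_recovery_errors) <= 0.15

    def test_needs_four_distinct_concentrations(self):
        with pytest.raises(InvalidInputError):
            screening.fit_dose_response([1.0, 1.0, 10.0, 10.0], [0, 0, 1, 1])


class TestEfficacyWindow:
    def test_interior_window(self):
        table = pd.DataFrame({
            "concentration_uM": [0.1, 1.0, 10.0, 100.0],
            "phenoscore": [0.1, 0.8, 0.9, 0.2],
        })
        win = screening.efficacy_window(table, strong_cutoff=0.5)
        assert win.window == (1.0, 10.0)
        assert win.strengths == ("weak", "strong", "strong", "weak")

    def test_all_weak_gives_empty_window(self):
        table = pd.DataFrame({"concentration_uM": [1.0, 10.0], "phenoscore": [0.1, 0.2]})
        win = screening.efficacy_window(table, strong_cutoff=0.5)
        assert win.window == () and win.width == 0

    def test_first_longest_run_wins_ties(self):
        table = pd.DataFrame({
            "concentration_uM": [0.1, 1.0, 10.0, 100.0],
            "phenoscore": [0.8, 0.1, 0.8, 0.1],
        })
        win = screening.efficacy_window(table, strong_cutoff=0.5)
        assert win.window == (0.1,)

    def test_bell_shaped_compound_excludes_top_concentration(self, battery):
        """A two-arm dose law loses the phenotype at high dose, so the
        window must exclude the top of the ladder."""
        bell = sd.DoseLaw(ec50_uM=1.0, ec50_hi_uM=20.0)
        archetype = sd.generate_well_profile(
            sd.CLASS_DEFAULTS["etomidate_like"], sd.ETOMIDATE_LIKE_DOSE_LAW,
            6.25, battery, seed=0, noise_free=True,
        )
        wells = sd.generate_dose_series(
            sd.CLASS_DEFAULTS["etomidate_like"], bell, replicates=2, seed=1
        )
        rows = [
            {"concentration_uM": w.concentration_uM,
             "phenoscore": ph.phenoscore(w, archetype.mi).phenoscore}
            for w in wells
        ]
        win = screening.efficacy_window(pd.DataFrame(rows), strong_cutoff=0.5)
        assert win.width >= 1
        assert max(win.concentrations) not in win.window

    def test_empty_table_rejected(self):
        with pytest.raises(InvalidInputError):
            screening.efficacy_window(pd.DataFrame(columns=["concentration_uM", "phenoscore"]), 0.5)


class TestReproducibilityRate:
    def test_printed_bookkeeping_counts(self):
        """46 of 57 primary hits confirming at >= 1 concentration -> 80.7%."""
        rows = []
        for i in range(57):
            passes = i < 46
            for conc in (1.0, 10.0):
                rows.append({
                    "compound_id": f"H{i:02d}",
                    "concentration_uM": conc,
                    "phenoscore": 0.9 if (passes and conc == 10.0) else 0.1,
                })
        rate = screening.reproducibility_rate(
            [f"H{i:02d}" for i in range(57)], pd.DataFrame(rows), strong_cutoff=0.5
        )
        assert rate == pytest.approx(46 / 57)
        assert round(rate, 3) == 0.807

    def test_all_pass(self):
        retests = pd.DataFrame({
            "compound_id": ["A", "B"], "concentration_uM": [1.0, 1.0],
            "phenoscore": [0.9, 0.8],
        })
        assert screening.reproducibility_rate(["A", "B"], retests, 0.5) == 1.0

    def test_missing_retests_listed(self):
        retests = pd.DataFrame({
            "compound_id": ["A"], "concentration_uM": [1.0], "phenoscore": [0.9]
        })
        with pytest.raises(MissingDataError, match="B"):
            screening.reproducibility_rate(["A", "B"], retests, 0.5)

    def test_ground_truth_bookkeeping(self):
        """Planted hits keep their dose law, decoys flat: the rate equals the
        planted fraction exactly."""
        rng = np.random.default_rng(0)
        rows, hits = [], []
        for i in range(20):
            cid = f"X{i:02d}"
            hits.append(cid)
            active = i < 12
            for conc in (0.1, 1.0, 10.0):
                score = 0.7 / (1 + (1.0 / conc) ** 2) if active else 0.05
                rows.append({"compound_id": cid, "concentration_uM": conc,
                             "phenoscore": score + rng.normal(0, 1e-3)})
        rate = screening.reproducibility_rate(hits, pd.DataFrame(rows), strong_cutoff=0.4)
        assert rate == pytest.approx(12 / 20)
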