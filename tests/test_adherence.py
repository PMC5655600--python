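"""Episode construction, pattern verdicts, and stratified summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfclaims import build_episodes, classify_adherence, stratify
from hfclaims.adherence import AdherenceOptions, classify_bundle, required_classes
from hfclaims.codes import NYHA

from conftest import make_bundle, make_patient, make_rx

BASE = pd.Timestamp("2011-01-01")


def day(n: int) -> pd.Timestamp:
    return BASE + pd.Timedelta(days=n)


def rx_frame(fills, atc="C07AB02"):
    """fills: list of (day offset, supply_days) for one patient."""
    rows = [make_rx("a", day(d), atc, supply=s) for d, s in fills]
    return pd.DataFrame(rows, columns=["patient_id", "dispense_date", "atc_code", "supply_days"])


def brute_force_episodes(fills, gap_tolerance):
    """Day-by-day coverage scan with gap bridging; the independent oracle."""
    covered = set()
    for d, s in fills:
        covered.update(range(d, d + s))
    if not covered:
        return []
    days = sorted(covered)
    episodes = []
    start = prev = days[0]
    for d in days[1:]:
        if d - prev - 1 > gap_tolerance:
            episodes.append((start, prev))
            start = d
        prev = d
    episodes.append((start, prev))
    return episodes


class TestBuildEpisodes:
    def test_gap_within_tolerance_bridges(self):
        eps = build_episodes(rx_frame([(0, 30), (100, 30)]))["BETA_BLOCKER"]
        assert len(eps) == 1
        assert (eps[0].start, eps[0].end) == (day(0), day(129))

    def test_gap_beyond_tolerance_splits(self):
        eps = build_episodes(rx_frame([(0, 30), (130, 30)]))["BETA_BLOCKER"]
        assert len(eps) == 2
        assert (eps[0].start, eps[0].end) == (day(0), day(29))
        assert (eps[1].start, eps[1].end) == (day(130), day(159))

    def test_acei_and_arb_pool_into_ras_track(self):
        rows = [make_rx("a", day(0), "C09AA02", 30), make_rx("a", day(40), "C09CA01", 30)]
        eps = build_episodes(pd.DataFrame(rows))
        assert len(eps["RAS"]) == 1
        assert eps["RAS"][0].end == day(69)
        assert len(eps["ACEI"]) == 1 and len(eps["ARB"]) == 1

    def test_mra_feeds_diuretic_track_by_default(self):
        eps = build_episodes(rx_frame([(0, 30)], atc="C03DA01"))
        assert "MRA" in eps and "DIURETIC" in eps
        eps_off = build_episodes(rx_frame([(0, 30)], atc="C03DA01"), mra_counts_as_diuretic=False)
        assert "DIURETIC" not in eps_off

    def test_combination_product_feeds_both_tracks(self):
        eps = build_episodes(rx_frame([(0, 30)], atc="C09BA02"))
        assert {"ACEI", "RAS", "DIURETIC"} <= set(eps)

    def test_negative_supply_is_data_error(self):
        with pytest.raises(ValueError):
            build_episodes(rx_frame([(0, -5)]))

    def test_matches_daily_coverage_oracle_on_random_histories(self):
        rng = np.random.default_rng(2011)
        for _ in range(1000):
            n = int(rng.integers(0, 9))
            fills = [(int(rng.integers(0, 400)), int(rng.integers(1, 120))) for _ in range(n)]
            tol = int(rng.choice([30, 90]))
            got = build_episodes(rx_frame(fills), gap_tolerance=tol).get("BETA_BLOCKER", [])
            expected = brute_force_episodes(fills, tol)
            assert [((e.start - BASE).days, (e.end - BASE).days) for e in got] == expected

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 150)), min_size=0, max_size=10
        ),
        st.integers(1, 120),
    )
    def test_oracle_equivalence_property(self, fills, tol):
        got = build_episodes(rx_frame(fills), gap_tolerance=tol).get("BETA_BLOCKER", [])
        assert [((e.start - BASE).days, (e.end - BASE).days) for e in got] == brute_force_episodes(fills, tol)


def verdict_for(fills_by_atc, nyha, death=None, **opts):
    rows = []
    for atc, fills in fills_by_atc.items():
        rows += [make_rx("a", day(d), atc, supply=s) for d, s in fills]
    disp = pd.DataFrame(rows, columns=["patient_id", "dispense_date", "atc_code", "supply_days"])
    episodes = build_episodes(disp, gap_tolerance=opts.get("gap_tolerance", 90))
    return classify_adherence(
        "a", nyha, BASE, episodes, death_date=death, options=AdherenceOptions(**opts)
    )


def continuous():
    """Refill stream covering the full two-year window without gaps."""
    return [(k * 30, 30) for k in range(25)]


class TestClassifyAdherence:
    def test_nyha_iv_without_mra_meets_only_less_strict(self):
        v = verdict_for(
            {"C09AA02": continuous(), "C07AB02": continuous(), "C03CA01": continuous()},
            NYHA.IV,
        )
        assert v.less_strict is True and v.strict is False

    def test_nyha_iv_with_mra_meets_both(self):
        v = verdict_for(
            {
                "C09AA02": continuous(),
                "C07AB02": continuous(),
                "C03CA01": continuous(),
                "C03DA01": continuous(),
            },
            NYHA.IV,
        )
        assert v.strict is True and v.less_strict is True

    def test_nyha_i_with_arb_only_meets_both(self):
        v = verdict_for({"C09CA01": continuous()}, NYHA.I)
        assert v.strict is True and v.less_strict is True

    def test_nyha_ii_missing_beta_blocker_fails_both(self):
        v = verdict_for({"C09AA02": continuous(), "C03CA01": continuous()}, NYHA.II)
        assert v.strict is False and v.less_strict is False

    def test_late_initiation_fails(self):
        late = [(120 + k * 30, 30) for k in range(22)]
        v = verdict_for({"C09AA02": late}, NYHA.I)
        assert v.less_strict is False

    def test_super_threshold_mid_gap_fails(self):
        fills = [(0, 30), (200, 30)] + [(200 + k * 30, 30) for k in range(1, 19)]
        v = verdict_for({"C09AA02": fills}, NYHA.I)
        assert v.less_strict is False

    def test_regular_refills_with_permitted_gaps_pass(self):
        fills = [(k * 100, 30) for k in range(8)]  # 70-day gaps <= 90
        v = verdict_for({"C09AA02": fills}, NYHA.I)
        assert v.less_strict is True

    def test_death_censoring_shortens_the_window(self):
        # coverage for the first year only; patient dies at day 200
        fills = [(k * 30, 30) for k in range(8)]
        v = verdict_for({"C09AA02": fills}, NYHA.I, death=day(200))
        assert v.less_strict is True
        assert v.censor_date == day(200)
        # the same stream fails without the death censor
        assert verdict_for({"C09AA02": fills}, NYHA.I).less_strict is False

    def test_events_after_death_never_matter(self):
        fills = [(k * 30, 30) for k in range(8)]
        extra = fills + [(500, 30)]  # dispensed after death: must not change anything
        v1 = verdict_for({"C09AA02": fills}, NYHA.I, death=day(200))
        v2 = verdict_for({"C09AA02": extra}, NYHA.I, death=day(200))
        assert (v1.strict, v1.less_strict) == (v2.strict, v2.less_strict)

    def test_other_class_is_excluded_sentinel(self):
        v = verdict_for({"C09AA02": continuous()}, NYHA.OTHER)
        assert v.strict is None and v.less_strict is None and not v.eligible

    def test_ras_switch_keeps_pooled_coverage(self):
        fills_acei = [(k * 30, 30) for k in range(12)]
        fills_arb = [(360 + k * 30, 30) for k in range(13)]
        v = verdict_for({"C09AA02": fills_acei, "C09CA01": fills_arb}, NYHA.I)
        assert v.less_strict is True

    def test_first_quarter_initiation_variant(self):
        one_fill = [(10, 30)]
        strict_view = verdict_for({"C09AA02": one_fill}, NYHA.I)
        q1_view = verdict_for({"C09AA02": one_fill}, NYHA.I, first_quarter_initiation=True)
        assert strict_view.less_strict is False
        assert q1_view.less_strict is True


class TestRequirements:
    def test_strict_superset_and_class_identity(self):
        for nyha in (NYHA.I, NYHA.II, NYHA.III, NYHA.IV):
            strict = set(required_classes(nyha, "strict"))
            less = set(required_classes(nyha, "less_strict"))
            assert less <= strict
            if nyha in (NYHA.I, NYHA.II):
                assert strict == less

    def test_dominance_on_synthetic_patients(self, paperlike_study, paperlike_results):
        v = paperlike_results.verdicts
        eligible = v[v["eligible"]]
        assert (eligible["strict"].astype(bool) <= eligible["less_strict"].astype(bool)).all()
        # on classes I-II the two verdicts coincide
        low = eligible[eligible["nyha"].isin(["I", "II"])]
        assert (low["strict"] == low["less_strict"]).all()

    def test_adding_a_dispensation_never_breaks_adherence(self, paperlike_study, paperlike_results):
        rng = np.random.default_rng(3)
        cohort = paperlike_results.cohort
        verdicts = paperlike_results.verdicts.set_index("patient_id")
        disp = paperlike_study.bundle.dispensations
        eligible = cohort[cohort["nyha"] != "OTHER"]
        sample = eligible.sample(n=min(60, len(eligible)), random_state=7)
        for rec in sample.itertuples(index=False):
            extra_day = pd.Timestamp(rec.index_date) + pd.Timedelta(days=int(rng.integers(0, 700)))
            censor = verdicts.loc[rec.patient_id, "censor_date"]
            extra_day = min(extra_day, pd.Timestamp(censor))
            atc = str(rng.choice(["C09AA02", "C09CA01", "C07AB02", "C03CA01", "C03DA01"]))
            augmented = pd.concat(
                [
                    disp[disp["patient_id"] == rec.patient_id],
                    pd.DataFrame([make_rx(rec.patient_id, extra_day, atc, 30)]),
                ],
                ignore_index=True,
            )
            base = verdicts.loc[rec.patient_id]
            new = classify_bundle(pd.DataFrame([rec._asdict()]), augmented).iloc[0]
            if base["strict"]:
                assert new["strict"]
            if base["less_strict"]:
                assert new["less_strict"]


class TestStratify:
    def make_tables(self, strict_flags, less_flags, **cols):
        n = len(strict_flags)
        ids = [f"p{i}" for i in range(n)]
        verdicts = pd.DataFrame(
            {
                "patient_id": ids,
                "nyha": cols.get("nyha", ["II"] * n),
                "eligible": [True] * n,
                "strict": strict_flags,
                "less_strict": less_flags,
                "censor_date": [BASE] * n,
            }
        )
        cohort = pd.DataFrame(
            {
                "patient_id": ids,
                "age_band": cols.get("age_band", ["70-74"] * n),
                "sex": cols.get("sex", ["F"] * n),
                "hospitalized_in_id_year": cols.get("hosp", [False] * n),
                "died_in_study": cols.get("died", [False] * n),
            }
        )
        return verdicts, cohort

    def test_all_true_gives_share_one_everywhere(self):
        v, c = self.make_tables([True] * 5, [True] * 5, sex=["F", "M", "F", "M", "F"])
        strata = stratify(v, c)
        assert (strata["by_sex"]["strict_share"] == 1.0).all()
        assert strata["overall"].iloc[0]["strict_share"] == 1.0

    def test_empty_stratum_share_is_nan_not_zero(self):
        v, c = self.make_tables([], [])
        strata = stratify(v, c)
        assert np.isnan(strata["overall"].iloc[0]["strict_share"])

    def test_stratum_shares_recombine_to_overall(self):
        rng = np.random.default_rng(17)
        n = 400
        strict = list(rng.random(n) < 0.4)
        less = [s or (r < 0.3) for s, r in zip(strict, rng.random(n))]
        sexes = list(rng.choice(["M", "F"], size=n))
        v, c = self.make_tables(strict, less, sex=sexes)
        strata = stratify(v, c)
        by_sex = strata["by_sex"]
        overall = strata["overall"].iloc[0]
        recombined = (by_sex["strict_share"] * by_sex["n"]).sum() / by_sex["n"].sum()
        assert recombined == pytest.approx(overall["strict_share"], abs=1e-12)

    def test_outcome_shares_by_adherence_group(self):
        v, c = self.make_tables(
            [True, True, False, False],
            [True, True, True, False],
            died=[True, False, True, True],
        )
        strata = stratify(v, c)
        out = strata["outcomes_by_adherence"].set_index("group")
        assert out.loc["strict_adherent", "died_share"] == 0.5
        assert out.loc["not_strict_adherent", "died_share"] == 1.0
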