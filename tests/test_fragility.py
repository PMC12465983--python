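import pytest
from scipy import stats

from metafrag import (
    ScenarioSpec,
    TooFewStudiesError,
    TwoByTwoTable,
    apply_plan,
    assess_significance,
    fisher_exact_p,
    fragility_index_ma,
    fragility_index_ma_exact,
    fragility_index_study,
    fragility_quotient,
    pool_random,
)
from metafrag.effects import StudyEffect

from conftest import make_ma, random_small_ma

ALL_KEYS = ("FE", "S1", "S2", "S3", "S4")

#: Oracle-verified minimum flip counts for the F1 fixture, frozen as a
#: regression anchor (breadth-first enumeration, cap 12).
F1_EXPECTED = {"FE": 5, "S1": 1, "S2": 3, "S3": 1, "S4": 3}


def _fit(dataset, key):
    from metafrag._core import fit_tables

    spec = ScenarioSpec.from_key(key, "OR")
    e1, n1, e0, n0 = dataset.count_arrays()
    return fit_tables(e1[None], n1[None], e0[None], n0[None], spec), spec


class TestAssessSignificance:
    @pytest.mark.parametrize(
        "ci, expected",
        [
            ((0.1, 0.5), "significant"),
            ((-0.1, 0.5), "nonsignificant"),
            ((-0.5, -0.1), "significant"),
            ((0.0, 0.5), "nonsignificant"),  # boundary: interval touches the null
        ],
    )
    def test_interval_rule(self, ci, expected):
        r = pool_random(
            [StudyEffect(0.3, 0.2, False, True), StudyEffect(0.3, 0.2, False, True)],
            tau2=0.0,
            ci_method="normal",
        )
        fake = r.__class__(**{**r.__dict__, "ci_low": ci[0], "ci_high": ci[1]})
        assert assess_significance(fake) == expected


class TestFragilityQuotient:
    def test_exact_ratio(self):
        assert fragility_quotient(5, 1000) == pytest.approx(0.005)
        assert fragility_quotient(1, 200) == pytest.approx(0.005)

    def test_not_attainable_propagates(self):
        assert fragility_quotient(None, 1000) is None

    def test_fi_zero_disallowed(self):
        with pytest.raises(ValueError):
            fragility_quotient(0, 100)


class TestFixtureF1:
    @pytest.mark.parametrize("key", ALL_KEYS)
    def test_frozen_minimums_beam_and_oracle(self, fixture_f1, key):
        spec = ScenarioSpec.from_key(key, "OR")
        beam = fragility_index_ma(fixture_f1, spec)
        exact = fragility_index_ma_exact(fixture_f1, spec, cap=12)
        assert exact.fi == F1_EXPECTED[key]
        assert beam.fi == exact.fi

    def test_fq_definition(self, fixture_f1):
        spec = ScenarioSpec.from_key("FE", "OR")
        res = fragility_index_ma(fixture_f1, spec)
        assert res.fq == pytest.approx(res.fi / fixture_f1.total_n)
        assert 0 < res.fq <= 1


class TestPlanValidity:
    @pytest.mark.parametrize("key", ("FE", "S1", "S4"))
    def test_plan_flips_verdict_and_prefixes_do_not(self, fixture_f1, key):
        spec = ScenarioSpec.from_key(key, "OR")
        res = fragility_index_ma_exact(fixture_f1, spec, cap=12)
        base, _ = _fit(fixture_f1, key)
        before = bool(base["significant"][0])
        for cut in range(len(res.plan)):
            prefix_ds = apply_plan(fixture_f1, res.plan[:cut])
            out, _ = _fit(prefix_ds, key)
            assert bool(out["significant"][0]) == before
        final, _ = _fit(apply_plan(fixture_f1, res.plan), key)
        assert bool(final["significant"][0]) != before
        assert len(res.plan) == res.fi
        assert len(res.trail) == res.fi

    def test_beam_plan_is_valid_too(self, fixture_f1):
        spec = ScenarioSpec.from_key("S2", "OR")
        res = fragility_index_ma(fixture_f1, spec)
        final, _ = _fit(apply_plan(fixture_f1, res.plan), "S2")
        assert bool(final["significant"][0]) is False


class TestSearchBehaviour:
    def test_one_flip_boundary_dataset(self):
        """A dataset sitting at the significance boundary flips with one change."""
        ds = make_ma([(13, 20, 5, 20), (12, 20, 6, 20)])
        spec = ScenarioSpec.from_key("FE", "OR")
        res = fragility_index_ma(ds, spec)
        assert res.fi >= 1
        exact = fragility_index_ma_exact(ds, spec, cap=6)
        assert res.fi == exact.fi

    def test_exact_never_exceeds_beam(self, rng):
        for _ in range(15):
            ds = random_small_ma(rng)
            spec = ScenarioSpec.from_key("FE", "OR")
            beam = fragility_index_ma(ds, spec, cap=4)
            exact = fragility_index_ma_exact(ds, spec, cap=4)
            if exact.fi is None:
                assert beam.fi is None
            else:
                assert beam.fi is not None and exact.fi <= beam.fi

    def test_cap_exhaustion_reports_not_attainable(self):
        # overwhelming effect: one flip cannot possibly rescue it at cap 1
        ds = make_ma([(90, 100, 10, 100), (85, 100, 15, 100)])
        spec = ScenarioSpec.from_key("FE", "OR")
        res = fragility_index_ma(ds, spec, cap=1)
        assert res.fi is None and res.fq is None and res.plan == ()

    def test_direction_labels(self, fixture_f1):
        sig = fragility_index_ma(fixture_f1, ScenarioSpec.from_key("FE", "OR"))
        assert sig.direction == "toward_null"
        nonsig = fragility_index_ma(fixture_f1, ScenarioSpec.from_key("S1", "OR"))
        assert nonsig.direction == "toward_significance"

    def test_direction_coherence_in_count_interior(self):
        """For a significant MA with theta > 0 whose counts stay far from
        any zero cell, every beam plan step weakly decreases theta."""
        ds = make_ma([(14, 30, 6, 30), (15, 30, 7, 30), (13, 30, 6, 30)])
        spec = ScenarioSpec.from_key("FE", "OR")
        base, _ = _fit(ds, "FE")
        assert bool(base["significant"][0]) and float(base["theta"][0]) > 0
        res = fragility_index_ma(ds, spec)
        thetas = [float(base["theta"][0])]
        for cut in range(1, res.fi + 1):
            out, _ = _fit(apply_plan(ds, res.plan[:cut]), "FE")
            thetas.append(float(out["theta"][0]))
        assert all(b <= a + 1e-12 for a, b in zip(thetas, thetas[1:]))

    def test_too_few_studies_rejected(self):
        ds = make_ma([(5, 10, 2, 10)])
        with pytest.raises(TooFewStudiesError):
            fragility_index_ma(ds, ScenarioSpec.from_key("FE", "OR"))


class TestStudyFragility:
    def test_fisher_p_matches_scipy(self, rng):
        for _ in range(50):
            n1 = int(rng.integers(2, 40))
            n0 = int(rng.integers(2, 40))
            e1 = int(rng.integers(0, n1 + 1))
            e0 = int(rng.integers(0, n0 + 1))
            ours = fisher_exact_p(e1, n1, e0, n0)
            ref = stats.fisher_exact([[e1, n1 - e1], [e0, n0 - e0]])[1]
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_frozen_fixture_value(self):
        """(1,20,9,20): Fisher p = 0.0084, two flips reach nonsignificance."""
        res = fragility_index_study(TwoByTwoTable(1, 20, 9, 20))
        assert res.fi == 2
        assert res.p_initial == pytest.approx(0.008361734, abs=1e-8)
        assert res.direction == "toward_null"

    def test_matches_plain_enumeration_oracle(self, rng):
        """Exhaustive double loop over net arm changes, independent of the
        package's vector enumeration."""
        for _ in range(10):
            n1 = int(rng.integers(8, 25))
            n0 = int(rng.integers(8, 25))
            e1 = int(rng.integers(0, n1 + 1))
            e0 = int(rng.integers(0, n0 + 1))
            table = TwoByTwoTable(e1, n1, e0, n0)
            res = fragility_index_study(table, cap=8)
            sig0 = stats.fisher_exact([[e1, n1 - e1], [e0, n0 - e0]])[1] < 0.05
            best = None
            for d1 in range(-e1, n1 - e1 + 1):
                for d0 in range(-e0, n0 - e0 + 1):
                    m = abs(d1) + abs(d0)
                    if m == 0 or m > 8:
                        continue
                    p = stats.fisher_exact(
                        [[e1 + d1, n1 - e1 - d1], [e0 + d0, n0 - e0 - d0]]
                    )[1]
                    if (p < 0.05) != sig0:
                        best = m if best is None else min(best, m)
            assert res.fi == best

    def test_fq_of_study(self):
        res = fragility_index_study(TwoByTwoTable(1, 20, 9, 20))
        assert res.fq == pytest.approx(res.fi / 40)
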