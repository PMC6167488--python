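import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from omega_access import synthetic_data as sd
from omega_access.accessibility import (
    AccessibilityProfile,
    CriteriaSpec,
    FrameOutcome,
    bootstrap_ci,
    classify_frame,
    compare_runs,
    profile,
)
from omega_access.errors import ContractError
from omega_access.geometry import GeometricRecord


def _rec(frame, site, hname, d, theta):
    return GeometricRecord(frame, site, (2, hname), d, theta)


class TestClassifyFrame:
    @pytest.mark.parametrize(
        "d,theta",
        [(2.8, 130.0), (2.5, 125.0), (2.5, 150.0), (2.8, 125.0), (2.8, 150.0)],
    )
    def test_boundaries_inclusive(self, d, theta):
        out = classify_frame([_rec(0, "omega", "H11", d, theta)])
        assert out.satisfied and out.site_label == "omega"

    @pytest.mark.parametrize(
        "d,theta", [(2.81, 130.0), (2.5, 124.99), (2.5, 150.01), (2.5, 160.0)]
    )
    def test_outside_window_unsatisfied(self, d, theta):
        out = classify_frame([_rec(0, "omega", "H11", d, theta)])
        assert not out.satisfied and out.site_label is None

    def test_closest_hydrogen_has_precedence(self):
        """A window-passing site cannot satisfy when another site's hydrogen
        is closer: rule (a) binds the decision to the global minimum d."""
        records = [
            _rec(0, "omega-1", "H21", 2.6, 140.0),
            _rec(0, "omega", "H11", 2.7, 135.0),
        ]
        out = classify_frame(records)
        assert out.satisfied and out.site_label == "omega-1"
        # and if the closest one fails the windows, nothing satisfies
        records = [
            _rec(0, "omega-1", "H21", 2.6, 160.0),
            _rec(0, "omega", "H11", 2.7, 135.0),
        ]
        out = classify_frame(records)
        assert not out.satisfied

    def test_relaxed_mode_is_superset(self, rng):
        spec = CriteriaSpec()
        relaxed = CriteriaSpec(require_global_closest=False)
        for _ in range(300):
            records = [
                _rec(0, site, h, float(rng.uniform(2.0, 4.0)),
                     float(rng.uniform(100.0, 170.0)))
                for site, h in [("omega", "H11"), ("omega", "H12"),
                                ("omega-1", "H21"), ("omega-2R", "H31")]
            ]
            strict = classify_frame(records, spec)
            loose = classify_frame(records, relaxed)
            if strict.satisfied:
                assert strict.site_label in loose.passing_sites

    def test_empty_records_rejected(self):
        with pytest.raises(ContractError):
            classify_frame([])


def _outcome(i, satisfied, site=None):
    return FrameOutcome(i, satisfied, site if satisfied else None, 2.6, 140.0)


class TestProfile:
    def test_basic_arithmetic(self):
        outcomes = [_outcome(i, i < 3, "omega") for i in range(10)]
        records = [[_rec(i, "omega", "H11", 2.6, 140.0)] for i in range(10)]
        prof = profile(outcomes, records)
        assert prof.satisfying_fraction == pytest.approx(0.3)
        assert prof.site_frequencies == {"omega": 1.0}
        assert prof.distance_only_frequencies == {"omega": 1.0}
        assert prof.all_frames_frequencies == {"omega": pytest.approx(0.3)}

    def test_no_satisfying_frames(self):
        outcomes = [_outcome(i, False) for i in range(5)]
        records = [[_rec(i, "omega-1", "H21", 3.4, 90.0)] for i in range(5)]
        prof = profile(outcomes, records)
        assert prof.satisfying_fraction == 0.0
        assert prof.site_frequencies == {}
        assert prof.distance_only_frequencies == {"omega-1": 1.0}

    def test_duplicate_frames_rejected(self):
        outcomes = [_outcome(0, True, "omega"), _outcome(0, False)]
        with pytest.raises(ContractError):
            profile(outcomes, [[_rec(0, "omega", "H11", 2.6, 140.0)]] * 2)

    def test_frequencies_sum_to_one(self, small_spec):
        records_by_frame, plans, _ = sd.sample_records(small_spec)
        outcomes = [classify_frame(r) for r in records_by_frame]
        prof = profile(outcomes, records_by_frame)
        if prof.satisfying_fraction > 0:
            assert sum(prof.site_frequencies.values()) == pytest.approx(1.0)
        assert sum(prof.distance_only_frequencies.values()) == pytest.approx(1.0)

    def test_generator_truth_recovered(self):
        """Site frequencies and the satisfying fraction recover the generator
        probabilities within 3 binomial standard errors at n = 20,000."""
        spec = sd.vk1_like_spec(n_frames=20_000, seed=5)
        records_by_frame, plans, truth = sd.sample_records(spec)
        outcomes = [classify_frame(r) for r in records_by_frame]
        prof = profile(outcomes, records_by_frame)
        n = spec.n_frames
        q = truth["pass_prob"]
        assert abs(prof.satisfying_fraction - q) <= 3 * np.sqrt(q * (1 - q) / n)
        n_sat = round(prof.satisfying_fraction * n)
        for site, p in truth["site_probs"].items():
            est = prof.site_frequencies.get(site, 0.0)
            se = np.sqrt(p * (1 - p) / n_sat)
            assert abs(est - p) <= max(3 * se, 1e-12), site
            est_d = prof.distance_only_frequencies.get(site, 0.0)
            se_d = np.sqrt(p * (1 - p) / n)
            assert abs(est_d - p) <= max(3 * se_d, 1e-12), site


class TestMonotonicity:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        d_max=st.floats(min_value=2.0, max_value=3.5),
        t_lo=st.floats(min_value=100.0, max_value=140.0),
        width=st.floats(min_value=1.0, max_value=40.0),
        shrink_d=st.floats(min_value=0.0, max_value=0.5),
        shrink_t=st.floats(min_value=0.0, max_value=10.0),
    )
    def test_tightening_never_increases_fraction(
        self, d_max, t_lo, width, shrink_d, shrink_t
    ):
        rng = np.random.default_rng(99)
        records_by_frame = [
            [
                _rec(i, "omega", "H11", float(rng.uniform(2.0, 4.0)),
                     float(rng.uniform(90.0, 170.0))),
                _rec(i, "omega-1", "H21", float(rng.uniform(2.0, 4.0)),
                     float(rng.uniform(90.0, 170.0))),
            ]
            for i in range(200)
        ]
        wide = CriteriaSpec(d_max=d_max, theta_min=t_lo, theta_max=t_lo + width)
        narrow_width = max(width - 2 * shrink_t, 0.5)
        narrow = CriteriaSpec(
            d_max=max(d_max - shrink_d, 0.1),
            theta_min=t_lo + shrink_t,
            theta_max=t_lo + shrink_t + narrow_width,
        )
        # only a true tightening is a valid comparison
        if not (narrow.theta_min >= wide.theta_min
                and narrow.theta_max <= wide.theta_max
                and narrow.d_max <= wide.d_max):
            return
        frac = lambda spec: np.mean(
            [classify_frame(r, spec).satisfied for r in records_by_frame]
        )
        assert frac(narrow) <= frac(wide)

    def test_at_most_one_site_per_frame(self, small_spec):
        records_by_frame, _, _ = sd.sample_records(small_spec)
        outcomes = [classify_frame(r) for r in records_by_frame]
        n_satisfied = sum(o.satisfied for o in outcomes)
        prof = profile(outcomes, records_by_frame)
        counts = {
            s: round(f * n_satisfied) for s, f in prof.site_frequencies.items()
        }
        assert sum(counts.values()) == n_satisfied


class TestBootstrap:
    def _outcomes(self, n, seed=0):
        spec = sd.vk1_like_spec(n_frames=n, seed=seed)
        records_by_frame, _, _ = sd.sample_records(spec)
        return [classify_frame(r) for r in records_by_frame]

    def test_deterministic_for_fixed_seed(self):
        outcomes = self._outcomes(400)
        a = bootstrap_ci(outcomes, n_boot=200, block=10, seed=42)
        b = bootstrap_ci(outcomes, n_boot=200, block=10, seed=42)
        assert a == b

    def test_identical_outcomes_zero_width(self):
        outcomes = [_outcome(i, True, "omega") for i in range(100)]
        ci = bootstrap_ci(outcomes, n_boot=100, block=1, seed=0)
        lo, hi = ci["omega"]
        assert lo == hi == 1.0

    def test_width_shrinks_like_root_n(self):
        widths = []
        for n in (500, 5000):
            ci = bootstrap_ci(self._outcomes(n, seed=7), n_boot=300, block=1, seed=1)
            lo, hi = ci["satisfying_fraction"]
            widths.append(hi - lo)
        ratio = widths[1] / widths[0]
        # 10x more frames: expect ~1/sqrt(10) ~ 0.32
        assert 0.15 < ratio < 0.55

    def test_block_larger_than_n_rejected(self):
        with pytest.raises(ContractError):
            bootstrap_ci(self._outcomes(100), n_boot=100, block=200, seed=0)


class TestCompareRuns:
    def _profile(self, freqs, n=100, sat=0.3, dist=None):
        return AccessibilityProfile(
            n_frames=n,
            satisfying_fraction=sat,
            site_frequencies=freqs,
            distance_only_frequencies=dist or freqs,
        )

    def test_identical_profiles_pool_to_same(self):
        p = self._profile({"omega": 0.9, "omega-1": 0.1})
        report = compare_runs([p, p, p])
        assert report.pooled.site_frequencies["omega"] == pytest.approx(0.9)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in report.dispersion.values())
        assert report.divergent_runs == []

    def test_divergent_top_site_flagged(self):
        a = self._profile({"omega": 0.9, "omega-1": 0.1})
        b = self._profile({"omega": 0.2, "omega-1": 0.8})
        report = compare_runs([a, a, b])
        assert report.divergent_runs == [2]

    def test_mismatched_site_sets_rejected(self):
        a = self._profile({"omega": 1.0})
        b = self._profile({"omega-1": 1.0})
        with pytest.raises(ContractError):
            compare_runs([a, b])

    def test_pooled_matches_combined_sample(self):
        """Pooling two generator runs equals analyzing the union of frames."""
        specs = [sd.vk1_like_spec(n_frames=3000, seed=s) for s in (21, 22)]
        profs, all_outcomes, all_records = [], [], []
        for spec in specs:
            records_by_frame, _, _ = sd.sample_records(spec)
            outcomes = [classify_frame(r) for r in records_by_frame]
            profs.append(profile(outcomes, records_by_frame))
            all_outcomes.extend(
                FrameOutcome(len(all_outcomes) + i, o.satisfied, o.site_label,
                             o.d, o.theta)
                for i, o in enumerate(outcomes)
            )
            all_records.extend(records_by_frame)
        pooled = compare_runs(profs).pooled
        # re-index records for the combined profile
        combined = profile(
            [FrameOutcome(i, o.satisfied, o.site_label, o.d, o.theta)
             for i, o in enumerate(all_outcomes)],
            all_records,
        )
        assert pooled.satisfying_fraction == pytest.approx(
            combined.satisfying_fraction
        )
        for site, f in combined.site_frequencies.items():
            assert pooled.site_frequencies[site] == pytest.approx(f)
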