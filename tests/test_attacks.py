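"""Attack scenarios: profiled, non-profiled, portability, identification."""

import numpy as np
import pytest

import erpleak as el


class TestProfiled:
    def test_informative_user_positive_pi(self, small_session):
        _, session = small_session
        res = el.profiled_attack(session, q_grid=(1, 5), R=200, seed=0)
        assert res.pi.pi > 0
        assert res.pi.ci_low > 0

    def test_null_user_pi_ci_overlaps_zero(self):
        profile = el.make_user_profile(seed=4, amplitude=0.0)
        session = el.simulate_session(profile,
                                      el.SessionConfig(reps_per_tag=30, seed=8))
        res = el.profiled_attack(session, q_grid=(1,), R=50, seed=0)
        assert (res.pi.pi <= 0) or (res.pi.ci_low <= 0 <= res.pi.ci_high)

    def test_report_schema(self, small_session):
        _, session = small_session
        res = el.profiled_attack(session, q_grid=(1, 2), R=100, seed=0)
        assert set(res.report.success.columns) == {"tag", "q", "success_rate"}
        assert sorted(res.report.success["tag"].unique()) == [1, 2, 3, 4, 5, 6]
        assert set(res.report.avg_rank.columns) == {"q", "avg_rank"}
        assert res.report.avg_rank["avg_rank"].between(1, 6).all()

    def test_average_pca_converges_before_raw_pca(self):
        """On matched sessions the average-PCA learning curve reaches an
        informative model with fewer profiling observations than raw PCA."""
        profile = el.make_user_profile(seed=7)
        session = el.simulate_session(profile,
                                      el.SessionConfig(seed=31, blink_rate=0.0))
        sizes = (60, 120, 240, 480)
        curves = {}
        for variant in ("average", "raw"):
            res = el.profiled_attack(session, variant=variant, q_grid=(1,),
                                     R=50, seed=0, learning_curve_sizes=sizes)
            curves[variant] = res.learning_curve["pi"].to_numpy()
        first_pos_avg = np.argmax(curves["average"] > 0)
        first_pos_raw = (np.argmax(curves["raw"] > 0)
                         if (curves["raw"] > 0).any() else len(sizes))
        assert curves["average"][-1] > curves["raw"][-1] - 0.02
        assert first_pos_avg <= first_pos_raw


class TestNonProfiled:
    def test_six_estimates_with_cis(self, small_session):
        _, session = small_session
        obs = el.preprocess_session(session)
        res = el.nonprofiled_attack(obs, seed=0)[0]
        assert len(res.pi_by_tag) == 6
        for pr in res.pi_by_tag.values():
            assert pr.ci_low <= pr.pi <= pr.ci_high + 1e-9

    def test_true_tag_matches_supervised_estimate(self, small_session):
        """Assuming the truly familiar tag reproduces the supervised LOO PI:
        the profiled estimate is the t=1 column of the non-profiled sweep."""
        _, session = small_session
        obs = el.preprocess_session(session)
        res = el.nonprofiled_attack(obs, seed=0)[0]
        red = el.reduce_observations(obs, variant="average", n_d=5)
        sup = el.estimate_pi(red.scores, el.pin_labels(red.tags), seed=0)
        assert res.pi_by_tag[1].pi == pytest.approx(sup.pi, abs=1e-12)

    def test_splits_are_disjoint_and_exhaustive(self, small_session):
        _, session = small_session
        obs = el.preprocess_session(session)
        parts = el.attacks._stratified_parts(np.random.default_rng(0),
                                             obs.tags, 2, None)
        assert np.intersect1d(parts[0], parts[1]).size == 0
        assert parts[0].size + parts[1].size == obs.n_epochs

    def test_too_small_subset_error(self, small_session):
        _, session = small_session
        obs = el.preprocess_session(session)
        with pytest.raises(ValueError, match="on-the-fly"):
            el.nonprofiled_attack(obs, q=10, seed=0)


class TestPortability:
    def test_self_portability_positive_and_optimistic(self, small_session):
        """Scoring a user with their own full-set model: PI is positive and at
        least the held-out (LOO) estimate, since the model saw every epoch."""
        _, session = small_session
        basis, model = el.fit_profile_model(session)
        obs = el.preprocess_session(session)
        self_pi = el.portability_attack(model, basis, obs)
        red = el.reduce_observations(obs)
        loo = el.estimate_pi(red.scores, el.pin_labels(red.tags), seed=0)
        assert self_pi.pi > 0
        assert self_pi.pi >= loo.pi - 1e-9

    def test_shared_profile_cohort_transfers(self):
        cfg = el.SessionConfig(reps_per_tag=24, blink_rate=0.0, seed=0)
        cohort = el.simulate_cohort(2, seed=17, spread=0.0, config=cfg)
        basis, model = el.fit_profile_model(cohort[0][1])
        obs_b = el.preprocess_session(cohort[1][1])
        res = el.portability_attack(model, basis, obs_b)
        assert res.pi > 0

    def test_dimension_mismatch_error(self, small_session):
        _, session = small_session
        basis, model = el.fit_profile_model(session)
        obs1 = el.preprocess_session(session, channels=("P7",))
        with pytest.raises(ValueError, match="mismatch"):
            el.portability_attack(model, basis, obs1)

    def test_single_nontarget_reduces_to_pairwise(self, small_cohort):
        """all-against-one with one non-target user is the pairwise transfer."""
        sessions = [s for _, s in small_cohort[:2]]
        pooled = el.all_against_one(sessions, 0, seed=0)
        basis, model = el.fit_profile_model(sessions[1])
        pair = el.portability_attack(model, basis,
                                     el.preprocess_session(sessions[0]), seed=0)
        assert pooled.pi == pytest.approx(pair.pi, abs=1e-12)

    def test_portability_below_self_profiled_on_average(self):
        """Transferred models never beat self-profiled ones on average."""
        cfg = el.SessionConfig(reps_per_tag=24, blink_rate=0.0, seed=0)
        diffs = []
        for s in range(4):
            cohort = el.simulate_cohort(2, seed=50 + s, spread=1.0, config=cfg)
            (pa, sa), (pb, sb) = cohort
            basis, model = el.fit_profile_model(sa)
            cross = el.portability_attack(model, basis,
                                          el.preprocess_session(sb))
            self_pi = el.portability_attack(model, basis,
                                            el.preprocess_session(sa))
            diffs.append(self_pi.pi - cross.pi)
        assert np.mean(diffs) > -0.01


class TestIdentification:
    def test_identifiable_cohort(self, small_cohort):
        sessions = [s for _, s in small_cohort]
        res = el.identify_user(sessions, seed=0)
        assert res.h_prior == pytest.approx(np.log2(3))
        assert res.overall_pi <= res.h_prior
        assert res.overall_pi > 0
        assert set(res.partial_pi) == {1, 2, 3}
        n_real = sum(int((el.preprocess_session(s).tags == 1).sum())
                     for s in sessions)
        assert res.confusion.to_numpy().sum() == n_real

    def test_posteriors_sum_to_one_per_epoch(self, small_cohort):
        sessions = [s for _, s in small_cohort]
        blocks, labels = [], []
        for s in sessions:
            obs = el.preprocess_session(s)
            keep = obs.tags == 1
            blocks.append(obs.vectors[keep])
            labels.append(np.full(int(keep.sum()), s.user_id))
        X = np.vstack(blocks)
        users = np.concatenate(labels)
        means = np.vstack([X[users == u].mean(0) for u in np.unique(users)])
        tm = el.TagMeans(means=means, counts=np.ones(3, int),
                         tag_values=np.unique(users))
        basis = el.average_pca(tm, n_d=2)
        scores = (X - basis.center) @ basis.components.T
        post, _ = el.cv_posteriors(scores, users, prior_mode="uniform")
        np.testing.assert_allclose(post.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_identical_users_not_identifiable(self):
        cfg = el.SessionConfig(reps_per_tag=24, blink_rate=0.0, seed=0)
        cohort = el.simulate_cohort(2, seed=13, spread=0.0, config=cfg)
        res = el.identify_user([s for _, s in cohort], seed=0)
        assert all(v <= 0.05 for v in res.partial_pi.values())

    def test_identification_beats_pin_recovery(self, small_cohort):
        """PI(U;O) exceeds the same pipeline's PI(P;O): who is watching leaks
        more than which code is familiar."""
        sessions = [s for _, s in small_cohort]
        ident = el.identify_user(sessions, seed=0)
        pin_pis = []
        for s in sessions:
            red = el.reduce_observations(el.preprocess_session(s))
            pin_pis.append(el.estimate_pi(red.scores,
                                          el.pin_labels(red.tags), seed=0).pi)
        assert ident.overall_pi > np.mean(pin_pis)
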