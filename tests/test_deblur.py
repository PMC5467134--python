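import numpy as np
import pytest
from scipy.sparse.linalg import lsqr

from ribodeconv.deblur import (
    ConsensusSignal,
    DeviationField,
    aligned_counts,
    blur_operator,
    convolve,
    deblur_transcript,
    e_step,
    init_consensus,
    m_step,
    objective,
    shift_for_length,
    shift_profile,
)
from ribodeconv.metablur import BLUR_HALF_WIDTH, BLUR_WIDTH, BlurVector, delta_blur
from ribodeconv.profiles import LengthProfile, ProfileSet, filter_profiles
from ribodeconv.synthetic import annotations_of, generate_truth, sample_reads
from ribodeconv.experiments import bench_spec


def dense_conv_matrix(weights, n):
    """Independent dense convolution matrix (explicit double loop)."""
    A = np.zeros((n, n))
    for i in range(n):
        for t in range(n):
            j = i - t
            if -BLUR_HALF_WIDTH <= j <= BLUR_HALF_WIDTH:
                A[i, t] = weights[j + BLUR_HALF_WIDTH]
    return A


class TestConvolve:
    def test_identity(self):
        s = np.random.default_rng(0).random(50)
        np.testing.assert_allclose(convolve(s, delta_blur(28, 0)), s)

    def test_two_spike_split(self):
        s = np.zeros(30)
        s[10] = 1.0
        w = np.zeros(BLUR_WIDTH)
        w[-1 + BLUR_HALF_WIDTH] = 0.5
        w[1 + BLUR_HALF_WIDTH] = 0.5
        out = convolve(s, w)
        assert out[9] == 0.5 and out[11] == 0.5
        assert out.sum() == 1.0

    def test_interior_mass_conserved(self):
        rng = np.random.default_rng(1)
        s = np.zeros(80)
        s[15:-15] = rng.random(50)  # 15-cell zero margins
        w = rng.random(BLUR_WIDTH)
        w /= w.sum()
        assert np.isclose(convolve(s, w).sum(), s.sum())

    def test_matches_dense_matrix(self):
        rng = np.random.default_rng(2)
        s = rng.random(40)
        w = rng.random(BLUR_WIDTH)
        np.testing.assert_allclose(convolve(s, w), dense_conv_matrix(w, 40) @ s)


class TestShiftProfile:
    def test_identity(self):
        v = np.arange(10.0)
        np.testing.assert_array_equal(shift_profile(v, 0), v)

    def test_length30_shift_is_two(self):
        assert shift_for_length(30) == 2
        v = np.zeros(10)
        v[5] = 1.0
        assert shift_profile(v, shift_for_length(30))[7] == 1.0

    def test_round_trip_up_to_borders(self):
        rng = np.random.default_rng(3)
        v = np.zeros(20)
        v[5:15] = rng.random(10)
        np.testing.assert_array_equal(shift_profile(shift_profile(v, 4), -4), v)


class TestInitConsensus:
    def test_in_frame_selection(self):
        p = LengthProfile("t", 28, [4, 1, 1, 2, 0, 0], alpha=8, l_up=0)
        c = init_consensus(p)
        np.testing.assert_allclose(c.values, np.array([4, 0, 0, 2, 0, 0]) / 6)

    def test_pure_frame0_shape_unchanged(self):
        p = LengthProfile("t", 28, [3, 0, 0, 1, 0, 0], alpha=4, l_up=0)
        c = init_consensus(p)
        np.testing.assert_allclose(c.values, np.array([3, 0, 0, 1, 0, 0]) / 4)

    def test_only_off_frame_mass_errors(self):
        p = LengthProfile("t", 28, [0, 5, 0, 0, 2, 0], alpha=7, l_up=0)
        with pytest.raises(ValueError, match="in-frame"):
            init_consensus(p)


class TestMStep:
    def _instance(self, seed, n):
        rng = np.random.default_rng(seed)
        w = rng.random(BLUR_WIDTH)
        blur = BlurVector(28, w / w.sum())
        c = rng.random(n)
        c /= c.sum()
        q = rng.random(n)
        q /= q.sum()
        return blur, ConsensusSignal("t", c), LengthProfile("t", 28, q, alpha=1.0, l_up=0)

    def test_zero_residual_gives_zero_deviation(self):
        rng = np.random.default_rng(4)
        w = rng.random(BLUR_WIDTH)
        blur = BlurVector(28, w / w.sum())
        c = rng.random(40)
        c /= c.sum()
        q = convolve(c, blur)
        p = LengthProfile("t", 28, q, alpha=1.0, l_up=0)
        eps = m_step(ConsensusSignal("t", c), p, blur)
        np.testing.assert_allclose(eps.values, 0.0, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_oracle(self, seed):
        n = 6 + 4 * seed
        blur, cons, p = self._instance(seed, n)
        eps = m_step(cons, p, blur).values
        A = dense_conv_matrix(blur.weights, n)
        r = A @ cons.values - p.counts
        oracle = np.linalg.solve(A.T @ A + np.eye(n), A.T @ r)
        np.testing.assert_allclose(eps, oracle, atol=1e-8)

    def test_linearity_in_residual(self):
        # the damped solver is linear: doubling the target doubles the solution
        rng = np.random.default_rng(5)
        w = rng.random(BLUR_WIDTH)
        w /= w.sum()
        A = blur_operator(w, 30)
        r = rng.standard_normal(30)
        x1 = lsqr(A, r, damp=1.0, atol=1e-12, btol=1e-12)[0]
        x2 = lsqr(A, 2 * r, damp=1.0, atol=1e-12, btol=1e-12)[0]
        np.testing.assert_allclose(x2, 2 * x1, atol=1e-9)

    def test_wrong_length_blur_rejected(self):
        blur, cons, p = self._instance(0, 12)
        with pytest.raises(ValueError):
            m_step(cons, p, BlurVector(29, blur.weights))


class TestEStep:
    def test_zero_deviations_fixed_point(self):
        c = ConsensusSignal("t", np.array([0.5, 0.25, 0.25]))
        out = e_step(c, {28: DeviationField(28, np.zeros(3))}, {28: 5.0})
        np.testing.assert_allclose(out.values, c.values)

    def test_cancellation(self):
        c = ConsensusSignal("t", np.array([0.5, 0.25, 0.25]))
        devs = {
            27: DeviationField(27, np.array([0.2, 0.0, 0.0])),
            28: DeviationField(28, np.array([-0.2, 0.0, 0.0])),
        }
        out = e_step(c, devs, {27: 1.0, 28: 1.0})
        np.testing.assert_allclose(out.values, c.values)

    def test_negative_cells_clipped_then_renormalized(self):
        c = ConsensusSignal("t", np.array([0.5, 0.25, 0.25]))
        devs = {28: DeviationField(28, np.array([0.6, 0.0, 0.0]))}
        out = e_step(c, devs, {28: 1.0})
        assert out.values[0] == 0.0
        np.testing.assert_allclose(out.values, [0.0, 0.5, 0.5])

    def test_annihilation_errors(self):
        c = ConsensusSignal("t", np.array([1.0, 0.0]))
        devs = {28: DeviationField(28, np.array([2.0, 0.0]))}
        with pytest.raises(ValueError, match="annihilated"):
            e_step(c, devs, {28: 1.0})


class TestObjective:
    def _toy(self, seed=6, n=20):
        rng = np.random.default_rng(seed)
        w = rng.random(BLUR_WIDTH)
        blur = BlurVector(28, w / w.sum())
        c = rng.random(n)
        c /= c.sum()
        q = rng.random(n)
        q /= q.sum()
        p = LengthProfile("t", 28, q, alpha=3.0, l_up=0)
        eps = DeviationField(28, 0.01 * rng.standard_normal(n))
        return ConsensusSignal("t", c), {28: eps}, {28: p}, {28: blur}

    def test_perfect_model_zero(self):
        rng = np.random.default_rng(7)
        w = rng.random(BLUR_WIDTH)
        blur = BlurVector(28, w / w.sum())
        c = rng.random(25)
        c /= c.sum()
        p = LengthProfile("t", 28, convolve(c, blur), alpha=2.0, l_up=0)
        cons = ConsensusSignal("t", c)
        assert objective(cons, {}, {28: p}, {28: blur}) < 1e-20

    def test_zero_deviation_reduces_to_residual_term(self):
        cons, _, profiles, blurs = self._toy()
        q = profiles[28].counts
        resid = q - convolve(cons.values, blurs[28])
        expected = profiles[28].alpha * float(resid @ resid)
        assert np.isclose(objective(cons, {}, profiles, blurs), expected)

    def test_termwise_oracle(self):
        cons, devs, profiles, blurs = self._toy()
        # independent termwise expansion with plain python loops
        n = cons.values.size
        w = blurs[28].weights
        eps = devs[28].values
        signal = [cons.values[i] - eps[i] for i in range(n)]
        total = 0.0
        for i in range(n):
            model = 0.0
            for j in range(-BLUR_HALF_WIDTH, BLUR_HALF_WIDTH + 1):
                if 0 <= i - j < n:
                    model += w[j + BLUR_HALF_WIDTH] * signal[i - j]
            total += (profiles[28].counts[i] - model) ** 2
        total += sum(e * e for e in eps)
        total *= profiles[28].alpha
        assert np.isclose(objective(cons, devs, profiles, blurs), total)


@pytest.fixture(scope="module")
def small_bench():
    spec = bench_spec(seed=2, n_transcripts=4)
    truth = generate_truth(spec)
    profiles = sample_reads(truth)
    sets = filter_profiles(profiles, annotations_of(truth))
    tmap = {t.annotation.transcript_id: t for t in truth.transcripts}
    return truth, sets, tmap


class TestDeblurTranscript:
    def test_recovers_planted_consensus(self, small_bench):
        truth, sets, tmap = small_bench
        rs = []
        for ps in sets:
            res = deblur_transcript(ps, truth.blurs)
            rs.append(
                np.corrcoef(res.consensus.values, tmap[ps.transcript_id].consensus)[0, 1]
            )
        assert np.median(rs) > 0.95

    def test_identity_blur_limit(self, small_bench):
        # with delta kernels the fixed point is the weighted average of the
        # aligned observed profiles (closed form)
        truth, sets, _ = small_bench
        ps = sets[0]
        blurs = {l: delta_blur(l, 0) for l in ps.read_lengths}
        res = deblur_transcript(ps, blurs, tol=1e-10, max_iter=2000)
        expected = np.zeros_like(res.consensus.values)
        for l, p in ps.profiles.items():
            expected += p.alpha * aligned_counts(p)
        expected /= expected.sum()
        assert np.corrcoef(res.consensus.values, expected)[0, 1] > 0.999

    def test_objective_monotone_per_step(self, small_bench):
        truth, sets, _ = small_bench
        res = deblur_transcript(sets[0], truth.blurs, tol=1e-6, max_iter=200)
        for row in res.trace:
            assert row["post_m"] <= row["pre_m"] + 1e-9
            assert row["post_e"] <= row["post_m"] + 1e-9

    def test_consensus_valid_after_every_e_step(self, small_bench):
        truth, sets, _ = small_bench
        res = deblur_transcript(sets[0], truth.blurs)
        assert np.all(res.consensus.values >= 0)
        assert np.isclose(res.consensus.values.sum(), 1.0)

    def test_per_length_more_consistent_than_observed(self, small_bench):
        # recovered per-length signals correlate with the consensus more
        # strongly than the raw aligned observed profiles do
        truth, sets, _ = small_bench
        improved = total = 0
        for ps in sets:
            res = deblur_transcript(ps, truth.blurs)
            for l, (p_true, k, _alpha) in res.per_length.items():
                aligned_true = shift_profile(p_true, k)
                aligned_obs = aligned_counts(ps.profiles[l])
                r_true = np.corrcoef(aligned_true, res.consensus.values)[0, 1]
                r_obs = np.corrcoef(aligned_obs, res.consensus.values)[0, 1]
                total += 1
                improved += r_true > r_obs
        assert improved / total > 0.9

    def test_missing_anchor_length_fallback(self, small_bench):
        truth, sets, _ = small_bench
        ps = sets[0]
        reduced = ProfileSet(
            ps.transcript_id,
            {l: p for l, p in ps.profiles.items() if l != 28},
            in_frame=ps.in_frame,
            annotation=ps.annotation,
        )
        res = deblur_transcript(reduced, truth.blurs)
        assert np.isclose(res.consensus.values.sum(), 1.0)
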