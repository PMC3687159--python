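import numpy as np
import pytest

from cascann.cascade_ann import (CascadeANN, TrainParams, forward, init_ann,
                                 logsig, mask_from_cascade, train_lm)
from cascann.cascade_builder import Cascade
from cascann.errors import ValidationError

LOGSIG_1 = 0.7310585786300049  # 1/(1+e^-1), 16 significant digits


def complete_cascade(n_upper=4, n_middle=2):
    upper = tuple(f"u{i}" for i in range(n_upper))
    middle = tuple(f"m{j}" for j in range(n_middle))
    return Cascade(target_gene="g", middle_tfs=middle, upper_tfs=upper,
                   input_edges=frozenset((u, m) for u in upper for m in middle))


def random_masked_cascade(rng, n_upper, n_middle):
    """A cascade with a random (valid) edge subset."""
    upper = tuple(f"u{i}" for i in range(n_upper))
    middle = tuple(f"m{j}" for j in range(n_middle))
    while True:
        edges = {(u, m) for u in upper for m in middle if rng.random() < 0.6}
        if {u for u, _ in edges} == set(upper) and {m for _, m in edges} == set(middle):
            return Cascade(target_gene="g", middle_tfs=middle, upper_tfs=upper,
                           input_edges=frozenset(edges))


def reference_forward(ann, X):
    """Independent scalar-loop oracle for the forward pass."""
    out = []
    for x in np.atleast_2d(X):
        y = ann.b_out
        for j in range(len(ann.cascade.middle_tfs)):
            z = ann.b_mid[j]
            for i in range(len(ann.cascade.upper_tfs)):
                z += x[i] * ann.W_in[i, j]
            y += ann.w_out[j] / (1.0 + np.exp(-z))
        out.append(y)
    return np.array(out)


class TestInit:
    def test_deterministic(self):
        c = complete_cascade()
        a, b = init_ann(c, 42), init_ann(c, 42)
        np.testing.assert_array_equal(a.pack(), b.pack())

    def test_free_parameter_count(self):
        # 8 edge weights + 2 hidden biases + 2 output weights + 1 output bias
        c = complete_cascade(4, 2)
        ann = init_ann(c, 0)
        assert ann.n_free_parameters == 13 == len(ann.pack())
        assert ann.n_free_parameters == c.n_free_parameters()

    def test_masked_entries_zero(self):
        rng = np.random.default_rng(3)
        c = random_masked_cascade(rng, 5, 3)
        ann = init_ann(c, 1)
        assert np.all(ann.W_in[~ann.mask] == 0.0)

    def test_init_range(self):
        ann = init_ann(complete_cascade(), 7)
        theta = ann.pack()
        assert np.all(theta >= -0.5) and np.all(theta <= 0.5)


class TestForward:
    def test_all_zero_parameters(self):
        c = complete_cascade()
        ann = init_ann(c, 0).unpack(np.zeros(15))
        np.testing.assert_array_equal(
            forward(ann, np.random.default_rng(0).normal(size=(5, 4))),
            np.zeros(5))

    def test_one_by_one_identity_net(self):
        c = Cascade(target_gene="g", middle_tfs=("m",), upper_tfs=("u",),
                    input_edges=frozenset({("u", "m")}))
        ann = CascadeANN(cascade=c, W_in=[[1.0]], b_mid=[0.0], w_out=[1.0],
                         b_out=0.0, mask=[[True]])
        assert forward(ann, [[0.0]])[0] == 0.5
        assert forward(ann, [[1.0]])[0] == pytest.approx(LOGSIG_1, abs=1e-12)

    def test_matches_reference_on_random_masked_nets(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            c = random_masked_cascade(rng, rng.integers(1, 5), rng.integers(1, 4))
            ann = init_ann(c, int(rng.integers(1 << 30)))
            X = rng.normal(0, 2, size=(6, len(c.upper_tfs)))
            np.testing.assert_allclose(forward(ann, X), reference_forward(ann, X),
                                       atol=1e-10, rtol=0)

    def test_nonfinite_input_rejected(self):
        ann = init_ann(complete_cascade(), 0)
        X = np.zeros((3, 4))
        X[1, 2] = np.nan
        with pytest.raises(ValidationError, match="1"):
            forward(ann, X)

    def test_permutation_equivariance(self):
        c = complete_cascade(3, 3)
        ann = init_ann(c, 5)
        perm = [2, 0, 1]
        permuted = CascadeANN(
            cascade=c, W_in=ann.W_in[:, perm], b_mid=ann.b_mid[perm],
            w_out=ann.w_out[perm], b_out=ann.b_out, mask=ann.mask[:, perm])
        X = np.random.default_rng(6).normal(size=(7, 3))
        np.testing.assert_allclose(forward(ann, X), forward(permuted, X),
                                   rtol=1e-12)

    def test_logsig_stable(self):
        assert logsig(np.array([-800.0]))[0] == 0.0
        assert logsig(np.array([800.0]))[0] == 1.0


class TestJacobian:
    def test_matches_central_finite_differences(self):
        from cascann.cascade_ann import _residuals_and_jacobian
        rng = np.random.default_rng(21)
        for _ in range(10):
            c = random_masked_cascade(rng, rng.integers(1, 4), rng.integers(1, 3))
            ann = init_ann(c, int(rng.integers(1 << 30)))
            X = rng.normal(size=(9, len(c.upper_tfs)))
            y = rng.normal(size=9)
            theta = ann.pack()
            r, J = _residuals_and_jacobian(ann, theta, X, y)
            # gradient of the MSE = (2/n) J' r
            grad = 2.0 / len(y) * (J.T @ r)
            eps = 1e-6
            for k in range(len(theta)):
                tp, tm = theta.copy(), theta.copy()
                tp[k] += eps
                tm[k] -= eps
                fd = (np.mean((forward(ann.unpack(tp), X) - y) ** 2)
                      - np.mean((forward(ann.unpack(tm), X) - y) ** 2)) / (2 * eps)
                assert grad[k] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestTrainLM:
    def test_constant_target_exact(self):
        c = complete_cascade(2, 1)
        ann = init_ann(c, 0)
        X = np.random.default_rng(0).normal(size=(20, 2))
        y = np.full(20, 3.25)
        trained, trace = train_lm(ann, X, y)
        mse = float(np.mean((forward(trained, X) - y) ** 2))
        assert mse <= 1e-10

    def test_masked_weights_stay_zero(self):
        rng = np.random.default_rng(9)
        c = random_masked_cascade(rng, 4, 3)
        ann = init_ann(c, 2)
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        trained, _ = train_lm(ann, X, y, X[:10], y[:10])
        assert np.all(trained.W_in[~trained.mask] == 0.0)

    def test_accepted_mse_strictly_decreasing(self):
        rng = np.random.default_rng(10)
        c = complete_cascade(3, 2)
        ann = init_ann(c, 3)
        X = rng.normal(size=(40, 3))
        y = np.sin(X[:, 0]) + 0.3 * X[:, 1]
        _, trace = train_lm(ann, X, y)
        mses = np.array(trace.train_mse)
        # only the terminal epoch may fail to accept a step (and then stops),
        # so every earlier transition is strictly decreasing
        assert np.all(np.diff(mses) <= 0)
        if len(mses) > 2:
            assert np.all(np.diff(mses[:-1]) < 0)

    def test_teacher_student_recovery(self):
        rng = np.random.default_rng(4)
        c = complete_cascade(3, 2)
        teacher = init_ann(c, rng)
        X = rng.normal(size=(200, 3))
        y = forward(teacher, X)
        student, _ = train_lm(init_ann(c, rng), X[:100], y[:100],
                              X[100:150], y[100:150])
        pred = forward(student, X[150:])
        cc = np.corrcoef(pred, y[150:])[0, 1]
        assert cc >= 0.99

    def test_best_validation_weights_restored(self):
        rng = np.random.default_rng(12)
        c = complete_cascade(2, 1)
        ann = init_ann(c, 1)
        X = rng.normal(size=(10, 2))
        y = rng.normal(size=10)  # pure noise: train MSE falls, val does not
        trained, trace = train_lm(ann, X[:6], y[:6], X[6:], y[6:])
        v = float(np.mean((forward(trained, X[6:]) - y[6:]) ** 2))
        assert v == pytest.approx(min(min(trace.val_mse), v), rel=1e-9)

    def test_params_validated(self):
        with pytest.raises(ValidationError):
            TrainParams(lambda0=-1)
        with pytest.raises(ValidationError):
            TrainParams(lambda_up=0.5)


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(13)
        c = random_masked_cascade(rng, 3, 2)
        ann = init_ann(c, 6)
        ann.save(tmp_path / "ann.json")
        back = CascadeANN.load(tmp_path / "ann.json")
        assert back.cascade == ann.cascade
        np.testing.assert_array_equal(back.pack(), ann.pack())
        np.testing.assert_array_equal(back.mask, ann.mask)
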