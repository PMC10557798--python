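"""KINN construction, forward semantics, gradient contract, training and
the mechanistic rate hand-off."""

import numpy as np
import pytest

from kinn.exceptions import SpecificationError
from kinn.kinetics import (
    RateAssignment,
    cas9_cycle_scheme,
    enumerate_ka_diagrams,
    propagate,
    steady_state_ka,
    StateOccupancy,
)
from kinn.model import (
    KinnArchitecture,
    LinkSpec,
    RateWindowSpec,
    TrainConfig,
    _ParamTensors,
    extract_rates,
    fit,
    forward_batch,
    init_params,
    ka_layer,
    load_checkpoint,
    log_rates,
    pearson,
    predict,
    save_checkpoint,
)
from kinn.search import default_windows
from kinn.simulate import SimulatorConfig, simulate_invitro, encode_invitro_dataset


def small_arch(head="ka_steady_state", L=20, d=2, n_channels=4):
    scheme = cas9_cycle_scheme(4, reservoir_concentration=1.0)
    return KinnArchitecture(
        scheme=scheme,
        windows=default_windows(scheme, L, width=4, kernel_size=d),
        input_length=L,
        n_channels=n_channels,
        output_head=head,
    )


def one_hot_input(rng, L=20, c=4):
    x = np.zeros((L, c))
    x[np.arange(L), rng.integers(0, c, L)] = 1.0
    return x


class TestLogRates:
    def test_zero_weights_give_bias(self, rng):
        arch = small_arch()
        params = init_params(arch, rng)
        for sym in params.kernels:
            params.kernels[sym][:] = 0.0
            params.biases[sym] = 0.7
        x = one_hot_input(rng)
        np.testing.assert_allclose(log_rates(arch, params, x), 0.7)

    def test_kernel_one_matches_positionwise_sum(self, rng):
        """d=1 computes a weighted sum of per-position contributions."""
        arch = small_arch(d=1)
        params = init_params(arch, rng)
        x = one_hot_input(rng)
        got = log_rates(arch, params, x)
        for e, w in enumerate(arch.windows):
            expected = params.biases[w.rate_symbol] + sum(
                float(x[p] @ params.kernels[w.rate_symbol][0])
                for p in range(w.start, w.end)
            )
            assert got[e] == pytest.approx(expected)

    def test_full_width_kernel_is_affine_map(self, rng):
        """d = j - i reduces the convolution to a fully connected layer."""
        arch = small_arch(d=4)
        params = init_params(arch, rng)
        x = one_hot_input(rng)
        got = log_rates(arch, params, x)
        for e, w in enumerate(arch.windows):
            flat_w = params.kernels[w.rate_symbol].ravel()
            flat_x = x[w.start:w.end].ravel()
            assert got[e] == pytest.approx(
                float(flat_x @ flat_w) + params.biases[w.rate_symbol])

    def test_window_outside_input_rejected(self):
        scheme = cas9_cycle_scheme(4)
        windows = list(default_windows(scheme, 20, 4, 1))
        windows[0] = RateWindowSpec("k01", 18, 24, 1)
        with pytest.raises(SpecificationError):
            KinnArchitecture(scheme=scheme, windows=tuple(windows),
                             input_length=20)


class TestKALayer:
    def test_equal_rates_proportional_to_diagram_counts(self, cycle4):
        ds = enumerate_ka_diagrams(cycle4)
        c = 0.3
        occ = ka_layer(ds, np.full(cycle4.n_edges, c))
        counts = np.array([len(ds.diagrams_for_terminal(a)) for a in range(4)])
        np.testing.assert_allclose(occ.vector, counts / counts.sum())

    def test_two_state_example(self):
        from kinn.kinetics import KineticScheme
        scheme = KineticScheme(n_states=2, edges=((0, 1), (1, 0)))
        ds = enumerate_ka_diagrams(scheme)
        occ = ka_layer(ds, np.log([2.0, 1.0]))
        np.testing.assert_allclose(occ.vector, [1 / 3, 2 / 3])

    def test_matches_kinetics_steady_state(self, cycle4, rng):
        ds = enumerate_ka_diagrams(cycle4)
        for _ in range(20):
            rates = RateAssignment.from_vector(
                cycle4, 10 ** rng.uniform(-2, 2, 7))
            log_k = np.log(rates.vector(cycle4) * cycle4.effective_rate_scale())
            occ = ka_layer(ds, log_k)
            oracle = steady_state_ka(cycle4, rates, ds)
            np.testing.assert_allclose(occ.vector, oracle.vector, atol=1e-9)


class TestPredict:
    def test_identity_link_returns_raw_activity(self, cycle4, rng):
        arch = small_arch()
        params = init_params(arch, rng)
        x = one_hot_input(rng)
        rates = extract_rates(arch, params, x)
        nu_oracle = float(
            rates.values["k30"] * steady_state_ka(cycle4, rates).vector[3])
        assert predict(arch, params, x) == pytest.approx(nu_oracle)

    def test_deterministic_on_identical_encodings(self, rng):
        arch = small_arch()
        params = init_params(arch, rng)
        x = one_hot_input(rng)
        assert predict(arch, params, x) == predict(arch, params, x.copy())

    def test_heads_agree_when_cut_is_rate_limiting(self, rng):
        """With the product step orders slower than the rest, the spectral
        and steady-state outputs coincide within 5%."""
        arch_ka = small_arch("ka_steady_state")
        arch_ei = small_arch("eigen_rate")
        params = init_params(arch_ka, rng)
        for sym in params.kernels:
            params.kernels[sym] *= 0.1
            params.biases[sym] = 0.0
        params.biases["k30"] = np.log(1e-4)
        x = one_hot_input(rng)
        ka = predict(arch_ka, params, x)
        ei = predict(arch_ei, params, x)
        assert abs(ka - ei) / ei < 0.05

    def test_gradient_contract_both_heads(self, rng):
        """Analytic gradients of the prediction match central finite
        differences to 1e-4 relative for every parameter."""
        for head in ("ka_steady_state", "eigen_rate"):
            arch = small_arch(head, L=12, d=2)
            arch = KinnArchitecture(
                scheme=arch.scheme,
                windows=default_windows(arch.scheme, 12, 3, 2),
                input_length=12, output_head=head,
                link_spec=LinkSpec("softplus", "identity", hidden=2),
            )
            params = init_params(arch, rng)
            x = one_hot_input(rng, L=12)
            pt = _ParamTensors(params)
            y, _ = forward_batch(arch, pt, x[None])
            y.backward(np.ones(1))
            eps = 1e-5
            for t in pt.all():
                it = np.nditer(t.data, flags=["multi_index"])
                for _ in it:
                    i = it.multi_index
                    t.data[i] += eps
                    up = predict(arch, pt.to_params(), x)
                    t.data[i] -= 2 * eps
                    dn = predict(arch, pt.to_params(), x)
                    t.data[i] += eps
                    fd = (up - dn) / (2 * eps)
                    assert t.grad[i] == pytest.approx(
                        fd, rel=1e-4, abs=1e-10)


@pytest.fixture(scope="module")
def planted():
    cfg = SimulatorConfig(n_sequences=700, seed=42)
    df = simulate_invitro(cfg)
    X, y = encode_invitro_dataset(df)
    scheme = cfg.scheme()
    windows = tuple(RateWindowSpec(sym, lo, hi, 1)
                    for sym, (lo, hi) in cfg.windows().items())
    arch = KinnArchitecture(scheme=scheme, windows=windows,
                            input_length=50, output_head="ka_steady_state")
    return cfg, df, X, y, arch


class TestFit:
    def test_recovers_planted_model(self, planted):
        cfg, df, X, y, arch = planted
        params, hist = fit(
            arch, (X[:500], y[:500]),
            TrainConfig(epochs=150, learning_rate=8e-2, seed=0, patience=30),
            val=(X[500:], y[500:]),
        )
        assert max(hist["val_pearson"]) > 0.85

    def test_constant_labels_warn_and_score_zero(self, planted, rng):
        _, _, X, _, arch = planted
        const = np.full(60, 0.5)
        with pytest.warns(RuntimeWarning, match="constant"):
            params, hist = fit(
                arch, (X[:60], const),
                TrainConfig(epochs=3, seed=0),
                val=(X[60:80], const[:20]),
            )
        assert hist["val_pearson"][0] == 0.0

    def test_same_seed_reproduces_history_bitwise(self, planted):
        _, _, X, y, arch = planted
        cfg = TrainConfig(epochs=5, seed=7, batch_size=32)
        _, h1 = fit(arch, (X[:100], y[:100]), cfg, val=(X[100:150], y[100:150]))
        _, h2 = fit(arch, (X[:100], y[:100]), cfg, val=(X[100:150], y[100:150]))
        assert h1 == h2

    def test_rates_local_to_windows(self, planted, rng):
        """Perturbing the input outside every window leaves the extracted
        rates unchanged."""
        _, _, X, y, arch = planted
        params, _ = fit(arch, (X[:80], y[:80]), TrainConfig(epochs=3, seed=0))
        x = X[0].copy()
        x2 = x.copy()
        x2[:5] = 0.0   # flanks outside the active-region windows
        x2[40:] = 0.0
        r1 = extract_rates(arch, params, x)
        r2 = extract_rates(arch, params, x2)
        assert r1.values == r2.values

    def test_extracted_rates_drive_kinetics(self, planted, rng):
        _, _, X, y, arch = planted
        params, _ = fit(arch, (X[:80], y[:80]), TrainConfig(epochs=3, seed=0))
        rates = extract_rates(arch, params, X[0])
        occ = propagate(arch.scheme, rates,
                        StateOccupancy(np.array([1.0, 0, 0, 0])), 0.5)
        assert occ.vector.sum() == pytest.approx(1.0, abs=1e-9)


def test_checkpoint_round_trip(tmp_path, rng):
    arch = small_arch(d=3)
    params = init_params(arch, rng, label_median=0.01)
    path = tmp_path / "model.json"
    save_checkpoint(path, arch, params)
    arch2, params2 = load_checkpoint(path)
    assert arch2 == arch
    x = one_hot_input(rng)
    assert predict(arch2, params2, x) == pytest.approx(predict(arch, params, x))


def test_parameter_count_is_small():
    """A 4-state KINN on the 25 x 13 encoding stays orders of magnitude
    below a generic two-conv + recurrent backbone."""
    scheme = cas9_cycle_scheme(4)
    arch = KinnArchitecture(
        scheme=scheme, windows=default_windows(scheme, 25, 5, 1),
        input_length=25, n_channels=13)
    from kinn.transfer import BackboneSpec, TransferModel
    from kinn.model import init_params as ip
    import numpy as np
    model = TransferModel(
        frozen_arch=arch,
        frozen_params=ip(arch, np.random.default_rng(0)),
        backbone_spec=BackboneSpec(conv1="k5", conv2="k3", recurrent="wide"),
    )
    backbone_n = sum(v.size for sub in model.params.values()
                     for v in sub.values())
    assert arch.n_parameters() * 50 < backbone_n


def test_pearson_nan_safety():
    with pytest.warns(RuntimeWarning):
        assert pearson(np.ones(5), np.arange(5.0)) == 0.0
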