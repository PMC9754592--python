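import numpy as np
import pytest

from msbnet.synthetic_phantom import PhantomParams, generate_volume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """A 48x48x16 phantom shared by I/O and evaluation tests."""
    return generate_volume(PhantomParams(height=48, width=48, depth=16,
                                         n_structures=6, smoothness=1.0,
                                         noise_sd=0.01, seed=99))


def numeric_gradcheck(model, x, loss_fn, names, eps=1e-6, tol=1e-5):
    """Compare analytic parameter gradients against central differences."""
    params = dict(model.named_parameters())
    out = model(x)
    loss, grad = loss_fn(out)
    model.zero_grad()
    model.backward(grad)
    for name in names:
        p = params[name]
        idx = tuple(0 for _ in p.value.shape)
        old = p.value[idx]
        p.value[idx] = old + eps
        lp, _ = loss_fn(model(x))
        p.value[idx] = old - eps
        lm, _ = loss_fn(model(x))
        p.value[idx] = old
        num = (lp - lm) / (2 * eps)
        ana = p.grad[idx]
        rel = abs(num - ana) / max(1e-10, abs(num) + abs(ana))
        assert rel < tol, f"gradient mismatch for {name}: numeric {num}, analytic {ana}"
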