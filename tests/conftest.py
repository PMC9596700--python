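import numpy as np
import pytest

from gazehmm import autodiff as ad


@pytest.fixture
def float64_graph():
    """Run autodiff in float64 for finite-difference gradient checks."""
    old = ad.DTYPE
    ad.DTYPE = np.float64
    yield
    ad.DTYPE = old


def gradcheck(f, x0, eps=1e-6):
    """Max abs difference between autodiff and central finite differences."""
    x = ad.Tensor(np.asarray(x0, dtype=float).copy(), requires_grad=True)
    f(x).backward()
    g = x.grad.copy()
    num = np.zeros_like(np.asarray(x0, dtype=float))
    flat_shape = num.shape
    for i in range(num.size):
        xp = np.asarray(x0, dtype=float).reshape(-1).copy()
        xm = xp.copy()
        xp[i] += eps
        xm[i] -= eps
        fp = f(ad.Tensor(xp.reshape(flat_shape))).data
        fm = f(ad.Tensor(xm.reshape(flat_shape))).data
        num.reshape(-1)[i] = (fp - fm) / (2 * eps)
    return float(np.abs(g - num).max())


@pytest.fixture
def tiny_stimuli():
    """A small 2-identity stimulus set at 20x20 px (fast to train on)."""
    from gazehmm.faces import generate_identity_prototypes, render_stimulus_set

    protos = generate_identity_prototypes(2, rng_seed=0, image_size=20)
    return render_stimulus_set(protos, exemplars_per_identity=6, rng_seed=1)


@pytest.fixture
def tiny_config():
    from gazehmm.training import TrainConfig

    return TrainConfig(
        n_identities=2,
        image_size=20,
        epochs=3,
        checkpoint_epochs=(1, 3),
        seed=0,
    )
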