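import numpy as np
import pytest

from dsaperf import phantom as ph


@pytest.fixture(scope="session")
def default_pair():
    """The canonical treated/control phantom pair under study conditions."""
    spec, deltas = ph.default_pre_post_spec(seed=7)
    pre, post, pre_truth, post_truth, truth_deltas = ph.make_pre_post(spec, deltas)
    return {
        "spec": spec,
        "pre": pre,
        "post": post,
        "pre_truth": pre_truth,
        "post_truth": post_truth,
        "truth_deltas": truth_deltas,
    }


@pytest.fixture()
def clean_phantom():
    """A noise- and texture-free single phantom with ground truth."""
    spec, _ = ph.default_pre_post_spec(seed=11)
    spec.noise_sd = 0.0
    spec.background_amp = 0.0
    seq, truth = ph.generate(spec)
    return spec, seq, truth


def random_gamma_curves(n, seed, dt=0.25, t_end=20.0):
    """Seeded random gamma-variate boluses with their sampled curves."""
    rng = np.random.default_rng(seed)
    out = []
    t = np.arange(0.0, t_end + dt / 2, dt)
    for _ in range(n):
        b = ph.GammaVariate(
            amplitude=float(rng.uniform(10, 50)),
            alpha=float(rng.uniform(1, 4)),
            beta=float(rng.uniform(0.5, 3)),
            t0=float(rng.uniform(0, 5)),
        )
        out.append((b, t, b(t)))
    return out
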