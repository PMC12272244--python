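import numpy as np
import pytest

from smval.forward import make_protocol


@pytest.fixture(scope="session")
def protocol():
    """The study acquisition: 3 shells x 43 directions + 3 b0."""
    return make_protocol()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def gauss_legendre_01(n=200):
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


def mixture_tensors(fracs, Ds):
    """Analytic diffusion/kurtosis tensors of a Gaussian mixture: the
    independent oracle for DKI and WMTI tests."""
    from smval.estimators import _W_IDX, DKITensors

    def sym4(A, B):
        S = np.zeros((3, 3, 3, 3))
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    for l in range(3):
                        S[i, j, k, l] = (A[i, j] * B[k, l]
                                         + A[i, k] * B[j, l]
                                         + A[i, l] * B[j, k]) / 3.0
        return S

    D = sum(f * Di for f, Di in zip(fracs, Ds))
    md = np.trace(D) / 3.0
    M2 = sum(f * sym4(Di, Di) for f, Di in zip(fracs, Ds)) - sym4(D, D)
    Wfull = 3.0 * M2 / md**2
    W = np.array([Wfull[i] for i in _W_IDX])
    return DKITensors(D=D, W=W)
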