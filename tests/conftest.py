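import numpy as np
import pytest

from ilvit.datapipe import SyntheticDatasetSpec, generate_synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """64 synthetic 4-class images at the reduced 32×32 test geometry."""
    return generate_synthetic(
        SyntheticDatasetSpec(per_class_count=16, image_size=32, seed=7))


def fd_gradcheck(f, arrays, eps=1e-6, tol=1e-4):
    """Compare autograd gradients against central finite differences."""
    from ilvit.tensor import Tensor

    tensors = [Tensor(a, requires_grad=True) for a in arrays]
    f(*tensors).sum().backward()
    for t in tensors:
        num = np.zeros_like(t.data)
        it = np.nditer(t.data, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = t.data[i]
            t.data[i] = orig + eps
            fp = f(*[Tensor(u.data) for u in tensors]).sum().item()
            t.data[i] = orig - eps
            fm = f(*[Tensor(u.data) for u in tensors]).sum().item()
            t.data[i] = orig
            num[i] = (fp - fm) / (2 * eps)
        err = np.max(np.abs(num - t.grad) / (np.abs(num) + 1.0))
        assert err < tol, f"gradient mismatch {err:.2e}"
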