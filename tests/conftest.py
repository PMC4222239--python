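import numpy as np
import pytest

from dnastore.codec import encode_message, production_code
from dnastore.fixtures import make_fixture_image
from dnastore.ldpc import build_regular_code


@pytest.fixture(scope="session")
def small_code():
    """Tiny reference code whose 2^6 codewords can be enumerated."""
    return build_regular_code(n=12, k=6, col_weight=3, seed=1)


@pytest.fixture(scope="session")
def prod_code():
    return production_code()


@pytest.fixture(scope="session")
def fixture_image():
    return make_fixture_image()


@pytest.fixture(scope="session")
def encoded_fixture(fixture_image):
    """The fixture image encoded with production parameters."""
    return encode_message(fixture_image)


def all_codewords(code):
    """Enumerate every codeword of a small code via the systematic encoder."""
    from dnastore.ldpc import ldpc_encode
    k = code.k
    words = []
    for x in range(2 ** k):
        info = np.array([(x >> (k - 1 - i)) & 1 for i in range(k)], dtype=np.uint8)
        words.append(ldpc_encode(info, code))
    return np.array(words, dtype=np.uint8)
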