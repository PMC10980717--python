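import numpy as np
import pytest

# Randomly generated 49% AT sequence used for the in-silico duplex;
# AT-rich stretch around positions 51-60 (ACTTTTTTTC).
SEQ300 = (
    "TGCAAGATTTGCAACCAGGCAGACTTAGCGGTAGGTCCTAGTGCAGCGGG"
    "ACTTTTTTTCTATAGTCGTTGAGAGGAGGAGTCGTCAGACCAGATACCTT"
    "TGATGTCCTGATTGGAAGGACCGTTGGCCCCCGACCCTTAGACAGTGTAC"
    "TCAGTTCTATAAACGAGCTATTAGATATGAGATCCGTAGATTGAAAAGGG"
    "TGACGGAATTCGCCCGGACGCAAAAGACGGACAGCTAGGTATCCTGAGCA"
    "CGGTTGCGCGTCCGAATCAAGCTCCTCTTTACAGGCCCCGGTTTCTGTTG")


@pytest.fixture(scope="session")
def seq300():
    return SEQ300


@pytest.fixture(scope="session")
def single_punctum_movie():
    """Tether movie with one immobile punctum carrying half the tether
    intensity, plus its ground truth."""
    from plectolab import synthdata as sd
    stack, gt = sd.gen_tether_movie(n_frames=10, puncta=((0.5, 0.0),),
                                    seed=4)
    return stack, gt


def assert_rel(actual, expected, tol):
    assert expected != 0
    assert abs(actual / expected - 1.0) <= tol, \
        f"{actual} vs {expected} (rel err {abs(actual/expected-1):.4f})"
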