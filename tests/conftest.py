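import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from micontact import PairedMSA, SyntheticSpec, build_mask, generate_annotations, generate_msa

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_msa(rows, d1, d2, reference_index=0, **kw):
    """Small hand-built paired alignment; rows are strings."""
    return PairedMSA(
        sequences=tuple(rows),
        ids=tuple(f"s{i}" for i in range(len(rows))),
        reference_index=reference_index,
        domain1_cols=tuple(d1),
        domain2_cols=tuple(d2),
        **kw,
    )


def random_paired_msa(rng, n_seq, len1, len2, alphabet="ACDE"):
    """Random small alignment for oracle-equivalence checks."""
    symbols = np.array(list(alphabet))
    arr = symbols[rng.integers(0, len(symbols), size=(n_seq, len1 + len2))]
    rows = ["".join(r) for r in arr]
    return make_msa(rows, range(len1), range(len1, len1 + len2),
                    domain1_start=1, domain2_start=len1 + 1)


@pytest.fixture(scope="session")
def standard_spec():
    """The standard synthetic case used across evaluation tests."""
    return SyntheticSpec(
        n_sequences=300, len1=20, len2=20, seed=7,
        coupled_pairs=((2, 25, 0.9), (5, 28, 0.8)),
        coupled_triples=((7, 30, 31, 0.5),),
        alphabet_size=20,
        conserved_cols=(10, 36), gapped_cols=(11, 37),
        contact_cols=(2, 5, 7, 25, 28, 30),
        patch_pairs=((30, 31), (33, 34)),
    )


@pytest.fixture(scope="session")
def standard_case(standard_spec):
    msa = generate_msa(standard_spec)
    annotations, dmap, coords = generate_annotations(standard_spec, msa)
    return {
        "spec": standard_spec,
        "msa": msa,
        "mask": build_mask(msa),
        "annotations": annotations,
        "dmap": dmap,
        "coords": coords,
    }
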