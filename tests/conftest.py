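import numpy as np
import pytest

import plasticore as pc


@pytest.fixture(scope="session")
def multiome():
    """One default simulated multiome dataset shared across tests."""
    cfg = pc.SimConfig(seed=1)
    rna, atac, fragments, signatures, motif_map, truth = pc.generate_multiome(cfg)
    return {
        "config": cfg,
        "rna": rna,
        "atac": atac,
        "fragments": fragments,
        "signatures": signatures,
        "motif_map": motif_map,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=5000, max_len=400):
    """Random (possibly overlapping) intervals for oracle tests."""
    out = []
    for i in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(
            pc.GenomicInterval(str(rng.choice(chroms)), start, start + length, ".", f"r{i}")
        )
    return out


def random_fragments(rng, n, cell_ids, chroms=("chr1", "chr2"), max_pos=5000, max_len=300):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(
            pc.FragmentRecord(
                str(rng.choice(chroms)),
                start,
                start + length,
                str(rng.choice(cell_ids)),
                int(rng.integers(1, 4)),
            )
        )
    return out
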