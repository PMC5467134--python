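import numpy as np
import pytest

from ribodeconv import experiments
from ribodeconv.profiles import LengthProfile, TranscriptAnnotation, window_bounds


@pytest.fixture
def annot100():
    """100-codon CDS with 24 nt of UTR either side."""
    return TranscriptAnnotation("t100", cds_start=24, cds_end=324, length=400)


def make_profile(
    annot: TranscriptAnnotation,
    read_length: int,
    cells: dict[int, float],
    l_up: int = 24,
) -> LengthProfile:
    """Build a LengthProfile from a {position: count} mapping."""
    up, down = window_bounds(annot, l_up)
    counts = np.zeros(up + down)
    for pos, value in cells.items():
        counts[pos + up] = value
    return LengthProfile(
        annot.transcript_id, read_length, counts, alpha=float(counts.sum()), l_up=l_up
    )


@pytest.fixture
def profile_factory():
    return make_profile


# -- session-scoped benchmark runs shared by acceptance and property tests ---


@pytest.fixture(scope="session")
def bench_result():
    return experiments.deblur_benchmark(seed=7)


@pytest.fixture(scope="session")
def blur_result():
    return experiments.blur_recovery(seed=11)


@pytest.fixture(scope="session")
def frameshift_result():
    return experiments.frameshift_benchmark(seed=21)


@pytest.fixture(scope="session")
def cdt_result():
    return experiments.cdt_benchmark(seed=5)
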