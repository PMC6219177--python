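"""Shared fixtures: synthetic references, read sets, and truth sets."""

import pytest
from hypothesis import settings

import svbench as sb

settings.register_profile("svbench", derandomize=True, deadline=None)
settings.load_profile("svbench")

CONTIGS_10M = {"chr1": 10_000_000}


@pytest.fixture(scope="session")
def reference():
    """A 60 kb pseudo-random reference (session-scoped: read-only)."""
    return sb.generate_reference(60_000, gc=0.5, seed=11)


@pytest.fixture(scope="session")
def background_reads(reference):
    """30x error-free paired reads over the session reference."""
    return sb.simulate_reads(reference, coverage=30.0, read_len=100,
                             fragment_mean=300.0, fragment_sd=30.0, seed=12)


@pytest.fixture(scope="session")
def truth_500():
    """500 non-overlapping random truth SVs on a 10 Mb coordinate space."""
    return sb.random_truth(500, CONTIGS_10M, seed=21)


@pytest.fixture()
def truth_60():
    return sb.random_truth(60, CONTIGS_10M, seed=22)


def make_sv(sv_id, pos, end, chrom="chr1", svtype="DEL", **kwargs):
    return sb.SVRecord(id=sv_id, chrom=chrom, pos=pos, end=end, svtype=svtype, **kwargs)
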