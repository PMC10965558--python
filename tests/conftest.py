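import numpy as np
import pytest

from cpgislet.sequence import ChromosomeSequence, CpGSiteList


@pytest.fixture
def chrom():
    """Factory for a ChromosomeSequence from a raw string."""

    def make(seq: str, name: str = "chrT") -> ChromosomeSequence:
        return ChromosomeSequence(name=name, seq=seq)

    return make


@pytest.fixture
def site_list():
    """Factory for a CpGSiteList from raw positions."""

    def make(positions, chrom: str = "chrT") -> CpGSiteList:
        return CpGSiteList(chrom=chrom, positions=np.asarray(positions, dtype=np.int64))

    return make


def brute_force_cpg_positions(seq: str) -> list[int]:
    """Independent oracle: every index j with seq[j:j+2] == 'CG'."""
    return [j for j in range(len(seq) - 1) if seq[j : j + 2] == "CG"]


def brute_force_clusters(positions, d: int, min_cpg: int) -> list[list[int]]:
    """Independent oracle: maximal runs with all successive gaps <= d."""
    positions = list(positions)
    if not positions:
        return []
    runs, cur = [], [positions[0]]
    for a, b in zip(positions, positions[1:]):
        if b - a - 1 <= d:
            cur.append(b)
        else:
            runs.append(cur)
            cur = [b]
    runs.append(cur)
    return [r for r in runs if len(r) >= min_cpg]


def random_site_list(rng: np.random.Generator, max_sites: int = 40) -> np.ndarray:
    """Random strictly-increasing positions with gaps >= 1 (diffs >= 2)."""
    n = int(rng.integers(0, max_sites + 1))
    if n == 0:
        return np.empty(0, dtype=np.int64)
    gaps = rng.integers(1, 60, size=n)  # inter-CpG distances d_i >= 1
    return np.cumsum(gaps + 1)
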