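import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clonedist import Dataset, SequenceRecord

settings.register_profile(
    "clonedist",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("clonedist")


@pytest.fixture
def rng():
    return np.random.default_rng(20180726)


@pytest.fixture
def tiny_dataset():
    """Six records, two V/J/length groups, one clonal pair per group."""
    rows = [
        ("s1", "IGHV1-2*02", "IGHJ4*02", "ACGTACGTACGT"),
        ("s2", "IGHV1-2*04", "IGHJ4*01", "ACGTACGTACGA"),
        ("s3", "IGHV1-2*02", "IGHJ4*02", "TTTTGGGGCCCC"),
        ("s4", "IGHV3-23*01", "IGHJ6*02", "AAACCCGGGTTTAAA"),
        ("s5", "IGHV3-23*01", "IGHJ6*02", "AAACCCGGGTTTAAT"),
        ("s6", "IGHV3-23*01", "IGHJ6*02", "CCCAAATTTGGGCCC"),
    ]
    return Dataset([SequenceRecord(*r) for r in rows], dialect="airr")


def random_junctions(rng, m, length, alphabet="ACGT"):
    """m random equal-length junction strings (possibly with duplicates)."""
    letters = np.array(list(alphabet))
    out = []
    for _ in range(m):
        if out and rng.random() < 0.15:  # inject exact duplicates
            out.append(out[int(rng.integers(len(out)))])
        else:
            out.append("".join(letters[rng.integers(len(letters), size=length)]))
    return out


def brute_force_nearest(junctions):
    """Independent oracle: all-pairs scan for min distance to a non-identical
    neighbor; None when every other sequence is identical (or absent)."""
    out = []
    for i, a in enumerate(junctions):
        best = None
        for j, b in enumerate(junctions):
            if i == j or a == b:
                continue
            d = sum(
                1 for ca, cb in zip(a, b) if ca != cb or "N" in (ca, cb)
            ) / len(a)
            if best is None or d < best:
                best = d
        out.append(best)
    return out


def union_find_clusters(junctions, t, link="lt"):
    """Independent oracle: transitive closure over sub-threshold pairs."""
    m = len(junctions)
    parent = list(range(m))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(m):
        for j in range(i + 1, m):
            if junctions[i] == junctions[j]:  # exact copies: distance 0
                d = 0.0
            else:
                d = sum(
                    1 for ca, cb in zip(junctions[i], junctions[j])
                    if ca != cb or "N" in (ca, cb)
                ) / len(junctions[i])
            if (d < t) if link == "lt" else (d <= t):
                parent[find(i)] = find(j)
    roots = [find(i) for i in range(m)]
    remap = {}
    return [remap.setdefault(r, len(remap)) for r in roots]
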