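import numpy as np
import pytest
from hypothesis import given, strategies as st

from clonedist import (
    distance_to_nearest_of,
    normalized_hamming,
    partition_by_vjl,
)
from conftest import brute_force_nearest, random_junctions


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("AAAA", "AAAA", 0.0),
        ("ACGT", "ACGA", 0.25),
        ("ACGT", "TGCA", 1.0),
        ("acgt", "ACGA", 0.25),   # case-insensitive
        ("ACGN", "ACGN", 0.25),   # N mismatches N
    ],
)
def test_normalized_hamming(a, b, expected):
    assert normalized_hamming(a, b) == expected


def test_normalized_hamming_rejects_bad_input():
    with pytest.raises(ValueError):
        normalized_hamming("ACG", "ACGT")
    with pytest.raises(ValueError):
        normalized_hamming("", "")


def test_partition_groups_by_collapsed_calls_and_length(tiny_dataset):
    groups = partition_by_vjl(tiny_dataset)
    assert [g.key for g in groups] == [
        ("IGHV1-2", "IGHJ4", 12),
        ("IGHV3-23", "IGHJ6", 15),
    ]
    assert groups[0].member_ids == ("s1", "s2", "s3")
    # allele level splits the first group (s1/s3 share *02 alleles, s2 not)
    allele_groups = partition_by_vjl(tiny_dataset, "allele", "allele")
    assert [g.member_ids for g in allele_groups] == [("s1", "s3"), ("s2",), ("s4", "s5", "s6")]


def test_distance_to_nearest_tiny_group():
    # nearest distances: AAAA->AAAT 0.25, AAAT->AAAA 0.25, TTTT->AAAT 0.75
    from clonedist import Dataset, SequenceRecord

    ds = Dataset([
        SequenceRecord("a", "IGHV1", "IGHJ1", "AAAA"),
        SequenceRecord("b", "IGHV1", "IGHJ1", "AAAT"),
        SequenceRecord("c", "IGHV1", "IGHJ1", "TTTT"),
    ])
    dtn = distance_to_nearest_of(ds)
    assert dtn.values == {"a": 0.25, "b": 0.25, "c": 0.75}


def test_identical_only_neighbors_are_undefined():
    from clonedist import Dataset, SequenceRecord

    ds = Dataset([
        SequenceRecord("a", "IGHV1", "IGHJ1", "AAAA"),
        SequenceRecord("b", "IGHV1", "IGHJ1", "AAAA"),
        SequenceRecord("lone", "IGHV9", "IGHJ1", "CCCC"),
    ])
    dtn = distance_to_nearest_of(ds)
    assert dtn.values == {"a": None, "b": None, "lone": None}
    assert dtn.n_defined == 0


def test_empty_dataset_gives_empty_groups():
    from clonedist import Dataset

    assert partition_by_vjl(Dataset([])) == []


@given(st.integers(0, 10_000))
def test_matches_brute_force_oracle(seed):
    """Vectorized distance-to-nearest equals the all-pairs scan exactly."""
    rng = np.random.default_rng(seed)
    m = int(rng.integers(1, 31))
    length = int(rng.integers(3, 20))
    juncs = random_junctions(rng, m, length, alphabet="ACGTN")
    from clonedist import Dataset, SequenceRecord

    ds = Dataset([
        SequenceRecord(f"s{i}", "IGHV1", "IGHJ1", j) for i, j in enumerate(juncs)
    ])
    dtn = distance_to_nearest_of(ds)
    expected = brute_force_nearest(juncs)
    got = [dtn.values[f"s{i}"] for i in range(m)]
    assert got == pytest.approx(expected)


@given(st.integers(0, 5_000))
def test_permutation_invariance(seed):
    """Reordering records never changes any sequence's distance value."""
    rng = np.random.default_rng(seed)
    juncs = random_junctions(rng, 12, 9)
    from clonedist import Dataset, SequenceRecord

    recs = [SequenceRecord(f"s{i}", "IGHV1", "IGHJ1", j) for i, j in enumerate(juncs)]
    base = distance_to_nearest_of(Dataset(list(recs))).values
    perm = [recs[i] for i in rng.permutation(len(recs))]
    shuffled = distance_to_nearest_of(Dataset(perm)).values
    assert shuffled == base


def test_defined_distances_in_unit_interval(rng):
    juncs = random_junctions(rng, 40, 12)
    from clonedist import Dataset, SequenceRecord

    ds = Dataset([SequenceRecord(f"s{i}", "IGHV1", "IGHJ1", j) for i, j in enumerate(juncs)])
    _, values = distance_to_nearest_of(ds).defined()
    assert np.all(values > 0) and np.all(values <= 1)


def test_global_scope_crosses_vj_but_not_length():
    from clonedist import Dataset, SequenceRecord

    ds = Dataset([
        SequenceRecord("a", "IGHV1", "IGHJ1", "AAAA"),
        SequenceRecord("b", "IGHV9", "IGHJ9", "AAAT"),   # other V/J, same length
        SequenceRecord("c", "IGHV1", "IGHJ1", "AAAAA"),  # other length
    ])
    grouped = distance_to_nearest_of(ds, scope="group")
    assert grouped.n_defined == 0
    global_ = distance_to_nearest_of(ds, scope="global")
    assert global_.values["a"] == 0.25 and global_.values["b"] == 0.25
    assert global_.values["c"] is None
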