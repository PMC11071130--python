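import gzip
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdbgc.cdbg_io import (CdbgInput, ColorKmerSet, InputError, canonicalize,
                           count_color, extract_kmers, load_cdbg,
                           read_kmer_list, revcomp, union_with_classes)
from conftest import THREE_COLOR_CLASSES

dna = st.text(alphabet="ACGT", min_size=2, max_size=40)


@pytest.mark.parametrize(
    "raw, canon",
    [
        ("TCAAA", "TCAAA"),     # reverse complement TTTGA is larger
        ("ACGT", "ACGT"),       # reverse-complement palindrome
        ("TTTTT", "AAAAA"),     # reverse complement is smaller
        ("ttttt", "AAAAA"),     # lowercase accepted
    ],
)
def test_canonicalize_examples(raw, canon):
    assert canonicalize(raw) == canon


def test_canonicalize_rejects_non_acgt_with_position():
    with pytest.raises(InputError, match="position 2"):
        canonicalize("ACNGT")


@settings(derandomize=True, max_examples=200)
@given(dna)
def test_canonicalize_idempotent_and_minimal(s):
    c = canonicalize(s)
    assert canonicalize(c) == c
    assert c == min(s, revcomp(s))


@pytest.mark.parametrize(
    "seq, k, expected",
    [
        ("TCAAAAT", 5, ["TCAAA", "CAAAA", "AAAAT"]),
        ("ACGNT", 3, ["ACG"]),   # windows overlapping N contribute nothing
        ("AC", 3, []),           # shorter than k
        ("acgnt", 3, ["ACG"]),   # case-folded before validation
    ],
)
def test_extract_kmers(seq, k, expected):
    assert extract_kmers(seq, k) == expected


def test_extract_kmers_preserves_multiplicity():
    # AAAA twice in AAAAA (windows AAAA, AAAA)
    assert Counter(extract_kmers("AAAAA", 4)) == Counter({"AAAA": 2})


def _write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def test_count_color_abundance_threshold(tmp_path):
    p = tmp_path / "a.fa"
    _write_fasta(p, [("r1", "TCAAAAT")])
    assert count_color([p], 5, 1).kmers == {"TCAAA", "CAAAA", "AAAAT"}
    assert count_color([p], 5, 2).kmers == set()


def test_count_color_merges_strands_across_records(tmp_path):
    p = tmp_path / "b.fa"
    _write_fasta(p, [("r1", "AAAAA"), ("r2", "TTTTT")])
    assert count_color([p], 5, 2).kmers == {"AAAAA"}


def test_count_color_accumulates_over_file_repeats(tmp_path):
    p = tmp_path / "c.fa"
    _write_fasta(p, [("r1", "TCAAAAT")])
    assert count_color([p, p], 5, 2).kmers == {"TCAAA", "CAAAA", "AAAAT"}


def test_count_color_reads_gzip(tmp_path):
    p = tmp_path / "d.fa.gz"
    with gzip.open(p, "wt") as fh:
        fh.write(">r1\nTCAAAAT\n")
    assert count_color([p], 5, 1).kmers == {"TCAAA", "CAAAA", "AAAAT"}


def test_count_color_rejects_non_fasta(tmp_path):
    p = tmp_path / "notfasta.fa"
    p.write_text("TCAAAAT\n")
    with pytest.raises(InputError, match="FASTA"):
        count_color([p], 5, 1)


def test_load_cdbg_manifest_order_and_kmers_passthrough(tmp_path):
    _write_fasta(tmp_path / "c0.fa", [("r", "TCAAAAT")])
    (tmp_path / "c1.kmers").write_text("TTTTT\nAAAAA\n")  # canonicalized, deduped
    _write_fasta(tmp_path / "c2.fa", [("r", "CAAAGT")])
    man = tmp_path / "manifest.txt"
    man.write_text("c0.fa\nc1.kmers\nc2.fa\n")
    E = load_cdbg(man, 5, 1)
    assert E.C == 3
    assert [cs.color_index for cs in E.colors] == [0, 1, 2]
    assert E.colors[1].kmers == {"AAAAA"}
    assert E.colors[2].kmers == {"CAAAG", "AAAGT"}


def test_load_cdbg_empty_manifest(tmp_path):
    man = tmp_path / "manifest.txt"
    man.write_text("\n  \n")
    with pytest.raises(InputError, match="empty manifest"):
        load_cdbg(man, 5, 1)


def test_load_cdbg_missing_file(tmp_path):
    man = tmp_path / "manifest.txt"
    man.write_text("nope.fa\n")
    with pytest.raises(InputError, match="missing file"):
        load_cdbg(man, 5, 1)


def test_read_kmer_list_validates_length(tmp_path):
    p = tmp_path / "x.kmers"
    p.write_text("ACGTA\nACG\n")
    with pytest.raises(InputError, match="length 3"):
        read_kmer_list(p, 5)


def test_union_with_classes_three_color_example(three_color_example):
    mapping = union_with_classes(three_color_example)
    assert mapping == THREE_COLOR_CLASSES
    assert set(mapping) == set(THREE_COLOR_CLASSES)


def test_union_single_color_is_all_ones():
    E = CdbgInput(k=5, C=1, colors=[ColorKmerSet(0, {"AAAAA", "CCCCC"})])
    assert set(union_with_classes(E).values()) == {1}


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.sets(st.sampled_from(
    ["AAAAA", "AAAAC", "AAAAG", "AAAAT", "AAACA", "AAACC"]), min_size=1),
    min_size=1, max_size=5))
def test_union_partition_recovery(sets):
    """Reading column i of the union back as a set recovers E_i exactly."""
    E = CdbgInput(k=5, C=len(sets),
                  colors=[ColorKmerSet(i, s) for i, s in enumerate(sets)])
    mapping = union_with_classes(E)
    assert len(mapping) <= sum(len(s) for s in sets)
    for i, s in enumerate(sets):
        bit = 1 << (len(sets) - 1 - i)
        assert {km for km, v in mapping.items() if v & bit} == s
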