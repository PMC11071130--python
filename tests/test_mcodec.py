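import numpy as np
import pytest

from cdbgc.classtable import assign_global_ids
from cdbgc.mcodec import (CodecError, LocalClassTable, SimplitigMeta,
                          choose_encoding, decode_local_table,
                          decode_run_length, decode_simplitig, diff_indices,
                          encode_local_table, encode_run_length,
                          encode_simplitig, local_table_bits)

from oracles import mode_cost, random_class_seq

ALL_MODES = [SimplitigMeta(d, u) for d in (0, 1, 2) for u in (False, True)]


# --- run-length quotient/remainder coding -------------------------------

@pytest.mark.parametrize(
    "run_len, divisor, bits",
    [
        (21, 16, "100101"),   # q=1, r=5
        (1, 16, "00001"),
        (16, 16, "100000"),   # q=1, r=0
        (0, 16, "00000"),
        (3, 4, "011"),
        (9, 2, "111101"),     # q=4 unary, r=1 in one bit
    ],
)
def test_run_length_encoding(run_len, divisor, bits):
    assert encode_run_length(run_len, divisor) == bits
    value, pos = decode_run_length(bits, 0, divisor)
    assert (value, pos) == (run_len, len(bits))


def test_run_length_round_trips_exhaustively():
    for divisor in (2, 4, 16, 64):
        for n in range(0, 2000):
            bits = encode_run_length(n, divisor)
            assert decode_run_length(bits, 0, divisor) == (n, len(bits))
    assert decode_run_length(encode_run_length(10000, 16), 0, 16)[0] == 10000


def test_run_length_rejects_bad_divisor():
    with pytest.raises(ValueError):
        encode_run_length(5, 12)


def test_run_length_truncation_detected():
    with pytest.raises(CodecError):
        decode_run_length("111", 0, 16)  # unary never terminated
    with pytest.raises(CodecError):
        decode_run_length("1001", 0, 16)  # remainder cut short


# --- difference indices -------------------------------------------------

@pytest.mark.parametrize(
    "prev, cur, C, expected",
    [
        (0b111, 0b011, 3, [0]),
        (0b010, 0b010, 3, []),
        (0b000000, 0b001001, 6, [2, 5]),
    ],
)
def test_diff_indices(prev, cur, C, expected):
    assert diff_indices(prev, cur, C) == expected


# --- metadata bits ------------------------------------------------------

def test_meta_three_bit_round_trip():
    for meta in ALL_MODES:
        assert SimplitigMeta.from_bits(meta.to_bits()) == meta
    with pytest.raises(CodecError):
        SimplitigMeta.from_bits("011")  # maxDif 3 reserved


# --- hand-worked simplitig encodings ------------------------------------

def _two_class_table():
    # classes 1 and 2 over C=2; the more frequent class 1 gets code "0"
    return assign_global_ids({1: 3, 2: 1})


def test_encode_monochrome_run():
    table = _two_class_table()
    m, local = encode_simplitig([1, 1, 1], SimplitigMeta(0, False), table, 16, 2)
    # store ("0" + code "0"), skip, end of run ("1" + runLen 2 -> "00010")
    assert m.bits == "00" + "1" + "00010"
    assert local is None
    out, pos = decode_simplitig(m.bits, 0, SimplitigMeta(0, False), table,
                                None, 3, 2, 16)
    assert out == [1, 1, 1] and pos == len(m.bits)


def test_encode_single_bit_difference():
    # u=1, v=5 over C=6 differ exactly at color index 3
    table = assign_global_ids({1: 2, 5: 1})
    m, _ = encode_simplitig([1, 5], SimplitigMeta(1, False), table, 16, 6)
    assert m.bits == "0" + "0" + "10" + "011"
    out, _ = decode_simplitig(m.bits, 0, SimplitigMeta(1, False), table,
                              None, 2, 6, 16)
    assert out == [1, 5]


def test_lone_kmer_stores_its_id():
    # three classes; class 2 receives the code "10"
    table = assign_global_ids({1: 2, 2: 1, 3: 1})
    assert table.codes[2] == "10"
    m, _ = encode_simplitig([2], SimplitigMeta(0, False), table, 16, 2)
    assert m.bits == "0" + "10"


def test_run_of_22_reproduces_printed_run_bits():
    table = _two_class_table()
    m, _ = encode_simplitig([1] * 22, SimplitigMeta(0, False), table, 16, 2)
    assert m.bits == "00" + "1" + "100101"  # runLen 21 under divisor 16
    out, _ = decode_simplitig(m.bits, 0, SimplitigMeta(0, False), table,
                              None, 22, 2, 16)
    assert out == [1] * 22


def test_two_bit_difference_under_maxdif_two():
    table = assign_global_ids({0b000000: 2, 0b001001: 1})
    m, _ = encode_simplitig([0b000000, 0b001001], SimplitigMeta(2, False),
                            table, 16, 6)
    # store, then "10" + h-flag "1" + indices 2 and 5 in 3 bits each
    assert m.bits == "0" + "0" + "10" + "1" + "010" + "101"
    out, _ = decode_simplitig(m.bits, 0, SimplitigMeta(2, False), table,
                              None, 2, 6, 16)
    assert out == [0b000000, 0b001001]


def test_single_class_table_costs_only_type_bits():
    table = assign_global_ids({0b1: 9})
    m, _ = encode_simplitig([1, 1, 1, 1], SimplitigMeta(0, False), table, 16, 1)
    # empty Huffman code: "0" store, skips, "1" + runLen 3
    assert m.bits == "0" + "1" + "00011"
    out, _ = decode_simplitig(m.bits, 0, SimplitigMeta(0, False), table,
                              None, 4, 1, 16)
    assert out == [1, 1, 1, 1]


def test_local_table_round_trip():
    table = assign_global_ids({1: 5, 2: 3, 3: 2, 4: 1})
    seq = [3, 3, 1, 3, 1, 1]
    m, local = encode_simplitig(seq, SimplitigMeta(0, True), table, 16, 3)
    assert local is not None and local.entries == [3, 1]  # first appearance
    bits = encode_local_table(local, table)
    assert len(bits) == local_table_bits(local, table)
    got, pos = decode_local_table(bits, 0, table)
    assert got.entries == local.entries and pos == len(bits)
    out, _ = decode_simplitig(m.bits, 0, SimplitigMeta(0, True), table,
                              local, len(seq), 3, 16)
    assert out == seq


def test_local_table_single_entry_uses_zero_id_bits():
    table = assign_global_ids({1: 5, 2: 5})
    m, local = encode_simplitig([2, 2], SimplitigMeta(0, True), table, 16, 2)
    assert local.ell == 1 and local.id_width == 0
    # store is 1 type bit + 0 ID bits, then the run marker
    assert m.bits == "0" + "1" + "00001"
    out, _ = decode_simplitig(m.bits, 0, SimplitigMeta(0, True), table,
                              local, 2, 2, 16)
    assert out == [2, 2]


# --- decoder corruption handling ----------------------------------------

def test_decoder_rejects_truncated_stream():
    table = _two_class_table()
    m, _ = encode_simplitig([1, 1, 1], SimplitigMeta(0, False), table, 16, 2)
    with pytest.raises(CodecError):
        decode_simplitig(m.bits[:-2], 0, SimplitigMeta(0, False), table,
                         None, 3, 2, 16)


def test_decoder_rejects_run_before_any_class():
    table = _two_class_table()
    with pytest.raises(CodecError, match="run marker"):
        decode_simplitig("100001", 0, SimplitigMeta(0, False), table,
                         None, 2, 2, 16)


def test_decoder_rejects_overshoot():
    table = _two_class_table()
    # store, then runLen 5 against a 3-k-mer simplitig
    bits = "00" + "1" + "00101"
    with pytest.raises(CodecError):
        decode_simplitig(bits, 0, SimplitigMeta(0, False), table, None, 3, 2, 16)


# --- randomized round-trips and the mode search -------------------------

def _random_instance(rng):
    C = int(rng.integers(1, 17))
    max_m = (1 << C) - 1
    M = int(rng.integers(1, min(12, max_m) + 1))
    base = int(rng.integers(1, max_m + 1))
    classes = {base}
    while len(classes) < M:
        # mix nearby classes (Hamming 1-2) with uniform draws
        if rng.random() < 0.6:
            v = base ^ (1 << int(rng.integers(0, C)))
            if C > 1 and rng.random() < 0.5:
                v ^= 1 << int(rng.integers(0, C))
        else:
            v = int(rng.integers(1, max_m + 1))
        if v:
            classes.add(v)
    freqs = {c: int(rng.integers(1, 50)) for c in classes}
    table = assign_global_ids(freqs)
    seq = random_class_seq(rng, list(classes), int(rng.integers(1, 200)))
    return C, table, seq


def test_round_trip_identity_over_random_sequences_all_modes():
    rng = np.random.default_rng(11)
    for _ in range(300):
        C, table, seq = _random_instance(rng)
        for meta in ALL_MODES:
            m, local = encode_simplitig(seq, meta, table, 16, C)
            out, pos = decode_simplitig(m.bits, 0, meta, table, local,
                                        len(seq), C, 16)
            assert out == seq
            assert pos == len(m.bits)


def test_choose_encoding_matches_independent_cost_oracle():
    rng = np.random.default_rng(13)
    for _ in range(150):
        C, table, seq = _random_instance(rng)
        choice = choose_encoding(seq, table, 16, C)
        oracle = {
            (d, u): mode_cost(seq, table.codes, table.M, C, d, u, 16)
            for d in (0, 1, 2) for u in (False, True)
        }
        assert choice.total_bits == min(oracle.values())
        assert choice.total_bits <= oracle[(0, False)]


def test_choose_encoding_tie_breaks_to_plain_mode():
    table = assign_global_ids({1: 1})
    choice = choose_encoding([1], table, 16, 1)
    assert choice.meta == SimplitigMeta(0, False)
    assert choice.total_bits == 3 + 1  # metadata + the lone store type bit


def test_choose_encoding_single_class_never_uses_local_table():
    table = assign_global_ids({3: 5, 1: 1})
    choice = choose_encoding([3] * 5, table, 16, 2)
    assert not choice.meta.use_local_id
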