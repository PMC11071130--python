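"""Independent reference implementations used to cross-check the codec.

These deliberately re-derive costs and structures from the encoding rules by
direct simulation, sharing no code with cdbgc.mcodec, so a bug there cannot
hide behind an identical bug here.
"""
from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np


def mode_cost(
    seq: List[int],
    codes: Dict[int, str],
    M: int,
    C: int,
    max_dif: int,
    use_local: bool,
    run_divisor: int,
) -> int:
    """Total bit cost (metadata + m + local table) of one mode, by case analysis."""
    wC = max(1, (C - 1).bit_length())
    rem_w = run_divisor.bit_length() - 1
    distinct: List[int] = []
    for c in seq:
        if c not in distinct:
            distinct.append(c)
    cost = 3
    if use_local:
        idw = (len(distinct) - 1).bit_length()
        cost += max(1, (M - 1).bit_length()) + sum(len(codes[c]) for c in distinct)

        def store(c: int) -> int:
            return 1 + idw
    else:

        def store(c: int) -> int:
            return 1 + len(codes[c])

    n = len(seq)
    for i, c in enumerate(seq):
        if i == 0:
            cost += store(c)
            continue
        if c == seq[i - 1]:
            if i + 1 < n and seq[i + 1] == c:
                continue  # skip
            j = i - 1
            run_len = 0
            while j >= 0 and seq[j] == c:
                run_len += 1
                j -= 1
            cost += (2 if max_dif else 1) + run_len // run_divisor + 1 + rem_w
        else:
            h = bin(c ^ seq[i - 1]).count("1")
            if 0 < h <= max_dif:
                cost += 2 + (1 if max_dif == 2 else 0) + h * wC
            else:
                cost += store(c)
    return cost


def random_class_table(rng: np.random.Generator, C: int, M: int):
    """Random (classes, freqs) over nonzero C-bit vectors; M <= 2^C - 1."""
    universe = 1 << C
    assert 1 <= M < universe
    if universe <= 1 << 16:
        classes = rng.choice(np.arange(1, universe), size=M, replace=False).tolist()
    else:
        picked = set()
        while len(picked) < M:
            # compose wide vectors from 16-bit draws (C may exceed 63 bits)
            v = 0
            for _ in range((C + 15) // 16):
                v = (v << 16) | int(rng.integers(0, 1 << 16))
            v &= universe - 1
            if v:
                picked.add(v)
        classes = sorted(picked)
    freqs = rng.integers(1, 1000, size=M).tolist()
    return {int(c): int(f) for c, f in zip(classes, freqs)}


def random_class_seq(
    rng: np.random.Generator, classes: List[int], length: int
) -> List[int]:
    """Run-structured random sequence: geometric runs over the class alphabet."""
    seq: List[int] = []
    cur = int(classes[rng.integers(len(classes))])
    while len(seq) < length:
        run = 1 + int(rng.geometric(0.25))
        seq.extend([cur] * min(run, length - len(seq)))
        cur = int(classes[rng.integers(len(classes))])
    return seq[:length]
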