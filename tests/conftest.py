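import pytest

from cdbgc.cdbg_io import CdbgInput, ColorKmerSet

# Three-color toy graph used across the suite: k=5, C=3, seven union k-mers,
# three distinct color classes ({0,1,2} -> 111, {1,2} -> 011, {1} -> 010).
THREE_COLOR_SETS = (
    {"TCAAA", "CAAAA", "AAAAT"},
    {"TCAAA", "CAAAA", "AAAAT", "AAATT", "CAAAG", "AAATC", "AATCG"},
    {"TCAAA", "CAAAA", "AAAAT", "AAATT", "CAAAG"},
)

THREE_COLOR_CLASSES = {
    "TCAAA": 0b111,
    "CAAAA": 0b111,
    "AAAAT": 0b111,
    "AAATT": 0b011,
    "CAAAG": 0b011,
    "AAATC": 0b010,
    "AATCG": 0b010,
}


@pytest.fixture
def three_color_example() -> CdbgInput:
    return CdbgInput(
        k=5,
        C=3,
        colors=[ColorKmerSet(i, set(s)) for i, s in enumerate(THREE_COLOR_SETS)],
    )
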