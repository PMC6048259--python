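"""Published reference values for the TorsinA-LULL1 interface study.

These are the printed study tables the worked examples start from: the
binding free-energy comparison between the wild-type TorsinA-LULL1 complex
and the dystonia-linked deletion mutant TorsinA(dE303)-LULL1, and the
per-residue-pair hydrogen-bond counts across the four systems (with and
without the VHH-BS2 crystallization nanobody).  They serve as inputs to the
arithmetic operations (ddG, Kd ratio, HbR) - not as values the pipeline
asserts into existence.
"""

#: Binding free-energy table (kcal/mol at 310 K).  Keys: method -> entries.
#: Each dG entry is (mean, reported spread).
BINDING_DG_TABLE = {
    "ABMD": {
        "dg_wt": (-14.12, 1.82),
        "dg_mut": (-9.45, 0.57),
        "ddg": (4.67, 1.26),
        "kd_ratio": 1961.64,
    },
    "MMPBSA": {
        "dg_wt": (-36.10, 1.11),
        "dg_mut": (-30.87, 1.14),
        "ddg": (5.23, 1.12),
        "kd_ratio": 4869.14,
    },
}

#: Temperature (K) at which the Kd ratios back-calculate from the ddG values.
BINDING_DG_TEMPERATURE = 310.0

#: Hydrogen-bond counts per residue pair (TorsinA residue - LULL1 residue)
#: in the four systems: TLV = wild type + nanobody, TdELV = mutant +
#: nanobody, TL = wild type alone, TdEL = mutant alone.
#: Rows: (pair, TLV, TdELV, TL, TdEL).
HBOND_COUNTS = [
    ("D277-S279", 13, 37, 0, 0),
    ("D262-W489", 28, 57, 48, 18),
    ("E427-K266", 28, 56, 56, 61),
    ("H426-K266", 10, 20, 0, 0),
    ("E458-K255", 17, 33, 32, 37),
    ("R461-D262", 94, 108, 145, 93),
    ("D462-K255", 47, 52, 53, 75),
    ("R258-E458", 160, 170, 240, 216),
    ("D273-K325", 66, 69, 97, 106),
    ("R318-E249", 116, 118, 246, 224),
    ("K263-S493", 33, 33, 38, 61),
    ("E457-K263", 79, 74, 124, 116),
    ("K321-Y276", 21, 19, 22, 11),
    ("R454-M250", 35, 24, 58, 42),
    ("D277-K321", 56, 38, 81, 90),
    ("D277-K325", 33, 22, 43, 32),
    ("D273-K321", 44, 24, 47, 44),
    ("R454-E249", 46, 18, 0, 0),
    ("E457-K271", 27, 9, 30, 30),
    ("H494-T270", 21, 7, 37, 5),
    ("R461-F252", 61, 16, 56, 3),
    ("D425-K266", 13, 3, 0, 0),
    ("R611-E398", 183, 0, 0, 0),
    ("R377-D574", 164, 0, 0, 0),
    ("R454-E248", 94, 0, 180, 0),
    ("D390-H86", 79, 0, 107, 0),
    ("G617-H83", 65, 0, 0, 0),
    ("S88-T565", 57, 0, 0, 0),
    ("R491-D116", 48, 0, 67, 0),
    ("T384-T571", 42, 0, 0, 0),
]


def hbond_count_dicts():
    """The four per-system pair -> count mappings, ready for ``hbr_table``."""
    tlv = {row[0]: row[1] for row in HBOND_COUNTS}
    tdelv = {row[0]: row[2] for row in HBOND_COUNTS}
    tl = {row[0]: row[3] for row in HBOND_COUNTS}
    tdel = {row[0]: row[4] for row in HBOND_COUNTS}
    return tlv, tdelv, tl, tdel
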