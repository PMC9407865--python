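import numpy as np
import pytest

from ripkit import simulate as sim
from ripkit.model import GenotypeCounts


@pytest.fixture(scope="session")
def fixture_loci():
    """Default two-locus fixture, fully generated once per session."""
    out = []
    for cfg in sim.default_locus_configs(seed=42):
        bait, model, library = sim.make_locus(cfg)
        assemblies, truth = sim.make_assemblies(bait, model, library, cfg)
        out.append(
            {
                "cfg": cfg,
                "bait": bait,
                "model": model,
                "library": library,
                "assemblies": assemblies,
                "truth": truth,
            }
        )
    return out


# Genotype counts reconstructed from published per-breed genotype
# frequencies times N, with the expected report strings (percent allele
# frequency, HWE p in the print dialect, 3-decimal PIC). The one row
# whose printed values are internally inconsistent (allele frequencies
# not summing to 100, PIC above the biallelic maximum) is excluded.
REFERENCE_ROWS = [
    # locus, breed, (n++, n+-, n--), freq_ins, hwe, pic
    ("RIP-A", "Large White", (63, 297, 90), "47.00", "<0.01", "0.374"),
    ("RIP-A", "Duroc", (3, 16, 5), "45.83", "0.09", "0.373"),
    ("RIP-A", "Landrace", (0, 9, 15), "18.75", "0.26", "0.258"),
    ("RIP-A", "Sujiang", (7, 9, 8), "47.92", "0.22", "0.375"),
    ("RIP-A", "Jiangquhai", (15, 5, 4), "72.92", "0.02", "0.317"),
    ("RIP-A", "Jinhua", (18, 0, 6), "75.00", "<0.01", "0.305"),
    ("RIP-A", "Rongchang", (7, 17, 0), "64.58", "0.01", "0.353"),
    ("RIP-B", "Large White", (21, 144, 264), "21.68", "0.81", "0.282"),
    ("RIP-B", "Duroc", (0, 11, 13), "22.92", "0.15", "0.291"),
    ("RIP-B", "Jiangquhai", (0, 3, 15), "8.33", None, "0.141"),
    ("RIP-B", "Jinhua", (1, 7, 16), "18.75", "0.83", "0.258"),
    ("RIP-C", "Large White", (0, 269, 160), "31.35", "<0.01", "0.338"),
    ("RIP-C", "Duroc", (0, 18, 6), "37.50", "<0.01", "0.359"),
    ("RIP-C", "Landrace", (0, 23, 1), "47.92", "<0.01", "0.375"),
    ("RIP-C", "Sujiang", (0, 16, 8), "33.33", "0.01", "0.346"),
    ("RIP-C", "Bama", (0, 21, 3), "43.75", "<0.01", "0.371"),
    ("RIP-C", "Jiangquhai", (0, 8, 16), "16.67", "0.33", "0.239"),
    ("RIP-C", "Erhualian", (0, 2, 22), "4.17", "0.83", "0.077"),
    ("RIP-C", "Jinhua", (0, 9, 15), "18.75", "0.26", "0.258"),
    ("RIP-C", "Wuzhishan", (6, 14, 4), "54.17", "0.39", "0.373"),
]


@pytest.fixture(scope="session")
def reference_counts():
    return [
        (locus, GenotypeCounts(breed, *counts), freq, hwe, pic)
        for locus, breed, counts, freq, hwe, pic in REFERENCE_ROWS
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
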