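import numpy as np
import pytest

import condiv as cv


@pytest.fixture
def tiny_alignment():
    """Three labeled sequences, 10 columns."""
    records = [
        ("s1", "ACDEFGHIKL"),
        ("s2", "ACDEFGHIKV"),
        ("s3", "ACDEFGHIK-"),
    ]
    labels = {"s1": "A/x", "s2": "A/y", "s3": "A"}
    return cv.LabeledAlignment(records=records, label_of=labels, n_columns=10)


@pytest.fixture
def planted_alignment():
    """Foreground/background alignment with 10 planted pattern columns and one
    4-column foreground-specific insert; the planting levels mirror a strongly
    family-conserved, background-divergent signature."""
    spec = cv.SyntheticAlignmentSpec(
        n_fg=200, n_bg=600, n_columns=150, seed=42,
        patterns=[cv.PlantedPattern(column=c, residues="E",
                                    conservation=0.95, bg_freq=0.05)
                  for c in (10, 24, 38, 52, 66, 80, 94, 108, 122, 136)],
        inserts=[cv.PlantedInsert(start=60, end=63)],
    )
    aln, truth = cv.gen_alignment(spec)
    return aln, truth


@pytest.fixture
def nested_alignment():
    """Family-wide patterns plus one subfamily-only pattern on a 2-level tree."""
    spec = cv.SyntheticAlignmentSpec(
        n_fg=200, n_bg=600, n_columns=150, seed=7,
        fg_sublabels=("CMGC/MAPK/p38", "CMGC/MAPK/JNK"),
        patterns=[
            cv.PlantedPattern(column=20, residues="E"),
            cv.PlantedPattern(column=40, residues="K"),
            cv.PlantedPattern(column=70, residues="W", group="CMGC/MAPK/p38"),
        ],
    )
    aln, truth = cv.gen_alignment(spec)
    return aln, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
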