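"""Shared fixtures: small synthetic studies and the committed worked toy.

The hand-computed decontamination toy (tests/data/decontam_toy_*.tsv) was
worked out on paper: one OTU present at similar scaled read numbers in the
NTC (removed), one far above the five-times boundary (subtracted:
500 - (1000/52)*2 = 461.54 -> 462 and 300 - (500/52)*2 = 280.77 -> 281),
and one absent from all controls (untouched).
"""

from pathlib import Path

import pytest

from aerosource import io, synth

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_counts():
    return io.read_count_table(DATA / "decontam_toy_counts.tsv")


@pytest.fixture(scope="session")
def toy_meta():
    return io.read_sample_info(DATA / "decontam_toy_meta.tsv")


@pytest.fixture(scope="session")
def toy_expected():
    return io.read_count_table(DATA / "decontam_toy_expected.tsv")


@pytest.fixture(scope="session")
def small_cfg():
    """A fast study: 4 sites, 80 OTUs, 4k reads."""
    return synth.SynthConfig(
        n_sites=4, n_otus=80, n_plant_otus=16, n_contam_otus=10,
        mixing_m=0.4, library_size=4000, seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return synth.generate_study(small_cfg)
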