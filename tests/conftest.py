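import pytest
from hypothesis import settings

from selenospec.chrom_io import default_ida, default_windows

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ida():
    return default_ida()


@pytest.fixture(scope="session")
def windows():
    return default_windows()


# Synthetic 85-residue selenoprotein-W-like fixture: six tryptic fragments
# (no internal K/R, no cleavage site followed by P), of which the five
# "observed" ones span 75 of 85 residues.
SELENOW_SEGMENTS = [
    "ACDEFGHIWYMK",          # 1-12   observed
    "LNQSTVACDEFGHIK",       # 13-27  observed
    "MNQSTVWYACDEFGHILMNK",  # 28-47  observed
    "ACDEFGHIWR",            # 48-57  NOT observed
    "STVWYACDEFGHILMNQK",    # 58-75  observed
    "ACDEFGHIWK",            # 76-85  observed
]


@pytest.fixture(scope="session")
def synthetic_selenow():
    sequence = "".join(SELENOW_SEGMENTS)
    assert len(sequence) == 85
    observed_segments = [s for i, s in enumerate(SELENOW_SEGMENTS) if i != 3]
    return sequence, observed_segments
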