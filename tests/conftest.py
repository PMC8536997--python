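from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from hvrcall.motif_model import build_pattern_pair, default_motifs

REPO_ROOT = Path(__file__).resolve().parent.parent
DATA_DIR = REPO_ROOT / "data"


@pytest.fixture(scope="session")
def motifs():
    return default_motifs()


@pytest.fixture(scope="session")
def patterns(motifs):
    return build_pattern_pair(*motifs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sample_summary_df():
    return pd.read_csv(DATA_DIR / "honey_samples.tsv", sep="\t")


@pytest.fixture(scope="session")
def abundant_df():
    return pd.read_csv(DATA_DIR / "abundant_alleles.tsv", sep="\t")
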