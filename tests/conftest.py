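from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from pgcausal.containers import PROTEIN, TRANSCRIPT, OmicsMatrix, PairedOmics

DATA_DIR = Path(__file__).parent / "data"


def make_paired(transcript: np.ndarray, protein: np.ndarray | None = None,
                feature_ids=None, sample_ids=None) -> PairedOmics:
    """Build a PairedOmics from raw arrays (protein defaults to transcript)."""
    transcript = np.asarray(transcript, dtype=float)
    if protein is None:
        protein = transcript.copy()
    n_feat, n_samp = transcript.shape
    feature_ids = feature_ids or [f"G{i + 1:02d}" for i in range(n_feat)]
    sample_ids = sample_ids or [f"T{i + 1:02d}" for i in range(n_samp)]
    return PairedOmics(
        OmicsMatrix(TRANSCRIPT, pd.DataFrame(transcript, feature_ids, sample_ids)),
        OmicsMatrix(PROTEIN, pd.DataFrame(np.asarray(protein, dtype=float),
                                          feature_ids, sample_ids)),
    )


@pytest.fixture
def filter_fixture() -> PairedOmics:
    """The committed 10-feature, 15-sample fixture with hand-counted
    filter pass/fail status."""
    from pgcausal.containers import read_paired_omics

    return read_paired_omics(
        DATA_DIR / "transcript_fixture.tsv", DATA_DIR / "protein_fixture.tsv"
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
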