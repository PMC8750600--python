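"""In-memory containers for paired omics data and their TSV dialect.

Expression matrices are stored features x samples in a :class:`pandas.DataFrame`
whose index holds feature identifiers and whose columns hold sample (tissue)
identifiers.  The two layers of a :class:`PairedOmics` object always share the
same feature list (same order) and the same sample list, which is what makes
per-pair transcript-protein comparisons and consensus network construction
well defined.

The on-disk format is plain TSV: first column = feature ID, header row =
sample IDs, missing values written as ``NA``.  Zeros are valid observations,
never missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = "NA"

TRANSCRIPT = "transcript"
PROTEIN = "protein"


@dataclass
class OmicsMatrix:
    """One expression layer: nonnegative abundances, features x samples."""

    layer: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.layer not in (TRANSCRIPT, PROTEIN):
            raise ValueError(f"unknown layer tag {self.layer!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature identifiers")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        self.values = self.values.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(self, feature_ids: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.layer, self.values.loc[list(feature_ids)])


@dataclass
class PairedOmics:
    """Matched transcript + protein matrices over identical features/samples."""

    transcript: OmicsMatrix
    protein: OmicsMatrix

    def __post_init__(self) -> None:
        if self.transcript.feature_ids != self.protein.feature_ids:
            raise ValueError("layers disagree on feature identifiers")
        if self.transcript.sample_ids != self.protein.sample_ids:
            raise ValueError("layers disagree on sample identifiers")

    @property
    def feature_ids(self) -> list[str]:
        return self.transcript.feature_ids

    @property
    def sample_ids(self) -> list[str]:
        return self.transcript.sample_ids

    @property
    def n_features(self) -> int:
        return self.transcript.n_features

    @property
    def n_samples(self) -> int:
        return self.transcript.n_samples

    @property
    def layers(self) -> tuple[OmicsMatrix, OmicsMatrix]:
        return (self.transcript, self.protein)

    def subset(self, feature_ids: Sequence[str]) -> "PairedOmics":
        return PairedOmics(
            self.transcript.subset(feature_ids), self.protein.subset(feature_ids)
        )


def write_omics_tsv(matrix: OmicsMatrix, path: str | Path) -> None:
    """Write one layer as TSV (feature ID column named ``feature``)."""
    out = matrix.values.copy()
    out.index.name = "feature"
    out.to_csv(path, sep="\t", na_rep=MISSING)


def read_omics_tsv(path: str | Path, layer: str) -> OmicsMatrix:
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[MISSING], keep_default_na=False
    )
    df.index = df.index.astype(str)
    return OmicsMatrix(layer, df)


def write_paired_omics(data: PairedOmics, directory: str | Path) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        TRANSCRIPT: directory / "transcript.tsv",
        PROTEIN: directory / "protein.tsv",
    }
    write_omics_tsv(data.transcript, paths[TRANSCRIPT])
    write_omics_tsv(data.protein, paths[PROTEIN])
    return paths


def read_paired_omics(
    transcript_path: str | Path, protein_path: str | Path
) -> PairedOmics:
    return PairedOmics(
        read_omics_tsv(transcript_path, TRANSCRIPT),
        read_omics_tsv(protein_path, PROTEIN),
    )
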