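"""Similarity-matrix file format: labelled TSV at 17 significant digits."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .network import SimilarityMatrix


def matrix_filename(subject_id: str, metric: str, atlas: str) -> str:
    return f"{subject_id}_{metric}_{atlas}.klsm.tsv"


def write_similarity_matrix(mat: SimilarityMatrix, path: str | os.PathLike) -> str:
    """Full square matrix with a header row and label column, 17 significant
    digits (lossless for binary64)."""
    df = pd.DataFrame(mat.values, index=mat.labels, columns=mat.labels)
    df.to_csv(path, sep="\t", float_format="%.17g", index_label="roi")
    return str(path)


def read_similarity_matrix(
    path: str | os.PathLike,
    metric: str = "",
    atlas: str = "",
    subject_id: str = "",
) -> SimilarityMatrix:
    """Read and validate a matrix file; asymmetry beyond 1e-12 or a
    non-unit diagonal raises naming the offending cell."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    labels = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != labels:
        raise ValueError(f"{path}: row labels do not match column labels")
    v = df.to_numpy(dtype=float)
    asym = np.abs(v - v.T)
    if asym.max() > 1e-12:
        i, j = np.unravel_index(int(np.argmax(asym)), asym.shape)
        raise ValueError(
            f"{path}: asymmetry {asym[i, j]:.3e} at cell ({labels[i]}, {labels[j]})"
        )
    diag = np.diag(v)
    if np.any(diag != 1.0):
        i = int(np.flatnonzero(diag != 1.0)[0])
        raise ValueError(f"{path}: diagonal element ({labels[i]}, {labels[i]}) = {diag[i]!r}, expected 1")
    # tolerated sub-1e-12 asymmetry is canonicalized from the upper triangle
    iu = np.triu_indices(len(labels), k=1)
    v[(iu[1], iu[0])] = v[iu]
    return SimilarityMatrix(
        labels=labels, values=v, metric=metric, atlas=atlas, subject_id=subject_id
    )
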