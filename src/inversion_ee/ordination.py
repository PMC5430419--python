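"""Correlation-matrix PCA of transformed arrangement frequencies.

Frequencies are mapped to y = 2*sqrt(p) (the angular-scale transform used
for ordination of inversion polymorphism data), arranged into an
observation x variable matrix with population x generation rows and
arrangements (all chromosomes concatenated) as columns, and decomposed by
eigen-analysis of the variable correlation matrix.  Axis shares of variance
are 100 * lambda_i / sum(lambda).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    loadings: pd.DataFrame  # variables x axes
    scores: pd.DataFrame  # observations x axes
    dropped_variables: list


def transform_frequencies(
    freqs: pd.DataFrame,
    unit: str = "replicate",
    absent_value: float = 0.0,
) -> pd.DataFrame:
    """Pivot a frequency table to a 2*sqrt(p) observation x variable matrix.

    ``unit="replicate"`` makes one row per (foundation, replicate,
    generation); ``unit="foundation"`` averages replicate frequencies first.
    An arrangement absent from a scored chromosome group is a genuine zero
    and becomes ``absent_value``; a chromosome never scored for an
    observation leaves its variables undefined and raises.
    """
    if np.any((freqs["p"] < 0) | (freqs["p"] > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    df = freqs.copy()
    if unit == "foundation":
        df = (
            df.groupby(["foundation", "generation", "chromosome", "arrangement"], as_index=False)["p"]
            .mean()
        )
        df["replicate"] = "mean"
    elif unit != "replicate":
        raise ValueError(f"unknown observation unit {unit!r}")
    df["variable"] = df["chromosome"].astype(str) + ":" + df["arrangement"].astype(str)
    wide = df.pivot_table(
        index=["foundation", "replicate", "generation"],
        columns="variable", values="p", aggfunc="first",
    )
    # distinguish "absent in a scored chromosome" (fill) from "never scored"
    scored = df.pivot_table(
        index=["foundation", "replicate", "generation"],
        columns="chromosome", values="p", aggfunc="size",
    )
    chrom_of = {
        var: var.split(":", 1)[0] for var in wide.columns
    }
    for var in wide.columns:
        unscored = scored[chrom_of[var]].isna()
        if (wide[var].isna() & ~unscored).any():
            wide.loc[wide[var].isna() & ~unscored, var] = absent_value
        if (wide[var].isna() & unscored).any():
            obs = wide.index[wide[var].isna()][0]
            raise ValueError(
                f"chromosome {chrom_of[var]} unscored for observation {obs}; "
                "cannot impute its arrangement frequencies"
            )
    return 2.0 * np.sqrt(wide)


def pca_correlation(matrix: pd.DataFrame) -> PCAResult:
    """PCA via eigen-decomposition of the variable correlation matrix.

    Zero-variance variables are dropped with a warning (their correlation is
    undefined).  Axis signs are fixed so the largest-magnitude loading on
    each axis is positive, making loadings reproducible across linear
    algebra backends.  Scores are the standardized data projected on the
    eigenvectors; their per-axis variance equals the eigenvalue.
    """
    X = pd.DataFrame(matrix)
    if len(X) < 2:
        raise ValueError("need >= 2 observations")
    sd = X.std(axis=0, ddof=1)
    dropped = list(X.columns[(sd == 0) | sd.isna()])
    if dropped:
        warnings.warn(f"dropping zero-variance variable(s): {dropped}")
        X = X.drop(columns=dropped)
        sd = sd.drop(index=dropped)
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z.to_numpy(float), rowvar=False)
    R = np.atleast_2d(R)
    lam, vec = np.linalg.eigh(R)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    vec = vec[:, order]
    # sign convention: largest-|loading| entry positive on each axis
    for j in range(vec.shape[1]):
        i = np.argmax(np.abs(vec[:, j]))
        if vec[i, j] < 0:
            vec[:, j] = -vec[:, j]
    axes = [f"PC{i + 1}" for i in range(len(lam))]
    loadings = pd.DataFrame(vec, index=X.columns, columns=axes)
    scores = pd.DataFrame(Z.to_numpy(float) @ vec, index=X.index, columns=axes)
    return PCAResult(
        eigenvalues=lam,
        percent_variance=100.0 * lam / lam.sum(),
        loadings=loadings,
        scores=scores,
        dropped_variables=dropped,
    )
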