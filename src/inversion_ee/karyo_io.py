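"""Readers, writers and validation for karyotype count and phenotype assay tables.

The central object is a long-format table of chromosomal-arrangement counts:
one row per (foundation, replicate, generation, chromosome, arrangement),
where ``count`` is the number of sampled chromosome copies carrying that
arrangement.  Arrangements of one chromosome are mutually exclusive alleles,
so within each (foundation, replicate, generation, chromosome) group the
counts sum to the number of chromosomes karyotyped in that population sample
(65-159 males in the study design this package models).

Tables are plain :class:`pandas.DataFrame` objects validated by the functions
here; there is deliberately no wrapper class, so the full pandas API remains
available for downstream grouping and plotting.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

KARYO_COLUMNS = ["foundation", "replicate", "generation", "chromosome", "arrangement", "count"]
KARYO_GROUP = ["foundation", "replicate", "generation", "chromosome"]
PHENO_COLUMNS = ["foundation", "replicate", "generation", "trait", "individual_id", "value"]

#: label used for assays of the long-established control populations
CONTROL_LABEL = "CONTROL"
#: replicate label used for samples taken before replication of a foundation
POOLED_LABEL = "pooled"


class SchemaError(ValueError):
    """A required column is missing or has the wrong dtype."""


class ValidationError(ValueError):
    """Table contents violate an invariant (negative count, duplicate row...)."""


def validate_karyotype_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a karyotype count table and return it with canonical dtypes.

    Raises
    ------
    SchemaError
        if a required column is absent.
    ValidationError
        if any count is negative or non-integral, a generation is negative,
        or an arrangement label repeats within a sampling group.
    """
    missing = [c for c in KARYO_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"karyotype table missing column(s): {missing}")
    df = df.loc[:, KARYO_COLUMNS].copy()
    counts = pd.to_numeric(df["count"], errors="coerce")
    if counts.isna().any():
        bad = df.loc[counts.isna()].iloc[0]
        raise ValidationError(f"non-numeric count in record {bad.to_dict()}")
    if (counts < 0).any():
        bad = df.loc[counts < 0].iloc[0]
        raise ValidationError(f"negative count in record {bad.to_dict()}")
    if (counts != counts.round()).any():
        bad = df.loc[counts != counts.round()].iloc[0]
        raise ValidationError(f"non-integer count in record {bad.to_dict()}")
    df["count"] = counts.astype(int)
    df["generation"] = pd.to_numeric(df["generation"], errors="raise").astype(int)
    if (df["generation"] < 0).any():
        raise ValidationError("negative generation number")
    dup = df.duplicated(subset=KARYO_GROUP + ["arrangement"], keep=False)
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise ValidationError(
            f"duplicate arrangement within a sampling group: {bad.to_dict()}"
        )
    return df.reset_index(drop=True)


def read_karyotype_counts(path: str | Path, dialect: str = ",") -> pd.DataFrame:
    """Read a long-format karyotype count table (CSV by default, TSV via ``dialect='\\t'``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=dialect, comment="#")
    return validate_karyotype_counts(df)


def write_karyotype_counts(df: pd.DataFrame, path: str | Path, dialect: str = ",") -> None:
    validate_karyotype_counts(df).to_csv(path, sep=dialect, index=False)


def counts_to_frequencies(counts: pd.DataFrame) -> pd.DataFrame:
    """Convert arrangement counts to within-group frequencies.

    Returns the same keyed rows with columns ``p`` (count / group total) and
    ``n`` (total chromosomes sampled in the group).  Frequencies in each
    (foundation, replicate, generation, chromosome) group sum to one.
    """
    counts = validate_karyotype_counts(counts)
    totals = counts.groupby(KARYO_GROUP)["count"].transform("sum")
    if (totals == 0).any():
        bad = counts.loc[totals == 0, KARYO_GROUP].iloc[0]
        raise ValidationError(f"group with zero total count: {bad.to_dict()}")
    out = counts.copy()
    out["p"] = out["count"] / totals
    out["n"] = totals.astype(int)
    return out.drop(columns="count")


def frequencies_to_counts(freqs: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`counts_to_frequencies` (rounds ``p * n`` to integers)."""
    out = freqs.copy()
    out["count"] = np.rint(out["p"] * out["n"]).astype(int)
    return validate_karyotype_counts(out[KARYO_COLUMNS])


def common_arrangements(
    freqs: pd.DataFrame,
    threshold: float = 0.05,
    scope: str = "per_foundation",
):
    """Arrangements exceeding a frequency threshold, the study's ">5%" filter.

    An arrangement qualifies when its frequency is strictly greater than
    ``threshold`` in at least one replicate-population x generation sample
    (max rule), so initially rare arrangements that rise above the threshold
    in any sample are retained.

    Parameters
    ----------
    scope:
        ``"per_foundation"`` applies the rule within each foundation and
        returns ``{foundation: [(chromosome, arrangement), ...]}``;
        ``"joint"`` applies it across all populations and returns a flat
        sorted list of (chromosome, arrangement) pairs.
    """
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must lie in [0, 1), got {threshold}")
    if scope not in ("per_foundation", "joint"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "joint":
        peak = freqs.groupby(["chromosome", "arrangement"])["p"].max()
        return sorted(peak.index[peak > threshold].tolist())
    peak = freqs.groupby(["foundation", "chromosome", "arrangement"])["p"].max()
    kept = peak.index[peak > threshold].tolist()
    out: dict[str, list[tuple[str, str]]] = {}
    for foundation, chrom, arr in sorted(kept):
        out.setdefault(foundation, []).append((chrom, arr))
    return out


def read_census(path: str | Path) -> dict[int, int]:
    """Read a ``{generation: census size}`` JSON sidecar."""
    with open(path) as fh:
        raw = json.load(fh)
    census = {int(k): int(v) for k, v in raw.items()}
    if any(v <= 0 for v in census.values()):
        raise ValidationError("census sizes must be positive")
    return census


def write_census(census: dict[int, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({str(k): int(v) for k, v in sorted(census.items())}, fh, indent=1)


def validate_pheno_assay(df: pd.DataFrame, require_controls: bool = True) -> pd.DataFrame:
    """Validate a phenotype assay table.

    Every (generation, trait) combination assayed for an experimental
    foundation must also appear for the synchronously assayed control
    populations (foundation == ``CONTROL``), because all trajectory analyses
    are taken relative to the control means.
    """
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"phenotype table missing column(s): {missing}")
    df = df.loc[:, PHENO_COLUMNS].copy()
    df["generation"] = pd.to_numeric(df["generation"], errors="raise").astype(int)
    df["value"] = pd.to_numeric(df["value"], errors="raise").astype(float)
    if df["value"].isna().any():
        raise ValidationError("missing trait values")
    if require_controls:
        is_ctrl = df["foundation"] == CONTROL_LABEL
        exp_keys = set(map(tuple, df.loc[~is_ctrl, ["generation", "trait"]].drop_duplicates().values))
        ctrl_keys = set(map(tuple, df.loc[is_ctrl, ["generation", "trait"]].drop_duplicates().values))
        orphan = exp_keys - ctrl_keys
        if orphan:
            gen, trait = sorted(orphan)[0]
            raise ValidationError(
                f"no synchronous control assay for generation {gen}, trait {trait!r}"
            )
    return df.reset_index(drop=True)


def read_pheno_assay(path: str | Path, dialect: str = ",", require_controls: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, sep=dialect, comment="#")
    return validate_pheno_assay(df, require_controls=require_controls)


def write_pheno_assay(df: pd.DataFrame, path: str | Path, dialect: str = ",") -> None:
    validate_pheno_assay(df, require_controls=False).to_csv(path, sep=dialect, index=False)
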