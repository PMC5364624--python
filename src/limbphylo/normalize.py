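"""Expression normalization: FPKM, median-of-ratios size factors, floors.

FPKM(g, s) = count(g, s) / ((length(g)/1e3) * (total(s)/1e6)).  Between-sample
normalization follows the median-of-ratios scheme: each sample's factor is the
median, over genes with a positive geometric mean across samples, of that
sample's count divided by the gene's geometric mean.  Values below the
detection floor (default 1e-3 FPKM) are kept numerically but can be flagged;
log transforms use the floor as pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DETECTION_FLOOR = 1e-3

STAGES = ("ridge", "bud", "paddle")
LIMBS = ("fore", "hind")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative FPKM values."""

    values: pd.DataFrame
    detection_floor: float = DETECTION_FLOOR

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("FPKM values must be non-negative")
        if self.detection_floor < 0:
            raise ValueError("detection floor must be non-negative")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene IDs")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample IDs")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def detected(self) -> pd.DataFrame:
        """Boolean mask of values at or above the detection floor."""
        return self.values >= self.detection_floor

    def log2(self) -> pd.DataFrame:
        """log2(FPKM + floor); the floor doubles as pseudocount."""
        return np.log2(self.values + self.detection_floor)


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.index.duplicated().any():
        raise ValueError("duplicate gene IDs in count matrix")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample IDs in count matrix")
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")


def compute_fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    detection_floor: float = DETECTION_FLOOR,
) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped fragments.

    Parameters
    ----------
    counts : DataFrame
        Non-negative integer fragment counts, genes x samples.
    lengths : Series
        Transcript length in bp per gene; must cover every gene in `counts`.
    """
    _check_counts(counts)
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing gene lengths for: {list(missing[:5])}")
    lens = lengths.loc[counts.index].astype(float)
    if (lens <= 0).any():
        bad = lens.index[lens <= 0][0]
        raise ValueError(f"non-positive length for gene {bad}")
    totals = counts.sum(axis=0).astype(float)
    if len(counts) and (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"sample {bad} has zero total count")
    fpkm = counts.div(lens / 1e3, axis=0).div(totals / 1e6, axis=1)
    return ExpressionMatrix(fpkm, detection_floor=detection_floor)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    The reference is the per-gene geometric mean across samples; genes with
    a zero count in any sample drop out of the reference (their geometric
    mean is zero).
    """
    _check_counts(counts)
    vals = counts.values.astype(float)
    with np.errstate(divide="ignore"):
        log_counts = np.log(vals)
    positive = np.isfinite(log_counts).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "pseudo-reference fallback is disabled"
        )
    log_ref = log_counts[positive].mean(axis=1)
    ratios = np.exp(log_counts[positive] - log_ref[:, None])
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def apply_size_factors(expr: ExpressionMatrix, factors: pd.Series) -> ExpressionMatrix:
    """Divide each sample column by its size factor."""
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    scaled = expr.values.div(factors.loc[expr.samples], axis=1)
    return ExpressionMatrix(scaled, detection_floor=expr.detection_floor)


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts divided columnwise by median-of-ratios size factors."""
    return counts.div(size_factors(counts), axis=1)


def average_replicates(
    expr: ExpressionMatrix, samples: pd.DataFrame
) -> ExpressionMatrix:
    """Arithmetic mean of FPKM over replicates of each (species, limb, stage).

    Returns one profile per condition, columns named
    ``{species}|{limb}|{stage}`` in species, limb, stage order.
    """
    required = {"species", "limb", "stage"}
    if not required <= set(samples.columns):
        raise ValueError(f"sample table must have columns {sorted(required)}")
    meta = samples.loc[expr.samples]
    cols = {}
    for species in meta["species"].unique():
        for limb in LIMBS:
            for stage in STAGES:
                mask = (
                    (meta["species"] == species)
                    & (meta["limb"] == limb)
                    & (meta["stage"] == stage)
                )
                if mask.any():
                    label = f"{species}|{limb}|{stage}"
                    cols[label] = expr.values.loc[:, mask.values].mean(axis=1)
    return ExpressionMatrix(pd.DataFrame(cols), detection_floor=expr.detection_floor)


def condition_label(species: str, limb: str, stage: str) -> str:
    return f"{species}|{limb}|{stage}"
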