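"""Depth normalization: SRS, total-sum scaling, and rarefaction primitives.

SRS (scaling with ranked subsampling) deterministically rescales a sample's
counts to a fixed target depth C_min: counts are scaled by C_min/total, the
integer parts are kept, and the fractional remainder is allocated one read at
a time to the features with the largest fractional parts.  Unlike classical
rarefaction it is non-random (in the default tie-break mode) and preserves
the rank order of features.

`rarefy_with_replacement` is the multinomial bootstrap the core-microbiota
procedure builds on: `depth` reads drawn with replacement from the sample's
empirical composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from coregrad._utils import as_rng
from coregrad.data_model import FeatureTable


class InsufficientDepthError(ValueError):
    """A sample's total count is below the requested normalization depth."""


@dataclass(frozen=True)
class SrsParams:
    """SRS parameters.

    c_min: target depth every retained sample is scaled to (study values:
        5,000 reads for fly samples, 500 for fruit pulp).
    tie_break: how fractional-part ties in the remainder allocation are
        resolved.  "deterministic" (default) prefers the larger scaled value,
        then input order, making the output reproducible without a seed;
        "random" draws the tie order from `seed`.
    """

    c_min: int
    tie_break: Literal["deterministic", "random"] = "deterministic"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.c_min < 0:
            raise ValueError("c_min must be >= 0")
        if self.tie_break not in ("deterministic", "random"):
            raise ValueError("tie_break must be 'deterministic' or 'random'")


def srs_normalize_sample(counts: np.ndarray, params: SrsParams) -> np.ndarray:
    """Scale one sample's counts to sum exactly to params.c_min.

    Output is entrywise <= input and the ranking of features by output count
    is a non-strict refinement of the input ranking.  Raises
    InsufficientDepthError when the sample total is below c_min so callers
    can flag (not silently drop) shallow samples.
    """
    counts = np.asarray(counts)
    if counts.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = int(counts.sum())
    if total < params.c_min:
        raise InsufficientDepthError(
            f"sample total {total} is below target depth {params.c_min}"
        )
    if params.c_min == 0:
        return np.zeros_like(counts, dtype=np.int64)
    scaled = counts * (params.c_min / total)
    floors = np.floor(scaled).astype(np.int64)
    remainder = params.c_min - int(floors.sum())
    if remainder > 0:
        frac = scaled - floors
        if params.tie_break == "deterministic":
            # ties on fractional part: larger scaled value first, then input order
            order = np.lexsort((np.arange(counts.size), -scaled, -frac))
        else:
            rng = as_rng(params.seed)
            order = np.lexsort((rng.permutation(counts.size), -frac))
        floors[order[:remainder]] += 1
    return floors


def srs_normalize_table(
    table: FeatureTable, params: SrsParams
) -> tuple[FeatureTable, list[str]]:
    """Apply SRS per sample; returns (normalized table, excluded sample ids).

    Samples whose total is below c_min are excluded from the output table and
    reported in the exclusion list.  All retained columns sum to c_min.
    Features that become all-zero are retained (shape stability).
    """
    out = {}
    excluded: list[str] = []
    for sample in table.sample_ids:
        col = table.data[sample].to_numpy()
        try:
            out[sample] = srs_normalize_sample(col, params)
        except InsufficientDepthError:
            excluded.append(sample)
    if not out:
        raise InsufficientDepthError(
            f"every sample is below the target depth {params.c_min}"
        )
    import pandas as pd

    df = pd.DataFrame(out, index=table.feature_ids)
    df.index.name = table.data.index.name
    return FeatureTable(df), excluded


def tss_normalize(table: FeatureTable):
    """Total-sum scaling: each sample's counts divided by its total."""
    totals = table.sample_totals()
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"samples with zero total counts: {list(zero.index)}")
    return table.data / totals


def rarefy_with_replacement(
    counts: np.ndarray, depth: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Multinomial bootstrap of one sample: `depth` reads drawn with replacement.

    Probabilities are counts/total; the output always sums to `depth`.
    Distinct from classical (hypergeometric, without-replacement) rarefaction.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot rarefy a sample with zero total count")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = as_rng(seed)
    return rng.multinomial(depth, counts / total)


def rarefy_without_replacement(
    counts: np.ndarray, depth: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Classical rarefaction: subsample `depth` reads without replacement."""
    counts = np.asarray(counts)
    total = int(counts.sum())
    if total <= 0:
        raise ValueError("cannot rarefy a sample with zero total count")
    if depth > total:
        raise InsufficientDepthError(
            f"depth {depth} exceeds sample total {total} for without-replacement rarefaction"
        )
    rng = as_rng(seed)
    return rng.multivariate_hypergeometric(counts.astype(np.int64), depth)
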