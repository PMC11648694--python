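"""Bootstrap estimation of the core microbiota, group-wise cores and Venn regions.

The core of a sample group is estimated by repeated rarefaction with
replacement: in each of `n_boot` replicates every sample is re-drawn
multinomially at a fixed depth, a feature's prevalence is the fraction of
samples in which it survives (count > 0), and the feature "passes" the
replicate when that prevalence reaches `prevalence_threshold`.  A feature
belongs to the core when it passes at least `subsample_support` of the
replicates (study settings: 1,000 replicates, 95% support, prevalence 75%
for fly samples and 65% for the leakier fruit-pulp communities).

An alternative mode bootstraps sample columns instead of reads, for the
reading of "sub-sampling" in which the sampling unit is the specimen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from coregrad._utils import as_rng, derive_seed
from coregrad.data_model import FeatureTable


@dataclass(frozen=True)
class CoreParams:
    """Parameters of the bootstrap core-microbiota procedure.

    depth=None rarefies each sample at its own total (the multinomial
    bootstrap; uniform when tables arrive depth-normalized).  mode="reads"
    rarefies reads within samples, mode="samples" resamples sample columns.
    """

    n_boot: int = 1000
    subsample_support: float = 0.95
    prevalence_threshold: float = 0.75
    depth: int | None = None
    seed: int | None = None
    mode: Literal["reads", "samples"] = "reads"

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        for name in ("subsample_support", "prevalence_threshold"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.depth is not None and self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.mode not in ("reads", "samples"):
            raise ValueError("mode must be 'reads' or 'samples'")


@dataclass(frozen=True)
class CoreResult:
    """Per-feature bootstrap support and the resulting core set.

    support(f) = fraction of replicates in which f's prevalence reached the
    prevalence threshold; core_set = {f : support(f) >= subsample_support}.
    """

    support: pd.Series
    mean_prevalence: pd.Series
    params: CoreParams
    n_samples: int

    @property
    def core_set(self) -> list[str]:
        return list(self.support.index[self.support >= self.params.subsample_support])

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"support": self.support, "mean_prevalence": self.mean_prevalence}
        )
        df["in_core"] = self.support >= self.params.subsample_support
        df.index.name = "feature_id"
        return df


def bootstrap_core(table: FeatureTable, params: CoreParams) -> CoreResult:
    """Estimate bootstrap support for core membership of every feature."""
    n_features, n_samples = table.shape
    if n_samples < 2:
        raise ValueError("need >= 2 samples to estimate a core")
    totals = table.sample_totals()
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"samples with zero total counts: {list(zero.index)}")
    rng = as_rng(params.seed)
    counts = table.counts
    if params.mode == "reads":
        presence_count = np.zeros((params.n_boot, n_features), dtype=np.int32)
        for s in range(n_samples):
            col = counts[:, s].astype(float)
            depth = params.depth if params.depth is not None else int(col.sum())
            draws = rng.multinomial(depth, col / col.sum(), size=params.n_boot)
            presence_count += draws > 0
        prevalence = presence_count / n_samples
    else:
        raw_presence = (counts > 0).T  # samples × features
        choices = rng.integers(0, n_samples, size=(params.n_boot, n_samples))
        prevalence = raw_presence[choices].mean(axis=1)
    passes = prevalence >= params.prevalence_threshold
    support = pd.Series(passes.mean(axis=0), index=table.feature_ids, name="support")
    mean_prev = pd.Series(
        prevalence.mean(axis=0), index=table.feature_ids, name="mean_prevalence"
    )
    return CoreResult(
        support=support, mean_prevalence=mean_prev, params=params, n_samples=n_samples
    )


def group_cores(
    table: FeatureTable,
    metadata: pd.DataFrame,
    grouping: str | pd.Series,
    params: CoreParams,
    group_params: Mapping[str, CoreParams] | None = None,
) -> dict[str, CoreResult]:
    """Run bootstrap_core independently per sample group.

    `grouping` is a metadata column name or a per-sample Series.  A group may
    carry its own parameters via `group_params` (e.g. a lower prevalence
    threshold for pulp).  Each group gets an independent seed derived from
    params.seed and the group name, so adding a group never perturbs others.
    """
    if isinstance(grouping, str):
        if grouping not in metadata.columns:
            raise KeyError(f"metadata has no column '{grouping}'")
        labels = metadata.loc[table.sample_ids, grouping]
    else:
        labels = grouping.loc[table.sample_ids]
    results: dict[str, CoreResult] = {}
    for group in sorted(labels.dropna().unique().astype(str)):
        members = [s for s, g in labels.items() if str(g) == group]
        if len(members) < 2:
            raise ValueError(f"group '{group}' has only {len(members)} sample(s)")
        p = (group_params or {}).get(group, params)
        p = replace(p, seed=derive_seed(params.seed, "group", group))
        results[group] = bootstrap_core(table.select_samples(members), p)
    return results


def core_intersections(
    cores: Mapping[str, CoreResult | set | frozenset | list],
) -> dict[tuple[str, ...], list[str]]:
    """Partition the union of group cores into exclusive/shared Venn regions.

    Returns a map from a sorted tuple of group names to the features found in
    exactly those groups' cores; only non-empty regions are reported, and the
    regions partition the union of all cores.
    """
    if not cores:
        raise ValueError("need >= 1 group")
    sets = {
        g: set(c.core_set) if isinstance(c, CoreResult) else set(c)
        for g, c in cores.items()
    }
    regions: dict[tuple[str, ...], list[str]] = {}
    union = set().union(*sets.values())
    for feature in sorted(union):
        signature = tuple(sorted(g for g, s in sets.items() if feature in s))
        regions.setdefault(signature, []).append(feature)
    return regions


def annotate_core(core: CoreResult, trait_table: pd.DataFrame) -> pd.DataFrame:
    """Join externally predicted traits (e.g. nif genes) onto core members.

    Core members missing from the trait table are flagged `unannotated`,
    never dropped.  An empty core yields an empty summary.
    """
    members = core.core_set
    out = pd.DataFrame(index=pd.Index(members, name="feature_id"))
    out["support"] = core.support.loc[members]
    annotated = [f in trait_table.index for f in members]
    out["annotated"] = annotated
    for col in trait_table.columns:
        out[col] = [
            trait_table.at[f, col] if ok else pd.NA for f, ok in zip(members, annotated)
        ]
    return out
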