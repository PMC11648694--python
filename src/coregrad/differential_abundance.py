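"""Gradient associations (log-linear models + BH FDR) and LDA-effect-size biomarkers.

`fit_gradient_models` regresses, per genus, log2 total-sum-scaled relative
abundance on a continuous gradient (latitude or altitude): the zero-handling
pseudocount is half the feature's smallest nonzero relative abundance, the
slope is tested with a two-sided t-test, and Benjamini–Hochberg q-values are
computed across all tested features.  Features below a prevalence floor are
reported as untested rather than silently dropped.

`lefse_scores` implements the two-stage LDA-effect-size biomarker procedure:
a Kruskal–Wallis screen at `alpha`, then a bootstrapped one-axis linear
discriminant whose per-feature effect size averages the discriminant-axis
class-mean difference (back-projected to the feature) with the raw class-mean
difference; the reported score is log10 of that effect on the conventional
per-million abundance scale.  A feature is a biomarker when it survives the
screen and its score exceeds `lda_threshold` (study cutoffs: p < 0.05,
LDA > 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

from coregrad._utils import as_rng
from coregrad.data_model import FeatureTable
from coregrad.normalization import tss_normalize


def fit_gradient_models(
    table: FeatureTable,
    covariate,
    min_prevalence: float = 0.10,
) -> pd.DataFrame:
    """Per-feature OLS of log2 TSS relative abundance on a continuous covariate.

    Returns a DataFrame with one row per feature: coefficient (slope of log2
    relative abundance per covariate unit), std_error, p_value, q_value (BH
    across tested features), n_samples_used, prevalence and a `tested` flag.
    Features with prevalence < min_prevalence, all-zero features, and
    constant-response features are reported untested with missing p.
    """
    ids = table.sample_ids
    if isinstance(covariate, pd.Series) and set(ids) <= set(covariate.index):
        x = covariate.loc[ids].to_numpy(dtype=float)
    else:
        x = np.asarray(covariate, dtype=float)
        if len(x) != len(ids):
            raise ValueError("covariate length does not match the table samples")
    if len(ids) < 3:
        raise ValueError("need at least 3 samples to fit gradient models")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")

    rel = tss_normalize(table)
    rows = []
    for feature in table.feature_ids:
        y_rel = rel.loc[feature].to_numpy(dtype=float)
        prevalence = float((y_rel > 0).mean())
        record = {
            "feature": feature,
            "coefficient": np.nan,
            "std_error": np.nan,
            "p_value": np.nan,
            "n_samples_used": len(ids),
            "prevalence": prevalence,
            "tested": False,
        }
        if prevalence == 0 or prevalence < min_prevalence:
            rows.append(record)
            continue
        pseudo = y_rel[y_rel > 0].min() / 2.0
        y = np.log2(y_rel + pseudo)
        if np.ptp(y) == 0:
            # constant response: slope is exactly 0 but untestable
            record["coefficient"] = 0.0
            record["std_error"] = 0.0
            rows.append(record)
            continue
        fit = scipy.stats.linregress(x, y)
        record.update(
            coefficient=float(fit.slope),
            std_error=float(fit.stderr),
            p_value=float(fit.pvalue),
            tested=True,
        )
        rows.append(record)
    out = pd.DataFrame(rows).set_index("feature")
    out["q_value"] = np.nan
    tested = out["tested"] & out["p_value"].notna()
    if tested.any():
        out.loc[tested, "q_value"] = multipletests(
            out.loc[tested, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    return out


def kruskal_wallis(values: Sequence[float], classes: Sequence) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and chi-squared p over >= 2 classes.

    The fully degenerate case (identical values everywhere, tie correction
    zero) is defined as H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(classes)
    if len(values) != len(labels):
        raise ValueError("values and classes have different lengths")
    levels = np.unique(labels)
    if len(levels) < 2:
        raise ValueError("need >= 2 classes")
    groups = [values[labels == lvl] for lvl in levels]
    if any(len(g) == 0 for g in groups):
        raise ValueError("every class must be non-empty")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*groups)
    return float(h), float(p)


@dataclass(frozen=True)
class _LefseDefaults:
    alpha: float = 0.05
    lda_threshold: float = 2.0
    n_boot: int = 30
    boot_fraction: float = 2.0 / 3.0


def _lda_effects(
    x: np.ndarray, y: np.ndarray, levels: np.ndarray
) -> np.ndarray | None:
    """Per-feature LEfSe effect sizes from a one-axis LDA on one bootstrap.

    effect_j = mean over class pairs of |w_j * (w . (mu_a - mu_b)) +
    (mu_a_j - mu_b_j)| / 2 with w the unit first discriminant axis.
    """
    try:
        lda = LinearDiscriminantAnalysis(solver="svd")
        lda.fit(x, y)
        w = lda.scalings_[:, 0]
    except (np.linalg.LinAlgError, ValueError):
        return None
    norm = np.linalg.norm(w)
    if norm == 0 or not np.all(np.isfinite(w)):
        return None
    w = w / norm
    mus = {lvl: x[y == lvl].mean(axis=0) for lvl in levels}
    effects = np.zeros(x.shape[1])
    n_pairs = 0
    for i in range(len(levels)):
        for jj in range(i + 1, len(levels)):
            delta = mus[levels[i]] - mus[levels[jj]]
            proj = float(w @ delta)
            effects += np.abs(w * proj + delta) / 2.0
            n_pairs += 1
    return effects / n_pairs


def lefse_scores(
    abundance: pd.DataFrame | FeatureTable,
    classes,
    alpha: float = _LefseDefaults.alpha,
    lda_threshold: float = _LefseDefaults.lda_threshold,
    n_boot: int = _LefseDefaults.n_boot,
    boot_fraction: float = _LefseDefaults.boot_fraction,
    seed: int | None = None,
) -> pd.DataFrame:
    """LDA-effect-size biomarker scores per feature across sample classes.

    `abundance` is a features × samples table; a raw FeatureTable is
    TSS-normalized and scaled to the per-million convention, while a float
    DataFrame is assumed already on that scale.  With more than two classes a
    biomarker must be consistently enriched in the same class across every
    pairwise comparison (strict mode).  Returns one row per feature with
    enriched_class, kw_p_value, lda_score and the boolean `passes`.
    """
    if isinstance(abundance, FeatureTable):
        data = tss_normalize(abundance) * 1e6
    else:
        data = abundance.astype(float)
    ids = list(data.columns)
    if isinstance(classes, pd.Series) and set(ids) <= set(classes.index):
        labels = classes.loc[ids].to_numpy()
    else:
        labels = np.asarray(classes)
        if len(labels) != len(ids):
            raise ValueError("classes length does not match the table samples")
    labels = labels.astype(str)
    levels = np.unique(labels)
    if len(levels) < 2:
        raise ValueError("need >= 2 classes")

    features = list(data.index)
    x_all = data.to_numpy().T  # samples × features
    kw_p = np.empty(len(features))
    for i in range(len(features)):
        kw_p[i] = kruskal_wallis(x_all[:, i], labels)[1]
    surviving = np.where(kw_p < alpha)[0]

    # class with the highest mean, and strict pairwise consistency
    class_means = np.stack([x_all[labels == lvl].mean(axis=0) for lvl in levels])
    top = class_means.argmax(axis=0)
    enriched = np.array([levels[t] for t in top])
    consistent = np.array(
        [
            all(
                class_means[top[i], i] >= class_means[c, i]
                for c in range(len(levels))
                if c != top[i]
            )
            for i in range(len(features))
        ]
    )

    effects = np.full(len(features), np.nan)
    if len(surviving) > 0:
        rng = as_rng(seed)
        sums = np.zeros(len(surviving))
        n_used = 0
        for _ in range(n_boot):
            idx: list[int] = []
            ok = True
            for lvl in levels:
                members = np.where(labels == lvl)[0]
                take = int(np.floor(boot_fraction * len(members)))
                if take < 2:
                    ok = False
                    break
                idx.extend(rng.choice(members, size=take, replace=False))
            if not ok:
                continue
            idx_arr = np.asarray(idx)
            eff = _lda_effects(x_all[np.ix_(idx_arr, surviving)], labels[idx_arr], levels)
            if eff is None:
                continue
            sums += eff
            n_used += 1
        if n_used == 0:
            raise ValueError(
                "every bootstrap was skipped: a class has too few samples "
                f"at boot_fraction={boot_fraction}"
            )
        effects[surviving] = sums / n_used

    with np.errstate(invalid="ignore"):
        lda_score = np.where(
            np.isnan(effects), np.nan, np.log10(np.maximum(effects, 1.0))
        )
    passes = (
        (kw_p < alpha)
        & consistent
        & np.where(np.isnan(lda_score), False, lda_score > lda_threshold)
    )
    out = pd.DataFrame(
        {
            "feature": features,
            "enriched_class": enriched,
            "kw_p_value": kw_p,
            "lda_score": lda_score,
            "passes": passes,
        }
    ).set_index("feature")
    return out
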