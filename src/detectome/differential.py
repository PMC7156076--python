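"""Moderated two-group differential contrast on detection levels.

The statistic is the empirical-Bayes moderated t: per-feature residual
variances s_g^2 (pooled, d = n1 + n2 - 2 df) are shrunk toward an ensemble
prior by assuming s_g^2 ~ s0^2 * F(d, d0) — equivalently a scaled inverse
chi-square prior on the true variances.  The posterior variance

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

replaces s_g^2 in the ordinary two-sample t, and the moderated statistic

    t~_g = logFC_g / (s~_g * sqrt(1/n1 + 1/n2))

is referred to a t distribution with d0 + d degrees of freedom.  The prior
(d0, s0^2) is estimated from the log-variance ensemble by the
method-of-moments equations

    Var[log s^2] = trigamma(d/2) + trigamma(d0/2)
    E[log s^2]   = log s0^2 + digamma(d/2) - log(d/2)
                             - digamma(d0/2) + log(d0/2)

inverting the trigamma numerically.  With d0 = 0 the statistic reduces to
the ordinary pooled t; with d0 -> inf all features share one variance and
the ordering collapses to |logFC|.  Multiple testing uses Benjamini-
Hochberg step-up FDR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .model import (
    DetectionLevelMatrix,
    DetectomeError,
    SampleAnnotation,
    annotations_frame,
    validate_differential_table,
)


def _split_groups(
    levels: DetectionLevelMatrix,
    annotations: Sequence[SampleAnnotation],
    case_label: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    ann = annotations_frame(annotations)
    scoped = [s for s in levels.sample_ids if s in ann.index]
    missing = [s for s in levels.sample_ids if s not in ann.index]
    if missing:
        raise DetectomeError(f"unannotated sample(s): {missing}")
    grp = ann.loc[scoped, "group"]
    case_samples = list(grp.index[grp == case_label])
    ctrl_samples = list(grp.index[grp != case_label])
    if len(case_samples) < 2 or len(ctrl_samples) < 2:
        raise DetectomeError(
            f"each group needs >= 2 samples (got {len(case_samples)} "
            f"{case_label!r} vs {len(ctrl_samples)} other)"
        )
    return levels.levels[case_samples], levels.levels[ctrl_samples]


def two_group_stats(
    levels: DetectionLevelMatrix,
    annotations: Sequence[SampleAnnotation],
    case_label: str = "case",
) -> pd.DataFrame:
    """Per-miRNA logFC (case mean - control mean, log2 scale) and AveExpr
    (grand mean over all scoped samples)."""
    case, ctrl = _split_groups(levels, annotations, case_label)
    both = pd.concat([case, ctrl], axis=1)
    return pd.DataFrame(
        {
            "logFC": case.mean(axis=1) - ctrl.mean(axis=1),
            "AveExpr": both.mean(axis=1),
        }
    )


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        raise DetectomeError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-12 * x:
            break
    return x


@dataclass(frozen=True)
class VariancePrior:
    """Ensemble prior for the residual variances: s^2 ~ s0^2 F(d, d0)."""

    prior_df: float  # d0; may be inf
    prior_var: float  # s0^2
    fallback: bool = False  # True when the moment fit failed and d0=4 was used


FALLBACK_PRIOR_DF = 4.0


def fit_variance_prior(s2: np.ndarray, residual_df: int) -> VariancePrior:
    """Method-of-moments fit of (d0, s0^2) from the observed s^2 ensemble.

    Operates on z = log(s^2) of the strictly positive variances.  When the
    excess spread Var(z) - trigamma(d/2) is non-positive the moments give
    no finite-information solution and the fit falls back to d0 = 4.
    """
    d = residual_df
    z = np.log(s2[s2 > 0])
    if z.size < 2:
        raise DetectomeError("need >= 2 positive residual variances to fit the prior")
    e = z - digamma(d / 2.0) + math.log(d / 2.0)
    evar = float(np.var(z, ddof=1)) - float(polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0 = math.exp(float(np.mean(e)) + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
        return VariancePrior(prior_df=d0, prior_var=s0)
    d0 = FALLBACK_PRIOR_DF
    s0 = math.exp(float(np.mean(e)) + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return VariancePrior(prior_df=d0, prior_var=s0, fallback=True)


def moderated_t(
    levels: DetectionLevelMatrix,
    annotations: Sequence[SampleAnnotation],
    case_label: str = "case",
    prior_df: float | str = "auto",
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Moderated-t differential table, sorted by |t| descending.

    ``prior_df='auto'`` estimates (d0, s0^2) from the data; a number fixes
    d0 (0 gives the ordinary pooled t; inf needs ``prior_var``).  Columns:
    logFC, AveExpr, t, p_value, adj_p_value.
    """
    case, ctrl = _split_groups(levels, annotations, case_label)
    n1, n2 = case.shape[1], ctrl.shape[1]
    d = n1 + n2 - 2
    logfc = case.mean(axis=1) - ctrl.mean(axis=1)
    aveexpr = pd.concat([case, ctrl], axis=1).mean(axis=1)
    s2 = (
        (n1 - 1) * case.var(axis=1, ddof=1) + (n2 - 1) * ctrl.var(axis=1, ddof=1)
    ) / d
    s2v = s2.to_numpy(float)

    if prior_df == "auto":
        prior = fit_variance_prior(s2v, d)
        d0, s02 = prior.prior_df, prior.prior_var
    else:
        d0 = float(prior_df)
        if d0 < 0:
            raise DetectomeError("prior_df must be non-negative")
        if math.isinf(d0):
            if prior_var is None:
                raise DetectomeError("prior_var required when prior_df is infinite")
            s02 = float(prior_var)
        else:
            s02 = float(prior_var) if prior_var is not None else 0.0

    if math.isinf(d0):
        s2_post = np.full_like(s2v, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + d * s2v) / (d0 + d)
        df_total = d0 + d
    if (s2_post <= 0).any():
        raise DetectomeError(
            "zero posterior variance: with prior_df=0 every feature needs "
            "positive residual variance"
        )
    u = math.sqrt(1.0 / n1 + 1.0 / n2)
    tstat = logfc.to_numpy(float) / (np.sqrt(s2_post) * u)
    if math.isinf(df_total):
        from scipy.stats import norm

        p = 2.0 * norm.sf(np.abs(tstat))
    else:
        p = 2.0 * t_dist.sf(np.abs(tstat), df_total)
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "AveExpr": aveexpr,
            "t": tstat,
            "p_value": p,
            "adj_p_value": bh_adjust(p),
        },
        index=levels.levels.index,
    )
    table = table.iloc[np.argsort(-np.abs(table["t"].to_numpy()), kind="stable")]
    return validate_differential_table(table)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DetectomeError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class DifferentialSelection:
    """Raw-p selection plus the post-adjustment count and a volcano table."""

    selected: list[str]  # raw p < threshold, ordered by |t| descending
    n_selected: int
    n_adjusted_significant: int
    threshold: float
    volcano: pd.DataFrame  # logFC vs -log10 p for every miRNA


def select_and_report(
    table: pd.DataFrame, p_threshold: float = 0.05
) -> DifferentialSelection:
    """Select miRNAs at raw p < threshold and count adjusted survivors.

    The selected subset is what feeds the post-hoc clustering heatmap; the
    volcano table carries logFC vs -log10 p for every miRNA.
    """
    validate_differential_table(table)
    sel = table.index[table["p_value"] < p_threshold]
    with np.errstate(divide="ignore"):
        neg_log10 = -np.log10(table["p_value"].to_numpy(float))
    return DifferentialSelection(
        selected=list(sel),
        n_selected=len(sel),
        n_adjusted_significant=int((table["adj_p_value"] < p_threshold).sum()),
        threshold=p_threshold,
        volcano=pd.DataFrame(
            {"logFC": table["logFC"], "neg_log10_p": neg_log10}, index=table.index
        ),
    )
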