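"""Direct-correlation (DC) target scoring.

The DC method scores a compound-protein pair by the correlation between the
compound's chemical-treatment profile and the protein's genetic-perturbation
profile: knock-down profiles for inhibition, over-expression profiles for
activation. High correlation marks a candidate interaction, and the
coefficient itself is the prediction score. The module also provides the
known-vs-other distribution comparison (one-sided Mann-Whitney rank-sum with
tie correction) used to check that known interacting pairs score higher than
the rest.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, UndefinedCorrelationError
from .gold_standard import LabelMatrix
from .signatures import AggregatedProfile

logger = logging.getLogger(__name__)

CORRELATION_METHODS = ("pearson", "spearman")


def correlation(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> float:
    """Pearson or Spearman correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if method not in CORRELATION_METHODS:
        raise ConfigurationError(f"unknown correlation method {method!r}")
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("vectors must be 1-d and of equal length")
    if x.size < 3:
        raise ConfigurationError("need at least 3 elements")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant vector")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    return float(stats.spearmanr(x, y).statistic)


def _profile_matrix(
    profiles: Mapping[str, AggregatedProfile] | pd.DataFrame,
) -> tuple[list[str], np.ndarray]:
    if isinstance(profiles, pd.DataFrame):
        return list(profiles.index), profiles.to_numpy(dtype=float)
    ids = list(profiles)
    return ids, np.vstack([profiles[i].values for i in ids])


def dc_score_matrix(
    compound_profiles: Mapping[str, AggregatedProfile] | pd.DataFrame,
    protein_profiles: Mapping[str, AggregatedProfile] | pd.DataFrame,
    *,
    method: str = "pearson",
    mode: str | None = None,
) -> pd.DataFrame:
    """Correlation of every compound profile with every protein profile.

    ``mode`` is bookkeeping only: the caller supplies knock-down profiles for
    inhibition scoring and over-expression profiles for activation scoring.
    Pairs involving a constant profile get NaN and are logged. Returns a
    compounds x proteins DataFrame; ``df.attrs["mode"]`` records the mode.
    """
    if method not in CORRELATION_METHODS:
        raise ConfigurationError(f"unknown correlation method {method!r}")
    cids, X = _profile_matrix(compound_profiles)
    pids, P = _profile_matrix(protein_profiles)
    if X.shape[1] != P.shape[1]:
        raise ConfigurationError(
            f"feature-space mismatch: compounds have {X.shape[1]} features, "
            f"proteins have {P.shape[1]}"
        )
    if method == "spearman":
        X = stats.rankdata(X, axis=1)
        P = stats.rankdata(P, axis=1)
    Xc = X - X.mean(axis=1, keepdims=True)
    Pc = P - P.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    pn = np.linalg.norm(Pc, axis=1)
    const_x, const_p = xn == 0, pn == 0
    if const_x.any() or const_p.any():
        logger.warning(
            "constant profiles skipped: %d compound(s), %d protein(s)",
            int(const_x.sum()),
            int(const_p.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = (Xc @ Pc.T) / np.outer(xn, pn)
    scores[const_x, :] = np.nan
    scores[:, const_p] = np.nan
    df = pd.DataFrame(scores, index=cids, columns=pids)
    df.attrs["mode"] = mode
    df.attrs["method"] = method
    return df


@dataclass
class DistributionComparison:
    statistic: float
    pvalue: float  # one-sided: positives greater
    n_positives: int
    n_negatives: int
    group_summaries: pd.DataFrame


def compare_distributions(
    scores: pd.DataFrame,
    labels: LabelMatrix,
    compound_groups: Mapping[str, str] | None = None,
) -> DistributionComparison:
    """Do known interacting pairs score higher than the other pairs?

    One-sided Mann-Whitney rank-sum (positives greater) with tie correction.
    ``compound_groups`` optionally maps compounds to a group label (e.g. a
    therapeutic class); per-group five-number summaries of positive and
    negative scores are returned for box-plot export.
    """
    aligned = scores.reindex(index=labels.compounds, columns=labels.proteins)
    vals = aligned.to_numpy(dtype=float)
    finite = np.isfinite(vals)
    pos = vals[(labels.labels == 1) & finite]
    neg = vals[(labels.labels == -1) & finite]
    if pos.size == 0 or neg.size == 0:
        raise ConfigurationError("need at least one positive and one negative score")
    pooled = np.concatenate([pos, neg])
    if np.ptp(pooled) == 0:
        # degenerate: every score tied; tie-corrected z is 0/0, convention z=0
        statistic, pvalue = pos.size * neg.size / 2.0, 0.5
    else:
        res = stats.mannwhitneyu(pos, neg, alternative="greater")
        statistic, pvalue = float(res.statistic), float(res.pvalue)

    rows = []
    groups = {"all"} if compound_groups is None else set(compound_groups.values())
    for group in sorted(groups):
        if compound_groups is None:
            sel = np.ones(len(labels.compounds), dtype=bool)
        else:
            sel = np.array(
                [compound_groups.get(c) == group for c in labels.compounds]
            )
        gvals = vals[sel]
        gl = labels.labels[sel]
        gfin = np.isfinite(gvals)
        for kind, mask in (("known", gl == 1), ("other", gl == -1)):
            sample = gvals[mask & gfin]
            if sample.size:
                q1, med, q3 = np.percentile(sample, [25, 50, 75])
                rows.append((group, kind, sample.size, q1, med, q3))
            else:
                rows.append((group, kind, 0, np.nan, np.nan, np.nan))
    summaries = pd.DataFrame(
        rows, columns=["group", "pair_kind", "n", "q1", "median", "q3"]
    )
    return DistributionComparison(statistic, pvalue, pos.size, neg.size, summaries)


def write_scores(scores: pd.DataFrame, wide_path, long_path=None) -> None:
    """Score matrix as wide TSV, plus optionally as a ranked long TSV."""
    scores.to_csv(wide_path, sep="\t", index_label="compound_id")
    if long_path is not None:
        long = scores.stack().rename("score").reset_index()
        long.columns = ["compound_id", "protein_id", "score"]
        long["mode"] = scores.attrs.get("mode")
        long = long.sort_values(
            ["score", "compound_id", "protein_id"], ascending=[False, True, True]
        ).reset_index(drop=True)
        long["rank"] = np.arange(1, len(long) + 1)
        long.to_csv(long_path, sep="\t", index=False)
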