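"""Compound-wise cross-validation and per-protein AUC/AUPR scoring.

The benchmark protocol splits *compounds* (not pairs) into k folds, so no
compound contributes to both training and test, scores every test compound
against every protein, pools test scores across folds, and computes
per-protein AUC and AUPR over the pooled test compounds. A protein's
*degree* is its number of known ligands in the full gold standard;
:func:`stratify_by_degree` summarises accuracy by degree bins, since
proteins with few known ligands are the hard case the joint-learning method
targets.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .dc import dc_score_matrix
from .errors import ConfigurationError
from .gold_standard import LabelMatrix, balanced_subsample
from .jl import FeatureMatrix, ProteinSimilarity, fit_joint, predict_scores

logger = logging.getLogger(__name__)

METHODS = ("dc", "jl")


def compound_kfold_split(
    compounds: Sequence[str], k: int, seed: int
) -> dict[str, int]:
    """Disjoint, exhaustive folds over compounds; sizes differ by at most 1."""
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if k > len(compounds):
        raise ConfigurationError(f"k={k} exceeds number of compounds ({len(compounds)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(compounds))
    folds = np.empty(len(compounds), dtype=int)
    for f, chunk in enumerate(np.array_split(order, k)):
        folds[chunk] = f
    return {c: int(folds[i]) for i, c in enumerate(compounds)}


def _check_two_class(labels: np.ndarray) -> None:
    if (labels == 1).sum() == 0 or (labels == -1).sum() == 0:
        raise ConfigurationError("need at least one positive and one negative")


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random positive outranks a random negative (ties 1/2)."""
    labels = np.asarray(labels)
    _check_two_class(labels)
    return float(roc_auc_score(labels == 1, np.asarray(scores, dtype=float)))


def aupr(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Average precision (step-wise precision-over-recall integral)."""
    labels = np.asarray(labels)
    _check_two_class(labels)
    return float(average_precision_score(labels == 1, np.asarray(scores, dtype=float)))


@dataclass
class CVResult:
    mode: str | None
    method: str
    table: pd.DataFrame  # protein_id, degree, auc, aupr, n_test_pos, n_test_neg
    fold_assignment: dict[str, int]
    excluded_proteins: list[str]
    summary: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.summary = {
            "mean_auc": float(self.table["auc"].mean()),
            "mean_aupr": float(self.table["aupr"].mean()),
            "n_proteins": int(len(self.table)),
        }

    def write(self, tsv_path, json_path=None) -> None:
        self.table.to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            import json

            payload = {
                "mode": self.mode,
                "method": self.method,
                **self.summary,
                "excluded_proteins": self.excluded_proteins,
            }
            with open(json_path, "w") as fh:
                json.dump(payload, fh, indent=2)


def _parse_sampling(sampling) -> tuple[str, int]:
    if sampling in (None, "all", "all_negatives"):
        return "all", 0
    if isinstance(sampling, tuple) and sampling[0] == "balanced":
        return "balanced", int(sampling[1])
    if isinstance(sampling, str) and sampling.startswith("balanced"):
        _, _, ratio = sampling.partition(":")
        return "balanced", int(ratio or 3)
    raise ConfigurationError(f"unknown sampling spec {sampling!r}")


def cross_validate(
    features: FeatureMatrix,
    labels: LabelMatrix,
    *,
    method: str,
    protein_profiles: FeatureMatrix | None = None,
    similarity: ProteinSimilarity | None = None,
    k: int = 5,
    seed: int = 0,
    sampling="all",
    lam1: float = 1.0,
    lam2: float = 1.0,
    correlation_method: str = "pearson",
) -> CVResult:
    """Compound-wise k-fold CV of the DC or JL method.

    DC needs ``protein_profiles`` (genetic-perturbation features per protein,
    same feature space as ``features``); it involves no fitting, but the
    identical fold protocol is applied so test sets match JL's. JL needs
    ``similarity``; balanced negative subsampling (``sampling="balanced:3"``)
    applies to the *training* labels only — the test set is never subsampled.
    """
    if method not in METHODS:
        raise ConfigurationError(f"unknown method {method!r}")
    if set(labels.compounds) != set(features.ids):
        raise ConfigurationError("label compounds must match feature ids")
    if method == "dc" and protein_profiles is None:
        raise ConfigurationError("method 'dc' requires protein_profiles")
    if method == "jl" and similarity is None:
        raise ConfigurationError("method 'jl' requires similarity")
    sampling_kind, ratio = _parse_sampling(sampling)

    compounds = list(labels.compounds)
    proteins = list(labels.proteins)
    folds = compound_kfold_split(compounds, k, seed)
    pooled = pd.DataFrame(np.nan, index=compounds, columns=proteins)

    if method == "dc":
        feat_df = pd.DataFrame(features.subset(compounds).X, index=compounds)
        prot_df = pd.DataFrame(
            protein_profiles.X, index=list(protein_profiles.ids)
        ).reindex(proteins)
        if prot_df.isna().any().any():
            raise ConfigurationError("protein_profiles missing some label proteins")
        all_scores = dc_score_matrix(feat_df, prot_df, method=correlation_method)
        for f in range(k):
            test = [c for c in compounds if folds[c] == f]
            pooled.loc[test] = all_scores.loc[test].to_numpy()
    else:
        for f in range(k):
            test = [c for c in compounds if folds[c] == f]
            train = [c for c in compounds if folds[c] != f]
            y_train = labels.subset_compounds(train)
            if sampling_kind == "balanced":
                y_train = balanced_subsample(y_train, ratio, seed=seed * 1000 + f)
            model = fit_joint(features.subset(train), y_train, similarity, lam1, lam2)
            pooled.loc[test] = predict_scores(model, features.subset(test)).to_numpy()

    degree = (labels.labels == 1).sum(axis=0)
    rows, excluded = [], []
    for j, protein in enumerate(proteins):
        s = pooled[protein].to_numpy(dtype=float)
        y = labels.labels[:, j]
        ok = np.isfinite(s)
        if (y[ok] == 1).sum() == 0 or (y[ok] == -1).sum() == 0:
            excluded.append(protein)
            continue
        rows.append(
            {
                "protein_id": protein,
                "degree": int(degree[j]),
                "auc": auc(s[ok], y[ok]),
                "aupr": aupr(s[ok], y[ok]),
                "n_test_pos": int((y[ok] == 1).sum()),
                "n_test_neg": int((y[ok] == -1).sum()),
            }
        )
    if excluded:
        logger.info("%d protein(s) excluded (single-class test sets)", len(excluded))
    table = pd.DataFrame(
        rows, columns=["protein_id", "degree", "auc", "aupr", "n_test_pos", "n_test_neg"]
    )
    return CVResult(labels.mode, method, table, folds, excluded)


def stratify_by_degree(
    result: CVResult, bin_edges: Sequence[tuple[float, float]]
) -> pd.DataFrame:
    """Per-degree-bin accuracy summaries (bins are inclusive [lo, hi])."""
    degrees = result.table["degree"].to_numpy()
    covered = np.zeros(len(degrees), dtype=bool)
    rows = []
    for lo, hi in bin_edges:
        sel = (degrees >= lo) & (degrees <= hi)
        covered |= sel
        sub = result.table[sel]
        rows.append(
            {
                "bin": f"[{lo:g}, {hi:g}]",
                "lo": lo,
                "hi": hi,
                "count": int(sel.sum()),
                "mean_auc": float(sub["auc"].mean()) if len(sub) else np.nan,
                "median_auc": float(sub["auc"].median()) if len(sub) else np.nan,
                "mean_aupr": float(sub["aupr"].mean()) if len(sub) else np.nan,
                "median_aupr": float(sub["aupr"].median()) if len(sub) else np.nan,
            }
        )
    if not covered.all():
        raise ConfigurationError("bin edges do not cover all observed degrees")
    return pd.DataFrame(rows)


def select_jl_hyperparameters(
    features: FeatureMatrix,
    labels: LabelMatrix,
    similarity: ProteinSimilarity,
    lam1_grid: Sequence[float] = (0.1, 1.0, 10.0),
    lam2_grid: Sequence[float] = (0.0, 0.1, 1.0, 10.0),
    *,
    k: int = 3,
    seed: int = 0,
) -> tuple[float, float, pd.DataFrame]:
    """Grid selection of (lam1, lam2) by inner compound-wise CV mean AUC."""
    rows = []
    for lam1 in lam1_grid:
        for lam2 in lam2_grid:
            res = cross_validate(
                features, labels, method="jl", similarity=similarity,
                k=k, seed=seed, lam1=lam1, lam2=lam2,
            )
            rows.append({"lam1": lam1, "lam2": lam2, "mean_auc": res.summary["mean_auc"]})
    table = pd.DataFrame(rows)
    best = table.loc[table["mean_auc"].idxmax()]
    return float(best["lam1"]), float(best["lam2"]), table
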