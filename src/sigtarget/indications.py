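"""Mode-aware drug-indication inference.

A drug's *target profile* is the set of (protein, mode) pairs it is known or
predicted to modulate; a disease's target profile is the set of therapeutic
targets and the mode (inhibition or activation) required for benefit. A drug
is linked to a disease when they share at least one target — and, with mode
distinction on, the drug must act on that target in the required mode. This
mode matching is what separates, say, dopamine-receptor agonists (Parkinson
medications) from dopamine-receptor antagonists (antipsychotics) even though
both hit the same protein.

Predicted targets enter the drug profiles through a global top-fraction
threshold on the per-mode score matrix (top 5% by default).
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .evaluation import auc, aupr
from .gold_standard import InteractionTable

logger = logging.getLogger(__name__)


@dataclass
class TargetProfile:
    """Set of (protein, mode) entries with per-entry provenance."""

    owner_id: str
    entries: dict[tuple[str, str], str] = field(default_factory=dict)
    # entry -> provenance, "known" | "predicted"

    def add(self, protein: str, mode: str, provenance: str) -> None:
        key = (protein, mode)
        # known takes precedence over predicted on overlap
        if self.entries.get(key) != "known":
            self.entries[key] = provenance

    def keys(self) -> set[tuple[str, str]]:
        return set(self.entries)


@dataclass
class DrugDiseasePrediction:
    drug_id: str
    disease_id: str
    shared_targets: set[tuple[str, str]]
    score: int
    linked: bool

    def __post_init__(self) -> None:
        assert self.linked == (self.score >= 1)


def threshold_top_fraction(
    scores: pd.DataFrame, fraction: float, mode: str
) -> set[tuple[str, str, str]]:
    """Globally highest-scoring ceil(fraction * #pairs) pairs of one mode.

    Ties at the cut are broken by (compound_id, protein_id) lexicographic
    order for determinism. NaN scores are never selected.
    """
    if not 0 < fraction <= 1:
        raise ConfigurationError("fraction must be in (0, 1]")
    if scores.size == 0:
        raise ConfigurationError("empty score matrix")
    n = math.ceil(fraction * scores.size)
    long = scores.stack(future_stack=True).rename("score").reset_index()
    long.columns = ["compound_id", "protein_id", "score"]
    long = long[np.isfinite(long["score"])]
    long = long.sort_values(
        ["score", "compound_id", "protein_id"], ascending=[False, True, True],
        kind="mergesort",
    )
    top = long.head(n)
    return {(r.compound_id, r.protein_id, mode) for r in top.itertuples(index=False)}


def build_drug_profile(
    drug_id: str,
    known: InteractionTable | Iterable[tuple[str, str, str]],
    predicted: Iterable[tuple[str, str, str]] = (),
) -> TargetProfile:
    """Union of known and predicted (protein, mode) targets of one drug."""
    triples = known.positives if isinstance(known, InteractionTable) else known
    profile = TargetProfile(drug_id)
    for compound, protein, mode in triples:
        if compound == drug_id:
            profile.add(protein, mode, "known")
    for compound, protein, mode in predicted:
        if compound == drug_id:
            profile.add(protein, mode, "predicted")
    return profile


def build_disease_profile(
    disease_id: str, targets: Iterable[tuple[str, str]]
) -> TargetProfile:
    profile = TargetProfile(disease_id)
    for protein, mode in targets:
        profile.add(protein, mode, "known")
    return profile


def link_drugs_to_diseases(
    drug_profiles: Mapping[str, TargetProfile],
    disease_profiles: Mapping[str, TargetProfile],
    distinguish_modes: bool = True,
) -> list[DrugDiseasePrediction]:
    """Link every drug-disease pair sharing >= 1 (mode-matched) target.

    With ``distinguish_modes=False`` the mode annotation is ignored and any
    shared protein links the pair — the baseline that earlier indication
    methods used. The score is the number of shared (mode-matched) targets.
    """
    out = []
    for drug_id, drug in drug_profiles.items():
        dkeys = drug.keys()
        dprot = {p for p, _ in dkeys}
        for disease_id, disease in disease_profiles.items():
            zkeys = disease.keys()
            if distinguish_modes:
                shared = dkeys & zkeys
            else:
                shared = {e for e in zkeys if e[0] in dprot}
            score = len(shared)
            out.append(
                DrugDiseasePrediction(drug_id, disease_id, shared, score, score >= 1)
            )
    return out


def evaluate_indications(
    predictions: Sequence[DrugDiseasePrediction],
    known_drug_disease: set[tuple[str, str]],
) -> pd.DataFrame:
    """Per-disease AUC/AUPR of drug rankings against known indications.

    Diseases whose drugs are all indicated or all non-indicated are skipped
    (logged). Returns one row per evaluable disease.
    """
    by_disease: dict[str, list[DrugDiseasePrediction]] = {}
    for p in predictions:
        by_disease.setdefault(p.disease_id, []).append(p)
    rows, skipped = [], []
    for disease_id, preds in by_disease.items():
        scores = [p.score for p in preds]
        labels = [1 if (p.drug_id, disease_id) in known_drug_disease else -1 for p in preds]
        if len(set(labels)) < 2:
            skipped.append(disease_id)
            continue
        rows.append(
            {
                "disease_id": disease_id,
                "auc": auc(scores, labels),
                "aupr": aupr(scores, labels),
                "n_known": labels.count(1),
                "n_other": labels.count(-1),
            }
        )
    if skipped:
        logger.info("%d disease(s) skipped (single class): %s", len(skipped), skipped)
    return pd.DataFrame(rows, columns=["disease_id", "auc", "aupr", "n_known", "n_other"])


def export_edge_list(
    drug_profiles: Mapping[str, TargetProfile],
    predictions: Sequence[DrugDiseasePrediction],
    path,
) -> None:
    """Cytoscape-importable edge list: drug-(inhibits|activates)-protein and
    drug-treats-disease edges for linked pairs."""
    rows = []
    verb = {"inhibition": "inhibits", "activation": "activates"}
    for drug_id, profile in drug_profiles.items():
        for (protein, mode), provenance in profile.entries.items():
            rows.append((drug_id, verb[mode], protein, provenance))
    for p in predictions:
        if p.linked:
            rows.append((p.drug_id, "treats", p.disease_id, f"score={p.score}"))
    pd.DataFrame(rows, columns=["source", "interaction", "target", "annotation"]).to_csv(
        path, sep="\t", index=False
    )
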