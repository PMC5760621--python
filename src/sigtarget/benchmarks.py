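"""Benchmark studies on synthetic data.

Each function defines one self-contained study — fixed conditions, a seed,
and a computed quantity — used both by the validation suite and by the
reproduction script. The conditions are part of the study definitions:
problem sizes follow the generator defaults (978 landmark genes, multiple
cell lines) scaled to desk-size compound/protein universes; the study of
low-degree transfer fixes a clustered world (three well-annotated proteins
plus one single-ligand protein per program cluster, program correlation
0.9) with coupling strengths on the scale of the data Gram matrix.
"""

from __future__ import annotations

import numpy as np

from .evaluation import cross_validate
from .gold_standard import InteractionTable, build_label_matrix
from .indications import (
    build_disease_profile,
    build_drug_profile,
    evaluate_indications,
    link_drugs_to_diseases,
)
from .jl import FeatureMatrix, build_protein_similarity
from .dc import compare_distributions, correlation, dc_score_matrix
from .signatures import cell_average
from .simulate import SyntheticConfig, generate


def sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % 2**31)


# ---------------------------------------------------------------------------
# negative-set construction at the benchmark universe sizes


def synthetic_positive_pairs(n_compounds, n_proteins, n_positives, seed):
    """Deterministic distinct (compound, protein) index pairs."""
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_compounds * n_proteins, size=n_positives, replace=False)
    return {(f"c{i // n_proteins}", f"p{i % n_proteins}") for i in chosen}


def negative_set_count(n_compounds: int, n_proteins: int, n_positives: int,
                       seed: int = 0) -> int:
    """Negatives of an all-pairs label matrix over the given universes."""
    pairs = synthetic_positive_pairs(n_compounds, n_proteins, n_positives, seed)
    table = InteractionTable(
        {(c, p, "inhibition") for c, p in pairs},
        tuple(f"c{i}" for i in range(n_compounds)),
        tuple(f"p{j}" for j in range(n_proteins)),
    )
    return build_label_matrix(table, "inhibition").n_negatives


# ---------------------------------------------------------------------------
# CV calibration and signal recovery


def _cv_world(config: SyntheticConfig):
    ds = generate(config)
    chem = FeatureMatrix.from_profiles(cell_average(ds.chemical))
    kd = FeatureMatrix.from_profiles(cell_average(ds.knockdown))
    labels = build_label_matrix(ds.interactions, "inhibition")
    return ds, chem, kd, labels


def null_calibration(seed: int) -> dict[str, float]:
    """DC and JL mean per-protein CV AUC with zero planted signal."""
    cfg = SyntheticConfig(
        n_proteins=20, n_compounds=300, signal_strength=0.0,
        fraction_activators=0.0, seed=sub_seed(seed, 1),
    )
    _, chem, kd, labels = _cv_world(cfg)
    dc = cross_validate(chem, labels, method="dc", protein_profiles=kd,
                        k=5, seed=sub_seed(seed, 2))
    jl = cross_validate(chem, labels, method="jl",
                        similarity=build_protein_similarity(kd),
                        k=5, seed=sub_seed(seed, 2))
    return {"dc": dc.summary["mean_auc"], "jl": jl.summary["mean_auc"]}


def high_snr_recovery(seed: int) -> dict[str, float]:
    """DC mean CV AUC and known-vs-other rank-sum p at strong planted signal."""
    cfg = SyntheticConfig(
        n_proteins=20, n_compounds=300, signal_strength=10.0,
        fraction_activators=0.0, seed=sub_seed(seed, 3),
    )
    ds, chem, kd, labels = _cv_world(cfg)
    dc = cross_validate(chem, labels, method="dc", protein_profiles=kd,
                        k=5, seed=sub_seed(seed, 4))
    scores = dc_score_matrix(
        cell_average(ds.chemical), cell_average(ds.knockdown), mode="inhibition"
    )
    comparison = compare_distributions(scores, labels)
    return {"dc": dc.summary["mean_auc"], "known_vs_other_p": comparison.pvalue}


LOW_DEGREE_STUDY = dict(
    degrees=(10, 10, 10, 1) * 3,
    n_decoys=27,
    n_cell_lines_knockdown=20,
    signal_strength=0.11,
    protein_program_correlation=0.9,
    cluster_size=4,
    lam1=300.0,
    lam2=1000.0,
)


def low_degree_transfer(seed: int) -> dict[str, float]:
    """DC vs JL per-protein CV AUC split by protein degree.

    World: program clusters of four proteins (three with 10 ligands each,
    one with a single ligand) at within-cluster program correlation 0.9;
    weak signal so that single-ligand proteins cannot be learned alone, and
    20 knock-down cell lines so the similarity graph is estimable.
    """
    p = LOW_DEGREE_STUDY
    degrees = list(p["degrees"])
    cfg = SyntheticConfig(
        n_proteins=len(degrees),
        n_compounds=sum(degrees) + p["n_decoys"],
        n_cell_lines_knockdown=p["n_cell_lines_knockdown"],
        protein_degrees=degrees,
        signal_strength=p["signal_strength"],
        fraction_activators=0.0,
        protein_program_correlation=p["protein_program_correlation"],
        cluster_size=p["cluster_size"],
        seed=sub_seed(seed, 5),
    )
    _, chem, kd, labels = _cv_world(cfg)
    cv_seed = sub_seed(seed, 6)
    dc = cross_validate(chem, labels, method="dc", protein_profiles=kd,
                        k=5, seed=cv_seed)
    jl = cross_validate(chem, labels, method="jl",
                        similarity=build_protein_similarity(kd),
                        k=5, seed=cv_seed, lam1=p["lam1"], lam2=p["lam2"])
    out = {}
    for name, res in (("dc", dc), ("jl", jl)):
        t = res.table
        out[f"{name}_low_degree"] = float(t[t.degree == 1]["auc"].mean())
        out[f"{name}_high_degree"] = float(t[t.degree == 10]["auc"].mean())
        out[f"{name}_overall"] = res.summary["mean_auc"]
    return out


# ---------------------------------------------------------------------------
# mode-aware indication inference


def mode_distinction_study(seed: int, n_diseases: int = 10,
                           drugs_per_disease: int = 6) -> dict[str, float]:
    """Indication AUC with vs without inhibition/activation distinction.

    Constructed world: each disease requires one protein in one mode; half
    of the drugs sharing that protein act in the required mode (truly
    indicated), half act in the opposite mode. Without mode distinction the
    two halves are indistinguishable.
    """
    rng = np.random.default_rng(sub_seed(seed, 7))
    modes = ("inhibition", "activation")
    drugs, diseases, known = {}, {}, set()
    k = 0
    for z in range(n_diseases):
        protein = f"P{z}"
        mode = modes[int(rng.integers(2))]
        other = modes[1 - modes.index(mode)]
        diseases[f"z{z}"] = build_disease_profile(f"z{z}", {(protein, mode)})
        for i in range(drugs_per_disease):
            drug = f"d{k}"
            k += 1
            drug_mode = mode if i < drugs_per_disease // 2 else other
            drugs[drug] = build_drug_profile(drug, {(drug, protein, drug_mode)})
            if drug_mode == mode:
                known.add((drug, f"z{z}"))
    with_modes = evaluate_indications(
        link_drugs_to_diseases(drugs, diseases, True), known
    )
    without = evaluate_indications(
        link_drugs_to_diseases(drugs, diseases, False), known
    )
    return {
        "with_distinction": float(with_modes["auc"].mean()),
        "without_distinction": float(without["auc"].mean()),
        "n_drugs": len(drugs),
    }


# ---------------------------------------------------------------------------
# activator attenuation


def attenuation_study(seed: int, attenuation: float = 0.3) -> dict[str, float]:
    """Mean planted-pair correlation for inhibitors vs attenuated activators."""
    cfg = SyntheticConfig(
        activator_attenuation=attenuation, seed=sub_seed(seed, 8)
    )
    ds = generate(cfg)
    chem = cell_average(ds.chemical)
    kd = cell_average(ds.knockdown)
    oe = cell_average(ds.overexpression)
    by_mode = {"inhibition": [], "activation": []}
    for c, p, m in ds.interactions.positives:
        prot = kd if m == "inhibition" else oe
        by_mode[m].append(correlation(chem[c].values, prot[p].values))
    return {
        "inhibitor_mean_corr": float(np.mean(by_mode["inhibition"])),
        "activator_mean_corr": float(np.mean(by_mode["activation"])),
        "n_pairs": sum(len(v) for v in by_mode.values()),
    }
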