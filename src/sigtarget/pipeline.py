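"""End-to-end pipeline: simulate -> aggregate -> gold standard -> predict ->
cross-validate -> indications, driven by a YAML/JSON config.

Every intermediate is written in its standard text format, and a JSON
manifest records the config, package and library versions, and the per-stage
sub-seed, so a run is reproducible bit-for-bit from (config, inputs). A
single global ``seed`` is the only randomness knob; each stage derives its
own sub-seed from it deterministically.

Config schema (all stages except ``simulate``/``aggregate``/
``gold_standard`` are optional)::

    seed: 7
    outdir: run/
    mode: inhibition              # inhibition | activation
    aggregation: average          # average | concatenate
    simulate: {...SyntheticConfig fields...}
    predict: {method: dc|jl, correlation: pearson, lam1: 1.0, lam2: 1.0}
    cv: {k: 5, sampling: all}     # sampling: all | "balanced:3"
    indications:
      top_fraction: 0.05
      distinguish_modes: true
      n_diseases: 6               # diseases synthesized from the planted
      targets_per_disease: 2      # interactions (or give disease_targets: path)
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__, io
from .dc import compare_distributions, dc_score_matrix, write_scores
from .errors import ConfigurationError
from .evaluation import cross_validate
from .gold_standard import build_label_matrix
from .indications import (
    build_disease_profile,
    build_drug_profile,
    evaluate_indications,
    export_edge_list,
    link_drugs_to_diseases,
    threshold_top_fraction,
)
from .jl import FeatureMatrix, build_protein_similarity, fit_joint, predict_scores
from .signatures import aggregate_replicates, cell_average, cell_concatenate
from .simulate import SyntheticConfig, generate

logger = logging.getLogger(__name__)

_TOP_KEYS = {
    "seed", "outdir", "mode", "aggregation", "simulate", "predict", "cv",
    "indications",
}


def _sub_seed(seed: int, stage_index: int) -> int:
    return int(np.random.SeedSequence([seed, stage_index]).generate_state(1)[0] % 2**31)


def load_config(config: str | Path | dict) -> dict:
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        config = yaml.safe_load(text)
    if not isinstance(config, dict):
        raise ConfigurationError("config must be a mapping")
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("seed", "outdir", "simulate"):
        if key not in config:
            raise ConfigurationError(f"config missing required key: {key}")
    mode = config.get("mode", "inhibition")
    if mode not in ("inhibition", "activation"):
        raise ConfigurationError(f"config field 'mode': unknown value {mode!r}")
    agg = config.get("aggregation", "average")
    if agg not in ("average", "concatenate"):
        raise ConfigurationError(f"config field 'aggregation': unknown value {agg!r}")
    method = config.get("predict", {}).get("method", "dc")
    if method not in ("dc", "jl"):
        raise ConfigurationError(f"config field 'predict.method': unknown value {method!r}")
    return config


def run_pipeline(config: str | Path | dict, outdir: str | Path | None = None) -> dict:
    """Run all configured stages; returns the manifest (also written to disk)."""
    cfg = load_config(config)
    outdir = Path(outdir or cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    mode = cfg.get("mode", "inhibition")
    manifest: dict[str, Any] = {
        "config": cfg,
        "versions": {"sigtarget": __version__, "numpy": np.__version__},
        "stages": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def record(stage: str, sub_seed: int | None, outputs: list[str], **extra) -> None:
        manifest["stages"][stage] = {
            "sub_seed": sub_seed,
            "outputs": outputs,
            **extra,
        }

    # -- simulate -----------------------------------------------------------
    sim_seed = _sub_seed(seed, 0)
    sim_kwargs = dict(cfg["simulate"])
    sim_kwargs.pop("seed", None)
    try:
        sim_cfg = SyntheticConfig(seed=sim_seed, **sim_kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"config field 'simulate': {exc}") from exc
    ds = generate(sim_cfg)
    sim_out = []
    for name, sigset in (
        ("chemical", ds.chemical),
        ("knockdown", ds.knockdown),
        ("overexpression", ds.overexpression),
    ):
        path = outdir / f"signatures_{name}.gct"
        io.write_gct(sigset, path)
        sim_out.append(str(path))
    pos_path = outdir / "planted_interactions.tsv"
    io.write_positives_tsv(ds.interactions.positives, pos_path)
    sim_out.append(str(pos_path))
    record("simulate", sim_seed, sim_out)

    # -- aggregate ----------------------------------------------------------
    agg = cfg.get("aggregation", "average")
    genetic = ds.knockdown if mode == "inhibition" else ds.overexpression
    chem = aggregate_replicates(ds.chemical)
    genetic = aggregate_replicates(genetic)
    if agg == "average":
        chem_profiles = cell_average(chem)
        prot_profiles = cell_average(genetic)
    else:
        order = sorted(set(chem.cell_lines()) | set(genetic.cell_lines()))
        chem_profiles = cell_concatenate(chem, order)
        prot_profiles = cell_concatenate(genetic, order)
    chem_feat = FeatureMatrix.from_profiles(chem_profiles)
    prot_feat = FeatureMatrix.from_profiles(prot_profiles)
    agg_out = []
    for name, feat in (("compound", chem_feat), ("protein", prot_feat)):
        path = outdir / f"features_{name}.tsv"
        io.write_feature_tsv(feat, path)
        agg_out.append(str(path))
    record("aggregate", None, agg_out, aggregation=agg)

    # -- gold standard ------------------------------------------------------
    labels = build_label_matrix(ds.interactions, mode)
    labels_path = outdir / f"labels_{mode}.tsv"
    io.write_label_triplets(labels, labels_path)
    record(
        "gold_standard", None, [str(labels_path)],
        n_positives=labels.n_positives, n_negatives=labels.n_negatives,
    )

    # -- predict ------------------------------------------------------------
    pred_cfg = dict(cfg.get("predict", {"method": "dc"}))
    method = pred_cfg.get("method", "dc")
    similarity = build_protein_similarity(prot_feat)
    if method == "dc":
        scores = dc_score_matrix(
            dict(chem_profiles), dict(prot_profiles),
            method=pred_cfg.get("correlation", "pearson"), mode=mode,
        )
    else:
        model = fit_joint(
            chem_feat, labels, similarity,
            float(pred_cfg.get("lam1", 1.0)), float(pred_cfg.get("lam2", 1.0)),
        )
        model.save(outdir / "jl_weights.tsv", outdir / "jl_meta.json")
        scores = predict_scores(model, chem_feat)
    score_wide = outdir / f"scores_{method}_{mode}.tsv"
    score_long = outdir / f"scores_{method}_{mode}_ranked.tsv"
    write_scores(scores, score_wide, score_long)
    comparison = compare_distributions(scores, labels)
    record(
        "predict", None, [str(score_wide), str(score_long)], method=method,
        known_vs_other_p=comparison.pvalue,
    )

    # -- cross-validation ---------------------------------------------------
    if "cv" in cfg:
        cv_cfg = dict(cfg["cv"])
        cv_seed = _sub_seed(seed, 4)
        result = cross_validate(
            chem_feat, labels,
            method=method,
            protein_profiles=prot_feat if method == "dc" else None,
            similarity=similarity if method == "jl" else None,
            k=int(cv_cfg.get("k", 5)),
            seed=cv_seed,
            sampling=cv_cfg.get("sampling", "all"),
            lam1=float(pred_cfg.get("lam1", 1.0)),
            lam2=float(pred_cfg.get("lam2", 1.0)),
        )
        cv_tsv = outdir / f"cv_{method}_{mode}.tsv"
        cv_json = outdir / f"cv_{method}_{mode}.json"
        result.write(cv_tsv, cv_json)
        record("cv", cv_seed, [str(cv_tsv), str(cv_json)], **result.summary)

    # -- indications --------------------------------------------------------
    if "indications" in cfg:
        ind_cfg = dict(cfg["indications"])
        ind_seed = _sub_seed(seed, 5)
        predicted = threshold_top_fraction(
            scores, float(ind_cfg.get("top_fraction", 0.05)), mode
        )
        drugs = list(labels.compounds)
        drug_profiles = {
            d: build_drug_profile(d, ds.interactions, predicted) for d in drugs
        }
        if "disease_targets" in ind_cfg:
            disease_targets = io.read_disease_targets_tsv(ind_cfg["disease_targets"])
        else:
            disease_targets = _synthesize_diseases(
                ds, int(ind_cfg.get("n_diseases", 6)),
                int(ind_cfg.get("targets_per_disease", 2)), ind_seed,
            )
        disease_profiles = {
            z: build_disease_profile(z, targets)
            for z, targets in disease_targets.items()
        }
        predictions = link_drugs_to_diseases(
            drug_profiles, disease_profiles,
            bool(ind_cfg.get("distinguish_modes", True)),
        )
        edge_path = outdir / "drug_target_disease_edges.tsv"
        export_edge_list(drug_profiles, predictions, edge_path)
        record("indications", ind_seed, [str(edge_path)],
               n_linked=sum(p.linked for p in predictions))

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _synthesize_diseases(
    ds, n_diseases: int, targets_per_disease: int, seed: int
) -> dict[str, set[tuple[str, str]]]:
    """Disease target tables drawn from the planted protein universe."""
    rng = np.random.default_rng(seed)
    proteins = list(ds.interactions.protein_universe)
    out: dict[str, set[tuple[str, str]]] = {}
    for z in range(n_diseases):
        chosen = rng.choice(len(proteins), size=min(targets_per_disease, len(proteins)),
                            replace=False)
        out[f"D{z + 1:03d}"] = {
            (proteins[j], "inhibition" if rng.random() < 0.5 else "activation")
            for j in chosen
        }
    return out
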