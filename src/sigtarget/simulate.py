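"""Synthetic LINCS-like perturbation datasets with planted targets.

The generator emulates the structure of landmark-gene perturbation screens:
a fixed ordered gene space (978 genes by default), chemical-treatment,
gene-knock-down and gene-over-expression signature sets profiled in several
cell lines, and planted compound-target relationships under the generative
hypothesis behind transcriptome-based target prediction: an inhibitor's
expression signature resembles the knock-down signature of its target, and
an activator's resembles the over-expression signature of its target.

Each protein ``m`` carries two latent transcriptional programs: ``g_m`` (the
knock-down direction) and ``h_m`` (the over-expression direction, drawn
independently — over-expression need not mirror knock-down). Programs are
drawn i.i.d. per gene with sd = ``signal_strength * noise_sd``, so
``signal_strength`` is the planted-program-to-noise amplitude ratio and the
expected planted-pair Pearson correlation is roughly s^2 / (s^2 + 1).
Observed signatures add an additive per-cell-line offset (shared within a
cell line) and i.i.d. Gaussian noise:

    knockdown(m, c)      = g_m + offset_c + eps
    overexpression(m, c) = h_m + offset_c + eps
    inhibitor of T (c)   = sum_{m in T} g_m + offset_c + eps
    activator of T (c)   = attenuation * sum_{m in T} h_m + offset_c + eps

``activator_attenuation`` scales down the activator signal, modelling the
negative-feedback damping that makes activation correlations weaker than
inhibition correlations in real screens. Everything is deterministic under
``(config, seed)``.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .gold_standard import InteractionTable
from .signatures import GeneSpace, SignatureSet

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "generate_raw_plate"]


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``degree`` sets how many targets each compound gets: an int for a fixed
    count or ``("geometric", p)`` for 1 + Geometric(p). ``protein_degrees``,
    when given, overrides it: protein ``m`` receives exactly
    ``protein_degrees[m]`` dedicated single-target ligands (requires
    ``n_compounds >= sum(protein_degrees)``; surplus compounds get no
    target). ``cluster_size``/``protein_program_correlation`` give
    consecutive proteins within a cluster latent programs with the stated
    pairwise correlation, inducing a clustered protein-similarity structure.
    """

    n_genes: int = 978
    n_proteins: int = 20
    n_compounds: int = 100
    n_cell_lines_chemical: int = 3
    n_cell_lines_knockdown: int = 2
    n_cell_lines_overexpression: int = 2
    degree: int | tuple[str, float] = 1
    protein_degrees: Sequence[int] | None = None
    signal_strength: float = 1.0
    activator_attenuation: float = 0.5
    fraction_activators: float = 0.2
    protein_program_correlation: float = 0.0
    cluster_size: int = 1
    protein_signal_scale: Sequence[float] | None = None
    noise_sd: float = 1.0
    cell_effect_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_genes, self.n_proteins, self.n_compounds,
            self.n_cell_lines_chemical, self.n_cell_lines_knockdown,
            self.n_cell_lines_overexpression, self.cluster_size,
        )
        if any(c < 1 for c in counts):
            raise ConfigurationError("all counts must be >= 1")
        if self.signal_strength < 0:
            raise ConfigurationError("signal_strength must be >= 0")
        if not 0 <= self.activator_attenuation <= 1:
            raise ConfigurationError("activator_attenuation must be in [0, 1]")
        if not 0 <= self.fraction_activators <= 1:
            raise ConfigurationError("fraction_activators must be in [0, 1]")
        if not 0 <= self.protein_program_correlation <= 1:
            raise ConfigurationError("protein_program_correlation must be in [0, 1]")
        if self.protein_degrees is not None:
            if len(self.protein_degrees) != self.n_proteins:
                raise ConfigurationError("protein_degrees length must equal n_proteins")
            if sum(self.protein_degrees) > self.n_compounds:
                raise ConfigurationError(
                    "protein_degrees requires more compounds than available"
                )
        if isinstance(self.degree, int) and self.degree > self.n_proteins:
            raise ConfigurationError("degree exceeds number of proteins")


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    gene_space: GeneSpace
    chemical: SignatureSet
    knockdown: SignatureSet
    overexpression: SignatureSet
    interactions: InteractionTable
    compound_modes: dict[str, str]  # compound -> "inhibition" | "activation"
    programs_kd: np.ndarray = field(repr=False)  # (M, n_genes), g_m
    programs_oe: np.ndarray = field(repr=False)  # (M, n_genes), h_m


def _correlated_programs(
    rng: np.random.Generator, M: int, n_genes: int, rho: float, cluster_size: int,
    scale: float,
) -> np.ndarray:
    """Programs with pairwise correlation rho within consecutive clusters."""
    own = rng.normal(size=(M, n_genes))
    if rho == 0.0 or cluster_size == 1:
        return scale * own
    n_clusters = -(-M // cluster_size)
    shared = rng.normal(size=(n_clusters, n_genes))
    out = np.empty_like(own)
    for m in range(M):
        out[m] = np.sqrt(rho) * shared[m // cluster_size] + np.sqrt(1 - rho) * own[m]
    return scale * out


def _draw_targets(
    rng: np.random.Generator, cfg: SyntheticConfig, proteins: Sequence[str]
) -> tuple[list[list[int]], None]:
    """Target index list per compound."""
    if cfg.protein_degrees is not None:
        targets: list[list[int]] = []
        for m, deg in enumerate(cfg.protein_degrees):
            targets.extend([[m]] * int(deg))
        targets.extend([[] for _ in range(cfg.n_compounds - len(targets))])
        return targets, None
    targets = []
    for _ in range(cfg.n_compounds):
        if isinstance(cfg.degree, int):
            k = cfg.degree
        else:
            kind, p = cfg.degree
            if kind != "geometric":
                raise ConfigurationError(f"unknown degree distribution {kind!r}")
            k = min(int(rng.geometric(p)), len(proteins))  # support starts at 1
        targets.append(sorted(rng.choice(len(proteins), size=k, replace=False)))
    return targets, None


def generate(config: SyntheticConfig, seed: int | None = None) -> SyntheticDataset:
    """Generate a full synthetic dataset; deterministic under (config, seed)."""
    cfg = config if seed is None else replace(config, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    gene_space = GeneSpace.default(cfg.n_genes)
    proteins = [f"P{m + 1:04d}" for m in range(cfg.n_proteins)]
    compounds = [f"C{i + 1:05d}" for i in range(cfg.n_compounds)]

    scale = cfg.signal_strength * cfg.noise_sd
    g = _correlated_programs(
        rng, cfg.n_proteins, cfg.n_genes, cfg.protein_program_correlation,
        cfg.cluster_size, scale,
    )
    h = _correlated_programs(
        rng, cfg.n_proteins, cfg.n_genes, cfg.protein_program_correlation,
        cfg.cluster_size, scale,
    )
    if cfg.protein_signal_scale is not None:
        mult = np.asarray(cfg.protein_signal_scale, dtype=float)[:, None]
        g, h = g * mult, h * mult

    targets, _ = _draw_targets(rng, cfg, proteins)
    n_act = int(round(cfg.fraction_activators * cfg.n_compounds))
    act_idx = set(rng.choice(cfg.n_compounds, size=n_act, replace=False)) if n_act else set()
    compound_modes = {
        c: ("activation" if i in act_idx else "inhibition")
        for i, c in enumerate(compounds)
    }

    def offsets(n_cells: int) -> np.ndarray:
        return rng.normal(scale=cfg.cell_effect_sd, size=(n_cells, cfg.n_genes))

    # chemical treatment signatures
    chem = SignatureSet(gene_space, "chemical")
    chem_cells = [f"CELL{c + 1:02d}" for c in range(cfg.n_cell_lines_chemical)]
    chem_off = offsets(len(chem_cells))
    for i, comp in enumerate(compounds):
        if compound_modes[comp] == "inhibition":
            signal = g[targets[i]].sum(axis=0) if targets[i] else 0.0
        else:
            signal = (
                cfg.activator_attenuation * h[targets[i]].sum(axis=0)
                if targets[i]
                else 0.0
            )
        for c, cell in enumerate(chem_cells):
            noise = rng.normal(scale=cfg.noise_sd, size=cfg.n_genes)
            chem.add(comp, cell, signal + chem_off[c] + noise)

    # genetic perturbation signatures
    kd = SignatureSet(gene_space, "knockdown")
    kd_cells = [f"KCELL{c + 1:02d}" for c in range(cfg.n_cell_lines_knockdown)]
    kd_off = offsets(len(kd_cells))
    for m, prot in enumerate(proteins):
        for c, cell in enumerate(kd_cells):
            noise = rng.normal(scale=cfg.noise_sd, size=cfg.n_genes)
            kd.add(prot, cell, g[m] + kd_off[c] + noise)

    oe = SignatureSet(gene_space, "overexpression")
    oe_cells = [f"OCELL{c + 1:02d}" for c in range(cfg.n_cell_lines_overexpression)]
    oe_off = offsets(len(oe_cells))
    for m, prot in enumerate(proteins):
        for c, cell in enumerate(oe_cells):
            noise = rng.normal(scale=cfg.noise_sd, size=cfg.n_genes)
            oe.add(prot, cell, h[m] + oe_off[c] + noise)

    positives = {
        (compounds[i], proteins[m], compound_modes[compounds[i]])
        for i in range(cfg.n_compounds)
        for m in targets[i]
    }
    table = InteractionTable(positives, tuple(compounds), tuple(proteins))
    return SyntheticDataset(
        cfg, gene_space, chem, kd, oe, table, compound_modes, g, h
    )


def generate_raw_plate(
    config: SyntheticConfig,
    n_controls: int = 4,
    *,
    plate_noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[str], dict[str, tuple[str, str]], SyntheticDataset]:
    """Raw expression plate whose z-scored treatments recover the signatures.

    Controls get a deterministic zero-mean, unit-population-sd spread around
    a per-gene baseline, so with ``plate_noise_sd=0`` the z-scores of the
    treatment wells reproduce the planted chemical signatures exactly.
    Returns (plate genes x wells, control well ids, well -> (entity, cell)
    map, the underlying dataset).
    """
    if n_controls < 2:
        raise ConfigurationError("need at least 2 control wells")
    ds = generate(config, seed=seed)
    cfg = ds.config
    rng = np.random.default_rng(cfg.seed + 1)
    genes = list(ds.gene_space.gene_ids)
    baseline = rng.normal(loc=8.0, scale=1.0, size=cfg.n_genes)

    # fixed control pattern: standardized ramp (population mean 0, sd 1)
    ramp = np.arange(n_controls, dtype=float)
    pattern = (ramp - ramp.mean()) / ramp.std(ddof=0)

    plate: dict[str, np.ndarray] = {}
    controls = [f"ctl_{j + 1:02d}" for j in range(n_controls)]
    for j, well in enumerate(controls):
        plate[well] = baseline + pattern[j]
    well_info: dict[str, tuple[str, str]] = {}
    for (entity, cell), z in ds.chemical.items():
        well = f"trt_{entity}|{cell}"
        noise = rng.normal(scale=plate_noise_sd, size=cfg.n_genes) if plate_noise_sd else 0.0
        plate[well] = baseline + z + noise
        well_info[well] = (entity, cell)
    frame = pd.DataFrame(plate, index=genes)
    return frame, controls, well_info, ds
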