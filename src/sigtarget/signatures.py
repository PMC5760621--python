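"""Perturbation-signature containers and aggregation.

A *signature* is a vector of per-gene differential-expression z-scores
induced by one perturbagen (a compound treatment, a gene knock-down, or a
gene over-expression) in one cell line, aligned to a fixed ordered gene
space (978 landmark genes by default). This module provides the containers
(:class:`GeneSpace`, :class:`Signature`, :class:`SignatureSet`,
:class:`AggregatedProfile`), control-based z-scoring of raw plates, replicate
collapsing, and the two multi-cell-line aggregation operators used as
feature maps downstream: cell-averaging (element-wise mean over cell lines)
and cell-concatenating (block concatenation in a fixed cell-line order).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

PERT_TYPES = ("chemical", "knockdown", "overexpression", "control")

#: control genes whose z-score is forced to 0 when the control sd is below this
SD_FLOOR = 1e-8


@dataclass(frozen=True)
class GeneSpace:
    """Ordered, immutable list of gene identifiers shared by a dataset."""

    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ConfigurationError("gene identifiers must be unique")
        if len(self.gene_ids) == 0:
            raise ConfigurationError("gene space must be non-empty")

    def __len__(self) -> int:
        return len(self.gene_ids)

    @classmethod
    def default(cls, n_genes: int = 978) -> "GeneSpace":
        """Numbered landmark-style gene space ``g0001 .. gNNNN``."""
        width = max(4, len(str(n_genes)))
        return cls(tuple(f"g{i + 1:0{width}d}" for i in range(n_genes)))


@dataclass
class Signature:
    """One perturbagen x cell-line z-score vector."""

    entity_id: str
    pert_type: str
    cell_line: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.pert_type not in PERT_TYPES:
            raise ConfigurationError(
                f"unknown pert_type {self.pert_type!r}; expected one of {PERT_TYPES}"
            )
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise InputError(
                f"signature ({self.entity_id}, {self.cell_line}) has non-finite values"
            )


class SignatureSet:
    """Signatures of one perturbation type on a shared gene space.

    Keyed by ``(entity_id, cell_line)``. Replicate wells (several vectors for
    the same key) may be held transiently; :func:`aggregate_replicates`
    collapses them, and vector accessors refuse to guess while replicates are
    present.
    """

    def __init__(self, gene_space: GeneSpace, pert_type: str) -> None:
        if pert_type not in PERT_TYPES:
            raise ConfigurationError(f"unknown pert_type {pert_type!r}")
        self.gene_space = gene_space
        self.pert_type = pert_type
        self._store: dict[tuple[str, str], list[np.ndarray]] = {}

    # -- construction -------------------------------------------------------

    def add(self, entity_id: str, cell_line: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self.gene_space),):
            raise ConfigurationError(
                f"signature length {values.shape} does not match gene space "
                f"({len(self.gene_space)})"
            )
        if not np.all(np.isfinite(values)):
            raise InputError(f"non-finite values for ({entity_id}, {cell_line})")
        self._store.setdefault((entity_id, cell_line), []).append(values)

    @classmethod
    def from_signatures(
        cls, gene_space: GeneSpace, pert_type: str, signatures: Iterable[Signature]
    ) -> "SignatureSet":
        out = cls(gene_space, pert_type)
        for sig in signatures:
            if sig.pert_type != pert_type:
                raise ConfigurationError(
                    f"mixed pert_type: set is {pert_type!r}, got {sig.pert_type!r}"
                )
            out.add(sig.entity_id, sig.cell_line, sig.values)
        return out

    # -- inspection ---------------------------------------------------------

    def keys(self) -> list[tuple[str, str]]:
        return list(self._store)

    def entities(self) -> list[str]:
        seen: dict[str, None] = {}
        for entity, _ in self._store:
            seen.setdefault(entity)
        return list(seen)

    def cell_lines(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, cell in self._store:
            seen.setdefault(cell)
        return list(seen)

    @property
    def has_replicates(self) -> bool:
        return any(len(v) > 1 for v in self._store.values())

    def __len__(self) -> int:
        return sum(len(v) for v in self._store.values())

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._store

    def get(self, entity_id: str, cell_line: str) -> np.ndarray:
        reps = self._store[(entity_id, cell_line)]
        if len(reps) > 1:
            raise ConfigurationError(
                f"({entity_id}, {cell_line}) holds {len(reps)} replicates; "
                "run aggregate_replicates first"
            )
        return reps[0]

    def items(self) -> Iterable[tuple[tuple[str, str], np.ndarray]]:
        for key in self._store:
            yield key, self.get(*key)

    def to_frame(self) -> pd.DataFrame:
        """Genes x signatures wide table; columns are ``entity|cell``."""
        cols = {f"{e}|{c}": v for (e, c), v in self.items()}
        return pd.DataFrame(cols, index=list(self.gene_space.gene_ids))


@dataclass
class AggregatedProfile:
    """Per-entity feature vector after cell-averaging or cell-concatenating."""

    entity_id: str
    mode_of_aggregation: str  # "cell_average" | "cell_concatenate"
    values: np.ndarray
    cell_line_order: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def zscore_normalize(
    raw_plate: pd.DataFrame,
    control_wells: Sequence[str],
    *,
    pert_type: str = "chemical",
    well_info: Mapping[str, tuple[str, str]] | None = None,
) -> SignatureSet:
    """z-score treatment wells of a raw plate against its control wells.

    Parameters
    ----------
    raw_plate
        Genes x wells expression table (rows indexed by gene id).
    control_wells
        Column names of the control wells (at least two).
    well_info
        Optional map ``well -> (entity_id, cell_line)`` for the treatment
        wells; wells without an entry become ``(well, "plate")``.

    For each treatment well and gene ``g``,
    ``z = (x_g - mean_ctl(g)) / sd_ctl(g)`` with the population sd (ddof=0)
    over control wells. Genes whose control sd is below ``SD_FLOOR`` get
    ``z = 0`` with a logged warning. Control wells are excluded from the
    output.
    """
    control_wells = list(control_wells)
    if len(control_wells) < 2:
        raise ConfigurationError(
            f"need at least 2 control wells, got {len(control_wells)}"
        )
    missing = [w for w in control_wells if w not in raw_plate.columns]
    if missing:
        raise ConfigurationError(f"control wells not on plate: {missing}")
    bad_wells = raw_plate.columns[~np.isfinite(raw_plate.to_numpy()).all(axis=0)]
    if len(bad_wells):
        raise InputError(f"non-finite raw values in well(s) {list(bad_wells)}")

    ctl = raw_plate[control_wells].to_numpy()
    mu = ctl.mean(axis=1)
    sd = ctl.std(axis=1, ddof=0)
    flat = sd < SD_FLOOR
    if flat.any():
        logger.warning(
            "%d gene(s) with near-zero control sd; z forced to 0", int(flat.sum())
        )
    safe_sd = np.where(flat, 1.0, sd)

    gene_space = GeneSpace(tuple(raw_plate.index))
    out = SignatureSet(gene_space, pert_type)
    for well in raw_plate.columns:
        if well in control_wells:
            continue
        z = (raw_plate[well].to_numpy() - mu) / safe_sd
        z[flat] = 0.0
        entity, cell = (well_info or {}).get(well, (well, "plate"))
        out.add(entity, cell, z)
    return out


def aggregate_replicates(sigset: SignatureSet) -> SignatureSet:
    """Collapse replicate wells to their unweighted element-wise mean."""
    out = SignatureSet(sigset.gene_space, sigset.pert_type)
    for key, reps in sigset._store.items():
        out.add(key[0], key[1], np.mean(reps, axis=0))
    return out


def cell_average(sigset: SignatureSet) -> dict[str, AggregatedProfile]:
    """Element-wise mean over the cell lines in which each entity was profiled.

    No imputation: an entity averaged over the cell lines it actually has.
    """
    by_entity: dict[str, list[np.ndarray]] = {}
    for (entity, _), values in sigset.items():
        by_entity.setdefault(entity, []).append(values)
    return {
        entity: AggregatedProfile(entity, "cell_average", np.mean(vecs, axis=0))
        for entity, vecs in by_entity.items()
    }


def cell_concatenate(
    sigset: SignatureSet, cell_line_order: Sequence[str]
) -> dict[str, AggregatedProfile]:
    """Concatenate each entity's per-cell-line signatures in a fixed order.

    Blocks for cell lines in which the entity was not profiled are
    zero-filled (a z-score of "no change"), keeping a fixed feature length of
    ``|genes| * |cell_line_order|`` for every entity.
    """
    order = tuple(cell_line_order)
    if not order:
        raise ConfigurationError("cell_line_order must be non-empty")
    present = set(sigset.cell_lines())
    unknown = present - set(order)
    if unknown:
        raise ConfigurationError(
            f"cell line(s) {sorted(unknown)} present in data but absent from "
            "cell_line_order"
        )
    n = len(sigset.gene_space)
    entities = sigset.entities()
    out: dict[str, AggregatedProfile] = {}
    for entity in entities:
        blocks = []
        for cell in order:
            if (entity, cell) in sigset:
                blocks.append(sigset.get(entity, cell))
            else:
                blocks.append(np.zeros(n))
        out[entity] = AggregatedProfile(
            entity, "cell_concatenate", np.concatenate(blocks), order
        )
    return out
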