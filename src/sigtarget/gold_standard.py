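"""Mode-annotated gold-standard construction.

Raw compound-protein interaction records (pooled from public databases such
as ChEMBL, DrugBank, MATADOR, ...) are turned into two mode-specific
positive sets — *inhibition* and *activation* — and the complementary
negative sets. Mode assignment follows the curation rules used for
transcriptome-based target prediction benchmarks: the free-text definition
field decides first (inhibitor/antagonist vs. activator/agonist); records
without a definition fall back to the affinity unit (IC50 and Ki are
inhibitory assays). Records are kept when flagged active or when the binding
affinity is below a cutoff (30 uM by default). Negatives are *all*
compound x protein pairs over the declared universes that are not positives
of the mode.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

MODES = ("inhibition", "activation")

INHIBITORY_KEYWORDS = ("inhibitor", "antagonist")
ACTIVATORY_KEYWORDS = ("activator", "agonist")
INHIBITORY_AFFINITY_TYPES = ("IC50", "Ki")

DEFAULT_AFFINITY_CUTOFF_UM = 30.0


@dataclass
class InteractionRecord:
    compound_id: str
    protein_id: str
    definition: str = ""
    affinity_type: str = "none"  # IC50 | Ki | EC50 | Kd | none
    affinity_value: float | None = None  # concentration in uM
    active_flag: bool | None = None
    source_db: str = ""

    def __post_init__(self) -> None:
        if self.affinity_value is not None and self.affinity_value <= 0:
            raise InputError(
                f"non-positive affinity for ({self.compound_id}, {self.protein_id})"
            )


def assign_mode(record: InteractionRecord) -> str | None:
    """Classify a record as inhibition, activation, or neither.

    Keyword matching is case-insensitive substring. Because "antagonist"
    contains "agonist", inhibitory keyword occurrences are removed from the
    text before the activatory check. A record whose definition matches both
    keyword families is rejected (returns None) with a logged conflict.
    """
    text = record.definition.lower()
    inhibitory = any(kw in text for kw in INHIBITORY_KEYWORDS)
    residual = text
    for kw in INHIBITORY_KEYWORDS:
        residual = residual.replace(kw, " ")
    activatory = any(kw in residual for kw in ACTIVATORY_KEYWORDS)
    if inhibitory and activatory:
        logger.warning(
            "conflicting definition %r for (%s, %s); record dropped",
            record.definition,
            record.compound_id,
            record.protein_id,
        )
        return None
    if inhibitory:
        return "inhibition"
    if activatory:
        return "activation"
    if record.affinity_type in INHIBITORY_AFFINITY_TYPES:
        return "inhibition"
    return None


def filter_active(
    records: Iterable[InteractionRecord],
    affinity_cutoff_uM: float = DEFAULT_AFFINITY_CUTOFF_UM,
) -> list[InteractionRecord]:
    """Keep records flagged active or with affinity below the cutoff.

    Deduplicates on (compound, protein, mode), keeping the first occurrence;
    records to which no mode can be assigned are dropped.
    """
    if affinity_cutoff_uM <= 0:
        raise ConfigurationError("affinity_cutoff_uM must be > 0")
    seen: set[tuple[str, str, str]] = set()
    kept: list[InteractionRecord] = []
    for rec in records:
        active = rec.active_flag is True or (
            rec.affinity_value is not None and rec.affinity_value < affinity_cutoff_uM
        )
        if not active:
            continue
        mode = assign_mode(rec)
        if mode is None:
            continue
        key = (rec.compound_id, rec.protein_id, mode)
        if key in seen:
            continue
        seen.add(key)
        kept.append(rec)
    return kept


@dataclass
class InteractionTable:
    """Mode-annotated positives over declared compound/protein universes."""

    positives: set[tuple[str, str, str]]  # (compound, protein, mode)
    compound_universe: tuple[str, ...]
    protein_universe: tuple[str, ...]

    def __post_init__(self) -> None:
        compounds = set(self.compound_universe)
        proteins = set(self.protein_universe)
        if len(compounds) != len(self.compound_universe):
            raise ConfigurationError("duplicate compounds in universe")
        if len(proteins) != len(self.protein_universe):
            raise ConfigurationError("duplicate proteins in universe")
        for c, p, mode in self.positives:
            if mode not in MODES:
                raise InputError(f"unknown mode {mode!r}")
            if c not in compounds:
                raise InputError(f"positive references compound {c!r} outside universe")
            if p not in proteins:
                raise InputError(f"positive references protein {p!r} outside universe")

    def positives_of(self, mode: str) -> set[tuple[str, str]]:
        return {(c, p) for c, p, m in self.positives if m == mode}

    @classmethod
    def from_records(
        cls,
        records: Iterable[InteractionRecord],
        *,
        affinity_cutoff_uM: float = DEFAULT_AFFINITY_CUTOFF_UM,
        compound_universe: Sequence[str] | None = None,
        protein_universe: Sequence[str] | None = None,
    ) -> "InteractionTable":
        """Filter, mode-assign, and assemble a table.

        When universes are not given they default to the entities appearing
        in the kept records. Positives referencing entities outside an
        explicit universe (e.g. entities lacking signatures) are dropped
        with a log message.
        """
        kept = filter_active(records, affinity_cutoff_uM)
        triples = {(r.compound_id, r.protein_id, assign_mode(r)) for r in kept}
        if compound_universe is None:
            compound_universe = sorted({c for c, _, _ in triples})
        if protein_universe is None:
            protein_universe = sorted({p for _, p, _ in triples})
        cset, pset = set(compound_universe), set(protein_universe)
        dropped = {t for t in triples if t[0] not in cset or t[1] not in pset}
        if dropped:
            logger.info("%d positive(s) outside the universes dropped", len(dropped))
        return cls(triples - dropped, tuple(compound_universe), tuple(protein_universe))


@dataclass
class LabelMatrix:
    """Dense +1/-1 labels over compound x protein pairs for one mode.

    ``mask`` (optional) marks the pairs in play after subsampling; ``None``
    means every pair.
    """

    mode: str
    compounds: tuple[str, ...]
    proteins: tuple[str, ...]
    labels: np.ndarray  # (n_compounds, n_proteins), entries +1/-1
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != (len(self.compounds), len(self.proteins)):
            raise ConfigurationError("label matrix shape mismatch")
        if not np.isin(self.labels, (-1, 1)).all():
            raise InputError("labels must be +1 or -1")

    @property
    def n_positives(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_negatives(self) -> int:
        return int((self.labels == -1).sum())

    def subset_compounds(self, compounds: Sequence[str]) -> "LabelMatrix":
        idx = [self.compounds.index(c) for c in compounds]
        mask = None if self.mask is None else self.mask[idx]
        return LabelMatrix(
            self.mode, tuple(compounds), self.proteins, self.labels[idx], mask
        )


def build_label_matrix(table: InteractionTable, mode: str) -> LabelMatrix:
    """All-pairs label matrix: +1 for positives of the mode, -1 elsewhere."""
    if mode not in MODES:
        raise ConfigurationError(f"unknown mode {mode!r}")
    if not table.compound_universe or not table.protein_universe:
        raise ConfigurationError("empty universe")
    cidx = {c: i for i, c in enumerate(table.compound_universe)}
    pidx = {p: j for j, p in enumerate(table.protein_universe)}
    labels = np.full((len(cidx), len(pidx)), -1, dtype=np.int8)
    for c, p in table.positives_of(mode):
        labels[cidx[c], pidx[p]] = 1
    return LabelMatrix(mode, table.compound_universe, table.protein_universe, labels)


def balanced_subsample(matrix: LabelMatrix, ratio: int, seed: int) -> LabelMatrix:
    """Per protein, keep all positives and ``ratio`` x as many random negatives.

    Proteins with fewer negatives than the quota keep them all. Returns a
    copy of ``matrix`` whose ``mask`` marks the retained pairs.
    """
    if ratio < 1:
        raise ConfigurationError("ratio must be >= 1")
    rng = np.random.default_rng(seed)
    mask = np.zeros_like(matrix.labels, dtype=bool)
    for j in range(len(matrix.proteins)):
        pos = np.flatnonzero(matrix.labels[:, j] == 1)
        neg = np.flatnonzero(matrix.labels[:, j] == -1)
        mask[pos, j] = True
        quota = ratio * len(pos)
        if len(neg) <= quota:
            mask[neg, j] = True
        else:
            mask[rng.choice(neg, size=quota, replace=False), j] = True
    return LabelMatrix(matrix.mode, matrix.compounds, matrix.proteins, matrix.labels, mask)
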