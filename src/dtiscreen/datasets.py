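"""Labeled drug-target interaction dataset construction.

Training and external-validation sets are assembled from normalized
interaction tables:

1. deduplicate on the ``(drug_id, target_id)`` key across sources,
2. extract weak binders (bioactivity strictly above 10 uM) as negatives,
3. optionally screen the ligand library for chemical redundancy
   (Tanimoto similarity on 1024-bit path fingerprints),
4. allocate the negative pool across the positive sets at a ~1.5
   negative:positive ratio by seeded draw without replacement, and
5. encode every record as protein-block || drug-block features
   (width :data:`PAIR_WIDTH`).
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .drug_descriptors import DRUG_WIDTH, drug_features, drug_feature_labels, parse_ligand
from .protein_descriptors import PROTEIN_WIDTH, ProteinSequence, protein_features

__all__ = [
    "PAIR_WIDTH",
    "InteractionRecord",
    "LabeledDataset",
    "SplitSpec",
    "dedup_interactions",
    "filter_weak_binders",
    "fingerprint_redundancy_report",
    "allocate_negatives",
    "encode_dataset",
    "read_interactions",
    "write_interactions",
]

logger = logging.getLogger(__name__)

#: width of one encoded drug-target pair: 407 protein + 323 drug descriptors
PAIR_WIDTH = PROTEIN_WIDTH + DRUG_WIDTH

#: weak-binder bioactivity threshold in micromolar
WEAK_BINDER_UM = 10.0

LABELS = ("positive", "negative", "unknown")
MEASURES = ("Ki", "Kd", "IC50", "other")


@dataclass(frozen=True)
class InteractionRecord:
    """One (drug, target) pair with label, provenance and optional bioactivity.

    ``bioactivity`` is in micromolar and must be positive when present.
    The pair key ``(drug_id, target_id)`` is the identity used everywhere.
    """

    drug_id: str
    target_id: str
    label: str = "unknown"
    source: str = ""
    bioactivity: Optional[float] = None
    measure: Optional[str] = None

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.bioactivity is not None and self.bioactivity <= 0:
            raise ValueError(
                f"bioactivity must be positive, got {self.bioactivity}"
            )
        if self.measure is not None and self.measure not in MEASURES:
            raise ValueError(f"measure must be one of {MEASURES}")

    @property
    def key(self) -> Tuple[str, str]:
        return (self.drug_id, self.target_id)


@dataclass
class LabeledDataset:
    """Interaction records plus their aligned feature matrix and labels."""

    records: List[InteractionRecord]
    features: np.ndarray
    labels: np.ndarray
    feature_names: Tuple[str, ...] = ()

    def __post_init__(self):
        n = len(self.records)
        if self.features.shape != (n, PAIR_WIDTH):
            raise ValueError(
                f"feature matrix must be {n}x{PAIR_WIDTH}, "
                f"got {self.features.shape}"
            )
        if len(self.labels) != n:
            raise ValueError("labels and records must align")
        keys = [r.key for r in self.records]
        if len(set(keys)) != n:
            raise ValueError("duplicate (drug_id, target_id) keys in dataset")

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SplitSpec:
    """Negative-allocation policy: ratio, seed and positive-set order."""

    ratio: float = 1.5
    seed: int = 0
    set_order: Tuple[str, ...] = ()

    def __post_init__(self):
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")


def dedup_interactions(
    records: Iterable[InteractionRecord],
    set_order: Sequence[str] = (),
) -> List[InteractionRecord]:
    """One record per (drug_id, target_id) key.

    The earliest-source record wins, where source priority follows
    ``set_order`` (sources not listed rank after listed ones, in first-seen
    order).  A positive/negative label conflict between duplicates keeps the
    positive and logs the conflict.
    """
    priority = {name: i for i, name in enumerate(set_order)}
    chosen: Dict[Tuple[str, str], InteractionRecord] = {}
    order: List[Tuple[str, str]] = []
    for rec in records:
        if rec.key not in chosen:
            chosen[rec.key] = rec
            order.append(rec.key)
            continue
        kept = chosen[rec.key]
        if {kept.label, rec.label} == {"positive", "negative"}:
            logger.warning(
                "label conflict for %s: keeping positive", rec.key
            )
            winner = kept if kept.label == "positive" else rec
        else:
            def rank(r):
                return priority.get(r.source, len(priority) + 1)
            winner = rec if rank(rec) < rank(kept) else kept
        chosen[rec.key] = winner
    return [chosen[k] for k in order]


def filter_weak_binders(
    records: Iterable[InteractionRecord],
    threshold_um: float = WEAK_BINDER_UM,
) -> List[InteractionRecord]:
    """Extract weak binders as negative examples.

    Keeps records whose bioactivity is **strictly** greater than
    ``threshold_um`` (micromolar) and relabels them negative; a record
    exactly at the threshold is never returned.  Records without a
    bioactivity are skipped with a log entry.
    """
    out = []
    for rec in records:
        if rec.bioactivity is None:
            logger.info("skipping %s: no bioactivity value", rec.key)
            continue
        if rec.bioactivity > threshold_um:
            out.append(replace(rec, label="negative"))
    return out


def nm_to_um(value_nm: float) -> float:
    """Convert a bioactivity from nanomolar to micromolar."""
    return value_nm / 1000.0


def fingerprint_redundancy_report(
    ligands: Sequence, cutoff: float = 0.85
) -> Tuple[float, int]:
    """Fraction of unordered ligand pairs with Tanimoto similarity > cutoff.

    Similarity is computed on 1024-bit path-based binary fingerprints.
    Returns ``(fraction_above, pair_count)``; fewer than 2 ligands yields
    ``(0.0, 0)``.
    """
    from rdkit.Chem import RDKFingerprint
    from rdkit.DataStructs import TanimotoSimilarity

    mols = []
    for lig in ligands:
        mols.append(lig.molecule if hasattr(lig, "molecule") else lig)
    if len(mols) < 2:
        return 0.0, 0
    fps = [RDKFingerprint(m, fpSize=1024) for m in mols]
    n_pairs = 0
    n_above = 0
    for i in range(len(fps)):
        for j in range(i + 1, len(fps)):
            n_pairs += 1
            if TanimotoSimilarity(fps[i], fps[j]) > cutoff:
                n_above += 1
    return n_above / n_pairs, n_pairs


def allocate_negatives(
    positive_sets: Sequence[Sequence[InteractionRecord]],
    negative_pool: Sequence[InteractionRecord],
    spec: SplitSpec,
    override: Optional[Sequence[int]] = None,
) -> List[List[InteractionRecord]]:
    """Distribute the negative pool over the positive sets.

    Set *i* receives ``round(ratio * |positives_i|)`` negatives drawn
    without replacement (seeded), in ``set_order``; whatever remains after
    the last quota goes to the last set, so the union of the outputs is
    exactly the pool and the outputs are pairwise disjoint.  ``override``
    replaces the computed quotas with explicit per-set counts (used to
    replicate externally fixed split sizes).  A pool smaller than the first
    quota falls back to proportional allocation with a warning.
    """
    pool_keys = {r.key for r in negative_pool}
    for pos in positive_sets:
        clash = pool_keys & {r.key for r in pos}
        if clash:
            raise ValueError(
                f"negative pool overlaps positives on {len(clash)} keys, "
                f"e.g. {sorted(clash)[:3]}"
            )
    n_sets = len(positive_sets)
    if override is not None:
        if len(override) != n_sets:
            raise ValueError("override must give one quota per positive set")
        quotas = list(override)
    else:
        quotas = [round(spec.ratio * len(pos)) for pos in positive_sets]
        if quotas and quotas[0] > len(negative_pool):
            logger.warning(
                "pool (%d) smaller than first quota (%d); "
                "falling back to proportional allocation",
                len(negative_pool), quotas[0],
            )
            total_pos = sum(len(p) for p in positive_sets) or 1
            quotas = [
                round(len(negative_pool) * len(pos) / total_pos)
                for pos in positive_sets
            ]
    rng = random.Random(spec.seed)
    shuffled = list(negative_pool)
    rng.shuffle(shuffled)
    out: List[List[InteractionRecord]] = []
    start = 0
    for i, quota in enumerate(quotas):
        if i == n_sets - 1:
            chunk = shuffled[start:]  # remainder to the last set
        else:
            chunk = shuffled[start:start + quota]
        out.append(chunk)
        start += len(chunk)
    return out


def encode_dataset(
    records: Sequence[InteractionRecord],
    protein_seqs: Mapping[str, ProteinSequence],
    ligand_table: Mapping[str, str],
) -> LabeledDataset:
    """Featurize records into a LabeledDataset (row = protein || drug).

    Entities are featurized once and cached, so a dataset over P proteins
    and D drugs costs P + D featurizations.  Records whose target has no
    sequence or whose drug has no (parsable) SMILES are dropped with a
    logged identifier.
    """
    protein_cache: Dict[str, np.ndarray] = {}
    drug_cache: Dict[str, np.ndarray] = {}
    kept: List[InteractionRecord] = []
    rows: List[np.ndarray] = []
    protein_labels: Tuple[str, ...] = ()
    for rec in records:
        if rec.target_id not in protein_cache:
            seq = protein_seqs.get(rec.target_id)
            if seq is None:
                logger.warning("dropping %s: no sequence for target %s",
                               rec.key, rec.target_id)
                continue
            try:
                block = protein_features(seq)
            except Exception as exc:
                logger.warning("dropping %s: %s", rec.key, exc)
                continue
            protein_cache[rec.target_id] = block.values
            protein_labels = block.labels
        if rec.drug_id not in drug_cache:
            smiles = ligand_table.get(rec.drug_id)
            if smiles is None:
                logger.warning("dropping %s: no SMILES for drug %s",
                               rec.key, rec.drug_id)
                continue
            try:
                drug_cache[rec.drug_id] = drug_features(smiles, rec.drug_id).values
            except Exception as exc:
                logger.warning("dropping %s: %s", rec.key, exc)
                continue
        kept.append(rec)
        rows.append(
            np.concatenate([protein_cache[rec.target_id], drug_cache[rec.drug_id]])
        )
    features = (
        np.vstack(rows) if rows else np.empty((0, PAIR_WIDTH))
    )
    labels = np.array([1 if r.label == "positive" else 0 for r in kept])
    names = tuple(f"protein.{x}" for x in protein_labels) + tuple(
        f"drug.{x}" for x in drug_feature_labels()
    )
    if not protein_labels:  # empty dataset: synthesize names lazily
        names = ()
    return LabeledDataset(kept, features, labels, names)


# ---------------------------------------------------------------------------
# I/O: normalized interaction TSV

_COLUMNS = ("drug_id", "target_id", "label", "source", "bioactivity_um", "measure")


def read_interactions(path) -> List[InteractionRecord]:
    """Read the normalized interaction TSV
    (``drug_id target_id label source bioactivity_um [measure]``)."""
    out = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "drug_id":
                continue
            fields += [""] * (6 - len(fields))
            bio = float(fields[4]) if fields[4] else None
            out.append(InteractionRecord(
                fields[0], fields[1],
                fields[2] or "unknown", fields[3],
                bio, fields[5] or None,
            ))
    return out


def write_interactions(records: Sequence[InteractionRecord], path) -> None:
    """Write the normalized interaction TSV readable by
    :func:`read_interactions`."""
    with open(path, "w") as handle:
        handle.write("\t".join(_COLUMNS) + "\n")
        for r in records:
            bio = "" if r.bioactivity is None else repr(r.bioactivity)
            handle.write(
                f"{r.drug_id}\t{r.target_id}\t{r.label}\t{r.source}\t"
                f"{bio}\t{r.measure or ''}\n"
            )
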