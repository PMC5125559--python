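"""All-against-all candidate screening and ranked report generation.

The prioritized target shortlist is crossed with the ligand library
(target-major, ligand-minor order), every pair is featurized and scored
with the trained forest, and candidates are ranked by positive-class
probability.  Ties break on (target_id, drug_id) so reports regenerate
byte-identically under a fixed model and seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .datasets import InteractionRecord, encode_dataset
from .model import TrainedModel, predict_probability
from .protein_descriptors import ProteinSequence

__all__ = [
    "PredictionRecord",
    "cartesian_candidates",
    "rank_candidates",
    "export_report",
    "read_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictionRecord:
    """A screened candidate pair with its positive-class probability."""

    target_id: str
    drug_id: str
    probability: float

    def __post_init__(self):
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(
                f"probability must be in [0, 1], got {self.probability}"
            )


def cartesian_candidates(
    targets: Sequence[str],
    ligands: Sequence[str],
    exclude_known: bool = False,
    known: Optional[Set[Tuple[str, str]]] = None,
) -> List[Tuple[str, str]]:
    """All (target, drug) pairs, target-major then ligand-minor.

    ``exclude_known`` removes pairs present in ``known`` (keys are
    ``(drug_id, target_id)``); by default known pairs are kept, matching a
    screen over the full ligand library including training drugs.
    """
    for name, ids in (("targets", targets), ("ligands", ligands)):
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate ids in {name} list")
    known = known or set()
    pairs = []
    for t in targets:
        for d in ligands:
            if exclude_known and (d, t) in known:
                continue
            pairs.append((t, d))
    return pairs


def rank_candidates(
    model: TrainedModel,
    pairs: Sequence[Tuple[str, str]],
    protein_seqs: Mapping[str, ProteinSequence],
    ligand_table: Mapping[str, str],
    top_n: Optional[int] = None,
) -> List[PredictionRecord]:
    """Score candidate pairs and rank by probability descending.

    Unfeaturizable pairs (missing sequence/SMILES) are dropped with a log
    entry.  Probabilities are kept at full precision internally; rounding
    to 2 decimals happens only at report time.
    """
    records = [
        InteractionRecord(drug_id=d, target_id=t) for t, d in pairs
    ]
    dataset = encode_dataset(records, protein_seqs, ligand_table)
    dropped = len(records) - len(dataset)
    if dropped:
        logger.warning("dropped %d unfeaturizable candidate pairs", dropped)
    if len(dataset) == 0:
        return []
    probs = predict_probability(model, dataset.features)
    out = [
        PredictionRecord(rec.target_id, rec.drug_id, float(p))
        for rec, p in zip(dataset.records, probs)
    ]
    out.sort(key=lambda r: (-r.probability, r.target_id, r.drug_id))
    if top_n is not None:
        out = out[:max(top_n, 0)]
    return out


def _provenance(model: TrainedModel, seed: Optional[int], n: int) -> str:
    digest = hashlib.sha256()
    digest.update(str(model.config).encode())
    digest.update(",".join(model.feature_names).encode())
    for est in model.forest.estimators_[:1]:
        digest.update(str(est.tree_.node_count).encode())
    return (
        f"# model_hash={digest.hexdigest()[:16]} "
        f"seed={'' if seed is None else seed} n_records={n}"
    )


def export_report(
    records: Sequence[PredictionRecord],
    path,
    model: Optional[TrainedModel] = None,
    seed: Optional[int] = None,
) -> None:
    """Write the ranked screening report TSV.

    Columns are ``target_id  drug_id  probability`` (probability at 2
    decimals); a comment line carries provenance (model hash, seed, record
    count) when a model is given.
    """
    with open(path, "w") as handle:
        if model is not None:
            handle.write(_provenance(model, seed, len(records)) + "\n")
        handle.write("target_id\tdrug_id\tprobability\n")
        for rec in records:
            handle.write(
                f"{rec.target_id}\t{rec.drug_id}\t{rec.probability:.2f}\n"
            )


def read_report(path) -> List[PredictionRecord]:
    """Read a report written by :func:`export_report` (2-dp probabilities)."""
    out = []
    with open(path) as handle:
        for line in handle:
            if line.startswith("#") or line.startswith("target_id"):
                continue
            if not line.strip():
                continue
            t, d, p = line.rstrip("\n").split("\t")
            out.append(PredictionRecord(t, d, float(p)))
    return out
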