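"""Sequence-derived protein descriptors: AAC, Moran autocorrelation, CTD.

A protein target is featurized from its primary sequence alone into a fixed
407-value block:

* 20 amino-acid composition (AAC) fractions,
* 240 Moran autocorrelation values (8 physicochemical property scales x
  lags 1..30), measuring sequence-order correlation of a z-normalized
  property, and
* 147 CTD values (7 attributes x [3 Composition + 3 Transition + 15
  Distribution]) after mapping residues into three physicochemical groups.

The block structure (20 + 240 + 147 = 407) is contractual: labels ship with
the values and downstream feature matrices depend on the ordering.

Property scales and group partitions ship as versioned TSV data files; see
``data/moran_scales.tsv`` and ``data/ctd_groups.tsv``.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "AAC_WIDTH",
    "MORAN_WIDTH",
    "CTD_WIDTH",
    "PROTEIN_WIDTH",
    "ProteinSequence",
    "PropertyScale",
    "ProteinFeatureBlock",
    "load_moran_scales",
    "load_ctd_groups",
    "amino_acid_composition",
    "moran_autocorrelation",
    "ctd_descriptors",
    "protein_features",
    "read_fasta",
]

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)
_NONSTANDARD = frozenset("BJOUXZ")

MORAN_MAX_LAG = 30

#: block sizes of the protein feature vector
AAC_WIDTH = 20
MORAN_WIDTH = 8 * MORAN_MAX_LAG  # 240
CTD_WIDTH = 7 * (3 + 3 + 15)  # 147
PROTEIN_WIDTH = AAC_WIDTH + MORAN_WIDTH + CTD_WIDTH  # 407


class SequenceError(ValueError):
    """Invalid residue or sequence too short for the requested descriptor."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein identifier plus residues over the 20-letter alphabet.

    ``strip_nonstandard=True`` removes B/J/O/U/X/Z before validation
    (logged); otherwise any character outside the standard alphabet raises
    :class:`SequenceError` naming the first offending position.
    """

    id: str
    residues: str

    def __init__(self, id: str, residues: str, strip_nonstandard: bool = False):
        residues = residues.upper()
        if strip_nonstandard:
            cleaned = "".join(c for c in residues if c not in _NONSTANDARD)
            if len(cleaned) != len(residues):
                logger.info(
                    "stripped %d nonstandard residues from %s",
                    len(residues) - len(cleaned), id,
                )
            residues = cleaned
        for pos, char in enumerate(residues, start=1):
            if char not in _AA_SET:
                raise SequenceError(
                    f"{id}: invalid residue {char!r} at position {pos}"
                )
        if not residues:
            raise SequenceError(f"{id}: empty sequence")
        object.__setattr__(self, "id", id)
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PropertyScale:
    """Residue -> value map for one physicochemical property.

    ``normalized()`` returns the z-scored scale (mean 0, sd 1 over the 20
    residues), the form used by the Moran computation; Moran descriptors are
    therefore invariant to affine transforms a*scale+b (a>0) of the raw values.
    """

    name: str
    values: Dict[str, float]
    normalized: bool = False

    def __post_init__(self):
        if set(self.values) != _AA_SET:
            missing = _AA_SET - set(self.values)
            extra = set(self.values) - _AA_SET
            raise ValueError(
                f"scale {self.name}: bad residue coverage "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )

    def normalize(self) -> "PropertyScale":
        if self.normalized:
            return self
        vals = np.array([self.values[a] for a in AMINO_ACIDS])
        mu, sigma = vals.mean(), vals.std()  # population sd over the 20 residues
        if sigma == 0:
            raise ValueError(f"scale {self.name} is constant; cannot normalize")
        zvals = (vals - mu) / sigma
        return PropertyScale(
            self.name, dict(zip(AMINO_ACIDS, zvals.tolist())), normalized=True
        )


@dataclass(frozen=True)
class ProteinFeatureBlock:
    """Ordered 407-value protein feature vector with aligned labels."""

    values: np.ndarray
    labels: Tuple[str, ...]

    def __post_init__(self):
        if len(self.values) != PROTEIN_WIDTH or len(self.labels) != PROTEIN_WIDTH:
            raise ValueError(
                f"protein block must have {PROTEIN_WIDTH} values, "
                f"got {len(self.values)}"
            )


def _data_lines(filename: str):
    text = resources.files("dtiscreen.data").joinpath(filename).read_text()
    for line in text.splitlines():
        if line and not line.startswith("#"):
            yield line.split("\t")


def load_moran_scales() -> List[PropertyScale]:
    """Load the 8 embedded Moran property scales (raw, unnormalized)."""
    rows = list(_data_lines("moran_scales.tsv"))
    header = rows[0]
    residues = header[1:]
    scales = []
    for row in rows[1:]:
        values = {aa: float(v) for aa, v in zip(residues, row[1:])}
        scales.append(PropertyScale(row[0], values))
    return scales


def load_ctd_groups() -> List[Tuple[str, Tuple[str, str, str]]]:
    """Load the 7 embedded CTD three-group partitions, validated."""
    rows = list(_data_lines("ctd_groups.tsv"))
    attributes = []
    for row in rows[1:]:
        name, groups = row[0], tuple(row[1:4])
        combined = "".join(groups)
        if sorted(combined) != sorted(AMINO_ACIDS):
            raise ValueError(
                f"CTD attribute {name}: groups must partition the 20 residues"
            )
        attributes.append((name, groups))
    return attributes


def amino_acid_composition(seq: ProteinSequence) -> np.ndarray:
    """Fraction of each amino-acid type, in fixed order A,C,D,...,Y.

    The 20 values sum to 1 for any valid sequence.
    """
    n = len(seq)
    counts = np.array([seq.residues.count(a) for a in AMINO_ACIDS], dtype=float)
    return counts / n


def moran_autocorrelation(
    seq: ProteinSequence,
    scales: Sequence[PropertyScale] | None = None,
    max_lag: int = MORAN_MAX_LAG,
) -> np.ndarray:
    """Moran autocorrelation I(d) for each property scale and lag d=1..max_lag.

    I(d) = [ (1/(N-d)) sum_{i=1..N-d} (P_i - Pbar)(P_{i+d} - Pbar) ]
           / [ (1/N) sum_{i=1..N} (P_i - Pbar)^2 ]

    where P_i is the normalized property value of residue i and Pbar the mean
    over the sequence.  Zero-variance sequences (homopolymers) yield 0.0 by
    convention.  Ordering is scale-major, lag-minor (8 x 30 = 240 values).
    """
    if scales is None:
        scales = load_moran_scales()
    n = len(seq)
    if n <= max_lag:
        raise SequenceError(
            f"{seq.id}: sequence length {n} too short for Moran lag {max_lag} "
            f"(minimum {max_lag + 1})"
        )
    out = np.empty(len(scales) * max_lag)
    pos = 0
    for scale in scales:
        norm = scale.normalize()
        p = np.array([norm.values[c] for c in seq.residues])
        pbar = p.mean()
        dev = p - pbar
        denom = np.dot(dev, dev) / n
        for d in range(1, max_lag + 1):
            if denom == 0:
                out[pos] = 0.0
            else:
                num = np.dot(dev[:-d], dev[d:]) / (n - d)
                out[pos] = num / denom
            pos += 1
    return out


def _distribution(positions: List[int], n: int) -> List[float]:
    """First/25%/50%/75%/100% occurrence positions of a group, as % of N."""
    if not positions:
        return [0.0] * 5
    count = len(positions)
    out = []
    for q in (0.0, 0.25, 0.5, 0.75, 1.0):
        idx = max(1, math.ceil(q * count))  # 1-based occurrence index
        out.append(100.0 * positions[idx - 1] / n)
    return out


def ctd_descriptors(
    seq: ProteinSequence,
    attributes: Sequence[Tuple[str, Tuple[str, str, str]]] | None = None,
) -> np.ndarray:
    """Composition/Transition/Distribution descriptors, 147 values.

    Per attribute: 3 composition fractions, 3 transition frequencies over the
    unordered group pairs {1,2},{1,3},{2,3} divided by (N-1), and 15
    distribution values (per group: position of the first occurrence and of
    the 25/50/75/100% occurrence quantiles, as percent of N; all 0 for an
    absent group).  Attribute-major ordering.
    """
    if attributes is None:
        attributes = load_ctd_groups()
    n = len(seq)
    if n < 2:
        raise SequenceError(f"{seq.id}: CTD needs length >= 2, got {n}")
    out: List[float] = []
    for name, groups in attributes:
        combined = "".join(groups)
        if sorted(combined) != sorted(AMINO_ACIDS):
            raise ValueError(
                f"CTD attribute {name}: groups must partition the 20 residues"
            )
        residue_group = {}
        for gi, group in enumerate(groups, start=1):
            for aa in group:
                residue_group[aa] = gi
        encoded = [residue_group[c] for c in seq.residues]
        # composition
        for gi in (1, 2, 3):
            out.append(encoded.count(gi) / n)
        # transition: adjacent pairs with one residue in each of two groups
        trans = {(1, 2): 0, (1, 3): 0, (2, 3): 0}
        for a, b in zip(encoded, encoded[1:]):
            key = (min(a, b), max(a, b))
            if a != b:
                trans[key] += 1
        for pair in ((1, 2), (1, 3), (2, 3)):
            out.append(trans[pair] / (n - 1))
        # distribution
        for gi in (1, 2, 3):
            positions = [i for i, g in enumerate(encoded, start=1) if g == gi]
            out.extend(_distribution(positions, n))
    return np.array(out)


def _labels(
    scales: Sequence[PropertyScale],
    attributes: Sequence[Tuple[str, Tuple[str, str, str]]],
    max_lag: int,
) -> Tuple[str, ...]:
    labels = [f"aac.{a}" for a in AMINO_ACIDS]
    for scale in scales:
        labels.extend(f"moran.{scale.name}.d{d}" for d in range(1, max_lag + 1))
    for name, _ in attributes:
        labels.extend(f"ctd.{name}.comp.g{g}" for g in (1, 2, 3))
        labels.extend(f"ctd.{name}.trans.g{a}{b}" for a, b in ((1, 2), (1, 3), (2, 3)))
        for g in (1, 2, 3):
            labels.extend(
                f"ctd.{name}.dist.g{g}.{q}" for q in ("first", "q25", "q50", "q75", "q100")
            )
    return tuple(labels)


def protein_features(seq: ProteinSequence) -> ProteinFeatureBlock:
    """Full 407-value protein block: AAC (20) || Moran (240) || CTD (147)."""
    scales = load_moran_scales()
    attributes = load_ctd_groups()
    values = np.concatenate([
        amino_acid_composition(seq),
        moran_autocorrelation(seq, scales),
        ctd_descriptors(seq, attributes),
    ])
    return ProteinFeatureBlock(values, _labels(scales, attributes, MORAN_MAX_LAG))


def read_fasta(path, strip_nonstandard: bool = False) -> List[ProteinSequence]:
    """Read a multi-record FASTA; the id is the description up to the first
    whitespace."""
    from Bio import SeqIO

    return [
        ProteinSequence(rec.id, str(rec.seq), strip_nonstandard=strip_nonstandard)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
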