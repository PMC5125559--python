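"""SMILES-derived 2D molecular descriptors for ligands.

A ligand is featurized from its SMILES into a fixed 323-value block:

====================  =====  ==========================================
block                 width  content
====================  =====  ==========================================
const                 30     element/bond/ring counts, weight, H-bond
                             donors/acceptors, path-count statistics
conn                  23     molecular connectivity (chi) indices:
                             simple, valence and n-variant, path and
                             cluster subgraphs
prop                  6      bulk molecular properties (logP, molar
                             refractivity, TPSA, ...)
kappa                 7      Kier kappa shape indices 1-3, their
                             alpha-modified forms, and Hall-Kier alpha
charge                12     Gasteiger partial-charge summary statistics
maccs                 166    MACCS substructure keys (binary)
estate                79     E-state atom-type occurrence counts
====================  =====  ==========================================

All descriptors are 2D (no conformer generation).  Salts are reduced to
their largest organic fragment before computation.  Values that are
undefined on degenerate molecules (e.g. kappa3 of methane) are emitted as
0.0 with a debug log entry, never NaN.  The 323-name manifest ships as
package data (``data/drug_manifest.json``) so the feature order is
contractual.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Sequence, Tuple

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, GraphDescriptors, MACCSkeys, rdMolDescriptors, rdmolops

__all__ = [
    "DRUG_WIDTH",
    "BLOCK_WIDTHS",
    "Ligand",
    "DrugFeatureBlock",
    "SmilesParseError",
    "parse_ligand",
    "constitutional_descriptors",
    "connectivity_indices",
    "molecular_properties",
    "kappa_shape",
    "charge_descriptors",
    "maccs_keys",
    "estate_fingerprint",
    "drug_features",
    "drug_feature_labels",
    "read_ligand_table",
    "write_feature_matrix",
]

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

BLOCK_WIDTHS = {
    "const": 30,
    "conn": 23,
    "prop": 6,
    "kappa": 7,
    "charge": 12,
    "maccs": 166,
    "estate": 79,
}
DRUG_WIDTH = sum(BLOCK_WIDTHS.values())  # 323


class SmilesParseError(ValueError):
    """SMILES string could not be parsed into a molecule."""


@dataclass(frozen=True)
class Ligand:
    """Identifier, original SMILES, and the parsed (desalted) molecule."""

    id: str
    smiles: str
    molecule: object

    @property
    def canonical_smiles(self) -> str:
        return Chem.MolToSmiles(self.molecule)


@dataclass(frozen=True)
class DrugFeatureBlock:
    """Ordered 323-value drug feature vector with aligned labels."""

    values: np.ndarray
    labels: Tuple[str, ...]

    def __post_init__(self):
        if len(self.values) != DRUG_WIDTH or len(self.labels) != DRUG_WIDTH:
            raise ValueError(
                f"drug block must have {DRUG_WIDTH} values, got {len(self.values)}"
            )


def parse_ligand(id: str, smiles: str) -> Ligand:
    """Parse SMILES into a canonical molecule, keeping the largest fragment.

    Multi-fragment inputs (salts such as ``[Na+].CC(=O)O``) are reduced to
    the fragment with the most heavy atoms before descriptor computation.
    Hydrogens stay implicit.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError(f"{id}: empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise SmilesParseError(f"{id}: unparsable SMILES {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        mol = max(frags, key=lambda f: f.GetNumHeavyAtoms())
        logger.debug("%s: reduced %d fragments to largest", id, len(frags))
    # round-trip through canonical SMILES so the atom order (and therefore
    # every floating-point summation order downstream) is canonical too
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    return Ligand(id, smiles, mol)


# ---------------------------------------------------------------------------
# constitutional block (30)

_ELEMENTS = ["C", "N", "O", "S", "P", "F", "Cl", "Br", "I"]


def _path_counts(mol, max_len: int = 5) -> List[int]:
    """Number of simple paths of each bond length 1..max_len."""
    return [
        len(Chem.FindAllPathsOfLengthN(mol, k, useBonds=True))
        for k in range(1, max_len + 1)
    ]


def constitutional_descriptors(mol) -> np.ndarray:
    """30 element/bond/ring/path count descriptors plus molecular weight."""
    bonds = mol.GetBonds()
    bond_counts = {"SINGLE": 0, "DOUBLE": 0, "TRIPLE": 0, "AROMATIC": 0}
    for b in bonds:
        name = b.GetBondType().name
        if name in bond_counts:
            bond_counts[name] += 1
    n_hetero = sum(
        1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6)
    )
    n_halogen = sum(
        1 for a in mol.GetAtoms() if a.GetAtomicNum() in (9, 17, 35, 53)
    )
    ring_info = mol.GetRingInfo()
    values = [
        mol.GetNumHeavyAtoms(),
        mol.GetNumAtoms(onlyExplicit=False),  # includes implicit H
        sum(a.GetTotalNumHs() for a in mol.GetAtoms()),
        *[
            sum(1 for a in mol.GetAtoms() if a.GetSymbol() == el)
            for el in _ELEMENTS
        ],
        n_hetero,
        n_halogen,
        mol.GetNumBonds(),
        bond_counts["SINGLE"],
        bond_counts["DOUBLE"],
        bond_counts["TRIPLE"],
        bond_counts["AROMATIC"],
        rdMolDescriptors.CalcNumRotatableBonds(mol),
        ring_info.NumRings(),
        rdMolDescriptors.CalcNumAromaticRings(mol),
        Descriptors.MolWt(mol),
        rdMolDescriptors.CalcNumHBD(mol),
        rdMolDescriptors.CalcNumHBA(mol),
        *_path_counts(mol, 5),
    ]
    assert len(values) == BLOCK_WIDTHS["const"]
    return np.array(values, dtype=float)


_CONST_LABELS = (
    ["n_heavy", "n_atoms_total", "n_hydrogens"]
    + [f"n_{el}" for el in _ELEMENTS]
    + [
        "n_heteroatoms", "n_halogens", "n_bonds", "n_single_bonds",
        "n_double_bonds", "n_triple_bonds", "n_aromatic_bonds",
        "n_rotatable_bonds", "n_rings", "n_aromatic_rings",
        "mol_weight", "n_hbd", "n_hba",
    ]
    + [f"path_count_{k}" for k in range(1, 6)]
)


# ---------------------------------------------------------------------------
# connectivity block (23)

def _simple_delta(atom) -> int:
    return atom.GetDegree()


def _simple_chi_path(mol, order: int) -> float:
    """Simple path chi of given order: sum over paths of prod(delta)^-1/2.

    Order 0 sums over atoms, order 1 over bonds (the Randic index), higher
    orders over simple paths of that many bonds.
    """
    deltas = [_simple_delta(a) for a in mol.GetAtoms()]
    if order == 0:
        return float(sum(d ** -0.5 for d in deltas if d > 0))
    total = 0.0
    for path in Chem.FindAllPathsOfLengthN(mol, order, useBonds=True):
        atoms = _path_atoms(mol, path)
        prod = 1.0
        ok = True
        for idx in atoms:
            if deltas[idx] == 0:
                ok = False
                break
            prod *= deltas[idx]
        if ok:
            total += prod ** -0.5
    return total


def _path_atoms(mol, bond_path) -> List[int]:
    """Ordered atom indices visited by a bond path."""
    bonds = [mol.GetBondWithIdx(b) for b in bond_path]
    if len(bonds) == 1:
        return [bonds[0].GetBeginAtomIdx(), bonds[0].GetEndAtomIdx()]
    atoms: List[int] = []
    first, second = bonds[0], bonds[1]
    shared = {first.GetBeginAtomIdx(), first.GetEndAtomIdx()} & {
        second.GetBeginAtomIdx(), second.GetEndAtomIdx()
    }
    start = ({first.GetBeginAtomIdx(), first.GetEndAtomIdx()} - shared).pop()
    atoms.append(start)
    current = start
    for bond in bonds:
        current = bond.GetOtherAtomIdx(current)
        atoms.append(current)
    return atoms


def _cluster_chi(mol, n_branches: int, delta_fn) -> float:
    """Cluster chi: star subgraphs of 3 or 4 edges around a central atom."""
    total = 0.0
    for atom in mol.GetAtoms():
        neighbors = list(atom.GetNeighbors())
        if len(neighbors) < n_branches:
            continue
        dc = delta_fn(atom)
        if dc <= 0:
            continue
        for combo in itertools.combinations(neighbors, n_branches):
            prod = dc
            ok = True
            for nb in combo:
                dn = delta_fn(nb)
                if dn <= 0:
                    ok = False
                    break
                prod *= dn
            if ok:
                total += prod ** -0.5
    return total


def _valence_delta(atom) -> float:
    """Kier-Hall valence delta: (Zv - h) / (Z - Zv - 1) for heavy atoms."""
    z = atom.GetAtomicNum()
    zv = Chem.GetPeriodicTable().GetNOuterElecs(z)
    h = atom.GetTotalNumHs()
    if z <= 10:
        return float(zv - h)
    return (zv - h) / float(z - zv - 1)


def _valence_chi_path(mol, order: int) -> float:
    deltas = [_valence_delta(a) for a in mol.GetAtoms()]
    if order == 0:
        return float(sum(d ** -0.5 for d in deltas if d > 0))
    total = 0.0
    for path in Chem.FindAllPathsOfLengthN(mol, order, useBonds=True):
        atoms = _path_atoms(mol, path)
        prod = 1.0
        ok = True
        for idx in atoms:
            if deltas[idx] <= 0:
                ok = False
                break
            prod *= deltas[idx]
        if ok:
            total += prod ** -0.5
    return total


def connectivity_indices(mol) -> np.ndarray:
    """23 molecular connectivity (chi) indices.

    Simple path chi orders 0-6, simple cluster chi 3c/4c, mean Randic
    index, valence path chi orders 0-6, valence cluster chi 3c/4c, mean
    valence chi1, and the RDKit n-variant chi orders 0-4 (valence deltas
    with hydrogen-suppressed perturbation).  Single atoms take the
    degenerate value 0 for every order >= 1 by the delta-degree convention.
    """
    n_bonds = mol.GetNumBonds()
    chi_simple = [_simple_chi_path(mol, k) for k in range(0, 7)]
    chi_valence = [_valence_chi_path(mol, k) for k in range(0, 7)]
    values = [
        *chi_simple,
        _cluster_chi(mol, 3, _simple_delta),
        _cluster_chi(mol, 4, _simple_delta),
        chi_simple[1] / n_bonds if n_bonds else 0.0,
        *chi_valence,
        _cluster_chi(mol, 3, _valence_delta),
        _cluster_chi(mol, 4, _valence_delta),
        chi_valence[1] / n_bonds if n_bonds else 0.0,
        GraphDescriptors.Chi0n(mol),
        GraphDescriptors.Chi1n(mol),
        GraphDescriptors.Chi2n(mol),
    ]
    assert len(values) == BLOCK_WIDTHS["conn"]
    return np.array(values, dtype=float)


_CONN_LABELS = (
    [f"chi{k}p" for k in range(0, 7)]
    + ["chi3c", "chi4c", "mean_chi1"]
    + [f"chi{k}pv" for k in range(0, 7)]
    + ["chi3cv", "chi4cv", "mean_chi1v"]
    + ["chi0n", "chi1n", "chi2n"]
)


# ---------------------------------------------------------------------------
# property (6), kappa (7), charge (12)

def molecular_properties(mol) -> np.ndarray:
    """6 bulk properties: Crippen logP and molar refractivity, TPSA,
    Labute approximate surface area, fraction of sp3 carbons, Bertz
    complexity."""
    values = [
        Crippen.MolLogP(mol),
        Crippen.MolMR(mol),
        rdMolDescriptors.CalcTPSA(mol),
        rdMolDescriptors.CalcLabuteASA(mol),
        rdMolDescriptors.CalcFractionCSP3(mol),
        GraphDescriptors.BertzCT(mol),
    ]
    assert len(values) == BLOCK_WIDTHS["prop"]
    return np.array(values, dtype=float)


_PROP_LABELS = ["logp", "molar_refractivity", "tpsa", "labute_asa",
                "fraction_csp3", "bertz_ct"]


def _kappa_alpha_modified(mol) -> Tuple[float, float, float]:
    """Alpha-modified kappa 1-3 from heavy-atom count, path counts and
    Hall-Kier alpha.  Degenerate denominators yield 0."""
    a = mol.GetNumHeavyAtoms()
    alpha = GraphDescriptors.HallKierAlpha(mol)
    p1 = mol.GetNumBonds()
    p2 = len(Chem.FindAllPathsOfLengthN(mol, 2, useBonds=True))
    p3 = len(Chem.FindAllPathsOfLengthN(mol, 3, useBonds=True))
    ka1 = (a + alpha) * (a + alpha - 1) ** 2 / (p1 + alpha) ** 2 if p1 + alpha > 0 else 0.0
    ka2 = (a + alpha - 1) * (a + alpha - 2) ** 2 / (p2 + alpha) ** 2 if p2 + alpha > 0 else 0.0
    if a % 2:
        ka3 = (a + alpha - 1) * (a + alpha - 3) ** 2 / (p3 + alpha) ** 2 if p3 + alpha > 0 else 0.0
    else:
        ka3 = (a + alpha - 3) * (a + alpha - 2) ** 2 / (p3 + alpha) ** 2 if p3 + alpha > 0 else 0.0
    return ka1, ka2, ka3


def kappa_shape(mol) -> np.ndarray:
    """7 Kier shape indices: kappa1-3, alpha-modified kappa1-3, and the
    Hall-Kier alpha itself.  Single-atom molecules yield defined 0 values."""
    try:
        k1, k2, k3 = (
            GraphDescriptors.Kappa1(mol),
            GraphDescriptors.Kappa2(mol),
            GraphDescriptors.Kappa3(mol),
        )
    except Exception:  # degenerate molecule
        logger.debug("kappa undefined for %s", Chem.MolToSmiles(mol))
        k1 = k2 = k3 = 0.0
    ka1, ka2, ka3 = _kappa_alpha_modified(mol)
    values = [k1, k2, k3, ka1, ka2, ka3, GraphDescriptors.HallKierAlpha(mol)]
    values = [0.0 if (isinstance(v, float) and (math.isnan(v) or math.isinf(v))) else v
              for v in values]
    assert len(values) == BLOCK_WIDTHS["kappa"]
    return np.array(values, dtype=float)


_KAPPA_LABELS = ["kappa1", "kappa2", "kappa3",
                 "kappa1_alpha", "kappa2_alpha", "kappa3_alpha",
                 "hall_kier_alpha"]


def charge_descriptors(mol) -> np.ndarray:
    """12 Gasteiger partial-charge summary statistics.

    Charges are computed on heavy atoms with the implicit-hydrogen
    contribution folded into the bonded heavy atom.
    """
    mol = Chem.Mol(mol)
    try:
        Chem.rdPartialCharges.ComputeGasteigerCharges(mol)
        charges = []
        for atom in mol.GetAtoms():
            q = atom.GetDoubleProp("_GasteigerCharge")
            qh = atom.GetDoubleProp("_GasteigerHCharge")
            if math.isnan(q) or math.isinf(q):
                q = 0.0
            if math.isnan(qh) or math.isinf(qh):
                qh = 0.0
            charges.append(q + qh)
        q = np.array(charges)
    except Exception:
        logger.debug("Gasteiger charges undefined; emitting zeros")
        q = np.zeros(mol.GetNumAtoms())
    pos = q[q > 0]
    neg = q[q < 0]
    total_pos = float(pos.sum()) if pos.size else 0.0
    total_neg = float(neg.sum()) if neg.size else 0.0
    total_abs = float(np.abs(q).sum())
    values = [
        float(q.max()) if q.size else 0.0,          # most positive charge
        float(q.min()) if q.size else 0.0,          # most negative charge
        total_pos,
        total_neg,
        total_abs,
        float(q.mean()) if q.size else 0.0,
        float(np.abs(q).mean()) if q.size else 0.0,
        float(q.var()) if q.size else 0.0,
        float(q.max() / total_pos) if total_pos > 0 else 0.0,   # relative pos
        float(q.min() / total_neg) if total_neg < 0 else 0.0,   # relative neg
        float(total_pos - abs(total_neg)),          # net charge balance
        float(np.square(q).sum()),                  # total squared charge
    ]
    assert len(values) == BLOCK_WIDTHS["charge"]
    return np.array(values, dtype=float)


_CHARGE_LABELS = [
    "q_max", "q_min", "q_pos_total", "q_neg_total", "q_abs_total",
    "q_mean", "q_abs_mean", "q_variance", "q_max_relative",
    "q_min_relative", "q_net_balance", "q_squared_total",
]


# ---------------------------------------------------------------------------
# fingerprints

def maccs_keys(mol) -> np.ndarray:
    """166 binary MACCS keys (key i at position i-1)."""
    bv = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
    return np.array([int(bv.GetBit(i)) for i in range(1, 167)], dtype=float)


def estate_fingerprint(mol) -> np.ndarray:
    """Occurrence counts over the 79 Kier-Hall E-state atom types.

    The total count equals the number of heavy atoms for molecules whose
    atoms are all typeable.
    """
    from rdkit.Chem.EState import AtomTypes

    if AtomTypes.esPatterns is None:
        AtomTypes.BuildPatts()
    type_index = {name: i for i, (name, _) in enumerate(AtomTypes.esPatterns)}
    counts = np.zeros(len(type_index))
    for types in AtomTypes.TypeAtoms(mol):
        # per-atom count (a substructure-match count would undercount
        # symmetry-equivalent atoms); untypeable atoms contribute nothing
        if types:
            counts[type_index[types[0]]] += 1
    return counts


# ---------------------------------------------------------------------------
# assembly

def drug_feature_labels() -> Tuple[str, ...]:
    """The 323 feature names in contractual order (block-prefixed)."""
    labels = (
        [f"const.{x}" for x in _CONST_LABELS]
        + [f"conn.{x}" for x in _CONN_LABELS]
        + [f"prop.{x}" for x in _PROP_LABELS]
        + [f"kappa.{x}" for x in _KAPPA_LABELS]
        + [f"charge.{x}" for x in _CHARGE_LABELS]
        + [f"maccs.key{i}" for i in range(1, 167)]
        + [f"estate.type{i}" for i in range(1, 80)]
    )
    return tuple(labels)


def drug_features(smiles: str, id: str = "") -> DrugFeatureBlock:
    """Full 323-value drug block from a SMILES string."""
    ligand = smiles if isinstance(smiles, Ligand) else parse_ligand(id or smiles, smiles)
    mol = ligand.molecule
    values = np.concatenate([
        constitutional_descriptors(mol),
        connectivity_indices(mol),
        molecular_properties(mol),
        kappa_shape(mol),
        charge_descriptors(mol),
        maccs_keys(mol),
        estate_fingerprint(mol),
    ])
    values = np.nan_to_num(values, nan=0.0, posinf=0.0, neginf=0.0)
    return DrugFeatureBlock(values, drug_feature_labels())


def verify_manifest() -> bool:
    """Check the shipped manifest matches the in-code label order."""
    text = resources.files("dtiscreen.data").joinpath("drug_manifest.json").read_text()
    manifest = json.loads(text)
    return tuple(manifest["labels"]) == drug_feature_labels()


# ---------------------------------------------------------------------------
# I/O

def read_ligand_table(path) -> List[Tuple[str, str]]:
    """Read a ligand TSV (``id<TAB>smiles``, optional header)."""
    out = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("id", "ligand_id", "drug_id"):
                continue
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected id<TAB>smiles"
                )
            out.append((fields[0], fields[1]))
    return out


def write_feature_matrix(rows: Dict[str, np.ndarray], path) -> None:
    """Write a per-ligand feature matrix TSV with the 323-name header."""
    labels = drug_feature_labels()
    with open(path, "w") as handle:
        handle.write("id\t" + "\t".join(labels) + "\n")
        for lig_id in sorted(rows):
            vals = "\t".join(repr(float(v)) for v in rows[lig_id])
            handle.write(f"{lig_id}\t{vals}\n")
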