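"""Desk-scale synthetic inputs for every pipeline stage.

Everything the pipeline consumes — PPI edge lists, protein FASTA, ligand
tables, labeled interaction lists — can be generated here deterministically
from a seed, so the full prioritize/train/screen path is exercisable
without any database download.

The labeled DTI generator injects class signal *through the real feature
pipeline*: a pair's latent score is a linear function of its protein's
amino-acid-composition features (z-scored over the generated pool), scaled
by ``effect_size`` and perturbed by logistic noise.  ``effect_size = 0``
therefore yields labels independent of the features (null datasets), while
large effect sizes yield strongly separable datasets; separability is
monotone in the effect size.  Synthetic bioactivities accompany each
record (negatives above the 10 uM weak-binder threshold, positives below)
so threshold filtering is exercisable on fixture data.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datasets import InteractionRecord, LabeledDataset, encode_dataset
from .interactome import InteractomeGraph
from .protein_descriptors import AMINO_ACIDS, ProteinSequence, amino_acid_composition

__all__ = [
    "GRAPH_KINDS",
    "make_graph",
    "write_string_links",
    "random_protein",
    "fixture_ligands",
    "write_fasta",
    "write_ligand_table",
    "synthetic_dti_dataset",
    "write_fixture_bundle",
]

GRAPH_KINDS = ("path", "ring", "star", "complete", "random", "two_community")

#: ~20 small molecules, including salt forms to exercise the
#: largest-fragment rule; all parse and featurize to the full drug block
FIXTURE_SMILES: Tuple[Tuple[str, str], ...] = (
    ("LIG01", "CC(=O)OC1=CC=CC=C1C(=O)O"),           # aspirin
    ("LIG02", "CN1C=NC2=C1C(=O)N(C)C(=O)N2C"),       # caffeine
    ("LIG03", "CC(C)CC1=CC=C(C=C1)C(C)C(=O)O"),      # ibuprofen
    ("LIG04", "CC(=O)NC1=CC=C(O)C=C1"),              # paracetamol
    ("LIG05", "CCO"),                                # ethanol
    ("LIG06", "OCC1OC(O)C(O)C(O)C1O"),               # a pyranose sugar
    ("LIG07", "[Na+].CC(=O)[O-]"),                   # sodium acetate (salt)
    ("LIG08", "CN(C)C(=N)NC(=N)N"),                  # metformin
    ("LIG09", "NC1=CC=C(C=C1)S(N)(=O)=O"),           # sulfanilamide
    ("LIG10", "c1ccncc1"),                           # pyridine
    ("LIG11", "Oc1ccccc1"),                          # phenol
    ("LIG12", "Cc1ccccc1"),                          # toluene
    ("LIG13", "CC(C)=O"),                            # acetone
    ("LIG14", "NC(N)=O"),                            # urea
    ("LIG15", "NCC(O)=O"),                           # glycine
    ("LIG16", "c1c[nH]cn1"),                         # imidazole
    ("LIG17", "C1CCCCC1"),                           # cyclohexane
    ("LIG18", "CN1CCCC1c1cccnc1"),                   # nicotine
    ("LIG19", "OC(=O)c1ccccc1O"),                    # salicylic acid
    ("LIG20", "Cl.CCN"),                             # ethylamine HCl (salt)
)

#: AAC weights carrying the synthetic class signal (sparse, fixed).
#: The vector (A+1, N+1, G-1, Q-1) sums to zero within every group of every
#: CTD partition, so the composition-derived CTD features are uncorrelated
#: with the signal and the signal stays concentrated in the aac block.
_SIGNAL_WEIGHTS = {"A": 1.0, "N": 1.0, "G": -1.0, "Q": -1.0}


def make_graph(kind: str, n: int, seed: int = 0, p: float = 0.2) -> InteractomeGraph:
    """Build a named-topology graph with nodes ``P0001..P{n}``.

    Kinds: path, ring, star (node 1 is the center), complete, random
    (Erdos-Renyi with edge probability ``p``), two_community (two dense
    halves joined by one bridge edge).
    """
    if kind not in GRAPH_KINDS:
        raise ValueError(f"unknown graph kind {kind!r}; choose from {GRAPH_KINDS}")
    if n < 1:
        raise ValueError("n must be >= 1")
    names = [f"P{i + 1:04d}" for i in range(n)]
    g = InteractomeGraph()
    g.add_nodes_from(names)
    rng = np.random.default_rng(seed)
    if kind == "path":
        g.add_edges_from(zip(names, names[1:]))
    elif kind == "ring":
        g.add_edges_from(zip(names, names[1:]))
        if n > 2:
            g.add_edge(names[-1], names[0])
    elif kind == "star":
        g.add_edges_from((names[0], x) for x in names[1:])
    elif kind == "complete":
        g.add_edges_from(
            (names[i], names[j]) for i in range(n) for j in range(i + 1, n)
        )
    elif kind == "random":
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    g.add_edge(names[i], names[j])
    elif kind == "two_community":
        half = max(1, n // 2)
        for lo, hi in ((0, half), (half, n)):
            for i in range(lo, hi):
                for j in range(i + 1, hi):
                    if rng.random() < 0.8:
                        g.add_edge(names[i], names[j])
        if half < n:
            g.add_edge(names[0], names[half])
    return g


def write_string_links(graph: InteractomeGraph, path, score: int = 900) -> None:
    """Write the graph as a STRING ``protein.links``-dialect file.

    Edges without a stored confidence get ``score``; the file round-trips
    through ``interactome.parse_string_links``.
    """
    with open(path, "w") as handle:
        handle.write("protein1 protein2 combined_score\n")
        for u, v, data in sorted(graph.edges(data=True)):
            s = data.get("confidence", score)
            handle.write(f"{u} {v} {s}\n")


def random_protein(length: int, seed: int = 0, id: str = "SYN0001") -> ProteinSequence:
    """Uniform random sequence over the 20-residue alphabet."""
    rng = np.random.default_rng(seed)
    letters = rng.choice(list(AMINO_ACIDS), size=length)
    return ProteinSequence(id, "".join(letters))


def fixture_ligands() -> List[Tuple[str, str]]:
    """The embedded static ligand table (id, SMILES)."""
    return list(FIXTURE_SMILES)


def write_fasta(seqs: Sequence[ProteinSequence], path) -> None:
    with open(path, "w") as handle:
        for seq in seqs:
            handle.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), 60):
                handle.write(seq.residues[i:i + 60] + "\n")


def write_ligand_table(ligands: Sequence[Tuple[str, str]], path) -> None:
    with open(path, "w") as handle:
        handle.write("id\tsmiles\n")
        for lig_id, smiles in ligands:
            handle.write(f"{lig_id}\t{smiles}\n")


def _protein_scores(seqs: Sequence[ProteinSequence]) -> np.ndarray:
    """Standardized signal score per protein from its AAC features."""
    aac = np.vstack([amino_acid_composition(s) for s in seqs])
    mu = aac.mean(axis=0)
    sd = aac.std(axis=0)
    sd[sd == 0] = 1.0
    z = (aac - mu) / sd
    w = np.array([_SIGNAL_WEIGHTS.get(a, 0.0) for a in AMINO_ACIDS])
    raw = z @ w
    sd = raw.std()
    # standardize over the pool so effect_size is dimensionless (latent
    # signal sd per unit effect_size equals the logistic noise scale)
    return (raw - raw.mean()) / (sd if sd > 0 else 1.0)


def _generate_interactions(
    n_pos: int,
    n_neg: int,
    effect_size: float,
    seed: int,
    n_proteins: Optional[int] = None,
    seq_length: Tuple[int, int] = (60, 120),
):
    """Draw records + entity maps (the un-encoded form of the generator)."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    n_total = n_pos + n_neg
    rng = np.random.default_rng(seed)
    ligands = fixture_ligands()
    if n_proteins is None:
        # default: a protein pool with entity repetition across pairs, the
        # regime of real interaction corpora (the same target binds many
        # drugs).  Pass n_proteins=n_pos+n_neg for a one-protein-per-pair
        # design in which no protein feature can act as an identity
        # fingerprint and only the aac signal separates the classes.
        n_proteins = max(10, math.ceil(1.2 * n_total / len(ligands)))
    seqs = [
        random_protein(
            int(rng.integers(seq_length[0], seq_length[1] + 1)),
            seed=int(rng.integers(0, 2**31 - 1)),
            id=f"SYN{i + 1:04d}",
        )
        for i in range(n_proteins)
    ]
    seq_map = {s.id: s for s in seqs}
    ligand_map = dict(ligands)

    if n_proteins >= n_total:
        chosen = rng.choice(n_proteins, size=n_total, replace=False)
        pairs = [
            (ligands[int(rng.integers(len(ligands)))][0], seqs[int(i)].id)
            for i in chosen
        ]
    else:
        all_pairs = [(d, t.id) for t in seqs for d, _ in ligands]
        idx = rng.choice(len(all_pairs), size=n_total, replace=False)
        pairs = [all_pairs[i] for i in idx]

    scores = _protein_scores(seqs)
    score_map = dict(zip(seq_map, scores))
    noise = rng.logistic(size=n_total)
    latent = np.array(
        [effect_size * score_map[t] for _, t in pairs]
    ) + noise
    order = np.argsort(-latent)
    is_pos = np.zeros(n_total, dtype=bool)
    is_pos[order[:n_pos]] = True

    records = []
    for (drug_id, target_id), pos in zip(pairs, is_pos):
        if pos:
            bio = float(10.0 * rng.beta(2, 5))          # < 10 uM
            label = "positive"
        else:
            bio = float(10.0 * (1.0 + rng.lognormal())) # > 10 uM
            label = "negative"
        records.append(InteractionRecord(
            drug_id, target_id, label, source="synthetic",
            bioactivity=bio, measure="IC50",
        ))
    return records, seq_map, ligand_map


def synthetic_dti_dataset(
    n_pos: int,
    n_neg: int,
    effect_size: float = 4.0,
    seed: int = 0,
    n_proteins: Optional[int] = None,
    seq_length: Tuple[int, int] = (60, 120),
) -> LabeledDataset:
    """Generate a labeled DTI dataset with tunable signal.

    ``n_pos + n_neg`` unique (drug, target) pairs are drawn over random
    proteins and the embedded ligand library; the ``n_pos`` pairs with the
    highest latent score ``effect_size * protein_AAC_score + logistic
    noise`` become positives.  Records carry synthetic bioactivities
    (positives below, negatives above the 10 uM threshold) and are encoded
    through the real featurization pipeline.
    """
    records, seq_map, ligand_map = _generate_interactions(
        n_pos, n_neg, effect_size, seed, n_proteins, seq_length
    )
    return encode_dataset(records, seq_map, ligand_map)


def write_fixture_bundle(
    out_dir,
    seed: int = 0,
    graph_kind: str = "random",
    n_nodes: int = 40,
    n_pos: int = 60,
    n_neg: int = 90,
    effect_size: float = 4.0,
) -> Dict[str, str]:
    """Emit a complete fixture bundle (graph, FASTA, ligand TSV,
    interaction TSV) to a directory; returns the path map."""
    import os

    from .datasets import write_interactions

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "graph": os.path.join(out_dir, "interactome.links.txt"),
        "fasta": os.path.join(out_dir, "proteins.fasta"),
        "ligands": os.path.join(out_dir, "ligands.tsv"),
        "interactions": os.path.join(out_dir, "interactions.tsv"),
    }
    records, seq_map, _ = _generate_interactions(n_pos, n_neg, effect_size, seed)
    # the interactome is built over the same proteins the DTI records use,
    # so a shortlist derived from it is screenable against the FASTA
    protein_ids = sorted(seq_map)
    graph = make_graph(graph_kind, min(n_nodes, len(protein_ids)), seed=seed)
    import networkx as nx

    mapping = dict(zip(sorted(graph.nodes), protein_ids))
    relabeled = InteractomeGraph()
    relabeled.add_nodes_from(mapping[n] for n in graph.nodes)
    relabeled.add_edges_from(
        (mapping[u], mapping[v], d) for u, v, d in graph.edges(data=True)
    )
    write_string_links(relabeled, paths["graph"])
    write_fasta(list(seq_map.values()), paths["fasta"])
    write_ligand_table(fixture_ligands(), paths["ligands"])
    write_interactions(records, paths["interactions"])
    return paths
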