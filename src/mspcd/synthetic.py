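"""Synthetic circRNA-disease datasets with planted cluster structure.

The generator emulates the statistical structure the prediction method
assumes: circRNAs with similar functions associate with similar
diseases.  CircRNAs and diseases are partitioned into paired blocks;
associations are dense within a paired block and sparse across blocks;
each circRNA block descends from one ancestor nucleotide sequence by
point mutation (so within-block sequence similarity exceeds
between-block similarity); GO-term and miRNA annotations are drawn
mostly from a per-block pool; and the disease vocabulary DAG is a tree
whose subtrees group same-block diseases.  Stated fractions of circRNAs
lack sequences and of diseases sit outside the DAG, exercising the
flag-gated fusion fallbacks.  Everything is a deterministic function of
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .dataio import (
    AssociationMatrix,
    DiseaseDAG,
    SequenceSet,
    write_association_table,
    write_dag,
    write_fasta,
)
from .errors import ParameterError

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_dataset",
           "generate_worked_example", "write_dataset"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Sizes, block structure and noise levels of a generated dataset.

    The defaults give a desk-scale problem (300 circRNAs x 40 diseases,
    6 paired blocks) that a full pipeline run handles in minutes while
    leaving enough signal for the network to recover the planted
    structure.  p_in / p_out are the within-/cross-block association
    probabilities; mutation_rate is the per-base substitution rate of
    block members relative to their ancestor sequence.
    """

    n_circ: int = 300
    n_disease: int = 40
    n_blocks: int = 6
    p_in: float = 0.30
    p_out: float = 0.01
    seq_len: int = 100
    mutation_rate: float = 0.05
    n_go: int = 120
    n_mirna: int = 80
    annotations_per_entity: int = 5
    frac_no_sequence: float = 0.1
    frac_no_dag: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_in", "p_out", "mutation_rate", "frac_no_sequence", "frac_no_dag"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.p_out >= self.p_in:
            raise ParameterError("p_out must be smaller than p_in")
        if self.n_circ < self.n_blocks or self.n_disease < self.n_blocks:
            raise ParameterError("each block needs at least one circRNA and one disease")


class SyntheticDataset(NamedTuple):
    Sd: AssociationMatrix
    sequences: SequenceSet
    Sg: AssociationMatrix
    Sm: AssociationMatrix
    dag: DiseaseDAG
    circ_blocks: np.ndarray
    disease_blocks: np.ndarray


def _block_labels(n: int, n_blocks: int) -> np.ndarray:
    """Contiguous, nearly equal-sized block assignment."""
    return np.sort(np.arange(n) % n_blocks)


def _mutate(rng: np.random.Generator, ancestor: np.ndarray, rate: float) -> str:
    seq = ancestor.copy()
    hit = rng.random(seq.shape[0]) < rate
    if hit.any():
        # substitute with a uniformly chosen *different* base
        shifts = rng.integers(1, 4, size=int(hit.sum()))
        idx = np.flatnonzero(hit)
        codes = np.searchsorted(_BASES, seq[idx])
        seq[idx] = _BASES[(codes + shifts) % 4]
    return "".join(seq)


def _annotations(
    rng: np.random.Generator,
    blocks: np.ndarray,
    n_vocab: int,
    n_blocks: int,
    per_entity: int,
    pool_prob: float = 0.8,
) -> np.ndarray:
    """Binary annotation matrix: each entity draws annotations from its
    block's slice of the vocabulary with probability *pool_prob*, from
    the full vocabulary otherwise."""
    vocab_blocks = np.arange(n_vocab) % n_blocks
    out = np.zeros((blocks.shape[0], n_vocab), dtype=np.int8)
    for i, b in enumerate(blocks):
        pool = np.flatnonzero(vocab_blocks == b)
        for _ in range(per_entity):
            if pool.size and rng.random() < pool_prob:
                term = pool[rng.integers(pool.size)]
            else:
                term = rng.integers(n_vocab)
            out[i, term] = 1
    return out


def generate_dataset(config: SyntheticConfig = SyntheticConfig()) -> SyntheticDataset:
    """Draw a complete dataset (associations, sequences, GO/miRNA
    annotations, disease DAG) from the planted-block model."""
    rng = np.random.default_rng(config.seed)
    circ_ids = [f"circ_{i:04d}" for i in range(config.n_circ)]
    dis_ids = [f"disease_{j:03d}" for j in range(config.n_disease)]
    cb = _block_labels(config.n_circ, config.n_blocks)
    db = _block_labels(config.n_disease, config.n_blocks)

    same = cb[:, None] == db[None, :]
    prob = np.where(same, config.p_in, config.p_out)
    values = (rng.random(prob.shape) < prob).astype(np.int8)
    if values.sum() == 0:  # tiny configs can come up empty; plant one edge
        values[0, int(np.flatnonzero(db == cb[0])[0])] = 1
    Sd = AssociationMatrix(values, circ_ids, dis_ids)

    ancestors = rng.choice(_BASES, size=(config.n_blocks, config.seq_len))
    n_noseq = int(round(config.frac_no_sequence * config.n_circ))
    no_seq = set(rng.choice(config.n_circ, size=n_noseq, replace=False).tolist())
    sequences = {
        circ_ids[i]: _mutate(rng, ancestors[cb[i]], config.mutation_rate)
        for i in range(config.n_circ)
        if i not in no_seq
    }

    Sg = AssociationMatrix(
        _annotations(rng, cb, config.n_go, config.n_blocks, config.annotations_per_entity),
        circ_ids,
        [f"GO_{t:04d}" for t in range(config.n_go)],
    )
    Sm = AssociationMatrix(
        _annotations(rng, cb, config.n_mirna, config.n_blocks, config.annotations_per_entity),
        circ_ids,
        [f"mir_{t:03d}" for t in range(config.n_mirna)],
    )

    n_nodag = int(round(config.frac_no_dag * config.n_disease))
    no_dag = set(rng.choice(config.n_disease, size=n_nodag, replace=False).tolist())
    edges: list[tuple[str, str]] = []
    root = "mesh_root"
    for b in range(config.n_blocks):
        group = f"mesh_group_{b}"
        edges.append((root, group))
        attached: list[str] = []
        for j in np.flatnonzero(db == b):
            if j in no_dag:
                continue
            # attach under the group term or chain under an earlier
            # same-block disease, giving subtrees of varying depth
            if attached and rng.random() < 0.5:
                parent = attached[rng.integers(len(attached))]
            else:
                parent = group
            edges.append((parent, dis_ids[j]))
            attached.append(dis_ids[j])
    dag = DiseaseDAG.from_edges(edges)
    return SyntheticDataset(Sd, SequenceSet(sequences), Sg, Sm, dag, cb, db)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Write all artifacts in the standard on-disk formats; returns the
    path of each file keyed by artifact name."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "associations": str(outdir / "associations.tsv"),
        "sequences": str(outdir / "sequences.fasta"),
        "go": str(outdir / "circ_go.tsv"),
        "mirna": str(outdir / "circ_mirna.tsv"),
        "dag": str(outdir / "disease_dag.tsv"),
    }
    write_association_table(ds.Sd, paths["associations"])
    write_fasta(ds.sequences, paths["sequences"])
    write_association_table(ds.Sg, paths["go"])
    write_association_table(ds.Sm, paths["mirna"])
    write_dag(ds.dag, paths["dag"])
    return paths


def generate_worked_example() -> SyntheticDataset:
    """A fixed miniature dataset (5 circRNAs x 4 diseases) whose base and
    fused similarities are small enough to verify by hand; used by the
    documentation and the golden-value tests."""
    circ_ids = ["c1", "c2", "c3", "c4", "c5"]
    dis_ids = ["d1", "d2", "d3", "d4"]
    Sd = AssociationMatrix(
        np.array(
            [
                [1, 1, 0, 0],
                [1, 0, 0, 0],
                [0, 1, 1, 0],
                [0, 0, 0, 1],
                [0, 0, 1, 1],
            ]
        ),
        circ_ids,
        dis_ids,
    )
    sequences = SequenceSet(
        {"c1": "ACGT", "c2": "ACGT", "c3": "AGGT", "c4": "ACG"}  # c5 has no sequence
    )
    Sg = AssociationMatrix(
        np.array([[1, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [0, 1, 1]]),
        circ_ids,
        ["g1", "g2", "g3"],
    )
    Sm = AssociationMatrix(
        np.array([[1, 0], [1, 1], [0, 1], [1, 0], [0, 1]]),
        circ_ids,
        ["m1", "m2"],
    )
    # d4 is deliberately outside the DAG
    dag = DiseaseDAG.from_edges([("r", "d1"), ("r", "d2"), ("d2", "d3")])
    cb = np.array([0, 0, 0, 1, 1])
    db = np.array([0, 0, 1, 1])
    return SyntheticDataset(Sd, sequences, Sg, Sm, dag, cb, db)
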