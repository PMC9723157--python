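"""Synthetic-data generators with known ground truth.

Everything the pipeline consumes can be generated here: gene trees drawn
from the multispecies coalescent (MSC) on a known species tree, DNA
alignments evolved along those gene trees under JC69, orthogroup membership
tables with a planted single-copy fraction, and reads with planted
low-quality ends. All generators are deterministic under a fixed seed.

The MSC branch lengths are in coalescent units (2N generations = 1 unit, the
ASTRAL convention), which makes the closed-form quartet concordance
probability 1 - (2/3)e^(-T) for an internal branch of length T an exact
oracle. A substitution scale factor mu converts gene trees to substitution
units for sequence simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .trees import Node, Tree


# ---------------------------------------------------------------------------
# models and configuration
# ---------------------------------------------------------------------------


@dataclass
class SpeciesTreeModel:
    """Rooted binary species tree with branch lengths in coalescent units,
    plus a substitution scale ``mu`` (substitutions per coalescent unit).

    The tree must be ultrametric in coalescent units: the global-clock
    coalescent below is otherwise ill-defined.
    """

    tree: Tree
    mu: float = 1.0

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        for nd in self.tree.root.postorder():
            if not nd.is_leaf and len(nd.children) != 2:
                raise ValueError("species tree must be strictly binary (rooted)")
            if nd is not self.tree.root and nd.length is None:
                raise ValueError("species tree needs branch lengths on all edges")
        self._ages = _node_ages(self.tree)

    @property
    def ages(self) -> dict:
        return self._ages


def _node_ages(tree: Tree, tol: float = 1e-6) -> dict:
    ages: dict = {}
    for nd in tree.root.postorder():
        if nd.is_leaf:
            ages[id(nd)] = 0.0
        else:
            cand = [ages[id(c)] + c.length for c in nd.children]
            if max(cand) - min(cand) > tol * max(1.0, max(cand)):
                raise ValueError(
                    "species tree must be ultrametric in coalescent units "
                    f"(node ages from children disagree: {cand})"
                )
            ages[id(nd)] = float(np.mean(cand))
    return ages


@dataclass
class RogueSpec:
    """Plant aberrantly long terminal branches: in ``fraction`` of genes,
    taxon's terminal branch is multiplied by ``multiplier``."""

    taxon: str
    fraction: float
    multiplier: float = 20.0

    def __post_init__(self):
        if not 0 <= self.fraction <= 1:
            raise ValueError("fraction must be in [0, 1]")
        if self.multiplier <= 1:
            raise ValueError("multiplier must exceed 1")


@dataclass
class SimulationConfig:
    """Knobs for a gene-tree simulation run. A seed is mandatory: every
    stochastic operation in this module is reproducible."""

    n_genes: int
    seed: int
    p_miss: float = 0.0
    rogues: Sequence[RogueSpec] = field(default_factory=tuple)

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not 0 <= self.p_miss < 1:
            raise ValueError("p_miss must be in [0, 1)")


# ---------------------------------------------------------------------------
# multispecies coalescent
# ---------------------------------------------------------------------------


def _coalesce_in_interval(lineages, t0, t1, rng):
    """Standard coalescent among ``lineages`` (list of (Node, time)) between
    global times t0 and t1 (t1 may be inf); rate k(k-1)/2 per unit."""
    t = t0
    lineages = list(lineages)
    while len(lineages) > 1:
        k = len(lineages)
        t = t + rng.exponential(2.0 / (k * (k - 1)))
        if t > t1:
            break
        i, j = rng.choice(k, size=2, replace=False)
        (na, ta), (nb, tb) = lineages[i], lineages[j]
        parent = Node()
        parent.add_child(na)
        parent.add_child(nb)
        na.length = t - ta
        nb.length = t - tb
        lineages = [lineages[m] for m in range(k) if m not in (i, j)]
        lineages.append((parent, t))
    return lineages


def _simulate_one_gene_tree(model: SpeciesTreeModel, rng) -> Tree:
    ages = model.ages
    pending: dict = {}
    for nd in model.tree.root.postorder():
        if nd.is_leaf:
            lineages = [(Node(label=nd.label), 0.0)]
        else:
            lineages = []
            for c in nd.children:
                lineages.extend(pending.pop(id(c)))
        t0 = ages[id(nd)]
        t1 = np.inf if nd is model.tree.root else t0 + nd.length
        pending[id(nd)] = _coalesce_in_interval(lineages, t0, t1, rng)
    (root, _), = pending[id(model.tree.root)]
    return Tree(root)


def simulate_msc_gene_trees(
    model: SpeciesTreeModel,
    config: SimulationConfig,
    units: str = "coalescent",
) -> list:
    """Draw ``config.n_genes`` gene trees from the MSC on ``model``.

    One lineage is sampled per species tip (matching one transcriptome per
    taxon). Within every species-tree branch of length T, the k lineages
    entering from below coalesce with exponential waiting times at rate
    k(k-1)/2 per coalescent unit; survivors pass upward; above the root
    coalescence continues to a single lineage.

    Per-gene taxon dropout is applied independently with probability
    ``config.p_miss``; a draw that would leave fewer than two leaves is
    redrawn. ``units='substitution'`` multiplies branch lengths by mu.
    Rogue injection is a separate step (:func:`inject_rogues`).
    """
    if units not in ("coalescent", "substitution"):
        raise ValueError(f"unknown units {units!r}")
    rng = np.random.default_rng(config.seed)
    taxa = sorted(model.tree.leaf_labels)
    out = []
    for _ in range(config.n_genes):
        gt = _simulate_one_gene_tree(model, rng)
        if config.p_miss > 0:
            while True:
                drop = [t for t in taxa if rng.random() < config.p_miss]
                if len(taxa) - len(drop) >= 2:
                    break
            if drop:
                gt = gt.prune(drop)
        if units == "substitution":
            gt = gt.scaled(model.mu)
        out.append(gt)
    return out


def inject_rogues(
    gene_trees: Sequence[Tree],
    rogues: Sequence[RogueSpec],
    seed: int,
):
    """Multiply planted taxa's terminal branches in a random subset of genes.

    Returns ``(new_trees, truth)`` where truth is a list of
    ``(gene_index, taxon)`` pairs actually planted.
    """
    rng = np.random.default_rng(seed)
    trees = [t.copy() for t in gene_trees]
    truth = []
    for spec in rogues:
        present = [
            i for i, t in enumerate(trees) if spec.taxon in t.leaf_labels
        ]
        k = int(round(spec.fraction * len(present)))
        chosen = rng.choice(len(present), size=k, replace=False) if k else []
        for ci in sorted(int(c) for c in np.asarray(chosen)):
            gi = present[ci]
            for leaf in trees[gi].leaves():
                if leaf.label == spec.taxon:
                    leaf.length = (leaf.length or 0.0) * spec.multiplier
            truth.append((gi, spec.taxon))
    return trees, truth


# ---------------------------------------------------------------------------
# sequence simulation (JC69)
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_jc_alignment(gene: Tree, n_sites: int, seed: int):
    """Evolve an alignment along ``gene`` under JC69.

    The root sequence is uniform over {A,C,G,T}; along a branch of length d
    (substitution units) each site differs from its parent with probability
    (3/4)(1 - e^(-4d/3)), the JC69 closed form; a substituted site takes one
    of the three other bases uniformly.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    leaves = gene.leaves()
    if not leaves:
        raise ValueError("gene tree has no leaves")
    rng = np.random.default_rng(seed)
    states = {id(gene.root): rng.integers(0, 4, size=n_sites, dtype=np.uint8)}
    taxa, seqs = [], []
    for nd in gene.root.preorder():
        if nd is gene.root:
            pass
        else:
            d = nd.length
            if d is None or d < 0 or not np.isfinite(d):
                raise ValueError("gene tree needs finite non-negative lengths")
            p = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
            parent_state = states[id(nd.parent)]
            mutate = rng.random(n_sites) < p
            child = parent_state.copy()
            if mutate.any():
                shift = rng.integers(1, 4, size=int(mutate.sum()), dtype=np.uint8)
                child[mutate] = (child[mutate] + shift) % 4
            states[id(nd)] = child
        if nd.is_leaf:
            taxa.append(nd.label)
            seqs.append(_BASES[states[id(nd)]].tobytes().decode("ascii"))
    from .alignments import Alignment

    order = np.argsort(taxa)
    return Alignment([taxa[i] for i in order], [seqs[i] for i in order])


# ---------------------------------------------------------------------------
# orthogroup tables
# ---------------------------------------------------------------------------


def generate_orthogroup_table(
    n_orthogroups: int,
    genomes: Sequence[str],
    single_copy_fraction: float,
    copy_dist: Optional[Callable] = None,
    seed: int = 0,
):
    """Build a (gene_id, genome_id, orthogroup_id) table with a planted
    fraction of strictly single-copy orthogroups.

    ``copy_dist(rng, size)`` draws per-genome copy counts for non-planted
    orthogroups (default: Poisson(1.2)); an all-ones draw is rejected so the
    planted set is exactly the single-copy ground truth.

    Returns ``(DataFrame, planted_set)``.
    """
    genomes = list(genomes)
    if not genomes:
        raise ValueError("genome list must be non-empty")
    if not 0 <= single_copy_fraction <= 1:
        raise ValueError("single_copy_fraction must be in [0, 1]")
    if copy_dist is None:
        copy_dist = lambda rng, size: rng.poisson(1.2, size=size)
    rng = np.random.default_rng(seed)
    n_planted = int(round(single_copy_fraction * n_orthogroups))
    records = []
    planted = set()
    counter = 0
    for og_idx in range(n_orthogroups):
        og = f"OG{og_idx + 1:05d}"
        if og_idx < n_planted:
            counts = np.ones(len(genomes), dtype=int)
            planted.add(og)
        else:
            while True:
                counts = np.asarray(copy_dist(rng, len(genomes)), dtype=int)
                if (counts < 0).any():
                    raise ValueError("copy_dist produced negative counts")
                if not (counts == 1).all():
                    break
        for genome, c in zip(genomes, counts):
            for _ in range(int(c)):
                counter += 1
                records.append((f"{genome}_g{counter:06d}", genome, og))
    table = pd.DataFrame(records, columns=["gene_id", "genome_id", "orthogroup_id"])
    return table, frozenset(planted)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


@dataclass
class Read:
    id: str
    bases: str
    quals: list

    def __post_init__(self):
        if len(self.bases) != len(self.quals):
            raise ValueError(f"read {self.id}: bases and scores differ in length")


@dataclass
class ReadSet:
    reads: list

    def __len__(self):
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def to_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                qual = "".join(chr(q + 33) for q in r.quals)
                fh.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")

    @classmethod
    def from_fastq(cls, path) -> "ReadSet":
        from Bio import SeqIO

        reads = []
        for rec in SeqIO.parse(str(path), "fastq"):
            reads.append(
                Read(
                    rec.id,
                    str(rec.seq),
                    list(rec.letter_annotations["phred_quality"]),
                )
            )
        return cls(reads)


def generate_reads(
    n_reads: int,
    length: int,
    quality_range=(30, 41),
    planted_bad_ends: float = 0.0,
    seed: int = 0,
):
    """Simulate reads with uniformly high base qualities, planting a terminal
    run of three sub-Q20 bases in a fraction of them.

    Returns ``(ReadSet, truth)`` where truth lists ``(read_id, end)`` with
    end in {'5p', '3p'} for every planted defect.
    """
    if length < 1:
        raise ValueError("read length must be >= 1")
    if not 0 <= planted_bad_ends <= 1:
        raise ValueError("planted_bad_ends must be in [0, 1]")
    lo, hi = quality_range
    if not (0 <= lo <= hi <= 41):
        raise ValueError("quality_range must lie within Phred 0..41")
    rng = np.random.default_rng(seed)
    n_planted = int(round(planted_bad_ends * n_reads))
    planted_idx = set(
        int(i) for i in rng.choice(n_reads, size=n_planted, replace=False)
    ) if n_planted else set()
    reads, truth = [], []
    for i in range(n_reads):
        bases = _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
        quals = rng.integers(lo, hi + 1, size=length).tolist()
        rid = f"read{i + 1:06d}"
        if i in planted_idx and length >= 3:
            end = "3p" if rng.random() < 0.5 else "5p"
            bad = rng.integers(2, 20, size=3).tolist()
            if end == "3p":
                quals[-3:] = bad
            else:
                quals[:3] = bad
            truth.append((rid, end))
        reads.append(Read(rid, bases, quals))
    return ReadSet(reads), truth
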