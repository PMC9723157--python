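"""Per-branch gene and site concordance/discordance factors, the chi-square
test of equal support for the two nearest-neighbour alternatives (the ILS
null), quartet frequencies and the quartet-based polytomy test.

Definitions. For an internal branch of a binary reference tree with
surrounding taxon blocks (A, B, C, D) and reference resolution AB|CD:

* gCF — percentage of *decisive* gene trees (those sampling all four blocks)
  containing the branch; gDF1/gDF2 — percentages supporting the two
  nearest-neighbour alternatives AC|BD and AD|BC; gDFP — all remaining
  (paraphyletic/unresolved) discordance. gCF+gDF1+gDF2+gDFP = 100 exactly.
* sCF — mean (over sampled quartets a∈A, b∈B, c∈C, d∈D) percentage of
  decisive sites supporting ab|cd; a site is decisive for a quartet iff all
  four taxa carry unambiguous bases and the pattern has exactly two states,
  each twice. sCF+sDF1+sDF2 = 100 per quartet and in the mean.
* gEF/sEF — chi-square test (1 df) of equal support for the two alternatives;
  failure to reject is the pattern expected under incomplete lineage sorting.

Branches with no decisive gene trees/sites report null factors, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .alignments import Alignment
from .trees import (
    Branch,
    GeneTreeCategory,
    Quadripartition,
    Tree,
    classify_gene_tree,
    reference_branches,
)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class EqualityTest:
    chi2: float
    p: float


def equality_test(n1: int, n2: int) -> Optional[EqualityTest]:
    """Chi-square test of H0: equal support for the two nearest-neighbour
    alternatives. chi2 = (n1-n2)^2/(n1+n2), upper tail at 1 df.

    Returns None (undefined, flagged by the caller) when both counts are 0.
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be non-negative")
    if n1 + n2 == 0:
        return None
    chi2 = (n1 - n2) ** 2 / (n1 + n2)
    return EqualityTest(chi2=float(chi2), p=float(stats.chi2.sf(chi2, df=1)))


@dataclass
class BranchConcordance:
    """Per-branch record. Percentage fields are None when the branch has no
    decisive gene trees (gene fields) or no decisive sites (site fields)."""

    branch_id: str
    split: frozenset
    length: Optional[float] = None
    # gene fields
    gcf: Optional[float] = None
    gdf1: Optional[float] = None
    gdf2: Optional[float] = None
    gdfp: Optional[float] = None
    gn: int = 0
    n_concordant: int = 0
    n_df1: int = 0
    n_df2: int = 0
    n_paraphyletic: int = 0
    gef: Optional[EqualityTest] = None
    # site fields
    scf: Optional[float] = None
    sdf1: Optional[float] = None
    sdf2: Optional[float] = None
    sn: Optional[float] = None
    sef: Optional[EqualityTest] = None

    @property
    def gef_p(self) -> Optional[float]:
        return self.gef.p if self.gef else None

    @property
    def sef_p(self) -> Optional[float]:
        return self.sef.p if self.sef else None


@dataclass
class QuartetFrequencies:
    """Relative frequencies of the three resolutions around a branch among
    gene trees resolving one of them (paraphyletic and non-decisive trees are
    excluded from the denominator)."""

    q_main: Optional[float]
    q_alt1: Optional[float]
    q_alt2: Optional[float]
    n_decisive: int
    counts: tuple = (0, 0, 0)

    @classmethod
    def from_counts(cls, n_main: int, n_alt1: int, n_alt2: int) -> "QuartetFrequencies":
        n = n_main + n_alt1 + n_alt2
        if n == 0:
            return cls(None, None, None, 0, (0, 0, 0))
        return cls(
            n_main / n, n_alt1 / n, n_alt2 / n, n, (n_main, n_alt1, n_alt2)
        )


@dataclass
class PolytomyTestResult:
    chi2: float
    df: int
    p: float

    def rejects(self, alpha: float = 0.05) -> bool:
        return self.p < alpha


# ---------------------------------------------------------------------------
# gene concordance factors
# ---------------------------------------------------------------------------


def _check_reference(reference: Tree) -> None:
    poly = reference.polytomies()
    if poly or len(reference.root.children) > 3:
        labels = [sorted(_clade_labels(nd))[:3] for nd in poly]
        raise ValueError(
            f"reference tree must be binary; polytomous nodes above: {labels}"
        )


def _clade_labels(nd):
    out = set()
    stack = [nd]
    while stack:
        cur = stack.pop()
        if cur.is_leaf:
            out.add(cur.label)
        else:
            stack.extend(cur.children)
    return out


def _classify_all(reference, gene_trees, allow_polytomies=False):
    if not allow_polytomies:
        _check_reference(reference)
    branches = reference_branches(reference, strict=not allow_polytomies)
    universe = reference.leaf_labels
    gene_info = []
    for gt in gene_trees:
        unknown = gt.leaf_labels - universe
        if unknown:
            raise ValueError(
                f"gene-tree labels outside reference taxa: {sorted(unknown)}"
            )
        gene_info.append((gt, gt.split_sides()))
    table = {}
    for br in branches:
        counts = {cat: 0 for cat in GeneTreeCategory}
        for gt, sides in gene_info:
            cat = classify_gene_tree(gt, br.quadripartition, _sides=sides)
            counts[cat] += 1
        table[br] = counts
    return branches, table


def gene_concordance_factors(
    reference: Tree,
    gene_trees: Sequence[Tree],
    allow_polytomies: bool = False,
) -> list:
    """Per-branch gene concordance/discordance factors plus the gEF equality
    test on the two alternative-resolution gene counts.

    The reference must be binary (``allow_polytomies=True`` instead skips
    branches without a quadripartition). Gene trees may be incomplete and/or
    polytomous; each contributes only to branches it is decisive for.
    """
    branches, table = _classify_all(reference, gene_trees, allow_polytomies)
    out = []
    for br in branches:
        c = table[br]
        gn = sum(v for k, v in c.items() if k != GeneTreeCategory.NOT_DECISIVE)
        rec = BranchConcordance(
            branch_id=br.branch_id,
            split=br.split,
            length=br.length,
            gn=gn,
            n_concordant=c[GeneTreeCategory.CONCORDANT],
            n_df1=c[GeneTreeCategory.DF1],
            n_df2=c[GeneTreeCategory.DF2],
            n_paraphyletic=c[GeneTreeCategory.PARAPHYLY],
        )
        if gn > 0:
            rec.gcf = 100.0 * rec.n_concordant / gn
            rec.gdf1 = 100.0 * rec.n_df1 / gn
            rec.gdf2 = 100.0 * rec.n_df2 / gn
            rec.gdfp = 100.0 * rec.n_paraphyletic / gn
            rec.gef = equality_test(rec.n_df1, rec.n_df2)
        out.append(rec)
    return out


def quartet_frequencies(
    reference: Tree,
    split,
    gene_trees: Sequence[Tree],
) -> QuartetFrequencies:
    """Relative frequencies of the three resolutions of one branch
    (identified by ``split``, a leaf-label set on one side) among gene trees
    that resolve the surrounding quadripartition one way or another."""
    from .trees import quadripartition as _quad

    q = _quad(reference, split)
    counts = {cat: 0 for cat in GeneTreeCategory}
    for gt in gene_trees:
        counts[classify_gene_tree(gt, q)] += 1
    return QuartetFrequencies.from_counts(
        counts[GeneTreeCategory.CONCORDANT],
        counts[GeneTreeCategory.DF1],
        counts[GeneTreeCategory.DF2],
    )


def quartet_topology_frequencies(
    reference: Tree,
    split,
    gene_trees: Sequence[Tree],
) -> QuartetFrequencies:
    """Quartet-based frequencies of the three resolutions around a branch.

    Every quartet (a, b, c, d) with one taxon per surrounding block is
    enumerated; for each gene tree sampling all four taxa, the induced
    quartet topology (always resolved in a binary gene tree; unresolved
    quartets from polytomies are skipped) is tallied. This is the
    ASTRAL-style normalized quartet frequency, and under the multispecies
    coalescent its expectation for the main resolution is exactly
    1 - (2/3)e^(-T) for a branch of length T coalescent units.
    """
    from .trees import quadripartition as _quad

    q = _quad(reference, split)
    blocks = [sorted(q.a), sorted(q.b), sorted(q.c), sorted(q.d)]
    counts = [0, 0, 0]
    for gt in gene_trees:
        leaves = gt.leaf_labels
        sides = gt.split_sides()
        for a in blocks[0]:
            if a not in leaves:
                continue
            for b in blocks[1]:
                if b not in leaves:
                    continue
                for c in blocks[2]:
                    if c not in leaves:
                        continue
                    for d in blocks[3]:
                        if d not in leaves:
                            continue
                        topo = _quartet_topology(sides, a, b, c, d)
                        if topo is not None:
                            counts[topo] += 1
    return QuartetFrequencies.from_counts(*counts)


def _quartet_topology(sides, a, b, c, d) -> Optional[int]:
    """Induced topology of a leaf quartet from a gene tree's split sides:
    0 = ab|cd, 1 = ac|bd, 2 = ad|bc, None = unresolved."""
    for side in sides:
        ina, inb, inc, ind = a in side, b in side, c in side, d in side
        if ina + inb + inc + ind != 2:
            continue
        if ina and inb:
            return 0
        if ina and inc:
            return 1
        if ina and ind:
            return 2
        if inc and ind:
            return 0
        if inb and ind:
            return 1
        if inb and inc:
            return 2
    return None


def polytomy_test(freq: QuartetFrequencies) -> PolytomyTestResult:
    """Chi-square test (2 df) of the hard-polytomy null that the three
    resolutions around a branch are equally frequent among resolving gene
    trees (the quartet-based polytomy test)."""
    if freq.n_decisive < 1:
        raise ValueError("polytomy test undefined without resolving gene trees")
    obs = np.asarray(freq.counts, dtype=float)
    n = obs.sum()
    exp = n / 3.0
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return PolytomyTestResult(chi2=chi2, df=2, p=float(stats.chi2.sf(chi2, df=2)))


# ---------------------------------------------------------------------------
# site concordance factors
# ---------------------------------------------------------------------------


def _quartet_site_counts(codes: np.ndarray, ia, ib, ic, id_) -> tuple:
    """(n_main, n_df1, n_df2) decisive-site counts for one quartet of row
    indices into the coded supermatrix."""
    a, b, c, d = codes[ia], codes[ib], codes[ic], codes[id_]
    ok = (a < 4) & (b < 4) & (c < 4) & (d < 4)
    main = ok & (a == b) & (c == d) & (a != c)
    df1 = ok & (a == c) & (b == d) & (a != b)
    df2 = ok & (a == d) & (b == c) & (a != b)
    return int(main.sum()), int(df1.sum()), int(df2.sum())


def site_concordance_factors(
    reference: Tree,
    supermatrix: Alignment,
    n_quartets: int = 1000,
    seed: Optional[int] = None,
    exhaustive: bool = False,
    allow_polytomies: bool = False,
) -> list:
    """Per-branch site concordance/discordance factors.

    For each internal branch, ``n_quartets`` quartets (one taxon per
    surrounding block, uniform with replacement) are sampled from the
    supermatrix; per quartet the decisive sites are tallied into the three
    resolutions; sCF/sDF1/sDF2 are means over quartets with at least one
    decisive site and sN is the mean decisive-site count over those same
    quartets. The sEF equality test pools the two alternatives' decisive-site
    counts across sampled quartets. ``exhaustive=True`` enumerates every
    quartet once instead of sampling. Branches with a block absent from the
    supermatrix, or with no decisive sites anywhere, are reported undefined.
    """
    if n_quartets < 1:
        raise ValueError("n_quartets must be >= 1")
    if not allow_polytomies:
        _check_reference(reference)
    branches = reference_branches(reference, strict=not allow_polytomies)
    rng = np.random.default_rng(seed)
    codes = supermatrix.codes()
    index = {t: i for i, t in enumerate(supermatrix.taxa)}
    out = []
    for br in branches:
        q = br.quadripartition
        rec = BranchConcordance(
            branch_id=br.branch_id, split=br.split, length=br.length
        )
        blocks = []
        missing_block = False
        for block in (q.a, q.b, q.c, q.d):
            idx = [index[t] for t in sorted(block) if t in index]
            if not idx:
                missing_block = True
                break
            blocks.append(np.asarray(idx))
        if missing_block:
            out.append(rec)
            continue

        if exhaustive:
            quartets = [
                (ia, ib, ic, id_)
                for ia in blocks[0]
                for ib in blocks[1]
                for ic in blocks[2]
                for id_ in blocks[3]
            ]
            weights = [1] * len(quartets)
        else:
            draws = np.stack(
                [blk[rng.integers(0, len(blk), size=n_quartets)] for blk in blocks],
                axis=1,
            )
            uniq, cnt = np.unique(draws, axis=0, return_counts=True)
            quartets = [tuple(row) for row in uniq]
            weights = cnt.tolist()

        fracs, ns, wts = [], [], []
        tot_df1 = tot_df2 = 0
        for (ia, ib, ic, id_), w in zip(quartets, weights):
            n_main, n_df1, n_df2 = _quartet_site_counts(codes, ia, ib, ic, id_)
            n_dec = n_main + n_df1 + n_df2
            tot_df1 += w * n_df1
            tot_df2 += w * n_df2
            if n_dec == 0:
                continue
            fracs.append((n_main / n_dec, n_df1 / n_dec, n_df2 / n_dec))
            ns.append(n_dec)
            wts.append(w)
        if fracs:
            arr = np.asarray(fracs)
            w = np.asarray(wts, dtype=float)
            w /= w.sum()
            rec.scf = float(100.0 * (arr[:, 0] * w).sum())
            rec.sdf1 = float(100.0 * (arr[:, 1] * w).sum())
            rec.sdf2 = float(100.0 * (arr[:, 2] * w).sum())
            rec.sn = float((np.asarray(ns, dtype=float) * w).sum())
            rec.sef = equality_test(tot_df1, tot_df2)
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def concordance_table(
    reference: Tree,
    gene_trees: Sequence[Tree],
    supermatrix: Optional[Alignment] = None,
    n_quartets: int = 1000,
    seed: Optional[int] = None,
    allow_polytomies: bool = False,
) -> list:
    """Gene factors for every internal branch, merged with site factors when
    a supermatrix is supplied. Returns a list of BranchConcordance."""
    gene = gene_concordance_factors(reference, gene_trees, allow_polytomies)
    if supermatrix is None:
        return gene
    site = site_concordance_factors(
        reference,
        supermatrix,
        n_quartets=n_quartets,
        seed=seed,
        allow_polytomies=allow_polytomies,
    )
    by_split = {rec.split: rec for rec in site}
    for rec in gene:
        s = by_split.get(rec.split)
        if s is not None:
            rec.scf, rec.sdf1, rec.sdf2, rec.sn, rec.sef = (
                s.scf,
                s.sdf1,
                s.sdf2,
                s.sn,
                s.sef,
            )
    return gene
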