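"""Data-curation filters: read QC, isoform abundance filtering, consensus
scaffolding, iterative alignment occupancy trimming, rogue-taxon filtering
and gene-tree completeness filtering.

Defaults throughout are the curation thresholds the pipeline was designed
around: Q20 three-base end trimming, median-Q22 / >3-N / <40 bp read
discards, 1% FPKM isoform retention, 95% scaffold identity, 90% alignment
occupancy with at most 10 trim/realign iterations, and per-species rogue
detection on long terminal branches.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .alignments import Alignment
from .simulate import Read, ReadSet
from .trees import Tree


# ---------------------------------------------------------------------------
# read quality filtering
# ---------------------------------------------------------------------------


@dataclass
class ReadFilterParams:
    window: int = 3
    q_low: int = 20
    median_min: int = 22
    max_uncalled: int = 3
    min_length: int = 40

    def __post_init__(self):
        if min(self.window, self.median_min, self.min_length) < 1:
            raise ValueError("window, median_min and min_length must be positive")
        if not (0 <= self.q_low <= 60 and 0 <= self.median_min <= 60):
            raise ValueError("quality thresholds outside Phred range")


def _trim_low_quality_ends(quals: Sequence[int], window: int, q_low: int):
    """Return (start, end) of the retained slice.

    Repeatedly locates the run of ``window`` consecutive sub-threshold bases
    closest to either end and removes it together with the (shorter) segment
    between it and that end, until no such run remains. Deterministic and
    idempotent; when low-quality runs sit only at the read ends this is plain
    end-trimming. Ties trim the 3' side.
    """
    q = np.asarray(quals)
    s, e = 0, len(q)
    while e - s >= window:
        low = q[s:e] < q_low
        # windows: positions i (relative to s) where low[i:i+window] all True
        run = np.convolve(low.astype(int), np.ones(window, dtype=int), "valid")
        hits = np.flatnonzero(run == window)
        if hits.size == 0:
            break
        i_left, i_right = int(hits[0]), int(hits[-1])
        cost_left = i_left + window
        cost_right = (e - s) - i_right
        if cost_right <= cost_left:
            e = s + i_right
        else:
            s = s + i_left + window
    return s, e


def quality_filter_reads(reads: ReadSet, params: Optional[ReadFilterParams] = None):
    """Trim low-quality ends and discard poor reads.

    Per read, in order: (1) end-trim runs of ``window`` consecutive bases
    below ``q_low``; (2) discard if the median quality of the remaining bases
    is below ``median_min`` (lower median for even lengths); (3) discard if
    more than ``max_uncalled`` 'N' bases remain; (4) discard if shorter than
    ``min_length``. Idempotent.

    Returns ``(ReadSet, log)``; the log is a DataFrame with one row per read
    recording the action taken and the rule that fired.
    """
    params = params or ReadFilterParams()
    kept, log = [], []
    for r in reads:
        s, e = _trim_low_quality_ends(r.quals, params.window, params.q_low)
        bases, quals = r.bases[s:e], list(r.quals[s:e])
        trimmed = len(bases) != len(r.bases)
        if not bases:
            log.append((r.id, "discarded", "min_length", 0))
            continue
        n = len(quals)
        median_q = sorted(quals)[(n - 1) // 2]
        if median_q < params.median_min:
            log.append((r.id, "discarded", "median_quality", n))
            continue
        if bases.count("N") > params.max_uncalled:
            log.append((r.id, "discarded", "uncalled_bases", n))
            continue
        if n < params.min_length:
            log.append((r.id, "discarded", "min_length", n))
            continue
        kept.append(Read(r.id, bases, quals))
        log.append((r.id, "trimmed" if trimmed else "retained", "", n))
    log_df = pd.DataFrame(log, columns=["read_id", "action", "rule", "final_length"])
    return ReadSet(kept), log_df


# ---------------------------------------------------------------------------
# isoform abundance filtering
# ---------------------------------------------------------------------------


def abundance_filter_isoforms(table: pd.DataFrame, min_fraction: float = 0.01):
    """Retain isoforms contributing at least ``min_fraction`` of their gene's
    total FPKM (default 1%). Genes whose total FPKM is zero retain nothing.

    ``table`` needs columns gene_id, isoform_id, fpkm. Returns
    ``(retained_isoform_set, log DataFrame)``.
    """
    if (table["fpkm"] < 0).any():
        bad = table.loc[table["fpkm"] < 0, "isoform_id"].tolist()
        raise ValueError(f"negative FPKM for isoforms: {bad}")
    totals = table.groupby("gene_id")["fpkm"].transform("sum")
    frac = np.where(totals > 0, table["fpkm"] / totals.replace(0, np.nan), 0.0)
    # tiny slack so an isoform at exactly the threshold fraction is retained
    keep = (totals > 0) & (frac + 1e-12 >= min_fraction)
    retained = set(table.loc[keep, "isoform_id"])
    log = table.assign(gene_total=totals, retained=keep)[
        ["gene_id", "isoform_id", "fpkm", "gene_total", "retained"]
    ]
    return retained, log


# ---------------------------------------------------------------------------
# consensus scaffolding
# ---------------------------------------------------------------------------


@dataclass
class ScaffoldParams:
    identity_threshold: float = 0.95

    def __post_init__(self):
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold must be in (0, 1]")


MISSING = "MISSING"

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}

_DNA_OK = frozenset("ACGTRYSWKMBDHVN")


def _overlap_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    # free end gaps: overlap alignment
    try:
        aligner.open_end_insertion_score = 0
        aligner.extend_end_insertion_score = 0
        aligner.open_end_deletion_score = 0
        aligner.extend_end_deletion_score = 0
    except AttributeError:  # older Biopython
        aligner.target_end_open_gap_score = 0
        aligner.target_end_extend_gap_score = 0
        aligner.query_end_open_gap_score = 0
        aligner.query_end_extend_gap_score = 0
    return aligner


def _pair_identity(a: str, b: str, aligner) -> tuple:
    """(identity over aligned non-gap overlap columns, overlap length)."""
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    both = [(x, y) for x, y in zip(sa, sb) if x != "-" and y != "-"]
    if not both:
        return 1.0, 0
    matches = sum(1 for x, y in both if x == y)
    return matches / len(both), len(both)


@dataclass
class ScaffoldResult:
    status: str  # "consensus" or "missing"
    sequence: Optional[str]
    min_identity: float

    @property
    def is_missing(self) -> bool:
        return self.status == "missing"


def scaffold_consensus(
    transcripts: Sequence[str],
    params: Optional[ScaffoldParams] = None,
) -> ScaffoldResult:
    """Merge multiple transcripts for one sample x orthogroup into a
    consensus, or return a MISSING verdict.

    Every overlapping pair must align with identity >= the threshold over
    their non-gap overlap columns; one divergent pair makes the whole sample
    missing for that orthogroup. Consensus takes the majority base per
    column with ties encoded as IUPAC ambiguity codes; fragments with no
    overlap are concatenated in the given scaffold order. The verdict is
    invariant to the order of the input list.
    """
    params = params or ScaffoldParams()
    seqs = [s.upper() for s in transcripts]
    if not seqs:
        raise ValueError("scaffold_consensus needs at least one sequence")
    for s in seqs:
        bad = set(s) - _DNA_OK
        if bad:
            raise ValueError(f"non-DNA characters in transcript: {sorted(bad)}")
    if len(seqs) == 1:
        return ScaffoldResult("consensus", seqs[0], 1.0)

    aligner = _overlap_aligner()
    min_ident = 1.0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            ident, overlap = _pair_identity(seqs[i], seqs[j], aligner)
            if overlap > 0:
                min_ident = min(min_ident, ident)
    if min_ident < params.identity_threshold:
        return ScaffoldResult("missing", None, min_ident)

    # progressive merge into per-column base counts
    columns = [dict([(b, 1)]) for b in seqs[0]]
    for s in seqs[1:]:
        cons = "".join(_majority(col) for col in columns)
        aln = aligner.align(cons, s)[0]
        ca, cb = str(aln[0]), str(aln[1])
        if all(x == "-" or y == "-" for x, y in zip(ca, cb)):
            columns.extend(dict([(b, 1)]) for b in s)  # no overlap: concatenate
            continue
        merged = []
        ci = 0
        for x, y in zip(ca, cb):
            if x != "-":
                col = columns[ci]
                ci += 1
            else:
                col = {}
            if y != "-":
                col[y] = col.get(y, 0) + 1
            if col:
                merged.append(col)
        columns = merged
    return ScaffoldResult("consensus", "".join(_majority(c) for c in columns), min_ident)


def _majority(col: dict) -> str:
    best = max(col.values())
    winners = frozenset(b for b, n in col.items() if n == best and b in "ACGT")
    if not winners:  # ambiguity codes only; pass through the commonest
        return max(sorted(col), key=lambda b: col[b])
    return _IUPAC.get(winners, "N")


# ---------------------------------------------------------------------------
# iterative occupancy trimming
# ---------------------------------------------------------------------------


@dataclass
class TrimParams:
    site_occupancy_min: float = 0.90
    seq_length_fraction_min: float = 0.90
    max_iterations: int = 10

    def __post_init__(self):
        if not (0 < self.site_occupancy_min <= 1 and 0 < self.seq_length_fraction_min <= 1):
            raise ValueError("occupancy fractions must be in (0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class TrimIteration:
    iteration: int
    columns_removed: int
    sequences_removed: int


def iterative_occupancy_trim(
    aln: Alignment,
    params: Optional[TrimParams] = None,
    realigner: Optional[Callable] = None,
):
    """Iteratively remove low-occupancy sites and short sequences, realigning
    survivors, until a fixed point or ``max_iterations``.

    Each iteration: (a) drop columns whose non-gap occupancy is below
    ``site_occupancy_min``; (b) drop sequences whose non-gap length is below
    ``seq_length_fraction_min`` of the current width; (c) realign survivors
    (default realigner keeps the surviving columns as-is). Site and sequence
    counts never increase. Returns ``(Alignment, [TrimIteration, ...])``; if
    every sequence is removed the result is an empty alignment, not a crash.
    """
    params = params or TrimParams()
    if aln.n_taxa == 0:
        raise ValueError("empty alignment")
    log = []
    current = aln
    for it in range(1, params.max_iterations + 1):
        mask = current.nongap_mask()
        occ = mask.mean(axis=0) if current.n_taxa else np.array([])
        keep_cols = occ >= params.site_occupancy_min
        ncols_removed = int((~keep_cols).sum())
        if ncols_removed:
            current = current.subset_columns(keep_cols)
            mask = mask[:, keep_cols]
        width = current.width
        if width == 0:
            log.append(TrimIteration(it, ncols_removed, current.n_taxa))
            return Alignment([], []), log
        seq_len = mask.sum(axis=1)
        keep_rows = seq_len >= params.seq_length_fraction_min * width
        nrows_removed = int((~keep_rows).sum())
        if nrows_removed:
            taxa = [t for t, k in zip(current.taxa, keep_rows) if k]
            current = current.subset_taxa(taxa)
        log.append(TrimIteration(it, ncols_removed, nrows_removed))
        if current.n_taxa == 0:
            return Alignment([], []), log
        if ncols_removed == 0 and nrows_removed == 0:
            break
        if realigner is not None:
            degapped = [s.replace("-", "") for s in current.sequences]
            current = realigner(current.taxa, degapped)
    return current, log


# ---------------------------------------------------------------------------
# rogue-taxon filtering
# ---------------------------------------------------------------------------


@dataclass
class RogueParams:
    quantile: float = 0.95
    min_diameter_ratio: float = 0.5
    min_genes: int = 3

    def __post_init__(self):
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must be in (0, 1)")
        if not 0 < self.min_diameter_ratio < 1:
            raise ValueError("min_diameter_ratio must be in (0, 1)")


def _leaf_distances(tree: Tree) -> dict:
    """Dijkstra-free pairwise leaf distances via postorder accumulation."""
    # distances from each node to leaves below: (label, dist) lists
    below: dict = {}
    dists: dict = {}
    for nd in tree.root.postorder():
        if nd.is_leaf:
            below[id(nd)] = [(nd.label, 0.0)]
            continue
        lists = []
        for c in nd.children:
            if c.length is None:
                raise ValueError("rogue filtering needs branch lengths")
            lists.append([(lab, d + c.length) for lab, d in below[id(c)]])
        for i in range(len(lists)):
            for j in range(i + 1, len(lists)):
                for la, da in lists[i]:
                    for lb, db in lists[j]:
                        dists[frozenset((la, lb))] = da + db
        below[id(nd)] = [x for lst in lists for x in lst]
    return dists


def _diameters(tree: Tree):
    """(diameter, {taxon: diameter without taxon}) from pairwise distances."""
    dists = _leaf_distances(tree)
    if not dists:
        return 0.0, {}
    diam = max(dists.values())
    taxa = tree.leaf_labels
    out = {}
    for t in taxa:
        rest = [d for pair, d in dists.items() if t not in pair]
        out[t] = max(rest) if rest else 0.0
    return diam, out


def rogue_taxon_filter(
    gene_trees: Sequence[Tree],
    params: Optional[RogueParams] = None,
):
    """Flag (gene, taxon) pairs whose removal collapses an aberrant share of
    the gene tree's diameter, then prune the flagged leaves per gene.

    Signature for (gene, taxon): (diameter - diameter_without_taxon) /
    diameter. A pair is flagged iff its signature reaches the absolute
    ``min_diameter_ratio`` AND exceeds the per-taxon empirical ``quantile``
    of the null portion of that taxon's signature distribution (signatures
    below the hard ratio). Taxa observed in fewer than ``min_genes`` gene
    trees are never flagged.

    Returns ``(flags, filtered_trees, signatures)``: flags is a list of
    (gene_index, taxon); signatures a DataFrame for inspection.
    """
    params = params or RogueParams()
    if len(gene_trees) < 2:
        raise ValueError("rogue filtering needs at least two gene trees")
    rows = []
    for gi, t in enumerate(gene_trees):
        if t.n_leaves < 4:  # diameter signature degenerate below a quartet
            continue
        diam, without = _diameters(t)
        for taxon, dw in without.items():
            sig = 0.0 if diam <= 0 else (diam - dw) / diam
            rows.append((gi, taxon, sig))
    if not rows:
        raise ValueError("rogue filtering needs gene trees with >= 4 leaves")
    sigs = pd.DataFrame(rows, columns=["gene", "taxon", "signature"])

    flags = []
    for taxon, grp in sigs.groupby("taxon"):
        if len(grp) < params.min_genes:
            continue
        vals = grp["signature"].to_numpy()
        null = vals[vals < params.min_diameter_ratio]
        thr = float(np.quantile(null, params.quantile)) if null.size else 0.0
        hit = grp[(grp["signature"] >= params.min_diameter_ratio) & (grp["signature"] > thr)]
        flags.extend((int(g), taxon) for g in hit["gene"])
    flags.sort()

    by_gene: dict = {}
    for g, taxon in flags:
        by_gene.setdefault(g, set()).add(taxon)
    filtered = []
    for gi, t in enumerate(gene_trees):
        drop = by_gene.get(gi)
        if drop and t.n_leaves - len(drop) >= 2:
            filtered.append(t.prune(drop))
        else:  # flags reported but a sub-2-leaf remnant is never produced
            filtered.append(t)
    return flags, filtered, sigs


def min_taxa_filter(gene_trees: Sequence[Tree], min_taxa: int) -> list:
    """Retain gene trees sampling at least ``min_taxa`` leaves."""
    if min_taxa < 4:
        raise ValueError("min_taxa must be >= 4 (quartets need four leaves)")
    return [t for t in gene_trees if t.n_leaves >= min_taxa]
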