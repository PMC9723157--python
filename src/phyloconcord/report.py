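"""Summary reporting: per-branch concordance tables (TSV), annotated Newick,
threshold-exceedance fractions and branch-length correlations."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .concordance import BranchConcordance
from .trees import Tree

TABLE_COLUMNS = [
    "branch_id",
    "length",
    "gCF",
    "gDF1",
    "gDF2",
    "gDFP",
    "gN",
    "sCF",
    "sDF1",
    "sDF2",
    "sN",
    "gEF_p",
    "sEF_p",
]


def _fmt(x, nd=4) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        if np.isnan(x):
            return "NA"
        return f"{x:.{nd}f}"
    return str(x)


def branch_table_rows(branches: Sequence[BranchConcordance]) -> list:
    rows = []
    for b in branches:
        rows.append(
            [
                b.branch_id,
                _fmt(b.length),
                _fmt(b.gcf),
                _fmt(b.gdf1),
                _fmt(b.gdf2),
                _fmt(b.gdfp),
                str(b.gn),
                _fmt(b.scf),
                _fmt(b.sdf1),
                _fmt(b.sdf2),
                _fmt(b.sn),
                _fmt(b.gef_p, 6),
                _fmt(b.sef_p, 6),
            ]
        )
    return rows


def write_branch_table(
    branches: Sequence[BranchConcordance],
    path,
    provenance: Optional[dict] = None,
) -> None:
    """Byte-deterministic TSV with provenance header comments."""
    with open(path, "w") as fh:
        from . import __version__

        fh.write(f"# phyloconcord {__version__} per-branch concordance table\n")
        for k in sorted(provenance or {}):
            fh.write(f"# {k}={provenance[k]}\n")
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for row in branch_table_rows(branches):
            fh.write("\t".join(row) + "\n")


def read_branch_table(path) -> list:
    """Round-trip reader for :func:`write_branch_table` output."""
    branches = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            vals = dict(zip(header, line.split("\t")))
            conv = lambda v: None if v == "NA" else float(v)
            b = BranchConcordance(
                branch_id=vals["branch_id"],
                split=frozenset(vals["branch_id"].split(",")),
                length=conv(vals["length"]),
                gcf=conv(vals["gCF"]),
                gdf1=conv(vals["gDF1"]),
                gdf2=conv(vals["gDF2"]),
                gdfp=conv(vals["gDFP"]),
                gn=int(vals["gN"]),
                scf=conv(vals["sCF"]),
                sdf1=conv(vals["sDF1"]),
                sdf2=conv(vals["sDF2"]),
                sn=conv(vals["sN"]),
            )
            branches.append(b)
    return branches


def write_annotated_newick(
    reference: Tree, branches: Sequence[BranchConcordance], path
) -> None:
    """Write the reference tree with concordance factors attached to internal
    nodes as label annotations (gCF/sCF, NA where undefined)."""
    tree = reference.copy()
    by_split = {b.split: b for b in branches}
    universe = tree.leaf_labels
    seen = set()  # a degree-2 root maps two edges onto one unrooted branch
    for nd in tree.root.postorder():
        if nd.is_leaf or nd is tree.root:
            continue
        clade = frozenset(l.label for l in _leaves_below(nd))
        rec = by_split.get(clade) or by_split.get(universe - clade)
        if rec is not None and rec.split not in seen:
            seen.add(rec.split)
            nd.support = None
            nd.label = f"gCF={_fmt(rec.gcf, 1)}/sCF={_fmt(rec.scf, 1)}"
    with open(path, "w") as fh:
        fh.write(tree.write_newick(supports=False) + "\n")


def _leaves_below(nd):
    stack, out = [nd], []
    while stack:
        cur = stack.pop()
        if cur.is_leaf:
            out.append(cur)
        else:
            stack.extend(cur.children)
    return out


@dataclass
class Correlation:
    r: float
    p: float
    n: int


@dataclass
class SummaryReport:
    n_branches: int
    n_gene_defined: int
    n_site_defined: int
    gcf_threshold: float
    scf_threshold: float
    frac_gcf_over: Optional[float]
    frac_scf_over: Optional[float]
    pearson_length_gcf: Optional[Correlation]
    pearson_length_scf: Optional[Correlation]


def _exceedance(values, threshold):
    vals = [v for v in values if v is not None]
    if not vals:
        return None, 0
    return sum(1 for v in vals if v > threshold) / len(vals), len(vals)


def _pearson(lengths, values) -> Optional[Correlation]:
    pairs = [
        (l, v) for l, v in zip(lengths, values) if l is not None and v is not None
    ]
    if len(pairs) < 3:
        return None
    x = np.asarray([p[0] for p in pairs])
    y = np.asarray([p[1] for p in pairs])
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    r, p = stats.pearsonr(x, y)
    return Correlation(r=float(r), p=float(p), n=len(pairs))


def summarize(
    branches: Sequence[BranchConcordance],
    gcf_threshold: float = 50.0,
    scf_threshold: float = 33.0,
) -> SummaryReport:
    """Distribution summaries over defined branches: strict-exceedance
    fractions (branch has factor > threshold) and Pearson correlations of
    internal branch length with gCF and sCF. Undefined branches are excluded
    from every denominator; constant inputs yield a null correlation."""
    if not branches or all(b.gcf is None and b.scf is None for b in branches):
        raise ValueError("no defined branches to summarize")
    gcfs = [b.gcf for b in branches]
    scfs = [b.scf for b in branches]
    lengths = [b.length for b in branches]
    frac_g, n_g = _exceedance(gcfs, gcf_threshold)
    frac_s, n_s = _exceedance(scfs, scf_threshold)
    return SummaryReport(
        n_branches=len(branches),
        n_gene_defined=n_g,
        n_site_defined=n_s,
        gcf_threshold=gcf_threshold,
        scf_threshold=scf_threshold,
        frac_gcf_over=frac_g,
        frac_scf_over=frac_s,
        pearson_length_gcf=_pearson(lengths, gcfs),
        pearson_length_scf=_pearson(lengths, scfs),
    )
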