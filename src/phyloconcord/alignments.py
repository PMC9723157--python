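"""Alignment container, FASTA I/O, supermatrix concatenation and
RAxML-style partition schemes."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO

GAP_CHARS = frozenset("-")
MISSING_CHARS = frozenset("?")
UNAMBIGUOUS = frozenset("ACGT")

# numeric codes used by the site-pattern machinery
_CODE = np.full(256, 255, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i


@dataclass
class Alignment:
    """Equal-length sequences over the DNA alphabet plus gap ('-') and
    missing ('?'/'N') symbols. Taxa are unique and ordered."""

    taxa: list
    sequences: list

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa and sequences differ in length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa in alignment")
        widths = {len(s) for s in self.sequences}
        if len(widths) > 1:
            raise ValueError(f"rows differ in length: {sorted(widths)}")

    @property
    def width(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    def codes(self) -> np.ndarray:
        """uint8 matrix: A,C,G,T -> 0..3; every other symbol -> 255."""
        if not self.sequences:
            return np.zeros((0, 0), dtype=np.uint8)
        flat = np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype=np.uint8
        ).reshape(self.n_taxa, self.width)
        return _CODE[flat]

    def nongap_mask(self) -> np.ndarray:
        """Boolean matrix, True where the cell holds a residue (not '-'/'?')."""
        if not self.sequences:
            return np.zeros((0, 0), dtype=bool)
        flat = np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype=np.uint8
        ).reshape(self.n_taxa, self.width)
        return (flat != ord("-")) & (flat != ord("?"))

    def subset_columns(self, keep: np.ndarray) -> "Alignment":
        idx = np.flatnonzero(keep) if keep.dtype == bool else np.asarray(keep)
        seqs = ["".join(s[i] for i in idx) for s in self.sequences]
        return Alignment(list(self.taxa), seqs)

    def subset_taxa(self, keep: Sequence[str]) -> "Alignment":
        keep = list(keep)
        return Alignment(keep, [self.row(t) for t in keep])

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        taxa, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            seqs.append(str(rec.seq).upper())
        if not taxa:
            raise ValueError(f"no sequences in {path}")
        return cls(taxa, seqs)

    def to_fasta(self, path, wrap: int = 0) -> None:
        with open(path, "w") as fh:
            for t, s in zip(self.taxa, self.sequences):
                fh.write(f">{t}\n")
                if wrap:
                    for i in range(0, len(s), wrap):
                        fh.write(s[i : i + wrap] + "\n")
                else:
                    fh.write(s + "\n")


@dataclass
class PartitionScheme:
    """Named partitions over 1-based supermatrix sites, stored as
    (start, end, step) range triples (RAxML '\\3' codon ranges)."""

    partitions: dict  # name -> list of (start, end, step)

    def sites(self, name: str) -> np.ndarray:
        out = []
        for start, end, step in self.partitions[name]:
            out.append(np.arange(start, end + 1, step))
        return np.concatenate(out) if out else np.array([], dtype=int)

    def size(self, name: str) -> int:
        return int(self.sites(name).size)

    def validate(self, width: int) -> None:
        all_sites = np.concatenate(
            [self.sites(n) for n in self.partitions]
        ) if self.partitions else np.array([], dtype=int)
        if all_sites.size != width or len(np.unique(all_sites)) != all_sites.size:
            raise ValueError("partitions must be disjoint and cover all sites")
        if all_sites.size and (all_sites.min() < 1 or all_sites.max() > width):
            raise ValueError("partition sites out of range")

    def to_raxml(self) -> str:
        lines = []
        for name, ranges in self.partitions.items():
            spans = ", ".join(
                f"{s}-{e}" if step == 1 else f"{s}-{e}\\{step}"
                for s, e, step in ranges
            )
            lines.append(f"DNA, {name} = {spans}")
        return "\n".join(lines) + "\n"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_raxml())


def concatenate_supermatrix(
    gene_alignments: Sequence,
    taxon_universe: Optional[Sequence[str]] = None,
    scheme_kind: str = "per_gene",
):
    """Concatenate named per-gene alignments into a supermatrix.

    ``gene_alignments`` is a sequence of (name, Alignment) pairs. Taxa absent
    from a gene are padded with '?' across that gene's columns; gaps from the
    source alignments are preserved as '-'.

    ``scheme_kind``:
      * ``per_gene``  — one partition per gene
      * ``codon_12_3`` — two partitions: codon positions 1+2 and position 3
        (every gene must have width divisible by 3)

    Returns ``(Alignment, PartitionScheme)``.
    """
    if scheme_kind not in ("per_gene", "codon_12_3"):
        raise ValueError(f"unknown scheme_kind {scheme_kind!r}")
    names = [n for n, _ in gene_alignments]
    if len(set(names)) != len(names):
        raise ValueError("duplicate gene names")
    if taxon_universe is None:
        universe: list = sorted({t for _, a in gene_alignments for t in a.taxa})
    else:
        universe = list(taxon_universe)

    rows = {t: [] for t in universe}
    offsets = []
    pos = 0
    for name, aln in gene_alignments:
        if scheme_kind == "codon_12_3" and aln.width % 3 != 0:
            raise ValueError(
                f"gene {name!r} width {aln.width} is not a multiple of 3 "
                "(required for codon partitioning)"
            )
        offsets.append((name, pos + 1, pos + aln.width))
        for t in universe:
            if t in aln.taxa:
                rows[t].append(aln.row(t))
            else:
                rows[t].append("?" * aln.width)
        pos += aln.width

    supermatrix = Alignment(universe, ["".join(rows[t]) for t in universe])

    if scheme_kind == "per_gene":
        parts = {name: [(s, e, 1)] for name, s, e in offsets}
    else:
        p12, p3 = [], []
        for name, s, e in offsets:
            p12.append((s, e, 3))
            p12.append((s + 1, e, 3))
            p3.append((s + 2, e, 3))
        parts = {"codon12": p12, "codon3": p3}
    scheme = PartitionScheme(parts)
    scheme.validate(supermatrix.width)
    return supermatrix, scheme
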