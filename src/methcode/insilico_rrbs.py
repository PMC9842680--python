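"""In silico restriction digest and expected RRBS coverage.

RRBS enriches CpG-rich loci by digesting genomic DNA with MspI (C^CGG)
and TaqI (T^CGA), size-selecting the fragments, and sequencing the
fragment ends. This module reproduces that selection computationally:
it locates restriction sites, partitions a sequence into digest
fragments, applies size selection, and reports which CpGs of annotated
genomic elements fall into the simulated reads. It also provides
scaffold concatenation into pseudo-chromosomes with a reversible
coordinate map, for fragmented assemblies.

All coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

MSPI = "CCGG"
TAQI = "TCGA"
DEFAULT_MOTIFS = (MSPI, TAQI)

_VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class DigestFragment:
    """One restriction fragment surviving size selection.

    ``read_intervals`` are the two simulated single-end reads: the first
    and last ``read_length`` bp of the fragment (clamped to the fragment
    for fragments shorter than a read).
    """

    chrom: str
    start: int
    end: int
    read_intervals: Tuple[Tuple[int, int], Tuple[int, int]]

    @property
    def length(self) -> int:
        return self.end - self.start


def find_restriction_sites(seq: str, motifs: Sequence[str] = DEFAULT_MOTIFS) -> Dict[str, List[int]]:
    """Locate all (possibly overlapping) occurrences of each motif.

    Parameters
    ----------
    seq:
        DNA sequence over A/C/G/T/N (case-insensitive). N never matches.
    motifs:
        Recognition sites, default MspI (CCGG) and TaqI (TCGA).

    Returns
    -------
    dict mapping motif -> sorted list of 0-based start positions.
    """
    if not motifs:
        raise ValueError("motifs must be non-empty")
    seq = seq.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    out: Dict[str, List[int]] = {}
    for motif in motifs:
        motif_u = motif.upper()
        positions: List[int] = []
        i = seq.find(motif_u)
        while i != -1:
            positions.append(i)
            i = seq.find(motif_u, i + 1)
        out[motif_u] = positions
    return out


def merged_cut_positions(sites: Mapping[str, Sequence[int]], cut_offset: int = 1) -> List[int]:
    """Cut positions from site starts (C^CGG, T^CGA: offset 1), sorted, deduplicated."""
    cuts = sorted({p + cut_offset for positions in sites.values() for p in positions})
    return cuts


def digest_and_select(
    seq_len: int,
    sites: Mapping[str, Sequence[int]],
    min_len: int = 50,
    max_len: int = 1000,
    read_length: int = 50,
    chrom: str = "chr",
    cut_offset: int = 1,
) -> List[DigestFragment]:
    """Partition [0, seq_len) at restriction cuts and size-select.

    Cut positions are ``site_start + cut_offset`` (the enzymes cleave
    after the first base of the recognition site). Terminal fragments
    bounded by the sequence ends are included. Size bounds are inclusive
    on both ends.
    """
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) > max_len ({max_len})")
    cuts = merged_cut_positions(sites, cut_offset)
    bounds = [0] + [c for c in cuts if 0 < c < seq_len] + [seq_len]
    fragments: List[DigestFragment] = []
    for start, end in zip(bounds[:-1], bounds[1:]):
        length = end - start
        if length < min_len or length > max_len:
            continue
        rl = min(read_length, length)
        reads = ((start, start + rl), (end - rl, end))
        fragments.append(DigestFragment(chrom, start, end, reads))
    return fragments


def candidate_fragments(seq_len: int, sites: Mapping[str, Sequence[int]], cut_offset: int = 1) -> List[Tuple[int, int]]:
    """All digest intervals before size selection; tiles [0, seq_len) exactly."""
    cuts = merged_cut_positions(sites, cut_offset)
    bounds = [0] + [c for c in cuts if 0 < c < seq_len] + [seq_len]
    return list(zip(bounds[:-1], bounds[1:]))


@dataclass
class ScaffoldMap:
    """Bidirectional map between scaffold and pseudo-chromosome coordinates."""

    # (chrom, offset, scaffold_name, scaffold_len) per placed scaffold
    placements: List[Tuple[str, int, str, int]] = field(default_factory=list)
    _by_scaffold: Dict[str, Tuple[str, int, int]] = field(default_factory=dict)

    def add(self, chrom: str, offset: int, scaffold: str, length: int) -> None:
        self.placements.append((chrom, offset, scaffold, length))
        self._by_scaffold[scaffold] = (chrom, offset, length)

    def to_pseudo(self, scaffold: str, pos: int) -> Tuple[str, int]:
        chrom, offset, length = self._by_scaffold[scaffold]
        if not 0 <= pos < length:
            raise ValueError(f"position {pos} outside scaffold {scaffold} (len {length})")
        return chrom, offset + pos

    def to_original(self, chrom: str, pos: int) -> Tuple[str, int]:
        for c, offset, scaffold, length in self.placements:
            if c == chrom and offset <= pos < offset + length:
                return scaffold, pos - offset
        raise ValueError(f"{chrom}:{pos} falls in spacer or outside any scaffold")


def concat_scaffolds(
    scaffolds: Sequence[Tuple[str, str]],
    n_chrom: int = 20,
    spacer: int = 100,
) -> Tuple[Dict[str, str], ScaffoldMap]:
    """Concatenate scaffolds round-robin into <= n_chrom pseudo-chromosomes.

    Adjacent scaffolds on one pseudo-chromosome are separated by exactly
    ``spacer`` N bases. Returns the pseudo-chromosome sequences and a
    coordinate map that round-trips every non-N position.
    """
    if not scaffolds:
        raise ValueError("need at least one scaffold")
    n_used = min(n_chrom, len(scaffolds))
    parts: List[List[Tuple[str, str]]] = [[] for _ in range(n_used)]
    for i, rec in enumerate(scaffolds):
        parts[i % n_used].append(rec)
    chroms: Dict[str, str] = {}
    cmap = ScaffoldMap()
    pad = "N" * spacer
    for ci, members in enumerate(parts):
        name = f"pchr{ci + 1}"
        pieces: List[str] = []
        offset = 0
        for j, (sname, seq) in enumerate(members):
            if j > 0:
                pieces.append(pad)
                offset += spacer
            cmap.add(name, offset, sname, len(seq))
            pieces.append(seq)
            offset += len(seq)
        chroms[name] = "".join(pieces)
    return chroms, cmap


@dataclass
class ElementCoverageReport:
    """Fraction of element-class CpGs falling inside simulated RRBS reads."""

    rows: Dict[str, Tuple[int, int, Optional[float]]]  # class -> (n_total, n_covered, fraction)

    def fraction(self, element_class: str) -> Optional[float]:
        return self.rows[element_class][2]


def promoter_interval(start: int, end: int, strand: str, upstream: int = 1000, downstream: int = 500) -> Tuple[int, int]:
    """Promoter window around the TSS, strand-aware, 0-based half-open.

    Plus strand: TSS = start, window [TSS - upstream, TSS + downstream).
    Minus strand: TSS = end - 1 (last base), upstream extends toward
    higher coordinates: [TSS - downstream + 1, TSS + upstream + 1).
    """
    if strand == "+":
        return start - upstream, start + downstream
    tss = end - 1
    return tss - downstream + 1, tss + upstream + 1


def element_coverage(
    cpg_positions: Sequence[int],
    fragments: Sequence[DigestFragment],
    elements: Mapping[str, Sequence[Tuple[int, int]]],
    genes: Optional[Sequence[Tuple[int, int, str]]] = None,
    promoter_def: Tuple[int, int] = (1000, 500),
) -> ElementCoverageReport:
    """Per-class fraction of CpGs covered by any simulated read interval.

    ``elements`` maps class name -> list of (start, end) intervals.
    ``genes`` (start, end, strand) triples additionally yield a
    ``promoter`` class using ``promoter_def = (upstream, downstream)``
    around the strand-aware TSS. A class with zero CpGs gets fraction
    None (missing), never zero.
    """
    cpgs = sorted(cpg_positions)
    reads = sorted(iv for f in fragments for iv in f.read_intervals)
    covered = set()
    ri = 0
    for p in cpgs:
        while ri < len(reads) and reads[ri][1] <= p:
            ri += 1
        j = ri
        while j < len(reads) and reads[j][0] <= p:
            if reads[j][0] <= p < reads[j][1]:
                covered.add(p)
                break
            j += 1

    classes: Dict[str, List[Tuple[int, int]]] = {k: list(v) for k, v in elements.items()}
    if genes is not None:
        up, down = promoter_def
        classes["promoter"] = [promoter_interval(s, e, st, up, down) for s, e, st in genes]

    rows: Dict[str, Tuple[int, int, Optional[float]]] = {}
    for cls, ivs in classes.items():
        in_cls = [p for p in cpgs if any(s <= p < e for s, e in ivs)]
        n_total = len(in_cls)
        n_cov = sum(1 for p in in_cls if p in covered)
        frac = n_cov / n_total if n_total > 0 else None
        rows[cls] = (n_total, n_cov, frac)
    n_total = len(cpgs)
    n_cov = len(covered)
    rows["genome_wide"] = (n_total, n_cov, n_cov / n_total if n_total else None)
    return ElementCoverageReport(rows)


def cpg_positions_of(seq: str) -> List[int]:
    """0-based positions of the C of every CpG dinucleotide; N disqualifies."""
    seq = seq.upper()
    return [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]
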