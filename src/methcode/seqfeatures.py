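"""Sequence-composition features of consensus reference fragments.

k-mer spectra, C/G/CpG composition with observed/expected CpG ratio,
CpG-island calls under the Gardiner-Garden (GC >= 0.50, obs/exp >=
0.6) and Takai-Jones (GC >= 0.55, obs/exp >= 0.65) criteria evaluated
over sliding 50 bp windows, and 3-mer-based species distances with
hierarchical clustering.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform


def all_kmers(k: int) -> List[str]:
    return ["".join(t) for t in itertools.product("ACGT", repeat=k)]


@dataclass
class KmerSpectrum:
    k: int
    frequencies: pd.Series  # index: the 4^k k-mers
    n_positions_counted: int


ISLAND_CRITERIA = {
    "gardiner_garden": (0.50, 0.6),
    "takai_jones": (0.55, 0.65),
}


def kmer_spectrum(fragments: Sequence[str], k: int) -> KmerSpectrum:
    """Pooled overlapping k-mer frequencies across fragments.

    Windows containing non-ACGT characters are skipped; counting pools
    positions across fragments (each position weighs equally, so longer
    fragments contribute more).
    """
    if not 1 <= k <= 10:
        raise ValueError("k must be in 1..10")
    kmers = all_kmers(k)
    counts = dict.fromkeys(kmers, 0)
    n = 0
    for frag in fragments:
        s = frag.upper()
        for i in range(len(s) - k + 1):
            w = s[i:i + k]
            if w in counts:
                counts[w] += 1
                n += 1
    if n == 0:
        raise ValueError("no countable k-mer positions in input fragments")
    freqs = pd.Series({m: counts[m] / n for m in kmers}, dtype=float)
    return KmerSpectrum(k=k, frequencies=freqs, n_positions_counted=n)


@dataclass
class CgComposition:
    freq_c: float
    freq_g: float
    freq_cpg: float
    obs_exp_cpg: Optional[float]
    n_cpgs: int


def cg_composition(fragments: Sequence[str]) -> CgComposition:
    """Pooled C, G, and CpG frequencies with observed/expected CpG ratio.

    obs/exp = (#CpG x N) / (#C x #G) where N is the pooled base count;
    missing when the sequence lacks C or G. Dinucleotides are counted
    within fragments only (never across fragment boundaries).
    """
    if not fragments:
        raise ValueError("no fragments")
    n_c = n_g = n_cpg = n_bases = n_dinuc = 0
    for frag in fragments:
        s = frag.upper()
        n_bases += len(s)
        n_c += s.count("C")
        n_g += s.count("G")
        n_dinuc += max(0, len(s) - 1)
        n_cpg += sum(1 for i in range(len(s) - 1) if s[i:i + 2] == "CG")
    obs_exp = (n_cpg * n_bases) / (n_c * n_g) if n_c * n_g > 0 else None
    return CgComposition(
        freq_c=n_c / n_bases,
        freq_g=n_g / n_bases,
        freq_cpg=n_cpg / n_dinuc if n_dinuc else 0.0,
        obs_exp_cpg=obs_exp,
        n_cpgs=n_cpg,
    )


def _window_is_island(window: str, gc_min: float, oe_min: float) -> bool:
    n = len(window)
    n_c = window.count("C")
    n_g = window.count("G")
    gc = (n_c + n_g) / n
    if gc < gc_min:
        return False
    if n_c * n_g == 0:
        return False
    n_cpg = sum(1 for i in range(n - 1) if window[i:i + 2] == "CG")
    oe = (n_cpg * n) / (n_c * n_g)
    return oe >= oe_min


def fragment_is_island(fragment: str, criterion: str = "gardiner_garden", window: int = 50, step: int = 1) -> bool:
    """True iff any sliding window of the fragment passes both thresholds."""
    gc_min, oe_min = ISLAND_CRITERIA[criterion]
    s = fragment.upper()
    if len(s) < window:
        return False
    for i in range(0, len(s) - window + 1, step):
        if _window_is_island(s[i:i + window], gc_min, oe_min):
            return True
    return False


def island_fraction(fragments: Sequence[str], criterion: str = "gardiner_garden", window: int = 50, step: int = 1) -> float:
    """Fraction of fragments qualifying as CpG islands under the criterion."""
    if not fragments:
        raise ValueError("no fragments")
    return float(np.mean([fragment_is_island(f, criterion, window, step) for f in fragments]))


def species_kmer_clustering(
    spectra: Mapping[str, KmerSpectrum],
    linkage_method: str = "complete",
) -> Tuple[pd.DataFrame, str]:
    """Euclidean species distance matrix on k-mer spectra + dendrogram.

    Species with a missing spectrum are excluded with a warning.
    Returns the distance matrix and the dendrogram as a Newick string
    (leaves = species ids; ties broken by lexicographic id through the
    sorted input order).
    """
    names = sorted(s for s in spectra if spectra[s] is not None)
    dropped = sorted(set(spectra) - set(names))
    if dropped:
        warnings.warn(f"species without spectra excluded: {dropped}")
    if len(names) < 2:
        raise ValueError("need at least two species with spectra")
    X = np.vstack([spectra[s].frequencies.to_numpy() for s in names])
    D = squareform(pdist(X, metric="euclidean"))
    dist_df = pd.DataFrame(D, index=names, columns=names)
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method=linkage_method)
    tree = hierarchy.to_tree(Z)

    def newick(node) -> str:
        if node.is_leaf():
            return names[node.id]
        left = newick(node.get_left())
        right = newick(node.get_right())
        return f"({left}:{node.dist - node.get_left().dist:.6g},{right}:{node.dist - node.get_right().dist:.6g})"

    return dist_df, newick(tree) + ";"


def feature_table(
    fragment_sets: Mapping[str, Sequence[str]],
    ks: Sequence[int] = (1, 2, 3),
) -> pd.DataFrame:
    """Species x feature table: k-mer frequencies, CG composition, island fractions."""
    rows = {}
    for sp, frags in fragment_sets.items():
        row: Dict[str, float] = {}
        for k in ks:
            spec = kmer_spectrum(frags, k)
            for m, f in spec.frequencies.items():
                row[f"k{k}_{m}"] = f
        comp = cg_composition(frags)
        row["freq_C"] = comp.freq_c
        row["freq_G"] = comp.freq_g
        row["freq_CpG"] = comp.freq_cpg
        row["obs_exp_cpg"] = comp.obs_exp_cpg if comp.obs_exp_cpg is not None else np.nan
        row["n_cpgs"] = comp.n_cpgs
        row["island_gardiner_garden"] = island_fraction(frags, "gardiner_garden")
        row["island_takai_jones"] = island_fraction(frags, "takai_jones")
        rows[sp] = row
    return pd.DataFrame(rows).T
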