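"""Coverage-based fragment QC and inter-sample CpG overlap.

Consensus fragments with anomalous read coverage betray artefacts that
a reference-free workflow cannot detect positionally: genomic repeats
(collapsed into one fragment, hence uniformly over-covered),
PCR-amplified fragments (over-covered in single samples), and private
fragments (covered only in one individual, e.g. individual-specific
restriction-site polymorphisms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

FLAGS = ("repeat", "amplified", "private", "none")


@dataclass
class CoverageFlags:
    per_fragment: pd.Series  # fragment -> flag
    per_sample_fractions: pd.DataFrame  # sample x flag -> fraction of fragments

    def flagged(self, flag: str) -> List[str]:
        return list(self.per_fragment[self.per_fragment == flag].index)


def classify_fragments(
    coverage: pd.DataFrame,
    individuals: Mapping[str, str],
    high_factor: float = 4.0,
    reliable_factor: float = 0.5,
    repeat_frac: float = 0.8,
    amplified_frac: float = 0.2,
) -> CoverageFlags:
    """Flag fragments as repeat / amplified / private from read coverage.

    ``coverage`` is a fragment x sample read-count table. Per sample,
    average coverage is the mean over fragments with nonzero counts; a
    fragment is reliably covered above ``reliable_factor`` times that
    average and highly covered above ``high_factor`` times (both
    strict). Highly covered in > 80% of samples => repeat; highly
    covered in < 20% (but at least once) => amplified; reliably covered
    in > 80% of one individual's samples and < 20% of every other
    individual's => private (needs >= 4 samples and >= 2 individuals).
    Precedence: repeat > amplified > private.
    """
    cov = coverage.astype(float)
    usable = []
    for s in cov.columns:
        col = cov[s]
        if (col > 0).sum() == 0:
            warnings.warn(f"sample {s} has all-zero coverage; excluded")
            continue
        usable.append(s)
    cov = cov[usable]
    n_samples = len(usable)
    if n_samples == 0:
        raise ValueError("no usable samples")

    avg = cov.apply(lambda col: col[col > 0].mean(), axis=0)
    highly = cov.gt(high_factor * avg, axis=1)
    reliably = cov.gt(reliable_factor * avg, axis=1)

    frac_high = highly.mean(axis=1)
    any_high = highly.any(axis=1)

    flags = pd.Series("none", index=cov.index, dtype=object)

    # private rule needs the sample structure
    indiv = {s: individuals[s] for s in usable}
    by_indiv: Dict[str, List[str]] = {}
    for s, i in indiv.items():
        by_indiv.setdefault(i, []).append(s)
    private_ok = n_samples >= 4 and len(by_indiv) >= 2
    private_mask = pd.Series(False, index=cov.index)
    if private_ok:
        for ind, samples in by_indiv.items():
            others = [s for s in usable if indiv[s] != ind]
            own_frac = reliably[samples].mean(axis=1)
            other_frac = reliably[others].mean(axis=1)
            private_mask |= (own_frac > repeat_frac) & (other_frac < amplified_frac)

    amplified_mask = (frac_high < amplified_frac) & any_high
    repeat_mask = frac_high > repeat_frac

    flags[private_mask] = "private"
    flags[amplified_mask] = "amplified"
    flags[repeat_mask] = "repeat"

    frac_rows = {}
    for s in usable:
        frac_rows[s] = {f: (flags == f).mean() for f in FLAGS}
    return CoverageFlags(per_fragment=flags, per_sample_fractions=pd.DataFrame(frac_rows).T)


def pair_overlap(a: Set, b: Set, denominator: str = "mean") -> float:
    """Overlap of two covered-CpG sets: |A∩B| / mean(|A|, |B|) by default."""
    if not a or not b:
        return 0.0
    inter = len(a & b)
    if denominator == "mean":
        denom = (len(a) + len(b)) / 2.0
    elif denominator == "min":
        denom = min(len(a), len(b))
    elif denominator == "jaccard":
        denom = len(a | b)
    else:
        raise ValueError(f"unknown denominator rule {denominator!r}")
    return inter / denom


def cpg_overlap(
    covered_sets: Mapping[str, Set],
    threshold: float = 0.5,
    denominator: str = "mean",
) -> Tuple[float, bool]:
    """Mean pairwise covered-CpG overlap and keep/drop decision.

    Returns (mean overlap, keep). A species is dropped when the mean
    overlap falls strictly below ``threshold``.
    """
    samples = sorted(covered_sets)
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    vals = [pair_overlap(covered_sets[a], covered_sets[b], denominator)
            for a, b in combinations(samples, 2)]
    mean = float(np.mean(vals))
    return mean, mean >= threshold
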