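"""Genome-wide methylation aggregation and erosion (PDR) statistics.

Aggregation runs unweighted up the hierarchy cytosine -> fragment ->
sample -> species. Erosion is quantified by the proportion of
discordant reads (PDR): a read covering >= 4 valid CpGs is concordant
when all its CpGs share one state and discordant otherwise; the PDR of
a CpG is the discordant fraction of valid reads covering it. Under the
null model of independent per-CpG methylation at level m, a read with
n CpGs is discordant with probability 1 - m^n - (1-m)^n, which is
maximal at m = 0.5 — the expected-PDR reference curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .reffree_core import MethylationCallSet


@dataclass
class SpeciesProfile:
    species_id: str
    mean_cpg_methylation: float
    fragment_bin_fractions: Tuple[float, float, float]  # low <0.2, mid [0.2,0.8], high >0.8
    pdr: Optional[float]
    noncpg_methylation: Dict[str, float]
    n_samples: int


def _fragment_means(counts: pd.DataFrame, context: str = "CpG") -> pd.DataFrame:
    """Per sample x fragment: unweighted mean cytosine ratio and total reads."""
    sub = counts[(counts["context"] == context) & (counts["n_total"] > 0)].copy()
    sub["ratio"] = sub["n_meth"] / sub["n_total"]
    g = sub.groupby(["sample", "fragment"]).agg(
        mean_ratio=("ratio", "mean"), total_reads=("n_total", "sum"),
        mean_reads=("n_total", "mean")).reset_index()
    return g


def aggregate_species(
    callset: MethylationCallSet,
    species_id: str = "species",
    min_fragment_reads: int = 10,
) -> SpeciesProfile:
    """Species-level methylation mean and low/mid/high fragment bins.

    Fragment mean = unweighted mean of its CpG cytosine ratios; sample
    mean = mean over fragments; species mean = mean over samples. Bins
    use only fragments with >= ``min_fragment_reads`` total reads;
    boundaries: low [0, 0.2), mid [0.2, 0.8], high (0.8, 1].
    """
    counts = callset.counts
    if counts.empty:
        raise ValueError("empty call set")
    fm = _fragment_means(counts)
    sample_means = fm.groupby("sample")["mean_ratio"].mean()
    species_mean = float(sample_means.mean())

    binned = fm[fm["total_reads"] >= min_fragment_reads]
    if binned.empty:
        warnings.warn("no fragment passes the bin coverage filter; bins missing")
        bins = (np.nan, np.nan, np.nan)
    else:
        per_sample = []
        for s, sub in binned.groupby("sample"):
            r = sub["mean_ratio"].to_numpy()
            low = float(np.mean(r < 0.2))
            high = float(np.mean(r > 0.8))
            per_sample.append((low, 1.0 - low - high, high))
        bins = tuple(float(np.mean([b[i] for b in per_sample])) for i in range(3))

    noncpg = {}
    for ctx in ("CpA", "CpC", "CpT"):
        sub = counts[(counts["context"] == ctx) & (counts["n_total"] > 0)]
        if len(sub):
            ratios = sub["n_meth"] / sub["n_total"]
            noncpg[ctx] = float(ratios.mean())
    return SpeciesProfile(
        species_id=species_id,
        mean_cpg_methylation=species_mean,
        fragment_bin_fractions=bins,
        pdr=None,
        noncpg_methylation=noncpg,
        n_samples=sample_means.shape[0],
    )


# ---------------------------------------------------------------------------
# Non-CpG methylation in brain vs other tissues
# ---------------------------------------------------------------------------

def noncpg_level(counts: pd.DataFrame) -> float:
    """Mean non-CpG (CpA/CpC/CpT) cytosine methylation ratio."""
    sub = counts[counts["context"].isin(["CpA", "CpC", "CpT"]) & (counts["n_total"] > 0)]
    if sub.empty:
        return np.nan
    return float((sub["n_meth"] / sub["n_total"]).mean())


def noncpg_brain_logratio(
    per_species: Mapping[str, Mapping[str, pd.DataFrame]],
    brain_label: str = "brain",
) -> Tuple[pd.Series, Optional[float]]:
    """Per-species ln(brain non-CpG / mean other-tissue non-CpG) and a
    one-sided paired Wilcoxon p-value for brain excess across species.

    ``per_species`` maps species -> tissue -> counts table. Species
    lacking a brain sample, a non-brain tissue, or with a zero
    denominator are excluded with a warning.
    """
    ratios = {}
    for sp, tissues in per_species.items():
        if brain_label not in tissues:
            continue
        others = [noncpg_level(t) for name, t in tissues.items() if name != brain_label]
        others = [x for x in others if np.isfinite(x)]
        if not others:
            continue
        brain = noncpg_level(tissues[brain_label])
        denom = float(np.mean(others))
        if not np.isfinite(brain) or denom <= 0:
            warnings.warn(f"species {sp} excluded from non-CpG log-ratio (zero denominator)")
            continue
        ratios[sp] = float(np.log(brain / denom))
    series = pd.Series(ratios, dtype=float)
    if len(series) < 2 or np.allclose(series, 0):
        return series, None
    stat = stats.wilcoxon(series, alternative="greater")
    return series, float(stat.pvalue)


# ---------------------------------------------------------------------------
# PDR
# ---------------------------------------------------------------------------

def classify_read_concordance(
    states: Sequence[Optional[str]],
    min_valid_cpgs: int = 4,
    drop_end_cpgs: bool = True,
) -> str:
    """Classify one read's CpG state vector.

    The first and last CpG on the read are disregarded as potentially
    unreliable; reads with fewer than ``min_valid_cpgs`` valid ('M'/'U')
    states among the rest are 'invalid'; uniform states are
    'concordant', mixed 'discordant'.
    """
    inner = list(states[1:-1]) if drop_end_cpgs and len(states) >= 2 else list(states)
    valid = [s for s in inner if s in ("M", "U")]
    if len(valid) < min_valid_cpgs:
        return "invalid"
    return "concordant" if len(set(valid)) == 1 else "discordant"


def compute_pdr(
    callset: MethylationCallSet,
    min_valid_cpgs: int = 4,
    drop_end_cpgs: bool = True,
) -> Tuple[pd.DataFrame, pd.Series, float]:
    """Per-CpG, per-sample, and overall PDR from retained read vectors.

    A valid read contributes its classification to every CpG it validly
    covers (the non-end CpGs with an M/U state). CpG PDR = discordant /
    (concordant + discordant); sample PDR = unweighted mean over CpGs
    with >= 1 valid read; the overall value is the mean over samples.
    """
    rows: Dict[Tuple[str, str, int], List[int]] = {}
    for (sample, fragment), reads in callset.read_states.items():
        for states in reads:
            cls = classify_read_concordance(states, min_valid_cpgs, drop_end_cpgs)
            if cls == "invalid":
                continue
            inner_idx = range(1, len(states) - 1) if drop_end_cpgs and len(states) >= 2 else range(len(states))
            for i in inner_idx:
                if states[i] in ("M", "U"):
                    key = (sample, fragment, i)
                    c = rows.setdefault(key, [0, 0])
                    if cls == "discordant":
                        c[0] += 1
                    c[1] += 1
    recs = [(s, f, i, d, n, d / n) for (s, f, i), (d, n) in rows.items()]
    per_cpg = pd.DataFrame(recs, columns=["sample", "fragment", "cpg_index", "n_discordant", "n_valid", "pdr"])
    if per_cpg.empty:
        raise ValueError("no valid reads anywhere")
    per_sample = per_cpg.groupby("sample")["pdr"].mean()
    return per_cpg, per_sample, float(per_sample.mean())


@dataclass
class ExpectedPdrCurve:
    m_grid: np.ndarray
    n_cpgs_per_read: int
    expected: np.ndarray
    argmax_m: float


def expected_pdr(m_grid: Optional[np.ndarray] = None, n: int = 4) -> ExpectedPdrCurve:
    """Null expected PDR as a function of methylation level m.

    With n independent CpGs per read each methylated with probability
    m, a read is discordant unless all CpGs agree:
    E[PDR](m) = 1 - m^n - (1-m)^n. The curve vanishes at m in {0, 1},
    is symmetric about 0.5, and peaks there.
    """
    if n < 4:
        raise ValueError("n must be >= 4 (minimum valid CpGs per read)")
    if m_grid is None:
        m_grid = np.arange(0.0, 1.0 + 1e-12, 0.001)
    m_grid = np.asarray(m_grid, dtype=float)
    expected = 1.0 - m_grid ** n - (1.0 - m_grid) ** n
    argmax = float(m_grid[int(np.argmax(expected))])
    return ExpectedPdrCurve(m_grid=m_grid, n_cpgs_per_read=n, expected=expected, argmax_m=argmax)
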