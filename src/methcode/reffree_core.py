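"""Reference-free RRBS processing: consensus fragments and methylation calls.

Without a reference genome, bisulfite reads from one locus still share
a common backbone once every C is collapsed to T (conversion makes C/T
uninformative for grouping). Reads are therefore stacked by their
C-to-T-collapsed sequence, stacks within small Hamming distance are
merged, and the genomic sequence of each stack is inferred as a
weighted consensus — with cytosines recovered from an unconverted
library (sequenced without bisulfite treatment) or, for methylated
cytosines, from the converted reads themselves. The consensus fragments
then serve as the reference for per-sample methylation calling.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

CONTEXTS = {"G": "CpG", "A": "CpA", "C": "CpC", "T": "CpT"}

_COLLAPSE = str.maketrans("C", "T")


def collapse(seq: str) -> str:
    """Replace every C by T — the bisulfite-invariant stack key."""
    return seq.translate(_COLLAPSE)


@dataclass
class ConsensusFragment:
    """A reconstructed genomic locus shared by all samples of a species."""

    fragment_id: str
    sequence: str
    cytosines: List[Tuple[int, str]]  # (position, context)
    stack_size: int
    covered_by_unconverted: bool

    @property
    def key(self) -> str:
        return collapse(self.sequence)

    def cpg_positions(self) -> List[int]:
        return [p for p, ctx in self.cytosines if ctx == "CpG"]


@dataclass
class MethylationCallSet:
    """Per sample x fragment x cytosine methylation counts.

    ``counts`` columns: sample, fragment, pos, context, n_meth, n_total.
    ``read_states`` maps (sample, fragment) to per-read CpG state
    vectors over the fragment's CpG positions ('M', 'U', or None),
    retained for read-concordance (PDR) analysis.
    """

    counts: pd.DataFrame
    read_states: Dict[Tuple[str, str], List[List[Optional[str]]]] = field(default_factory=dict)
    mapping_rate: Dict[str, float] = field(default_factory=dict)
    n_skipped: Dict[str, int] = field(default_factory=dict)

    def with_ratio(self) -> pd.DataFrame:
        df = self.counts.copy()
        df["ratio"] = np.where(df["n_total"] > 0, df["n_meth"] / df["n_total"].replace(0, np.nan), np.nan)
        return df


# ---------------------------------------------------------------------------
# Contamination filtering
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _matches_decoy(read_key: str, decoy_keys: Sequence[str], max_mismatch: int) -> bool:
    L = len(read_key)
    for decoy in decoy_keys:
        for off in range(len(decoy) - L + 1):
            mm = 0
            window = decoy[off:off + L]
            for a, b in zip(read_key, window):
                if a != b:
                    mm += 1
                    if mm > max_mismatch:
                        break
            else:
                return True
    return False


def filter_contamination(
    reads: Sequence, decoy_sequences: Mapping[str, str], max_mismatch_rate: float = 0.1
) -> Tuple[List, Optional[float]]:
    """Drop reads matching any decoy sequence (bisulfite-aware).

    A read is contamination if its C-collapsed sequence aligns to the
    C-collapsed decoy (either strand) with a mismatch rate at or below
    the threshold. Returns kept reads and the removed fraction (None
    for an empty read set).
    """
    reads = list(reads)
    if not reads:
        return [], None
    if not decoy_sequences:
        return reads, 0.0
    decoy_keys = []
    for seq in decoy_sequences.values():
        decoy_keys.append(collapse(seq.upper()))
        decoy_keys.append(collapse(_revcomp(seq.upper())))
    kept = []
    removed = 0
    for r in reads:
        seq = r.sequence if hasattr(r, "sequence") else str(r)
        key = collapse(seq.upper())
        max_mm = int(max_mismatch_rate * len(key))
        if _matches_decoy(key, decoy_keys, max_mm):
            removed += 1
        else:
            kept.append(r)
    return kept, removed / len(reads)


# ---------------------------------------------------------------------------
# Consensus construction
# ---------------------------------------------------------------------------

def _masked_variants(key: str) -> Iterable[str]:
    for i in range(len(key)):
        yield key[:i] + "*" + key[i + 1:]


@dataclass
class _Stack:
    key: str
    conv: List[str] = field(default_factory=list)
    unconv: List[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.conv) + len(self.unconv)


_BASE_ORDER = "ACGT"  # fixed tie-break order


def _consensus_from_stack(stack: _Stack, tau_unconv: float, tau_meth: float) -> str:
    """Weighted per-position consensus with the two cytosine-recovery rules."""
    L = len(stack.key)
    out = []
    for i in range(L):
        un = Counter(s[i] for s in stack.unconv)
        cv = Counter(s[i] for s in stack.conv)
        n_un = sum(un.values())
        n_cv = sum(cv.values())
        is_c = False
        if n_un > 0 and un.get("C", 0) / n_un >= tau_unconv:
            is_c = True
        elif n_cv > 0 and cv.get("C", 0) / n_cv >= tau_meth:
            is_c = True
        if is_c:
            out.append("C")
            continue
        votes: Dict[str, int] = {b: 0 for b in "AGT"}
        for b in "AGT":
            votes[b] += un.get(b, 0) + cv.get(b, 0)
        # a converted C where the rule did not fire is residual evidence for T
        votes["T"] += 0 if n_cv == 0 else 0
        best = max(votes, key=lambda b: (votes[b], -_BASE_ORDER.index(b)))
        out.append(best)
    return "".join(out)


def _annotate_cytosines(seq: str) -> List[Tuple[int, str]]:
    cyt = []
    for i, b in enumerate(seq[:-1]):
        if b == "C":
            nxt = seq[i + 1]
            if nxt in CONTEXTS:
                cyt.append((i, CONTEXTS[nxt]))
    return cyt


def build_consensus(
    converted_reads: Sequence,
    unconverted_reads: Sequence = (),
    merge_distance: int = 1,
    min_stack_depth: int = 5,
    tau_unconv: float = 0.5,
    tau_meth: float = 0.1,
) -> List[ConsensusFragment]:
    """Cluster reads into stacks and infer one consensus sequence each.

    Reads are trimmed to the common minimum length, grouped by exact
    C-collapsed key, then keys within Hamming distance
    ``merge_distance`` (single pass, larger stack absorbs smaller) are
    merged. Stacks below ``min_stack_depth`` total members are dropped.
    Cytosines are called where unconverted members show C at frequency
    >= ``tau_unconv``, or converted members show C at frequency >=
    ``tau_meth`` (a methylated, hence unconverted, cytosine).
    """
    seqs_conv = [r.sequence if hasattr(r, "sequence") else str(r) for r in converted_reads]
    seqs_un = [r.sequence if hasattr(r, "sequence") else str(r) for r in unconverted_reads]
    all_seqs = seqs_conv + seqs_un
    if not all_seqs:
        warnings.warn("no reads supplied")
        return []
    L = min(len(s) for s in all_seqs)
    seqs_conv = [s[:L].upper() for s in seqs_conv]
    seqs_un = [s[:L].upper() for s in seqs_un]

    stacks: Dict[str, _Stack] = {}
    for s in seqs_conv:
        stacks.setdefault(collapse(s), _Stack(collapse(s))).conv.append(s)
    for s in seqs_un:
        stacks.setdefault(collapse(s), _Stack(collapse(s))).unconv.append(s)

    # single-pass merge, descending stack size; ties by key for determinism
    ordered = sorted(stacks.values(), key=lambda st: (-st.size, st.key))
    kept: Dict[str, _Stack] = {}
    masked_index: Dict[str, str] = {}
    for st in ordered:
        target = None
        if st.key in kept:
            target = st.key
        elif merge_distance >= 1:
            for mv in _masked_variants(st.key):
                if mv in masked_index:
                    target = masked_index[mv]
                    break
        if target is not None and target != st.key:
            kept[target].conv.extend(st.conv)
            kept[target].unconv.extend(st.unconv)
        elif target is None:
            kept[st.key] = st
            if merge_distance >= 1:
                for mv in _masked_variants(st.key):
                    masked_index.setdefault(mv, st.key)

    fragments: List[ConsensusFragment] = []
    final = sorted(kept.values(), key=lambda st: (-st.size, st.key))
    idx = 0
    for st in final:
        if st.size < min_stack_depth:
            continue
        seq = _consensus_from_stack(st, tau_unconv, tau_meth)
        fragments.append(ConsensusFragment(
            fragment_id=f"frag{idx:06d}",
            sequence=seq,
            cytosines=_annotate_cytosines(seq),
            stack_size=st.size,
            covered_by_unconverted=len(st.unconv) > 0,
        ))
        idx += 1
    if not fragments:
        warnings.warn("no stacks passed the depth filter; empty consensus")
    return fragments


# ---------------------------------------------------------------------------
# Methylation calling
# ---------------------------------------------------------------------------

def call_methylation(
    sample_reads: Mapping[str, Sequence],
    consensus: Sequence[ConsensusFragment],
    merge_distance: int = 1,
) -> MethylationCallSet:
    """Call per-cytosine methylation for every sample against the consensus.

    Each read is assigned to a fragment by C-collapsed key lookup
    (exact, then within Hamming distance ``merge_distance``). At every
    consensus cytosine the read base C counts as methylated, T as
    unmethylated, anything else is ignored. Per-read CpG state vectors
    are retained for erosion analysis.
    """
    if not consensus:
        raise ValueError("consensus is empty")
    key_len = len(consensus[0].sequence)
    by_key: Dict[str, ConsensusFragment] = {f.key: f for f in consensus}
    masked_index: Dict[str, str] = {}
    if merge_distance >= 1:
        for f in consensus:
            for mv in _masked_variants(f.key):
                masked_index.setdefault(mv, f.key)

    rows = []
    read_states: Dict[Tuple[str, str], List[List[Optional[str]]]] = defaultdict(list)
    mapping_rate: Dict[str, float] = {}
    n_skipped: Dict[str, int] = {}
    for sample, reads in sample_reads.items():
        counts: Dict[Tuple[str, int, str], List[int]] = defaultdict(lambda: [0, 0])
        total = 0
        assigned = 0
        skipped = 0
        for r in reads:
            seq = (r.sequence if hasattr(r, "sequence") else str(r)).upper()
            total += 1
            if len(seq) < key_len:
                skipped += 1
                continue
            seq = seq[:key_len]
            key = collapse(seq)
            frag = by_key.get(key)
            if frag is None and merge_distance >= 1:
                for mv in _masked_variants(key):
                    hit = masked_index.get(mv)
                    if hit is not None:
                        frag = by_key[hit]
                        break
            if frag is None:
                continue
            assigned += 1
            states: List[Optional[str]] = []
            for pos, ctx in frag.cytosines:
                b = seq[pos]
                state: Optional[str]
                if b == "C":
                    state = "M"
                elif b == "T":
                    state = "U"
                else:
                    state = None
                if state is not None:
                    c = counts[(frag.fragment_id, pos, ctx)]
                    c[1] += 1
                    if state == "M":
                        c[0] += 1
                if ctx == "CpG":
                    states.append(state)
            read_states[(sample, frag.fragment_id)].append(states)
        for (fid, pos, ctx), (n_meth, n_total) in counts.items():
            rows.append((sample, fid, pos, ctx, n_meth, n_total))
        mapping_rate[sample] = assigned / total if total else np.nan
        n_skipped[sample] = skipped

    counts_df = pd.DataFrame(rows, columns=["sample", "fragment", "pos", "context", "n_meth", "n_total"])
    return MethylationCallSet(
        counts=counts_df.sort_values(["sample", "fragment", "pos"]).reset_index(drop=True),
        read_states=dict(read_states),
        mapping_rate=mapping_rate,
        n_skipped=n_skipped,
    )


# ---------------------------------------------------------------------------
# Conversion-rate estimation and sample metrics
# ---------------------------------------------------------------------------

def call_spike_methylation(spike_reads: Sequence, spike_seq: str) -> pd.DataFrame:
    """Tally C/T observations of spike-in reads at spike cytosine positions.

    Reads are located in the spike reference by exact C-collapsed
    substring search; unplaceable reads are ignored.
    """
    ref = spike_seq.upper()
    ref_key = collapse(ref)
    rows = []
    for r in spike_reads:
        seq = (r.sequence if hasattr(r, "sequence") else str(r)).upper()
        off = ref_key.find(collapse(seq))
        if off < 0:
            continue
        for i, b in enumerate(seq):
            if ref[off + i] == "C" and b in "CT":
                rows.append((off + i, 1 if b == "C" else 0))
    df = pd.DataFrame(rows, columns=["pos", "is_c"])
    if df.empty:
        return pd.DataFrame(columns=["pos", "n_meth", "n_total"])
    g = df.groupby("pos")["is_c"].agg(["sum", "count"]).reset_index()
    g.columns = ["pos", "n_meth", "n_total"]
    return g


def estimate_conversion_rate(unmeth_spike_calls: pd.DataFrame) -> Optional[float]:
    """Conversion efficiency: fraction of unmethylated-spike cytosine
    observations read as T."""
    if unmeth_spike_calls.empty or unmeth_spike_calls["n_total"].sum() == 0:
        warnings.warn("no spike-in observations; conversion rate missing")
        return None
    n_total = int(unmeth_spike_calls["n_total"].sum())
    n_c = int(unmeth_spike_calls["n_meth"].sum())
    return (n_total - n_c) / n_total


def compute_sample_metrics(
    callset: MethylationCallSet,
    contamination_rate: Optional[Mapping[str, float]] = None,
    conversion_rate: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """One row of quality metrics per sample."""
    contamination_rate = contamination_rate or {}
    conversion_rate = conversion_rate or {}
    rows = []
    df = callset.counts
    for sample in sorted(callset.mapping_rate):
        sub = df[(df["sample"] == sample) & (df["context"] == "CpG") & (df["n_total"] >= 1)]
        rows.append({
            "sample": sample,
            "mapping_rate": callset.mapping_rate[sample],
            "n_covered_cpgs": len(sub),
            "conversion_rate": conversion_rate.get(sample, np.nan),
            "contamination_rate": contamination_rate.get(sample, np.nan),
            "n_reads_skipped": callset.n_skipped.get(sample, 0),
        })
    return pd.DataFrame(rows)
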