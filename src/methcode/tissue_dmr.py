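"""Tissue-level differential methylation and TF motif analysis.

Heart-vs-liver (or any two-tissue) differential methylation runs in
three stages: a per-CpG moderated two-group t-test (empirical-Bayes
variance shrinkage across CpGs), combination of per-CpG p-values
within each consensus fragment by a correlation-corrected (Brown-style)
Fisher test, and a combined-rank selection of the top-500 fragments per
direction by p-value, relative difference, and absolute difference.
Selected fragment sets feed a PWM motif enrichment (exact-threshold
log-odds scanning, one-sided Fisher exact test, BH correction), whose
significant hits are translated into per-TF tissue-activity calls and a
regulator network via user-supplied preference / expression / target
tables. A variance decomposition quantifies how much of the
between-sample structure tissue vs individual explains.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

# ---------------------------------------------------------------------------
# Variance decomposition
# ---------------------------------------------------------------------------

@dataclass
class VarianceDecomposition:
    per_species: pd.DataFrame  # species x (r2_tissue, r2_individual, n_pairs_*)
    p_value: Optional[float]   # two-sided paired Wilcoxon across species


def _pair_r2(a: pd.Series, b: pd.Series, min_shared: int) -> Optional[float]:
    common = a.index.intersection(b.index)
    if len(common) < min_shared:
        return None
    x, y = a.loc[common], b.loc[common]
    if x.std() == 0 or y.std() == 0:
        return None
    return float(stats.pearsonr(x, y)[0] ** 2)


def variance_decomposition(
    fragment_means: Mapping[str, pd.DataFrame],
    metadata: pd.DataFrame,
    min_shared_fragments: int = 100,
) -> VarianceDecomposition:
    """Average squared Pearson correlation by tissue and by individual.

    ``fragment_means`` maps species -> table with columns (sample,
    fragment, mean_ratio); ``metadata`` has columns sample, species,
    tissue, individual. r2_tissue averages over same-tissue /
    different-individual sample pairs, r2_individual over
    same-individual / different-tissue pairs; pairs share at least
    ``min_shared_fragments`` fragments. Species need >= 2 individuals,
    >= 2 tissues, and at least one tissue shared between individuals.
    The group-level p-value is a two-sided paired Wilcoxon on
    (r2_tissue - r2_individual) across species.
    """
    rows = {}
    for sp, fm in fragment_means.items():
        meta = metadata[metadata["species"] == sp].set_index("sample")
        if meta["individual"].nunique() < 2 or meta["tissue"].nunique() < 2:
            continue
        shared_tissue = meta.groupby("tissue")["individual"].nunique()
        if not (shared_tissue >= 2).any():
            continue
        profiles = {s: g.set_index("fragment")["mean_ratio"]
                    for s, g in fm.groupby("sample") if s in meta.index}
        r2_t, r2_i = [], []
        for a, b in combinations(sorted(profiles), 2):
            ta, tb = meta.loc[a, "tissue"], meta.loc[b, "tissue"]
            ia, ib = meta.loc[a, "individual"], meta.loc[b, "individual"]
            if ta == tb and ia != ib:
                r2 = _pair_r2(profiles[a], profiles[b], min_shared_fragments)
                if r2 is not None:
                    r2_t.append(r2)
            elif ia == ib and ta != tb:
                r2 = _pair_r2(profiles[a], profiles[b], min_shared_fragments)
                if r2 is not None:
                    r2_i.append(r2)
        rows[sp] = {
            "r2_tissue": float(np.mean(r2_t)) if r2_t else np.nan,
            "r2_individual": float(np.mean(r2_i)) if r2_i else np.nan,
            "n_pairs_tissue": len(r2_t),
            "n_pairs_individual": len(r2_i),
        }
    table = pd.DataFrame(rows).T
    p = None
    if len(table) >= 2:
        ok = table[["r2_tissue", "r2_individual"]].dropna()
        diffs = ok["r2_tissue"] - ok["r2_individual"]
        if len(diffs) >= 2 and not np.allclose(diffs, 0):
            p = float(stats.wilcoxon(diffs, alternative="two-sided").pvalue)
    return VarianceDecomposition(per_species=table, p_value=p)


# ---------------------------------------------------------------------------
# Moderated per-CpG test
# ---------------------------------------------------------------------------

def _fit_f_dist(s2: np.ndarray, df: float) -> Tuple[float, float]:
    """Moment fit of a scaled F prior to sample variances.

    Returns (d0, s0^2): the prior degrees of freedom and prior
    variance such that s^2 ~ s0^2 F(df, d0). d0 = inf means no excess
    dispersion (variances are exchangeable).
    """
    s2 = np.asarray(s2, float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 2:
        return np.inf, float(np.mean(s2)) if len(s2) else 1.0
    z = np.log(s2)
    e = z - digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(math.exp(e_mean))
    # invert trigamma by Newton iteration
    x = 0.5 + 1.0 / e_var
    for _ in range(50):
        tri = float(polygamma(1, x))
        diff = tri - e_var
        deriv = float(polygamma(2, x))
        step = diff / deriv
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < 1e-10:
            x = x_new
            break
        x = x_new
    d0 = 2.0 * x
    s0_2 = math.exp(e_mean + digamma(x) - math.log(x))
    return d0, s0_2


def cpg_differential_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
) -> pd.DataFrame:
    """Moderated two-group t-test per CpG with BH-adjusted q-values.

    ``group_a`` / ``group_b`` are CpG x sample matrices of methylation
    ratios (NaN allowed). Per-CpG pooled variances are shrunk toward a
    prior fitted across CpGs: s2_post = (d0 s0^2 + d s^2)/(d0 + d),
    and the t statistic is referred to d0 + d degrees of freedom.
    """
    A = np.asarray(group_a, float)
    B = np.asarray(group_b, float)
    if A.ndim == 1:
        A = A[None, :]
        B = B[None, :]
    n_a = np.sum(np.isfinite(A), axis=1)
    n_b = np.sum(np.isfinite(B), axis=1)
    if np.all(n_a < 2) or np.all(n_b < 2):
        raise ValueError("need >= 2 samples per tissue")
    mean_a = np.nanmean(np.where(np.isfinite(A), A, np.nan), axis=1)
    mean_b = np.nanmean(np.where(np.isfinite(B), B, np.nan), axis=1)
    var_a = np.nanvar(A, axis=1, ddof=1)
    var_b = np.nanvar(B, axis=1, ddof=1)
    d = n_a + n_b - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / d
    valid = (n_a >= 2) & (n_b >= 2) & np.isfinite(s2)

    df_typical = float(np.median(d[valid])) if valid.any() else 2.0
    pos = valid & (s2 > 0)
    if pos.sum() >= 10:
        d0, s0_2 = _fit_f_dist(s2[pos], df_typical)
    else:
        if valid.any() and not pos.any():
            warnings.warn("all variances zero; falling back to unmoderated exact comparison")
        d0, s0_2 = np.inf, float(np.nanmean(s2[valid])) if valid.any() else 1.0
        if not np.isfinite(s0_2) or s0_2 <= 0:
            s0_2 = 1e-8

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_post = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_post = d0 + d
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
        t = (mean_a - mean_b) / se
    p = np.full(len(t), np.nan)
    finite = valid & np.isfinite(t)
    if np.isscalar(df_post) or np.ndim(df_post) == 0:
        df_arr = np.full(len(t), df_post)
    else:
        df_arr = np.asarray(df_post, float)
    inf_df = ~np.isfinite(df_arr)
    p[finite & inf_df] = 2.0 * stats.norm.sf(np.abs(t[finite & inf_df]))
    fin = finite & ~inf_df
    p[fin] = 2.0 * stats.t.sf(np.abs(t[fin]), df_arr[fin])
    zero_sig = valid & ~np.isfinite(t)  # zero variance and zero difference, or 0/0
    same = valid & (np.abs(mean_a - mean_b) < 1e-15)
    p[same & ~np.isfinite(p)] = 1.0
    p[valid & ~np.isfinite(p)] = 1.0

    out = pd.DataFrame({
        "mean_a": mean_a, "mean_b": mean_b, "diff": mean_a - mean_b,
        "t": t, "p": p,
    })
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN passed through)."""
    p = np.asarray(p, float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    ps = p[ok]
    m = len(ps)
    if m == 0:
        return q
    order = np.argsort(ps)
    ranked = ps[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.clip(ranked, 0, 1)
    q[ok] = adj
    return q


# ---------------------------------------------------------------------------
# Fragment-level p-value combination
# ---------------------------------------------------------------------------

def combine_fragment_p(
    p_values: Sequence[float],
    method: str = "brown",
    correlation: Optional[np.ndarray] = None,
) -> float:
    """Combine per-CpG p-values of one fragment.

    fisher: X = -2 sum ln p referred to chi-square with 2m df. brown:
    the same statistic referred to a scaled chi-square whose moments
    absorb the inter-CpG correlation (pairwise correlations of the
    underlying CpG signals, approximated by Brown's polynomial); with
    no correlation estimate it degrades to plain Fisher.
    """
    p = np.asarray(list(p_values), float)
    if len(p) == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0):
        warnings.warn("p-value of 0 clipped to 1e-300")
        p = np.clip(p, 1e-300, 1.0)
    m = len(p)
    X = -2.0 * np.log(p).sum()
    if m == 1:
        return float(p[0])
    if method == "fisher" or correlation is None:
        return float(stats.chi2.sf(X, 2 * m))
    if method != "brown":
        raise ValueError(f"unknown method {method!r}")
    cov_sum = 0.0
    for i in range(m):
        for j in range(i + 1, m):
            rho = correlation[i, j]
            if not np.isfinite(rho):
                continue
            rho = float(np.clip(rho, -1.0, 1.0))
            if rho >= 0:
                cov_sum += rho * (3.25 + 0.75 * rho)
            else:
                cov_sum += rho * (3.27 + 0.71 * rho)
    e_x = 2.0 * m
    var_x = 4.0 * m + 2.0 * cov_sum
    if var_x <= 0:
        return float(stats.chi2.sf(X, 2 * m))
    f = 2.0 * e_x ** 2 / var_x
    c = var_x / (2.0 * e_x)
    return float(stats.chi2.sf(X / c, f))


def fragment_level_p(
    cpg_table: pd.DataFrame,
    ratios_a: Optional[np.ndarray] = None,
    ratios_b: Optional[np.ndarray] = None,
    method: str = "brown",
) -> pd.DataFrame:
    """Per-fragment combined p from a per-CpG test table.

    ``cpg_table`` needs columns fragment and p (one row per CpG, in
    matrix row order when ratio matrices are given). For the brown
    method, per-fragment inter-CpG correlations are estimated from the
    concatenated per-sample ratios of both groups.
    """
    rows = []
    for frag, sub in cpg_table.groupby("fragment"):
        p = sub["p"].dropna().to_numpy()
        if len(p) == 0:
            continue
        corr = None
        if method == "brown" and ratios_a is not None and len(sub) > 1:
            idx = sub.index.to_numpy()
            M = np.hstack([ratios_a[idx], ratios_b[idx]])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                corr = pd.DataFrame(M.T).corr().to_numpy()
        rows.append({"fragment": frag, "p_combined": combine_fragment_p(p, method, corr),
                     "n_cpgs": len(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Combined-rank DMR selection
# ---------------------------------------------------------------------------

@dataclass
class DmrResult:
    table: pd.DataFrame  # per fragment: stats, ranks, direction, selected

    def selected(self, direction: Optional[str] = None) -> pd.DataFrame:
        df = self.table[self.table["selected"]]
        if direction is not None:
            df = df[df["direction"] == direction]
        return df


def rank_dmrs(
    fragment_stats: pd.DataFrame,
    top_k: int = 500,
    p_thresh: float = 0.05,
    min_coverage: float = 2.0,
) -> DmrResult:
    """Combined-rank selection of differential fragments per direction.

    ``fragment_stats`` columns: fragment, p_combined, mean_a, mean_b,
    coverage_a, coverage_b. Relative difference uses the mean of the
    two tissue means as denominator. Within each direction fragments
    are ranked ascending by p, by -|relative diff|, and by -|absolute
    diff|; the combined rank is the maximum of the three; the top_k
    smallest combined ranks among fragments with p < ``p_thresh`` and
    coverage >= ``min_coverage`` in both tissues are selected. Ties
    break by fragment id.
    """
    df = fragment_stats.copy()
    df["abs_diff"] = df["mean_a"] - df["mean_b"]
    denom = (df["mean_a"] + df["mean_b"]) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        df["rel_diff"] = np.where(denom > 0, df["abs_diff"] / denom, 0.0)
    df["direction"] = np.where(df["abs_diff"] < 0, "hypo_in_a", "hypo_in_b")
    df["eligible"] = (
        (df["p_combined"] < p_thresh)
        & (df["coverage_a"] >= min_coverage)
        & (df["coverage_b"] >= min_coverage)
    )
    df["selected"] = False
    for direction, sub in df.groupby("direction"):
        sub = sub.sort_values("fragment")
        r_p = sub["p_combined"].rank(method="min")
        r_rel = (-sub["rel_diff"].abs()).rank(method="min")
        r_abs = (-sub["abs_diff"].abs()).rank(method="min")
        combined = pd.concat([r_p, r_rel, r_abs], axis=1).max(axis=1)
        df.loc[sub.index, "rank_p"] = r_p
        df.loc[sub.index, "rank_rel"] = r_rel
        df.loc[sub.index, "rank_abs"] = r_abs
        df.loc[sub.index, "combined_rank"] = combined
        elig = sub.index[df.loc[sub.index, "eligible"]]
        chosen = df.loc[elig].sort_values(["combined_rank", "fragment"]).head(top_k).index
        df.loc[chosen, "selected"] = True
    return DmrResult(table=df)


# ---------------------------------------------------------------------------
# PWM motif enrichment
# ---------------------------------------------------------------------------

@dataclass
class Pwm:
    name: str
    matrix: np.ndarray  # length x 4 (A, C, G, T), column-stochastic rows

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


def read_meme(path_or_text: str) -> List[Pwm]:
    """Parse MEME-format position weight matrices (minimal subset)."""
    if "\n" in path_or_text or "MOTIF" in path_or_text.upper().split("/")[-1][:5]:
        text = path_or_text if "\n" in path_or_text else open(path_or_text).read()
    else:
        text = open(path_or_text).read()
    pwms: List[Pwm] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            name = parts[1] if len(parts) > 1 else f"motif{len(pwms)}"
            rows = []
            i += 1
            while i < len(lines):
                l = lines[i].strip()
                if l.startswith("letter-probability"):
                    i += 1
                    continue
                vals = l.split()
                if len(vals) == 4:
                    try:
                        rows.append([float(v) for v in vals])
                        i += 1
                        continue
                    except ValueError:
                        pass
                if rows or l.startswith("MOTIF"):
                    break
                i += 1
            mat = np.array(rows, float)
            if mat.size == 0 or np.any(mat.sum(axis=1) <= 0):
                raise ValueError(f"invalid motif {name}: empty or zero-sum rows")
            mat = mat / mat.sum(axis=1, keepdims=True)
            pwms.append(Pwm(name, mat))
        else:
            i += 1
    return pwms


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _log_odds(pwm: Pwm, background: np.ndarray, pseudo: float = 1e-3) -> np.ndarray:
    p = (pwm.matrix + pseudo) / (1 + 4 * pseudo)
    return np.log2(p / background[None, :])


def pwm_score_threshold(
    score_matrix: np.ndarray, background: np.ndarray, hit_p: float = 1e-4, granularity: float = 0.01
) -> float:
    """Smallest score whose null exceedance probability is <= hit_p.

    Exact distribution of the window score under the 0-order background
    via dynamic programming over a discretized score histogram
    (column-by-column convolution).
    """
    Q = np.round(score_matrix / granularity).astype(int)
    dist: Dict[int, float] = {0: 1.0}
    for col in Q:
        new: Dict[int, float] = {}
        for s, pr in dist.items():
            for b in range(4):
                key = s + col[b]
                new[key] = new.get(key, 0.0) + pr * background[b]
        dist = new
    scores = np.array(sorted(dist))
    probs = np.array([dist[s] for s in scores])
    tail = np.cumsum(probs[::-1])[::-1]
    exceed = np.nonzero(tail <= hit_p)[0]
    # rounding each column to `granularity` shifts sums by at most half a
    # bin per column; subtract that bound so continuous-scale window scores
    # compare against the discretized threshold without false negatives
    margin = granularity * score_matrix.shape[0] / 2.0
    if len(exceed) == 0:
        return float(scores[-1] * granularity + granularity)  # unreachable threshold
    return float(scores[exceed[0]] * granularity - margin)


_COMP = str.maketrans("ACGTN", "TGCAN")


def _scan_hit(seq: str, lo: np.ndarray, threshold: float) -> bool:
    L = lo.shape[0]
    for strand_seq in (seq, seq.translate(_COMP)[::-1]):
        s = strand_seq.upper()
        for i in range(len(s) - L + 1):
            score = 0.0
            ok = True
            for j in range(L):
                b = _BASE_IDX.get(s[i + j])
                if b is None:
                    ok = False
                    break
                score += lo[j, b]
            if ok and score >= threshold:
                return True
    return False


@dataclass
class MotifEnrichment:
    table: pd.DataFrame  # motif, direction, odds_ratio, p, q, significant


def motif_enrichment(
    foreground: Mapping[str, Sequence[str]],
    pwms: Sequence[Pwm],
    hit_p: float = 1e-4,
) -> MotifEnrichment:
    """Motif hit enrichment between opposed fragment sets.

    ``foreground`` maps direction label -> sequences; each direction is
    tested against the union of the other directions as background
    (one-sided Fisher exact, more hits in foreground), with BH
    adjustment across motifs x directions. The 0-order background for
    scoring is estimated from all input sequences.
    """
    all_seqs = [s for seqs in foreground.values() for s in seqs]
    if not all_seqs or any(len(v) == 0 for v in foreground.values()):
        raise ValueError("every direction needs at least one sequence")
    counts = np.zeros(4)
    for s in all_seqs:
        su = s.upper()
        for b, i in _BASE_IDX.items():
            counts[i] += su.count(b)
    background = counts / counts.sum() if counts.sum() else np.full(4, 0.25)
    background = np.clip(background, 1e-6, None)
    background = background / background.sum()

    rows = []
    for pwm in pwms:
        lo = _log_odds(pwm, background)
        thr = pwm_score_threshold(lo, background, hit_p)
        hits = {d: np.array([_scan_hit(s, lo, thr) for s in seqs])
                for d, seqs in foreground.items()}
        for d in foreground:
            fg = hits[d]
            bg = np.concatenate([hits[o] for o in foreground if o != d])
            table = [[int(fg.sum()), int((~fg).sum())], [int(bg.sum()), int((~bg).sum())]]
            odds, p = stats.fisher_exact(table, alternative="greater")
            rows.append({"motif": pwm.name, "direction": d, "n_fg_hits": int(fg.sum()),
                         "n_bg_hits": int(bg.sum()), "odds_ratio": odds, "p": p})
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["q"] < 0.05
    return MotifEnrichment(table=df)


# ---------------------------------------------------------------------------
# TF activity and network
# ---------------------------------------------------------------------------

def tf_activity_and_network(
    enrichment: MotifEnrichment,
    preference: pd.DataFrame,   # tf, preference in {methylated, unmethylated}
    expression: pd.DataFrame,   # tf, heart, liver (normalized expression)
    targets: Optional[pd.DataFrame] = None,  # tf, target, sign
    tissue_a: str = "heart",
    tissue_b: str = "liver",
    expression_threshold: float = 1.0,
    min_enrichments: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Translate motif enrichments into per-TF tissue-activity calls.

    Direction labels are ``hypo_in_<tissue>`` (hypomethylated in that
    tissue, equivalently hypermethylated in the other). A TF preferring
    unmethylated sites enriched among fragments hypomethylated in a
    tissue is active there; a TF preferring methylated sites enriched
    among fragments hypermethylated in a tissue is likewise active
    there. TFs need expression > threshold in at least one tissue.
    Returns (activity calls, network edge list from active TFs to their
    targets).
    """
    pref = preference.set_index("tf")["preference"].to_dict()
    expr = expression.set_index("tf")
    sig = enrichment.table[enrichment.table["significant"]]
    if min_enrichments and len(sig) < min_enrichments:
        sig = sig.iloc[0:0]
    calls = []
    for tf in sorted(set(enrichment.table["motif"])):
        p = pref.get(tf)
        if p is None:
            calls.append({"tf": tf, "preference": None, "expression_ok": False, "activity": "none"})
            continue
        e_ok = False
        if tf in expr.index:
            e_ok = bool((expr.loc[tf, [tissue_a, tissue_b]] > expression_threshold).any())
        activity = "none"
        if e_ok:
            tf_sig = sig[sig["motif"] == tf]
            for _, row in tf_sig.iterrows():
                hypo_tissue = row["direction"].replace("hypo_in_", "")
                hyper_tissue = tissue_b if hypo_tissue == tissue_a else tissue_a
                if p == "unmethylated":
                    activity = hypo_tissue
                elif p == "methylated":
                    activity = hyper_tissue
        calls.append({"tf": tf, "preference": p, "expression_ok": e_ok, "activity": activity})
    calls_df = pd.DataFrame(calls)
    edges = pd.DataFrame(columns=["tf", "target", "sign", "activity"])
    if targets is not None:
        active = calls_df[calls_df["activity"] != "none"]
        edges = targets.merge(active[["tf", "activity"]], on="tf", how="inner")
    return calls_df, edges
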