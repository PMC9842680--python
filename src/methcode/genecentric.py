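"""Gene-centric, reference-based analysis of consensus fragments.

Consensus fragments are cross-mapped to annotated genomes by ungapped
seed-and-extend alignment (11-mer seeds, both strands, mismatch rate
<= 0.2, ambiguous best hits discarded); methylation calls lifted onto
the best genome feed meta-gene profiles (100 bp flank bins over +/- 5
kb, 200 bp body bins), a promoter matrix in human-ortholog space (50 x
50 bp bins spanning 2500 bp upstream of the TSS), neighborhood-graph
embedding with Leiden communities (plus a scrambled control), and
species-held-out tissue / taxon classification with tree ensembles
that route missing values natively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Cross-mapping
# ---------------------------------------------------------------------------

@dataclass
class MappedFragment:
    fragment_id: str
    genome: str
    chrom: str
    start: int
    end: int
    strand: str
    n_mismatches: int


@dataclass
class CrossMapping:
    mappings: Dict[str, MappedFragment]  # fragment -> best placement (best genome only)
    mapping_rate: Dict[str, float]       # per genome
    best_genome: Optional[str]


def _index_genome(chroms: Mapping[str, str], seed_len: int) -> Dict[str, List[Tuple[str, int]]]:
    index: Dict[str, List[Tuple[str, int]]] = {}
    for chrom, seq in chroms.items():
        s = seq.upper()
        for i in range(len(s) - seed_len + 1):
            w = s[i:i + seed_len]
            if "N" in w:
                continue
            index.setdefault(w, []).append((chrom, i))
    return index


def _count_mismatches(a: str, b: str, limit: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def _map_one(
    frag: str,
    chroms: Mapping[str, str],
    index: Dict[str, List[Tuple[str, int]]],
    seed_len: int,
    max_rate: float,
) -> Optional[Tuple[str, int, int, str, int]]:
    L = len(frag)
    limit = int(max_rate * L)
    candidates: Dict[Tuple[str, int, str], None] = {}
    for strand, seq in (("+", frag.upper()), ("-", _revcomp(frag.upper()))):
        for off in range(0, max(1, L - seed_len + 1), seed_len):
            w = seq[off:off + seed_len]
            if len(w) < seed_len:
                break
            for chrom, pos in index.get(w, ()):  # diagonal start
                start = pos - off
                if start < 0 or start + L > len(chroms[chrom]):
                    continue
                candidates[(chrom, start, strand)] = None
    best: List[Tuple[str, int, str, int]] = []
    best_mm = limit + 1
    for (chrom, start, strand) in candidates:
        seq = frag.upper() if strand == "+" else _revcomp(frag.upper())
        mm = _count_mismatches(seq, chroms[chrom].upper()[start:start + L], best_mm)
        if mm < best_mm:
            best_mm = mm
            best = [(chrom, start, strand, mm)]
        elif mm == best_mm and mm <= limit:
            best.append((chrom, start, strand, mm))
    if best_mm > limit or len(best) != 1:
        return None  # unmapped or ambiguous
    chrom, start, strand, mm = best[0]
    return chrom, start, start + L, strand, mm


def crossmap_fragments(
    fragments: Mapping[str, str],
    genomes: Mapping[str, Mapping[str, str]],
    max_mismatch_rate: float = 0.2,
    seed_len: int = 11,
) -> CrossMapping:
    """Map fragments to candidate genomes; pick the best genome.

    Per fragment and genome, the placement with fewest mismatches wins;
    ties between distinct locations make the fragment ambiguous (left
    unmapped). The genome with the highest fraction of mapped fragments
    becomes ``best_genome`` and supplies the retained placements.
    """
    if not genomes:
        raise ValueError("need at least one candidate genome")
    per_genome: Dict[str, Dict[str, MappedFragment]] = {}
    rates: Dict[str, float] = {}
    for gname, chroms in genomes.items():
        index = _index_genome(chroms, seed_len)
        mapped: Dict[str, MappedFragment] = {}
        for fid, frag in fragments.items():
            hit = _map_one(frag, chroms, index, seed_len, max_mismatch_rate)
            if hit is None:
                continue
            chrom, start, end, strand, mm = hit
            assert mm / (end - start) <= max_mismatch_rate
            mapped[fid] = MappedFragment(fid, gname, chrom, start, end, strand, mm)
        per_genome[gname] = mapped
        rates[gname] = len(mapped) / len(fragments) if fragments else 0.0
    best = max(rates, key=lambda g: (rates[g], g)) if any(rates.values()) else None
    if best is None:
        warnings.warn("no genome yields any mapping")
        return CrossMapping({}, rates, None)
    return CrossMapping(per_genome[best], rates, best)


# ---------------------------------------------------------------------------
# Gene profiles
# ---------------------------------------------------------------------------

@dataclass
class GeneProfile:
    per_gene: pd.DataFrame    # gene x bin, NaN for missing bins
    meta: pd.Series           # mean profile over genes with any data
    bin_labels: List[str]
    dip_statistic: float      # mean(all bins) - min(promoter bins)


def _bin_means(calls: pd.DataFrame, chrom: str, intervals: List[Tuple[int, int]]) -> List[float]:
    sub = calls[calls["chrom"] == chrom]
    out = []
    for s, e in intervals:
        vals = sub[(sub["pos"] >= s) & (sub["pos"] < e)]["ratio"]
        out.append(float(vals.mean()) if len(vals) else np.nan)
    return out


def gene_profile(
    calls: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = 5000,
    flank_bin: int = 100,
    body_bin: int = 200,
    n_body_bins_meta: int = 20,
    promoter_window: Tuple[int, int] = (1000, 500),
) -> GeneProfile:
    """Meta-gene methylation profile with flank and body bins.

    ``calls`` columns: chrom, pos, ratio (per-CpG methylation on the
    genome); ``genes`` columns: gene, chrom, start, end, strand. The
    upstream flank (5' of the TSS) occupies bins 0..49, the gene body
    (rescaled to ``n_body_bins_meta`` bins) follows, then the
    downstream flank; minus-strand genes are flipped so bin 0 is always
    5' upstream. The promoter dip statistic is the mean over all bins
    minus the minimum over the promoter bins (those covering
    ``promoter_window`` = (upstream, downstream) bp around the TSS).
    """
    n_flank = flank // flank_bin
    calls = calls.copy()
    rows = {}
    for _, g in genes.iterrows():
        start, end, strand = int(g["start"]), int(g["end"]), g["strand"]
        up = [(start - flank + i * flank_bin, start - flank + (i + 1) * flank_bin) for i in range(n_flank)]
        down = [(end + i * flank_bin, end + (i + 1) * flank_bin) for i in range(n_flank)]
        n_body = max(1, -(-(end - start) // body_bin))
        body = [(start + i * body_bin, min(end, start + (i + 1) * body_bin)) for i in range(n_body)]
        vals_up = _bin_means(calls, g["chrom"], up)
        vals_body = _bin_means(calls, g["chrom"], body)
        vals_down = _bin_means(calls, g["chrom"], down)
        if strand == "-":
            vals_up, vals_down = vals_down[::-1], vals_up[::-1]
            vals_body = vals_body[::-1]
        # rescale body to the fixed meta grid
        body_arr = np.asarray(vals_body, float)
        if len(body_arr) == n_body_bins_meta:
            body_meta = body_arr
        else:
            xp = np.linspace(0, 1, len(body_arr))
            xq = np.linspace(0, 1, n_body_bins_meta)
            ok = np.isfinite(body_arr)
            body_meta = np.interp(xq, xp[ok], body_arr[ok]) if ok.any() else np.full(n_body_bins_meta, np.nan)
        rows[g["gene"]] = np.concatenate([vals_up, body_meta, vals_down])
    labels = (
        [f"up{(-flank + i * flank_bin)}" for i in range(n_flank)]
        + [f"body{i}" for i in range(n_body_bins_meta)]
        + [f"down{i * flank_bin}" for i in range(n_flank)]
    )
    per_gene = pd.DataFrame(rows, index=labels).T
    with_data = per_gene.dropna(how="all")
    meta = with_data.mean(axis=0)
    up_bp, down_bp = promoter_window
    n_prom_up = up_bp // flank_bin
    n_prom_body = max(1, int(round(down_bp / body_bin)))
    prom_idx = list(range(n_flank - n_prom_up, n_flank + n_prom_body))
    dip = float(np.nanmean(meta) - np.nanmin(meta.iloc[prom_idx])) if meta.iloc[prom_idx].notna().any() else np.nan
    return GeneProfile(per_gene=per_gene, meta=meta, bin_labels=labels, dip_statistic=dip)


# ---------------------------------------------------------------------------
# Promoter matrix in ortholog space
# ---------------------------------------------------------------------------

def promoter_methylation(
    calls: pd.DataFrame,
    genes: pd.DataFrame,
    span: int = 2500,
    n_bins: int = 50,
) -> pd.Series:
    """Per-gene promoter methylation: mean over 50 x 50 bp upstream bins.

    Upstream means 5' of the TSS on the gene's strand. Bins without
    data are skipped (not imputed); a gene with no covered bin is NaN.
    """
    bin_w = span // n_bins
    out = {}
    for _, g in genes.iterrows():
        start, end, strand = int(g["start"]), int(g["end"]), g["strand"]
        if strand == "+":
            ivs = [(start - span + i * bin_w, start - span + (i + 1) * bin_w) for i in range(n_bins)]
        else:
            ivs = [(end + i * bin_w, end + (i + 1) * bin_w) for i in range(n_bins)]
        vals = [v for v in _bin_means(calls, g["chrom"], ivs) if np.isfinite(v)]
        out[g["gene"]] = float(np.mean(vals)) if vals else np.nan
    return pd.Series(out, dtype=float)


def promoter_matrix(
    per_sample_promoters: Mapping[str, pd.Series],
    gene_to_ncbi: pd.DataFrame,
    ncbi_to_human: pd.DataFrame,
) -> pd.DataFrame:
    """Sample x human-ortholog promoter methylation matrix.

    Dictionaries are two-column tables (gene, ncbi) and (ncbi, human).
    Duplicate rows are dropped with a warning; genes lacking an
    ortholog are dropped; multiple source genes landing on one human
    ortholog are averaged. Missing promoters stay NaN.
    """
    def _clean(df: pd.DataFrame) -> pd.DataFrame:
        d = df.drop_duplicates()
        if len(d) < len(df):
            warnings.warn("duplicate dictionary rows deduplicated")
        return d

    g2n = _clean(gene_to_ncbi).set_index(gene_to_ncbi.columns[0])[gene_to_ncbi.columns[1]].to_dict()
    n2h = _clean(ncbi_to_human).set_index(ncbi_to_human.columns[0])[ncbi_to_human.columns[1]].to_dict()
    rows = {}
    for sample, series in per_sample_promoters.items():
        agg: Dict[str, List[float]] = {}
        for gene, val in series.items():
            ncbi = g2n.get(gene)
            human = n2h.get(ncbi) if ncbi is not None else None
            if human is None or not np.isfinite(val):
                continue
            agg.setdefault(human, []).append(float(val))
        rows[sample] = {h: float(np.mean(v)) for h, v in agg.items()}
    return pd.DataFrame(rows).T.sort_index(axis=1)


# ---------------------------------------------------------------------------
# Embedding + clustering
# ---------------------------------------------------------------------------

def scramble_matrix(matrix: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Permute non-missing values over non-missing positions (mask kept)."""
    rng = np.random.default_rng(seed)
    M = matrix.to_numpy(float).copy()
    mask = np.isfinite(M)
    vals = M[mask]
    M[mask] = rng.permutation(vals)
    return pd.DataFrame(M, index=matrix.index, columns=matrix.columns)


def _filter_complete_corr(corr: pd.DataFrame) -> pd.DataFrame:
    """Iteratively drop the row/column with most undefined pairs."""
    c = corr.copy()
    while c.isna().to_numpy().any():
        worst = c.isna().sum(axis=1).idxmax()
        c = c.drop(index=worst, columns=worst)
    return c


@dataclass
class EmbeddingResult:
    embedding: pd.DataFrame        # rows x (x, y)
    clusters: pd.Series            # row -> community label
    scrambled_embedding: pd.DataFrame
    scrambled_clusters: pd.Series


def embed_and_cluster(
    matrix: pd.DataFrame,
    mode: str = "samples",
    n_neighbors: Optional[int] = None,
    min_dist: Optional[float] = None,
    spread: Optional[float] = None,
    resolution: float = 0.06,
    min_row_cover: Optional[int] = None,
    min_col_cover: Optional[int] = None,
    seed: int = 0,
) -> EmbeddingResult:
    """Correlation-based 2-D embedding plus Leiden communities.

    mode='samples' embeds rows with defaults n_neighbors=20,
    min_dist=2, spread=1 and coverage filters (columns covered in >100
    rows, rows covering >400 columns); mode='genes' transposes the
    matrix first and uses n_neighbors=15, min_dist=0.05, spread=1.5
    with filters (>400, >50). Pairwise-complete Pearson correlation
    feeds both a UMAP embedding on 1-corr distances and a k-nearest-
    neighbor graph clustered by Leiden at the given resolution. The
    scrambled control permutes non-missing values over non-missing
    positions and repeats the procedure.
    """
    import igraph
    import leidenalg
    import umap

    if mode == "samples":
        params = dict(n_neighbors=20, min_dist=2.0, spread=1.0)
        filt = (100, 400)
        M = matrix
    elif mode == "genes":
        params = dict(n_neighbors=15, min_dist=0.05, spread=1.5)
        filt = (400, 50)
        M = matrix.T
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if n_neighbors is not None:
        params["n_neighbors"] = n_neighbors
    if min_dist is not None:
        params["min_dist"] = min_dist
    if spread is not None:
        params["spread"] = spread
    # the embedding library requires spread >= min_dist
    params["spread"] = max(params["spread"], params["min_dist"])
    col_min = filt[0] if min_col_cover is None else min_col_cover
    row_min = filt[1] if min_row_cover is None else min_row_cover

    def _run(mat: pd.DataFrame) -> Tuple[pd.DataFrame, pd.Series]:
        m = mat.loc[:, mat.notna().sum(axis=0) > col_min]
        m = m.loc[m.notna().sum(axis=1) > row_min]
        if len(m) < 10:
            raise ValueError("filters leave fewer than 10 rows")
        corr = m.T.corr(min_periods=2)
        np.fill_diagonal(corr.to_numpy(), 1.0)
        corr = _filter_complete_corr(corr)
        dist = 1.0 - corr
        nn = min(params["n_neighbors"], len(dist) - 1)
        reducer = umap.UMAP(
            n_neighbors=nn, min_dist=params["min_dist"], spread=params["spread"],
            metric="precomputed", random_state=seed, n_components=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            emb = reducer.fit_transform(dist.to_numpy())
        # kNN graph on the same distances for community detection
        D = dist.to_numpy()
        edges: Set[Tuple[int, int]] = set()
        for i in range(len(D)):
            order = np.argsort(D[i])
            for j in order[1:nn + 1]:
                edges.add((min(i, int(j)), max(i, int(j))))
        g = igraph.Graph(n=len(D), edges=sorted(edges))
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution, seed=seed)
        clusters = pd.Series(part.membership, index=dist.index)
        emb_df = pd.DataFrame(emb, index=dist.index, columns=["x", "y"])
        return emb_df, clusters

    emb, clusters = _run(M)
    scr = scramble_matrix(M, seed=seed + 1)
    emb_s, clusters_s = _run(scr)
    return EmbeddingResult(emb, clusters, emb_s, clusters_s)


# ---------------------------------------------------------------------------
# Species-held-out classification
# ---------------------------------------------------------------------------

@dataclass
class HeldOutResult:
    mean_auc: float
    per_rep_auc: List[float]
    importances: pd.Series
    scrambled_mean_auc: float


def classify_held_out(
    matrix: pd.DataFrame,
    labels: pd.Series,
    species: pd.Series,
    n_train_species: int = 80,
    n_reps: int = 100,
    min_gene_cover: float = 0.6,
    min_sample_cover: float = 0.12,
    n_trees: int = 100,
    seed: int = 0,
) -> HeldOutResult:
    """Species-disjoint held-out classification on the promoter matrix.

    Rows are samples, columns ortholog genes; ``labels`` is the binary
    task (tissue or taxon) and ``species`` maps each sample to its
    species. Genes must be covered in >= 60% of samples and samples
    cover >= 12% of genes. Each repetition draws ``n_train_species``
    species for training and tests on the rest (no species straddles
    the split — asserted); the classifier is a random forest whose
    trees route missing values natively, so no imputation happens.
    The scrambled control permutes non-missing values over non-missing
    positions before the identical procedure.
    """
    from sklearn.ensemble import RandomForestClassifier

    M = matrix.loc[:, matrix.notna().mean(axis=0) >= min_gene_cover]
    M = M.loc[M.notna().mean(axis=1) >= min_sample_cover]
    y = labels.loc[M.index]
    sp = species.loc[M.index]
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValueError("need a binary task")
    y_bin = (y == classes[1]).astype(int)
    uniq_species = np.array(sorted(sp.unique()))
    if n_train_species >= len(uniq_species):
        raise ValueError("n_train_species must leave held-out species")
    rng = np.random.default_rng(seed)

    def _run(mat: pd.DataFrame) -> Tuple[float, pd.Series]:
        aucs = []
        imps = np.zeros(mat.shape[1])
        reps_done = 0
        attempts = 0
        while reps_done < n_reps and attempts < 10 * n_reps:
            attempts += 1
            train_sp = set(rng.choice(uniq_species, size=n_train_species, replace=False))
            tr_mask = sp.isin(train_sp).to_numpy()
            te_mask = ~tr_mask
            assert not (set(sp[tr_mask]) & set(sp[te_mask]))
            y_tr, y_te = y_bin[tr_mask], y_bin[te_mask]
            if y_tr.nunique() < 2 or y_te.nunique() < 2:
                continue  # one-class draw: discard and redraw
            clf = RandomForestClassifier(
                n_estimators=n_trees, random_state=int(rng.integers(2 ** 31)), n_jobs=1)
            clf.fit(mat.to_numpy()[tr_mask], y_tr)
            prob = clf.predict_proba(mat.to_numpy()[te_mask])[:, 1]
            from .genomic_code import evaluate_auc
            aucs.append(evaluate_auc(prob, ["high" if v else "low" for v in y_te]))
            imps += clf.feature_importances_
            reps_done += 1
        if reps_done == 0:
            raise ValueError("no repetition yielded two-class splits")
        return float(np.mean(aucs)), pd.Series(imps / reps_done, index=mat.columns), aucs

    mean_auc, importances, per_rep = _run(M)
    scr = scramble_matrix(M, seed=seed + 1)
    assert (scr.isna() == M.isna()).all().all()
    scr_auc, _, _ = _run(scr)
    return HeldOutResult(mean_auc=mean_auc, per_rep_auc=per_rep,
                         importances=importances, scrambled_mean_auc=scr_auc)
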