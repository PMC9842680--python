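"""Synthetic multi-species RRBS study generator.

Emulates the structure of a cross-species RRBS methylation study:
species related by an ultrametric pure-birth tree, per-species genomes
with restriction-site and CpG-island structure, a planted logistic
sequence-to-methylation rule over 3-mer frequencies (the "genomic
code"), tissue and individual effects on the logit scale, bisulfite
conversion noise, fully methylated / fully unmethylated spike-in
controls, and optional methylated 9-mer repeat expansions standing in
for "inverted" species. Everything is deterministic given a seed.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .insilico_rrbs import (
    DigestFragment,
    cpg_positions_of,
    digest_and_select,
    find_restriction_sites,
)

ALL_3MERS = ["".join(t) for t in itertools.product("ACGT", repeat=3)]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

@dataclass
class SpeciesTree:
    """Rooted binary ultrametric tree over named species with group labels."""

    tree: dendropy.Tree
    leaf_names: List[str]
    group_labels: Dict[str, str]

    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    def vcv(self) -> Tuple[np.ndarray, List[str]]:
        """Brownian covariance matrix: shared root-to-MRCA path length per pair."""
        tree = self.tree
        pdm = {}
        # depth of each node from the root
        depth: Dict[dendropy.Node, float] = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                depth[node] = 0.0
            else:
                depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
        leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
        names = self.leaf_names
        n = len(names)
        V = np.zeros((n, n))
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if j < i:
                    continue
                if a == b:
                    V[i, j] = depth[leaves[a]]
                else:
                    mrca = tree.mrca(taxa=[leaves[a].taxon, leaves[b].taxon])
                    V[i, j] = V[j, i] = depth[mrca]
        return V, names


DEFAULT_GROUPS = ("mammal", "bird", "reptile", "amphibian", "fish", "invertebrate")


def simulate_tree(n_species: int, seed: int, groups: Sequence[str] = DEFAULT_GROUPS) -> SpeciesTree:
    """Pure-birth (Yule) ultrametric tree with ``n_species`` leaves.

    Lineages split at exponential waiting times (rate = number of
    extant lineages); all leaves end at the present, so root-to-leaf
    depth is identical across leaves. Deterministic given ``seed``.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    # each active tip records its birth time
    active: List[Tuple[dendropy.Node, float]] = [(tree.seed_node, 0.0)]
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        idx = rng.integers(len(active))
        node, birth = active.pop(idx)
        node.edge.length = t - birth if node.parent_node is not None else None
        for _ in range(2):
            child = node.new_child()
            active.append((child, t))
    t_end = t + rng.exponential(1.0 / len(active))
    leaf_names = [f"sp{i + 1:02d}" for i in range(n_species)]
    # assign names in the order tips were created for stable output
    for (node, birth), name in zip(active, leaf_names):
        node.edge.length = t_end - birth
        node.taxon = taxa.new_taxon(label=name)
    group_labels = {name: groups[i % len(groups)] for i, name in enumerate(leaf_names)}
    return SpeciesTree(tree=tree, leaf_names=leaf_names, group_labels=group_labels)


def star_tree(names: Sequence[str], depth: float = 1.0) -> SpeciesTree:
    """Star phylogeny: all tips attach directly to the root at equal depth."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    for name in names:
        child = tree.seed_node.new_child()
        child.edge.length = depth
        child.taxon = taxa.new_taxon(label=name)
    return SpeciesTree(tree=tree, leaf_names=list(names), group_labels={n: "all" for n in names})


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    sequence: str
    islands: List[Tuple[int, int]]
    genes: List[Tuple[int, int, str]]
    repeats: List[Tuple[int, int]]

    def cpg_positions(self) -> List[int]:
        return cpg_positions_of(self.sequence)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.array(list("ACGT")), size=n, p=p)


def simulate_genome(
    length: int,
    gc_content: float = 0.4,
    island_count: int = 0,
    repeat_spec: Optional[Tuple[str, int]] = None,
    seed: int = 0,
    island_len: int = 300,
    gene_density: float = 1 / 5000,
) -> SyntheticGenome:
    """Random genome with CpG islands, genes, and optional planted repeats.

    Islands are ``island_len`` bp blocks built from CG-rich dinucleotide
    sampling (heavily CpG-enriched). Genes are non-overlapping stranded
    intervals at roughly one per 5 kb. ``repeat_spec = (ninemer, copies)``
    overwrites ``copies`` non-overlapping positions with the 9-mer.
    """
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if island_count * island_len > length:
        raise ValueError("island_count * island length exceeds genome length")
    rng = np.random.default_rng(seed)
    seq = _random_bases(rng, length, gc_content)

    # place islands on a non-overlapping grid
    islands: List[Tuple[int, int]] = []
    if island_count:
        slots = length // island_len
        starts = rng.choice(slots, size=island_count, replace=False) * island_len
        for s in np.sort(starts):
            block = []
            while len(block) < island_len:
                r = rng.random()
                if r < 0.4:
                    block.extend("CG")
                elif r < 0.7:
                    block.append(rng.choice(np.array(list("CG"))))
                else:
                    block.append(rng.choice(np.array(list("AT"))))
            seq[s:s + island_len] = np.array(block[:island_len])
            islands.append((int(s), int(s + island_len)))

    repeats: List[Tuple[int, int]] = []
    if repeat_spec is not None:
        unit, copies = repeat_spec
        L = len(unit)
        occupied = [(s, e) for s, e in islands]
        placed = 0
        attempts = 0
        while placed < copies and attempts < copies * 50:
            attempts += 1
            s = int(rng.integers(0, length - L))
            if any(s < e and s + L > b for b, e in occupied):
                continue
            seq[s:s + L] = np.array(list(unit))
            occupied.append((s, s + L))
            repeats.append((s, s + L))
            placed += 1
        if placed < copies:
            warnings.warn(f"placed only {placed}/{copies} repeat copies")

    genes: List[Tuple[int, int, str]] = []
    n_genes = max(1, int(length * gene_density))
    gene_len = 1500
    stride = length // (n_genes + 1)
    for g in range(n_genes):
        s = (g + 1) * stride
        if s + gene_len >= length:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append((s, s + gene_len, strand))

    return SyntheticGenome("".join(seq.tolist()), islands, genes, repeats)


# ---------------------------------------------------------------------------
# Planted code and true methylome
# ---------------------------------------------------------------------------

@dataclass
class PlantedCode:
    """Logistic sequence-to-methylation rule over 3-mer frequencies."""

    kmer_weights: Dict[str, float]
    intercept: float = 0.0
    inverted: Dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(ALL_3MERS) - set(self.kmer_weights)
        if missing:
            for m in missing:
                self.kmer_weights[m] = 0.0

    def logit(self, seq: str, species: Optional[str] = None) -> float:
        freqs = kmer_frequencies(seq, 3)
        sign = -1.0 if species is not None and self.inverted.get(species, False) else 1.0
        return self.intercept + sign * sum(self.kmer_weights[m] * f for m, f in freqs.items())

    def probability(self, seq: str, species: Optional[str] = None) -> float:
        return 1.0 / (1.0 + math.exp(-self.logit(seq, species)))


def random_planted_code(seed: int, scale: float = 3.0, intercept: float = 0.0) -> PlantedCode:
    """Random 3-mer weight vector, centred, with standard deviation ``scale``.

    On frequency features (which sum to 1) centring keeps the intercept
    meaningful; scale >= 2 gives strongly predictable methylation states.
    """
    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, 1.0, size=64)
    w = (w - w.mean()) / w.std() * scale * 64  # per-unit-frequency scale
    return PlantedCode({m: float(x) for m, x in zip(ALL_3MERS, w)}, intercept=intercept)


def kmer_frequencies(seq: str, k: int) -> Dict[str, float]:
    """Overlapping k-mer frequencies of one sequence; non-ACGT windows skipped."""
    counts: Dict[str, int] = {}
    n = 0
    s = seq.upper()
    for i in range(len(s) - k + 1):
        w = s[i:i + k]
        if any(c not in "ACGT" for c in w):
            continue
        counts[w] = counts.get(w, 0) + 1
        n += 1
    if n == 0:
        return {}
    return {w: c / n for w, c in counts.items()}


def _full_freq_vector(seq: str, kmers: Sequence[str], k: int) -> Dict[str, float]:
    f = kmer_frequencies(seq, k)
    return {m: f.get(m, 0.0) for m in kmers}


@dataclass
class SampleDesign:
    sample_id: str
    species: str
    tissue: str
    individual: str


@dataclass
class TrueMethylome:
    """Planted per-fragment, per-sample methylation probabilities.

    ``probs[(fragment_id, sample_id)]`` is an array over the fragment's
    CpG cytosines. Fragment-level base probability comes from the
    planted code; tissue and individual offsets act on the logit scale;
    per-CpG jitter and Gaussian noise are applied before clipping.
    """

    probs: Dict[Tuple[str, str], np.ndarray]
    base_prob: Dict[str, float]
    tissue_effect_set: Dict[str, Dict[str, float]]  # fragment -> tissue -> logit offset
    individual_effect_set: Dict[str, Dict[str, float]]
    noise_sd: float = 0.0


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def assign_methylome(
    fragments: Mapping[str, str],
    code: PlantedCode,
    design: Sequence[SampleDesign],
    species: Optional[str] = None,
    tissue_effects: Optional[Mapping[str, Mapping[str, float]]] = None,
    individual_effects: Optional[Mapping[str, Mapping[str, float]]] = None,
    noise_sd: float = 0.0,
    cpg_jitter_sd: float = 0.0,
    seed: int = 0,
) -> TrueMethylome:
    """Assign per-CpG methylation probabilities to fragments x samples.

    Base probability per fragment is ``logistic(intercept + sum
    weight * 3-mer frequency)`` (sign-flipped for inverted species).
    Tissue / individual logit offsets apply only to listed fragments.
    """
    tissue_effects = dict(tissue_effects or {})
    individual_effects = dict(individual_effects or {})
    tissues = {d.tissue for d in design}
    individuals = {d.individual for d in design}
    for frag, offsets in tissue_effects.items():
        unknown = set(offsets) - tissues
        if unknown:
            raise ValueError(f"unknown tissue label(s) {sorted(unknown)} in effect set")
    for frag, offsets in individual_effects.items():
        unknown = set(offsets) - individuals
        if unknown:
            raise ValueError(f"unknown individual label(s) {sorted(unknown)} in effect set")

    rng = np.random.default_rng(seed)
    base_logit = {fid: code.logit(seq, species) for fid, seq in fragments.items()}
    n_cpgs = {fid: max(1, len(cpg_positions_of(seq))) for fid, seq in fragments.items()}
    probs: Dict[Tuple[str, str], np.ndarray] = {}
    for fid in fragments:
        for d in design:
            logit = base_logit[fid]
            logit += tissue_effects.get(fid, {}).get(d.tissue, 0.0)
            logit += individual_effects.get(fid, {}).get(d.individual, 0.0)
            if noise_sd > 0:
                logit += rng.normal(0.0, noise_sd)
            p = _logistic(np.full(n_cpgs[fid], logit))
            if cpg_jitter_sd > 0:
                p = p + rng.normal(0.0, cpg_jitter_sd, size=p.shape)
            probs[(fid, d.sample_id)] = np.clip(p, 0.0, 1.0)
    return TrueMethylome(
        probs=probs,
        base_prob={fid: float(_logistic(np.array([l]))[0]) for fid, l in base_logit.items()},
        tissue_effect_set=dict(tissue_effects),
        individual_effect_set=dict(individual_effects),
        noise_sd=noise_sd,
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadSimConfig:
    read_length: int = 50
    mean_coverage: float = 20.0
    conversion_rate: float = 0.99
    over_conversion: float = 0.005
    seq_error_rate: float = 0.0
    spike_in_fraction: float = 0.001
    noncpg_level: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conversion_rate", "over_conversion", "seq_error_rate", "spike_in_fraction", "noncpg_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


def _spike_sequence(seed: int, length: int = 200) -> str:
    rng = np.random.default_rng(seed)
    # CpG-rich so that conversion behaviour is observable
    bases = []
    while len(bases) < length:
        r = rng.random()
        if r < 0.3:
            bases.extend("CG")
        else:
            bases.append("ACGT"[rng.integers(4)])
    return "".join(bases[:length])


SPIKE_METHYLATED = _spike_sequence(101)
SPIKE_UNMETHYLATED = _spike_sequence(202)


@dataclass
class SimulatedRead:
    name: str
    sequence: str
    fragment_id: Optional[str]  # None for spike-ins
    is_spike: bool = False
    spike_methylated: bool = False


def fragment_read_templates(fragment_seq: str, read_length: int) -> List[Tuple[str, str]]:
    """The four read templates of one fragment: both ends, both strands.

    Directional protocol: plus-strand reads start at the fragment 5'
    ends of each strand. Returns (strand_tag, template sequence).
    """
    rl = min(read_length, len(fragment_seq))
    plus = fragment_seq[:rl]
    minus = revcomp(fragment_seq)[:rl]
    plus_end = fragment_seq[-rl:]
    minus_end = revcomp(fragment_seq)[-rl:]
    return [("+s", plus), ("-s", minus), ("+e", plus_end), ("-e", minus_end)]


def _convert_read(
    template: str,
    meth_prob: float,
    cfg: ReadSimConfig,
    rng: np.random.Generator,
    per_c_prob: Optional[Mapping[int, float]] = None,
) -> str:
    """Apply bisulfite conversion to every C of a read template.

    ``per_c_prob`` optionally overrides the methylation probability at
    specific template positions (used for CpG-context cytosines); other
    cytosines use ``meth_prob``.
    """
    out = list(template)
    for i, b in enumerate(out):
        if b != "C":
            continue
        p = per_c_prob.get(i, meth_prob) if per_c_prob is not None else meth_prob
        methylated = rng.random() < p
        if methylated:
            if rng.random() < cfg.over_conversion:
                out[i] = "T"
        else:
            if rng.random() < cfg.conversion_rate:
                out[i] = "T"
    return "".join(out)


def _apply_seq_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[rng.integers(4)]
    return "".join(out)


def simulate_rrbs_reads(
    fragments: Mapping[str, str],
    methylome: TrueMethylome,
    design: Sequence[SampleDesign],
    cfg: ReadSimConfig,
) -> Dict[str, List[SimulatedRead]]:
    """Simulate converted RRBS reads for every sample.

    Reads are the first ``read_length`` bases of each fragment end on
    each strand (four templates per fragment). CpG-context cytosines
    convert according to the planted per-fragment probability; other
    cytosines use ``cfg.noncpg_level``. Spike-in controls (one fully
    methylated, one fully unmethylated) are added at
    ``cfg.spike_in_fraction`` of the genomic read count.
    """
    if not fragments:
        warnings.warn("no fragments supplied; returning empty read sets")
        return {d.sample_id: [] for d in design}
    rng = np.random.default_rng(cfg.seed)
    reads_per_end = cfg.mean_coverage
    out: Dict[str, List[SimulatedRead]] = {}
    for d in design:
        sample_reads: List[SimulatedRead] = []
        counter = 0
        for fid, seq in fragments.items():
            probs = methylome.probs.get((fid, d.sample_id))
            frag_p = float(np.mean(probs)) if probs is not None and len(probs) else 0.5
            for tag, template in fragment_read_templates(seq, cfg.read_length):
                # CpG positions on the template strand
                cpg_on_template = {i: frag_p for i in cpg_positions_of(template)}
                n = int(rng.poisson(reads_per_end / 2.0))  # 2 strands per end
                for _ in range(n):
                    conv = _convert_read(template, cfg.noncpg_level, cfg, rng, cpg_on_template)
                    conv = _apply_seq_errors(conv, cfg.seq_error_rate, rng)
                    counter += 1
                    sample_reads.append(SimulatedRead(
                        name=f"{d.sample_id}:{fid}:{tag}:{counter}",
                        sequence=conv, fragment_id=fid))
        n_spike = int(round(len(sample_reads) * cfg.spike_in_fraction))
        for si in range(max(n_spike, 0)):
            meth = si % 2 == 0
            src = SPIKE_METHYLATED if meth else SPIKE_UNMETHYLATED
            start = int(rng.integers(0, len(src) - cfg.read_length))
            template = src[start:start + cfg.read_length]
            conv = _convert_read(template, 1.0 if meth else 0.0, cfg, rng)
            sample_reads.append(SimulatedRead(
                name=f"{d.sample_id}:spike:{si}", sequence=conv,
                fragment_id=None, is_spike=True, spike_methylated=meth))
        out[d.sample_id] = sample_reads
    return out


def simulate_unconverted_reads(
    fragments: Mapping[str, str],
    cfg: ReadSimConfig,
    coverage: Optional[float] = None,
) -> List[SimulatedRead]:
    """Unconverted library: raw fragment-end templates, no C->T conversion."""
    rng = np.random.default_rng(cfg.seed + 1)
    cov = coverage if coverage is not None else cfg.mean_coverage
    reads: List[SimulatedRead] = []
    counter = 0
    for fid, seq in fragments.items():
        for tag, template in fragment_read_templates(seq, cfg.read_length):
            n = int(rng.poisson(cov / 2.0))
            for _ in range(n):
                out = _apply_seq_errors(template, cfg.seq_error_rate, rng)
                counter += 1
                reads.append(SimulatedRead(
                    name=f"unconv:{fid}:{tag}:{counter}", sequence=out, fragment_id=fid))
    return reads


def digest_genome(genome_seq: str, cfg: ReadSimConfig, min_len: int = 50, max_len: int = 1000) -> Dict[str, str]:
    """Digest a genome and return size-selected fragment sequences by id."""
    sites = find_restriction_sites(genome_seq)
    frags = digest_and_select(len(genome_seq), sites, min_len, max_len, cfg.read_length)
    if not frags:
        warnings.warn("zero fragments after size selection")
        return {}
    return {f"frag{i:05d}": genome_seq[f.start:f.end] for i, f in enumerate(frags)}


def write_fastq(reads: Iterable[SimulatedRead], path: str, quality_char: str = "?") -> None:
    """Write reads as Sanger FASTQ with constant Q30 quality."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{quality_char * len(r.sequence)}\n")
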