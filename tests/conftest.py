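"""Shared fixtures: small synthetic studies generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methcode import genomic_code as gc
from methcode import synthetic_data as sd


def make_labeled_set(
    code: sd.PlantedCode,
    species: str,
    n_per_class: int,
    seq_len: int = 60,
    inverted: bool = False,
    seed: int = 0,
    max_draws: int = 200_000,
) -> gc.LabeledFragmentSet:
    """Random sequences labeled high/low by the planted logistic code.

    Mirrors fragment discretization: sequences with planted probability
    > 0.8 are 'high', < 0.2 'low'; intermediate sequences are skipped.
    """
    rng = np.random.default_rng(seed)
    rows = {"high": [], "low": []}
    bases = np.array(list("ACGT"))
    i = 0
    while (len(rows["high"]) < n_per_class or len(rows["low"]) < n_per_class) and i < max_draws:
        seq = "".join(rng.choice(bases, size=seq_len))
        p = code.probability(seq, species if inverted else None)
        if inverted:
            p = 1.0 - code.probability(seq)
        i += 1
        if p > 0.8 and len(rows["high"]) < n_per_class:
            rows["high"].append((f"{species}_f{i}", seq, "high"))
        elif p < 0.2 and len(rows["low"]) < n_per_class:
            rows["low"].append((f"{species}_f{i}", seq, "low"))
    frame = pd.DataFrame(rows["high"] + rows["low"], columns=["fragment", "sequence", "label"])
    return gc.LabeledFragmentSet(frame.reset_index(drop=True), species)


@pytest.fixture(scope="session")
def planted_code() -> sd.PlantedCode:
    return sd.random_planted_code(17, scale=4.0)


@pytest.fixture(scope="session")
def small_study():
    """One species, one sample, error-free reads at high coverage."""
    genome = sd.simulate_genome(60_000, 0.45, 3, None, seed=11)
    cfg = sd.ReadSimConfig(mean_coverage=24, conversion_rate=1.0, over_conversion=0.0,
                           seq_error_rate=0.0, spike_in_fraction=0.0, seed=5)
    fragments = sd.digest_genome(genome.sequence, cfg)
    code = sd.random_planted_code(3, scale=2.0)
    design = [sd.SampleDesign("s1", "sp01", "heart", "i1"),
              sd.SampleDesign("s2", "sp01", "liver", "i1")]
    methylome = sd.assign_methylome(fragments, code, design, seed=7)
    reads = sd.simulate_rrbs_reads(fragments, methylome, design, cfg)
    unconverted = sd.simulate_unconverted_reads(fragments, cfg)
    return {
        "genome": genome,
        "fragments": fragments,
        "code": code,
        "design": design,
        "methylome": methylome,
        "reads": reads,
        "unconverted": unconverted,
        "cfg": cfg,
    }
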