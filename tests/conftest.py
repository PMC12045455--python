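import numpy as np
import pandas as pd
import pytest

from xenotrack.io import RepertoireSample


def make_sample(freq_by_key: dict, total: int = 10000, **metadata) -> RepertoireSample:
    """Build a repertoire sample from a {clonotype: frequency} mapping.

    Template counts are frequency * total (must come out integral) so
    derived frequencies are exact.
    """
    keys = list(freq_by_key)
    freqs = np.array([freq_by_key[k] for k in keys], dtype=float)
    templates = freqs * total
    assert np.allclose(templates, np.round(templates)), "frequencies must tile the total"
    clones = pd.DataFrame(
        {
            "cdr3_nt": keys,
            "cdr3_aa": [f"aa_{k}" for k in keys],
            "v_call": ["TRBV1-1*01"] * len(keys),
            "j_call": ["TRBJ1-1*01"] * len(keys),
            "templates": pd.array(np.round(templates), dtype="Float64"),
            "frequency": freqs / freqs.sum(),
            "productive": True,
        }
    )
    return RepertoireSample(clones=clones, **metadata)


def random_sample(rng: np.random.Generator, n_clones: int = 500, depth: int = 20000,
                  alphabet: int = 4, length: int = 12, **metadata) -> RepertoireSample:
    """Random clone table with unique nucleotide keys."""
    keys = set()
    while len(keys) < n_clones:
        keys.add("".join(rng.choice(list("ACGT"[:alphabet]), size=length)))
    keys = sorted(keys)
    counts = rng.multinomial(depth, rng.dirichlet(np.ones(n_clones)))
    keep = counts > 0
    clones = pd.DataFrame(
        {
            "cdr3_nt": np.array(keys)[keep],
            "cdr3_aa": [k[:4] for k in np.array(keys)[keep]],
            "v_call": rng.choice([f"TRBV{i}-1*01" for i in range(1, 10)], size=keep.sum()),
            "j_call": "TRBJ1-1*01",
            "templates": pd.array(counts[keep].astype(float), dtype="Float64"),
            "frequency": counts[keep] / counts[keep].sum(),
            "productive": True,
        }
    )
    return RepertoireSample(clones=clones, **metadata)


@pytest.fixture(scope="session")
def default_truth():
    """One default-condition simulation shared by read-only tests."""
    from xenotrack.simulate import SimulationConfig, simulate_baseline

    config = SimulationConfig(seed=11)
    baseline, truth = simulate_baseline(config)
    return baseline, truth, config
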