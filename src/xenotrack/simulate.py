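"""Synthetic repertoire and single-cell data with known ground truth.

The generator emulates the statistical structure of a pig-to-human
xenotransplant clone-tracking study:

* a heavy-tailed pre-transplant blood repertoire (clone sizes drawn from
  a truncated power law or lognormal, multinomially sampled to depth);
* CFSE-low MLR-proliferated samples in which designated xenoreactive
  clones dominate the divided pool while weakly proliferating bystanders
  contaminate it at a low per-clone rate;
* largely non-overlapping direct- and indirect-pathway reactive sets;
* post-transplant timepoints where lymphopenia-driven expansion is far
  stronger for reactive clones, and expanded clones acquire extra
  codon-degenerate nucleotide variants per amino-acid CDR3 (clonal
  convergence);
* compartment subsamples (lymphocele, biopsy) enriched for reactive
  clones at small sequencing depth;
* mixed human/pig single cells with species-prefixed gene counts and a
  10x-style TCR contig table.

Every clone and cell is traceable to a ground-truth label, so downstream
calling and tracking can be scored exactly. All draws flow from one seed
through named substreams, so each stage is independently reproducible.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from xenotrack.io import RepertoireSample, clonotype_key

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS]

_CODON_TABLE = {}
for _c in _SENSE_CODONS:
    from Bio.Seq import Seq as _Seq

    _CODON_TABLE[_c] = str(_Seq(_c).translate())
_SYNONYMS = {
    c: [d for d in _SENSE_CODONS if d != c and _CODON_TABLE[d] == _CODON_TABLE[c]]
    for c in _SENSE_CODONS
}

_V_GENES = [f"TRBV{i}-1*01" for i in range(2, 31)]
_J_GENES = [f"TRBJ{i}-{j}*01" for i in (1, 2) for j in range(1, 7)]

PATHWAYS = ("direct", "indirect")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named random substream: one master seed, independent streams per
    simulation stage."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe a desk-scale analogue of the study conditions:
    a 1,000-clone repertoire sequenced to 10,000 templates, with
    direct/indirect reactive sets in roughly the CD4>CD8 and
    direct>indirect proportions observed in MLRs, a small overlap
    between pathways, weak bystander contamination of the divided pool,
    and post-transplant folds that favour reactive clones strongly at
    the rejection timepoints.
    """

    n_clones: int = 1000
    clone_size_dist: str = "powerlaw"  # or "lognormal"
    powerlaw_exponent: float = 2.2  # density exponent of clone sizes
    powerlaw_truncation: float = 15.0  # largest/smallest clone-size ratio
    lognormal_sigma: float = 2.0
    cd4_fraction: float = 0.6
    n_reactive_direct_cd4: int = 40
    n_reactive_direct_cd8: int = 25
    n_reactive_indirect_cd4: int = 30
    n_reactive_indirect_cd8: int = 10
    overlap_fraction: float = 0.03
    mlr_expansion_factor: float = 3.0  # minimum expansion of reactive clones
    bystander_rate: float = 0.05
    bystander_factor_range: tuple = (0.05, 0.5)
    posttx_reactive_fold: dict = field(
        default_factory=lambda: {"POD14": 2.0, "POD28": 5.0, "POD33": 20.0, "POD49": 20.0}
    )
    posttx_nonreactive_fold: dict = field(
        default_factory=lambda: {"POD14": 2.0, "POD28": 2.0, "POD33": 2.0, "POD49": 2.0}
    )
    drift_sigma: float = 0.3  # lognormal per-clone drift at each timepoint
    immunodominance_sigma: float = 1.5  # spread of clone-specific reactive expansion
    sequencing_depth: int = 10000
    nt_variants_mean: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_clones < 0:
            raise ValueError("n_clones must be >= 0")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if not 0 <= self.bystander_rate <= 1:
            raise ValueError("bystander_rate must lie in [0, 1]")
        if self.sequencing_depth < 1:
            raise ValueError("sequencing_depth must be >= 1")
        if self.mlr_expansion_factor <= 0:
            raise ValueError("mlr_expansion_factor must be positive")
        if self.clone_size_dist not in ("powerlaw", "lognormal"):
            raise ValueError(f"unknown clone_size_dist {self.clone_size_dist!r}")


@dataclass
class GroundTruth:
    """Truth labels for every simulated clonotype.

    ``clones`` has one row per clonotype: its sequences, V/J calls,
    subset (CD4/CD8), reactive pathway (``none``/``direct``/
    ``indirect``/``both``) and true baseline frequency.
    """

    clones: pd.DataFrame
    config: SimulationConfig

    def keys(self, key_mode: str = "nt") -> pd.Series:
        return clonotype_key(self.clones, key_mode)

    def reactive_mask(self, pathway: str | None = None, subset: str | None = None) -> np.ndarray:
        pw = self.clones["pathway"]
        if pathway is None:
            mask = pw != "none"
        else:
            mask = (pw == pathway) | (pw == "both")
        if subset is not None:
            mask = mask & (self.clones["subset"] == subset)
        return mask.to_numpy()

    def reactive_keys(
        self, key_mode: str = "nt", pathway: str | None = None, subset: str | None = None
    ) -> set:
        return set(self.keys(key_mode)[self.reactive_mask(pathway, subset)])


def _random_cdr3_nt(rng: np.random.Generator) -> str:
    """Random in-frame CDR3 nucleotide sequence, 11-17 codons, no stop,
    flanked by the canonical C...F motif."""
    n_codons = int(rng.integers(11, 18))
    inner = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    return "TGT" + "".join(inner) + "TTT"


def _synonymous_variant(nt: str, rng: np.random.Generator) -> str:
    """A codon-degenerate variant of ``nt`` encoding the same peptide."""
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    order = rng.permutation(len(codons))
    for idx in order:
        syn = _SYNONYMS.get(codons[idx], [])
        if syn:
            new = codons.copy()
            new[idx] = syn[int(rng.integers(len(syn)))]
            return "".join(new)
    return nt


def _baseline_probs(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_clones
    if config.clone_size_dist == "powerlaw":
        # density exponent a -> Pareto shape a-1, truncated by inverse CDF
        # so the largest pre-transplant clone stays below ~1% of templates
        # (hyperexpansion is a post-transplant phenomenon)
        shape = config.powerlaw_exponent - 1.0
        if shape <= 0:
            raise ValueError("powerlaw exponent must exceed 1")
        t = config.powerlaw_truncation
        if t <= 1:
            raise ValueError("powerlaw_truncation must exceed 1")
        u = rng.random(n)
        sizes = (1.0 - u * (1.0 - t**-shape)) ** (-1.0 / shape)
    else:
        sizes = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma, size=n)
    return sizes / sizes.sum()


def _sample_to_table(
    truth: GroundTruth,
    probs: np.ndarray,
    depth: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Multinomial draw of ``depth`` templates over the truth clone list;
    returns a clone table holding only clones with >= 1 template."""
    counts = rng.multinomial(depth, probs / probs.sum())
    present = counts > 0
    tc = truth.clones.loc[present].copy()
    tc["templates"] = counts[present].astype(float)
    total = float(tc["templates"].sum())
    tc["frequency"] = tc["templates"] / total
    tc["productive"] = True
    cols = ["cdr3_nt", "cdr3_aa", "v_call", "j_call", "templates", "frequency", "productive"]
    out = tc[cols].reset_index(drop=True)
    out["templates"] = out["templates"].astype("Float64")
    out["clone_id"] = tc["clone_id"].to_numpy()
    return out


def simulate_baseline(config: SimulationConfig) -> tuple[RepertoireSample, GroundTruth]:
    """Pre-transplant unstimulated blood repertoire plus ground truth.

    Clone frequencies follow the configured heavy-tailed distribution;
    reactive labels (pathway x subset) are assigned uniformly at random
    within each subset, with ``overlap_fraction`` of each pathway pair
    shared (labelled ``both``). The emitted sample is a multinomial draw
    of ``sequencing_depth`` templates.
    """
    rng = substream(config.seed, "baseline")
    n = config.n_clones
    nts = []
    seen = set()
    while len(nts) < n:
        s = _random_cdr3_nt(rng)
        if s not in seen:
            seen.add(s)
            nts.append(s)
    from Bio.Seq import Seq

    aas = [str(Seq(s).translate()) for s in nts]
    clones = pd.DataFrame(
        {
            "clone_id": np.arange(n),
            "cdr3_nt": nts,
            "cdr3_aa": aas,
            "v_call": rng.choice(_V_GENES, size=n),
            "j_call": rng.choice(_J_GENES, size=n),
            "subset": np.where(rng.random(n) < config.cd4_fraction, "CD4", "CD8"),
            "pathway": "none",
        }
    )
    clones["baseline_freq"] = _baseline_probs(config, rng) if n else np.array([])

    for subset, nd, ni in [
        ("CD4", config.n_reactive_direct_cd4, config.n_reactive_indirect_cd4),
        ("CD8", config.n_reactive_direct_cd8, config.n_reactive_indirect_cd8),
    ]:
        pool = clones.index[clones["subset"] == subset].to_numpy()
        n_overlap = int(round(config.overlap_fraction * min(nd, ni)))
        n_total = nd + ni - n_overlap
        if n_total > len(pool):
            raise ValueError(f"not enough {subset} clones for requested reactive counts")
        chosen = rng.choice(pool, size=n_total, replace=False)
        clones.loc[chosen[: nd - n_overlap], "pathway"] = "direct"
        clones.loc[chosen[nd - n_overlap : nd], "pathway"] = "both"
        clones.loc[chosen[nd:], "pathway"] = "indirect"

    truth = GroundTruth(clones=clones, config=config)
    table = _sample_to_table(truth, clones["baseline_freq"].to_numpy(), config.sequencing_depth, rng)
    sample = RepertoireSample(
        clones=table,
        timepoint="preTx",
        compartment="blood",
        subset="CD3",
        stimulation="unstim",
    )
    return sample, truth


def simulate_mlr(
    baseline: RepertoireSample,
    truth: GroundTruth,
    pathway: str,
    config: SimulationConfig | None = None,
    subset: str | None = None,
    timepoint: str = "preTx",
) -> RepertoireSample:
    """A CFSE-low (divided) MLR population for one stimulation pathway.

    Only proliferating clones appear: reactive clones of the pathway
    (and, when ``subset`` is given, of that sorted subset) carry weight
    ``baseline_freq * E`` with expansion ``E`` at least
    ``mlr_expansion_factor`` (scaled by a long-tailed lognormal
    multiplier). Each non-reactive clone contaminates the sorted divided
    pool with probability ``bystander_rate``, entering at its baseline
    frequency times a weak factor from ``bystander_factor_range`` — the
    divided pool is therefore dominated by truly proliferating reactive
    cells with a small bystander/sorting-error background, which is the
    situation the two-fold calling rule is designed to clean up.
    Weights are renormalised and multinomially sampled to depth.
    """
    config = config or truth.config
    if pathway not in PATHWAYS:
        raise ValueError(f"pathway must be one of {PATHWAYS}")
    rng = substream(config.seed, f"mlr_{pathway}_{subset}_{timepoint}")
    clones = truth.clones
    reactive = truth.reactive_mask(pathway=pathway, subset=subset)
    in_subset = (
        np.ones(len(clones), bool) if subset is None else (clones["subset"] == subset).to_numpy()
    )
    if reactive.sum() == 0:
        warnings.warn(
            f"no designated reactive clones for pathway {pathway!r} subset {subset!r}; "
            "returning a bystander-only sample"
        )
    base = clones["baseline_freq"].to_numpy()
    weights = np.zeros(len(clones))
    e = config.mlr_expansion_factor * rng.lognormal(mean=1.2, sigma=0.6, size=int(reactive.sum()))
    weights[reactive] = base[reactive] * e
    reactive_mass = weights.sum()
    bystander = in_subset & ~reactive & (rng.random(len(clones)) < config.bystander_rate)
    lo, hi = config.bystander_factor_range
    # contamination scales with the proliferated pool so a bystander's
    # divided-pool frequency stays near baseline_freq * factor (< 2x)
    scale = reactive_mass if reactive_mass > 0 else 1.0
    weights[bystander] = (
        base[bystander] * rng.uniform(lo, hi, size=int(bystander.sum())) * scale
    )
    if weights.sum() == 0:
        raise ValueError("no proliferating clones; cannot form a divided population")
    table = _sample_to_table(truth, weights, config.sequencing_depth, rng)
    return RepertoireSample(
        clones=table,
        timepoint=timepoint,
        compartment="in_vitro",
        subset=subset or "CD3",
        stimulation=f"{pathway}_mlr",
    )


def simulate_longitudinal(
    baseline: RepertoireSample,
    truth: GroundTruth,
    config: SimulationConfig | None = None,
    timepoints: list[str] | None = None,
    subset: str = "CD3",
) -> list[RepertoireSample]:
    """Post-transplant blood samples across timepoints.

    ``subset`` emulates the flow sort applied before sequencing:
    ``"CD3"`` keeps the whole T cell pool, while ``"CD4"``/``"CD8"``
    restrict to that subset's clones with frequencies renormalised
    within it — the scale on which the sorted post-transplant
    repertoires are reported.

    At each timepoint true frequencies are the baseline frequencies
    scaled by ``posttx_nonreactive_fold`` (the uniform lymphopenia-driven
    background) plus, for reactive clones, a clone-specific
    antigen-driven excess: the fold is ``nf + (rf - nf) * c`` where
    ``c`` is a mean-one lognormal immunodominance factor drawn once per
    clone (spread ``immunodominance_sigma``) and held fixed across
    timepoints, so the same immunodominant clones recur at every
    rejection timepoint. When ``rf == nf`` the excess vanishes exactly
    and reactive and non-reactive clones are statistically
    exchangeable. Frequencies are perturbed by a per-clone lognormal
    drift, renormalised and multinomially sampled. Clones whose applied
    fold is >= 2 acquire Poisson(``nt_variants_mean``) extra synonymous
    nucleotide variants, splitting their templates — emulating the
    convergent, antigen-driven expansion signature.
    """
    config = config or truth.config
    if timepoints is None:
        timepoints = list(config.posttx_reactive_fold)
    if subset not in ("CD3", "CD4", "CD8"):
        raise ValueError(f"subset must be CD3, CD4 or CD8, not {subset!r}")
    base = truth.clones["baseline_freq"].to_numpy().copy()
    if subset != "CD3":
        base = base * (truth.clones["subset"] == subset).to_numpy()
        if base.sum() == 0:
            raise ValueError(f"no clones in subset {subset}")
    reactive = truth.reactive_mask()
    sigma = config.immunodominance_sigma
    dom_rng = substream(config.seed, "immunodominance")
    dominance = dom_rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(base))
    samples = []
    for tp in timepoints:
        rng = substream(config.seed, f"longitudinal_{subset}_{tp}")
        rf = config.posttx_reactive_fold.get(tp, 1.0)
        nf = config.posttx_nonreactive_fold.get(tp, 1.0)
        folds = np.where(reactive, np.maximum(nf + (rf - nf) * dominance, 0.0), nf)
        drift = rng.lognormal(mean=-0.5 * config.drift_sigma**2, sigma=config.drift_sigma, size=len(base))
        weights = base * folds * drift
        table = _sample_to_table(truth, weights, config.sequencing_depth, rng)
        if config.nt_variants_mean > 0:
            table = _add_nt_variants(table, truth, folds, config, rng)
        samples.append(
            RepertoireSample(
                clones=table,
                timepoint=tp,
                compartment="blood",
                subset=subset,
                stimulation="unstim",
            )
        )
    return samples


def _add_nt_variants(
    table: pd.DataFrame,
    truth: GroundTruth,
    folds: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    fold_by_id = dict(zip(truth.clones["clone_id"], folds))
    rows = []
    for _, row in table.iterrows():
        t = int(row["templates"])
        expanded = fold_by_id.get(row["clone_id"], 1.0) >= 2.0
        k = int(rng.poisson(config.nt_variants_mean)) if expanded else 0
        k = min(k, t - 1)  # every variant needs at least one template
        if k <= 0:
            rows.append(row)
            continue
        variants = {row["cdr3_nt"]}
        for _ in range(k):
            for _attempt in range(10):
                v = _synonymous_variant(row["cdr3_nt"], rng)
                if v not in variants:
                    variants.add(v)
                    break
        variants = sorted(variants)
        split = rng.multinomial(t - len(variants), np.full(len(variants), 1 / len(variants))) + 1
        for v, tv in zip(variants, split):
            r = row.copy()
            r["cdr3_nt"] = v
            r["templates"] = float(tv)
            rows.append(r)
    out = pd.DataFrame(rows).reset_index(drop=True)
    out["templates"] = out["templates"].astype("Float64")
    out["frequency"] = (out["templates"] / out["templates"].sum()).astype(float)
    return out


def simulate_compartment(
    source: RepertoireSample,
    truth: GroundTruth,
    enrichment: float = 5.0,
    depth: int = 500,
    compartment: str = "lymphocele",
    timepoint: str | None = None,
) -> RepertoireSample:
    """Tissue-compartment subsample enriched for reactive clones.

    Sampling weights are the source sample's frequencies with reactive
    clones multiplied by ``enrichment`` before a multinomial draw at
    (typically small) ``depth`` — emulating lymphocele or biopsy
    repertoires dominated by infiltrating reactive cells.
    """
    if enrichment <= 0:
        raise ValueError("enrichment must be positive")
    config = truth.config
    tp = timepoint or source.timepoint
    rng = substream(config.seed, f"compartment_{compartment}_{tp}")
    reactive_ids = set(truth.clones.loc[truth.reactive_mask(), "clone_id"])
    src = source.clones
    weights = np.zeros(len(truth.clones))
    freq_by_id = dict(zip(src["clone_id"], src["frequency"]))
    base_ids = truth.clones["clone_id"].to_numpy()
    finite_boost = enrichment if np.isfinite(enrichment) else 1.0
    for i, cid in enumerate(base_ids):
        f = freq_by_id.get(cid, 0.0)
        if cid in reactive_ids:
            weights[i] = f * finite_boost
        elif np.isfinite(enrichment):
            weights[i] = f
        # infinite enrichment: non-reactive weight stays zero
    table = _sample_to_table(truth, weights, depth, rng)
    return RepertoireSample(
        clones=table,
        timepoint=tp,
        compartment=compartment,
        subset="CD3",
        stimulation="unstim",
        platform="rna_biopsy",
    )


N_GENES_PER_SPECIES = 40
HUMAN_PREFIX = "GRCh38_"
PIG_PREFIX = "SusScr11_"


def simulate_single_cells(
    truth: GroundTruth,
    n_cells: int = 1000,
    pig_fraction: float = 0.1,
    doublet_fraction: float = 0.0,
    depth_per_cell: int = 1000,
    t_cell_fraction: float = 0.6,
    reactive_cell_fraction: float = 0.3,
    cross_contamination: float = 0.005,
    n_clusters: int = 4,
    reactive_cluster: int = 3,
):
    """Mixed-species single-cell counts plus a 10x-style TCR contig table.

    Pure human cells draw transcripts almost entirely from human genes,
    pure pig cells from pig genes (a small ``cross_contamination``
    fraction emulates ambient RNA), and human-pig doublets mix 50/50. A
    ``t_cell_fraction`` of human cells carry a TCR-beta clonotype, of
    which ``reactive_cell_fraction`` come from the reactive truth set;
    reactive T cells concentrate in ``reactive_cluster``.

    Returns ``(adata, contigs, cell_truth)``: an AnnData of counts with
    species-prefixed gene identifiers, the contig annotation DataFrame,
    and the per-cell truth table.
    """
    import anndata as ad
    from scipy import sparse

    if not 0 <= pig_fraction <= 1 or not 0 <= doublet_fraction <= 1:
        raise ValueError("pig_fraction and doublet_fraction must lie in [0, 1]")
    config = truth.config
    rng = substream(config.seed, "single_cells")
    genes = [f"{HUMAN_PREFIX}GENE{i}" for i in range(N_GENES_PER_SPECIES)] + [
        f"{PIG_PREFIX}GENE{i}" for i in range(N_GENES_PER_SPECIES)
    ]
    species = ["human"] * N_GENES_PER_SPECIES + ["pig"] * N_GENES_PER_SPECIES
    hum_expr = rng.dirichlet(np.ones(N_GENES_PER_SPECIES))
    pig_expr = rng.dirichlet(np.ones(N_GENES_PER_SPECIES))

    u = rng.random(n_cells)
    truth_species = np.where(
        u < doublet_fraction, "doublet", np.where(u < doublet_fraction + pig_fraction * (1 - doublet_fraction), "pig", "human")
    )
    barcodes = [f"CELL{i:05d}-1" for i in range(n_cells)]

    X = np.zeros((n_cells, 2 * N_GENES_PER_SPECIES), dtype=np.int64)
    for i, sp in enumerate(truth_species):
        if sp == "human":
            h_share = 1.0 - cross_contamination
        elif sp == "pig":
            h_share = cross_contamination
        else:
            h_share = 0.5
        probs = np.concatenate([h_share * hum_expr, (1 - h_share) * pig_expr])
        X[i] = rng.multinomial(depth_per_cell, probs)

    # TCR clonotypes on human T cells
    clones = truth.clones
    reactive = truth.reactive_mask()
    base = clones["baseline_freq"].to_numpy()
    p_reactive = base * reactive
    p_nonreactive = base * ~reactive
    contig_rows = []
    cell_clonotype = np.array([""] * n_cells, dtype=object)
    cell_reactive = np.zeros(n_cells, dtype=bool)
    for i, sp in enumerate(truth_species):
        if sp != "human" or rng.random() >= t_cell_fraction:
            continue
        if reactive.any() and rng.random() < reactive_cell_fraction:
            idx = rng.choice(len(clones), p=p_reactive / p_reactive.sum())
            cell_reactive[i] = True
        else:
            idx = rng.choice(len(clones), p=p_nonreactive / p_nonreactive.sum())
        row = clones.iloc[idx]
        cell_clonotype[i] = row["cdr3_nt"]
        contig_rows.append(
            {
                "barcode": barcodes[i],
                "is_cell": "True",
                "high_confidence": "True",
                "chain": "TRB",
                "v_gene": row["v_call"],
                "j_gene": row["j_call"],
                "cdr3": row["cdr3_aa"],
                "cdr3_nt": row["cdr3_nt"],
                "productive": "True",
            }
        )
    contigs = pd.DataFrame(
        contig_rows,
        columns=[
            "barcode", "is_cell", "high_confidence", "chain",
            "v_gene", "j_gene", "cdr3", "cdr3_nt", "productive",
        ],
    )

    # cluster labels: reactive T cells concentrate in one cluster
    cluster = rng.integers(0, n_clusters, size=n_cells)
    cluster[cell_reactive] = reactive_cluster

    adata = ad.AnnData(
        X=sparse.csr_matrix(X),
        obs=pd.DataFrame({"species_true": truth_species, "cluster": cluster.astype(str)}, index=barcodes),
        var=pd.DataFrame({"species": species}, index=genes),
    )
    cell_truth = pd.DataFrame(
        {
            "barcode": barcodes,
            "species_true": truth_species,
            "clonotype_nt": cell_clonotype,
            "is_reactive_true": cell_reactive,
            "cluster": cluster.astype(str),
        }
    )
    return adata, contigs, cell_truth
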