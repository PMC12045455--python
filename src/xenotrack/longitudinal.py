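"""Repertoire diversity and clone-set tracking statistics.

Diversity metrics follow the bulk TCR-sequencing conventions: clonality
is one minus the Shannon-entropy evenness (natural log, normalised by
log of the number of unique clones), R20 is the fraction of unique
clonotypes (largest first) needed to cover 20% of templates, and
hyperexpanded clonotypes are those exceeding 1% of the repertoire.

Clone-set tracking compares a reactive set against the non-reactive
control across timepoints: cumulative frequency, its fold change from
the pre-transplant baseline, and relative clonal/template detection
rates (reactive detection ratio divided by non-reactive detection
ratio, so values above 1 indicate selective reactive expansion beyond
any lymphopenia-driven background). Significance uses Fisher's exact
test for hyperexpanded proportions and the pooled two-proportion z test
for detection rates. The clonal-convergence statistic is the mean
number of distinct nucleotide rearrangements per amino-acid CDR3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportions_ztest

from xenotrack.io import EmptySampleError, RepertoireSample, clonotype_key
from xenotrack.reactivity import NonReactiveSet, ReactiveCloneSet


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    method: str


@dataclass
class DiversityResult:
    clonality: float
    r20: float
    hyperexpanded_clones: int
    hyperexpanded_fraction: float
    n_unique_clones: int
    n_templates: int | None


def _frequencies(sample: RepertoireSample) -> np.ndarray:
    f = sample.productive["frequency"].to_numpy(dtype=float)
    if f.size == 0:
        raise EmptySampleError("sample has no productive clones")
    return f


def clonality(sample: RepertoireSample) -> float:
    """1 - H/ln(R): 0 for a perfectly even repertoire, 1 for a
    monoclonal one (single-clone samples return 1 by convention)."""
    f = _frequencies(sample)
    r = f.size
    if r == 1:
        return 1.0
    f = f / f.sum()
    h = float(-(f * np.log(f)).sum())
    return 1.0 - h / np.log(r)


def r20(sample: RepertoireSample, quantile: float = 0.20) -> float:
    """Fraction of unique clonotypes, largest first, covering 20% of
    templates; smaller values mean dominance by few clones."""
    f = np.sort(_frequencies(sample))[::-1]
    f = f / f.sum()
    k = int(np.searchsorted(np.cumsum(f), quantile - 1e-12) + 1)
    return k / f.size


def hyperexpanded_fraction(sample: RepertoireSample, threshold: float = 0.01) -> dict:
    """Clones strictly above ``threshold`` frequency: their count and
    summed frequency."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    f = _frequencies(sample)
    mask = f > threshold
    return {"clone_count": int(mask.sum()), "template_fraction": float(f[mask].sum())}


def fisher_hyperexpanded(
    sample: RepertoireSample,
    baseline: RepertoireSample,
    threshold: float = 0.01,
    level: str = "clone",
) -> TestResult:
    """Two-sided Fisher exact test comparing the hyperexpanded
    compartment between a sample and the pre-transplant baseline.

    ``level="clone"`` (default) counts clonotypes above vs below the
    threshold; ``level="template"`` counts templates inside vs outside
    hyperexpanded clones, which weighs the abundance of the expanded
    compartment rather than the number of distinct clones and has far
    more counting resolution at modest repertoire sizes.
    """
    if level == "clone":
        hs = hyperexpanded_fraction(sample, threshold)["clone_count"]
        hb = hyperexpanded_fraction(baseline, threshold)["clone_count"]
        ns = _frequencies(sample).size - hs
        nb = _frequencies(baseline).size - hb
    elif level == "template":
        if sample.total_templates is None or baseline.total_templates is None:
            raise ValueError("template-level test requires template counts")
        hs = int(round(hyperexpanded_fraction(sample, threshold)["template_fraction"]
                       * sample.total_templates))
        hb = int(round(hyperexpanded_fraction(baseline, threshold)["template_fraction"]
                       * baseline.total_templates))
        ns = sample.total_templates - hs
        nb = baseline.total_templates - hb
    else:
        raise ValueError("level must be 'clone' or 'template'")
    table = np.array([[hs, ns], [hb, nb]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate contingency table (zero margin); p = 1")
        return TestResult(statistic=1.0, pvalue=1.0, method="fisher_exact")
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return TestResult(statistic=float(odds), pvalue=float(p), method="fisher_exact")


def subset_normalize(cd3_sample: RepertoireSample, subset_fraction: float) -> RepertoireSample:
    """Rescale clone frequencies measured within total CD3 cells onto a
    within-subset scale by dividing by the flow-cytometric subset
    fraction (capped at 1). Used to place mixed pre-transplant CD3 data
    on the same scale as sorted post-transplant CD4/CD8 repertoires;
    the output frequencies intentionally no longer sum to 1."""
    if not 0 < subset_fraction <= 1:
        raise ValueError("subset_fraction must lie in (0, 1]")
    clones = cd3_sample.clones.copy()
    clones["frequency"] = np.minimum(clones["frequency"] / subset_fraction, 1.0)
    return cd3_sample.with_clones(clones)


def cumulative_frequency(keys, sample: RepertoireSample, key_mode: str = "nt") -> float:
    """Summed sample frequency over a set of clonotype keys (absent keys
    contribute zero)."""
    prod = sample.productive
    if prod.shape[0] == 0:
        return 0.0
    k = clonotype_key(prod, key_mode)
    return float(prod.loc[k.isin(set(keys)), "frequency"].sum())


def fold_change(
    keys,
    post_sample: RepertoireSample,
    pre_sample: RepertoireSample,
    key_mode: str = "nt",
) -> float:
    """Cumulative-frequency fold change of a clone set, post vs pre;
    ``inf`` when the set is undetected pre-transplant."""
    pre = cumulative_frequency(keys, pre_sample, key_mode)
    post = cumulative_frequency(keys, post_sample, key_mode)
    if pre == 0:
        return np.inf if post > 0 else np.nan
    return post / pre


def _detected_keys(sample: RepertoireSample, key_mode: str) -> set:
    """Keys detected (>= 1 template, or any frequency on RNA platforms)."""
    prod = sample.productive
    return set(clonotype_key(prod, key_mode))


def detection_counts(
    keys,
    post_sample: RepertoireSample,
    pre_sample: RepertoireSample,
    key_mode: str = "nt",
) -> dict:
    """Of the set's clones detected pre-transplant, how many are
    re-detected post-transplant; plus template-level cumulative
    frequencies for the template-level ratio."""
    keys = set(keys)
    pre_detected = keys & _detected_keys(pre_sample, key_mode)
    post_detected = pre_detected & _detected_keys(post_sample, key_mode)
    return {
        "n_pre": len(pre_detected),
        "n_post": len(post_detected),
        "freq_pre": cumulative_frequency(pre_detected, pre_sample, key_mode),
        "freq_post": cumulative_frequency(pre_detected, post_sample, key_mode),
    }


def relative_detection(
    reactive: ReactiveCloneSet | set,
    nonreactive: NonReactiveSet | set,
    post_sample: RepertoireSample,
    pre_sample: RepertoireSample,
    level: str = "clonal",
    key_mode: str = "nt",
) -> float:
    """Reactive-set enrichment relative to the non-reactive control.

    ``clonal`` level: (reactive clones re-detected post / detected pre)
    divided by the same ratio for non-reactive clones. ``template``
    level: ratio of cumulative-frequency fold changes. Values above 1
    indicate reactive-specific expansion beyond the lymphopenia-driven
    background; ``inf`` with a diagnostic when a denominator is zero.
    Both sets are restricted to clones detected pre-transplant.
    """
    if level not in ("clonal", "template"):
        raise ValueError("level must be 'clonal' or 'template'")
    r_keys = reactive.keys if hasattr(reactive, "keys") and not isinstance(reactive, set) else set(reactive)
    n_keys = nonreactive.keys if hasattr(nonreactive, "keys") and not isinstance(nonreactive, set) else set(nonreactive)
    rc = detection_counts(r_keys, post_sample, pre_sample, key_mode)
    nc = detection_counts(n_keys, post_sample, pre_sample, key_mode)
    if level == "clonal":
        terms = {
            "reactive clones detected pre": rc["n_pre"],
            "nonreactive clones detected pre": nc["n_pre"],
            "nonreactive clones detected post": nc["n_post"],
        }
        for name, v in terms.items():
            if v == 0:
                warnings.warn(f"zero denominator term: {name}")
                return np.inf
        return (rc["n_post"] / rc["n_pre"]) / (nc["n_post"] / nc["n_pre"])
    terms = {
        "reactive pre-transplant cumulative frequency": rc["freq_pre"],
        "nonreactive pre-transplant cumulative frequency": nc["freq_pre"],
        "nonreactive post-transplant cumulative frequency": nc["freq_post"],
    }
    for name, v in terms.items():
        if v == 0:
            warnings.warn(f"zero denominator term: {name}")
            return np.inf
    return (rc["freq_post"] / rc["freq_pre"]) / (nc["freq_post"] / nc["freq_pre"])


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Pooled two-proportion z test, two-sided."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if x1 + x2 == 0 or x1 + x2 == n1 + n2:
        warnings.warn("degenerate pooled proportion; z = 0, p = 1")
        return TestResult(statistic=0.0, pvalue=1.0, method="two_proportion_z")
    z, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
    return TestResult(statistic=float(z), pvalue=float(p), method="two_proportion_z")


def convergence_ratio(sample: RepertoireSample, keys=None, key_mode: str = "aa") -> float:
    """Mean number of distinct nucleotide CDR3 sequences per amino-acid
    CDR3, optionally restricted to a clone set.

    Restriction by amino-acid keys (the default mode) is the natural
    choice: synonymous nucleotide variants of a set member share its
    amino-acid key, so newly arisen variants count toward convergence.
    """
    prod = sample.productive
    if keys is not None:
        k = clonotype_key(prod, key_mode)
        prod = prod.loc[k.isin(set(keys))]
    if prod.shape[0] == 0:
        raise EmptySampleError("no productive clones after restriction")
    return float(prod.groupby("cdr3_aa")["cdr3_nt"].nunique().mean())


def top_clones(
    sample: RepertoireSample,
    n: int = 5,
    reactive: ReactiveCloneSet | None = None,
    key_mode: str = "nt",
) -> pd.DataFrame:
    """The ``n`` highest-frequency productive clones (ties broken
    lexicographically by key), annotated with reactive-set membership
    when a reactive set is supplied."""
    prod = sample.productive.copy()
    prod["key"] = clonotype_key(prod, key_mode)
    prod = prod.sort_values(["frequency", "key"], ascending=[False, True]).head(n)
    if reactive is not None:
        prod["reactive"] = prod["key"].isin(reactive.keys)
    return prod.reset_index(drop=True)


def overlap_cumfreq_matrix(samples: list[RepertoireSample], key_mode: str = "nt") -> pd.DataFrame:
    """Matrix of shared-clone cumulative frequencies: entry (i, j) is
    the cumulative frequency, within sample i, of clonotypes also
    detected in sample j. The diagonal is 1 by construction."""
    keysets = [_detected_keys(s, key_mode) for s in samples]
    ids = [s.sample_id for s in samples]
    mat = np.zeros((len(samples), len(samples)))
    for i, s in enumerate(samples):
        for j, ks in enumerate(keysets):
            mat[i, j] = 1.0 if i == j else cumulative_frequency(ks, s, key_mode)
    return pd.DataFrame(mat, index=ids, columns=ids)


def track_sets(
    reactive: ReactiveCloneSet | set,
    nonreactive: NonReactiveSet | set,
    post_samples: list[RepertoireSample],
    pre_sample: RepertoireSample,
    key_mode: str = "nt",
) -> pd.DataFrame:
    """Tidy per-timepoint tracking table for a reactive/non-reactive
    set pair: cumulative frequencies, fold changes, relative detection
    rates at both levels, and pooled-z p-values comparing clonal
    detection proportions."""
    r_keys = reactive.keys if hasattr(reactive, "keys") and not isinstance(reactive, set) else set(reactive)
    n_keys = nonreactive.keys if hasattr(nonreactive, "keys") and not isinstance(nonreactive, set) else set(nonreactive)
    rows = []
    for post in post_samples:
        rc = detection_counts(r_keys, post, pre_sample, key_mode)
        nc = detection_counts(n_keys, post, pre_sample, key_mode)
        if rc["n_pre"] and nc["n_pre"]:
            z = two_proportion_z(rc["n_post"], rc["n_pre"], nc["n_post"], nc["n_pre"])
            z_stat, z_p = z.statistic, z.pvalue
        else:
            z_stat, z_p = np.nan, np.nan
        rows.append(
            {
                "timepoint": post.timepoint,
                "cumulative_frequency": cumulative_frequency(r_keys, post, key_mode),
                "n_clones_detected": len(r_keys & _detected_keys(post, key_mode)),
                "fold_change": fold_change(r_keys, post, pre_sample, key_mode),
                "relative_clonal_detection": relative_detection(
                    r_keys, n_keys, post, pre_sample, "clonal", key_mode
                ),
                "relative_template_detection": relative_detection(
                    r_keys, n_keys, post, pre_sample, "template", key_mode
                ),
                "z_statistic": z_stat,
                "z_pvalue": z_p,
            }
        )
    return pd.DataFrame(rows)


def diversity(sample: RepertoireSample, hyper_threshold: float = 0.01) -> DiversityResult:
    """All repertoire-level diversity metrics for one sample."""
    h = hyperexpanded_fraction(sample, hyper_threshold)
    return DiversityResult(
        clonality=clonality(sample),
        r20=r20(sample),
        hyperexpanded_clones=h["clone_count"],
        hyperexpanded_fraction=h["template_fraction"],
        n_unique_clones=sample.n_clones,
        n_templates=sample.total_templates,
    )
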