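"""Calling donor-reactive clones from MLR stimulated/unstimulated pairs.

A clonotype is called reactive when its frequency in the divided
(CFSE-low) MLR population is at least ``fold_threshold`` times its
pre-transplant unstimulated frequency — the two-fold rule that excludes
bystander proliferation and sorting errors. Clones absent from the
baseline are admitted when they carry at least ``min_templates``
templates in the divided population, with the fold recorded as infinite.

Pathway assignment is purely set-membership driven: a clone expanded
only in direct MLRs is direct, only in indirect MLRs is indirect, and a
clone expanded in both — or detected only in a late post-transplant
MLR — is labelled undefined. The non-reactive control set holds every
pre-transplant blood clone absent from all proliferated populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from xenotrack.io import RepertoireSample, clonotype_key

ENTRY_COLUMNS = [
    "key", "subset", "pathway", "source_mlrs",
    "stim_frequency", "baseline_frequency", "fold",
]


@dataclass
class ReactiveCloneSet:
    """Clonotype keys called reactive, with provenance.

    ``entries`` has one row per key: subset of the sorted population of
    origin, pathway label (``direct``/``indirect``/``undefined`` or
    ``unassigned`` before merging), source MLR sample identifiers,
    stimulated and baseline frequencies, and the fold (``inf`` when the
    clone was undetected pre-transplant). Rows are ordered by descending
    stimulated frequency, ties broken lexicographically by key.
    """

    entries: pd.DataFrame
    key_mode: str = "nt"

    def __post_init__(self):
        missing = [c for c in ENTRY_COLUMNS if c not in self.entries.columns]
        if missing:
            raise ValueError(f"entries missing column(s) {missing}")
        self.entries = (
            self.entries.sort_values(
                ["stim_frequency", "key"], ascending=[False, True]
            ).reset_index(drop=True)
        )

    @property
    def keys(self) -> set:
        return set(self.entries["key"])

    def __len__(self) -> int:
        return len(self.entries)

    def subset_keys(self, subset: str) -> set:
        e = self.entries
        return set(e.loc[e["subset"] == subset, "key"])

    def rekey(self, key_mode: str) -> "ReactiveCloneSet":
        """Re-key the set under another clonotype mode (e.g. ``aa_v``
        for matching RNA-derived biopsy or single-cell clonotypes
        against a DNA-called set). Requires the sequence columns
        (``cdr3_nt``, ``cdr3_aa``, ``v_call``); entries collapsing onto
        one new key keep the highest-stim-frequency representative."""
        if key_mode == self.key_mode:
            return self
        for col in ("cdr3_nt", "cdr3_aa", "v_call"):
            if col not in self.entries.columns:
                raise ValueError(f"cannot rekey: entries lack {col!r}")
        e = self.entries.copy()
        e["key"] = clonotype_key(e, key_mode)
        e = e.sort_values(
            ["stim_frequency", "key"], ascending=[False, True]
        ).drop_duplicates("key", keep="first")
        return ReactiveCloneSet(entries=e.reset_index(drop=True), key_mode=key_mode)

    def to_tsv(self, path) -> None:
        out = self.entries.copy()
        out["source_mlrs"] = out["source_mlrs"].map(lambda s: ";".join(s))
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, key_mode: str = "nt") -> "ReactiveCloneSet":
        e = pd.read_csv(path, sep="\t", dtype={"key": str})
        e["source_mlrs"] = e["source_mlrs"].fillna("").map(
            lambda s: [x for x in str(s).split(";") if x]
        )
        return cls(entries=e, key_mode=key_mode)


@dataclass
class NonReactiveSet:
    """Control clonotypes: present pre-transplant, absent from every
    proliferated MLR population."""

    entries: pd.DataFrame  # columns: key, baseline_frequency
    key_mode: str = "nt"

    @property
    def keys(self) -> set:
        return set(self.entries["key"])

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)


def _keyed_productive(sample: RepertoireSample, key_mode: str) -> pd.DataFrame:
    """Productive records aggregated by clonotype key, keeping the
    sequence fields of each key's largest contributor."""
    prod = sample.productive.copy()
    if prod.shape[0] == 0:
        return pd.DataFrame(
            columns=["key", "templates", "frequency", "cdr3_nt", "cdr3_aa", "v_call"]
        )
    prod["key"] = clonotype_key(prod, key_mode)
    prod = prod.sort_values(["frequency", "cdr3_nt"], ascending=[False, True])
    agg = prod.groupby("key", sort=True).agg(
        templates=("templates", "sum"),
        frequency=("frequency", "sum"),
        cdr3_nt=("cdr3_nt", "first"),
        cdr3_aa=("cdr3_aa", "first"),
        v_call=("v_call", "first"),
    )
    return agg.reset_index()


def call_reactive(
    stimulated: RepertoireSample,
    baseline_unstim: RepertoireSample,
    fold_threshold: float = 2.0,
    min_templates: int = 2,
    key_mode: str = "nt",
) -> ReactiveCloneSet:
    """Call reactive clones from one divided-population/baseline pair.

    A clone is included iff it is detected in the stimulated sample with
    at least ``min_templates`` templates AND it is either absent from
    the baseline (fold recorded as ``inf``) or its stimulated frequency
    is at least ``fold_threshold`` times its baseline frequency.

    The baseline must be the pre-transplant *unstimulated* repertoire of
    the same subject, even when post-transplant PBMCs served as MLR
    responders.
    """
    if stimulated.subject != baseline_unstim.subject:
        raise ValueError(
            f"subject mismatch: {stimulated.subject!r} vs {baseline_unstim.subject!r}"
        )
    stim = _keyed_productive(stimulated, key_mode)
    base = _keyed_productive(baseline_unstim, key_mode)
    if stim.shape[0] == 0:
        warnings.warn("empty stimulated sample; returning an empty reactive set")
        return ReactiveCloneSet(
            entries=pd.DataFrame(columns=ENTRY_COLUMNS), key_mode=key_mode
        )
    base_freq = dict(zip(base["key"], base["frequency"]))
    rows = []
    for _, r in stim.iterrows():
        if pd.notna(r["templates"]) and r["templates"] < min_templates:
            continue
        bf = base_freq.get(r["key"])
        if bf is None:
            fold = np.inf
        else:
            fold = r["frequency"] / bf
            if fold < fold_threshold:
                continue
        rows.append(
            {
                "key": r["key"],
                "subset": stimulated.subset,
                "pathway": "unassigned",
                "source_mlrs": [stimulated.sample_id],
                "stim_frequency": r["frequency"],
                "baseline_frequency": np.nan if bf is None else bf,
                "fold": fold,
                "cdr3_nt": r["cdr3_nt"],
                "cdr3_aa": r["cdr3_aa"],
                "v_call": r["v_call"],
            }
        )
    entries = pd.DataFrame(rows, columns=ENTRY_COLUMNS + ["cdr3_nt", "cdr3_aa", "v_call"])
    return ReactiveCloneSet(entries=entries, key_mode=key_mode)


def assign_pathway(
    direct_sets: list[ReactiveCloneSet],
    indirect_sets: list[ReactiveCloneSet],
    late_only_sets: list[ReactiveCloneSet] = (),
) -> ReactiveCloneSet:
    """Merge per-MLR reactive sets into one pathway-labelled set.

    A key appearing only among direct MLRs is ``direct``; only among
    indirect MLRs ``indirect``; in both pathways, or exclusively in a
    late-only MLR, ``undefined``. The subset label is carried from the
    sorted population of origin; keys claimed as CD4 by one MLR and CD8
    by another are flagged ``ambiguous`` (excluded from subset-specific
    statistics downstream).
    """
    all_sets = list(direct_sets) + list(indirect_sets) + list(late_only_sets)
    if not all_sets:
        raise ValueError("no reactive sets supplied")
    modes = {s.key_mode for s in all_sets}
    if len(modes) > 1:
        raise ValueError(f"mismatched key modes across sets: {sorted(modes)}")
    key_mode = all_sets[0].key_mode

    direct_keys = set().union(*(s.keys for s in direct_sets)) if direct_sets else set()
    indirect_keys = set().union(*(s.keys for s in indirect_sets)) if indirect_sets else set()
    late_keys = set().union(*(s.keys for s in late_only_sets)) if late_only_sets else set()

    frames = [s.entries for s in all_sets if len(s)]
    merged = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=ENTRY_COLUMNS)

    rows = []
    n_ambiguous = 0
    for key, grp in merged.groupby("key", sort=True):
        in_d, in_i = key in direct_keys, key in indirect_keys
        if in_d and not in_i:
            pathway = "direct"
        elif in_i and not in_d:
            pathway = "indirect"
        else:  # in both, or only in a late_only set
            pathway = "undefined"
        subsets = set(grp["subset"])
        if {"CD4", "CD8"} <= subsets:
            subset = "ambiguous"
            n_ambiguous += 1
        else:
            subset = grp["subset"].iloc[0]
        bf = grp["baseline_frequency"].dropna()
        row = {
            "key": key,
            "subset": subset,
            "pathway": pathway,
            "source_mlrs": sorted({m for ms in grp["source_mlrs"] for m in ms}),
            "stim_frequency": float(grp["stim_frequency"].max()),
            "baseline_frequency": float(bf.iloc[0]) if len(bf) else np.nan,
            "fold": float(grp["fold"].max()),
        }
        for col in ("cdr3_nt", "cdr3_aa", "v_call"):
            if col in grp.columns:
                row[col] = grp[col].iloc[0]
        rows.append(row)
    if n_ambiguous:
        warnings.warn(
            f"{n_ambiguous} clone(s) with conflicting CD4/CD8 subset labels "
            "flagged ambiguous"
        )
    if rows:
        entries = pd.DataFrame(rows)
    else:
        entries = pd.DataFrame(columns=ENTRY_COLUMNS)
    return ReactiveCloneSet(entries=entries, key_mode=key_mode)


def define_nonreactive(
    pre_tx_blood: RepertoireSample,
    all_proliferated: list[RepertoireSample],
    key_mode: str = "nt",
) -> NonReactiveSet:
    """Control set: pre-transplant blood clones absent from every
    proliferated MLR population."""
    pre = _keyed_productive(pre_tx_blood, key_mode)
    if pre.shape[0] == 0:
        raise ValueError("pre-transplant sample has no productive clones")
    excluded = set()
    for s in all_proliferated:
        excluded |= set(_keyed_productive(s, key_mode)["key"])
    keep = pre[~pre["key"].isin(excluded)]
    entries = keep.rename(columns={"frequency": "baseline_frequency"})[
        ["key", "baseline_frequency"]
    ].reset_index(drop=True)
    return NonReactiveSet(entries=entries, key_mode=key_mode)


def overlap_clones(
    sample_a: RepertoireSample,
    sample_b: RepertoireSample,
    key_mode: str = "nt",
) -> dict:
    """Clonotype overlap between two repertoires.

    Returns unique-clone counts for each input and their intersection,
    plus the paired frequency table (frequency 0 where a key is absent)
    used for the frequency-correlation plots that reveal pathway
    disjointness.
    """
    a = _keyed_productive(sample_a, key_mode)
    b = _keyed_productive(sample_b, key_mode)
    pairs = a[["key", "frequency"]].merge(
        b[["key", "frequency"]], on="key", how="outer", suffixes=("_a", "_b")
    )
    pairs = pairs.fillna({"frequency_a": 0.0, "frequency_b": 0.0}).sort_values("key")
    n_shared = int(((pairs["frequency_a"] > 0) & (pairs["frequency_b"] > 0)).sum())
    return {
        "n_a": int(a.shape[0]),
        "n_b": int(b.shape[0]),
        "n_shared": n_shared,
        "pairs": pairs.reset_index(drop=True),
    }
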