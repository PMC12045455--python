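"""Cross-compartment clone tracing and mixed-species single-cell work.

Single cells from a pig-to-human xenograft carry transcripts of both
species; each cell is classified as human, pig, or ambiguous from its
species-resolved transcript counts, pig cells are removed, and the
surviving human T cells are matched against the bulk-defined reactive
clone set (amino-acid + V-family keys by default, because single-cell
and biopsy clonotypes are RNA-derived while reactive calling is
DNA-based). Clone sets are also traced across repertoire samples from
different compartments and timepoints.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from xenotrack.io import RepertoireSample, clonotype_key, v_family
from xenotrack.reactivity import ReactiveCloneSet

CELL_COLUMNS = [
    "barcode", "human_transcripts", "pig_transcripts", "species_call",
    "clonotype", "reactive_membership", "reactive_subset", "multi_chain", "cluster",
]


def classify_species(
    human_count: int,
    pig_count: int,
    min_total: int = 200,
    purity: float = 0.9,
) -> str:
    """Species call from per-cell transcript counts.

    ``human`` when the human share of transcripts is at least
    ``purity``, ``pig`` when it is at most ``1 - purity``, otherwise
    ``ambiguous``; cells with fewer than ``min_total`` transcripts are
    always ambiguous. The call is scale-invariant above the total-count
    floor.
    """
    if human_count < 0 or pig_count < 0:
        raise ValueError("transcript counts must be non-negative")
    total = human_count + pig_count
    if total < min_total:
        return "ambiguous"
    share = human_count / total
    if share >= purity:
        return "human"
    if share <= 1 - purity:
        return "pig"
    return "ambiguous"


def species_counts(adata) -> pd.DataFrame:
    """Per-cell human/pig transcript totals from an AnnData whose var
    carries a ``species`` column (or species-prefixed gene ids)."""
    if "species" in adata.var.columns:
        species = adata.var["species"].to_numpy()
    else:
        species = np.where(
            adata.var_names.str.lower().str.startswith(("grch", "hg", "human")),
            "human",
            "pig",
        )
    X = adata.X
    human = np.asarray(X[:, species == "human"].sum(axis=1)).ravel()
    pig = np.asarray(X[:, species == "pig"].sum(axis=1)).ravel()
    return pd.DataFrame(
        {"barcode": adata.obs_names, "human_transcripts": human, "pig_transcripts": pig}
    ).reset_index(drop=True)


def annotate_cells(
    adata,
    min_total: int = 200,
    purity: float = 0.9,
) -> pd.DataFrame:
    """Cell annotation table with species calls for every cell."""
    cells = species_counts(adata)
    cells["species_call"] = [
        classify_species(h, p, min_total=min_total, purity=purity)
        for h, p in zip(cells["human_transcripts"], cells["pig_transcripts"])
    ]
    cells["clonotype"] = None
    cells["reactive_membership"] = None
    cells["reactive_subset"] = None
    cells["multi_chain"] = False
    cells["cluster"] = (
        adata.obs["cluster"].to_numpy() if "cluster" in adata.obs.columns else None
    )
    return cells[CELL_COLUMNS]


def filter_pig_cells(cells: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Remove non-human cells; returns (human cells, removed counts by
    class)."""
    removed = cells.loc[cells["species_call"] != "human", "species_call"].value_counts()
    kept = cells[cells["species_call"] == "human"].reset_index(drop=True)
    return kept, {k: int(v) for k, v in removed.items()}


def _contig_keys(contigs: pd.DataFrame, key_mode: str) -> pd.Series:
    df = pd.DataFrame(
        {
            "cdr3_nt": contigs.get("cdr3_nt", ""),
            "cdr3_aa": contigs.get("cdr3", contigs.get("cdr3_aa", "")),
            "v_call": contigs.get("v_gene", contigs.get("v_call", "")),
        }
    )
    return clonotype_key(df, key_mode)


def match_clonotypes(
    cells: pd.DataFrame,
    contigs: pd.DataFrame,
    reactive: ReactiveCloneSet,
    key_mode: str = "aa_v",
) -> pd.DataFrame:
    """Annotate cells whose TCR-beta clonotype matches the reactive set.

    Only beta-chain (TRB) contigs count — reactive sets are TCRB-defined,
    so an alpha-only match never marks a cell reactive. Cells with
    several beta chains match if any chain matches and are flagged
    ``multi_chain``.
    """
    if reactive.key_mode != key_mode:
        raise ValueError(
            f"key-mode mismatch: reactive set is {reactive.key_mode!r}, requested {key_mode!r}"
        )
    cells = cells.copy()
    if contigs.shape[0] == 0:
        return cells
    trb = contigs[contigs["chain"] == "TRB"].copy()
    if "productive" in trb.columns:
        trb = trb[trb["productive"].astype(str).str.upper().isin(["T", "TRUE"])]
    trb["key"] = _contig_keys(trb, key_mode)
    per_cell = trb.groupby("barcode")["key"].agg(list)
    pathway = dict(zip(reactive.entries["key"], reactive.entries["pathway"]))
    subset = dict(zip(reactive.entries["key"], reactive.entries["subset"]))
    idx = cells.set_index("barcode").index
    for barcode, keylist in per_cell.items():
        if barcode not in idx:
            continue
        row = cells.index[cells["barcode"] == barcode][0]
        cells.at[row, "clonotype"] = keylist[0]
        cells.at[row, "multi_chain"] = len(set(keylist)) > 1
        hits = [k for k in keylist if k in pathway]
        if hits:
            cells.at[row, "clonotype"] = hits[0]
            cells.at[row, "reactive_membership"] = pathway[hits[0]]
            cells.at[row, "reactive_subset"] = subset[hits[0]]
    return cells


def cluster_occupancy(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster tally of cells, reactive cells, reactive fraction and
    per-pathway counts; clusters with zero cells are omitted."""
    rows = []
    for cluster, grp in cells.groupby("cluster", sort=True):
        reactive = grp["reactive_membership"].notna()
        row = {
            "cluster": cluster,
            "n_cells": len(grp),
            "n_reactive": int(reactive.sum()),
            "reactive_fraction": float(reactive.mean()) if len(grp) else 0.0,
        }
        for pw in ("direct", "indirect", "undefined", "unassigned"):
            row[f"n_{pw}"] = int((grp["reactive_membership"] == pw).sum())
        rows.append(row)
    return pd.DataFrame(rows)


def trace_clones(
    keys,
    samples: list[RepertoireSample],
    key_mode: str = "aa_v",
) -> pd.DataFrame:
    """Frequency of each clonotype key in each sample (0 when absent),
    one row per key and one column per sample, with presence implied by
    positivity. Used to follow clones lymphocele -> blood -> biopsy."""
    keys = sorted(set(keys))
    data = {}
    for s in samples:
        prod = s.productive
        k = clonotype_key(prod, key_mode)
        agg: dict[str, float] = {}
        for kk, f in zip(k, prod["frequency"]):
            agg[kk] = agg.get(kk, 0.0) + float(f)
        data[s.sample_id] = [agg.get(key, 0.0) for key in keys]
    return pd.DataFrame(data, index=keys)


def traceable_keys(keys, samples: list[RepertoireSample], key_mode: str = "aa_v") -> set:
    """Keys detected in every sample of the given compartment chain."""
    matrix = trace_clones(keys, samples, key_mode)
    return set(matrix.index[(matrix > 0).all(axis=1)])
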