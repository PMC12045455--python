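"""Reading, validating and writing TCR-beta clone tables.

Clone tables arrive in three dialects:

* ``airr`` — AIRR Community Rearrangement TSV (``junction``,
  ``junction_aa``, ``v_call``, ``j_call``, ``duplicate_count``,
  ``productive``).
* ``immunoseq`` — the Adaptive immunoSEQ-style export (``rearrangement``,
  ``amino_acid``, ``v_gene``, ``j_gene``, ``templates``, ``frame_type``).
* ``rna_biopsy`` — RNA-derived biopsy clonotype tables that carry
  frequencies but may lack template-level counts.

Internally every sample is a :class:`RepertoireSample`: a pandas DataFrame
of clone records plus sample-level metadata. Frequencies are always
recomputed over productive templates on load, so downstream statistics
never depend on whatever normalisation the upstream platform applied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Seq import Seq

CLONE_COLUMNS = [
    "cdr3_nt",
    "cdr3_aa",
    "v_call",
    "j_call",
    "templates",
    "frequency",
    "productive",
]

KEY_MODES = ("nt", "aa", "aa_v")

COMPARTMENTS = ("blood", "lymphocele", "kidney", "lymph_node", "in_vitro")
SUBSETS = ("CD4", "CD8", "CD3", "unsorted")
STIMULATIONS = ("unstim", "direct_mlr", "indirect_mlr")
PLATFORMS = ("dna_bulk", "rna_biopsy", "single_cell")

_AIRR_COLUMNS = {
    "junction": "cdr3_nt",
    "junction_aa": "cdr3_aa",
    "v_call": "v_call",
    "j_call": "j_call",
    "duplicate_count": "templates",
    "productive": "productive",
}
_IMMUNOSEQ_COLUMNS = {
    "rearrangement": "cdr3_nt",
    "amino_acid": "cdr3_aa",
    "v_gene": "v_call",
    "j_gene": "j_call",
    "templates": "templates",
    "frame_type": "frame_type",
}
_RNA_BIOPSY_REQUIRED = ["cdr3_nt", "cdr3_aa", "v_call", "j_call", "frequency"]


class CloneTableFormatError(ValueError):
    """A clone table file does not conform to the requested dialect."""


class EmptySampleError(ValueError):
    """A sample contains no productive clone records."""


@dataclass
class RepertoireSample:
    """A clone table plus its sample-level metadata.

    Parameters
    ----------
    clones
        DataFrame with columns ``cdr3_nt``, ``cdr3_aa``, ``v_call``,
        ``j_call``, ``templates`` (nullable for RNA platforms),
        ``frequency``, ``productive``.
    subject, timepoint, compartment, subset, stimulation, platform
        Provenance labels; ``compartment``/``subset``/``stimulation``/
        ``platform`` are restricted to the study vocabulary.
    """

    clones: pd.DataFrame
    subject: str = "S1"
    timepoint: str = "preTx"
    compartment: str = "blood"
    subset: str = "unsorted"
    stimulation: str = "unstim"
    platform: str = "dna_bulk"
    sample_id: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.subset not in SUBSETS:
            raise ValueError(f"unknown subset {self.subset!r}")
        if self.stimulation not in STIMULATIONS:
            raise ValueError(f"unknown stimulation {self.stimulation!r}")
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.sample_id is None:
            self.sample_id = (
                f"{self.subject}_{self.timepoint}_{self.compartment}_"
                f"{self.subset}_{self.stimulation}"
            )

    @property
    def productive(self) -> pd.DataFrame:
        """Productive clone records only."""
        return self.clones[self.clones["productive"]]

    @property
    def n_clones(self) -> int:
        return int(self.productive.shape[0])

    @property
    def total_templates(self) -> int | None:
        t = self.productive["templates"]
        if t.isna().any():
            return None
        return int(t.sum())

    def with_clones(self, clones: pd.DataFrame) -> "RepertoireSample":
        return replace(self, clones=clones)


def translate_cdr3(nt: str) -> str | None:
    """Translate a nucleotide CDR3; ``None`` if the length is not a codon
    multiple or the string contains non-ACGT characters."""
    nt = str(nt).upper()
    if len(nt) == 0 or len(nt) % 3 != 0 or re.search(r"[^ACGT]", nt):
        return None
    return str(Seq(nt).translate())


def v_family(v_call: str) -> str:
    """Gene family of a V call: the label up to the first ``-`` or allele
    separator (``TRBV12-3*01`` -> ``TRBV12``)."""
    return re.split(r"[-*/]", str(v_call))[0]


def clonotype_key(clones: pd.DataFrame, mode: str = "nt") -> pd.Series:
    """String clonotype keys for each record under the chosen mode.

    ``nt`` keys on the nucleotide CDR3 (DNA-platform comparisons);
    ``aa`` on the amino-acid CDR3; ``aa_v`` on amino-acid CDR3 plus
    V-gene family (the default for cross-platform matching, where the
    nucleotide sequence is not comparable between DNA and RNA assays).
    """
    if mode not in KEY_MODES:
        raise ValueError(f"unknown key mode {mode!r}; expected one of {KEY_MODES}")
    if mode == "nt":
        return clones["cdr3_nt"].astype(str)
    if mode == "aa":
        return clones["cdr3_aa"].astype(str)
    return clones["cdr3_aa"].astype(str) + "|" + clones["v_call"].map(v_family)


def _recompute_frequencies(clones: pd.DataFrame) -> pd.DataFrame:
    """Frequencies over productive templates (or given frequencies,
    renormalised, when templates are absent)."""
    clones = clones.copy()
    prod = clones["productive"]
    given = clones["frequency"].copy() if "frequency" in clones else None
    clones["frequency"] = 0.0
    if prod.sum() == 0:
        return clones
    if clones.loc[prod, "templates"].notna().all():
        total = float(clones.loc[prod, "templates"].sum())
        clones.loc[prod, "frequency"] = clones.loc[prod, "templates"] / total
    else:
        if given is None or given[prod].isna().any():
            raise CloneTableFormatError(
                "records lack both template counts and frequencies"
            )
        total = float(given[prod].sum())
        clones.loc[prod, "frequency"] = given[prod] / total
    return clones


def _finalize(clones: pd.DataFrame, dialect: str, path) -> pd.DataFrame:
    clones["templates"] = clones["templates"].astype("Float64")
    if dialect != "rna_biopsy":
        if clones["templates"].isna().any():
            raise CloneTableFormatError(f"{path}: missing template counts")
        # DNA-based samples: a retained record implies >= 1 template
        if (clones["templates"] < 1).any():
            raise CloneTableFormatError(f"{path}: template counts below 1")
    clones = _recompute_frequencies(clones)
    if not clones["productive"].any():
        raise EmptySampleError(f"{path}: no productive records")
    return clones.reset_index(drop=True)[CLONE_COLUMNS]


def read_clone_table(path, dialect: str = "airr", **metadata) -> RepertoireSample:
    """Read a clone table file into a validated :class:`RepertoireSample`.

    Parameters
    ----------
    path
        TSV file in the given dialect.
    dialect
        ``"airr"``, ``"immunoseq"`` or ``"rna_biopsy"``.
    **metadata
        Sample metadata (``subject``, ``timepoint``, ``compartment``,
        ``subset``, ``stimulation``, ``platform``) forwarded to the
        sample; ``rna_biopsy`` forces ``platform="rna_biopsy"``.

    Raises
    ------
    CloneTableFormatError
        If a mandatory column of the dialect is missing.
    EmptySampleError
        If the table holds no productive record.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if dialect == "airr":
        missing = [c for c in _AIRR_COLUMNS if c not in df.columns]
        if missing:
            raise CloneTableFormatError(f"{path}: missing AIRR column(s) {missing}")
        clones = df.rename(columns=_AIRR_COLUMNS)[list(_AIRR_COLUMNS.values())].copy()
        clones["productive"] = clones["productive"].str.upper().isin(["T", "TRUE"])
        clones["templates"] = pd.to_numeric(clones["templates"], errors="coerce")
    elif dialect == "immunoseq":
        missing = [c for c in _IMMUNOSEQ_COLUMNS if c not in df.columns]
        if missing:
            raise CloneTableFormatError(
                f"{path}: missing immunoSEQ column(s) {missing}"
            )
        clones = df.rename(columns=_IMMUNOSEQ_COLUMNS)[
            list(_IMMUNOSEQ_COLUMNS.values())
        ].copy()
        clones["productive"] = clones.pop("frame_type").str.lower() == "in"
        clones["templates"] = pd.to_numeric(clones["templates"], errors="coerce")
    elif dialect == "rna_biopsy":
        missing = [c for c in _RNA_BIOPSY_REQUIRED if c not in df.columns]
        if missing:
            raise CloneTableFormatError(
                f"{path}: missing rna_biopsy column(s) {missing}"
            )
        clones = df.copy()
        if "templates" not in clones.columns:
            clones["templates"] = np.nan
        clones["templates"] = pd.to_numeric(clones["templates"], errors="coerce")
        clones["frequency"] = pd.to_numeric(clones["frequency"], errors="coerce")
        if "productive" in clones.columns:
            clones["productive"] = clones["productive"].str.upper().isin(["T", "TRUE"])
        else:
            aa = clones["cdr3_aa"].astype(str)
            clones["productive"] = ~aa.str.contains(r"\*", regex=True) & (
                clones["cdr3_nt"].str.len() % 3 == 0
            )
        metadata.setdefault("platform", "rna_biopsy")
        clones = clones[
            ["cdr3_nt", "cdr3_aa", "v_call", "j_call", "templates", "frequency",
             "productive"]
        ]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if "frequency" not in clones.columns:
        clones["frequency"] = np.nan
    clones = _finalize(clones, dialect, path)
    return RepertoireSample(clones=clones, **metadata)


def write_clone_table(sample: RepertoireSample, path, dialect: str = "airr") -> None:
    """Serialise a sample to TSV in the given dialect.

    Column order is fixed per dialect so output is bit-stable; a
    round-trip through :func:`read_clone_table` reproduces the sample.
    """
    clones = sample.clones
    if clones.shape[0] == 0:
        raise EmptySampleError("refusing to serialize a sample with no clones")
    if dialect == "airr":
        out = pd.DataFrame(
            {
                "junction": clones["cdr3_nt"],
                "junction_aa": clones["cdr3_aa"],
                "v_call": clones["v_call"],
                "j_call": clones["j_call"],
                "duplicate_count": clones["templates"].astype("Int64"),
                "productive": np.where(clones["productive"], "T", "F"),
            }
        )
    elif dialect == "immunoseq":
        out = pd.DataFrame(
            {
                "rearrangement": clones["cdr3_nt"],
                "amino_acid": clones["cdr3_aa"],
                "v_gene": clones["v_call"],
                "j_gene": clones["j_call"],
                "templates": clones["templates"].astype("Int64"),
                "frame_type": np.where(clones["productive"], "In", "Out"),
            }
        )
    elif dialect == "rna_biopsy":
        out = pd.DataFrame(
            {
                "cdr3_nt": clones["cdr3_nt"],
                "cdr3_aa": clones["cdr3_aa"],
                "v_call": clones["v_call"],
                "j_call": clones["j_call"],
                "frequency": clones["frequency"].map(lambda f: f"{f:.12g}"),
                "productive": np.where(clones["productive"], "T", "F"),
            }
        )
        if clones["templates"].notna().all():
            out.insert(4, "templates", clones["templates"].astype("Int64"))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    out.to_csv(path, sep="\t", index=False)


def merge_by_clonotype(sample: RepertoireSample, key_mode: str = "nt") -> RepertoireSample:
    """Aggregate records sharing a clonotype key.

    Templates are summed, frequencies recomputed. Under the ``aa`` and
    ``aa_v`` modes the number of distinct contributing nucleotide
    sequences is retained per key in an ``nt_variants`` column — the raw
    material of the clonal-convergence statistic. The representative
    ``cdr3_nt``/``v_call``/``j_call`` of each merged record is that of
    its largest contributor; ties resolve lexicographically so the merge
    is deterministic.
    """
    clones = sample.clones.copy()
    clones["_key"] = clonotype_key(clones, key_mode)
    has_templates = clones["templates"].notna().all()
    weight = clones["templates"] if has_templates else clones["frequency"]
    clones["_weight"] = weight.astype(float)

    rows = []
    for (key, prod), grp in clones.groupby(["_key", "productive"], sort=True):
        grp = grp.sort_values(["_weight", "cdr3_nt"], ascending=[False, True])
        rep = grp.iloc[0]
        rows.append(
            {
                "cdr3_nt": rep["cdr3_nt"],
                "cdr3_aa": rep["cdr3_aa"],
                "v_call": rep["v_call"],
                "j_call": rep["j_call"],
                "templates": grp["templates"].sum()
                if has_templates
                else np.nan,
                "frequency": grp["frequency"].sum(),
                "productive": prod,
                "key": key,
                "nt_variants": int(grp["cdr3_nt"].nunique()),
            }
        )
    merged = pd.DataFrame(rows)
    merged["templates"] = merged["templates"].astype("Float64")
    merged = _recompute_frequencies(merged)
    merged = merged.sort_values(
        ["frequency", "key"], ascending=[False, True]
    ).reset_index(drop=True)
    return sample.with_clones(merged[CLONE_COLUMNS + ["key", "nt_variants"]])


def validate_sample(sample: RepertoireSample, atol: float = 1e-9) -> None:
    """Check the frequency-normalisation invariant; raise on violation."""
    prod = sample.productive
    if prod.shape[0] == 0:
        raise EmptySampleError("no productive clones")
    total = float(prod["frequency"].sum())
    if abs(total - 1.0) > atol:
        raise ValueError(f"productive frequencies sum to {total}, not 1")
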