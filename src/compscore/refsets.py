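"""Positive/negative variant reference sets under annotation and MAF filters.

The benchmark's positive class can be drawn at several stringency levels:
all disease-annotated variants ("original"), only HGMD disease-causing
mutations (DM), the intersection of HGMD DM with ClinVar-pathogenic, its
complement (DM but absent from ClinVar), and MAF-restricted versions of the
DM-and-ClinVar set using ExAC allele frequencies.  Negatives are always the
non-disease-annotated variants and are never MAF-filtered.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import DegenerateSetError, InputError

HGMD_CLASSES = {"DM", "DM?", "DP", "DFP", "FP", "none"}
CLINVAR_STATUSES = {"pathogenic", "other", "absent"}

REFSET_MODES = (
    "original",
    "dm_only",
    "dm_and_clinvar",
    "dm_not_clinvar",
    "exac_any",
    "exac_lt_1e-5",
    "exac_lt_1e-4",
    "exac_lt_1e-3",
)

_EXAC_THRESHOLDS = {"exac_lt_1e-5": 1e-5, "exac_lt_1e-4": 1e-4, "exac_lt_1e-3": 1e-3}

_PROTEIN_CHANGE_RE = re.compile(r"^[A-Z]\d+[A-Z]$")


@dataclass
class VariantRecord:
    """One missense variant with its annotations and scores."""

    gene: str
    protein_change: str
    disease_associated: bool
    hgmd_class: str = "none"
    clinvar_status: str = "absent"
    exac_maf: float | None = None
    scores: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not _PROTEIN_CHANGE_RE.match(self.protein_change):
            raise InputError(
                f"protein_change {self.protein_change!r} is not ref-position-alt"
            )
        if self.hgmd_class not in HGMD_CLASSES:
            raise InputError(f"unknown HGMD class {self.hgmd_class!r}")
        if self.clinvar_status not in CLINVAR_STATUSES:
            raise InputError(f"unknown ClinVar status {self.clinvar_status!r}")
        if self.exac_maf is not None and not 0 <= self.exac_maf <= 1:
            raise InputError(f"exac_maf {self.exac_maf} outside [0, 1]")


@dataclass
class ReferenceSet:
    positives: list[VariantRecord]
    negatives: list[VariantRecord]
    mode: str

    @property
    def prior(self) -> float:
        return len(self.positives) / (len(self.positives) + len(self.negatives))


def classify_causality(hgmd_class: str) -> str:
    """HGMD DM mutations are treated as causal; every other class (likely
    disease-causing, disease-associated and functional polymorphisms, or no
    annotation) as noncausal."""
    if hgmd_class not in HGMD_CLASSES:
        raise InputError(f"unknown HGMD class {hgmd_class!r}")
    return "causal" if hgmd_class == "DM" else "noncausal"


def _positive_filter(rec: VariantRecord, mode: str) -> bool:
    dm = rec.hgmd_class == "DM"
    clinvar_path = rec.clinvar_status == "pathogenic"
    if mode == "original":
        return True
    if mode == "dm_only":
        return dm
    if mode == "dm_and_clinvar":
        return dm and clinvar_path
    if mode == "dm_not_clinvar":
        # DM mutations absent from ClinVar entirely
        return dm and rec.clinvar_status == "absent"
    # ExAC modes restrict within the DM-and-ClinVar-pathogenic intersection;
    # records with no MAF are excluded from every exac_* mode.
    if not (dm and clinvar_path) or rec.exac_maf is None:
        return False
    if mode == "exac_any":
        return True
    return rec.exac_maf < _EXAC_THRESHOLDS[mode]


def build_reference(table: list[VariantRecord], mode: str) -> ReferenceSet:
    """Filter the positive class per ``mode``; negatives pass through unfiltered."""
    if mode not in REFSET_MODES:
        raise InputError(f"unknown reference-set mode {mode!r}")
    if not table:
        raise InputError("build_reference: empty variant table")
    positives = [
        r for r in table if r.disease_associated and _positive_filter(r, mode)
    ]
    negatives = [r for r in table if not r.disease_associated]
    if not positives or not negatives:
        raise DegenerateSetError(
            f"mode {mode!r} yields {len(positives)} positives / {len(negatives)} negatives"
        )
    return ReferenceSet(positives=positives, negatives=negatives, mode=mode)


def records_from_frame(df: pd.DataFrame, score_columns: list[str] | None = None) -> list[VariantRecord]:
    """Build VariantRecords from a cohort table (as written by the simulator)."""
    if score_columns is None:
        score_columns = [
            c
            for c in df.columns
            if c
            not in (
                "gene",
                "protein_change",
                "label",
                "truth",
                "hgmd_class",
                "clinvar_status",
                "exac_maf",
            )
        ]
    records = []
    for _, row in df.iterrows():
        maf = row.get("exac_maf")
        maf = None if pd.isna(maf) else float(maf)
        records.append(
            VariantRecord(
                gene=str(row["gene"]),
                protein_change=str(row["protein_change"]),
                disease_associated=bool(row["label"]),
                hgmd_class=str(row.get("hgmd_class", "none")),
                clinvar_status=str(row.get("clinvar_status", "absent")),
                exac_maf=maf,
                scores={c: float(row[c]) for c in score_columns if not pd.isna(row[c])},
            )
        )
    return records


def refset_frame(refset: ReferenceSet) -> pd.DataFrame:
    """Flatten a reference set back to a labeled table (for the CLI)."""
    rows = []
    for label, recs in ((1, refset.positives), (0, refset.negatives)):
        for r in recs:
            rows.append(
                {
                    "gene": r.gene,
                    "protein_change": r.protein_change,
                    "label": label,
                    "hgmd_class": r.hgmd_class,
                    "clinvar_status": r.clinvar_status,
                    "exac_maf": r.exac_maf,
                    **r.scores,
                }
            )
    return pd.DataFrame(rows)
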