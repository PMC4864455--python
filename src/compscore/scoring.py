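"""Complementation scores: categorical FCS and kinetic FCT, plus reversed mode.

FCS (functional complementation by spotting) maps a curated four-level spot
growth grade onto {0, 0.6, 0.8, 1}, with values above 0.5 read as
deleterious.  FCT (functional complementation by liquid time course) places
a variant on a continuous 0-1 scale between the wild-type allele (mu = 1,
FCT = 0) and the GFP control (mu = mu_GFP, FCT = 1):

    FCT = (1 - mu_VARIANT) / (1 - mu_GFP)

Some genes behave in reverse: the wild-type human allele slows the yeast
host and loss-of-function variants grow *faster* than wild type (the
uroporphyrinogen III synthase case).  For such genes the grade vocabulary
inverts and FCT is scored against the fastest-growing variant:

    FCT_rev = (mu_VARIANT - 1) / (mu_FASTEST - 1)

Both FCT forms are clamped to [0, 1]; the raw value is kept for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AssayInvalidError, InputError, ModeInapplicableError
from .growth import RelativeRate

#: Scores at or above this are called deleterious throughout the pipeline.
DELETERIOUS_THRESHOLD = 0.6

STANDARD_GRADES = {
    "wildtype_like": 0.0,
    "reduced": 0.6,
    "severely_reduced": 0.8,
    "complete_loss": 1.0,
}

REVERSED_GRADES = {
    "wildtype_like": 0.0,
    "slightly_increased": 0.6,
    "increased": 0.8,
    "greatly_increased": 1.0,
}


@dataclass
class ComplementationGrade:
    value: str
    mode: str = "standard"

    def __post_init__(self) -> None:
        if self.mode not in ("standard", "reversed"):
            raise InputError(f"unknown grade mode {self.mode!r}")
        table = STANDARD_GRADES if self.mode == "standard" else REVERSED_GRADES
        if self.value not in table:
            raise InputError(f"unknown {self.mode} grade token {self.value!r}")


@dataclass
class FcsScore:
    value: float


@dataclass
class FctScore:
    value: float
    raw: float
    mode: str = "standard"


def fcs_score(grade: ComplementationGrade) -> FcsScore:
    """Map a complementation grade to its semiquantitative FCS level."""
    table = STANDARD_GRADES if grade.mode == "standard" else REVERSED_GRADES
    return FcsScore(value=table[grade.value])


def _as_mu(x) -> float:
    return float(x.mu) if isinstance(x, RelativeRate) else float(x)


def fct_score(mu_variant, mu_gfp) -> FctScore:
    """Standard FCT: where the variant sits between wild-type rescue and GFP.

    Requires the GFP control to grow slower than the wild-type-allele strain
    (mu_GFP < 1); otherwise there is no complementation signal window.
    """
    mv, mg = _as_mu(mu_variant), _as_mu(mu_gfp)
    if mg >= 1:
        raise AssayInvalidError(
            f"mu_GFP = {mg:g} >= 1: GFP control grows as fast as the wild-type allele"
        )
    raw = (1.0 - mv) / (1.0 - mg)
    return FctScore(value=float(np.clip(raw, 0.0, 1.0)), raw=float(raw), mode="standard")


def fct_score_reversed(mu_variant, mu_fastest) -> FctScore:
    """Reversed FCT for genes whose deleterious variants outgrow wild type."""
    mv, mf = _as_mu(mu_variant), _as_mu(mu_fastest)
    if mf <= 1:
        raise ModeInapplicableError(
            f"mu_FASTEST = {mf:g} <= 1: no variant grows faster than wild type"
        )
    if mv > mf:
        raise InputError("mu_variant exceeds mu_fastest")
    raw = (mv - 1.0) / (mf - 1.0)
    return FctScore(value=float(np.clip(raw, 0.0, 1.0)), raw=float(raw), mode="reversed")


def detect_reversed_gene(mus: list) -> bool:
    """Decide whether a gene should be scored in reversed mode.

    Rule: the median relative growth rate across the gene's variants exceeds
    1 (variants tend to outgrow the wild-type allele).  With fewer than 3
    variants the evidence is insufficient and standard mode is kept.
    """
    values = [_as_mu(m) for m in mus]
    if len(values) < 3:
        return False
    return float(np.median(values)) > 1.0
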