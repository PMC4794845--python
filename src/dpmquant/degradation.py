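"""Degradation-byproduct detection and quantitation for a target protein.

In-vivo proteolysis (e.g. by cathepsin D) leaves byproduct peptides whose
termini are not tryptic, distinguishing them from peptides produced by
the in-vitro trypsin digestion.  Known byproducts reported on a source
species (e.g. bovine MBP) are transferred to the human target sequence by
global pairwise alignment, identified PSMs are classified as *exact*
matches (the byproduct itself, carrying a degradation signature) or
*partial* matches (longer tryptic peptides containing the byproduct), and
the percent degradation is

    exact area x 100 / (exact area + partial area)

per group, normalized to the reference group to give a degradation ratio
(1 = normal degradation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import DesignError, MappingError
from .psm_io import TRYPTIC_RESIDUES, GroupDesign, PsmRecord

logger = logging.getLogger(__name__)


@dataclass
class ByproductDefinition:
    """A degradation byproduct mapped onto the target protein.

    ``source_sequence`` may carry a trailing ``#`` marking a citrullinated
    terminal Arg (e.g. ``YLATASTMDHAR#``); coordinates are 1-based
    inclusive on the target sequence.
    """

    source_sequence: str
    mapped_sequence: str
    start: int
    end: int

    @property
    def bare_source(self) -> str:
        return self.source_sequence.replace("#", "")


def _needle_aligner() -> Align.PairwiseAligner:
    # EMBOSS Needle defaults: BLOSUM62, gap open 10, extend 0.5, free end gaps.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    for attr in (
        "open_end_insertion_score",
        "extend_end_insertion_score",
        "open_end_deletion_score",
        "extend_end_deletion_score",
    ):
        setattr(aligner, attr, 0.0)
    return aligner


def map_byproduct(
    source_peptide: str, source_protein_seq: str, target_protein_seq: str
) -> ByproductDefinition:
    """Transfer a source-species byproduct peptide to target coordinates.

    The two proteins are globally aligned (Needleman-Wunsch with Needle
    default scoring); the target residues aligned to the source peptide's
    span, gaps removed, give the mapped peptide and its 1-based span.
    """
    bare = source_peptide.replace("#", "")
    start0 = source_protein_seq.find(bare)
    if start0 < 0:
        raise MappingError(
            f"byproduct {bare!r} is not a substring of the source protein"
        )
    alignment = _needle_aligner().align(source_protein_seq, target_protein_seq)[0]
    indices = alignment.indices  # 2 x n_columns, -1 at gaps
    src_idx, tgt_idx = indices[0], indices[1]
    span = set(range(start0, start0 + len(bare)))
    mapped = [int(t) for s, t in zip(src_idx, tgt_idx) if s in span and t >= 0]
    if not mapped:
        raise MappingError(f"byproduct {bare!r} aligns entirely to gaps")
    first, last = mapped[0], mapped[-1]
    return ByproductDefinition(
        source_sequence=source_peptide,
        mapped_sequence=target_protein_seq[first : last + 1],
        start=first + 1,
        end=last + 1,
    )


def _nterm_tryptic(record: PsmRecord) -> bool:
    return record.prev_aa in TRYPTIC_RESIDUES or record.prev_aa == "-"


def _cterm_tryptic(record: PsmRecord) -> bool:
    return record.peptide[-1] in TRYPTIC_RESIDUES or record.next_aa == "-"


def _modified_terminal_kr(record: PsmRecord) -> bool:
    """Any annotated modification on a terminal Lys/Arg (e.g. citrulline)."""
    n = len(record.peptide)
    return any(
        m.position in (1, n) and m.residue in TRYPTIC_RESIDUES for m in record.mods
    )


def is_degradation_product(record: PsmRecord) -> bool:
    """In-vivo signature: a non-tryptic terminus or a modified terminal K/R."""
    return (
        not _nterm_tryptic(record)
        or not _cterm_tryptic(record)
        or _modified_terminal_kr(record)
    )


def classify_match(
    record: PsmRecord, byproduct: ByproductDefinition, target_seq: str | None = None
) -> str:
    """Classify a PSM against a byproduct: ``exact``, ``partial`` or ``none``.

    Exact: bare sequence equals the mapped byproduct and the peptide shows
    a degradation signature (rejecting peptides produced by the in-vitro
    tryptic digestion).  Partial: a fully tryptic peptide that strictly
    contains the mapped sequence.
    """
    mapped = byproduct.mapped_sequence
    if record.peptide == mapped:
        return "exact" if is_degradation_product(record) else "none"
    if (
        mapped in record.peptide
        and _nterm_tryptic(record)
        and _cterm_tryptic(record)
        and not _modified_terminal_kr(record)
    ):
        return "partial"
    return "none"


@dataclass
class DegradationQuant:
    """Exact/partial areas and degradation statistics for one group."""

    byproduct: ByproductDefinition
    group: str
    exact_area: float
    partial_area: float
    pct_degradation: float
    ratio_vs_control: float


def pct_degradation(exact_area: float, partial_area: float) -> float:
    """Percent degradation: exact x 100 / (exact + partial); NaN when empty."""
    total = exact_area + partial_area
    if total <= 0:
        return math.nan
    return exact_area * 100.0 / total


def degradation_ratio(
    records: Sequence[PsmRecord],
    byproduct: ByproductDefinition,
    design: GroupDesign,
    protein_acc: str | None = None,
) -> dict[str, DegradationQuant]:
    """Per-group percent degradation and its ratio to the reference group."""
    exact: dict[str, float] = {g: 0.0 for g in design.groups}
    partial: dict[str, float] = {g: 0.0 for g in design.groups}
    for r in records:
        if r.is_decoy:
            continue
        if protein_acc is not None and r.protein_acc != protein_acc:
            continue
        label = classify_match(r, byproduct)
        if label == "none":
            continue
        bucket = exact if label == "exact" else partial
        for g in design.groups:
            bucket[g] += r.area(design.channel_of(g))

    ref = design.reference_group
    ctrl_pct = pct_degradation(exact[ref], partial[ref])
    if math.isnan(ctrl_pct) or ctrl_pct == 0.0:
        logger.warning(
            "reference group has no usable byproduct area for %s; "
            "degradation ratios undefined",
            byproduct.bare_source,
        )
    out: dict[str, DegradationQuant] = {}
    for g in design.groups:
        pct = pct_degradation(exact[g], partial[g])
        if math.isnan(pct) or math.isnan(ctrl_pct) or ctrl_pct == 0.0:
            ratio = math.nan
        else:
            ratio = pct / ctrl_pct
        out[g] = DegradationQuant(byproduct, g, exact[g], partial[g], pct, ratio)
    return out


def severity_ratio(
    ratios_by_protein: Mapping[str, Mapping[str, float]],
    numerator_acc: str,
    denominator_acc: str,
) -> dict[str, float]:
    """Ratio of two proteins' group-vs-control ratios (e.g. MAG / PLP).

    A lower value indicates greater white-matter pathology severity: the
    numerator protein (MAG) degrades comparably across groups under
    ischemia while the denominator (PLP) scales with pathology.
    """
    for acc in (numerator_acc, denominator_acc):
        if acc not in ratios_by_protein:
            raise DesignError(f"protein {acc!r} not quantified")
    num, den = ratios_by_protein[numerator_acc], ratios_by_protein[denominator_acc]
    out: dict[str, float] = {}
    for group in num:
        if group not in den:
            raise DesignError(f"group {group!r} missing for {denominator_acc!r}")
        d = den[group]
        out[group] = num[group] / d if d > 0 else math.nan
    return out
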