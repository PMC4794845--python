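"""Reading, validation and qualification filtering of PSM tables.

Input is a tab-separated table with one row per peptide-spectrum match
(PSM) and the columns

    run_id, peptide, mods, protein_acc, is_decoy, confidence_pct,
    unused_score, area_<channel> (one per reporter channel),
    prev_aa, next_aa

``mods`` encodes modifications as ``Name@pos(R)`` tokens joined by ``;``
with 1-based positions inside the peptide, e.g.
``Deamidated@3(Q);Citrullination@12(R)``.  ``prev_aa``/``next_aa`` are the
flanking residues in the parent protein, or ``-`` at a protein terminus.

The qualification filter mirrors standard target-decoy practice for
isobaric-label shotgun data: peptides must reach a confidence threshold,
their protein must carry a sufficient unused evidence score, and the
retained set's decoy-estimated FDR (2 x decoys/total x 100 %) must stay
under a bound, enforced by raising the confidence cutoff until it does.
"""

from __future__ import annotations

import logging
import math
import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError

logger = logging.getLogger(__name__)

TRYPTIC_RESIDUES = frozenset("KR")

_MOD_RE = re.compile(r"^(?P<name>[A-Za-z0-9_+\-]+)@(?P<pos>\d+)\((?P<res>[A-Z])\)$")

REQUIRED_COLUMNS = (
    "run_id",
    "peptide",
    "mods",
    "protein_acc",
    "is_decoy",
    "confidence_pct",
    "unused_score",
    "prev_aa",
    "next_aa",
)


@dataclass(frozen=True)
class Mod:
    """One modification: 1-based position in the peptide, residue, name."""

    position: int
    residue: str
    name: str

    def __str__(self) -> str:
        return f"{self.name}@{self.position}({self.residue})"


def parse_mods(text: str) -> tuple[Mod, ...]:
    """Parse a ``Name@pos(R);...`` modification string (empty -> no mods)."""
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return ()
    text = str(text).strip()
    if not text:
        return ()
    mods = []
    for token in text.split(";"):
        m = _MOD_RE.match(token.strip())
        if m is None:
            raise FormatError(f"unparseable modification token {token!r}")
        mods.append(Mod(int(m.group("pos")), m.group("res"), m.group("name")))
    return tuple(mods)


def format_mods(mods: Iterable[Mod]) -> str:
    return ";".join(str(m) for m in mods)


@dataclass
class PsmRecord:
    """One confidently assigned peptide with reporter areas and context."""

    run_id: str
    peptide: str
    protein_acc: str
    is_decoy: bool
    confidence_pct: float
    unused_score: float
    reporter_areas: Mapping[str, float]
    mods: tuple[Mod, ...] = ()
    prev_aa: str = "-"
    next_aa: str = "-"

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence_pct <= 100.0:
            raise FormatError(
                f"confidence {self.confidence_pct!r} outside [0, 100] for {self.peptide}"
            )
        for mod in self.mods:
            if not 1 <= mod.position <= len(self.peptide):
                raise FormatError(f"mod {mod} outside peptide {self.peptide!r}")
            if self.peptide[mod.position - 1] != mod.residue:
                raise FormatError(
                    f"mod {mod} disagrees with residue "
                    f"{self.peptide[mod.position - 1]!r} in {self.peptide!r}"
                )
        for channel, area in self.reporter_areas.items():
            if not np.isfinite(area) or area < 0:
                raise FormatError(
                    f"non-finite/negative area {area!r} in channel {channel}"
                )

    def area(self, channel: str) -> float:
        return float(self.reporter_areas.get(channel, 0.0))

    def has_mod(self, name: str) -> bool:
        return any(m.name == name for m in self.mods)

    def mod_state_key(self) -> tuple:
        """Distinct-peptide key: sequence plus full modification state."""
        return (self.peptide, tuple(sorted((m.position, m.name) for m in self.mods)))


@dataclass(frozen=True)
class GroupDesign:
    """Channel-to-group mapping and replicate structure of a pooled run.

    Default follows a 4-plex labelling where 114 carries the pooled
    controls, 116 the female dementia pool and 117 the male dementia pool;
    channel 115 may be present in tables but stays unmapped.
    """

    channel_map: Mapping[str, str] = field(
        default_factory=lambda: {"114": "control", "116": "female", "117": "male"}
    )
    replicates: tuple[str, ...] = ("run1", "run2", "run3")
    reference_group: str = "control"

    def __post_init__(self) -> None:
        if self.reference_group not in self.channel_map.values():
            raise DesignError(
                f"reference group {self.reference_group!r} absent from channel map"
            )

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for g in self.channel_map.values():
            seen.setdefault(g)
        return tuple(seen)

    @property
    def test_groups(self) -> tuple[str, ...]:
        return tuple(g for g in self.groups if g != self.reference_group)

    def channel_of(self, group: str) -> str:
        for channel, g in self.channel_map.items():
            if g == group:
                return channel
        raise DesignError(f"group {group!r} not present in design")


@dataclass(frozen=True)
class QualificationCriteria:
    """Identification qualification thresholds.

    ``min_unused_score`` of 2 corresponds to 99 % protein confidence via
    conf = (1 - 10^-score) x 100.
    """

    max_fdr_pct: float = 1.0
    min_unused_score: float = 2.0
    min_peptide_conf_pct: float = 99.0

    def __post_init__(self) -> None:
        for name in ("max_fdr_pct", "min_unused_score", "min_peptide_conf_pct"):
            if getattr(self, name) < 0:
                raise FormatError(f"{name} must be non-negative")


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise FormatError(f"unparseable boolean {value!r}")


def records_from_frame(
    df: pd.DataFrame, design: GroupDesign, stats: dict | None = None
) -> list[PsmRecord]:
    """Build validated records from a PSM table already loaded as a frame.

    Rows with a missing or negative reporter area in any channel column are
    dropped (and counted in ``stats``/the log) rather than rejected.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"PSM table lacks required column(s): {', '.join(missing)}")
    area_cols = [c for c in df.columns if c.startswith("area_")]
    for channel in design.channel_map:
        if f"area_{channel}" not in df.columns:
            raise DesignError(f"design channel {channel!r} has no area_ column")

    areas = df[area_cols].apply(pd.to_numeric, errors="coerce")
    bad = areas.isna().any(axis=1) | (areas < 0).any(axis=1)
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.info("dropped %d row(s) with missing/negative reporter areas", n_dropped)
    if stats is not None:
        stats["n_rows"] = int(len(df))
        stats["n_dropped_bad_area"] = n_dropped

    channels = [c[len("area_") :] for c in area_cols]
    records: list[PsmRecord] = []
    kept = df.loc[~bad]
    kept_areas = areas.loc[~bad]
    for (_, row), (_, arow) in zip(kept.iterrows(), kept_areas.iterrows()):
        records.append(
            PsmRecord(
                run_id=str(row["run_id"]),
                peptide=str(row["peptide"]).upper(),
                protein_acc=str(row["protein_acc"]),
                is_decoy=_parse_bool(row["is_decoy"]),
                confidence_pct=float(row["confidence_pct"]),
                unused_score=float(row["unused_score"]),
                reporter_areas={
                    ch: float(arow[f"area_{ch}"]) for ch in channels
                },
                mods=parse_mods(row["mods"]),
                prev_aa=str(row["prev_aa"]) or "-",
                next_aa=str(row["next_aa"]) or "-",
            )
        )
    return records


def read_psm_table(
    path, design: GroupDesign, stats: dict | None = None
) -> list[PsmRecord]:
    """Read and validate a PSM TSV (``#``-prefixed header comments allowed)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    df = df.mask(df == "")
    if "mods" in df.columns:
        df["mods"] = df["mods"].fillna("")
    return records_from_frame(df, design, stats=stats)


def records_to_frame(records: Sequence[PsmRecord]) -> pd.DataFrame:
    """Serialize records back to the documented TSV schema."""
    channels = sorted({ch for r in records for ch in r.reporter_areas})
    rows = []
    for r in records:
        row = {
            "run_id": r.run_id,
            "peptide": r.peptide,
            "mods": format_mods(r.mods),
            "protein_acc": r.protein_acc,
            "is_decoy": r.is_decoy,
            "confidence_pct": r.confidence_pct,
            "unused_score": r.unused_score,
        }
        for ch in channels:
            row[f"area_{ch}"] = r.area(ch)
        row["prev_aa"] = r.prev_aa
        row["next_aa"] = r.next_aa
        rows.append(row)
    return pd.DataFrame(rows)


def compute_decoy_fdr(records: Sequence[PsmRecord]) -> float:
    """Decoy-estimated FDR in percent: 2.0 x (decoy hits / total hits) x 100."""
    if not records:
        raise FormatError("cannot compute FDR of an empty record list")
    n_decoy = sum(1 for r in records if r.is_decoy)
    return 2.0 * (n_decoy / len(records)) * 100.0


def unused_score_to_confidence(score: float) -> float:
    """Convert an unused protein score to percent confidence.

    conf = (1 - 10^-score) x 100, so a score of 2 corresponds to 99 %.
    """
    if score < 0:
        raise FormatError("unused score must be non-negative")
    return (1.0 - 10.0 ** (-score)) * 100.0


def qualify_identifications(
    records: Sequence[PsmRecord],
    criteria: QualificationCriteria | None = None,
    keep_decoys: bool = False,
) -> list[PsmRecord]:
    """Apply the identification qualification criteria.

    Records must pass the protein-level unused-score gate and a peptide
    confidence cutoff.  The cutoff starts at ``min_peptide_conf_pct`` and is
    raised through the observed confidence values until the decoy-estimated
    FDR of the retained set (decoys still included) is at most
    ``max_fdr_pct``; decoys are then removed unless ``keep_decoys``.

    Returns an empty list (with a warning) when no cutoff satisfies the
    FDR bound.
    """
    criteria = criteria or QualificationCriteria()
    pool = [r for r in records if r.unused_score >= criteria.min_unused_score]
    n_gate = len(records) - len(pool)
    if n_gate:
        logger.info("unused-score gate removed %d record(s)", n_gate)

    cutoffs = [criteria.min_peptide_conf_pct]
    cutoffs += sorted(
        {r.confidence_pct for r in pool if r.confidence_pct > criteria.min_peptide_conf_pct}
    )
    for cutoff in cutoffs:
        retained = [r for r in pool if r.confidence_pct >= cutoff]
        if not retained:
            break
        if compute_decoy_fdr(retained) <= criteria.max_fdr_pct:
            logger.info(
                "qualification cutoff %.4f%% retains %d of %d records (FDR %.3f%%)",
                cutoff,
                len(retained),
                len(records),
                compute_decoy_fdr(retained),
            )
            if keep_decoys:
                return retained
            return [r for r in retained if not r.is_decoy]
    logger.warning(
        "no confidence cutoff achieves FDR <= %.2f%%; returning no identifications",
        criteria.max_fdr_pct,
    )
    return []


def intersect_replicates(
    records: Sequence[PsmRecord], design: GroupDesign
) -> set[str]:
    """Accessions with at least one qualifying peptide in every replicate."""
    runs_by_acc: dict[str, set[str]] = defaultdict(set)
    for r in records:
        if not r.is_decoy:
            runs_by_acc[r.protein_acc].add(r.run_id)
    required = set(design.replicates)
    return {acc for acc, runs in runs_by_acc.items() if required <= runs}
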