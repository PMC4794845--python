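"""Degenerative protein modification (DPM) quantitation.

Covers deamidation (Asn/Gln, +0.984 Da) and citrullination (Arg,
+0.984 Da) as assigned by the upstream search engine: peptide-level
stoichiometry, site-level reporter-area comparison across groups
(one-way ANOVA with Bonferroni), whole-proteome modification rates by
spectral counting with a disease-association chi-square, and modified
amino-acid-pair intensity profiles.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, MappingError
from .psm_io import GroupDesign, PsmRecord

logger = logging.getLogger(__name__)

#: Residues eligible for each supported modification.
ELIGIBLE_RESIDUES = {"Deamidated": "NQ", "Citrullination": "R"}


@dataclass
class ModSiteQuant:
    """Reporter areas of one modified residue, per group and replicate."""

    protein_acc: str
    residue: str
    position: int  # 1-based protein coordinate
    mod_name: str
    group_areas: dict[str, float] = field(default_factory=dict)
    replicate_areas: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class StoichiometryResult:
    """Fraction of distinct peptides of a protein carrying a modification."""

    protein_acc: str
    mod_name: str
    n_modified: int
    n_total: int

    @property
    def pct_of_peptides(self) -> float:
        return 100.0 * self.n_modified / self.n_total if self.n_total else math.nan


@dataclass
class AaPairProfile:
    """Summed group areas for one (modified residue, C-terminal neighbor)."""

    mod_name: str
    pair: tuple[str, str]
    group_areas: dict[str, float] = field(default_factory=dict)


def map_peptide_mods_to_protein(
    record: PsmRecord, reference: str
) -> list[tuple[int, str, str]]:
    """Convert peptide-local modified positions to protein coordinates.

    Returns (position, residue, mod_name) triples with 1-based positions
    on ``reference``.  A peptide occurring more than once maps to its
    first occurrence with a logged warning.
    """
    offset = reference.find(record.peptide)
    if offset < 0:
        raise MappingError(
            f"peptide {record.peptide!r} absent from reference of {record.protein_acc}"
        )
    if reference.find(record.peptide, offset + 1) >= 0:
        logger.warning(
            "peptide %s occurs more than once in %s; using first occurrence",
            record.peptide,
            record.protein_acc,
        )
    out = []
    for mod in record.mods:
        pos = offset + mod.position  # 1-based protein coordinate
        if reference[pos - 1] != mod.residue:
            raise MappingError(
                f"modified residue {mod.residue} at protein position {pos} "
                f"disagrees with reference {reference[pos - 1]}"
            )
        out.append((pos, mod.residue, mod.name))
    return out


def collect_site_quant(
    records: Sequence[PsmRecord],
    reference: str,
    design: GroupDesign,
    protein_acc: str,
) -> dict[tuple[int, str], ModSiteQuant]:
    """Accumulate per-site reporter areas for one protein across records."""
    sites: dict[tuple[int, str], ModSiteQuant] = {}
    for r in records:
        if r.protein_acc != protein_acc or r.is_decoy or not r.mods:
            continue
        for pos, res, mod_name in map_peptide_mods_to_protein(r, reference):
            key = (pos, mod_name)
            site = sites.get(key)
            if site is None:
                site = sites[key] = ModSiteQuant(protein_acc, res, pos, mod_name)
            for group in design.groups:
                area = r.area(design.channel_of(group))
                site.group_areas[group] = site.group_areas.get(group, 0.0) + area
                rep_key = (group, r.run_id)
                site.replicate_areas[rep_key] = (
                    site.replicate_areas.get(rep_key, 0.0) + area
                )
    return sites


def stoichiometry(
    records: Sequence[PsmRecord], mod_name: str, protein_acc: str | None = None
) -> StoichiometryResult:
    """Percent of distinct peptides carrying at least one such modification.

    Distinct peptides are keyed by (sequence, full modification state), so
    duplicated PSMs of an already-counted species do not change the result.
    """
    if protein_acc is not None:
        records = [r for r in records if r.protein_acc == protein_acc]
    acc = protein_acc or (records[0].protein_acc if records else "")
    distinct: dict[tuple, bool] = {}
    for r in records:
        if r.is_decoy:
            continue
        distinct[r.mod_state_key()] = r.has_mod(mod_name)
    n_total = len(distinct)
    n_modified = sum(distinct.values())
    return StoichiometryResult(acc, mod_name, n_modified, n_total)


def site_group_comparison(
    site: ModSiteQuant, min_replicates: int = 2
) -> tuple[float, float]:
    """One-way ANOVA of replicate areas across groups for one site.

    Returns (F, p).  Sites without at least two groups carrying
    ``min_replicates`` replicate areas are excluded (NaN, NaN); a site
    with zero between-group variance gets F = 0, p = 1.
    """
    by_group: dict[str, list[float]] = defaultdict(list)
    for (group, _run), area in site.replicate_areas.items():
        by_group[group].append(area)
    samples = [v for v in by_group.values() if len(v) >= min_replicates]
    if len(samples) < 2:
        return math.nan, math.nan
    flat = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    means = [float(np.mean(s)) for s in samples]
    if np.allclose(flat, flat[0]):
        return 0.0, 1.0
    if np.allclose(means, means[0]):
        return 0.0, 1.0
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


def _site_list(sites) -> list[ModSiteQuant]:
    items = sites.values() if isinstance(sites, Mapping) else sites
    return sorted(items, key=lambda s: (s.protein_acc, s.position, s.mod_name))


def site_anova_table(sites, min_replicates: int = 2) -> pd.DataFrame:
    """ANOVA over all sites with Bonferroni correction by sites tested.

    ``sites`` may be the mapping from :func:`collect_site_quant` or any
    iterable of :class:`ModSiteQuant` (possibly spanning proteins).
    """
    rows = []
    for site in _site_list(sites):
        f, p = site_group_comparison(site, min_replicates=min_replicates)
        rows.append(
            {
                "protein_acc": site.protein_acc,
                "position": site.position,
                "residue": site.residue,
                "mod_name": site.mod_name,
                "f_stat": f,
                "p_raw": p,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    m = int(df["p_raw"].notna().sum())
    df["p_bonferroni"] = (df["p_raw"] * m).clip(upper=1.0)
    return df


@dataclass
class DpmRateResult:
    """Per-group modified-spectra percentages and disease-association test."""

    mod_name: str
    pct_by_group: dict[str, float]
    counts: dict[str, tuple[int, int]]  # group -> (modified, total)
    chi_square: float
    p_value: float
    table: np.ndarray  # 2x2 (dementia pooled vs reference) x (mod, unmod)


def proteome_dpm_rate(
    records: Sequence[PsmRecord], design: GroupDesign, mod_name: str
) -> DpmRateResult:
    """Spectral-counting modification rate per group plus pooled chi-square.

    A PSM counts toward a group when its reporter area in that group's
    channel is positive; the chi-square (1 df, no continuity correction)
    tests modified-vs-unmodified counts of the pooled dementia groups
    against the reference group.
    """
    counts: dict[str, tuple[int, int]] = {}
    for group in design.groups:
        ch = design.channel_of(group)
        present = [r for r in records if not r.is_decoy and r.area(ch) > 0]
        if not present:
            raise DesignError(f"group {group!r} has no spectral counts")
        modified = sum(1 for r in present if r.has_mod(mod_name))
        counts[group] = (modified, len(present))
    pct = {g: 100.0 * m / n for g, (m, n) in counts.items()}
    ref = design.reference_group
    dem_mod = sum(m for g, (m, _n) in counts.items() if g != ref)
    dem_tot = sum(n for g, (_m, n) in counts.items() if g != ref)
    ref_mod, ref_tot = counts[ref]
    table = np.array(
        [[dem_mod, dem_tot - dem_mod], [ref_mod, ref_tot - ref_mod]], dtype=float
    )
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p = stats.chi2_contingency(table, correction=False)[:2]
    return DpmRateResult(mod_name, pct, counts, float(chi2), float(p), table)


def aa_pair_profile(
    records: Sequence[PsmRecord], design: GroupDesign, mod_name: str
) -> list[AaPairProfile]:
    """Group intensity areas per (modified residue, C-terminal neighbor).

    The neighbor is the next residue within the peptide, or the flanking
    ``next_aa`` (``-`` at a protein terminus) for a modification at the
    peptide C-terminus.  Pairs never observed are simply absent.
    """
    profiles: dict[tuple[str, str], AaPairProfile] = {}
    for r in records:
        if r.is_decoy:
            continue
        for mod in r.mods:
            if mod.name != mod_name:
                continue
            if mod.position < len(r.peptide):
                neighbor = r.peptide[mod.position]
            else:
                neighbor = r.next_aa or "-"
            pair = (mod.residue, neighbor)
            prof = profiles.get(pair)
            if prof is None:
                prof = profiles[pair] = AaPairProfile(mod_name, pair)
            for group in design.groups:
                area = r.area(design.channel_of(group))
                prof.group_areas[group] = prof.group_areas.get(group, 0.0) + area
    return [profiles[k] for k in sorted(profiles)]


def pair_matrix(profiles: Sequence[AaPairProfile], design: GroupDesign) -> pd.DataFrame:
    """Heatmap-ready pair x group area matrix (absent pairs absent)."""
    rows = {
        f"{p.pair[0]}-{p.pair[1]}": {
            g: p.group_areas.get(g, 0.0) for g in design.groups
        }
        for p in profiles
    }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def relative_site_levels(sites, design: GroupDesign) -> pd.DataFrame:
    """Group area over reference-group area at matched sites.

    Sites absent from the reference group are reported unnormalized with
    a flag instead of dividing by zero.
    """
    ref = design.reference_group
    rows = []
    for site in _site_list(sites):
        ref_area = site.group_areas.get(ref, 0.0)
        row = {
            "protein_acc": site.protein_acc,
            "position": site.position,
            "residue": site.residue,
            "mod_name": site.mod_name,
            "normalized": ref_area > 0,
        }
        for g in design.groups:
            area = site.group_areas.get(g, 0.0)
            row[g] = area / ref_area if ref_area > 0 else area
        rows.append(row)
    return pd.DataFrame(rows)
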