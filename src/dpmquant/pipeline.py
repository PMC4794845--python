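"""End-to-end orchestration: filter -> quantify -> DPM -> degradation -> report.

A single YAML config drives the whole analysis; every output table carries
the config hash in a header comment and a JSON manifest records versions,
stage counts and filter effects so identical config + inputs give
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .degradation import degradation_ratio, map_byproduct, severity_ratio
from .dpm_quant import (
    ELIGIBLE_RESIDUES,
    aa_pair_profile,
    collect_site_quant,
    pair_matrix,
    proteome_dpm_rate,
    relative_site_levels,
    site_anova_table,
    stoichiometry,
)
from .errors import ConfigError, DesignError
from .protein_quant import (
    ProteinQuantResult,
    heatmap_matrix,
    quantify_proteins,
    ratio_cv_profile,
)
from .psm_io import (
    GroupDesign,
    PsmRecord,
    QualificationCriteria,
    intersect_replicates,
    qualify_identifications,
    read_psm_table,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    psm_paths: tuple[str, ...]
    fasta_path: str | None = None
    design: GroupDesign = field(default_factory=GroupDesign)
    criteria: QualificationCriteria = field(default_factory=QualificationCriteria)
    up_cut: float = 1.5
    alpha: float = 0.05
    gender_diff: float = 0.2
    strong_diff: float = 0.9
    mod_names: tuple[str, ...] = tuple(sorted(ELIGIBLE_RESIDUES))
    byproducts: tuple[Mapping, ...] = ()
    severity_numerator: str | None = None
    severity_denominator: str | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for value in (self.up_cut, self.alpha, self.gender_diff, self.strong_diff):
            if value <= 0:
                raise ConfigError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = Path(path).parent

        def resolve(p):
            p = Path(p)
            return str(p if p.is_absolute() else base / p)

        design_raw = raw.get("design", {})
        design = GroupDesign(
            channel_map={
                str(k): str(v)
                for k, v in design_raw.get(
                    "channel_map", {"114": "control", "116": "female", "117": "male"}
                ).items()
            },
            replicates=tuple(design_raw.get("replicates", ("run1", "run2", "run3"))),
            reference_group=design_raw.get("reference_group", "control"),
        )
        criteria = QualificationCriteria(**raw.get("criteria", {}))
        thresholds = raw.get("thresholds", {})
        severity = raw.get("severity", {}) or {}
        psm = raw.get("psm")
        if not psm:
            raise ConfigError("config must list at least one PSM table under 'psm'")
        return cls(
            psm_paths=tuple(resolve(p) for p in psm),
            fasta_path=resolve(raw["fasta"]) if raw.get("fasta") else None,
            design=design,
            criteria=criteria,
            up_cut=float(thresholds.get("up_cut", 1.5)),
            alpha=float(thresholds.get("alpha", 0.05)),
            gender_diff=float(thresholds.get("gender_diff", 0.2)),
            strong_diff=float(thresholds.get("strong_diff", 0.9)),
            byproducts=tuple(raw.get("byproducts", ())),
            severity_numerator=severity.get("numerator"),
            severity_denominator=severity.get("denominator"),
            out_dir=resolve(raw["out_dir"]) if raw.get("out_dir") else None,
        )

    def to_canonical_dict(self) -> dict:
        return {
            "psm_paths": list(self.psm_paths),
            "fasta_path": self.fasta_path,
            "channel_map": dict(self.design.channel_map),
            "replicates": list(self.design.replicates),
            "reference_group": self.design.reference_group,
            "criteria": {
                "max_fdr_pct": self.criteria.max_fdr_pct,
                "min_unused_score": self.criteria.min_unused_score,
                "min_peptide_conf_pct": self.criteria.min_peptide_conf_pct,
            },
            "thresholds": {
                "up_cut": self.up_cut,
                "alpha": self.alpha,
                "gender_diff": self.gender_diff,
                "strong_diff": self.strong_diff,
            },
            "byproducts": [dict(b) for b in self.byproducts],
            "severity": [self.severity_numerator, self.severity_denominator],
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_canonical_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


@dataclass
class PipelineResult:
    """All tables produced by one pipeline run."""

    qualified: list[PsmRecord]
    accessions: set[str]
    quant: ProteinQuantResult
    cv_table: pd.DataFrame
    cv_summary: dict
    stoichiometry: pd.DataFrame
    site_areas: pd.DataFrame
    site_anova: pd.DataFrame
    proteome_rates: pd.DataFrame
    pair_tables: dict[str, pd.DataFrame]
    degradation: pd.DataFrame
    severity: pd.DataFrame
    manifest: dict


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=not isinstance(df.index, pd.RangeIndex))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage of the analysis under one configuration."""
    for p in config.psm_paths:
        if not Path(p).exists():
            raise ConfigError(f"[stage: input] PSM table not found: {p}")
    if config.fasta_path is not None and not Path(config.fasta_path).exists():
        raise ConfigError(f"[stage: input] FASTA not found: {config.fasta_path}")
    if config.byproducts and config.fasta_path is None:
        raise ConfigError("[stage: input] byproducts configured but no FASTA given")

    design = config.design
    manifest: dict = {
        "dpmquant_version": __version__,
        "config_hash": config.config_hash(),
        "config": config.to_canonical_dict(),
    }

    # --- stage: filter ----------------------------------------------------
    records: list[PsmRecord] = []
    read_stats: dict = {}
    for p in config.psm_paths:
        stats: dict = {}
        records.extend(read_psm_table(p, design, stats=stats))
        read_stats[str(p)] = stats
    manifest["read"] = read_stats
    manifest["n_records"] = len(records)
    qualified = qualify_identifications(records, config.criteria)
    manifest["n_qualified"] = len(qualified)
    accessions = intersect_replicates(qualified, design)
    manifest["n_proteins_all_replicates"] = len(accessions)
    if not qualified:
        raise DesignError("[stage: filter] no records pass qualification")

    # --- stage: quantify --------------------------------------------------
    quant = quantify_proteins(
        qualified,
        design,
        accessions=accessions,
        up_cut=config.up_cut,
        alpha=config.alpha,
        diff_cut=config.gender_diff,
        strong_diff=config.strong_diff,
    )
    cv_table, cv_summary = ratio_cv_profile(quant.per_replicate_ratios)
    if not cv_table.empty:
        cv_table[["protein_acc", "group"]] = pd.DataFrame(
            cv_table["key"].tolist(), index=cv_table.index
        )
        cv_table = cv_table.drop(columns="key")
    manifest["bh_thresholds"] = {
        g: (None if math.isnan(t) else t) for g, t in quant.bh_thresholds.items()
    }
    manifest["cv_summary"] = cv_summary

    # --- stage: dpm -------------------------------------------------------
    sequences = read_fasta(config.fasta_path) if config.fasta_path else {}
    stoich_rows = []
    all_sites = []
    target_accs = [a for a in sorted(accessions) if a in sequences] or sorted(
        sequences
    )
    for acc in target_accs:
        acc_records = [r for r in qualified if r.protein_acc == acc]
        if not acc_records:
            continue
        for mod in config.mod_names:
            s = stoichiometry(acc_records, mod, protein_acc=acc)
            stoich_rows.append(
                {
                    "protein_acc": acc,
                    "mod_name": mod,
                    "n_modified": s.n_modified,
                    "n_total": s.n_total,
                    "pct_of_peptides": s.pct_of_peptides,
                }
            )
        sites = collect_site_quant(acc_records, sequences[acc], design, acc)
        all_sites.extend(sites.values())
    stoich_df = pd.DataFrame(stoich_rows)
    site_areas = relative_site_levels(all_sites, design) if all_sites else pd.DataFrame()
    site_anova = site_anova_table(all_sites) if all_sites else pd.DataFrame()

    rate_rows = []
    pair_tables: dict[str, pd.DataFrame] = {}
    for mod in config.mod_names:
        try:
            rate = proteome_dpm_rate(qualified, design, mod)
        except DesignError:
            continue
        for g, pct in rate.pct_by_group.items():
            rate_rows.append(
                {
                    "mod_name": mod,
                    "group": g,
                    "n_modified": rate.counts[g][0],
                    "n_spectra": rate.counts[g][1],
                    "pct_modified": pct,
                    "chi_square": rate.chi_square,
                    "p_value": rate.p_value,
                }
            )
        pair_tables[mod] = pair_matrix(
            aa_pair_profile(qualified, design, mod), design
        )
    rates_df = pd.DataFrame(rate_rows)

    # --- stage: degrade ---------------------------------------------------
    deg_rows = []
    for bp_cfg in config.byproducts:
        target_acc = bp_cfg.get("target_acc")
        if target_acc not in sequences:
            raise ConfigError(
                f"[stage: degrade] byproduct target {target_acc!r} absent from FASTA"
            )
        target_seq = sequences[target_acc]
        source_acc = bp_cfg.get("source_acc")
        source_seq = sequences.get(source_acc, target_seq) if source_acc else target_seq
        byproduct = map_byproduct(bp_cfg["peptide"], source_seq, target_seq)
        quants = degradation_ratio(
            qualified, byproduct, design, protein_acc=target_acc
        )
        for g, q in quants.items():
            deg_rows.append(
                {
                    "byproduct": bp_cfg["peptide"],
                    "target_acc": target_acc,
                    "start": byproduct.start,
                    "end": byproduct.end,
                    "group": g,
                    "exact_area": q.exact_area,
                    "partial_area": q.partial_area,
                    "pct_degradation": q.pct_degradation,
                    "ratio_vs_control": q.ratio_vs_control,
                }
            )
    deg_df = pd.DataFrame(deg_rows)

    # --- stage: severity --------------------------------------------------
    severity_df = pd.DataFrame()
    if config.severity_numerator and config.severity_denominator:
        ratios = {
            acc: dict(zip(sub["group"], sub["ratio"]))
            for acc, sub in quant.stats.groupby("protein_acc")
        }
        sev = severity_ratio(
            ratios, config.severity_numerator, config.severity_denominator
        )
        severity_df = pd.DataFrame(
            [{"group": g, "severity_ratio": v} for g, v in sorted(sev.items())]
        )

    result = PipelineResult(
        qualified=qualified,
        accessions=accessions,
        quant=quant,
        cv_table=cv_table,
        cv_summary=cv_summary,
        stoichiometry=stoich_df,
        site_areas=site_areas,
        site_anova=site_anova,
        proteome_rates=rates_df,
        pair_tables=pair_tables,
        degradation=deg_df,
        severity=severity_df,
        manifest=manifest,
    )
    if config.out_dir:
        write_report(result, config)
    return result


def write_report(result: PipelineResult, config: PipelineConfig) -> dict[str, Path]:
    """Write every table plus the run manifest under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    paths: dict[str, Path] = {}

    def write(name: str, df: pd.DataFrame):
        path = out / f"{name}.tsv"
        _write_tsv(df, path, h)
        paths[name] = path

    write("protein_stats", result.quant.stats)
    calls_df = pd.DataFrame(
        [
            {
                "protein_acc": acc,
                "female_ratio": c.female_ratio,
                "male_ratio": c.male_ratio,
                "gender_difference": c.gender_difference,
                "gender_quotient": c.gender_quotient,
                "is_gender_differential": c.is_gender_differential,
                "significance_tier": c.significance_tier,
                **{f"call_{g}": v for g, v in sorted(c.call_vs_control.items())},
                **{f"modulated_{g}": v for g, v in sorted(c.modulated.items())},
            }
            for acc, c in sorted(result.quant.calls.items())
        ]
    )
    write("regulation_calls", calls_df)
    write("heatmap_matrix", heatmap_matrix(result.quant, config.design))
    write("ratio_cv", result.cv_table)
    write("stoichiometry", result.stoichiometry)
    write("site_areas", result.site_areas)
    write("site_anova", result.site_anova)
    write("proteome_dpm_rates", result.proteome_rates)
    for mod, table in result.pair_tables.items():
        write(f"pairs_{mod.lower()}", table)
    write("degradation", result.degradation)
    write("severity", result.severity)

    manifest_path = out / "manifest.json"
    versions = {}
    for name in ("numpy", "scipy", "pandas", "statsmodels", "Bio"):
        try:
            versions[name] = __import__(name).__version__
        except Exception:  # pragma: no cover
            versions[name] = "unknown"
    manifest = dict(result.manifest, versions=versions)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    paths["manifest"] = manifest_path
    return paths
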