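"""Synthetic PSM-table generator with known ground truth.

Emulates a pooled three-group (control / female / male), 4-plex-labelled,
triplicate-run shotgun experiment: tryptic peptides of random protein
sequences carry log-normal reporter areas, group channels are scaled by
per-protein fold changes, eligible residues (Asn/Gln for deamidation,
Arg for citrullination) are modified at per-group rates, decoy PSMs are
emitted with shuffled sequences, and a synthetic MBP-like fixture protein
carries two degradation byproducts with areas set so that the percent
degradation per group equals the configured state exactly in the
noiseless limit.

Groups that share a modification rate share one Bernoulli draw per
residue (one pooled molecular species); groups with different rates split
into separate per-pattern PSM rows whose channel areas are non-zero only
for the matching groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DesignError
from .psm_io import GroupDesign, Mod, format_mods

#: Amino-acid alphabet and approximate natural frequencies (K+R ~ 11 %).
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_FREQ = np.array(
    [0.074, 0.025, 0.054, 0.054, 0.047, 0.074, 0.026, 0.068, 0.058, 0.099,
     0.025, 0.045, 0.039, 0.034, 0.052, 0.057, 0.051, 0.073, 0.013, 0.032]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

ELIGIBLE = {"Deamidated": "NQ", "Citrullination": "R"}

MBP_FIXTURE_ACC = "MBP_SYN"
#: In-vivo byproducts carried by the fixture; '#' marks a citrullinated
#: terminal Arg.  Spans are 1-based inclusive on the fixture sequence.
BYPRODUCTS = ({"peptide": "TQDENPVVHF", "span": (81, 90), "terminal_mod": None},
              {"peptide": "YLATASTMDHAR#", "span": (111, 122),
               "terminal_mod": "Citrullination"})
_PARTIAL_SPANS = {"TQDENPVVHF": (75, 95), "YLATASTMDHAR#": (111, 126)}


def synthetic_mbp_sequence() -> str:
    """Synthetic MBP-like fixture sequence (not a database entry).

    Constructed so that the degenerative epitope QDENPVV occupies residues
    82-88, the byproduct TQDENPVVHF spans 81-90 inside the tryptic peptide
    75-95, and YLATASTMDHAR spans 111-122 inside the tryptic peptide
    111-126.  The background alphabet excludes K/R (and C) so the only
    tryptic sites are the planted ones.
    """
    rng = np.random.default_rng(20160317)
    background = np.array(list("ADEFGHILMNPQSTVWY"))
    seq = rng.choice(background, size=200)
    seq[73] = "K"                      # position 74: tryptic site
    seq[74:80] = list("HGSLPQ")        # 75-80
    seq[80:90] = list("TQDENPVVHF")    # 81-90 (QDENPVV at 82-88)
    seq[90:95] = list("GSLSK")         # 91-95, tryptic site at 95
    seq[109] = "K"                     # position 110: tryptic site
    seq[110:122] = list("YLATASTMDHAR")  # 111-122, terminal Arg at 122
    seq[125] = "K"                     # position 126: tryptic site
    return "".join(seq)


@dataclass
class SyntheticConfig:
    """Study conditions of a simulated pooled iTRAQ experiment."""

    n_proteins: int = 50
    peptides_per_protein: tuple[int, int] = (4, 10)
    true_fold_changes: Mapping[str, object] | None = None  # group -> fold | {acc: fold}
    dpm_rates: Mapping[tuple[str, str], float] = field(default_factory=dict)
    degradation_state: Mapping[str, float] | None = None  # group -> target pct
    noise_cv: float = 0.15
    decoy_fraction: float = 0.0
    n_replicates: int = 3
    seed: int = 0
    protein_length: int = 300

    def validate(self) -> None:
        if self.n_proteins < 1 or self.n_replicates < 1:
            raise ConfigError("n_proteins and n_replicates must be >= 1")
        lo, hi = self.peptides_per_protein
        if not 1 <= lo <= hi:
            raise ConfigError("peptides_per_protein must be a 1 <= lo <= hi range")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if not 0.0 <= self.decoy_fraction < 1.0:
            raise ConfigError("decoy_fraction must lie in [0, 1)")
        for key, rate in self.dpm_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"dpm rate {key} = {rate} outside [0, 1]")
        if self.degradation_state is not None:
            for g, pct in self.degradation_state.items():
                if not 0.0 <= pct <= 100.0:
                    raise ConfigError(f"degradation_state[{g!r}] outside [0, 100]")


@dataclass
class SyntheticDataset:
    """Generated PSM table, ground truth, and reference sequences."""

    psm: pd.DataFrame
    truth: pd.DataFrame
    truth_degradation: pd.DataFrame
    sequences: dict[str, str]
    design: GroupDesign
    config: SyntheticConfig

    def to_dir(self, path) -> dict[str, Path]:
        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "psm": out / "psm.tsv",
            "truth": out / "truth_proteins.tsv",
            "truth_degradation": out / "truth_degradation.tsv",
            "fasta": out / "reference.fasta",
        }
        self.psm.to_csv(paths["psm"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        self.truth_degradation.to_csv(paths["truth_degradation"], sep="\t", index=False)
        with open(paths["fasta"], "w") as fh:
            for acc, seq in self.sequences.items():
                fh.write(f">{acc} synthetic\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        return paths


def _tryptic_spans(seq: str) -> list[tuple[int, int]]:
    """Half-open tryptic spans (cut after every K/R)."""
    spans, start = [], 0
    for i, aa in enumerate(seq):
        if aa in "KR":
            spans.append((start, i + 1))
            start = i + 1
    if start < len(seq):
        spans.append((start, len(seq)))
    return spans


def _flanks(seq: str, start: int, end: int) -> tuple[str, str]:
    prev = seq[start - 1] if start > 0 else "-"
    nxt = seq[end] if end < len(seq) else "-"
    return prev, nxt


def _fold_for(fold_spec, acc: str) -> float:
    if fold_spec is None:
        return 1.0
    if isinstance(fold_spec, Mapping):
        return float(fold_spec.get(acc, 1.0))
    return float(fold_spec)


def _call_for(fold: float, up_cut: float = 1.5) -> str:
    down_cut = round(1.0 / up_cut, 2)
    return "up" if fold > up_cut else ("down" if fold < down_cut else "unchanged")


def generate(
    config: SyntheticConfig, design: GroupDesign | None = None
) -> SyntheticDataset:
    """Generate a deterministic PSM table and ground truth for ``config``."""
    config.validate()
    design = design or GroupDesign()
    rng = np.random.default_rng(config.seed)
    groups = design.groups
    ref = design.reference_group
    channels = sorted(set(design.channel_map) | {"115"})
    sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))

    def noise() -> float:
        if config.noise_cv == 0:
            return 1.0
        return float(rng.lognormal(-sigma * sigma / 2.0, sigma))

    # --- reference proteins and their sampled tryptic peptides -----------
    sequences: dict[str, str] = {}
    proteins: list[dict] = []
    for i in range(config.n_proteins):
        acc = f"P{i + 1:04d}"
        seq = "".join(rng.choice(list(_AA), size=config.protein_length, p=_AA_FREQ))
        sequences[acc] = seq
        spans = [(s, e) for s, e in _tryptic_spans(seq) if 6 <= e - s <= 30]
        lo, hi = config.peptides_per_protein
        want = int(rng.integers(lo, hi + 1))
        if spans:
            idx = rng.choice(len(spans), size=min(want, len(spans)), replace=False)
            chosen = [spans[j] for j in sorted(idx)]
        else:
            chosen = []
        proteins.append(
            {"acc": acc, "seq": seq, "spans": chosen,
             "unused": float(rng.uniform(2.0, 13.0))}
        )
    if config.degradation_state is not None:
        sequences[MBP_FIXTURE_ACC] = synthetic_mbp_sequence()

    folds = {
        (p["acc"], g): (
            1.0 if g == ref else _fold_for((config.true_fold_changes or {}).get(g), p["acc"])
        )
        for p in proteins
        for g in groups
    }

    mod_rates = {
        mod: {g: float(config.dpm_rates.get((g, mod), 0.0)) for g in groups}
        for mod in sorted(ELIGIBLE)
    }

    runs = [f"run{k + 1}" for k in range(config.n_replicates)]
    rows: list[dict] = []

    def emit(run, peptide, mods, acc, conf_u, unused, area_by_group, prev, nxt,
             decoy=False):
        row = {
            "run_id": run,
            "peptide": peptide,
            "mods": format_mods(mods),
            "protein_acc": acc,
            "is_decoy": decoy,
            "confidence_pct": (1.0 - 10.0 ** (-conf_u)) * 100.0,
            "unused_score": unused,
        }
        for ch in channels:
            g = design.channel_map.get(ch)
            row[f"area_{ch}"] = area_by_group.get(g, 0.0) if g else 0.0
        row["prev_aa"] = prev
        row["next_aa"] = nxt
        rows.append(row)

    for run in runs:
        for prot in proteins:
            acc, seq = prot["acc"], prot["seq"]
            for start, end in prot["spans"]:
                peptide = seq[start:end]
                prev, nxt = _flanks(seq, start, end)
                base = 10.0 ** rng.normal(4.0, 0.4)
                # Per-group modification pattern; equal rates share a draw.
                pattern_by_group: dict[str, frozenset] = {g: frozenset() for g in groups}
                for mod in sorted(ELIGIBLE):
                    eligible = [
                        j + 1 for j, aa in enumerate(peptide) if aa in ELIGIBLE[mod]
                    ]
                    if not eligible:
                        continue
                    rates = mod_rates[mod]
                    draw_for_rate: dict[float, frozenset] = {}
                    for rate in sorted(set(rates.values())):
                        if rate <= 0:
                            draw_for_rate[rate] = frozenset()
                        else:
                            hits = rng.random(len(eligible)) < rate
                            draw_for_rate[rate] = frozenset(
                                Mod(pos, peptide[pos - 1], mod)
                                for pos, h in zip(eligible, hits)
                                if h
                            )
                    for g in groups:
                        pattern_by_group[g] = pattern_by_group[g] | draw_for_rate[rates[g]]
                by_pattern: dict[frozenset, list[str]] = {}
                for g in groups:
                    by_pattern.setdefault(pattern_by_group[g], []).append(g)
                for pattern, pat_groups in by_pattern.items():
                    areas = {
                        g: base * folds[(acc, g)] * noise() for g in pat_groups
                    }
                    mods = tuple(sorted(pattern, key=lambda m: m.position))
                    emit(run, peptide, mods, acc, rng.uniform(2.2, 5.0),
                         prot["unused"], areas, prev, nxt)

        # --- degradation fixture ----------------------------------------
        if config.degradation_state is not None:
            mbp = sequences[MBP_FIXTURE_ACC]
            total = 2.0e5
            state = {
                g: float(config.degradation_state.get(g, 50.0)) for g in groups
            }
            for bp in BYPRODUCTS:
                bare = bp["peptide"].replace("#", "")
                s1, e1 = bp["span"]
                prev, nxt = _flanks(mbp, s1 - 1, e1)
                mods = ()
                if bp["terminal_mod"]:
                    mods = (Mod(len(bare), bare[-1], bp["terminal_mod"]),)
                exact_areas = {
                    g: total * state[g] / 100.0 * noise() for g in groups
                }
                emit(run, bare, mods, MBP_FIXTURE_ACC, rng.uniform(3.0, 5.0),
                     12.0, exact_areas, prev, nxt)
                ps, pe = _PARTIAL_SPANS[bp["peptide"]]
                partial_pep = mbp[ps - 1 : pe]
                pprev, pnxt = _flanks(mbp, ps - 1, pe)
                partial_areas = {
                    g: total * (1.0 - state[g] / 100.0) * noise() for g in groups
                }
                emit(run, partial_pep, (), MBP_FIXTURE_ACC, rng.uniform(3.0, 5.0),
                     12.0, partial_areas, pprev, pnxt)

    # --- decoys ----------------------------------------------------------
    n_targets = len(rows)
    if config.decoy_fraction > 0 and n_targets:
        n_decoys = int(round(
            n_targets * config.decoy_fraction / (1.0 - config.decoy_fraction)
        ))
        all_peptides = [
            seq[s:e] for p in proteins for (s, e) in p["spans"] for seq in (p["seq"],)
        ] or ["".join(rng.choice(list(_AA), size=12, p=_AA_FREQ))]
        for i in range(n_decoys):
            template = all_peptides[int(rng.integers(len(all_peptides)))]
            peptide = "".join(rng.permutation(list(template)))
            base = 10.0 ** rng.normal(4.0, 0.4)
            areas = {g: base * noise() for g in groups}
            emit(
                rng.choice(runs), peptide, (), f"DECOY_{i + 1:05d}",
                rng.uniform(0.3, 2.2), float(rng.uniform(2.0, 6.0)), areas,
                "K", "-", decoy=True,
            )

    columns = (
        ["run_id", "peptide", "mods", "protein_acc", "is_decoy",
         "confidence_pct", "unused_score"]
        + [f"area_{ch}" for ch in channels]
        + ["prev_aa", "next_aa"]
    )
    psm = pd.DataFrame(rows, columns=columns)

    truth = pd.DataFrame(
        [
            {
                "protein_acc": p["acc"],
                "group": g,
                "true_fold": folds[(p["acc"], g)],
                "true_call": _call_for(folds[(p["acc"], g)]),
            }
            for p in proteins
            for g in design.test_groups
        ]
    )
    deg_rows = []
    if config.degradation_state is not None:
        state = {g: float(config.degradation_state.get(g, 50.0)) for g in groups}
        for bp in BYPRODUCTS:
            for g in groups:
                ratio = state[g] / state[ref] if state[ref] > 0 else math.nan
                deg_rows.append(
                    {"byproduct": bp["peptide"], "group": g,
                     "true_pct": state[g], "true_ratio": ratio}
                )
    truth_degradation = pd.DataFrame(
        deg_rows, columns=["byproduct", "group", "true_pct", "true_ratio"]
    )
    return SyntheticDataset(psm, truth, truth_degradation, sequences, design, config)


@dataclass
class RecoveryReport:
    """Agreement between pipeline output and generator ground truth."""

    confusion: pd.DataFrame
    sensitivity_up: float
    false_positive_rate: float
    n_proteins: int
    degradation_mae: float = math.nan


def truth_compare(
    stats: pd.DataFrame,
    truth: pd.DataFrame,
    degradation: pd.DataFrame | None = None,
    truth_degradation: pd.DataFrame | None = None,
) -> RecoveryReport:
    """Confusion matrix of regulation calls plus degradation-ratio error.

    ``stats`` is the protein statistics table from ``quantify_proteins``
    (columns protein_acc, group, call, modulated); a protein counts as
    called up/down only when it is also modulated.
    """
    merged = stats.merge(truth, on=["protein_acc", "group"], how="inner")
    if merged.empty:
        raise DesignError("pipeline output and ground truth share no proteins")
    predicted = np.where(merged["modulated"], merged["call"], "unchanged")
    confusion = pd.crosstab(
        merged["true_call"], pd.Series(predicted, name="predicted_call")
    )
    true_up = merged["true_call"] == "up"
    sens = float((predicted[true_up] == "up").mean()) if true_up.any() else math.nan
    true_null = merged["true_call"] == "unchanged"
    fpr = (
        float((predicted[true_null] != "unchanged").mean())
        if true_null.any()
        else math.nan
    )
    mae = math.nan
    if degradation is not None and truth_degradation is not None and len(degradation):
        dm = degradation.merge(truth_degradation, on=["byproduct", "group"])
        err = (dm["ratio_vs_control"] - dm["true_ratio"]).abs()
        if err.notna().any():
            mae = float(err.dropna().mean())
    return RecoveryReport(
        confusion, sens, fpr, int(merged["protein_acc"].nunique()), mae
    )
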