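# dpmquant

Quantitative analysis of pooled, isobaric-tag (iTRAQ 4-plex) shotgun
proteomics of brain tissue, aimed at the questions that arise when
comparing dementia groups against age-matched controls: which proteins
are differentially expressed, how extensively proteins carry
*degenerative protein modifications* (DPMs — deamidation of Asn/Gln and
citrullination of Arg, both +0.984 Da), and whether degradation of
myelin basic protein (MBP) is altered.

The package consumes peptide-spectrum-match (PSM) tables exported by a
database search engine (one row per identified peptide with sequence,
modification annotations, decoy flag, confidence, and per-channel
reporter-ion areas) plus reference protein sequences in FASTA, and runs
a five-stage analysis:

1. **Qualification filtering** (`psm_io`) — target-decoy FDR control by
   the doubling formula FDR = 2·(decoys/total)·100 %, an unused protein
   score gate (score ≥ 2 ⇔ 99 % confidence via conf = 1 − 10⁻ˢᶜᵒʳᵉ), and
   a peptide confidence cutoff raised until FDR ≤ 1 %; proteins are kept
   only when identified in every replicate run.
2. **Protein quantitation** (`protein_quant`) — weighted average of
   peptide log₁₀ ratios per protein with the *error factor*
   EF = 10^(S_MW·t₀.₉₇₅,n−1), a Student *t* on the bias-corrected mean
   (t = (x̄_w − log bias)/S_MW, n−1 df), and a two-cell likelihood-ratio
   G-test on summed reporter areas,

   G = 2·(Ctrl·ln[Ctrl/m] + Dem·ln[Dem/m]), m = (Ctrl+Dem)/2,

   referred to χ²(1) and Benjamini–Hochberg-corrected across proteins.
   Regulation calls combine BH significance with fold-change cutoffs
   (>1.5 up, <0.67 down); gender-differential proteins have
   |female − male| ratio difference ≥ 0.2 (≥ 0.9 for the strong tier).
3. **DPM quantitation** (`dpm_quant`) — peptide-level modification
   stoichiometry, per-site reporter-area comparison across groups
   (one-way ANOVA + Bonferroni), proteome-wide modification rates by
   spectral counting with a pooled 2×2 chi-square, and modified
   amino-acid-pair intensity profiles.
4. **Degradation scoring** (`degradation`) — known in-vivo byproducts
   (e.g. cathepsin-D products of MBP) are transferred across species by
   Needleman–Wunsch alignment, PSMs are classified as *exact* matches
   (byproduct with a non-tryptic or modified K/R terminus) or *partial*
   matches (longer tryptic peptides containing it), and
   %degradation = exact·100/(exact+partial) is reported per group,
   normalized to controls; a MAG/PLP-style severity ratio is derived
   from the protein table.
5. **Reporting** (`pipeline` + `dpmquant` CLI) — TSV tables and a JSON
   manifest, all stamped with the config hash for reproducibility.

A first-class synthetic-data module (`synthetic_data`) generates PSM
tables with known ground truth (fold changes, modification rates,
degradation states, decoy fraction, log-normal reporter noise) so every
stage is testable without access to a raw dataset.

## Worked example

```bash
dpmquant simulate --out demo/sim --seed 11
# write demo/config.yaml pointing at demo/sim/psm.tsv + reference.fasta
dpmquant run --config demo/config.yaml
```

or, equivalently, from Python:

```python
from dpmquant import SyntheticConfig, generate, PipelineConfig, run_pipeline

ds = generate(SyntheticConfig(
    n_proteins=15, peptides_per_protein=(4, 6), noise_cv=0.15,
    decoy_fraction=0.3, seed=11,
    true_fold_changes={"female": {"P0001": 2.0, "P0002": 2.0, "P0003": 2.0}},
    dpm_rates={("control", "Deamidated"): 0.05, ("female", "Deamidated"): 0.15,
               ("male", "Deamidated"): 0.05, ("female", "Citrullination"): 0.10},
    degradation_state={"control": 50.0, "female": 25.0, "male": 60.0},
))
paths = ds.to_dir("demo/sim")
```

With the matching pipeline config this prints/writes (seed 11):

```
qualified: 286 PSMs, 16 proteins identified in all three runs

protein_acc  group   n_peptides  ratio   error_factor  p_value  p_bh  call       modulated
P0001        female  14          1.8659  1.2065        0.0000   0.0   up         True
P0001        male    15          0.9366  1.2543        0.5449   0.0   unchanged  False

byproduct    group    pct_degradation  ratio_vs_control
TQDENPVVHF   control  50.235           1.000
TQDENPVVHF   female   24.026           0.478
TQDENPVVHF   male     58.279           1.160

group   severity_ratio
female  0.48
male    1.03
```

Reading: protein P0001 was simulated at a true 2-fold increase in the
female channel only, and is called up-regulated and modulated there
(ratio 1.87, BH-corrected G-test p ≈ 0) with a gender difference of 0.93
(strong tier), while the male channel stays unchanged. The MBP-like
fixture protein was simulated with 25 % degradation in females against
50 % in controls, and the pipeline recovers a degradation ratio of 0.48
for the TQDENPVVHF byproduct (1 = normal degradation). The severity
ratio below 0.5 in the female group mirrors the greater simulated
white-matter-pathology signal in that group.

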