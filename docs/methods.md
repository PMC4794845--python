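# Methods

## Data model

The unit of input is a peptide-spectrum match (PSM): a peptide sequence
with 1-based modification annotations, a protein accession, a decoy
flag, a percent confidence, a protein-level unused evidence score,
per-channel reporter-ion areas, and the flanking residues in the parent
protein (`-` at a protein terminus). The experimental design maps
reporter channels to pooled groups — by default 114 → control,
116 → female, 117 → male, with channel 115 present but unmapped — and
declares the replicate runs (default three). Pooling means biological
replication is at the run level: every statistical statement below is
about the pooled group signal, not about subjects.

## Identification qualification

Three criteria gate identifications, with defaults FDR ≤ 1 %, unused
score ≥ 2, peptide confidence ≥ 99 %:

* **Unused score gate.** The search engine's protein-level evidence
  score; score *s* corresponds to confidence (1 − 10⁻ˢ)·100 %, so the
  default 2 equals 99 %. The score arrives per row and is applied as a
  gate on each PSM's protein.
* **Confidence cutoff with FDR control.** The decoy-estimated FDR of a
  retained set is 2·(decoys/total)·100 % (the doubling reflects that a
  concatenated target-decoy search produces false target hits at about
  the decoy rate). The cutoff starts at the configured minimum
  confidence and is raised through the observed confidence values until
  the retained set's FDR is within the bound; this sweep is monotone, so
  the first satisfying cutoff is the least conservative one. If no
  cutoff satisfies the bound the result is empty with a warning, not an
  error.
* **Replicate intersection.** Only proteins with at least one
  qualifying peptide in *every* replicate run enter protein-level
  inference.

## Protein-level inference

Per test group, each PSM with positive areas in both the group and
reference channels contributes a log₁₀ ratio. A global multiplicative
**log bias** — the median peptide log ratio, computed per replicate — is
subtracted first; this normalization assumes the bulk of proteins are
unchanged, which is why the benchmark that regulates *every* simulated
protein (see Validation) is run with normalization disabled.

Peptide ratios are combined with weights equal to the peptide's summed
reporter area across the two channels (intense peptides are measured
more precisely; the upstream tool's exact weighting is proprietary, so
this package defines its own). With reliability weights *w* the
weighted mean is x̄_w = Σwx/Σw and

S_MW² = [Σw(x − x̄_w)² / (Σw − Σw²/Σw)] / n_eff,  n_eff = (Σw)²/Σw²,

i.e. the unbiased weighted variance divided by the effective sample
size — the weighted standard deviation *of the weighted average*. With
equal weights this is the ordinary standard error s/√n. From it:

* **Error factor** EF = 10^(S_MW · t₀.₉₇₅,n−1): the multiplicative 95 %
  uncertainty bound of the protein ratio (EF ≥ 1 always).
* **Student t** = (x̄_w − log bias)/S_MW with n−1 df, two-sided p. With
  a single peptide S_MW, t, p and EF are reported as NaN markers; a
  protein whose peptide ratios are all identical to the bias gets
  t = 0, p = 1 by convention.

Independently, summed reporter areas per protein (reference vs group,
rounded to integers — the statistic treats areas as counts) feed the
two-cell likelihood-ratio **G-test** with the 0·ln 0 = 0 convention and
a χ²(1) upper-tail p, Benjamini–Hochberg-corrected per group at
α = 0.05. The BH step-up also yields the data-driven raw-p threshold
(the largest raw p still declared significant).

**Calls.** Up if ratio > 1.5, down if ratio < 0.67 (1/1.5 applied as the
rounded 0.67 exactly), otherwise unchanged; a protein is *modulated*
only when the call is non-null **and** its BH-corrected G-test p is
under α. Gender-differential proteins have |female − male| ≥ 0.2, with
a strong tier at p < 0.001 and difference ≥ 0.9; the tier uses the
protein's minimum BH-corrected p across the two dementia groups. The
female/male quotient is reported alongside. Replicate-level protein
ratios give a %CV profile (100·SD/mean) whose distribution summary
(fraction under 20 %/50 %) documents ratio reproducibility.

Note the G-test on large summed areas is extremely sensitive — almost
any protein deviates "significantly" from perfect area equality — so the
fold-change cutoff, not the G-test, is the binding constraint for false
positives; the G-test mainly removes low-area, unstable ratios.

## DPM quantitation

* **Stoichiometry**: distinct peptides are keyed by (sequence, full
  modification state); the statistic is the percent of distinct
  peptides of a protein carrying ≥ 1 residue with the modification.
  Duplicated PSMs of a counted species change nothing.
* **Site quantitation**: peptide-local modification positions are
  mapped to protein coordinates (first occurrence on repeats, with a
  warning; absence from the reference is an error). Per site, reporter
  areas accumulate per group and per (group, run); groups are compared
  by one-way ANOVA over replicate areas (≥ 2 groups with ≥ 2 replicates
  required, otherwise the site is excluded), Bonferroni-corrected by
  the number of sites tested. Relative site levels divide each group's
  area by the control area, flagging sites absent from control instead
  of dividing by zero.
* **Proteome rates**: spectral counting — a PSM counts toward a group
  when its area in that group's channel is positive; the rate is the
  percent of counted PSMs carrying the modification, hence invariant to
  area scaling. Disease association is a 2×2 chi-square (1 df, no
  continuity correction) of pooled dementia groups vs control.
* **Amino-acid pairs**: each modified residue contributes its peptide's
  group areas to the pair (residue, immediate C-terminal neighbor),
  using the flanking residue when the modification sits at the peptide
  C-terminus. The C-terminal direction is a package choice (the
  alternative N-terminal reading is symmetric to implement); pairs
  never observed are simply absent from the matrix.

## Degradation scoring

Byproducts reported on a source species are transferred to the target
protein by global Needleman–Wunsch alignment with EMBOSS Needle default
scoring (BLOSUM62, gap open 10, extend 0.5, end gaps free); the target
columns aligned to the source peptide, gaps removed, give the mapped
peptide and span. A trailing `#` on a byproduct marks a citrullinated
terminal Arg.

Classification: a PSM is an **exact** match when its bare sequence
equals the mapped byproduct *and* it carries an in-vivo signature — a
non-tryptic terminus (previous residue not K/R and not the protein
N-terminus; or last residue not K/R with a following residue) or any
annotated modification on a terminal K/R. It is a **partial** match when
it is fully tryptic, carries no terminal-K/R modification, and strictly
contains the mapped sequence. Exact and partial are mutually exclusive
by construction. Percent degradation is exact·100/(exact+partial) per
group, and the degradation ratio divides each group's percentage by the
control percentage (control ratio ≡ 1 whenever defined; a zero or empty
control yields NaN with a warning). Modified and unmodified forms of a
byproduct sequence both accumulate into the exact pool when they carry
the in-vivo signature.

The **severity ratio** divides one protein's group-vs-control ratio by
another's (MAG/PLP in the white-matter application): the numerator is
chosen to be gender-stable under ischemic degradation while the
denominator scales with pathology, so lower values indicate more severe
white-matter involvement.

## Synthetic data

The generator emulates the pooled triplicate design: random protein
sequences (natural residue frequencies, K+R ≈ 11 % so tryptic peptide
lengths are realistic), 4–10 sampled tryptic peptides per protein,
log-normal peptide abundances (median 10⁴), per-channel log-normal
multiplicative noise with configurable CV (default 15 %, matching the
ratio-scale analysis), per-group fold changes (scalar or per-protein),
per-group per-residue modification rates, decoys at a configurable
fraction with shuffled sequences and a lower confidence range
(targets: confidence from unused-score draws in [2.2, 5]; decoys:
[0.3, 2.2], so a confidence sweep can always reach FDR ≤ 1 %), and an
MBP-like fixture protein carrying the two byproducts with exact/partial
areas set so the noiseless percent degradation equals the configured
state exactly.

Groups sharing a modification rate share one Bernoulli draw per residue
— one pooled molecular species — so a uniform-rate configuration emits
exactly one PSM per peptide and the closed-form peptide-level
stoichiometry expectation 1 − (1−p)ᵏ holds (k = eligible residues).
Groups with different rates draw independently and split into
per-pattern PSM rows whose channel areas are positive only for the
matching groups.

The fixture MBP sequence is synthetic (generated programmatically, not
a database entry): the degenerative epitope QDENPVV occupies residues
82–88, TQDENPVVHF spans 81–90 inside the tryptic peptide 75–95, and
YLATASTMDHAR spans 111–122 inside 111–126, so literature coordinates
for these byproducts reproduce on the fixture. The fixture protein is
emitted only through the degradation path, keeping its configured
percentages undiluted by ordinary tryptic PSMs of the same spans. Users
analysing real data must supply the FASTA matching their accession
numbering (MBP isoform numbering differs between the classic and long
forms).

What the generator does **not** emulate: spectra, retention time, m/z,
charge states, missed cleavages, peptide-level interference between
co-eluting species, protein inference ambiguity, or between-subject
variance (the pooling design hides it in reality too). Passing
recovery tests therefore demonstrate correctness of the statistical
machinery under the stated noise model, not performance on real data.

## Validation choices and problem sizes

* G-test equivalence is checked against an independent two-cell
  log-likelihood-ratio oracle (1,000 random pairs, 10⁻⁹ agreement),
  plus symmetry, non-negativity and monotonicity properties. The
  implementation guards against floating-point underflow of the
  cell/mean ratio for subnormal cells.
* BH correction is checked against a hand-computed step-up example and
  monotonicity/Bonferroni-domination properties over random vectors.
* Regulation-call recovery runs at fold 2.0, six peptides/protein, 15 %
  noise, three replicates, 200 proteins (sensitivity ≥ 0.9), and a
  200-protein global-null at the same noise (false-positive rate
  ≤ 0.07 at α = 0.05). Because the sensitivity condition regulates
  every protein, the median-bias normalization — which presumes a
  mostly-null proteome — is disabled for that run and enabled for the
  null run.
* Alignment mapping is validated on closed-form toys (substitution-only
  targets keep coordinates; a known insertion shifts them) rather than
  a re-implemented affine-gap DP, which would add risk without
  independence.
* The %CV estimator is validated directly on log-normal replicate
  ratios with known CV; note that a ratio of two independently noised
  channels has CV ≈ √2 times the per-channel CV, so generator-level
  ratio CVs sit above the configured channel noise.

## Known limitations

* Modification assignments are taken from the input annotations; no
  spectral re-localization or isotope-pattern validation is attempted.
* The G-test treats reporter areas as counts; its χ²(1) calibration on
  areas is empirical, and the package deliberately pairs it with the
  fold-change cutoff as described above.
* Protein inference/grouping is out of scope — accessions are taken as
  given.
* With a single peptide, protein-level uncertainty is undefined rather
  than imputed.
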