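# Methods

## Disorder calling and segmentation

A residue is called disordered when its predictor score is **at or above
0.5** (inclusive; configurable). A long disordered region (LDR) is a maximal
run of at least `min_len = 30` consecutive called residues; runs are maximal
by construction (flanked by an uncalled residue or the protein boundary), so
LDRs on one protein are non-overlapping, non-adjacent and sorted. Disorder
binding regions (DBRs) apply the identical rule to an ANCHOR-style
binding-propensity track. The alternative reading of the DBR rule — a
predicted binding region *containing* 30 disordered residues in total rather
than consecutively — is deliberately not the default: the consecutive-run
interpretation mirrors the LDR definition and ANCHOR's own long-region
convention, and keeps the two region types directly comparable.

Coordinates are half-open 0-based internally and 1-based inclusive in every
output file. Proteins shorter than `min_len` simply never produce a region;
there is no special case. No smoothing or merging of nearby runs is applied.

Sequences containing ambiguous residues are removed before analysis. The
default ambiguous set is all six non-standard IUPAC letters
`{B, J, O, U, X, Z}`; users wanting the narrower `{B, X, Z}` filter can pass
it explicitly.

## Proteome statistics

"Mean content of disordered residues" is the **unweighted mean of
per-protein percentages**, consistent with the other per-protein means
reported alongside it (`pooled=True` gives the residue-pooled fraction
instead). Content bins are left-closed/right-open deciles by default, with
the last bin closed so 100% is counted.

Two-proteome comparisons:

* residue-level: 2×2 table of pooled {disordered, ordered} residue counts ×
  group, Pearson chi-square, df = 1;
* protein-level: 2×2 table of {has LDR, no LDR} × group;
* per-protein quantities (LDR/DBR counts, coverage): two-sided Wilcoxon
  rank-sum. For pooled sample sizes ≤ 18 the p-value is computed by full
  permutation enumeration over all C(n+m, n) group assignments with
  midranks for ties (two-sided convention: P(|U′ − nm/2| ≥ |U − nm/2|));
  larger samples use the tie-corrected normal approximation *without*
  continuity correction, so identical samples give exactly p = 1.

The Yates continuity correction is off by default — Pearson's statistic is
the named test — but available as a flag since R's `chisq.test` default
differs. p-values are stored exactly; printing clamps values below 2.2e-16
to "< 2.2e-16" to match R-style reporting. Note that the residue-level
chi-square treats residues as independent counts; residues within a protein
are correlated in reality (and in the simulator, by construction), so that
test is anti-conservative at the residue level and is reported as a
descriptive effect-size statistic. Calibration checks therefore use the
protein-level table, whose units are independent.

## GO enrichment

A protein is *disordered* when it has at least one LDR. Annotations are
kept when PPV > 0.7 (strict, configurable); duplicate (protein, term) rows
keep the maximum PPV. Only terms present in both groups (default ontology:
biological process) enter the between-groups analysis.

**Between groups:** for each common term, the 2×2 table restricts to the
proteins annotated with the term — rows disordered/not-disordered, columns
the two groups. The *excess* is the focal group's observed disordered count
minus its expectation under independence; `direction_positive = excess > 0`
identifies terms more disordered in the focal group. Results are ranked by
p-value; terms with no disordered protein in either group, or with a zero
marginal, are skipped with a logged notice rather than failing the batch.
An optional whole-proteome-background mode exists for sensitivity analysis.

**Within one group:** per term, disorder status × annotation status over
the whole proteome, Pearson chi-square with an automatic two-sided Fisher
exact fallback when any expected cell is below 5 (small GO classes break
the asymptotic approximation).

Multiple-testing adjustment is **off by default** (the ranked raw p-values
are the primary output); Benjamini–Hochberg is available behind a flag and
delegates to statsmodels. Annotations are not propagated up the GO DAG.

## Synthetic proteomes

The generator emulates the data a two-proteome disorder survey consumes:

* **Lengths**: log-normal, median 350 aa, σ = 0.45, clipped to [30, 5000].
* **Hidden disorder**: a two-state Markov chain over residues with stay
  probabilities `p_oo`, `p_dd`, simulated as alternating geometric runs.
  Its stationary disordered fraction is `(1−p_oo)/((1−p_oo)+(1−p_dd))` in
  closed form.
* **Scores**: Beta emissions per state — disorder tracks Beta(8.5, 1.5)
  (mean 0.85) in the disordered state and Beta(1.5, 8.5) (mean 0.15) in the
  ordered state; binding tracks Beta(5.5, 1.5) / Beta(1.2, 8.0) on the same
  state path, so DBRs co-occur with LDRs as in real data (a flag decouples
  them). The *observed* disorder fraction mixes the stationary fraction
  with the two Beta upper tails at 0.5; `expected_disorder_fraction`
  computes it analytically, and the acceptance script checks the simulation
  against it.
* **Group defaults**: `p_dd = 0.997` (mean disordered run 333 residues)
  with `p_oo = 0.998842` (focal) and `0.998468` (comparison), solved from
  the closed form so observed disorder lands near 28.2% and 34.0% — the
  regime of a camelid-versus-human comparison — while roughly half of all
  proteins carry an LDR (~48% vs ~57%) and the mean LDR count per protein
  is ~0.94 vs ~1.17. A two-parameter chain cannot match every per-protein
  statistic at once: mean LDR length here is ~105 residues, shorter than
  the 170–215 seen in real proteomes. The per-residue and per-protein rates
  were prioritised because the statistical tests operate on them.
* **Annotations**: each (protein, term) is annotated with baseline
  probability 0.15; for a *planted* term, the annotation **odds** of truly
  disordered proteins in the focal group are multiplied by θ. Emitted PPVs
  are Beta(9, 1.5), so most pass the 0.7 filter. A protein is *truly
  disordered* when its hidden path has a run ≥ 30.
* **Ambiguity spikes**: by default 2% of sequences get one ambiguous letter,
  exercising the cleaning filter.
* **Determinism**: one global seed; per-protein substreams are keyed by
  (seed, group, protein id), so single proteins regenerate identically
  regardless of proteome size, and fixture files are byte-identical across
  runs.

What the simulator does **not** model: amino-acid composition bias of real
IDRs (sequences are uniform over the 20 standard letters — no pipeline
stage reads composition, and the sequences must not be used to test
composition-aware predictors), evolutionary relatedness between the groups,
GO DAG structure, and realistic GO class-size distributions (real classes
annotate ~1% of a proteome; the default 15% keeps per-term tables testable
at simulation scale). Passing tests therefore validate the statistical
machinery, not predictor accuracy on real sequences.

## Validation design and known limitations

* **Null calibration** uses the protein-level (has-LDR) chi-square across
  200 replicate pairs simulated from identical parameters: rejection at
  α = 0.05 stays within 5% ± 3%. The residue-level test is excluded by
  design — Markov-correlated residues violate its independence assumption.
* **Planted-effect recovery** plants 10 of 50 terms at annotation odds
  ratio θ = 20 in the focal group (500 proteins/group, annotation baseline
  0.15). The between-groups table measures the *residual* association
  after background disorder: its odds ratio is roughly
  `[π_d·p_planted/(π_o·p_base)] / [π_d′/π_o′]`, which attenuates θ = 20 to
  a table OR near 3.8 (and θ = 5 to near 2, where per-term power at
  p < 0.01 is only ~50% at these sample sizes). θ = 20 puts the per-term
  z-score near 4.5, so ≥ 80% recovery with no more than 2 of the 40 null
  terms flagged is reliably met.
* **Problem sizes** in tests and the acceptance script (250–2000 proteins
  per group, 200 null replicates) were chosen as the smallest sizes at
  which the binomial/KS tolerances above are meaningful.
* Wilcoxon exact enumeration is O(C(n+m, n)) and capped at pooled size 18;
  beyond that the normal approximation is used. For heavily tied small
  samples the permutation distribution *with* midranks is the reference
  convention throughout.
* CD-HIT-style redundancy clustering is an external preprocessing step:
  the pipeline assumes de-duplicated input and does not re-implement it.
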