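# ymarker

Design and in silico validation of Y-chromosome-specific multiplex PCR
markers for sexing dioecious plants, built around the *Cannabis sativa*
use case: males are unwanted in most hemp and cannabinoid crops, young
plants cannot be sexed by eye, and a PCR assay on seedling DNA settles
the question in hours.

## Who this is for

Molecular breeders and plant geneticists who have X- and Y-linked gene
copies (e.g. from a segregation analysis of a cross) and want a
deterministic, fully scriptable route from those sequences to a
gel-readable multiplex: two Y-specific primer pairs plus one autosomal
control whose band says "the PCR worked".

## The method

1. **Gene selection.** Among sex-linked genes, keep those whose Y copy
   is still expressed, restrict to the oldest evolutionary stratum
   (highest X–Y divergence, hence sites most likely shared across
   cultivars), rank by synonymous divergence *dS* and keep the top 20,
   then drop genes with introns < 300 bp.  *dS* is estimated with the
   Nei–Gojobori (1986) method: per-codon synonymous/nonsynonymous site
   counts, pathway-averaged difference counts, and the Jukes–Cantor
   correction dS = −(3/4)·ln(1 − (4/3)·pS).
2. **Fixed X–Y differences.** Each of ≥3 X haplotype copies (ideally
   from distinct cultivars) is globally aligned to the Y copy; a site is
   *fixed* when every X carries the same base and the Y differs.
3. **Allele-anchored primer design.** Candidate primer pairs on the Y
   gene (including its intron) are filtered on length, Tm
   (nearest-neighbor thermodynamics), GC, product size, and
   primer-dimer complementarity; a pair is Y-specific only if its
   amplicon spans ≥ 2 fixed differences and one primer puts a fixed
   difference in its 3′-terminal bases, where a mismatch against the X
   allele blocks extension.
4. **In silico PCR.** Primer binding sites are scanned on both strands
   of male and female genome templates (≤ 2 mismatches, 3′-terminal
   bases exact); a Y-specific pair must amplify exactly once in males
   and never in females.
5. **Assay evaluation.** Per-sample calls (control band absent → failed;
   control + Y band → male; control only → female) are summarized into
   per-cultivar confusion counts, the true positive success rate, and
   the specificity (no males called female).

A synthetic-data generator simulates the whole regime — stratified X–Y
divergence, multiple X haplotypes, introns, chromosome-scale templates,
192-sample cultivar cohorts — so every stage is testable end to end
without any downloads.

## Worked example

```bash
ymarker evaluate --published --out-dir out_eval
```

prints the packaged 192-sample, 12-cultivar validation table:

```
cultivar    n male_as_male female_as_female male_as_female female_as_male failed tpr_percent
      Pu   22           10               12              0              0      0         100
      Cr   30           15               14              0              1      0          97
     ...  ...          ...              ...            ...            ...    ...         ...
   Total  192           96               95              0              1      0        99.5
```

191 of 192 samples are concordant (true positive rate 99.5%); the one
discordant sample is a phenotypic female called male, so no male was
ever called female (specificity 100%).

Run the entire pipeline on a simulated cohort:

```bash
ymarker all --seed 3 --out-dir out_all
```

which simulates a 192-sample cohort, designs the 3-plex (at seed 3:
product sizes 464/539/600 bp, ≥ 60 bp apart, 3/3 members valid in
silico, assay true positive rate 100.0%), validates it against every
sample genome, runs the simulated assay, and writes
`primer_table.tsv`, `panel.yaml`, `marker_validation.tsv` and a
Table-style `summary.tsv` under `out_all/`.

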