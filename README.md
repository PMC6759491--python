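# crosskit

Planning and paternity-testing toolkit for hybrid breeding by **random
inter-pollination** of genotyped inbred (doubled haploid, DH) lines.

Instead of making all `n(n-1)/2` controlled crosses, a group of `n`
genotyped lines is inter-pollinated at random, the F1 progeny of each
maternal line is grown in a "maternal row", elite individuals are selected
by phenotype, and only those are genotyped to recover their paternal line by
likelihood-ratio paternity testing. `crosskit` provides the four pieces such
a program needs:

- **`crosskit.design`** — exact combinatorics of family-size planning.
  The probability `Q(n, k, m)` that a row of `k` offspring contains at least
  `m` of the `n-1` other lines as fathers is computed from Stirling numbers
  of the second kind with arbitrary-precision integer/rational arithmetic
  (floats only at rendering). Includes minimum-family-size search, grid
  tables, and a brute-force enumeration oracle.
- **`crosskit.genotypes`** — multilocus SSR genotype data model and CSV I/O
  for candidate-parent and offspring panels; allele frequencies, observed /
  expected heterozygosity, PIC, and one-parent non-exclusion probability;
  detection of genotypically identical lines (which make paternity
  non-unique).
- **`crosskit.paternity`** — LOD-score paternity assignment for offspring
  with recorded mothers: Mendelian transition probabilities blended with a
  typing-error model, Monte-Carlo calibration of strict (95%) / relaxed
  (80%) confidence thresholds on the best-candidate LOD (or the Δ gap to the
  runner-up), mismatch-based exclusion, ambiguity groups for identical
  candidates, and reciprocal/duplicate detection among selected hybrids.
- **`crosskit.simulate`** — end-to-end simulator: homozygous DH panel
  generation, uniform inter-pollination (optionally self-incompatible),
  typing noise, an additive GCA + SCA-like phenotype model with truncation
  selection, and a recovery experiment that checks the empirical paternal
  diversity per row against the closed-form `Q(n, k, m)` and measures
  assignment accuracy.

## CLI

All functionality is exposed through one entry point (also available as
`python -m crosskit.cli`):

```bash
# minimum offspring per maternal row for 31 lines, all 30 fathers, p >= 0.5
crosskit plan --n 31 --m 30 --p 0.5

# probability grid (rows k, columns m), rendered at 3 decimals
crosskit table --n 61 --k-min 60 --k-max 720 --k-step 60 --m 60,54,48

# per-locus diversity statistics from a genotype CSV
crosskit stats --genotypes parents.csv

# paternity assignment with simulated confidence thresholds
crosskit assign --parents parents.csv --offspring offspring.csv \
    --error 0.002 --typed 0.998 --seed 1 --out assignments.tsv

# reciprocal / duplicate combinations among assignments
crosskit reciprocals --assignments assignments.tsv

# full breeding-scheme simulation + recovery report
crosskit simulate --config sim.yaml --seed 1 --out run/
```

Genotype CSVs have columns `line_id, role, maternal_id` followed by
`<locus>.a1, <locus>.a2` pairs; missing loci are coded `0`. Commands that
write an output path also emit a JSON run manifest (parameters, seed,
package version, input digests) for bit-identical reproduction.

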