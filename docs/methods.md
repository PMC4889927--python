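# Methods

## Model and assumptions

The pipeline analyses paired affinity purifications: an ends phase
(monobiotinylated duplex DNA, one free double-strand end exposed) versus
a control phase (bibiotinylated duplex, no free end), resolved by
blue-native PAGE into four bands (720, 480, 240 kDa, common). The unit of
analysis is the excised band pair: every ends-phase band is paired with
the corresponding band of the control lane, even when that band is not
visible — an absent control file means "no proteins identified", not
missing data.

Semi-quantitation uses emPAI = 10^(N_obs/N_observable) − 1. The emPAI
literature defines the observable count loosely; here a peptide is
observable when it is fully tryptic (cleavage C-terminal to K or R except
before P, zero missed cleavages by default) and its monoisotopic mass at
some charge state z ∈ {2, 3, 4} gives (m + z·1.00728)/z within
[400, 2000] Th. These constants mirror the acquisition settings of the
instrument that produced the data this pipeline targets, and all are
exposed as parameters. Masses are monoisotopic with no modifications;
since the specificity index only ever compares a protein with itself
across samples, any consistent mass convention yields the same index.
Residue masses ship as a package data table
(`dnaends/data/residue_masses.tsv`) and are cross-checked against an
independent mass calculator in the test suite. Observed peptides are
counted as distinct sequences (charge states and modified forms
collapse). If a search reports more observed peptides than the 0-missed
observable count (possible with missed cleavages), the count is clamped
with a warning, keeping emPAI ≤ 9.

The specificity index for one protein is I = (Σᵢ Mᵢ/(Mᵢ+Bᵢ))/N over the
experiments where the protein was identified at all. Conventions:

* absence from one phase contributes 0 emPAI on that side; an experiment
  where the protein is absent from both phases does not count toward N,
  so no 0/0 term can arise;
* "identified" means identified on either phase by default; a switch
  (`identified_on="ends"`) restricts N to ends-phase detections, since
  the narrower reading is also defensible;
* the study design is asymmetric (six ends experiments, five control
  experiments). The unpaired sixth experiment is included with B = 0 and
  flagged; `paired_only=True` restricts the index to the five paired
  experiments. Both behaviours are first-class because the original
  handling is not documented;
* N ≥ 3 is required for I to be defined; I ≥ 0.9 retains (an exact tie
  at the cutoff is retained — removal is for I strictly below it);
* I is computed pooled per protein (per-experiment emPAI summed across
  bands; the headline filter) and per band (the granularity at which the
  band pairs were excised).

Band analyses: membership is the union over experiments of the ends-phase
bands where a protein was seen, restricted to proteins in ≥ 4 of 6
experiments (the Venn threshold); all other reporting uses ≥ 3 of 6.
Pairwise sharing counts use plain intersection (a protein in three bands
counts toward each pair it covers). "Relative abundance" per band is the
across-band fraction of the mean per-band emPAI — the only normalisation
consistent with comparing a protein solely with itself. Ranking by
abundance sums ends-phase emPAI per protein, descending, ties broken
lexicographically. Functional classes are consumed from a user-supplied
table (multi-label; proteins without a label are "unclassified"), never
computed, because ontology versions drift.

## Synthetic data

The generator emulates the study conditions: 6 ends + 5 control
experiments, 4 bands, and three protein classes. Per
(experiment, phase, band) sample, a protein appears with probability
band_propensity × phase-detection × (1 − dropout); when present its emPAI
is drawn as 10^Normal(μ, σ) and back-converted to a peptide count
n = round(N_observable · log10(emPAI + 1)), clamped to
[min_peptides, N_observable]. emPAI is simulated directly rather than via
spectra because the pipeline's inputs are identification tables.

Default roster (overridable): 40 ends-specific, 40 generic binders, 20
contaminants — large enough for non-trivial Venn structure, small enough
that a full study simulates in well under a second. Parameter choices:

* ends-specific: 1–4 bands (mostly one, echoing the predominance of
  band-exclusive proteins in this kind of separation), propensity 0.95,
  control detection 0, dropout 0.05, μ ~ Normal(0, 0.4), σ = 0.3;
* generic binders: 2–4 bands (a generic duplex binder is expected in
  several assemblies), same abundance law on both phases (so the expected
  per-experiment ratio is 0.5 and E[I] ≈ 0.5), dropout 0.05;
* contaminants: all bands at propensity 0.3, both phases, lower abundance
  (μ ~ Normal(−0.5, 0.3)), dropout 0.2 — sporadic background, some of
  which fails the N ≥ 3 rule, as background does in practice.

σ = 0.3 on the log10 scale (a ~2-fold typical spread) is a realistic
replicate-to-replicate dispersion for label-free semi-quantitation.
Protein sequences are generated randomly (uniform residues, length
150–600) and their observable counts computed by the package's own
digestion, so the simulated tables round-trip the real quantitation path.

Randomness: one global seed; each (experiment, phase, band, protein)
cell draws from a dedicated `SeedSequence` substream whose spawn key is
the cell coordinates plus the accession bytes. Adding roster proteins
therefore never perturbs existing draws, and outputs are byte-stable.

What the generator does *not* emulate: protein-to-protein differences in
peptide ionisability, shared-peptide protein inference, search-engine FDR
behaviour, gel-migration artefacts, or correlated dropout between bands.
Passing recovery tests therefore demonstrates that the index and filter
behave as designed under the stated statistical structure, not that the
thresholds are optimal for any particular real data set.

Class recovery is evaluated over proteins meeting the N ≥ 3 replication
rule — the same population the published analysis reports on. For a
considered ends-specific protein every Bᵢ = 0, so I = 1 is forced and
retention is exact; for a symmetric generic binder the probability of
I ≥ 0.9 under the default law is below 1 % (checked by an independent
Monte-Carlo oracle in the acceptance tests).

## Numerical and design notes

* The digestion keeps duplicate peptides and N→C order, so the 0-missed
  digest concatenates back to the protein; observable counting
  deduplicates sequences.
* Table outputs are sorted (accession, then band) with a fixed float
  format, so every writer is byte-deterministic; reports carry no
  timestamps (timestamps live in `run.log`).
* The specificity filter partitions exhaustively: undefined I (N below
  minimum) is removed with the rest, never silently dropped.
* Venn counting is exact set algebra over the 15 regions; conservation
  (Σ regions = total) is asserted in tests against brute-force
  enumeration.
* Problem sizes in the test and acceptance runs (100-protein roster,
  20-seed recovery sweeps, 400-study Monte Carlo) were chosen so the full
  analysis remains interactive on a single CPU while keeping Monte-Carlo
  standard errors well inside the asserted margins.

## Known limitations

* No protein inference: accessions are taken as given, shared peptides
  are not re-assigned.
* No statistical test accompanies the index; I ≥ 0.9 is a fixed
  decision rule, as defined, not an estimator with a p-value.
* Count-only identification tables cannot validate peptide-level
  deduplication across files; sequence mode can.
* The reproduction of the published band-membership counts requires the
  original per-band identification lists, which live in the authors'
  purification database; the corresponding acceptance test documents the
  expected values and runs whenever that data is placed under
  `data/study_identifications/`.
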