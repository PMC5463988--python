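# Methods

## The compositional model

A protein with non-ionized elemental formula C_c H_h N_n O_o S_s has an
average oxidation state of carbon

    Z_C = (-h + 3n + 2o + 2s + z) / c

with formal charge z.  Gaining or losing protons changes h and z together,
so Z_C is invariant to ionization; the package always evaluates Z_C on the
non-ionized formula.  The formula of a polypeptide is the sum of its residue
formulas (free amino acid minus H2O) plus one H2O per chain for the terminal
groups; the terminal water is included by default and is toggleable.  The
terminal H2O has no effect on Z_C (its -h + 2o contribution is zero) and
contributes +1/length to the water demand.  Nonstandard residue codes
(B, Z, X, U, O) are dropped with a logged count, not imputed.

The hydration-state metric is componential, not structural: the formation
reaction of the protein from a basis set of chemical components is balanced
exactly, and the H2O coefficient divided by sequence length is the water
demand per residue, n̄_H2O.  The default basis is glutamine, glutamic acid,
cysteine, H2O and O2 ("QEC"), optionally extended with the proton ("QEC+")
so that charged (ionized) formulas can be represented; an inorganic basis
(CO2, NH3, H2S, H2O, O2) and user-defined bases run through the same code
path, a square linear solve over the element (and charge) balance with a
rank check and a 1e-9 residual guard.  Under QEC, n̄_O2 correlates strongly
and positively with Z_C while n̄_H2O stays nearly decorrelated from Z_C,
which is the reason for preferring it over the inorganic basis; the
`basis_correlation_report` function reproduces this comparison on any
proteome.

Typical values for human-like proteins: Z_C between about -0.25 and +0.05,
n̄_H2O around -0.75 (the -1 from the peptide condensation per residue plus
basis-species contributions).

## Group comparisons

For one dataset (up- and down-expressed ID lists), IDs first pass through an
accession-updates mapping, IDs reported in both directions are removed from
both groups, and within-group duplicates are collapsed; every removal is
counted and available to the JSON event log.  Isoform-suffixed accessions
fall back to the parent accession when the isoform itself has no
composition.  Groups are then compared on Z_C and n̄_H2O by:

* the difference of group means, Δ (up minus down);
* a two-sided Wilcoxon rank-sum p-value -- exact enumeration when both
  groups have at most 25 members and the pooled values are tie-free,
  otherwise the midrank normal approximation with continuity correction;
* the common language effect size, CLES = 100 (#{x_i > y_j} + 0.5 #ties) /
  (n1 n2).  Ties get half credit so that cles(x,y) + cles(y,x) = 100; ties
  are rare for continuous compositional metrics.

Classification thresholds: |Δ| > 0.01 counts as "large", p < 0.05 as
"significant", CLES outside [40, 60] as a strong effect.  The grouping
predicate used for merged diagrams selects datasets whose primary metric
exceeds the Δ threshold with the requested sign while the other metric is
neither significant nor strong.

## Thermodynamic model

The per-residue chemical affinity of the formation reaction from the QEC+
basis is evaluated as A* = A/(2.303RT) = logK - logQ:

    A* = logK + n̄_Cys log a_Cys + n̄_Glu log a_Glu + n̄_Gln log a_Gln
         + n̄_H2O log a_H2O + n̄_O2 log f_O2 - z̄ pH - log a_residue

O2 enters as a gas-phase fugacity (gaseous O2 is the reference state), H2O
as a liquid-standard-state activity, and the proton term is -z̄ pH.  Default
activities: log a_Cys = -3.6, log a_Glu = -4.5, log a_Gln = -3.2 (mean human
plasma concentrations), pH 7, unit residue activity, T = 310.15 K, 1 bar.
R = 8.314462618 J/(mol K); energies are J/mol internally.  A* is affine in
(log f_O2, log a_H2O) with slopes (n̄_O2, n̄_H2O); grid evaluation uses this
identity, and the additive terms of every affinity value are retained so the
total can be audited against their sum (1e-9).  Changing log a_residue
shifts all proteins' A* equally and therefore cannot change any rank-based
result.

### The Gibbs-energy table

Standard Gibbs energies are a versioned plain-text input
(`species, kind, formula, G0_Jmol, source`), validated on load (schema,
residue-formula consistency, completeness).  The packaged default
(`data/thermo_qec_310K.tsv`, built by `scripts/build_thermo_table.py`) is an
**estimate**, constructed without access to the primary group-additivity
compilations from: CODATA water; widely reproduced aqueous glycine and
alanine values; functional-group replacement increments derived from
reference organics (methane/methanol for H->OH, methane/acetic acid for
H->COOH); a thermodynamic cycle through the glutamine hydrolysis energy for
the amide groups (the same cycle reproduces the known NH4+ formation energy,
which is the internal check of the method); and a uniform peptide-bond
condensation penalty of +12 kJ/mol per residue.  Lys, Arg, His, Trp, Met and
Pro carry the largest uncertainties (up to a few tens of kJ/mol); the
`source` column flags the provenance of every row.  The 12 K carry-over from
298.15 K is below these uncertainties and is omitted.

Consequences: all rank-based outputs (WRD fields, equipotential existence,
group classifications) are invariant to the uniform components of the table
error, because a constant shift per residue moves every protein's A*
equally.  Absolute equipotential positions do inherit the differential
error -- order a few log f_O2 units.  With the estimated table, equipotential
lines for hypoxia-like synthetic experiments fall near log f_O2 ~ -69 to
-68, in the physically expected window.  Users wanting quantitative
agreement with HKF-based calculations should regenerate the table from such
a calculation; the file format, not the numbers, is the contract.

### Ionization

The original calculations delegate protein ionization to group
thermodynamics in external software; here it is a Henderson-Hasselbalch
surrogate: each ionizable side chain (Asp 3.65, Glu 4.25, His 6.00,
Cys 8.30, Tyr 10.07, Lys 10.53, Arg 12.48) and the chain termini (N 8.00,
C 3.55) contributes a fractional charge from the acid/base fraction at the
given pH, and a Gibbs correction of alpha * (+2.303RT pKa) per deprotonated
acidic group or alpha * (-2.303RT pKa) per protonated basic group.  The
ionized formula C_c H_(h+z) ... ^z is projected onto QEC+, making the proton
coefficient equal the charge.  Disabling the model reproduces the
non-ionized calculation exactly, and with it results are pH-independent.
On merged hyperosmotic-like diagrams the surrogate lowers the equipotential
line by a few tenths of a log a_H2O unit -- the same direction as, but
smaller than, the ~1 unit reported for full group-thermodynamic ionization;
this is reported informatively by the acceptance script, not asserted.

## Potential diagrams

At every node of a log f_O2 x log a_H2O grid (default [-72, -60] x [-4, 2],
129x129 -- bracketing the physically relevant clustering region), the
affinities of all proteins in a dataset are ranked ascending with midranks
for ties and summarized by the weighted rank difference

    WRD = 2 ( (n_down/n) Σ r_up - (n_up/n) Σ r_down ),

equivalently WRD = 2U - n_up n_down with U the Mann-Whitney count, so
|WRD| <= n_up n_down with equality exactly at complete rank separation, WRD
is antisymmetric under swapping groups, and invariant under strictly
monotone transforms of the affinities.  The zero level ("equipotential
line") is extracted by marching squares with linear interpolation; the
scalar position of a contour is the mean vertex coordinate along the chosen
axis (x for oxidation-state groups, y for hydration-state groups).  A field
of one sign reports "no crossing"; an identically zero field is a plateau
and reports the axis midpoint.  Diagrams with identical grids merge by the
node-wise arithmetic mean; per-member contour positions are summarized by
the median and quartiles using the linear-interpolation quantile convention.

Because the WRD field is piecewise constant in the conditions (ranks change
only at affinity crossings), the contour of the interpolated field is the
deterministic, resolution-convergent definition of the equipotential line.

## Synthetic data

One synthetic experiment is two groups of proteins sampled from multinomial
residue frequencies.  Group frequencies are exponential tilts of a
human-proteome-like baseline along residue Z_C and residue water demand:
f_i ∝ baseline_i exp(beta Zc_i + gamma w_i).  Tilts are calibrated by
root-finding so that the expected (carbon-weighted) metric shift equals a
target; presets: hypoxia (ΔZ_C ≈ -0.03), cancer (+0.03), hyperosmotic
(Δn̄_H2O ≈ -0.02), matching the magnitudes characteristic of the
corresponding study conditions.  Lengths are log-normal with median 375
residues and log-sd 0.5, floored at 20 (a human-proteome-like scale; no
specific distribution is required by the analysis).  Default group sizes are
100/100.  All randomness derives from a single integer seed, and identical
seeds give byte-identical output tables.

The baseline frequencies come from a packaged stand-in for the mean human
proteome composition (`data/human_proteome_mean_aa_synthetic.csv`): widely
published approximate human residue frequencies at a representative mean
length of 560, labelled synthetic because it is not derived from an actual
proteome file.  What the generator does *not* emulate: correlated residue
usage within protein families, organism-specific composition, isoform
structure, or the ID-mapping noise of real studies -- so passing recovery
tests demonstrates statistical correctness of the pipeline, not robustness
to real-data mapping problems.

A noise note for diagram summaries: the equipotential position of a sampled
dataset has a between-seed standard error of ~0.1-0.35 log f_O2 units at
these group sizes, while the systematic dependence of the expected position
on the tilt *magnitude* is only a few hundredths of a log unit per tilt
step (a chord-curvature effect of logK vs n̄_O2 along the tilt path).  The
monotone dependence is therefore verified on deterministic expected
(mean-proteome) compositions, where it is exact; with sampled data only the
sign and significance of the compositional recovery are testable in
reasonable compute.

## Redox balance

The lipid-protein balance assumes the carbon-weighted mean oxidation state
of the combined lipid + protein pool is equal in cancer and hypoxic cells,
lipid composition fixed at a representative triacylglycerol
(1-palmitoyl-2,3-dioleoyl-glycerol, C55H102O6, Z_C = -18/11 ≈ -1.636,
0.0640 mol C/g), and only the lipid:protein weight ratio and the protein
Z_C change.  With the packaged mean protein (Z_C ≈ -0.121), hypoxic ratio
0.19 and protein shifts -0.03 (hypoxia) to +0.03 (cancer) relative to
normal, the conservation equation is linear in the unknown ratio and gives
a cancer ratio of ~0.226, an increase of ~19% over the hypoxic ratio, with
~2.7 mmol of electrons transferred per gram of protein.  Carbon-mole
weighting is used because conserving carbon-weighted Z_C is algebraically
identical to conserving electrons relative to any fixed reference oxidation
state.  Alternative normal-cell baselines (0.15, 0.16) ship as presets.
Atomic weights: C 12.011, H 1.008, N 14.007, O 15.999, S 32.06.

## Problem sizes and numerical choices

Default analysis sizes were chosen so a complete synthetic study (simulate,
compare, classify, diagram, merge) runs in well under five minutes on one
CPU: recovery simulations use 100 seeds at 100/100 proteins; merged
diagrams use 65x65 or 129x129 grids.  Projection residual tolerance 1e-9
per element; affinity audit tolerance 1e-9; exact-test cutoff at group size
25; quantiles by linear interpolation; midranks for all ties.  Degenerate
inputs: constant metrics give NaN correlations (flagged, not raised),
single-sign WRD fields give "no crossing", identical groups give p = 1 and
CLES = 50, and the redox solve raises when lipid and cancer-protein
oxidation states coincide (no finite solution exists).

## Known limitations

* The Gibbs-energy table is an estimate; absolute affinities and absolute
  equipotential positions carry a few log units of systematic uncertainty
  (rank statistics do not).
* The pKa ionization surrogate reproduces the direction but not the full
  magnitude of the group-thermodynamic ionization effect on equipotential
  positions.
* No temperature or pressure dependence: everything is fixed at 310.15 K,
  1 bar.
* Up/down calls are consumed as given; re-deriving them from raw study
  tables (fold-change cutoffs and similar) is out of scope, as are online
  ID-mapping services.
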