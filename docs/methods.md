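# Methods

## Scope and model

`mpcscreen` implements a single-ligand, ligand-based pharmacophore screen
for MPC inhibitors together with the downstream assay analytics that turn
plate reads, oxygraph traces and dose–response points into the quantities a
medicinal-chemistry campaign reports: ranked hits, IC50s, fold potencies,
respiratory control ratios and Rule-of-Five compliance.

The structural biology upstream of the pharmacophore (homology modelling of
the MPC1/MPC2 dimer, binding-site mutagenesis) and statistical testing
across treatment groups are out of scope; the pipeline starts from the
reference ligand's 3D conformer and ends at descriptive assay tables.

## Compound registry

The registry (`data/registry.csv`) carries curated SMILES for UK-5099, the
seven cyanoacrylic acid actives (BE1976, BE1978, BE1980, BE1984, BE1985,
BE2617, BE2623), the des-cyano control BE1975, the ethyl ester BE1988 and
the six ethyl esters 3a–3f, together with measured IC50s (nM) and reported
ESI-MS (M+1)+ values. E-geometry of the acrylate double bond is encoded
explicitly. Three entries are flagged *provisional*: BE1985 is registered as
(E)-2-cyano-3-[3-(3-bromophenyl)-1H-pyrazol-4-yl]acrylic acid, the most
literal reading of its name; BE1975 and BE1988 have no fully specified
structures and are represented generically (a des-cyano analog and an ethyl
ester of BE1976) solely to exercise the structure–activity filters.
UK-5099's registry IC50 (240 nM) is the value consistent with the measured
fold relations of the actives (7-fold vs 33 nM, 6-fold vs 39 nM, 3-fold vs
731 nM); it is carried as registry data, not embedded in analysis code.

Two mass conventions matter. Nominal mass sums integer most-abundant-isotope
masses over all atoms, so ESI m/z values are integers ((M+1)+ = nominal + 1,
(M−1)− = nominal − 1). The reported value for BE1984 (186) is inconsistent
with its structure (C11H9NO2, nominal 187, M+1 = 188); the registry keeps
the reported number, the computed value is left to disagree, and BE1984 is
excluded from mass checks. Rule-of-Five descriptors are computed on the
neutral (protonated-acid) form: molecular weight, Crippen atomic-contribution
logP, and classical Lipinski donor (O–H/N–H) and acceptor (N+O) counts,
with violations counted against MW > 500, logP > 5, HBD > 5, HBA > 10.

## Feature perception and the hypothesis

Features are perceived on 3D conformers by substructure pattern:

- **N** (negative ionizable): carboxylate, positioned at the centroid of the
  two oxygens, no direction. With `ionized=True` (the screening default)
  neutral carboxylic acids count as ionizable, so decks can be stored in
  neutral form; descriptors always use the neutral form.
- **A** (acceptor): nitrile nitrogen with direction along the C≡N axis
  (the lone-pair extension); non-carboxyl carbonyl oxygens (C→O axis) and
  pyridine-type aromatic nitrogens (outward bond bisector) are also
  perceived. Carboxyl oxygens fold into the N feature and are not
  double-counted as acceptors.
- **Ar** (aromatic ring): one feature per aromatic ring, positioned at the
  ring centroid with direction equal to the best-fit-plane normal. The
  normal's sign is arbitrary; all comparisons are sign-invariant.

The hypothesis takes one site per required kind (default N, A, Ar) from the
reference conformer. When several aromatic rings are available, the ring
whose centroid lies nearest the midpoint of the N and A sites is selected —
for UK-5099 this is the five-membered ring of the indole. The default
per-site matching tolerance is 2.0 Å, a conventional value in pharmacophore
software. Excluded-volume spheres are not modelled, so the included-volume
score S_ivol is 0 and inert at its default zero weight.

In pipeline runs where the screening deck contains the reference compound,
the hypothesis is built from the reference's own first library conformer.
This mirrors screening practice — the reference geometry is part of the
prepared collection — and makes the reference's self-match (S = 3) the
attainable maximum of the screen.

## Scoring

Matching is strict: a conformer is a candidate only if an injective,
kind-compatible assignment of all hypothesis sites to its features exists.
Every assignment is evaluated:

1. Matched feature positions are superposed onto the site positions by
   least-squares rigid superposition (Kabsch, SVD with reflection guard);
   S_align is the post-fit RMS deviation in Å.
2. The site term is `max(0, 1 − S_align/C_align)`: the formula would go
   negative past the alignment cutoff, and a pose beyond the cutoff earns
   no site credit.
3. S_vec averages, over vector-bearing matched sites, the cosine between
   the rotated feature direction and the site direction. Ring normals are
   compared via |cos|; every per-site cosine is clamped at 0 so
   anti-alignment is not rewarded. With no vector-bearing sites S_vec is 1.
4. S_vol is the intersection-over-union of heavy-atom van der Waals volumes
   between the superposed pose and the reference conformer, evaluated on a
   regular grid (default 0.3 Å spacing, Bondi radii) with cell-centred
   sampling, which halves the surface-discretization bias; two spheres at
   one radius's distance agree with the closed-form lens/union ratio to
   within 2% at this spacing.

The best assignment (highest S, ties broken by lower S_align, then
assignment order) defines the conformer's score; a compound's score is the
maximum over its conformers ("best pose"). Survivors are sorted by S
descending (ties: lower S_align, then compound id) and given 1-based ranks;
the default hit-list depth is 7. Assignments whose site+vector part cannot
beat the current best even with a perfect volume term skip the grid
evaluation; this prunes most of the cost without changing any score.

## Synthetic deck

The deck generator emulates a lead-like commercial screening collection at
desk scale. It combines the registry actives, the six ester negatives, an
optional reference entry, and `n_decoys` decoys drawn without replacement
from an enumerated pool: 18 aryl/heteroaryl scaffolds × 12 small
substituents, carrying either the cyanoacrylate warhead (`warhead_fraction`,
default 0.3 — these can legitimately match the hypothesis) or a
carboxylate-free tail (these can never produce an N feature and must never
be hits). All decoys are valence-legal, parseable and under 500 Da, so
Rule-of-Five filtering is non-trivial but mostly passing. Conformers are
embedded by ETKDG distance geometry with MMFF minimization, 5 per molecule
by default — a desk-scale choice; the screening functions accept any depth.
Decoy SMILES enumeration is exhaustive and sorted, then permuted by the
seeded stream, so a deck is a pure function of its spec.

What the deck does *not* emulate: the size (10^6) and chemical diversity of
a real commercial library, tautomer/stereoisomer enumeration, and any
realistic pharmacology of the decoys. Passing screens on this deck show the
scoring chain behaves correctly (self-match maximal, all-feature rule
enforced, deterministic ranking), not that the hypothesis would retrieve
novel chemotypes from a real library.

## Assay simulation and analysis

**Dose–response.** Simulated responses follow the four-parameter
log-logistic (Hill) inhibition curve
`y(d) = bottom + (top − bottom)/(1 + (d/IC50)^hill)` with multiplicative
log-normal noise `exp(ε)`, `ε ~ N(0, cv)`. The fit is bounded least squares
on (log10 IC50, hill, top, bottom) with 5 starts at quantiles of the log
dose grid; IC50 is bounded to a decade beyond the dose grid, and the bottom
plateau is floored at zero for non-negative data (a response cannot be
driven below full inhibition). A response whose per-dose dynamic range is
below 5 response units is reported as "no inhibition detected" rather than
fitted. Default simulated conditions for recovery studies are the assay's:
8 log-spaced doses from 1 nM to 10 µM, triplicates, cv = 5%. Under these
conditions the median relative IC50 error across 200 simulations is below
10%, and a log-scale residual-bootstrap 95% interval covers the truth at a
compatible rate.

**BRET.** Plates are simulated as two-channel time series (donor ≈485 nm,
acceptor ≈620/640 nm; the analysis accepts either acceptor label since the
emission band naming varies with filter sets). Dimer wells step their true
ratio by a configured fraction at the injection reading; donor-only wells
carry only bleed-through. Analysis divides acceptor by donor per reading,
subtracts the mean donor-only ratio at the same reading, averages replicate
wells per treatment, and normalizes to the mean of the last 3 readings
before injection ("immediately prior" is not a count; 3 is the package's
convention). The baseline window therefore has mean 1 by construction, and
the whole computation is invariant to a common gain applied to both
channels.

**OCR/RCR.** O2 traces are piecewise linear in concentration (nmol/mL) with
non-positive segment slopes, optional residual-fraction segments for
inhibitor additions, and additive noise. OCR over a window is the negative
least-squares slope times chamber volume (default 2 mL), rescaled to 50 µg
of mitochondrial protein; RCR is OCR(state 3)/OCR(state 4). Windows need at
least 3 readings.

## Determinism and seeding

Every generator derives its stream from a global seed plus a CRC32 hash of
the generator's name, so adding a generator never shifts another's draws.
Conformer embedding seeds are derived per molecule index. Re-running any
stage — or the whole pipeline — with the same configuration reproduces
byte-identical tables.

## Known limitations

- The hypothesis is single-ligand; common-pharmacophore perception over a
  training set is not implemented.
- Scoring is rigid: conformational flexibility enters only through the
  enumerated conformer set, not through on-the-fly torsional optimization.
- The negative-cosine clamp in S_vec and the zero floor of the site term
  are the package's own conventions for cases the scoring formula leaves
  open; both are documented in the scoring section and covered by tests.
- Nominal (integer) masses are appropriate for the reported ESI values but
  not a substitute for exact monoisotopic masses.
- Predicted ADME properties beyond the Rule of Five (solubility, hERG,
  CNS activity, metabolic stability) are out of scope.
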