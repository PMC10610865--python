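# Methods

## Scope and data model

The package analyzes inter-chain residue contacts in multi-frame atomic
structures (multi-model PDB, one chain id per molecule, coordinates in Å,
author residue numbering preserved verbatim) and fits Hill dose–response
curves to normalized voltage-clamp currents. The trajectory container
assumes a constant topology across frames and performs no periodic-boundary
handling: real MD input is expected pre-imaged and whole. Binary trajectory
formats are out of scope; a desk-scale multi-model PDB is the interchange
format.

## Contact typing

Six contact types are detected per frame between atoms on *different*
chains (intra-chain analysis sits behind a flag). The geometric criteria
are community-standard interface definitions; every cutoff is configurable
(`ContactParams`), and the defaults are:

| type | criterion | default |
|---|---|---|
| H hydrogen bond | donor–acceptor heavy distance; D–H···A angle if hydrogens present, antecedent–D···A angle otherwise | ≤ 3.5 Å; ≥ 120°; ≥ 90° |
| I ionic bridge | oppositely charged group heavy atoms | ≤ 4.0 Å |
| D ion–dipole | charged atom to polar uncharged O/N | ≤ 4.0 Å |
| P π-cation | cation to aromatic ring centroid, within the axial cone | ≤ 6.0 Å; half-angle 45° |
| S stacking | ring-centroid distance; inter-normal angle in the parallel or T band | ≤ 5.5 Å; ≤ 30° or 60–90° |
| M hydrophobic | apolar–apolar heavy atoms (f > 0 on both) | ≤ 4.5 Å |

Angle conventions: undirected axes (ring normals, centroid–cation vectors)
are folded into [0°, 90°]; ring centroids and normals come from an SVD
best-fit plane. A donor whose bonded antecedent is absent from the file
passes on distance alone. Protonation is physiological and fixed: Arg/Lys
positive, Asp/Glu negative, His neutral (no pKa prediction). Like-charge
proximity emits no event but is logged, since formally repelling side
chains can still touch through their aliphatic stems — which the M detector
reports, hence "hydrophobic contacts between apparently polar/charged
residues" in interface tables.

Hydrophobicity is atomic: each template atom carries a Ghose–Crippen-style
constant *f* whose sign marks apolar (f > 0: aliphatic/aromatic carbons,
sulfur) versus polar (f ≤ 0: N, O, and carbons bonded into amide,
carboxylate or guanidinium groups). The magnitudes are approximate package
constants shipped as versioned JSON (`data/residue_chemistry.json`)
together with donors/acceptors/charges/ring sets for all twenty standard
amino acids; only the signs matter in the default binary M mode. An
optional molecular-hydrophobic-potential weighted mode scores a residue
pair as Σ f_a·f_b·exp(−α·d) over qualifying atom pairs (α = 0.5 Å⁻¹) and
emits one event when the score reaches a threshold; the binary mode is the
default because it is exactly testable.

The detectors are vectorized (scipy `cdist`); the test suite holds them to
*exact* event-set agreement with an independently coded pure-Python
all-pairs oracle (Newell ring normals rather than SVD; identical on planar
rings) on 1000 random two-chain frames, plus invariance under rigid-body
motion and chain relabeling and monotonicity under cutoff tightening.

## Lifetimes, averaging, filtering, maps

The relative lifetime of a (residue pair, type) is the number of frames
with at least one atom-level event of that type divided by the number of
frames analyzed; duplicate atom pairs within a frame count once. The
denominator is the full trajectory by default; an equilibration offset can
drop the first k frames. For symmetric multimers (e.g. three identical
ligand copies on a homotrimer), copies are renamed onto canonical chain
labels and averaged with missing contacts counted as lifetime 0 — all
copies share the trajectory length, so the denominator is common.

Threshold filtering keeps rows whose lifetime *strictly* exceeds the
per-type threshold (defaults: 10 % for H, I, D, P, S; 30 % for M),
matching the reporting convention of interface tables; a lifetime exactly
at the threshold drops. Filtering is idempotent and monotone in the
thresholds.

The interface map sums lifetimes of *all* types per (ligand residue,
receptor residue). The map is built from the unfiltered table: the
summation describes total interaction intensity, not the reporting
threshold, so sub-threshold contacts contribute. An inclusive receptor
window (e.g. 280–370) restricts the receptor axis to the interacting
stretch; the map total equals the windowed table total by construction.

Reports group rows by ligand residue (ascending author number) and
annotate each partner with type letters in the fixed order I, H, M, P, S;
ion–dipole (D) is pooled under I in reports — interface tables
conventionally use one letter for "ionic bridge or ion–dipole" — while
detectors and lifetime tables keep the two distinct. Region attribution
maps ligand residues onto named intervals; only the three-finger-toxin
'head' (residues 13–16) ships as a default, since loop boundaries vary
between toxins and belong in configuration.

## Hill dose–response model

Per-oocyte peak currents are normalized to that oocyte's control response
(signed amplitudes; the control self-normalizes to 1). The fitted curve is

    Y(c) = Bottom + (1 − Bottom) / (1 + 10^((X − LogIC50)·nH)),  X = log10(c/nM)

with Top fixed at 1 (the normalization defines the scale), Bottom free in
[0, 1] — the residual current at saturating inhibitor, so maximal
inhibition is 1 − Bottom — and nH > 0 internally. A decreasing inhibition
curve can be written with either sign of nH depending on whether the
exponent is (X − LogIC50) or (LogIC50 − X); published tables use both
conventions, so the package stores and reports slope magnitudes.
Zero-concentration points serve normalization QC and are excluded from
fits (the model's c → 0 limit is 1 by construction).

Fitting is least squares via lmfit with multi-start initialization
(LogIC50 at the 25/50/75 % quantiles of the observed X range × nH ∈
{0.8, 1.6, 3.2}; best chi-square wins); bounds are LogIC50 within the data
range ± 2 decades, Bottom ∈ [0, 1], nH ∈ [0.05, 10]. Standard errors come
from the asymptotic covariance (NaN when inestimable). A curve whose
observed response span is below 0.05 is flagged degenerate rather than
fitted silently, and non-convergence is reported in the result object, not
raised. Group parameters are reported as mean ± SEM over per-replicate
fits, matching the per-oocyte experimental design; a pooled fit over all
replicates is available but not the default.

Noiseless round trips (generate → refit) recover parameters to optimizer
tolerance across IC50 ∈ [50, 1000] nM, Bottom ∈ {0, 0.2, 0.4}, nH ∈
{1, 2, 3}, and for every published parameter triple shipped in
`asictox.params`.

### Group comparison

For each parameter (LogIC50, Bottom, nH) the package runs one-way ANOVA
(scipy) and Dunnett's many-to-one comparison against the reference
construct. IC50 is compared on the LogIC50 scale, where the sampling
distribution is far closer to normal. Dunnett adjusted p-values are
computed by Monte Carlo: the null distribution of max_j |T_j| over the
many-to-one contrasts is simulated (default 50 000 draws, seeded) from
independent group means and a pooled chi-square variance, and the adjusted
p of comparison j is the null exceedance probability of |t_j|. The null
distribution depends only on the group sizes and is cached and shared
across datasets. Monte-Carlo noise is clamped to the exact analytic
bounds raw p ≤ adjusted p ≤ min(k·raw p, 1); the bounds follow from the
max statistic and the union bound, so the clamp only removes simulation
jitter. Tiers follow the conventional cutpoints (\*, \*\*, \*\*\*, \*\*\*\*
at 0.05, 0.01, 0.001, 0.0001). scipy's analytic Dunnett implementation
serves as an independent cross-check in the tests, and empirical
family-wise error on null simulations stays at the nominal level.

## Synthetic generators

`generate_planted_trajectory` emulates one thing only: inter-chain residue
pairs that satisfy or violate a chosen contact criterion on a known
per-frame schedule. Each planted pair occupies its own site (60 Å apart)
built from minimal side-chain fragments chosen so that *only* the planted
type fires — e.g. a Lys amine opposite an Asp carboxylate placed at the
ionic cutoff minus the margin but with the donor angle broken, so no
hydrogen bond sneaks in. In "absent" frames the partner fragment is
displaced 25 Å, violating every criterion by far more than the margin; the
margin is validated ≤ 0.8 Å so that, in particular, a planted stacking
pair (centroids at 5.5 − margin Å) can never leak a hydrophobic contact
(atoms ≥ 4.7 Å apart). The default schedule is deterministic — present in
the first round(lifetime × n_frames) frames — so lifetime recovery is
exact to 1/n_frames; a Bernoulli schedule is available for stochastic
tests. Reusing a residue across specs would demand conflicting geometry
and is rejected. What this generator does *not* emulate: folded protein
context, solvent, membranes, correlated contact dynamics, or thermal
geometry fluctuation — passing tests certify the analysis pipeline, not
force-field realism.

`generate_dose_response` draws every replicate at every grid concentration
(each oocyte sees the full series), as prediction + additive Gaussian
noise on the normalized fraction, clipped to [0, 1.2] — normalized
currents can exceed control slightly through noise, but not without bound.
The default grid spans 0–10 µM over 8 points and includes the 370 nM and
1.1 µM single-dose test concentrations used in oocyte work; the default
replicate count is 5, the middle of the experimental n = 4–7 range; the
default noise sd of 0.05 reflects typical per-point SEMs of normalized
currents. Real recordings additionally show rundown, desensitization
carry-over and heteroscedastic noise, none of which are modelled.

`random_frame` builds random two-chain frames from the chemistry
templates — atoms follow their bond graph at ~1.45 Å, aromatic rings are
rigid planar polygons (the tryptophan indole is a single rigid planar
template so its fused rings stay coplanar) — used for the oracle
equivalence and invariance tests.

## Numerical choices and problem sizes

Strict inequalities at all distance/angle cutoffs and at the lifetime
thresholds are as documented above; boundary coincidences have measure
zero for continuous coordinates. Test problem sizes are chosen desk-scale:
500-frame planted trajectories for lifetime recovery, 1000 random frames
(≤ 60 atoms) for oracle equivalence, 6 replicates × 8 concentrations per
stochastic recovery cell, 2000 null simulations for family-wise error.

## Known limitations

* Contact criteria are declared defaults, not values inferred from any
  particular MD analysis package; results depend on them, which is why
  they are configurable and reported alongside outputs.
* The hydrophobicity constants are sign-faithful approximations; the
  weighted MHP score should be treated as a relative, not absolute, scale.
* No water-mediated bridges, metal coordination, halogen bonds, or
  protonation-state prediction.
* Hill parameter identifiability degrades at shallow slopes with high
  residual plateaus when the IC50 sits near the edge of the measured
  concentration range: with nH ≈ 1 and Bottom ≈ 0.4, the plateau lies
  at or beyond 10 µM, Bottom and LogIC50 become strongly correlated, and
  the per-replicate LogIC50 standard deviation approaches the
  Cramér–Rao limit of ~0.12–0.22 log units at 5 % noise. Median-of-few
  recovery inside 15 % is then not guaranteed by any estimator; widening
  the concentration range, steeper slopes, or more replicates are the
  remedies.
* Dunnett adjusted p-values are Monte-Carlo estimates; with the default
  50 000 draws their standard error is ≈ 0.001 near p = 0.05.
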