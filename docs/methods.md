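# Methods

## Scope and model

ptmlee implements a reference-based ("perturbation theory") linear
predictor of the signed enantiomeric excess ee_R for chiral-acid-catalyzed
intermolecular α-amidoalkylation reactions, together with the machinery
around it: Markov-chain molecular descriptors, chirality canonicalization,
reference-selection heuristics, Monte-Carlo condition enrichment,
chemical-space counting and a synthetic-data generator.

A reaction is five molecules (substrate, nucleophile, catalyst, solvent,
product), three conditions (temperature T in °C, time t in h, catalyst
loading in mol%) and an outcome (ee in %, product CIP label). The pairwise
model

    ee_R(q)_calc = ee_R(r)_obs + Σ_k a_k·ΔV_k(q,r) + Σ_k b_k·ΔD_k(q,r) + e0

corrects a known reference outcome for how the query differs in three
condition deltas and nine descriptor deltas on fixed property/role/group
slots (α:Cat/Cuns, α:Prod/HetNoX, EA:Prod/Csat, EA:Cat/HetNoX, χ:Nuc/Het,
χ:Cat/HetNoX, Vvdw:Sub/Tot, Zv:Cat/Cuns, Zv:Solv/Cuns). Conditions enter in
their printed units (°C, h, mol%) without standardization because the
published coefficients were fitted against raw deltas. A classic
reference-free variant applies the analogous twelve raw inputs of the query
alone; it is shipped as printed (including its implausibly steep loading
coefficient, 912.48 per mol%) with this warning as documentation.

## Chirality convention

Every reaction is expressed in the (R)-catalyst frame. Reactions run with
the (S)-catalyst are mirrored — the product CIP label flipped R↔S — after
which ee_R = +ee for an (R)-product, −ee for an (S)-product, 0 for a
racemate. The mirror step encodes the empirical symmetry that inverting
catalyst chirality inverts product configuration at unchanged magnitude.
Mirroring is an involution, |ee_R| preserves the observed ee, and per
reaction family the mean ee_R of R-products is ≥ 0 and of S-products ≤ 0 by
construction; these are tested invariants. All descriptors are achiral: the
chirality information lives exclusively in the sign of ee_R. This is valid
because the reactions create a single stereocenter.

## Descriptors

On the hydrogen-suppressed heavy-atom graph a Markov chain steps from atom
i to j with probability proportional to the Sanderson electronegativity of
the destination atom over the closed neighborhood (self + bonded atoms);
one chain is shared by all five properties. The descriptor is the double
mean

    D_k(m)_g = 1/(d_max·|g|) · Σ_{d=1..5} Σ_{a∈g} (Π^d p_k)_a

over walk depths d = 1..5 and the atoms of group g. Dividing by |g| as
well as d_max makes the descriptor intensive: every value is a convex
combination of atomic constants and hence bounded by the molecule's
property range, which keeps regression coefficients commensurable across
molecules of different size (an unnormalized group sum would scale with
atom count). An empty group contributes 0 so that, e.g., a hydrocarbon
solvent still yields a full 5 × 5 block.

Groups: a carbon is unsaturated iff aromatic or incident to a double or
triple bond; heteroatoms are all non-carbons; the non-halogen subset
excludes F/Cl/Br/I. Disconnected SMILES (salts) produce a block-diagonal
chain, so per-component computation agrees with whole-matrix computation.

The atomic parameter table (H, B, C, N, O, F, Si, P, S, Cl, Br, I) packages
standard literature constants — valence-electron counts, Bondi van der
Waals volumes (Batsanov radius for boron), Sanderson electronegativities,
CRC static polarizabilities and electron affinities (nitrogen's unbound
anion entered as 0 eV). The table is versioned and its version is recorded
in every descriptor block and report header, because descriptor values — 
and therefore any coefficients fitted against them — are meaningful only
relative to a parameter table and chain convention. The original predictor
was fitted against a descriptor implementation whose exact weighting is not
public; this package's engine defines its own documented dialect, so the
published coefficients define the functional form here but dataset-level
statistics printed for them are not reproduced, only recomputed
conditionally (see "Dataset-dependent checks").

## Reference selection

H1 picks the reference minimizing a norm of the 12-component PTO vector.
The default norm standardizes each component by its SD over all candidate
pairs and takes the L1 sum — scale-free across the heterogeneous units and
free of cross-term choices. The norm is a plug-in strategy (std_l1, std_l2,
or |model-predicted Δee|) and the chosen strategy is recorded in every
result, since any single choice is an interpretation. Components constant
across candidates (SD = 0) carry no ranking information and are left
unscaled. Ties break to the lowest reference id for determinism. The query
itself is always excluded (leave-self-out). H2 averages the per-reference
predictions over all references; because the model is linear this equals
the model applied to the mean PTO plus the mean reference ee_R, which is
cross-checked as an internal consistency test.

Predictions are clipped to the physical range [−100, 100] with a flag, and
the raw unclipped value is retained, since the linear form is unbounded.
The sign of the (clipped) prediction is the predicted product CIP label.

## Monte-Carlo enrichment

Synthetic records clone a family member's structures and ee_R and resample
only T, t and loading as min + u·step with u drawn uniformly from
{0..n_max}, n_max = ⌈(max − min)/step⌉, clamped at max (the ceiling makes
the clamp reachable, as the boundary rule implies). The dataset grids are
T ∈ [−78, 66] step 10 °C, t ∈ [1, 240] step 1 h, load ∈ [2, 30] step 1
mol%. The stream is MT19937 with an explicit, mandatory seed. ee_R is
copied unchanged on the stated assumption that one-step condition changes
do not measurably move the excess; descriptors are never perturbed.
Enrichment plans target rare families with counts small relative to the
base so family abundances shift by under ~2 percentage points — an
invariant the tests check on a 150-reaction base, since on very small
tables even one added record moves a singleton family's share more than
that.

## Chemical-space counting

N_comb multiplies the four molecule counts; N_exp multiplies the three
range/step quotients keeping full precision and rounding only the final
product (so 14.4 · 239 · 28 → 96,365 rather than truncating 14.4 first);
N_max = N_comb · N_exp. The conditions-scan server limits (T ∈ [−78, 70]
step 20, t ∈ [0.5, 72] step 1, load ∈ [2, 5] step 1) are deliberately
distinct from the dataset grids used for MC enrichment: the former bound
what a scan may request, the latter describe the curated data.

## Refitting

`fit_mlr` is ordinary least squares (statsmodels OLS) on the 12 PTOs plus
intercept, reporting R, R², SEE (residual standard error), F and
per-coefficient SE/t/two-sided p (no multiple-testing correction).
Rank-deficient designs raise an error naming constant columns. Pair
generation offers all n·(n−1) ordered pairs or a seeded uniform subsample;
pair-level splits may share reactions across splits, as pairwise designs
generally do.

## Synthetic data generator

Fixture tables draw role molecules from pools of ≤ 8-heavy-atom organics
(so the dense-matrix test oracle stays fast), conditions from the dataset
lattices, and set ee_R = base + c·(f_i − f_base) for a random baseline
reaction, where f is the 12-slot feature vector and c the generating
coefficients, plus optional Gaussian noise, clipped to [−100, 100] (a spec
error is raised if most values clip). Because pair deltas are differences
of per-reaction features, the pairwise relationship among generated
reactions is exactly linear with intercept 0; the shipped generating model
therefore has e0 = 0 and all 13 fitted parameters are identifiable.
Product configurations are assigned from sign(ee_R), so generated tables
satisfy the canonicalization invariants by construction.

For parameter-recovery studies, noise is added to the pair targets
(`perturb_pairs`), making pair errors independent as OLS standard errors
assume. Noise injected per reaction instead is shared by every pair
containing that reaction; the resulting error correlation makes OLS SEs
anti-conservative (observed empirically as recovery z-scores of ~7–12
versus ~2 under independent pair noise), which is why the recovery checks
use pair-level noise and why refit SEs on real pair data should be read
with that caveat.

What passing on synthetic data does not show: the generator reproduces the
schema and noise structure, not real reaction chemistry — no correlation
between structure and conditions, no family-specific mechanisms, no
heteroscedastic measurement error. Conclusions about the real literature
table require the table itself.

## Dataset-dependent checks

Statistics of the curated 332-reaction literature table (mean conditions,
refit correlations, heuristic R² values) depend on third-party
supplementary data that is not vendored and on the original descriptor
dialect. `ptmlee.benchmarks.dataset_benchmarks(path)` computes them when a
table CSV is supplied and returns a structured "data unavailable" report
otherwise; the test suite exercises this machinery on a synthetic
stand-in table and never asserts the published values.

## Problem sizes and numerical choices

The shipped verification runs use 100 oracle molecules, 1,000 antisymmetry
pairs, 2,000 fitted pairs (80 reactions), 10,000 MC draws per grid and
60-reaction heuristic tables — sizes at which every quantity is stable to
well inside its tolerance. Oracle agreement is asserted at 1e-10 (iterative
propagation vs explicit matrix powers differ only by float association),
antisymmetry at 1e-9 (exact in IEEE arithmetic), noise-free recovery at
1e-6, noisy recovery at 3 reported SE. Structural scans refuse requests
beyond a configurable cap (default 10,000 combinations) rather than
attempting them.

## Known limitations

- Descriptor dialect: printed coefficients came from a different descriptor
  implementation; absolute predictions for real reactions with this
  package's engine will differ from the original server's.
- The classic model is documented but not recommended; its printed scale is
  implausible and it provides no reference traceability.
- CIP labels are inputs, never computed from 3D structure; product SMILES
  is required, not derived from substrate + nucleophile.
- Only single-stereocenter reactions are covered by the sign convention.
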