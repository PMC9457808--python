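# Methods

## Model and response

The package implements a QSTR analysis for carbamate acute oral toxicity.
The response is log(1/C) = −log₁₀(LD₅₀/MW), with LD₅₀ in mg/kg and MW in
g/mol, so C is the lethal dose on the mmol/kg scale and larger values mean
higher toxicity. The model is ordinary multiple linear regression on ten
descriptors; the published coefficient vector is frozen in
`modeling.PUBLISHED_MODEL` and used only for prediction, never refit.

Fitting goes through a QR/orthogonal factorisation (statsmodels OLS on an
explicit intercept column), not the normal equations. Reported statistics:

- R² = 1 − SSE/SST on the fitted data; RMSE = √(SSE/n) (no degrees-of-freedom
  correction, matching the convention of the validation literature this
  follows); MAE = mean |residual|.
- Q²_LOO = 1 − PRESS/SST with PRESS from the exact hat-matrix shortcut
  e_i/(1−h_ii). The explicit n-fold refit loop is retained as an
  independent route (`q2_loo(..., method="refit")`) and the two agree to
  1e−10 in tests. A model is flagged acceptable when Q²_LOO > 0.5.
- k-fold CV (default k = 5): rows are shuffled by seed and split into
  near-equal folds; out-of-fold R² uses the held-out fold's own mean.
  Because the study's fold-assignment procedure is not fully specified, a
  second mode (`mode="median_r2"`) draws 25 candidate assignments and keeps
  the one with the median mean-R², for sensitivity checks.
- Standardized coefficients are coeff·sd(x)/sd(y) with population
  (n-denominator) standard deviations; p-values are two-sided t-tests with
  no multiple-testing correction (each is compared to 0.05 individually).

The train/test split holds out int(0.15·n) compounds drawn uniformly
without replacement — 26 of 178, leaving 152 training compounds, which is
the split the published applicability-domain cutoff h\* = 3(p+1)/n =
33/152 ≈ 0.217 presupposes.

## Applicability domain

Leverages h_i = x_iᵀ(XᵀX)⁻¹x_i are computed from the thin QR factorisation
of the intercept-augmented training design; new compounds are projected
with the training (XᵀX)⁻¹. A compound is in-domain when h ≤ h\* and an
outlier when its standardized residual (residual / training RMSE) exceeds
3 in magnitude; `williams_data` exports the table behind the Williams plot
and `plot_williams` renders it.

## Descriptor conventions

Descriptor software differs in conventions the descriptor names do not pin
down. The choices here (all overridable via `config.Conventions`):

- **Unsat** = NRG₅₆₇ + nDB + 2·nTB + (nAB+1)/2. The literal aromatic term
  gives 0.5 to molecules with no aromatic bonds; by default the term is 0
  when nAB = 0 (a saturated molecule has zero unsaturation), and
  `unsat_literal = true` restores the printed formula. Ring count uses the
  smallest set of smallest rings; aromatic bonds are counted once and are
  excluded from the double-bond count.
- **Unsat-p** divides Unsat by the number of heavy atoms that are not
  halogens (F, Cl, Br, I, At) and carry no bonded hydrogen; when that
  denominator is zero the ratio is undefined and the corresponding DLS_05
  rule counts as failed. DLS_05 = (satisfied rules)/2 with rule 1
  nNO/nC3 ∈ [0.10, 1.80] (inclusive) and rule 2 Unsat-p ≤ 0.43.
- **LOC** prunes all degree-1 vertices of the heavy-atom graph in
  simultaneous rounds; the removal-round class sizes (plus the surviving
  core) partition the heavy atoms and LOC is the Shannon entropy (bits) of
  that partition. It is bounded by log₂(A).
- **nROCON** is the binary presence of a non-aromatic carbon bonded to the
  sp³ oxygen of a C–O–C(=O)–N fragment; carbamic acids (H on that oxygen)
  and oxime carbamates (N on that oxygen) score 0.
- **B05[X-Y]** is 1 iff some X,Y atom pair sits at shortest-path distance
  exactly 5 on the hydrogen-depleted graph.
- **SpPosA_RG** builds G_ij = 1/r_ij² (Å⁻², zero diagonal) over heavy atoms
  and returns the sum of eigenvalues above 1e−10·max|λ| divided by the
  heavy-atom count; `sppos_include_h` adds hydrogens. Atom pairs closer
  than 1e−6 Å are a geometry error.
- **H4m** uses the molecular influence matrix H = M(MᵀM)⁻¹Mᵀ of the
  centered coordinates (pseudo-inverse for planar/linear geometries, where
  trace(H) = rank(M) < 3), weights m_i/m_C, and sums H_ij·w_i·w_j over
  unordered pairs at topological distance 4 with H_ij > 0. Heavy atoms
  only by default (`getaway_include_h` adds hydrogens, with distances
  measured on the same atom set); fewer than five atoms gives 0.
- **Conceptual DFT**: I = −E_HOMO, A = −E_LUMO (Koopmans),
  μ = −(I+A)/2, η = (I−A)/2, ω = μ²/2η. The η = I−A convention (factor 2)
  is available as `hardness_factor = full`. Orbital energies are ingested
  as printed, with no sign correction.

Whether the reference descriptor software includes hydrogens in the
GETAWAY/geometry matrices, and its exact SpPosA normalisation, is not
documented; exact numeric parity with it is therefore not promised — the
convention flags exist so either choice can be reproduced. On the embedded
fixture geometries the computed SpPosA_RG values (≈0.28–0.33) sit somewhat
below the worked-example range (0.415–0.438), consistent with geometry- and
convention-level differences; tests treat the corridor as a soft warning.

Structures are parsed with RDKit's default aromaticity and ring perception,
which is kept fixed because the aromatic-bond count feeds Unsat, nROCON and
B05. Multi-fragment inputs (salts) keep the largest heavy-atom fragment
with a logged warning. Geometric descriptors require an input 3D geometry
(SDF); the package never generates conformers silently, because embedded
geometries do not reproduce quantum-chemically optimised ones. Molecules
without coordinates get missing values (never silent zeros) in the
descriptor table, and rows with missing model descriptors are excluded from
fitting with a logged count, never imputed.

## Genetic-algorithm subset selection

Chromosomes are fixed-size descriptor subsets. Fitness is Q²_LOO (default)
or R² of the OLS fit; selection is tournament (size 3), crossover keeps the
parents' intersection and samples the symmetric difference uniformly before
repairing to the fixed size, mutation swaps one member, and one elite
survives each generation. Defaults: population 100, generations 200,
crossover 0.8, mutation 0.1 — conventional values, exposed in `GAConfig`;
the planted-recovery tests and the acceptance script run population 60 ×
60 generations, which already recovers 10/10 planted descriptors across
seeds on study-sized data. Results are deterministic given the seed, and a
hall of fame of the 10 best unique subsets is returned (ties keep
first-seen order).

## Synthetic data

`gen_linear_dataset` emulates the statistical shape of the study's
descriptor matrix: latent Gaussians with a *fixed* population correlation
structure (the correlation matrix is a property of the emulated descriptor
space, so it does not vary with the sampling seed), optional binary columns
obtained by thresholding at quantiles matched to target frequencies, and a
linear response with Gaussian noise. The paper-regime preset uses n = 178,
the published ten-descriptor correlation matrix as the population structure
(max pairwise |r| = 0.45), three binary columns with frequencies 0.27 /
0.94 / 0.36 echoing the worked-example nROCON, B05[C-N] and B05[N-O]
columns, planted coefficients equal to the published standardized-effect
ladder, and noise sd 0.484. The near-always-1 column is kept at 0.94
rather than higher because a singleton minority class (appreciably likely
at n = 178 above 0.97) has leverage 1 and makes the LOO residual
undefined; 0.94 preserves the near-degenerate-column hazard the prefilter
must tolerate while keeping validation well defined.

The noise sd was calibrated once by `calibrate_paper_noise`: the signal
variance is estimated by simulation at zero noise and the population
target ρ² is back-solved from the in-sample target R² = 0.6584 through the
degrees-of-freedom inflation 1−E[R²] ≈ (1−ρ²)(n−p−1)/(n−1). Under these
conditions the 50-seed mean full-data R² is ≈ 0.65; individual seeds
scatter with sd ≈ 0.04, which is the sampling noise of R² itself at
n = 178 (≈ √(4ρ²(1−ρ²)²/n)) — no generator can make every seed's R² land
within a ±0.06 band at this sample size, so ensemble statements are made
about means.

What the simulator does *not* emulate: real descriptor marginals (counts,
bounded indices), heteroscedastic or non-Gaussian toxicity noise,
measurement error in LD₅₀, and any structure–descriptor coupling. Passing
tests on simulated data therefore validate the statistical machinery
(estimation, validation identities, subset recovery, domain logic), not
the chemistry of any particular compound set.

`toy_carbamate_set` provides 26 hand-authored molecules (O-aryl, O-alkyl
and oxime carbamates, amines, alcohols, hydrocarbons, heteroaromatics)
whose nCt, nROCON, B05 and DLS_05 values were assigned by hand structural
analysis and serve as the oracle for the descriptor code. Example
derivations: for propoxur (2-isopropoxyphenyl N-methylcarbamate), the
bond path N→C(=O)→O→C1→C2→O(ether) has length 5, so B05[N-O] = 1; for
ethyl N,N-dimethylcarbamate the farthest carbon from the nitrogen is 4
bonds away (the only 5-bond path connects two carbons), so B05[C-N] = 0.
Fixture coordinates are frozen literals from a one-time seeded
distance-geometry embedding with force-field refinement — deliberately
*not* regenerated at test time, and not a substitute for optimised
geometries. The worked-example table of the published model (11 compounds
with descriptors, response and set labels) is transcribed verbatim and
checksum-tested.

## Numerical and degenerate-input choices

- Eigenvalue positivity threshold λ > 1e−10·max|λ| avoids counting
  numerical zeros in SpPosA_RG.
- A leverage of 1 (hat shortcut denominator 0) raises an error rather than
  returning infinities.
- A constant response has SST = 0: R² and Q² are reported as 0.
- Rank-deficient designs raise an error naming the collinear columns.
- Prefilter ties (equal |correlation to y|) drop the later column in input
  order; on the worked-example rows the constant B05[C-N] column is dropped
  by the constant-column rule and the remaining nine descriptors survive
  the 0.90 screen (max pairwise |r| 0.863).
- The 15% test fraction is truncated, not rounded: int(0.15·178) = 26 is
  the only choice consistent with the published h\* = 33/152.

## Known limitations

- Quantum-chemical inputs (orbital energies, Hirshfeld charges) must be
  supplied; the package computes conceptual-DFT indices from them but
  cannot produce them.
- Geometric descriptors depend on the input geometry; values from
  embedded conformers differ systematically from optimised structures.
- Bit-for-bit parity with commercial descriptor software is out of scope;
  the convention flags bound, but do not eliminate, the ambiguity.
- The full 178-compound descriptor table of the original study is not
  bundled, so the published full-data fit statistics cannot be recomputed
  here; the study-regime simulation ensemble and the worked-example
  predictions are the reproducible surface.
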