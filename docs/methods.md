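# Methods

This note documents the models behind each pipeline stage, the parameter
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical choices that a user extending the package
should know about.

## Sequence properties

All composition statistics operate on the canonical 20-letter alphabet.
Non-canonical letters (X, B, Z, U, gaps, stops) are dropped with a logged
warning before analysis: composition fractions are undefined for ambiguity
codes, and silently remapping them would bias the entropy and charge
statistics. A sequence that becomes empty after cleaning is an error.

**Sequence entropy** is the Shannon entropy of the composition in bits
(base 2), so its ceiling is log2(20) = 4.32 for a perfectly uniform
composition and its floor 0 for a homopolymer. Base 2 is fixed because the
scan threshold (3.83 bits, below) is calibrated on that scale.

**Isoelectric point** solves Q(pH) = 0 by bisection on [0, 14] to
|Q| < 1e-6, where Q sums Henderson–Hasselbalch fractional charges of D, E,
C, Y, H, K, R and the two termini. The pKa table is the EMBOSS set by
default and fully configurable — pI values shift by a few tenths of a pH
unit between published tables, so comparisons should always use one table.
Degenerate sequences whose titratable groups are all basic (all acidic)
under the active table have no zero crossing; the declared cap 14 (0) is
returned with a warning rather than an error, since such sequences do occur
in sliced domain sets.

**Folding propensity** is a charge/hydropathy discriminant,
FP = c1·⟨H⟩ − |⟨R⟩| − c0, with ⟨H⟩ the mean Kyte–Doolittle hydropathy
rescaled to [0, 1] and ⟨R⟩ the mean formal charge per residue at neutral pH
(K, R = +1; D, E = −1; H = 0, its model pKa being below 7). The defaults
c1 = 2.785, c0 = 1.151 place the folded/disordered boundary along the
classic charge–hydropathy discrimination line, with FP > 0 predicting
folded. Both coefficients, the hydropathy scale and the charge assignment
are keyword-configurable because published variants of this family of
predictors differ in their exact constants; conclusions in this pipeline
rest on the sign and on differences between domain classes, which are robust
to that choice.

**Z-scores** are (value − μ)/σ against a pluggable reference population.
`ReferencePopulation.from_sequences` fits μ and σ for every property from
any FASTA set, so a real proteome-scale reference (e.g. an *E. coli*
solubility dataset) can be dropped in; the package ships only a synthetic
stand-in (see below).

## Fab curation

Sequences are taken from observed ATOM-record residues in author order, not
SEQRES: every residue that enters the statistics must have coordinates for
the structure-based stages, and author numbering in deposited files is too
unreliable to define search windows. Positions are therefore 1-based indices
into the observed sequence. Common modified residues (MSE, SEC, PTR, ...)
map to their parent amino acid; HETATM records are ignored.

The stages, in order:

1. **Chain selection** — exactly one H and one L chain; files missing either
   are rejected, duplicated chain identifiers are ambiguous and rejected.
2. **Interquartile length filter** — keep records with heavy and light chain
   lengths inside [Q1, Q3] (inclusive), quartiles computed by linear
   interpolation over the input set. Inclusive bounds reproduce a
   "between these values" selection; on a real Fab snapshot the bounds come
   out near 219–228 (heavy) and 213–218 (light).
3. **Motif split** — the heavy chain splits at the first `VS[SA]` match
   whose first residue lies in positions 110–130; the light chain at the
   first `E[LIV]KR` match in 100–115, falling back to `TVL[GSA]` only when
   the first pattern finds nothing (the fallback pattern exists to rescue
   otherwise-lost records, so it must not pre-empt the primary one). The
   motif's first residue *starts* the constant domain; the sources behind
   the windows do not state motif ownership, so this choice is recorded in
   the report and can be flipped. Ties break to the leftmost match.
4. **Domain length filter** — all four domains within ±10 residues
   (inclusive) of their class mean over the current set. Because the means
   are recomputed from the surviving set, re-application can shrink the set
   further; the pipeline applies it once.

Every exclusion carries a reason code in the `CurationReport`, whose stage
counts are monotonically non-increasing and byte-identical across reruns on
the same input.

## Continuum electrostatics

The model treats every ionisable group as sited at the water-accessible
surface, interacting through a Debye–Hückel screened Coulomb potential with
the dielectric of bulk water:

    W_ij = C exp(−κ r_ij) / (ε_r r_ij),  C = e² N_A / (4π ε0) ≈ 1389.35 kJ·Å/mol

Defaults: ε_r = 78.4, T = 298.15 K, I = 0.15 M (κ ≈ 0.127 Å⁻¹ from the
standard Debye expression, no ion-exclusion radius). There is no dielectric
boundary, desolvation/Born term, or conformational sampling — by
construction, so that the folded/unfolded difference is purely the
interaction term. The unfolded reference is the same site set with all
W_ij = 0, titrating at model pKas (Asp 4.0, Glu 4.4, His 6.3, Lys 10.4,
Arg 12.0, Tyr 9.6, Cys 8.3, N-term 7.5, C-term 3.8; configurable).

Site positions are charged-group centroids (Asp OD1/OD2, Glu OE1/OE2,
Lys NZ, Arg CZ, His ND1/NE2 midpoint, Tyr OH, Cys SG, termini N and
C/OXT); a residue missing those atoms falls back to its centroid with a
warning. Cys pairs with SG–SG < 2.5 Å are treated as disulfide-bonded and
excluded from titration. Pair distances below 2.0 Å are clamped with a
warning (the point-charge form diverges); coincident sites are an error.

**Exact route** (N ≤ 20 sites): the partition function is summed over all
2^N protonation microstates with energy
E(x) = ln10·RT·Σᵢ(pH − pKaᵢ)·protᵢ + Σ_{i<j} W_ij qᵢqⱼ, where q = prot − 1
for acids and q = prot for bases. ΔG_chg(pH) = −RT ln(Z/Z_free); per-site
pKas are interpolated at half-protonation on a pH grid (0–14, step 0.25 by
default; ΔG is evaluated at exactly pH 7).

**Monte Carlo route** (larger N): Metropolis sampling over single-site flips
(one attempt per site per sweep) plus paired flips for strongly coupled
pairs (|W_ij| > 2 kJ/mol), which decorrelate salt bridges that single flips
cross only through an unfavourable intermediate. ΔG_chg comes from
thermodynamic integration over a coupling λ scaling all W_ij:
dG/dλ = ⟨U_int⟩_λ, integrated on a 5-point Gauss–Legendre λ ladder.
Gauss–Legendre nodes (rather than an evenly spaced ladder) were chosen
because ⟨U_int⟩_λ is smooth and the quadrature error of an even 5-point rule
would not be covered by the reported Monte-Carlo standard error; the ladder
is configurable. Standard errors come from 25-batch means; the protonation
SE is floored at the rule-of-three resolution 3/n for sites never observed
to flip (an unobserved transition over n samples bounds the rate near 3/n,
it does not make it zero). A result whose ΔG standard error exceeds a
tolerance (1 kJ/mol default) is flagged `converged=False` rather than
silently returned. Fixed seeds give bit-identical output.

A note on validating MC against the exact route: a 3-standard-error band is
a 99.73% band, so across the ~350 individual comparisons the test suite
makes, one or two exceedances are *expected* from a correct sampler (and the
SE is itself a 25-batch estimate, widening the tails slightly). The suite
therefore asserts the band together with its own error rate — at most 2.5%
of comparisons beyond 3 SE and none beyond 6 SE — instead of demanding an
outcome that correct code would fail most of the time.

**Dimerisation**: ΔΔG = ΔG(AB) − ΔG(A) − ΔG(B), with an atom-count identity
check between the complex and its subunits. The same subtraction scheme is
used for surface burial.

## Solvent-accessible surface area

Shrake–Rupley point sampling: each atom's van der Waals sphere is expanded
by the probe radius (1.4 Å) and covered with a golden-section Fibonacci
lattice (960 points by default); the accessible area is the exposed-point
fraction times the expanded-sphere area. Radii are a standard per-element
protein set (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å; configurable). Polar
area is the N/O (plus attached polar H) contribution; S counts as non-polar
by default since its partition is convention-dependent. Neighbour search
uses a k-d tree.

Accuracy: an isolated sphere is exact to <0.5% at 960 points; two-sphere
overlaps match the analytic spherical-cap areas to ~1%. Totals are exactly
translation-invariant (the lattice rides on the atom centres) but
rotation-invariant only to sampling resolution (~1%), as for any fixed-mesh
implementation. The accessible surface — not the molecular (Connolly)
surface — is what "burial" means throughout.

## The CH1-likeness scan

The scan vector components are raw composition fractions, not z-scores: the
differenced-cosine construction is defined on the composition simplex, and
the z-score presentation of per-amino-acid panels is display-only. For a
domain X, cos(X) compares (X − CL_REF) with (CH1_REF − CL_REF); CH1_REF and
CL_REF are inputs (single representative sequences or explicit composition
vectors). A domain passes iff cosine > 0.3 *and* entropy < 3.83 bits, both
strict. Results are ranked by cosine descending with the id as
deterministic tie-break; a domain coinciding with CL_REF has an undefined
direction and is reported with a NaN cosine, ranked last, never passing.

## Synthetic data: what it does and does not show

The generators are pure functions of (parameters, seed) and their outputs
are guaranteed to satisfy the preconditions of the stage they feed.

- **Fab-like chain pairs** plant the interdomain motifs at requested
  in-window positions and exclude the motif-initiating letters from the rest
  of the window, so the planted occurrence is the unique in-window match.
  Chain lengths default to the interquartile bounds of a curated Fab set
  (219–228 / 213–218). Outside the motif machinery the sequences are
  uniform-random — they have no framework conservation, so curation tests
  exercise the split logic, not motif discovery in realistic backgrounds.
- **Toy structures** place charged-group centroids exactly at requested
  coordinates with minimal backbone scaffolds; they make no attempt at Ig
  fold geometry, so electrostatics/SASA tests validate the energetics and
  geometry code, not biological magnitudes.
- **Reference populations** control the K−R distribution by construction
  (drawn normal deviates standardised to the target mean/SD before sequence
  assembly, so realised moments match within rounding); all other properties
  take whatever values the random background realises, and the fitted
  (μ, σ) table is returned with the sequences.
- **IgSF cohorts** draw per-sequence compositions from Dirichlet
  distributions around class profiles and sequences multinomially from
  those. The CH1-like profile is the CL-like profile pushed along a fixed
  direction (enriched P, S, T, V, G; depleted D, E, F, I, Q, R, Y — the
  composition signature separating CH1 from CL) and sharpened to ~3.5 bits,
  so planted members sit inside the double threshold with wide margins,
  while the near-uniform background (concentration 300, lengths 100–140)
  stays above ~3.9 bits. Passing the planted-recovery test therefore shows
  the scan geometry and thresholds work as designed; it says nothing about
  recovering CH1-like domains in a real IgSF snapshot, where margins are
  narrower and compositions are not Dirichlet.

## Problem sizes and runtime

The test suite and the acceptance script run everything at desk scale: 50
random titration systems of 2–12 sites (8000 MC sweeps, 1000 equilibration),
a 205-domain scan cohort, 50 synthetic Fabs, and 960–2000-point SASA
fixtures. These sizes give the statistical margins discussed above while
keeping a full run to a couple of minutes; all of them are ordinary keyword
arguments, so larger runs are a caller's choice.

## Known limitations

- The electrostatic model has no desolvation or dielectric boundary, so
  buried charges are treated as if solvent-exposed; absolute ΔG values for
  real domains carry the corresponding systematic, and comparisons between
  domains are the intended use.
- pI and folding-propensity constants are table-dependent; defaults are
  documented above and configurable.
- Curation assumes the H/L chain naming convention and will miss
  non-standard depositions by design.
- The quartile and domain-length filters depend on the input ensemble, so
  dataset-level counts are snapshot-dependent by construction.
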