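# igfab

Sequence-composition and continuum-electrostatics analysis of antibody Fab
domains and the wider immunoglobulin superfamily (IgSF).

## The problem

The CH1 domain of an IgG heavy chain is an atypical intrinsically disordered
protein: alone it does not fold, and it only acquires its Ig fold on pairing
with the light-chain CL domain — the interaction that couples antibody
assembly to secretion through BiP-mediated ER retention. Yet standard
disorder predictors call CH1 folded. This package re-implements, as a tested
reusable pipeline, an analysis that asks *which sequence and structure
properties actually distinguish CH1* from the other Fab domains (VH, VL, CL),
and then scans the human IgSF for non-antibody domains that share the CH1
signature and may likewise couple folding to assembly.

It is aimed at structural bioinformaticians and antibody engineers who want
the individual stages — domain curation, composition profiling, titration
energetics, surface burial, the CH1-likeness scan — as composable library
functions with a thin CLI.

## What it computes

**Sequence properties** (module `igfab.seqprops`). For a domain sequence with
composition fractions $f_a$:

- sequence entropy $S = -\sum_a f_a \log_2 f_a \in [0, \log_2 20 = 4.32]$ bits;
- lysine-minus-arginine content $K{-}R = 100(f_K - f_R)$, a solubility
  correlate;
- aromatic content $100(f_F + f_W + f_Y)$;
- isoelectric point pI by bisection on the Henderson–Hasselbalch net charge
  (EMBOSS pKa set by default, termini included);
- a charge/hydropathy folding propensity
  $FP = c_1\langle H\rangle - |\langle R\rangle| - c_0$ (Kyte–Doolittle
  hydropathy rescaled to $[0,1]$; $FP > 0$ predicts folded);
- each property optionally reported as a z-score
  $(x - \mu)/\sigma$ against a reference population (e.g. an *E. coli*
  solubility proteome; a synthetic stand-in ships with the package).

**Fab curation** (`igfab.curation`). From PDB-format files: retain exactly
the H and L chains; filter by interquartile chain length; split each chain at
the conserved interdomain motif — heavy `VS[SA]` with first residue in
positions 110–130, light `E[LIV]KR` then `TVL[GSA]` in 100–115 — into
VH/CH1 and VL/CL; filter domains to ±10 residues of the class mean; emit
domain and dimer (VL:VH, CL:CH1) structures and sequences.

**Charge interactions** (`igfab.electrostatics`). Ionisable sites (D, E, H,
K, R, Y, C sidechains plus termini) interact through a Debye–Hückel screened
Coulomb potential $W_{ij} = C\,e^{-\kappa r_{ij}}/(\varepsilon_r r_{ij})$
with the dielectric of water. Protonation states are sampled exactly (all
$2^N$ microstates) or by Metropolis Monte Carlo with thermodynamic
integration; the ionisable-group interaction free energy at pH 7,
$\Delta G_{\mathrm{chg}} = -RT\ln(Z/Z_{\mathrm{free}})$, estimates the charge
contribution to folded-state stability (negative = stabilising), and
$\Delta\Delta G = \Delta G(AB) - \Delta G(A) - \Delta G(B)$ the contribution
to dimerisation.

**Surface burial** (`igfab.sasa`). Shrake–Rupley solvent-accessible surface
area with a polar/non-polar partition;
interface burial $= \mathrm{SASA}(A) + \mathrm{SASA}(B) - \mathrm{SASA}(AB)$.

**The CH1-likeness scan** (`igfab.igsf`). For each IgSF domain composition
$X$, the cosine between the differenced vectors $(X - CL_{REF})$ and
$(CH1_{REF} - CL_{REF})$ measures whether $X$ deviates from CL in the same
direction CH1 does; combined with low sequence entropy it forms the double
threshold (cosine $> 0.3$, entropy $< 3.83$ bits) that flags CH1-like
candidates.

**Synthetic data** (`igfab.synthetic`) generates fixtures for every stage:
motif-bearing Fab-like chain pairs, toy structures with ionisable groups at
controlled coordinates, reference populations with controlled moments, and
IgSF cohorts with planted CH1-like members.

## Worked example

```python
import numpy as np
from igfab import (DomainSequence, SolventModel, composition,
                   sequence_entropy, enumerate_titration,
                   extract_ionizable_sites, scan_igsf)
from igfab.synthetic import CohortSpec, generate_igsf_cohort

# entropy extremes: uniform 20-letter composition vs homopolymer
print(round(sequence_entropy(composition(DomainSequence("u", "ACDEFGHIKLMNPQRSTVWY"))), 2))
# 4.32   (log2 20 — the entropy ceiling)
print(sequence_entropy(composition(DomainSequence("h", "AAAA"))))
# 0.0

# a planted-cohort scan: 5 CH1-like members among 200 background domains
domains, ch1_ref, cl_ref, truth = generate_igsf_cohort(CohortSpec(seed=0))
hits = [r for r in scan_igsf(domains, ch1_ref, cl_ref) if r.passes]
print([h.domain_id for h in hits])
# ['CH1LIKE000:1-126', 'CH1LIKE002:1-100', 'CH1LIKE003:1-134',
#  'CH1LIKE001:1-120', 'CH1LIKE004:1-117']   (exactly the planted members,
# ranked by cosine; every background domain fails the double threshold)
```

From the shell, against a toy salt bridge (an Asp and a Lys with
charged-group centroids 4 Å apart):

```sh
igfab simulate --seed 4 -o fixtures
igfab titrate fixtures/salt_bridge.pdb
# 4 sites; dG_charge(pH 7) = -13.64 kJ/mol (exact)
```

The negative sign says the ion pair (plus the nearby termini of this tiny
peptide) stabilises the "folded" arrangement, exactly the quantity the
pipeline reports per Fab domain and per dimer interface.

## Scope notes

Structure retrieval (PDB text search, SAbDab queries, UniProt) is out of
scope: structure files, CDR annotation tables and reference sequence sets are
consumed as inputs. No Poisson–Boltzmann solver, dielectric boundary or
desolvation term is included — the electrostatic model deliberately treats
every ionisable group as solvent-exposed. Multiple sequence alignment and
phylogenetics are likewise out of scope. See `docs/methods.md` for the model
assumptions, parameter defaults and limitations.
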