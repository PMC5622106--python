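"""Debye-Hückel continuum electrostatics of ionisable groups.

Ionisable sites taken from a structure interact through a screened Coulomb
potential with the dielectric of bulk water; protonation states are sampled
either by exact enumeration of all 2^N microstates or by Metropolis Monte
Carlo. The ionisable-group interaction free energy at pH 7 estimates the
contribution of charge interactions to folded-state stability, and a
subtraction scheme gives the contribution to dimerisation.

The model places every site at the solvent-accessible surface: there is no
dielectric boundary, desolvation penalty or conformational sampling. The
unfolded-state reference is the same set of sites with all interactions
switched off, titrating at their model pKas, so the folding contribution is
purely the interaction term.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.constants import Avogadro, Boltzmann, elementary_charge, epsilon_0
from scipy.special import logsumexp

from ._pdb import residues_of

logger = logging.getLogger(__name__)

#: Gas constant in kJ/mol/K.
R_KJ = 8.31446261815324e-3
LN10 = math.log(10.0)

#: e^2 N_A / (4 pi eps_0), in kJ * Angstrom / mol: the Coulomb energy of two
#: unit charges 1 Angstrom apart in vacuum.
COULOMB_KJ_A = (elementary_charge ** 2 * Avogadro
                / (4.0 * math.pi * epsilon_0)) * 1e10 / 1000.0

#: Model (intrinsic) pKas; configurable.
MODEL_PKA = {
    "Asp": 4.0, "Glu": 4.4, "His": 6.3, "Lys": 10.4, "Arg": 12.0,
    "Tyr": 9.6, "Cys": 8.3, "Nterm": 7.5, "Cterm": 3.8,
}
ACIDIC_TYPES = frozenset({"Asp", "Glu", "Tyr", "Cys", "Cterm"})
BASIC_TYPES = frozenset({"His", "Lys", "Arg", "Nterm"})

#: Atoms whose centroid locates the charged group of each site type.
CHARGED_GROUP_ATOMS = {
    "Asp": ("OD1", "OD2"), "Glu": ("OE1", "OE2"), "Lys": ("NZ",),
    "Arg": ("CZ",), "His": ("ND1", "NE2"), "Tyr": ("OH",), "Cys": ("SG",),
}
RESNAME_TO_TYPE = {"ASP": "Asp", "GLU": "Glu", "LYS": "Lys", "ARG": "Arg",
                   "HIS": "His", "TYR": "Tyr", "CYS": "Cys"}

DEFAULT_PH_GRID = np.arange(0.0, 14.0 + 1e-9, 0.25)

EXACT_ENUMERATION_CAP = 20


@dataclass(frozen=True)
class IonizableSite:
    """One titratable group: a sidechain or a chain terminus."""

    name: str              # e.g. "H:ASP45" or "H:Nterm"
    site_type: str         # Asp, Glu, His, Lys, Arg, Tyr, Cys, Nterm, Cterm
    model_pKa: float
    position: np.ndarray   # charged-group centroid, Angstrom

    def __post_init__(self) -> None:
        if not (0.0 < self.model_pKa < 14.0):
            raise ValueError(f"model pKa {self.model_pKa} outside (0, 14)")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)

    @property
    def is_acid(self) -> bool:
        return self.site_type in ACIDIC_TYPES

    @property
    def charge_offset(self) -> float:
        """q = protonation + offset: -1 for acids, 0 for bases."""
        return -1.0 if self.is_acid else 0.0


@dataclass(frozen=True)
class SolventModel:
    """Aqueous solvent: dielectric, ionic strength, temperature, screening."""

    eps_r: float = 78.4
    ionic_strength: float = 0.15  # mol/L
    temperature: float = 298.15   # K

    def __post_init__(self) -> None:
        if self.eps_r <= 0:
            raise ValueError("eps_r must be > 0")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be >= 0")

    @property
    def kappa(self) -> float:
        """Debye screening constant, 1/Angstrom; zero at zero ionic strength."""
        if self.ionic_strength == 0.0:
            return 0.0
        # kappa^2 = 2 e^2 N_A (1000 I) / (eps0 eps_r kB T), SI, then to 1/A
        k2 = (2.0 * elementary_charge ** 2 * Avogadro * 1000.0
              * self.ionic_strength
              / (epsilon_0 * self.eps_r * Boltzmann * self.temperature))
        return math.sqrt(k2) * 1e-10

    @property
    def RT(self) -> float:
        """kJ/mol."""
        return R_KJ * self.temperature


@dataclass
class TitrationResult:
    """Titration curves, interpolated pKas, and the interaction free energy."""

    sites: list[IonizableSite]
    ph_grid: np.ndarray
    mean_protonation: np.ndarray       # (n_sites, n_ph)
    pkas: np.ndarray                   # pH of half-protonation, nan if none
    dg_charge: float                   # kJ/mol at pH 7; negative = stabilising
    method: str                        # "exact" | "monte_carlo"
    dg_se: float = 0.0
    protonation_se: np.ndarray | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        p = self.mean_protonation
        if p.size and (p.min() < -1e-9 or p.max() > 1.0 + 1e-9):
            raise ValueError("mean protonations outside [0, 1]")


class TooManySitesError(ValueError):
    """Exact enumeration requested above the 2^N cap; use mc_titration."""


# ---------------------------------------------------------------------------
# site extraction

def extract_ionizable_sites(structure,
                            model_pka: Mapping[str, float] = MODEL_PKA,
                            disulfide_cutoff: float = 2.5) -> list[IonizableSite]:
    """Ionisable sites of a structure: sidechains plus per-chain termini.

    Positions are the centroids of the charged-group atoms; a residue with
    those atoms missing falls back to its centroid with a warning. Cys pairs
    whose SG atoms lie within ``disulfide_cutoff`` Angstrom are treated as
    disulfide-bonded and excluded from titration.
    """
    residues = residues_of(structure)
    if not residues:
        raise ValueError("empty structure: no protein residues")

    def centroid(res, atoms):
        coords = [res[a].coord for a in atoms if a in res]
        if len(coords) == len(atoms) and coords:
            return np.mean(coords, axis=0)
        logger.warning("%s %s: charged-group atoms missing; using residue "
                       "centroid", res.get_resname(), res.id[1])
        return np.mean([a.coord for a in res], axis=0)

    sites: list[IonizableSite] = []
    by_chain: dict[str, list] = {}
    for res in residues:
        by_chain.setdefault(res.get_parent().id if res.get_parent() else "?",
                            []).append(res)

    cys_sites: list[tuple[IonizableSite, np.ndarray]] = []
    for chain_id, chain_res in by_chain.items():
        for res in chain_res:
            stype = RESNAME_TO_TYPE.get(res.get_resname().strip())
            if stype is None:
                continue
            pos = centroid(res, CHARGED_GROUP_ATOMS[stype])
            site = IonizableSite(f"{chain_id}:{res.get_resname()}{res.id[1]}",
                                 stype, model_pka[stype], pos)
            if stype == "Cys":
                sg = res["SG"].coord if "SG" in res else pos
                cys_sites.append((site, np.asarray(sg, dtype=float)))
            else:
                sites.append(site)
        # termini
        first, last = chain_res[0], chain_res[-1]
        n_pos = first["N"].coord if "N" in first else centroid(first, ())
        c_atom = "OXT" if "OXT" in last else "C"
        c_pos = last[c_atom].coord if c_atom in last else centroid(last, ())
        sites.append(IonizableSite(f"{chain_id}:Nterm", "Nterm",
                                   model_pka["Nterm"], np.asarray(n_pos, float)))
        sites.append(IonizableSite(f"{chain_id}:Cterm", "Cterm",
                                   model_pka["Cterm"], np.asarray(c_pos, float)))

    # exclude disulfide-bonded cysteines
    bonded = set()
    for i in range(len(cys_sites)):
        for j in range(i + 1, len(cys_sites)):
            if np.linalg.norm(cys_sites[i][1] - cys_sites[j][1]) < disulfide_cutoff:
                bonded.update({i, j})
    for k, (site, _) in enumerate(cys_sites):
        if k in bonded:
            logger.info("%s: disulfide-bonded, excluded from titration", site.name)
        else:
            sites.append(site)
    return sites


# ---------------------------------------------------------------------------
# pair energies

def pair_energy(i: IonizableSite, j: IonizableSite, solvent: SolventModel,
                min_distance: float = 2.0) -> float:
    """Screened Coulomb energy per unit-charge product, kJ/mol.

    W = C exp(-kappa r) / (eps_r r); multiplied by q_i q_j in microstate
    energies. Distances below ``min_distance`` are clamped with a warning.
    """
    r = float(np.linalg.norm(i.position - j.position))
    if r == 0.0:
        raise ValueError(f"coincident sites {i.name} and {j.name}")
    if r < min_distance:
        logger.warning("sites %s and %s at %.2f A; clamped to %.2f A",
                       i.name, j.name, r, min_distance)
        r = min_distance
    return COULOMB_KJ_A * math.exp(-solvent.kappa * r) / (solvent.eps_r * r)


def interaction_matrix(sites: Sequence[IonizableSite], solvent: SolventModel,
                       min_distance: float = 2.0) -> np.ndarray:
    """Symmetric W matrix (zero diagonal) of pairwise energies, kJ/mol."""
    n = len(sites)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            W[i, j] = W[j, i] = pair_energy(sites[i], sites[j], solvent,
                                            min_distance)
    return W


def _site_arrays(sites: Sequence[IonizableSite]):
    pka = np.array([s.model_pKa for s in sites])
    offset = np.array([s.charge_offset for s in sites])
    return pka, offset


# ---------------------------------------------------------------------------
# exact enumeration

def enumerate_titration(sites: Sequence[IonizableSite], solvent: SolventModel,
                        ph_grid: np.ndarray = DEFAULT_PH_GRID,
                        dg_ph: float = 7.0,
                        W: np.ndarray | None = None) -> TitrationResult:
    """Exact titration by summing over all 2^N protonation microstates.

    The microstate energy at pH and full coupling is

        E(x) = ln(10) RT sum_i (pH - pKa_i) prot_i
               + sum_{i<j} W_ij q_i(x) q_j(x),

    with q = prot - 1 for acids and q = prot for bases. Boltzmann averages
    give the mean protonation per site; the interaction free energy is
    dG(pH) = -RT ln(Z / Z_free) with Z_free the same sum at W = 0.
    """
    n = len(sites)
    if n == 0:
        return TitrationResult([], np.asarray(ph_grid), np.zeros((0, len(ph_grid))),
                               np.zeros(0), 0.0, "exact")
    if n > EXACT_ENUMERATION_CAP:
        raise TooManySitesError(
            f"{n} sites exceeds the exact-enumeration cap "
            f"({EXACT_ENUMERATION_CAP}); use mc_titration")
    ph_grid = np.asarray(ph_grid, dtype=float)
    if W is None:
        W = interaction_matrix(sites, solvent)
    pka, offset = _site_arrays(sites)
    RT = solvent.RT

    states = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(np.float64)
    q = states + offset
    e_int = 0.5 * np.einsum("si,ij,sj->s", q, W, q)
    s_tot = states.sum(axis=1)
    s_pka = states @ pka

    def log_z_and_theta(ph, interacting):
        e_self = LN10 * RT * (ph * s_tot - s_pka)
        e = e_self + (e_int if interacting else 0.0)
        log_w = -e / RT
        log_z = logsumexp(log_w)
        weights = np.exp(log_w - log_z)
        return log_z, weights @ states

    theta = np.empty((n, len(ph_grid)))
    for k, ph in enumerate(ph_grid):
        _, th = log_z_and_theta(ph, True)
        theta[:, k] = th

    lz_int, _ = log_z_and_theta(dg_ph, True)
    lz_free, _ = log_z_and_theta(dg_ph, False)
    dg = -RT * (lz_int - lz_free)

    return TitrationResult(list(sites), ph_grid, theta,
                           _interpolate_pkas(ph_grid, theta), float(dg), "exact")


def _interpolate_pkas(ph_grid: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """pH of half-protonation per site, linear interpolation; nan if no crossing."""
    pkas = np.full(theta.shape[0], np.nan)
    for i, curve in enumerate(theta):
        above = curve >= 0.5
        if above.all() or (~above).all():
            continue
        # theta is non-increasing in pH for weakly coupled sites; find the
        # first downward crossing of 0.5
        for k in range(len(ph_grid) - 1):
            y0, y1 = curve[k], curve[k + 1]
            if y0 >= 0.5 > y1:
                pkas[i] = ph_grid[k] + (y0 - 0.5) / (y0 - y1) * (
                    ph_grid[k + 1] - ph_grid[k])
                break
    return pkas


# ---------------------------------------------------------------------------
# Monte Carlo

def gauss_legendre_ladder(n_points: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights mapped to [0, 1] for the lambda ladder."""
    x, w = leggauss(n_points)
    return 0.5 * (x + 1.0), 0.5 * w


def _mc_sample(pka, offset, W, RT, ph, lam, n_sweeps, n_equil, rng,
               coupled_pairs, n_batches=25):
    """Metropolis sampling at one (pH, lambda); returns batch means.

    Moves: one attempted flip per site per sweep, plus a paired flip for each
    strongly coupled pair. Returns per-batch means of protonation (n_batches,
    n_sites) and of the interaction energy U = 0.5 q W q (n_batches,).
    """
    n = len(pka)
    prot = (rng.random(n) < 0.5).astype(float)
    self_coef = LN10 * RT * (ph - pka)
    beta = 1.0 / RT

    def attempt_single(i):
        nonlocal prot
        d = 1.0 - 2.0 * prot[i]  # +1 if deprotonated, else -1
        q = prot + offset
        de = d * self_coef[i] + lam * d * (W[i] @ q)
        if de <= 0 or rng.random() < math.exp(-beta * de):
            prot[i] += d

    def attempt_pair(i, j):
        nonlocal prot
        di = 1.0 - 2.0 * prot[i]
        dj = 1.0 - 2.0 * prot[j]
        q = prot + offset
        de = (di * self_coef[i] + dj * self_coef[j]
              + lam * (di * (W[i] @ q) + dj * (W[j] @ q) + di * dj * W[i, j]))
        if de <= 0 or rng.random() < math.exp(-beta * de):
            prot[i] += di
            prot[j] += dj

    n_prod = n_sweeps - n_equil
    prot_sum = np.zeros((n_batches, n))
    u_sum = np.zeros(n_batches)
    batch_len = np.zeros(n_batches)
    for sweep in range(n_sweeps):
        for i in range(n):
            attempt_single(i)
        for (i, j) in coupled_pairs:
            attempt_pair(i, j)
        if sweep >= n_equil:
            b = (sweep - n_equil) * n_batches // n_prod
            q = prot + offset
            prot_sum[b] += prot
            u_sum[b] += 0.5 * q @ W @ q
            batch_len[b] += 1
    return prot_sum / batch_len[:, None], u_sum / batch_len


def mc_titration(sites: Sequence[IonizableSite], solvent: SolventModel,
                 ph_grid: np.ndarray = DEFAULT_PH_GRID,
                 n_sweeps: int = 1500, n_equil: int = 300,
                 seed: int | None = 0,
                 dg_ph: float = 7.0,
                 lambda_ladder: tuple[np.ndarray, np.ndarray] | None = None,
                 pair_coupling_threshold: float = 2.0,
                 se_tolerance: float = 1.0,
                 W: np.ndarray | None = None) -> TitrationResult:
    """Monte Carlo titration with thermodynamic integration for dG.

    Mean protonations (with batch-mean standard errors) are sampled at full
    coupling for every pH on the grid. The interaction free energy at
    ``dg_ph`` is the integral over lambda of the mean interaction energy,
    evaluated on a Gauss-Legendre lambda ladder; its standard error combines
    the per-node errors through the quadrature weights. A result whose dG
    standard error exceeds ``se_tolerance`` (kJ/mol) is flagged as
    non-converged rather than silently returned.
    """
    if not (n_sweeps > n_equil > 0):
        raise ValueError("need n_sweeps > n_equil > 0")
    n = len(sites)
    ph_grid = np.asarray(ph_grid, dtype=float)
    if n == 0:
        return TitrationResult([], ph_grid, np.zeros((0, len(ph_grid))),
                               np.zeros(0), 0.0, "monte_carlo")
    rng = np.random.default_rng(seed)
    if W is None:
        W = interaction_matrix(sites, solvent)
    pka, offset = _site_arrays(sites)
    RT = solvent.RT
    coupled = [(i, j) for i in range(n) for j in range(i + 1, n)
               if abs(W[i, j]) > pair_coupling_threshold]

    n_batches = 25
    theta = np.empty((n, len(ph_grid)))
    theta_se = np.empty((n, len(ph_grid)))
    for k, ph in enumerate(ph_grid):
        pb, _ = _mc_sample(pka, offset, W, RT, ph, 1.0, n_sweeps, n_equil,
                           rng, coupled, n_batches)
        theta[:, k] = pb.mean(axis=0)
        theta_se[:, k] = pb.std(axis=0, ddof=1) / math.sqrt(n_batches)
    theta = np.clip(theta, 0.0, 1.0)
    # rule of three: a site never seen to flip in n samples is known to
    # protonation ~3/n, not exactly; floor the batch-mean error accordingly
    theta_se = np.maximum(theta_se, 3.0 / (n_sweeps - n_equil))

    if lambda_ladder is None:
        lambda_ladder = gauss_legendre_ladder(5)
    nodes, weights = lambda_ladder
    u_means = np.empty(len(nodes))
    u_ses = np.empty(len(nodes))
    for m, lam in enumerate(nodes):
        _, ub = _mc_sample(pka, offset, W, RT, dg_ph, float(lam),
                           n_sweeps, n_equil, rng, coupled, n_batches)
        u_means[m] = ub.mean()
        u_ses[m] = ub.std(ddof=1) / math.sqrt(n_batches)
    dg = float(weights @ u_means)
    dg_se = float(math.sqrt(np.sum((weights * u_ses) ** 2)))
    converged = dg_se <= se_tolerance
    if not converged:
        logger.warning("MC dG standard error %.3f kJ/mol above tolerance %.3f",
                       dg_se, se_tolerance)

    return TitrationResult(list(sites), ph_grid, theta,
                           _interpolate_pkas(ph_grid, theta), dg,
                           "monte_carlo", dg_se=dg_se,
                           protonation_se=theta_se, converged=converged)


# ---------------------------------------------------------------------------
# folding / dimerisation energies

def charge_folding_energy(structure, solvent: SolventModel | None = None,
                          pH: float = 7.0, cap: int = EXACT_ENUMERATION_CAP,
                          mc_params: Mapping | None = None) -> float:
    """Ionisable-group interaction free energy at the given pH, kJ/mol.

    Negative values mean charge interactions stabilise the folded state.
    Exact enumeration up to ``cap`` sites, Monte Carlo beyond.
    """
    solvent = solvent or SolventModel()
    sites = extract_ionizable_sites(structure)
    if not sites:
        return 0.0
    if len(sites) <= cap:
        res = enumerate_titration(sites, solvent, ph_grid=np.array([pH]),
                                  dg_ph=pH)
    else:
        res = mc_titration(sites, solvent, ph_grid=np.array([pH]), dg_ph=pH,
                           **(mc_params or {}))
    return res.dg_charge


def dimer_charge_energy(A, B, AB, solvent: SolventModel | None = None,
                        pH: float = 7.0, **kwargs) -> float:
    """Charge contribution to dimerisation: dG(AB) - dG(A) - dG(B), kJ/mol."""
    from ._pdb import atom_count
    if atom_count(AB) != atom_count(A) + atom_count(B):
        raise ValueError("dimer atom count does not match the sum of subunits")
    solvent = solvent or SolventModel()
    return (charge_folding_energy(AB, solvent, pH, **kwargs)
            - charge_folding_energy(A, solvent, pH, **kwargs)
            - charge_folding_energy(B, solvent, pH, **kwargs))
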