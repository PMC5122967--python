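"""Solvent-accessible surface areas, buried surface, and screened-Coulomb ESP.

SASA uses the Shrake-Rupley numerical quadrature: each heavy atom carries a
deterministic quasi-uniform point set (golden-section spiral) on its solvent
sphere of radius r_atom + probe, and the accessible area is the exposed-point
fraction times the sphere area.  The default radii are a NACCESS-like
united-atom (Chothia) set with a 1.4 A water probe; hydrogens are ignored
under united-atom radii.

The electrostatic surface potential is a linearized Debye-Hueckel screened
Coulomb sum over formal charges,

    phi(p) = (l_B(T) / eps_r_rel) * sum_i q_i * exp(-kappa d_i) / d_i   [kT/e]

with the Bjerrum-type constant l_B = e^2 / (4 pi eps0 kB T) (about 560 A at
298 K, i.e. 7.1 A once divided by water's eps_r = 78.5) and the inverse Debye
length kappa computed from the 1:1 ionic strength.  This is a deliberately
simple surrogate for a full Poisson-Boltzmann solver: signs, gradients and
the topology of negative-potential patches are meaningful; absolute
magnitudes near the protein are not.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
from scipy import constants
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .structure_io import Selection, StructureEnsemble, select

__all__ = [
    "SurfaceError",
    "RADII_SETS",
    "SASAResult",
    "SurfacePotential",
    "Basin",
    "BasinReport",
    "sphere_points",
    "shrake_rupley",
    "surface_points",
    "buried_surface",
    "fraction_buried",
    "formal_charges",
    "debye_kappa",
    "esp_potential",
    "find_basins",
    "compare_esp",
]


class SurfaceError(ValueError):
    pass


# United-atom (NACCESS/Chothia-like) and Bondi element radii in A.
RADII_SETS: dict[str, dict[str, float]] = {
    "chothia": {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.80, "SE": 1.90},
    "bondi": {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90,
              "H": 1.20},
}


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-section spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * i
    return np.column_stack([
        np.sin(phi) * np.cos(theta),
        np.sin(phi) * np.sin(theta),
        np.cos(phi),
    ])


@dataclasses.dataclass
class SASAResult:
    """Per-atom accessible areas (A^2) for the atoms used in the calculation."""

    atom_indices: np.ndarray       # columns of the parent ensemble
    areas: np.ndarray              # per-atom SASA
    radii: np.ndarray
    probe: float
    n_points: int
    radii_set: str

    @property
    def total(self) -> float:
        return float(self.areas.sum())

    def residue_totals(self, ensemble: StructureEnsemble,
                       sidechain_only: bool = False) -> dict[tuple[str, int], float]:
        from .structure_io import BACKBONE_ATOMS
        out: dict[tuple[str, int], float] = {}
        for idx, area in zip(self.atom_indices, self.areas):
            a = ensemble.atoms[int(idx)]
            if sidechain_only and (a.atom_name in BACKBONE_ATOMS or a.atom_name == "OXT"):
                continue
            key = (a.chain_id, a.res_seq)
            out[key] = out.get(key, 0.0) + float(area)
        return out


def _radii_for(ensemble: StructureEnsemble, atom_indices: np.ndarray,
               radii_set: str, include_hydrogens: bool) -> tuple[np.ndarray, np.ndarray]:
    """Filter out hydrogens (unless included) and look up radii; error on unknowns."""
    try:
        table = RADII_SETS[radii_set]
    except KeyError:
        raise SurfaceError(f"unknown radii set {radii_set!r}; have {sorted(RADII_SETS)}")
    kept, radii, unknown = [], [], []
    for i in atom_indices:
        a = ensemble.atoms[int(i)]
        el = a.element.upper()
        if el == "H" and not include_hydrogens:
            continue
        if el not in table:
            unknown.append(f"{a.chain_id}/{a.res_seq}/{a.atom_name} ({el})")
            continue
        kept.append(int(i))
        radii.append(table[el])
    if unknown:
        raise SurfaceError(f"no radius for atoms: {', '.join(unknown[:10])}")
    return np.asarray(kept, int), np.asarray(radii, float)


def _exposure(coords: np.ndarray, radii: np.ndarray, probe: float,
              n_points: int) -> tuple[np.ndarray, list[np.ndarray]]:
    """Exposed-point counts and exposed point coordinates per atom."""
    ext = radii + probe
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = ext.max()
    counts = np.zeros(len(coords), dtype=int)
    exposed_pts: list[np.ndarray] = []
    for i in range(len(coords)):
        pts = coords[i] + ext[i] * unit
        neighbors = tree.query_ball_point(coords[i], ext[i] + max_r)
        mask = np.ones(n_points, dtype=bool)
        for j in neighbors:
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            mask &= d2 > ext[j] ** 2
        counts[i] = int(mask.sum())
        exposed_pts.append(pts[mask])
    return counts, exposed_pts


def shrake_rupley(
    ensemble: StructureEnsemble,
    model: int = 0,
    atom_indices: np.ndarray | None = None,
    radii_set: str = "chothia",
    probe: float = 1.4,
    n_points: int = 960,
    include_hydrogens: bool = False,
) -> SASAResult:
    """Numerical SASA of one model (optionally restricted to an atom subset)."""
    if atom_indices is None:
        atom_indices = np.arange(ensemble.n_atoms)
    kept, radii = _radii_for(ensemble, np.asarray(atom_indices, int),
                             radii_set, include_hydrogens)
    if len(kept) == 0:
        raise SurfaceError("no atoms left after hydrogen/radius filtering")
    coords = ensemble.coords[model, kept]
    counts, _ = _exposure(coords, radii, probe, n_points)
    areas = counts / n_points * 4.0 * math.pi * (radii + probe) ** 2
    return SASAResult(atom_indices=kept, areas=areas, radii=radii,
                      probe=probe, n_points=n_points, radii_set=radii_set)


@dataclasses.dataclass
class SurfacePotential:
    """Exposed quadrature points, each carrying an area and a potential in kT/e."""

    points: np.ndarray        # (P, 3)
    point_area: np.ndarray    # (P,)
    owner_atom: np.ndarray    # (P,) ensemble atom column of the owning atom
    phi: np.ndarray | None = None
    clamped: np.ndarray | None = None   # points closer than d_min to a charge

    @property
    def total_area(self) -> float:
        return float(self.point_area.sum())


def surface_points(
    ensemble: StructureEnsemble,
    model: int = 0,
    atom_indices: np.ndarray | None = None,
    radii_set: str = "chothia",
    probe: float = 1.4,
    n_points: int = 960,
) -> SurfacePotential:
    """SASA dot surface: exposed points with per-point areas (no potential yet)."""
    if atom_indices is None:
        atom_indices = np.arange(ensemble.n_atoms)
    kept, radii = _radii_for(ensemble, np.asarray(atom_indices, int), radii_set, False)
    coords = ensemble.coords[model, kept]
    _, exposed = _exposure(coords, radii, probe, n_points)
    pts, areas, owners = [], [], []
    for i, p in enumerate(exposed):
        if len(p) == 0:
            continue
        pts.append(p)
        area_per_point = 4.0 * math.pi * (radii[i] + probe) ** 2 / n_points
        areas.append(np.full(len(p), area_per_point))
        owners.append(np.full(len(p), kept[i], dtype=int))
    if not pts:
        raise SurfaceError("structure has no exposed surface points")
    return SurfacePotential(
        points=np.concatenate(pts),
        point_area=np.concatenate(areas),
        owner_atom=np.concatenate(owners),
    )


# ---------------------------------------------------------------------------
# Buried surface
# ---------------------------------------------------------------------------

def buried_surface(
    ensemble: StructureEnsemble,
    entity_a: Selection | str,
    entity_b: Selection | str,
    models: Sequence[int] | None = None,
    **sasa_kwargs,
) -> dict:
    """Buried surface area of an interface, averaged over the chosen models.

    BSA_total(model) = SASA(A alone) + SASA(B alone) - SASA(A union B),
    summed over both partners (not halved).  Also returns the per-entity and
    per-residue SASA loss, averaged over models.
    """
    ia = select(ensemble, entity_a)
    ib = select(ensemble, entity_b)
    if np.intersect1d(ia, ib).size:
        raise SurfaceError("entity selections overlap")
    if models is None:
        models = range(ensemble.n_models)
    totals, loss_a, loss_b = [], [], []
    per_res_acc: dict[tuple[str, int], list[float]] = {}
    for m in models:
        sa = shrake_rupley(ensemble, model=m, atom_indices=ia, **sasa_kwargs)
        sb = shrake_rupley(ensemble, model=m, atom_indices=ib, **sasa_kwargs)
        sc = shrake_rupley(ensemble, model=m,
                           atom_indices=np.concatenate([ia, ib]), **sasa_kwargs)
        totals.append(sa.total + sb.total - sc.total)
        res_free = sa.residue_totals(ensemble) | sb.residue_totals(ensemble)
        res_cplx = sc.residue_totals(ensemble)
        a_res = set(sa.residue_totals(ensemble))
        d_a = d_b = 0.0
        for key, free_area in res_free.items():
            d = free_area - res_cplx.get(key, 0.0)
            per_res_acc.setdefault(key, []).append(d)
            if key in a_res:
                d_a += d
            else:
                d_b += d
        loss_a.append(d_a)
        loss_b.append(d_b)
    return {
        "bsa_total": float(np.mean(totals)),
        "bsa_sd": float(np.std(totals, ddof=1)) if len(totals) > 1 else 0.0,
        "per_entity": {"A": float(np.mean(loss_a)), "B": float(np.mean(loss_b))},
        "per_residue": {k: float(np.mean(v)) for k, v in per_res_acc.items()},
        "n_models": len(list(models)),
    }


def fraction_buried(
    ensemble: StructureEnsemble,
    residue_selections: Sequence[Selection | str],
    entity: Selection | str,
    models: Sequence[int] | None = None,
    **sasa_kwargs,
) -> dict:
    """Fraction of each selection's surface lost on complex formation.

    ``entity`` selects the free-state partner that contains the residues
    (their SASA is computed within that entity alone); the complex is the
    whole ensemble.  fraction = 1 - SASA_complex / SASA_free.  The group
    mean is weighted by each selection's free-state area.
    """
    ie = select(ensemble, entity)
    if models is None:
        models = range(ensemble.n_models)
    models = list(models)
    fractions: dict[str, list[float]] = {}
    weights: dict[str, list[float]] = {}
    for m in models:
        s_free = shrake_rupley(ensemble, model=m, atom_indices=ie, **sasa_kwargs)
        s_cplx = shrake_rupley(ensemble, model=m, **sasa_kwargs)
        free_by_atom = dict(zip(s_free.atom_indices, s_free.areas))
        cplx_by_atom = dict(zip(s_cplx.atom_indices, s_cplx.areas))
        for sel in residue_selections:
            key = str(sel)
            idx = select(ensemble, sel)
            free_area = sum(free_by_atom.get(int(i), 0.0) for i in idx)
            cplx_area = sum(cplx_by_atom.get(int(i), 0.0) for i in idx)
            if free_area <= 0:
                continue  # fully buried even in the free entity; skip with no weight
            fractions.setdefault(key, []).append(1.0 - cplx_area / free_area)
            weights.setdefault(key, []).append(free_area)
    per_sel = {k: float(np.mean(v)) for k, v in fractions.items()}
    w = np.array([np.mean(weights[k]) for k in per_sel])
    f = np.array(list(per_sel.values()))
    group = float(np.sum(w * f) / np.sum(w)) if len(f) else float("nan")
    return {"per_selection": per_sel, "group_mean": group}


# ---------------------------------------------------------------------------
# Electrostatics
# ---------------------------------------------------------------------------

# Formal pH-7 charge model: fractional charges on symmetric carboxylate /
# guanidinium oxygens and nitrogens, +1 on lysine NZ, termini +-1.
_SIDECHAIN_CHARGES = {
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5, ("ARG", "NH2"): 0.5,
}


def formal_charges(ensemble: StructureEnsemble, termini: bool = True) -> np.ndarray:
    """Per-atom formal charges (e) under the pH-7 model."""
    q = np.zeros(ensemble.n_atoms)
    index = ensemble.atom_index()
    for i, a in enumerate(ensemble.atoms):
        q[i] = _SIDECHAIN_CHARGES.get((a.res_name, a.atom_name), 0.0)
    if termini:
        for chain in sorted({a.chain_id for a in ensemble.atoms}):
            res = ensemble.residues(chain)
            first, last = res[0], res[-1]
            key_n = (chain, first[1], "N")
            if key_n in index:
                q[index[key_n]] += 1.0
            key_oxt = (chain, last[1], "OXT")
            key_o = (chain, last[1], "O")
            if key_oxt in index and key_o in index:
                q[index[key_oxt]] += -0.5
                q[index[key_o]] += -0.5
            elif key_o in index:
                q[index[key_o]] += -1.0
    return q


def debye_kappa(ionic_strength: float, epsilon_r: float = 78.5,
                temperature: float = 298.15) -> float:
    """Inverse Debye length (1/A) for a 1:1 electrolyte at the given molarity."""
    if ionic_strength < 0:
        raise SurfaceError("ionic strength must be >= 0")
    if ionic_strength == 0:
        return 0.0
    l_b = _coulomb_constant(temperature) / epsilon_r  # Bjerrum length, A
    n_per_a3 = ionic_strength * constants.N_A / 1e27  # mol/L -> ions/A^3
    return math.sqrt(8.0 * math.pi * l_b * n_per_a3)


def _coulomb_constant(temperature: float) -> float:
    """e^2 / (4 pi eps0 kB T) in Angstrom (the vacuum Bjerrum length)."""
    return (constants.e ** 2 /
            (4 * math.pi * constants.epsilon_0 * constants.k * temperature)) * 1e10


def esp_potential(
    ensemble: StructureEnsemble,
    model: int = 0,
    charges: np.ndarray | None = None,
    eval_points: SurfacePotential | np.ndarray | None = None,
    ionic_strength: float = 0.1,
    epsilon_r: float = 78.5,
    temperature: float = 298.15,
    d_min: float = 0.5,
    **surface_kwargs,
) -> SurfacePotential:
    """Screened-Coulomb potential (kT/e) on a point cloud (default: the dot surface).

    Evaluation points closer than ``d_min`` to a charge are clamped to
    ``d_min`` and flagged rather than allowed to blow up.
    """
    if charges is None:
        charges = formal_charges(ensemble)
    charges = np.asarray(charges, float)
    if charges.shape != (ensemble.n_atoms,):
        raise SurfaceError("charges must be one value per ensemble atom")
    if isinstance(eval_points, SurfacePotential):
        sp = eval_points
    elif eval_points is None:
        sp = surface_points(ensemble, model=model, **surface_kwargs)
    else:
        pts = np.asarray(eval_points, float)
        sp = SurfacePotential(points=pts, point_area=np.zeros(len(pts)),
                              owner_atom=np.full(len(pts), -1))
    kappa = debye_kappa(ionic_strength, epsilon_r, temperature)
    const = _coulomb_constant(temperature) / epsilon_r
    charged = np.nonzero(charges)[0]
    q = charges[charged]
    centers = ensemble.coords[model, charged]
    d = np.linalg.norm(sp.points[:, None, :] - centers[None, :, :], axis=2)
    clamped = (d < d_min).any(axis=1)
    d = np.maximum(d, d_min)
    phi = const * np.sum(q[None, :] * np.exp(-kappa * d) / d, axis=1)
    return SurfacePotential(points=sp.points, point_area=sp.point_area,
                            owner_atom=sp.owner_atom, phi=phi, clamped=clamped)


# ---------------------------------------------------------------------------
# Basin detection
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Basin:
    member_points: np.ndarray    # indices into the SurfacePotential arrays
    area: float                  # A^2
    min_phi: float               # kT/e
    centroid: np.ndarray         # area-weighted, A
    min_dist_to_target: float | None = None


@dataclasses.dataclass
class BasinReport:
    basins: list[Basin]
    threshold: float
    link_distance: float

    def __len__(self) -> int:
        return len(self.basins)


def find_basins(
    sp: SurfacePotential,
    threshold: float,
    link_distance: float = 2.0,
    target_point: np.ndarray | None = None,
) -> BasinReport:
    """Connected negative-potential surface patches.

    Points with phi <= threshold are single-linkage clustered at
    ``link_distance``; patches come back sorted by area, each with its
    minimum potential, area-weighted centroid and (optionally) the minimum
    distance of any member point to a target position such as a key
    coordinating carboxylate.
    """
    if sp.phi is None:
        raise SurfaceError("surface potential has no phi values")
    if threshold >= 0:
        raise SurfaceError("basin threshold must be negative (negative-ESP patches)")
    mask = np.where(sp.phi <= threshold)[0]
    if mask.size == 0:
        return BasinReport(basins=[], threshold=threshold, link_distance=link_distance)
    pts = sp.points[mask]
    tree = cKDTree(pts)
    pairs = tree.query_pairs(link_distance, output_type="ndarray")
    n = len(pts)
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    ) if len(pairs) else coo_matrix((n, n))
    n_comp, labels = connected_components(graph, directed=False)
    basins = []
    for c in range(n_comp):
        members = mask[labels == c]
        areas = sp.point_area[members]
        w = areas / areas.sum() if areas.sum() > 0 else np.full(len(members), 1 / len(members))
        centroid = (sp.points[members] * w[:, None]).sum(axis=0)
        dist = None
        if target_point is not None:
            dist = float(np.min(np.linalg.norm(sp.points[members] - target_point, axis=1)))
        basins.append(Basin(
            member_points=members,
            area=float(areas.sum()),
            min_phi=float(sp.phi[members].min()),
            centroid=centroid,
            min_dist_to_target=dist,
        ))
    basins.sort(key=lambda b: -b.area)
    return BasinReport(basins=basins, threshold=threshold, link_distance=link_distance)


def compare_esp(
    ensemble_with: StructureEnsemble,
    ensemble_without: StructureEnsemble,
    region: Selection | str,
    model: int = 0,
    **esp_kwargs,
) -> dict:
    """Area-weighted mean surface potential over a region in two structures.

    The region (e.g. a Ca2+-binding loop) must resolve in both; returns the
    mean phi with and without the partner and their difference (with minus
    without) — negative when the partner adds acidic groups near the region.
    """
    out = {}
    for tag, ens in (("with", ensemble_with), ("without", ensemble_without)):
        idx = set(int(i) for i in select(ens, region))
        sp = esp_potential(ens, model=model, **esp_kwargs)
        member = np.isin(sp.owner_atom, list(idx))
        if not member.any():
            raise SurfaceError(f"region has no exposed surface in the '{tag}' structure")
        w = sp.point_area[member]
        out[tag] = float(np.sum(sp.phi[member] * w) / np.sum(w))
    out["delta"] = out["with"] - out["without"]
    return out
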