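"""Ground-truth generators: ideal backbones, shift tables, PRE, NOE and RDC data.

Every generator is a pure function of its arguments (and a mandatory seed
where noise is involved), so each analysis stage in the package can be tested
against exactly known inputs without any external file.

Backbones are built from ideal internal coordinates (Engh-Huber-like bond
lengths and angles, hard-coded in one table) using the standard NeRF chain
extension; an alpha-helix uses phi = -57, psi = -47, omega = 180 degrees.
The paramagnetic intensity model is the two-parameter exponential form used
for spin-label PRE analysis:

    Gamma2 = K / r^6
    I_ox / I_red = R2 * exp(-Gamma2 * t) / (R2 + Gamma2)

with R2 the diamagnetic transverse rate and t the total evolution delay.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from . import geometry
from .restraints import DistanceRestraint, RDCRecord, RestraintError, SaupeTensor, backcalc_rdc
from .structure_io import AtomSite, Selection, StructureEnsemble, select

__all__ = [
    "HelixSpec",
    "PRESimParams",
    "build_helix",
    "build_two_helix",
    "gen_shift_tables",
    "gen_pre_intensities",
    "gen_noe_restraints",
    "gen_rdc",
    "pre_ratio_model",
    "IDEAL_GEOMETRY",
]

AA_3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

# Ideal covalent geometry (A / degrees), one table so the builder has no
# force-field dependency.
IDEAL_GEOMETRY = {
    "N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
    "CA-CB": 1.530, "N-H": 1.010,
    "C-N-CA": 121.7, "N-CA-C": 111.2, "CA-C-N": 116.2,
    "CA-C-O": 120.8, "N-CA-CB": 110.5, "C-N-H": 119.0,
}


class SyntheticError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class HelixSpec:
    """Backbone build recipe; defaults give an ideal alpha-helix."""

    n_res: int
    phi: float = -57.0
    psi: float = -47.0
    omega: float = 180.0
    sequence: str | None = None  # 1-letter; defaults to poly-Ala

    def __post_init__(self) -> None:
        if self.n_res < 4:
            raise SyntheticError("need at least 4 residues")
        for ang in (self.phi, self.psi, self.omega):
            if not (-180.0 < ang <= 180.0):
                raise SyntheticError(f"angle {ang} outside (-180, 180]")
        if self.sequence is not None and len(self.sequence) != self.n_res:
            raise SyntheticError("sequence length must equal n_res")

    def residue_names(self) -> list[str]:
        seq = self.sequence or "A" * self.n_res
        try:
            return [AA_3[c.upper()] for c in seq]
        except KeyError as exc:
            raise SyntheticError(f"unknown residue letter {exc}") from exc


@dataclasses.dataclass(frozen=True)
class PRESimParams:
    """Parameters of the spin-label intensity model (all positive)."""

    K: float = 1.2e8          # A^6 s^-1; sets the ~15 A half-broadening radius
    R2_dia: float = 20.0      # s^-1 diamagnetic transverse rate
    t_delay: float = 0.010    # s total INEPT evolution time
    noise_sd: float = 0.0     # intensity units (I_red is generated at 100)
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.K, self.R2_dia, self.t_delay) <= 0 or self.noise_sd < 0:
            raise SyntheticError("PRE parameters must be positive (noise_sd >= 0)")
        if self.noise_sd > 0 and self.seed is None:
            raise SyntheticError("a seed is required whenever noise is generated")


# ---------------------------------------------------------------------------
# NeRF backbone construction
# ---------------------------------------------------------------------------

def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position d with |cd| = bond, angle(b,c,d) and torsion(a,b,c,d) given (degrees)."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_helix(spec: HelixSpec, chain_id: str = "A") -> StructureEnsemble:
    """Build a single-model backbone (N, CA, C, O, CB, amide H) from ideal geometry."""
    g = IDEAL_GEOMETRY
    names = spec.residue_names()
    atoms: list[AtomSite] = []
    coords: list[np.ndarray] = []

    def add(res_seq: int, res_name: str, atom_name: str, element: str, xyz: np.ndarray) -> None:
        atoms.append(AtomSite(chain_id, res_seq, res_name, atom_name, element))
        coords.append(xyz)

    N = np.array([0.0, 0.0, 0.0])
    CA = N + np.array([g["N-CA"], 0.0, 0.0])
    ang = math.radians(g["N-CA-C"])
    C = CA + g["CA-C"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    prev = {"N": N, "CA": CA, "C": C}
    for i, res_name in enumerate(names, start=1):
        if i > 1:
            N = _place(prev["N"], prev["CA"], prev["C"], g["C-N"], g["CA-C-N"], spec.psi)
            CA = _place(prev["CA"], prev["C"], N, g["N-CA"], g["C-N-CA"], spec.omega)
            C = _place(prev["C"], N, CA, g["CA-C"], g["N-CA-C"], spec.phi)
        add(i, res_name, "N", "N", N)
        if i > 1 and res_name != "PRO":
            # amide H in the peptide plane, anti to CA(i) across the C-N bond
            tor_h = (spec.omega - 180.0) % 360.0
            H = _place(prev["CA"], prev["C"], N, g["N-H"], g["C-N-H"],
                       tor_h if tor_h <= 180.0 else tor_h - 360.0)
            add(i, res_name, "H", "H", H)
        add(i, res_name, "CA", "C", CA)
        if res_name != "GLY":
            CB = _place(C, N, CA, g["CA-CB"], g["N-CA-CB"], 122.6)
            add(i, res_name, "CB", "C", CB)
        add(i, res_name, "C", "C", C)
        # carbonyl O anti to the next amide N (psi + 180)
        O = _place(N, CA, C, g["C-O"], g["CA-C-O"],
                   (spec.psi + 180.0) % 360.0 - 180.0)
        add(i, res_name, "O", "O", O)
        prev = {"N": N, "CA": CA, "C": C}

    order = sorted(range(len(atoms)), key=lambda k: (atoms[k].chain_id, atoms[k].res_seq,
                                                     atoms[k].atom_name))
    ens = StructureEnsemble(
        atoms=[atoms[k] for k in order],
        coords=np.asarray([coords[k] for k in order])[None, :, :],
        chain_map={chain_id: chain_id},
        offsets={},
    )
    return ens


def _axis_to_z(ens: StructureEnsemble) -> StructureEnsemble:
    """Rigidly move a single-model helix so its fitted axis is +z through the origin."""
    ca = select(ens, Selection("*", (), "named", ("CA",)))
    seg = geometry.fit_helix_axis(ens.coords[0, ca])
    d = seg.direction
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(d, z)
    s = np.linalg.norm(v)
    c = float(np.dot(d, z))
    if s < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)
    centered = ens.transformed(np.eye(3), -seg.point)
    return centered.transformed(R, np.zeros(3))


def _rotation_about_x(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array([
        [1, 0, 0],
        [0, math.cos(a), -math.sin(a)],
        [0, math.sin(a), math.cos(a)],
    ])


def build_two_helix(
    spec_a: HelixSpec,
    spec_b: HelixSpec,
    crossing_angle: float,
    separation: float = 10.0,
) -> StructureEnsemble:
    """Two ideal helices with a controlled crossing angle and axis separation.

    Helix A runs along +z through the origin; helix B is rotated by
    ``crossing_angle`` about x and displaced by ``separation`` along y, so the
    interhelical angle recovered from the C-alpha axes equals the request to
    within the axis-fit error (< 2 degrees for regular helices).
    """
    if not (0.0 <= crossing_angle <= 180.0):
        raise SyntheticError("crossing angle must be in [0, 180] degrees")
    if separation < 4.0:
        raise SyntheticError(f"separation {separation} A would clash (< 4 A)")
    ha = _axis_to_z(build_helix(spec_a, chain_id="A"))
    hb = _axis_to_z(build_helix(spec_b, chain_id="B"))
    hb = hb.transformed(_rotation_about_x(crossing_angle),
                        np.array([0.0, separation, 0.0]))
    atoms = list(ha.atoms) + list(hb.atoms)
    coords = np.concatenate([ha.coords, hb.coords], axis=1)
    return StructureEnsemble(
        atoms=atoms, coords=coords,
        chain_map={"A": "A", "B": "B"}, offsets={},
    )


# ---------------------------------------------------------------------------
# Spectral observables
# ---------------------------------------------------------------------------

def gen_shift_tables(
    n_res: int,
    perturbed_ranges: Sequence[tuple[tuple[int, int], float, float]] = (),
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Free/bound amide shift tables with localized perturbations.

    ``perturbed_ranges`` is a list of ``((lo, hi), dH_mean, dN_mean)``; the
    bound-state table shifts those residues by the given amounts.  With
    ``noise_sd = 0`` the tables differ exactly and only by the perturbations.
    Gaussian noise of the given sd (ppm, applied to 1H; 5x on 15N to mimic
    the wider nitrogen distribution) is added independently to both states.
    """
    covered: set[int] = set()
    for (lo, hi), _, _ in perturbed_ranges:
        rng_set = set(range(lo, hi + 1))
        if not rng_set <= set(range(1, n_res + 1)):
            raise SyntheticError(f"range {lo}-{hi} outside 1..{n_res}")
        if covered & rng_set:
            raise SyntheticError("perturbed ranges overlap")
        covered |= rng_set
    if noise_sd > 0 and seed is None:
        raise SyntheticError("a seed is required for noisy shift tables")
    rng = np.random.default_rng(seed)
    res = np.arange(1, n_res + 1)
    base_h = np.full(n_res, 8.30)
    base_n = np.full(n_res, 119.5)

    def table(dh: np.ndarray, dn: np.ndarray) -> pd.DataFrame:
        noise_h = rng.normal(0, noise_sd, n_res) if noise_sd > 0 else 0.0
        noise_n = rng.normal(0, 5 * noise_sd, n_res) if noise_sd > 0 else 0.0
        return pd.DataFrame({
            "res_seq": res,
            "res_name": ["ALA"] * n_res,
            "H_ppm": base_h + dh + noise_h,
            "N_ppm": base_n + dn + noise_n,
        })

    dh = np.zeros(n_res)
    dn = np.zeros(n_res)
    for (lo, hi), dh_mean, dn_mean in perturbed_ranges:
        dh[lo - 1:hi] += dh_mean
        dn[lo - 1:hi] += dn_mean
    free = table(np.zeros(n_res), np.zeros(n_res))
    bound = table(dh, dn)
    return free, bound


def pre_ratio_model(r: np.ndarray | float, params: PRESimParams) -> np.ndarray | float:
    """Noise-free I_ox/I_red at distance r (A) under the exponential PRE model."""
    r = np.asarray(r, float)
    gamma2 = params.K * r ** -6.0
    return params.R2_dia * np.exp(-gamma2 * params.t_delay) / (params.R2_dia + gamma2)


def gen_pre_intensities(
    structure: StructureEnsemble,
    label_atom: Selection | str,
    params: PRESimParams,
) -> pd.DataFrame:
    """Oxidized/reduced amide intensities for a spin label at a chosen atom.

    Output columns: res_seq, I_ox, I_red, noise_sd.  Residues with no amide
    proton (N-terminus, prolines) appear with NaN intensities so downstream
    code flags them missing rather than treating them as broadened.
    """
    li = select(structure, label_atom)
    if len(li) != 1:
        raise SyntheticError(f"label selection must resolve to one atom, got {len(li)}")
    label_xyz = structure.coords[0, li[0]]
    index = structure.atom_index()
    rng = np.random.default_rng(params.seed) if params.noise_sd > 0 else None
    rows = []
    for chain, res_seq, _ in structure.residues():
        key = (chain, res_seq, "H")
        if key not in index:
            rows.append((chain, res_seq, np.nan, np.nan, params.noise_sd))
            continue
        r = float(np.linalg.norm(structure.coords[0, index[key]] - label_xyz))
        ratio = float(pre_ratio_model(r, params))
        i_red, i_ox = 100.0, 100.0 * ratio
        if rng is not None:
            i_ox += rng.normal(0, params.noise_sd)
            i_red += rng.normal(0, params.noise_sd)
        rows.append((chain, res_seq, i_ox, i_red, params.noise_sd))
    return pd.DataFrame(rows, columns=["chain", "res_seq", "I_ox", "I_red", "noise_sd"])


def gen_noe_restraints(
    structure: StructureEnsemble,
    cutoff: float = 5.0,
    bound_pad: float = 0.5,
) -> list[DistanceRestraint]:
    """NOE-like restraints from true distances in a single-model structure.

    One restraint per unordered proton pair within ``cutoff`` (C-alpha pairs
    when the structure carries no protons); bounds [1.8, d_true + pad], so by
    construction the generating model violates nothing.
    """
    if structure.n_models != 1:
        raise SyntheticError("restraint generation expects a single-model structure")
    if cutoff <= 1.8:
        raise SyntheticError("cutoff must exceed the 1.8 A lower bound")
    h_idx = [i for i, a in enumerate(structure.atoms) if a.is_hydrogen]
    if not h_idx:
        h_idx = [i for i, a in enumerate(structure.atoms) if a.atom_name == "CA"]
    X = structure.coords[0]
    out: list[DistanceRestraint] = []
    for p in range(len(h_idx)):
        for q in range(p + 1, len(h_idx)):
            i, j = h_idx[p], h_idx[q]
            d = float(np.linalg.norm(X[i] - X[j]))
            if d <= cutoff:
                a, b = structure.atoms[i], structure.atoms[j]
                out.append(DistanceRestraint((a.key(),), (b.key(),),
                                             1.8, d + bound_pad, "noe"))
    return out


def gen_rdc(
    structure: StructureEnsemble,
    tensor: SaupeTensor,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> list[RDCRecord]:
    """Back-calculated H-N couplings for every residue with an amide, plus noise."""
    if noise_sd > 0 and seed is None:
        raise SyntheticError("a seed is required for noisy RDC sets")
    index = structure.atom_index()
    records = [
        RDCRecord(chain, res_seq, 0.0)
        for chain, res_seq, _ in structure.residues()
        if (chain, res_seq, "N") in index and (chain, res_seq, "H") in index
    ]
    if len(records) < 5:
        raise RestraintError(f"only {len(records)} N-H vectors; tensor under-determined")
    d = backcalc_rdc(structure, tensor, records)
    if noise_sd > 0:
        d = d + np.random.default_rng(seed).normal(0, noise_sd, len(d))
    return [dataclasses.replace(rec, d_obs=float(v)) for rec, v in zip(records, d)]
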