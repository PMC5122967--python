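"""Rigid-body superposition, ensemble RMSD, helix axes, EF-hand angles, H-bonds.

The superposition is the classic Kabsch least-squares fit with the reflection
correction; pairwise ensemble RMSD follows the convention used for NMR
structure statistics (superpose on the scored selection itself, report
mean +/- sd over all unordered model pairs).

EF-hand interhelical angles are computed from principal-axis fits to the
C-alpha clouds of the two helices, both axes oriented N->C, angle reported in
[0, 180] degrees.  Because published angle tables depend on the exact axis
definition, the classification windows (closed / semi-open / open) are
calibration inputs, not constants.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Sequence

import numpy as np

from .structure_io import Selection, SelectionError, StructureEnsemble, select

__all__ = [
    "GeometryError",
    "HelixSegment",
    "EFHandAngles",
    "HBond",
    "kabsch_superpose",
    "ensemble_pairwise_rmsd",
    "fit_helix_axis",
    "interhelical_angle",
    "efhand_angle",
    "hbond_scan",
]


class GeometryError(ValueError):
    pass


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` with the proper rotation ``R`` and translation
    ``t`` such that ``mobile @ R.T + t`` best fits ``reference`` in the
    least-squares sense.  Degenerate (collinear or too small) point sets are
    rejected because the rotation is then not unique.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError("coordinate sets must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise GeometryError("need at least 3 atoms to superpose")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    sv = np.linalg.svd(Pc, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise GeometryError("degenerate (collinear) coordinate set")
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return R, t, rmsd


def ensemble_pairwise_rmsd(
    ensemble: StructureEnsemble, selection: Selection | str
) -> tuple[float, float, int]:
    """Mean +/- sd RMSD over all unordered model pairs on a selection.

    Each pair is superposed on the selection itself before scoring.  Returns
    ``(mean, sd, n_pairs)``; sd is the sample standard deviation (0 for a
    single pair).
    """
    if ensemble.n_models < 2:
        raise GeometryError("pairwise RMSD needs at least two models")
    idx = select(ensemble, selection)
    coords = ensemble.coords[:, idx, :]
    rmsds = []
    for i, j in itertools.combinations(range(ensemble.n_models), 2):
        _, _, r = kabsch_superpose(coords[i], coords[j])
        rmsds.append(r)
    arr = np.asarray(rmsds)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd, len(arr)


@dataclasses.dataclass(frozen=True)
class HelixSegment:
    """Axis fit to a helical segment: point on axis, unit direction (N->C)."""

    point: np.ndarray
    direction: np.ndarray
    anisotropy: float  # ratio of 1st to 2nd singular value of the CA cloud
    n_res: int

    @property
    def well_defined(self) -> bool:
        """False for blob-like (non-elongated) point clouds."""
        return self.anisotropy >= 1.5


def fit_helix_axis(ca_coords: np.ndarray) -> HelixSegment:
    """Principal axis of a C-alpha cloud, oriented from first toward last residue."""
    X = np.asarray(ca_coords, float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise GeometryError("expected (n, 3) C-alpha coordinates")
    if X.shape[0] < 4:
        raise GeometryError("need at least 4 residues to fit a helix axis")
    centroid = X.mean(axis=0)
    _, S, Vt = np.linalg.svd(X - centroid)
    direction = Vt[0]
    if np.dot(direction, X[-1] - X[0]) < 0:
        direction = -direction
    anisotropy = float(S[0] / S[1]) if S[1] > 1e-12 else float("inf")
    return HelixSegment(point=centroid, direction=direction / np.linalg.norm(direction),
                        anisotropy=anisotropy, n_res=X.shape[0])


def interhelical_angle(seg1: HelixSegment, seg2: HelixSegment) -> float:
    """Angle between two N->C oriented helix axes, degrees in [0, 180]."""
    c = float(np.clip(np.dot(seg1.direction, seg2.direction), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


@dataclasses.dataclass
class EFHandAngles:
    """Per-model and mean interhelical angle of an EF-hand site, with a state call."""

    site: str
    per_model: np.ndarray  # degrees, one per model
    mean: float
    sd: float
    call: str  # closed | semi-open | open | unassigned


def efhand_angle(
    ensemble: StructureEnsemble,
    helix1: Selection | str,
    helix2: Selection | str,
    site: str = "",
    closed_ref: float | None = None,
    open_ref: float | None = None,
    window: float = 15.0,
) -> EFHandAngles:
    """Interhelical angle of an EF-hand helix pair for every model.

    ``closed_ref``/``open_ref`` are reference angles (degrees) measured with
    this same axis convention on apo and Ca2+-loaded structures; the state
    call is *closed*/*open* when within ``window`` degrees of the respective
    reference, *semi-open* when strictly between the two windows, and
    *unassigned* when references are not supplied or the angle falls outside
    the bracket.
    """
    def _ca(selection: Selection | str) -> np.ndarray:
        if isinstance(selection, str):
            selection = Selection.parse(selection)
        sel = dataclasses.replace(selection, atom_class="named", atom_names=("CA",))
        return select(ensemble, sel)

    i1, i2 = _ca(helix1), _ca(helix2)
    angles = []
    for m in range(ensemble.n_models):
        a1 = fit_helix_axis(ensemble.coords[m, i1])
        a2 = fit_helix_axis(ensemble.coords[m, i2])
        angles.append(interhelical_angle(a1, a2))
    arr = np.asarray(angles)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0

    call = "unassigned"
    if closed_ref is not None and open_ref is not None:
        lo, hi = sorted((closed_ref, open_ref))
        if abs(mean - closed_ref) <= window:
            call = "closed"
        elif abs(mean - open_ref) <= window:
            call = "open"
        elif lo < mean < hi:
            call = "semi-open"
    return EFHandAngles(site=site, per_model=arr, mean=mean, sd=sd, call=call)


@dataclasses.dataclass(frozen=True)
class HBond:
    donor: tuple[str, int, str]      # (chain, res_seq, atom_name)
    acceptor: tuple[str, int, str]
    distance: float
    model_id: int


def hbond_scan(
    ensemble: StructureEnsemble,
    donors: Selection | str,
    acceptors: Selection | str,
    d_cutoff: float = 3.5,
) -> tuple[list[HBond], dict[tuple[tuple, tuple], float]]:
    """Distance-criterion hydrogen-bond scan over all models.

    Every donor-acceptor atom pair within ``d_cutoff`` (A) counts as a bond
    in that model.  The default 3.5 A suits heavy-atom (N...O) distances; use
    ~2.5-3.0 A when the donor selection names the hydrogens themselves.
    Returns the per-model bond list and a persistence map
    ``(donor, acceptor) -> fraction of models containing the bond``.
    """
    di = select(ensemble, donors)
    ai = select(ensemble, acceptors)
    bonds: list[HBond] = []
    seen_in_models: dict[tuple[tuple, tuple], int] = {}
    for m in range(ensemble.n_models):
        D = ensemble.coords[m, di]
        A = ensemble.coords[m, ai]
        dist = np.linalg.norm(D[:, None, :] - A[None, :, :], axis=2)
        for p, q in zip(*np.where(dist <= d_cutoff)):
            da, aa = ensemble.atoms[di[p]], ensemble.atoms[ai[q]]
            if da.key() == aa.key():
                continue
            bond = HBond(donor=da.key(), acceptor=aa.key(),
                         distance=float(dist[p, q]), model_id=m + 1)
            bonds.append(bond)
            seen_in_models[(da.key(), aa.key())] = seen_in_models.get((da.key(), aa.key()), 0) + 1
    persistence = {k: v / ensemble.n_models for k, v in seen_in_models.items()}
    return bonds, persistence
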