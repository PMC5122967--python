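"""NOE distance restraints, violation statistics and RDC/Saupe-tensor fitting.

Distance restraints carry (possibly multi-atom, i.e. ambiguous) selections on
each side.  Effective distances for ambiguous restraints use r^-6 summation,

    r_eff = ( sum_{a in A, b in B} r_ab^-6 )^(-1/6),

the standard treatment for ambiguous NOEs, and the violation of a restraint
is max(0, r_eff - upper, lower - r_eff).  Ensemble statistics average the
per-restraint violations within each model first, then report mean +/- sd
over models — the convention behind "0.0xx +/- 0.00x A" style tables; the
alternative mean over violated restraints only is reported alongside.

The Saupe (alignment) order matrix is fitted to observed H-N couplings by
linear least squares over its five independent elements:

    D_i = b_i^T S b_i,   S traceless symmetric,

with b_i the unit N->H bond vector.  The axial component Da = S_zz / 2 and
rhombicity R = (2/3) (S_xx - S_yy) / S_zz follow the usual |S_zz| >= |S_yy|
>= |S_xx| eigenvalue ordering, which confines R to [0, 2/3].
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .structure_io import StructureEnsemble

__all__ = [
    "RestraintError",
    "AtomRef",
    "DistanceRestraint",
    "RDCRecord",
    "SaupeTensor",
    "ViolationStats",
    "parse_restraints",
    "write_restraints_tsv",
    "categorize",
    "violations",
    "nh_vectors",
    "fit_saupe",
    "backcalc_rdc",
    "q_factor",
    "da_rhombicity",
    "CATEGORIES",
]

AtomRef = tuple[str, int, str]  # (chain, res_seq, atom_name)

CATEGORIES = (
    "intraresidue", "sequential", "medium", "long",
    "intermolecular", "ambiguous", "hbond",
)


class RestraintError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class DistanceRestraint:
    """A (possibly ambiguous) distance bound between two atom groups."""

    group_a: tuple[AtomRef, ...]
    group_b: tuple[AtomRef, ...]
    lower: float
    upper: float
    source: str = "noe"

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise RestraintError("empty atom group in restraint")
        if not (0 < self.lower <= self.upper):
            raise RestraintError(
                f"invalid bounds [{self.lower}, {self.upper}] (need 0 < lower <= upper)"
            )


@dataclasses.dataclass(frozen=True)
class RDCRecord:
    chain_id: str
    res_seq: int
    d_obs: float  # Hz
    atom_pair: tuple[str, str] = ("N", "H")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def parse_restraints(
    path: str | Path, dialect: str = "native_tsv"
) -> tuple[list[DistanceRestraint], list[str]]:
    """Parse a restraint file; returns (restraints, rejected-line report).

    ``native_tsv`` columns: chainA resA atomA chainB resB atomB lower upper
    [source]; atomA/atomB may be '|'-separated lists (ambiguity).  The
    ``xplor_assign`` dialect understands ``assign (sel) (sel) d dminus dplus``
    with ``segid``/``resid``/``name`` clauses joined by ``or`` inside each
    selection; bounds become [d - dminus, d + dplus].
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise RestraintError(f"{path}: empty restraint file")
    if dialect == "native_tsv":
        return _parse_native_tsv(text)
    if dialect == "xplor_assign":
        return _parse_xplor(text)
    raise RestraintError(f"unknown restraint dialect {dialect!r}")


def _parse_native_tsv(text: str) -> tuple[list[DistanceRestraint], list[str]]:
    out: list[DistanceRestraint] = []
    rejected: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 8:
            rejected.append(f"line {lineno}: expected >=8 fields, got {len(fields)}")
            continue
        try:
            ca, ra, aa, cb, rb, ab, lo, hi = fields[:8]
            source = fields[8] if len(fields) > 8 else "noe"
            ga = tuple((ca, int(ra), n) for n in aa.split("|"))
            gb = tuple((cb, int(rb), n) for n in ab.split("|"))
            out.append(DistanceRestraint(ga, gb, float(lo), float(hi), source))
        except (ValueError, RestraintError) as exc:
            rejected.append(f"line {lineno}: {exc}")
    if not out and not rejected:
        raise RestraintError("no restraints found")
    return out, rejected


_XPLOR_SEL = re.compile(
    r"(?:segid\s+(\w+))?\s*(?:and\s+)?resid\s+(\d+)\s+and\s+name\s+([\w#*+%]+)",
    re.IGNORECASE,
)


def _parse_xplor_selection(sel: str) -> tuple[AtomRef, ...] | None:
    refs: list[AtomRef] = []
    for clause in re.split(r"\bor\b", sel, flags=re.IGNORECASE):
        m = _XPLOR_SEL.search(clause)
        if not m:
            return None
        segid = m.group(1) or "A"
        refs.append((segid, int(m.group(2)), m.group(3).upper()))
    return tuple(refs)


def _parse_xplor(text: str) -> tuple[list[DistanceRestraint], list[str]]:
    out: list[DistanceRestraint] = []
    rejected: list[str] = []
    # normalize whitespace so each 'assign' statement is one unit
    stmts = re.split(r"(?i)\bassign\b", re.sub(r"\s+", " ", text))
    for stmt in stmts:
        stmt = stmt.strip()
        if not stmt or stmt.startswith("!"):
            continue
        m = re.match(
            r"\((?P<sa>.+?)\)\s*\((?P<sb>.+?)\)\s*"
            r"(?P<d>[\d.]+)\s+(?P<dm>[\d.]+)\s+(?P<dp>[\d.]+)",
            stmt,
        )
        if not m:
            rejected.append(f"unparsed statement: {stmt[:60]!r}")
            continue
        ga = _parse_xplor_selection(m.group("sa"))
        gb = _parse_xplor_selection(m.group("sb"))
        if ga is None or gb is None:
            rejected.append(f"unresolvable selection in: {stmt[:60]!r}")
            continue
        d, dm, dp = (float(m.group(k)) for k in ("d", "dm", "dp"))
        try:
            out.append(DistanceRestraint(ga, gb, d - dm, d + dp, "noe"))
        except RestraintError as exc:
            rejected.append(f"{stmt[:40]!r}: {exc}")
    if not out and not rejected:
        raise RestraintError("no assign statements found")
    return out, rejected


def write_restraints_tsv(restraints: Iterable[DistanceRestraint], path: str | Path) -> Path:
    path = Path(path)
    lines = ["#chainA\tresA\tatomA\tchainB\tresB\tatomB\tlower\tupper\tsource"]
    for r in restraints:
        ca, ra = r.group_a[0][0], r.group_a[0][1]
        cb, rb = r.group_b[0][0], r.group_b[0][1]
        aa = "|".join(n for _, _, n in r.group_a)
        ab = "|".join(n for _, _, n in r.group_b)
        lines.append(f"{ca}\t{ra}\t{aa}\t{cb}\t{rb}\t{ab}\t{r.lower:.3f}\t{r.upper:.3f}\t{r.source}")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Categorisation (structure-statistics table convention)
# ---------------------------------------------------------------------------

def categorize(
    restraints: Sequence[DistanceRestraint],
    chain_map: Mapping[str, str] | None = None,
) -> dict[str, int]:
    """Count restraints per category.

    Precedence: hydrogen-bond source tag, then intermolecular (chains
    differ), then ambiguous (either side spans multiple residues), then the
    sequence-separation classes |i-j| = 0 / 1 / (1,5) / >= 5.  The returned
    dict also carries ``ambiguous_or_groups``: the count of restraints with
    any multi-atom side regardless of residue span, the alternative reading
    of "ambiguous" some tables use.
    """
    counts = {c: 0 for c in CATEGORIES}
    or_groups = 0
    for r in restraints:
        if len(r.group_a) > 1 or len(r.group_b) > 1:
            or_groups += 1
        if r.source == "hbond":
            counts["hbond"] += 1
            continue
        chains_a = {c for c, _, _ in r.group_a}
        chains_b = {c for c, _, _ in r.group_b}
        if chains_a.isdisjoint(chains_b):
            counts["intermolecular"] += 1
            continue
        res_a = {x for _, x, _ in r.group_a}
        res_b = {x for _, x, _ in r.group_b}
        if len(res_a) > 1 or len(res_b) > 1:
            counts["ambiguous"] += 1
            continue
        sep = abs(next(iter(res_a)) - next(iter(res_b)))
        if sep == 0:
            counts["intraresidue"] += 1
        elif sep == 1:
            counts["sequential"] += 1
        elif sep < 5:
            counts["medium"] += 1
        else:
            counts["long"] += 1
    counts["ambiguous_or_groups"] = or_groups
    return counts


# ---------------------------------------------------------------------------
# Violations
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ViolationStats:
    per_restraint_mean: np.ndarray    # mean violation of each restraint over models (A)
    per_model_mean: np.ndarray        # mean violation over restraints, per model (A)
    mean: float                       # mean of per_model_mean
    sd: float                         # sd of per_model_mean over models
    max: float                        # largest single violation anywhere
    mean_violated_only: float         # alternative convention
    n_excluded: int                   # restraints dropped for unresolvable atoms


def _r_eff(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    d = np.linalg.norm(coords_a[:, None, :] - coords_b[None, :, :], axis=2)
    return float(np.sum(d ** -6.0) ** (-1.0 / 6.0))


def violations(
    ensemble: StructureEnsemble, restraints: Sequence[DistanceRestraint]
) -> ViolationStats:
    """Per-model and ensemble violation statistics with r^-6 ambiguity averaging."""
    index = ensemble.atom_index()
    resolved: list[tuple[np.ndarray, np.ndarray, float, float]] = []
    n_excluded = 0
    for r in restraints:
        try:
            ia = np.array([index[ref] for ref in r.group_a])
            ib = np.array([index[ref] for ref in r.group_b])
        except KeyError:
            n_excluded += 1
            continue
        resolved.append((ia, ib, r.lower, r.upper))
    if not resolved:
        raise RestraintError("no restraint could be resolved against the ensemble")
    M = ensemble.n_models
    viol = np.zeros((M, len(resolved)))
    for m in range(M):
        X = ensemble.coords[m]
        for k, (ia, ib, lo, hi) in enumerate(resolved):
            r_eff = _r_eff(X[ia], X[ib])
            viol[m, k] = max(0.0, r_eff - hi, lo - r_eff)
    per_model = viol.mean(axis=1)
    violated = viol[viol > 0]
    return ViolationStats(
        per_restraint_mean=viol.mean(axis=0),
        per_model_mean=per_model,
        mean=float(per_model.mean()),
        sd=float(per_model.std(ddof=1)) if M > 1 else 0.0,
        max=float(viol.max()),
        mean_violated_only=float(violated.mean()) if violated.size else 0.0,
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# RDC / Saupe tensor
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SaupeTensor:
    """Traceless symmetric order matrix, Hz-scaled (absorbs the dipolar prefactor)."""

    matrix: np.ndarray  # (3, 3)

    def __post_init__(self) -> None:
        S = np.asarray(self.matrix, float)
        if S.shape != (3, 3):
            raise RestraintError("Saupe matrix must be 3x3")
        if not np.allclose(S, S.T, atol=1e-9):
            raise RestraintError("Saupe matrix must be symmetric")
        if abs(np.trace(S)) > 1e-6 * max(1.0, np.abs(S).max()):
            raise RestraintError("Saupe matrix must be traceless")
        self.matrix = S

    @classmethod
    def from_da_rhombicity(
        cls, da: float, rhombicity: float, rotation: np.ndarray | None = None
    ) -> "SaupeTensor":
        """Construct from axial component Da (Hz) and rhombicity R in [0, 2/3]."""
        if not (0 <= rhombicity <= 2.0 / 3.0):
            raise RestraintError("rhombicity must lie in [0, 2/3]")
        szz = 2.0 * da
        sxx = szz * (-1.0 + 1.5 * rhombicity) / 2.0
        syy = szz * (-1.0 - 1.5 * rhombicity) / 2.0
        S = np.diag([sxx, syy, szz])
        if rotation is not None:
            R = np.asarray(rotation, float)
            S = R @ S @ R.T
        return cls(S)

    @property
    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues ordered |Szz| >= |Syy| >= |Sxx| (returned as [Sxx, Syy, Szz])."""
        w = np.linalg.eigvalsh(self.matrix)
        order = np.argsort(np.abs(w))  # ascending |.|: Sxx, Syy, Szz
        return w[order]

    @property
    def da(self) -> float:
        return float(self.eigenvalues[2] / 2.0)

    @property
    def rhombicity(self) -> float:
        sxx, syy, szz = self.eigenvalues
        if szz == 0:
            raise RestraintError("Szz = 0: Da/rhombicity undefined")
        return float((2.0 / 3.0) * (sxx - syy) / szz)

    @property
    def five(self) -> np.ndarray:
        """Independent elements (Sxx, Syy, Sxy, Sxz, Syz) of the matrix frame."""
        S = self.matrix
        return np.array([S[0, 0], S[1, 1], S[0, 1], S[0, 2], S[1, 2]])


def nh_vectors(
    ensemble: StructureEnsemble,
    records: Sequence[RDCRecord],
    model: int = 0,
) -> tuple[np.ndarray, list[RDCRecord]]:
    """Unit N->H bond vectors for the records resolvable in the given model."""
    index = ensemble.atom_index()
    vecs, kept = [], []
    X = ensemble.coords[model]
    for rec in records:
        na, ha = rec.atom_pair
        try:
            i_n = index[(rec.chain_id, rec.res_seq, na)]
            i_h = index[(rec.chain_id, rec.res_seq, ha)]
        except KeyError:
            continue
        v = X[i_h] - X[i_n]
        nrm = np.linalg.norm(v)
        if nrm < 1e-6:
            continue
        vecs.append(v / nrm)
        kept.append(rec)
    return np.asarray(vecs), kept


def _design_matrix(b: np.ndarray) -> np.ndarray:
    bx, by, bz = b[:, 0], b[:, 1], b[:, 2]
    return np.column_stack([
        bx ** 2 - bz ** 2,
        by ** 2 - bz ** 2,
        2 * bx * by,
        2 * bx * bz,
        2 * by * bz,
    ])


def fit_saupe(
    ensemble: StructureEnsemble,
    records: Sequence[RDCRecord],
    model: int = 0,
) -> tuple[SaupeTensor, dict]:
    """Least-squares Saupe tensor from observed couplings on one model.

    Returns the tensor and a diagnostics dict with the residual rms,
    back-calculated couplings, Q factor and design-matrix condition number.
    Raises when fewer than 5 independent vectors are available (the five
    tensor elements would be under-determined).
    """
    b, kept = nh_vectors(ensemble, records, model)
    if len(kept) < 5:
        raise RestraintError(f"only {len(kept)} usable N-H vectors; need >= 5")
    A = _design_matrix(b)
    d_obs = np.array([r.d_obs for r in kept])
    if np.linalg.matrix_rank(A, tol=1e-8) < 5:
        raise RestraintError("alignment tensor under-determined (degenerate bond vectors)")
    x, _, _, sv = np.linalg.lstsq(A, d_obs, rcond=None)
    sxx, syy, sxy, sxz, syz = x
    S = np.array([
        [sxx, sxy, sxz],
        [sxy, syy, syz],
        [sxz, syz, -sxx - syy],
    ])
    tensor = SaupeTensor(S)
    d_calc = A @ x
    diag = {
        "condition_number": float(sv[0] / sv[-1]),
        "rms_residual": float(np.sqrt(np.mean((d_obs - d_calc) ** 2))),
        "d_calc": d_calc,
        "records": kept,
        "q_factor": q_factor(d_obs, d_calc),
    }
    return tensor, diag


def backcalc_rdc(
    ensemble: StructureEnsemble,
    tensor: SaupeTensor,
    records: Sequence[RDCRecord],
    model: int = 0,
) -> np.ndarray:
    """Couplings D_i = b_i^T S b_i (Hz) for each record's N-H vector."""
    b, kept = nh_vectors(ensemble, records, model)
    if len(kept) != len(records):
        missing = len(records) - len(kept)
        raise RestraintError(f"{missing} RDC records lack N/H atoms in the structure")
    return np.einsum("ij,jk,ik->i", b, tensor.matrix, b)


def q_factor(d_obs: np.ndarray, d_calc: np.ndarray) -> float:
    """Cornilescu-style quality factor sqrt(sum (obs-calc)^2 / sum obs^2)."""
    d_obs = np.asarray(d_obs, float)
    d_calc = np.asarray(d_calc, float)
    denom = float(np.sum(d_obs ** 2))
    if denom == 0:
        raise RestraintError("Q factor undefined: observed couplings are all zero")
    return float(np.sqrt(np.sum((d_obs - d_calc) ** 2) / denom))


def da_rhombicity(tensor: SaupeTensor) -> tuple[float, float]:
    """(Da in Hz, rhombicity) of an alignment tensor."""
    return tensor.da, tensor.rhombicity
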