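"""Chemical-shift perturbation, titration saturation, CSI calls and het-NOE ratios.

The combined amide perturbation between two states uses the weighted
Euclidean norm

    d_comb = sqrt(dH^2 + (alpha * dN)^2),

with alpha defaulting to 0.2 — the widespread dN/5 scaling that puts the
15N dimension on the 1H ppm scale.  Steady-state 15N{1H} NOE ratios are
I_sat / I_nosat with the uncertainty propagated from the spectral noise sd,

    sigma_NOE = |ratio| * sqrt((s_sat/I_sat)^2 + (s_nosat/I_nosat)^2).

Shift tables are plain DataFrames with columns ``res_seq, res_name, H_ppm,
N_ppm`` and optionally ``CA_ppm, CB_ppm, CO_ppm``; missing observations are
NaN and stay missing through every operation (never imputed, never zero).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ShiftAnalysisError",
    "DEFAULT_ALPHA",
    "RANDOM_COIL_CA",
    "read_shift_table",
    "write_shift_table",
    "combined_shift_change",
    "csp_profile",
    "region_mean",
    "saturation_check",
    "csi_call",
    "hetnoe",
]

DEFAULT_ALPHA = 0.2

# Random-coil C-alpha shifts (ppm) for CSI-style secondary-structure calls.
RANDOM_COIL_CA: dict[str, float] = {
    "ALA": 52.5, "ARG": 56.0, "ASN": 52.8, "ASP": 54.2, "CYS": 58.2,
    "GLN": 56.2, "GLU": 56.6, "GLY": 45.1, "HIS": 55.0, "ILE": 61.1,
    "LEU": 55.1, "LYS": 56.2, "MET": 55.4, "PHE": 57.7, "PRO": 63.3,
    "SER": 58.3, "THR": 61.8, "TRP": 57.5, "TYR": 57.9, "VAL": 62.2,
}


class ShiftAnalysisError(ValueError):
    pass


def read_shift_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"res_seq", "H_ppm", "N_ppm"}
    if not required <= set(df.columns):
        raise ShiftAnalysisError(f"{path}: shift table needs columns {sorted(required)}")
    if df["res_seq"].duplicated().any():
        raise ShiftAnalysisError(f"{path}: duplicate residues in shift table")
    return df


def write_shift_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
    return path


def combined_shift_change(dH, dN, alpha: float = DEFAULT_ALPHA):
    """Weighted combined amide shift change (ppm); NaN-propagating, vectorized."""
    if alpha <= 0:
        raise ShiftAnalysisError("alpha must be positive")
    dH = np.asarray(dH, float)
    dN = np.asarray(dN, float)
    out = np.sqrt(dH ** 2 + (alpha * dN) ** 2)
    return float(out) if out.ndim == 0 else out


def csp_profile(
    free: pd.DataFrame, bound: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Per-residue perturbation profile between two states.

    Columns: res_seq, dH, dN, d_comb; a residue missing (or NaN) in either
    state is present with NaN.  The weighting used is stored in
    ``df.attrs["alpha"]``.
    """
    merged = free.merge(bound, on="res_seq", how="outer", suffixes=("_free", "_bound"))
    if merged.empty or not (
        merged["H_ppm_free"].notna() & merged["H_ppm_bound"].notna()
    ).any():
        raise ShiftAnalysisError("free and bound tables share no measured residues")
    dH = merged["H_ppm_bound"] - merged["H_ppm_free"]
    dN = merged["N_ppm_bound"] - merged["N_ppm_free"]
    out = pd.DataFrame({
        "res_seq": merged["res_seq"].astype(int),
        "dH": dH,
        "dN": dN,
        "d_comb": combined_shift_change(dH.to_numpy(), dN.to_numpy(), alpha),
    }).sort_values("res_seq", ignore_index=True)
    out.attrs["alpha"] = alpha
    return out


def region_mean(profile: pd.DataFrame, residue_range: tuple[int, int]) -> tuple[float, int]:
    """Arithmetic mean of d_comb over a residue range; returns (mean, n_used)."""
    lo, hi = residue_range
    sub = profile[(profile["res_seq"] >= lo) & (profile["res_seq"] <= hi)]["d_comb"].dropna()
    if sub.empty:
        raise ShiftAnalysisError(f"no measured residues in range {lo}-{hi}")
    return float(sub.mean()), int(sub.size)


def saturation_check(
    titration: Sequence[tuple[float, pd.DataFrame]],
    tol: float = 0.005,
) -> float | None:
    """Molar ratio at which a titration stops moving.

    ``titration`` is a list of (molar_ratio, CSP profile vs the free state),
    ratios strictly increasing.  Returns the smallest ratio after which the
    mean absolute per-residue change of d_comb to the next point drops below
    ``tol`` (ppm), or None when the series never saturates.
    """
    if len(titration) < 3:
        raise ShiftAnalysisError("need at least 3 titration points")
    ratios = [r for r, _ in titration]
    if any(b <= a for a, b in zip(ratios, ratios[1:])):
        raise ShiftAnalysisError("molar ratios must be strictly increasing")
    for (r_prev, p_prev), (r_next, p_next) in zip(titration, titration[1:]):
        merged = p_prev.merge(p_next, on="res_seq", suffixes=("_a", "_b"))
        diff = (merged["d_comb_b"] - merged["d_comb_a"]).abs().dropna()
        if not diff.empty and float(diff.mean()) < tol:
            return r_prev
    return None


def csi_call(
    shift_table: pd.DataFrame,
    random_coil: Mapping[str, float] | None = None,
    deadband: float = 0.7,
    min_run: int = 4,
) -> pd.DataFrame:
    """Simplified C-alpha chemical-shift-index secondary-structure calls.

    Index per residue: +1 if (CA_obs - CA_coil) > +deadband, -1 if below
    -deadband, else 0.  Runs of >= ``min_run`` consecutive +1 become H
    (helix), runs of -1 become E (strand), everything else C (coil).
    """
    if "CA_ppm" not in shift_table.columns or shift_table["CA_ppm"].dropna().empty:
        raise ShiftAnalysisError(
            "no C-alpha shifts present; CSI needs carbon data "
            "(use the amide-only CSP operations otherwise)"
        )
    coil = dict(RANDOM_COIL_CA if random_coil is None else random_coil)
    df = shift_table.sort_values("res_seq", ignore_index=True)
    delta = np.array([
        row.CA_ppm - coil.get(row.res_name, np.nan) for row in df.itertuples()
    ])
    idx = np.where(np.isnan(delta), 0, np.sign(delta) * (np.abs(delta) > deadband))
    idx = idx.astype(int)
    call = np.full(len(df), "C", dtype="<U1")
    run_start = 0
    for i in range(1, len(idx) + 1):
        if i == len(idx) or idx[i] != idx[run_start] or df.res_seq[i] != df.res_seq[i - 1] + 1:
            if i - run_start >= min_run and idx[run_start] != 0:
                call[run_start:i] = "H" if idx[run_start] > 0 else "E"
            run_start = i
    return pd.DataFrame({
        "res_seq": df["res_seq"],
        "delta_ca": delta,
        "index": idx,
        "call": call,
    })


def hetnoe(
    sat: pd.DataFrame,
    nosat: pd.DataFrame,
    noise_sd_sat: float,
    noise_sd_nosat: float,
) -> pd.DataFrame:
    """Steady-state heteronuclear NOE ratios with propagated uncertainties.

    ``sat``/``nosat`` carry columns res_seq, intensity.  Rows whose reference
    intensity is within 3x the spectral noise are flagged unreliable and get
    NaN ratios (they would otherwise produce arbitrarily wild values).
    """
    if noise_sd_sat <= 0 or noise_sd_nosat <= 0:
        raise ShiftAnalysisError("noise standard deviations must be positive")
    merged = sat.merge(nosat, on="res_seq", suffixes=("_sat", "_nosat"))
    i_sat = merged["intensity_sat"].to_numpy(float)
    i_nosat = merged["intensity_nosat"].to_numpy(float)
    unreliable = np.abs(i_nosat) <= 3 * noise_sd_nosat
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = i_sat / i_nosat
        sigma = np.abs(ratio) * np.sqrt(
            (noise_sd_sat / i_sat) ** 2 + (noise_sd_nosat / i_nosat) ** 2
        )
    ratio[unreliable] = np.nan
    sigma[unreliable] = np.nan
    return pd.DataFrame({
        "res_seq": merged["res_seq"].astype(int),
        "I_sat": i_sat,
        "I_nosat": i_nosat,
        "noe": ratio,
        "sigma_noe": sigma,
        "unreliable": unreliable,
    })
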