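"""CSV interfaces: DSC curves, Kissinger point sets, spectral series.

All on-disk temperatures are °C and heating rates °C·min⁻¹ (matching how
thermal-analysis tables are printed); kelvin is used in memory.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics_models import DSCCurve
from .raman_unmix import Spectrum, SpectrumSeries

__all__ = [
    "read_dsc_csv",
    "write_dsc_csv",
    "read_kissinger_csv",
    "read_spectrum_series_csv",
    "write_spectrum_series_csv",
]

C0 = 273.15


def write_dsc_csv(curve: DSCCurve, path, sidecar: bool = True) -> None:
    """One curve per file, header ``T_C,phi_W_per_g``; metadata sidecar."""
    path = Path(path)
    pd.DataFrame({"T_C": curve.T - C0, "phi_W_per_g": curve.phi}).to_csv(
        path, index=False
    )
    if sidecar:
        meta = path.with_suffix(path.suffix + ".meta")
        meta.write_text(
            f"q_plus_C_min = {curve.q_plus}\n"
            f"dH_total_J_g = {curve.dH_total}\n"
            f"sign_convention = {curve.sign_convention}\n"
        )


def _read_keyvalue(path: Path) -> dict:
    out = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        k, v = (s.strip() for s in line.split("=", 1))
        try:
            out[k] = float(v)
        except ValueError:
            out[k] = v
    return out


def read_dsc_csv(path, q_plus: float | None = None) -> DSCCurve:
    """Read a ``T_C,phi_W_per_g`` curve; q⁺ from the sidecar unless given."""
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = path.with_suffix(path.suffix + ".meta")
    meta = _read_keyvalue(meta_path) if meta_path.exists() else {}
    if q_plus is None:
        q_plus = meta.get("q_plus_C_min")
    if q_plus is None:
        raise ValueError("heating rate not given and no sidecar found")
    T = df["T_C"].to_numpy() + C0
    phi = df["phi_W_per_g"].to_numpy()
    return DSCCurve(
        T=T,
        phi=phi,
        dH_total=float(meta.get("dH_total_J_g", np.nan)),
        baseline=np.zeros_like(phi),
        q_plus=float(q_plus),
        sign_convention=str(meta.get("sign_convention", "exo up")),
    )


def read_kissinger_csv(path) -> pd.DataFrame:
    """Columns ``q_C_min``, ``T_char_C`` and optional ``label``."""
    df = pd.read_csv(path)
    missing = {"q_C_min", "T_char_C"} - set(df.columns)
    if missing:
        raise ValueError(f"Kissinger CSV missing column(s) {sorted(missing)}")
    return df


def write_spectrum_series_csv(series: SpectrumSeries, path, stamps_path) -> None:
    """First column ``wavenumber_cm1``, one column per acquisition; stamp
    sidecar CSV with ``t_s`` and ``T_C`` per column."""
    data = {"wavenumber_cm1": series.spectra[0].wavenumber}
    stamps = []
    for i, s in enumerate(series.spectra):
        col = f"acq{i:04d}"
        data[col] = s.counts
        stamps.append({"column": col, "t_s": s.t_stamp, "T_C": s.T_stamp - C0})
    pd.DataFrame(data).to_csv(path, index=False)
    pd.DataFrame(stamps).to_csv(stamps_path, index=False)


def read_spectrum_series_csv(
    path, stamps_path, amorphous_ref_path, crystalline_ref_path, window
) -> SpectrumSeries:
    """Inverse of :func:`write_spectrum_series_csv`; references are
    two-column CSVs (wavenumber_cm1, counts)."""
    df = pd.read_csv(path)
    stamps = pd.read_csv(stamps_path).set_index("column")
    grid = df["wavenumber_cm1"].to_numpy()
    spectra = [
        Spectrum(
            wavenumber=grid,
            counts=df[col].to_numpy(),
            t_stamp=float(stamps.loc[col, "t_s"]),
            T_stamp=float(stamps.loc[col, "T_C"]) + C0,
        )
        for col in df.columns[1:]
    ]
    refs = []
    for p in (amorphous_ref_path, crystalline_ref_path):
        rdf = pd.read_csv(p)
        refs.append(
            Spectrum(wavenumber=rdf.iloc[:, 0].to_numpy(), counts=rdf.iloc[:, 1].to_numpy())
        )
    return SpectrumSeries(
        spectra=spectra, amorphous_ref=refs[0], crystalline_ref=refs[1], window=tuple(window)
    )
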