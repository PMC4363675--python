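"""Reading and writing spectra sets and single spectra.

CSV dialect for a :class:`~granupls.spectra.SpectraSet`: one row per
spectrum with columns ``sample_id``, ``concentration`` (mg g^-1), ``mesh``,
``replicate`` (empty once averaged), followed by one intensity column per
grid point, headed by its wavenumber. A minimal JCAMP-DX 4.24 writer and
reader (``##XYDATA=(X++(Y..Y))``, AFFN, fixed step) covers single-spectrum
export/import.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import SpectraSet, Spectrum, WavenumberGrid

__all__ = ["write_csv", "read_csv", "write_jcamp", "read_jcamp"]

_META_COLS = ["sample_id", "concentration", "mesh", "replicate"]


def write_csv(data: SpectraSet, path) -> None:
    """Write a SpectraSet in the package's CSV dialect (deterministic)."""
    cols = [f"{w:.10g}" for w in data.grid.wavenumbers]
    df = pd.DataFrame(data.intensities, columns=cols)
    df.insert(0, "replicate",
              "" if data.replicate is None else data.replicate)
    df.insert(0, "mesh", data.mesh)
    df.insert(0, "concentration", data.concentrations)
    df.insert(0, "sample_id", data.sample_ids)
    df.to_csv(path, index=False, float_format="%.10g")


def read_csv(path) -> SpectraSet:
    """Read the CSV dialect back into a SpectraSet.

    The grid is reconstructed from the wavenumber headers; ascending
    storage is accepted and normalised to the canonical descending
    orientation.
    """
    df = pd.read_csv(path)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"CSV is missing required columns {missing}")
    wn = np.array([float(c) for c in df.columns[len(_META_COLS):]])
    if len(wn) < 8:
        raise ValueError("fewer than 8 spectral columns")
    steps = np.diff(wn)
    step = np.abs(steps).mean()
    if not np.allclose(np.abs(steps), step, rtol=1e-6):
        raise ValueError("wavenumber grid is not uniform")
    X = df.iloc[:, len(_META_COLS):].to_numpy(dtype=float)
    if wn[0] < wn[-1]:  # normalise to descending
        wn = wn[::-1]
        X = X[:, ::-1]
    grid = WavenumberGrid(start=float(wn[0]), stop=float(wn[-1]), step=float(step))
    rep = df["replicate"]
    replicate = None if rep.isna().all() else rep.to_numpy(dtype=int)
    return SpectraSet(
        grid=grid,
        intensities=X,
        concentrations=df["concentration"].to_numpy(dtype=float),
        mesh=df["mesh"].to_numpy(dtype=int),
        sample_ids=df["sample_id"].to_numpy(dtype=str),
        replicate=replicate,
    )


def write_jcamp(spectrum: Spectrum, path, title: str = "granupls spectrum") -> None:
    """Write one spectrum as a minimal JCAMP-DX 4.24 file (AFFN X++(Y..Y))."""
    wn = spectrum.wavenumbers
    y = spectrum.intensity
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=NEAR INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        f"##FIRSTX={wn[0]:.6f}",
        f"##LASTX={wn[-1]:.6f}",
        f"##DELTAX={(wn[-1] - wn[0]) / (len(wn) - 1):.6f}",
        f"##NPOINTS={len(wn)}",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 6
    for i in range(0, len(y), per_line):
        chunk = y[i:i + per_line]
        lines.append(f"{wn[i]:.4f} " + " ".join(f"{v:.8g}" for v in chunk))
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def read_jcamp(path) -> Spectrum:
    """Read a single fixed-step ``(X++(Y..Y))`` JCAMP-DX spectrum."""
    fields: dict[str, str] = {}
    ys: list[float] = []
    in_data = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper()
            if key == "XYDATA":
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            fields[key] = val.strip()
            continue
        if in_data:
            parts = line.split()
            ys.extend(float(v) for v in parts[1:])  # first token is X
    for req in ("FIRSTX", "LASTX", "NPOINTS"):
        if req not in fields:
            raise ValueError(f"JCAMP-DX file missing ##{req}")
    npts = int(fields["NPOINTS"])
    if len(ys) != npts:
        raise ValueError(f"expected {npts} Y values, found {len(ys)}")
    first, last = float(fields["FIRSTX"]), float(fields["LASTX"])
    yfac = float(fields.get("YFACTOR", "1.0"))
    xfac = float(fields.get("XFACTOR", "1.0"))
    step = abs(last - first) * xfac / (npts - 1)
    grid = WavenumberGrid(start=first * xfac, stop=last * xfac, step=step)
    return Spectrum(grid, np.array(ys) * yfac,
                    meta={"title": fields.get("TITLE", "")})
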