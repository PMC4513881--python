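"""Delimited-text readers/writers and report output.

File schemas (all plain text, comma-separated unless noted):

* anisotropy titration: columns ``conc_nM``, ``r``, optional ``r_err``.
* shift table (one file per titration point): columns ``residue``,
  ``aa``, ``dh``, ``dn``; optional ``volume``, ``ca``, ``co``,
  ``hetnoe``.
* shift-trajectory manifest (YAML): ``label_conc`` optional; ``points``
  is an ordered list of mappings with ``file``, ``equivalents``,
  ``p_total_uM``, ``r_total_uM`` and optional ``folded_volume``.
* spectra matrix: first column ``wavelength_nm``, one column per
  titration point; a YAML manifest lists ``equivalents`` per column.
* reports: JSON (machine) plus a plain-text summary; input SHA-256
  hashes are recorded for provenance.

A minimal subset of the NMR-STAR chemical-shift loop is also readable so
that BMRB-style depositions can feed the secondary-shift analysis.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anisotropy import AnisotropyTitration
from .cd import SpectraMatrix
from .nmr import ShiftTable, ShiftTrajectory, TitrationPoint

__all__ = [
    "read_titration_csv",
    "write_titration_csv",
    "read_shift_table",
    "write_shift_table",
    "read_shift_trajectory",
    "write_shift_trajectory",
    "read_spectra",
    "write_spectra",
    "read_nmr_star_shifts",
    "write_report",
    "sha256_of",
]


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _require_columns(df: pd.DataFrame, cols: set[str], path) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")


def read_titration_csv(path: str | Path, label_conc: float = 50.0) -> AnisotropyTitration:
    """Read an anisotropy titration (columns conc_nM, r[, r_err])."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, {"conc_nM", "r"}, path)
    bad = df[~np.isfinite(df["r"])]
    if len(bad):
        lines = (bad.index + 2).tolist()  # 1-based, plus header
        raise ValueError(f"{path}: non-finite anisotropy values at lines {lines}")
    return AnisotropyTitration(
        ligand_conc=df["conc_nM"].to_numpy(),
        r=df["r"].to_numpy(),
        r_err=df["r_err"].to_numpy() if "r_err" in df.columns else None,
        label_conc=label_conc,
        label=str(Path(path).stem),
    )


def write_titration_csv(t: AnisotropyTitration, path: str | Path) -> None:
    df = pd.DataFrame({"conc_nM": t.ligand_conc, "r": t.r})
    if t.r_err is not None:
        df["r_err"] = t.r_err
    df.to_csv(path, index=False)


_SHIFT_COLS = ["residue", "aa", "dh", "dn", "volume", "ca", "co", "hetnoe"]


def read_shift_table(path: str | Path) -> ShiftTable:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, {"residue", "aa", "dh", "dn"}, path)
    return ShiftTable(df[[c for c in _SHIFT_COLS if c in df.columns]].copy())


def write_shift_table(table: ShiftTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def write_shift_trajectory(traj: ShiftTrajectory, directory: str | Path) -> Path:
    """Write one CSV per point plus a manifest.yaml; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, pt in enumerate(traj.points):
        fname = f"point_{i:02d}.csv"
        write_shift_table(pt.shifts, directory / fname)
        entry = {
            "file": fname,
            "equivalents": float(pt.equivalents),
            "p_total_uM": float(pt.p_total),
            "r_total_uM": float(pt.r_total),
        }
        if pt.folded_volume is not None:
            entry["folded_volume"] = float(pt.folded_volume)
        entries.append(entry)
    manifest = directory / "manifest.yaml"
    manifest.write_text(yaml.safe_dump({"points": entries}, sort_keys=False))
    return manifest


def read_shift_trajectory(manifest_path: str | Path) -> ShiftTrajectory:
    manifest_path = Path(manifest_path)
    spec = yaml.safe_load(manifest_path.read_text())
    if not isinstance(spec, dict) or "points" not in spec:
        raise ValueError(f"{manifest_path}: manifest must contain a 'points' list")
    points = []
    for entry in spec["points"]:
        fpath = manifest_path.parent / entry["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"manifest references absent point file: {fpath}")
        points.append(
            TitrationPoint(
                equivalents=float(entry["equivalents"]),
                p_total=float(entry["p_total_uM"]),
                r_total=float(entry["r_total_uM"]),
                shifts=read_shift_table(fpath),
                folded_volume=(
                    float(entry["folded_volume"]) if "folded_volume" in entry else None
                ),
            )
        )
    return ShiftTrajectory(points)


def write_spectra(m: SpectraMatrix, path: str | Path, manifest_path: str | Path | None = None):
    """Write a spectra matrix (wavelength_nm + one column per point) and manifest."""
    path = Path(path)
    cols = {"wavelength_nm": m.wavelengths}
    for i in range(m.n_points):
        cols[f"point_{i:02d}"] = m.D[i]
    pd.DataFrame(cols).to_csv(path, index=False)
    if manifest_path is None:
        manifest_path = path.with_suffix(".manifest.yaml")
    eqs = m.equivalents.tolist() if m.equivalents is not None else None
    Path(manifest_path).write_text(yaml.safe_dump({"equivalents": eqs}, sort_keys=False))
    return Path(manifest_path)


def read_spectra(path: str | Path, manifest_path: str | Path | None = None) -> SpectraMatrix:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    _require_columns(df, {"wavelength_nm"}, path)
    point_cols = [c for c in df.columns if c != "wavelength_nm"]
    if not point_cols:
        raise ValueError(f"{path}: no titration-point columns")
    equivalents = None
    if manifest_path is None:
        candidate = path.with_suffix(".manifest.yaml")
        manifest_path = candidate if candidate.exists() else None
    if manifest_path is not None:
        spec = yaml.safe_load(Path(manifest_path).read_text())
        if spec.get("equivalents") is not None:
            equivalents = np.asarray(spec["equivalents"], dtype=float)
            if len(equivalents) != len(point_cols):
                raise ValueError(
                    f"{manifest_path}: {len(equivalents)} equivalents for "
                    f"{len(point_cols)} spectra columns"
                )
    return SpectraMatrix(
        wavelengths=df["wavelength_nm"].to_numpy(),
        D=df[point_cols].to_numpy().T,
        equivalents=equivalents,
    )


# Mapping from NMR-STAR atom names to shift-table columns; only the
# backbone nuclei the analyses consume.
_STAR_ATOMS = {"H": "dh", "N": "dn", "CA": "ca", "C": "co"}


def read_nmr_star_shifts(path: str | Path) -> ShiftTable:
    """Read a minimal NMR-STAR chemical-shift loop into a ShiftTable.

    Consumes only the ``_Atom_chem_shift`` loop tags for residue number,
    residue type, atom name and shift value; H, N, CA and C (carbonyl)
    atoms are kept.  This covers BMRB-style depositions of backbone
    assignments.
    """
    three_to_one = {
        "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
        "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
        "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
        "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
    }
    # split the file into loop_ ... stop_ blocks of (tags, data rows)
    loops: list[tuple[list[str], list[list[str]]]] = []
    tags: list[str] = []
    rows: list[list[str]] = []
    state = "outside"
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line == "loop_":
            state, tags, rows = "tags", [], []
            continue
        if state == "outside" or not line or line.startswith("#"):
            continue
        if line == "stop_":
            loops.append((tags, rows))
            state = "outside"
            continue
        if line.startswith("_"):
            if state == "tags":
                tags.append(line.split(".")[-1] if "." in line else line.lstrip("_"))
            continue
        state = "data"
        rows.append(line.split())

    def tag_index(loop_tags, *names):
        for n in names:
            if n in loop_tags:
                return loop_tags.index(n)
        return None

    i_seq = i_comp = i_atom = i_val = None
    for loop_tags, loop_rows in loops:
        i_seq = tag_index(loop_tags, "Seq_ID", "Comp_index_ID", "Residue_seq_code")
        i_comp = tag_index(loop_tags, "Comp_ID", "Residue_label")
        i_atom = tag_index(loop_tags, "Atom_ID", "Atom_name")
        i_val = tag_index(loop_tags, "Val", "Chem_shift_val", "Chem_shift_value")
        if None not in (i_seq, i_comp, i_atom, i_val):
            rows = loop_rows
            break
    else:
        raise ValueError(f"{path}: no parsable chemical-shift loop found")

    records: dict[int, dict] = {}
    for row in rows:
        if len(row) <= max(i_seq, i_comp, i_atom, i_val):
            continue
        atom = row[i_atom]
        if atom not in _STAR_ATOMS:
            continue
        seq = int(row[i_seq])
        rec = records.setdefault(
            seq, {"residue": seq, "aa": three_to_one.get(row[i_comp].upper(), "X")}
        )
        rec[_STAR_ATOMS[atom]] = float(row[i_val])
    if not records:
        raise ValueError(f"{path}: chemical-shift loop contained no usable atoms")
    df = pd.DataFrame(sorted(records.values(), key=lambda r: r["residue"]))
    for col in ("dh", "dn"):
        if col not in df.columns:
            df[col] = np.nan
    return ShiftTable(df)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_report(results: dict, directory: str | Path, name: str = "report") -> Path:
    """Write a JSON report plus a human-readable text summary.

    The JSON is deterministic for identical ``results`` (sorted keys,
    fixed separators); any timestamp should live under a separate
    ``meta`` key supplied by the caller.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    json_path = directory / f"{name}.json"
    json_path.write_text(
        json.dumps(_jsonify(results), indent=2, sort_keys=True) + "\n"
    )
    txt_path = directory / f"{name}.txt"
    lines = [f"{name} summary", "=" * (len(name) + 8)]

    def render(d, indent=0):
        for k, v in d.items():
            if isinstance(v, dict):
                lines.append("  " * indent + f"{k}:")
                render(v, indent + 1)
            elif isinstance(v, (list, np.ndarray)) and len(str(v)) > 80:
                lines.append("  " * indent + f"{k}: [{len(v)} values]")
            else:
                lines.append("  " * indent + f"{k}: {v}")

    render(_jsonify(results))
    txt_path.write_text("\n".join(lines) + "\n")
    return json_path
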