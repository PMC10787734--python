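"""Reading and writing spectra, specimen manifests and feature matrices.

Spectrum files are two-column text (mass in Da, intensity), comma- or
tab-separated, with an optional header; mzML is read by a minimal
built-in parser (first spectrum, standard base64/zlib encodings).
A collection is described by a manifest CSV with columns ``specimen_id,
replicate_id, file, species, genus, class, phylum`` (case-insensitive;
taxon columns may be blank for query-only spectra). Feature matrices
round-trip through CSV with metadata columns first and feature columns
named by their bin mass with four decimals.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .peaks import FeatureMatrix
from .spectra import RawSpectrum, TaxonLabel

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_collection",
    "write_feature_matrix",
    "read_feature_matrix",
]

_MANIFEST_COLS = ["specimen_id", "replicate_id", "file",
                  "species", "genus", "class", "phylum"]
_META_COLS = ["specimen_id", "replicate_id", "species", "genus",
              "class_", "phylum", "sex"]


def _read_mzml_arrays(path) -> tuple[np.ndarray, np.ndarray]:
    """m/z and intensity arrays of the first spectrum of an mzML file.

    A deliberately small reader for the standard encoding: base64 binary
    arrays, 32/64-bit little-endian floats, optionally zlib-compressed,
    identified by the usual PSI-MS controlled-vocabulary accessions.
    """
    import base64
    import struct
    import zlib

    from lxml import etree

    ns = "{http://psi.hupo.org/ms/mzml}"
    tree = etree.parse(str(path))
    spectrum = tree.find(f".//{ns}spectrum")
    if spectrum is None:
        spectrum = tree.find(".//spectrum")  # tolerate missing namespace
        ns = ""
    if spectrum is None:
        raise ValueError(f"{path}: mzML file contains no spectrum")
    arrays: dict[str, np.ndarray] = {}
    for bda in spectrum.iter(f"{ns}binaryDataArray"):
        accessions = {cv.get("accession")
                      for cv in bda.iter(f"{ns}cvParam")}
        node = bda.find(f"{ns}binary")
        raw = base64.b64decode((node.text or "").strip())
        if "MS:1000574" in accessions:  # zlib compression
            raw = zlib.decompress(raw)
        kind = "f" if "MS:1000521" in accessions else "d"  # 32- vs 64-bit
        width = 4 if kind == "f" else 8
        values = np.asarray(struct.unpack(f"<{len(raw) // width}{kind}", raw))
        if "MS:1000514" in accessions:
            arrays["mz"] = values
        elif "MS:1000515" in accessions:
            arrays["intensity"] = values
    if "mz" not in arrays or "intensity" not in arrays:
        raise ValueError(f"{path}: spectrum lacks m/z or intensity array")
    return arrays["mz"].astype(float), arrays["intensity"].astype(float)


def _merge_duplicates(masses: np.ndarray, intensities: np.ndarray):
    """Sort ascending and merge duplicate masses by summing intensities."""
    order = np.argsort(masses, kind="stable")
    masses, intensities = masses[order], intensities[order]
    uniq, inv = np.unique(masses, return_inverse=True)
    if len(uniq) != len(masses):
        intensities = np.bincount(inv, weights=intensities)
        masses = uniq
    return masses, intensities


def read_spectrum(path, fmt: str | None = None, **meta) -> RawSpectrum:
    """Read one spectrum from CSV/TSV (two numeric columns) or mzML.

    Rows are sorted ascending by mass; duplicate masses are merged by
    summing their intensities (the conservative choice for ion counts).
    Extra keyword arguments (``specimen_id`` etc.) are attached to the
    returned spectrum. Malformed numeric fields raise with the file line
    number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        suffix = path.suffix.lower().lstrip(".")
        fmt = {"csv": "csv", "tsv": "tsv", "txt": "csv", "mzml": "mzml"}.get(
            suffix, "csv")
    if fmt == "mzml":
        masses, intens = _read_mzml_arrays(path)
    elif fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        raw = pd.read_csv(path, sep=sep, header=None, comment="#",
                          skip_blank_lines=True, dtype=str)
        if raw.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns, found {raw.shape[1]}")
        raw = raw.iloc[:, :2]
        start = 0
        try:  # optional single header line
            float(raw.iat[0, 0]), float(raw.iat[0, 1])
        except (ValueError, TypeError):
            start = 1
        body = raw.iloc[start:]
        if body.empty:
            raise ValueError(f"{path}: no data rows")
        masses = pd.to_numeric(body.iloc[:, 0], errors="coerce").to_numpy()
        intens = pd.to_numeric(body.iloc[:, 1], errors="coerce").to_numpy()
        for name, arr in (("mass", masses), ("intensity", intens)):
            bad = np.flatnonzero(np.isnan(arr))
            if len(bad):
                line = body.index[bad[0]] + 1  # 1-based file line
                raise ValueError(
                    f"{path}: non-numeric {name} field at line {line}")
    else:
        raise ValueError(f"unknown spectrum format '{fmt}'")
    if len(masses) == 0:
        raise ValueError(f"{path}: empty spectrum")
    masses, intens = _merge_duplicates(masses, intens)
    return RawSpectrum(masses=masses, intensities=intens, **meta)


def write_spectrum(s: RawSpectrum, path) -> None:
    """Write a spectrum as two-column CSV (mass, intensity)."""
    pd.DataFrame({"mass": s.masses, "intensity": s.intensities}).to_csv(
        path, index=False, float_format="%.17g")


def read_collection(manifest_path, spectra_dir=None) -> list[RawSpectrum]:
    """Read all spectra listed in a manifest CSV, metadata attached.

    ``spectra_dir`` defaults to the manifest's directory. Missing files
    are reported all at once; duplicated (specimen_id, replicate_id)
    keys are an error. Row order is preserved.
    """
    manifest_path = Path(manifest_path)
    spectra_dir = Path(spectra_dir) if spectra_dir else manifest_path.parent
    df = pd.read_csv(manifest_path, dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    missing_cols = [c for c in _MANIFEST_COLS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"manifest lacks column(s): {', '.join(missing_cols)}")
    keys = list(zip(df["specimen_id"], df["replicate_id"]))
    if len(set(keys)) != len(keys):
        dupes = pd.Series(keys)[pd.Series(keys).duplicated()].unique()
        raise ValueError(f"duplicate (specimen_id, replicate_id): {list(dupes)}")
    paths = [spectra_dir / f for f in df["file"]]
    absent = [str(p) for p in paths if not p.exists()]
    if absent:
        raise FileNotFoundError("missing spectrum file(s): " + ", ".join(absent))
    out = []
    for (_, row), p in zip(df.iterrows(), paths):
        taxon = TaxonLabel(species=row["species"], genus=row["genus"],
                           class_=row["class"], phylum=row["phylum"],
                           sex=row.get("sex", ""))
        out.append(read_spectrum(p, specimen_id=row["specimen_id"],
                                 replicate_id=row["replicate_id"], taxon=taxon))
    return out


def _feature_column_names(feature_masses: np.ndarray) -> list[str]:
    """Bin masses formatted to 4 decimals; collisions disambiguated."""
    names, seen = [], {}
    warned = False
    for m in feature_masses:
        base = f"{m:.4f}"
        if base in seen:
            seen[base] += 1
            suffix = chr(ord("a") + seen[base])  # _b, _c, ...
            name = f"{base}_{suffix}"
            if not warned:
                warnings.warn("feature names collide after rounding to 4 "
                              "decimals; suffixing duplicates", RuntimeWarning,
                              stacklevel=3)
                warned = True
        else:
            seen[base] = 0
            name = base
        names.append(name)
    return names


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    """Write a feature matrix as CSV: metadata columns, then features."""
    if len(matrix) == 0 or matrix.intensities.shape[1] == 0:
        raise ValueError("refusing to write an empty feature matrix")
    names = _feature_column_names(matrix.feature_masses)
    out = matrix.meta[_META_COLS].copy()
    vals = pd.DataFrame(matrix.values, columns=names, index=out.index)
    pd.concat([out, vals], axis=1).to_csv(path, index=False,
                                          float_format="%.17g")


def read_feature_matrix(path) -> FeatureMatrix:
    """Read a feature matrix written by :func:`write_feature_matrix`."""
    df = pd.read_csv(path, dtype={c: str for c in _META_COLS})
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"feature matrix lacks metadata column(s): {missing}")
    meta = df[_META_COLS].fillna("")
    feat = df.drop(columns=_META_COLS)
    if feat.shape[1] == 0:
        raise ValueError("feature matrix has no feature columns")
    masses = [float(str(c).split("_")[0]) for c in feat.columns]
    # restore strictly increasing masses: suffixed duplicates get a tiny bump
    masses = np.asarray(masses)
    for j in range(1, len(masses)):
        if masses[j] <= masses[j - 1]:
            masses[j] = np.nextafter(masses[j - 1], np.inf)
    intens = pd.DataFrame(feat.to_numpy(dtype=float), columns=masses)
    idx = (meta["specimen_id"] if (meta["replicate_id"] == "").all()
           else meta["specimen_id"] + "__" + meta["replicate_id"])
    intens.index = idx.to_numpy()
    meta.index = intens.index
    return FeatureMatrix(intens, meta)
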