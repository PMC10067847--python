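"""Reading and writing of MSI-related file formats.

Centroided MSI data arrives as a processed-mode imzML/ibd pair, a full-profile
single-pixel spectrum as a two-column m/z-intensity CSV, and metabolite
annotations as a METASPACE-style CSV export.  Everything is assembled into
plain in-memory containers (:class:`PeakMatrix`, :class:`ProfileSpectrum`,
:class:`AnnotationSet`) that the rest of the package operates on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "ProfileSpectrum",
    "PeakMatrix",
    "AnnotationSet",
    "Annotation",
    "read_imzml",
    "write_imzml",
    "read_profile_csv",
    "read_annotations",
    "METASPACE_SCHEMA",
]


@dataclass
class ProfileSpectrum:
    """A single full-profile mass spectrum.

    Parameters
    ----------
    mz : ndarray
        Strictly increasing m/z values in Da.
    intensity : ndarray
        Nonnegative intensities, same length as ``mz``.
    source_pixel : tuple of int, optional
        (x, y) index of the pixel the spectrum was sampled from.
    """

    mz: np.ndarray
    intensity: np.ndarray
    source_pixel: tuple | None = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz values must be strictly increasing")
        if np.any(self.intensity < 0):
            bad = int(np.flatnonzero(self.intensity < 0)[0])
            raise ValueError(f"negative intensity at index {bad}")

    def __len__(self):
        return self.mz.size


@dataclass
class PeakMatrix:
    """Sparse pixels x binned-m/z table of centroided intensities.

    ``coords`` holds 0-based integer (x, y) grid coordinates, one row per
    measured pixel; ``values`` is a sparse nonnegative matrix with one column
    per entry of the strictly increasing ``mz_axis``.
    """

    coords: np.ndarray
    mz_axis: np.ndarray
    values: sparse.csr_matrix
    pixel_size_um: float = 50.0
    polarity: str = "positive"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=int).reshape(-1, 2)
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        if not sparse.issparse(self.values):
            self.values = sparse.csr_matrix(np.asarray(self.values, dtype=float))
        self.values = self.values.tocsr()
        if self.values.shape != (len(self.coords), len(self.mz_axis)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.coords)} pixels x {len(self.mz_axis)} m/z bins"
            )
        if self.mz_axis.size and np.any(np.diff(self.mz_axis) <= 0):
            raise ValueError("mz_axis must be strictly increasing")
        if len(self.coords):
            uniq, counts = np.unique(self.coords, axis=0, return_counts=True)
            if np.any(counts > 1):
                dup = uniq[counts > 1][0]
                raise ValueError(
                    f"duplicate pixel coordinate {(int(dup[0]), int(dup[1]))}"
                )
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("intensities must be nonnegative")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    def dense(self) -> np.ndarray:
        return self.values.toarray()


@dataclass
class Annotation:
    moi_name: str
    formula: str
    adduct: str
    theoretical_mz: float
    fdr_level: float


@dataclass
class AnnotationSet:
    """Filtered METASPACE-style annotation entries."""

    entries: list = field(default_factory=list)
    n_dropped: int = 0

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def read_imzml(path) -> PeakMatrix:
    """Read a processed (centroided) imzML/ibd pair into a :class:`PeakMatrix`.

    The 1-based pixel indices of the imzML file are converted to 0-based
    coordinates.  Continuous-mode (profile) files are rejected: the framework
    consumes vendor-centroided peak lists only.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    try:
        parser = ImzMLParser(str(path))
    except IndexError:
        # zero-spectrum file: the parser trips over empty coordinate arrays
        header = open(path, encoding="ISO-8859-1").read()
        if 'name="continuous"' in header:
            raise ValueError(
                "profile imzML unsupported; centroid first (file is continuous mode)"
            ) from None
        return PeakMatrix(np.empty((0, 2), int), np.empty(0), sparse.csr_matrix((0, 0)))
    fd = parser.metadata.pretty().get("file_description", {})
    if fd.get("continuous"):
        raise ValueError(
            "profile imzML unsupported; centroid first (file is continuous mode)"
        )
    polarity = "positive"
    spectrum_groups = parser.metadata.pretty().get("referenceable_param_groups", {})
    for grp in spectrum_groups.values():
        if grp.get("negative scan"):
            polarity = "negative"

    n = len(parser.coordinates)
    coords = np.array([(c[0] - 1, c[1] - 1) for c in parser.coordinates], int).reshape(-1, 2)
    uniq, counts = np.unique(coords, axis=0, return_counts=True) if n else (coords, np.array([]))
    if n and np.any(counts > 1):
        dup = uniq[counts > 1][0]
        raise ValueError(
            f"duplicate pixel coordinate {(int(dup[0]), int(dup[1]))} in {path}"
        )

    all_mz, all_int, row_idx = [], [], []
    for i in range(n):
        mzs, ints = parser.getspectrum(i)
        all_mz.append(np.asarray(mzs, float))
        all_int.append(np.asarray(ints, float))
        row_idx.append(np.full(len(mzs), i))
    if n and sum(a.size for a in all_mz):
        mz_cat = np.concatenate(all_mz)
        mz_axis = np.unique(mz_cat)
        col = np.searchsorted(mz_axis, mz_cat)
        rows = np.concatenate(row_idx)
        vals = np.concatenate(all_int)
        mat = sparse.coo_matrix((vals, (rows, col)), shape=(n, mz_axis.size)).tocsr()
    else:
        mz_axis = np.empty(0)
        mat = sparse.csr_matrix((n, 0))
    return PeakMatrix(coords, mz_axis, mat, polarity=polarity)


def write_imzml(pm: PeakMatrix, path) -> None:
    """Write a :class:`PeakMatrix` as a processed-mode imzML/ibd pair.

    m/z values are stored as 64-bit floats and intensities as 32-bit floats,
    the common dialect; :func:`read_imzml` accepts both widths.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if pm.n_pixels == 0:
        _write_empty_imzml(pm, path)
        return
    with ImzMLWriter(
        str(path),
        polarity=pm.polarity,
        mode="processed",
        mz_dtype=np.float64,
        intensity_dtype=np.float32,
    ) as writer:
        rows = pm.values.tocsr()
        for i, (x, y) in enumerate(pm.coords):
            row = rows.getrow(i)
            order = np.argsort(row.indices)
            mzs = pm.mz_axis[row.indices[order]]
            ints = row.data[order]
            writer.addSpectrum(mzs, ints, (int(x) + 1, int(y) + 1, 1))


_EMPTY_IMZML = """<?xml version="1.0" encoding="ISO-8859-1"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1">
  <cvList count="3">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" version="1.3.1" URI="http://psidev.info/ms/mzML/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" version="1.15" URI="http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"/>
    <cv id="IMS" fullName="Imaging MS Ontology" version="0.9.1" URI="http://www.maldi-msi.org/download/imzml/imagingMS.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="IMS" accession="IMS:1000031" name="processed" value=""/>
      <cvParam cvRef="IMS" accession="IMS:1000080" name="universally unique identifier" value="{00000000-0000-0000-0000-000000000000}"/>
    </fileContent>
  </fileDescription>
  <referenceableParamGroupList count="2">
    <referenceableParamGroup id="mzArray">
      <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="IMS" accession="IMS:1000101" name="external data" value="true"/>
    </referenceableParamGroup>
    <referenceableParamGroup id="intensityArray">
      <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
      <cvParam cvRef="MS" accession="MS:1000521" name="32-bit float" value=""/>
      <cvParam cvRef="IMS" accession="IMS:1000101" name="external data" value="true"/>
    </referenceableParamGroup>
  </referenceableParamGroupList>
  <softwareList count="1">
    <software id="spotmap" version="0"/>
  </softwareList>
  <scanSettingsList count="1">
    <scanSettings id="scanSettings1">
      <cvParam cvRef="IMS" accession="IMS:1000042" name="max count of pixels x" value="0"/>
      <cvParam cvRef="IMS" accession="IMS:1000043" name="max count of pixels y" value="0"/>
    </scanSettings>
  </scanSettingsList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1"/>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="export">
      <processingMethod order="0" softwareRef="spotmap">
        <cvParam cvRef="MS" accession="MS:1000530" name="file format conversion" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
  <run defaultInstrumentConfigurationRef="IC1" id="run0">
    <spectrumList count="0" defaultDataProcessingRef="export">
    </spectrumList>
  </run>
</mzML>
"""


def _write_empty_imzml(pm: PeakMatrix, path) -> None:
    """Zero-spectrum processed imzML/ibd pair (the writer library needs >= 1)."""
    import uuid
    from pathlib import Path

    path = Path(str(path))
    path.write_text(_EMPTY_IMZML)
    path.with_suffix(".ibd").write_bytes(uuid.UUID(int=0).bytes)


def read_profile_csv(path) -> ProfileSpectrum:
    """Read a two-column m/z-intensity CSV into a :class:`ProfileSpectrum`.

    A non-numeric header row is tolerated.  Unsorted rows are sorted with a
    warning; a negative intensity raises with the offending row index.
    """
    try:
        df = pd.read_csv(path, header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"could not parse profile CSV {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError(f"profile CSV {path} needs two columns (m/z, intensity)")
    # tolerate a header line
    first = df.iloc[0, :2]
    if not np.all([_is_number(v) for v in first]):
        df = df.iloc[1:]
    try:
        mz = df.iloc[:, 0].astype(float).to_numpy()
        inten = df.iloc[:, 1].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric values in profile CSV {path}") from exc
    if np.any(inten < 0):
        bad = int(np.flatnonzero(inten < 0)[0])
        raise ValueError(f"negative intensity in profile CSV {path} at data row {bad}")
    if np.any(np.diff(mz) < 0):
        warnings.warn("profile CSV rows were not m/z-sorted; sorting", stacklevel=2)
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
    keep = np.concatenate([[True], np.diff(mz) > 0])
    return ProfileSpectrum(mz[keep], inten[keep])


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


#: Default column names of current METASPACE annotation CSV exports.
METASPACE_SCHEMA = {
    "name": "moleculeNames",
    "formula": "formula",
    "adduct": "adduct",
    "mz": "mz",
    "fdr": "fdr",
}


def read_annotations(path, fdr_max: float = 0.2, schema: dict | None = None) -> AnnotationSet:
    """Read a METASPACE-style annotation CSV keeping entries with FDR <= ``fdr_max``.

    ``schema`` maps the logical fields (name, formula, adduct, mz, fdr) to the
    CSV column names, defaulting to the current METASPACE export header.
    """
    schema = {**METASPACE_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, comment="#")
    for key in ("formula", "adduct", "mz", "fdr"):
        if schema[key] not in df.columns:
            raise ValueError(f"annotation CSV missing required column '{schema[key]}'")
    name_col = schema["name"] if schema["name"] in df.columns else schema["formula"]
    entries, dropped = [], 0
    for _, row in df.iterrows():
        fdr = float(row[schema["fdr"]])
        if fdr > fdr_max:
            dropped += 1
            continue
        entries.append(
            Annotation(
                moi_name=str(row[name_col]),
                formula=str(row[schema["formula"]]),
                adduct=str(row[schema["adduct"]]),
                theoretical_mz=float(row[schema["mz"]]),
                fdr_level=fdr,
            )
        )
    return AnnotationSet(entries=entries, n_dropped=dropped)
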