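"""Peak-intensity tables and spectral preprocessing.

TOF-SIMS evidence enters the analysis as a table of positive-ion fragment
peak intensities: one row per recorded spectrum, one column per selected
amino-acid fragment, with per-row metadata (sample id, sample group,
substrate chemistry).  A *sample* is the set of rows sharing a
``sample_id`` — in practice several non-overlapping analysis areas of the
same physical surface.

Preprocessing follows the standard protein-SIMS recipe: restrict to a
curated fragment list, normalise each spectrum to the summed intensity of
the selected peaks (removing total-yield variation between acquisitions),
and mean-centre before fitting a principal-component model.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "IonFragment",
    "FragmentLibrary",
    "PeakTable",
    "load_default_library",
    "read_fragment_library",
    "read_peak_table",
    "write_peak_table",
    "select_peaks",
    "normalize_to_selected_sum",
    "mean_center",
]

GROUPS = ("bare", "fc_ref", "fab2_ref", "igg")
SUBSTRATES = ("APTES", "APTES_GA", "NHS_silane")
ENRICHMENT_CLASSES = ("Fc", "Fab", "neutral", "substrate")

METADATA_COLUMNS = ("sample_id", "group", "substrate")


class PeakTableFormatError(ValueError):
    """Malformed peak-table file (missing metadata, bad values)."""


@dataclass(frozen=True)
class IonFragment:
    """One secondary-ion fragment peak.

    ``enrichment_class`` records which exposed antibody domain (or the
    bare substrate) the fragment reports on: fragments of proline,
    arginine, histidine and phenylalanine are enriched in the Fc domain;
    fragments of serine, alanine, leucine and threonine in the F(ab')2
    arms; CH4N+ and the C2H5S+/SiO2H+ mass overlap carry substrate signal.
    """

    label: str
    nominal_mass: float
    amino_acid: str
    enrichment_class: str

    def __post_init__(self) -> None:
        if self.nominal_mass <= 0:
            raise ValueError(f"nominal_mass must be > 0, got {self.nominal_mass}")
        if self.enrichment_class not in ENRICHMENT_CLASSES:
            raise ValueError(
                f"enrichment_class {self.enrichment_class!r} not one of "
                f"{ENRICHMENT_CLASSES}"
            )


@dataclass(frozen=True)
class FragmentLibrary:
    """An ordered collection of :class:`IonFragment` with unique labels."""

    fragments: tuple[IonFragment, ...]

    def __post_init__(self) -> None:
        labels = [f.label for f in self.fragments]
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise ValueError(f"duplicate fragment labels: {sorted(dupes)}")

    @property
    def labels(self) -> list[str]:
        return [f.label for f in self.fragments]

    def by_class(self, enrichment_class: str) -> list[IonFragment]:
        return [f for f in self.fragments if f.enrichment_class == enrichment_class]

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)


def read_fragment_library(path) -> FragmentLibrary:
    """Read a fragment library CSV (label, nominal_mass, amino_acid, enrichment_class)."""
    df = pd.read_csv(path)
    required = {"label", "nominal_mass", "amino_acid", "enrichment_class"}
    missing = required - set(df.columns)
    if missing:
        raise PeakTableFormatError(f"fragment library missing columns: {sorted(missing)}")
    frags = tuple(
        IonFragment(
            label=str(r.label),
            nominal_mass=float(r.nominal_mass),
            amino_acid=str(r.amino_acid),
            enrichment_class=str(r.enrichment_class),
        )
        for r in df.itertuples()
    )
    return FragmentLibrary(frags)


def load_default_library() -> FragmentLibrary:
    """The packaged 36-fragment amino-acid peak list.

    The exact peak selection used in any given study is instrument- and
    protocol-specific; this default covers the standard immonium and
    related ions for all twenty amino acids, with domain-enrichment
    classes assigned for the fragments known to discriminate exposed Fc
    from F(ab')2 regions, and is fully overridable via config.
    """
    ref = importlib.resources.files("igg_orient").joinpath("data/fragment_library.csv")
    with importlib.resources.as_file(ref) as p:
        return read_fragment_library(p)


@dataclass
class PeakTable:
    """Samples-by-peaks intensity matrix with per-row metadata.

    Rows are individual recorded spectra; ``meta`` has one row per
    spectrum with columns ``sample_id``, ``group`` and ``substrate``.
    """

    meta: pd.DataFrame
    peaks: list[str]
    intensities: np.ndarray
    normalized: bool = field(default=False)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D (spectra x peaks)")
        n, p = self.intensities.shape
        if len(self.meta) != n:
            raise ValueError(
                f"metadata rows ({len(self.meta)}) != intensity rows ({n})"
            )
        if len(self.peaks) != p:
            raise ValueError(f"peak labels ({len(self.peaks)}) != columns ({p})")
        for col in METADATA_COLUMNS:
            if col not in self.meta.columns:
                raise PeakTableFormatError(f"missing metadata column {col!r}")
        if np.any(self.intensities < 0):
            i, j = np.argwhere(self.intensities < 0)[0]
            raise ValueError(
                "negative intensity at sample_id "
                f"{self.meta['sample_id'].iloc[i]!r}, peak {self.peaks[j]!r}"
            )
        bad_groups = set(self.meta["group"]) - set(GROUPS)
        if bad_groups:
            raise PeakTableFormatError(f"unknown group labels: {sorted(bad_groups)}")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meta["sample_id"])

    def subset_rows(self, mask: np.ndarray) -> "PeakTable":
        return PeakTable(
            meta=self.meta.loc[np.asarray(mask)].reset_index(drop=True),
            peaks=list(self.peaks),
            intensities=self.intensities[np.asarray(mask)],
            normalized=self.normalized,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [
                self.meta.reset_index(drop=True),
                pd.DataFrame(self.intensities, columns=self.peaks),
            ],
            axis=1,
        )


def read_peak_table(path) -> PeakTable:
    """Read a wide-CSV peak table.

    Layout: metadata columns ``sample_id,group,substrate`` first, then one
    column per peak, one row per recorded spectrum.  Negative or
    non-numeric intensities are rejected with the offending cell named.
    """
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise PeakTableFormatError(f"missing metadata column(s): {missing}")
    peak_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    if not peak_cols:
        raise PeakTableFormatError("no peak columns found")
    raw = df[peak_cols]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().values.any():
        i, j = np.argwhere(numeric.isna().values)[0]
        raise PeakTableFormatError(
            f"non-numeric intensity at row {i} (sample_id "
            f"{df['sample_id'].iloc[i]!r}), column {peak_cols[j]!r}: "
            f"{raw.iloc[i, j]!r}"
        )
    values = numeric.to_numpy(dtype=float)
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise PeakTableFormatError(
            f"negative intensity at row {i} (sample_id "
            f"{df['sample_id'].iloc[i]!r}), column {peak_cols[j]!r}"
        )
    meta = df[list(METADATA_COLUMNS)].astype(str)
    return PeakTable(meta=meta, peaks=peak_cols, intensities=values)


def write_peak_table(table: PeakTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def select_peaks(table: PeakTable, peak_list: list[str]) -> PeakTable:
    """Column-subset ``table`` to ``peak_list``, in the requested order."""
    missing = [p for p in peak_list if p not in table.peaks]
    if missing:
        raise KeyError(f"peaks not present in table: {missing}")
    idx = [table.peaks.index(p) for p in peak_list]
    return PeakTable(
        meta=table.meta.copy(),
        peaks=list(peak_list),
        intensities=table.intensities[:, idx],
        normalized=False,
    )


def normalize_to_selected_sum(table: PeakTable) -> PeakTable:
    """Divide each spectrum by its summed intensity over the selected peaks.

    Every output row sums to 1; rows with zero total intensity are an
    error (they indicate a corrupted acquisition, not real data).
    """
    sums = table.intensities.sum(axis=1)
    if np.any(sums <= 0):
        i = int(np.argmin(sums))
        raise ValueError(
            f"spectrum with non-positive total intensity: sample_id "
            f"{table.meta['sample_id'].iloc[i]!r}"
        )
    return PeakTable(
        meta=table.meta.copy(),
        peaks=list(table.peaks),
        intensities=table.intensities / sums[:, None],
        normalized=True,
    )


def mean_center(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-centre a spectra matrix; returns (centered, column means).

    The mean vector is retained so later spectra can be projected onto a
    model fitted on the centred data.  A single row cannot be centred
    meaningfully for a PCA fit and is rejected.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if matrix.shape[0] < 2:
        raise ValueError("mean-centering requires at least 2 rows")
    mean = matrix.mean(axis=0)
    return matrix - mean, mean
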