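"""Domain types shared by the pipeline stages.

The containers are thin wrappers around :mod:`pandas` objects; each validates
its invariants on construction so that downstream code can assume well-formed
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import IntegrityError, MassAssignmentError, ParameterError, ShapeError

#: Representation tags produced by the pipeline.
METHOD_TAGS = (
    "ms1_presence",
    "ms1_log10",
    "mfp_avg",
    "mfp_massgrouped",
    "cc_avg",
    "cc_massgrouped",
)

#: Precursor m/z window applied to every representation (Th).
DEFAULT_MZ_RANGE = (100.0, 900.0)

#: Default mass-group boundaries: seven bins over the m/z window (Th).
DEFAULT_MASS_EDGES = (100.0, 250.0, 300.0, 350.0, 400.0, 450.0, 550.0, 900.0)


@dataclass(frozen=True)
class MassGroupScheme:
    """Partition of the precursor m/z axis into contiguous bins.

    Bins are half-open ``[lo, hi)`` except the last, which is closed so the
    upper boundary of the overall window is included.
    """

    edges: tuple[float, ...] = DEFAULT_MASS_EDGES

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        if len(edges) < 2:
            raise ParameterError("a mass-group scheme needs at least 2 edges")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ParameterError(f"mass-group edges must be strictly increasing: {edges}")
        object.__setattr__(self, "edges", edges)

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def labels(self) -> list[str]:
        return [f"{lo:g}-{hi:g}" for lo, hi in zip(self.edges, self.edges[1:])]

    def assign(self, mz) -> np.ndarray:
        """Map m/z values to bin indices; raise if any value is out of range."""
        mz = np.asarray(mz, dtype=float)
        lo, hi = self.edges[0], self.edges[-1]
        if mz.size and (mz.min() < lo or mz.max() > hi):
            bad = mz[(mz < lo) | (mz > hi)]
            raise MassAssignmentError(
                f"m/z value(s) outside [{lo:g}, {hi:g}]: {bad[:5].tolist()}"
            )
        idx = np.searchsorted(self.edges, mz, side="right") - 1
        # the closed upper end of the last bin
        idx[mz == hi] = self.n_bins - 1
        return idx.astype(int)


@dataclass
class FeatureTable:
    """Aligned LC-MS peaks with per-sample intensities (peak areas).

    Parameters
    ----------
    peaks:
        One row per peak, indexed by peak id, with ``mz`` (Th) and ``rt``
        (minutes) columns.
    intensities:
        Peaks x samples matrix of non-negative peak areas; 0 means the peak
        was not detected in that sample.
    """

    peaks: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        if not {"mz", "rt"}.issubset(self.peaks.columns):
            raise ShapeError("peaks frame needs 'mz' and 'rt' columns")
        if self.peaks.index.has_duplicates:
            dup = self.peaks.index[self.peaks.index.duplicated()][:5].tolist()
            raise IntegrityError(f"duplicate peak ids: {dup}")
        if self.intensities.columns.has_duplicates:
            raise IntegrityError("duplicate sample identifiers")
        if not self.peaks.index.equals(self.intensities.index):
            raise ShapeError("peaks and intensities must share the same peak index")
        if (self.peaks["mz"] <= 0).any():
            raise IntegrityError("m/z values must be positive")
        if (self.peaks["rt"] < 0).any():
            raise IntegrityError("retention times must be non-negative")
        if (self.intensities.to_numpy() < 0).any():
            raise IntegrityError("intensities must be non-negative")

    @property
    def peak_ids(self) -> pd.Index:
        return self.peaks.index

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]


@dataclass
class PredictionSet:
    """Per-(sample, peak) probabilistic characteristic vectors.

    Each row corresponds to one MS/MS acquisition event in one specific
    sample.  Column labels are the stable ``absoluteIndex`` keys of the
    characteristic definitions.
    """

    fingerprint_defs: pd.DataFrame  # index: absolute_index, column: description
    class_defs: pd.DataFrame
    fingerprints: pd.DataFrame  # MultiIndex (sample, peak_id) x fingerprint indices
    classes: pd.DataFrame  # MultiIndex (sample, peak_id) x class indices
    mz: pd.Series  # MultiIndex (sample, peak_id) -> precursor m/z

    def __post_init__(self) -> None:
        for defs, probs, kind in (
            (self.fingerprint_defs, self.fingerprints, "fingerprint"),
            (self.class_defs, self.classes, "compound_class"),
        ):
            if defs.index.has_duplicates:
                raise IntegrityError(f"duplicate absolute_index in {kind} definitions")
            if not defs.index.is_monotonic_increasing:
                raise IntegrityError(f"{kind} definitions must be ordered by absolute_index")
            if list(probs.columns) != list(defs.index):
                raise ShapeError(
                    f"{kind} vector length {probs.shape[1]} does not match "
                    f"{len(defs)} definitions (or column order differs)"
                )
            vals = probs.to_numpy()
            if vals.size and (np.nanmin(vals) < 0.0 or np.nanmax(vals) > 1.0):
                raise IntegrityError(f"{kind} probabilities outside [0, 1]")
            if np.isnan(vals).any():
                raise IntegrityError(f"{kind} probabilities contain NaN")
        if not self.fingerprints.index.equals(self.classes.index):
            raise ShapeError("fingerprint and class tables must cover the same records")
        if not self.fingerprints.index.equals(self.mz.index):
            raise ShapeError("mz series must cover the same records as the predictions")
        if self.fingerprints.index.has_duplicates:
            raise IntegrityError("duplicate (sample, peak) prediction records")

    @property
    def samples(self) -> list[str]:
        if len(self.fingerprints) == 0:
            return []
        return sorted(self.fingerprints.index.get_level_values(0).unique())

    @property
    def n_records(self) -> int:
        return len(self.fingerprints)

    def vector_length(self, kind: str) -> int:
        if kind == "fingerprint":
            return len(self.fingerprint_defs)
        if kind == "compound_class":
            return len(self.class_defs)
        raise ParameterError(f"unknown characteristic kind: {kind!r}")


@dataclass
class SampleMetadata:
    """Sample annotations: biome (EMPO level 4), contributor and origin."""

    table: pd.DataFrame  # index: sample_id; columns: biome, contributor, origin

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][:5].tolist()
            raise IntegrityError(f"duplicate sample ids in metadata: {dup}")
        if not {"biome", "contributor"}.issubset(self.table.columns):
            raise ShapeError("metadata needs 'biome' and 'contributor' columns")
        if "origin" not in self.table.columns:
            self.table = self.table.assign(origin="")
        biomes = self.table["biome"]
        if biomes.isna().any() or (biomes.astype(str).str.strip() == "").any():
            bad = self.table.index[
                biomes.isna() | (biomes.astype(str).str.strip() == "")
            ][:5].tolist()
            raise IntegrityError(f"samples with empty biome: {bad}")
        if len(self.table) == 0:
            raise IntegrityError("metadata table is empty")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    @property
    def biomes(self) -> list[str]:
        """Biome categories in stable sorted order."""
        return sorted(self.table["biome"].unique())

    def labels_for(self, samples) -> pd.Series:
        """Biome labels aligned to the given sample order."""
        missing = [s for s in samples if s not in self.table.index]
        if missing:
            raise IntegrityError(f"samples absent from metadata: {missing[:5]}")
        return self.table.loc[list(samples), "biome"]


@dataclass
class MethodMatrix:
    """Samples x features matrix for one representation.

    ``method`` is one of :data:`METHOD_TAGS` (custom tags are accepted for
    derived matrices, e.g. after feature selection).
    """

    method: str
    values: pd.DataFrame  # index: sample, columns: feature names
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size and np.isnan(arr.astype(float)).any():
            raise IntegrityError("method matrix contains NaN")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise IntegrityError("method matrix has duplicate sample or feature labels")
        if self.method in ("mfp_avg", "mfp_massgrouped", "cc_avg", "cc_massgrouped"):
            if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
                raise IntegrityError(f"{self.method} values must lie in [0, 1]")
        if self.method == "ms1_presence" and arr.size:
            if not np.isin(arr, (0.0, 1.0)).all():
                raise IntegrityError("presence/absence values must be 0 or 1")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, features, method: str | None = None) -> "MethodMatrix":
        """Restrict to a feature subset (order follows the current columns)."""
        keep = [c for c in self.values.columns if c in set(features)]
        return MethodMatrix(method or self.method, self.values[keep], dict(self.meta))
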