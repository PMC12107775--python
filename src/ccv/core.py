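"""Building the six sample representations.

A chemical characteristics vector (CCV) summarizes one sample: per-peak
probabilistic characteristic predictions are binarized at a threshold and
averaged over the sample's MS/MS peaks, so each entry is the fraction of
characterized compounds predicted to carry that characteristic.  The
mass-grouped variant averages within precursor-mass bins and concatenates the
per-bin vectors.  Two MS1 representations (presence/absence and log10
intensity) serve as benchmarks built from the aligned peak table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import EmptySampleError, NoInformativeFeaturesError, ParameterError
from .types import (
    DEFAULT_MZ_RANGE,
    METHOD_TAGS,
    FeatureTable,
    MassGroupScheme,
    MethodMatrix,
    PredictionSet,
)

logger = logging.getLogger(__name__)

_KIND_PREFIX = {"fingerprint": "fp", "compound_class": "cc"}


def binarize(probs, threshold: float = 0.5) -> np.ndarray:
    """Turn probabilities into presence/absence calls.

    An entry is 1 when its probability is **greater than or equal to** the
    threshold (inclusive boundary convention).
    """
    if not 0.0 < threshold < 1.0:
        raise ParameterError(f"threshold must be in (0, 1), got {threshold}")
    probs = np.asarray(probs, dtype=float)
    if probs.size and (probs.min() < 0.0 or probs.max() > 1.0):
        raise ParameterError("probabilities must lie in [0, 1]")
    return (probs >= threshold).astype(np.int8)


def peaks_for_sample(sample, preds: PredictionSet, kind: str = "fingerprint",
                     mz_range=DEFAULT_MZ_RANGE, threshold: float = 0.5):
    """Binary characteristic vectors for one sample's qualifying MS/MS peaks.

    Only peaks whose MS/MS was acquired in this specific sample and whose
    precursor m/z lies in ``[lo, hi]`` (both bounds inclusive) qualify.

    Returns
    -------
    (vectors, mz):
        ``vectors`` is an (n_peaks, n_characteristics) int array, ``mz`` the
        matching precursor masses.  Both are empty when nothing qualifies.
    """
    probs = preds.fingerprints if kind == "fingerprint" else preds.classes
    n_char = preds.vector_length(kind)
    if preds.n_records == 0 or sample not in probs.index.get_level_values(0):
        return np.empty((0, n_char), dtype=np.int8), np.empty(0)
    block = probs.xs(sample, level="sample")
    mz = preds.mz.xs(sample, level="sample").to_numpy()
    lo, hi = mz_range
    keep = (mz >= lo) & (mz <= hi)
    return binarize(block.to_numpy()[keep], threshold), mz[keep]


def average_ccv(vectors) -> np.ndarray:
    """Column-wise mean of binary vectors: the fraction of peaks with each bit."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.size == 0:
        raise EmptySampleError("no MS/MS peaks for sample")
    if vectors.ndim != 2:
        raise ParameterError("expected a 2-D stack of equal-length vectors")
    return vectors.mean(axis=0)


def massgrouped_ccv(vectors, mz, scheme: MassGroupScheme | None = None) -> np.ndarray:
    """Per-mass-bin CCVs concatenated in bin order.

    Bins with no peaks contribute an all-zero block so the output always has
    length ``n_bins * n_characteristics``; uninformative all-zero columns are
    removed later by :func:`filter_uniform`.
    """
    scheme = scheme or MassGroupScheme()
    vectors = np.asarray(vectors, dtype=float)
    if vectors.size == 0:
        raise EmptySampleError("no MS/MS peaks for sample")
    bins = scheme.assign(mz)
    n_char = vectors.shape[1]
    blocks = []
    for b in range(scheme.n_bins):
        mask = bins == b
        if mask.any():
            blocks.append(vectors[mask].mean(axis=0))
        else:
            blocks.append(np.zeros(n_char))
    return np.concatenate(blocks)


def ccv_feature_names(preds: PredictionSet, kind: str,
                      scheme: MassGroupScheme | None = None) -> list[str]:
    """Feature labels carrying the absolute index and, if grouped, the bin."""
    prefix = _KIND_PREFIX[kind]
    defs = preds.fingerprint_defs if kind == "fingerprint" else preds.class_defs
    base = [f"{prefix}_{i}" for i in defs.index]
    if scheme is None:
        return base
    return [f"{name}|{label}" for label in scheme.labels for name in base]


def build_ccv_matrix(preds: PredictionSet, kind: str = "fingerprint",
                     grouped: bool = False, scheme: MassGroupScheme | None = None,
                     mz_range=DEFAULT_MZ_RANGE, threshold: float = 0.5) -> MethodMatrix:
    """Assemble the samples x characteristics CCV matrix for one variant.

    Samples with zero qualifying MS/MS peaks are excluded with a warning
    rather than emitting an all-zero row: an all-zero CCV would be a claim
    about chemistry, not missingness.
    """
    if kind not in _KIND_PREFIX:
        raise ParameterError(f"unknown characteristic kind: {kind!r}")
    use_scheme = (scheme or MassGroupScheme()) if grouped else None
    rows, kept, skipped = [], [], []
    for sample in preds.samples:
        vectors, mz = peaks_for_sample(sample, preds, kind=kind,
                                       mz_range=mz_range, threshold=threshold)
        if len(vectors) == 0:
            skipped.append(sample)
            continue
        ccv = (massgrouped_ccv(vectors, mz, use_scheme) if grouped
               else average_ccv(vectors))
        rows.append(ccv)
        kept.append(sample)
    if skipped:
        logger.warning("excluded %d sample(s) with zero qualifying MS/MS peaks: %s",
                       len(skipped), skipped[:5])
    if not kept:
        raise EmptySampleError("no sample has qualifying MS/MS peaks")
    prefix = "mfp" if kind == "fingerprint" else "cc"
    tag = f"{prefix}_massgrouped" if grouped else f"{prefix}_avg"
    values = pd.DataFrame(np.vstack(rows), index=pd.Index(kept, name="sample"),
                          columns=ccv_feature_names(preds, kind, use_scheme))
    return MethodMatrix(tag, values, meta={"skipped_samples": skipped})


def ms1_matrix(table: FeatureTable, mode: str = "presence",
               mz_range=DEFAULT_MZ_RANGE) -> MethodMatrix:
    """Benchmark MS1 matrix from the aligned peak table.

    ``presence``: 1 iff the peak area is > 0.  ``log10``: log10 of the area
    for detected peaks, 0 for absent ones (keeps absent below any detected
    peak with area >= 1 and avoids -inf).
    """
    if mode not in ("presence", "log10"):
        raise ParameterError(f"mode must be 'presence' or 'log10', got {mode!r}")
    lo, hi = mz_range
    keep = (table.peaks["mz"] >= lo) & (table.peaks["mz"] <= hi)
    intens = table.intensities.loc[keep].T  # rows = samples
    arr = intens.to_numpy().astype(float)
    if mode == "presence":
        out = (arr > 0).astype(float)
        tag = "ms1_presence"
    else:
        out = np.where(arr > 0, np.log10(arr, where=arr > 0,
                                         out=np.zeros_like(arr)), 0.0)
        tag = "ms1_log10"
    values = pd.DataFrame(out, index=pd.Index(intens.index, name="sample"),
                          columns=[f"peak_{p}" for p in intens.columns])
    return MethodMatrix(tag, values)


def filter_uniform(matrix: MethodMatrix) -> MethodMatrix:
    """Drop columns whose value is identical across all samples (exact equality)."""
    arr = matrix.values
    keep = [c for c in arr.columns if arr[c].nunique(dropna=False) > 1]
    n_dropped = matrix.n_features - len(keep)
    if not keep:
        raise NoInformativeFeaturesError("no informative features")
    if n_dropped:
        logger.info("filter_uniform(%s): dropped %d uniform feature(s), kept %d",
                    matrix.method, n_dropped, len(keep))
    meta = dict(matrix.meta)
    meta["uniform_features_removed"] = n_dropped
    return MethodMatrix(matrix.method, arr[keep], meta)


def to_percent(ccv) -> np.ndarray:
    """Scale fractions to percent of LC-MS peaks per sample."""
    ccv = np.asarray(ccv, dtype=float)
    if ccv.size and (ccv.min() < 0.0 or ccv.max() > 1.0):
        raise ParameterError("CCV fractions must lie in [0, 1]")
    return ccv * 100.0


def build_method_matrix(tag: str, table: FeatureTable | None,
                        preds: PredictionSet | None,
                        scheme: MassGroupScheme | None = None,
                        mz_range=DEFAULT_MZ_RANGE,
                        threshold: float = 0.5) -> MethodMatrix:
    """Dispatch on a representation tag."""
    if tag not in METHOD_TAGS:
        raise ParameterError(
            f"unknown method tag {tag!r}; allowed: {', '.join(METHOD_TAGS)}"
        )
    if tag.startswith("ms1"):
        if table is None:
            raise ParameterError(f"{tag} requires a feature table")
        return ms1_matrix(table, mode=tag.removeprefix("ms1_"), mz_range=mz_range)
    if preds is None:
        raise ParameterError(f"{tag} requires a prediction set")
    kind = "fingerprint" if tag.startswith("mfp") else "compound_class"
    grouped = tag.endswith("massgrouped")
    return build_ccv_matrix(preds, kind=kind, grouped=grouped, scheme=scheme,
                            mz_range=mz_range, threshold=threshold)
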