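"""Readers and writers for the tabular formats the pipeline touches.

Supported formats
-----------------
* feature quantification CSV in the GNPS/MZmine dialect (``row ID``,
  ``row m/z``, ``row retention time`` plus one ``<sample> Peak area`` column
  per sample);
* wide prediction tables (one row per (sample, peak) MS/MS event, one column
  per characteristic, keyed by ``absoluteIndex``), with the characteristic
  definitions shipped as separate two-column tables;
* sample metadata (CSV or TSV);
* method matrices as TSV with the representation tag in a ``#`` comment line.

All files are UTF-8 text with ``.`` as the decimal separator.  Readers are
pure: the same file always yields the same in-memory object.
"""

from __future__ import annotations

import io
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError
from .types import FeatureTable, MethodMatrix, PredictionSet, SampleMetadata

_QUANT_REQUIRED = ("row ID", "row m/z", "row retention time")
_AREA_SUFFIX = " Peak area"


# ---------------------------------------------------------------------------
# quantification table
# ---------------------------------------------------------------------------

def read_quant_table(path) -> FeatureTable:
    """Read a GNPS/MZmine feature quantification CSV.

    Sample names are the intensity column names with the ``" Peak area"``
    suffix stripped; blank intensity cells are read as 0 (not detected).
    A trailing empty column (GNPS exports often end rows with a comma) is
    tolerated.
    """
    df = pd.read_csv(path, sep=",")
    df = df.loc[:, ~df.columns.str.match(r"^Unnamed: \d+$")]
    for col in _QUANT_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"quant table is missing mandatory column {col!r}")
    area_cols = [c for c in df.columns if c.endswith(_AREA_SUFFIX)]
    if not area_cols:
        raise FormatError(f"quant table has no {_AREA_SUFFIX!r} columns")
    ids = df["row ID"].astype(str)
    if ids.duplicated().any():
        raise IntegrityError(
            f"duplicate row IDs: {ids[ids.duplicated()].head().tolist()}"
        )
    peaks = pd.DataFrame(
        {
            "mz": pd.to_numeric(df["row m/z"]),
            "rt": pd.to_numeric(df["row retention time"]),
        },
        index=pd.Index(ids, name="peak_id"),
    )
    intens = df[area_cols].apply(pd.to_numeric, errors="coerce").fillna(0.0)
    intens.index = peaks.index
    intens.columns = [c[: -len(_AREA_SUFFIX)] for c in area_cols]
    return FeatureTable(peaks=peaks, intensities=intens)


def write_quant_table(table: FeatureTable, path) -> None:
    """Write a FeatureTable back to the GNPS/MZmine CSV dialect."""
    out = pd.DataFrame({
        "row ID": table.peak_ids,
        "row m/z": table.peaks["mz"].to_numpy(),
        "row retention time": table.peaks["rt"].to_numpy(),
    })
    for sample in table.samples:
        out[f"{sample}{_AREA_SUFFIX}"] = table.intensities[sample].to_numpy()
    out.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# prediction tables
# ---------------------------------------------------------------------------

def _read_definitions(path, kind: str) -> pd.DataFrame:
    defs = pd.read_csv(path, sep="\t")
    if "absolute_index" not in defs.columns or "description" not in defs.columns:
        raise FormatError(
            f"{kind} definition file needs 'absolute_index' and 'description' columns"
        )
    defs = defs.astype({"absolute_index": int}).set_index("absolute_index")
    if defs.index.has_duplicates:
        raise IntegrityError(f"duplicate absolute_index in {kind} definitions")
    return defs.sort_index()


def _read_prediction_table(path, defs: pd.DataFrame, kind: str):
    df = pd.read_csv(path, sep="\t")
    fixed = ["sample", "peak_id", "mz"]
    for col in fixed:
        if col not in df.columns:
            raise FormatError(f"{kind} prediction table is missing column {col!r}")
    prob_cols = [c for c in df.columns if c not in fixed]
    expected = [str(i) for i in defs.index]
    if prob_cols != expected:
        raise FormatError(
            f"{kind} prediction table has {len(prob_cols)} probability columns, "
            f"expected {len(expected)} ordered by absolute_index"
        )
    idx = pd.MultiIndex.from_arrays(
        [df["sample"].astype(str), df["peak_id"].astype(str)],
        names=("sample", "peak_id"),
    )
    probs = df[prob_cols].astype(float)
    probs.index = idx
    probs.columns = defs.index
    mz = pd.Series(pd.to_numeric(df["mz"]).to_numpy(), index=idx, name="mz")
    return probs, mz


def read_predictions(fp_path, cc_path, defs_fp, defs_cc,
                     metadata: SampleMetadata | None = None) -> PredictionSet:
    """Read fingerprint and compound-class prediction tables.

    Validation (shape against definitions, probabilities within [0, 1])
    happens in :class:`~ccv.types.PredictionSet`.  When ``metadata`` is given,
    samples absent from it trigger a warning but their records are retained.
    """
    fdefs = _read_definitions(defs_fp, "fingerprint")
    cdefs = _read_definitions(defs_cc, "compound_class")
    fprobs, fmz = _read_prediction_table(fp_path, fdefs, "fingerprint")
    cprobs, _ = _read_prediction_table(cc_path, cdefs, "compound_class")
    preds = PredictionSet(
        fingerprint_defs=fdefs,
        class_defs=cdefs,
        fingerprints=fprobs,
        classes=cprobs,
        mz=fmz,
    )
    if metadata is not None and preds.n_records:
        known = set(metadata.samples)
        unknown = sorted(set(preds.samples) - known)
        if unknown:
            warnings.warn(
                f"prediction records for samples absent from metadata: {unknown[:5]}",
                stacklevel=2,
            )
    return preds


def write_predictions(preds: PredictionSet, fp_path, cc_path, defs_fp, defs_cc) -> None:
    """Write a PredictionSet in the wide-table dialect read_predictions expects."""
    for defs, path in ((preds.fingerprint_defs, defs_fp), (preds.class_defs, defs_cc)):
        defs.reset_index().to_csv(path, sep="\t", index=False)
    for probs, path in ((preds.fingerprints, fp_path), (preds.classes, cc_path)):
        out = probs.copy()
        out.columns = [str(c) for c in probs.columns]
        out.insert(0, "mz", preds.mz.to_numpy())
        out = out.reset_index()
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def read_metadata(path) -> SampleMetadata:
    """Read a sample metadata table (TSV if the extension says so, else CSV)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    if "sample_id" not in df.columns:
        raise FormatError("metadata needs a 'sample_id' column")
    for col in ("biome", "contributor"):
        if col not in df.columns:
            raise FormatError(f"metadata needs a {col!r} column")
    table = df.set_index("sample_id")
    return SampleMetadata(table=table[[c for c in ("biome", "contributor", "origin")
                                       if c in table.columns]])


def write_metadata(meta: SampleMetadata, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    meta.table.reset_index().rename(columns={"index": "sample_id"}).to_csv(
        path, sep=sep, index=False
    )


# ---------------------------------------------------------------------------
# method matrices
# ---------------------------------------------------------------------------

def write_matrix(matrix: MethodMatrix, path) -> None:
    """Write a method matrix as TSV with the tag in a ``# method:`` header.

    Values are serialized with 17 significant digits so a round-trip is exact
    to well beyond 12 significant digits.  NaN cells are refused: every
    representation is total by construction.
    """
    arr = matrix.values.to_numpy().astype(float)
    if arr.size and np.isnan(arr).any():
        raise IntegrityError("refusing to write a matrix containing NaN")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# method: {matrix.method}\n")
        matrix.values.to_csv(fh, sep="\t", index_label="sample",
                             float_format="%.17g")


def read_matrix(path) -> MethodMatrix:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("# method:"):
            raise FormatError("matrix file lacks the '# method:' header comment")
        method = first.split(":", 1)[1].strip()
        df = pd.read_csv(io.StringIO(fh.read()), sep="\t", index_col="sample")
    return MethodMatrix(method=method, values=df)


# ---------------------------------------------------------------------------
# study bundle convenience layer (directory layout used by the CLI)
# ---------------------------------------------------------------------------

STUDY_FILES = {
    "quant": "quant.csv",
    "fp": "predictions_fingerprint.tsv",
    "cc": "predictions_class.tsv",
    "defs_fp": "definitions_fingerprint.tsv",
    "defs_cc": "definitions_class.tsv",
    "metadata": "metadata.tsv",
}


def write_study(table: FeatureTable, preds: PredictionSet, meta: SampleMetadata,
                out_dir) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {k: out_dir / v for k, v in STUDY_FILES.items()}
    write_quant_table(table, paths["quant"])
    write_predictions(preds, paths["fp"], paths["cc"], paths["defs_fp"], paths["defs_cc"])
    write_metadata(meta, paths["metadata"])
    return paths


def read_study(in_dir):
    in_dir = Path(in_dir)
    paths = {k: in_dir / v for k, v in STUDY_FILES.items()}
    table = read_quant_table(paths["quant"])
    meta = read_metadata(paths["metadata"])
    preds = read_predictions(paths["fp"], paths["cc"], paths["defs_fp"],
                             paths["defs_cc"], metadata=meta)
    return table, preds, meta
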