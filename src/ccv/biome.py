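"""Interpreting CCVs: compound-class ratios per biome and within-biome contrasts.

All ratio outputs are on the percent scale (CCV fractions x 100, i.e. the %
of MS/MS-characterized LC-MS peaks per sample annotated with a class).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import ParameterError
from .types import MassGroupScheme, MethodMatrix, SampleMetadata

#: combined group size at or below which the exact rank-sum null is enumerated
EXACT_LIMIT = 12


@dataclass
class ClassRatioSummary:
    """Per-biome distributions of per-sample class percentages."""

    per_sample: pd.DataFrame  # index sample; columns: biome + one column per class (%)
    summary: pd.DataFrame  # index (biome, characteristic); mean/min/max/n


def _resolve_features(matrix: MethodMatrix, characteristics) -> list[str]:
    available = set(matrix.feature_names)
    resolved = []
    for c in characteristics:
        name = c if isinstance(c, str) else f"cc_{c}"
        if name not in available:
            preview = ", ".join(matrix.feature_names[:10])
            raise ParameterError(
                f"characteristic {c!r} not in matrix; available start with: {preview}"
            )
        resolved.append(name)
    return resolved


def class_ratio_table(matrix: MethodMatrix, metadata: SampleMetadata,
                      characteristics) -> ClassRatioSummary:
    """Per-biome % distributions for selected compound classes.

    ``characteristics`` may be absolute indices (ints) or full feature names.
    """
    features = _resolve_features(matrix, characteristics)
    pct = matrix.values[features] * 100.0
    biome = metadata.labels_for(matrix.samples)
    per_sample = pct.copy()
    per_sample.insert(0, "biome", biome.to_numpy())
    records = []
    for b, grp in per_sample.groupby("biome", sort=True):
        for f in features:
            vals = grp[f]
            records.append({
                "biome": b, "characteristic": f, "mean": vals.mean(),
                "min": vals.min(), "max": vals.max(), "n_samples": len(vals),
            })
    summary = pd.DataFrame.from_records(records).set_index(["biome", "characteristic"])
    return ClassRatioSummary(per_sample=per_sample, summary=summary)


@dataclass
class RankSumResult:
    statistic: float  # rank-sum of group 1 (midranks)
    pvalue: float
    method: str  # "exact" or "normal"


def ranksum_compare(group1, group2) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    The statistic is the rank-sum of ``group1`` over the pooled midranks.
    When ``n1 + n2 <= EXACT_LIMIT`` the null distribution is enumerated over
    all C(n1+n2, n1) rank assignments (correct under ties); otherwise the
    tie-corrected normal approximation is used.
    """
    g1 = np.asarray(group1, float)
    g2 = np.asarray(group2, float)
    if g1.size == 0 or g2.size == 0:
        raise ParameterError("both groups must be non-empty")
    pooled = np.concatenate([g1, g2])
    ranks = rankdata(pooled)
    n1, n2 = g1.size, g2.size
    n = n1 + n2
    w_obs = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0
    if n <= EXACT_LIMIT:
        dev = abs(w_obs - mu)
        hits = sum(
            1 for idx in combinations(range(n), n1)
            if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9
        )
        p = hits / comb(n, n1)
        return RankSumResult(statistic=w_obs, pvalue=min(p, 1.0), method="exact")
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0.0:
        return RankSumResult(statistic=w_obs, pvalue=1.0, method="normal")
    z = (w_obs - mu) / np.sqrt(var)
    p = min(2.0 * float(norm.sf(abs(z))), 1.0)
    return RankSumResult(statistic=w_obs, pvalue=max(p, np.nextafter(0, 1)),
                         method="normal")


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (optional; contrasts report raw p by default)."""
    p = np.asarray(pvalues, float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        k = m - rank_from_end
        running = min(running, p[i] * m / k)
        adj[i] = running
    return adj


def contrast_groups(matrix: MethodMatrix, metadata: SampleMetadata, biome: str,
                    groupby: str = "contributor", characteristics=None,
                    adjust: bool = False) -> pd.DataFrame:
    """Rank-sum contrasts between two metadata-defined subgroups of one biome.

    The subgroup split comes from a metadata column (contributor/origin), not
    from clustering.  Requires exactly two subgroups.
    """
    meta = metadata.table
    in_biome = [s for s in matrix.samples if meta.loc[s, "biome"] == biome]
    if not in_biome:
        raise ParameterError(f"no samples of biome {biome!r} in the matrix")
    groups = meta.loc[in_biome, groupby]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ParameterError(
            f"biome {biome!r} has {len(levels)} {groupby} level(s); need exactly 2"
        )
    features = (_resolve_features(matrix, characteristics)
                if characteristics is not None else matrix.feature_names)
    pct = matrix.values.loc[in_biome, features] * 100.0
    g1 = pct.loc[groups[groups == levels[0]].index]
    g2 = pct.loc[groups[groups == levels[1]].index]
    rows = []
    for f in features:
        res = ranksum_compare(g1[f], g2[f])
        rows.append({
            "characteristic": f, "group1": levels[0], "group2": levels[1],
            "mean1_pct": g1[f].mean(), "mean2_pct": g2[f].mean(),
            "statistic": res.statistic, "pvalue": res.pvalue, "method": res.method,
        })
    out = pd.DataFrame(rows).set_index("characteristic")
    if adjust:
        out["pvalue_bh"] = benjamini_hochberg(out["pvalue"].to_numpy())
    return out


def massgroup_class_profile(matrix: MethodMatrix, metadata: SampleMetadata,
                            characteristic,
                            scheme: MassGroupScheme | None = None) -> pd.DataFrame:
    """Per-biome, per-mass-bin % distributions for one compound class.

    Expects a mass-grouped class matrix whose columns are named
    ``cc_<index>|<bin label>``; returns a long table with one row per
    (sample, bin).
    """
    scheme = scheme or MassGroupScheme()
    name = characteristic if isinstance(characteristic, str) else f"cc_{characteristic}"
    cols = [f"{name}|{label}" for label in scheme.labels]
    missing = [c for c in cols if c not in set(matrix.feature_names)]
    if missing:
        raise ParameterError(
            f"characteristic {characteristic!r} missing bin column(s) {missing[:3]}; "
            "pass the pre-filter mass-grouped class matrix"
        )
    biome = metadata.labels_for(matrix.samples)
    rows = []
    for sample in matrix.samples:
        for label, col in zip(scheme.labels, cols):
            rows.append({
                "sample": sample, "biome": biome[sample], "mass_group": label,
                "percent": matrix.values.loc[sample, col] * 100.0,
            })
    return pd.DataFrame(rows)
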