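"""Synthetic study generator.

Emulates the post-prediction data layer of an untargeted LC-MS/MS study: an
aligned feature quantification table, per-(sample, peak) probabilistic
fingerprint/class vectors, and sample metadata with biome / contributor
structure.  The generative model is this module's own and is intentionally
simple:

* each characteristic gets a global baseline probability drawn from a Beta
  distribution;
* each biome shifts a disjoint block of "informative" characteristics toward
  1 by the effect size delta (``p -> p*(1-delta) + delta``);
* per MS/MS peak, probabilities are jittered around the sample's biome
  profile with a Beta distribution of fixed concentration;
* intensities are log-normal (median 1e5, sigma = 1 decade); precursor m/z
  values are drawn bin-uniformly from the default mass-group scheme so every
  peak lands in exactly one bin;
* MS/MS acquisition is a per-(sample, detected peak) coin flip with the
  configured coverage;
* optionally, a fraction of one biome's samples form a subgroup whose class
  profile is shifted on chosen characteristics (mirrored in the contributor
  column so metadata-driven contrasts can find it).

A truth record listing the planted informative indices and subgroup members
is returned alongside the data so recovery tests need no re-derivation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .types import (
    DEFAULT_MASS_EDGES,
    FeatureTable,
    MassGroupScheme,
    PredictionSet,
    SampleMetadata,
)


@dataclass
class SubgroupSpec:
    """A planted two-group split inside one biome (class characteristics only)."""

    biome: int  # biome index (0-based)
    fraction: float = 0.5
    characteristics: tuple[int, ...] = ()  # class absolute indices to shift


@dataclass
class StudyConfig:
    n_biomes: int = 11
    samples_per_biome: int = 5
    peaks_per_sample: tuple[int, int] = (200, 2000)
    msms_fraction: float = 0.62
    n_fingerprint: int = 5899
    n_class: int = 2723
    n_informative: int = 10  # per biome, per characteristic kind
    effect_size: float = 0.5  # delta in [0, 1]
    subgroup: SubgroupSpec | None = None
    mz_edges: tuple[float, ...] = DEFAULT_MASS_EDGES
    mz_weights: tuple[float, ...] | None = None  # per-bin mixture weights
    baseline_beta: tuple[float, float] = (1.2, 8.0)
    concentration: float = 12.0  # Beta concentration of the per-peak jitter
    rt_range: tuple[float, float] = (0.5, 14.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.msms_fraction <= 1.0:
            raise ConfigError("msms_fraction must be in (0, 1]")
        if self.effect_size < 0.0 or self.effect_size > 1.0:
            raise ConfigError("effect_size must be in [0, 1]")
        for name in ("n_biomes", "samples_per_biome", "n_fingerprint",
                     "n_class", "n_informative"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        lo, hi = self.peaks_per_sample
        if lo < 1 or hi < lo:
            raise ConfigError("peaks_per_sample must be a (low, high) range with low >= 1")
        needed = self.n_biomes * self.n_informative
        if needed > min(self.n_fingerprint, self.n_class):
            raise ConfigError(
                f"n_biomes * n_informative = {needed} exceeds the shortest "
                f"characteristic vector ({min(self.n_fingerprint, self.n_class)})"
            )
        if self.subgroup is not None:
            if not 0 <= self.subgroup.biome < self.n_biomes:
                raise ConfigError("subgroup.biome out of range")
            if not 0.0 < self.subgroup.fraction < 1.0:
                raise ConfigError("subgroup.fraction must be in (0, 1)")
            if any(c >= self.n_class for c in self.subgroup.characteristics):
                raise ConfigError("subgroup characteristics exceed n_class")


def _draw_mz(rng, n, edges, weights):
    edges = np.asarray(edges, float)
    n_bins = edges.size - 1
    w = (np.full(n_bins, 1.0 / n_bins) if weights is None
         else np.asarray(weights, float) / np.sum(weights))
    bins = rng.choice(n_bins, size=n, p=w)
    return rng.uniform(edges[bins], edges[bins + 1])


def _profiles(rng, n_char, n_biomes, n_informative, delta, beta_params):
    a, b = beta_params
    baseline = rng.beta(a, b, size=n_char)
    profiles = np.tile(baseline, (n_biomes, 1))
    informative = {}
    for bi in range(n_biomes):
        idx = np.arange(bi * n_informative, (bi + 1) * n_informative)
        profiles[bi, idx] = baseline[idx] * (1.0 - delta) + delta
        informative[bi] = idx
    return profiles, informative


def _jitter(rng, profile, n_rows, kappa):
    """Per-peak Beta jitter around a profile vector, clipped to valid params."""
    p = np.clip(profile, 0.02, 0.98)
    a = np.broadcast_to(p * kappa, (n_rows, p.size))
    b = np.broadcast_to((1.0 - p) * kappa, (n_rows, p.size))
    return np.clip(rng.beta(a, b), 0.0, 1.0)


def generate_study(config: StudyConfig):
    """Generate (FeatureTable, PredictionSet, SampleMetadata, truth record).

    Fully reproducible: all randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_biomes = config.n_biomes
    biome_names = [f"biome_{i + 1:02d}" for i in range(n_biomes)]

    fp_profiles, fp_informative = _profiles(
        rng, config.n_fingerprint, n_biomes, config.n_informative,
        config.effect_size, config.baseline_beta)
    cc_profiles, cc_informative = _profiles(
        rng, config.n_class, n_biomes, config.n_informative,
        config.effect_size, config.baseline_beta)

    # aligned peak pool shared by all samples
    lo, hi = config.peaks_per_sample
    n_pool = int(np.ceil(hi * 1.25))
    pool_mz = _draw_mz(rng, n_pool, config.mz_edges, config.mz_weights)
    pool_rt = rng.uniform(*config.rt_range, size=n_pool)
    peak_ids = np.array([f"pk{i + 1:06d}" for i in range(n_pool)])

    # sample roster with biome / contributor / subgroup structure
    samples, biomes, contributors, origins, subgroup_members = [], [], [], [], []
    for bi, bname in enumerate(biome_names):
        n_sub = 0
        if config.subgroup is not None and config.subgroup.biome == bi:
            n_sub = max(1, int(round(config.subgroup.fraction
                                     * config.samples_per_biome)))
        for si in range(config.samples_per_biome):
            sid = f"{bname}_s{si + 1:02d}"
            in_sub = si < n_sub
            samples.append(sid)
            biomes.append(bname)
            contributors.append(f"{bname}_grp{'B' if in_sub else 'A'}")
            origins.append(f"site_{si % 3 + 1}")
            if in_sub:
                subgroup_members.append(sid)

    intensities = np.zeros((n_pool, len(samples)))
    fp_rows, cc_rows, mz_rows, index_rows = [], [], [], []
    sub_chars = (np.asarray(config.subgroup.characteristics, int)
                 if config.subgroup is not None else np.empty(0, int))

    for col, sid in enumerate(samples):
        bi = biome_names.index(biomes[col])
        n_s = int(rng.integers(lo, hi + 1))
        detected = rng.choice(n_pool, size=n_s, replace=False)
        detected.sort()
        intensities[detected, col] = 10.0 ** rng.normal(5.0, 1.0, size=n_s)
        has_msms = rng.random(n_s) < config.msms_fraction
        msms = detected[has_msms]
        if msms.size == 0:
            continue
        cc_profile = cc_profiles[bi]
        if sid in subgroup_members and sub_chars.size:
            cc_profile = cc_profile.copy()
            cc_profile[sub_chars] = (cc_profile[sub_chars]
                                     * (1.0 - config.effect_size)
                                     + config.effect_size)
        fp_rows.append(_jitter(rng, fp_profiles[bi], msms.size, config.concentration))
        cc_rows.append(_jitter(rng, cc_profile, msms.size, config.concentration))
        mz_rows.append(pool_mz[msms])
        index_rows.extend((sid, pid) for pid in peak_ids[msms])

    peak_index = pd.Index(peak_ids, name="peak_id")
    table = FeatureTable(
        peaks=pd.DataFrame({"mz": pool_mz, "rt": pool_rt}, index=peak_index),
        intensities=pd.DataFrame(intensities, index=peak_index, columns=samples),
    )
    meta = SampleMetadata(table=pd.DataFrame(
        {"biome": biomes, "contributor": contributors, "origin": origins},
        index=pd.Index(samples, name="sample_id"),
    ))
    record_index = pd.MultiIndex.from_tuples(index_rows, names=("sample", "peak_id"))
    fp_defs = pd.DataFrame(
        {"description": [f"substructure bit {i}" for i in range(config.n_fingerprint)]},
        index=pd.RangeIndex(config.n_fingerprint, name="absolute_index"))
    cc_defs = pd.DataFrame(
        {"description": [f"compound class {i}" for i in range(config.n_class)]},
        index=pd.RangeIndex(config.n_class, name="absolute_index"))
    preds = PredictionSet(
        fingerprint_defs=fp_defs,
        class_defs=cc_defs,
        fingerprints=pd.DataFrame(
            np.vstack(fp_rows) if fp_rows else np.empty((0, config.n_fingerprint)),
            index=record_index, columns=fp_defs.index),
        classes=pd.DataFrame(
            np.vstack(cc_rows) if cc_rows else np.empty((0, config.n_class)),
            index=record_index, columns=cc_defs.index),
        mz=pd.Series(np.concatenate(mz_rows) if mz_rows else np.empty(0),
                     index=record_index, name="mz"),
    )
    truth = {
        "informative_fingerprint": {biome_names[b]: idx.tolist()
                                    for b, idx in fp_informative.items()},
        "informative_class": {biome_names[b]: idx.tolist()
                              for b, idx in cc_informative.items()},
        "subgroup_samples": subgroup_members,
        "config": _config_dict(config),
    }
    return table, preds, meta, truth


def _config_dict(config: StudyConfig) -> dict:
    d = asdict(config)
    if d.get("subgroup") is not None:
        d["subgroup"] = dict(d["subgroup"])
    return d


FIXTURES = {
    # fast fixture for unit tests: 3 biomes x 5 samples, <= 50 peaks/sample
    "tiny": StudyConfig(
        n_biomes=3, samples_per_biome=5, peaks_per_sample=(30, 50),
        msms_fraction=0.62, n_fingerprint=20, n_class=10, n_informative=3,
        effect_size=0.6, seed=42,
    ),
    # study-scale characteristic vectors (5899 fingerprint bits, 2723 class
    # bits, 11 biomes); peak counts are kept modest so generation stays fast
    "default": StudyConfig(
        n_biomes=11, samples_per_biome=3, peaks_per_sample=(150, 300),
        msms_fraction=0.62, n_fingerprint=5899, n_class=2723, n_informative=25,
        effect_size=0.5, seed=42,
    ),
}


def make_fixture(name: str = "tiny"):
    """Generate a packaged study: ``tiny`` for tests, ``default`` at study scale."""
    if name not in FIXTURES:
        raise ConfigError(f"unknown fixture {name!r}; allowed: {sorted(FIXTURES)}")
    return generate_study(FIXTURES[name])
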