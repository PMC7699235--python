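"""Synthetic microbiome + metabolome cohorts with planted structure.

The study design emulated here is a small case/control cohort (11 lung
cancer patients, 8 healthy controls) profiled on three platforms: 16S OTU
abundances, GC-MS volatile metabolites (ppm) and NMR non-volatile
metabolites (µmol/g), about 470 features in total. Abundances follow a
log-normal model: on the log2 scale each feature is a baseline plus an
optional latent module factor, an optional case/control shift, and
Gaussian noise; the result is exponentiated to a non-negative abundance
and structural zeros are injected cell-wise.

Ground truth (module membership, planted shifts, latent factors) is
returned alongside the tables so every downstream stage can be scored.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    METABOLITE,
    OTU,
    FeatureTable,
    MergedDataset,
    TraitTable,
)

__all__ = ["SynthConfig", "GroundTruth", "generate_study", "fixture_44"]


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic cohort generator.

    Defaults mirror the emulated study: 11 patients vs 8 controls; 198
    OTUs, 223 volatile and 49 non-volatile metabolites; four planted
    co-varying modules with sizes spanning 33-121 features; 44 features
    carrying a planted case/control shift of 4 log2 units.
    """

    n_patients: int = 11
    n_controls: int = 8
    n_otus: int = 198
    n_vocs: int = 223
    n_nonvocs: int = 49
    n_modules: int = 4
    module_sizes: tuple[int, ...] = (121, 90, 55, 33)
    factor_loading: float = 0.8
    n_shifted: int = 44
    shift_lfc: float = 4.0
    zero_inflation: float = 0.1
    noise_sd: float = 1.0
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.n_patients + self.n_controls

    @property
    def n_features(self) -> int:
        return self.n_otus + self.n_vocs + self.n_nonvocs

    def validate(self) -> None:
        for name in (
            "n_patients",
            "n_controls",
            "n_otus",
            "n_vocs",
            "n_nonvocs",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if sum(self.module_sizes) > self.n_features:
            raise ValueError("module sizes exceed the total feature count")
        if not (0.0 <= self.factor_loading < 1.0):
            raise ValueError("factor_loading must lie in [0, 1)")
        if not (0.0 <= self.zero_inflation < 1.0):
            raise ValueError("zero_inflation must lie in [0, 1)")
        if self.n_shifted < 0 or self.n_shifted > self.n_features:
            raise ValueError("n_shifted out of range")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclasses.dataclass
class GroundTruth:
    """Planted structure: module ids (-1 = none), true shifts, latent factors."""

    module: pd.Series
    shift: pd.Series
    factors: pd.DataFrame  # modules x samples

    def members(self, module_id: int) -> list:
        return list(self.module.index[self.module == module_id])


def _feature_ids(config: SynthConfig) -> tuple[list[str], list[str], list[str]]:
    otus = [f"OTU_{i+1:03d}" for i in range(config.n_otus)]
    vocs = [f"VOC_{i+1:03d}" for i in range(config.n_vocs)]
    nonvocs = [f"NVM_{i+1:03d}" for i in range(config.n_nonvocs)]
    return otus, vocs, nonvocs


def _sample_ids(config: SynthConfig) -> list[str]:
    return [f"P_{i+1:02d}" for i in range(config.n_patients)] + [
        f"C_{i+1:02d}" for i in range(config.n_controls)
    ]


def generate_study(config: SynthConfig) -> tuple[MergedDataset, GroundTruth]:
    """Draw one synthetic cohort under ``config``.

    Log2 abundance of feature i in sample k:

        log2 x_ik = mu_i + (loading * f_m(k) + sqrt(1-loading^2) * sd * e)
                    + shift_i * g(k)                    [module members]
        log2 x_ik = mu_i + sd * e + shift_i * g(k)      [non-members]

    with f_m the module's standard-normal latent factor, e standard normal,
    sd = ``noise_sd``, g the case indicator and mu_i ~ U(2, 8). The planted
    case/control shift is carried by one whole module -- the largest one
    whose size fits inside ``n_shifted`` -- topped up from non-module
    features, so the shift never cuts a module in half; when no module
    fits, only non-module features are shifted. Structural zeros are then
    injected cell-wise with probability ``zero_inflation``. Identical
    configs give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    otus, vocs, nonvocs = _feature_ids(config)
    features = otus + vocs + nonvocs
    samples = _sample_ids(config)
    n_f, n_s = len(features), len(samples)

    # module membership: random feature subset so modules span omics layers
    module = np.full(n_f, -1, dtype=int)
    perm = rng.permutation(n_f)
    pos = 0
    for m, size in enumerate(config.module_sizes):
        module[perm[pos : pos + size]] = m
        pos += size

    # planted case/control shifts: one whole module carries the condition
    # signal (the module whose size is nearest n_shifted, so the shift never
    # splits a module into shifted and unshifted halves), topped up from
    # non-module features when n_shifted exceeds that module's size
    shift = np.zeros(n_f)
    fitting = [
        m
        for m in range(config.n_modules)
        if config.module_sizes[m] <= config.n_shifted
    ]
    if config.n_shifted and fitting:
        # largest module that n_shifted can cover entirely
        chosen = max(fitting, key=lambda m: (config.module_sizes[m], -m))
        members = [i for i in range(n_f) if module[i] == chosen]
        pool = members + [int(i) for i in perm[pos:]]
        shift[pool[: config.n_shifted]] = config.shift_lfc
    elif config.n_shifted:
        # no module fits inside n_shifted: shift non-module features only
        shift[perm[pos : pos + config.n_shifted]] = config.shift_lfc

    factors = rng.standard_normal((config.n_modules, n_s))
    eps = rng.standard_normal((n_f, n_s))
    loading = config.factor_loading
    signal = np.empty((n_f, n_s))
    in_module = module >= 0
    signal[~in_module] = config.noise_sd * eps[~in_module]
    if in_module.any():
        f = factors[module[in_module]]
        signal[in_module] = (
            loading * f
            + np.sqrt(1.0 - loading**2) * config.noise_sd * eps[in_module]
        )

    g = np.array([1.0] * config.n_patients + [0.0] * config.n_controls)
    mu = rng.uniform(2.0, 8.0, size=n_f)
    log2x = mu[:, None] + signal + shift[:, None] * g[None, :]
    x = np.exp2(log2x)
    if config.zero_inflation > 0:
        zeros = rng.random((n_f, n_s)) < config.zero_inflation
        x[zeros] = 0.0

    kind = pd.Series(
        [OTU] * config.n_otus + [METABOLITE] * (config.n_vocs + config.n_nonvocs),
        index=features,
    )
    units = pd.Series(
        ["counts"] * config.n_otus
        + ["ppm"] * config.n_vocs
        + ["umol/g"] * config.n_nonvocs,
        index=features,
    )
    table = FeatureTable(pd.DataFrame(x, index=features, columns=samples), kind, units)
    treatment = pd.Series(np.nan, index=samples)
    # responder status for patients only (balanced-ish assignment)
    treatment.iloc[: config.n_patients] = (
        rng.random(config.n_patients) < 0.5
    ).astype(float)
    traits = TraitTable(
        pd.Series([1] * config.n_patients + [0] * config.n_controls, index=samples),
        treatment,
    )
    truth = GroundTruth(
        module=pd.Series(module, index=features),
        shift=pd.Series(shift, index=features),
        factors=pd.DataFrame(
            factors,
            index=[f"module_{m}" for m in range(config.n_modules)],
            columns=samples,
        ),
    )
    return MergedDataset(table, traits), truth


# ---------------------------------------------------------------------------
# deterministic screening fixture


def fixture_44(seed: int = 0) -> MergedDataset:
    """A cohort built so that exactly 44 features survive default screening.

    15 OTUs and 29 (volatile) metabolites are given large case/control
    shifts (~6.5 log2 units against ~0.6 within-group SD) plus block-wise
    latent factors, so they clear the presence, IQR, fold-change and
    permutation-FDR filters with wide margins. Every other feature is
    engineered to fail a *deterministic* filter: either it is present in
    at most 4 of 19 samples (presence < 25%) or it is expressed in all
    samples with case and control means equal (|LFC| ~ 0 << 3.4). No
    non-survivor relies on the stochastic permutation screen alone, which
    keeps the survivor count exact for any seed.
    """
    rng = np.random.default_rng(seed)
    config = SynthConfig()  # only for the id layout / cohort sizes
    otus, vocs, nonvocs = _feature_ids(config)
    features = otus + vocs + nonvocs
    samples = _sample_ids(config)
    n_s = len(samples)
    n_pat = config.n_patients
    g = np.array([1.0] * n_pat + [0.0] * config.n_controls)

    # 4 blocks of correlated survivors: sizes 14/14/13 in the "giant" part
    # plus a 3-feature satellite (2 OTUs + 1 metabolite)
    blocks = {}
    giant = otus[:13] + vocs[:28]
    blocks.update({f: 0 for f in giant[:14]})
    blocks.update({f: 1 for f in giant[14:28]})
    blocks.update({f: 2 for f in giant[28:]})
    for f in (otus[13], otus[14], vocs[28]):
        blocks[f] = 3

    delta = 6.5  # planted case/control shift, log2 units
    lam = 0.5  # block factor scale
    sd_w = 0.3  # independent within-group noise
    factors = rng.standard_normal((4, n_s))

    rows = []
    for f in features:
        mu = rng.uniform(3.0, 7.0)
        if f in blocks:
            b = blocks[f]
            log2x = (
                mu
                + delta * g
                + lam * factors[b]
                + sd_w * rng.standard_normal(n_s)
            )
            rows.append(np.exp2(log2x))
        else:
            mode = rng.random()
            if mode < 0.45:
                # sparse: present in at most 4/19 samples -> presence < 25%
                x = np.zeros(n_s)
                k = rng.integers(0, 5)
                if k:
                    idx = rng.choice(n_s, size=k, replace=False)
                    x[idx] = np.exp2(mu + rng.standard_normal(k))
                rows.append(x)
            else:
                # expressed everywhere, no group difference: |LFC| ~ 0
                log2x = mu + 0.5 * rng.standard_normal(n_s)
                rows.append(np.exp2(log2x))
    x = np.vstack(rows)

    kind = pd.Series(
        [OTU] * config.n_otus + [METABOLITE] * (config.n_vocs + config.n_nonvocs),
        index=features,
    )
    units = pd.Series(
        ["counts"] * config.n_otus
        + ["ppm"] * config.n_vocs
        + ["umol/g"] * config.n_nonvocs,
        index=features,
    )
    table = FeatureTable(pd.DataFrame(x, index=features, columns=samples), kind, units)
    treatment = pd.Series(np.nan, index=samples)
    treatment.iloc[:n_pat] = (rng.random(n_pat) < 0.5).astype(float)
    traits = TraitTable(
        pd.Series([1] * n_pat + [0] * config.n_controls, index=samples), treatment
    )
    return MergedDataset(table, traits)
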