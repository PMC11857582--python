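"""Synthetic twin cohorts with a prescribed A/C/E (or A/D/E) covariance structure.

The generator follows the classical twin algebra directly: each family draws
standard-normal latent additive-genetic (A), shared-environment (C) or
dominance (D), and unique-environment (E) scores per member, with correlation
across members of 1 (MZ) / 0.5 (DZ) for A, 1 / 0.25 for D, 1 for C and 0 for
E.  A trait value is then

    y = intercept + beta_age * age + beta_sex * [sex == M]
        + total_sd * (a*A + c*C + d*D + e*E)

with path coefficients a = sqrt(a2) etc., so the pre-covariate within-pair
covariance is exactly total_sd^2 * (a2 + c2) for MZ and total_sd^2 *
(a2/2 + c2) for DZ (dominance: weights 1 and 1/4).

The default demographic layout mirrors the study cohort: 37 ordinary MZ
pairs, 19 ordinary DZ pairs and 2 MZ triplet sets — 56 ordinary pairs that
expand to 62 analyzable pairs (43 MZ + 19 DZ) — with ages drawn uniformly on
median +/- IQR/2 (50 +/- 13.5 years), 71.2% female pairs, and sex and age
shared within a family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import MANDATORY_COLUMNS, CohortTable

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class TraitSpec:
    """Generating model for one trait.

    ``a2``/``c2``/``d2``/``e2`` are standardized variance proportions; under
    ``model="ACE"`` dominance must be zero and under ``model="ADE"`` the
    shared environment must be zero (the two are not jointly identifiable in
    the classical design).  ``e2=None`` fills the remainder to 1.
    """

    name: str
    a2: float
    c2: float = 0.0
    d2: float = 0.0
    e2: float | None = None
    model: str = "ACE"
    total_sd: float = 1.0
    mean_intercept: float = 0.0
    beta_age: float = 0.0
    beta_sex: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("ACE", "ADE"):
            raise ValidationError(f"trait model must be ACE or ADE, got {self.model!r}")
        if self.model == "ACE" and self.d2 != 0.0:
            raise ValidationError("d2 must be 0 under an ACE trait model")
        if self.model == "ADE" and self.c2 != 0.0:
            raise ValidationError("c2 must be 0 under an ADE trait model")
        if self.e2 is None:
            object.__setattr__(self, "e2", 1.0 - self.a2 - self.c2 - self.d2)
        for nm in ("a2", "c2", "d2", "e2"):
            v = getattr(self, nm)
            if not -_SUM_TOL <= v <= 1.0 + _SUM_TOL:
                raise ValidationError(f"{nm} must lie in [0, 1], got {v}")
        total = self.a2 + self.c2 + self.d2 + self.e2
        if abs(total - 1.0) > _SUM_TOL:
            raise ValidationError(f"variance proportions must sum to 1, got {total}")
        if not self.total_sd > 0:
            raise ValidationError(f"total_sd must be positive, got {self.total_sd}")


@dataclass(frozen=True)
class SimulationConfig:
    """Demographic layout and trait list for one simulated cohort.

    Pair counts are *ordinary* (pre-expansion) pairs; each triplet set adds
    three pairs of ``triplet_zygosity`` after :func:`expand_triplets`.
    """

    traits: tuple[TraitSpec, ...]
    n_mz_pairs: int = 37
    n_dz_pairs: int = 19
    n_triplet_sets: int = 2
    triplet_zygosity: str = "MZ"
    age_median: float = 50.0
    age_iqr: float = 27.0
    sex_female_fraction: float = 0.712
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.traits, list):
            object.__setattr__(self, "traits", tuple(self.traits))
        if not self.traits:
            raise ValidationError("at least one TraitSpec is required")
        for n in (self.n_mz_pairs, self.n_dz_pairs, self.n_triplet_sets):
            if n < 0:
                raise ValidationError("pair/set counts must be nonnegative")
        if self.n_mz_pairs + self.n_dz_pairs + self.n_triplet_sets == 0:
            raise ValidationError("cohort must contain at least one pair or triplet set")
        if self.triplet_zygosity not in ("MZ", "DZ"):
            raise ValidationError("triplet_zygosity must be MZ or DZ")
        if not 0.0 <= self.sex_female_fraction <= 1.0:
            raise ValidationError("sex_female_fraction must lie in [0, 1]")


# sharing coefficients: correlation of the latent factor between family members
_A_SHARE = {"MZ": 1.0, "DZ": 0.5}
_D_SHARE = {"MZ": 1.0, "DZ": 0.25}


def _shared_latents(
    rng: np.random.Generator, n_families: int, size: int, share: float
) -> np.ndarray:
    """Equicorrelated standard-normal latents: (n_families, size) with the
    given between-member correlation."""
    common = rng.standard_normal(n_families)
    unique = rng.standard_normal((n_families, size))
    return np.sqrt(share) * common[:, None] + np.sqrt(1.0 - share) * unique


def _simulate_block(
    rng: np.random.Generator,
    config: SimulationConfig,
    n_families: int,
    size: int,
    zygosity: str,
) -> dict[str, np.ndarray]:
    """Simulate one homogeneous block of families (all same zygosity/size)."""
    lo = config.age_median - config.age_iqr / 2.0
    hi = config.age_median + config.age_iqr / 2.0
    ages = rng.uniform(lo, hi, n_families)
    female = rng.random(n_families) < config.sex_female_fraction
    sex_num = (~female).astype(float)  # F=0, M=1, shared within the family
    out = {"age": ages, "female": female}
    for spec in config.traits:
        lat = (
            np.sqrt(spec.a2) * _shared_latents(rng, n_families, size, _A_SHARE[zygosity])
            + np.sqrt(spec.c2) * _shared_latents(rng, n_families, size, 1.0)
            + np.sqrt(spec.d2) * _shared_latents(rng, n_families, size, _D_SHARE[zygosity])
            + np.sqrt(spec.e2) * rng.standard_normal((n_families, size))
        )
        out[spec.name] = (
            spec.mean_intercept
            + spec.beta_age * ages[:, None]
            + spec.beta_sex * sex_num[:, None]
            + spec.total_sd * lat
        )
    return out


def simulate_cohort(config: SimulationConfig) -> CohortTable:
    """Simulate a twin cohort; same config (including seed) gives identical output.

    Triplet sets are emitted as three rows sharing a ``set_id`` with an empty
    ``pair_id``; run :func:`expand_triplets` to turn them into analyzable pairs.
    """
    rng = np.random.default_rng(config.seed)
    blocks = [
        ("MZ", 2, config.n_mz_pairs),
        ("DZ", 2, config.n_dz_pairs),
        (config.triplet_zygosity, 3, config.n_triplet_sets),
    ]
    frames = []
    subj_offset = 0
    pair_offset = 0
    for zyg, size, n_fam in blocks:
        if n_fam == 0:
            continue
        blk = _simulate_block(rng, config, n_fam, size, zyg)
        n_rows = n_fam * size
        fam_idx = np.repeat(np.arange(n_fam), size)
        if size == 2:
            pair_ids = [f"pair{pair_offset + i + 1:04d}" for i in fam_idx]
            set_ids = [""] * n_rows
            pair_offset += n_fam
        else:
            pair_ids = [""] * n_rows
            set_ids = [f"set{i + 1:02d}" for i in fam_idx]
        data = {
            "subject_id": [f"subj{subj_offset + i + 1:05d}" for i in range(n_rows)],
            "pair_id": pair_ids,
            "set_id": set_ids,
            "zygosity": zyg,
            "sex": np.where(blk["female"][fam_idx], "F", "M"),
            "age_years": blk["age"][fam_idx],
        }
        for spec in config.traits:
            data[spec.name] = blk[spec.name].ravel()
        frames.append(pd.DataFrame(data))
        subj_offset += n_rows
    df = pd.concat(frames, ignore_index=True)[
        list(MANDATORY_COLUMNS) + [t.name for t in config.traits]
    ]
    return CohortTable(df)


def expand_triplets(cohort: CohortTable) -> CohortTable:
    """Expand each 3-member triplet set into the three possible twin pairs.

    A set {X, Y, Z} yields pairs (X, Y), (X, Z), (Y, Z) with fresh pair ids
    and the set's zygosity; subject rows are duplicated across the pairs they
    participate in.  Ordinary pairs pass through unchanged.
    """
    df = cohort.df
    is_set = (df["set_id"] != "") & (df["pair_id"] == "")
    ordinary = df[~is_set]
    out_frames = [ordinary]
    existing = set(ordinary["pair_id"])
    k = 0
    for set_id, grp in df[is_set].groupby("set_id", sort=True):
        if len(grp) != 3:
            raise ValidationError(
                f"triplet set {set_id!r} has {len(grp)} members; exactly 3 required"
            )
        for i, j in itertools.combinations(range(3), 2):
            while True:
                k += 1
                new_id = f"{set_id}_pair{k}"
                if new_id not in existing:
                    break
            sub = grp.iloc[[i, j]].copy()
            sub["pair_id"] = new_id
            out_frames.append(sub)
    out = pd.concat(out_frames, ignore_index=True)
    return CohortTable(out)


def study_traits() -> tuple[TraitSpec, ...]:
    """Default trait battery: regional gray-matter volumes (cm^3), average
    cortical thicknesses (mm), and infratentorial volumes, with generating
    A/C/E proportions matching the reported regional estimates and plausible
    adult means, dispersions and age/sex effects."""
    vol = dict(model="ACE", c2=0.0)
    return (
        # supratentorial cortical gray-matter volumes (AE-like: c2 = 0)
        TraitSpec("total_gm_volume", a2=0.924, total_sd=50.0, mean_intercept=560.0,
                  beta_age=-1.5, beta_sex=45.0, **vol),
        TraitSpec("frontal_gm_volume", a2=0.912, total_sd=18.0, mean_intercept=160.0,
                  beta_age=-0.45, beta_sex=13.0, **vol),
        TraitSpec("temporal_gm_volume", a2=0.907, total_sd=12.0, mean_intercept=110.0,
                  beta_age=-0.30, beta_sex=9.0, **vol),
        TraitSpec("parietal_gm_volume", a2=0.879, total_sd=11.0, mean_intercept=95.0,
                  beta_age=-0.28, beta_sex=8.0, **vol),
        TraitSpec("occipital_gm_volume", a2=0.880, total_sd=8.0, mean_intercept=60.0,
                  beta_age=-0.15, beta_sex=5.0, **vol),
        TraitSpec("precentral_gm_volume", a2=0.900, total_sd=3.0, mean_intercept=22.0,
                  beta_age=-0.06, beta_sex=1.8, **vol),
        TraitSpec("postcentral_gm_volume", a2=0.860, total_sd=2.5, mean_intercept=18.0,
                  beta_age=-0.05, beta_sex=1.5, **vol),
        # average cortical thickness: frontal/temporal/pre-central are CE-like
        TraitSpec("frontal_thickness", a2=0.0, c2=0.630, total_sd=0.12, mean_intercept=2.60,
                  beta_age=-0.004, beta_sex=0.02),
        TraitSpec("temporal_thickness", a2=0.0, c2=0.665, total_sd=0.13, mean_intercept=2.80,
                  beta_age=-0.004, beta_sex=0.02),
        TraitSpec("precentral_thickness", a2=0.0, c2=0.666, total_sd=0.12, mean_intercept=2.50,
                  beta_age=-0.004, beta_sex=0.02),
        TraitSpec("parietal_thickness", a2=0.879, total_sd=0.11, mean_intercept=2.30,
                  beta_age=-0.004, beta_sex=0.02, **vol),
        TraitSpec("occipital_thickness", a2=0.881, total_sd=0.10, mean_intercept=2.00,
                  beta_age=-0.004, beta_sex=0.02, **vol),
        TraitSpec("postcentral_thickness", a2=0.677, total_sd=0.11, mean_intercept=2.10,
                  beta_age=-0.004, beta_sex=0.02, **vol),
        # infratentorial volumes
        TraitSpec("brainstem_volume", a2=0.926, total_sd=2.5, mean_intercept=23.0,
                  beta_age=-0.03, beta_sex=2.0, **vol),
        TraitSpec("cerebellum_total_volume", a2=0.905, total_sd=12.0, mean_intercept=140.0,
                  beta_age=-0.30, beta_sex=10.0, **vol),
        TraitSpec("cerebellum_gm_volume", a2=0.915, total_sd=10.0, mean_intercept=105.0,
                  beta_age=-0.25, beta_sex=8.0, **vol),
    )


def default_config(seed: int = 0) -> SimulationConfig:
    """Study-layout cohort (56 ordinary pairs + 2 MZ triplet sets) over the
    default trait battery."""
    return SimulationConfig(traits=study_traits(), seed=seed)
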