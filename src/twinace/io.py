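"""Cohort tables: reading, writing, validation, exclusions, and pair assembly.

The ingestion contract is a tidy per-subject CSV with the mandatory columns
``subject_id, pair_id, set_id, zygosity, sex, age_years`` followed by one
numeric column per morphometric trait (volumes in cm^3, thicknesses in mm).
Zygosity is ``MZ``/``DZ``; sex is ``F``/``M``; missing trait values may be
encoded as an empty cell or ``NA``.  Triplet sets (three subjects sharing a
``set_id`` and carrying no ``pair_id``) are expanded into the three possible
twin pairs before analysis.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CohortFormatError, ValidationError

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("subject_id", "pair_id", "set_id", "zygosity", "sex", "age_years")
ZYGOSITIES = ("MZ", "DZ")
SEXES = ("F", "M")


@dataclass(frozen=True)
class TwinPairRecord:
    """One analyzable pair for a single trait: both members' values plus covariates."""

    pair_id: str
    zygosity: str
    values: tuple[float, float]
    ages: tuple[float, float]
    sexes: tuple[str, str]

    def __post_init__(self) -> None:
        if self.zygosity not in ZYGOSITIES:
            raise ValidationError(f"zygosity must be MZ or DZ, got {self.zygosity!r}")
        if any(s not in SEXES for s in self.sexes):
            raise ValidationError(f"sexes must be F or M, got {self.sexes!r}")


class CohortTable:
    """A validated per-subject table of twins, their covariates and trait values.

    Wraps a :class:`pandas.DataFrame` whose first columns are the mandatory
    identifier/covariate columns; every remaining column is a trait.  Subjects
    belonging to an unexpanded triplet set carry a ``set_id`` and an empty
    ``pair_id``; after :func:`twinace.simulate.expand_triplets` every row has a
    ``pair_id`` mapping to exactly two rows.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise CohortFormatError(f"missing mandatory column(s): {', '.join(missing)}")
        df = df.copy()
        for col in ("subject_id", "pair_id", "set_id", "zygosity", "sex"):
            df[col] = df[col].astype("string").fillna("")
        df["age_years"] = pd.to_numeric(df["age_years"], errors="coerce")
        trait_cols = [c for c in df.columns if c not in MANDATORY_COLUMNS]
        for col in trait_cols:
            if pd.api.types.is_numeric_dtype(df[col]):
                continue
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "") \
                & (df[col].astype(str).str.upper() != "NA")
            if bad.any():
                logger.warning(
                    "trait %r: %d unparseable value(s) treated as missing", col, int(bad.sum())
                )
            df[col] = coerced
        self.df = df.reset_index(drop=True)
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self.df
        bad_zyg = ~df["zygosity"].isin(ZYGOSITIES)
        if bad_zyg.any():
            raise ValidationError(f"invalid zygosity values: {sorted(df.loc[bad_zyg, 'zygosity'].unique())}")
        bad_sex = ~df["sex"].isin(SEXES)
        if bad_sex.any():
            raise ValidationError(f"invalid sex values: {sorted(df.loc[bad_sex, 'sex'].unique())}")
        paired = df[df["pair_id"] != ""]
        if not paired.empty:
            dup = paired.duplicated(subset=["pair_id", "subject_id"])
            if dup.any():
                raise ValidationError(
                    f"duplicate subject_id within pair(s): "
                    f"{sorted(paired.loc[dup, 'pair_id'].unique())}"
                )
            # sex may differ pre-exclusion (opposite-sex pairs are removed later);
            # zygosity differing within a pair is always a data error
            combos = paired[["pair_id", "zygosity"]].drop_duplicates()
            bad_pairs = combos["pair_id"][combos["pair_id"].duplicated()]
            if not bad_pairs.empty:
                raise ValidationError(
                    f"zygosity not constant within pair(s): {sorted(bad_pairs.unique())}"
                )

    @property
    def traits(self) -> list[str]:
        return [c for c in self.df.columns if c not in MANDATORY_COLUMNS]

    @property
    def n_subjects(self) -> int:
        return len(self.df)

    @property
    def pair_ids(self) -> list[str]:
        return [p for p in self.df["pair_id"].unique() if p != ""]

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CohortTable({self.n_subjects} subjects, {self.n_pairs} pairs, "
            f"{len(self.traits)} traits)"
        )

    def write_csv(self, path: str | Path) -> None:
        """Write the tidy CSV (UTF-8, '.' decimal separator, header mandatory).

        Floats use %.17g so that write -> read round trips exactly."""
        self.df.to_csv(path, index=False, encoding="utf-8", float_format="%.17g")


def read_cohort(path: str | Path) -> CohortTable:
    """Read and validate a cohort CSV.

    Unparseable numeric cells become missing values (logged); a missing
    mandatory column raises :class:`CohortFormatError` naming the column, and
    a duplicated ``subject_id`` within a pair raises :class:`ValidationError`.
    """
    df = pd.read_csv(
        path,
        dtype={c: str for c in ("subject_id", "pair_id", "set_id", "zygosity", "sex")},
        keep_default_na=True,
        na_values=["NA", ""],
        encoding="utf-8",
        float_precision="round_trip",
    )
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.write_csv(path)


@dataclass
class ExclusionRecord:
    pair_id: str
    reason: str


def apply_exclusions(
    cohort: CohortTable,
    exclusions: Sequence[tuple[str, str]] | pd.DataFrame | None = None,
) -> tuple[CohortTable, list[ExclusionRecord]]:
    """Apply the study's exclusion rules and return the filtered cohort plus a log.

    Removes incomplete pairs (a ``pair_id`` with only one subject row),
    opposite-sex pairs, and any pair listed in the optional external
    ``exclusions`` table of ``(pair_id, reason)`` rows — the vehicle for
    reasons not derivable from the data itself (missed appointments, imaging
    quality).  Idempotent; an empty result is allowed with a warning.
    """
    log: list[ExclusionRecord] = []
    df = cohort.df
    drop_ids: dict[str, str] = {}

    if exclusions is not None:
        if isinstance(exclusions, pd.DataFrame):
            rows = exclusions.iloc[:, :2].itertuples(index=False)
        else:
            rows = iter(exclusions)
        for pair_id, reason in rows:
            drop_ids.setdefault(str(pair_id), str(reason))

    paired = df[df["pair_id"] != ""]
    sizes = paired.groupby("pair_id").size()
    for pid in sizes[sizes != 2].index:
        drop_ids.setdefault(pid, "incomplete pair")
    sex_n = paired.groupby("pair_id")["sex"].nunique()
    for pid in sex_n[sex_n > 1].index:
        drop_ids.setdefault(pid, "opposite-sex")

    for pid, reason in sorted(drop_ids.items()):
        log.append(ExclusionRecord(pair_id=pid, reason=reason))
        logger.info("excluding pair %s: %s", pid, reason)

    kept = df[~df["pair_id"].isin(drop_ids)].reset_index(drop=True)
    if kept.empty:
        warnings.warn("all pairs excluded; cohort is empty", stacklevel=2)
    return CohortTable(kept, validate=False), log


def pairs_for_trait(cohort: CohortTable, trait: str) -> list[TwinPairRecord]:
    """Assemble complete :class:`TwinPairRecord` objects for one trait.

    Pairs where either member is missing the trait value are dropped; member
    ordering follows file order (downstream correlation code is order-invariant
    by double entry).
    """
    if trait not in cohort.traits:
        raise KeyError(f"unknown trait {trait!r}; available: {cohort.traits}")
    df = cohort.df[cohort.df["pair_id"] != ""]
    if df.empty:
        return []
    codes, uniques = pd.factorize(df["pair_id"])
    counts = np.bincount(codes)
    complete = counts[codes] == 2
    df = df[complete]
    codes = codes[complete]
    # stable sort groups members by pair while preserving file order within a pair
    order = np.argsort(codes, kind="stable")
    pid = df["pair_id"].to_numpy()[order].reshape(-1, 2)
    zyg = df["zygosity"].to_numpy()[order].reshape(-1, 2)
    sex = df["sex"].to_numpy()[order].reshape(-1, 2)
    age = df["age_years"].to_numpy(dtype=float)[order].reshape(-1, 2)
    val = df[trait].to_numpy(dtype=float)[order].reshape(-1, 2)
    keep = ~np.isnan(val).any(axis=1)
    return [
        TwinPairRecord(
            pair_id=str(pid[i, 0]),
            zygosity=str(zyg[i, 0]),
            values=(float(val[i, 0]), float(val[i, 1])),
            ages=(float(age[i, 0]), float(age[i, 1])),
            sexes=(str(sex[i, 0]), str(sex[i, 1])),
        )
        for i in np.flatnonzero(keep)
    ]


def split_by_zygosity(
    pairs: Iterable[TwinPairRecord],
) -> tuple[list[TwinPairRecord], list[TwinPairRecord]]:
    """Split a pair list into (MZ, DZ) sublists."""
    mz = [p for p in pairs if p.zygosity == "MZ"]
    dz = [p for p in pairs if p.zygosity == "DZ"]
    return mz, dz
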