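"""Test-day records and design-matrix construction.

The unknown vector is laid out as ``[fixed | additive | permanent]``:

* fixed — all herd-test-day (HTD) levels, then DIM classes per parity with
  the first class of each parity dropped (HTD and DIM classes are
  confounded with an intercept within parity);
* additive — one contiguous coefficient block per pedigree animal holding
  (intercept a, slope v) pairs in parity order, so that the additive
  covariance is the Kronecker product ``A (x) Phi``;
* permanent — the analogous (pe, q) blocks for cows with records.

Every record carries covariates (1, f) on its animal's and cow's pair for
its parity, where f = f(THI) is the heat load of the test day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from heatnorm.relationships import Pedigree


@dataclass(frozen=True)
class TestDayRecord:
    """One test-day phenotype observation."""

    cow: str
    herd_test_day: str
    parity: int
    dim: int
    yield_value: float
    heat_load: float

    def __post_init__(self) -> None:
        if not (5 <= self.dim <= 305):
            raise ValueError(f"DIM must be in [5, 305], got {self.dim}")
        if self.heat_load < 0:
            raise ValueError(f"heat load must be >= 0, got {self.heat_load}")


@dataclass(frozen=True)
class ModelSpec:
    """Structural choices of the test-day model."""

    dim_class_width: int = 20
    dim_min: int = 5
    dim_max: int = 305
    thi_threshold: float = 68.0
    parities: tuple[int, ...] = (1, 2, 3)
    min_tests_per_lactation: int = 6
    #: which fixed factors to fit; empty tuple = no fixed effects (for
    #: degenerate/closed-form checks).
    fixed_factors: tuple[str, ...] = ("htd", "dim")

    def dim_class(self, dim: int) -> int:
        """1-based DIM class: [5, 24], [25, 44], ... (last class absorbs
        the remainder up to dim_max)."""
        if not (self.dim_min <= dim <= self.dim_max):
            raise ValueError(f"DIM {dim} outside [{self.dim_min}, {self.dim_max}]")
        return (dim - self.dim_min) // self.dim_class_width + 1


@dataclass
class DesignSystem:
    """Assembled incidence structures for one trait run."""

    W: sp.csr_matrix  # n_records x n_coef full design
    y: np.ndarray
    record_parity: np.ndarray  # parity per record (values from spec.parities)
    parities: tuple[int, ...]
    n_fixed: int
    animal_ids: list[str]
    cow_ids: list[str]
    fixed_labels: list[str]
    spec: ModelSpec
    #: contiguous sampling blocks: size-1 for fixed, size-2 per
    #: (animal|cow, parity) pair
    block_start: np.ndarray = field(default=None, repr=False)
    block_size: np.ndarray = field(default=None, repr=False)

    @property
    def n_parities(self) -> int:
        return len(self.parities)

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_cows(self) -> int:
        return len(self.cow_ids)

    @property
    def n_coef(self) -> int:
        return self.W.shape[1]

    @property
    def additive_slice(self) -> slice:
        return slice(self.n_fixed, self.n_fixed + 2 * self.n_parities * self.n_animals)

    @property
    def permanent_slice(self) -> slice:
        a = self.n_fixed + 2 * self.n_parities * self.n_animals
        return slice(a, a + 2 * self.n_parities * self.n_cows)

    def additive_index(self, animal: str, parity: int, slope: bool = False) -> int:
        i = self.animal_ids.index(animal)
        l = self.parities.index(parity)
        return self.n_fixed + i * 2 * self.n_parities + 2 * l + int(slope)

    def permanent_index(self, cow: str, parity: int, slope: bool = False) -> int:
        i = self.cow_ids.index(cow)
        l = self.parities.index(parity)
        return (
            self.permanent_slice.start
            + i * 2 * self.n_parities
            + 2 * l
            + int(slope)
        )


def build_design(
    records: Sequence[TestDayRecord],
    ped: Pedigree,
    spec: ModelSpec = ModelSpec(),
) -> DesignSystem:
    """Assemble the sparse design for one trait.

    Fixed-effect identifiability: all HTD levels are kept and the first DIM
    class present within each parity is dropped.  Raises ``KeyError``
    listing any record cows absent from the pedigree.
    """
    missing = sorted({r.cow for r in records} - set(ped.ids))
    if missing:
        raise KeyError(f"record cows missing from pedigree: {missing}")
    bad_par = sorted({r.parity for r in records} - set(spec.parities))
    if bad_par:
        raise ValueError(f"records with unmodelled parities: {bad_par}")

    n_rec = len(records)
    parities = spec.parities
    np_par = len(parities)

    # Fixed-effect levels.
    fixed_labels: list[str] = []
    col_of: dict[str, int] = {}
    if "htd" in spec.fixed_factors:
        for lev in sorted({r.herd_test_day for r in records}):
            col_of[f"htd:{lev}"] = len(fixed_labels)
            fixed_labels.append(f"htd:{lev}")
    if "dim" in spec.fixed_factors:
        for l in parities:
            classes = sorted({spec.dim_class(r.dim) for r in records if r.parity == l})
            for c in classes[1:]:  # drop first class per parity
                col_of[f"dim:p{l}:c{c}"] = len(fixed_labels)
                fixed_labels.append(f"dim:p{l}:c{c}")
    n_fixed = len(fixed_labels)

    animal_ids = list(ped.ids)
    animal_code = {a: i for i, a in enumerate(animal_ids)}
    cow_ids = sorted({r.cow for r in records}, key=lambda c: animal_code[c])
    cow_code = {c: i for i, c in enumerate(cow_ids)}
    n_anim, n_cows = len(animal_ids), len(cow_ids)
    add_off = n_fixed
    pe_off = n_fixed + 2 * np_par * n_anim
    n_coef = pe_off + 2 * np_par * n_cows

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    y = np.empty(n_rec)
    rec_par = np.empty(n_rec, dtype=np.int32)
    for i, r in enumerate(records):
        y[i] = r.yield_value
        rec_par[i] = r.parity
        l = parities.index(r.parity)
        if "htd" in spec.fixed_factors:
            rows.append(i)
            cols.append(col_of[f"htd:{r.herd_test_day}"])
            vals.append(1.0)
        if "dim" in spec.fixed_factors:
            key = f"dim:p{r.parity}:c{spec.dim_class(r.dim)}"
            if key in col_of:
                rows.append(i)
                cols.append(col_of[key])
                vals.append(1.0)
        a0 = add_off + animal_code[r.cow] * 2 * np_par + 2 * l
        p0 = pe_off + cow_code[r.cow] * 2 * np_par + 2 * l
        for c0 in (a0, p0):
            rows.append(i)
            cols.append(c0)
            vals.append(1.0)
            if r.heat_load != 0.0:
                rows.append(i)
                cols.append(c0 + 1)
                vals.append(r.heat_load)
    W = sp.csr_matrix((vals, (rows, cols)), shape=(n_rec, n_coef))

    # Sampling blocks: scalars for fixed, (intercept, slope) pairs after.
    starts = list(range(n_fixed)) + list(range(n_fixed, n_coef, 2))
    sizes = [1] * n_fixed + [2] * ((n_coef - n_fixed) // 2)
    return DesignSystem(
        W=W,
        y=y,
        record_parity=rec_par,
        parities=parities,
        n_fixed=n_fixed,
        animal_ids=animal_ids,
        cow_ids=cow_ids,
        fixed_labels=fixed_labels,
        spec=spec,
        block_start=np.array(starts, dtype=np.int64),
        block_size=np.array(sizes, dtype=np.int64),
    )


def apply_record_edits(
    df: pd.DataFrame, spec: ModelSpec = ModelSpec()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Standard test-day edits on a raw phenotype table.

    Drops records outside DIM [dim_min, dim_max], parities beyond those
    modelled, and whole lactations with fewer than
    ``min_tests_per_lactation`` tests.  Returns the surviving table and
    per-rule drop counts.
    """
    report = {}
    n0 = len(df)
    df = df[(df["dim"] >= spec.dim_min) & (df["dim"] <= spec.dim_max)]
    report["dim_range"] = n0 - len(df)
    n1 = len(df)
    df = df[df["parity"].isin(spec.parities)]
    report["parity"] = n1 - len(df)
    counts = df.groupby(["cow", "parity"])["dim"].transform("size")
    n2 = len(df)
    df = df[counts >= spec.min_tests_per_lactation]
    report["short_lactation"] = n2 - len(df)
    report["retained"] = len(df)
    return df.reset_index(drop=True), report


def read_test_day_records(path) -> pd.DataFrame:
    """Read the raw phenotype table
    (cow, herd, test_date, parity, dim, milk, fat, protein)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype={"cow": str, "herd": str})
    required = {"cow", "herd", "test_date", "parity", "dim"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return df


def records_from_table(
    df: pd.DataFrame, trait: str, heat_load_col: str = "heat_load"
) -> list[TestDayRecord]:
    """Turn an edited phenotype table (with attached heat loads) into records
    for one trait; HTD labels are herd x test date x parity."""
    return [
        TestDayRecord(
            cow=str(r.cow),
            herd_test_day=f"{r.herd}|{r.test_date}|{r.parity}",
            parity=int(r.parity),
            dim=int(r.dim),
            yield_value=float(getattr(r, trait)),
            heat_load=float(getattr(r, heat_load_col)),
        )
        for r in df.itertuples(index=False)
    ]
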