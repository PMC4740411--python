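"""Indirect age-sex standardization.

Given per-area event counts and populations by stratum, the national
stratum-specific rate is ``r_s = sum_i O[i,s] / sum_i n[i,s]``, the expected
count in area *i* is ``E_i = sum_s r_s * n[i,s]``, and the standardized
mortality ratio is ``SMR_i = O_i / E_i``.  When the rates are computed from
the study table itself (the default), standardization conserves totals:
``sum_i E_i == sum_i O_i`` exactly, so the population-weighted national SMR
is 1 by construction.  An option to supply externally published rates is
provided, in which case conservation does not hold.

Raw SMRs in small areas are dominated by Poisson noise (an area with E = 0.5
doubles its SMR with a single extra event); the spatial model in
:mod:`caremap.leroux` supplies the stabilized version.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import StratifiedAreaTable
from .errors import ValidationError


@dataclass(frozen=True)
class NationalRates:
    """Event rate per person for each stratum."""

    strata: tuple[str, ...]
    rates: np.ndarray  # shape (n_strata,)

    def __post_init__(self) -> None:
        if self.rates.shape != (len(self.strata),):
            raise ValidationError("one rate per stratum required")
        if np.any(self.rates < 0):
            raise ValidationError("rates must be non-negative")


@dataclass(frozen=True)
class ExpectedCounts:
    """Expected events per area under national stratum rates."""

    area_ids: tuple[str, ...]
    expected: np.ndarray  # shape (n_areas,)

    @property
    def zero_expected(self) -> np.ndarray:
        """Mask of areas with E == 0 (no population in any stratum with a
        positive rate); these cannot enter an offset model."""
        return self.expected == 0.0


@dataclass(frozen=True)
class SMRVector:
    """Raw standardized mortality ratios, with an explicit defined-mask."""

    area_ids: tuple[str, ...]
    smr: np.ndarray  # NaN where undefined (O == E == 0)
    defined: np.ndarray  # boolean

    def __post_init__(self) -> None:
        ok = self.smr[self.defined]
        if np.any(~np.isfinite(ok)) or np.any(ok < 0):
            raise ValidationError("defined SMRs must be finite and >= 0")


def national_rates(
    table: StratifiedAreaTable,
    external: NationalRates | None = None,
) -> NationalRates:
    """Pooled national rate per stratum, or pass-through of external rates.

    A stratum with zero national population but observed events is a
    contradiction and raises; zero population with zero events gets rate 0.
    """
    if external is not None:
        if set(external.strata) != set(table.strata):
            raise ValidationError("external rates do not cover the table's strata")
        order = [external.strata.index(s) for s in table.strata]
        return NationalRates(table.strata, external.rates[list(order)])
    tot_o = table.observed.sum(axis=0).astype(float)
    tot_n = table.population.sum(axis=0).astype(float)
    bad = (tot_n == 0) & (tot_o > 0)
    if bad.any():
        s = table.strata[int(np.argmax(bad))]
        raise ValidationError(
            f"stratum {s!r} has observed events but zero national population"
        )
    with np.errstate(invalid="ignore"):
        rates = np.where(tot_n > 0, tot_o / np.where(tot_n > 0, tot_n, 1.0), 0.0)
    return NationalRates(table.strata, rates)


def expected_counts(
    table: StratifiedAreaTable, rates: NationalRates
) -> ExpectedCounts:
    """``E_i = sum_s r_s * n[i,s]`` for every area."""
    if tuple(rates.strata) != tuple(table.strata):
        raise ValidationError("rates and table use different stratum sets")
    e = table.population.astype(float) @ rates.rates
    return ExpectedCounts(table.area_ids, e)


def smr(table: StratifiedAreaTable, expected: ExpectedCounts) -> SMRVector:
    """Elementwise ``O_i / E_i``.

    Areas with ``E == 0`` and ``O == 0`` are flagged undefined (NaN), never
    silently zero.  ``E == 0`` with ``O > 0`` means the expected counts were
    not derived consistently from this table and raises.
    """
    if tuple(expected.area_ids) != tuple(table.area_ids):
        raise ValidationError("expected counts computed for different areas")
    o = table.observed_totals.astype(float)
    e = expected.expected
    inconsistent = (e == 0) & (o > 0)
    if inconsistent.any():
        aid = table.area_ids[int(np.argmax(inconsistent))]
        raise ValidationError(
            f"area {aid!r} has zero expected count but positive observed "
            "count; standardization inputs are inconsistent"
        )
    defined = e > 0
    out = np.full_like(e, np.nan)
    out[defined] = o[defined] / e[defined]
    return SMRVector(table.area_ids, out, defined)


def standardize(
    table: StratifiedAreaTable,
    external: NationalRates | None = None,
) -> tuple[NationalRates, ExpectedCounts, SMRVector]:
    """Convenience: rates -> expected counts -> SMR in one call."""
    r = national_rates(table, external)
    e = expected_counts(table, r)
    return r, e, smr(table, e)
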