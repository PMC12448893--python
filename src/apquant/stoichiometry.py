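"""Partitioning a shared bait among competing complexes.

Because every complex engages the bait through a direct-binder subunit in
1:1 stoichiometry, the molar amount of each complex captured in a pulldown
equals the summed molar amount of its direct binders, which iBAQ estimates
up to a common constant.  The per-complex share of the bait is therefore

    proportion(c) = sum_{d in direct(c)} iBAQ(d) / sum_{c'} sum_d iBAQ(d)

and the bait mass balance — how much of the recovered bait the direct
binders jointly account for — is the same numerator total divided by the
bait's own iBAQ.  Interchangeable direct binders (paralogous subunits that
occupy the same slot) are summed within their complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .digest import IbaqTable
from .io import ComplexCatalog


@dataclass
class ComplexAbundance:
    """Per-complex bait partition plus overall mass balance."""

    frame: pd.DataFrame  # index complex; direct_binder_ibaq_sum, proportion, members_detected
    bait_id: str | None
    bait_ibaq: float | None
    mass_balance: float | None
    undetected_binders: dict[str, list[str]] = field(default_factory=dict)

    @property
    def proportions(self) -> dict[str, float]:
        return self.frame["proportion"].to_dict()

    @property
    def percentages(self) -> dict[str, int]:
        """Proportions rounded to integer percent (full precision in frame)."""
        return {k: round(100 * v) for k, v in self.proportions.items()}

    def top_share(self, n: int = 3) -> float:
        """Combined share (fraction) of the ``n`` most abundant complexes."""
        return float(self.frame["proportion"].nlargest(n).sum())


def complex_proportions(ibaq: IbaqTable, catalog: ComplexCatalog) -> ComplexAbundance:
    """Partition the bait among the catalog's complexes by direct-binder
    iBAQ sums.  Undetected direct binders contribute 0 and are reported."""
    rows = {}
    undetected: dict[str, list[str]] = {}
    for cdef in catalog:
        total = 0.0
        missing = []
        for pid in cdef.direct_binders:
            value = ibaq.ibaq_mean(pid) if pid in ibaq else np.nan
            if np.isnan(value):
                missing.append(pid)
            else:
                total += value
        detected = sum(
            1
            for pid in cdef.members
            if pid in ibaq and not np.isnan(ibaq.ibaq_mean(pid))
        )
        rows[cdef.name] = {
            "direct_binder_ibaq_sum": total,
            "members_detected": detected,
        }
        if missing:
            undetected[cdef.name] = missing
    frame = pd.DataFrame.from_dict(rows, orient="index")
    grand_total = float(frame["direct_binder_ibaq_sum"].sum())
    if grand_total <= 0:
        raise ValueError("no direct binder detected in any complex")
    frame["proportion"] = frame["direct_binder_ibaq_sum"] / grand_total
    frame["percent"] = (100 * frame["proportion"]).round().astype(int)
    return ComplexAbundance(
        frame=frame,
        bait_id=None,
        bait_ibaq=None,
        mass_balance=None,
        undetected_binders=undetected,
    )


def bait_mass_balance(ibaq: IbaqTable, bait_id: str, catalog: ComplexCatalog) -> float:
    """Fraction of recovered bait accounted for by summed direct-binder
    iBAQ under 1:1 binding. Values > 1 indicate over-assignment."""
    if bait_id not in ibaq or np.isnan(ibaq.ibaq_mean(bait_id)):
        raise ValueError(f"bait {bait_id!r} not detected")
    bait_value = ibaq.ibaq_mean(bait_id)
    total = 0.0
    for cdef in catalog:
        for pid in cdef.direct_binders:
            if pid in ibaq:
                v = ibaq.ibaq_mean(pid)
                if not np.isnan(v):
                    total += v
    balance = total / bait_value
    if balance > 1:
        import warnings

        warnings.warn(
            f"mass balance {balance:.3f} > 1: direct binders over-assigned",
            stacklevel=2,
        )
    return balance


@dataclass
class SubunitRatio:
    numerator: str
    denominator: str
    ratio: float | None  # None when undefined (either side undetected)

    @property
    def formatted(self) -> str:
        """'R:1' with one decimal; 'undefined' when a side is missing."""
        if self.ratio is None:
            return "undefined"
        return f"{self.ratio:.1f}:1"


def subunit_ratio(ibaq: IbaqTable, numerator_id: str, denominator_id: str) -> SubunitRatio:
    """iBAQ abundance ratio of two subunits (molar, length-bias free)."""
    def value(pid: str) -> float:
        if pid not in ibaq:
            raise ValueError(f"protein {pid!r} not in iBAQ table")
        return ibaq.ibaq_mean(pid)

    num, den = value(numerator_id), value(denominator_id)
    if np.isnan(num) or np.isnan(den) or den == 0:
        return SubunitRatio(numerator_id, denominator_id, None)
    return SubunitRatio(numerator_id, denominator_id, float(num / den))


@dataclass
class BindingChangeMatrix:
    """Catalog-ordered mutant-vs-reference differential-binding matrix.

    ``difference`` and ``q`` are proteins x mutants frames (NaN where the
    component was not quantified); ``complex_of`` maps each row to its
    complex; ``summary`` counts significantly increased / decreased
    components per (complex, mutant).
    """

    difference: pd.DataFrame
    q: pd.DataFrame
    complex_of: pd.Series
    summary: pd.DataFrame
    fdr_level: float

    def direction(self, protein: str, mutant: str) -> str:
        d = self.difference.at[protein, mutant]
        qv = self.q.at[protein, mutant]
        if np.isnan(d):
            return "missing"
        if qv <= self.fdr_level:
            return "increased" if d > 0 else "decreased"
        return "unchanged"


def differential_binding_matrix(
    results_by_mutant: Mapping[str, pd.DataFrame],
    catalog: ComplexCatalog,
    fdr_level: float = 0.05,
) -> BindingChangeMatrix:
    """Assemble per-mutant enrichment results into a complex-ordered matrix.

    ``results_by_mutant`` maps mutant name to a results table indexed by
    protein with ``difference`` and ``q`` columns (each computed against the
    same wild-type reference).  Components absent from a mutant's results
    are NaN, never zero.
    """
    # catalog order: complex by complex, member order preserved, first
    # complex wins for shared subunits
    order: list[str] = []
    complex_of: dict[str, str] = {}
    for cdef in catalog:
        for pid in cdef.members:
            if pid not in complex_of:
                complex_of[pid] = cdef.name
                order.append(pid)

    mutants = list(results_by_mutant)
    diff = pd.DataFrame(np.nan, index=order, columns=mutants)
    qmat = pd.DataFrame(np.nan, index=order, columns=mutants)
    for mutant, res in results_by_mutant.items():
        overlap = [p for p in order if p in res.index]
        if not overlap:
            raise ValueError(f"mutant {mutant!r}: no catalog proteins in results")
        diff.loc[overlap, mutant] = res.loc[overlap, "difference"].astype(float)
        qmat.loc[overlap, mutant] = res.loc[overlap, "q"].astype(float)

    rows = []
    for cdef in catalog:
        members = [p for p in order if complex_of[p] == cdef.name]
        for mutant in mutants:
            d = diff.loc[members, mutant]
            q = qmat.loc[members, mutant]
            sig = q <= fdr_level
            rows.append(
                {
                    "complex": cdef.name,
                    "mutant": mutant,
                    "n_components": len(members),
                    "n_quantified": int(d.notna().sum()),
                    "n_increased": int(((d > 0) & sig).sum()),
                    "n_decreased": int(((d < 0) & sig).sum()),
                }
            )
    summary = pd.DataFrame(rows)
    return BindingChangeMatrix(
        difference=diff,
        q=qmat,
        complex_of=pd.Series(complex_of).loc[order],
        summary=summary,
        fdr_level=fdr_level,
    )


# --- model / results interface -------------------------------------------


@dataclass
class ComplexPartitionResults:
    """Fitted bait-partition estimates with ratios and mass balance."""

    abundance: ComplexAbundance
    mass_balance: float | None
    bait_id: str | None
    ratios: list[SubunitRatio] = field(default_factory=list)

    def summary(self) -> str:
        lines = ["Complex partition of bait-bound material (direct-binder iBAQ)"]
        frame = self.abundance.frame.sort_values("proportion", ascending=False)
        for name, row in frame.iterrows():
            lines.append(
                f"  {name:<12} {int(row['percent']):>3d}%  "
                f"(iBAQ sum {row['direct_binder_ibaq_sum']:.3e}, "
                f"{int(row['members_detected'])} members detected)"
            )
        lines.append(f"  top-3 share: {round(100 * self.abundance.top_share(3))}%")
        if self.mass_balance is not None:
            lines.append(
                f"  bait mass balance ({self.bait_id}): "
                f"{100 * self.mass_balance:.1f}% of bait accounted for"
            )
        for r in self.ratios:
            lines.append(f"  {r.numerator}/{r.denominator} ratio: {r.formatted}")
        for cname, missing in self.abundance.undetected_binders.items():
            lines.append(f"  note: {cname} direct binder(s) undetected: {missing}")
        return "\n".join(lines)

    def pie(self, ax=None):
        """Pie chart of the complex proportions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        frame = self.abundance.frame.sort_values("proportion", ascending=False)
        ax.pie(frame["proportion"], labels=frame.index, autopct="%d%%")
        return ax


class ComplexPartitionModel:
    """Estimates how a shared bait is partitioned among complexes.

    Parameters
    ----------
    ibaq : IbaqTable
    catalog : ComplexCatalog
    bait_id : str, optional
        Enables the mass-balance check when given.
    """

    def __init__(self, ibaq: IbaqTable, catalog: ComplexCatalog,
                 bait_id: str | None = None):
        self.ibaq = ibaq
        self.catalog = catalog
        self.bait_id = bait_id

    def fit(self, ratio_pairs: list[tuple[str, str]] | None = None) -> ComplexPartitionResults:
        abundance = complex_proportions(self.ibaq, self.catalog)
        balance = None
        if self.bait_id is not None:
            balance = bait_mass_balance(self.ibaq, self.bait_id, self.catalog)
            abundance.bait_id = self.bait_id
            abundance.bait_ibaq = self.ibaq.ibaq_mean(self.bait_id)
            abundance.mass_balance = balance
        ratios = [
            subunit_ratio(self.ibaq, a, b) for a, b in (ratio_pairs or [])
        ]
        return ComplexPartitionResults(
            abundance=abundance,
            mass_balance=balance,
            bait_id=self.bait_id,
            ratios=ratios,
        )
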