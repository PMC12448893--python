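"""Label-free differential-binding statistics.

The workflow mirrors the standard Perseus-style label-free analysis:

1. drop flagged rows (reverse / contaminant / only-identified-by-site);
2. log2-transform intensities (zero -> missing);
3. median-centre each sample;
4. keep proteins with >= ``min_valid`` measurements in at least one group;
5. impute remaining missing values from a down-shifted Gaussian
   (per-sample mean - ``downshift`` * sd, width ``width`` * sd) — the
   missing-not-at-random assumption that absent signals sit at the
   detection floor;
6. two-sided pooled-variance (Student's) t-tests per protein;
7. permutation-based FDR on the SAM-style statistic
   ``d_i = diff_i / (se_i + s0)``: group labels are permuted (exhaustively
   when feasible), and for each threshold the expected number of permuted
   exceedances is compared with the observed count.

These steps are implemented here rather than delegated, since the fully
parameterized statistic is the package's point; scipy supplies only
distribution functions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ProteinGroupsTable, SampleDesign, filter_flagged


@dataclass
class LogIntensityMatrix:
    """Proteins x samples log2-intensity matrix; NaN marks missing."""

    values: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        self.design.validate_against(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """True where a measurement is present."""
        return self.values.notna()

    def group_columns(self, group: str) -> list[str]:
        return [c for c in self.values.columns if self.design.groups[c] == group]


@dataclass(frozen=True)
class ImputeParams:
    """Down-shifted Gaussian imputation settings (Perseus convention):
    missing cells draw from Normal(mu - downshift*sigma, (width*sigma)^2)
    with mu, sigma from the observed values of the same sample."""

    width: float = 0.3
    downshift: float = 1.8
    per_column: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.downshift <= 0:
            raise ValueError("downshift must be > 0")


@dataclass(frozen=True)
class TestParams:
    fdr_level: float = 0.05
    n_permutations: int = 250
    s0: float = 0.0
    min_valid: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must be in (0, 1)")
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0")


def log2_transform(table: ProteinGroupsTable, which: str = "lfq",
                   design: SampleDesign | None = None) -> LogIntensityMatrix:
    """Log2 intensities; zeros become missing (NaN)."""
    intens = table.intensities(which)
    values = intens.where(intens > 0).apply(np.log2)
    if design is None:
        raise ValueError("a SampleDesign is required")
    return LogIntensityMatrix(values=values, design=design)


def median_normalize(m: LogIntensityMatrix) -> LogIntensityMatrix:
    """Subtract each sample's median over present values (idempotent)."""
    medians = m.values.median(axis=0, skipna=True)
    if medians.isna().any():
        empty = list(medians.index[medians.isna()])
        raise ValueError(f"sample(s) with no present values: {empty}")
    return LogIntensityMatrix(values=m.values - medians, design=m.design)


def filter_min_valid(m: LogIntensityMatrix, min_valid: int = 3) -> LogIntensityMatrix:
    """Keep proteins with >= min_valid present values in at least one group."""
    keep = pd.Series(False, index=m.values.index)
    for group in {m.design.treatment, m.design.control}:
        cols = m.group_columns(group)
        if min_valid > len(cols):
            warnings.warn(
                f"min_valid={min_valid} exceeds size of group {group!r} "
                f"({len(cols)} samples); that group can never qualify",
                stacklevel=2,
            )
        keep |= m.mask[cols].sum(axis=1) >= min_valid
    return LogIntensityMatrix(values=m.values.loc[keep].copy(), design=m.design)


def impute_gaussian_downshift(m: LogIntensityMatrix,
                              params: ImputeParams | None = None) -> LogIntensityMatrix:
    """Replace missing cells with draws from the down-shifted Gaussian."""
    if params is None:
        params = ImputeParams()
    rng = np.random.default_rng(params.seed)
    values = m.values.copy()
    if params.per_column:
        for col in values.columns:
            observed = values[col].dropna()
            if len(observed) < 2:
                raise ValueError(f"column {col!r}: need >= 2 present values")
            mu, sigma = float(observed.mean()), float(observed.std(ddof=1))
            if sigma == 0:
                raise ValueError(f"column {col!r}: zero spread, imputation degenerate")
            miss = values[col].isna()
            if miss.any():
                values.loc[miss, col] = rng.normal(
                    mu - params.downshift * sigma,
                    params.width * sigma,
                    size=int(miss.sum()),
                )
    else:
        flat = values.to_numpy().ravel()
        observed = flat[~np.isnan(flat)]
        if observed.size < 2:
            raise ValueError("need >= 2 present values for whole-matrix imputation")
        mu, sigma = float(observed.mean()), float(observed.std(ddof=1))
        if sigma == 0:
            raise ValueError("zero spread, imputation degenerate")
        miss = np.isnan(flat)
        flat[miss] = rng.normal(
            mu - params.downshift * sigma, params.width * sigma, size=int(miss.sum())
        )
        values = pd.DataFrame(
            flat.reshape(values.shape), index=values.index, columns=values.columns
        )
    return LogIntensityMatrix(values=values, design=m.design)


def _ttest_arrays(a: np.ndarray, b: np.ndarray, s0: float = 0.0):
    """Row-wise pooled-variance two-sample t.

    Returns (difference a-b, se, t, two-sided p, d) with d = diff/(se+s0).
    Zero pooled variance gives t = +/-inf and p = 0 (documented convention);
    a zero difference on top of zero variance gives t = 0, p = 1.
    """
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need >= 2 samples")
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    df = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0),
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
        p = np.where(
            np.isinf(t), 0.0, np.where(t == 0, 1.0, 2.0 * sps.t.sf(np.abs(t), df))
        )
        d = np.where(se + s0 > 0, diff / (se + s0),
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    return diff, se, t, p, d


def two_sample_ttest(m: LogIntensityMatrix,
                     contrast: tuple[str, str] | None = None) -> pd.DataFrame:
    """Per-protein Student's t-test (treatment - control).

    Requires a fully-present matrix (impute first).
    """
    if m.values.isna().any().any():
        raise ValueError("matrix contains missing values; impute first")
    if contrast is None:
        contrast = (m.design.treatment, m.design.control)
    a = m.values[m.group_columns(contrast[0])].to_numpy()
    b = m.values[m.group_columns(contrast[1])].to_numpy()
    diff, se, t, p, _ = _ttest_arrays(a, b)
    return pd.DataFrame(
        {"difference": diff, "se": se, "t": t, "p": p}, index=m.values.index
    )


def _label_assignments(n1: int, n2: int) -> list[np.ndarray]:
    """All distinct assignments of n1 'treatment' slots among n1+n2 samples,
    as index arrays into the concatenated sample axis.  The identity
    (observed labelling) is first."""
    n = n1 + n2
    out = [np.array(c) for c in combinations(range(n), n1)]
    identity = tuple(range(n1))
    out.sort(key=lambda c: tuple(c) != identity)
    return out


def n_distinct_assignments(n1: int, n2: int) -> int:
    return math.comb(n1 + n2, n1)


def permutation_fdr(m: LogIntensityMatrix,
                    contrast: tuple[str, str] | None = None,
                    params: TestParams | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Permutation-based FDR on the SAM-style statistic.

    For each candidate threshold (the observed |d| values, descending),
    the estimated FDR is the mean count of permuted |d*| exceeding the
    threshold divided by the observed count; q-values are the running
    minimum of that estimate from the smallest |d| upwards, capped at 1.

    When the number of distinct group-label assignments is at most
    ``n_permutations``, all of them are used (exhaustive mode, including
    the observed labelling); otherwise ``n_permutations`` assignments are
    drawn uniformly at random excluding the identity.
    """
    if params is None:
        params = TestParams()
    if contrast is None:
        contrast = (m.design.treatment, m.design.control)
    if m.values.isna().any().any():
        raise ValueError("matrix contains missing values; impute first")
    cols1 = m.group_columns(contrast[0])
    cols2 = m.group_columns(contrast[1])
    n1, n2 = len(cols1), len(cols2)
    if n_distinct_assignments(n1, n2) < 2:
        raise ValueError("fewer than 2 distinct group-label assignments")
    X = m.values[cols1 + cols2].to_numpy()

    diff, se, t, p, d_obs = _ttest_arrays(X[:, :n1], X[:, n1:], s0=params.s0)
    abs_obs = np.abs(d_obs)

    exhaustive = n_distinct_assignments(n1, n2) <= params.n_permutations
    if exhaustive:
        assignments = _label_assignments(n1, n2)
    else:
        rng = np.random.default_rng(seed)
        identity = tuple(range(n1))
        seen: set[tuple[int, ...]] = set()
        assignments = []
        while len(assignments) < params.n_permutations:
            perm = tuple(sorted(rng.choice(n1 + n2, size=n1, replace=False)))
            if perm == identity or perm in seen:
                continue
            seen.add(perm)
            assignments.append(np.array(perm))

    all_idx = np.arange(n1 + n2)
    perm_abs = np.empty((len(assignments), X.shape[0]))
    for k, idx1 in enumerate(assignments):
        idx2 = np.setdiff1d(all_idx, idx1)
        *_, d_perm = _ttest_arrays(X[:, idx1], X[:, idx2], s0=params.s0)
        perm_abs[k] = np.abs(d_perm)

    # FDR at each observed |d| as threshold, then monotonize.
    order = np.argsort(-abs_obs, kind="stable")
    sorted_abs = abs_obs[order]
    # ties: every protein at a tied |d| exceeds the threshold
    observed_count = np.searchsorted(-sorted_abs, -sorted_abs, side="right").astype(float)
    flat = np.sort(perm_abs.ravel())
    exceed_total = flat.size - np.searchsorted(flat, sorted_abs, side="left")
    mean_perm_count = exceed_total / float(len(assignments))
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(observed_count > 0, mean_perm_count / observed_count, 0.0)
    fdr = np.minimum(fdr, 1.0)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted

    out = pd.DataFrame(
        {
            "difference": diff,
            "se": se,
            "t": t,
            "p": p,
            "d": d_obs,
            "q": q,
            "significant": q <= params.fdr_level,
        },
        index=m.values.index,
    )
    out.attrs["n_permutations_used"] = len(assignments)
    out.attrs["exhaustive"] = exhaustive
    return out


# --- model / results interface -------------------------------------------


@dataclass
class EnrichmentResults:
    """Results of an enrichment (differential-binding) analysis.

    Attributes
    ----------
    table : DataFrame indexed by protein with columns difference (log2,
        treatment - control), se, t, p, d, q, significant.
    stage_log : list of (stage name, rows remaining) in pipeline order.
    params : the TestParams used.
    """

    table: pd.DataFrame
    stage_log: list[tuple[str, int]]
    params: TestParams
    impute_params: ImputeParams
    contrast: tuple[str, str]

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def enriched(self) -> pd.DataFrame:
        """Significant proteins with positive difference (bound above
        control).  In bait-vs-control designs this is the interactor list:
        median normalization centres each sample on its bulk background, so
        rows detected only in the bait samples push the bait medians up and
        the background drifts slightly negative — significant *depleted*
        proteins are an expected artifact of that centring, not binders."""
        return self.table[self.table["significant"] & (self.table["difference"] > 0)]

    @property
    def n_enriched(self) -> int:
        return int(len(self.enriched))

    def summary(self) -> str:
        lines = [
            "Enrichment analysis (two-sided Student's t, permutation FDR)",
            f"  contrast:        {self.contrast[0]} vs {self.contrast[1]}",
            f"  FDR level:       {self.params.fdr_level}",
            f"  s0:              {self.params.s0}",
            f"  imputation:      width={self.impute_params.width}, "
            f"downshift={self.impute_params.downshift}",
            "  stages:",
        ]
        for stage, n in self.stage_log:
            lines.append(f"    {stage:<18} {n:>6} proteins")
        lines.append(f"  significant:     {self.n_significant} at q <= {self.params.fdr_level}")
        lines.append(f"  enriched:        {self.n_enriched} (significant and positive)")
        top = self.significant.sort_values("q").head(10)
        if len(top):
            lines.append("  top hits (by q, then |difference|):")
            for pid, row in top.iterrows():
                lines.append(
                    f"    {pid:<16} diff={row['difference']:+7.2f}  "
                    f"t={row['t']:+8.2f}  q={row['q']:.4f}"
                )
        return "\n".join(lines)

    def volcano(self, ax=None):
        """Volcano plot: log2 difference vs -log10 p, hits highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        tab = self.table
        logp = -np.log10(np.clip(tab["p"], 1e-300, None))
        sig = tab["significant"]
        ax.scatter(tab.loc[~sig, "difference"], logp[~sig], s=8, c="0.6", lw=0)
        ax.scatter(tab.loc[sig, "difference"], logp[sig], s=10, c="crimson", lw=0)
        ax.set_xlabel(f"log2 difference ({self.contrast[0]} - {self.contrast[1]})")
        ax.set_ylabel("-log10 p")
        return ax


class EnrichmentModel:
    """Differential-binding model for a bait-vs-control pulldown.

    Wraps the full label-free workflow (flag filtering, log2, median
    centring, valid-value filtering, MNAR imputation, Student's t with
    permutation FDR) behind a statsmodels-style ``fit()``.

    Parameters
    ----------
    table : ProteinGroupsTable
    design : SampleDesign
    which : {"lfq", "raw"}
        Which intensity columns to analyse (LFQ by default).
    """

    def __init__(self, table: ProteinGroupsTable, design: SampleDesign,
                 which: str = "lfq", min_valid: int = 3):
        design.validate_against(table.samples)
        self.table = table
        self.design = design
        self.which = "intensity" if which == "raw" else which
        self.min_valid = min_valid

    @classmethod
    def from_files(cls, table_path, design_path, **kwargs) -> "EnrichmentModel":
        from .io import read_design, read_protein_groups

        return cls(read_protein_groups(table_path), read_design(design_path), **kwargs)

    def fit(self, params: TestParams | None = None,
            impute_params: ImputeParams | None = None,
            seed: int = 0) -> EnrichmentResults:
        if params is None:
            params = TestParams(min_valid=self.min_valid)
        if impute_params is None:
            impute_params = ImputeParams(seed=seed)
        log: list[tuple[str, int]] = [("input", len(self.table))]
        filtered, _ = filter_flagged(self.table)
        log.append(("filter_flagged", len(filtered)))
        if len(filtered) == 0:
            raise ValueError("no rows left after flag filtering")
        m = log2_transform(filtered, which=self.which, design=self.design)
        m = median_normalize(m)
        log.append(("median_normalize", len(m.values)))
        m = filter_min_valid(m, params.min_valid)
        log.append(("filter_min_valid", len(m.values)))
        if len(m.values) == 0:
            raise ValueError("no rows left after valid-value filtering")
        m = impute_gaussian_downshift(m, impute_params)
        result = permutation_fdr(m, params=params, seed=seed)
        log.append(("tested", len(result)))
        return EnrichmentResults(
            table=result,
            stage_log=log,
            params=params,
            impute_params=impute_params,
            contrast=(self.design.treatment, self.design.control),
        )


def enrichment_analysis(table: ProteinGroupsTable, design: SampleDesign,
                        params: TestParams | None = None,
                        impute_params: ImputeParams | None = None,
                        which: str = "lfq", seed: int = 0) -> EnrichmentResults:
    """Functional shorthand for ``EnrichmentModel(...).fit(...)``."""
    return EnrichmentModel(table, design, which=which).fit(
        params=params, impute_params=impute_params, seed=seed
    )


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    n_intersection: int
    pct_a_in_b: float | None
    pct_b_in_a: float | None

    @property
    def pct_a_in_b_rounded(self) -> int | None:
        return None if self.pct_a_in_b is None else round(self.pct_a_in_b)

    @property
    def pct_b_in_a_rounded(self) -> int | None:
        return None if self.pct_b_in_a is None else round(self.pct_b_in_a)


def set_overlap(set_a: Sequence[str], set_b: Sequence[str]) -> OverlapResult:
    """Venn-style overlap of two identifier sets with shared percentages."""
    a, b = set(set_a), set(set_b)
    inter = len(a & b)
    return OverlapResult(
        n_a=len(a),
        n_b=len(b),
        n_intersection=inter,
        pct_a_in_b=100.0 * inter / len(a) if a else None,
        pct_b_in_a=100.0 * inter / len(b) if b else None,
    )
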