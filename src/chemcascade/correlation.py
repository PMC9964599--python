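"""Target-activity vs cell-activity correlation mining.

Filters target bioactivity annotations (binding assays on single human
proteins, exact nanomolar values), pairs per-target potencies with
antiproliferative potencies on a named cell line, and selects targets whose
Spearman rank correlation is strong (rho >= 0.40 by default), significant
(p <= 0.05) and robust (lower confidence bound also >= 0.40).

Because Spearman's rho is invariant under strictly monotone transforms,
correlations are computed on raw nanomolar values — raw nM and -log10
potency give identical results. A positive rho means compounds potent on
the target tend to be potent on the cells (both scales: lower = stronger).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .curation import (
    TARGET_STANDARD_TYPES,
    BioactivityRecord,
    dedup_best,
)
from .errors import (
    DuplicateKeyError,
    InsufficientDataError,
    UndefinedCorrelationError,
)

TARGET_FILTER_DEFAULTS = {
    "relation": "=",
    "units": "nM",
    "target_type": "Single protein",
    "target_organism": "Homo Sapiens",
    "assay_type": "B",
}


@dataclass(frozen=True)
class PairedPotencyVector:
    """Per-(target, cell line) inner join of potencies, one pair per compound."""

    target_id: str
    cell_line: str
    pairs: tuple[tuple[str, float, float], ...]  # (compound_id, target_nm, cell_nm)

    @property
    def n(self) -> int:
        return len(self.pairs)

    @property
    def target_values(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs])

    @property
    def cell_values(self) -> np.ndarray:
        return np.array([p[2] for p in self.pairs])


@dataclass(frozen=True)
class TargetCorrelationResult:
    target_id: str
    cell_line: str
    n: int
    rho: float
    p_value: float
    ci_low: float
    ci_high: float
    selected: bool
    diagnostic: str = ""


def filter_target_bioactivities(
    records: Sequence[BioactivityRecord],
) -> list[BioactivityRecord]:
    """Apply the six target-record retention clauses, then dedup per (compound, target).

    Clauses: standard type in {IC50, Ki, Kd, EC50}; relation exactly "=";
    unit exactly "nM"; target type "Single protein"; organism "Homo
    Sapiens"; assay type "B" (binding). Dedup keeps the most potent record.
    """
    kept = [
        r
        for r in records
        if r.standard_type in TARGET_STANDARD_TYPES
        and r.standard_relation == TARGET_FILTER_DEFAULTS["relation"]
        and r.standard_units == TARGET_FILTER_DEFAULTS["units"]
        and r.target_type == TARGET_FILTER_DEFAULTS["target_type"]
        and r.target_organism == TARGET_FILTER_DEFAULTS["target_organism"]
        and r.assay_type == TARGET_FILTER_DEFAULTS["assay_type"]
    ]
    return dedup_best(kept)


def min_annotation_filter(
    records: Sequence[BioactivityRecord],
    min_n: int = 10,
) -> list[str]:
    """Target ids with at least ``min_n`` distinct compound annotations."""
    counts: dict[str, set[str]] = {}
    order: list[str] = []
    for r in records:
        if r.scope_id not in counts:
            counts[r.scope_id] = set()
            order.append(r.scope_id)
        counts[r.scope_id].add(r.compound_id)
    return [t for t in order if len(counts[t]) >= min_n]


def build_pairs(
    target_records: Sequence[BioactivityRecord],
    cell_records: Sequence[BioactivityRecord],
    cell_line: str,
    restrict_to_highly_active: bool = False,
    potency_cutoff_nm: float = 1000.0,
) -> PairedPotencyVector:
    """Inner-join one target's records with one cell line's records on compound.

    Both inputs must be deduplicated (one record per compound per scope).
    By default all paired compounds enter the correlation; with
    ``restrict_to_highly_active`` only pairs whose cell potency is at or
    below ``potency_cutoff_nm`` are kept.

    Raises
    ------
    DuplicateKeyError
        If either side carries more than one record per compound.
    """
    targets = [r for r in target_records]
    cells = [r for r in cell_records if r.scope_id == cell_line]
    t_ids = [r.compound_id for r in targets]
    c_ids = [r.compound_id for r in cells]
    if len(set(t_ids)) != len(t_ids) or len(set(c_ids)) != len(c_ids):
        raise DuplicateKeyError("records must be deduplicated before pairing")
    target_id = targets[0].scope_id if targets else ""
    cell_map = {r.compound_id: r.standard_value for r in cells}
    pairs = tuple(
        (r.compound_id, r.standard_value, cell_map[r.compound_id])
        for r in targets
        if r.compound_id in cell_map
        and (not restrict_to_highly_active or cell_map[r.compound_id] <= potency_cutoff_nm)
    )
    return PairedPotencyVector(target_id=target_id, cell_line=cell_line, pairs=pairs)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-aware Spearman rho with the t-distribution p-value (n-2 df).

    Raises
    ------
    InsufficientDataError
        If fewer than 3 pairs.
    UndefinedCorrelationError
        If either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise InsufficientDataError(f"need n >= 3 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the vectors")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def rho_confidence_interval(
    rho: float,
    n: int,
    level: float = 0.95,
) -> tuple[float, float]:
    """Fisher-z interval for Spearman's rho, Bonett–Wright standard error.

    z = atanh(rho) +/- z_crit * sqrt((1 + rho^2/2) / (n - 3)), back-
    transformed with tanh.

    Raises
    ------
    InsufficientDataError
        If n < 4.
    """
    if n < 4:
        raise InsufficientDataError(f"need n >= 4 for the interval, got {n}")
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie strictly inside (-1, 1)")
    z = np.arctanh(rho)
    se = np.sqrt((1.0 + rho**2 / 2.0) / (n - 3))
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se))


def bootstrap_rho_interval(
    x: Sequence[float],
    y: Sequence[float],
    level: float = 0.95,
    n_resamples: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Seeded percentile-bootstrap interval for Spearman's rho (alternative)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(x)
    rhos = np.empty(n_resamples)
    for b in range(n_resamples):
        idx = rng.integers(0, n, n)
        xr, yr = x[idx], y[idx]
        if np.ptp(xr) == 0 or np.ptp(yr) == 0:
            rhos[b] = 0.0
        else:
            rhos[b] = stats.spearmanr(xr, yr).statistic
    lo = (1.0 - level) / 2.0
    return float(np.quantile(rhos, lo)), float(np.quantile(rhos, 1.0 - lo))


def correlate(
    vector: PairedPotencyVector,
    rho_min: float = 0.40,
    p_max: float = 0.05,
    require_ci: bool = True,
    ci_level: float = 0.95,
) -> TargetCorrelationResult:
    """Score one paired vector and evaluate the selection criteria.

    Vectors that are too short or have zero variance are reported as
    not-selected with a diagnostic instead of raising, so a pipeline over
    many targets never aborts on a degenerate one.
    """

    def _fail(diag: str) -> TargetCorrelationResult:
        return TargetCorrelationResult(
            target_id=vector.target_id,
            cell_line=vector.cell_line,
            n=vector.n,
            rho=float("nan"),
            p_value=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            selected=False,
            diagnostic=diag,
        )

    try:
        rho, p = spearman(vector.target_values, vector.cell_values)
    except InsufficientDataError:
        return _fail("insufficient data")
    except UndefinedCorrelationError:
        return _fail("zero variance")
    if vector.n < 4 or abs(rho) >= 1.0:
        ci_low, ci_high = (rho, rho) if abs(rho) >= 1.0 else (float("nan"), float("nan"))
        diag = "degenerate interval"
    else:
        ci_low, ci_high = rho_confidence_interval(rho, vector.n, ci_level)
        diag = ""
    selected = rho >= rho_min and p <= p_max and (not require_ci or ci_low >= rho_min)
    return TargetCorrelationResult(
        target_id=vector.target_id,
        cell_line=vector.cell_line,
        n=vector.n,
        rho=rho,
        p_value=p,
        ci_low=ci_low,
        ci_high=ci_high,
        selected=selected,
        diagnostic=diag,
    )


def select_targets(
    results: Iterable[TargetCorrelationResult],
    rho_min: float = 0.40,
    p_max: float = 0.05,
    require_ci: bool = True,
) -> list[TargetCorrelationResult]:
    """Retain results with rho >= rho_min, p <= p_max and (optionally) ci_low >= rho_min."""
    out = []
    for r in results:
        if not np.isfinite(r.rho):
            continue
        if r.rho >= rho_min and r.p_value <= p_max:
            if require_ci and not (np.isfinite(r.ci_low) and r.ci_low >= rho_min):
                continue
            out.append(r)
    return out
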