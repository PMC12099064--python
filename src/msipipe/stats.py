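"""Concordance statistics: IHC class logic, exact tests, CIs, ROC, and the
MSI-versus-IHC diagnostic summary.

The mismatch-repair (MMR) class of a sample is derived from its four
protein stains by precedence: any uninterpretable stain makes the result
NA; otherwise any clear loss is MMR-deficient (MMRd) even when another
protein is merely equivocal, as MMR function requires all four proteins;
otherwise any equivocal stain leaves the status equivocal; otherwise the
sample is MMR-proficient (MMRp).

Hypothesis tests wrap scipy where scipy implements the exact procedure
(2x2 Fisher, Mann-Whitney, Kruskal-Wallis). The r x c Fisher exact test
is computed here by full enumeration of all tables with the observed
margins — scipy has no r x c exact test — and refuses tables beyond an
enumeration budget rather than silently falling back to an asymptotic
approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .errors import IhcFormatError, StatsError

PROTEINS = ("mlh1", "pms2", "msh2", "msh6")
IHC_TOKENS = ("retained", "loss", "equivocal", "uninterpretable")

MMR_CLASSES = ("MMRd", "equivocal", "MMRp", "NA")
MSI_CALLS = ("MSS", "uncertain", "MSI-H")

#: relative tolerance when comparing table probabilities in exact tests
_FISHER_RELTOL = 1e-7


# ---------------------------------------------------------------------------
# IHC records and MMR class logic


@dataclass(frozen=True)
class IhcRecord:
    """Per-protein IHC staining statuses for one sample."""

    sample_id: str
    mlh1: str
    pms2: str
    msh2: str
    msh6: str

    def __post_init__(self) -> None:
        for protein in PROTEINS:
            status = getattr(self, protein)
            if status not in IHC_TOKENS:
                raise IhcFormatError(
                    f"sample {self.sample_id!r}: unknown {protein} status "
                    f"{status!r}; expected one of {IHC_TOKENS}"
                )

    def status(self, protein: str) -> str:
        return getattr(self, protein)


def derive_mmr_class(record: IhcRecord) -> str:
    """MMR class with precedence uninterpretable > loss > equivocal."""
    statuses = [record.status(p) for p in PROTEINS]
    if "uninterpretable" in statuses:
        return "NA"
    if "loss" in statuses:
        return "MMRd"
    if "equivocal" in statuses:
        return "equivocal"
    return "MMRp"


def classify_loss_pattern(record: IhcRecord) -> str:
    """Canonical loss-pattern label for an MMR-deficient record.

    Heterodimer logic groups patterns: MutS-alpha co-loss (MSH2+MSH6),
    MutL-alpha co-loss (PMS2 lost with MLH1 lost *or* equivocal, since
    punctate MLH1 staining with PMS2 loss is read as MLH1 loss), isolated
    MSH6 (allowing equivocal MSH2), isolated PMS2, and everything else.
    """
    if derive_mmr_class(record) != "MMRd":
        raise StatsError("loss patterns are defined only for MMRd records")
    m1, p2, m2, m6 = (record.status(p) for p in PROTEINS)
    if m2 == "loss" and m6 == "loss" and m1 == "retained" and p2 == "retained":
        return "MSH2/MSH6"
    if p2 == "loss" and m1 in ("loss", "equivocal") and m2 == "retained" and m6 == "retained":
        return "MLH1/PMS2"
    if m6 == "loss" and m1 == "retained" and p2 == "retained" and m2 in ("retained", "equivocal"):
        return "MSH6 only"
    if p2 == "loss" and m1 == "retained" and m2 == "retained" and m6 == "retained":
        return "PMS2 only"
    return "other"


def read_ihc_csv(path: Union[str, Path]) -> List[IhcRecord]:
    """Read ``sample_id, mlh1, pms2, msh2, msh6`` CSV into records."""
    df = pd.read_csv(path, dtype=str)
    expected = ["sample_id", *PROTEINS]
    if list(df.columns) != expected:
        raise IhcFormatError(
            f"{path}: columns must be {expected}, got {list(df.columns)}"
        )
    return [
        IhcRecord(
            sample_id=row.sample_id,
            mlh1=row.mlh1,
            pms2=row.pms2,
            msh2=row.msh2,
            msh6=row.msh6,
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# exact binomial CI


def clopper_pearson(x: int, n: int, conf: float = 0.95) -> Tuple[float, float]:
    """Exact (Clopper-Pearson) binomial CI from Beta quantiles.

    Closed-form boundaries: lower = 0 when x = 0, upper = 1 when x = n.
    """
    if n < 1 or not 0 <= x <= n:
        raise StatsError(f"need 0 <= x <= n with n >= 1, got x={x}, n={n}")
    if not 0.0 < conf < 1.0:
        raise StatsError("confidence level must lie in (0, 1)")
    alpha = 1.0 - conf
    lower = 0.0 if x == 0 else float(sps.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(sps.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


# ---------------------------------------------------------------------------
# Fisher exact tests


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> Tuple[float, float]:
    """Two-sided Fisher exact p and conditional-MLE odds ratio for a 2x2.

    A zero margin makes every table with those margins identical, so
    p = 1.0 by convention (odds ratio reported as nan).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise StatsError("table must be 2x2 with non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0, float("nan")
    p = float(sps.fisher_exact(t, alternative="two-sided").pvalue)
    orr = float(_odds_ratio(t, kind="conditional").statistic)
    return p, orr


def sample_odds_ratio(table: Sequence[Sequence[int]]) -> float:
    """Plain cross-product odds ratio (ad/bc); inf/0 allowed at boundaries."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def _log_table_prob(
    cells: np.ndarray, lg_margins: float, lgn: float
) -> float:
    return lg_margins - lgn - sum(math.lgamma(c + 1) for c in cells.flat)


def fisher_exact_rxc(
    table: Sequence[Sequence[int]], budget: int = 200
) -> float:
    """Two-sided Fisher exact p for an r x c table by full enumeration.

    Sums the multivariate hypergeometric probabilities of every table
    with the observed margins whose probability does not exceed the
    observed table's (within relative tolerance 1e-7). Tables with total
    count above ``budget`` are refused — there is deliberately no
    asymptotic fallback.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or min(t.shape) < 2 or (t < 0).any():
        raise StatsError("table must be r x c (r, c >= 2) with counts >= 0")
    n = int(t.sum())
    if n == 0:
        return 1.0
    if n > budget:
        raise StatsError(
            f"table too large for exact enumeration (n={n} > budget={budget})"
        )
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        # a zero margin fixes those cells at 0; drop and retry
        t = t[row_sums > 0][:, col_sums > 0]
        if t.ndim != 2 or min(t.shape) < 2:
            return 1.0
        return fisher_exact_rxc(t, budget=budget)

    lg_margins = sum(math.lgamma(r + 1) for r in row_sums) + sum(
        math.lgamma(c + 1) for c in col_sums
    )
    lgn = math.lgamma(n + 1)
    log_p_obs = _log_table_prob(t, lg_margins, lgn)
    threshold = log_p_obs + math.log1p(_FISHER_RELTOL)

    r, c = t.shape
    total = 0.0

    def recurse(row: int, remaining_cols: np.ndarray, lg_cells: float) -> None:
        nonlocal total
        if row == r - 1:
            # last row forced by the column margins
            lg = lg_cells + sum(
                math.lgamma(v + 1) for v in remaining_cols
            )
            log_p = lg_margins - lgn - lg
            if log_p <= threshold:
                total += math.exp(log_p)
            return
        target = int(row_sums[row])

        def fill(col: int, left: int, cols: np.ndarray, lg_row: float) -> None:
            if col == c - 1:
                if left <= cols[col]:
                    new_cols = cols.copy()
                    new_cols[col] -= left
                    recurse(
                        row + 1,
                        new_cols,
                        lg_row + math.lgamma(left + 1),
                    )
                return
            for v in range(min(left, int(cols[col])) + 1):
                new_cols = cols.copy()
                new_cols[col] -= v
                fill(col + 1, left - v, new_cols, lg_row + math.lgamma(v + 1))

        fill(0, target, remaining_cols, lg_cells)

    recurse(0, col_sums.copy(), 0.0)
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# rank tests and ROC


def mann_whitney(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, float]:
    """Mann-Whitney U (for ``x``) and two-sided p.

    Exact permutation null when the pooled sample is small (n <= 12) and
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise StatsError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    if len(pooled) <= 12 and tie_free:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-squared p with k-1 df."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise StatsError("need >= 2 nonempty groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    res = sps.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC area via the Mann-Whitney formulation.

    AUC = (concordant pairs + 0.5 * tied pairs) / (n_pos * n_neg),
    computed from midranks so ties contribute exactly 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise StatsError("scores and labels must have equal length")
    pos = labels == 1
    neg = labels == 0
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise StatsError("both label classes must be present")
    ranks = sps.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# diagnostic concordance


@dataclass
class ProportionEstimate:
    """x/n with an exact CI; ``estimate`` is None when n = 0."""

    numerator: int
    denominator: int
    estimate: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]


def _proportion(x: int, n: int, conf: float) -> ProportionEstimate:
    if n == 0:
        return ProportionEstimate(x, 0, None, None, None)
    lo, hi = clopper_pearson(x, n, conf)
    return ProportionEstimate(x, n, x / n, lo, hi)


@dataclass
class ConcordanceReport:
    """MSI x MMR cross-tabulation with sensitivity/specificity."""

    crosstab: pd.DataFrame  # rows: MMR classes, columns: MSI calls
    sensitivity: ProportionEstimate
    specificity: ProportionEstimate
    n_total: int
    n_conclusive: int


def diagnostic_summary(
    msi_calls: Mapping[str, str],
    mmr_classes: Mapping[str, str],
    conf: float = 0.95,
) -> ConcordanceReport:
    """Cross-tabulate per-sample MSI calls against MMR IHC classes.

    Sensitivity = MSI-H among conclusive MMRd; specificity = MSS among
    conclusive MMRp. Samples with NA or equivocal IHC, or an uncertain
    MSI call, are excluded from those denominators (but kept in the
    cross-tabulation, which conserves every input pair). A "fail" MSI
    call is tabulated under "uncertain" as non-conclusive.
    """
    if set(msi_calls) != set(mmr_classes):
        only_msi = sorted(set(msi_calls) - set(mmr_classes))
        only_mmr = sorted(set(mmr_classes) - set(msi_calls))
        raise StatsError(
            f"unpaired sample ids: MSI-only {only_msi}, IHC-only {only_mmr}"
        )
    counts = pd.DataFrame(0, index=list(MMR_CLASSES), columns=list(MSI_CALLS))
    for sid, call in msi_calls.items():
        mmr = mmr_classes[sid]
        if mmr not in MMR_CLASSES:
            raise StatsError(f"sample {sid!r}: unknown MMR class {mmr!r}")
        col = call if call in MSI_CALLS else "uncertain"
        counts.loc[mmr, col] += 1

    sens_n = int(counts.loc["MMRd", ["MSS", "MSI-H"]].sum())
    sens_x = int(counts.loc["MMRd", "MSI-H"])
    spec_n = int(counts.loc["MMRp", ["MSS", "MSI-H"]].sum())
    spec_x = int(counts.loc["MMRp", "MSS"])
    n_total = int(counts.to_numpy().sum())
    return ConcordanceReport(
        crosstab=counts,
        sensitivity=_proportion(sens_x, sens_n, conf),
        specificity=_proportion(spec_x, spec_n, conf),
        n_total=n_total,
        n_conclusive=sens_n + spec_n,
    )
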