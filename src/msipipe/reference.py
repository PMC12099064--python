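"""Recompute the published reference-cohort statistics from first principles.

Everything here is *derived at run time* from the aggregate tables in
:mod:`msipipe.cohort`: MMR classes come from the IHC logic, frequencies
and CIs from the exact binomial machinery, sensitivity/specificity from
the diagnostic cross-tabulation, and the tumour-type association from the
r x c Fisher exact enumeration. ``REFERENCE_EXPECTED`` holds the values
the original study printed, for comparison only — no computed statistic
is read from it.
"""

from __future__ import annotations

from typing import Dict

import pandas as pd

from .cohort import TUMOUR_TYPES, reference_cohort
from .stats import (
    IhcRecord,
    classify_loss_pattern,
    clopper_pearson,
    derive_mmr_class,
    diagnostic_summary,
    fisher_exact_rxc,
)

#: values printed by the original study (percentages on the 0-100 scale)
REFERENCE_EXPECTED: Dict[str, float] = {
    "sensitivity_pct": 83.0,
    "sensitivity_ci_low_pct": 70.0,
    "sensitivity_ci_high_pct": 93.0,
    "specificity_pct": 100.0,
    "specificity_ci_low_pct": 93.0,
    "specificity_ci_high_pct": 100.0,
    "mmrd_frequency_pct": 47.1,
    "mmrd_ci_low_pct": 37.3,
    "mmrd_ci_high_pct": 57.2,
    "msih_frequency_pct": 39.3,
    "msih_ci_low_pct": 30.0,
    "msih_ci_high_pct": 49.2,
    "mss_frequency_pct": 59.8,
    "mss_ci_low_pct": 49.9,
    "mss_ci_high_pct": 69.2,
    "pattern_msh2_msh6_pct": 55.0,
    "pattern_mlh1_pms2_pct": 31.0,
    "pattern_isolated_msh6_pct": 8.0,
    "tumour_type_fisher_p": 4.74e-3,
}


def reference_statistics() -> Dict[str, float]:
    """All headline statistics of the reference cohort, recomputed."""
    df = reference_cohort()
    records = [
        IhcRecord(r.sample_id, r.mlh1, r.pms2, r.msh2, r.msh6)
        for r in df.itertuples()
    ]
    mmr = {r.sample_id: derive_mmr_class(r) for r in records}
    msi = dict(zip(df["sample_id"], df["msi_call"]))

    out: Dict[str, float] = {}

    # cohort-level frequencies
    n_all = len(df)
    n_interpretable = sum(1 for c in mmr.values() if c != "NA")
    n_mmrd = sum(1 for c in mmr.values() if c == "MMRd")
    lo, hi = clopper_pearson(n_mmrd, n_interpretable)
    out["mmrd_frequency_pct"] = 100 * n_mmrd / n_interpretable
    out["mmrd_ci_low_pct"], out["mmrd_ci_high_pct"] = 100 * lo, 100 * hi
    out["n_interpretable_ihc"] = n_interpretable

    for call, key in (("MSI-H", "msih"), ("MSS", "mss")):
        x = sum(1 for c in msi.values() if c == call)
        lo, hi = clopper_pearson(x, n_all)
        out[f"{key}_frequency_pct"] = 100 * x / n_all
        out[f"{key}_ci_low_pct"], out[f"{key}_ci_high_pct"] = 100 * lo, 100 * hi

    # concordance
    report = diagnostic_summary(msi, mmr)
    out["sensitivity_pct"] = 100 * report.sensitivity.estimate
    out["sensitivity_ci_low_pct"] = 100 * report.sensitivity.ci_low
    out["sensitivity_ci_high_pct"] = 100 * report.sensitivity.ci_high
    out["specificity_pct"] = 100 * report.specificity.estimate
    out["specificity_ci_low_pct"] = 100 * report.specificity.ci_low
    out["specificity_ci_high_pct"] = 100 * report.specificity.ci_high
    out["n_conclusive"] = report.n_conclusive

    # loss patterns among MMRd
    mmrd_records = [r for r in records if mmr[r.sample_id] == "MMRd"]
    patterns = [classify_loss_pattern(r) for r in mmrd_records]
    n_mmrd = len(mmrd_records)
    out["pattern_msh2_msh6_pct"] = 100 * patterns.count("MSH2/MSH6") / n_mmrd
    out["pattern_mlh1_pms2_pct"] = 100 * patterns.count("MLH1/PMS2") / n_mmrd
    out["pattern_isolated_msh6_pct"] = 100 * patterns.count("MSH6 only") / n_mmrd
    out["n_mmrd"] = n_mmrd

    # tumour type x IHC class association (NA excluded, 3 x 3)
    sub = df.assign(mmr_class=[mmr[s] for s in df["sample_id"]])
    sub = sub[sub["mmr_class"] != "NA"]
    table = pd.crosstab(sub["mmr_class"], sub["tumour_type"])
    table = table.reindex(index=["MMRd", "equivocal", "MMRp"],
                          columns=list(TUMOUR_TYPES), fill_value=0)
    out["tumour_type_fisher_p"] = fisher_exact_rxc(table.to_numpy())

    return out
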