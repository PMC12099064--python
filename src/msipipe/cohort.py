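"""Reference screening cohort shipped with the package.

A published clinical validation study screened 107 consecutive sebaceous
tumours with four-protein MMR immunohistochemistry and an amplicon MSI
assay, reporting the results only as aggregate cross-tabulations:
staining pattern x MSI call, and tumour type x IHC class. This module
holds those aggregate counts and expands them into a deterministic
per-sample table so the pipeline's concordance layer can recompute every
published statistic.

The expansion is *synthetic at the sample level*: which tumour type goes
with which staining pattern inside an IHC class is not published, so the
assignment here is an arbitrary (but fixed) margin-preserving one. Every
statistic the package recomputes from this table — frequencies, CIs,
sensitivity/specificity, the tumour-type association test — depends only
on the published margins, which the expansion preserves exactly.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import pandas as pd

from .stats import IhcRecord

#: staining pattern x MSI call counts among the 107 tumours
#: (pattern statuses ordered mlh1, pms2, msh2, msh6; calls MSS/uncertain/MSI-H)
PATTERN_MSI_COUNTS: List[Tuple[Dict[str, str], Tuple[int, int, int]]] = [
    # MMR-deficient patterns
    ({"mlh1": "loss", "pms2": "loss", "msh2": "loss", "msh6": "loss"}, (0, 0, 1)),
    ({"mlh1": "retained", "pms2": "loss", "msh2": "loss", "msh6": "loss"}, (0, 0, 1)),
    ({"mlh1": "retained", "pms2": "retained", "msh2": "loss", "msh6": "loss"}, (1, 0, 26)),
    ({"mlh1": "retained", "pms2": "retained", "msh2": "equivocal", "msh6": "loss"}, (0, 1, 0)),
    ({"mlh1": "retained", "pms2": "retained", "msh2": "retained", "msh6": "loss"}, (2, 0, 1)),
    ({"mlh1": "loss", "pms2": "loss", "msh2": "retained", "msh6": "retained"}, (1, 0, 5)),
    ({"mlh1": "equivocal", "pms2": "loss", "msh2": "retained", "msh6": "retained"}, (4, 0, 5)),
    ({"mlh1": "retained", "pms2": "loss", "msh2": "retained", "msh6": "retained"}, (0, 0, 1)),
    # equivocal IHC
    ({"mlh1": "equivocal", "pms2": "equivocal", "msh2": "retained", "msh6": "retained"}, (1, 0, 0)),
    ({"mlh1": "retained", "pms2": "equivocal", "msh2": "retained", "msh6": "retained"}, (2, 0, 0)),
    # MMR-proficient
    ({"mlh1": "retained", "pms2": "retained", "msh2": "retained", "msh6": "retained"}, (52, 0, 0)),
    # uninterpretable IHC
    ({"mlh1": "uninterpretable", "pms2": "uninterpretable",
      "msh2": "uninterpretable", "msh6": "uninterpretable"}, (1, 0, 2)),
]

#: tumour type x IHC class counts (columns sebaceoma, adenoma, carcinoma)
TYPE_CLASS_COUNTS: Dict[str, Dict[str, int]] = {
    "MMRd": {"sebaceoma": 14, "adenoma": 32, "carcinoma": 3},
    "equivocal": {"sebaceoma": 0, "adenoma": 0, "carcinoma": 3},
    "MMRp": {"sebaceoma": 18, "adenoma": 27, "carcinoma": 7},
    "NA": {"sebaceoma": 1, "adenoma": 2, "carcinoma": 0},
}

TUMOUR_TYPES = ("sebaceoma", "adenoma", "carcinoma")

_MSI_CALLS = ("MSS", "uncertain", "MSI-H")


def reference_cohort() -> pd.DataFrame:
    """Deterministic per-sample expansion of the aggregate tables.

    Returns a DataFrame with one row per tumour and columns
    ``sample_id, tumour_type, mlh1, pms2, msh2, msh6, msi_call``. The
    within-class tumour-type assignment is synthetic (see module
    docstring); both published margins are preserved exactly.
    """
    from .stats import derive_mmr_class

    rows = []
    for pattern, calls in PATTERN_MSI_COUNTS:
        for call, count in zip(_MSI_CALLS, calls):
            rows.extend({**pattern, "msi_call": call} for _ in range(count))
    # group rows by derived MMR class, then deal tumour types out in the
    # fixed order sebaceoma -> adenoma -> carcinoma within each class
    df = pd.DataFrame(rows)
    df["mmr_class"] = [
        derive_mmr_class(
            IhcRecord("tmp", r.mlh1, r.pms2, r.msh2, r.msh6)
        )
        for r in df.itertuples()
    ]
    assigned = []
    for mmr_class, group in df.groupby("mmr_class", sort=False):
        types = []
        for tumour_type in TUMOUR_TYPES:
            types.extend([tumour_type] * TYPE_CLASS_COUNTS[mmr_class][tumour_type])
        if len(types) != len(group):
            raise AssertionError(
                f"margin mismatch for {mmr_class}: {len(types)} vs {len(group)}"
            )
        part = group.copy()
        part["tumour_type"] = types
        assigned.append(part)
    out = pd.concat(assigned).sort_index()
    out.insert(0, "sample_id", [f"ST{i + 1:03d}" for i in range(len(out))])
    return out[
        ["sample_id", "tumour_type", "mlh1", "pms2", "msh2", "msh6", "msi_call"]
    ].reset_index(drop=True)


def cohort_ihc_records(df: pd.DataFrame = None) -> List[IhcRecord]:
    """IHC records for the reference cohort (or any cohort DataFrame)."""
    if df is None:
        df = reference_cohort()
    return [
        IhcRecord(r.sample_id, r.mlh1, r.pms2, r.msh2, r.msh6)
        for r in df.itertuples()
    ]
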