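"""Naive-Bayes microsatellite-instability scoring.

Two features summarise each marker's spectrum relative to a
sample-specific reference length:

* ``del_freq`` — fraction of assigned reads whose repeat length is
  strictly below the reference length. Somatic deletions and PCR stutter
  both contribute, but at very different rates.
* ``allelic_bias`` — among deletion reads, the proportion carrying the
  single most frequent deleted length. Clonal somatic deletions are
  unimodal (bias near 1 at high tumour fraction), stutter is dispersed.

The classifier places independent Beta class-conditional densities on
both features for each marker, one pair per class (MSS, MSI-H), fitted by
the method of moments on a labelled cohort. The sample score is the
natural-log naive-Bayes factor

    score = prior_log_odds
          + sum over markers [ log f(x | MSI-H) - log f(x | MSS) ]

summed over both features; positive scores call MSI-H, negative call
MSS. Scores inside a confirmation band (default +/-5) request a repeat
assay: a same-sign repeat confirms the call, a conflicting repeat yields
an "uncertain" call with the reported score set to 0. Samples whose
median marker depth fails QC are called "fail".

Feature values are shrunk away from {0, 1} by x -> (x*n + 0.5)/(n + 1)
(n = class training size) both at fit and at evaluation time, and Beta
densities are floored at 1e-300 before taking logs, so no log-ratio is
ever infinite. Markers with zero depth are simply omitted from the sum —
naive Bayes marginalises cleanly over missing evidence.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.stats import beta as beta_dist

from .errors import ModelIOError, ScoringError, TrainingError
from .panel import Panel
from .spectra import SampleSpectra

MSS = "MSS"
MSI_H = "MSI-H"
CLASSES = (MSS, MSI_H)

MODEL_SCHEMA = "msipipe-model-1"

#: density floor applied before taking logs
DENSITY_FLOOR = 1e-300
_LOG_FLOOR = math.log(DENSITY_FLOOR)

RESULTS_COLUMNS = ("sample_id", "msi_score", "qc", "call", "needs_repeat")


@dataclass(frozen=True)
class MarkerFeatures:
    """Deletion-frequency / allelic-bias summary of one marker."""

    marker: str
    del_freq: float
    allelic_bias: float

    def __post_init__(self) -> None:
        for label, v in (("del_freq", self.del_freq), ("allelic_bias", self.allelic_bias)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{label} must lie in [0, 1], got {v}")
        if (self.allelic_bias == 0.0) != (self.del_freq == 0.0):
            raise ValueError(
                "allelic_bias must be 0 exactly when there are no deletion reads"
            )


@dataclass(frozen=True)
class BetaParams:
    """Beta(alpha, beta) parameters for one feature in one class."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("Beta parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass
class MsiModel:
    """Per-marker, per-class Beta conditionals plus the class prior.

    ``params[marker][class][feature]`` holds a :class:`BetaParams`;
    ``n_per_class`` records the training-cohort size of each class and is
    reused as the shrinkage constant at scoring time.
    """

    params: Dict[str, Dict[str, Dict[str, BetaParams]]]
    n_per_class: Dict[str, int]
    prior_log_odds: float = 0.0
    schema: str = MODEL_SCHEMA

    @property
    def markers(self) -> List[str]:
        return list(self.params)


@dataclass
class MsiResult:
    """Sample-level MSI call."""

    sample_id: str
    msi_score: float
    qc: bool
    call: str  # one of {"MSI-H", "MSS", "uncertain", "fail"}
    needs_repeat: bool
    repeat_scores: Optional[List[float]] = None


# ---------------------------------------------------------------------------
# features


def _reference_length(counts: Dict[int, int], panel_ref: int) -> int:
    """Sample-specific reference length.

    The modal observed length, if within one unit of the panel reference
    (tolerates germline length polymorphism), otherwise the panel
    reference (so a clonal somatic deletion cannot redefine the baseline).
    Modal ties prefer the length closest to the panel reference, then the
    longer allele.
    """
    modal = max(counts, key=lambda L: (counts[L], -abs(L - panel_ref), L))
    return modal if abs(modal - panel_ref) <= 1 else panel_ref


def compute_features(spectra: SampleSpectra, panel: Panel) -> List[MarkerFeatures]:
    """One :class:`MarkerFeatures` per marker with depth > 0, in panel order."""
    out: List[MarkerFeatures] = []
    for m in panel:
        spec = spectra.spectra.get(m.name)
        if spec is None or spec.depth == 0:
            continue
        ref = _reference_length(spec.counts, m.ref_length)
        depth = spec.depth
        del_counts = {L: c for L, c in spec.counts.items() if L < ref}
        n_del = sum(del_counts.values())
        del_freq = n_del / depth
        bias = max(del_counts.values()) / n_del if n_del else 0.0
        out.append(MarkerFeatures(marker=m.name, del_freq=del_freq, allelic_bias=bias))
    return out


# ---------------------------------------------------------------------------
# training


def _shrink(x: float, n: int) -> float:
    """Pull x in [0,1] into the open interval: (x*n + 0.5) / (n + 1)."""
    return (x * n + 0.5) / (n + 1)


def _moment_fit(values: Sequence[float], n_class: int) -> BetaParams:
    """Method-of-moments Beta fit on shrunk values; Beta(1,1) fallback when
    the moment equations have no valid solution (degenerate variance)."""
    shrunk = np.array([_shrink(v, n_class) for v in values], dtype=float)
    if len(shrunk) < 2:
        return BetaParams(1.0, 1.0)
    m = float(shrunk.mean())
    v = float(shrunk.var())  # population moments
    if v <= 0.0 or v >= m * (1.0 - m):
        return BetaParams(1.0, 1.0)
    common = m * (1.0 - m) / v - 1.0
    alpha, b = m * common, (1.0 - m) * common
    if alpha <= 0 or b <= 0:
        return BetaParams(1.0, 1.0)
    return BetaParams(alpha, b)


def fit_model(
    cohort: Iterable[Tuple[SampleSpectra, str]],
    panel: Panel,
    prior_log_odds: float = 0.0,
    min_per_class: int = 5,
) -> MsiModel:
    """Fit per-marker Beta class-conditionals on a labelled cohort.

    ``cohort`` pairs each sample's spectra with its class label (``"MSS"``
    or ``"MSI-H"``). Requires at least ``min_per_class`` samples in each
    class; a marker observed in no sample at all is a training error.
    """
    cohort = list(cohort)
    by_class: Dict[str, List[SampleSpectra]] = {c: [] for c in CLASSES}
    for sample, label in cohort:
        if label not in by_class:
            raise TrainingError(
                f"unknown class label {label!r}; expected one of {CLASSES}"
            )
        by_class[label].append(sample)
    for c in CLASSES:
        if len(by_class[c]) < min_per_class:
            raise TrainingError(
                f"class {c} has {len(by_class[c])} samples; "
                f"need >= {min_per_class}"
            )

    feats: Dict[str, Dict[str, Dict[str, List[float]]]] = {
        m.name: {c: {"del": [], "bias": []} for c in CLASSES} for m in panel
    }
    for c in CLASSES:
        for sample in by_class[c]:
            for f in compute_features(sample, panel):
                feats[f.marker][c]["del"].append(f.del_freq)
                feats[f.marker][c]["bias"].append(f.allelic_bias)

    params: Dict[str, Dict[str, Dict[str, BetaParams]]] = {}
    for m in panel:
        n_obs = sum(len(feats[m.name][c]["del"]) for c in CLASSES)
        if n_obs == 0:
            raise TrainingError(
                f"marker {m.name!r} has no observations in any training sample"
            )
        params[m.name] = {
            c: {
                "del": _moment_fit(feats[m.name][c]["del"], len(by_class[c])),
                "bias": _moment_fit(feats[m.name][c]["bias"], len(by_class[c])),
            }
            for c in CLASSES
        }

    return MsiModel(
        params=params,
        n_per_class={c: len(by_class[c]) for c in CLASSES},
        prior_log_odds=prior_log_odds,
    )


# ---------------------------------------------------------------------------
# scoring


def _log_density(x: float, p: BetaParams) -> float:
    lp = float(beta_dist.logpdf(x, p.alpha, p.beta))
    if not math.isfinite(lp) or lp < _LOG_FLOOR:
        return _LOG_FLOOR
    return lp


def msi_score(features: Sequence[MarkerFeatures], model: MsiModel) -> float:
    """Natural-log naive-Bayes factor for MSI-H versus MSS."""
    score = model.prior_log_odds
    for f in features:
        if f.marker not in model.params:
            raise ScoringError(f"marker {f.marker!r} absent from model")
        per_class = model.params[f.marker]
        for feature_name, value in (("del", f.del_freq), ("bias", f.allelic_bias)):
            terms = {}
            for c in CLASSES:
                x = _shrink(value, model.n_per_class[c])
                terms[c] = _log_density(x, per_class[c][feature_name])
            score += terms[MSI_H] - terms[MSS]
    return score


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def classify(
    score: float,
    qc: bool,
    band: float = 5.0,
    repeat_score: Optional[float] = None,
    sample_id: str = "sample",
) -> MsiResult:
    """Turn a score into a clinical call.

    QC failure dominates. |score| >= band calls by sign with no repeat.
    Inside the band a repeat assay is requested; a same-sign repeat
    confirms the call, while a conflicting (opposite-sign or zero) repeat
    yields ``uncertain`` with the reported score set to 0. With no repeat
    supplied, a non-zero in-band score is a provisional call by sign with
    ``needs_repeat`` set; a score of exactly 0 is ``uncertain``.
    """
    if not qc:
        return MsiResult(sample_id, score, False, "fail", False)
    if abs(score) >= band and _sign(score) != 0:
        return MsiResult(sample_id, score, True, MSI_H if score > 0 else MSS, False)
    # inside the confirmation band
    if repeat_score is None:
        if _sign(score) == 0:
            return MsiResult(sample_id, 0.0, True, "uncertain", True)
        return MsiResult(
            sample_id, score, True, MSI_H if score > 0 else MSS, True
        )
    repeats = [repeat_score]
    if _sign(repeat_score) == _sign(score) and _sign(score) != 0:
        call = MSI_H if score > 0 else MSS
        return MsiResult(sample_id, score, True, call, True, repeats)
    return MsiResult(sample_id, 0.0, True, "uncertain", True, repeats)


# ---------------------------------------------------------------------------
# model I/O


def save_model(model: MsiModel, path: Union[str, Path]) -> None:
    """Serialise the model as versioned JSON (full float precision)."""
    doc = {
        "schema": model.schema,
        "prior_log_odds": model.prior_log_odds,
        "n_per_class": model.n_per_class,
        "params": {
            marker: {
                c: {
                    feat: {"alpha": p.alpha, "beta": p.beta}
                    for feat, p in per_feat.items()
                }
                for c, per_feat in per_class.items()
            }
            for marker, per_class in model.params.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_model(path: Union[str, Path]) -> MsiModel:
    """Load a model written by :func:`save_model`; schema-checked."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelIOError(f"cannot read model {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("schema") != MODEL_SCHEMA:
        raise ModelIOError(
            f"model {path}: unsupported schema {doc.get('schema')!r}; "
            f"expected {MODEL_SCHEMA!r}"
        )
    try:
        params = {
            marker: {
                c: {
                    feat: BetaParams(float(p["alpha"]), float(p["beta"]))
                    for feat, p in per_feat.items()
                }
                for c, per_feat in per_class.items()
            }
            for marker, per_class in doc["params"].items()
        }
        model = MsiModel(
            params=params,
            n_per_class={c: int(n) for c, n in doc["n_per_class"].items()},
            prior_log_odds=float(doc["prior_log_odds"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelIOError(f"model {path}: malformed content: {exc}") from exc
    return model


def write_results_tsv(results: Iterable[MsiResult], path: Union[str, Path]) -> None:
    """Write per-sample calls as TSV."""
    with open(path, "w") as fh:
        fh.write("\t".join(RESULTS_COLUMNS) + "\n")
        for r in results:
            fh.write(
                f"{r.sample_id}\t{r.msi_score:.6g}\t"
                f"{'pass' if r.qc else 'fail'}\t{r.call}\t"
                f"{str(r.needs_repeat).lower()}\n"
            )
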