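"""End-to-end synthetic benchmark: simulate, train, score, summarise.

Runs the whole pipeline on a seeded synthetic cohort — by default 50 MSS,
30 MSI-H and 10 MSH6-like samples at the generator's study conditions —
with an even train/test split of the MSS and MSI-H samples (MSH6-like
samples are never trained on; they are held out entirely to probe
attenuated instability). Samples whose score lands inside the
confirmation band are re-simulated once, mimicking the clinical repeat
assay, and classified by the repeat rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .classifier import (
    MSI_H,
    MSS,
    MsiModel,
    MsiResult,
    classify,
    compute_features,
    fit_model,
    msi_score,
)
from .panel import Panel, default_panel
from .simulate import MSH6_LIKE, SimulationConfig, simulate_cohort, simulate_spectrum
from .spectra import SampleSpectra, qc_pass
from .stats import mann_whitney, roc_auc


@dataclass
class BenchmarkResult:
    """Summary of one synthetic pipeline run."""

    model: MsiModel
    results: List[MsiResult]
    true_class: Dict[str, str]
    scores: Dict[str, float]
    mss_accuracy: float
    msih_accuracy: float
    auc: float
    median_score: Dict[str, float]
    n_test: Dict[str, int]


def _resimulate(
    sample: SampleSpectra,
    fraction: float,
    config: SimulationConfig,
    panel: Panel,
    rng: np.random.Generator,
) -> SampleSpectra:
    """Fresh replicate of one sample (the repeat assay)."""
    spectra = {}
    for m in panel:
        depth = int(rng.poisson(config.depth_mean))
        spectra[m.name] = simulate_spectrum(
            m, m.ref_length, max(depth, 1), config.stutter_rate,
            fraction, config.somatic_del_units, rng,
        )
    return SampleSpectra(sample_id=sample.sample_id, spectra=spectra)


def run_benchmark(
    seed: int,
    n_mss: int = 50,
    n_msih: int = 30,
    n_msh6like: int = 10,
    band: float = 5.0,
    min_median_depth: int = 100,
    panel: Optional[Panel] = None,
    config_kwargs: Optional[dict] = None,
) -> BenchmarkResult:
    """Simulate, train on half of the MSS/MSI-H samples, score the rest.

    Returns per-class call accuracies (after the repeat rule), the ROC AUC
    of the score for MSI-H vs MSS on the test set, and median scores per
    class including the held-out MSH6-like samples.
    """
    if panel is None:
        panel = default_panel()
    config = SimulationConfig(
        seed=seed,
        n_mss=n_mss,
        n_msih=n_msih,
        n_msh6like=n_msh6like,
        **(config_kwargs or {}),
    )
    samples, truths = simulate_cohort(config, panel)
    true_class = {t.sample_id: t.true_class for t in truths}
    fraction = {
        MSS: 0.0,
        MSI_H: config.somatic_fraction,
        MSH6_LIKE: config.somatic_fraction * config.msh6_fraction_multiplier,
    }

    train, test = [], []
    seen: Dict[str, int] = {}
    for s in samples:
        cls = true_class[s.sample_id]
        idx = seen.get(cls, 0)
        seen[cls] = idx + 1
        if cls in (MSS, MSI_H) and idx % 2 == 0:
            train.append((s, cls))
        else:
            test.append(s)

    model = fit_model(train, panel)

    repeat_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    results: List[MsiResult] = []
    scores: Dict[str, float] = {}
    for s in test:
        feats = compute_features(s, panel)
        score = msi_score(feats, model)
        scores[s.sample_id] = score
        qc = qc_pass(s, min_median_depth)
        repeat = None
        if qc and abs(score) < band:
            replicate = _resimulate(
                s, fraction[true_class[s.sample_id]], config, panel, repeat_rng
            )
            repeat = msi_score(compute_features(replicate, panel), model)
        results.append(
            classify(score, qc, band=band, repeat_score=repeat, sample_id=s.sample_id)
        )

    def _accuracy(cls: str, want: str) -> Tuple[float, int]:
        rel = [r for r in results if true_class[r.sample_id] == cls]
        if not rel:
            return float("nan"), 0
        return sum(r.call == want for r in rel) / len(rel), len(rel)

    mss_acc, n_mss_test = _accuracy(MSS, MSS)
    msih_acc, n_msih_test = _accuracy(MSI_H, MSI_H)

    auc_scores, auc_labels = [], []
    for r in results:
        cls = true_class[r.sample_id]
        if cls in (MSS, MSI_H):
            auc_scores.append(scores[r.sample_id])
            auc_labels.append(1 if cls == MSI_H else 0)
    auc = roc_auc(auc_scores, auc_labels)

    median_score = {}
    for cls in (MSS, MSI_H, MSH6_LIKE):
        vals = [scores[r.sample_id] for r in results if true_class[r.sample_id] == cls]
        if vals:
            median_score[cls] = float(np.median(vals))

    return BenchmarkResult(
        model=model,
        results=results,
        true_class=true_class,
        scores=scores,
        mss_accuracy=mss_acc,
        msih_accuracy=msih_acc,
        auc=auc,
        median_score=median_score,
        n_test={MSS: n_mss_test, MSI_H: n_msih_test,
                MSH6_LIKE: sum(1 for r in results if true_class[r.sample_id] == MSH6_LIKE)},
    )
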