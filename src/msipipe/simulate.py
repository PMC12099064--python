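"""Seeded synthetic cohorts: allele spectra, reads, and truth labels.

The generator emulates the statistical structure an amplicon MSI assay
sees, without modelling base-level sequencing error:

* **PCR stutter** — deletion-biased slippage. A read deletes at least one
  repeat unit with probability ``1 - (1 - stutter_rate)^L`` (L = template
  length in units, so longer tracts stutter more), and the deleted size
  follows a geometric tail (continuation 0.5) truncated at the template
  length. Insertion stutter is not modelled.
* **Somatic deletion alleles** — MSI-H samples carry a clonal deletion of
  ``somatic_del_units`` units at every marker, sampled per read at the
  clonal fraction ``somatic_fraction``. MSS samples have fraction 0.
* **Attenuated instability** — an "MSH6-like" subclass uses the MSI-H
  fraction scaled by ``msh6_fraction_multiplier`` (< 1), mimicking the
  weaker mononucleotide instability of isolated MSH6 deficiency.
* **Depth** — per-marker read depth is Poisson around ``depth_mean``
  (default 2000, the assay's nominal target), which exercises the
  median-depth QC rule; ``marker_dropout_prob`` optionally zeroes whole
  markers.

Every sample gets a :class:`TruthRecord` with an IHC staining pattern
consistent with its class: MSI-H samples draw a loss pattern from the
empirical distribution observed among MMR-deficient tumours in the
reference cohort, MSH6-like samples get isolated MSH6 loss, MSS samples
retain all four proteins. All outputs are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

import numpy as np

from .errors import ConfigError
from .panel import MarkerDefinition, Panel
from .spectra import AlleleSpectrum, SampleSpectra

MSS = "MSS"
MSI_H = "MSI-H"
MSH6_LIKE = "MSH6-like"

PROTEINS = ("mlh1", "pms2", "msh2", "msh6")

TRUTH_COLUMNS = ("sample_id", "true_class") + PROTEINS

#: IHC loss patterns among MMR-deficient tumours in the reference cohort,
#: excluding isolated MSH6 loss (which defines the MSH6-like class), with
#: their observed frequencies (weights sum to 45).
_MSIH_IHC_PATTERNS: List[Tuple[Dict[str, str], int]] = [
    ({"mlh1": "loss", "pms2": "loss", "msh2": "loss", "msh6": "loss"}, 1),
    ({"mlh1": "retained", "pms2": "loss", "msh2": "loss", "msh6": "loss"}, 1),
    ({"mlh1": "retained", "pms2": "retained", "msh2": "loss", "msh6": "loss"}, 27),
    ({"mlh1": "loss", "pms2": "loss", "msh2": "retained", "msh6": "retained"}, 6),
    ({"mlh1": "equivocal", "pms2": "loss", "msh2": "retained", "msh6": "retained"}, 9),
    ({"mlh1": "retained", "pms2": "loss", "msh2": "retained", "msh6": "retained"}, 1),
]

_RETAINED = {p: "retained" for p in PROTEINS}
_MSH6_ONLY = {"mlh1": "retained", "pms2": "retained", "msh2": "retained", "msh6": "loss"}


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters (defaults are the study conditions)."""

    seed: int
    n_mss: int = 0
    n_msih: int = 0
    n_msh6like: int = 0
    depth_mean: int = 2000
    stutter_rate: float = 0.002
    somatic_fraction: float = 0.35
    msh6_fraction_multiplier: float = 0.35
    somatic_del_units: int = 3
    marker_dropout_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.n_mss < 0 or self.n_msih < 0 or self.n_msh6like < 0:
            raise ConfigError("class counts must be non-negative")
        if self.n_mss + self.n_msih + self.n_msh6like == 0:
            raise ConfigError("at least one class count must be positive")
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be positive")
        for name in ("stutter_rate", "somatic_fraction", "marker_dropout_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.msh6_fraction_multiplier <= 1.0:
            raise ConfigError("msh6_fraction_multiplier must lie in (0, 1]")
        if self.somatic_del_units < 0:
            raise ConfigError("somatic_del_units must be non-negative")


@dataclass(frozen=True)
class TruthRecord:
    """Simulated ground truth for one sample."""

    sample_id: str
    true_class: str  # MSS | MSI-H | MSH6-like
    ihc_pattern: Dict[str, str] = field(default_factory=dict)


def simulate_spectrum(
    marker: MarkerDefinition,
    true_length: int,
    depth: int,
    stutter_rate: float,
    somatic_fraction: float,
    somatic_del_units: int,
    rng: np.random.Generator,
) -> AlleleSpectrum:
    """Draw one marker's allele spectrum under the stutter + clonal model.

    Each read picks its template (reference length, or reference minus the
    somatic deletion, at the clonal fraction), then loses a truncated-
    geometric number of repeat units to stutter.
    """
    if depth <= 0:
        raise ConfigError("depth must be positive")
    if not 0.0 <= stutter_rate <= 1.0 or not 0.0 <= somatic_fraction <= 1.0:
        raise ConfigError("stutter_rate and somatic_fraction must lie in [0, 1]")

    somatic = rng.random(depth) < somatic_fraction
    template = np.full(depth, true_length, dtype=np.int64)
    template[somatic] = max(true_length - somatic_del_units, 0)

    # per-read slippage probability grows with template length
    p_del = 1.0 - np.power(1.0 - stutter_rate, template)
    stutters = rng.random(depth) < p_del
    d = np.zeros(depth, dtype=np.int64)
    n_stutter = int(stutters.sum())
    if n_stutter:
        # geometric tail: P(D = k | D >= 1) proportional to 0.5^(k-1)
        d[stutters] = rng.geometric(0.5, n_stutter)
    observed = np.maximum(template - d, 0)

    lengths, counts = np.unique(observed, return_counts=True)
    return AlleleSpectrum(
        marker=marker.name,
        counts={int(L): int(c) for L, c in zip(lengths, counts)},
    )


def _class_plan(config: SimulationConfig) -> List[Tuple[str, str, float]]:
    """(sample_id, class, somatic fraction) for every sample, in fixed order."""
    plan = []
    for i in range(config.n_mss):
        plan.append((f"MSS_{i + 1:03d}", MSS, 0.0))
    for i in range(config.n_msih):
        plan.append((f"MSIH_{i + 1:03d}", MSI_H, config.somatic_fraction))
    for i in range(config.n_msh6like):
        plan.append(
            (
                f"MSH6L_{i + 1:03d}",
                MSH6_LIKE,
                config.somatic_fraction * config.msh6_fraction_multiplier,
            )
        )
    return plan


def _draw_ihc(true_class: str, rng: np.random.Generator) -> Dict[str, str]:
    if true_class == MSS:
        return dict(_RETAINED)
    if true_class == MSH6_LIKE:
        return dict(_MSH6_ONLY)
    weights = np.array([w for _, w in _MSIH_IHC_PATTERNS], dtype=float)
    idx = rng.choice(len(_MSIH_IHC_PATTERNS), p=weights / weights.sum())
    return dict(_MSIH_IHC_PATTERNS[idx][0])


def simulate_cohort(
    config: SimulationConfig,
    panel: Optional[Panel] = None,
) -> Tuple[List[SampleSpectra], List[TruthRecord]]:
    """Simulate a labelled cohort on ``panel`` (default: shipped panel)."""
    if panel is None:
        from .panel import default_panel

        panel = default_panel()
    rng = np.random.default_rng(config.seed)
    samples: List[SampleSpectra] = []
    truths: List[TruthRecord] = []
    for sample_id, true_class, fraction in _class_plan(config):
        spectra: Dict[str, AlleleSpectrum] = {}
        for m in panel:
            depth = int(rng.poisson(config.depth_mean))
            dropped = (
                config.marker_dropout_prob > 0.0
                and rng.random() < config.marker_dropout_prob
            )
            if depth == 0 or dropped:
                spectra[m.name] = AlleleSpectrum(marker=m.name, counts={})
                continue
            spectra[m.name] = simulate_spectrum(
                m,
                m.ref_length,
                depth,
                config.stutter_rate,
                fraction,
                config.somatic_del_units,
                rng,
            )
        samples.append(SampleSpectra(sample_id=sample_id, spectra=spectra))
        truths.append(
            TruthRecord(
                sample_id=sample_id,
                true_class=true_class,
                ihc_pattern=_draw_ihc(true_class, rng),
            )
        )
    return samples, truths


def emit_reads(
    spectra: Union[SampleSpectra, Iterable[SampleSpectra]],
    panel: Panel,
    path: Union[str, Path],
    rng: Optional[np.random.Generator] = None,
) -> int:
    """Write one FASTQ read per spectrum count: flank5 + unit*length + flank3.

    Base qualities are constant ('I'). If ``rng`` is given, the read order
    is shuffled (deterministically for a seeded generator); extraction is
    order-independent either way. Returns the number of reads written.
    """
    if isinstance(spectra, SampleSpectra):
        spectra = [spectra]
    reads: List[Tuple[str, str]] = []
    for sample in spectra:
        for marker_name, spec in sample.spectra.items():
            m = panel[marker_name]
            for length, count in spec.counts.items():
                seq = m.flank5 + m.repeat_unit * length + m.flank3
                for i in range(count):
                    reads.append(
                        (f"{sample.sample_id}:{marker_name}:{length}:{i + 1}", seq)
                    )
    if rng is not None:
        order = rng.permutation(len(reads))
        reads = [reads[i] for i in order]
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    return len(reads)


def write_truth_csv(truths: Iterable[TruthRecord], path: Union[str, Path]) -> None:
    """Truth table CSV: ``sample_id, true_class, mlh1, pms2, msh2, msh6``."""
    with open(path, "w") as fh:
        fh.write(",".join(TRUTH_COLUMNS) + "\n")
        for t in truths:
            statuses = ",".join(t.ihc_pattern.get(p, "retained") for p in PROTEINS)
            fh.write(f"{t.sample_id},{t.true_class},{statuses}\n")


def read_truth_csv(path: Union[str, Path]) -> List[TruthRecord]:
    """Read a truth CSV written by :func:`write_truth_csv`."""
    truths: List[TruthRecord] = []
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if tuple(header) != TRUTH_COLUMNS:
            raise ConfigError(
                f"{path}: header must be {list(TRUTH_COLUMNS)}, got {header}"
            )
        for line in fh:
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != len(TRUTH_COLUMNS):
                raise ConfigError(f"{path}: malformed row {line!r}")
            truths.append(
                TruthRecord(
                    sample_id=fields[0],
                    true_class=fields[1],
                    ihc_pattern=dict(zip(PROTEINS, fields[2:])),
                )
            )
    return truths
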