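"""Flank-anchored extraction of per-marker allele-length spectra from reads.

Each read is assigned to at most one marker: the first marker in panel
order whose 5' and 3' flanks both occur in the read (5' before 3'), on
either the forward sequence or its reverse complement. The repeat length
is the number of complete repeat-unit copies between the two anchors;
partial trailing units are not counted. Anchoring is exact-match and
deterministic — there is no alignment step, so spectra produced by any
upstream (including a real aligner) can be supplied as TSV instead.

Sample-level QC follows the clinical rule: a sample passes when the
median per-marker read depth reaches a threshold (default 100). The
median uses the *lower-median* convention for even marker counts, the
conservative choice for a pass/fail gate.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

from Bio import SeqIO

from .errors import FastqFormatError, SpectraFormatError
from .panel import Panel

SPECTRA_COLUMNS = ("sample_id", "marker", "length", "count")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AlleleSpectrum:
    """Histogram of observed repeat lengths (in units) at one marker."""

    marker: str
    counts: Dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: Dict[int, int] = {}
        for length, count in self.counts.items():
            length, count = int(length), int(count)
            if length < 0:
                raise SpectraFormatError(
                    f"marker {self.marker}: negative repeat length {length}"
                )
            if count < 0:
                raise SpectraFormatError(
                    f"marker {self.marker}: negative count at length {length}"
                )
            if count > 0:
                clean[length] = clean.get(length, 0) + count
        self.counts = dict(sorted(clean.items()))

    @property
    def depth(self) -> int:
        """Total assigned reads at this marker."""
        return sum(self.counts.values())


def _lower_median(values: List[int]) -> int:
    """Lower median: element at index (n-1)//2 of the sorted values."""
    if not values:
        return 0
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


@dataclass
class SampleSpectra:
    """All per-marker spectra for one sample.

    ``n_unassigned`` counts input reads that matched no marker; extraction
    conserves reads: assigned + unassigned == total input records.
    """

    sample_id: str
    spectra: Dict[str, AlleleSpectrum]
    n_unassigned: int = 0

    @property
    def median_depth(self) -> int:
        return _lower_median([s.depth for s in self.spectra.values()])

    @property
    def total_assigned(self) -> int:
        return sum(s.depth for s in self.spectra.values())


def _count_leading_units(segment: str, unit: str) -> int:
    """Number of complete copies of ``unit`` at the start of ``segment``."""
    n, step = 0, len(unit)
    pos = 0
    while segment.startswith(unit, pos):
        n += 1
        pos += step
    return n


def _match_read(seq: str, panel: Panel) -> Optional[Tuple[str, int]]:
    """Return (marker name, repeat length) for the first anchoring marker."""
    rc = _revcomp(seq)
    for m in panel:
        for s in (seq, rc):
            start5 = s.find(m.flank5)
            if start5 < 0:
                continue
            end5 = start5 + len(m.flank5)
            start3 = s.find(m.flank3, end5)
            if start3 < 0:
                continue
            return m.name, _count_leading_units(s[end5:start3], m.repeat_unit)
    return None


def extract_spectra(
    reads: Union[str, Path, io.TextIOBase, Iterable],
    panel: Panel,
    sample_id: str = "sample",
) -> SampleSpectra:
    """Assign FASTQ reads to markers and tally repeat-length spectra.

    ``reads`` may be a FASTQ path, an open text handle, or any iterable of
    Biopython ``SeqRecord`` objects. Empty input yields depth-0 spectra for
    every marker (not an error). A malformed FASTQ raises
    :class:`~msipipe.errors.FastqFormatError` naming the record number.
    """
    counts: Dict[str, Dict[int, int]] = {m.name: {} for m in panel}
    unassigned = 0

    if isinstance(reads, (str, Path)):
        handle = open(reads)
        records = SeqIO.parse(handle, "fastq")
        close = handle.close
    elif isinstance(reads, io.TextIOBase):
        records = SeqIO.parse(reads, "fastq")
        close = None
    else:
        records = iter(reads)
        close = None

    record_no = 0
    try:
        while True:
            try:
                rec = next(records)
            except StopIteration:
                break
            except ValueError as exc:
                raise FastqFormatError(
                    f"unreadable FASTQ at record {record_no + 1}: {exc}"
                ) from exc
            record_no += 1
            hit = _match_read(str(rec.seq).upper(), panel)
            if hit is None:
                unassigned += 1
            else:
                marker, length = hit
                counts[marker][length] = counts[marker].get(length, 0) + 1
    finally:
        if close is not None:
            close()

    spectra = {
        name: AlleleSpectrum(marker=name, counts=c) for name, c in counts.items()
    }
    return SampleSpectra(sample_id=sample_id, spectra=spectra, n_unassigned=unassigned)


def qc_pass(spectra: SampleSpectra, min_median_depth: int = 100) -> bool:
    """True iff the (lower-)median per-marker depth meets the threshold."""
    return spectra.median_depth >= min_median_depth


def write_spectra_tsv(
    samples: Union[SampleSpectra, Iterable[SampleSpectra]],
    path: Union[str, Path],
) -> None:
    """Write one or more samples as TSV rows ``sample_id, marker, length, count``.

    Markers with zero depth are written as a single zero-count row so the
    marker set round-trips even without a panel.
    """
    if isinstance(samples, SampleSpectra):
        samples = [samples]
    with open(path, "w") as fh:
        fh.write("\t".join(SPECTRA_COLUMNS) + "\n")
        for sample in samples:
            for marker, spec in sample.spectra.items():
                if not spec.counts:
                    fh.write(f"{sample.sample_id}\t{marker}\t0\t0\n")
                for length, count in spec.counts.items():
                    fh.write(f"{sample.sample_id}\t{marker}\t{length}\t{count}\n")


def read_spectra_tsv(
    path: Union[str, Path],
    panel: Optional[Panel] = None,
) -> List[SampleSpectra]:
    """Read a spectra TSV; returns one :class:`SampleSpectra` per sample id,
    in file order. If ``panel`` is given, markers absent from the file are
    filled in with depth-0 spectra and unknown markers are rejected.
    """
    path = Path(path)
    per_sample: Dict[str, Dict[str, Dict[int, int]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != SPECTRA_COLUMNS:
            raise SpectraFormatError(
                f"{path}: header must be {list(SPECTRA_COLUMNS)}, got {header}"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise SpectraFormatError(
                    f"{path}:{lineno}: expected 4 fields, got {len(fields)}"
                )
            sample_id, marker, length_s, count_s = fields
            try:
                length, count = int(length_s), int(count_s)
            except ValueError:
                raise SpectraFormatError(
                    f"{path}:{lineno}: length and count must be integers"
                ) from None
            if length < 0 or count < 0:
                raise SpectraFormatError(
                    f"{path}:{lineno}: negative length or count"
                )
            if panel is not None and marker not in panel.names:
                raise SpectraFormatError(
                    f"{path}:{lineno}: marker {marker!r} not in panel"
                )
            marker_counts = per_sample.setdefault(sample_id, {}).setdefault(
                marker, {}
            )
            if count > 0:
                marker_counts[length] = marker_counts.get(length, 0) + count

    samples: List[SampleSpectra] = []
    for sample_id, markers in per_sample.items():
        if panel is not None:
            for name in panel.names:
                markers.setdefault(name, {})
            markers = {name: markers[name] for name in panel.names}
        spectra = {
            name: AlleleSpectrum(marker=name, counts=c)
            for name, c in markers.items()
        }
        samples.append(SampleSpectra(sample_id=sample_id, spectra=spectra))
    return samples
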