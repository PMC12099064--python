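"""Microsatellite marker panel definition, loading and validation.

A marker is a repeat locus described by its repeat unit, the number of
repeat units in the reference allele, and two flanking anchor sequences
used to locate the repeat in a read. Repeat lengths are counted in repeat
*units*, not base pairs, so mono- and dinucleotide markers share one
convention.

The default panel shipped with the package holds 14 synthetic poly-A
markers (reference lengths 18-27 units): the marker sequences of the
clinical assay this panel emulates are not published, and the scoring and
simulation layers only need lengths and flanks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, List, Union

from .errors import PanelError

_DNA_RE = re.compile(r"^[ACGT]+$")

#: number of repeat-unit copies that, if present at a flank's junction end,
#: make anchoring ambiguous
_MAX_JUNCTION_RUN = 3

PANEL_COLUMNS = ("name", "repeat_unit", "ref_length", "flank5", "flank3")


@dataclass(frozen=True)
class MarkerDefinition:
    """One microsatellite marker locus.

    Parameters
    ----------
    name : str
        Unique marker identifier within a panel.
    repeat_unit : str
        Repeat motif, e.g. ``"A"`` for a poly-A homopolymer.
    ref_length : int
        Number of repeat-unit copies in the reference allele (>= 5).
    flank5, flank3 : str
        Anchoring sequences immediately 5' and 3' of the repeat tract
        (>= 8 nt each). Neither junction end may carry a run of three or
        more repeat-unit copies, which would make the repeat boundary
        ambiguous.
    """

    name: str
    repeat_unit: str
    ref_length: int
    flank5: str
    flank3: str

    def __post_init__(self) -> None:
        if not self.name:
            raise PanelError("marker name must be non-empty")
        if len(self.repeat_unit) < 1 or not _DNA_RE.match(self.repeat_unit):
            raise PanelError(
                f"marker {self.name!r}: repeat_unit must be a non-empty ACGT string"
            )
        if self.ref_length < 5:
            raise PanelError(
                f"marker {self.name!r}: ref_length must be >= 5 units, "
                f"got {self.ref_length}"
            )
        for label, flank in (("flank5", self.flank5), ("flank3", self.flank3)):
            if len(flank) < 8 or not _DNA_RE.match(flank):
                raise PanelError(
                    f"marker {self.name!r}: {label} must be an ACGT string of "
                    f">= 8 nt"
                )
        run = self.repeat_unit * _MAX_JUNCTION_RUN
        if self.flank5.endswith(run):
            raise PanelError(
                f"marker {self.name!r}: flank5 ends with {run!r}; the repeat "
                "boundary would be ambiguous"
            )
        if self.flank3.startswith(run):
            raise PanelError(
                f"marker {self.name!r}: flank3 begins with {run!r}; the repeat "
                "boundary would be ambiguous"
            )


@dataclass(frozen=True)
class Panel:
    """An ordered collection of markers with unique names."""

    markers: tuple  # tuple[MarkerDefinition, ...]
    version: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        names = [m.name for m in self.markers]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise PanelError(f"duplicate marker names in panel: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    @property
    def names(self) -> List[str]:
        return [m.name for m in self.markers]

    def __getitem__(self, name: str) -> MarkerDefinition:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)


def load_panel(path: Union[str, Path]) -> Panel:
    """Read a panel TSV (columns ``name, repeat_unit, ref_length, flank5,
    flank3``; ``#`` lines are comments) and return a validated :class:`Panel`.

    Raises :class:`~msipipe.errors.PanelError` naming the offending line on
    malformed rows, duplicate names or flank/repeat ambiguity.
    """
    path = Path(path)
    markers: List[MarkerDefinition] = []
    version = str(path.name)
    with open(path) as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("# version:"):
                version = line.split(":", 1)[1].strip()
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if tuple(fields) != PANEL_COLUMNS:
                    raise PanelError(
                        f"{path}:{lineno}: header must be "
                        f"{list(PANEL_COLUMNS)}, got {fields}"
                    )
                header_seen = True
                continue
            if len(fields) != len(PANEL_COLUMNS):
                raise PanelError(
                    f"{path}:{lineno}: expected {len(PANEL_COLUMNS)} "
                    f"tab-separated fields, got {len(fields)}"
                )
            name, unit, ref_len, f5, f3 = fields
            try:
                ref_length = int(ref_len)
            except ValueError:
                raise PanelError(
                    f"{path}:{lineno}: ref_length {ref_len!r} is not an integer"
                ) from None
            try:
                markers.append(
                    MarkerDefinition(name, unit, ref_length, f5, f3)
                )
            except PanelError as exc:
                raise PanelError(f"{path}:{lineno}: {exc}") from None
        if not header_seen:
            raise PanelError(f"{path}: no header row found")
    return Panel(markers=tuple(markers), version=version)


def write_panel(panel: Panel, path: Union[str, Path]) -> None:
    """Write ``panel`` as a TSV that :func:`load_panel` round-trips exactly."""
    with open(path, "w") as fh:
        fh.write(f"# version: {panel.version}\n")
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for m in panel:
            fh.write(
                f"{m.name}\t{m.repeat_unit}\t{m.ref_length}\t{m.flank5}\t{m.flank3}\n"
            )


def default_panel() -> Panel:
    """The 14-marker synthetic poly-A panel shipped with the package."""
    ref = resources.files("msipipe.data").joinpath("default_panel.tsv")
    with resources.as_file(ref) as path:
        panel = load_panel(path)
    return Panel(markers=panel.markers, version="msipipe-default-1")
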