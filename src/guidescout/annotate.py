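"""BED-interval annotation and the flat tab-delimited result writer.

Annotation is interval overlap in 0-based half-open coordinates: a
candidate receives every track label whose interval shares at least one
base with the candidate's full-site interval; candidates with no overlap
get the sentinel ``NONE``.  Multiple overlapping labels for one track join
with ``;`` in a single column.  BED scores and strands are ignored — only
the name column (or, for 3-column BED, a synthesised ``chrom:start-stop``
label) is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

NO_ANNOTATION = "NONE"


@dataclass
class AnnotationTrack:
    name: str
    #: contig -> sorted list of (start, end, label), 0-based half-open
    intervals: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)
    _trees: dict[str, IntervalTree] | None = None

    def add(self, contig: str, start: int, end: int, label: str) -> None:
        if start >= end:
            raise ValueError(
                f"invalid interval [{start}, {end}) on {contig}"
            )
        self.intervals.setdefault(contig, []).append((start, end, label))
        self._trees = None

    def _tree(self, contig: str) -> IntervalTree | None:
        if self._trees is None:
            self._trees = {
                c: IntervalTree.from_tuples(iv)
                for c, iv in self.intervals.items()
            }
            for c in self.intervals:
                self.intervals[c].sort()
        return self._trees.get(contig)

    def labels(self, contig: str, start: int, stop: int) -> list[str]:
        """Labels of every interval overlapping [start, stop) by >= 1 base,
        in (start, end, label) order."""
        tree = self._tree(contig)
        if tree is None:
            return []
        found = sorted((iv.begin, iv.end, iv.data) for iv in tree.overlap(start, stop))
        return [label for _b, _e, label in found]


def read_bed(path, name: str | None = None,
             known_contigs: set[str] | None = None) -> AnnotationTrack:
    """Load a 3/4/6-column BED file as an annotation track.

    Unknown contigs are warned about but kept; malformed lines are a hard
    error with the line number.
    """
    path = Path(path)
    track = AnnotationTrack(name or path.stem)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 tab-separated BED "
                    f"columns, got {len(cols)}"
                )
            contig = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer BED coordinates"
                ) from None
            if start >= end or start < 0:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            label = cols[3] if len(cols) >= 4 and cols[3] else f"{contig}:{start}-{end}"
            if known_contigs is not None and contig not in known_contigs:
                logger.warning("%s:%d: contig %r not in reference; kept",
                               path, lineno, contig)
            track.add(contig, start, end, label)
    return track


def annotate(candidates, track: AnnotationTrack) -> list[str]:
    """One ``;``-joined label string per candidate (``NONE`` if none).

    ``candidates`` supply ``contig``/``start``/``stop`` attributes (e.g.
    TargetSite) or (contig, start, stop) tuples.
    """
    out = []
    for cand in candidates:
        if hasattr(cand, "contig"):
            contig, start, stop = cand.contig, cand.start, cand.stop
        else:
            contig, start, stop = cand
        labels = track.labels(contig, start, stop)
        out.append(";".join(labels) if labels else NO_ANNOTATION)
    return out


def write_table(df, path) -> None:
    """Write the flat results table: one header row, tab-separated, no
    index, newline-terminated; round-trips through read_table."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA", lineterminator="\n")


def read_table(path):
    """Read a results table with every column as text, so values (and the
    ``NA`` sentinel) survive a write->read->write cycle byte-identically."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
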