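"""Exhaustive both-strand CRISPR target discovery from FASTA.

Scanning is vectorised: each contig becomes a byte array, each PAM pattern
becomes a set of per-offset IUPAC membership lookups, and candidate starts
on both strands fall out of a few boolean reductions.  Sites containing
ambiguous (non-ACGT) bases cannot be two-bit encoded and are skipped with
a tally.  Coordinates are 0-based half-open on the forward strand
throughout; protospacer and PAM strings are reported in guide orientation.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO

from .enzymes import IUPAC, EnzymeSpec, reverse_complement

logger = logging.getLogger(__name__)

#: flanking bases captured on each side of the full site for on-target models
CONTEXT_FLANK = 10

_COMPLEMENT_SYM = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class TargetSite:
    """One discovered protospacer+PAM site.

    ``start``/``stop`` bound the full site (protospacer and PAM) on the
    forward strand, 0-based half-open.  ``protospacer``/``pam`` are in guide
    orientation (reverse-complemented for '-' sites).  ``context`` is the
    guide-oriented site plus 10 flanking bases on each side, or None when
    the site sits too close to a contig edge for the full window.
    """

    contig: str
    start: int
    stop: int
    strand: str
    protospacer: str
    pam: str
    context: str | None = None

    def site(self, enzyme: EnzymeSpec) -> str:
        """Full site string in guide orientation."""
        return enzyme.site_string(self.protospacer, self.pam)


@dataclass
class DiscoveryStats:
    sites_emitted: int = 0
    skipped_non_acgt: int = 0
    skipped_soft_masked: int = 0
    contigs: int = 0


def iter_fasta(source) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from a FASTA path (optionally gzipped), an
    open handle, or an iterable of (name, sequence) pairs."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as handle:
            first = handle.read(1)
            if first == "":
                logger.warning("empty FASTA %s", path)
                return
            if first != ">":
                raise ValueError(f"malformed FASTA {path}: does not start with '>'")
            handle.seek(0)
            seen = set()
            for rec in SeqIO.parse(handle, "fasta"):
                if rec.id in seen:
                    raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
                seen.add(rec.id)
                yield rec.id, str(rec.seq)
    elif isinstance(source, dict):
        yield from source.items()
    else:
        yield from source


def _membership_lut(symbols: str) -> np.ndarray:
    """256-entry boolean lookup: which byte values satisfy an IUPAC class."""
    lut = np.zeros(256, dtype=bool)
    for b in symbols:
        lut[ord(b)] = True
    return lut


def _pattern_constraints(enzyme: EnzymeSpec, pattern: str, strand: str) -> list[tuple[int, np.ndarray]]:
    """Per-site-offset IUPAC constraints a forward-strand slice must satisfy
    for ``pattern`` to match on ``strand``."""
    m = enzyme.site_len
    pam_len = enzyme.pam_len
    constraints = []
    for j, sym in enumerate(pattern):
        if enzyme.pam_side == "three_prime":
            guide_pos = enzyme.protospacer_len + j
        else:
            guide_pos = j
        if strand == "+":
            rel, allowed = guide_pos, IUPAC[sym]
        else:
            rel = m - 1 - guide_pos
            allowed = IUPAC[sym.translate(_COMPLEMENT_SYM)]
        if allowed != "ACGT":  # an N constrains nothing
            constraints.append((rel, _membership_lut(allowed)))
    return constraints


def _candidate_starts(arr: np.ndarray, constraints, m: int) -> np.ndarray:
    n = arr.size
    if n < m:
        return np.empty(0, dtype=np.int64)
    valid = np.ones(n - m + 1, dtype=bool)
    for rel, lut in constraints:
        valid &= lut[arr[rel: rel + n - m + 1]]
    return np.nonzero(valid)[0]


def discover_targets(
    fasta,
    enzyme: EnzymeSpec,
    stats: DiscoveryStats | None = None,
    skip_soft_masked: bool = False,
) -> Iterator[TargetSite]:
    """Stream every PAM-matching site on both strands of ``fasta``.

    Sites are emitted in ascending (contig order, start, strand) order;
    overlapping sites are all emitted.  A position/strand matching several
    PAM patterns is emitted once with the first matching pattern's bases.
    Lower-case (soft-masked) bases are uppercased and used unless
    ``skip_soft_masked`` is set, in which case sites touching them are
    dropped and tallied.
    """
    if stats is None:
        stats = DiscoveryStats()
    m = enzyme.site_len
    acgt_lut = _membership_lut("ACGT")
    for contig, raw_seq in iter_fasta(fasta):
        stats.contigs += 1
        soft = None
        if skip_soft_masked:
            soft = np.frombuffer(raw_seq.encode("ascii"), dtype=np.uint8)
            soft = (soft >= ord("a"))  # lowercase a-z
        seq = raw_seq.upper()
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        site_ok = None
        if arr.size >= m:
            ok = acgt_lut[arr]
            # site_ok[s] = all bases in [s, s+m) are unambiguous
            csum = np.concatenate(([0], np.cumsum(ok)))
            site_ok = (csum[m:] - csum[:-m]) == m
            if soft is not None:
                scs = np.concatenate(([0], np.cumsum(soft)))
                site_ok &= (scs[m:] - scs[:-m]) == 0

        found: list[tuple[int, str, int]] = []  # (start, strand, pattern idx)
        seen: set[tuple[int, str]] = set()
        for pi, pattern in enumerate(enzyme.pams):
            for strand in "+-":
                cons = _pattern_constraints(enzyme, pattern, strand)
                for s in _candidate_starts(arr, cons, m):
                    key = (int(s), strand)
                    if key in seen:
                        continue
                    seen.add(key)
                    found.append((int(s), strand, pi))
        # first matching pattern wins for duplicated (pos, strand); the
        # pattern-major loop above plus `seen` guarantees that already.
        found.sort(key=lambda t: (t[0], t[1]))

        for s, strand, _pi in found:
            if not site_ok[s]:
                if soft is not None and soft[s: s + m].any():
                    stats.skipped_soft_masked += 1
                else:
                    stats.skipped_non_acgt += 1
                continue
            fwd = seq[s: s + m]
            oriented = fwd if strand == "+" else reverse_complement(fwd)
            protospacer, pam = enzyme.split_site(oriented)
            context = None
            if s - CONTEXT_FLANK >= 0 and s + m + CONTEXT_FLANK <= len(seq):
                window = seq[s - CONTEXT_FLANK: s + m + CONTEXT_FLANK]
                if all(c in "ACGT" for c in window):
                    context = window if strand == "+" else reverse_complement(window)
            stats.sites_emitted += 1
            yield TargetSite(
                contig=contig, start=s, stop=s + m, strand=strand,
                protospacer=protospacer, pam=pam, context=context,
            )
    logger.info(
        "discovery: %d sites from %d contig(s); %d skipped (non-ACGT), "
        "%d skipped (soft-masked)",
        stats.sites_emitted, stats.contigs,
        stats.skipped_non_acgt, stats.skipped_soft_masked,
    )


def random_targets(
    n: int,
    enzyme: EnzymeSpec,
    seed: int,
    only_unidirectional: bool = False,
) -> list[TargetSite]:
    """Generate ``n`` uniform-random protospacer+PAM sequences.

    PAM bases are drawn uniformly from each pattern position's IUPAC class
    (patterns chosen uniformly for multi-PAM enzymes).  With
    ``only_unidirectional``, any draw whose site string also presents a
    valid PAM on the opposite strand is rejected and redrawn, so each
    emitted sequence contains exactly one candidate target.  Deterministic
    under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    out: list[TargetSite] = []
    i = 0
    while len(out) < n:
        protospacer = "".join(rng.choice(bases, size=enzyme.protospacer_len))
        pattern = enzyme.pams[int(rng.integers(len(enzyme.pams)))]
        pam = "".join(
            IUPAC[sym][int(rng.integers(len(IUPAC[sym])))] for sym in pattern
        )
        site = enzyme.site_string(protospacer, pam)
        if only_unidirectional:
            hits = list(discover_targets({"q": site}, enzyme))
            if len(hits) != 1:
                continue
        out.append(TargetSite(
            contig=f"random{i}", start=0, stop=enzyme.site_len, strand="+",
            protospacer=protospacer, pam=pam, context=None,
        ))
        i += 1
    return out
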