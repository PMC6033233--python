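"""Mismatch-bounded off-target search against the binned database.

The key filtering idea: a bin groups every target sharing its first ``p``
protospacer bases, and the Hamming distance between a guide's prefix and a
bin's prefix lower-bounds the distance to every target inside.  So a guide
only needs to visit bins whose prefix is within ``k`` mismatches — the
*plan*.  The union of planned bins over all guides is traversed once, in
ascending prefix order, and each bin is decompressed exactly once no
matter how many guides visit it.  When nearly every non-empty bin would be
visited anyway (> 95%), the whole database is scanned linearly instead to
avoid per-bin seek overhead; both modes return identical results.

Mismatch counting covers protospacer positions only — every database entry
already carried a valid PAM at build time.  A guide whose accumulated
off-target occurrence tally exceeds ``limit`` (default 2000) is flagged
*overflow* and dropped from further comparison; downstream scoring treats
such guides as unscorable for off-target metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import bitcodec
from .bitcodec import COUNT_MAX
from .database import TargetDatabase, DatabaseHeader
from .discovery import TargetSite, discover_targets
from .enzymes import EnzymeSpec

DEFAULT_MAX_MISMATCH = 4
DEFAULT_OFFTARGET_LIMIT = 2000
#: fraction of non-empty bins above which a full linear scan is cheaper
FULL_SCAN_FRACTION = 0.95

MODE_SELECTIVE = "selective"
MODE_LINEAR = "linear"


@dataclass
class OffTargetHit:
    """One genomic target within ``k`` mismatches of a guide."""

    sequence: str                       # full site, guide orientation
    mismatches: int                     # protospacer positions only
    occurrences: int                    # count field (saturates at 65535)
    positions: list[tuple[str, int, str]]  # (contig, start, strand)


@dataclass
class SearchResult:
    guide: TargetSite
    hits: list[OffTargetHit] = field(default_factory=list)
    overflow: bool = False

    @property
    def total_offtarget_occurrences(self) -> int:
        return sum(h.occurrences for h in self.hits)


def sites_from_strings(seqs: list[str], enzyme: EnzymeSpec) -> list[TargetSite]:
    """Wrap bare site strings (guide orientation, protospacer+PAM) as
    query TargetSites with no genomic coordinates."""
    out = []
    for i, s in enumerate(seqs):
        if len(s) != enzyme.site_len:
            raise ValueError(
                f"site {s!r} is not {enzyme.site_len} bases for {enzyme.name}"
            )
        proto, pam = enzyme.split_site(s)
        out.append(TargetSite(
            contig=f"query{i}", start=0, stop=enzyme.site_len, strand="+",
            protospacer=proto, pam=pam,
        ))
    return out


def _prefix_hamming(guide_codes: np.ndarray, bin_codes: np.ndarray,
                    prefix_len: int) -> np.ndarray:
    """(n_guides, n_bins) Hamming distances between packed prefixes."""
    x = guide_codes[:, None] ^ bin_codes[None, :]
    folded = (x | (x >> np.uint64(1))) & np.uint64(0x5555555555555555)
    return np.bitwise_count(folded).astype(np.uint8)


def _encode_guides(guides: list[TargetSite], header: DatabaseHeader):
    enz = header.enzyme
    pcodes = np.empty(len(guides), dtype=np.uint64)
    words = np.empty(len(guides), dtype=np.uint64)
    for i, g in enumerate(guides):
        prefix, word = bitcodec.split_prefix(
            g.site(enz), header.prefix_len, enz.pam_len, enz.pam_side
        )
        pcodes[i] = bitcodec.encode_bases(prefix)
        words[i] = word
    return pcodes, words


def plan_bins(guides: list[TargetSite], k: int, header: DatabaseHeader):
    """Planned prefixes per guide over the full 4^p space.

    Returns (per-guide list of sets of prefix codes, global visit set).  A
    prefix is planned iff its Hamming distance to the guide's first ``p``
    protospacer bases is <= k; since that distance lower-bounds the total
    mismatch count, no hit can hide in an unplanned bin.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    p = header.prefix_len
    all_codes = np.arange(4 ** p, dtype=np.uint64)
    gcodes, _ = _encode_guides(guides, header)
    hd = _prefix_hamming(gcodes, all_codes, p)
    per_guide = [set(map(int, all_codes[hd[i] <= k])) for i in range(len(guides))]
    global_set = set().union(*per_guide) if per_guide else set()
    return per_guide, global_set


def full_scan_fallback_decision(global_bins, header: DatabaseHeader) -> str:
    """LINEAR when the plan would visit > 95% of non-empty bins."""
    nonempty = set(header.bins)
    if not nonempty:
        return MODE_SELECTIVE
    visited = len(nonempty & set(global_bins))
    return MODE_LINEAR if visited > FULL_SCAN_FRACTION * len(nonempty) else MODE_SELECTIVE


def _decode_positions(header: DatabaseHeader, pos_words: np.ndarray):
    out = []
    for pw in pos_words:
        ci, off, strand = bitcodec.decode_position(int(pw))
        out.append((header.contigs[ci][0], off, strand))
    return out


def search(
    db: TargetDatabase,
    guides: list[TargetSite],
    k: int = DEFAULT_MAX_MISMATCH,
    limit: int = DEFAULT_OFFTARGET_LIMIT,
    mode: str = "auto",
    enzyme: EnzymeSpec | None = None,
    stats: dict | None = None,
) -> list[SearchResult]:
    """All database targets within ``k`` protospacer mismatches per guide.

    ``enzyme`` (when given, e.g. from the query side) must match the
    database's enzyme.  ``mode`` forces ``linear``/``selective`` traversal;
    ``auto`` applies the 95% fallback rule.  Traversal is ascending bin
    prefix then ascending entry, which makes the overflow flag
    deterministic.
    """
    header = db.header
    if enzyme is not None and enzyme.to_dict() != header.enzyme.to_dict():
        raise ValueError(
            f"guide enzyme {enzyme.name!r} does not match database enzyme "
            f"{header.enzyme.name!r}"
        )
    results = [SearchResult(g) for g in guides]
    if not guides:
        if stats is not None:
            stats.update(mode=MODE_SELECTIVE, bins_visited=0)
        return results

    p = header.prefix_len
    gcodes, gwords = _encode_guides(guides, header)
    nonempty = np.array(db.nonempty_prefixes, dtype=np.uint64)
    hd = _prefix_hamming(gcodes, nonempty, p)  # (n_guides, n_nonempty)

    if mode == "auto":
        # the 95% rule over non-empty bins (planned-and-present fraction)
        visited = int((hd <= k).any(axis=0).sum())
        chosen = (MODE_LINEAR
                  if nonempty.size and visited > FULL_SCAN_FRACTION * nonempty.size
                  else MODE_SELECTIVE)
    elif mode in (MODE_LINEAR, MODE_SELECTIVE):
        chosen = mode
    else:
        raise ValueError(f"unknown traversal mode {mode!r}")

    if chosen == MODE_SELECTIVE:
        bin_idx = np.nonzero((hd <= k).any(axis=0))[0]
    else:
        bin_idx = np.arange(nonempty.size)

    mask = np.uint64(header.comparison_mask)
    low = np.uint64(0x5555555555555555)
    active = np.ones(len(guides), dtype=bool)
    occ_total = np.zeros(len(guides), dtype=np.int64)
    suffix_len = header.suffix_len
    enz = header.enzyme
    bins_visited = 0

    for bi in bin_idx:
        col = hd[:, bi]
        gsel = np.nonzero(active & (col <= k))[0]
        if gsel.size == 0:
            continue
        tbin = db.read_bin(int(nonempty[bi]))
        bins_visited += 1
        if tbin.n_entries == 0:
            continue
        x = (gwords[gsel, None] ^ tbin.words[None, :]) & mask
        folded = (x | (x >> np.uint64(1))) & low
        total_mm = np.bitwise_count(folded).astype(np.int64) + col[gsel, None]
        prefix_str = tbin.prefix
        for row, gi in enumerate(gsel):
            hit_entries = np.nonzero(total_mm[row] <= k)[0]
            if hit_entries.size == 0:
                continue
            res = results[gi]
            for ei in hit_entries:
                word = int(tbin.words[ei])
                occ = word & COUNT_MAX
                occ_total[gi] += occ
                res.hits.append(OffTargetHit(
                    sequence=bitcodec.join_prefix(
                        prefix_str, word, suffix_len, enz.pam_len, enz.pam_side),
                    mismatches=int(total_mm[row, ei]),
                    occurrences=occ,
                    positions=_decode_positions(header, tbin.entry_positions(int(ei))),
                ))
                if occ_total[gi] > limit:
                    res.overflow = True
                    active[gi] = False
                    break

    if stats is not None:
        stats.update(mode=chosen, bins_visited=bins_visited,
                     overflowed=int(sum(r.overflow for r in results)))
    return results


def brute_force_search(
    fasta,
    guides: list[TargetSite],
    k: int,
    enzyme: EnzymeSpec,
    limit: int = DEFAULT_OFFTARGET_LIMIT,
) -> list[SearchResult]:
    """Naive ground-truth search: every discovered site against every guide.

    Independent of the binary database and the 2-bit codec — sites are
    compared as character arrays — so it serves as the oracle the indexed
    search is verified against.  Hit ordering and overflow semantics match
    ``search`` (ascending protospacer-then-PAM order).
    """
    # collapse discovered sites to distinct sequences with their positions
    by_seq: dict[tuple[str, str], list[tuple[str, int, str]]] = {}
    for site in discover_targets(fasta, enzyme):
        by_seq.setdefault((site.protospacer, site.pam), []).append(
            (site.contig, site.start, site.strand)
        )
    keys = sorted(by_seq)  # (protospacer, pam) lexicographic == DB order
    protos = np.frombuffer(
        "".join(kp for kp, _ in keys).encode("ascii"), dtype=np.uint8
    ).reshape(len(keys), enzyme.protospacer_len) if keys else np.empty((0, 0), np.uint8)

    results = [SearchResult(g) for g in guides]
    for gi, g in enumerate(guides):
        if len(keys) == 0:
            continue
        garr = np.frombuffer(g.protospacer.encode("ascii"), dtype=np.uint8)
        mm = (protos != garr[None, :]).sum(axis=1)
        res = results[gi]
        total = 0
        for si in np.nonzero(mm <= k)[0]:
            proto, pam = keys[si]
            positions = by_seq[(proto, pam)]
            occ = min(len(positions), COUNT_MAX)
            total += occ
            res.hits.append(OffTargetHit(
                sequence=enzyme.site_string(proto, pam),
                mismatches=int(mm[si]),
                occurrences=occ,
                positions=positions,
            ))
            if total > limit:
                res.overflow = True
                break
    return results
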