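"""Off-target specificity scores and design-rule flags.

Two specificity metrics operate on a guide's enumerated off-target hits:

* **Hsu 2013 aggregate** (0-100, higher = more specific).  Each off-target
  contributes a single-hit score: the product of per-position penalties
  ``(1 - M[p])`` over its mismatched protospacer positions, damped by the
  mean pairwise distance between mismatches and by the squared mismatch
  count, scaled to 0-100.  The guide's aggregate is
  ``100 * 100 / (100 + sum of single-hit scores)``, each genomic occurrence
  contributing once; a guide with no off-targets scores 100.

* **CFD** (cutting frequency determination, 0-1 per hit, lower max = more
  specific).  The product over mismatched positions of empirically derived
  penalties keyed by (position, guide RNA base, target-strand DNA base),
  times a penalty on the last two PAM bases.  An identical protospacer
  with a canonical NGG PAM scores 1.0.  ``cfd_max`` reports the worst
  (largest) hit.

Both metrics are defined for 20-base Cas9-style guides with a 3-base
3' PAM; other enzymes receive a no-score marker (None).  One occurrence
matching the candidate's own genomic site is excluded from both by
default, otherwise every guide drawn from the reference would be capped
at 50 by its self-hit.

Design-rule flags (GC fraction outside [0.25, 0.75], a TTTT tract that can
terminate pol III transcription) and the reciprocal-off-target flag (a hit
elsewhere inside the queried region, risking deletion of the intervening
sequence) are computed here as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources as importlib_resources
from itertools import combinations

import numpy as np
import pandas as pd

from .enzymes import EnzymeSpec
from .search import OffTargetHit, SearchResult

logger = logging.getLogger(__name__)

GC_HIGH_FRACTION = 0.75
GC_LOW_FRACTION = 0.25
POLY_T_TRACT = "TTTT"

_RNA = {"A": "A", "C": "C", "G": "G", "T": "U"}
_DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _read_resource(filename: str) -> pd.DataFrame:
    path = importlib_resources.files("guidescout.resources").joinpath(filename)
    with importlib_resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#")


# ---------------------------------------------------------------- Hsu 2013

def load_hsu_weights(path=None) -> np.ndarray:
    """Per-position mismatch penalty weights M[1..20], PAM-distal first."""
    df = _read_resource("hsu2013_weights.tsv") if path is None \
        else pd.read_csv(path, sep="\t", comment="#")
    df = df.sort_values("position")
    if list(df["position"]) != list(range(1, 21)):
        raise ValueError("Hsu weight table must cover positions 1..20")
    w = df["weight"].to_numpy(float)
    if ((w < 0) | (w > 1)).any():
        raise ValueError("Hsu weights must lie in [0, 1]")
    return w


def _mismatch_positions(guide_proto: str, off_proto: str) -> list[int]:
    """1-based mismatched positions, PAM-distal = 1."""
    return [i + 1 for i, (a, b) in enumerate(zip(guide_proto, off_proto)) if a != b]


def hsu_single(guide_proto: str, off_proto: str, weights: np.ndarray) -> float | None:
    """Single-hit Hsu score in (0, 100]; None for non-20-mer input."""
    if len(guide_proto) != 20 or len(off_proto) != 20:
        return None
    pos = _mismatch_positions(guide_proto, off_proto)
    m = len(pos)
    if m == 0:
        return 100.0
    prod = 1.0
    for p in pos:
        prod *= 1.0 - weights[p - 1]
    if m == 1:
        return 100.0 * prod
    pairs = list(combinations(pos, 2))
    mean_dist = sum(abs(a - b) for a, b in pairs) / len(pairs)
    dist_term = 1.0 / (((19.0 - mean_dist) / 19.0) * 4.0 + 1.0)
    return 100.0 * prod * dist_term / (m * m)


def hsu_aggregate(
    guide_proto: str,
    hits: list[OffTargetHit],
    weights: np.ndarray,
    enzyme: EnzymeSpec,
) -> float | None:
    """Aggregate specificity 100*100/(100 + sum over occurrences); 100 with
    no off-targets.  Hits are assumed already purged of the self-hit."""
    if len(guide_proto) != 20 or enzyme.pam_side != "three_prime":
        return None
    total = 0.0
    for h in hits:
        proto, _pam = enzyme.split_site(h.sequence)
        s = hsu_single(guide_proto, proto, weights)
        if s is None:
            return None
        total += h.occurrences * s
    return 100.0 * 100.0 / (100.0 + total)


# -------------------------------------------------------------------- CFD

@dataclass
class CfdTable:
    """Per-position mismatch penalties and PAM-tail penalties.

    ``penalty[(position, guide RNA base, DNA base)]`` where the DNA base is
    on the strand the guide hybridises to, so a Watson-Crick pair (rA:dT,
    rC:dG, rG:dC, rU:dA) is a match and implicitly scores 1.
    """

    penalty: dict[tuple[int, str, str], float]
    pam_penalty: dict[str, float]

    def validate(self, protospacer_len: int = 20) -> None:
        for (pos, r, d), v in self.penalty.items():
            if not 1 <= pos <= protospacer_len:
                raise ValueError(f"CFD position {pos} out of range")
            if r not in "ACGU" or d not in "ACGT":
                raise ValueError(f"bad CFD key ({pos}, {r!r}, {d!r})")
            if _RNA.get(_DNA_COMPLEMENT.get(d, "?"), None) == r:
                if v != 1.0:
                    raise ValueError(
                        f"CFD entry ({pos},{r},{d}) is a Watson-Crick match "
                        f"and must score 1"
                    )
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"CFD penalty {v} outside [0, 1]")
        for tail, v in self.pam_penalty.items():
            if len(tail) != 2 or not set(tail) <= set("ACGT"):
                raise ValueError(f"bad PAM tail {tail!r}")
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"PAM penalty {v} outside [0, 1]")


def load_cfd_table(mismatch_path=None, pam_path=None) -> CfdTable:
    mm = _read_resource("cfd_mismatch_penalties_synthetic.tsv") \
        if mismatch_path is None else pd.read_csv(mismatch_path, sep="\t", comment="#")
    pam = _read_resource("cfd_pam_penalties.tsv") \
        if pam_path is None else pd.read_csv(pam_path, sep="\t", comment="#")
    table = CfdTable(
        penalty={
            (int(r.position), str(r.guide_rna), str(r.dna)): float(r.penalty)
            for r in mm.itertuples()
        },
        pam_penalty={str(r.pam_tail): float(r.penalty) for r in pam.itertuples()},
    )
    table.validate()
    return table


def cfd_score(
    guide_proto: str, off_proto: str, off_pam: str, table: CfdTable
) -> float | None:
    """CFD for one hit: product of mismatch penalties x PAM-tail penalty."""
    if len(guide_proto) != 20 or len(off_proto) != 20 or len(off_pam) != 3:
        return None
    score = 1.0
    for i, (g, o) in enumerate(zip(guide_proto, off_proto)):
        if g == o:
            continue
        key = (i + 1, _RNA[g], _DNA_COMPLEMENT[o])
        p = table.penalty.get(key)
        if p is None:
            raise KeyError(f"CFD table lacks entry for {key}")
        score *= p
    tail = off_pam[1:]
    p = table.pam_penalty.get(tail)
    if p is None:
        logger.warning("PAM tail %r absent from CFD table; penalty 0", tail)
        p = 0.0
    return score * p


def cfd_max(
    guide_proto: str,
    hits: list[OffTargetHit],
    table: CfdTable,
    enzyme: EnzymeSpec,
) -> float | None:
    """Worst-case (maximum) CFD over non-self hits; 0.0 with no hits."""
    if len(guide_proto) != 20 or enzyme.pam_side != "three_prime" \
            or enzyme.pam_len != 3:
        return None
    best = 0.0
    for h in hits:
        proto, pam = enzyme.split_site(h.sequence)
        s = cfd_score(guide_proto, proto, pam, table)
        if s is None:
            return None
        best = max(best, s)
    return best


# ---------------------------------------------------------- flags & misc

def flag_basic(protospacer: str) -> dict[str, bool]:
    """GC-content and poly-thymine design flags from the guide string alone."""
    gc = sum(c in "GC" for c in protospacer) / len(protospacer)
    return {
        "gc_high": gc > GC_HIGH_FRACTION,
        "gc_low": gc < GC_LOW_FRACTION,
        "polyT": POLY_T_TRACT in protospacer,
    }


def remove_self_hit(result: SearchResult, enzyme: EnzymeSpec,
                    by_coordinates: bool = True) -> list[OffTargetHit]:
    """Hits with one occurrence of the candidate's own site removed.

    When the candidate carries genomic coordinates, the occurrence matching
    (contig, start, strand) exactly is removed; otherwise one occurrence of
    the zero-mismatch, identical-sequence hit is removed.  Hits never go
    negative: a self-only hit disappears entirely.
    """
    g = result.guide
    own_site = g.site(enzyme)
    out: list[OffTargetHit] = []
    removed = False
    for h in result.hits:
        if not removed:
            if by_coordinates and h.positions:
                if (g.contig, g.start, g.strand) in h.positions:
                    removed = True
                    positions = [p for p in h.positions
                                 if p != (g.contig, g.start, g.strand)]
                    if h.occurrences - 1 > 0:
                        out.append(OffTargetHit(
                            h.sequence, h.mismatches, h.occurrences - 1,
                            positions))
                    continue
            elif h.mismatches == 0 and h.sequence == own_site:
                removed = True
                if h.occurrences - 1 > 0:
                    out.append(OffTargetHit(
                        h.sequence, h.mismatches, h.occurrences - 1,
                        h.positions[1:] if h.positions else []))
                continue
        out.append(h)
    return out


def reciprocal_offtargets(
    results: list[SearchResult],
    regions: dict[str, list[tuple[int, int]]],
    enzyme: EnzymeSpec,
) -> list[bool]:
    """Per-candidate flag: some hit position other than the candidate's own
    site overlaps the queried region set (0-based half-open intervals)."""
    try:
        from intervaltree import IntervalTree
        trees = {c: IntervalTree.from_tuples([(s, e) for s, e in iv if s < e])
                 for c, iv in regions.items()}
        def overlaps(contig, start, stop):
            t = trees.get(contig)
            return bool(t and t.overlap(start, stop))
    except ImportError:  # pragma: no cover - intervaltree is a hard dep
        def overlaps(contig, start, stop):
            return any(s < stop and start < e
                       for s, e in regions.get(contig, []))
    flags = []
    m = enzyme.site_len
    for res in results:
        g = res.guide
        flag = False
        for h in res.hits:
            for (contig, start, strand) in h.positions:
                if (contig, start, strand) == (g.contig, g.start, g.strand):
                    continue
                if overlaps(contig, start, start + m):
                    flag = True
                    break
            if flag:
                break
        flags.append(flag)
    return flags
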