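"""Flat-table serialisation of search results and the scoring driver.

The discover table has one row per candidate guide::

    contig start stop target context orientation overflow otCount offTargets

``offTargets`` packs each hit as ``sequence_mismatches_occurrences``
(comma-separated, ascending sequence order), optionally followed by
``<contig:start^strand;...>`` when positions are requested.  The score
step appends metric columns to the same table.  All floats are written
with fixed precision so identical inputs give byte-identical files.
"""

from __future__ import annotations

import logging
import re

import pandas as pd

from . import ranking, scoring
from .annotate import AnnotationTrack, annotate
from .discovery import TargetSite
from .enzymes import EnzymeSpec
from .ontarget import load_models
from .search import OffTargetHit, SearchResult

logger = logging.getLogger(__name__)

DISCOVER_COLUMNS = [
    "contig", "start", "stop", "target", "context", "orientation",
    "overflow", "otCount", "offTargets",
]

OFFTARGET_SCORE_METRICS = ("hsu2013", "cfd")
ONTARGET_METRICS = ("doench2014", "crisprscan")
KNOWN_METRICS = OFFTARGET_SCORE_METRICS + ONTARGET_METRICS + ("basic", "rank")

_POS_RE = re.compile(r"^([A-Za-z]+[0-9]+(?:_[0-9]+)?[A-Z]*_\d+_\d+)$")


def format_hit(hit: OffTargetHit, include_positions: bool) -> str:
    s = f"{hit.sequence}_{hit.mismatches}_{hit.occurrences}"
    if include_positions and hit.positions:
        s += "<" + ";".join(
            f"{c}:{p}^{st}" for c, p, st in hit.positions
        ) + ">"
    return s


def parse_offtargets(field: str) -> list[OffTargetHit]:
    """Inverse of the ``offTargets`` column encoding."""
    if field in ("", "NONE") or pd.isna(field):
        return []
    hits = []
    for tok in field.split(","):
        pos_part = None
        if "<" in tok:
            tok, pos_part = tok[:-1].split("<", 1)
        seq, mm, occ = tok.rsplit("_", 2)
        positions = []
        if pos_part:
            for p in pos_part.split(";"):
                loc, strand = p.rsplit("^", 1)
                contig, start = loc.rsplit(":", 1)
                positions.append((contig, int(start), strand))
        hits.append(OffTargetHit(seq, int(mm), int(occ), positions))
    return hits


def results_to_frame(
    results: list[SearchResult],
    enzyme: EnzymeSpec,
    include_positions: bool = False,
) -> pd.DataFrame:
    rows = []
    for res in results:
        g = res.guide
        rows.append({
            "contig": g.contig,
            "start": g.start,
            "stop": g.stop,
            "target": g.site(enzyme),
            "context": g.context if g.context else "NONE",
            "orientation": g.strand,
            "overflow": "OVERFLOW" if res.overflow else "OK",
            "otCount": res.total_offtarget_occurrences,
            "offTargets": ",".join(
                format_hit(h, include_positions) for h in res.hits
            ) or "NONE",
        })
    return pd.DataFrame(rows, columns=DISCOVER_COLUMNS)


def frame_to_results(df: pd.DataFrame, enzyme: EnzymeSpec) -> list[SearchResult]:
    """Rebuild SearchResult objects from a discover table."""
    out = []
    for row in df.itertuples(index=False):
        proto, pam = enzyme.split_site(str(row.target))
        guide = TargetSite(
            contig=str(row.contig), start=int(row.start), stop=int(row.stop),
            strand=str(row.orientation), protospacer=proto, pam=pam,
            context=None if str(row.context) == "NONE" else str(row.context),
        )
        out.append(SearchResult(
            guide=guide,
            hits=parse_offtargets(row.offTargets),
            overflow=(str(row.overflow) == "OVERFLOW"),
        ))
    return out


def _fmt(x, digits) -> str:
    if x is None or (isinstance(x, float) and x != x):
        return "NA"
    return f"{x:.{digits}f}"


def score_results(
    results: list[SearchResult],
    enzyme: EnzymeSpec,
    metrics: list[str],
    tracks: list[AnnotationTrack] = (),
    regions: dict[str, list[tuple[int, int]]] | None = None,
    include_self_hits: bool = False,
    top_n: int = ranking.DEFAULT_TOP_N,
    include_positions: bool = False,
) -> pd.DataFrame:
    """The full characterisation table for a set of searched candidates.

    Off-target metrics are withheld (NA) from overflow guides, whose hit
    enumeration stopped early.  With ``rank``, every scoring metric
    requested earlier in ``metrics`` becomes one ballot (Hsu and on-target
    models: higher is better; CFD max measures risk: lower is better).
    """
    for m in metrics:
        if m not in KNOWN_METRICS:
            raise ValueError(
                f"unknown metric {m!r}; known: {', '.join(KNOWN_METRICS)}"
            )
    df = results_to_frame(results, enzyme, include_positions=include_positions)
    cleaned = [
        scoring.remove_self_hit(r, enzyme) if not include_self_hits else r.hits
        for r in results
    ]

    float_cols: dict[str, int] = {}
    if "hsu2013" in metrics:
        weights = scoring.load_hsu_weights()
        df["hsu2013"] = [
            None if res.overflow else
            scoring.hsu_aggregate(res.guide.protospacer, hits, weights, enzyme)
            for res, hits in zip(results, cleaned)
        ]
        float_cols["hsu2013"] = 4
    if "cfd" in metrics:
        table = scoring.load_cfd_table()
        df["cfd"] = [
            None if res.overflow else
            scoring.cfd_max(res.guide.protospacer, hits, table, enzyme)
            for res, hits in zip(results, cleaned)
        ]
        float_cols["cfd"] = 6
    wanted_models = [m for m in ONTARGET_METRICS if m in metrics]
    if wanted_models:
        models = load_models()
        proto_off = scoring_context_offset(enzyme)
        for name in wanted_models:
            model = models[name]
            df[name] = [
                model.score(res.guide.context, proto_off) for res in results
            ]
            float_cols[name] = 6
    if "basic" in metrics:
        flags = [scoring.flag_basic(res.guide.protospacer) for res in results]
        for key in ("gc_high", "gc_low", "polyT"):
            df[key] = [int(f[key]) for f in flags]
        if regions is None:
            regions = candidate_span_regions(results)
        have_positions = any(h.positions for hits in cleaned for h in hits)
        if have_positions or not any(hits for hits in cleaned):
            df["reciprocal"] = [
                int(f) for f in scoring.reciprocal_offtargets(
                    [SearchResult(r.guide, h, r.overflow)
                     for r, h in zip(results, cleaned)],
                    regions, enzyme)
            ]
        else:
            logger.warning(
                "no hit positions available (discover run without position "
                "output); reciprocal flag left NA")
            df["reciprocal"] = "NA"

    for track in tracks:
        df[track.name] = annotate(
            [(r.guide.contig, r.guide.start, r.guide.stop) for r in results],
            track,
        )

    if "rank" in metrics:
        ballots = [(m, ranking.METRIC_DIRECTIONS[m])
                   for m in metrics if m in ranking.METRIC_DIRECTIONS]
        if not ballots:
            raise ValueError("rank requested but no scoring metrics precede it")
        agg = ranking.rank_aggregate(df, ballots, top_n=top_n)
        df["medianRank"] = agg["medianRank"]
        df["schulzeRank"] = [
            "NA" if pd.isna(v) else int(v) for v in agg["schulzeRank"]
        ]
        float_cols["medianRank"] = 1

    for col, digits in float_cols.items():
        df[col] = [_fmt(v, digits) if not isinstance(v, str) else v
                   for v in df[col]]
    return df


def scoring_context_offset(enzyme: EnzymeSpec) -> int:
    """Index of the protospacer start within a stored context window."""
    from .discovery import CONTEXT_FLANK

    return CONTEXT_FLANK + (enzyme.pam_len if enzyme.pam_side == "five_prime" else 0)


def candidate_span_regions(results: list[SearchResult]) -> dict[str, list[tuple[int, int]]]:
    """Default region of interest: the per-contig span of the candidates."""
    spans: dict[str, tuple[int, int]] = {}
    for r in results:
        g = r.guide
        lo, hi = spans.get(g.contig, (g.start, g.stop))
        spans[g.contig] = (min(lo, g.start), max(hi, g.stop))
    return {c: [v] for c, v in spans.items()}
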