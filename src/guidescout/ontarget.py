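"""On-target activity models as positional-weight sums.

Both widely used Cas9 on-target activity metrics — the Doench 2014
rule-set-1 regression and the Moreno-Mateos/Vejnar CRISPRScan model — share
one shape: a linear sum of position-specific mononucleotide and
dinucleotide indicator weights over a fixed sequence window around the
protospacer (30-mer for Doench 2014: 4 bases upstream, 20-mer protospacer,
3-base PAM, 3 downstream; 35-mer for CRISPRScan), optionally with
GC-content terms and an intercept, passed through a logistic (Doench) or
identity (CRISPRScan) output transform.  This module implements that shape
generically; the coefficients live in TSV resource files so models can be
swapped without code changes.

A model declares the context window it needs; when a candidate sits too
close to a contig edge to supply it, evaluation returns ``None`` (a
no-score marker) rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources as importlib_resources

import pandas as pd

TRANSFORMS = ("identity", "logistic")
FEATURE_KINDS = ("mono", "di", "gc_low", "gc_high", "intercept")


@dataclass(frozen=True)
class PWTerm:
    kind: str        # mono | di | gc_low | gc_high
    position: int    # 0-based index into the model window (gc: GC threshold)
    bases: str       # "A" / "GT" / "" for gc terms
    weight: float


@dataclass
class PositionWeightModel:
    """A window, an intercept, a bag of indicator terms, and a transform.

    ``window_start`` is the window's offset relative to the protospacer
    start in guide orientation (negative = upstream); ``window_len`` is its
    length.  GC terms apply ``weight * |gc_count - threshold|`` over the
    protospacer when the count is below (gc_low) / above (gc_high) the
    threshold.
    """

    name: str
    window_start: int
    window_len: int
    transform: str = "identity"
    intercept: float = 0.0
    terms: list[PWTerm] = field(default_factory=list)
    protospacer_len: int = 20

    def __post_init__(self):
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        for t in self.terms:
            if t.kind in ("mono", "di"):
                if not 0 <= t.position <= self.window_len - len(t.bases):
                    raise ValueError(
                        f"{self.name}: term {t} lies outside the "
                        f"{self.window_len}-base window"
                    )
                if not set(t.bases) <= set("ACGT") or \
                        len(t.bases) != (1 if t.kind == "mono" else 2):
                    raise ValueError(f"{self.name}: bad bases in term {t}")
            elif t.kind not in ("gc_low", "gc_high"):
                raise ValueError(f"{self.name}: unknown feature kind {t.kind!r}")

    def score(self, context: str | None, proto_start: int) -> float | None:
        """Evaluate on ``context`` where ``proto_start`` is the index of the
        protospacer's first base within ``context``.  Returns None when the
        declared window is not fully available."""
        if context is None:
            return None
        lo = proto_start + self.window_start
        hi = lo + self.window_len
        if lo < 0 or hi > len(context):
            return None
        window = context[lo:hi]
        if any(c not in "ACGT" for c in window):
            return None
        total = self.intercept
        proto_in_window = -self.window_start
        gc = None
        for t in self.terms:
            if t.kind == "mono" or t.kind == "di":
                if window[t.position: t.position + len(t.bases)] == t.bases:
                    total += t.weight
            else:
                if gc is None:
                    proto = window[proto_in_window: proto_in_window + self.protospacer_len]
                    gc = sum(c in "GC" for c in proto)
                if t.kind == "gc_low" and gc < t.position:
                    total += t.weight * (t.position - gc)
                elif t.kind == "gc_high" and gc > t.position:
                    total += t.weight * (gc - t.position)
        if self.transform == "logistic":
            return 1.0 / (1.0 + math.exp(-total))
        return total


def _resource_path(filename: str):
    return importlib_resources.files("guidescout.resources").joinpath(filename)


def load_models(path=None) -> dict[str, PositionWeightModel]:
    """Load positional-weight models from the TSV schema
    (model, feature, position, bases, weight).

    Meta rows: feature ``window`` (position = start offset, bases = length),
    ``transform`` (bases = identity|logistic), ``intercept`` (weight).
    Term rows use feature kinds mono/di/gc_low/gc_high.
    """
    if path is None:
        with importlib_resources.as_file(
            _resource_path("ontarget_models_synthetic.tsv")
        ) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    required = {"model", "feature", "position", "bases", "weight"}
    if set(df.columns) != required:
        raise ValueError(
            f"model table must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    models: dict[str, PositionWeightModel] = {}
    for name, grp in df.groupby("model", sort=False):
        meta = {r.feature: r for r in grp.itertuples() if r.feature in
                ("window", "transform", "intercept")}
        if "window" not in meta:
            raise ValueError(f"model {name!r}: missing window declaration")
        terms = [
            PWTerm(r.feature, int(r.position),
                   "" if pd.isna(r.bases) else str(r.bases), float(r.weight))
            for r in grp.itertuples()
            if r.feature in ("mono", "di", "gc_low", "gc_high")
        ]
        models[name] = PositionWeightModel(
            name=name,
            window_start=int(meta["window"].position),
            window_len=int(meta["window"].bases),
            transform=(str(meta["transform"].bases)
                       if "transform" in meta else "identity"),
            intercept=(float(meta["intercept"].weight)
                       if "intercept" in meta else 0.0),
            terms=terms,
        )
    return models
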