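"""Deterministic synthetic genomes with planted off-targets.

Every other module is testable without downloading a reference: this
module writes random-background contigs at a requested GC content and
plants copies of a chosen guide's site mutated at an exact number of
protospacer positions (the PAM bases are left intact, so every plant
remains discoverable).  The returned truth table records where each plant
went and at what mismatch distance.

Random background can, by chance, contain additional near-matches to a
guide, so truth-table checks should assert *superset* recovery of the
plants; exact-set comparisons belong against the brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .discovery import TargetSite
from .enzymes import EnzymeSpec, reverse_complement

_BASES = np.array(list("ACGT"))


def synth_genome(
    seed: int,
    length: int,
    gc: float = 0.5,
    n_contigs: int = 1,
) -> dict[str, str]:
    """Deterministic random contigs at the requested GC fraction.

    ``length`` is the total length, split evenly across ``n_contigs``.
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = {}
    per = length // n_contigs
    for i in range(n_contigs):
        n = per if i < n_contigs - 1 else length - per * (n_contigs - 1)
        genome[f"contig{i}"] = "".join(rng.choice(_BASES, size=n, p=probs))
    return genome


def write_fasta(genome: dict[str, str], path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")
    return path


@dataclass(frozen=True)
class PlantRecord:
    contig: str
    pos: int        # forward-strand start of the full site
    strand: str
    d: int          # exact protospacer mismatches to the guide
    site: str       # planted full site, guide orientation


def _mutate_protospacer(proto: str, d: int, rng) -> str:
    pos = rng.choice(len(proto), size=d, replace=False)
    out = list(proto)
    for p in pos:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[int(rng.integers(3))]
    return "".join(out)


def plant_offtargets(
    genome: dict[str, str],
    guide: TargetSite,
    enzyme: EnzymeSpec,
    spec: list[tuple[int, int]],
    seed: int,
    margin: int = 12,
) -> tuple[dict[str, str], list[PlantRecord]]:
    """Overwrite background with mutated copies of ``guide``'s site.

    ``spec`` lists (mismatch distance d, copies).  Each plant mutates
    exactly ``d`` distinct protospacer positions to different bases and
    keeps the guide's PAM bases, placed on a random strand at
    non-overlapping slots at least ``margin`` bases apart and away from
    contig edges.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    m = enzyme.site_len
    total = sum(c for _d, c in spec)
    slots: list[tuple[str, int]] = []
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    contigs = sorted(genome)
    sizes = np.array([len(genome[c]) for c in contigs], dtype=float)
    if (sizes < 2 * (m + margin)).all():
        raise ValueError("genome too small to plant into")
    for _ in range(total):
        for _attempt in range(1000):
            ci = int(rng.choice(len(contigs), p=sizes / sizes.sum()))
            contig = contigs[ci]
            hi = len(genome[contig]) - m - margin
            if hi <= margin:
                continue
            pos = int(rng.integers(margin, hi))
            if all(pos + m + margin <= s or e + margin <= pos
                   for s, e in taken[contig]):
                taken[contig].append((pos, pos + m))
                slots.append((contig, pos))
                break
        else:
            raise ValueError("genome too small for the requested plants")

    new = dict(genome)
    truth: list[PlantRecord] = []
    si = 0
    for d, copies in spec:
        for _ in range(copies):
            contig, pos = slots[si]
            si += 1
            proto = _mutate_protospacer(guide.protospacer, d, rng)
            site = enzyme.site_string(proto, guide.pam)
            strand = "+" if rng.integers(2) == 0 else "-"
            fwd = site if strand == "+" else reverse_complement(site)
            seq = new[contig]
            new[contig] = seq[:pos] + fwd + seq[pos + m:]
            truth.append(PlantRecord(contig, pos, strand, d, site))
    return new, truth


def write_truth_table(truth: list[PlantRecord], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("contig\tpos\tstrand\td\tsite\n")
        for r in truth:
            fh.write(f"{r.contig}\t{r.pos}\t{r.strand}\t{r.d}\t{r.site}\n")
    return path
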