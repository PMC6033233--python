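"""CRISPR enzyme definitions and IUPAC PAM matching.

An enzyme is a PAM pattern set plus a geometry: which side of the
protospacer the PAM sits on and how long the protospacer is.  Three
registered enzymes cover the common nucleases: SpCas9 with its canonical
3' NGG PAM, SpCas9 allowing the weaker NAG alternative, and Cpf1 (Cas12a)
with a 5' TTTN PAM.
"""

from __future__ import annotations

from dataclasses import dataclass

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def pam_matches(pattern: str, bases: str) -> bool:
    """True iff every base falls in its IUPAC class for ``pattern``."""
    if len(pattern) != len(bases):
        raise ValueError(
            f"pattern {pattern!r} and bases {bases!r} differ in length"
        )
    for sym, base in zip(pattern, bases):
        allowed = IUPAC.get(sym)
        if allowed is None:
            raise ValueError(f"unknown IUPAC symbol {sym!r} in {pattern!r}")
        if base not in allowed:
            return False
    return True


@dataclass(frozen=True)
class EnzymeSpec:
    """What counts as a target for one CRISPR enzyme.

    ``pams`` are equal-length IUPAC patterns in guide orientation;
    ``pam_side`` says whether the PAM precedes (five_prime, Cpf1-style) or
    follows (three_prime, Cas9-style) the protospacer.  The full site
    (protospacer + PAM) must fit in 24 bases so targets pack into the
    64-bit database words.
    """

    name: str
    pams: tuple[str, ...]
    pam_side: str  # "three_prime" | "five_prime"
    protospacer_len: int = 20

    def __post_init__(self):
        if self.pam_side not in ("three_prime", "five_prime"):
            raise ValueError(f"bad pam_side {self.pam_side!r}")
        lengths = {len(p) for p in self.pams}
        if len(lengths) != 1:
            raise ValueError("all PAM patterns must share one length")
        for p in self.pams:
            for sym in p:
                if sym not in IUPAC:
                    raise ValueError(f"unknown IUPAC symbol {sym!r} in PAM {p!r}")
        if self.site_len > 24:
            raise ValueError(
                f"site length {self.site_len} exceeds the 24-base encoding cap"
            )

    @property
    def pam_len(self) -> int:
        return len(self.pams[0])

    @property
    def site_len(self) -> int:
        return self.protospacer_len + self.pam_len

    def site_string(self, protospacer: str, pam: str) -> str:
        """Assemble a full site in guide orientation."""
        if self.pam_side == "three_prime":
            return protospacer + pam
        return pam + protospacer

    def split_site(self, site: str) -> tuple[str, str]:
        """Full site in guide orientation -> (protospacer, pam)."""
        if self.pam_side == "three_prime":
            return site[: self.protospacer_len], site[self.protospacer_len:]
        return site[self.pam_len:], site[: self.pam_len]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "pams": list(self.pams),
            "pam_side": self.pam_side,
            "protospacer_len": self.protospacer_len,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnzymeSpec":
        return cls(
            name=d["name"],
            pams=tuple(d["pams"]),
            pam_side=d["pam_side"],
            protospacer_len=d["protospacer_len"],
        )


ENZYMES: dict[str, EnzymeSpec] = {
    "spcas9ngg": EnzymeSpec("spcas9ngg", ("NGG",), "three_prime", 20),
    "spcas9ngg-nag": EnzymeSpec("spcas9ngg-nag", ("NGG", "NAG"), "three_prime", 20),
    "cpf1": EnzymeSpec("cpf1", ("TTTN",), "five_prime", 20),
}


def get_enzyme(name: str) -> EnzymeSpec:
    try:
        return ENZYMES[name]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {name!r}; registered: {sorted(ENZYMES)}"
        ) from None
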