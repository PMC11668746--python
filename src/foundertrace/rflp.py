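"""In-silico PCR and restriction-digest genotyping (RFLP).

Simulates a PCR-RFLP assay at the fragment-size level: an amplicon is
extracted from a template by exact primer matching, digested with a
restriction enzyme described by an IUPAC degenerate recognition sequence,
and the resulting fragment-size pattern is matched against the expected
wild-type and mutant patterns to call a genotype, the way a band pattern is
read off a polyacrylamide gel.

Thermodynamics is out of scope: primers bind by exact string match only and
fragments are compared by size (optionally within a co-migration tolerance),
never by sequence.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from Bio.Seq import Seq

__all__ = [
    "RestrictionEnzyme",
    "PrimerPair",
    "DigestResult",
    "Genotype",
    "HPY188III",
    "simulate_pcr",
    "find_sites",
    "digest",
    "genotype_from_fragments",
    "NoAmplificationError",
    "NonSpecificAmplificationError",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def _iupac_regex(pattern: str) -> re.Pattern:
    # lookahead so overlapping matches are all reported
    body = "".join(
        c if len(_IUPAC[c]) == 1 else f"[{_IUPAC[c]}]" for c in pattern
    )
    return re.compile(f"(?=({body}))")


class NoAmplificationError(ValueError):
    """A primer has no binding site on the template."""


class NonSpecificAmplificationError(ValueError):
    """More than one product would amplify; carries all product sequences."""

    def __init__(self, products: list[str]):
        self.products = products
        super().__init__(
            f"non-specific amplification: {len(products)} products of lengths "
            f"{[len(p) for p in products]}"
        )


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme: degenerate recognition site plus top-strand cut offset.

    ``cut_offset`` is the 0-based position of the cut within the recognition
    site on the top strand (0 .. len(recognition)).  At construction the
    recognition site is checked for self-complementarity; palindromic sites
    (e.g. TCNNGA) need only a single-strand scan, others are scanned on both
    strands.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        if not rec or any(c not in _IUPAC for c in rec):
            raise ValueError(f"recognition {self.recognition!r} is not IUPAC DNA")
        if not 0 <= self.cut_offset <= len(rec):
            raise ValueError("cut_offset outside recognition site")
        object.__setattr__(self, "recognition", rec)

    @property
    def is_self_complementary(self) -> bool:
        return revcomp(self.recognition) == self.recognition


#: Hpy188III: TC^NNGA.  The recognition site is self-complementary, so a
#: top-strand scan finds every site.
HPY188III = RestrictionEnzyme(name="Hpy188III", recognition="TCNNGA", cut_offset=2)


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse PCR primers, both written 5'->3' on their own strand."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for label, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not p or any(c not in "ACGT" for c in p.upper()):
                raise ValueError(f"{label} primer must be non-empty A/C/G/T")
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())


@dataclass(frozen=True)
class DigestResult:
    """Fragment sizes (bp, multiset) of a linear restriction digest."""

    fragment_lengths: tuple[int, ...]
    n_sites: int

    def __post_init__(self) -> None:
        if len(self.fragment_lengths) != self.n_sites + 1:
            raise ValueError("linear digest must yield n_sites + 1 fragments")
        if any(f <= 0 for f in self.fragment_lengths):
            raise ValueError("fragment lengths must be positive")

    @property
    def sizes(self) -> Counter:
        return Counter(self.fragment_lengths)


class Genotype(str, Enum):
    WT_WT = "WT/WT"
    WT_MUT = "WT/mut"
    MUT_MUT = "mut/mut"
    UNCALLED = "uncalled"


def simulate_pcr(template: str, primers: PrimerPair) -> str:
    """Extract the PCR product defined by exact primer matches.

    The product runs from the first base of the forward primer's binding
    site through the last base of the reverse primer's binding site (the
    reverse complement of the reverse primer, downstream of the forward
    hit).  Raises :class:`NoAmplificationError` if either primer has no
    site, :class:`NonSpecificAmplificationError` listing all products if
    more than one (forward, reverse) pairing would amplify.
    """
    template = template.upper()
    fwd = primers.forward
    rev_site = str(Seq(primers.reverse).reverse_complement())

    fwd_hits = [m.start() for m in re.finditer(f"(?={re.escape(fwd)})", template)]
    rev_hits = [m.start() for m in re.finditer(f"(?={re.escape(rev_site)})", template)]
    if not fwd_hits or not rev_hits:
        missing = "forward" if not fwd_hits else "reverse"
        raise NoAmplificationError(f"no amplification: {missing} primer site absent")

    products = []
    for f in fwd_hits:
        for r in rev_hits:
            if r >= f + len(fwd):  # reverse site strictly downstream
                products.append(template[f : r + len(rev_site)])
    # de-duplicate identical coordinates while preserving order
    products = list(dict.fromkeys(products))
    if not products:
        raise NoAmplificationError(
            "no amplification: reverse site not downstream of forward site"
        )
    if len(products) > 1:
        raise NonSpecificAmplificationError(products)
    return products[0]


def find_sites(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """All cut coordinates of ``enzyme`` in ``seq`` (0-based, cut before index).

    The degenerate recognition pattern is scanned on the top strand;
    overlapping matches are all reported.  For non-self-complementary
    enzymes the bottom strand is scanned too (as a top-strand match of the
    reverse-complement pattern, with the cut offset mirrored).
    """
    seq = seq.upper()
    if any(c not in "ACGT" for c in seq):
        raise ValueError("sequence must be A/C/G/T")
    rec = enzyme.recognition
    cuts = {m.start() + enzyme.cut_offset for m in _iupac_regex(rec).finditer(seq)}
    if not enzyme.is_self_complementary:
        rc = revcomp(rec)
        mirrored = len(rec) - enzyme.cut_offset
        cuts |= {
            m.start() + mirrored for m in _iupac_regex(rc).finditer(seq)
        }
    return sorted(cuts)


def digest(seq: str, enzyme: RestrictionEnzyme) -> DigestResult:
    """Digest a linear molecule: fragments between consecutive cut coordinates."""
    seq = seq.upper()
    cuts = [c for c in find_sites(seq, enzyme) if 0 < c < len(seq)]
    bounds = [0, *cuts, len(seq)]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestResult(fragment_lengths=fragments, n_sites=len(cuts))


def _gel_pattern(sizes: Iterable[int], tolerance_bp: int) -> list[int]:
    """Distinct band sizes as seen on a gel: sizes within tolerance co-migrate."""
    out: list[int] = []
    for s in sorted(set(sizes), reverse=True):
        if not out or out[-1] - s > tolerance_bp:
            out.append(s)
    return out


def _patterns_match(observed: list[int], expected: list[int], tol: int) -> bool:
    return len(observed) == len(expected) and all(
        abs(o - e) <= tol for o, e in zip(observed, expected)
    )


def genotype_from_fragments(
    observed: Sequence[int],
    wt_pattern: Sequence[int],
    mut_pattern: Sequence[int],
    tolerance_bp: int = 0,
) -> Genotype:
    """Call a genotype from a digest band pattern.

    The observed sizes are matched against the wild-type pattern, the mutant
    pattern, and their union (the heterozygote; a size present in both
    alleles appears as a single band, as on a gel).  Each comparison treats
    sizes within ``tolerance_bp`` as one band.  An observed pattern matching
    none, or more than one, of the three candidates is ``UNCALLED``.
    """
    if not wt_pattern or not mut_pattern:
        raise ValueError("allele patterns must be non-empty")
    if sorted(wt_pattern) == sorted(mut_pattern):
        raise ValueError("allele patterns must be distinct")
    obs = _gel_pattern(observed, tolerance_bp)
    candidates = {
        Genotype.WT_WT: _gel_pattern(wt_pattern, tolerance_bp),
        Genotype.MUT_MUT: _gel_pattern(mut_pattern, tolerance_bp),
        Genotype.WT_MUT: _gel_pattern([*wt_pattern, *mut_pattern], tolerance_bp),
    }
    hits = [g for g, pat in candidates.items() if _patterns_match(obs, pat, tolerance_bp)]
    if len(hits) == 1:
        return hits[0]
    return Genotype.UNCALLED
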