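"""IUPAC consensus scanning for GAS and ISRE promoter elements.

GAS (gamma-activated sequence, bound by pSTAT1 homodimers): ``TTNCNNNAA``;
ISRE (interferon-stimulated response element, bound by ISGF3):
``TTTCNNTTYY``.  Both strands are scanned by default, all overlapping
matches are reported, coordinates are 0-based half-open on the forward
strand, and an ``N`` in the subject sequence matches nothing except a
pattern ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

GAS = "TTNCNNNAA"
ISRE = "TTTCNNTTYY"


@dataclass(frozen=True)
class MotifPattern:
    name: str
    iupac: str

    def __post_init__(self):
        if len(self.iupac) < 4:
            raise ValueError("pattern length must be >= 4")
        bad = [c for c in self.iupac.upper() if c not in IUPAC]
        if bad:
            raise ValueError(f"illegal IUPAC codes {bad} in {self.iupac!r}")


@dataclass(frozen=True)
class MotifHit:
    start: int        # 0-based, forward-strand coordinates
    end: int          # half-open
    strand: str       # '+' or '-'
    matched: str      # subsequence on the matched strand
    pattern: str      # pattern name


GAS_PATTERN = MotifPattern("GAS", GAS)
ISRE_PATTERN = MotifPattern("ISRE", ISRE)


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _match_at(seq: str, pat: str, i: int) -> bool:
    for p, s in zip(pat, seq[i:i + len(pat)]):
        if s == "N":
            if p != "N":   # subject N only matches pattern N
                return False
        elif s not in IUPAC[p]:
            return False
    return True


def scan(sequence: str, pattern: MotifPattern,
         both_strands: bool = True) -> list:
    """All (overlapping) motif matches; reverse-strand hits are reported in
    forward coordinates with the matched text of the reverse strand."""
    seq = sequence.upper()
    for pos, c in enumerate(seq):
        if c not in "ACGTN":
            raise ValueError(f"illegal character {c!r} at position {pos}")
    pat = pattern.iupac.upper()
    L, n = len(pat), len(seq)
    hits = [MotifHit(i, i + L, "+", seq[i:i + L], pattern.name)
            for i in range(n - L + 1) if _match_at(seq, pat, i)]
    if both_strands:
        rc = reverse_complement(seq)
        for i in range(n - L + 1):
            if _match_at(rc, pat, i):
                start = n - i - L
                hits.append(MotifHit(start, start + L, "-", rc[i:i + L],
                                     pattern.name))
    return sorted(hits, key=lambda h: (h.start, h.strand))


def classify_promoter(hits_gas, hits_isre, window=(-1250, 1750),
                      tss: int = 0) -> str:
    """Promoter class from motif presence within a TSS-relative window.

    Hit coordinates are promoter coordinates with the TSS at ``tss``;
    ``window`` is (upstream, downstream) relative to the TSS.
    Returns one of GAS_only / ISRE_only / both / none.
    """
    lo, hi = tss + window[0], tss + window[1]
    has_gas = any(lo <= h.start < hi for h in hits_gas)
    has_isre = any(lo <= h.start < hi for h in hits_isre)
    return {(True, False): "GAS_only", (False, True): "ISRE_only",
            (True, True): "both", (False, False): "none"}[
        (has_gas, has_isre)]


def hits_to_bed(hits, seqid: str) -> str:
    """BED-like TSV (seqid, start, end, name, strand) for a hit list."""
    lines = [f"{seqid}\t{h.start}\t{h.end}\t{h.pattern}\t{h.strand}"
             for h in hits]
    return "\n".join(lines) + ("\n" if lines else "")
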