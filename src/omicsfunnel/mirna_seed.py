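"""TargetScan-style microRNA seed-match scanner for 3'UTR sequences.

Site types, for a mature miRNA read 5'->3' (positions 1..n):

* ``8mer``      — reverse complement of miRNA positions 2-8, followed by an A
                  at target position 1 (the 3' end of the site);
* ``7mer-m8``   — reverse complement of positions 2-8 alone;
* ``7mer-1A``   — reverse complement of positions 2-7, followed by an A.

The position-1 "A" is required as a literal A in the UTR (the TargetScan
convention), not as complementarity to miRNA position 1.  Overlapping sites
at different offsets are all reported, but each locus reports only its
strongest type (8mer > 7mer-m8 > 7mer-1A).  Coordinates are 1-based,
inclusive, on the input UTR; ``site_seq`` echoes the input alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")
_ALPHABETS = {"dna": set("ACGTN"), "rna": set("ACGUN")}

SITE_TYPES = ("8mer", "7mer-m8", "7mer-1A")


@dataclass(frozen=True)
class SeedSite:
    utr_id: str
    site_type: str
    start: int  # 1-based
    end: int  # 1-based inclusive
    site_seq: str

    def __post_init__(self) -> None:
        expected = 8 if self.site_type == "8mer" else 7
        if self.end - self.start + 1 != expected:
            raise ValueError(f"{self.site_type} span must be {expected} nt")

    def to_bed(self) -> tuple:
        """(chrom, start, end) with 0-based half-open coordinates."""
        return (self.utr_id, self.start - 1, self.end)


def reverse_complement(seq: str, alphabet: str = "dna") -> str:
    """Antiparallel complement of a DNA or RNA sequence."""
    if alphabet not in _ALPHABETS:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    upper = seq.upper()
    valid = _ALPHABETS[alphabet]
    for position, base in enumerate(upper, start=1):
        if base not in valid:
            raise ValueError(
                f"invalid {alphabet.upper()} character {base!r} at position {position}"
            )
    table = _DNA_COMPLEMENT if alphabet == "dna" else _RNA_COMPLEMENT
    return upper.translate(table)[::-1]


def find_seed_sites(mature_mirna: str, utr_seq: str, utr_id: str = "utr") -> list:
    """Scan a 3'UTR for 8mer, 7mer-m8 and 7mer-1A seed-match sites.

    The mature miRNA is given 5'->3' (RNA; T is accepted and normalised).
    The UTR may be DNA or RNA; matching is done in a normalised DNA alphabet
    and the reported ``site_seq`` is the original UTR slice.
    """
    mirna = mature_mirna.upper().replace("T", "U")
    if len(mirna) < 8:
        raise ValueError(f"mature miRNA must be >= 8 nt, got {len(mirna)}")
    for position, base in enumerate(mirna, start=1):
        if base not in _ALPHABETS["rna"]:
            raise ValueError(f"invalid RNA character {base!r} at position {position}")

    utr_norm = utr_seq.upper().replace("U", "T")
    for position, base in enumerate(utr_norm, start=1):
        if base not in _ALPHABETS["dna"]:
            raise ValueError(f"invalid UTR character {base!r} at position {position}")

    # revcomp of seed positions 2-8, in the UTR (DNA) alphabet
    match_2_8 = reverse_complement(mirna[1:8], "rna").replace("U", "T")
    eight_mer = match_2_8 + "A"
    seven_1a = match_2_8[1:] + "A"  # revcomp of positions 2-7, then A

    sites = []
    starts_8mer = set()
    n = len(utr_norm)
    for i in range(n - 8 + 1):
        if utr_norm[i : i + 8] == eight_mer:
            starts_8mer.add(i)
            sites.append(
                SeedSite(utr_id, "8mer", i + 1, i + 8, utr_seq[i : i + 8])
            )
    spans_7mer_m8 = set()
    for i in range(n - 7 + 1):
        if utr_norm[i : i + 7] == match_2_8 and i not in starts_8mer:
            spans_7mer_m8.add(i)
            sites.append(
                SeedSite(utr_id, "7mer-m8", i + 1, i + 7, utr_seq[i : i + 7])
            )
    for i in range(n - 7 + 1):
        if (
            utr_norm[i : i + 7] == seven_1a
            and (i - 1) not in starts_8mer  # shadowed by an 8mer one base 5'
            and i not in spans_7mer_m8  # same locus, weaker type
        ):
            sites.append(
                SeedSite(utr_id, "7mer-1A", i + 1, i + 7, utr_seq[i : i + 7])
            )
    sites.sort(key=lambda s: (s.start, s.end))
    return sites
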