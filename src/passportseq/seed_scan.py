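"""Canonical miRNA seed-match scanning and mirSNP classification.

A miRNA's seed is nucleotides 2-8 of its mature sequence. Its canonical
target sites on an mRNA (read 5'->3', T equivalent to U) are:

=========  =====================================================  ======
site type  mRNA pattern                                           length
=========  =====================================================  ======
8mer       revcomp(miRNA 2-8) followed by A                       8
7mer-m8    revcomp(miRNA 2-8)                                     7
7mer-A1    revcomp(miRNA 2-7) followed by A                       7
6mer       revcomp(miRNA 2-7)                                     6
=========  =====================================================  ======

The A opposite miRNA position 1 is a literal adenosine on the mRNA, not
a pairing requirement. Pairing is Watson-Crick only (no GU wobble).
Longer site types mask the shorter site types they contain at the same
locus, so an 8mer is not additionally reported as a 7mer-m8, 7mer-A1 or
6mer.

A SNP is classified against each miRNA by scanning short windows around
each allele and comparing the site sets that overlap the variant base:
a site present only with the reference allele means the variant destroys
it (``site_lost``), only with the alternate allele means it creates one
(``site_gained``), present in both but of different type means
``site_type_changed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._seq import RNA_BASES, revcomp, rna_to_dna
from .errors import InsufficientFlank, MiRNATooShort, PassportSeqError
from .panel_design import REFERENCE, VARIANT, MirSNP

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
SITE_LENGTHS = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}

SITE_LOST = "site_lost"
SITE_GAINED = "site_gained"
SITE_TYPE_CHANGED = "site_type_changed"
UNCHANGED = "unchanged"


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA, sequence 5'->3' in RNA alphabet (T tolerated)."""

    name: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper().replace("T", "U")
        bad = set(seq) - RNA_BASES
        if bad:
            raise PassportSeqError(
                f"miRNA {self.name}: non-ACGU character(s) {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def site_patterns(self) -> dict[str, str]:
        """DNA patterns an mRNA must contain for each canonical site type."""
        if len(self.sequence) < 8:
            raise MiRNATooShort(
                f"miRNA {self.name} is {len(self.sequence)} nt; need >= 8"
            )
        seq_dna = rna_to_dna(self.sequence)
        m2_8 = revcomp(seq_dna[1:8])  # complement of seed positions 2-8
        m2_7 = revcomp(seq_dna[1:7])
        return {
            "8mer": m2_8 + "A",
            "7mer-m8": m2_8,
            "7mer-A1": m2_7 + "A",
            "6mer": m2_7,
        }


@dataclass(frozen=True)
class SeedMatch:
    mirna_name: str
    site_type: str
    start: int  # 1-based offset of the site's 5'-most base in the window
    allele_class: str = REFERENCE

    @property
    def end(self) -> int:
        """1-based inclusive end position."""
        return self.start + SITE_LENGTHS[self.site_type] - 1

    def overlaps(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class MirSnpClassification:
    snp_id: str
    mirna_name: str
    status: str
    ref_site_type: str | None = None
    alt_site_type: str | None = None
    site_start: int | None = None


def seed_sites(window: str, mirna: MiRNA, allele_class: str = REFERENCE) -> list[SeedMatch]:
    """All canonical seed-match sites of *mirna* in *window*.

    The window is mRNA-sense DNA (or RNA; U is read as T). Matches of a
    longer site type mask matches of shorter types whose interval they
    contain; among same-length 7mers, 7mer-m8 takes precedence.
    """
    win = rna_to_dna(window)
    patterns = mirna.site_patterns()
    kept: list[SeedMatch] = []
    for site_type in SITE_TYPES:  # longest / highest-precedence first
        pattern = patterns[site_type]
        start = win.find(pattern)
        while start != -1:
            cand = SeedMatch(mirna.name, site_type, start + 1, allele_class)
            contained = any(
                k.start <= cand.start and cand.end <= k.end for k in kept
            )
            if not contained:
                kept.append(cand)
            start = win.find(pattern, start + 1)
    kept.sort(key=lambda m: (m.start, -SITE_LENGTHS[m.site_type]))
    return kept


def _scan_window(snp: MirSNP, allele_class: str, flank_width: int) -> tuple[str, int]:
    """(window, 1-based allele position) for the classification scan."""
    if len(snp.flank5) < flank_width or len(snp.flank3) < flank_width:
        raise InsufficientFlank(
            f"{snp.snp_id}: classification needs >= {flank_width} nt flank "
            f"on both sides (got {len(snp.flank5)}/{len(snp.flank3)})"
        )
    window = (
        snp.flank5[-flank_width:] + snp.allele(allele_class) + snp.flank3[:flank_width]
    )
    return window, flank_width + 1


def classify_mirsnp(
    snp: MirSNP,
    mirnas: Iterable[MiRNA],
    flank_width: int = 8,
    include_unchanged: bool = False,
) -> list[MirSnpClassification]:
    """Compare allele-overlapping seed sites between the two alleles.

    Only sites whose span covers the variant base count: a SNP cannot
    alter a site it does not touch. By default only miRNAs whose status
    is not ``unchanged`` are returned.
    """
    ref_win, pos = _scan_window(snp, REFERENCE, flank_width)
    alt_win, _ = _scan_window(snp, VARIANT, flank_width)
    out = []
    for mirna in mirnas:
        ref_hits = [m for m in seed_sites(ref_win, mirna, REFERENCE) if m.overlaps(pos)]
        alt_hits = [m for m in seed_sites(alt_win, mirna, VARIANT) if m.overlaps(pos)]
        if ref_hits and not alt_hits:
            status = SITE_LOST
        elif alt_hits and not ref_hits:
            status = SITE_GAINED
        elif ref_hits and alt_hits:
            same = {(m.site_type, m.start) for m in ref_hits} == {
                (m.site_type, m.start) for m in alt_hits
            }
            status = UNCHANGED if same else SITE_TYPE_CHANGED
        else:
            status = UNCHANGED
        if status == UNCHANGED and not include_unchanged:
            continue
        first = (ref_hits or alt_hits)[0] if (ref_hits or alt_hits) else None
        out.append(
            MirSnpClassification(
                snp_id=snp.snp_id,
                mirna_name=mirna.name,
                status=status,
                ref_site_type=ref_hits[0].site_type if ref_hits else None,
                alt_site_type=alt_hits[0].site_type if alt_hits else None,
                site_start=first.start if first else None,
            )
        )
    return out


def scan_panel(
    snps: Sequence[MirSNP],
    mirnas: Sequence[MiRNA],
    flank_width: int = 8,
    include_unchanged: bool = False,
):
    """Classify every SNP in a panel against every miRNA.

    Returns a pandas DataFrame with one row per (snp, miRNA)
    classification plus an ``error`` column; per-SNP failures (e.g.
    short flanks) are recorded there rather than aborting the scan.
    """
    import pandas as pd

    rows = []
    for snp in snps:
        try:
            for c in classify_mirsnp(snp, mirnas, flank_width, include_unchanged):
                rows.append(
                    {
                        "snp_id": c.snp_id,
                        "mirna": c.mirna_name,
                        "status": c.status,
                        "ref_site_type": c.ref_site_type or "",
                        "alt_site_type": c.alt_site_type or "",
                        "site_start": "" if c.site_start is None else c.site_start,
                        "error": "",
                    }
                )
        except PassportSeqError as exc:
            rows.append(
                {
                    "snp_id": snp.snp_id,
                    "mirna": "",
                    "status": "",
                    "ref_site_type": "",
                    "alt_site_type": "",
                    "site_start": "",
                    "error": str(exc),
                }
            )
    columns = [
        "snp_id", "mirna", "status", "ref_site_type",
        "alt_site_type", "site_start", "error",
    ]
    return pd.DataFrame(rows, columns=columns)
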