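"""Allele-resolved oligo panel design.

Each biallelic 3' UTR SNP is turned into two 32-nt *test windows* — the
variant position flanked by 22 nt on the 5' side and 9 nt on the 3' side,
one window per allele — and each window is wrapped in constant universal
primer arms to give a 63-nt synthesis fragment. The set of all fragments
is the allele-resolved reference library that read assignment and
counting key on.

Coordinates are on the annotated transcript (3' UTR) strand: the designer
never reverse-complements. Flanks must already be mRNA-sense.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._seq import gc_fraction, max_homopolymer, validate_dna
from .errors import (
    DesignError,
    DuplicateWindow,
    InsufficientFlank,
    InvalidWindow,
    NonSNV,
)

#: Universal primer-binding arms added 5' and 3' of every test window.
ARM5 = "GTAATTCTAGGAGCTC"
ARM3 = "CGTTCTAGAGTCGGG"

#: Window geometry: 22 nt upstream + allele + 9 nt downstream = 32 nt,
#: so the allele base always sits at window position 23 (1-based).
FLANK5_LEN = 22
FLANK3_LEN = 9
WINDOW_LEN = FLANK5_LEN + 1 + FLANK3_LEN
FRAGMENT_LEN = len(ARM5) + WINDOW_LEN + len(ARM3)
ALLELE_POS = FLANK5_LEN + 1  # 1-based position of the allele in the window

REFERENCE = "reference"
VARIANT = "variant"

#: Restriction sites used to linearize the reporter vector; an internal
#: occurrence inside a window would be cut during cloning.
_ENZYME_SITES = {"SacI": "GAGCTC", "BmtI": "GCTAGC"}


@dataclass(frozen=True)
class MirSNP:
    """One biallelic variant with its mRNA-sense flanking context."""

    snp_id: str
    ref_allele: str
    alt_allele: str
    flank5: str
    flank3: str
    contig: str = ""
    position: int = 0
    gene: str | None = None
    source: str | None = None

    def __post_init__(self):
        ref = self.ref_allele.upper()
        alt = self.alt_allele.upper()
        if len(ref) != 1 or len(alt) != 1:
            raise NonSNV(
                f"{self.snp_id}: alleles must be single bases "
                f"(got {self.ref_allele!r}/{self.alt_allele!r})"
            )
        ref = validate_dna(ref, f"{self.snp_id} ref allele")
        alt = validate_dna(alt, f"{self.snp_id} alt allele")
        if ref == alt:
            raise DesignError(f"{self.snp_id}: ref and alt alleles are identical")
        object.__setattr__(self, "ref_allele", ref)
        object.__setattr__(self, "alt_allele", alt)
        object.__setattr__(
            self, "flank5", validate_dna(self.flank5, f"{self.snp_id} flank5")
        )
        object.__setattr__(
            self, "flank3", validate_dna(self.flank3, f"{self.snp_id} flank3")
        )

    def allele(self, allele_class: str) -> str:
        if allele_class == REFERENCE:
            return self.ref_allele
        if allele_class == VARIANT:
            return self.alt_allele
        raise ValueError(f"unknown allele_class {allele_class!r}")


@dataclass(frozen=True)
class TestFragment:
    """One 63-nt synthesis unit: arm5 + 32-nt allele window + arm3."""

    __test__ = False  # "Test" is assay vocabulary, not a pytest class

    snp_id: str
    allele_class: str
    window: str
    fragment: str = field(default="")
    arm5: str = ARM5
    arm3: str = ARM3

    def __post_init__(self):
        if not self.fragment:
            object.__setattr__(self, "fragment", self.arm5 + self.window + self.arm3)
        assert self.fragment == self.arm5 + self.window + self.arm3

    @property
    def fragment_id(self) -> str:
        suffix = "REF" if self.allele_class == REFERENCE else "VAR"
        return f"{self.snp_id}_{suffix}"


@dataclass
class ReferenceLibrary:
    """Ordered collection of test fragments; the assay's reference."""

    fragments: list[TestFragment]

    def __post_init__(self):
        bodies: dict[str, str] = {}
        for frag in self.fragments:
            prior = bodies.get(frag.fragment)
            if prior is not None:
                raise DuplicateWindow(
                    f"fragments {prior} and {frag.fragment_id} share an "
                    f"identical body",
                    snp_ids=(prior.rsplit("_", 1)[0], frag.snp_id),
                )
            bodies[frag.fragment] = frag.fragment_id

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    @property
    def fragment_ids(self) -> list[str]:
        return [f.fragment_id for f in self.fragments]

    def by_id(self, fragment_id: str) -> TestFragment:
        for frag in self.fragments:
            if frag.fragment_id == fragment_id:
                return frag
        raise KeyError(fragment_id)

    def to_fasta(self, path) -> None:
        from . import interface_io

        interface_io.write_fasta(
            path, [(f.fragment_id, f.fragment) for f in self.fragments]
        )

    @classmethod
    def from_fasta(cls, path) -> "ReferenceLibrary":
        from . import interface_io

        fragments = []
        for name, seq in interface_io.read_fasta(path):
            snp_id, suffix = name.rsplit("_", 1)
            if suffix not in ("REF", "VAR"):
                raise InvalidWindow(
                    f"fragment id {name!r} does not end in _REF/_VAR"
                )
            body = validate_dna(seq, name)
            if len(body) != FRAGMENT_LEN or not (
                body.startswith(ARM5) and body.endswith(ARM3)
            ):
                raise InvalidWindow(
                    f"record {name!r} is not a {FRAGMENT_LEN}-nt arm-flanked fragment"
                )
            window = body[len(ARM5) : len(ARM5) + WINDOW_LEN]
            fragments.append(
                TestFragment(
                    snp_id=snp_id,
                    allele_class=REFERENCE if suffix == "REF" else VARIANT,
                    window=window,
                )
            )
        return cls(fragments)


def build_test_window(snp: MirSNP, allele_class: str) -> str:
    """32-nt allele-centered test window: flank5[-22:] + allele + flank3[:9]."""
    if len(snp.flank5) < FLANK5_LEN or len(snp.flank3) < FLANK3_LEN:
        raise InsufficientFlank(
            f"{snp.snp_id}: need >={FLANK5_LEN} nt 5' and >={FLANK3_LEN} nt 3' "
            f"flank (got {len(snp.flank5)}/{len(snp.flank3)})"
        )
    window = snp.flank5[-FLANK5_LEN:] + snp.allele(allele_class) + snp.flank3[:FLANK3_LEN]
    assert len(window) == WINDOW_LEN
    return window


def build_test_fragment(window: str) -> str:
    """Wrap a 32-nt window in the universal arms -> 63-nt fragment."""
    window = window.upper()
    if len(window) != WINDOW_LEN or set(window) - set("ACGT"):
        raise InvalidWindow(
            f"window must be {WINDOW_LEN} nt of ACGT, got {window!r}"
        )
    return ARM5 + window + ARM3


def screen_fragment(fragment: TestFragment) -> list[str]:
    """Synthesis/cloning QC warnings for one fragment; never fails.

    Flags restriction sites (SacI/BmtI) inside the window, homopolymer
    runs of 8 or more, and extreme GC content.
    """
    warnings = []
    for enzyme, site in _ENZYME_SITES.items():
        if site in fragment.window:
            warnings.append(
                f"{fragment.fragment_id}: internal {enzyme} site ({site}) in window"
            )
    run = max_homopolymer(fragment.window)
    if run >= 8:
        warnings.append(
            f"{fragment.fragment_id}: homopolymer run of {run} nt in window"
        )
    gc = gc_fraction(fragment.window)
    if not 0.1 <= gc <= 0.9:
        warnings.append(
            f"{fragment.fragment_id}: window GC fraction {gc:.2f} outside [0.10, 0.90]"
        )
    return warnings


def design_panel(snps: Iterable[MirSNP]) -> ReferenceLibrary:
    """Design the full allele-resolved library: 2 fragments per SNP.

    Fragments are emitted reference-then-variant per SNP, in panel order.
    Per-SNP design failures are re-raised with the snp_id prefixed;
    duplicate fragment bodies across the panel raise
    :class:`DuplicateWindow` naming both SNPs.
    """
    snps = list(snps)
    seen_ids: set[str] = set()
    for snp in snps:
        if snp.snp_id in seen_ids:
            raise DesignError(f"duplicate snp_id {snp.snp_id!r} in panel")
        seen_ids.add(snp.snp_id)
    fragments = []
    for snp in snps:
        for allele_class in (REFERENCE, VARIANT):
            window = build_test_window(snp, allele_class)
            fragments.append(
                TestFragment(snp_id=snp.snp_id, allele_class=allele_class, window=window)
            )
    return ReferenceLibrary(fragments)


def design_report(library: ReferenceLibrary) -> "list[dict]":
    """Rows for the design-report TSV: per SNP windows plus QC warnings."""
    by_snp: dict[str, dict] = {}
    for frag in library:
        row = by_snp.setdefault(frag.snp_id, {"snp_id": frag.snp_id, "warnings": []})
        key = "window_ref" if frag.allele_class == REFERENCE else "window_var"
        row[key] = frag.window
        row["warnings"].extend(screen_fragment(frag))
    for row in by_snp.values():
        row["warnings"] = ";".join(row["warnings"])
    return list(by_snp.values())
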