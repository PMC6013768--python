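"""Read processing: dual-barcode demultiplexing, allele-aware fragment
assignment, counting, and library QC.

Every amplicon read carries a 6-nt sample barcode at each end:
``fwd_bc + fragment body + revcomp(rev_bc)``. A read is assigned to a
sample only when BOTH barcodes match perfectly, in either read
orientation (reads are canonicalized to the forward strand). Barcode
error correction is deliberately absent.

Assignment of the trimmed read to a library fragment is deterministic:
an exact-match fast path, then a global edit-distance fallback with a
uniqueness margin. Because the two alleles of a SNP differ at exactly
one base, the margin rule guarantees a read equidistant between REF and
VAR bodies is dropped as ambiguous rather than counted for either
allele. This plays the role an aligner's mapping-quality filter plays in
pipelines built on read mapping, and is strictly conservative about
allele ambiguity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import edlib
import numpy as np
import pandas as pd

from ._seq import revcomp, validate_dna
from .errors import (
    DuplicateBarcodePair,
    NoInputSamples,
    TooFewReplicates,
    UnknownFragmentId,
)
from .panel_design import ARM3, ARM5, ReferenceLibrary

BARCODE_LEN = 6

INPUT = "input"
CDNA = "cdna"

UNASSIGNED_NO_BARCODE = "no_barcode_match"
UNASSIGNED_TOO_MANY_EDITS = "too_many_edits"
UNASSIGNED_AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class BarcodePair:
    fwd: str
    rev: str

    def __post_init__(self):
        for name, bc in (("fwd", self.fwd), ("rev", self.rev)):
            up = validate_dna(bc, f"{name} barcode")
            if len(up) != BARCODE_LEN:
                raise DuplicateBarcodePair(
                    f"{name} barcode {bc!r} is not {BARCODE_LEN} nt"
                )
            object.__setattr__(self, name, up)


@dataclass(frozen=True)
class SampleRow:
    sample_id: str
    role: str  # "input" or "cdna"
    cell_line: str  # "-" for input samples
    replicate: int
    run: str
    barcode: BarcodePair


@dataclass
class SampleSheet:
    rows: list[SampleRow]

    def __post_init__(self):
        ids = set()
        pairs = {}
        for row in self.rows:
            if row.sample_id in ids:
                raise DuplicateBarcodePair(f"duplicate sample_id {row.sample_id!r}")
            ids.add(row.sample_id)
            key = (row.barcode.fwd, row.barcode.rev)
            if key in pairs:
                raise DuplicateBarcodePair(
                    f"barcode pair {key} shared by samples "
                    f"{pairs[key]!r} and {row.sample_id!r}"
                )
            pairs[key] = row.sample_id
            if row.role not in (INPUT, CDNA):
                raise DuplicateBarcodePair(
                    f"sample {row.sample_id}: role must be input or cdna"
                )
            if row.role == CDNA and (not row.cell_line or row.cell_line == "-"):
                raise DuplicateBarcodePair(
                    f"cdna sample {row.sample_id} has no cell line"
                )

    def __len__(self):
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.rows]

    def input_samples(self) -> list[SampleRow]:
        return [r for r in self.rows if r.role == INPUT]

    def cdna_samples(self, cell_line: str | None = None, run: str | None = None):
        out = [r for r in self.rows if r.role == CDNA]
        if cell_line is not None:
            out = [r for r in out if r.cell_line == cell_line]
        if run is not None:
            out = [r for r in out if r.run == run]
        return out

    @property
    def cell_lines(self) -> list[str]:
        seen = []
        for r in self.cdna_samples():
            if r.cell_line not in seen:
                seen.append(r.cell_line)
        return seen


@dataclass(frozen=True)
class SequencedRead:
    read_id: str
    bases: str
    qualities: str = ""

    def __post_init__(self):
        if self.qualities and len(self.qualities) != len(self.bases):
            raise ValueError(f"read {self.read_id}: |qualities| != |bases|")


@dataclass
class DemuxResult:
    """Per-sample canonicalized, barcode-trimmed reads plus the rejects."""

    assigned: dict[str, list[SequencedRead]]
    unassigned: list[SequencedRead]

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.assigned.values())

    @property
    def n_total(self) -> int:
        return self.n_assigned + len(self.unassigned)


def demultiplex(reads: Iterable[SequencedRead], sheet: SampleSheet) -> DemuxResult:
    """Split reads by perfect dual barcodes; trim and canonicalize.

    A read is assigned to sample *s* iff it starts with ``s.fwd`` and
    ends with ``revcomp(s.rev)`` — testing the read as given first, then
    its reverse complement. Barcode-pair uniqueness makes the assignment
    unambiguous. Everything else lands in ``unassigned``.
    """
    lookup = {
        (row.barcode.fwd, revcomp(row.barcode.rev)): row.sample_id for row in sheet
    }
    result = DemuxResult(assigned={row.sample_id: [] for row in sheet}, unassigned=[])
    for read in reads:
        assigned = False
        for bases, quals in (
            (read.bases, read.qualities),
            (revcomp(read.bases), read.qualities[::-1]),
        ):
            if len(bases) < 2 * BARCODE_LEN:
                continue
            sample = lookup.get((bases[:BARCODE_LEN], bases[-BARCODE_LEN:]))
            if sample is not None:
                result.assigned[sample].append(
                    SequencedRead(
                        read.read_id,
                        bases[BARCODE_LEN:-BARCODE_LEN],
                        quals[BARCODE_LEN:-BARCODE_LEN] if quals else "",
                    )
                )
                assigned = True
                break
        if not assigned:
            result.unassigned.append(read)
    return result


class FragmentAssigner:
    """Assign trimmed reads to library fragments.

    Fast path: exact match of the read (or the read with universal arms
    stripped) against fragment bodies and bare windows. Slow path:
    global (Needleman-Wunsch) edit distance against every fragment body;
    accept the best fragment iff its distance is at most ``max_edits``
    and beats the runner-up by at least ``min_margin`` edits.
    """

    def __init__(self, library: ReferenceLibrary, max_edits: int = 2, min_margin: int = 1):
        if len(library) == 0:
            raise UnknownFragmentId("reference library is empty")
        self.max_edits = max_edits
        self.min_margin = min_margin
        self._ids = library.fragment_ids
        self._bodies = [f.fragment for f in library]
        self._exact: dict[str, str] = {}
        for frag in library:
            self._exact[frag.fragment] = frag.fragment_id
            self._exact.setdefault(frag.window, frag.fragment_id)

    def assign(self, bases: str) -> tuple[str | None, str | None]:
        """Returns (fragment_id, None) or (None, reason)."""
        hit = self._exact.get(bases)
        if hit is not None:
            return hit, None
        # tolerate exact bodies with intact arms inside slightly longer reads
        if bases.startswith(ARM5) and bases.endswith(ARM3):
            hit = self._exact.get(bases[len(ARM5) : -len(ARM3)])
            if hit is not None:
                return hit, None
        k = self.max_edits + self.min_margin  # distances beyond best+margin are moot
        best_d = second_d = k + 1
        best_i = -1
        for i, body in enumerate(self._bodies):
            d = edlib.align(bases, body, mode="NW", k=k)["editDistance"]
            if d == -1:
                continue
            if d < best_d:
                second_d, best_d, best_i = best_d, d, i
            elif d < second_d:
                second_d = d
        if best_i == -1 or best_d > self.max_edits:
            return None, UNASSIGNED_TOO_MANY_EDITS
        if second_d - best_d < self.min_margin:
            return None, UNASSIGNED_AMBIGUOUS
        return self._ids[best_i], None


def assign_read(
    read: SequencedRead,
    library: ReferenceLibrary,
    max_edits: int = 2,
    min_margin: int = 1,
) -> tuple[str | None, str | None]:
    """One-shot wrapper around :class:`FragmentAssigner`."""
    return FragmentAssigner(library, max_edits, min_margin).assign(read.bases)


def count_matrix(
    assignments: dict[str, Iterable[str]],
    library: ReferenceLibrary,
    sheet: SampleSheet,
) -> pd.DataFrame:
    """Tabulate per-sample fragment assignments into fragments x samples.

    Rows cover ALL library fragments (zero-filled); columns follow sheet
    order. ``assignments[sample_id]`` iterates assigned fragment ids.
    """
    ids = library.fragment_ids
    index = {fid: i for i, fid in enumerate(ids)}
    mat = np.zeros((len(ids), len(sheet)), dtype=np.int64)
    for j, row in enumerate(sheet):
        for fid in assignments.get(row.sample_id, ()):
            i = index.get(fid)
            if i is None:
                raise UnknownFragmentId(f"fragment id {fid!r} not in library")
            mat[i, j] += 1
    return pd.DataFrame(mat, index=ids, columns=sheet.sample_ids)


def process_reads(
    reads: Iterable[SequencedRead],
    library: ReferenceLibrary,
    sheet: SampleSheet,
    max_edits: int = 2,
    min_margin: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stream reads through demux + assignment into a count matrix.

    Returns ``(counts, summary)`` where summary has per-sample assigned
    and unassigned-by-reason read totals. Reads are processed one at a
    time; only the matrix and tallies are held in memory.
    """
    lookup = {
        (row.barcode.fwd, revcomp(row.barcode.rev)): row.sample_id for row in sheet
    }
    assigner = FragmentAssigner(library, max_edits, min_margin)
    ids = library.fragment_ids
    index = {fid: i for i, fid in enumerate(ids)}
    col = {sid: j for j, sid in enumerate(sheet.sample_ids)}
    mat = np.zeros((len(ids), len(sheet)), dtype=np.int64)
    tallies = {
        sid: {"assigned": 0, UNASSIGNED_TOO_MANY_EDITS: 0, UNASSIGNED_AMBIGUOUS: 0}
        for sid in sheet.sample_ids
    }
    n_no_barcode = 0
    for read in reads:
        sample = None
        for bases in (read.bases, revcomp(read.bases)):
            if len(bases) < 2 * BARCODE_LEN:
                continue
            sample = lookup.get((bases[:BARCODE_LEN], bases[-BARCODE_LEN:]))
            if sample is not None:
                body = bases[BARCODE_LEN:-BARCODE_LEN]
                break
        if sample is None:
            n_no_barcode += 1
            continue
        fid, reason = assigner.assign(body)
        if fid is None:
            tallies[sample][reason] += 1
        else:
            mat[index[fid], col[sample]] += 1
            tallies[sample]["assigned"] += 1
    counts = pd.DataFrame(mat, index=ids, columns=sheet.sample_ids)
    summary = pd.DataFrame(
        [
            {
                "sample_id": sid,
                "assigned": t["assigned"],
                "too_many_edits": t[UNASSIGNED_TOO_MANY_EDITS],
                "ambiguous": t[UNASSIGNED_AMBIGUOUS],
            }
            for sid, t in tallies.items()
        ]
    )
    summary.attrs["no_barcode_match"] = n_no_barcode
    return counts, summary


@dataclass
class LibraryQCReport:
    per_fragment: pd.DataFrame  # fragment_id, input_reads, detected
    representation_fraction: float


def representation_report(
    counts: pd.DataFrame, sheet: SampleSheet, detection_min: int = 1
) -> LibraryQCReport:
    """Fraction of library fragments detected in the input-plasmid pool."""
    input_ids = [r.sample_id for r in sheet.input_samples()]
    if not input_ids:
        raise NoInputSamples("no input-role samples in sheet")
    totals = counts[input_ids].sum(axis=1)
    detected = totals >= detection_min
    per_fragment = pd.DataFrame(
        {
            "fragment_id": counts.index,
            "input_reads": totals.to_numpy(),
            "detected": detected.to_numpy(),
        }
    )
    return LibraryQCReport(
        per_fragment=per_fragment,
        representation_fraction=float(detected.mean()),
    )


def replicate_r2(
    counts: pd.DataFrame,
    sheet: SampleSheet,
    cell_line: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Pairwise replicate R^2 on input-normalized log2 counts.

    Per fragment the normalized value is
    ``log2((count + c) / (mean input count + c))`` with pseudocount
    ``c`` admitting zeros; R^2 is the squared Pearson correlation of
    those per-fragment vectors for each replicate pair. QC only — this
    transformation never feeds the statistical testing.
    """
    cdna = sheet.cdna_samples(cell_line=cell_line)
    if len(cdna) < 2:
        raise TooFewReplicates(
            f"cell line {cell_line!r} has {len(cdna)} cdna replicate(s); need >= 2"
        )
    input_ids = [r.sample_id for r in sheet.input_samples()]
    if not input_ids:
        raise NoInputSamples("replicate R^2 needs input samples for normalization")
    ref_mean = counts[input_ids].mean(axis=1).to_numpy()
    norm = {
        r.sample_id: np.log2(
            (counts[r.sample_id].to_numpy() + pseudocount) / (ref_mean + pseudocount)
        )
        for r in cdna
    }
    names = [r.sample_id for r in cdna]
    table = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            r = np.corrcoef(norm[a], norm[b])[0, 1]
            table.loc[a, b] = table.loc[b, a] = r * r
    return table
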